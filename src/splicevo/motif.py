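"""PROSITE-syntax pattern compilation and scanning, plus consensus blocks.

PROSITE patterns describe protein motifs position by position: a fixed
residue (``H``), any residue (``x``), an allowed set (``[RK]``), a
forbidden set (``{P}``), each optionally repeated ``(n)`` or ``(m,n)``
times, with ``<``/``>`` anchoring the pattern to the termini. The classic
phosphofructokinase signature PS00433,
``[RK]-x(4)-[GAS]-H-x-[QL]-[QR]-[GS]-[GF]-x(5)-[DE]-[RL]``, is a fixed
19-residue pattern of this grammar.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from splicevo.errors import AlignmentError, PatternSyntaxError
from splicevo.seqio import PROTEIN_ALPHABET

_ELEMENT_RE = re.compile(
    r"""^(?:
        (?P<fixed>[A-Za-z])
      | \[(?P<allowed>[A-Za-z]+)\]
      | \{(?P<forbidden>[A-Za-z]+)\}
    )
    (?:\((?P<m>\d+)(?:,(?P<n>\d+))?\))?$""",
    re.VERBOSE,
)


@dataclass(frozen=True)
class PatternElement:
    """One position constraint with a repeat range [min_repeat, max_repeat]."""

    kind: str  # "fixed" | "any" | "allowed" | "forbidden"
    residues: frozenset
    min_repeat: int
    max_repeat: int

    def matches(self, residue: str) -> bool:
        if self.kind == "any":
            return True
        if self.kind == "forbidden":
            return residue not in self.residues
        return residue in self.residues


@dataclass(frozen=True)
class CompiledPattern:
    """A parsed PROSITE pattern as an ordered list of position constraints."""

    elements: tuple[PatternElement, ...]
    anchored_start: bool = False
    anchored_end: bool = False

    @property
    def fixed_length(self) -> int | None:
        """Total length when every repeat is single-valued, else ``None``."""
        if any(e.min_repeat != e.max_repeat for e in self.elements):
            return None
        return sum(e.min_repeat for e in self.elements)

    @property
    def min_length(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(e.max_repeat for e in self.elements)


@dataclass(frozen=True)
class MotifMatch:
    """One occurrence of a pattern in a peptide (0-based ``start``)."""

    start: int
    length: int
    matched_subsequence: str


def compile_prosite(pattern: str) -> CompiledPattern:
    """Compile a PROSITE pattern string into a :class:`CompiledPattern`.

    Elements are separated by ``-``; a trailing ``.`` (as printed in the
    PROSITE database) is tolerated. Malformed brackets or repeat counts
    raise :class:`PatternSyntaxError` with the element's position in the
    pattern string.
    """
    text = pattern.strip()
    if text.endswith("."):
        text = text[:-1]
    anchored_start = text.startswith("<")
    if anchored_start:
        text = text[1:]
    anchored_end = text.endswith(">")
    if anchored_end:
        text = text[:-1]
    if not text:
        raise PatternSyntaxError("empty pattern")

    elements: list[PatternElement] = []
    pos = 0
    for token in text.split("-"):
        if not token:
            raise PatternSyntaxError("empty element", pos)
        m = _ELEMENT_RE.match(token)
        if m is None:
            raise PatternSyntaxError(f"malformed element {token!r}", pos)
        lo = int(m.group("m")) if m.group("m") else 1
        hi = int(m.group("n")) if m.group("n") else lo
        if lo < 1 or hi < lo:
            raise PatternSyntaxError(f"bad repeat count in {token!r}", pos)
        if m.group("fixed"):
            residue = m.group("fixed").upper()
            if residue == "X":
                elements.append(PatternElement("any", frozenset(), lo, hi))
            else:
                if residue not in PROTEIN_ALPHABET:
                    raise PatternSyntaxError(f"unknown residue {residue!r}", pos)
                elements.append(PatternElement("fixed", frozenset(residue), lo, hi))
        elif m.group("allowed"):
            elements.append(
                PatternElement("allowed", frozenset(m.group("allowed").upper()), lo, hi)
            )
        else:
            elements.append(
                PatternElement("forbidden", frozenset(m.group("forbidden").upper()), lo, hi)
            )
        pos += len(token) + 1
    return CompiledPattern(tuple(elements), anchored_start, anchored_end)


def scan(pattern: CompiledPattern, peptide: str, overlapping: bool = True) -> list[MotifMatch]:
    """All matches of ``pattern`` in ``peptide``, left to right.

    Variable repeats are matched greedily with backtracking, so a match is
    reported at a start position iff some repeat assignment succeeds
    there (the witness reported is the greedy/longest one). With
    ``overlapping=False`` only leftmost non-overlapping matches are kept.
    ``X`` in the peptide matches only ``x`` elements or sets containing X.
    """
    pep = peptide.upper()
    n = len(pep)
    starts = range(n + 1) if not pattern.anchored_start else range(1)
    matches: list[MotifMatch] = []
    next_free = 0
    for start in starts:
        if not overlapping and start < next_free:
            continue
        end = _match_here(pattern, pep, start)
        if end is None:
            continue
        matches.append(MotifMatch(start, end - start, pep[start:end]))
        next_free = end
    return matches


def _match_here(pattern: CompiledPattern, pep: str, start: int) -> int | None:
    """End position of a match beginning exactly at ``start``, or None."""
    n = len(pep)

    def backtrack(elem_idx: int, pos: int) -> int | None:
        if elem_idx == len(pattern.elements):
            if pattern.anchored_end and pos != n:
                return None
            return pos
        elem = pattern.elements[elem_idx]
        # count how far this element can extend greedily
        max_take = 0
        while (
            max_take < elem.max_repeat
            and pos + max_take < n
            and elem.matches(pep[pos + max_take])
        ):
            max_take += 1
        for take in range(max_take, elem.min_repeat - 1, -1):
            result = backtrack(elem_idx + 1, pos + take)
            if result is not None:
                return result
        return None

    return backtrack(0, start)


def consensus_blocks(
    msa: list, min_block: int = 5
) -> list[tuple[int, str]]:
    """Maximal runs of fully conserved, gap-free alignment columns.

    ``msa`` rows may be strings or objects with a ``sequence`` attribute;
    all rows must be equally long (gap character ``-``). Returns
    ``(column_start, consensus_string)`` for every run of at least
    ``min_block`` columns where all rows share one residue.
    """
    rows = [getattr(r, "sequence", r).upper() for r in msa]
    if not rows:
        raise AlignmentError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise AlignmentError("ragged alignment: rows differ in length")

    blocks: list[tuple[int, str]] = []
    run_start = None
    for col in range(width + 1):
        conserved = False
        if col < width:
            residue = rows[0][col]
            conserved = residue != "-" and all(r[col] == residue for r in rows)
        if conserved:
            if run_start is None:
                run_start = col
        else:
            if run_start is not None and col - run_start >= min_block:
                blocks.append((run_start, rows[0][run_start:col]))
            run_start = None
    return blocks
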