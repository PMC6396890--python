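"""Exon-intron architecture inference and splice-junction bookkeeping.

The central operation maps a coding (mRNA/CDS) sequence onto its genomic
sequence as a chain of gap-free exons separated by introns, validates the
canonical GT..AG dinucleotides, and computes intron phases (the position
of each intron relative to the reading frame: phase 0 between codons,
phase 1 after the first codon base, phase 2 after the second).

Junctions can be rendered in, and parsed back from, the compact notation
used in comparative gene-structure tables, e.g. ``GAA,G/gtaaataaaa`` for a
phase-1 donor: uppercase exon context, a comma at the codon boundary, and
lowercase intron flank.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from splicevo.errors import (
    DegenerateIntronError,
    MappingError,
    NotationError,
    RangeError,
    SplicevoError,
)
from splicevo.seqio import SeqRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: sentinel for an unknown intron phase (partial model, frame unknown)
UNKNOWN = "unknown"
#: sentinel for a missing donor/acceptor side in junction notation
ABSENT = None


@dataclass
class GeneModel:
    """Ordered exon segments of one gene on a genomic sequence.

    Exons are 0-based half-open intervals, strictly increasing and
    non-overlapping; the gaps between consecutive exons are the introns.
    ``coding_offset`` is the position within the concatenated exon
    sequence where the reading frame begins (``None`` if the frame is
    unknown for a partial model).
    """

    seq_id: str
    gene_id: str
    exons: list[tuple[int, int]]
    coding_offset: int | None = 0
    partial_5prime: bool = False
    partial_3prime: bool = False
    strand: str = "+"

    def __post_init__(self):
        if self.strand != "+":
            raise SplicevoError(
                "only forward-strand gene models are supported; got strand "
                f"{self.strand!r}"
            )
        if not self.exons:
            raise SplicevoError(f"gene {self.gene_id!r}: no exons")
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        prev_end = -1
        for start, end in self.exons:
            if start < 0 or end <= start:
                raise RangeError(f"gene {self.gene_id!r}: empty or negative exon ({start},{end})")
            if start <= prev_end:
                raise RangeError(f"gene {self.gene_id!r}: exons overlap or are unsorted")
            prev_end = end
        if self.coding_offset is not None and self.coding_offset < 0:
            raise SplicevoError("coding_offset must be >= 0")
        total = self.total_exon_length
        if total < 3 and not (self.partial_5prime or self.partial_3prime):
            raise SplicevoError(
                f"gene {self.gene_id!r}: complete model must span at least one codon"
            )

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def total_exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exon_sequences(self, genomic: SeqRecord) -> list[str]:
        if self.exons[-1][1] > len(genomic):
            raise RangeError(
                f"gene {self.gene_id!r}: exon end {self.exons[-1][1]} exceeds "
                f"sequence {genomic.id!r} of length {len(genomic)}"
            )
        return [genomic.sequence[s:e] for s, e in self.exons]

    def intron_sequences(self, genomic: SeqRecord) -> list[str]:
        return [genomic.sequence[s:e] for s, e in self.introns]

    def spliced_sequence(self, genomic: SeqRecord) -> str:
        return "".join(self.exon_sequences(genomic))


@dataclass(frozen=True)
class SpliceJunction:
    """One intron's donor/acceptor dinucleotides, length and phase."""

    intron_index: int
    intron_length: int
    donor_dinucleotide: str | None
    acceptor_dinucleotide: str | None
    phase: int | str
    canonical: bool


# ---------------------------------------------------------------------------
# Spliced CDS -> genomic mapping
# ---------------------------------------------------------------------------

_INF = (float("inf"),)


def map_cds_to_genomic(
    cds: SeqRecord,
    genomic: SeqRecord,
    min_exon: int = 12,
    max_mismatch_rate: float = 0.02,
    min_intron: int = 20,
    gene_id: str | None = None,
) -> GeneModel:
    """Infer the exon chain that spells out ``cds`` on ``genomic``.

    Exons are gap-free (substitutions allowed up to ``max_mismatch_rate``
    of the covered CDS, no indels within exons); internal introns must be
    at least ``min_intron`` nt. The chain is found by dynamic programming
    over candidate diagonals seeded by exact matches of length
    ``min_exon``, optimising lexicographically: (1) maximal CDS coverage,
    (2) fewest exonic mismatches, (3) most canonical GT..AG introns,
    (4) leftmost donor positions.

    Raises :class:`MappingError` if no chain covers at least 90% of the
    CDS within the mismatch budget. An uncovered CDS prefix/suffix sets
    the corresponding partial flag; ``coding_offset`` is adjusted so the
    original CDS frame is preserved on the mapped model.
    """
    C, G = cds.sequence, genomic.sequence
    L, N = len(C), len(G)
    if L < min_exon:
        raise MappingError(f"CDS shorter than min_exon ({L} < {min_exon})")
    if N < L:
        raise MappingError("genomic sequence shorter than CDS")

    diags = _seed_diagonals(C, G, min_exon)
    if not diags:
        raise MappingError(f"no exact seed match of length {min_exon} between CDS and genomic")

    # per-diagonal cumulative mismatch counts: mism[d][c] over cds prefix c
    c_arr = np.frombuffer(C.encode(), dtype=np.uint8)
    g_arr = np.frombuffer(G.encode(), dtype=np.uint8)
    mism: dict[int, np.ndarray] = {}
    limit: dict[int, int] = {}
    for d in diags:
        span = min(L, N - d)
        neq = (c_arr[:span] != g_arr[d : d + span]).astype(np.int64)
        cum = np.zeros(span + 1, dtype=np.int64)
        np.cumsum(neq, out=cum[1:])
        mism[d] = cum
        limit[d] = span

    # Cost tuples (combined, -canonical, donor positions, mismatches) are
    # compared lexicographically; smaller is better on every component.
    # "combined" charges 1 per uncovered CDS base and `w` per exonic
    # mismatch, with w = ceil(1/max_mismatch_rate), so extending coverage
    # over a segment is only worthwhile below the allowed mismatch rate.
    # S[(c, d)]    best cost of a chain about to start an exon on diagonal d
    #              at CDS position c (plus a backpointer)
    # E[(c, d)]    best cost of a chain whose last exon, on diagonal d,
    #              ends exactly at CDS position c
    # entry_best[d] running min over eligible exon-entry points on d, with
    #              the mismatch-dependent components expressed relative to
    #              mism[d]
    w = int(np.ceil(1.0 / max_mismatch_rate)) if max_mismatch_rate > 0 else L + 1
    S: dict[tuple[int, int], tuple] = {}
    S_back: dict[tuple[int, int], tuple] = {}
    E: dict[tuple[int, int], tuple] = {}
    E_back: dict[tuple[int, int], tuple] = {}
    entry_best: dict[int, tuple] = {}
    entry_back: dict[int, int] = {}

    best_final: tuple | None = None
    best_final_state: tuple[int, int] | None = None

    for c in range(0, L + 1):
        # promote entries made at c - min_exon: exons must be >= min_exon long
        cp = c - min_exon
        if cp >= 0:
            for d in diags:
                key = (cp, d)
                if key in S and cp <= limit[d]:
                    cost = S[key]
                    m0 = int(mism[d][cp])
                    adj = (cost[0] - w * m0, cost[1], cost[2], cost[3] - m0)
                    if d not in entry_best or adj < entry_best[d]:
                        entry_best[d] = adj
                        entry_back[d] = cp
        # close exons ending at c
        for d in diags:
            if d in entry_best and c <= limit[d]:
                adj = entry_best[d]
                m1 = int(mism[d][c])
                cost = (adj[0] + w * m1, adj[1], adj[2], adj[3] + m1)
                E[(c, d)] = cost
                E_back[(c, d)] = entry_back[d]
                final = (cost[0] + (L - c), cost[1], cost[2], cost[3])
                if best_final is None or final < best_final:
                    best_final = final
                    best_final_state = (c, d)
        if c == L:
            break
        # open exons starting at c
        for d in diags:
            if c > limit[d]:
                continue
            # as the first exon of the chain (uncovered prefix of length c)
            best: tuple | None = (c, 0, (), 0)
            back: tuple = ("start",)
            # or following an intron from an exon ending at c on d_prev
            for d_prev in diags:
                if d - d_prev < min_intron:
                    continue
                prev = E.get((c, d_prev))
                if prev is None:
                    continue
                donor_pos = c + d_prev
                acc_end = c + d
                canonical = G[donor_pos : donor_pos + 2] == "GT" and G[acc_end - 2 : acc_end] == "AG"
                cand = (
                    prev[0],
                    prev[1] - (1 if canonical else 0),
                    prev[2] + (donor_pos,),
                    prev[3],
                )
                if cand < best:
                    best = cand
                    back = ("intron", d_prev)
            S[(c, d)] = best
            S_back[(c, d)] = back

    if best_final is None or best_final_state is None:
        raise MappingError("no exon chain covers at least 90% of the CDS")
    mismatches = best_final[3]
    covered = L - (best_final[0] - w * mismatches)
    if covered < 0.9 * L:
        raise MappingError(
            f"best exon chain covers only {covered}/{L} CDS nucleotides (< 90%)"
        )
    if mismatches > max_mismatch_rate * covered:
        raise MappingError(
            f"best exon chain needs {mismatches} substitutions over {covered} "
            f"covered nucleotides (> {max_mismatch_rate:.2%} budget)"
        )

    # trace back the winning chain
    segments: list[tuple[int, int, int]] = []  # (c_start, c_end, diagonal)
    c, d = best_final_state
    while True:
        c_start = E_back[(c, d)]
        segments.append((c_start, c, d))
        kind, *rest = S_back[(c_start, d)]
        if kind == "start":
            break
        d = rest[0]
        c = c_start
    segments.reverse()

    a = segments[0][0]
    b = segments[-1][1]
    exons = [(cs + d, ce + d) for cs, ce, d in segments]
    return GeneModel(
        seq_id=genomic.id,
        gene_id=gene_id or cds.id,
        exons=exons,
        coding_offset=(-a) % 3,
        partial_5prime=a > 0,
        partial_3prime=b < L,
    )


def _seed_diagonals(C: str, G: str, k: int) -> list[int]:
    """Diagonals (genomic_pos - cds_pos) carrying an exact k-mer match."""
    index: dict[str, list[int]] = defaultdict(list)
    for g in range(len(G) - k + 1):
        index[G[g : g + k]].append(g)
    diags: set[int] = set()
    for c in range(len(C) - k + 1):
        for g in index.get(C[c : c + k], ()):
            if g - c >= 0:
                diags.add(g - c)
    return sorted(diags)


# ---------------------------------------------------------------------------
# Junctions and the comma notation
# ---------------------------------------------------------------------------

def junctions(
    model: GeneModel, genomic: SeqRecord, numbering_offset: int = 1
) -> list[SpliceJunction]:
    """One :class:`SpliceJunction` per intron of ``model``.

    The donor is the first two intron nucleotides, the acceptor the last
    two; an intron is canonical iff donor == GT and acceptor == AG. The
    phase is the number of coding nucleotides upstream of the junction
    modulo 3, or :data:`UNKNOWN` when the model's frame is unknown.
    Intron numbering starts at ``numbering_offset`` so partial models can
    adopt a reference species' exon numbering scheme.
    """
    out = []
    G = genomic.sequence
    cum = 0
    for i, ((estart, eend), (istart, iend)) in enumerate(zip(model.exons, model.introns)):
        cum += eend - estart
        length = iend - istart
        if length < 4:
            raise DegenerateIntronError(
                f"gene {model.gene_id!r}: intron {i + numbering_offset} is only "
                f"{length} nt (< 4)"
            )
        donor = G[istart : istart + 2]
        acceptor = G[iend - 2 : iend]
        if model.coding_offset is None:
            phase: int | str = UNKNOWN
        else:
            phase = (cum - model.coding_offset) % 3
        out.append(
            SpliceJunction(
                intron_index=i + numbering_offset,
                intron_length=length,
                donor_dinucleotide=donor,
                acceptor_dinucleotide=acceptor,
                phase=phase,
                canonical=(donor == "GT" and acceptor == "AG"),
            )
        )
    return out


def format_junction(
    model: GeneModel,
    genomic: SeqRecord,
    intron_index: int,
    flank: int = 10,
) -> tuple[str, str]:
    """Render one junction in comma notation.

    The donor string shows the exonic context upstream of the intron
    (uppercase, with a comma at the last codon boundary when the phase is
    non-zero), a ``/``, then the first ``flank`` intron nucleotides in
    lowercase. The acceptor string mirrors it: the last ``flank`` intron
    nucleotides, ``/``, then the downstream exonic context with a comma
    after the nucleotides that complete the split codon.
    """
    n_introns = len(model.introns)
    if not 1 <= intron_index <= n_introns:
        raise IndexError(f"intron_index {intron_index} out of range 1..{n_introns}")
    i = intron_index - 1
    juncs = junctions(model, genomic)
    phase = juncs[i].phase
    if phase == UNKNOWN:
        raise NotationError("cannot format a junction of unknown phase")
    istart, iend = model.introns[i]
    intron_seq = genomic.sequence[istart:iend].lower()

    spliced = model.spliced_sequence(genomic)
    upstream_len = sum(e - s for s, e in model.exons[: i + 1])
    up = spliced[:upstream_len]
    down = spliced[upstream_len:]

    want_up = 3 + phase
    ex_up = up[-want_up:] if len(up) >= want_up else up
    if phase > 0 and len(ex_up) > phase:
        ex_up = ex_up[:-phase] + "," + ex_up[-phase:]
    donor_string = f"{ex_up}/{intron_seq[:flank]}"

    if phase == 0:
        ex_down = down[:3]
    else:
        completing = 3 - phase
        ex_down = down[:completing] + "," + down[completing : completing + 3]
    acceptor_string = f"{intron_seq[-flank:] if flank else ''}/{ex_down}"
    return donor_string, acceptor_string


def parse_junction_notation(
    donor_string: str, acceptor_string: str
) -> tuple[int, str | None, str | None]:
    """Invert :func:`format_junction`: recover (phase, donor, acceptor).

    The donor side's comma placement is authoritative for the phase; the
    acceptor side is checked for consistency. A side given as the literal
    ``NA`` yields :data:`ABSENT` for its dinucleotide. Case encodes exon
    (upper) vs intron (lower).
    """
    donor_phase = acceptor_phase = None
    donor_dinuc = acceptor_dinuc = ABSENT

    if donor_string.strip().upper() != "NA":
        exon_part, intron_part = _split_junction_side(donor_string, "donor")
        _check_case(exon_part, intron_part, "donor")
        donor_phase = len(exon_part.split(",", 1)[1]) if "," in exon_part else 0
        donor_dinuc = intron_part[:2].upper()
    if acceptor_string.strip().upper() != "NA":
        intron_part, exon_part = _split_junction_side(acceptor_string, "acceptor")
        _check_case(exon_part, intron_part, "acceptor")
        if "," in exon_part:
            before = exon_part.split(",", 1)[0]
            if not 1 <= len(before) <= 2:
                raise NotationError(
                    f"acceptor {acceptor_string!r}: {len(before)} nucleotides before "
                    "the comma (expected 1 or 2)"
                )
            acceptor_phase = 3 - len(before)
        else:
            acceptor_phase = 0
        acceptor_dinuc = intron_part[-2:].upper()

    if donor_phase is None and acceptor_phase is None:
        raise NotationError("both junction sides are NA")
    if donor_phase is not None and acceptor_phase is not None and donor_phase != acceptor_phase:
        raise NotationError(
            f"donor encodes phase {donor_phase} but acceptor encodes phase {acceptor_phase}"
        )
    phase = donor_phase if donor_phase is not None else acceptor_phase
    if phase not in (0, 1, 2):
        raise NotationError(f"implausible phase {phase} from comma placement")
    return phase, donor_dinuc, acceptor_dinuc


def _split_junction_side(s: str, side: str) -> tuple[str, str]:
    parts = s.strip().split("/")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise NotationError(f"{side} string {s!r} must contain exactly one '/'")
    return parts[0], parts[1]


def _check_case(exon_part: str, intron_part: str, side: str) -> None:
    if not exon_part.replace(",", "").isupper():
        raise NotationError(f"{side}: exon side {exon_part!r} must be uppercase")
    if not intron_part.islower():
        raise NotationError(f"{side}: intron side {intron_part!r} must be lowercase")


# ---------------------------------------------------------------------------
# Summary statistics and table export
# ---------------------------------------------------------------------------

def exon_region_stats(
    model: GeneModel, genomic: SeqRecord | None = None
) -> tuple[int, int, int, int]:
    """(total exon nt, n exons, n introns, encoded residues).

    Residues are ``floor((total_exon_nt - coding_offset) / 3)``; when the
    3' end is complete, ``genomic`` is supplied and the final codon is a
    stop (TAA/TAG/TGA), the stop is excluded from the residue count.
    """
    total = model.total_exon_length
    offset = model.coding_offset or 0
    residues = max(0, (total - offset)) // 3
    if residues and genomic is not None and not model.partial_3prime:
        coding = model.spliced_sequence(genomic)[offset:]
        last_codon = coding[3 * (residues - 1) : 3 * residues]
        if last_codon in STOP_CODONS:
            residues -= 1
    return total, len(model.exons), len(model.introns), residues


def junction_table(
    model: GeneModel,
    genomic: SeqRecord,
    gene_name: str | None = None,
    numbering_offset: int = 1,
    flank: int = 10,
):
    """Junctions of one gene as a tidy table (comparative-table layout:
    gene, intron number, intron length, 5' and 3' splice-site notation,
    intron phase)."""
    import pandas as pd

    rows = []
    for j in junctions(model, genomic, numbering_offset=numbering_offset):
        local = j.intron_index - numbering_offset + 1
        if j.phase == UNKNOWN:
            donor_s = acceptor_s = "NA"
            phase_s = "NA"
        else:
            donor_s, acceptor_s = format_junction(model, genomic, local, flank=flank)
            phase_s = str(j.phase)
        rows.append(
            {
                "Gene": gene_name or model.gene_id,
                "Intron number": j.intron_index,
                "Intron length": j.intron_length,
                "5' splice site (exon/intron)": donor_s,
                "3' splice site (intron/exon)": acceptor_s,
                "Intron phase": phase_s,
            }
        )
    return pd.DataFrame(rows)
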