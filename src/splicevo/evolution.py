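"""Pairwise substitution spectra and evolutionary distances.

Sites are compared under pairwise deletion: an alignment column is used
for a given pair only when neither row carries a gap or ambiguity at it.
Differing columns split into transitions (A<->G, C<->T) and transversions,
optionally stratified by codon position.

Distances:

* p-distance — the raw proportion of differing comparable sites.
* Tamura-Nei (TN93) — a multiple-hit correction that allows unequal base
  frequencies and distinct A<->G and C<->T transition rates. With the
  observed proportions P1 (A<->G), P2 (C<->T) and Q (transversions), and
  base frequencies estimated from the pooled pair (purines
  piR = piA + piG, pyrimidines piY = piC + piT),

      d = -(2 piA piG / piR) ln(1 - piR P1 / (2 piA piG) - Q / (2 piR))
          -(2 piC piT / piY) ln(1 - piY P2 / (2 piC piT) - Q / (2 piY))
          -2 (piR piY - piA piG piY/piR - piC piT piR/piY)
             ln(1 - Q / (2 piR piY))

  Any non-positive logarithm argument marks the pair saturated (+inf).
* Poisson correction — amino-acid distance -ln(1 - p).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from splicevo.errors import AlignmentError, UndefinedDistanceError

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_NUC_OK = frozenset("ACGT")


class SaturationWarning(UserWarning):
    """A corrected distance is undefined (log of a non-positive number)."""


@dataclass(frozen=True)
class SubstitutionTable:
    """Transition/transversion counts for one pair, by codon position.

    ``counts[p][0]`` / ``counts[p][1]`` are transition / transversion
    counts at codon position p+1; ``sites_compared`` is the number of
    columns surviving pairwise deletion.
    """

    pair: tuple[str, str]
    counts: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    sites_compared: int

    @property
    def transitions(self) -> int:
        return sum(row[0] for row in self.counts)

    @property
    def transversions(self) -> int:
        return sum(row[1] for row in self.counts)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances over labelled taxa."""

    taxa: list[str]
    d: np.ndarray
    model_tag: str

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")

    def __getitem__(self, pair):
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.d[i, j])

    @property
    def has_saturated(self) -> bool:
        return bool(np.isinf(self.d).any())

    def to_phylip(self) -> str:
        lines = [f" {len(self.taxa)}"]
        for label, row in zip(self.taxa, self.d):
            cells = " ".join(f"{x:.6f}" for x in row)
            lines.append(f"{label:<10s} {cells}")
        return "\n".join(lines) + "\n"


def _as_seq(row) -> str:
    return getattr(row, "sequence", row).upper()


def _comparable_mask(a: str, b: str, alphabet=_NUC_OK) -> list[int]:
    if len(a) != len(b):
        raise AlignmentError(f"aligned rows differ in length ({len(a)} vs {len(b)})")
    return [i for i in range(len(a)) if a[i] in alphabet and b[i] in alphabet]


def substitution_spectrum(seq_a, seq_b, frame_offset: int = 0, pair=("a", "b")) -> SubstitutionTable:
    """Count transitions/transversions by codon position for one pair.

    Columns with a gap or N in either row are excluded (pairwise
    deletion). Codon position of column i is
    ``((i - frame_offset) mod 3) + 1``.
    """
    a, b = _as_seq(seq_a), _as_seq(seq_b)
    cols = _comparable_mask(a, b)
    counts = [[0, 0], [0, 0], [0, 0]]
    for i in cols:
        if a[i] == b[i]:
            continue
        pos = (i - frame_offset) % 3
        is_transition = {a[i], b[i]} <= PURINES or {a[i], b[i]} <= PYRIMIDINES
        counts[pos][0 if is_transition else 1] += 1
    return SubstitutionTable(
        pair=(getattr(seq_a, "id", pair[0]), getattr(seq_b, "id", pair[1])),
        counts=tuple(tuple(row) for row in counts),
        sites_compared=len(cols),
    )


def p_distance(seq_a, seq_b, alphabet=_NUC_OK) -> float:
    """Proportion of differing sites among comparable sites."""
    a, b = _as_seq(seq_a), _as_seq(seq_b)
    cols = _comparable_mask(a, b, alphabet)
    if not cols:
        raise UndefinedDistanceError("no comparable columns between the two rows")
    diffs = sum(1 for i in cols if a[i] != b[i])
    return diffs / len(cols)


def tn93_distance(seq_a, seq_b) -> float:
    """Tamura-Nei (1993) corrected nucleotide distance.

    Base frequencies are estimated from the pooled pair of sequences
    (comparable columns only). Returns ``inf`` (with a
    :class:`SaturationWarning`) when the correction is undefined.
    """
    a, b = _as_seq(seq_a), _as_seq(seq_b)
    cols = _comparable_mask(a, b)
    n = len(cols)
    if n == 0:
        raise UndefinedDistanceError("no comparable columns between the two rows")

    freq = {base: 0 for base in "ACGT"}
    p1_count = p2_count = q_count = 0
    for i in cols:
        freq[a[i]] += 1
        freq[b[i]] += 1
        if a[i] == b[i]:
            continue
        pair = {a[i], b[i]}
        if pair <= PURINES:
            p1_count += 1
        elif pair <= PYRIMIDINES:
            p2_count += 1
        else:
            q_count += 1
    if p1_count + p2_count + q_count == 0:
        return 0.0

    total = 2 * n
    pi = {base: freq[base] / total for base in "ACGT"}
    piA, piC, piG, piT = pi["A"], pi["C"], pi["G"], pi["T"]
    piR, piY = piA + piG, piC + piT
    P1, P2, Q = p1_count / n, p2_count / n, q_count / n

    try:
        if piA * piG == 0 or piC * piT == 0 or piR * piY == 0:
            raise ValueError
        w1 = 2 * piA * piG / piR
        w2 = 2 * piC * piT / piY
        w3 = 2 * (piR * piY - piA * piG * piY / piR - piC * piT * piR / piY)
        arg1 = 1 - P1 / w1 - Q / (2 * piR)
        arg2 = 1 - P2 / w2 - Q / (2 * piY)
        arg3 = 1 - Q / (2 * piR * piY)
        if arg1 <= 0 or arg2 <= 0 or arg3 <= 0:
            raise ValueError
        d = -w1 * math.log(arg1) - w2 * math.log(arg2) - w3 * math.log(arg3)
    except ValueError:
        warnings.warn(
            "TN93 correction undefined for this pair (saturated); reporting inf",
            SaturationWarning,
            stacklevel=2,
        )
        return float("inf")
    return max(0.0, d)


def poisson_distance(pep_a, pep_b) -> float:
    """Poisson-corrected amino-acid distance ``-ln(1 - p)``.

    Columns with a gap, ``X`` or ``*`` in either row are excluded.
    """
    amino = frozenset("ACDEFGHIKLMNPQRSTVWY")
    p = p_distance(pep_a, pep_b, alphabet=amino)
    if p >= 1.0:
        warnings.warn(
            "Poisson correction undefined at p == 1; reporting inf",
            SaturationWarning,
            stacklevel=2,
        )
        return float("inf")
    return -math.log(1.0 - p)


_MODEL_FUNCS = {
    "p": p_distance,
    "tn93": tn93_distance,
    "poisson": poisson_distance,
}


def distance_matrix(alignment: list, model: str = "tn93") -> DistanceMatrix:
    """All pairwise distances of an alignment under one model.

    ``alignment`` rows may be strings or records with ``id``/``sequence``;
    at least 3 rows are required.
    """
    if model not in _MODEL_FUNCS:
        raise ValueError(f"unknown model {model!r} (choose from {sorted(_MODEL_FUNCS)})")
    if len(alignment) < 3:
        raise AlignmentError("need at least 3 rows for a distance matrix")
    labels = [getattr(row, "id", f"seq{i+1}") for i, row in enumerate(alignment)]
    func = _MODEL_FUNCS[model]
    n = len(alignment)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = func(alignment[i], alignment[j])
    return DistanceMatrix(taxa=labels, d=d, model_tag=model)
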