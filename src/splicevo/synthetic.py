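"""Synthetic gene models and TN93-evolved ortholog sets with planted truth.

Every pipeline stage is testable without downloading any accession: this
module generates multi-exon protein-coding genes with canonical gt..ag
introns of chosen lengths and phases, evolves coding sequence along a
known tree under a Tamura-Nei (TN93) substitution process, draws intron
lengths independently per taxon (the no-indel stand-in for intron
insertions/deletions), and can plant a lineage-specific exonization —
a copy of one taxon's exon inside an orthologous intron of another.

The ``apis7`` preset mimics a honey-bee-like study design: a pair of
dwarf-like taxa diverging first, one giant-like taxon, three medium-like
taxa and an outgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from splicevo.errors import ConfigError
from splicevo.gene_structure import GeneModel
from splicevo.phylo import PhyloTree, TreeNode
from splicevo.seqio import SeqRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class SimConfig:
    """Parameters of the synthetic-data generator.

    Defaults emulate the study conditions this pipeline targets: 7 exons
    (honey-bee PFK/PK-like partials have 6-7), exon lengths 60-200 nt,
    intron lengths 67-550 nt (the printed intron range), AT-rich base
    composition (~67% A+T, as in honey-bee genomic DNA), and transition
    rates four times the transversion rate so transitions dominate the
    observed substitutions.
    """

    seed: int = 0
    n_exons: int = 7
    exon_length_range: tuple[int, int] = (60, 200)
    intron_length_range: tuple[int, int] = (67, 550)
    planted_phases: list[int] | None = None
    base_frequencies: tuple[float, float, float, float] = (0.335, 0.165, 0.165, 0.335)
    kappa1: float = 4.0
    kappa2: float = 4.0
    tree: PhyloTree | None = None
    exonization: tuple[int, str, int] | None = None  # (donor exon, target taxon, target intron)
    flank: int = 30

    def __post_init__(self):
        if self.n_exons < 1:
            raise ConfigError("n_exons must be >= 1")
        for lo, hi in (self.exon_length_range, self.intron_length_range):
            if lo < 1 or hi < lo:
                raise ConfigError("length ranges must be positive with min <= max")
        if self.intron_length_range[0] < 24:
            raise ConfigError("minimum intron length must be >= 24")
        if abs(sum(self.base_frequencies) - 1.0) > 1e-9:
            raise ConfigError("base frequencies must sum to 1")
        if any(f <= 0 for f in self.base_frequencies):
            raise ConfigError("base frequencies must be positive")
        if self.kappa1 <= 0 or self.kappa2 <= 0:
            raise ConfigError("kappa rate multipliers must be positive")
        if self.planted_phases is not None:
            if len(self.planted_phases) != self.n_exons - 1:
                raise ConfigError(
                    f"planted_phases must have n_exons - 1 = {self.n_exons - 1} entries"
                )
            if any(p not in (0, 1, 2) for p in self.planted_phases):
                raise ConfigError("phases must be 0, 1 or 2")
        if self.tree is not None:
            for node in self.tree.root.walk():
                if node.length < 0:
                    raise ConfigError("branch lengths must be >= 0")


def _random_seq(rng: np.random.Generator, length: int, freqs) -> str:
    idx = rng.choice(4, size=length, p=list(freqs))
    return _BASES[idx].tobytes().decode()


def simulate_gene_model(cfg: SimConfig, gene_id: str = "sim") -> tuple[SeqRecord, GeneModel]:
    """Generate a genomic sequence and its ground-truth gene model.

    Exon lengths are drawn uniformly in ``exon_length_range`` and then
    nudged by 0-2 nt so the cumulative coding length at each junction
    realises the planted intron phases exactly (and the total is a
    multiple of 3). Every intron begins ``gt`` and ends ``ag``. Output is
    deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.exon_length_range
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(cfg.n_exons)]

    phases = cfg.planted_phases
    if phases is None and cfg.n_exons > 1:
        # no requested pattern: draw intron phases uniformly
        phases = [int(p) for p in rng.integers(0, 3, size=cfg.n_exons - 1)]
    cum = 0
    for i in range(cfg.n_exons):
        cum += lengths[i]
        if phases is not None and i < cfg.n_exons - 1:
            want = phases[i]
        else:  # last exon: complete the final codon
            want = 0
        bump = (want - cum) % 3
        lengths[i] += bump
        cum += bump

    ilo, ihi = cfg.intron_length_range
    intron_lengths = [
        int(rng.integers(ilo, ihi + 1)) for _ in range(cfg.n_exons - 1)
    ]

    parts = []
    exons = []
    pos = cfg.flank
    parts.append(_random_seq(rng, cfg.flank, cfg.base_frequencies))
    for i, elen in enumerate(lengths):
        exon_seq = _random_seq(rng, elen, cfg.base_frequencies)
        parts.append(exon_seq)
        exons.append((pos, pos + elen))
        pos += elen
        if i < cfg.n_exons - 1:
            ilen = intron_lengths[i]
            body = _random_seq(rng, ilen - 4, cfg.base_frequencies)
            parts.append("GT" + body + "AG")
            pos += ilen
    parts.append(_random_seq(rng, cfg.flank, cfg.base_frequencies))

    genomic = SeqRecord(f"{gene_id}_genomic", "".join(parts))
    truth = GeneModel(
        seq_id=genomic.id, gene_id=gene_id, exons=exons, coding_offset=0
    )
    return genomic, truth


# ---------------------------------------------------------------------------
# TN93 evolution along a tree
# ---------------------------------------------------------------------------

def tn93_rate_matrix(base_frequencies, kappa1: float, kappa2: float) -> np.ndarray:
    """TN93 instantaneous rate matrix (rows = from-base, order ACGT),
    scaled so the expected substitution rate is 1 per site per unit
    branch length. ``kappa1``/``kappa2`` are the A<->G and C<->T rate
    multipliers relative to transversions."""
    pi = np.asarray(base_frequencies, dtype=float)
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            pair = {i, j}
            if pair == {0, 2}:  # A<->G
                rate = kappa1
            elif pair == {1, 3}:  # C<->T
                rate = kappa2
            else:
                rate = 1.0
            q[i, j] = rate * pi[j]
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(pi * np.diag(q)).sum()
    return q / mu


def evolve_alignment(root_seq: SeqRecord, cfg: SimConfig) -> list[SeqRecord]:
    """Evolve ``root_seq`` along ``cfg.tree`` under TN93; one gap-free row
    per leaf, labelled by the leaf. Sites evolve independently; there is
    no indel process, so the rows are already aligned."""
    if cfg.tree is None:
        raise ConfigError("cfg.tree is required for evolve_alignment")
    rng = np.random.default_rng(cfg.seed)
    q = tn93_rate_matrix(cfg.base_frequencies, cfg.kappa1, cfg.kappa2)
    root_idx = np.array([_BASE_INDEX[b] for b in root_seq.sequence], dtype=np.int64)

    out: list[SeqRecord] = []

    def descend(node: TreeNode, state: np.ndarray):
        for child in node.children:
            child_state = _evolve_branch(state, q, child.length, rng)
            if child.is_leaf:
                out.append(
                    SeqRecord(child.label, _BASES[child_state].tobytes().decode())
                )
            else:
                descend(child, child_state)

    descend(cfg.tree.root, root_idx)
    return out


def _evolve_branch(state: np.ndarray, q: np.ndarray, t: float, rng) -> np.ndarray:
    if t == 0:
        return state.copy()
    p = expm(q * t)
    p = np.clip(p, 0, None)
    p /= p.sum(axis=1, keepdims=True)
    new = state.copy()
    for b in range(4):
        mask = state == b
        n = int(mask.sum())
        if n:
            new[mask] = rng.choice(4, size=n, p=p[b])
    return new


# ---------------------------------------------------------------------------
# Ortholog sets and planted exonization
# ---------------------------------------------------------------------------

def simulate_ortholog_set(
    cfg: SimConfig, gene_id: str = "sim"
) -> dict[str, tuple[SeqRecord, GeneModel]]:
    """Per-taxon genomic sequences + truth models sharing one exon chain.

    A reference gene model fixes the exon lengths and phases; the
    concatenated coding sequence evolves along ``cfg.tree`` under TN93,
    then each taxon gets its own independently drawn introns (lengths and
    sequence), emulating intron-length divergence without an explicit
    indel process.
    """
    if cfg.tree is None:
        raise ConfigError("cfg.tree is required for simulate_ortholog_set")
    ref_genomic, ref_model = simulate_gene_model(cfg, gene_id=gene_id)
    root_cds = SeqRecord(f"{gene_id}_cds", ref_model.spliced_sequence(ref_genomic))
    rows = evolve_alignment(root_cds, cfg)
    exon_lengths = [e - s for s, e in ref_model.exons]

    genomes: dict[str, tuple[SeqRecord, GeneModel]] = {}
    for k, row in enumerate(rows):
        rng = np.random.default_rng([cfg.seed % (2**31), 1000 + k])
        ilo, ihi = cfg.intron_length_range
        parts = [_random_seq(rng, cfg.flank, cfg.base_frequencies)]
        exons = []
        pos = cfg.flank
        offset = 0
        for i, elen in enumerate(exon_lengths):
            parts.append(row.sequence[offset : offset + elen])
            exons.append((pos, pos + elen))
            offset += elen
            pos += elen
            if i < len(exon_lengths) - 1:
                ilen = int(rng.integers(ilo, ihi + 1))
                parts.append("GT" + _random_seq(rng, ilen - 4, cfg.base_frequencies) + "AG")
                pos += ilen
        parts.append(_random_seq(rng, cfg.flank, cfg.base_frequencies))
        genomic = SeqRecord(f"{row.id}", "".join(parts))
        genomes[row.id] = (
            genomic,
            GeneModel(seq_id=genomic.id, gene_id=f"{gene_id}_{row.id}", exons=exons),
        )
    return genomes


def plant_exonization(
    genomes: dict[str, tuple[SeqRecord, GeneModel]],
    cfg: SimConfig,
    donor_taxon: str,
    mutation_rate: float = 0.0,
) -> tuple[dict[str, tuple[SeqRecord, GeneModel]], dict]:
    """Copy one taxon's exon into another taxon's intron interior.

    ``cfg.exonization`` = (donor exon index, target taxon, target intron
    index), both 0-based. The copy (optionally mutated at
    ``mutation_rate`` per site) overwrites a window centred in the target
    intron, preserving coordinates and the gt..ag ends. Returns the
    modified genomes plus a ground-truth event record.
    """
    if cfg.exonization is None:
        raise ConfigError("cfg.exonization is not set")
    exon_idx, target_taxon, intron_idx = cfg.exonization
    if donor_taxon not in genomes or target_taxon not in genomes:
        raise ConfigError("donor or target taxon missing from genomes")
    donor_genomic, donor_model = genomes[donor_taxon]
    if not 0 <= exon_idx < len(donor_model.exons):
        raise ConfigError(f"donor exon index {exon_idx} out of range")
    target_genomic, target_model = genomes[target_taxon]
    if not 0 <= intron_idx < len(target_model.introns):
        raise ConfigError(f"target intron index {intron_idx} out of range")

    exon_seq = donor_model.exon_sequences(donor_genomic)[exon_idx]
    istart, iend = target_model.introns[intron_idx]
    ilen = iend - istart
    if ilen < len(exon_seq) + 8:
        raise ConfigError(
            f"target intron ({ilen} nt) too short for a {len(exon_seq)} nt insert"
        )

    rng = np.random.default_rng(cfg.seed)
    inserted = exon_seq
    if mutation_rate > 0:
        chars = np.frombuffer(inserted.encode(), dtype=np.uint8).copy()
        hits = np.nonzero(rng.random(len(chars)) < mutation_rate)[0]
        for h in hits:
            current = chars[h]
            options = [b for b in _BASES if b != current]
            chars[h] = options[int(rng.integers(3))]
        inserted = chars.tobytes().decode()

    pad = (ilen - len(exon_seq)) // 2
    start = istart + pad
    seq = target_genomic.sequence
    new_seq = seq[:start] + inserted + seq[start + len(inserted) :]
    new_genomic = SeqRecord(target_genomic.id, new_seq, target_genomic.description)
    new_genomes = dict(genomes)
    new_genomes[target_taxon] = (new_genomic, target_model)
    truth = {
        "kind": "exonized_in_intron",
        "donor_taxon": donor_taxon,
        "exon_index": exon_idx,
        "target_taxon": target_taxon,
        "intron_index": intron_idx,
        "location": (start - istart, start - istart + len(inserted)),
        "mutation_rate": mutation_rate,
    }
    return new_genomes, truth


# ---------------------------------------------------------------------------
# The apis7 preset
# ---------------------------------------------------------------------------

APIS7_TAXA = ("dwarf1", "dwarf2", "giant1", "medium1", "medium2", "medium3", "outgroup")


def apis7_tree() -> PhyloTree:
    """A 7-taxon honey-bee-like tree: the dwarf pair diverges first within
    the ingroup, the giant taxon is sister to the three medium taxa."""
    dwarfs = TreeNode(length=0.06, children=[
        TreeNode(label="dwarf1", length=0.03),
        TreeNode(label="dwarf2", length=0.03),
    ])
    med23 = TreeNode(length=0.02, children=[
        TreeNode(label="medium2", length=0.015),
        TreeNode(label="medium3", length=0.015),
    ])
    mediums = TreeNode(length=0.03, children=[
        TreeNode(label="medium1", length=0.03),
        med23,
    ])
    core = TreeNode(length=0.06, children=[
        TreeNode(label="giant1", length=0.05),
        mediums,
    ])
    root = TreeNode(children=[
        TreeNode(label="outgroup", length=0.35),
        dwarfs,
        core,
    ])
    return PhyloTree(root)


def apis7_config(seed: int = 0, **overrides) -> SimConfig:
    """The default study-shaped configuration over the apis7 tree."""
    cfg = SimConfig(seed=seed, tree=apis7_tree())
    return replace(cfg, **overrides) if overrides else cfg
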