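"""Cross-species comparison of exon-intron architectures.

Orthologous gene models are compared exon by exon: an order-preserving
1:1 correspondence between the two exon chains is found by dynamic
programming over per-exon global-alignment identities, unpaired exons
surface as gain/loss candidates, and an exon of one species can be
searched for inside the introns of the other (exonization: intronic
sequence in one lineage corresponding to a coding exon in another).

Gain vs loss is purely descriptive here — relative to the pair as given,
never to a reconstructed ancestor: an exon present in the first model but
absent from the second is reported as ``exon_gain``, the converse as
``exon_loss``; directionality on a phylogeny is the caller's call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from splicevo.errors import SplicevoError
from splicevo.gene_structure import GeneModel
from splicevo.seqio import SeqRecord

#: sentinel for an exon with no partner in the other species
ABSENT = None


@dataclass(frozen=True)
class GainLossEvent:
    """One exon gain/loss/exonization observation.

    ``exon_index`` is 0-based in the species bearing the exon. For
    ``exonized_in_intron`` events, ``intron_index`` (0-based) and
    ``location`` (0-based half-open interval within that intron) say
    where in the other species the exon sequence was found.
    """

    kind: str  # "exon_gain" | "exon_loss" | "exonized_in_intron"
    exon_index: int
    identity: float
    intron_index: int | None = None
    location: tuple[int, int] | None = None


@dataclass
class ArchitectureComparison:
    """Exon correspondence between two gene models plus detected events."""

    species_pair: tuple[str, str]
    exon_correspondence: list[tuple[int | None, int | None, float | None]]
    events: list[GainLossEvent] = field(default_factory=list)


def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def _alignment_identity(alignment) -> float:
    """Matches / alignment columns (gap columns count in the denominator)."""
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns if columns else 0.0


def pairwise_identity(seq_a: str, seq_b: str, mode: str = "global") -> float:
    """Identity of the best pairwise alignment under the module's scoring
    (match +1, mismatch -1, gap open -5, extend -1)."""
    alignment = _aligner(mode).align(seq_a, seq_b)[0]
    return _alignment_identity(alignment)


def align_architectures(
    model_a: GeneModel,
    genomic_a: SeqRecord,
    model_b: GeneModel,
    genomic_b: SeqRecord,
    min_identity: float = 0.7,
) -> ArchitectureComparison:
    """Order-preserving 1:1 exon correspondence between two gene models.

    Every candidate exon pair is globally aligned; the correspondence
    maximises summed identity over pairs at or above ``min_identity``
    (pairs below the threshold stay unpaired). Unpaired exons of model_a
    become ``exon_gain`` events, unpaired exons of model_b ``exon_loss``
    events.
    """
    exons_a = model_a.exon_sequences(genomic_a)
    exons_b = model_b.exon_sequences(genomic_b)
    if not exons_a or not exons_b:
        raise SplicevoError("cannot compare empty gene models")

    na, nb = len(exons_a), len(exons_b)
    identity = [[pairwise_identity(ea, eb) for eb in exons_b] for ea in exons_a]

    # Needleman-Wunsch over the exon chains: pairing scores identity,
    # skipping an exon scores 0; pairs under the threshold are forbidden.
    NEG = float("-inf")
    score = [[0.0] * (nb + 1) for _ in range(na + 1)]
    back = [[None] * (nb + 1) for _ in range(na + 1)]
    for i in range(1, na + 1):
        back[i][0] = "up"
    for j in range(1, nb + 1):
        back[0][j] = "left"
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            pair = (
                score[i - 1][j - 1] + identity[i - 1][j - 1]
                if identity[i - 1][j - 1] >= min_identity
                else NEG
            )
            up = score[i - 1][j]
            left = score[i][j - 1]
            best = max(pair, up, left)
            score[i][j] = best
            back[i][j] = "diag" if best == pair else ("up" if best == up else "left")

    correspondence: list[tuple[int | None, int | None, float | None]] = []
    i, j = na, nb
    while i > 0 or j > 0:
        move = back[i][j]
        if move == "diag":
            correspondence.append((i - 1, j - 1, identity[i - 1][j - 1]))
            i, j = i - 1, j - 1
        elif move == "up":
            correspondence.append((i - 1, ABSENT, None))
            i -= 1
        else:
            correspondence.append((ABSENT, j - 1, None))
            j -= 1
    correspondence.reverse()

    events = []
    for ia, ib, ident in correspondence:
        if ib is ABSENT:
            events.append(GainLossEvent("exon_gain", ia, 0.0))
        elif ia is ABSENT:
            events.append(GainLossEvent("exon_loss", ib, 0.0))
    return ArchitectureComparison(
        species_pair=(model_a.gene_id, model_b.gene_id),
        exon_correspondence=correspondence,
        events=events,
    )


def detect_exonization(
    exon_seq: SeqRecord,
    other_genomic: SeqRecord,
    other_model: GeneModel,
    min_identity: float = 0.7,
    min_coverage: float = 0.8,
    exon_index: int = 0,
) -> list[GainLossEvent]:
    """Search one species' exon inside every intron of another's model.

    Each intron is locally aligned against the exon; an
    ``exonized_in_intron`` event is reported when the alignment identity
    is at least ``min_identity`` over at least ``min_coverage`` of the
    exon. Event coordinates are 0-based within the intron.
    """
    if len(exon_seq) < 20:
        raise SplicevoError("exon query shorter than 20 nt")
    aligner = _aligner("local")
    events = []
    for intron_idx, intron in enumerate(other_model.intron_sequences(other_genomic)):
        if len(intron) < 4:
            continue
        alignments = aligner.align(exon_seq.sequence, intron)
        if len(alignments) == 0:
            continue
        best = alignments[0]
        ident = _alignment_identity(best)
        exon_cov = (best.aligned[0][-1][1] - best.aligned[0][0][0]) / len(exon_seq)
        if ident >= min_identity and exon_cov >= min_coverage:
            loc = (int(best.aligned[1][0][0]), int(best.aligned[1][-1][1]))
            events.append(
                GainLossEvent(
                    "exonized_in_intron",
                    exon_index=exon_index,
                    identity=ident,
                    intron_index=intron_idx,
                    location=loc,
                )
            )
    return events


def summarise_events(comparisons: list[ArchitectureComparison]):
    """Per-gene counts of each event kind, deduplicated by
    (kind, exon index) so the same exon seen against several partners is
    counted once."""
    import pandas as pd

    kinds = ["exon_gain", "exon_loss", "exonized_in_intron"]
    seen: dict[str, set] = {}
    for comp in comparisons:
        gene = comp.species_pair[0]
        bucket = seen.setdefault(gene, set())
        for ev in comp.events:
            bucket.add((ev.kind, ev.exon_index))
    rows = []
    for gene in sorted(seen):
        counts = {kind: 0 for kind in kinds}
        for kind, _ in seen[gene]:
            counts[kind] += 1
        rows.append({"gene": gene, **counts})
    if not rows:
        return pd.DataFrame(columns=["gene", *kinds])
    return pd.DataFrame(rows)
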