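# Methods

This note documents the models, algorithms and numerical choices behind
splicevo, and what the synthetic-data generator does and does not
emulate.

## Spliced CDS-to-genomic mapping

The mapper assumes the CDS differs from its genomic source only by the
excision of introns and by point substitutions — no indels within exons.
This matches the biology the pipeline targets (orthologous partial genes
sequenced from close relatives, where length differences are intronic)
and keeps the search exact.

Candidate exon placements are restricted to diagonals of the
CDS-vs-genomic comparison that carry at least one exact match of
`min_exon` (default 12) nucleotides. A dynamic programme then chains
exons across diagonals. The objective is lexicographic:

1. minimise a combined cost of 1 per uncovered CDS base plus
   `ceil(1/max_mismatch_rate)` per exonic mismatch — so extending
   coverage over a segment is worthwhile only below the allowed mismatch
   rate (default 2%, sized for Sanger-level error between a new sequence
   and a reference species);
2. maximise the number of canonical GT..AG introns;
3. prefer leftmost donor positions (a deterministic tie-break for
   boundary ambiguities such as `GTGT` donors).

Internal introns must be ≥ 20 nt (well below the shortest realistic
spliceosomal intron; it only exists to forbid spurious micro-introns) and
exons ≥ `min_exon`. After traceback, the chain must cover ≥ 90% of the
CDS and respect the mismatch budget, otherwise mapping fails loudly. An
uncovered prefix/suffix sets the corresponding partial flag and shifts
`coding_offset` so the original reading frame is preserved.

Intron **phase** is defined as coding-nucleotides-upstream mod 3
(0 between codons, 1 after the first codon base, 2 after the second).
This is the standard convention and reproduces the printed phase of every
complete junction in the comparative tables the package's tests encode.
The junction notation mirrors those tables: the donor shows the last
complete codon plus the phase nucleotides (comma at the codon boundary),
then `/` and the lowercase intron flank (default 10 nt); the acceptor
mirrors it. Parsing treats the donor side's comma as authoritative and
checks the acceptor side for consistency; a side printed `NA` yields an
absent dinucleotide.

Only forward-strand models are supported; the strand field exists but
`-` is rejected with a clear error. Reverse-strand placement adds no
analytical content here — callers reverse-complement first.

## PROSITE engine

Patterns are compiled element by element (fixed residue, `x`, allowed
`[..]`, forbidden `{..}`, repeats `(n)`/`(m,n)`, `<`/`>` anchors, a
tolerated trailing `.`). Scanning is greedy with backtracking per start
position: a match is reported at a position iff some repeat assignment
succeeds there, which is exactly the existence semantics PROSITE defines;
the reported witness is the greedy (longest) one. `x` matches any residue
including `X`; a peptide `X` otherwise matches only sets that contain X.
Consensus blocks are maximal runs (≥ 5 columns by default) where all
alignment rows share one residue; gap columns never conserve. No rows are
dropped implicitly.

## Architecture comparison and exonization

Per-exon identities come from global pairwise alignment with match +1,
mismatch −1, gap open −5, gap extend −1 (standard nucleotide defaults;
at the identity levels involved the result is insensitive to the exact
scores). Identity is matches / alignment columns, gaps counted in the
denominator. The exon-chain correspondence is a Needleman–Wunsch over
exons (pair score = identity, skip = 0) with pairs below `min_identity`
(default 0.7) forbidden, which makes the correspondence symmetric.

Exonization search locally aligns an exon against every intron of the
other model and reports hits with identity ≥ 0.7 covering ≥ 80% of the
exon. No published threshold exists for when an intronic segment "is" a
homologous exon, so both values are exposed as parameters. Gain/loss
labels are descriptive relative to the pair as given — the module never
reconstructs ancestral states; direction on a phylogeny is the caller's
interpretation.

## Substitution spectra and distances

All pairwise comparisons use **pairwise deletion**: a column is excluded
for a pair only when that pair has a gap or ambiguity in it. Partial
sequences differ in coverage, and pairwise deletion keeps every pair's
information; it is also the common default of the distance tools this
pipeline is patterned on. Codon position comes from the caller's frame
offset (taken from the gene model); there is no internal ORF guessing.

TN93 base frequencies are estimated per pair from the pooled pair of
sequences — reproducible without alignment-wide state. A non-positive
logarithm argument (saturation) yields +inf plus a `SaturationWarning`
rather than silent omission, so downstream NJ fails loudly. With equal
base frequencies and equal transition classes the formula collapses to
the Kimura-2-parameter form, which the tests verify on a grid.

## Neighbour-Joining and bootstrap

NJ joins the pair minimising Q(i,j) = (m−2)d(i,j) − Σd(i,·) − Σd(j,·),
ties broken by the smallest index pair in the current node ordering, so
output is deterministic. Negative branch lengths are clamped to zero with
the deficit moved to the sibling edge (the i–j path length through the
new node is preserved). The final three nodes attach to a trifurcating
root: the tree is unrooted; rooting on an outgroup is a display/export
operation only.

The bootstrap resampling unit is the alignment column (site), the same
choice the standard tools make; codon-triplet resampling was considered
and rejected for fidelity. Each replicate draws its column indices from a
single seeded generator, so results are reproducible and supports do not
depend on taxon input order. Supports are mapped onto the point-estimate
tree (one tree with node numbers, as comparative studies present them),
not onto a consensus tree. Replicates with saturated distances are
dropped from the denominator and counted on the returned tree.

Concatenation requires identical taxon sets across genes (no silent
gap-filling) and records per-gene column spans. Tree alignments may be
spliced coding sequence or full-length rows; the pipeline uses whatever
rows it is given, and with the no-indel generator the spliced coding rows
are already aligned.

## Synthetic generator

`simulate_gene_model` draws exon lengths uniformly (default 60–200 nt)
and nudges them by 0–2 nt so each junction realises its planted phase
(random phases when none are planted) and the total coding length is a
multiple of 3. Introns are uniform 67–550 nt — the printed range of the
honey-bee introns that motivated the defaults — and always begin `gt` and
end `ag`. Base composition defaults to 67% A+T, honey-bee-like.

`evolve_alignment` runs a continuous-time TN93 process site by site along
the tree (transition-probability matrix `expm(Qt)` per branch), with the
rate matrix scaled to one expected substitution per site per unit branch
length and κ₁ = κ₂ = 4 by default so transitions dominate observed
substitutions. There is **no indel process**: ortholog sets share exact
exon lengths, and intron-length divergence is emulated by drawing each
taxon's introns independently. Consequently passing tests demonstrate
correctness of the annotation, distance and tree machinery under
substitution-only divergence; they do not exercise alignment under
exonic indels, non-canonical splice sites, or sequencing error beyond
point substitutions.

The `apis7` preset (two dwarf-like taxa diverging first, a giant-like
taxon, three medium-like taxa, an outgroup at 0.35 substitutions/site)
mirrors the study design that motivated the package; with its default
branch lengths (internal edges 0.02–0.06) the planted splits are
comfortably recoverable, and the dwarf pair's basal position is confirmed
with ≥ 95% bootstrap support at 200 replicates in the acceptance tests.
Problem sizes there — 100 replicates of 50,000 sites for estimator
accuracy, 100 random 8-leaf trees for NJ consistency, 200 bootstrap
replicates — were chosen as the smallest runs at which the statistical
tolerances (±0.01 on a 0.2 distance; exact topology recovery) are stable
across seeds.

## Degenerate inputs and other numerical choices

* Introns shorter than 4 nt cannot carry both dinucleotides and raise a
  degenerate-intron error.
* A gene model with unknown frame (`coding_offset=None`, partial 5'
  material) reports phase `unknown` rather than guessing.
* Residue counts are `floor((exon_nt − offset)/3)`; a trailing stop codon
  is excluded only when the 3' end is complete and the sequence is
  available to check it.
* The GFF3 writer emits 1-based inclusive coordinates from the package's
  0-based half-open internals; the bundled reader round-trips models
  exactly (modulo row order).
* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; identical config + inputs + seed give byte-identical
  outputs.

## Known limitations

* Forward strand only; no trans-splicing; GC–AG/AT–AC introns are
  flagged non-canonical, never rescued.
* No maximum-likelihood tree search, no gamma-rate or codon models, no
  PROSITE profile (weight-matrix) entries, no profile-HMM domain search —
  externally computed domain coordinates can be carried as annotations.
* The exonization detector assumes the copied exon is recognisably
  similar (≥ ~70% identity); ancient or heavily eroded exonizations will
  be missed.
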