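"""Reading and writing the standard formats the pipeline touches.

FASTA comes in; GFF3 and Newick go out. Parsing is strict: alphabet
violations are reported with the offending record and offset rather than
silently passed downstream. Internally all coordinates are 0-based
half-open; emitted GFF3 is 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

from Bio.SeqIO.FastaIO import SimpleFastaParser

from splicevo.errors import AlphabetError, FormatError, LabelError, RangeError

if TYPE_CHECKING:  # pragma: no cover - type-only import avoids a cycle
    from splicevo.gene_structure import GeneModel
    from splicevo.phylo import PhyloTree

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_NEWICK_META = re.compile(r"[\s(),:;\[\]']")


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence over a declared alphabet.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    anything after it is the ``description``. Sequences are stored
    uppercase; ``mode`` is ``"nucleotide"`` (A/C/G/T/N) or ``"protein"``
    (20 amino acids + X).
    """

    id: str
    sequence: str
    description: str = ""
    mode: str = "nucleotide"

    def __post_init__(self):
        if not self.id:
            raise FormatError("SeqRecord id must be non-empty")
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        alphabet = _alphabet_for(self.mode)
        for offset, ch in enumerate(self.sequence):
            if ch not in alphabet:
                raise AlphabetError(
                    f"record {self.id!r}: illegal {self.mode} character "
                    f"{ch!r} at offset {offset}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def _alphabet_for(mode: str) -> frozenset:
    if mode == "nucleotide":
        return NUCLEOTIDE_ALPHABET
    if mode == "protein":
        return PROTEIN_ALPHABET
    raise ValueError(f"unknown mode {mode!r}")


def read_fasta(path, mode: str = "nucleotide") -> list[SeqRecord]:
    """Read a FASTA file into a list of validated :class:`SeqRecord`.

    Record order is preserved, lowercase input is uppercased and CR/LF
    line endings are tolerated. An empty file raises :class:`FormatError`;
    a character outside the alphabet for ``mode`` raises
    :class:`AlphabetError` naming the record and 0-based offset.
    """
    records: list[SeqRecord] = []
    with open(path, newline=None) as handle:
        for header, seq in SimpleFastaParser(handle):
            parts = header.split(None, 1)
            if not parts:
                raise FormatError(f"{path}: FASTA header with no id")
            rec_id = parts[0]
            description = parts[1] if len(parts) > 1 else ""
            records.append(SeqRecord(rec_id, seq, description, mode=mode))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as handle:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _exon_phases(model: "GeneModel") -> list[int]:
    """GFF3 phase per exon: bases to skip to reach the first codon base."""
    phases = []
    cum = 0
    for start, end in model.exons:
        if model.coding_offset > cum:
            phases.append((model.coding_offset - cum) % 3)
        else:
            phases.append((3 - (cum - model.coding_offset) % 3) % 3)
        cum += end - start
    return phases


def write_gff3(models: Iterable["GeneModel"], path, seq_lengths: dict[str, int] | None = None) -> None:
    """Serialise gene models as GFF3 (gene, exon and intron feature rows).

    Coordinates are converted from the internal 0-based half-open
    convention to 1-based inclusive. Rows are emitted in a deterministic
    order: by sequence id, then by gene start. When ``seq_lengths`` is
    given, exon coordinates beyond the sequence end raise
    :class:`RangeError`.
    """
    models = sorted(models, key=lambda m: (m.seq_id, m.exons[0][0], m.gene_id))
    lines = ["##gff-version 3"]
    for model in models:
        if seq_lengths is not None:
            length = seq_lengths.get(model.seq_id)
            if length is not None and model.exons[-1][1] > length:
                raise RangeError(
                    f"gene {model.gene_id!r}: exon end {model.exons[-1][1]} exceeds "
                    f"length {length} of sequence {model.seq_id!r}"
                )
        gene_attrs = f"ID={model.gene_id};coding_offset={model.coding_offset}"
        if model.partial_5prime:
            gene_attrs += ";partial_5prime=true"
        if model.partial_3prime:
            gene_attrs += ";partial_3prime=true"
        span_start, span_end = model.exons[0][0], model.exons[-1][1]
        lines.append(_gff_row(model.seq_id, "gene", span_start, span_end, ".", gene_attrs))
        phases = _exon_phases(model)
        for i, (start, end) in enumerate(model.exons):
            attrs = f"ID={model.gene_id}.exon{i + 1};Parent={model.gene_id}"
            lines.append(_gff_row(model.seq_id, "exon", start, end, str(phases[i]), attrs))
        for i, (start, end) in enumerate(model.introns):
            attrs = f"ID={model.gene_id}.intron{i + 1};Parent={model.gene_id}"
            lines.append(_gff_row(model.seq_id, "intron", start, end, ".", attrs))
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


def _gff_row(seq_id: str, kind: str, start0: int, end0: int, phase: str, attrs: str) -> str:
    return "\t".join(
        [seq_id, "splicevo", kind, str(start0 + 1), str(end0), ".", "+", phase, attrs]
    )


def read_gff3(path) -> list["GeneModel"]:
    """Internal GFF3 reader: reconstructs the gene models written by
    :func:`write_gff3` (round-trip identity modulo row ordering)."""
    from splicevo.gene_structure import GeneModel

    genes: dict[str, dict] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: expected 9 GFF3 columns, got {len(cols)}")
            seq_id, _src, kind, start, end, _score, _strand, _phase, attrs = cols
            attr_map = dict(
                item.split("=", 1) for item in attrs.split(";") if "=" in item
            )
            if kind == "gene":
                genes[attr_map["ID"]] = {
                    "seq_id": seq_id,
                    "coding_offset": int(attr_map.get("coding_offset", 0)),
                    "partial_5prime": attr_map.get("partial_5prime") == "true",
                    "partial_3prime": attr_map.get("partial_3prime") == "true",
                    "exons": [],
                }
            elif kind == "exon":
                parent = attr_map["Parent"]
                if parent not in genes:
                    raise FormatError(f"{path}: exon before its gene row ({parent})")
                genes[parent]["exons"].append((int(start) - 1, int(end)))
    models = []
    for gene_id, info in genes.items():
        models.append(
            GeneModel(
                seq_id=info["seq_id"],
                gene_id=gene_id,
                exons=sorted(info["exons"]),
                coding_offset=info["coding_offset"],
                partial_5prime=info["partial_5prime"],
                partial_3prime=info["partial_3prime"],
            )
        )
    return models


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree: "PhyloTree", path) -> None:
    """Serialise a tree as Newick with ``%.6f`` branch lengths and integer
    bootstrap supports as internal-node labels.

    Duplicate leaf labels or labels containing Newick metacharacters raise
    :class:`LabelError`.
    """
    labels = tree.leaf_labels()
    if len(labels) < 2:
        raise LabelError("tree must have at least 2 leaves")
    if len(set(labels)) != len(labels):
        raise LabelError("duplicate leaf labels")
    for label in labels:
        if _NEWICK_META.search(label):
            raise LabelError(f"leaf label {label!r} contains Newick metacharacters")
    with open(path, "w") as handle:
        handle.write(tree.to_newick() + "\n")
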