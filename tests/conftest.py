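import numpy as np
import pytest

from splicevo import SeqRecord
from splicevo.gene_structure import GeneModel


@pytest.fixture
def two_exon_gene():
    """A hand-built two-exon gene: exon1 (60 nt) + canonical 80-nt intron
    + exon2 (90 nt)."""
    e1 = "ATGGCAGATCGATCGATCGATCGGCTAGCTAAGCTAGCTAGCATCGATCGATCGATCGAT"
    e2 = (
        "TTTGGGCCCAAATTTGGGCCCAAATTTGGGCCCAAATTTGGGCCCAAA"
        "TTTGGGCCCAAATTTGGGCCCAAATTTGGGCCCAAATTTGGG"
    )
    intron = "GT" + "A" * 76 + "AG"
    genomic = SeqRecord("g1", e1 + intron + e2)
    cds = SeqRecord("c1", e1 + e2)
    truth = GeneModel(seq_id="g1", gene_id="c1", exons=[(0, 60), (140, 230)])
    return cds, genomic, truth


def random_dna(rng: np.random.Generator, length: int, at_rich: bool = False) -> str:
    p = [0.335, 0.165, 0.165, 0.335] if at_rich else [0.25] * 4
    return "".join(rng.choice(list("ACGT"), p=p, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
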