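import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicevo import (
    SeqRecord,
    exon_region_stats,
    format_junction,
    junctions,
    junction_table,
    map_cds_to_genomic,
    parse_junction_notation,
)
from splicevo.errors import (
    DegenerateIntronError,
    MappingError,
    NotationError,
    SplicevoError,
)
from splicevo.gene_structure import UNKNOWN, GeneModel
from splicevo.synthetic import SimConfig, simulate_gene_model

from conftest import random_dna
from helpers import best_exact_chain

# Every complete donor/acceptor pair printed in the comparative intron
# tables for the two honey-bee genes, with its printed phase. The one
# intron whose 5' side was not amplified (printed NA) is excluded.
TABLE_JUNCTIONS = [
    # A. andreniformis PFK part A / part B
    ("AAA/gtatatattatg", "attttactttag/GGT", 0),
    ("GAA,G/gtaaataaaa", "gtttatttag/GA,GAA", 1),
    ("TTG/gttagttattat", "taataataatag/GGT", 0),
    ("GGA,AA/gtatgtctt", "atatttttag/G,GGA", 2),
    # A. andreniformis PK-like
    ("TTA/gtacgatattaa", "ttatatttacag/GGA", 0),
    ("ATC,C/gttagtttat", "tcgatacag/AT,GAG", 1),
    ("ATG,A/gtatgcgtat", "tatttaaag/AT,ATT", 1),
    ("AAA/gtaagtctatta", "ttttttctccag/ATT", 0),
    ("AAG/gtagaaaaactt", "ttataaaaccag/GTA", 0),
    ("AAA,G/gtaaatatat", "gtaatttag/AG,AAG", 1),
    # A. c. indica PFK
    ("AAA/gtatgtattatg", "attttaatttag/GGT", 0),
    ("GAA,G/gtaagtaaaa", "tttatttag/GA,GAA", 1),
    ("CAG/gttcgcaatttt", "atataatttcag/GAA", 0),
    ("TTG/gttagttattat", "taataataatag/GGC", 0),
    ("GGA,AA/gtatgtctt", "ttttagttag/G,GGA", 2),
    # A. c. indica PK-like
    ("TTA/gtacgatattaa", "ttatatttacag/GGT", 0),
    ("ATC,C/gttagttttt", "tcaatacag/AT,GAG", 1),
    ("ATG,A/gtatgcgtat", "tatttaaag/AT,ATT", 1),
    ("AAA/gtaagtttatta", "ttttttctccag/ATG", 0),
    ("AAA/gtagaaaaactt", "attcaaaaccag/GTA", 0),
    ("AAA,G/gtaaatatat", "ataatttag/AG,GAA", 1),
]


def build_gene(rng, donor_flank, acceptor_flank, phase, intron_length=100):
    """Construct a two-exon gene whose single junction shows the given
    exonic flanks and intron ends at the given phase."""
    e1 = random_dna(rng, 30 + phase - len(donor_flank)) + donor_flank
    assert len(e1) % 3 == phase
    e2 = acceptor_flank + random_dna(rng, 30)
    filler = random_dna(rng, intron_length - len("gt") - len("ag") - 16).lower()
    intron = ("gt" + random_dna(rng, 8) + filler + random_dna(rng, 8) + "ag").upper()
    intron = intron[: intron_length - 2] + "AG"
    genomic = SeqRecord("g", e1 + intron + e2)
    model = GeneModel(
        seq_id="g", gene_id="gene", exons=[(0, len(e1)), (len(e1) + len(intron), len(e1) + len(intron) + len(e2))]
    )
    cds = SeqRecord("c", e1 + e2)
    return cds, genomic, model


class TestMapCdsToGenomic:
    def test_constructed_two_exon_identity(self, two_exon_gene):
        cds, genomic, truth = two_exon_gene
        model = map_cds_to_genomic(cds, genomic)
        assert model.exons == truth.exons
        assert model.introns == [(60, 140)]
        assert not model.partial_5prime and not model.partial_3prime

    def test_matches_exhaustive_enumeration_on_toys(self, rng):
        """On small random genes the DP chain equals the brute-force
        enumeration of all consistent chains under the same objective
        (canonical-maximising, leftmost donors)."""
        for seed in range(8):
            local = np.random.default_rng(seed)
            e1 = random_dna(local, 15)
            e2 = random_dna(local, 18)
            intron = "GT" + random_dna(local, 26) + "AG"
            genomic = SeqRecord("g", random_dna(local, 10) + e1 + intron + e2 + random_dna(local, 10))
            cds = SeqRecord("c", e1 + e2)
            oracle = best_exact_chain(cds.sequence, genomic.sequence, min_exon=9, min_intron=20)
            assert oracle is not None
            model = map_cds_to_genomic(cds, genomic, min_exon=9, max_mismatch_rate=0.0)
            assert model.exons == oracle

    def test_ambiguous_donor_resolved_like_enumeration(self):
        """A junction where the exon boundary could slide (GTGT at the
        donor) is resolved exactly as exhaustive enumeration dictates."""
        rng = np.random.default_rng(3)
        e1 = random_dna(rng, 15) + "AG"
        e2 = "GT" + random_dna(rng, 16)
        intron = "GT" + random_dna(rng, 30) + "AG"
        genomic = SeqRecord("g", e1 + intron + e2)
        cds = SeqRecord("c", e1 + e2)
        oracle = best_exact_chain(cds.sequence, genomic.sequence, min_exon=9, min_intron=20)
        model = map_cds_to_genomic(cds, genomic, min_exon=9, max_mismatch_rate=0.0)
        assert model.exons == oracle

    def test_recovers_simulated_seven_exon_model(self):
        cfg = SimConfig(seed=1, n_exons=7)
        genomic, truth = simulate_gene_model(cfg)
        cds = SeqRecord("cds", truth.spliced_sequence(genomic))
        model = map_cds_to_genomic(cds, genomic)
        assert model.exons == truth.exons

    def test_tolerates_substitutions_within_budget(self):
        cfg = SimConfig(seed=5, n_exons=4)
        genomic, truth = simulate_gene_model(cfg)
        cds_seq = list(truth.spliced_sequence(genomic))
        rng = np.random.default_rng(0)
        for pos in rng.choice(len(cds_seq), size=len(cds_seq) // 100, replace=False):
            cds_seq[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[cds_seq[pos]]
        model = map_cds_to_genomic(SeqRecord("cds", "".join(cds_seq)), genomic)
        assert model.exons == truth.exons

    def test_unmappable_cds_raises(self, rng):
        genomic = SeqRecord("g", random_dna(rng, 300))
        cds = SeqRecord("c", random_dna(np.random.default_rng(99), 90))
        with pytest.raises(MappingError):
            map_cds_to_genomic(cds, genomic)

    def test_uncovered_suffix_sets_partial_flag(self, two_exon_gene):
        cds, genomic, truth = two_exon_gene
        extended = SeqRecord("c", cds.sequence + "CCCGGGAATT")  # 10 extra nt, < 10% of 160
        model = map_cds_to_genomic(extended, genomic)
        assert model.partial_3prime and not model.partial_5prime
        assert model.exons == truth.exons

    def test_exon_intron_lengths_partition_span(self):
        cfg = SimConfig(seed=11, n_exons=5)
        genomic, truth = simulate_gene_model(cfg)
        model = map_cds_to_genomic(
            SeqRecord("cds", truth.spliced_sequence(genomic)), genomic
        )
        span = model.exons[-1][1] - model.exons[0][0]
        total = model.total_exon_length + sum(e - s for s, e in model.introns)
        assert total == span


class TestJunctions:
    def test_paper_style_junction_dinucleotides_and_phase(self, rng):
        """A junction built with the donor 'TTA/gtacgatattaa' and acceptor
        'ttatatttacag/GGA' context is canonical GT..AG at phase 0."""
        cds, genomic, model = build_gene(
            rng, "TTA", "GGA", phase=0, intron_length=214
        )
        genomic = SeqRecord(
            "g",
            genomic.sequence[: model.exons[0][1]]
            + "GTACGATATTAA"
            + genomic.sequence[model.exons[0][1] + 12 : model.introns[0][1] - 12]
            + "TTATATTTACAG"
            + genomic.sequence[model.introns[0][1] :],
        )
        (j,) = junctions(model, genomic)
        assert j.donor_dinucleotide == "GT"
        assert j.acceptor_dinucleotide == "AG"
        assert j.phase == 0
        assert j.canonical
        assert j.intron_length == 214

    def test_intron_after_complete_codon_is_phase_zero(self, two_exon_gene):
        cds, genomic, truth = two_exon_gene
        (j,) = junctions(truth, genomic)
        assert j.phase == 0

    def test_planted_phases_recovered(self):
        planted = [0, 1, 2, 1, 0, 2]
        cfg = SimConfig(seed=2, n_exons=7, planted_phases=planted)
        genomic, truth = simulate_gene_model(cfg)
        assert [j.phase for j in junctions(truth, genomic)] == planted
        assert all(j.canonical for j in junctions(truth, genomic))

    def test_numbering_offset_applied(self, two_exon_gene):
        _, genomic, truth = two_exon_gene
        (j,) = junctions(truth, genomic, numbering_offset=5)
        assert j.intron_index == 5

    def test_unknown_frame_gives_unknown_phase(self, two_exon_gene):
        _, genomic, truth = two_exon_gene
        partial = GeneModel(
            seq_id=truth.seq_id, gene_id=truth.gene_id, exons=truth.exons,
            coding_offset=None, partial_5prime=True,
        )
        (j,) = junctions(partial, genomic)
        assert j.phase is UNKNOWN

    def test_degenerate_intron_rejected(self):
        genomic = SeqRecord("g", "A" * 30 + "GTA" + "A" * 30)
        model = GeneModel(seq_id="g", gene_id="x", exons=[(0, 30), (33, 63)])
        with pytest.raises(DegenerateIntronError):
            junctions(model, genomic)


class TestFormatJunction:
    @pytest.mark.parametrize(
        "donor_flank,acceptor_flank,phase,expect_donor,expect_acceptor",
        [
            # phase 1: one nt after the comma on the donor side, two before
            # it on the acceptor side
            ("GAAG", "GAGAA", 1, "GAA,G/", "/GA,GAA"),
            # phase 2: two after the comma donor-side, one acceptor-side
            ("GGAAA", "GGGA", 2, "GGA,AA/", "/G,GGA"),
            # phase 0: no comma on either side
            ("AAA", "ATT", 0, "AAA/", "/ATT"),
        ],
    )
    def test_comma_placement_by_phase(
        self, rng, donor_flank, acceptor_flank, phase, expect_donor, expect_acceptor
    ):
        cds, genomic, model = build_gene(rng, donor_flank, acceptor_flank, phase)
        donor, acceptor = format_junction(model, genomic, 1)
        assert donor.startswith(expect_donor)
        assert acceptor.endswith(expect_acceptor)
        intron = genomic.sequence[model.introns[0][0] : model.introns[0][1]].lower()
        assert donor.split("/")[1] == intron[:10]
        assert acceptor.split("/")[0] == intron[-10:]

    def test_out_of_range_intron_index(self, two_exon_gene):
        _, genomic, truth = two_exon_gene
        with pytest.raises(IndexError):
            format_junction(truth, genomic, 2)

    def test_round_trip_against_junctions(self, rng):
        """parse(format(model, i)) reproduces phase and dinucleotides for
        every intron of many simulated models."""
        for seed in range(20):
            cfg = SimConfig(
                seed=seed,
                n_exons=4,
                planted_phases=list(np.random.default_rng(seed).integers(0, 3, size=3)),
            )
            genomic, truth = simulate_gene_model(cfg)
            expected = junctions(truth, genomic)
            for i, j in enumerate(expected, start=1):
                donor_s, acceptor_s = format_junction(truth, genomic, i)
                phase, donor, acceptor = parse_junction_notation(donor_s, acceptor_s)
                assert (phase, donor, acceptor) == (
                    j.phase, j.donor_dinucleotide, j.acceptor_dinucleotide,
                )


class TestParseJunctionNotation:
    @pytest.mark.parametrize("donor,acceptor,phase", TABLE_JUNCTIONS)
    def test_printed_table_rows(self, donor, acceptor, phase):
        """Every complete printed junction row parses to its printed phase
        with canonical GT/AG ends."""
        got_phase, got_donor, got_acceptor = parse_junction_notation(donor, acceptor)
        assert got_phase == phase
        assert got_donor == "GT"
        assert got_acceptor == "AG"

    def test_na_side_yields_absent(self):
        phase, donor, acceptor = parse_junction_notation("NA", "atataatttcag/GAA")
        assert donor is None
        assert acceptor == "AG"
        assert phase == 0

    def test_inconsistent_phases_rejected(self):
        with pytest.raises(NotationError):
            parse_junction_notation("GAA,G/gtaaataaaa", "gtttatttag/G,GAA")

    def test_missing_slash_rejected(self):
        with pytest.raises(NotationError):
            parse_junction_notation("GAAG gtaaataaaa", "gtttatttag/GA,GAA")


class TestExonRegionStats:
    @pytest.mark.parametrize(
        "total_nt,expected_residues",
        [(543, 181), (1446, 482), (537, 179), (510, 170)],
    )
    def test_partial_gene_residue_arithmetic(self, total_nt, expected_residues):
        model = GeneModel(
            seq_id="s", gene_id="g", exons=[(0, total_nt)],
            coding_offset=0, partial_5prime=True, partial_3prime=True,
        )
        total, n_exons, n_introns, residues = exon_region_stats(model)
        assert total == total_nt
        assert residues == expected_residues

    def test_floor_arithmetic_with_offset(self):
        model = GeneModel(
            seq_id="s", gene_id="g", exons=[(0, 4)], coding_offset=1,
            partial_5prime=True, partial_3prime=True,
        )
        assert exon_region_stats(model)[3] == 1

    def test_trailing_stop_excluded_when_complete(self):
        seq = "ATGGCATAA"  # Met-Ala-stop
        genomic = SeqRecord("g", seq)
        model = GeneModel(seq_id="g", gene_id="x", exons=[(0, 9)])
        assert exon_region_stats(model, genomic)[3] == 2

    def test_counts(self, two_exon_gene):
        _, _, truth = two_exon_gene
        total, n_exons, n_introns, _ = exon_region_stats(truth)
        assert (total, n_exons, n_introns) == (150, 2, 1)


def test_junction_table_columns(two_exon_gene):
    _, genomic, truth = two_exon_gene
    table = junction_table(truth, genomic, gene_name="PFK-like")
    assert list(table.columns) == [
        "Gene", "Intron number", "Intron length",
        "5' splice site (exon/intron)", "3' splice site (intron/exon)",
        "Intron phase",
    ]
    assert table.iloc[0]["Intron length"] == 80


def test_reverse_strand_rejected():
    with pytest.raises(SplicevoError):
        GeneModel(seq_id="s", gene_id="g", exons=[(0, 9)], strand="-")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**16),
    phases=st.lists(st.integers(0, 2), min_size=1, max_size=4),
)
def test_junction_notation_round_trip_property(seed, phases):
    """For any simulated gene, formatting then parsing every junction
    reproduces the planted phase and the canonical dinucleotides."""
    cfg = SimConfig(seed=seed, n_exons=len(phases) + 1, planted_phases=phases)
    genomic, truth = simulate_gene_model(cfg)
    for i, j in enumerate(junctions(truth, genomic), start=1):
        donor_s, acceptor_s = format_junction(truth, genomic, i)
        assert parse_junction_notation(donor_s, acceptor_s) == (j.phase, "GT", "AG")
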