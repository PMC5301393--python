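from __future__ import annotations

import numpy as np
import pytest

from p335 import insilico_pcr as pcr
from p335 import synthetic_data as syn
from p335.genome_io import GenomeRecord, reverse_complement

from oracles import amplicon_spans, primer_sites

PANEL = pcr.default_p335_panel()
BY_NAME = {p.name: p for p in PANEL}


def random_genome(seed, n=2000, gid="g", topology="linear"):
    rng = np.random.default_rng(seed)
    return GenomeRecord(gid, "".join(rng.choice(list("ACGT"), size=n)),
                        topology=topology)


class TestPrimerPair:
    def test_validation(self):
        with pytest.raises(ValueError, match="shorter"):
            pcr.PrimerPair("x", "ACGT", "ACGTACGTACGTACGTACGT")
        with pytest.raises(ValueError, match="non-ACGT"):
            pcr.PrimerPair("x", "ACGTACGTACGTACGN", "ACGTACGTACGTACGT")

    def test_panel_expected_sizes(self):
        expected = {"62503": 784, "98101": 268, "53801": 554, "98204": 412,
                    "LC3": 128, "38502": 1002, "Tuc2009U": None}
        assert {p.name: p.expected_size_bp for p in PANEL} == expected


class TestFindPrimerSites:
    def test_planted_verbatim(self):
        genome = random_genome(1)
        primer = BY_NAME["LC3"].forward
        seq = (genome.sequence[:100] + primer
               + genome.sequence[100 + len(primer):])
        sites = pcr.find_primer_sites(GenomeRecord("g", seq), primer)
        assert pcr.PrimerSite(100, "+", 0) in sites

    def test_planted_reverse_complement(self):
        genome = random_genome(2)
        primer = BY_NAME["LC3"].forward
        rc = reverse_complement(primer)
        seq = genome.sequence[:300] + rc + genome.sequence[300 + len(rc):]
        sites = pcr.find_primer_sites(GenomeRecord("g", seq), primer)
        assert pcr.PrimerSite(300, "-", 0) in sites

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_sliding_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genome = GenomeRecord(
            "g", "".join(rng.choice(list("ACGT"), size=600)))
        primer = "".join(rng.choice(list("ACGT"), size=18))
        params = pcr.MatchParams(max_mismatches=2, three_prime_exact_nt=4)
        ours = {(s.position, s.strand, s.mismatches)
                for s in pcr.find_primer_sites(genome, primer, params)}
        assert ours == primer_sites(genome.sequence, primer, 2, 4)

    def test_mismatch_monotonicity(self):
        genome = random_genome(3)
        primer = BY_NAME["62503"].forward
        sites = [
            {(s.position, s.strand)
             for s in pcr.find_primer_sites(
                 genome, primer, pcr.MatchParams(max_mismatches=mm))}
            for mm in (0, 2, 4)
        ]
        assert sites[0] <= sites[1] <= sites[2]

    def test_n_counts_as_mismatch(self):
        primer = "ACGTACGTACGTACGTAC"
        genome = GenomeRecord("g", "TTTT" + primer[:-6] + "N" + primer[-5:]
                              + "TTTT")
        assert pcr.find_primer_sites(genome, primer) == []
        params = pcr.MatchParams(max_mismatches=1, three_prime_exact_nt=5)
        sites = pcr.find_primer_sites(genome, primer, params)
        assert any(s.mismatches == 1 for s in sites)


class TestPredictAmplicons:
    def test_planted_spacings(self):
        for name, spacing in (("62503", 784), ("LC3", 128)):
            genome, _ = syn.plant_primer_sites(
                random_genome(5), BY_NAME[name], spacing, 400)
            amps = pcr.predict_amplicons(genome, BY_NAME[name])
            assert [a.length_bp for a in amps] == [spacing]
            assert amps[0].orientation == "+"

    def test_no_sites_no_amplicons(self):
        assert pcr.predict_amplicons(random_genome(6), BY_NAME["LC3"]) == []

    def test_two_forward_sites_two_amplicons(self):
        pair = BY_NAME["LC3"]
        genome = random_genome(7, n=3000)
        genome, _ = syn.plant_primer_sites(genome, pair, 500, 1000)
        seq = list(genome.sequence)
        seq[700:700 + len(pair.forward)] = pair.forward  # second forward site
        genome = GenomeRecord("g", "".join(seq))
        amps = pcr.predict_amplicons(genome, pair)
        assert sorted(a.length_bp for a in amps) == [500, 800]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_pairing_oracle(self, seed):
        pair = BY_NAME["98204"]
        rng = np.random.default_rng(seed)
        seq = list(random_genome(seed, n=4000).sequence)
        positions = rng.choice(range(0, 3900, 60), size=8, replace=False)
        for k, pos in enumerate(positions):
            site = [pair.forward, reverse_complement(pair.reverse),
                    pair.reverse, reverse_complement(pair.forward)][k % 4]
            seq[pos:pos + len(site)] = site
        genome = GenomeRecord("g", "".join(seq))
        params = pcr.MatchParams(max_product_bp=3000)
        ours = {(a.start, a.end, a.orientation)
                for a in pcr.predict_amplicons(genome, pair, params)}
        f = pcr.find_primer_sites(genome, pair.forward, params)
        r = pcr.find_primer_sites(genome, pair.reverse, params)
        expected = amplicon_spans(
            [s.position for s in f if s.strand == "+"],
            [(s.position, len(pair.reverse)) for s in r if s.strand == "-"],
            [s.position for s in r if s.strand == "+"],
            [(s.position, len(pair.forward)) for s in f if s.strand == "-"],
            len(pair.forward), len(pair.reverse), 3000)
        assert ours == expected

    def test_strand_reversal_invariance(self):
        pair = BY_NAME["53801"]
        genome, _ = syn.plant_primer_sites(random_genome(8), pair, 554, 300)
        fwd = pcr.predict_amplicons(genome, pair)
        flipped = GenomeRecord("g", reverse_complement(genome.sequence))
        rev = pcr.predict_amplicons(flipped, pair)
        assert [a.length_bp for a in fwd] == [a.length_bp for a in rev]
        assert {a.orientation for a in fwd} == {"+"}
        assert {a.orientation for a in rev} == {"-"}

    def test_max_product_monotonicity(self):
        pair = BY_NAME["38502"]
        genome, _ = syn.plant_primer_sites(random_genome(9, n=3000), pair,
                                           1002, 500)
        big = pcr.predict_amplicons(genome, pair,
                                    pcr.MatchParams(max_product_bp=5000))
        small = pcr.predict_amplicons(genome, pair,
                                      pcr.MatchParams(max_product_bp=900))
        assert small == [] and len(big) == 1

    def test_circular_genome_wraps(self):
        pair = BY_NAME["LC3"]
        # forward primer near the end, reverse site wrapping past the origin
        n = 1000
        base = random_genome(10, n=n).sequence
        seq = list(base)
        fpos = n - 60
        seq[fpos:fpos + len(pair.forward)] = pair.forward
        rc = reverse_complement(pair.reverse)
        rev_site_end = (fpos + 128) % n  # product of 128 wraps the origin
        rev_start = rev_site_end - len(pair.reverse)
        seq[rev_start:rev_site_end] = rc
        linear = GenomeRecord("g", "".join(seq), topology="linear")
        circular = GenomeRecord("g", "".join(seq), topology="circular")
        assert pcr.predict_amplicons(linear, pair) == []
        amps = pcr.predict_amplicons(circular, pair)
        assert [a.length_bp for a in amps] == [128]


class TestSimulateMultiplex:
    def test_planted_lc3_only(self):
        genome, _ = syn.plant_primer_sites(random_genome(11), BY_NAME["LC3"],
                                           128, 500)
        result = pcr.simulate_multiplex(genome, PANEL)
        assert result.called_labels == {"III/LC3"}
        assert "multiple_labels" not in result.flags

    def test_wrong_spacing_withholds_label(self):
        genome, _ = syn.plant_primer_sites(random_genome(12), BY_NAME["LC3"],
                                           200, 500)
        result = pcr.simulate_multiplex(genome, PANEL)
        assert result.called_labels == set()
        assert "LC3:size_mismatch" in result.flags
        assert result.amplicons["LC3"][0].length_bp == 200

    def test_two_pairs_conflict_flag(self):
        occupied = []
        genome, _ = syn.plant_primer_sites(
            random_genome(13, n=4000), BY_NAME["LC3"], 128, 200, occupied)
        genome, _ = syn.plant_primer_sites(
            genome, BY_NAME["62503"], 784, 1000, occupied)
        result = pcr.simulate_multiplex(genome, PANEL)
        assert result.called_labels == {"III/LC3", "IV/62503"}
        assert "multiple_labels" in result.flags

    def test_tuc2009u_unvalidated_path(self):
        pair = BY_NAME["Tuc2009U"]
        genome, _ = syn.plant_primer_sites(random_genome(14), pair, 300, 500)
        result = pcr.simulate_multiplex(genome, PANEL)
        assert result.unvalidated_labels == {"II/Tuc2009U"}
        assert result.called_labels == set()

    def test_duplicate_pair_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            pcr.simulate_multiplex(random_genome(15), [PANEL[0], PANEL[0]])

    def test_size_tolerance(self):
        genome, _ = syn.plant_primer_sites(random_genome(16), BY_NAME["LC3"],
                                           128 + 20, 500)
        result = pcr.simulate_multiplex(genome, PANEL)
        assert result.called_labels == {"III/LC3"}
        genome, _ = syn.plant_primer_sites(random_genome(16), BY_NAME["LC3"],
                                           128 + 21, 500)
        result = pcr.simulate_multiplex(genome, PANEL)
        assert result.called_labels == set()


def cwps_panel():
    rng = np.random.default_rng(99)
    mk = lambda: "".join(rng.choice(list("ACGT"), size=21))
    return [
        pcr.PrimerPair("cwpsA", mk(), mk(), 442, "A"),
        pcr.PrimerPair("cwpsB", mk(), mk(), 183, "B"),
        pcr.PrimerPair("cwpsC", mk(), mk(), 686, "C"),
        pcr.PrimerPair("rmlB", mk(), mk(), 891, "control"),
    ]


class TestCwpsType:
    def test_type_a_with_control(self):
        panel = cwps_panel()
        occupied = []
        genome, _ = syn.plant_primer_sites(random_genome(17, 4000), panel[0],
                                           442, 200, occupied)
        genome, _ = syn.plant_primer_sites(genome, panel[3], 891, 1500,
                                           occupied)
        assert pcr.cwps_type(genome, panel) == ("A", True)

    def test_control_only_is_unknown(self):
        panel = cwps_panel()
        genome, _ = syn.plant_primer_sites(random_genome(18, 4000), panel[3],
                                           891, 500)
        assert pcr.cwps_type(genome, panel) == ("unknown", True)

    def test_no_control_invalid(self):
        panel = cwps_panel()
        genome, _ = syn.plant_primer_sites(random_genome(19, 4000), panel[0],
                                           442, 500)
        assert pcr.cwps_type(genome, panel) == ("invalid", False)

    def test_missing_control_pair_config_error(self):
        with pytest.raises(ValueError, match="control"):
            pcr.cwps_type(random_genome(20), cwps_panel()[:3])


class TestPanelIO:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "panel.yaml"
        pcr.write_panel(PANEL, path)
        assert pcr.load_panel(path) == PANEL

    def test_tsv_panel(self, tmp_path):
        path = tmp_path / "panel.tsv"
        path.write_text(
            "name\tforward\treverse\texpected_size_bp\tlabel\n"
            "LC3\tcgttgaagtaaatggaagcttaac\tgaggatatttccccaccaattg\t128\tIII\n")
        (pair,) = pcr.load_panel(path)
        assert pair == pcr.PrimerPair(
            "LC3", "cgttgaagtaaatggaagcttaac", "gaggatatttccccaccaattg",
            128, "III")

    def test_packaged_panel(self):
        from importlib import resources

        path = resources.files("p335") / "data" / "p335_primers.yaml"
        assert pcr.load_panel(path) == PANEL
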