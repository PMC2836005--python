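import numpy as np
import pytest
from scipy import stats

from gingerscan import synthdata
from gingerscan.seqio import GenomeRecord, revcomp
from gingerscan.structure import iupac_match


class TestMutateSequence:
    def test_rate_zero_identity(self):
        s = "ACGTACGTAC" * 10
        assert synthdata.mutate_sequence(s, 0.0, seed=1) == s

    def test_rate_one_changes_every_base(self):
        s = "ACGTACGTAC" * 10
        out = synthdata.mutate_sequence(s, 1.0, seed=1)
        assert len(out) == len(s)
        assert all(a != b for a, b in zip(s, out))

    def test_observed_rate_within_three_binomial_sd(self):
        n, rate = 10_000, 0.005
        s = "A" * n
        out = synthdata.mutate_sequence(s, rate, seed=42)
        k = sum(1 for a, b in zip(s, out) if a != b)
        sd = (n * rate * (1 - rate)) ** 0.5
        assert abs(k - n * rate) <= 3 * sd

    def test_deterministic_for_seed(self):
        s = "ACGT" * 500
        assert (synthdata.mutate_sequence(s, 0.1, seed=7)
                == synthdata.mutate_sequence(s, 0.1, seed=7))

    def test_non_acgt_untouched(self):
        assert synthdata.mutate_sequence("NNNN", 1.0, seed=0) == "NNNN"


class TestGenerateGenome:
    def test_seed_determinism_byte_identical(self):
        cfg = dict(genome_length=50_000, n_elements=3, seed=1)
        g1, t1 = synthdata.generate_genome(synthdata.SimulationConfig(**cfg))
        g2, t2 = synthdata.generate_genome(synthdata.SimulationConfig(**cfg))
        assert g1.seq == g2.seq
        assert t1.truth_rows() == t2.truth_rows()

    def test_zero_elements_empty_truth(self):
        cfg = synthdata.SimulationConfig(genome_length=10_000, n_elements=0,
                                         seed=2)
        genome, truth = synthdata.generate_genome(cfg)
        assert len(genome.seq) == 10_000
        assert truth.elements == [] and truth.genes == []

    def test_capacity_error(self):
        with pytest.raises(synthdata.CapacityError):
            synthdata.SimulationConfig(genome_length=10_000, n_elements=5,
                                       seed=0)

    def test_tsd_construction_invariant_all_elements(self, small_sim):
        genome, truth = small_sim
        for a in truth.elements:
            assert genome.seq[a.start0 - 4:a.start0] == \
                genome.seq[a.end0:a.end0 + 4]

    def test_terminal_motif_on_planted_elements(self, small_sim):
        genome, truth = small_sim
        for a in truth.elements:
            elem = genome.seq[a.start0:a.end0]
            assert iupac_match(elem[:5], "TGTNR")
            assert iupac_match(elem[-5:], revcomp("TGTNR"))

    def test_roundtrip_exact_search_zero_divergence(self, small_sim):
        # every copy of the family template is findable by exact search
        genome, truth = small_sim
        template = genome.seq[truth.elements[0].start0:truth.elements[0].end0]
        hits, pos = [], genome.seq.find(template)
        while pos != -1:
            hits.append(pos)
            pos = genome.seq.find(template, pos + 1)
        assert hits == [a.start0 for a in truth.elements]

    def test_ginger1_ccgg_fraction_within_three_sd(self):
        cfg = synthdata.SimulationConfig(genome_length=800_000, n_elements=200,
                                         seed=2)
        _genome, truth = synthdata.generate_genome(cfg)
        tsds = [a.tsd.sequence for a in truth.elements]
        frac = tsds.count("CCGG") / len(tsds)
        sd = (0.75 * 0.25 / len(tsds)) ** 0.5
        assert abs(frac - 0.75) <= 3 * sd

    def test_tsd_profile_chisquare_not_rejected_at_n_1000(self):
        # category frequencies converge to the generator profile
        rng = np.random.default_rng(123)
        draws = [synthdata.draw_tsd(synthdata.DEFAULT_TSD_PROFILE, rng)
                 for _ in range(1000)]
        named = ["CCGG", "CCGT", "ACGG"]
        obs = [draws.count(k) for k in named]
        obs.append(1000 - sum(obs))
        exp = [750, 120, 120, 10]
        p = stats.chisquare(obs, exp).pvalue
        assert p > 0.01


class TestPlantElement:
    def test_flank_duplication_invariant(self):
        genome = GenomeRecord(id="g", seq=synthdata.random_background(
            20_000, 0.5, np.random.default_rng(0)))
        spec = synthdata.default_ginger1_spec()
        new, ann = synthdata.plant_element(
            genome, spec, 8000, np.random.default_rng(1))
        assert new.seq[ann.start0 - 4:ann.start0] == \
            new.seq[ann.end0:ann.end0 + 4]

    def test_ginger2_at_atatat_site(self):
        rng = np.random.default_rng(3)
        bg = synthdata.random_background(9000, 0.5, rng)
        seq = bg[:4000] + "ATATAT" + bg[4000:]
        genome = GenomeRecord(id="g", seq=seq)
        spec = synthdata.default_ginger2_spec()
        new, ann = synthdata.plant_element(genome, spec, 4000, rng)
        left = new.seq[ann.start0 - 4:ann.start0]
        assert left == new.seq[ann.end0:ann.end0 + 4]
        # the duplication is the core of the RTATAY site
        assert iupac_match(new.seq[ann.start0 - 5:ann.end0 + 5]
                           [:5], "RTATA")

    def test_planted_element_starts_with_tgtnr(self):
        genome = GenomeRecord(id="g", seq=synthdata.random_background(
            20_000, 0.5, np.random.default_rng(5)))
        spec = synthdata.default_ginger1_spec()
        new, ann = synthdata.plant_element(genome, spec, 9000,
                                           np.random.default_rng(6))
        head = new.seq[ann.start0:ann.start0 + 5]
        assert head[0] == "T" and head[1] == "G" and head[2] == "T"
        assert head[4] in "AG"

    def test_overlap_rejected(self):
        genome = GenomeRecord(id="g", seq=synthdata.random_background(
            20_000, 0.5, np.random.default_rng(7)))
        spec = synthdata.default_ginger1_spec()
        with pytest.raises(synthdata.SiteOverlapError):
            synthdata.plant_element(genome, spec, 5000,
                                    np.random.default_rng(8),
                                    occupied=[(4000, 6000)])


class TestFamilySpec:
    def test_tir_length_invariant(self):
        with pytest.raises(ValueError):
            synthdata.FamilySpec(group="Ginger1", element_length=100,
                                 tir_length=60)

    def test_intron_phase_must_match_offset(self):
        with pytest.raises(ValueError):
            synthdata.FamilySpec(group="Ginger1", element_length=4000,
                                 tir_length=100, intron_positions=[(301, 0)])

    def test_tsd_profile_must_sum_to_one(self):
        with pytest.raises(ValueError):
            synthdata.SimulationConfig(tsd_profile={"CCGG": 0.8, "other": 0.1})


def test_host_gene_fixtures_share_three_introns():
    fixtures = synthdata.host_gene_fixture_set(seed=0)
    descs = []
    for fx in fixtures:
        cum = 0
        ds = set()
        for (es, ee), intron in zip(fx["exons"], fx["introns"]):
            cum += ee - es
            ds.add((cum, intron[4]))
        descs.append(ds)
    shared = set.intersection(*descs)
    assert len(shared) == 3
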