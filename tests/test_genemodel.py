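import numpy as np
import pytest

from gingerscan import genemodel, synthdata
from gingerscan.seqio import GenomeRecord, revcomp


def _gene_genome(peptide, introns, seed=0, donor="GT", acceptor="AG",
                 pad=150):
    rng = np.random.default_rng(seed)
    seq, exons, intr, protein = synthdata.build_gene_sequence(
        peptide, introns, rng, donor=donor, acceptor=acceptor)
    left = synthdata.random_background(pad, 0.5, rng)
    right = synthdata.random_background(pad, 0.5, rng)
    genome = GenomeRecord(id="g", seq=left + seq + right)
    shift = len(left)
    exons = [(s + shift, e + shift) for s, e in exons]
    intr = [(s + shift, e + shift, d, a, p) for s, e, d, a, p in intr]
    return genome, exons, intr, protein


PEP = synthdata.GINGER1_TPASE


class TestReconstructCds:
    def test_intronless_exact_orf(self):
        genome, exons, _inr, protein = _gene_genome(PEP, [], seed=1)
        gm = genemodel.reconstruct_cds(genome, (0, len(genome.seq)), protein)
        assert gm is not None
        assert gm.protein == protein
        assert len(gm.exons) == 1
        assert gm.introns == []

    @pytest.mark.parametrize("introns", [
        [(300, 0)], [(301, 1)], [(302, 2)],
        [(150, 0), (601, 1), (800, 2)],
    ])
    def test_gt_ag_introns_recovered_exactly(self, introns):
        genome, _ex, truth_intr, protein = _gene_genome(PEP, introns, seed=2)
        gm = genemodel.reconstruct_cds(genome, (0, len(genome.seq)), protein)
        assert gm is not None
        got = [(s, e, p) for s, e, _d, _a, p in gm.introns]
        expect = [(s, e, p) for s, e, _d, _a, p in truth_intr]
        assert got == expect
        assert gm.protein == protein
        assert [i[2] for i in gm.introns] == ["GT"] * len(introns)
        assert [i[3] for i in gm.introns] == ["AG"] * len(introns)

    def test_gc_ag_needs_noncanonical_flag(self):
        genome, _ex, truth_intr, protein = _gene_genome(
            PEP, [(300, 0)], seed=3, donor="GC")
        strict = genemodel.reconstruct_cds(genome, (0, len(genome.seq)),
                                           protein)
        relaxed = genemodel.reconstruct_cds(genome, (0, len(genome.seq)),
                                            protein, allow_noncanonical=True)
        # without the flag the intron cannot be spliced out
        assert strict is None or strict.protein != protein
        assert relaxed is not None and relaxed.protein == protein
        assert relaxed.introns[0][2] == "GC"

    def test_minus_strand_model_mirrors_plus_strand(self):
        genome, _exons, _inr, protein = _gene_genome(PEP, [(300, 0)], seed=4)
        flipped = GenomeRecord(id="g", seq=revcomp(genome.seq))
        gm = genemodel.reconstruct_cds(flipped, (0, len(flipped.seq)),
                                       protein, strand="-")
        plus = genemodel.reconstruct_cds(genome, (0, len(genome.seq)), protein)
        assert gm is not None and gm.protein == protein
        n = len(genome.seq)
        expect = sorted((n - e, n - s) for s, e in plus.exons)
        assert [(int(s), int(e)) for s, e in gm.exons] == expect

    def test_no_model_below_threshold(self):
        rng = np.random.default_rng(5)
        genome = GenomeRecord(id="g", seq=synthdata.random_background(
            4000, 0.5, rng))
        assert genemodel.reconstruct_cds(genome, (0, 4000), PEP) is None

    def test_phases_consistent_with_exon_lengths(self):
        genome, _ex, _inr, protein = _gene_genome(
            PEP, [(150, 0), (601, 1)], seed=6)
        gm = genemodel.reconstruct_cds(genome, (0, len(genome.seq)), protein)
        assert [i[4] for i in gm.introns] == gm.recompute_phases()
        assert gm.cds_length() % 3 == 0


class TestScanMotifs:
    def test_ypyy_hit_at_offset(self):
        hits = genemodel.scan_motifs("AAAAYPYYAAAA")
        ypyy = [h for h in hits if h.motif_name == "YPYY"]
        assert len(ypyy) == 1 and ypyy[0].start == 4

    def test_degenerate_fpff_accepted(self):
        assert any(h.motif_name == "YPYY"
                   for h in genemodel.scan_motifs("AAFPFFAA"))

    def test_invariant_proline_required(self):
        assert not any(h.motif_name == "YPYY"
                       for h in genemodel.scan_motifs("AAYAYYAA"))

    def test_h2c2_and_dde_found_in_synthetic_integrase(self):
        names = {h.motif_name
                 for h in genemodel.scan_motifs(synthdata.GINGER1_INTEGRASE)}
        assert {"YPYY", "H2C2_ZF", "DDE", "GPYF"} <= names

    def test_ginger2_integrase_lacks_ypyy_and_gpyf(self):
        names = {h.motif_name
                 for h in genemodel.scan_motifs(synthdata.GINGER2_INTEGRASE)}
        assert "YPYY" not in names and "GPYF" not in names
        assert {"H2C2_ZF", "DDE"} <= names

    def test_gpyf_outside_cterminal_third_ignored(self):
        protein = "AGPY" + "A" * 200
        assert not any(h.motif_name == "GPYF"
                       for h in genemodel.scan_motifs(protein))

    def test_position_equivariance_under_prefix(self):
        protein = synthdata.GINGER1_INTEGRASE
        k = 17
        base = {(h.motif_name, h.start)
                for h in genemodel.scan_motifs(protein)}
        shifted = {(h.motif_name, h.start - k)
                   for h in genemodel.scan_motifs(
                       "A" * k + protein, integrase_end=k + len(protein))}
        assert base == shifted

    def test_empty_protein_error(self):
        with pytest.raises(ValueError):
            genemodel.scan_motifs("")


class TestClassifyCtermDomain:
    def _protein(self, kind):
        return synthdata.GINGER1_INTEGRASE + synthdata._make_tail(50, kind)

    def test_otu_tail(self):
        p = self._protein("OTU")
        assert genemodel.classify_cterm_domain(
            p, len(synthdata.GINGER1_INTEGRASE)) == "OTU"

    def test_plain_tail_none(self):
        p = self._protein("none")
        assert genemodel.classify_cterm_domain(
            p, len(synthdata.GINGER1_INTEGRASE)) == "none"

    def test_ulp1_with_phd(self):
        p = self._protein("Ulp1+PHD")
        assert genemodel.classify_cterm_domain(
            p, len(synthdata.GINGER1_INTEGRASE)) == "PHD+Ulp1"

    def test_never_both_otu_and_ulp1(self):
        p = self._protein("OTU") + synthdata._make_tail(51, "Ulp1")
        label = genemodel.classify_cterm_domain(
            p, len(synthdata.GINGER1_INTEGRASE))
        assert label in ("OTU", "Ulp1", "PHD+Ulp1")


class TestSharedIntrons:
    def _models(self, seed=0):
        models, rows = [], []
        for fx in synthdata.host_gene_fixture_set(seed=seed):
            gm = genemodel.GeneModel(
                contig=fx["name"], strand="+", exons=fx["exons"],
                introns=fx["introns"], protein=fx["protein"])
            models.append(gm)
            rows.append((fx["name"], fx["protein"]))  # identical -> gapless MSA
        return models, rows

    def test_identical_models_share_all_introns(self):
        models, msa = self._models()
        two = [models[2], models[2]]
        shared = genemodel.shared_introns(two, msa)
        assert len(shared) == len(models[2].introns)

    def test_host_gene_fixture_has_exactly_three_shared(self):
        models, msa = self._models()
        assert len(genemodel.shared_introns(models, msa)) == 3

    def test_same_position_different_phase_excluded(self):
        models, msa = self._models()
        m = models[2]
        intr = list(m.introns)
        s, e, d, a, p = intr[0]
        intr[0] = (s, e, d, a, (p + 1) % 3)
        altered = genemodel.GeneModel(contig=m.contig, strand=m.strand,
                                      exons=m.exons, introns=intr,
                                      protein=m.protein)
        shared = genemodel.shared_introns([models[0], altered], msa)
        assert len(shared) == 2

    def test_protein_missing_from_msa_error(self):
        models, msa = self._models()
        with pytest.raises(ValueError, match="not found"):
            genemodel.shared_introns(models, [("x", "MAAA")])
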