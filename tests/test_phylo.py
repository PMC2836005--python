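import itertools
import math

import numpy as np
import pytest

from gingerscan import phylo

from _oracles import exhaustive_me_total, random_additive_tree


class TestDistances:
    def test_identical_rows_zero_under_all_models(self):
        msa = [("a", "MKLV"), ("b", "MKLV")]
        for model in ("p", "poisson", "gamma"):
            dm = phylo.distance(msa, model=model)
            assert dm.d[0, 1] == 0.0

    def test_poisson_closed_form(self):
        assert phylo.correct_distance(0.5, "poisson") == \
            pytest.approx(-math.log(0.5))

    def test_gamma_closed_form(self):
        assert phylo.correct_distance(0.5, "gamma", 2.0) == \
            pytest.approx(2 * (math.sqrt(2) - 1))

    def test_p_equals_one_is_explicit_error(self):
        with pytest.raises(phylo.UndefinedDistanceError):
            phylo.correct_distance(1.0, "poisson")

    def test_pairwise_vs_complete_deletion(self):
        msa = [("a", "AAAA-A"), ("b", "AAAAAA"), ("c", "CCCC-C")]
        pw = phylo.distance(msa, model="p", deletion="pairwise")
        comp = phylo.distance(msa, model="p", deletion="complete")
        assert pw.d[0, 1] == 0.0
        assert comp.d[0, 2] == 1.0  # column 5 dropped for everyone

    def test_poisson_inverse_identity(self):
        for p in np.linspace(0.01, 0.95, 20):
            d = phylo.correct_distance(float(p), "poisson")
            assert 1 - math.exp(-d) == pytest.approx(p, abs=1e-12)

    def test_gamma_converges_to_poisson(self):
        g = phylo.correct_distance(0.5, "gamma", 1e4)
        po = phylo.correct_distance(0.5, "poisson")
        assert abs(g - po) / po < 1e-3

    def test_model_ordering_gamma_ge_poisson_ge_p(self):
        for p in np.linspace(0.05, 0.9, 10):
            p = float(p)
            assert phylo.correct_distance(p, "gamma", 2.0) >= \
                phylo.correct_distance(p, "poisson") >= p


class TestNJ:
    def test_quartet_topology_and_exact_path_lengths(self):
        taxa = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 6, 5], [3, 0, 7, 6],
                      [6, 7, 0, 3], [5, 6, 3, 0]], float)
        t = phylo.nj_tree(phylo.DistanceMatrix(taxa=taxa, d=d))
        bips = set(t.internal_bipartitions().values())
        assert frozenset({"C", "D"}) in bips
        for i, j in itertools.combinations(range(4), 2):
            assert t.path_length(taxa[i], taxa[j]) == pytest.approx(d[i, j])

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        t = phylo.nj_tree(phylo.DistanceMatrix(taxa=["a", "b", "c"], d=d))
        assert t.path_length("a", "b") == pytest.approx(2.0)
        assert t.path_length("a", "c") == pytest.approx(3.0)
        assert t.path_length("b", "c") == pytest.approx(5.0)

    def test_fewer_than_three_taxa_error(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError):
            phylo.nj_tree(phylo.DistanceMatrix(taxa=["a", "b"], d=d))

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_exact_on_random_additive_matrices(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        for _ in range(3):
            d = random_additive_tree(n_taxa, rng)
            taxa = [f"t{i}" for i in range(n_taxa)]
            t = phylo.nj_tree(phylo.DistanceMatrix(taxa=taxa, d=d))
            for i, j in itertools.combinations(range(n_taxa), 2):
                assert abs(t.path_length(taxa[i], taxa[j]) - d[i, j]) < 1e-9

    def test_ultrametric_matches_upgma_topology(self):
        from scipy.cluster.hierarchy import linkage, to_tree
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(7)
        # build an ultrametric matrix from a random UPGMA-style hierarchy
        n = 6
        pts = rng.normal(size=(n, 1))
        cond = np.abs(pts - pts.T)[np.triu_indices(n, 1)]
        Z = linkage(cond, method="average")
        # cophenetic distances are ultrametric by construction
        from scipy.cluster.hierarchy import cophenet
        d = squareform(cophenet(Z))
        taxa = [f"t{i}" for i in range(n)]
        t = phylo.nj_tree(phylo.DistanceMatrix(taxa=taxa, d=d))

        def scipy_bipartitions(Z, n):
            node = to_tree(Z)
            bips = set()

            def rec(nd):
                if nd.is_leaf():
                    return {f"t{nd.id}"}
                left, right = rec(nd.left), rec(nd.right)
                group = left | right
                if 1 < len(group) < n - 1:
                    bips.add(frozenset(group))
                return group

            rec(node)
            # canonicalize to the side not containing t0
            out = set()
            allt = frozenset(f"t{i}" for i in range(n))
            for b in bips:
                out.add(b if "t0" not in b else allt - b)
            return out

        assert set(t.internal_bipartitions().values()) == \
            scipy_bipartitions(Z, n)


class TestME:
    def test_additive_matrix_recovered_with_true_length(self):
        rng = np.random.default_rng(42)
        d = random_additive_tree(6, rng)
        taxa = [f"t{i}" for i in range(6)]
        dm = phylo.DistanceMatrix(taxa=taxa, d=d)
        me = phylo.me_tree(dm)
        expect = exhaustive_me_total(d)
        assert me.total_length() == pytest.approx(expect, abs=1e-8)
        for i, j in itertools.combinations(range(6), 2):
            assert abs(me.path_length(taxa[i], taxa[j]) - d[i, j]) < 1e-8

    def test_optimal_start_is_fixed_point(self):
        rng = np.random.default_rng(43)
        d = random_additive_tree(5, rng)
        dm = phylo.DistanceMatrix(taxa=[f"t{i}" for i in range(5)], d=d)
        nj = phylo.nj_tree(dm)
        me = phylo.me_tree(dm, start=nj)
        assert set(me.internal_bipartitions().values()) == \
            set(nj.internal_bipartitions().values())

    def test_me_never_longer_than_nj(self):
        rng = np.random.default_rng(44)
        d = random_additive_tree(5, rng)
        d += rng.uniform(0, 0.05, d.shape)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dm = phylo.DistanceMatrix(taxa=[f"t{i}" for i in range(5)], d=d)
        nj = phylo.nj_tree(dm)
        nj_fit = nj.copy()
        phylo.ols_branch_lengths(nj_fit, dm)
        me = phylo.me_tree(dm)
        assert me.total_length() <= nj_fit.total_length() + 1e-9


class TestBootstrap:
    MSA = [("A", "AAAAAAAAAACC"), ("B", "AAAAAAAAAACC"),
           ("C", "CCCCCCCCCCCC"), ("D", "CCCCCCCCCCAA")]

    def _builder(self, msa):
        return phylo.nj_tree(phylo.distance(msa, model="p"))

    def test_consistent_split_gets_full_support(self):
        t = phylo.bootstrap(self.MSA, 100, self._builder, seed=5)
        assert set(t.supports.values()) == {100.0}

    def test_deterministic_given_seed(self):
        t1 = phylo.bootstrap(self.MSA, 50, self._builder, seed=9)
        t2 = phylo.bootstrap(self.MSA, 50, self._builder, seed=9)
        assert t1.supports == t2.supports

    def test_supports_within_range(self):
        rng = np.random.default_rng(3)
        msa = [(f"t{i}", "".join(rng.choice(list("ACDE"), 30))) for i in range(5)]
        t = phylo.bootstrap(msa, 30, self._builder, seed=1)
        assert all(0.0 <= s <= 100.0 for s in t.supports.values())

    def test_zero_reps_error(self):
        with pytest.raises(ValueError):
            phylo.bootstrap(self.MSA, 0, self._builder, seed=0)


class TestNewick:
    def test_three_leaf_tree_single_line(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        t = phylo.nj_tree(phylo.DistanceMatrix(taxa=["a", "b", "c"], d=d))
        s = phylo.write_newick(t)
        assert s.endswith(";") and "\n" not in s

    def test_roundtrip_via_dendropy(self, tmp_path):
        import dendropy
        rng = np.random.default_rng(8)
        for n in (4, 6, 8):
            d = random_additive_tree(n, rng)
            taxa = [f"t{i}" for i in range(n)]
            t = phylo.nj_tree(phylo.DistanceMatrix(taxa=taxa, d=d))
            p = tmp_path / f"t{n}.nwk"
            phylo.write_newick(t, p)
            parsed = dendropy.Tree.get(path=str(p), schema="newick")
            pdm = parsed.phylogenetic_distance_matrix()
            tx = {x.label: x for x in parsed.taxon_namespace}
            for i, j in itertools.combinations(range(n), 2):
                got = pdm.patristic_distance(tx[taxa[i]], tx[taxa[j]])
                assert abs(got - d[i, j]) < 1e-9

    def test_supports_serialized_as_integers(self):
        t = phylo.bootstrap(TestBootstrap.MSA, 40,
                            lambda m: phylo.nj_tree(phylo.distance(m, "p")),
                            seed=2)
        s = t.newick()
        assert ")100:" in s


class TestProgressiveAlign:
    def test_identical_sequences_gapless(self):
        out = phylo.progressive_align(["MKLV", "MKLV"])
        assert out == ["MKLV", "MKLV"]

    def test_pairwise_score_matches_dp_oracle(self):
        out = phylo.progressive_align(["ACDE", "ACE"], gap_score=-4.0)
        a, b = out
        from Bio.Align import substitution_matrices
        b62 = substitution_matrices.load("BLOSUM62")
        score = sum(-4.0 if "-" in (x, y) else b62[x, y]
                    for x, y in zip(a, b))
        # oracle: full DP with the same scoring
        import numpy as np
        n, m = 4, 3
        D = np.zeros((n + 1, m + 1))
        D[:, 0] = np.arange(n + 1) * -4.0
        D[0, :] = np.arange(m + 1) * -4.0
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                D[i, j] = max(D[i - 1, j - 1] + b62["ACDE"[i - 1], "ACE"[j - 1]],
                              D[i - 1, j] - 4.0, D[i, j - 1] - 4.0)
        assert score == pytest.approx(D[n, m])

    def test_column_count_at_least_max_length(self):
        seqs = ["MKKLVI", "MKLV", "MKKLV"]
        out = phylo.progressive_align(seqs)
        assert len(out[0]) >= max(len(s) for s in seqs)
        for row, orig in zip(out, seqs):
            assert row.replace("-", "") == orig

    def test_dna_mode(self):
        out = phylo.progressive_align(["ACGTACGT", "ACGACGT", "ACGTACG"],
                                      alphabet="dna")
        assert all(len(r) == len(out[0]) for r in out)


def test_distance_tsv_roundtrip_and_phylip(tmp_path):
    d = np.array([[0, 1.5], [1.5, 0]])
    dm = phylo.DistanceMatrix(taxa=["a", "b"], d=d)
    p = tmp_path / "d.tsv"
    phylo.write_distance_tsv(dm, p)
    back = phylo.read_distance_tsv(p)
    assert back.taxa == ["a", "b"]
    assert np.allclose(back.d, d)
    phylip = tmp_path / "d.phy"
    phylip.write_text("2\na 0 1.5\nb 1.5 0\n")
    back2 = phylo.read_distance_tsv(phylip)
    assert np.allclose(back2.d, d)
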