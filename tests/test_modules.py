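import itertools

import networkx as nx
import numpy as np
import pytest

from ctsnet import (
    bh_adjust,
    candidate_modules,
    identify_modules,
    load_disease_genes,
    mapped_disease_genes,
    permutation_null,
    permutation_pvalue,
)
from conftest import make_ctn


def brute_force_bh(pvals):
    """Independent oracle: textbook step-up with monotonicity enforcement."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(1.0, pvals[i] * m / rank_from_top)
        running_min = min(running_min, val)
        adjusted[i] = running_min
    return adjusted


def exact_null_expectation(ctn, t):
    """Exact E[S_rand] by enumerating every C(|V|, t) draw."""
    g = ctn.network.to_networkx()
    verts = sorted(ctn.vertices)
    sizes = []
    for combo in itertools.combinations(verts, t):
        sub = g.subgraph(combo)
        sizes.append(max(len(c) for c in nx.connected_components(sub)))
    return np.mean(sizes)


class TestLoadDiseaseGenes:
    def test_dedupe_preserves_order(self, tmp_path):
        (tmp_path / "d.txt").write_text("A\nB\nB\nC\n")
        assert load_disease_genes(tmp_path / "d.txt") == ["A", "B", "C"]

    def test_comments_and_blanks_only_fatal(self, tmp_path):
        (tmp_path / "d.txt").write_text("# header\n\n   \n# more\n")
        with pytest.raises(ValueError, match="no genes"):
            load_disease_genes(tmp_path / "d.txt")

    def test_single_gene(self, tmp_path):
        (tmp_path / "d.txt").write_text("X\n")
        assert load_disease_genes(tmp_path / "d.txt") == ["X"]


class TestCandidateModules:
    def test_hand_enumeration(self):
        ctn = make_ctn(
            [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0), ("e", "f", 1.0)]
        )
        disease = ["a", "c", "d", "f"]
        assert mapped_disease_genes(ctn, disease) == ["a", "c", "d", "f"]
        mods = candidate_modules(ctn, disease, min_module_size=2)
        assert len(mods) == 1
        assert mods[0].genes == ("c", "d")
        assert mods[0].size == 2

    def test_singletons_with_min_size_one(self):
        ctn = make_ctn([("a", "b", 1.0), ("c", "d", 1.0)])
        mods = candidate_modules(ctn, ["a", "c"], min_module_size=1)
        assert [m.genes for m in mods] == [("a",), ("c",)]

    def test_no_disease_genes_in_network(self, caplog):
        ctn = make_ctn([("a", "b", 1.0)])
        with caplog.at_level("WARNING"):
            assert candidate_modules(ctn, ["x", "y"]) == []

    def test_full_vertex_disease_set(self):
        ctn = make_ctn([("a", "b", 1.0), ("b", "c", 1.0)])
        mods = candidate_modules(ctn, ["a", "b", "c"])
        assert len(mods) == 1
        assert mods[0].size == 3

    def test_isolated_network_vertices_count_toward_t(self):
        ctn = make_ctn([("a", "b", 1.0)], vertices={"a", "b", "z"})
        assert mapped_disease_genes(ctn, ["a", "z", "q"]) == ["a", "z"]


class TestPermutationNull:
    def test_full_draw_is_deterministic(self):
        ctn = make_ctn([("a", "b", 1.0), ("b", "c", 1.0), ("d", "e", 1.0)])
        null = permutation_null(ctn, t=5, n_perm=20, seed=0)
        assert (null.s_rand == 3).all()

    def test_single_gene_draw(self):
        ctn = make_ctn([("a", "b", 1.0), ("c", "d", 1.0)])
        null = permutation_null(ctn, t=1, n_perm=50, seed=0)
        assert (null.s_rand == 1).all()

    def test_triangle_pairs_always_connected(self):
        ctn = make_ctn([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
        null = permutation_null(ctn, t=2, n_perm=100, seed=0)
        assert (null.s_rand == 2).all()

    def test_t_exceeding_vertices_rejected(self):
        ctn = make_ctn([("a", "b", 1.0)])
        with pytest.raises(ValueError):
            permutation_null(ctn, t=3, n_perm=10, seed=0)

    def test_reproducible_given_seed(self):
        ctn = make_ctn(
            [(f"g{i}", f"g{i + 1}", 1.0) for i in range(9)]
        )
        a = permutation_null(ctn, t=4, n_perm=200, seed=7)
        b = permutation_null(ctn, t=4, n_perm=200, seed=7)
        np.testing.assert_array_equal(a.s_rand, b.s_rand)

    def test_empirical_mean_matches_enumeration(self):
        # path + triangle + isolated vertex, 8 vertices, t = 3
        ctn = make_ctn(
            [("a", "b", 1.0), ("b", "c", 1.0), ("d", "e", 1.0), ("e", "f", 1.0),
             ("d", "f", 1.0)],
            vertices={"a", "b", "c", "d", "e", "f", "g", "h"},
        )
        exact = exact_null_expectation(ctn, 3)
        null = permutation_null(ctn, t=3, n_perm=10000, seed=11)
        se = null.s_rand.std(ddof=1) / np.sqrt(null.n_perm)
        assert abs(null.s_rand.mean() - exact) < 3 * se


class TestPermutationPvalue:
    def test_fraction_strictly_greater(self):
        ctn = make_ctn([("a", "b", 1.0)], vertices={"a", "b", "c", "d"})
        null = permutation_null(ctn, t=2, n_perm=1000, seed=5)
        n_above = int((null.s_rand > 1).sum())
        assert permutation_pvalue(1, null) == n_above / 1000

    def test_sobs_at_maximum_gives_zero(self):
        ctn = make_ctn([("a", "b", 1.0), ("b", "c", 1.0)])
        null = permutation_null(ctn, t=3, n_perm=100, seed=0)
        assert permutation_pvalue(3, null) == 0.0

    def test_ties_do_not_count(self):
        ctn = make_ctn([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
        null = permutation_null(ctn, t=2, n_perm=100, seed=0)
        # every draw yields exactly s_rand = 2, so ties with s_obs = 2
        assert permutation_pvalue(2, null) == 0.0

    def test_pseudocount_estimator(self):
        ctn = make_ctn([("a", "b", 1.0), ("b", "c", 1.0)])
        null = permutation_null(ctn, t=3, n_perm=99, seed=0)
        assert permutation_pvalue(3, null, pseudocount=True) == 1 / 100

    def test_monotone_in_s_obs(self):
        ctn = make_ctn(
            [(f"g{i}", f"g{j}", 1.0) for i in range(8) for j in range(i + 1, 8)
             if (i + j) % 3 == 0],
            vertices={f"g{i}" for i in range(12)},
        )
        null = permutation_null(ctn, t=6, n_perm=500, seed=3)
        ps = [permutation_pvalue(s, null) for s in range(1, 7)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.05] * 4), [0.05] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            m = rng.integers(1, 30)
            p = rng.random(m)
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(list(p)), atol=1e-12)


class TestIdentifyModules:
    def small_inputs(self):
        ctn = make_ctn(
            [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0), ("x", "y", 1.0)],
            vertices={"a", "b", "c", "d", "x", "y"} | {f"z{i}" for i in range(30)},
        )
        return {"X": ctn}, ["a", "b", "c", "d", "x", "y"]

    def test_modules_found_and_annotated(self):
        ctns, disease = self.small_inputs()
        report = identify_modules(ctns, disease, n_perm=200, seed=1)
        assert list(report.table["size"]) == [4, 2]
        assert (report.table["T"] == 6).all()
        assert (report.table["q_fdr"] >= report.table["p_perm"]).all()
        # big module in a sparse background should beat the null easily
        assert report.table.iloc[0]["p_perm"] <= report.table.iloc[1]["p_perm"]

    def test_p_values_are_multiples_of_grid(self):
        ctns, disease = self.small_inputs()
        report = identify_modules(ctns, disease, n_perm=250, seed=2)
        ps = report.table["p_perm"].to_numpy()
        np.testing.assert_allclose(np.round(ps * 250), ps * 250, atol=1e-9)

    def test_no_candidates_gives_empty_report(self):
        ctn = make_ctn([("a", "b", 1.0)], vertices={"a", "b", "c"})
        report = identify_modules({"X": ctn}, ["zz"], n_perm=10, seed=1)
        assert report.table.empty

    def test_reports_are_byte_identical_across_runs(self, tmp_path):
        ctns, disease = self.small_inputs()
        for d in ("r1", "r2"):
            identify_modules(ctns, disease, n_perm=100, seed=9).write(tmp_path / d)
        assert (tmp_path / "r1" / "module_report.tsv").read_bytes() == (
            tmp_path / "r2" / "module_report.tsv"
        ).read_bytes()

    def test_single_type_run_matches_multi_type_slice(self):
        ctns, disease = self.small_inputs()
        ctns["Y"] = make_ctn(
            [("a", "b", 1.0)], cell_type="Y", vertices={"a", "b", "c", "d"}
        )
        multi = identify_modules(ctns, disease, n_perm=150, seed=4)
        solo = identify_modules({"X": ctns["X"]}, disease, n_perm=150, seed=4)
        multi_x = multi.table[multi.table["cell_type"] == "X"].reset_index(drop=True)
        np.testing.assert_array_equal(
            multi_x["p_perm"].to_numpy(), solo.table["p_perm"].to_numpy()
        )

    def test_per_cell_type_fdr_scope(self):
        ctns, disease = self.small_inputs()
        report = identify_modules(
            ctns, disease, n_perm=100, seed=1, fdr_scope="per-cell-type"
        )
        assert (report.table["q_fdr"] >= report.table["p_perm"]).all()
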