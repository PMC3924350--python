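"""Signed coexpression: similarity, TOM, modules, eigengenes, trait statistics."""

import numpy as np
import pandas as pd
import pytest

from mirweave.expression import ExpressionMatrix
from mirweave.wgcna import (AdjacencyMatrix, SimilarityMatrix, cor_pvalue_student,
                            detect_modules, extract_hub_network,
                            module_eigengenes, module_overlap,
                            pick_soft_threshold, relate_to_traits,
                            scale_free_fit, signed_similarity, soft_adjacency,
                            topological_overlap)
from conftest import hypergeom_tail_comb, make_matrix, tom_bruteforce


class TestSignedSimilarity:
    def test_correlation_extremes(self):
        x = np.array([1.0, 2, 3, 4, 5])
        m = make_matrix(np.vstack([x, 2 * x + 1, -x, 0.5 - x]), prefix="g")
        S = signed_similarity(m)
        assert S.values[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert S.values[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert S.values[2, 3] == pytest.approx(1.0, abs=1e-12)

    def test_uncorrelated_pair_half(self):
        x = np.array([1.0, -1, 1, -1])
        y = np.array([1.0, 1, -1, -1])
        S = signed_similarity(make_matrix(np.vstack([x, y]), prefix="g"))
        assert S.values[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_zero_variance_gene_dropped_with_warning(self):
        m = make_matrix(np.vstack([[1.0, 2, 3, 4], [5, 5, 5, 5]]), prefix="g")
        with pytest.warns(UserWarning, match="zero-variance"):
            S = signed_similarity(m)
        assert S.genes == ["g0"]


class TestSoftAdjacency:
    def test_powers(self):
        S = SimilarityMatrix(genes=["a", "b"],
                             values=np.array([[1.0, 0.5], [0.5, 1.0]]))
        A = soft_adjacency(S, beta=12)
        assert A.values[0, 1] == pytest.approx(0.5 ** 12, rel=1e-12)
        assert A.values[0, 0] == 1.0

    def test_monotone_in_similarity(self):
        rng = np.random.default_rng(0)
        s = np.sort(rng.random(50))
        a = s ** 7
        assert np.all(np.diff(a) >= 0)


class TestTopologicalOverlap:
    def _toy(self):
        a = np.array([[1.0, 0.8, 0.6], [0.8, 1.0, 0.0], [0.6, 0.0, 1.0]])
        return AdjacencyMatrix(genes=["g0", "g1", "g2"], values=a, beta=1)

    def test_hand_computed_values(self):
        tom = topological_overlap(self._toy())
        assert tom.values[1, 2] == pytest.approx(0.48 / 1.6, abs=1e-12)
        assert tom.values[0, 1] == pytest.approx(0.8 / 1.0, abs=1e-12)
        assert np.all(np.diag(tom.values) == 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.random((20, 20))
        a = ((s + s.T) / 2) ** 3
        np.fill_diagonal(a, 1.0)
        adj = AdjacencyMatrix(genes=[f"g{i}" for i in range(20)], values=a,
                              beta=3)
        tom = topological_overlap(adj)
        ref = tom_bruteforce(a)
        np.testing.assert_allclose(tom.values, ref, atol=1e-12)

    def test_bounds_and_symmetry(self):
        tom = topological_overlap(self._toy())
        assert np.all(tom.values >= 0) and np.all(tom.values <= 1)
        np.testing.assert_allclose(tom.values, tom.values.T, atol=1e-15)


class TestScaleFreeFit:
    def _heavy_tailed_similarity(self, n=400, seed=3):
        rng = np.random.default_rng(seed)
        w = rng.pareto(2.0, n) + 0.5
        w /= w.max()
        S = np.sqrt(np.outer(w, w))
        np.fill_diagonal(S, 1.0)
        return SimilarityMatrix(genes=[f"g{i}" for i in range(n)], values=S)

    def test_heavy_tailed_network_fits_well(self):
        sim = self._heavy_tailed_similarity()
        df = pick_soft_threshold(sim, beta_grid=(1, 2, 3, 4, 6, 8),
                                 r2_target=0.8)
        chosen = df.attrs["beta"]
        assert df.loc[df["beta"] == chosen, "r_squared"].iloc[0] >= 0.8
        # smallest beta reaching the target wins
        reaching = df[df["r_squared"] >= 0.8]
        assert chosen == reaching["beta"].iloc[0]

    def test_degenerate_connectivity_reports_zero(self):
        S = SimilarityMatrix(genes=["a", "b", "c"],
                             values=np.full((3, 3), 0.4) + 0.6 * np.eye(3))
        r2, slope, _ = scale_free_fit(soft_adjacency(S, 2))
        assert r2 == 0.0

    def test_single_beta_grid(self):
        sim = self._heavy_tailed_similarity(n=100)
        df = pick_soft_threshold(sim, beta_grid=(5,), r2_target=0.99)
        assert df.attrs["beta"] == 5

    def test_mean_connectivity_decreases_with_beta(self):
        sim = self._heavy_tailed_similarity(n=100)
        df = pick_soft_threshold(sim, beta_grid=(1, 2, 4, 8))
        assert np.all(np.diff(df["mean_k"]) < 0)


class TestDetectModules:
    def test_two_separable_blocks(self):
        n = 12
        d = np.ones((n, n))
        d[:6, :6] = 0.0
        d[6:, 6:] = 0.0
        np.fill_diagonal(d, 0.0)
        labels = detect_modules(d, [f"g{i}" for i in range(n)],
                                min_module_size=3, cut_height=0.99)
        groups = {}
        for g, m in labels.items():
            groups.setdefault(m, set()).add(g)
        assert "grey" not in groups
        assert sorted(len(v) for v in groups.values()) == [6, 6]

    def test_oversized_min_module_all_grey(self):
        d = np.zeros((4, 4))
        with pytest.warns(UserWarning, match="min_module_size"):
            labels = detect_modules(d, list("abcd"), min_module_size=10)
        assert set(labels.values()) == {"grey"}

    def test_all_noise_mostly_grey(self):
        rng = np.random.default_rng(21)
        m = make_matrix(rng.normal(0, 1, size=(300, 32)), prefix="g")
        S = signed_similarity(m)
        tom = topological_overlap(soft_adjacency(S, 12))
        labels = detect_modules(tom.dissimilarity, tom.genes,
                                min_module_size=30, cut_height=0.99,
                                expression=m)
        grey = sum(v == "grey" for v in labels.values())
        assert grey / len(labels) >= 0.9

    def test_size_ordered_color_names(self):
        n = 20
        d = np.ones((n, n))
        d[:12, :12] = 0.0
        d[12:, 12:] = 0.0
        np.fill_diagonal(d, 0.0)
        labels = detect_modules(d, [f"g{i}" for i in range(n)],
                                min_module_size=3, cut_height=0.99)
        big = {g for g, m in labels.items() if m == "turquoise"}
        small = {g for g, m in labels.items() if m == "blue"}
        assert len(big) == 12 and len(small) == 8


class TestModuleEigengenes:
    def test_identical_genes_give_shared_profile(self):
        x = np.array([1.0, 3, 2, 5, 4, 6])
        m = make_matrix(np.vstack([x, x, x]), prefix="g")
        labels = {"g0": "blue", "g1": "blue", "g2": "blue"}
        eig = module_eigengenes(m, labels)
        z = (x - x.mean()) / x.std()
        me = eig.loc["blue"].to_numpy()
        np.testing.assert_allclose(me / np.linalg.norm(me),
                                   z / np.linalg.norm(z), atol=1e-10)

    def test_equals_first_right_singular_vector(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, size=(8, 10))
        m = make_matrix(vals, prefix="g")
        labels = {f"g{i}": "red" for i in range(8)}
        eig = module_eigengenes(m, labels)
        z = (vals - vals.mean(1, keepdims=True)) / vals.std(1, keepdims=True)
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = eig.loc["red"].to_numpy()
        assert min(np.linalg.norm(me - vt[0]),
                   np.linalg.norm(me + vt[0])) < 1e-10

    def test_sign_convention(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            vals = np.random.default_rng(seed).normal(0, 1, (6, 12))
            m = make_matrix(vals, prefix="g")
            eig = module_eigengenes(m, {f"g{i}": "m" for i in range(6)})
            z = (vals - vals.mean(1, keepdims=True)) / vals.std(1, keepdims=True)
            assert np.dot(eig.loc["m"], z.mean(0)) >= 0

    def test_eigengene_variance_maximality(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, size=(10, 14))
        m = make_matrix(vals, prefix="g")
        eig = module_eigengenes(m, {f"g{i}": "m" for i in range(10)})
        z = (vals - vals.mean(1, keepdims=True)) / vals.std(1, keepdims=True)
        me = eig.loc["m"].to_numpy()
        var_me = np.var(z @ me)
        for row in z:
            u = row / np.linalg.norm(row)
            assert var_me >= np.var(z @ u) - 1e-10


class TestCorPvalue:
    @pytest.mark.parametrize("r, n, expected", [
        (0.63, 32, 1.08e-4),
        (-0.74, 32, 1.35e-6),
        (-0.63, 32, 1.08e-4),
    ])
    def test_printed_module_trait_pvalues(self, r, n, expected):
        assert cor_pvalue_student(r, n) == pytest.approx(expected, rel=0.10)

    def test_null_and_perfect(self):
        assert cor_pvalue_student(0.0, 20) == 1.0
        assert cor_pvalue_student(1.0, 20) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            cor_pvalue_student(0.5, 2)


class TestRelateToTraits:
    def _setup(self):
        rng = np.random.default_rng(7)
        trait = rng.normal(0, 1, 16)
        vals = rng.normal(0, 1, size=(6, 16))
        vals[0] = trait  # gene identical to the trait
        m = make_matrix(vals, prefix="g")
        labels = {f"g{i}": ("blue" if i < 3 else "grey") for i in range(6)}
        eig = module_eigengenes(m, labels)
        tr = pd.Series(trait, index=m.sample_ids)
        return m, eig, tr, labels

    def test_gene_equal_to_trait_gs_one(self):
        m, eig, tr, labels = self._setup()
        rel = relate_to_traits(m, eig, tr, labels=labels)
        assert rel["gene_stats"].loc["g0", "GS"] == pytest.approx(1.0, abs=1e-10)

    def test_sample_mismatch_rejected(self):
        m, eig, tr, labels = self._setup()
        with pytest.raises(ValueError, match="missing"):
            relate_to_traits(m, eig, tr.iloc[:4], labels=labels)

    def test_mirna_grid_bh_flags(self):
        m, eig, tr, labels = self._setup()
        prof = pd.DataFrame(np.vstack([tr.to_numpy(), -tr.to_numpy()]),
                            index=["mir-a", "mir-b"], columns=m.sample_ids)
        rel = relate_to_traits(m, eig, tr, mirna_profiles=prof, labels=labels)
        grid = rel["module_mirna"]
        assert set(grid["mirna_id"]) == {"mir-a", "mir-b"}
        assert np.all(grid["adj_p"] >= grid["p"] - 1e-12)

    def test_planted_module_eigengene_tracks_trait(self, default_dataset):
        _, mrna, traits, _, truth = default_dataset
        labels = {g: truth.module_labels[g] for g in mrna.feature_ids}
        labels = {g: (m if m != "noise" else "grey") for g, m in labels.items()}
        eig = module_eigengenes(mrna, labels)
        rel = relate_to_traits(mrna, eig, traits["consumption"], labels=labels)
        mt = rel["module_trait"]
        # strongest planted module (|rho| = 0.6) keeps a strong ME-trait r
        assert mt["r"].abs().max() >= 0.5


class TestModuleOverlap:
    def test_identical_assignments_diagonal_minimal(self):
        labels = {f"g{i}": ("a" if i < 6 else "b") for i in range(12)}
        df = module_overlap(labels, labels)
        for mod in ("a", "b"):
            sub = df[df["module_a"] == mod]
            diag = sub[sub["module_b"] == mod]["p"].iloc[0]
            assert diag == sub["p"].min()

    def test_cell_p_matches_enumeration(self):
        labels_a = {f"g{i}": ("a" if i < 5 else "b") for i in range(10)}
        labels_b = {f"g{i}": ("x" if i % 2 else "y") for i in range(10)}
        df = module_overlap(labels_a, labels_b)
        for _, row in df.iterrows():
            expected = hypergeom_tail_comb(int(row["overlap"]), 10,
                                           int(row["size_a"]),
                                           int(row["size_b"]))
            assert row["p"] == pytest.approx(expected, abs=1e-12)

    def test_random_assignments_rarely_significant(self):
        rng = np.random.default_rng(9)
        sig_fracs = []
        for _ in range(10):
            la = {f"g{i}": f"m{rng.integers(4)}" for i in range(200)}
            lb = {f"g{i}": f"n{rng.integers(4)}" for i in range(200)}
            df = module_overlap(la, lb)
            sig_fracs.append((df["adj_p"] < 0.10).mean())
        assert np.mean(sig_fracs) <= 0.10


class TestHubNetwork:
    def _gene_stats(self, mm, gs):
        return pd.DataFrame({
            "module": ["red"] * len(mm),
            "MM": mm,
            "GS": gs,
        }, index=[f"g{i}" for i in range(len(mm))])

    def _adjacency(self, a):
        return AdjacencyMatrix(genes=[f"g{i}" for i in range(a.shape[0])],
                               values=a, beta=1)

    def test_boundary_strictly_excluded(self):
        stats = self._gene_stats([0.5, 0.9, 0.8], [0.9, 0.9, 0.9])
        a = np.eye(3)
        out = extract_hub_network(stats, self._adjacency(a), "red")
        assert "g0" not in out["genes"]
        assert set(out["genes"]) == {"g1", "g2"}

    def test_hub_is_highest_connectivity(self):
        a = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, 0.1], [0.9, 0.1, 1.0]])
        stats = self._gene_stats([0.9, 0.9, 0.9], [0.9, 0.9, 0.9])
        out = extract_hub_network(stats, self._adjacency(a), "red")
        assert out["hub"] == "g0"
        assert out["connectivity"]["g0"] == pytest.approx(1.8)

    def test_impossible_threshold_empty(self):
        stats = self._gene_stats([0.9, 0.9], [0.9, 0.9])
        with pytest.warns(UserWarning, match="no gene"):
            out = extract_hub_network(stats, self._adjacency(np.eye(2)),
                                      "red", gs_min=1.0)
        assert out["hub"] is None and out["genes"] == []
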