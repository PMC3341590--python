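import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import exprmap as em
from exprmap.errors import ExprMapError, IncomparableGeneError
from exprmap.som import INCOMPARABLE, schedule


def matrix_from(values, exp="e1"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                      columns=[f"c{j}" for j in range(values.shape[1])])
    return em.ExpressionMatrix(df, {c: exp for c in df.columns})


class TestSimilarity:
    def test_self_correlation_is_one(self):
        assert em.similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_hand_expanded_pearson(self):
        # means 2 and 7/3; Σuᶜvᶜ = 3, Σuᶜ² = 2, Σvᶜ² = 42/9 → r = 9/√84
        assert em.similarity([1, 2, 3], [1, 2, 4]) == pytest.approx(9 / math.sqrt(84))

    def test_missing_components_excluded(self):
        u = [1.0, np.nan, 3.0, 4.0]
        v = [0.0, 7.0, 2.0, 3.0]
        expected = stats.pearsonr([1, 3, 4], [0, 2, 3]).statistic
        assert em.similarity(u, v) == pytest.approx(expected)

    def test_overlap_below_min_is_incomparable(self):
        u = [1.0, np.nan, np.nan, 4.0]
        assert em.similarity(u, [0, 1, 2, 3], min_overlap=3) == INCOMPARABLE
        assert em.similarity(u, [0, 1, 2, 3], min_overlap=2) != INCOMPARABLE

    def test_zero_variance_is_incomparable(self):
        assert em.similarity([2, 2, 2], [1, 2, 3]) == INCOMPARABLE
        assert em.similarity([1, 2, 3], [5, 5, 5]) == INCOMPARABLE

    def test_euclidean_normalized_by_overlap(self):
        # distance √2 over an overlap of 2 components (3rd is missing)
        u = [0.0, 0.0, np.nan, 1.0]
        v = [1.0, 0.0, 5.0, 0.0]
        got = em.similarity(u, v, metric="euclidean", min_overlap=2)
        assert got == pytest.approx(-math.sqrt(2) / math.sqrt(3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ExprMapError, match="length"):
            em.similarity([1, 2], [1, 2, 3])


class TestSchedule:
    def test_linear_decay_to_zero(self):
        total, lr0, r0 = 10, 0.1, 10.0
        alphas, radii = zip(*(schedule(t, total, lr0, r0) for t in range(total + 1)))
        np.testing.assert_allclose(alphas, lr0 * (1 - np.arange(11) / 10))
        np.testing.assert_allclose(radii, r0 * (1 - np.arange(11) / 10))
        assert alphas[-1] == 0.0 and radii[-1] == 0.0
        assert all(a >= b for a, b in zip(alphas, alphas[1:]))


class TestInitMap:
    def test_components_within_observed_range(self, tiny_matrix):
        cfg = em.SomConfig(width=4, height=3, seed=1)
        som = em.init_map(cfg, tiny_matrix)
        lo = tiny_matrix.values.min(axis=0).to_numpy()
        hi = tiny_matrix.values.max(axis=0).to_numpy()
        assert (som.weights >= lo).all() and (som.weights <= hi).all()

    def test_seed_determinism_and_variation(self, tiny_matrix):
        cfg = em.SomConfig(width=4, height=3, seed=5)
        a = em.init_map(cfg, tiny_matrix)
        b = em.init_map(cfg, tiny_matrix)
        np.testing.assert_array_equal(a.weights, b.weights)
        for other_seed in range(6, 16):
            other = em.init_map(em.SomConfig(width=4, height=3, seed=other_seed),
                                tiny_matrix)
            assert not np.array_equal(a.weights, other.weights)

    def test_unobserved_condition_rejected(self):
        df = pd.DataFrame([[1.0, np.nan], [2.0, np.nan]],
                          index=["g1", "g2"], columns=["c1", "c2"])
        m = em.ExpressionMatrix(df, {"c1": "e", "c2": "e"})
        with pytest.raises(ExprMapError, match="c2"):
            em.init_map(em.SomConfig(width=2, height=2, seed=0), m)


class TestTraining:
    def test_single_node_converges_to_profile(self):
        # 1×1 map, one gene: training is the scalar recursion
        # w ← w + α(t)(x − w); iterate it independently as the oracle.
        m = matrix_from([[1.0, -2.0, 0.5, 3.0]])
        cfg = em.SomConfig(width=1, height=1, presentations_per_gene=200,
                           seed=3, min_overlap=3)
        som = em.train(m, cfg)
        x = m.values.to_numpy()[0]
        w = em.init_map(cfg, m).weights[0, 0].copy()
        total = 200
        for t in range(total):
            alpha = cfg.lr0 * (1 - t / total)
            w = w + alpha * (x - w)
        np.testing.assert_allclose(som.weights[0, 0], w, rtol=0, atol=1e-12)
        np.testing.assert_allclose(som.weights[0, 0], x, atol=1e-3)

    @pytest.mark.parametrize("lr0", [0.05, 0.5, 1.0])
    def test_update_never_overshoots_input(self, lr0):
        # single presentation: w′ must lie between w and x componentwise
        m = matrix_from([[2.0, -1.0, 0.0, 4.0]])
        cfg = em.SomConfig(width=1, height=1, presentations_per_gene=1,
                           lr0=lr0, seed=9)
        w0 = em.init_map(cfg, m).weights[0, 0].copy()
        w1 = em.train(m, cfg).weights[0, 0]
        x = m.values.to_numpy()[0]
        lo, hi = np.minimum(w0, x), np.maximum(w0, x)
        assert ((w1 >= lo - 1e-12) & (w1 <= hi + 1e-12)).all()

    def test_missing_components_never_updated(self):
        # independent pure-Python replay of the documented procedure on a
        # 1×1 map (the BMU is always the single node): missing components
        # of the presented profile must leave the node component unchanged
        df = pd.DataFrame([[1.0, np.nan, 3.0], [0.0, 5.0, 1.0]],
                          index=["g0", "g1"], columns=["c0", "c1", "c2"])
        m = em.ExpressionMatrix(df, {c: "e1" for c in df.columns})
        cfg = em.SomConfig(width=1, height=1, presentations_per_gene=25,
                           seed=2, min_overlap=2)
        som = em.train(m, cfg)
        w = em.init_map(cfg, m).weights[0, 0].copy()
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
        total = 50
        draws = rng.integers(0, 2, size=total)
        vals = df.to_numpy()
        for t, g in enumerate(draws):
            alpha = cfg.lr0 * (1 - t / total)
            x = vals[g]
            obs = ~np.isnan(x)
            w[obs] += alpha * (x[obs] - w[obs])
        np.testing.assert_allclose(som.weights[0, 0], w, rtol=0, atol=1e-12)
        assert np.isfinite(som.weights).all()

    def test_bitwise_determinism(self, synthetic_data):
        matrix, _ = synthetic_data
        sub = em.ExpressionMatrix(matrix.values.iloc[:120], matrix.experiment_of)
        cfg = em.SomConfig(width=6, height=4, seed=17)
        a, b = em.train(sub, cfg), em.train(sub, cfg)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.assignment == b.assignment

    def test_incomparable_gene_raises_with_name(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0, 4.0],
                           [np.nan, np.nan, np.nan, 1.0]],
                          index=["g_ok", "g_bad"],
                          columns=["c0", "c1", "c2", "c3"])
        m = em.ExpressionMatrix(df, {c: "e1" for c in df.columns})
        cfg = em.SomConfig(width=2, height=2, presentations_per_gene=20, seed=0)
        with pytest.raises(IncomparableGeneError, match="g_bad"):
            em.train(m, cfg)

    def test_planted_profiles_land_close(self):
        spec = em.SyntheticSpec(n_genes=160, n_clusters=4, noise_sd=0.1,
                                missing_rate=0.0, seed=11)
        matrix, truth = em.generate_matrix(spec)
        matrix = em.median_shift(matrix)
        som = em.train(matrix, em.SomConfig(width=7, height=6, seed=11))
        pos = som.positions(matrix.gene_ids)
        cl = np.array([truth.cluster_of[g] for g in matrix.gene_ids])
        close = total = 0
        for c in range(4):
            p = pos[cl == c]
            d = np.abs(p[:, None, :] - p[None, :, :]).sum(-1)
            iu = np.triu_indices(len(p), k=1)
            close += (d[iu] <= 3).sum()
            total += len(iu[0])
        assert close / total >= 0.90

    @pytest.mark.parametrize("seed", range(5))
    def test_intra_cluster_distance_below_inter(self, seed):
        spec = em.SyntheticSpec(n_genes=300, n_clusters=4, seed=seed)
        matrix, truth = em.generate_matrix(spec)
        matrix = em.median_shift(matrix)
        som = em.train(matrix, em.SomConfig(width=10, height=8, seed=seed))
        pos = som.positions(matrix.gene_ids)
        cl = np.array([truth.cluster_of[g] for g in matrix.gene_ids])
        d = np.abs(pos[:, None, :] - pos[None, :, :]).sum(-1)
        same = cl[:, None] == cl[None, :]
        iu = np.triu_indices(len(cl), k=1)
        assert d[iu][same[iu]].mean() < d[iu][~same[iu]].mean()


class TestAssignment:
    def make_map(self, weights, assignment=None):
        h, w, c = weights.shape
        return em.SomMap(config=em.SomConfig(width=w, height=h, seed=0),
                         condition_ids=[f"c{j}" for j in range(c)],
                         weights=weights, assignment=assignment or {})

    def test_gene_matching_node_vector_lands_there(self):
        rng = np.random.default_rng(4)
        weights = rng.normal(size=(3, 4, 6))
        som = self.make_map(weights)
        target = weights[2, 3]
        m = matrix_from([target])
        assert em.assign(m, som)["g0"] == (3, 2)

    def test_identical_profiles_share_a_node(self, trained_map, synthetic_data):
        matrix, _ = synthetic_data
        profile = matrix.values.iloc[0].to_numpy()
        dup = em.ExpressionMatrix(
            pd.DataFrame([profile, profile], index=["a", "b"],
                         columns=matrix.condition_ids),
            matrix.experiment_of)
        got = em.assign(dup, trained_map)
        assert got["a"] == got["b"]

    def test_tie_break_smallest_y_then_x(self):
        # two identical node vectors at (1, 0) and (0, 1): (1, 0) wins (y first)
        base = np.array([[1.0, 2.0, 3.0]])
        weights = np.tile(np.array([3.0, 1.0, 2.0]), (2, 2, 1))
        weights[0, 1] = base
        weights[1, 0] = base
        som = self.make_map(weights)
        m = matrix_from(base)
        assert em.assign(m, som)["g0"] == (1, 0)


class TestNodeSummary:
    def test_counts_conserved_and_empty_nodes_listed(self, trained_map):
        summary = em.node_summary(trained_map)
        assert len(summary) == trained_map.config.n_nodes
        assert summary["n_genes"].sum() == len(trained_map.assignment)
        assert (summary["n_genes"] >= 0).all()

    def test_empty_node_reported_with_zero(self):
        cfg = em.SomConfig(width=2, height=2, seed=0)
        som = em.SomMap(config=cfg, condition_ids=["c0", "c1"],
                        weights=np.zeros((2, 2, 2)),
                        assignment={"g1": (0, 0), "g2": (0, 0), "g3": (1, 1)})
        summary = em.node_summary(som)
        assert len(summary) == 4
        row = summary[(summary.x == 1) & (summary.y == 0)].iloc[0]
        assert row.n_genes == 0
        assert summary["n_genes"].sum() == 3


class TestTopologyReproducibility:
    def test_coclustering_beats_chance_across_reseeded_maps(self, synthetic_data):
        matrix, _ = synthetic_data
        sub = em.ExpressionMatrix(matrix.values.iloc[:400], matrix.experiment_of)
        maps = [em.train(sub, em.SomConfig(width=10, height=8, seed=s))
                for s in range(5)]
        main, alts = maps[0], maps[1:]
        res = em.cocluster_reproducibility(main, alts, n_pairs=4000, seed=0)
        # chance oracle: shuffle each alternate's assignments by permutation
        rng = np.random.default_rng(123)
        shuffled = []
        for alt in alts:
            genes = list(alt.assignment)
            perm = rng.permutation(len(genes))
            coords = list(alt.assignment.values())
            shuffled.append(em.SomMap(
                config=alt.config, condition_ids=alt.condition_ids,
                weights=alt.weights,
                assignment={genes[i]: coords[perm[i]] for i in range(len(genes))}))
        null = em.cocluster_reproducibility(main, shuffled, n_pairs=4000, seed=0)
        assert res.frac_near > null.frac_near
        assert res.frac_same > null.frac_same
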