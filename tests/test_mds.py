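"""Similarity aggregation, nonmetric MDS, Procrustes and the Error statistic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from contourcues import CueVector
from contourcues.mds import (
    DissimilarityMatrix,
    aggregate_dissimilarity,
    compare_factor_sets,
    kruskal_stress,
    nonmetric_mds,
    normalized_error,
    procrustes_error,
    topographic_config,
)


def _euclid_dissim(points, ids=None):
    points = np.asarray(points, dtype=float)
    ids = ids or list(range(len(points)))
    return DissimilarityMatrix(squareform(pdist(points)), ids=ids)


def _trials(ratings_by_pair):
    rows = [("o1", a, b, rep, r)
            for (a, b), rs in ratings_by_pair.items() for rep, r in enumerate(rs)]
    return pd.DataFrame(rows, columns=["observer_id", "stimulus_a", "stimulus_b",
                                       "repetition", "rating"])


class TestAggregateDissimilarity:
    def test_identical_looking_gives_zero(self):
        d = aggregate_dissimilarity(_trials({("a", "b"): [5, 5], ("a", "c"): [5],
                                             ("b", "c"): [5]}))
        assert np.allclose(d.values, 0)

    def test_repeated_low_rating(self):
        d = aggregate_dissimilarity(_trials({("a", "b"): [1, 1, 1, 1]}))
        assert d.values[0, 1] == pytest.approx(4.0)

    def test_missing_pair_is_named(self):
        with pytest.raises(ValueError, match="'a'.*'c'"):
            aggregate_dissimilarity(_trials({("a", "b"): [3], ("b", "c"): [3]}))

    def test_54_stimuli_cover_1431_pairs(self):
        ids = [f"s{k:02d}" for k in range(54)]
        pairs = list(itertools.combinations(ids, 2))
        assert len(pairs) == 1431
        d = aggregate_dissimilarity(_trials({p: [3] for p in pairs}))
        assert d.n == 54
        iu = np.triu_indices(54, k=1)
        assert len(d.values[iu]) == 1431


class TestKruskalStress:
    def test_zero_for_rank_preserving_config(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(15, 2))
        assert kruskal_stress(pts, _euclid_dissim(pts)) < 1e-9

    def test_zero_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(15, 2))
        d = DissimilarityMatrix(squareform(pdist(pts)) ** 2, ids=list(range(15)))
        assert kruskal_stress(pts, d) < 1e-9

    def test_positive_for_random_configuration(self):
        rng = np.random.default_rng(2)
        d = _euclid_dissim(rng.normal(size=(12, 2)))
        assert kruskal_stress(rng.normal(size=(12, 1)), d) > 0.05

    def test_invariant_under_similarity_transform(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 2))
        d = _euclid_dissim(rng.normal(size=(12, 2)))
        s0 = kruskal_stress(pts, d)
        ang = 1.1
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        assert kruskal_stress(2.5 * pts @ rot + 7.0, d) == pytest.approx(s0, abs=1e-12)
        assert kruskal_stress(pts[:, ::-1], d) == pytest.approx(s0, abs=1e-12)

    def test_degenerate_configuration_raises(self):
        d = _euclid_dissim(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            kruskal_stress(np.ones((5, 2)), d)


class TestNonmetricMDS:
    def test_planted_2d_recovery(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(20, 2))
        cfg = nonmetric_mds(_euclid_dissim(pts), dims=2, seed=0)
        assert cfg.stress < 0.01
        scale = float(np.sum((pts - pts.mean(0)) ** 2))
        assert procrustes_error(pts, cfg.points) < 1e-3 * scale

    def test_stress_decreases_with_dimension(self):
        rng = np.random.default_rng(5)
        d = _euclid_dissim(rng.normal(size=(14, 3)))
        stresses = [nonmetric_mds(d, dims=k, seed=1).stress for k in (1, 2, 3)]
        assert stresses[0] >= stresses[1] - 1e-3
        assert stresses[1] >= stresses[2] - 1e-3

    def test_too_few_points_raises(self):
        d = _euclid_dissim(np.random.default_rng(0).normal(size=(3, 2)))
        with pytest.raises(ValueError):
            nonmetric_mds(d, dims=2, seed=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(6)
        d = _euclid_dissim(rng.normal(size=(10, 2)))
        a = nonmetric_mds(d, dims=2, seed=3)
        b = nonmetric_mds(d, dims=2, seed=3)
        assert np.array_equal(a.points, b.points)


class TestTopographicConfig:
    def _cues(self, vals):
        return [CueVector(cv, cl, sy, 1) for cv, cl, sy in vals]

    def test_single_factor_standardized(self):
        cues = self._cues([(0.1, -4, 0.2), (0.2, 0, 0.1), (0.0, 4, -0.3)])
        cfg = topographic_config(cues, {"closure"})
        assert cfg.shape == (3, 1)
        assert cfg.mean() == pytest.approx(0.0, abs=1e-12)
        assert cfg.std() == pytest.approx(1.0)

    def test_two_factor_config(self):
        cues = self._cues([(0.1, -4, 0.2), (0.2, 0, 0.1), (0.0, 4, -0.3)])
        assert topographic_config(cues, ("convexity", "closure")).shape == (3, 2)

    def test_zero_variance_factor_raises(self):
        cues = self._cues([(0.1, 0, 0.2), (0.2, 0, 0.1), (0.0, 0, -0.3)])
        with pytest.raises(ValueError, match="zero variance"):
            topographic_config(cues, {"closure"})

    def test_empty_factor_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            topographic_config(self._cues([(0.1, 0, 0.0)]), set())


class TestProcrustesError:
    def test_similarity_transformed_copy_is_exact(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10, 2))
        ang = 0.6
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        assert procrustes_error(pts, 3.2 * pts @ rot + 5.0) < 1e-18

    def test_reflection_is_allowed(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 2))
        assert procrustes_error(pts, pts[:, ::-1]) < 1e-18

    def test_collinear_closed_form(self):
        # P = (0,1,3), T = (0,1,2) in 1D: after centering, the optimal scale
        # is sum(p t)/sum(t^2) = 3/2 and the residual is
        # sum(p^2) - (sum(p t))^2 / sum(t^2) = 42/9 - 9/2 = 1/6
        p = np.array([[0.0], [1.0], [3.0]])
        t = np.array([[0.0], [1.0], [2.0]])
        assert procrustes_error(p, t) == pytest.approx(1.0 / 6.0, abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            procrustes_error(np.zeros((3, 2)), np.zeros((4, 2)))

    def test_symmetric_after_unit_normalization(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = rng.normal(size=(8, 2))
            b = rng.normal(size=(8, 2))
            a = (a - a.mean(0)) / np.linalg.norm(a - a.mean(0))
            b = (b - b.mean(0)) / np.linalg.norm(b - b.mean(0))
            assert procrustes_error(a, b) == pytest.approx(procrustes_error(b, a),
                                                           abs=1e-9)


class TestNormalizedError:
    def test_own_points_give_zero(self):
        rng = np.random.default_rng(10)
        d = _euclid_dissim(rng.normal(size=(12, 2)))
        cfg = nonmetric_mds(d, dims=2, seed=0, restarts=2)
        est = normalized_error(cfg, cfg.points, d, n_random=5, seed=1, restarts=2)
        assert est.raw_error == pytest.approx(0.0, abs=1e-12)
        assert est.normalized_error == pytest.approx(0.0, abs=1e-12)
        assert len(est.null_distribution) == 5

    def test_null_mechanism_self_consistency(self):
        # draws from the scrambling null, normalized by the null mean of
        # held-out draws, average to about 1
        rng = np.random.default_rng(11)
        d = _euclid_dissim(rng.normal(size=(12, 2)))
        cfg = nonmetric_mds(d, dims=2, seed=0, restarts=2)
        errs = []
        gen = np.random.default_rng(12)
        for _ in range(50):
            scrambled = d.permuted(gen)
            null_cfg = nonmetric_mds(scrambled, dims=2,
                                     seed=int(gen.integers(2**31)), restarts=2)
            errs.append(procrustes_error(cfg.points, null_cfg.points))
        errs = np.array(errs)
        total = errs.sum()
        normalized = errs * (len(errs) - 1) / (total - errs)  # each vs the rest
        assert normalized.mean() == pytest.approx(1.0, abs=0.1)

    def test_n_random_too_small(self):
        rng = np.random.default_rng(13)
        d = _euclid_dissim(rng.normal(size=(8, 2)))
        cfg = nonmetric_mds(d, dims=2, seed=0, restarts=2)
        with pytest.raises(ValueError):
            normalized_error(cfg, cfg.points, d, n_random=1)

    def test_planted_factor_structure_ranks_factor_sets(self):
        # dissimilarities built from closure+convexity distances: that factor
        # pair must fit better than symmetry alone
        from contourcues.synth import ObserverModel, simulate_similarity

        rng = np.random.default_rng(14)
        cues = [CueVector(rng.uniform(0, 0.25), int(rng.integers(-6, 7)),
                          rng.uniform(-1, 1), 1, patch_id=f"s{k}") for k in range(14)]
        for rep in range(3):
            model = ObserverModel(
                similarity_weights={"convexity": 1.0, "closure": 1.0, "symmetry": 0.0},
                noise_sd=0.3, seed=100 + rep)
            trials = simulate_similarity(cues, model)
            d = aggregate_dissimilarity(trials)
            order = {c.patch_id: c for c in cues}
            cs = [order[i] for i in d.ids]
            res = {}
            for fs in (("closure", "convexity"), ("symmetry",)):
                cfg = nonmetric_mds(d, dims=len(fs), seed=rep, restarts=2)
                t = topographic_config(cs, fs)
                res[fs] = normalized_error(cfg, t, d, n_random=8, seed=rep,
                                           restarts=2).normalized_error
            assert res[("closure", "convexity")] < res[("symmetry",)]


class TestCompareFactorSets:
    def test_identical_errors(self):
        out = compare_factor_sets({"a": [0.5, 0.6, 0.7], "b": [0.5, 0.6, 0.7]})
        row = out.iloc[0]
        assert row["mean_difference"] == 0.0
        assert row["p"] == 1.0

    def test_constant_offset_degenerate(self):
        out = compare_factor_sets({"a": [0.5, 0.6], "b": [0.6, 0.7]})
        assert out.iloc[0]["p"] == pytest.approx(0.0)

    def test_mismatched_participants_raise(self):
        with pytest.raises(ValueError):
            compare_factor_sets({"a": [1, 2], "b": [1, 2, 3]})

    def test_planted_effect_direction_recovered(self):
        rng = np.random.default_rng(15)
        hits = 0
        for _ in range(100):
            base = 1.0 + rng.normal(0, 0.05, size=6)
            out = compare_factor_sets({"low": base,
                                       "high": base + 0.1 + rng.normal(0, 0.05, size=6)})
            if out.iloc[0]["mean_difference"] < 0:
                hits += 1
        assert hits >= 90
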