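"""Perceptual-similarity analysis: nonmetric MDS, Procrustes and the Error statistic.

Rated similarities (5-point scale, 5 = identical-looking) are aggregated
into per-observer dissimilarity matrices. A perceptual configuration in
1-3 dimensions is found by nonmetric (Kruskal) MDS, whose fit is the
stress-1 statistic: the root of the normalized squared discrepancy between
configuration distances and their best monotone (isotonic) transform of
the dissimilarity ranks. Topographic configurations built from cue subsets
are compared to the perceptual one by full Procrustes alignment
(translation, rotation, reflection, uniform scale); the squared-sum of
aligned point distances is the Error, normalized by its mean over
configurations fitted to label-scrambled dissimilarities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

_FACTORS = ("convexity", "closure", "symmetry")


@dataclass
class DissimilarityMatrix:
    values: np.ndarray
    ids: list
    observer_id: str = ""
    n_repetitions: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("dissimilarity matrix must have zero diagonal")
        if (v < 0).any():
            raise ValueError("dissimilarities must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def permuted(self, rng: np.random.Generator) -> "DissimilarityMatrix":
        """Scramble similarity by permuting stimulus labels."""
        perm = rng.permutation(self.n)
        return DissimilarityMatrix(self.values[np.ix_(perm, perm)],
                                   ids=[self.ids[k] for k in perm],
                                   observer_id=self.observer_id,
                                   n_repetitions=self.n_repetitions)


@dataclass
class PerceptualConfig:
    points: np.ndarray
    stress: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)


@dataclass
class ErrorStat:
    raw_error: float
    normalized_error: float
    null_distribution: np.ndarray
    p_value: float


def aggregate_dissimilarity(trials: pd.DataFrame,
                            observer_id: str | None = None) -> DissimilarityMatrix:
    """Dissimilarity(i, j) = 5 - mean rating over repetitions of the pair.

    ``trials`` needs columns stimulus_a, stimulus_b, rating (1-5) and,
    when more than one observer is present, observer_id to select one.
    Every unordered pair must be rated at least once.
    """
    t = trials
    if observer_id is not None and "observer_id" in t.columns:
        t = t[t["observer_id"] == observer_id]
    elif "observer_id" in t.columns:
        obs = t["observer_id"].unique()
        if len(obs) > 1:
            raise ValueError("multiple observers present; pass observer_id")
        observer_id = obs[0]
    ids = sorted(set(t["stimulus_a"]) | set(t["stimulus_b"]))
    index = {s: k for k, s in enumerate(ids)}
    n = len(ids)
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=int)
    for a, b, r in zip(t["stimulus_a"], t["stimulus_b"], t["rating"]):
        i, j = index[a], index[b]
        total[i, j] += r
        total[j, i] += r
        count[i, j] += 1
        count[j, i] += 1
    iu = np.triu_indices(n, k=1)
    missing = count[iu] == 0
    if missing.any():
        k = int(np.flatnonzero(missing)[0])
        pair = (ids[iu[0][k]], ids[iu[1][k]])
        raise ValueError(f"missing rating for pair {pair}")
    values = np.zeros((n, n))
    values[iu] = 5.0 - total[iu] / count[iu]
    values = values + values.T
    n_rep = int(count[iu].max()) if n > 1 else 0
    return DissimilarityMatrix(values, ids=ids, observer_id=observer_id or "",
                               n_repetitions=n_rep)


def _config_distances(points: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return pdist(points)


def kruskal_stress(points: np.ndarray, d: DissimilarityMatrix) -> float:
    """Kruskal stress-1 of a configuration against rated dissimilarities.

    sqrt( sum (theta(d_ij) - dhat_ij)^2 / sum dhat_ij^2 ), with theta the
    isotonic (rank-order) regression of configuration distances dhat on the
    dissimilarities; tied dissimilarities are left unconstrained against
    each other (Kruskal's primary approach). Zero iff some monotone
    transform of the dissimilarities reproduces the distance rank order.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] != d.n:
        raise ValueError("configuration size does not match matrix")
    dhat = _config_distances(points)
    if np.allclose(dhat, 0):
        raise ValueError("degenerate configuration (all points identical)")
    iu = np.triu_indices(d.n, k=1)
    dij = d.values[iu]
    # primary tie handling: within ties, order by configuration distance
    order = np.lexsort((dhat, dij))
    iso = IsotonicRegression(increasing=True)
    disparities = iso.fit_transform(np.arange(len(dij)), dhat[order])
    num = float(np.sum((disparities - dhat[order]) ** 2))
    den = float(np.sum(dhat**2))
    return float(np.sqrt(num / den))


def _classical_scaling(d: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson double-centering start for the iterative fit."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:dims]
    lam = np.clip(w[idx], 0, None)
    return v[:, idx] * np.sqrt(lam)[None, :]


def nonmetric_mds(d: DissimilarityMatrix, dims: int, seed: int | None = None,
                  restarts: int = 10) -> PerceptualConfig:
    """Nonmetric MDS: iterative stress minimization, best of several starts.

    One run starts from the classical-scaling solution; the remaining
    ``restarts - 1`` runs start at random. The returned configuration is
    centered and carries the stress-1 value recomputed by
    :func:`kruskal_stress`. Deterministic under ``seed``.
    """
    if dims not in (1, 2, 3):
        raise ValueError("dims must be 1, 2 or 3")
    if d.n < dims + 2:
        raise ValueError("need at least dims + 2 stimuli")
    rng = np.random.default_rng(seed)
    candidates = []
    init = _classical_scaling(d.values, dims)
    pts, _ = smacof(d.values, metric=False, n_components=dims, init=init,
                    n_init=1, normalized_stress=True,
                    random_state=int(rng.integers(2**31)))
    candidates.append(pts)
    if restarts > 1:
        pts, _ = smacof(d.values, metric=False, n_components=dims,
                        n_init=restarts - 1, normalized_stress=True,
                        random_state=int(rng.integers(2**31)))
        candidates.append(pts)
    scored = [(kruskal_stress(p, d), p) for p in candidates]
    stress, best = min(scored, key=lambda sp: sp[0])
    best = best - best.mean(axis=0)
    return PerceptualConfig(points=best, stress=float(stress), seed=seed)


def topographic_config(cues: list, factors) -> np.ndarray:
    """Configuration whose coordinates are standardized cue values.

    ``factors`` is a non-empty subset of {"convexity", "closure",
    "symmetry"}; each selected factor is z-standardized across the
    stimulus set so the axes are commensurate under Procrustes.
    """
    factors = [f for f in _FACTORS if f in set(factors)]
    if not factors:
        raise ValueError("empty factor set")
    cols = []
    for f in factors:
        v = np.array([getattr(c, f) for c in cues], dtype=float)
        sd = v.std()
        if sd == 0:
            raise ValueError(f"zero variance in factor {f!r}")
        cols.append((v - v.mean()) / sd)
    return np.column_stack(cols)


def procrustes_error(p: np.ndarray, t: np.ndarray) -> float:
    """Squared-sum of point distances after full Procrustes alignment of t onto p.

    t is optimally translated, rotated, reflected and uniformly scaled
    (least squares); the residual sum of squared pairwise point distances
    is returned without any normalization.
    """
    p = np.asarray(p, dtype=float)
    t = np.asarray(t, dtype=float)
    if p.shape != t.shape:
        raise ValueError("configurations must have the same shape")
    pc = p - p.mean(axis=0)
    tc = t - t.mean(axis=0)
    norm_t = np.linalg.norm(tc)
    if norm_t == 0:
        return float(np.sum(pc**2))
    u, s, vt = np.linalg.svd(tc.T @ pc)
    rot = u @ vt  # reflection allowed
    scale = s.sum() / norm_t**2
    aligned = scale * tc @ rot
    return float(np.sum((pc - aligned) ** 2))


def normalized_error(p: PerceptualConfig, t: np.ndarray, d: DissimilarityMatrix,
                     n_random: int = 100, seed: int | None = None,
                     restarts: int = 10) -> ErrorStat:
    """Error of a topographic configuration, normalized by a scrambling null.

    The null recomputes the MDS configuration ``n_random`` times from
    label-permuted copies of the dissimilarity matrix and measures the
    Procrustes error of each against the perceptual configuration; the
    observed raw error is divided by the null mean. The p-value is a
    one-sided one-sample t-test of the null distribution against the
    observed value (alternative: null mean greater, i.e. the topographic
    configuration is closer than scrambled ones).
    """
    if n_random < 2:
        raise ValueError("n_random must be at least 2")
    dims = p.points.shape[1]
    raw = procrustes_error(p.points, t)
    rng = np.random.default_rng(seed)
    null = np.empty(n_random)
    for r in range(n_random):
        scrambled = d.permuted(rng)
        cfg = nonmetric_mds(scrambled, dims=dims,
                            seed=int(rng.integers(2**31)), restarts=restarts)
        null[r] = procrustes_error(p.points, cfg.points)
    mean_null = float(null.mean())
    norm = raw / mean_null if mean_null > 0 else np.inf
    tt = stats.ttest_1samp(null, raw, alternative="greater")
    return ErrorStat(raw_error=float(raw), normalized_error=float(norm),
                     null_distribution=null, p_value=float(tt.pvalue))


def compare_factor_sets(errors_by_participant: dict) -> pd.DataFrame:
    """Pairwise paired t-tests between factor sets' normalized errors.

    ``errors_by_participant`` maps a factor-set label to the vector of
    per-participant normalized errors (same participant order). Returns a
    frame with one row per factor-set pair: t, p, mean difference.
    """
    labels = list(errors_by_participant)
    lengths = {len(np.asarray(v)) for v in errors_by_participant.values()}
    if len(lengths) != 1:
        raise ValueError("factor sets must cover the same participants")
    if lengths.pop() < 2:
        raise ValueError("need at least 2 participants")
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a = np.asarray(errors_by_participant[labels[i]], dtype=float)
            b = np.asarray(errors_by_participant[labels[j]], dtype=float)
            diff = a - b
            if np.ptp(diff) == 0:
                # zero-variance difference: degenerate paired test
                if diff[0] == 0:
                    tstat, pval = 0.0, 1.0
                else:
                    tstat, pval = float(np.sign(diff[0]) * np.inf), 0.0
            else:
                res = stats.ttest_rel(a, b)
                tstat, pval = float(res.statistic), float(res.pvalue)
            rows.append((labels[i], labels[j], tstat, pval, float(diff.mean())))
    return pd.DataFrame(rows, columns=["set_a", "set_b", "t", "p", "mean_difference"])
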