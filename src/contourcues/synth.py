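"""Synthetic contour patches with planted cue structure, and simulated observers.

The generators plant known geometry -- a circular arc with curvature
1/radius, a closed radial-harmonic blob with an exactly mirror-symmetric
variant, and a smoothed random-walk open curve emulating the single open
natural contours that dominate segmentation datasets -- so every index and
analysis stage can be checked against ground truth. Observer models turn
cue vectors into noisy 5-point similarity ratings and 2AFC figure-direction
choices through simple latent-variable rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cues import CueVector
from .geometry import (
    HALF,
    PATCH_SIZE,
    ContourMap,
    ContourPatch,
    LocalFrame,
    _chain_through,
)

_FACTORS = ("convexity", "closure", "symmetry")


def _unit(angle_deg: float) -> np.ndarray:
    """Direction (d_row, d_col) of a tangent angle (0 deg = vertical)."""
    a = np.deg2rad(angle_deg)
    return np.array([np.cos(a), np.sin(a)])


def _left_normal(direction: np.ndarray) -> np.ndarray:
    return np.array([-direction[1], direction[0]])


def _pixels_to_patch(pixel_rows: np.ndarray, pixel_cols: np.ndarray,
                     chain: np.ndarray, provenance: str) -> ContourPatch:
    grid = np.zeros((PATCH_SIZE, PATCH_SIZE), dtype=np.uint8)
    grid[pixel_rows, pixel_cols] = 1
    return ContourPatch(grid, chain=chain, provenance=provenance)


def _dedupe_consecutive(pts: np.ndarray) -> np.ndarray:
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = (np.abs(np.diff(pts, axis=0)).max(axis=1) > 0)
    pts = pts[keep]
    # thin to a minimal 8-path: drop a pixel whenever its neighbors in the
    # chain are themselves 8-adjacent (redundant rasterization corners);
    # the patch center pixel is always kept
    center = np.array([HALF, HALF])
    changed = True
    while changed and len(pts) > 2:
        drop = np.zeros(len(pts), dtype=bool)
        k = 1
        while k < len(pts) - 1:
            redundant = np.abs(pts[k + 1] - pts[k - 1]).max() <= 1
            if redundant and not np.array_equal(pts[k], center):
                drop[k] = True
                k += 2
            else:
                k += 1
        changed = bool(drop.any())
        pts = pts[~drop]
    return pts


def generate_arc(radius: float, arc_extent: float = 120.0,
                 orientation: float = 0.0, center_offset: float = 0.0,
                 side: int = 1) -> ContourPatch:
    """Rasterized circular arc through the patch center.

    The tangent at the center equals ``orientation`` (0 deg = vertical) and
    the planted curvature is 1/radius. ``side`` (+1/-1) selects on which
    side of the tangent the circle center lies; ``center_offset`` slides the
    arc's angular midpoint along the circle by that many pixels of arc
    length (the arc must still pass through the patch center).
    ``arc_extent`` = 360 produces a closed circle.
    """
    if radius <= 2:
        raise ValueError("radius must exceed 2 px")
    c = np.array([HALF, HALF], dtype=float)
    t = _unit(orientation)
    n = float(np.sign(side)) * _left_normal(t)
    circle_center = c + radius * n

    phi_center = np.arctan2(c[1] - circle_center[1], c[0] - circle_center[0])
    half = np.deg2rad(arc_extent) / 2.0
    shift = center_offset / radius
    if abs(shift) > half:
        raise ValueError("arc does not pass through the patch center")
    phi0, phi1 = phi_center + shift - half, phi_center + shift + half
    step = min(0.2 / radius, np.deg2rad(0.5))
    phi = np.arange(phi0, phi1 + step, step)
    pts = circle_center[None, :] + radius * np.column_stack([np.cos(phi), np.sin(phi)])
    pix = np.rint(pts).astype(int)
    pix = _dedupe_consecutive(pix)

    inside = ((pix >= 0) & (pix < PATCH_SIZE)).all(axis=1)
    grid = np.zeros((PATCH_SIZE, PATCH_SIZE), dtype=np.uint8)
    grid[pix[inside, 0], pix[inside, 1]] = 1
    if grid[HALF, HALF] != 1:
        raise ValueError("arc does not pass through the patch center")
    chain = _chain_through(ContourMap(grid), (HALF, HALF))
    prov = f"arc(r={radius},extent={arc_extent},orient={orientation})"
    return ContourPatch(grid, chain=chain, provenance=prov)


def generate_blob(harmonic_amplitudes, mirror_symmetric: bool = True,
                  seed: int | None = None, axis_deg: float = 0.0,
                  base_radius: float = 15.0) -> ContourPatch:
    """Closed contour from a radial harmonic series, touching the patch center.

    r(phi) = base_radius + sum_k A_k cos((k+2) phi + p_k). With
    ``mirror_symmetric`` all phases are zero, giving an exact mirror axis
    at ``axis_deg``; when the axis is vertical (axis_deg = 0) the pixel set
    is explicitly symmetrized so the raster symmetry is exact. The blob is
    placed so its boundary passes through the patch center along the axis
    direction (the center pixel of a patch must lie on the contour).
    """
    amps = np.asarray(harmonic_amplitudes, dtype=float)
    rng = np.random.default_rng(seed)
    phases = np.zeros(len(amps)) if mirror_symmetric else rng.uniform(0, 2 * np.pi, len(amps))

    ks = np.arange(2, 2 + len(amps))
    phi = np.linspace(0, 2 * np.pi, 4000, endpoint=False)

    def radial(p: np.ndarray) -> np.ndarray:
        return base_radius + np.sum(
            amps[:, None] * np.cos(ks[:, None] * p[None, :] + phases[:, None]), axis=0
        )

    r = radial(phi)
    if r.min() <= 2:
        raise ValueError("self-intersecting parameterization (radius collapses)")
    if base_radius + np.abs(amps).sum() > HALF - 2:
        raise ValueError("blob does not fit in the patch")

    axis = _unit(axis_deg)  # direction of the planted axis
    c = np.array([HALF, HALF], dtype=float)
    # boundary point at phi=0 lies along +axis from the blob center; place it
    # at the patch center
    blob_center = c + radial(np.zeros(1))[0] * axis

    # local frame: phi measured from -axis so phi=0 maps to the touch point
    e1 = -axis
    e2 = _left_normal(axis)
    pts = (blob_center[None, :]
           + r[:, None] * (np.cos(phi)[:, None] * e1[None, :]
                           + np.sin(phi)[:, None] * e2[None, :]))
    pix = _dedupe_consecutive(np.rint(pts).astype(int))
    inside = ((pix >= 0) & (pix < PATCH_SIZE)).all(axis=1)
    pix = pix[inside]
    grid = np.zeros((PATCH_SIZE, PATCH_SIZE), dtype=np.uint8)
    grid[pix[:, 0], pix[:, 1]] = 1
    if mirror_symmetric and abs(axis_deg % 180.0) < 1e-9:
        grid = np.maximum(grid, grid[:, ::-1])  # exact raster symmetry about col 34
    if grid[HALF, HALF] != 1:
        grid[HALF, HALF] = 1
    chain = _chain_through(ContourMap(grid), (HALF, HALF))
    prov = f"blob(amps={list(amps)},sym={mirror_symmetric},axis={axis_deg})"
    return ContourPatch(grid, chain=chain, provenance=prov)


def generate_open_curve(smoothness: float = 1.0, seed: int | None = None,
                        step: float = 0.7) -> ContourPatch:
    """Smoothed random-walk open contour through the patch center.

    The heading performs a Gaussian random walk; the per-curve increment
    scale is 0.3/smoothness radians per step times a lognormal draw
    (sd 0.8 in log space), so a single smoothness setting produces curves
    from near-straight to tightly curled, spreading the cue indices over
    the convexity and closure bins. The curve is grown from the center in
    both directions until it leaves the patch. Higher smoothness gives
    straighter curves.
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    rng = np.random.default_rng(seed)
    sigma = 0.3 / smoothness * rng.lognormal(0.0, 0.8)
    theta0 = rng.uniform(0, np.pi)

    def grow(direction_sign: float) -> list[np.ndarray]:
        pts = []
        p = np.array([HALF, HALF], dtype=float)
        th = theta0
        for _ in range(400):
            th = th + rng.normal(0.0, sigma)
            p = p + direction_sign * step * np.array([np.cos(th), np.sin(th)])
            rr, cc = int(round(p[0])), int(round(p[1]))
            if not (0 <= rr < PATCH_SIZE and 0 <= cc < PATCH_SIZE):
                break
            pts.append(p.copy())
        return pts

    fwd = grow(+1.0)
    bwd = grow(-1.0)
    pts = np.array(bwd[::-1] + [np.array([HALF, HALF], dtype=float)] + fwd)
    pix = _dedupe_consecutive(np.rint(pts).astype(int))
    grid = np.zeros((PATCH_SIZE, PATCH_SIZE), dtype=np.uint8)
    grid[pix[:, 0], pix[:, 1]] = 1
    # the parametric order is the chain (consecutive rounded points are
    # 8-adjacent by the step size); re-tracing could split at self-touches
    prov = f"open_curve(smoothness={smoothness},seed={seed})"
    return ContourPatch(grid, chain=pix, provenance=prov)


@dataclass
class ObserverModel:
    """Latent-variable observer for similarity rating and 2AFC tasks.

    Similarity: the latent dissimilarity of a stimulus pair is the weighted
    Euclidean distance between their standardized cue vectors plus Gaussian
    trial noise, cut at four increasing thresholds into the 5-point scale
    (5 = identical-looking). Figure-ground: the probability of choosing the
    convex side is the clipped linear predictor of ``fg_weights`` (intercept,
    three cues, three pairwise products) on the raw cue vector.
    """

    similarity_weights: dict = field(
        default_factory=lambda: {"convexity": 1.0, "closure": 1.0, "symmetry": 1.0}
    )
    rating_thresholds: tuple = (0.5, 1.2, 2.0, 3.0)
    fg_weights: tuple = (0.5, 0.0, 0.05, 0.0, 0.0, 0.0, 0.0)
    noise_sd: float = 0.3
    seed: int | None = None
    observer_id: str = "sim"

    def __post_init__(self) -> None:
        t = np.asarray(self.rating_thresholds, dtype=float)
        if len(t) != 4 or not np.all(np.diff(t) > 0):
            raise ValueError("rating_thresholds must be 4 strictly increasing values")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.fg_weights) != 7:
            raise ValueError("fg_weights must have 7 entries (intercept, 3 cues, 3 products)")


def _standardized_cue_matrix(stimuli: list[CueVector]) -> np.ndarray:
    m = np.array([[s.convexity, s.closure, s.symmetry] for s in stimuli], dtype=float)
    mu = m.mean(axis=0)
    sd = m.std(axis=0)
    sd[sd == 0] = 1.0
    return (m - mu) / sd


def simulate_similarity(stimuli: list[CueVector], model: ObserverModel,
                        n_repetitions: int = 4) -> pd.DataFrame:
    """Per-trial 5-point similarity ratings for all unordered stimulus pairs.

    Columns: observer_id, stimulus_a, stimulus_b, repetition, rating.
    A set of 54 stimuli yields 1431 pairs x n_repetitions trials.
    """
    rng = np.random.default_rng(model.seed)
    z = _standardized_cue_matrix(stimuli)
    w = np.array([model.similarity_weights.get(f, 0.0) for f in _FACTORS])
    ids = [s.patch_id if s.patch_id is not None else str(k) for k, s in enumerate(stimuli)]
    thresholds = np.asarray(model.rating_thresholds)

    rows = []
    n = len(stimuli)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.sqrt(np.sum(w * (z[i] - z[j]) ** 2))
            for rep in range(n_repetitions):
                latent = d + rng.normal(0.0, model.noise_sd)
                rating = 5 - int(np.searchsorted(thresholds, latent, side="right"))
                rows.append((model.observer_id, ids[i], ids[j], rep, rating))
    return pd.DataFrame(rows, columns=["observer_id", "stimulus_a", "stimulus_b",
                                       "repetition", "rating"])


def _group_of(frame: LocalFrame) -> str:
    """Session group by contour orientation: within 45 deg of vertical -> vertical."""
    t = frame.tangent_deg % 180.0
    return "vertical" if (t < 45.0 or t >= 135.0) else "horizontal"


_ANSWER_DIRS = {
    "right": np.array([0.0, 1.0]),
    "left": np.array([0.0, -1.0]),
    "top": np.array([-1.0, 0.0]),
    "bottom": np.array([1.0, 0.0]),
}
GROUP_ANSWERS = {"vertical": ("left", "right"), "horizontal": ("top", "bottom")}


def fg_linear_predictor(cue: CueVector, weights) -> float:
    """Intercept + weighted cues + weighted pairwise products."""
    cv, cl, sy = cue.convexity, cue.closure, cue.symmetry
    x = np.array([1.0, cv, cl, sy, cv * cl, cv * sy, cl * sy])
    return float(np.dot(np.asarray(weights, dtype=float), x))


def simulate_fg(stimuli: list[CueVector], frames: list[LocalFrame],
                model: ObserverModel, n_reps: int = 100) -> pd.DataFrame:
    """Per-trial 2AFC figure-direction responses.

    P(choose convex side) is the clipped-to-[0,1] linear predictor of the
    observer's fg_weights; answers are emitted in the session group's
    direction vocabulary (right/left for the vertical group, top/bottom for
    the horizontal group). Patches whose convex normal has no component
    along the group's answer axis are skipped.
    """
    rng = np.random.default_rng(model.seed)
    rows = []
    for k, (cue, frame) in enumerate(zip(stimuli, frames)):
        pid = cue.patch_id if cue.patch_id is not None else str(k)
        group = _group_of(frame)
        a0, a1 = GROUP_ANSWERS[group]
        d0 = float(np.dot(_ANSWER_DIRS[a0], frame.convex_normal))
        if d0 == 0.0:
            continue
        convex_answer, concave_answer = (a0, a1) if d0 > 0 else (a1, a0)
        p = float(np.clip(fg_linear_predictor(cue, model.fg_weights), 0.0, 1.0))
        choices = rng.random(n_reps) < p
        for rep, chose_convex in enumerate(choices):
            rows.append((model.observer_id, pid, rep, group,
                         convex_answer if chose_convex else concave_answer))
    return pd.DataFrame(rows, columns=["observer_id", "patch_id", "repetition",
                                       "group", "answer"])
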