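"""Stimulus filtering, 5x5x8 class stratification, selection and rendering.

Patches are grouped by convexity bin (5), closure bin (5) and orientation
bin (8) into 200 possible classes; one patch is drawn uniformly at random
from each non-empty class. X-junction patches (contours crossing each
other) are excluded before stratification. Display stimuli are the binary
patches weighted by a Gaussian envelope (sigma = 17 px) centered on the
patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.morphology import skeletonize

from .cues import CueVector
from .geometry import HALF, PATCH_SIZE, ContourPatch

# convexity: printed outer bins [0, 0.018) and [0.222, 0.258]; three
# equal-width interior bins on [0.018, 0.222)
CONVEXITY_EDGES = np.array([0.0, 0.018, 0.086, 0.154, 0.222, 0.258])
# closure: outer bins [-8,-6) and (6,8]; interior [-6,-2), [-2,2], (2,6]
CLOSURE_EDGES = (-8.0, -6.0, -2.0, 2.0, 6.0, 8.0)

UNBINNED = "unbinned"


@dataclass(frozen=True)
class StimulusClass:
    convexity_bin: int  # 1..5
    closure_bin: int  # 1..5
    orientation_bin: int  # 1..8

    def __post_init__(self) -> None:
        if not (1 <= self.convexity_bin <= 5 and 1 <= self.closure_bin <= 5
                and 1 <= self.orientation_bin <= 8):
            raise ValueError("class indices out of range")


@dataclass
class StimulusSet:
    """One randomly chosen patch per non-empty stimulus class."""

    members: list  # (patch_id, CueVector, StimulusClass)
    seed: int | None = None


_RING = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]


def _branch_count(skel: np.ndarray, r: int, c: int) -> int:
    """Number of distinct chain branches meeting at (r, c).

    Counted as connected runs of skeleton pixels around the 8-neighborhood
    ring, so two adjacent neighbors along the same branch count once.
    """
    n = skel.shape[0]
    vals = []
    for dr, dc in _RING:
        rr, cc = r + dr, c + dc
        vals.append(bool(skel[rr, cc]) if 0 <= rr < n and 0 <= cc < n else False)
    if not any(vals):
        return 0
    if all(vals):
        return 1
    runs = 0
    for k in range(8):
        if vals[k] and not vals[k - 1]:
            runs += 1
    return runs


def has_x_junction(patch: ContourPatch) -> bool:
    """True iff the thinned contour has a pixel where >= 4 branches meet.

    T-junctions (3 branches) and simple curves do not count as crossings.
    """
    skel = skeletonize(patch.grid.astype(bool))
    for r, c in np.argwhere(skel):
        if _branch_count(skel, r, c) >= 4:
            return True
    return False


def contour_density(patch: ContourPatch) -> float:
    """Fraction of patch pixels on the contour (optional packing heuristic)."""
    return float(patch.grid.sum()) / patch.grid.size


def has_large_enclosure(patch: ContourPatch, area_fraction: float = 0.8) -> bool:
    """Optional whole-object heuristic: a closed region filling most of the patch."""
    from scipy import ndimage

    filled = ndimage.binary_fill_holes(patch.grid.astype(bool))
    interior = filled & ~patch.grid.astype(bool)
    return float(interior.sum()) / patch.grid.size > area_fraction


def assign_class(cues: CueVector):
    """Map a cue vector to its 5x5x8 stimulus class, or "unbinned".

    Bins are half-open lower-inclusive except the printed closed edges
    (convexity top bin closed at 0.258; closure bin [-2, 2] closed at both
    ends, hence (2, 6] and (6, 8] above it). Values outside [0, 0.258] or
    [-8, 8] fall outside the stratification.
    """
    cv = cues.convexity
    if cv < CONVEXITY_EDGES[0] or cv > CONVEXITY_EDGES[-1]:
        return UNBINNED
    if cv == CONVEXITY_EDGES[-1]:
        cv_bin = 5
    else:
        cv_bin = int(np.searchsorted(CONVEXITY_EDGES, cv, side="right"))

    cl = float(cues.closure)
    if cl < -8.0 or cl > 8.0:
        return UNBINNED
    if cl < -6.0:
        cl_bin = 1
    elif cl < -2.0:
        cl_bin = 2
    elif cl <= 2.0:
        cl_bin = 3
    elif cl <= 6.0:
        cl_bin = 4
    else:
        cl_bin = 5
    return StimulusClass(cv_bin, cl_bin, cues.orientation_bin)


def stratified_select(pool: list, seed: int | None = None) -> StimulusSet:
    """Choose one patch uniformly at random per non-empty class.

    ``pool`` holds (patch_id, CueVector) entries already screened for
    X-junctions; unbinned entries are skipped. Deterministic under ``seed``.
    """
    if not pool:
        raise ValueError("empty pool")
    by_class: dict[StimulusClass, list] = {}
    for patch_id, cues in pool:
        cls = assign_class(cues)
        if cls == UNBINNED:
            continue
        by_class.setdefault(cls, []).append((patch_id, cues))
    rng = np.random.default_rng(seed)
    members = []
    key = lambda c: (c.convexity_bin, c.closure_bin, c.orientation_bin)
    for cls in sorted(by_class, key=key):
        cands = by_class[cls]
        patch_id, cues = cands[rng.integers(len(cands))]
        members.append((patch_id, cues, cls))
    return StimulusSet(members=members, seed=seed)


def render_stimulus(patch: ContourPatch, sigma: float = 17.0) -> np.ndarray:
    """Gaussian-windowed display stimulus (float image, peak weight 1)."""
    rr, cc = np.mgrid[0:PATCH_SIZE, 0:PATCH_SIZE]
    d2 = (rr - HALF) ** 2 + (cc - HALF) ** 2
    return patch.grid * np.exp(-d2 / (2.0 * sigma**2))
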