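"""The three local Gestalt cue indices: Convexity, Closure and Symmetry.

Convexity is log(1 + |rho|) with rho the curvature at the patch center.
Closure is the difference in radial-ray contour-crossing counts between
two probe points offset +/-5 px from the center along the contour normal
(16 rays at 22.5 deg steps from each probe); it is positive when the
convex side is the more enclosed one. Symmetry is the per-length mirror-overlap
of the contour about the best axis (exhaustive search over axis rotation
and translation), normalized by the largest such overlap in the working
corpus, and signed negative when the optimal axis runs mainly through the
concave side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import HALF, PATCH_SIZE, ContourPatch, LocalFrame, orientation_bin

N_RAYS = 16
RAY_STEP_DEG = 22.5
PROBE_OFFSET = 5.0  # px from the center along the contour normal

# 1-pixel disk (4-connected cross) used to absorb rasterization jitter
_DILATION_DISK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

_THETA_GRID = np.arange(180)
_X_GRID = np.arange(-HALF, HALF + 1)


@dataclass
class CueVector:
    """The (Convexity, Closure, Symmetry) triple for one patch."""

    convexity: float
    closure: int
    symmetry: float
    orientation_bin: int
    patch_id: str | None = None

    def __post_init__(self) -> None:
        if self.convexity < 0:
            raise ValueError("convexity must be non-negative")
        if abs(self.closure) > N_RAYS:
            raise ValueError("closure out of range")
        if abs(self.symmetry) > 1 + 1e-12:
            raise ValueError("symmetry out of range")


@dataclass
class SymmetrySearchResult:
    """Outcome of the exhaustive mirror-axis search for one patch."""

    theta_star: float
    x_star: int
    dos_star: float
    length: int
    corpus_max_dos: float | None = None


def convexity(frame: LocalFrame) -> float:
    """log(1 + |rho|), natural log; zero for a straight contour."""
    return float(np.log1p(abs(frame.rho)))


def _ray_crosses(grid: np.ndarray, probe: np.ndarray, direction: np.ndarray) -> bool:
    """True if the ray from the probe intersects any contour pixel's unit cell.

    Exact slab test: pixel (r, c) occupies [r-1/2, r+1/2] x [c-1/2, c+1/2];
    the ray hits it iff the t-intervals of both slabs intersect at some
    t >= 0. Contour pixels lie inside the (convex) patch square, so the
    clipped ray reaches every cell the infinite ray does.
    """
    q = np.argwhere(grid).astype(float)
    if len(q) == 0:
        return False
    lo = np.zeros(len(q))
    hi = np.full(len(q), np.inf)
    valid = np.ones(len(q), dtype=bool)
    for k in range(2):
        dk = direction[k]
        if abs(dk) < 1e-12:
            valid &= np.abs(probe[k] - q[:, k]) <= 0.5
        else:
            a = (q[:, k] - 0.5 - probe[k]) / dk
            b = (q[:, k] + 0.5 - probe[k]) / dk
            lo = np.maximum(lo, np.minimum(a, b))
            hi = np.minimum(hi, np.maximum(a, b))
    return bool(np.any(valid & (lo <= hi)))


def crossing_count(patch: ContourPatch, probe: np.ndarray,
                   first_ray_direction: np.ndarray) -> int:
    """Number of the 16 radial lines from ``probe`` that cross the contour.

    Rays are spaced 22.5 deg apart, the first along ``first_ray_direction``;
    each ray counts at most once no matter how many times it crosses.
    """
    d0 = np.asarray(first_ray_direction, dtype=float)
    d0 = d0 / np.linalg.norm(d0)
    base = np.arctan2(d0[1], d0[0])
    count = 0
    for k in range(N_RAYS):
        ang = base + np.deg2rad(RAY_STEP_DEG) * k
        direction = np.array([np.cos(ang), np.sin(ang)])
        if _ray_crosses(patch.grid, probe, direction):
            count += 1
    return count


def closure(patch: ContourPatch, frame: LocalFrame) -> int:
    """Closure = N_convex - N_concave.

    N_convex counts crossings of the rays cast from the probe displaced
    5 px toward the convex side (the side of the osculating-circle center);
    N_concave from the opposite probe. A contour closing around the convex
    probe therefore yields a positive index, matching the convention that
    positive cues pull figure toward the convex side. For degenerate
    (straight) frames the default left-of-traversal normal fixes the sides.
    """
    center = np.array(patch.center, dtype=float)
    n = np.asarray(frame.convex_normal, dtype=float)
    convex_probe = center + PROBE_OFFSET * n
    concave_probe = center - PROBE_OFFSET * n
    for probe in (convex_probe, concave_probe):
        if not (0 <= probe[0] < PATCH_SIZE and 0 <= probe[1] < PATCH_SIZE):
            raise ValueError("probe point outside patch")
    n_convex = crossing_count(patch, convex_probe, n)
    n_concave = crossing_count(patch, concave_probe, -n)
    return n_convex - n_concave


def _rotation_matrix(theta_deg: float) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])


def _rotate_grid(grid: np.ndarray, theta_deg: float) -> np.ndarray:
    """Nearest-neighbor rotation about the patch center.

    Output pixel p samples input pixel c + M (p - c) with M the rotation
    matrix, so the candidate axis {col = const} in the rotated frame maps
    back to original coordinates through M.
    """
    c = np.array([HALF, HALF], dtype=float)
    m = _rotation_matrix(theta_deg)
    offset = c - m @ c
    return ndimage.affine_transform(grid, m, offset=offset, order=0,
                                    output=np.uint8, prefilter=False)


def _mirror_overlap(img: np.ndarray, axis_col: int) -> int:
    """Count pixels coinciding with their mirror image about ``axis_col``."""
    n = img.shape[1]
    c2 = 2 * axis_col
    k0 = max(0, c2 - (n - 1))
    k1 = min(n - 1, c2)
    if k1 < k0:
        return 0
    a = img[:, k0 : k1 + 1]
    hi = c2 - k0
    lo = c2 - k1 - 1
    b = img[:, hi : (lo if lo >= 0 else None) : -1]
    return int(np.sum(a & b))


def dos(patch: ContourPatch, theta: float, x: int, dilate: bool = True) -> float:
    """Degree of symmetry for one candidate axis.

    The patch is rotated by ``theta`` about its center and translated by
    ``x`` columns so the candidate axis becomes the central vertical; the
    returned value is the count of contour pixels coinciding with their
    mirror image about that column, divided by the contour pixel count of
    the same (rotated, possibly dilated) image. With ``dilate`` the image
    is thickened by a 1-pixel disk before the overlap, which absorbs
    rasterization jitter. Normalizing by the pixel count of the image
    actually overlapped keeps dos in [0, 1] with dos = 1 exactly when the
    raster is mirror symmetric at the candidate axis, independent of how
    much the dilation thickens a particular shape; for an untransformed,
    undilated patch this is the plain overlap-over-length ratio.
    """
    if patch.length == 0:
        raise ValueError("no contour")
    rot = _rotate_grid(patch.grid, theta)
    img = rot.astype(bool)
    if dilate:
        img = ndimage.binary_dilation(img, structure=_DILATION_DISK)
    denom = int(img.sum())
    if denom == 0:
        raise ValueError("no contour")
    # translating by x then mirroring about the center column equals
    # mirroring the untranslated image about column HALF - x
    overlap = _mirror_overlap(img, HALF - int(x))
    return overlap / denom


def optimal_axis(patch: ContourPatch, dilate: bool = True) -> SymmetrySearchResult:
    """Exhaustive search for the mirror axis maximizing dos.

    Grid: theta in {0..179} deg, x in {-34..34} px; ties broken by the
    smallest theta, then the smallest x.
    """
    if patch.length == 0:
        raise ValueError("no contour")
    best = (-1.0, 0, 0)
    for theta in _THETA_GRID:
        rot = _rotate_grid(patch.grid, float(theta)).astype(bool)
        if dilate:
            rot = ndimage.binary_dilation(rot, structure=_DILATION_DISK)
        denom = int(rot.sum())
        if denom == 0:
            continue
        for x in _X_GRID:
            score = _mirror_overlap(rot, HALF - int(x)) / denom
            if score > best[0] + 1e-12:
                best = (score, int(theta), int(x))
    return SymmetrySearchResult(theta_star=float(best[1]), x_star=best[2],
                                dos_star=best[0], length=patch.length)


def axis_points(result: SymmetrySearchResult, step: float = 0.25) -> np.ndarray:
    """Sample the optimal axis line in original patch coordinates.

    The axis is the central vertical of the rotated/translated frame mapped
    back through the rotation, clipped to the patch square.
    """
    m = _rotation_matrix(result.theta_star)
    c = np.array([HALF, HALF], dtype=float)
    u = m @ np.array([1.0, 0.0])  # along-axis direction
    v = m @ np.array([0.0, -float(result.x_star)])  # axis offset from center
    s = np.arange(-PATCH_SIZE, PATCH_SIZE + step, step)
    pts = c + v + s[:, None] * u[None, :]
    inside = ((pts >= 0) & (pts <= PATCH_SIZE - 1)).all(axis=1)
    return pts[inside]


def symmetry_index(patch: ContourPatch, frame: LocalFrame, corpus_max_dos: float,
                   search: SymmetrySearchResult | None = None,
                   dilate: bool = True) -> float:
    """Corpus-normalized, signed symmetry index in [-1, 1].

    Magnitude is dos at the optimal axis divided by the corpus maximum.
    The sign is negative iff the portion of the optimal axis lying on the
    convex side of the center (classified by the convex-side normal) is
    strictly shorter than the portion on the concave side.
    """
    if corpus_max_dos <= 0:
        raise ValueError("corpus_max_dos must be positive")
    if search is None:
        search = optimal_axis(patch, dilate=dilate)
    magnitude = search.dos_star / corpus_max_dos
    pts = axis_points(search)
    rel = pts - np.array(patch.center, dtype=float)
    side = rel @ np.asarray(frame.convex_normal, dtype=float)
    convex_len = int(np.sum(side > 0))
    concave_len = int(np.sum(side < 0))
    sign = -1.0 if convex_len < concave_len else 1.0
    return sign * magnitude


def cue_vector(patch: ContourPatch, frame: LocalFrame, corpus_max_dos: float,
               search: SymmetrySearchResult | None = None,
               patch_id: str | None = None) -> CueVector:
    """Bundle the three indices plus the orientation bin for one patch."""
    return CueVector(
        convexity=convexity(frame),
        closure=closure(patch, frame),
        symmetry=symmetry_index(patch, frame, corpus_max_dos, search=search),
        orientation_bin=orientation_bin(frame.tangent_deg),
        patch_id=patch_id,
    )
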