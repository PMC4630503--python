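"""Contour maps, patch extraction and the local frame at a patch center.

Coordinates are 0-based ``(row, col)`` with the row index increasing
downward. Tangent angles are measured from the vertical (0 deg = vertical)
and reduced modulo 180 deg. The local frame at a patch center is estimated
from a 41-pixel chain window (20 pixels to each side of the center): the
tangent by a total-least-squares line fit and the curvature by a
least-squares circle fit, whose center also defines the convex side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PATCH_SIZE = 69
HALF = PATCH_SIZE // 2  # 34
CHAIN_WINDOW = 41
CHAIN_HALF = CHAIN_WINDOW // 2  # 20
RHO_TOL = 1e-3  # 1/pixel; below this the frame is degenerate (straight)

_ORIENTATION_EDGES = np.array([0.0, 15.0, 30.0, 60.0, 90.0, 120.0, 150.0, 165.0, 180.0])

_NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


@dataclass
class ContourMap:
    """Binary raster of contours; nonzero pixels are contour pixels."""

    grid: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError("contour map grid must be 2-D")
        if not np.isin(grid, (0, 1)).all():
            raise ValueError("contour map values must be exactly 0 or 1")
        self.grid = grid.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass
class ContourPatch:
    """69x69 patch whose center pixel (34, 34) lies on a contour.

    ``chain`` is the ordered 8-connected pixel chain passing through the
    center, in patch coordinates.
    """

    grid: np.ndarray
    chain: np.ndarray
    center: tuple[int, int] = (HALF, HALF)
    provenance: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.shape != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError(f"patch grid must be {PATCH_SIZE}x{PATCH_SIZE}")
        if not np.isin(grid, (0, 1)).all():
            raise ValueError("patch values must be exactly 0 or 1")
        self.grid = grid.astype(np.uint8)
        self.chain = np.asarray(self.chain, dtype=int)
        if grid[self.center] != 1:
            raise ValueError("patch center is not on a contour")
        if not (self.chain == np.array(self.center)).all(axis=1).any():
            raise ValueError("chain does not contain the patch center")

    @property
    def length(self) -> int:
        """Contour pixel count of the whole patch (feeds dos normalization)."""
        return int(self.grid.sum())


@dataclass
class LocalFrame:
    """Tangent, signed curvature and convex-side normal at a patch center.

    ``rho`` is 1/(fitted circle radius) in 1/pixel; ``convex_normal`` is the
    unit vector from the center toward the osculating-circle center. When
    |rho| < RHO_TOL the frame is degenerate (straight contour) and the
    normal defaults to the left of the chain traversal direction.
    """

    tangent_deg: float
    rho: float
    convex_normal: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.convex_normal = np.asarray(self.convex_normal, dtype=float)


def trace_contours(cmap: ContourMap) -> list[np.ndarray]:
    """Decompose a binary map into maximal ordered 8-connected pixel chains.

    Every contour pixel belongs to exactly one chain. Open curves are traced
    from an endpoint (degree-1 pixel); at branch points the walk continues
    along the straightest unvisited neighbor (smallest turning angle), ties
    broken by lexicographic pixel order, which makes tracing deterministic.
    """
    grid = cmap.grid
    pixels = {tuple(p) for p in np.argwhere(grid)}
    if not pixels:
        return []
    neighbors: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for p in pixels:
        r, c = p
        neighbors[p] = [
            (r + dr, c + dc) for dr, dc in _NEIGHBOR_OFFSETS if (r + dr, c + dc) in pixels
        ]

    visited: set[tuple[int, int]] = set()
    chains: list[np.ndarray] = []

    def walk(start: tuple[int, int]) -> list[tuple[int, int]]:
        chain = [start]
        visited.add(start)
        prev_dir: tuple[int, int] | None = None
        cur = start
        while True:
            cands = [q for q in neighbors[cur] if q not in visited]
            if not cands:
                break
            if prev_dir is None or len(cands) == 1:
                nxt = min(cands)
            else:
                # straightest continuation: maximize cosine with prev_dir
                def key(q: tuple[int, int]) -> tuple[float, tuple[int, int]]:
                    d = (q[0] - cur[0], q[1] - cur[1])
                    nd = np.hypot(*d)
                    npv = np.hypot(*prev_dir)
                    cos = (d[0] * prev_dir[0] + d[1] * prev_dir[1]) / (nd * npv)
                    return (-cos, q)

                nxt = min(cands, key=key)
            prev_dir = (nxt[0] - cur[0], nxt[1] - cur[1])
            visited.add(nxt)
            chain.append(nxt)
            cur = nxt
        return chain

    # open curves first, starting from endpoints
    endpoints = sorted(p for p in pixels if len(neighbors[p]) <= 1)
    for p in endpoints:
        if p not in visited:
            chains.append(np.array(walk(p)))
    # remaining pixels (loops, leftover branch arms)
    for p in sorted(pixels):
        if p not in visited:
            chains.append(np.array(walk(p)))
    return chains


def extract_patch(cmap: ContourMap, center: tuple[int, int]) -> ContourPatch:
    """Cut the 69x69 window centered on a contour pixel.

    Raises if the center is off-contour or the window does not fit.
    """
    r, c = int(center[0]), int(center[1])
    rows, cols = cmap.shape
    if cmap.grid[r, c] != 1:
        raise ValueError("center not on contour")
    if r - HALF < 0 or c - HALF < 0 or r + HALF >= rows or c + HALF >= cols:
        raise ValueError("patch exceeds map")
    window = cmap.grid[r - HALF : r + HALF + 1, c - HALF : c + HALF + 1]
    sub = ContourMap(window, provenance=cmap.provenance)
    chain = _chain_through(sub, (HALF, HALF))
    return ContourPatch(window, chain=chain, provenance=f"{cmap.provenance}@({r},{c})")


def _chain_through(cmap: ContourMap, pixel: tuple[int, int]) -> np.ndarray:
    """The traced chain containing ``pixel``."""
    for chain in trace_contours(cmap):
        if (chain == np.array(pixel)).all(axis=1).any():
            return chain
    raise ValueError("center not on contour")


def _chain_is_closed(chain: np.ndarray) -> bool:
    if len(chain) < 4:
        return False
    d = np.abs(chain[0] - chain[-1])
    return d.max() <= 1


def local_frame(patch: ContourPatch, rho_tol: float = RHO_TOL) -> LocalFrame:
    """Estimate tangent, curvature and convex side over the 41-pixel window.

    The chain must extend at least 20 pixels to each side of the center
    (closed chains wrap around). Tangent: principal axis of the window
    points. Curvature: algebraic least-squares circle fit; rho = 1/radius.
    """
    chain = patch.chain
    idx = int(np.flatnonzero((chain == np.array(patch.center)).all(axis=1))[0])
    n = len(chain)
    closed = _chain_is_closed(chain)
    if closed and n >= CHAIN_WINDOW:
        window = chain[(np.arange(idx - CHAIN_HALF, idx + CHAIN_HALF + 1)) % n]
    else:
        if idx < CHAIN_HALF or idx + CHAIN_HALF >= n:
            raise ValueError("insufficient contour support")
        window = chain[idx - CHAIN_HALF : idx + CHAIN_HALF + 1]
    pts = window.astype(float)

    # tangent: total least squares via PCA
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    t = vt[0]  # (dr, dc)
    tangent_deg = float(np.degrees(np.arctan2(t[1], t[0])) % 180.0)

    # traversal direction at the center (for the degenerate default side)
    lo, hi = max(idx - 1, 0), min(idx + 1, n - 1)
    trav = chain[hi] - chain[lo]
    trav = trav / max(np.hypot(*trav), 1e-12)
    left = np.array([-trav[1], trav[0]], dtype=float)

    center_pt = np.array(patch.center, dtype=float)
    fit = _fit_circle(pts)
    if fit is None:
        return LocalFrame(tangent_deg, 0.0, left, degenerate=True)
    circ_center, radius = fit
    rho = 1.0 / radius
    if rho < rho_tol:
        return LocalFrame(tangent_deg, 0.0, left, degenerate=True)
    normal = circ_center - center_pt
    normal = normal / np.linalg.norm(normal)
    # for curved contours the tangent is taken perpendicular to the fitted
    # radius, which is less sensitive than the line fit to asymmetry of the
    # chain window around the center
    tangent_deg = float(np.degrees(np.arctan2(normal[0], -normal[1])) % 180.0)
    return LocalFrame(tangent_deg, float(rho), normal, degenerate=False)


def _fit_circle(pts: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Algebraic (Kasa) circle fit; None if the points are collinear."""
    x = pts[:, 0]
    y = pts[:, 1]
    a = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    try:
        sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    except np.linalg.LinAlgError:
        return None
    if rank < 3:
        return None
    cx, cy, c0 = sol
    r2 = c0 + cx**2 + cy**2
    if r2 <= 0:
        return None
    radius = float(np.sqrt(r2))
    if not np.isfinite(radius) or radius <= 0:
        return None
    return np.array([cx, cy]), radius


def orientation_bin(tangent_deg: float) -> int:
    """Bin a tangent angle into the eight (unequal-width) orientation classes.

    Edges: 0-15, 15-30, 30-60, 60-90, 90-120, 120-150, 150-165, 165-180
    degrees (0 deg = vertical), half-open lower-inclusive.
    """
    if not (0.0 <= tangent_deg < 180.0):
        raise ValueError("tangent angle must be in [0, 180)")
    return int(np.searchsorted(_ORIENTATION_EDGES, tangent_deg, side="right"))
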