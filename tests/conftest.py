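"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately use different algorithms from the package:
ray crossings by Amanatides-Woo grid traversal (the package uses slab
intersection tests), curvature by the analytic 1/r of a planted circle,
and connected-component pixel counts from scipy.ndimage labeling.
"""

from __future__ import annotations

import numpy as np
import pytest

from contourcues.cues import N_RAYS, PROBE_OFFSET, RAY_STEP_DEG
from contourcues.geometry import ContourMap, ContourPatch, _chain_through


def make_patch(grid: np.ndarray, chain: np.ndarray | None = None) -> ContourPatch:
    """Build a patch from a raw 69x69 grid, tracing the center chain."""
    if chain is None:
        chain = _chain_through(ContourMap(grid), (34, 34))
    return ContourPatch(grid, chain=chain)


def rot90_patch(patch: ContourPatch, k: int = 1) -> ContourPatch:
    """Rotate a patch by k*90 deg (grid and chain together)."""
    grid = patch.grid.copy()
    chain = patch.chain.copy()
    n = grid.shape[0]
    for _ in range(k % 4):
        grid = np.rot90(grid)
        chain = np.column_stack([n - 1 - chain[:, 1], chain[:, 0]])
    return ContourPatch(grid, chain=chain, provenance=patch.provenance + f"+rot{k * 90}")


def mirror_patch(patch: ContourPatch) -> ContourPatch:
    """Left-right mirror of a patch (grid and chain together)."""
    n = patch.grid.shape[0]
    grid = patch.grid[:, ::-1].copy()
    chain = np.column_stack([patch.chain[:, 0], n - 1 - patch.chain[:, 1]])
    return ContourPatch(grid, chain=chain, provenance=patch.provenance + "+mirror")


# ---------------------------------------------------------------- oracles


def dda_ray_crosses(grid: np.ndarray, probe: np.ndarray, d: np.ndarray) -> bool:
    """Grid-traversal oracle: does the ray visit any contour pixel cell?"""
    n = grid.shape[0]
    r, c = int(round(probe[0])), int(round(probe[1]))
    tr_d = abs(1.0 / d[0]) if d[0] != 0 else np.inf
    tc_d = abs(1.0 / d[1]) if d[1] != 0 else np.inf
    tr_max = ((r + 0.5 * np.sign(d[0])) - probe[0]) / d[0] if d[0] != 0 else np.inf
    tc_max = ((c + 0.5 * np.sign(d[1])) - probe[1]) / d[1] if d[1] != 0 else np.inf
    sr, sc = int(np.sign(d[0])), int(np.sign(d[1]))
    while 0 <= r < n and 0 <= c < n:
        if grid[r, c]:
            return True
        if abs(tr_max - tc_max) < 1e-12:
            # exact corner: the ray grazes both adjacent cells
            if 0 <= r + sr < n and grid[r + sr, c]:
                return True
            if 0 <= c + sc < n and grid[r, c + sc]:
                return True
            r += sr
            c += sc
            tr_max += tr_d
            tc_max += tc_d
        elif tr_max < tc_max:
            r += sr
            tr_max += tr_d
        else:
            c += sc
            tc_max += tc_d
    return False


def oracle_closure(patch: ContourPatch, frame) -> int:
    """Brute-force closure: DDA ray casting from both probe points."""
    center = np.array(patch.center, dtype=float)
    normal = np.asarray(frame.convex_normal, dtype=float)

    def count(probe: np.ndarray, first: np.ndarray) -> int:
        base = np.arctan2(first[1], first[0])
        hits = 0
        for k in range(N_RAYS):
            ang = base + np.deg2rad(RAY_STEP_DEG) * k
            if dda_ray_crosses(patch.grid, probe, np.array([np.cos(ang), np.sin(ang)])):
                hits += 1
        return hits

    return (count(center + PROBE_OFFSET * normal, normal)
            - count(center - PROBE_OFFSET * normal, -normal))


def open_curve_pool(n: int, start_seed: int = 0, smoothness: float = 1.0):
    """Open-curve patches with valid local frames (skipping short chains)."""
    from contourcues.geometry import local_frame
    from contourcues.synth import generate_open_curve

    out = []
    seed = start_seed
    while len(out) < n:
        try:
            patch = generate_open_curve(smoothness, seed=seed)
            frame = local_frame(patch)
            out.append((patch, frame))
        except ValueError:
            pass
        seed += 1
    return out


@pytest.fixture(scope="session")
def random_patch_pool():
    """20 open-curve patches with frames, shared across tests."""
    return open_curve_pool(20, start_seed=100)


@pytest.fixture
def vertical_line_patch() -> ContourPatch:
    grid = np.zeros((69, 69), dtype=np.uint8)
    grid[:, 34] = 1
    return make_patch(grid)
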