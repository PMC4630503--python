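"""Reading and writing contour maps, patches and tabular artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .geometry import ContourMap, ContourPatch


def load_map(path) -> ContourMap:
    """Read a contour map from an 8-bit grayscale PNG (nonzero = contour)
    or a whitespace-delimited 0/1 text grid."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        arr = np.asarray(Image.open(path).convert("L"))
        grid = (arr > 0).astype(np.uint8)
    else:
        grid = np.loadtxt(path, dtype=int)
        grid = np.atleast_2d(grid).astype(np.uint8)
    return ContourMap(grid, provenance=str(path))


def save_map(cmap: ContourMap, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".png":
        Image.fromarray((cmap.grid * 255).astype(np.uint8), mode="L").save(path)
    else:
        np.savetxt(path, cmap.grid, fmt="%d")


def save_patch(patch: ContourPatch, png_path) -> None:
    """Patch PNG plus a JSON sidecar with center, chain length and provenance."""
    png_path = Path(png_path)
    Image.fromarray((patch.grid * 255).astype(np.uint8), mode="L").save(png_path)
    sidecar = {
        "center": list(patch.center),
        "chain_length": int(len(patch.chain)),
        "provenance": patch.provenance,
    }
    png_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def save_stimulus(image: np.ndarray, path) -> None:
    """Gaussian-windowed stimulus as an 8-bit grayscale PNG."""
    arr = np.clip(image * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def cue_table_frame(records: list[dict]) -> pd.DataFrame:
    """Cue export schema: one row per patch."""
    cols = ["patch_id", "convexity", "closure", "symmetry", "orientation_deg",
            "orientation_bin", "theta_star", "x_star", "dos_star", "degenerate_flag"]
    return pd.DataFrame(records, columns=cols)
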