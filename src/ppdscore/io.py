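"""Readers/writers binding the pipeline stages: images, masks, CSV tables.

Every CSV written by the pipeline starts with a provenance header of
``#``-prefixed lines (package version, config hash, seed).  No timestamps
are written, so re-running a command on unchanged inputs yields
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import polygon2mask

from . import __version__
from .exceptions import ShapeError


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF photograph as an array (RGB or grayscale)."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return arr


def read_mask(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a user-supplied ROI mask.

    Single-channel PNG: nonzero pixels are ROI.  CSV: polygon vertices as
    ``x,y`` columns in 0-based pixel coordinates, rasterized against
    ``shape`` (required for CSV input).
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        if shape is None:
            raise ValueError("polygon masks need the target image shape")
        verts = pd.read_csv(path)
        if not {"x", "y"}.issubset(verts.columns):
            raise ValueError("polygon CSV must have x,y columns")
        # polygon2mask expects (row, col) = (y, x)
        return polygon2mask(shape, np.column_stack([verts["y"], verts["x"]]))
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ShapeError(f"mask at {path} is not a 2-D raster")
    return arr > 0


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed: int | None, config: Mapping | None = None) -> list[str]:
    lines = [f"# ppdscore {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config: {config_hash(config)}")
    return lines


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    """Write a CSV table with a provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = "\n".join(provenance_header(seed, config))
    with open(path, "w", newline="") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV table, skipping any provenance header lines."""
    return pd.read_csv(path, comment="#")
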