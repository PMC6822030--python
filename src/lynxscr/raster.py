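"""Export of pixel density surfaces.

Density surfaces live on the state-space grid (individuals per pixel).
They are written as ESRI ASCII grids (readable by any GIS, in the input
projected CRS) and as long-format CSV (x, y, density).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .statespace import StateSpace

__all__ = ["surface_to_grid", "write_ascii_grid", "write_surface_csv"]


def surface_to_grid(values: np.ndarray, ss: StateSpace) -> np.ndarray:
    """Reshape a per-pixel vector to an (nx, ny) array indexed [ix, iy]."""
    values = np.asarray(values, dtype=float)
    if values.size != ss.n_pixels:
        raise ValueError("surface length does not match the state-space")
    return values.reshape(ss.nx, ss.ny)


def write_ascii_grid(values: np.ndarray, ss: StateSpace, path, nodata=-9999.0):
    """Write a per-pixel surface as an ESRI ASCII grid (rows north to south)."""
    grid = surface_to_grid(values, ss)
    with open(path, "w") as fh:
        fh.write(f"ncols {ss.nx}\n")
        fh.write(f"nrows {ss.ny}\n")
        fh.write(f"xllcorner {ss.x0:.6f}\n")
        fh.write(f"yllcorner {ss.y0:.6f}\n")
        fh.write(f"cellsize {ss.resolution:.6f}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for iy in range(ss.ny - 1, -1, -1):  # top row first
            fh.write(" ".join(f"{grid[ix, iy]:.8g}" for ix in range(ss.nx)) + "\n")


def write_surface_csv(values: np.ndarray, ss: StateSpace, path):
    """Write a per-pixel surface as long-format CSV: x, y, density."""
    pd.DataFrame(
        {
            "x": ss.centers[:, 0],
            "y": ss.centers[:, 1],
            "density": np.asarray(values, dtype=float),
        }
    ).to_csv(path, index=False)
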