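"""Discrete state-space of candidate activity centers.

The state-space S is the rectangle obtained by buffering the outermost trap
locations (default 15 km, at least twice the expected movement scale sigma)
and discretizing it into square pixels (default 1.5 km, pixel area 2.25 km2).
Each pixel center is a candidate activity-center location over which the
individual likelihood is marginalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import TrapArray

__all__ = ["StateSpace", "build_state_space"]


@dataclass
class StateSpace:
    centers: np.ndarray  # (G, 2) pixel centers, meters
    resolution: float  # pixel side, meters
    buffer: float  # buffer width used around the traps, meters
    nx: int
    ny: int
    x0: float  # lower-left corner of the grid (not a pixel center)
    y0: float

    @property
    def n_pixels(self) -> int:
        return self.centers.shape[0]

    @property
    def pixel_area(self) -> float:
        """Pixel area in m2 (resolution squared)."""
        return self.resolution**2

    @property
    def area(self) -> float:
        """Total state-space area in m2."""
        return self.n_pixels * self.pixel_area

    def contains_traps(self, traps: TrapArray) -> bool:
        """Whether every trap lies within the hull of the pixel centers."""
        cx, cy = self.centers[:, 0], self.centers[:, 1]
        return bool(
            (traps.x >= cx.min()).all()
            and (traps.x <= cx.max()).all()
            and (traps.y >= cy.min()).all()
            and (traps.y <= cy.max()).all()
        )

    def buffer_adequate(self, sigma: float, factor: float = 2.0) -> bool:
        """Post-fit check that the buffer is at least ``factor`` * sigma."""
        return self.buffer >= factor * sigma


def build_state_space(
    traps: TrapArray, buffer: float = 15000.0, resolution: float = 1500.0
) -> StateSpace:
    """Regular pixel grid buffering the outermost traps.

    The grid spans [min_x - buffer, max_x + buffer] x [min_y - buffer,
    max_y + buffer] with ceil(span / resolution) pixels per axis; the first
    pixel center sits at min - buffer + resolution / 2.
    """
    if traps.n_sites == 0:
        raise ValueError("empty TrapArray")
    if buffer <= 0 or resolution <= 0:
        raise ValueError("buffer and resolution must be positive")
    x0 = traps.x.min() - buffer
    y0 = traps.y.min() - buffer
    nx = math.ceil((traps.x.max() + buffer - x0) / resolution)
    ny = math.ceil((traps.y.max() + buffer - y0) / resolution)
    xs = x0 + resolution * (np.arange(nx) + 0.5)
    ys = y0 + resolution * (np.arange(ny) + 0.5)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    return StateSpace(centers, float(resolution), float(buffer), nx, ny, x0, y0)
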