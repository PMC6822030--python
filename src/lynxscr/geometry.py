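"""Movement distances and effective-trapping-area geometry.

Nonspatial abundance estimates are converted to densities by dividing by an
effective trapping area (ETA): the convex hull of the trap locations dilated
by a buffer equal to the mean maximum distance moved (MMDM) or half of it
(HMMDM).  MMDM averages, over individuals photographed at more than one
site, the maximum pairwise distance between their capture sites.

For a convex hull the dilated area has the exact Minkowski closed form
A + P*w + pi*w^2 (hull area, perimeter, buffer width); degenerate hulls
reduce to pi*w^2 for a point and 2*L*w + pi*w^2 for a segment of length L.
That closed form is what `effective_trapping_area` reports; the shapely
buffer polygon is attached for mapping and export.  A union-of-discs
variant (a disc of radius w around every trap) is available for sensitivity
analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from shapely.geometry import MultiPoint
from shapely.ops import unary_union

from .io import EncounterData, TrapArray

__all__ = [
    "EtaResult",
    "mmdm",
    "max_distance_moved",
    "effective_trapping_area",
    "nonspatial_density",
]

_M2_PER_KM2 = 1e6
_M2_PER_100KM2 = 1e8


@dataclass
class EtaResult:
    """Effective-trapping-area summary (all lengths meters, areas m2)."""

    mmdm: float
    buffer_w: float
    hull_area: float
    hull_perimeter: float
    eta_area: float
    n_individuals_used: int
    polygon: object = None  # shapely geometry of the dilated hull

    @property
    def eta_km2(self) -> float:
        return self.eta_area / _M2_PER_KM2


def max_distance_moved(enc: EncounterData, traps: TrapArray) -> np.ndarray:
    """Per-individual maximum pairwise distance between capture sites.

    Individuals captured at a single site get NaN (they carry no movement
    information).  Duplicate detections and occasion structure are
    irrelevant: only the set of distinct capture sites matters.
    """
    out = np.full(enc.n_individuals, np.nan)
    site_any = enc.y.any(axis=2)  # (n, J)
    for i in range(enc.n_individuals):
        js = np.flatnonzero(site_any[i])
        if js.size >= 2:
            out[i] = pdist(traps.coords[js]).max()
    return out


def mmdm(enc: EncounterData, traps: TrapArray) -> float:
    """Mean maximum distance moved, meters.

    Averages `max_distance_moved` over individuals detected at more than
    one site.  With no eligible individual the MMDM is undefined: NaN is
    returned with a warning, and downstream density conversion refuses it.
    """
    m = max_distance_moved(enc, traps)
    eligible = m[np.isfinite(m)]
    if eligible.size == 0:
        warnings.warn(
            "no individual detected at more than one site; MMDM undefined",
            RuntimeWarning,
        )
        return float("nan")
    return float(eligible.mean())


def effective_trapping_area(
    traps: TrapArray,
    buffer_w: float,
    mmdm_value: float = float("nan"),
    n_individuals_used: int = 0,
    method: str = "hull",
) -> EtaResult:
    """Trap-array polygon dilated by ``buffer_w``.

    method='hull' (default): convex hull of the trap coordinates, ETA area
    by the exact closed form A + P*w + pi*w^2.  method='disc_union':
    union of discs of radius w centered on the traps (sensitivity variant;
    area from the union polygon).
    """
    if traps.n_sites == 0:
        raise ValueError("empty TrapArray")
    if not np.isfinite(buffer_w) or buffer_w < 0:
        raise ValueError(f"buffer width must be finite and >= 0, got {buffer_w}")
    hull = MultiPoint([tuple(c) for c in traps.coords]).convex_hull
    if hull.geom_type == "Polygon":
        area, perim = hull.area, hull.exterior.length
    elif hull.geom_type == "LineString":  # collinear traps
        area, perim = 0.0, 2.0 * hull.length
    else:  # single point (or coincident traps)
        area, perim = 0.0, 0.0
    polygon = hull.buffer(buffer_w, quad_segs=256) if buffer_w > 0 else hull
    if method == "hull":
        eta_area = area + perim * buffer_w + math.pi * buffer_w**2
    elif method == "disc_union":
        discs = unary_union(
            [
                MultiPoint([tuple(c)]).buffer(buffer_w, quad_segs=256)
                for c in traps.coords
            ]
        )
        polygon = discs
        eta_area = discs.area
    else:
        raise ValueError(f"unknown method {method!r}")
    return EtaResult(
        mmdm=float(mmdm_value),
        buffer_w=float(buffer_w),
        hull_area=float(area),
        hull_perimeter=float(perim),
        eta_area=float(eta_area),
        n_individuals_used=int(n_individuals_used),
        polygon=polygon,
    )


def nonspatial_density(N_hat: float, se_N: float, eta: EtaResult) -> tuple[float, float]:
    """Density per 100 km2 from an abundance estimate and an ETA.

    The ETA is treated as fixed: SE(D) = 100 * SE(N) / ETA(km2), matching
    the convention of reporting the abundance SE rescaled by the area.
    """
    if not np.isfinite(eta.eta_area) or eta.eta_area <= 0:
        raise ValueError("ETA area must be positive and finite")
    scale = _M2_PER_100KM2 / eta.eta_area
    return float(N_hat) * scale, float(se_N) * scale
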