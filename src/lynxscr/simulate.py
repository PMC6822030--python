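"""Synthetic camera-trap SCR data with the structure the estimators assume.

The generator emulates a systematic carnivore camera-trap survey: sites on
a checkerboard of 2.7 x 2.7 km cells (every second cell sampled, one
paired-camera site per sampled cell), activity centers from a homogeneous
Poisson process over the discrete state-space, half-normal Bernoulli
detection on active site-occasions, and sex known for only a minority of
individuals.  Individuals never detected are retained in the simulation
truth but omitted from the encounter data, as in a real survey.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .io import EncounterData, TrapArray
from .statespace import StateSpace

__all__ = [
    "SimTruth",
    "make_checkerboard_traps",
    "simulate_scr",
    "assign_sex",
    "write_truth",
    "read_truth",
]


@dataclass
class SimTruth:
    """Generating truth of one simulated session."""

    n_true: int
    centers: np.ndarray  # (N_true, 2) meters
    p0_true: float
    sigma_true: float
    seed: object
    detected: np.ndarray = None  # bool per simulated individual
    activity_used: np.ndarray = None  # mask actually applied (after dropout)

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        if self.n_true != self.centers.shape[0]:
            raise ValueError("n_true must equal the number of centers")
        if not 0.0 <= self.p0_true <= 1.0:
            raise ValueError("p0_true must lie in [0, 1]")
        if self.sigma_true <= 0:
            raise ValueError("sigma_true must be positive")


def make_checkerboard_traps(
    n_cells_x: int,
    n_cells_y: int,
    cell: float = 2700.0,
    origin: tuple = (0.0, 0.0),
    phase: int = 0,
    n_occasions: int = 1,
) -> TrapArray:
    """Systematic design: one site at the center of every second grid cell.

    Cells (row, col) with (row + col + phase) even are sampled; all
    site-occasions are active.  The 2.7 km default cell ensures at least
    one site per plausible lynx home range.
    """
    if n_cells_x < 1 or n_cells_y < 1:
        raise ValueError("need at least one cell per axis")
    if cell <= 0:
        raise ValueError("cell size must be positive")
    if phase not in (0, 1):
        raise ValueError("phase must be 0 or 1")
    ids, xs, ys = [], [], []
    for col in range(n_cells_x):
        for row in range(n_cells_y):
            if (row + col + phase) % 2 == 0:
                ids.append(f"S{len(ids) + 1:03d}")
                xs.append(origin[0] + (col + 0.5) * cell)
                ys.append(origin[1] + (row + 0.5) * cell)
    activity = np.ones((len(ids), n_occasions), dtype=np.int8)
    return TrapArray(ids, np.array(xs), np.array(ys), activity, cell_size=cell)


def simulate_scr(
    traps: TrapArray,
    statespace: StateSpace,
    p0: float,
    sigma: float,
    density: float | None = None,
    n_individuals: int | None = None,
    n_occasions: int | None = None,
    dropout: float = 0.0,
    seed=None,
    session_id: str = "sim",
) -> tuple[EncounterData, SimTruth]:
    """Simulate one session of half-normal SCR encounter histories.

    Either ``density`` (individuals per m2; N ~ Poisson(density * A)) or a
    fixed ``n_individuals`` must be given.  Activity centers are drawn by
    picking a state-space pixel uniformly and jittering uniformly within
    it, matching the estimator's discretization without lattice artifacts.
    ``dropout`` thins the activity mask per site-occasion (camera failure).
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if (density is None) == (n_individuals is None):
        raise ValueError("give exactly one of density and n_individuals")
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    activity = traps.activity
    if n_occasions is not None and n_occasions != traps.n_occasions:
        if not (traps.activity == 1).all():
            raise ValueError(
                "n_occasions override requires a fully active trap mask"
            )
        activity = np.ones((traps.n_sites, n_occasions), dtype=np.int8)
    if dropout > 0:
        keep = rng.random(activity.shape) >= dropout
        activity = (activity * keep).astype(np.int8)

    if density is not None:
        N = int(rng.poisson(density * statespace.area))
    else:
        N = int(n_individuals)
    pix = rng.integers(0, statespace.n_pixels, size=N)
    jitter = rng.uniform(
        -statespace.resolution / 2.0, statespace.resolution / 2.0, size=(N, 2)
    )
    centers = statespace.centers[pix] + jitter

    d2 = ((centers[:, None, :] - traps.coords[None, :, :]) ** 2).sum(axis=2)
    p = p0 * np.exp(-d2 / (2.0 * sigma**2))  # (N, J)
    K = activity.shape[1]
    y = (
        rng.random((N, traps.n_sites, K)) < p[:, :, None]
    ) & (activity[None, :, :] == 1)
    y = y.astype(np.int8)

    detected = y.reshape(N, -1).sum(axis=1) > 0
    ids = [f"L{i + 1:03d}" for i in range(N)]
    enc = EncounterData(
        [ids[i] for i in np.flatnonzero(detected)],
        ["U"] * int(detected.sum()),
        y[detected],
        session_id,
    )
    truth = SimTruth(
        n_true=N,
        centers=centers,
        p0_true=float(p0),
        sigma_true=float(sigma),
        seed=seed,
        detected=detected,
        activity_used=activity,
    )
    return enc, truth


def assign_sex(
    enc: EncounterData, p_female: float, p_male: float, seed=None
) -> EncounterData:
    """Assign iid sex labels F/M/U with P(U) = 1 - p_female - p_male.

    Emulates surveys where sex can be determined from photographs for only
    a minority of individuals.
    """
    if p_female < 0 or p_male < 0 or p_female + p_male > 1 + 1e-12:
        raise ValueError("need p_female, p_male >= 0 with sum <= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(enc.n_individuals)
    sex = np.where(u < p_female, "F", np.where(u < p_female + p_male, "M", "U"))
    return EncounterData(list(enc.individuals), list(sex), enc.y.copy(), enc.session_id)


def write_truth(truth: SimTruth, path) -> None:
    """JSON sidecar with the generating truth of a simulated session."""
    obj = {
        "n_true": truth.n_true,
        "centers": truth.centers.tolist(),
        "p0_true": truth.p0_true,
        "sigma_true": truth.sigma_true,
        "seed": truth.seed if isinstance(truth.seed, (int, type(None))) else str(truth.seed),
        "detected": None
        if truth.detected is None
        else [bool(b) for b in truth.detected],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        obj = json.load(fh)
    return SimTruth(
        n_true=obj["n_true"],
        centers=np.asarray(obj["centers"]),
        p0_true=obj["p0_true"],
        sigma_true=obj["sigma_true"],
        seed=obj.get("seed"),
        detected=None if obj.get("detected") is None else np.asarray(obj["detected"]),
    )
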