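"""Spatial capture-recapture likelihood with a half-normal detection function.

Model.  Individual i carries a latent activity center s_i; detection of i at
trap j on an occasion is Bernoulli with probability

    p_j(s) = p0 * exp(-d(j, s)^2 / (2 sigma^2)),

where d is Euclidean distance in meters, p0 the detection probability for a
trap placed exactly at the activity center, and sigma the movement scale.
Activity centers follow a homogeneous Poisson point process with intensity D
(individuals per m2) over the discrete state-space, giving the session
likelihood (a = pixel area, g indexes pixels)

    -log L = - sum_i log( sum_g D a P(y_i | s_g) ) + sum_g D a pdot(s_g)
             + log(n!),

with pdot(s) = 1 - prod_{j,k active} (1 - p_j(s)) the probability that an
individual centered at s is detected at least once.  Detection probability
does not vary between occasions, so P(y_i | s) depends on y_i only through
the per-site detection counts; this collapse is used throughout.

Multi-session surveys share (p0, sigma) within sharing groups while density
is estimated per session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln, logsumexp

from .io import EncounterData, SessionSet, TrapArray
from .statespace import StateSpace

__all__ = [
    "ScrParams",
    "half_normal_p",
    "marginal_individual_lik",
    "scr_negloglik",
    "session_log_terms",
]

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-12


def half_normal_p(d, p0: float, sigma: float):
    """Half-normal detection probability p0 * exp(-d^2 / (2 sigma^2)).

    d is distance in meters (scalar or array); the result lies in [0, p0]
    and decreases strictly in d.
    """
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distance must be nonnegative")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must lie in [0, 1]")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    out = p0 * np.exp(-(d**2) / (2.0 * sigma**2))
    return out if out.ndim else float(out)


@dataclass
class ScrParams:
    """SCR parameters on unconstrained scales.

    p0_logit and log_sigma hold one entry per detection-sharing group (in
    SessionSet.groups order); log_density holds one entry per session (log
    individuals per m2), in session order.
    """

    p0_logit: np.ndarray
    log_sigma: np.ndarray
    log_density: np.ndarray

    def __post_init__(self):
        self.p0_logit = np.atleast_1d(np.asarray(self.p0_logit, dtype=float))
        self.log_sigma = np.atleast_1d(np.asarray(self.log_sigma, dtype=float))
        self.log_density = np.atleast_1d(np.asarray(self.log_density, dtype=float))
        if self.p0_logit.shape != self.log_sigma.shape:
            raise ValueError("p0_logit and log_sigma must have matching shapes")
        if not (
            np.isfinite(self.p0_logit).all()
            and np.isfinite(self.log_sigma).all()
            and np.isfinite(self.log_density).all()
        ):
            raise ValueError("parameters must be finite")

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.p0_logit, self.log_sigma, self.log_density])

    @classmethod
    def from_vector(cls, v: np.ndarray, n_groups: int) -> "ScrParams":
        v = np.asarray(v, dtype=float)
        return cls(v[:n_groups], v[n_groups : 2 * n_groups], v[2 * n_groups :])

    @property
    def p0(self) -> np.ndarray:
        return expit(self.p0_logit)

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(self.log_sigma)


def _sq_dists(ss: StateSpace, traps: TrapArray) -> np.ndarray:
    """(G, J) squared pixel-center to trap distances in m2."""
    diff = ss.centers[:, None, :] - traps.coords[None, :, :]
    return np.einsum("gjd,gjd->gj", diff, diff)


def session_log_terms(
    traps: TrapArray,
    enc: EncounterData,
    ss: StateSpace,
    p0: float,
    sigma: float,
    d2: np.ndarray | None = None,
):
    """Per-pixel log terms shared by the likelihood and the density surface.

    Returns (logP, log_nodet) where logP[g, i] = log P(y_i | s_g) and
    log_nodet[g] = log P(no detection | s_g); pdot = -expm1(log_nodet).
    Detection counts per individual and site summarize y because p_j(s) is
    occasion-constant.
    """
    if d2 is None:
        d2 = _sq_dists(ss, traps)
    p = np.clip(p0 * np.exp(-d2 / (2.0 * sigma**2)), _P_FLOOR, _P_CEIL)
    lp = np.log(p)
    l1p = np.log1p(-p)
    k_active = traps.activity.sum(axis=1).astype(float)  # (J,)
    log_nodet = l1p @ k_active  # (G,)
    if enc.n_individuals:
        counts = enc.y.sum(axis=2).astype(float)  # (n, J)
        logP = log_nodet[:, None] + (lp - l1p) @ counts.T  # (G, n)
    else:
        logP = np.zeros((ss.n_pixels, 0))
    return logP, log_nodet


def marginal_individual_lik(
    y_i: np.ndarray,
    traps: TrapArray,
    ss: StateSpace,
    p0: float,
    sigma: float,
) -> float:
    """Activity-center-marginal likelihood of one encounter history.

    Returns (1/G) sum_g prod_{j,k active} p_j(s_g)^y [1 - p_j(s_g)]^(1-y),
    computed in log space; with a single pixel this is the plain Bernoulli
    product at that pixel.
    """
    y_i = np.asarray(y_i, dtype=np.int8)
    enc = _singleton(y_i, traps)
    logP, log_nodet = session_log_terms(traps, enc, ss, p0, sigma)
    if enc.n_individuals == 0:  # all-zero history
        return float(np.exp(logsumexp(log_nodet) - np.log(ss.n_pixels)))
    return float(np.exp(logsumexp(logP[:, 0]) - np.log(ss.n_pixels)))


def _singleton(y_i, traps):
    if y_i.sum() == 0:
        return EncounterData([], [], np.zeros((0,) + y_i.shape), "tmp")
    return EncounterData(["i1"], ["U"], y_i[None], "tmp")


def scr_negloglik(
    params: ScrParams, sessions: SessionSet, statespaces: dict
) -> float:
    """Joint negative log-likelihood over all sessions.

    statespaces maps session_id -> StateSpace.  Sessions within a sharing
    group use that group's (p0, sigma); each session uses its own density.
    Includes the log(n!) term, so values are comparable across
    parameterizations.
    """
    groups = sessions.groups
    gidx = {g: i for i, g in enumerate(groups)}
    if params.p0_logit.shape[0] != len(groups):
        raise ValueError(
            f"expected {len(groups)} detection-parameter groups, "
            f"got {params.p0_logit.shape[0]}"
        )
    if params.log_density.shape[0] != len(sessions.sessions):
        raise ValueError("log_density must have one entry per session")
    total = 0.0
    for s, (traps, enc) in enumerate(sessions.sessions):
        g = gidx[sessions.sharing[enc.session_id]]
        ss = statespaces[enc.session_id]
        total += _session_negloglik(
            traps, enc, ss,
            float(params.p0[g]), float(params.sigma[g]),
            float(np.exp(params.log_density[s])),
        )
    return float(total)


def _session_negloglik(traps, enc, ss, p0, sigma, density, d2=None):
    logP, log_nodet = session_log_terms(traps, enc, ss, p0, sigma, d2=d2)
    a = ss.pixel_area
    n = enc.n_individuals
    pdot = -np.expm1(log_nodet)
    exposure = density * a * pdot.sum()
    if n == 0:
        return exposure
    log_Da = np.log(density * a)
    per_ind = log_Da + logsumexp(logP, axis=0)  # (n,)
    return -per_ind.sum() + exposure + gammaln(n + 1)
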