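"""Maximum-likelihood SCR fitting and density surfaces.

`SCRModel` is a scikit-learn-style estimator: hyperparameters (state-space
buffer and resolution, optimizer settings) are constructor arguments, `fit`
takes a `SessionSet`, and fitted quantities carry trailing underscores.

Fitting maximizes the multi-session Poisson point-process likelihood of
`lynxscr.likelihood`.  The density of each session enters the likelihood
through its score equation D_s = n_s / (a * sum_g pdot_s(g)) at fixed
detection parameters, so densities are concentrated (profiled) out and the
optimizer runs on the detection parameters only; the profile maximum is the
joint maximum.  Standard errors come from the inverse observed information
of the *joint* likelihood (finite-difference Hessian over detection and
density parameters together).

Abundance is reported as expected abundance over the state-space,
N = D * A(S); realized abundance (detected individuals plus expected
undetected) is available via `realized_abundance` and coincides with N at
the MLE.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, logsumexp
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess

from .geometry import mmdm
from .io import SessionSet
from .likelihood import ScrParams, _session_negloglik, _sq_dists, scr_negloglik, session_log_terms
from .statespace import StateSpace, build_state_space

__all__ = ["SCRModel", "fit_scr", "density_surface"]

# m2 per 100 km2: densities are reported per 100 km2, the field convention
# for large-carnivore surveys
_M2_PER_100KM2 = 1e8

# deterministic jitters (logit-p0, log-sigma offsets) for multi-start
_START_OFFSETS = [
    (0.0, 0.0),
    (0.7, -0.5),
    (-0.7, 0.5),
    (1.4, 0.7),
    (-1.4, -0.7),
]


class SCRModel(BaseEstimator):
    """Multi-session SCR with half-normal detection and homogeneous density.

    Parameters
    ----------
    buffer : float
        State-space buffer around the outermost traps, meters.
    resolution : float
        State-space pixel side, meters.
    n_starts : int
        Number of optimizer starts, jittered deterministically around a
        method-of-moments initializer (sigma0 = MMDM / 2, p0_0 = 0.1).
    gtol : float
        Gradient-norm tolerance passed to L-BFGS-B.
    """

    def __init__(
        self,
        buffer: float = 15000.0,
        resolution: float = 1500.0,
        n_starts: int = 3,
        gtol: float = 1e-6,
    ):
        self.buffer = buffer
        self.resolution = resolution
        self.n_starts = n_starts
        self.gtol = gtol

    # -- fitting -----------------------------------------------------------

    def fit(self, sessions: SessionSet, statespaces: dict | None = None):
        """Fit shared detection parameters and per-session densities.

        statespaces (session_id -> StateSpace) may be supplied; otherwise
        each session gets `build_state_space(traps, buffer, resolution)`.
        """
        if not isinstance(sessions, SessionSet):
            sessions = SessionSet(list(sessions))
        groups = sessions.groups
        n_groups = len(groups)
        gidx = {g: i for i, g in enumerate(groups)}
        if statespaces is None:
            statespaces = {
                enc.session_id: build_state_space(traps, self.buffer, self.resolution)
                for traps, enc in sessions.sessions
            }
        for traps, enc in sessions.sessions:
            if enc.n_individuals == 0:
                raise ValueError(
                    f"session {enc.session_id!r} has no detected individuals"
                )
        # cache squared distances per session
        d2 = {
            enc.session_id: _sq_dists(statespaces[enc.session_id], traps)
            for traps, enc in sessions.sessions
        }

        def profile_nll(theta):
            p0 = expit(theta[:n_groups])
            sigma = np.exp(theta[n_groups:])
            total = 0.0
            for traps, enc in sessions.sessions:
                g = gidx[sessions.sharing[enc.session_id]]
                ss = statespaces[enc.session_id]
                dens = _profile_density(
                    traps, enc, ss, p0[g], sigma[g], d2[enc.session_id]
                )
                total += _session_negloglik(
                    traps, enc, ss, p0[g], sigma[g], dens, d2=d2[enc.session_id]
                )
            return total

        theta0 = self._initial_theta(sessions, gidx, n_groups)
        best = None
        for s in range(max(1, int(self.n_starts))):
            off = _START_OFFSETS[s % len(_START_OFFSETS)]
            start = theta0.copy()
            start[:n_groups] += off[0]
            start[n_groups:] += off[1]
            res = minimize(
                profile_nll,
                start,
                method="L-BFGS-B",
                options={"gtol": self.gtol, "ftol": 1e-12, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-9:
                best = res
        theta = best.x
        self.converged_ = bool(best.success)
        self.grad_norm_ = float(np.abs(best.jac).max())
        if not self.converged_:
            warnings.warn(
                f"SCR optimizer did not converge: {best.message}", RuntimeWarning
            )

        p0 = expit(theta[:n_groups])
        sigma = np.exp(theta[n_groups:])
        log_density = np.array(
            [
                np.log(
                    _profile_density(
                        traps, enc, statespaces[enc.session_id],
                        p0[gidx[sessions.sharing[enc.session_id]]],
                        sigma[gidx[sessions.sharing[enc.session_id]]],
                        d2[enc.session_id],
                    )
                )
                for traps, enc in sessions.sessions
            ]
        )
        self.params_ = ScrParams(theta[:n_groups], theta[n_groups:], log_density)
        self.sessions_ = sessions
        self.statespaces_ = statespaces
        self.groups_ = groups
        self.loglik_ = -scr_negloglik(self.params_, sessions, statespaces)
        self._compute_vcov(sessions, statespaces)
        self._summarize(sessions, statespaces, gidx)
        return self

    def _initial_theta(self, sessions, gidx, n_groups):
        sig0 = np.full(n_groups, np.nan)
        counts = np.zeros(n_groups)
        for traps, enc in sessions.sessions:
            g = gidx[sessions.sharing[enc.session_id]]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = mmdm(enc, traps)
            if np.isfinite(m) and m > 0:
                sig0[g] = np.nanmean([sig0[g], m / 2.0])
                counts[g] += 1
        sig0[~np.isfinite(sig0)] = self.buffer / 3.0
        return np.concatenate([np.full(n_groups, logit(0.1)), np.log(sig0)])

    def _compute_vcov(self, sessions, statespaces):
        v = self.params_.to_vector()
        n_groups = len(self.groups_)

        def joint(vec):
            return scr_negloglik(
                ScrParams.from_vector(vec, n_groups), sessions, statespaces
            )

        try:
            H = approx_hess(v, joint)
            vcov = np.linalg.inv(H)
            if not np.all(np.diag(vcov) > 0):
                raise np.linalg.LinAlgError("non-positive variance")
            # symmetrize finite-difference asymmetry
            self.vcov_ = (vcov + vcov.T) / 2.0
            self.se_ok_ = True
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular or indefinite Hessian; SEs reported as NaN",
                RuntimeWarning,
            )
            self.vcov_ = np.full((v.size, v.size), np.nan)
            self.se_ok_ = False

    def _summarize(self, sessions, statespaces, gidx):
        n_groups = len(self.groups_)
        se = np.sqrt(np.abs(np.diag(self.vcov_)))
        rows = []
        for s, (traps, enc) in enumerate(sessions.sessions):
            sid = enc.session_id
            g = gidx[sessions.sharing[sid]]
            ss = statespaces[sid]
            D = float(np.exp(self.params_.log_density[s]))
            A = ss.area
            N = D * A
            se_logD = se[2 * n_groups + s]
            rows.append(
                {
                    "session": sid,
                    "group": sessions.sharing[sid],
                    "n_individuals": enc.n_individuals,
                    "abundance": N,
                    "abundance_se": N * se_logD,
                    "density_100km2": D * _M2_PER_100KM2,
                    "density_se": D * _M2_PER_100KM2 * se_logD,
                    "p0_logit": self.params_.p0_logit[g],
                    "p0_logit_se": se[g],
                    "log_sigma": self.params_.log_sigma[g],
                    "log_sigma_se": se[n_groups + g],
                    "statespace_km2": A / 1e6,
                    "buffer_ge_2sigma": ss.buffer_adequate(
                        float(self.params_.sigma[g])
                    ),
                }
            )
        self.summary_ = pd.DataFrame(rows)

    # -- post-fit quantities ----------------------------------------------

    def _session(self, session_id):
        for s, (traps, enc) in enumerate(self.sessions_.sessions):
            if enc.session_id == session_id:
                return s, traps, enc
        raise KeyError(f"unknown session {session_id!r}")

    def density_surface(self, session_id) -> np.ndarray:
        """Expected activity centers per pixel for one session.

        Pixel g gets the posterior membership of each detected individual,
        sum_i Pr(s_i = g | y_i, theta), plus the expected undetected
        contribution D * a * (1 - pdot(s_g)).  The pixel sum equals the
        abundance estimate.
        """
        s, traps, enc = self._session(session_id)
        gi = self.groups_.index(self.sessions_.sharing[session_id])
        ss = self.statespaces_[session_id]
        p0 = float(self.params_.p0[gi])
        sigma = float(self.params_.sigma[gi])
        D = float(np.exp(self.params_.log_density[s]))
        logP, log_nodet = session_log_terms(traps, enc, ss, p0, sigma)
        surface = D * ss.pixel_area * np.exp(log_nodet)  # (1 - pdot) part
        if enc.n_individuals:
            post = np.exp(logP - logsumexp(logP, axis=0, keepdims=True))
            surface = surface + post.sum(axis=1)
        return surface

    def realized_abundance(self, session_id) -> tuple[float, float]:
        """Detected individuals plus expected undetected, with SE.

        Equals expected abundance at the MLE; its SE conditions on the
        observed n and is therefore smaller.
        """
        s, traps, enc = self._session(session_id)
        gi = self.groups_.index(self.sessions_.sharing[session_id])
        ss = self.statespaces_[session_id]
        _, log_nodet = session_log_terms(
            traps, enc, ss, float(self.params_.p0[gi]), float(self.params_.sigma[gi])
        )
        D = float(np.exp(self.params_.log_density[s]))
        undet_per_D = ss.pixel_area * np.exp(log_nodet).sum()
        n_groups = len(self.groups_)
        se_logD = float(np.sqrt(np.abs(self.vcov_[2 * n_groups + s, 2 * n_groups + s])))
        return enc.n_individuals + D * undet_per_D, D * undet_per_D * se_logD


def _profile_density(traps, enc, ss, p0, sigma, d2):
    """Closed-form density MLE at fixed detection parameters."""
    _, log_nodet = session_log_terms(traps, enc, ss, p0, sigma, d2=d2)
    pdot_sum = float(-np.expm1(log_nodet).sum())
    return enc.n_individuals / (ss.pixel_area * max(pdot_sum, 1e-300))


def fit_scr(sessions: SessionSet, **config) -> SCRModel:
    """Fit an SCRModel; keyword arguments are SCRModel hyperparameters."""
    statespaces = config.pop("statespaces", None)
    return SCRModel(**config).fit(sessions, statespaces=statespaces)


def density_surface(fit: SCRModel, session_id) -> np.ndarray:
    """Per-pixel expected activity centers for a fitted session."""
    return fit.density_surface(session_id)
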