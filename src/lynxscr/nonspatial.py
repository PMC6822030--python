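"""Closed-population abundance estimators M0 and Mh.

The spatial information is dropped: an individual is scored detected or not
in each occasion (detection at any site counts once), and the per-capture-
count frequencies f_c (number of individuals detected in exactly c of the K
occasions) summarize the data.

M0 assumes a common detection probability p for all individuals and
occasions and maximizes

    L(N, p) ∝ N! / (N - n)! * p^T * (1 - p)^(N K - T),      T = sum_c c f_c,

over real N >= n (profile p_hat(N) = T / (N K)).  Mh allows detection
probability to vary between individuals; the default estimator is Chao's
moment-based lower bound N = n + f1^2 / (2 f2), with the bias-corrected
form n + f1 (f1 - 1) / (2 (f2 + 1)) when f2 = 0, and Chao's variance
formula.  The first-order jackknife is available as an alternative because
the heterogeneity estimator actually used by any given study is often not
identifiable from its report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, polygamma
from sklearn.base import BaseEstimator

from .io import EncounterData

__all__ = [
    "CaptureFrequencies",
    "capture_frequencies",
    "M0Estimator",
    "MhEstimator",
    "fit_m0",
    "fit_mh_chao",
    "fit_mh_jackknife",
]


@dataclass
class CaptureFrequencies:
    """Capture-count frequencies: f[c-1] individuals seen in exactly c of K
    occasions; n = sum(f)."""

    K: int
    f: np.ndarray

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=int)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.f.shape != (self.K,):
            raise ValueError(f"f must have length K={self.K}")
        if (self.f < 0).any():
            raise ValueError("frequencies must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.f.sum())

    @property
    def total_detections(self) -> int:
        """T = sum_c c * f_c, the number of individual-occasion detections."""
        return int((np.arange(1, self.K + 1) * self.f).sum())


def capture_frequencies(enc: EncounterData, K: int | None = None) -> CaptureFrequencies:
    """Tally per-individual occasion-detection counts from encounter data.

    An individual is detected in occasion k if it was photographed at any
    site during k; multiple sites within one occasion count once.
    """
    if K is None:
        K = enc.y.shape[2]
    det = enc.y.any(axis=1)  # (n, K) occasion-level indicator
    counts = det.sum(axis=1)
    f = np.bincount(counts, minlength=K + 1)[1 : K + 1]
    return CaptureFrequencies(K, f)


class M0Estimator(BaseEstimator):
    """Closed-population model M0: constant detection probability.

    Fitted attributes: N_ (real-valued MLE), N_rounded_, p_, N_se_, p_se_,
    boundary_ (True when the likelihood increases without bound in N).
    """

    def __init__(self, N_max_factor: float = 1e4):
        self.N_max_factor = N_max_factor

    @staticmethod
    def loglik(N: float, p: float, freq: CaptureFrequencies) -> float:
        n, K, T = freq.n, freq.K, freq.total_detections
        if N < n or not 0 < p < 1:
            return -np.inf
        return (
            gammaln(N + 1)
            - gammaln(N - n + 1)
            + T * np.log(p)
            + (N * K - T) * np.log1p(-p)
        )

    def fit(self, freq: CaptureFrequencies):
        n, K, T = freq.n, freq.K, freq.total_detections
        if n < 1:
            raise ValueError("need at least one detected individual")
        if K < 2:
            raise ValueError("need at least two occasions")
        self.boundary_ = False
        if T == n * K:  # everyone detected at every occasion
            self.N_, self.p_ = float(n), 1.0
            self.N_se_ = self.p_se_ = float("nan")
            self.N_rounded_ = n
            return self

        def prof_nll(N):
            p = T / (N * K)
            return -self.loglik(N, p, freq)

        hi = n * self.N_max_factor
        res = minimize_scalar(
            prof_nll, bounds=(float(n), hi), method="bounded",
            options={"xatol": 1e-8 * n},
        )
        self.N_ = float(res.x)
        self.p_ = T / (self.N_ * K)
        if self.N_ > 0.99 * hi:
            self.boundary_ = True
            warnings.warn(
                "M0 likelihood maximized at the search boundary; the data "
                "(few repeat detections) do not support a finite estimate",
                RuntimeWarning,
            )
        self._standard_errors(freq)
        self.N_rounded_ = int(round(self.N_))
        return self

    def _standard_errors(self, freq):
        # analytic observed information; well-defined down to N = n
        n, K, T = freq.n, freq.K, freq.total_detections
        N, p = self.N_, self.p_
        i_NN = polygamma(1, N - n + 1) - polygamma(1, N + 1)
        i_Np = K / (1.0 - p)
        i_pp = T / p**2 + (N * K - T) / (1.0 - p) ** 2
        info = np.array([[i_NN, i_Np], [i_Np, i_pp]])
        try:
            vcov = np.linalg.inv(info)
            if vcov[0, 0] <= 0 or vcov[1, 1] <= 0:
                raise np.linalg.LinAlgError("non-positive variance")
            self.N_se_ = float(np.sqrt(vcov[0, 0]))
            self.p_se_ = float(np.sqrt(vcov[1, 1]))
        except np.linalg.LinAlgError:
            warnings.warn("singular information matrix for M0 SEs", RuntimeWarning)
            self.N_se_ = self.p_se_ = float("nan")


class MhEstimator(BaseEstimator):
    """Heterogeneous-detection abundance: Chao lower bound (default) or
    first-order jackknife.

    Fitted attributes: N_, N_se_, N_rounded_.
    """

    def __init__(self, method: str = "chao"):
        self.method = method

    def fit(self, freq: CaptureFrequencies):
        n, K = freq.n, freq.K
        if n < 1:
            raise ValueError("need at least one detected individual")
        f1 = int(freq.f[0])
        f2 = int(freq.f[1]) if K >= 2 else 0
        if self.method == "chao":
            if f1 == 0:
                self.N_, self.N_se_ = float(n), 0.0
            elif f2 > 0:
                self.N_ = n + f1**2 / (2.0 * f2)
                r = f1 / f2
                self.N_se_ = float(
                    np.sqrt(f2 * (0.25 * r**4 + r**3 + 0.5 * r**2))
                )
            else:
                self.N_ = n + f1 * (f1 - 1) / 2.0
                var = (
                    f1 * (f1 - 1) / 2.0
                    + f1 * (2 * f1 - 1) ** 2 / 4.0
                    - f1**4 / (4.0 * self.N_)
                )
                self.N_se_ = float(np.sqrt(max(var, 0.0)))
        elif self.method == "jackknife":
            self.N_ = n + f1 * (K - 1) / K
            # Burnham-Overton first-order jackknife variance
            c = np.arange(1, K + 1)
            a = np.where(c == 1, (2 * K - 1) / K, 1.0)
            var = float((a**2 * freq.f).sum() - self.N_)
            self.N_se_ = float(np.sqrt(max(var, 0.0)))
        else:
            raise ValueError(f"unknown Mh method {self.method!r}")
        self.N_ = float(self.N_)
        self.N_rounded_ = int(round(self.N_))
        return self


def fit_m0(freq: CaptureFrequencies) -> tuple[float, float, float, float]:
    """M0 MLE: returns (N_hat, p_hat, SE_N, SE_p)."""
    est = M0Estimator().fit(freq)
    return est.N_, est.p_, est.N_se_, est.p_se_


def fit_mh_chao(freq: CaptureFrequencies) -> tuple[float, float]:
    """Chao lower-bound Mh abundance: returns (N_hat, SE)."""
    est = MhEstimator(method="chao").fit(freq)
    return est.N_, est.N_se_


def fit_mh_jackknife(freq: CaptureFrequencies) -> tuple[float, float]:
    """First-order jackknife Mh abundance: returns (N_hat, SE)."""
    est = MhEstimator(method="jackknife").fit(freq)
    return est.N_, est.N_se_
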