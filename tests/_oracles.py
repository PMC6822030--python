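"""Independent brute-force oracles, deliberately naive.

These re-derive likelihood values by direct enumeration with plain Python
floats and loops, sharing no code path with the package implementation.
"""

import math

import numpy as np


def brute_scr_negloglik(sessions_params):
    """Naive multi-session SCR negative log-likelihood.

    sessions_params: list of dicts with keys traps, enc, ss, p0, sigma,
    density.  Enumerates pixels, sites, occasions and individuals directly.
    """
    total = 0.0
    for sp in sessions_params:
        traps, enc, ss = sp["traps"], sp["enc"], sp["ss"]
        p0, sigma, D = sp["p0"], sp["sigma"], sp["density"]
        a = ss.resolution**2
        G = ss.centers.shape[0]
        J = traps.n_sites
        K = traps.n_occasions
        n = enc.y.shape[0]

        def det_p(g, j):
            dx = ss.centers[g][0] - traps.x[j]
            dy = ss.centers[g][1] - traps.y[j]
            return p0 * math.exp(-(dx * dx + dy * dy) / (2.0 * sigma * sigma))

        exposure = 0.0
        for g in range(G):
            prod = 1.0
            for j in range(J):
                p = det_p(g, j)
                for k in range(K):
                    if traps.activity[j, k]:
                        prod *= 1.0 - p
            exposure += D * a * (1.0 - prod)
        total += exposure + math.lgamma(n + 1)
        for i in range(n):
            acc = 0.0
            for g in range(G):
                lik = 1.0
                for j in range(J):
                    p = det_p(g, j)
                    for k in range(K):
                        if traps.activity[j, k]:
                            lik *= p if enc.y[i, j, k] else 1.0 - p
                acc += D * a * lik
            total -= math.log(acc)
    return total


def m0_profile_grid(n, K, T, n_grid=400001, N_max_factor=50.0):
    """Grid-search M0 MLE of N: profile likelihood on a fine grid."""
    Ns = np.linspace(n, n * N_max_factor, n_grid)
    p = T / (Ns * K)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            [math.lgamma(N + 1) - math.lgamma(N - n + 1) for N in Ns]
            + T * np.log(p)
            + (Ns * K - T) * np.log1p(-p)
        )
    ll = np.asarray(ll)
    return float(Ns[np.nanargmax(ll)])


def truncated_binomial_mle(counts, K):
    """Zero-truncated binomial MLE of p by fine grid search."""
    counts = np.asarray(counts)
    ps = np.linspace(1e-6, 1 - 1e-6, 200001)
    pdot = 1.0 - (1.0 - ps) ** K
    ll = (
        counts.sum() * np.log(ps)
        + (counts.size * K - counts.sum()) * np.log1p(-ps)
        - counts.size * np.log(pdot)
    )
    return float(ps[np.argmax(ll)])
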