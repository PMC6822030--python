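import numpy as np
import pytest
from scipy.special import expit

from lynxscr import SCRModel, SessionSet, StateSpace, build_state_space
from lynxscr.io import EncounterData, TrapArray
from lynxscr.simulate import make_checkerboard_traps, simulate_scr

# generating values for the recovery experiment: the shared detection
# parameters of the 2013 surveys (logit p0 = -2.34, log sigma = 8.80) on a
# ~90-site checkerboard with 13 five-night occasions and ~30 expected
# activity centers in the 15-km-buffered state-space
RECOVERY_P0_LOGIT = -2.34
RECOVERY_LOG_SIGMA = 8.80
RECOVERY_EXPECTED_N = 30.0
RECOVERY_N_OCCASIONS = 13
RECOVERY_REPLICATES = 100


def make_tiny_instance(rng, G=None, J=None, K=None, n=None):
    """Random tiny SCR instance for enumeration oracles (G<=4, J<=3, K<=3,
    n<=3), valid under all data-model invariants."""
    G = G if G is not None else int(rng.integers(1, 5))
    J = J if J is not None else int(rng.integers(1, 4))
    K = K if K is not None else int(rng.integers(1, 4))
    n = n if n is not None else int(rng.integers(0, 4))
    coords = rng.uniform(300.0, 9000.0, size=(J, 2))
    activity = rng.integers(0, 2, size=(J, K))
    for j in range(J):
        if activity[j].sum() == 0:
            activity[j, rng.integers(K)] = 1
    traps = TrapArray(
        [f"T{j}" for j in range(J)], coords[:, 0], coords[:, 1], activity
    )
    centers = rng.uniform(0.0, 10000.0, size=(G, 2))
    res = float(rng.uniform(500.0, 2000.0))
    ss = StateSpace(centers, res, buffer=1000.0, nx=G, ny=1, x0=0.0, y0=0.0)
    y = np.zeros((n, J, K), dtype=np.int8)
    for i in range(n):
        y[i] = (rng.random((J, K)) < 0.45) & (activity == 1)
        if y[i].sum() == 0:
            j = int(rng.integers(J))
            k = int(rng.choice(np.flatnonzero(activity[j])))
            y[i, j, k] = 1
    enc = EncounterData([f"i{i}" for i in range(n)], ["U"] * n, y, "tiny")
    p0 = float(rng.uniform(0.05, 0.9))
    sigma = float(rng.uniform(800.0, 6000.0))
    density = float(max(n, 1) / (res**2 * G) * rng.uniform(0.3, 3.0))
    return dict(traps=traps, enc=enc, ss=ss, p0=p0, sigma=sigma, density=density)


@pytest.fixture(scope="session")
def recovery_traps():
    return make_checkerboard_traps(13, 14, n_occasions=RECOVERY_N_OCCASIONS)


@pytest.fixture(scope="session")
def recovery_fits(recovery_traps):
    """Replicate simulate-and-fit experiment at the study conditions.

    Returns per-replicate MLEs and Wald SEs for logit p0 and log sigma,
    plus one representative fitted model for surface checks.
    """
    ss = build_state_space(recovery_traps)
    p0 = float(expit(RECOVERY_P0_LOGIT))
    sigma = float(np.exp(RECOVERY_LOG_SIGMA))
    density = RECOVERY_EXPECTED_N / ss.area
    rows = {"p0_logit": [], "log_sigma": [], "p0_logit_se": [], "log_sigma_se": [],
            "n": [], "converged": []}
    first_fit = None
    for child in np.random.SeedSequence(987654321).spawn(RECOVERY_REPLICATES):
        enc, truth = simulate_scr(
            recovery_traps, ss, p0=p0, sigma=sigma, density=density,
            seed=np.random.default_rng(child),
        )
        if enc.n_individuals < 2:
            continue
        fit = SCRModel(n_starts=1).fit(
            SessionSet([(recovery_traps, enc)]), statespaces={"sim": ss}
        )
        r = fit.summary_.iloc[0]
        rows["p0_logit"].append(r.p0_logit)
        rows["log_sigma"].append(r.log_sigma)
        rows["p0_logit_se"].append(r.p0_logit_se)
        rows["log_sigma_se"].append(r.log_sigma_se)
        rows["n"].append(enc.n_individuals)
        rows["converged"].append(fit.converged_)
        if first_fit is None:
            first_fit = fit
    out = {k: np.asarray(v) for k, v in rows.items()}
    out["fit"] = first_fit
    out["truth"] = {"p0_logit": RECOVERY_P0_LOGIT, "log_sigma": RECOVERY_LOG_SIGMA}
    return out
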