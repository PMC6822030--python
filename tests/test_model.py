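"""SCR fitting: degenerate closed forms, sharing, surfaces, recovery."""

import numpy as np
import pytest
from scipy.special import expit

from lynxscr import SCRModel, SessionSet, StateSpace, build_state_space, fit_scr
from lynxscr.io import EncounterData, TrapArray
from lynxscr.simulate import make_checkerboard_traps, simulate_scr

from _oracles import truncated_binomial_mle


@pytest.fixture(scope="module")
def small_fit():
    """One moderate synthetic session fitted once, reused across checks."""
    traps = make_checkerboard_traps(8, 8, n_occasions=10)
    ss = build_state_space(traps, buffer=10000.0, resolution=2000.0)
    enc, truth = simulate_scr(
        traps, ss, p0=0.15, sigma=4000.0, density=25.0 / ss.area, seed=42
    )
    fit = SCRModel(buffer=10000.0, resolution=2000.0).fit(
        SessionSet([(traps, enc)]), statespaces={"sim": ss}
    )
    return traps, ss, enc, fit


def test_single_pixel_fit_matches_truncated_binomial_mle():
    """With one pixel and one trap the SCR model degenerates to a
    zero-truncated binomial: detection probability at the pixel's distance
    and N = n / pdot have closed forms."""
    K = 12
    traps = TrapArray(["T"], [2000.0], [2000.0], np.ones((1, K)))
    ss = StateSpace(np.array([[2000.0, 2500.0]]), 800.0, 0.0, 1, 1, 0.0, 0.0)
    counts = np.array([7, 4, 2, 9, 5])  # detections per individual over K
    y = np.zeros((5, 1, K), dtype=int)
    for i, c in enumerate(counts):
        y[i, 0, :c] = 1
    enc = EncounterData([f"i{i}" for i in range(5)], ["U"] * 5, y, "deg")
    fit = SCRModel(n_starts=3).fit(SessionSet([(traps, enc)]), statespaces={"deg": ss})
    p_hat_grid = truncated_binomial_mle(counts, K)
    d = 500.0
    p0 = float(fit.params_.p0[0])
    sigma = float(fit.params_.sigma[0])
    p_hat_fit = p0 * np.exp(-(d**2) / (2 * sigma**2))
    assert p_hat_fit == pytest.approx(p_hat_grid, rel=1e-4)
    N_hat = fit.summary_.abundance[0]
    assert N_hat == pytest.approx(5.0 / (1 - (1 - p_hat_grid) ** K), rel=1e-4)


def test_sharing_two_identical_sessions_equals_one_doubled_session():
    traps = make_checkerboard_traps(6, 6, n_occasions=8)
    ss = build_state_space(traps, buffer=8000.0, resolution=2000.0)
    enc, _ = simulate_scr(
        traps, ss, p0=0.2, sigma=3500.0, density=20.0 / ss.area, seed=5
    )
    e1 = EncounterData(enc.individuals, enc.sex, enc.y, "a")
    e2 = EncounterData(enc.individuals, enc.sex, enc.y.copy(), "b")
    shared = SCRModel(buffer=8000.0, resolution=2000.0).fit(
        SessionSet([(traps, e1), (traps, e2)], {"a": "g", "b": "g"})
    )
    doubled = EncounterData(
        [f"{i}_1" for i in enc.individuals] + [f"{i}_2" for i in enc.individuals],
        enc.sex * 2,
        np.concatenate([enc.y, enc.y]),
        "ab",
    )
    single = SCRModel(buffer=8000.0, resolution=2000.0).fit(
        SessionSet([(traps, doubled)])
    )
    assert shared.params_.p0_logit[0] == pytest.approx(
        single.params_.p0_logit[0], abs=1e-4
    )
    assert shared.params_.log_sigma[0] == pytest.approx(
        single.params_.log_sigma[0], abs=1e-4
    )
    # per-session densities halve relative to the doubled fit
    assert np.exp(shared.params_.log_density).sum() == pytest.approx(
        np.exp(single.params_.log_density[0]), rel=1e-3
    )


class TestDensitySurface:
    def test_pixel_sum_equals_abundance(self, small_fit):
        _, _, _, fit = small_fit
        surf = fit.density_surface("sim")
        assert surf.sum() == pytest.approx(fit.summary_.abundance[0], rel=1e-8)

    def test_vanishing_p0_gives_flat_surface(self, small_fit):
        """With no detection information the surface is the uniform prior
        intensity D * a in every pixel."""
        from lynxscr import ScrParams

        traps, ss, enc, fit = small_fit
        empty = EncounterData([], [], np.zeros((0, traps.n_sites, 10)), "none")
        lame = SCRModel(buffer=10000.0, resolution=2000.0)
        lame.sessions_ = SessionSet([(traps, empty)])
        lame.statespaces_ = {"none": ss}
        lame.groups_ = ["none"]
        log_D = float(fit.params_.log_density[0])
        lame.params_ = ScrParams([-30.0], fit.params_.log_sigma, [log_D])
        surf = lame.density_surface("none")
        expected = np.exp(log_D) * ss.pixel_area
        assert np.ptp(surf) / surf.mean() < 1e-9
        assert surf.mean() == pytest.approx(expected, rel=1e-9)

    def test_posterior_concentrates_at_the_capture_site(self):
        traps = make_checkerboard_traps(6, 6, n_occasions=10)
        ss = build_state_space(traps, buffer=6000.0, resolution=1500.0)
        j = 17
        y = np.zeros((1, traps.n_sites, 10), dtype=int)
        y[0, j, :] = 1  # one animal caught at one site every occasion
        enc = EncounterData(["loner"], ["U"], y, "one")
        fit = SCRModel(buffer=6000.0, resolution=1500.0, n_starts=1).fit(
            SessionSet([(traps, enc)]), statespaces={"one": ss}
        )
        surf = fit.density_surface("one")
        g = int(np.argmax(surf))
        d = np.hypot(*(ss.centers[g] - traps.coords[j]))
        assert d <= ss.resolution  # argmax pixel contains/abuts the site


def test_density_invariant_to_buffer_enlargement_beyond_2sigma():
    """Density should be stable (within its SE) when the state-space buffer
    grows past twice the movement scale, while abundance grows with area."""
    traps = make_checkerboard_traps(8, 8, n_occasions=10)
    sims = {}
    for buf in (9000.0, 13000.0):
        ss = build_state_space(traps, buffer=buf, resolution=1500.0)
        if "enc" not in sims:
            enc, _ = simulate_scr(
                traps, ss, p0=0.2, sigma=3000.0, density=30.0 / ss.area, seed=9
            )
            sims["enc"] = enc
        fit = SCRModel(buffer=buf, resolution=1500.0, n_starts=1).fit(
            SessionSet([(traps, sims["enc"])])
        )
        sims[buf] = fit.summary_.iloc[0]
    small, large = sims[9000.0], sims[13000.0]
    assert abs(large.density_100km2 - small.density_100km2) <= small.density_se
    assert large.abundance > small.abundance  # same D over a bigger area


def test_recovery_bias_within_monte_carlo_error(recovery_fits):
    """Replicate fits at the study conditions recover the generating
    detection parameters without detectable bias."""
    r = recovery_fits
    assert len(r["log_sigma"]) >= 25
    assert r["converged"].mean() > 0.9
    for key in ("log_sigma", "p0_logit"):
        est = r[key]
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - r["truth"][key]) <= 3 * mc_se, key


def test_wald_interval_coverage_for_log_sigma(recovery_fits):
    r = recovery_fits
    ok = np.isfinite(r["log_sigma_se"])
    cover = (
        np.abs(r["log_sigma"][ok] - r["truth"]["log_sigma"])
        <= 1.959963984540054 * r["log_sigma_se"][ok]
    )
    assert 0.90 <= cover.mean() <= 0.99


def test_fit_scr_wrapper_and_errors():
    traps = make_checkerboard_traps(4, 4, n_occasions=6)
    ss = build_state_space(traps, buffer=6000.0, resolution=2000.0)
    enc, _ = simulate_scr(traps, ss, p0=0.3, sigma=3000.0, n_individuals=15, seed=2)
    fit = fit_scr(SessionSet([(traps, enc)]), buffer=6000.0, resolution=2000.0,
                  n_starts=1)
    assert fit.summary_.abundance[0] > 0
    empty = EncounterData([], [], np.zeros((0, traps.n_sites, 6)), "none")
    with pytest.raises(ValueError, match="no detected individuals"):
        fit_scr(SessionSet([(traps, empty)]))
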