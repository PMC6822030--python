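"""Synthetic survey generator: design, detection model, reproducibility."""

import numpy as np
import pytest

from lynxscr import build_state_space
from lynxscr.simulate import (
    assign_sex,
    make_checkerboard_traps,
    read_truth,
    simulate_scr,
    write_truth,
)
from lynxscr.statespace import StateSpace


class TestCheckerboard:
    def test_even_grid_samples_half_the_cells(self):
        traps = make_checkerboard_traps(10, 10)
        assert traps.n_sites == 50

    def test_odd_grid_parity(self):
        assert make_checkerboard_traps(3, 3, phase=0).n_sites == 5
        assert make_checkerboard_traps(3, 3, phase=1).n_sites == 4

    def test_single_cell_site_at_center(self):
        traps = make_checkerboard_traps(1, 1, cell=2700.0, origin=(0.0, 0.0))
        assert traps.n_sites == 1
        assert traps.x[0] == pytest.approx(1350.0)
        assert traps.y[0] == pytest.approx(1350.0)
        assert traps.cell_size == 2700.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_checkerboard_traps(0, 3)
        with pytest.raises(ValueError):
            make_checkerboard_traps(3, 3, cell=-1.0)


@pytest.fixture(scope="module")
def design():
    traps = make_checkerboard_traps(6, 6, n_occasions=8)
    ss = build_state_space(traps, buffer=8000.0, resolution=2000.0)
    return traps, ss


class TestSimulateScr:
    def test_same_seed_bit_identical(self, design):
        traps, ss = design
        a = simulate_scr(traps, ss, p0=0.2, sigma=3000.0, density=20 / ss.area, seed=7)
        b = simulate_scr(traps, ss, p0=0.2, sigma=3000.0, density=20 / ss.area, seed=7)
        assert np.array_equal(a[0].y, b[0].y)
        assert np.array_equal(a[1].centers, b[1].centers)
        c = simulate_scr(traps, ss, p0=0.2, sigma=3000.0, density=20 / ss.area, seed=8)
        assert not np.array_equal(a[1].centers, c[1].centers)

    def test_p0_zero_detects_nobody(self, design):
        traps, ss = design
        enc, truth = simulate_scr(traps, ss, p0=0.0, sigma=3000.0,
                                  n_individuals=40, seed=1)
        assert enc.n_individuals == 0
        assert truth.n_true == 40

    def test_p0_one_huge_sigma_detects_everyone_everywhere(self, design):
        traps, ss = design
        enc, truth = simulate_scr(traps, ss, p0=1.0, sigma=1e9,
                                  n_individuals=5, seed=1)
        assert enc.n_individuals == 5
        assert (enc.y == traps.activity[None]).all()

    def test_individual_at_trap_sees_binomial_detections(self):
        """A center pinned at the trap with p0 = 0.5 and K = 20 yields on
        average 10 detections (binomial mean), within 3 MC SE."""
        K, reps = 20, 2000
        traps = make_checkerboard_traps(1, 1, n_occasions=K)
        # degenerate single-pixel state-space centered on the trap
        ss = StateSpace(np.array([[1350.0, 1350.0]]), 1e-6, 0.0, 1, 1, 0.0, 0.0)
        tot = 0
        for child in np.random.SeedSequence(4242).spawn(reps):
            enc, _ = simulate_scr(
                traps, ss, p0=0.5, sigma=5000.0, n_individuals=1,
                seed=np.random.default_rng(child),
            )
            tot += int(enc.y.sum())
        mean = tot / reps
        mc_se = np.sqrt(K * 0.25 / reps)
        assert abs(mean - 10.0) <= 3 * mc_se

    def test_detection_frequency_follows_half_normal(self, design):
        """Across many simulated individual-site pairs the empirical
        detection frequency tracks p0 exp(-d^2 / (2 sigma^2)) in distance
        bins, within 3 binomial MC SEs."""
        traps, ss = design
        p0, sigma = 0.4, 3000.0
        enc, truth = simulate_scr(
            traps, ss, p0=p0, sigma=sigma, n_individuals=4000,
            n_occasions=1, seed=99,
        )
        # reconstruct per-pair outcomes for all simulated individuals
        d = np.hypot(
            truth.centers[:, 0][:, None] - traps.x[None],
            truth.centers[:, 1][:, None] - traps.y[None],
        ).ravel()
        y_full = np.zeros((truth.n_true, traps.n_sites), dtype=int)
        y_full[truth.detected.nonzero()[0]] = enc.y[:, :, 0]
        obs = y_full.ravel()
        for lo, hi in [(0, 1500), (1500, 3000), (3000, 4500), (4500, 6000)]:
            sel = (d >= lo) & (d < hi)
            assert sel.sum() > 300
            p_mid = p0 * np.exp(-np.mean(d[sel] ** 2) / (2 * sigma**2))
            mc_se = np.sqrt(p_mid * (1 - p_mid) / sel.sum())
            assert abs(obs[sel].mean() - p_mid) <= 3 * mc_se + 0.01

    def test_detected_count_matches_conditional_expectation(self, design):
        """Conditional on the drawn centers, the number of detected
        individuals is a sum of independent Bernoullis with success
        pdot(center); the observed count stays within 3 SDs."""
        traps, ss = design
        p0, sigma, K = 0.25, 3000.0, 8
        enc, truth = simulate_scr(
            traps, ss, p0=p0, sigma=sigma, n_individuals=2000, seed=17
        )
        d2 = ((truth.centers[:, None, :] - traps.coords[None]) ** 2).sum(-1)
        p = p0 * np.exp(-d2 / (2 * sigma**2))
        pdot = 1 - ((1 - p) ** K).prod(axis=1)
        mean, sd = pdot.sum(), np.sqrt((pdot * (1 - pdot)).sum())
        assert abs(enc.n_individuals - mean) <= 3 * sd

    def test_dropout_thins_activity(self, design):
        traps, ss = design
        enc, truth = simulate_scr(
            traps, ss, p0=0.3, sigma=3000.0, n_individuals=30,
            dropout=0.5, seed=3,
        )
        frac = truth.activity_used.mean()
        assert 0.35 < frac < 0.65
        assert (enc.y * (1 - truth.activity_used[None])).sum() == 0

    def test_parameter_validation(self, design):
        traps, ss = design
        with pytest.raises(ValueError):
            simulate_scr(traps, ss, p0=1.5, sigma=1.0, n_individuals=1)
        with pytest.raises(ValueError):
            simulate_scr(traps, ss, p0=0.5, sigma=-1.0, n_individuals=1)
        with pytest.raises(ValueError):
            simulate_scr(traps, ss, p0=0.5, sigma=1.0)  # neither D nor N


class TestAssignSex:
    def _enc(self, design, n=92):
        traps, ss = design
        enc, _ = simulate_scr(traps, ss, p0=1.0, sigma=1e9, n_individuals=n, seed=0)
        return enc

    def test_degenerate_probabilities(self, design):
        enc = self._enc(design, n=10)
        assert set(assign_sex(enc, 0.0, 0.0, seed=1).sex) == {"U"}
        assert set(assign_sex(enc, 1.0, 0.0, seed=1).sex) == {"F"}

    def test_female_count_matches_binomial_mean(self, design):
        """With the observed study proportions (16 F, 13 M of 92) the mean
        female count over replicate labelings is 16 within 3 MC SE."""
        enc = self._enc(design, n=92)
        pf, pm = 16 / 92, 13 / 92
        counts = [
            list(assign_sex(enc, pf, pm, seed=c).sex).count("F")
            for c in range(600)
        ]
        mc_se = np.sqrt(92 * pf * (1 - pf) / len(counts))
        assert abs(np.mean(counts) - 16.0) <= 3 * mc_se

    def test_invalid_probabilities(self, design):
        enc = self._enc(design, n=5)
        with pytest.raises(ValueError):
            assign_sex(enc, 0.7, 0.5, seed=1)


def test_truth_sidecar_round_trip(tmp_path, design):
    traps, ss = design
    _, truth = simulate_scr(traps, ss, p0=0.2, sigma=3000.0, n_individuals=12, seed=5)
    write_truth(truth, tmp_path / "truth.json")
    back = read_truth(tmp_path / "truth.json")
    assert back.n_true == truth.n_true
    assert np.allclose(back.centers, truth.centers)
    assert back.sigma_true == truth.sigma_true
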