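import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinkloop import (
    bell_lifetime,
    fit_bell_robust,
    fit_survival_exponential,
    rmse_transition_scan,
    select_kwlc_parameters,
)
from kinkloop.constants import KBT_PNNM


class TestSurvivalFitting:
    def test_noiseless_decay_curve_exact(self):
        t = np.linspace(0, 100, 50)
        fit = fit_survival_exponential(decay_curve=(t, 100 * np.exp(-t / 20.0)))
        assert fit.tau == pytest.approx(20.0, rel=1e-6)

    def test_mle_sampling_distribution(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(20.0, 1000)
        fit = fit_survival_exponential(dwell_times=t)
        assert abs(fit.tau - 20.0) < 3 * 20.0 / math.sqrt(1000)
        assert fit.ci_low < 20.0 < fit.ci_high

    def test_censoring_correction(self):
        """Right-censoring at two lifetimes: total-time-over-events MLE
        recovers the true mean within 10%."""
        rng = np.random.default_rng(6)
        t = rng.exponential(20.0, 2000)
        window = 40.0
        cens = t > window
        obs = np.where(cens, window, t)
        fit = fit_survival_exponential(dwell_times=obs, censored=cens)
        assert fit.tau == pytest.approx(20.0, rel=0.1)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_survival_exponential(dwell_times=np.array([]))
        with pytest.raises(ValueError):
            fit_survival_exponential(dwell_times=np.full(20, 3.0))
        with pytest.raises(ValueError):
            fit_survival_exponential()


class TestBellLifetime:
    def test_zero_force_returns_tau0(self):
        assert bell_lifetime(72.24, 1.10, 0.0) == 72.24

    def test_paper_fit_parameters_at_8_pN(self):
        # 72.24 * exp(-8 * 1.10 / 4.114)
        assert bell_lifetime(72.24, 1.10, 8.0) == pytest.approx(8.51, abs=0.02)

    @given(
        st.floats(0.1, 20.0), st.floats(0.1, 20.0),
        st.floats(1.0, 200.0), st.floats(0.2, 3.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_exponential_force_additivity(self, f1, f2, tau0, dr0):
        lhs = bell_lifetime(tau0, dr0, f1 + f2) * bell_lifetime(tau0, dr0, 0.0)
        rhs = bell_lifetime(tau0, dr0, f1) * bell_lifetime(tau0, dr0, f2)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            bell_lifetime(10.0, 1.0, -1.0)


def _bell_points(forces, tau0=72.24, dr0=1.10, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    tau = tau0 * np.exp(-np.asarray(forces) * dr0 / KBT_PNNM)
    if noise:
        tau = tau * rng.lognormal(0.0, noise, len(tau))
    return tau


class TestRobustBellFit:
    def test_noiseless_exact_recovery(self):
        f = np.linspace(1, 9, 8)
        fit = fit_bell_robust(f, _bell_points(f))
        assert fit.tau0 == pytest.approx(72.24, rel=1e-6)
        assert fit.delta_r0 == pytest.approx(1.10, rel=1e-6)

    def test_noisy_recovery_within_two_se(self):
        f = np.linspace(1.5, 9, 15)
        fit = fit_bell_robust(f, _bell_points(f, noise=0.1, seed=3))
        assert abs(fit.tau0 - 72.24) < 2 * fit.se_tau0 + 1e-9
        assert abs(fit.delta_r0 - 1.10) < 2 * fit.se_delta_r0 + 1e-9

    def test_robust_beats_ordinary_least_squares_with_outliers(self):
        f = np.linspace(1.5, 9, 15)
        tau = _bell_points(f, noise=0.05, seed=4)
        tau[-1] *= 30.0  # gross outliers at the high-force end
        tau[-2] *= 25.0
        fit = fit_bell_robust(f, tau)
        slope_ols = np.polyfit(f, np.log(tau), 1)[0]
        dr0_ols = -slope_ols * KBT_PNNM
        assert abs(fit.delta_r0 - 1.10) < abs(dr0_ols - 1.10)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_bell_robust([3.0, 3.0, 3.0], [5.0, 5.0, 5.0])

    def test_fit_range_stability_for_elastic_data(self):
        """Restricting a purely elastic dataset to larger loops barely moves
        the slope (the fitted dr0)."""
        sizes = np.arange(60, 201, 10)
        f = 4.114 * 50 / (0.34 * sizes) * 1.2  # smooth monotone force proxy
        tau = _bell_points(f, noise=0.08, seed=9)
        fit_a = fit_bell_robust(f[sizes >= 60], tau[sizes >= 60])
        fit_b = fit_bell_robust(f[sizes >= 80], tau[sizes >= 80])
        assert abs(fit_a.delta_r0 - fit_b.delta_r0) < fit_a.se_delta_r0 + fit_b.se_delta_r0


def _force_table(sizes, soften_below=None):
    """Monotone elastic force proxy, optionally capped (softened) below a
    critical size — the generator-truth shape of a kinking transition."""
    sizes = np.asarray(sizes, dtype=float)
    f = 480.0 / sizes  # ~8 pN at 60 bp, monotone in size
    if soften_below is not None:
        f = np.minimum(f, 480.0 / soften_below)
    return f


class TestTransitionScan:
    def test_detects_generator_softening_size(self):
        sizes = np.arange(40, 201, 10)
        f_elastic = _force_table(sizes)
        f_true = _force_table(sizes, soften_below=60)
        tau = _bell_points(f_true, noise=0.05, seed=11)
        report = rmse_transition_scan(sizes, f_elastic, tau)
        assert report.critical_size_bp == pytest.approx(60, abs=10)

    def test_magnesium_style_transition_at_100(self):
        sizes = np.arange(40, 201, 10)
        f_elastic = _force_table(sizes)
        f_true = _force_table(sizes, soften_below=100)
        tau = _bell_points(f_true, noise=0.05, seed=12)
        report = rmse_transition_scan(sizes, f_elastic, tau)
        assert report.critical_size_bp == pytest.approx(100, abs=10)

    def test_self_consistent_elastic_data_detects_nothing(self):
        sizes = np.arange(40, 201, 10)
        f = _force_table(sizes)
        report = rmse_transition_scan(sizes, f, _bell_points(f))
        assert report.critical_size_bp is None

    def test_null_false_positive_rate_is_low(self):
        """Noise alone should rarely mimic a softening jump."""
        sizes = np.arange(40, 201, 10)
        f = _force_table(sizes)
        hits = sum(
            rmse_transition_scan(
                sizes, f, _bell_points(f, noise=0.05, seed=s)
            ).critical_size_bp is not None
            for s in range(5)
        )
        assert hits <= 1

    def test_needs_enough_sizes(self):
        with pytest.raises(ValueError):
            rmse_transition_scan([60, 80, 100], [3, 2, 1], [5, 10, 20])


class TestParameterSelection:
    @staticmethod
    def _family(h, b, sizes):
        # kink-limited force cap rising with the barrier height
        return np.minimum(_force_table(sizes), 0.45 * h)

    def test_self_consistent_recovery(self):
        sizes = np.arange(40, 201, 10)
        target = self._family(22.0, 0.3, sizes)
        grid = np.arange(14.0, 31.0, 2.0)
        best, table = select_kwlc_parameters(sizes, target, grid, 0.3, self._family)
        assert best == 22.0
        assert len(table) == len(grid)

    def test_elastic_target_selects_stiffest_candidate(self):
        sizes = np.arange(40, 201, 10)
        target = _force_table(sizes)  # never softens
        grid = np.arange(14.0, 27.0, 2.0)
        best, _ = select_kwlc_parameters(sizes, target, grid, 0.3, self._family)
        assert best == grid.max()

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            select_kwlc_parameters([60], [8.0], [20, 22], 0.3, self._family)
        with pytest.raises(ValueError):
            select_kwlc_parameters([60, 80], [8.0, 5.0], [], 0.3, self._family)
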