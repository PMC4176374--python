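import math

import numpy as np
import pytest
from scipy.integrate import quad

from kinkloop import (
    RestraintSpec,
    SamplerConfig,
    child_seed,
    circle_energy,
    fit_persistence_length,
    free_chain_distances,
    regular_polygon,
    sample_minicircle,
    sample_restrained_chain,
    straight_chain,
    tangent_correlation,
    total_energy,
)
from kinkloop.conformation import ChainConformation, circular_arc


class TestTotalEnergy:
    def test_straight_chain_costs_nothing(self, wlc, lsec, kwlc_na):
        conf = straight_chain(30, 0.34)
        for m in (wlc, kwlc_na):
            assert total_energy(conf, m) == pytest.approx(0.0, abs=1e-9)
        conf7 = straight_chain(10, 2.38)
        # |theta| is first-order sensitive to arccos rounding near zero
        assert total_energy(conf7, lsec) == pytest.approx(0.0, abs=1e-5)

    def test_regular_circle_closed_form(self, wlc):
        ring = regular_polygon(200, 0.34)
        expected = 2 * math.pi**2 * wlc.k / 200
        assert total_energy(ring, wlc) == pytest.approx(expected, rel=1e-9)
        assert circle_energy(wlc, 200) == pytest.approx(expected, rel=1e-12)

    def test_restraint_term(self, wlc):
        conf = straight_chain(60, 0.34)  # r = 20.4 nm
        spec = RestraintSpec(K=16.8, r0=5.0)
        expected = 0.5 * 16.8 * (20.4 - 5.0) ** 2
        assert total_energy(conf, wlc, spec) == pytest.approx(expected, rel=1e-9)

    def test_bad_link_length_rejected(self, wlc):
        v = straight_chain(10, 0.34).vertices.copy()
        v[5, 0] += 0.01
        with pytest.raises(ValueError):
            total_energy(ChainConformation(v, 0.34), wlc)


class TestRestrainedSampling:
    def test_seed_determinism(self, wlc):
        spec = RestraintSpec(K=16.8, r0=5.0)
        cfg = SamplerConfig(n_equil=10_000, n_samples=20_000, seed=42)
        a = sample_restrained_chain(wlc, 60, spec, cfg)
        b = sample_restrained_chain(wlc, 60, spec, cfg)
        assert np.array_equal(a.r_values, b.r_values)
        c = sample_restrained_chain(
            wlc, 60, spec, SamplerConfig(n_equil=10_000, n_samples=20_000, seed=43)
        )
        assert not np.array_equal(a.r_values, c.r_values)

    def test_acceptance_rate_reported_and_sane(self, wlc):
        spec = RestraintSpec(K=16.8, r0=5.0)
        s = sample_restrained_chain(
            wlc, 60, spec, SamplerConfig(n_equil=10_000, n_samples=50_000, seed=1)
        )
        assert 0.0 < s.acceptance < 1.0

    def test_bent_loop_pushes_ends_outward(self, wlc):
        """Bending stress makes the mean end separation exceed the restraint
        center — the sign behind the outward shear force."""
        spec = RestraintSpec(K=16.8, r0=5.0)
        s = sample_restrained_chain(
            wlc, 60, spec, SamplerConfig(n_samples=100_000, thin=4, seed=7)
        )
        assert s.delta_r.mean() > 0

    def test_two_link_angles_match_boltzmann_density(self, wlc):
        """Brute-force oracle: for a 2-link chain the restrained joint-angle
        density is exactly e^{-E - U(r)} sin(theta); the sampled empirical
        CDF must match the quadrature CDF (KS distance < 0.01)."""
        l, K, r0 = 0.34, 16.8, 0.5
        spec = RestraintSpec(K=K, r0=r0)
        s = sample_restrained_chain(
            wlc, 2, spec, SamplerConfig(n_samples=200_000, thin=2, seed=3)
        )
        theta = 2 * np.arccos(np.clip(s.r_values / (2 * l), -1, 1))

        def dens(t):
            r = 2 * l * math.cos(t / 2)
            return math.exp(-0.5 * wlc.k * t * t - 0.5 * K * (r - r0) ** 2) * math.sin(t)

        Z = quad(dens, 0, math.pi, limit=400)[0]
        grid = np.linspace(0, math.pi, 200)
        cdf = np.array([quad(dens, 0, g, limit=400)[0] / Z for g in grid])
        emp = np.searchsorted(np.sort(theta), grid) / len(theta)
        assert np.abs(emp - cdf).max() < 0.01

    def test_unrestrained_mean_square_extension(self, wlc):
        """Pivot sampling with no restraint reproduces the discrete chain
        closed form <r^2> = 2 Lp L - 2 Lp^2 (1 - e^{-L/Lp})."""
        s = sample_restrained_chain(
            wlc, 2000, None, SamplerConfig(n_samples=400_000, thin=2, seed=8)
        )
        L, Lp = 2000 * 0.34, 50.0
        theory = 2 * Lp * L - 2 * Lp**2 * (1 - math.exp(-L / Lp))
        assert (s.r_values**2).mean() == pytest.approx(theory, rel=0.08)


class TestFreeChains:
    def test_direct_sampling_matches_wlc_closed_form(self, wlc):
        r = free_chain_distances(wlc, 2000, 30_000, seed=12)
        L, Lp = 680.0, 50.0
        theory = 2 * Lp * L - 2 * Lp**2 * (1 - math.exp(-L / Lp))
        assert (r**2).mean() == pytest.approx(theory, rel=0.03)

    @pytest.mark.parametrize("model_name,n_links", [("wlc", 2000), ("lsec", 286)])
    def test_tangent_decorrelation_recovers_lp(self, model_name, n_links, wlc, lsec):
        m = {"wlc": wlc, "lsec": lsec}[model_name]
        sep, corr = tangent_correlation(m, n_links, 20_000, seed=21)
        assert fit_persistence_length(sep, corr) == pytest.approx(50.0, rel=0.04)


class TestMinicircle:
    def test_polygon_initial_angles(self):
        ring = regular_polygon(70, 0.34)
        assert np.allclose(np.degrees(ring.bend_angles()), 360.0 / 70, atol=1e-9)

    def test_closure_and_energy_floor(self, wlc):
        """Crankshaft moves preserve closure/link lengths exactly and the
        circle is the energy minimum, so the observed minimum total energy
        can never undercut the regular polygon's."""
        run = sample_minicircle(
            wlc, 100, SamplerConfig(n_equil=20_000, n_samples=50_000, seed=5)
        )
        assert run.min_energy >= circle_energy(wlc, 100) - 1e-9
        assert run.n_with_kink == 0  # elastic chains never cross theta_c = pi

    def test_seed_determinism(self, kwlc_mg):
        cfg = SamplerConfig(n_equil=5_000, n_samples=10_000, seed=11)
        a = sample_minicircle(kwlc_mg, 70, cfg)
        b = sample_minicircle(kwlc_mg, 70, cfg)
        assert a.n_with_kink == b.n_with_kink
        assert np.array_equal(a.angle_hist, b.angle_hist)

    def test_angle_histogram_normalizes(self, wlc):
        run = sample_minicircle(
            wlc, 70, SamplerConfig(n_equil=5_000, n_samples=20_000, seed=2)
        )
        centers, dens = run.angle_density()
        width = math.pi / len(centers)
        assert np.sum(dens) * width == pytest.approx(1.0, rel=1e-6)

    def test_too_small_ring_rejected(self, wlc):
        with pytest.raises(ValueError):
            sample_minicircle(wlc, 3, SamplerConfig(n_samples=10))


class TestSeeding:
    def test_child_seed_stable_named_and_bounded(self):
        a = child_seed(7, "force", "wlc", 60, 0)
        assert a == child_seed(7, "force", "wlc", 60, 0)
        assert a != child_seed(7, "force", "wlc", 60, 1)
        assert a != child_seed(8, "force", "wlc", 60, 0)
        assert 0 <= a < 2**31

    def test_arc_initialization_spans_requested_gap(self, wlc):
        arc = circular_arc(60, 0.34, 5.0)
        assert arc.end_to_end == pytest.approx(5.0, abs=1e-6)
        arc.validate()
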