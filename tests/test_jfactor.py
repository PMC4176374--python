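import math

import numpy as np
import pytest

from kinkloop import (
    SamplerConfig,
    UmbrellaWindow,
    WhamDensity,
    free_chain_distances,
    j_factor,
    wham_iterate,
)
from kinkloop.constants import MOLAR_PER_NM3
from kinkloop.jfactor_wham import check_overlap, sample_windows, window_ladder


def _known_density_windows(seed=7, n=200_000):
    """Multinomial window counts drawn from an analytically known 1D density
    under harmonic biases — the quadrature oracle for the WHAM solver."""
    rng = np.random.default_rng(seed)
    edges = np.linspace(0, 30, 301)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p_true = centers**2 * np.exp(-(centers**2) / 50.0)
    p_true /= p_true.sum()
    windows = []
    for K, r0 in [(0.5, 2.0), (0.5, 6.0), (0.2, 10.0), (0.0, 0.0)]:
        U = 0.5 * K * (centers - r0) ** 2
        w = p_true * np.exp(-U)
        w /= w.sum()
        counts = rng.multinomial(n, w)
        windows.append(UmbrellaWindow(counts=counts.astype(float), bias_energy=U))
    return windows, edges, centers, p_true


class TestWhamSolver:
    def test_single_unbiased_window_returns_raw_histogram(self):
        counts = np.array([0.0, 10, 30, 40, 20, 0])
        w = UmbrellaWindow(counts=counts, bias_energy=np.zeros(6))
        dens = wham_iterate([w])
        assert np.allclose(dens.p0, counts / counts.sum())

    def test_duplicating_the_window_set_changes_nothing(self):
        """Doubling every window rescales both sides of the WHAM equations,
        so the fixed point is exactly unchanged (duplicating a single noisy
        window shifts it only within statistical error)."""
        windows, edges, _, _ = _known_density_windows()
        a = wham_iterate(windows, bin_edges=edges, tol=1e-12)
        b = wham_iterate(windows + windows, bin_edges=edges, tol=1e-12)
        assert np.allclose(a.p0, b.p0, atol=1e-9)

    def test_recovers_known_density(self):
        windows, edges, centers, p_true = _known_density_windows()
        dens = wham_iterate(windows, bin_edges=edges)
        assert dens.converged
        mask = p_true > 1e-3  # bins with enough counts for a tight check
        rel = np.abs(dens.p0[mask] - p_true[mask]) / p_true[mask]
        # per-bin deviations are multinomial noise (up to ~15% at the mask
        # edge); the average must be tight
        assert rel.max() < 0.2
        assert rel.mean() < 0.03

    def test_initialization_independent_fixed_point(self):
        windows, edges, _, _ = _known_density_windows()
        pooled = wham_iterate(windows, bin_edges=edges)
        uniform = wham_iterate(
            windows, bin_edges=edges,
            p_init=np.ones_like(windows[0].counts),
        )
        assert np.allclose(pooled.p0, uniform.p0, atol=1e-6)

    def test_disjoint_windows_rejected(self):
        a = UmbrellaWindow(
            counts=np.array([100.0, 50, 0, 0, 0, 0]), bias_energy=np.zeros(6)
        )
        b = UmbrellaWindow(
            counts=np.array([0.0, 0, 0, 0, 50, 100]), bias_energy=np.zeros(6)
        )
        with pytest.raises(ValueError):
            check_overlap([a, b])

    def test_all_empty_rejected(self):
        w = UmbrellaWindow(counts=np.zeros(6), bias_energy=np.zeros(6))
        with pytest.raises(ValueError):
            wham_iterate([w])


class TestJFactor:
    def test_uniform_sphere(self):
        """For chain ends uniformly distributed in a ball of radius R the
        radial density is 3 r^2 / R^3, so J = 1.6606 * 3 / (4 pi R^3) molar
        at every interior separation."""
        R = 10.0
        edges = np.linspace(0, R, 101)
        centers = 0.5 * (edges[:-1] + edges[1:])
        p = centers**2
        p = p / p.sum()
        dens = WhamDensity(p0=p, bin_edges=edges, n_iter=1, converged=True,
                           residual=0.0)
        expected = MOLAR_PER_NM3 * 3.0 / (4 * math.pi * R**3)
        for r0 in (2.05, 5.05, 8.05):
            assert j_factor(dens, r0) == pytest.approx(expected, rel=0.01)

    def test_gaussian_chain_limit(self, flexible):
        """A long floppy chain is Gaussian, so the small-separation J factor
        approaches (3 / (2 pi <r^2>))^{3/2} in number density."""
        r = free_chain_distances(flexible, 200, 400_000, seed=17)
        edges = np.arange(0.0, 68.0, 0.25)
        hist, _ = np.histogram(r, bins=edges)
        dens = WhamDensity(p0=hist / hist.sum(), bin_edges=edges, n_iter=1,
                           converged=True, residual=0.0)
        r2 = float((r**2).mean())
        expected = (3 / (2 * math.pi * r2)) ** 1.5 * MOLAR_PER_NM3
        assert j_factor(dens, 3.0) == pytest.approx(expected, rel=0.2)

    def test_empty_bin_rejected(self):
        edges = np.linspace(0, 10, 11)
        p = np.ones(10) / 10
        p[4] = 0.0
        dens = WhamDensity(p0=p, bin_edges=edges, n_iter=1, converged=True,
                           residual=0.0)
        with pytest.raises(ValueError):
            j_factor(dens, 4.5)


class TestUmbrellaPipeline:
    def test_wham_density_matches_direct_sampling(self, flexible):
        """End-to-end check of the umbrella machinery: for a floppy chain the
        short-separation density is reachable by brute-force sampling, so the
        WHAM-stitched density must agree with the direct histogram."""
        n_links = 200
        ladder = window_ladder(flexible, n_links, 5.0)
        windows, edges = sample_windows(
            flexible, n_links, ladder,
            SamplerConfig(n_samples=60_000, thin=3, seed=31), bin_width=0.1,
        )
        check_overlap(windows)
        dens = wham_iterate(windows, bin_edges=edges)
        r = free_chain_distances(flexible, n_links, 500_000, seed=32)
        hist, _ = np.histogram(r, bins=edges)
        p_direct = hist / hist.sum()
        centers = dens.bin_centers
        for rq in (5.0, 8.0, 15.0):
            i = int(np.argmin(np.abs(centers - rq)))
            assert dens.p0[i] == pytest.approx(p_direct[i], rel=0.25)
        jw = j_factor(dens, 5.0)
        jd = (
            p_direct[int(np.argmin(np.abs(centers - 5.0)))]
            / dens.bin_width / (4 * math.pi * 25.0) * MOLAR_PER_NM3
        )
        assert jw == pytest.approx(jd, rel=0.25)

    def test_halving_windows_keeps_j_stable(self, flexible):
        n_links = 200
        ladder = window_ladder(flexible, n_links, 5.0)
        cfg = SamplerConfig(n_samples=50_000, thin=3, seed=41)
        w_full, edges = sample_windows(flexible, n_links, ladder, cfg)
        j_full = j_factor(wham_iterate(w_full, bin_edges=edges), 5.0)
        w_half = w_full[::2]
        j_half = j_factor(wham_iterate(w_half, bin_edges=edges), 5.0)
        assert j_half == pytest.approx(j_full, rel=0.3)
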