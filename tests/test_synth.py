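import numpy as np
import pandas as pd
import pytest

from kinkloop import (
    CONDITION_PRESETS,
    SynthConfig,
    bell_lifetime,
    elastica_force_law,
    force_law_from_table,
    generate_decay_counts,
    generate_dimer_dwells,
    generate_unlooping_times,
)
from kinkloop.io import read_survival_csv, write_survival_csv


@pytest.fixture(scope="module")
def wlc_law(wlc):
    return elastica_force_law(wlc)


class TestForceLaws:
    def test_table_lookup_and_missing_size(self):
        law = force_law_from_table({60: 8.0, 100: 3.0})
        assert law(60) == 8.0
        with pytest.raises(KeyError):
            law(70)

    def test_elastica_law_monotone_and_plausible(self, wlc_law):
        f = [wlc_law(s) for s in (40, 60, 100, 200)]
        assert all(a > b for a, b in zip(f, f[1:]))
        assert 5.0 < wlc_law(60) < 12.0  # pN scale of a 60-bp loop

    def test_elastica_tracks_monte_carlo(self, wlc, wlc_law):
        from kinkloop import SamplerConfig, estimate_force

        est = estimate_force(
            wlc, 80, config=SamplerConfig(n_samples=100_000, thin=8, seed=3)
        )
        assert wlc_law(80) == pytest.approx(est.force_pN, rel=0.2)


class TestUnloopingGenerator:
    def test_seed_determinism(self, wlc_law):
        cfg = SynthConfig(force_law=wlc_law, seed=7, n_molecules=20)
        a = generate_unlooping_times(cfg).data
        b = generate_unlooping_times(cfg).data
        pd.testing.assert_frame_equal(a, b)

    def test_mean_matches_bell_lifetime(self, wlc_law):
        cfg = SynthConfig(
            force_law=wlc_law, sizes_bp=(100,), n_molecules=10_000, seed=8
        )
        ds = generate_unlooping_times(cfg)
        tau_true = bell_lifetime(cfg.tau0_s, cfg.delta_r0_nm, wlc_law(100))
        assert ds.dwells(100.0).mean() == pytest.approx(
            tau_true, abs=3 * tau_true / 100.0
        )

    def test_mean_dwell_increases_with_loop_size(self, wlc_law):
        cfg = SynthConfig(force_law=wlc_law, n_molecules=400, seed=9)
        lt = generate_unlooping_times(cfg).lifetimes_by_size()
        tau = lt.sort_values("size_bp")["tau_s"].to_numpy()
        # monotone in expectation; allow small-sample jitter on neighbors
        assert tau[-1] > tau[0]
        assert (np.diff(tau) > 0).mean() > 0.7

    def test_censoring_and_frame_discretization(self, wlc_law):
        cfg = SynthConfig(
            force_law=wlc_law, sizes_bp=(60,), n_molecules=500, seed=10,
            frame_interval_s=0.5, observation_window_s=10.0,
        )
        ds = generate_unlooping_times(cfg)
        assert ds.data["dwell_s"].max() <= 10.0
        assert ds.data["censored"].any()
        uncens = ds.data.loc[~ds.data["censored"], "dwell_s"]
        assert np.allclose(np.mod(uncens / 0.5, 1.0), 0.0)

    def test_round_trip_recovery_per_size(self, wlc_law):
        cfg = SynthConfig(force_law=wlc_law, n_molecules=100, seed=11)
        ds = generate_unlooping_times(cfg)
        lt = ds.lifetimes_by_size()
        for _, row in lt.iterrows():
            truth = bell_lifetime(
                cfg.tau0_s, cfg.delta_r0_nm, ds.meta["forces_pN"][row["size_bp"]]
            )
            assert abs(row["tau_s"] - truth) < 3.5 * truth / 10.0  # 3.5 SE at n=100

    def test_condition_presets_flag_provenance(self):
        assert CONDITION_PRESETS["Na50"]["paper_derived"] is True
        assert not CONDITION_PRESETS["Mg5"]["paper_derived"]
        cfg = SynthConfig.for_condition(
            "Na50", force_law={60.0: 8.0}, sizes_bp=(60,)
        )
        assert cfg.tau0_s == 72.24 and cfg.delta_r0_nm == 1.10


class TestDecayCounts:
    def test_counts_structure(self, wlc_law):
        cfg = SynthConfig(force_law=wlc_law, sizes_bp=(60,), n_molecules=200, seed=12)
        ds = generate_unlooping_times(cfg)
        grid = np.linspace(0, 200, 80)
        curves = generate_decay_counts(ds, grid)
        n = curves.loc[curves["size_bp"] == 60.0, "n_looped"].to_numpy()
        assert n[0] == 200
        assert (np.diff(n) <= 0).all()

    def test_matches_exponential_envelope(self, wlc_law):
        cfg = SynthConfig(force_law=wlc_law, sizes_bp=(100,), n_molecules=2000, seed=13)
        ds = generate_unlooping_times(cfg)
        tau = bell_lifetime(cfg.tau0_s, cfg.delta_r0_nm, wlc_law(100))
        grid = np.linspace(0, 3 * tau, 30)
        curves = generate_decay_counts(ds, grid)
        n = curves["n_looped"].to_numpy()
        expected = 2000 * np.exp(-grid / tau)
        sd = np.sqrt(2000 * np.exp(-grid / tau) * (1 - np.exp(-grid / tau)) + 1)
        assert (np.abs(n - expected) < 4 * sd).all()

    def test_grid_beyond_longest_dwell_reaches_zero(self, wlc_law):
        cfg = SynthConfig(force_law=wlc_law, sizes_bp=(60,), n_molecules=50, seed=14)
        ds = generate_unlooping_times(cfg)
        tmax = ds.data["dwell_s"].max()
        curves = generate_decay_counts(ds, np.array([0.0, tmax + 1.0]))
        assert curves["n_looped"].iloc[-1] == 0


class TestDimerDwells:
    def test_moments_and_reproducibility(self):
        d = generate_dimer_dwells(72.24, 10_000, seed=15)
        assert d.mean() == pytest.approx(72.24, abs=3 * 0.7224)
        assert np.array_equal(d, generate_dimer_dwells(72.24, 10_000, seed=15))

    def test_empty_request(self):
        assert len(generate_dimer_dwells(72.24, 0, seed=1)) == 0

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            generate_dimer_dwells(-1.0, 10)


class TestSurvivalIO:
    def test_csv_round_trip(self, tmp_path, wlc_law):
        cfg = SynthConfig(force_law=wlc_law, sizes_bp=(60, 100), n_molecules=30,
                          seed=16)
        ds = generate_unlooping_times(cfg)
        ds.dimer_dwells_s = generate_dimer_dwells(cfg.tau0_s, 30, seed=17)
        path = tmp_path / "survival.csv"
        write_survival_csv(ds, path)
        back = read_survival_csv(path)
        pd.testing.assert_frame_equal(
            ds.data.reset_index(drop=True), back.data.reset_index(drop=True),
            check_dtype=False,
        )
        assert back.meta["tau0_s"] == cfg.tau0_s
        assert np.allclose(back.dimer_dwells_s, ds.dimer_dwells_s)
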