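"""End-to-end kinetic analysis of synthetic single-molecule unlooping data.

Generates per-molecule unlooping dwell times whose means follow the Bell
relationship tau(f) = tau(0) exp(-f dr0 / kBT) under a model force law, fits
single-exponential lifetimes per loop size, regresses log lifetime on force
(robust bisquare fit), and scans the fit range for a softening transition.
"""

import numpy as np

from kinkloop import (
    BendingModel,
    SynthConfig,
    elastica_force_law,
    fit_bell_robust,
    generate_unlooping_times,
    rmse_transition_scan,
)

wlc_law = elastica_force_law(BendingModel.wlc())
sizes = tuple(range(40, 201, 10))

# ground truth: elastic forces softened (capped) below 60 bp, as a kinking
# transition would produce
soft_law = lambda s: min(wlc_law(s), wlc_law(60))

cfg = SynthConfig(force_law=soft_law, tau0_s=72.24, delta_r0_nm=1.10,
                  sizes_bp=sizes, n_molecules=150, seed=5)
dataset = generate_unlooping_times(cfg)
lifetimes = dataset.lifetimes_by_size()
forces = np.array([wlc_law(s) for s in lifetimes["size_bp"]])  # analysis model

report = rmse_transition_scan(lifetimes["size_bp"], forces, lifetimes["tau_s"])
print(f"softening transition detected at {report.critical_size_bp:.0f} bp "
      f"(plateau RMSE {report.plateau_rmse:.3f})")

mask = lifetimes["size_bp"] >= report.critical_size_bp
fit = fit_bell_robust(forces[mask.to_numpy()], lifetimes.loc[mask, "tau_s"],
                      lifetimes.loc[mask, "size_bp"])
print(f"elastic-regime Bell fit: tau(0) = {fit.tau0:.1f} +/- {fit.se_tau0:.1f} s, "
      f"dr0 = {fit.delta_r0:.2f} +/- {fit.se_delta_r0:.2f} nm")
print(f"(generator truth: tau(0) = 72.24 s, dr0 = 1.10 nm)")
print()
print("Below the detected size the lifetimes sit above the elastic Bell")
print("line — the loops are softer than the worm-like chain predicts, the")
print("kinetic signature of kink formation.")
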