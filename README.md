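# kinkloop

Monte Carlo energetics of sharply bent DNA: shear forces on loop-closing
linkers, cyclization J factors, minicircle kink statistics, and Bell-model
unlooping kinetics for three coarse-grained bending models of
double-stranded DNA.

## The problem

Double-stranded DNA is well described at large scales by the worm-like
chain (WLC): bending energy quadratic in the local bend angle, persistence
length Lp ≈ 50 nm. Whether that elastic description survives *sharp*
bending — loops of 40–200 bp, where the chain must bend several degrees per
base pair — is contested. A sensitive kinetic probe: close a small loop
with a short annealed linker duplex and watch it open. The bent loop exerts
a shear force f on the linker, and the linker lifetime follows the Bell
relationship

    τ(f) = τ(0) · exp(−f·Δr0 / kBT),

so the lifetime-vs-size curve maps directly onto the model's force-vs-size
curve. Where measured lifetimes stop following the elastic prediction, the
DNA has softened — the kinetic signature of kink formation.

This package implements the complete computational side of that analysis
for users studying strong DNA bending:

* **Bending models** (`kinkloop.models`): WLC, the linear subelastic chain
  (LSEC, energy ∝ |θ| on 7-bp monomers), and the kinkable WLC
  (KWLC, E = min((k/2)θ², h + (θ−b)⁶)); rigidity calibration to a target
  persistence length; critical kink angle; kink free energy ΔG_k.
* **Samplers** (`kinkloop.sampler`): seeded numba pivot Monte Carlo for
  end-restrained loops, crankshaft Monte Carlo for exactly closed
  minicircles (with Hamiltonian replica exchange over the kink barrier for
  ergodicity), and exact direct sampling of free chains.
* **Shear force** (`kinkloop.force_estimator`): umbrella-sampled
  f = kBT⟨δr⟩/var(δr) with repeat/SEM control, plus the independent
  log-density-derivative estimator.
* **J factors** (`kinkloop.jfactor_wham`): umbrella-window ladders combined
  by WHAM into unbiased radial densities; J in molar units.
* **Minicircle kinks** (`kinkloop.minicircle_kinks`): kinking probability
  vs circle size.
* **Loop shapes** (`kinkloop.loop_geometry`): deterministic minimum-energy
  (teardrop) loops and their maximum per-bp bend.
* **Kinetics** (`kinkloop.bell_analysis`): exponential survival fits,
  robust (bisquare) Bell regression, RMSE range scan locating the softening
  transition, kink-barrier selection.
* **Synthetic data** (`kinkloop.synthetic_data`): single-molecule unlooping
  datasets with known ground truth, for end-to-end validation.

## Worked example

```python
from kinkloop import BendingModel, SamplerConfig, estimate_force, bell_lifetime

wlc = BendingModel.wlc()            # k calibrated so Lp = 50 nm
cfg = SamplerConfig(n_samples=200_000, thin=8, seed=1)
for size in (60, 100):
    est = estimate_force(wlc, size, config=cfg)
    tau = bell_lifetime(72.24, 1.10, est.force_pN)
    print(f"{size} bp: f = {est.force_pN:.2f} +/- {est.sem_pN:.2f} pN, "
          f"predicted linker lifetime {tau:.1f} s")
```

prints

```
60 bp: f = 8.86 +/- 0.06 pN, predicted linker lifetime 6.8 s
100 bp: f = 3.97 +/- 0.01 pN, predicted linker lifetime 25.0 s
```

A 60-bp loop presses on its linker with ≈8.8 pN, cutting the zero-force
linker lifetime (72 s for the 50 mM Na⁺ parameters) to seconds; a 100-bp
loop presses less than half as hard. The scripts in `examples/` walk
through each capability: force curves, kink energetics, teardrop shapes,
WHAM J factors, minicircle kinking and the full synthetic-data →
transition-scan pipeline.

A thin CLI mirrors the library for batch runs:

```
kinkloop force --model kwlc --h 22 --b 0.3 --sizes 40:200:10 --seed 7 --out force.csv
kinkloop simulate --condition Na50 --seed 3 --out surv.csv
kinkloop scan --survival surv.csv --out scan.json
```

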