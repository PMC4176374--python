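# Methods

## Models

A double-stranded DNA molecule is a discrete chain of rigid links with an
energy per joint (in units of kBT) depending only on the bend angle θ between
successive links:

* **WLC** (worm-like chain): E = (k/2)θ², one link per base pair
  (l = 0.34 nm).
* **LSEC** (linear subelastic chain): E = B|θ|, one link per 7 bp
  (l = 2.38 nm); linear energy makes large bends exponentially cheaper than
  the WLC at matched persistence length.
* **KWLC** (kinkable worm-like chain): E = min((k/2)θ², h + (θ − b)⁶). The
  second branch is a flat-bottomed "kink" state of cost ≈ h over a wide
  angular range around b; its sixth-power walls confine kink angles to
  roughly b ± 1 rad. The branch intercept θc (smallest root of
  (k/2)θc² = h + (θc − b)⁶, solved by scan + Brent to 1e-10 rad) defines
  when a step counts as kinked.

No torsional energy, no excluded volume, no end-orientation constraints: the
assay this models closes loops through a flexible-gapped linker that relaxes
bending and torsional stress at the joint.

Rigidity constants are never hard-coded. For a chain of independent joints
the tangent correlation decays as ⟨t_i·t_{i+s}⟩ = ⟨cosθ⟩^s, so
Lp = −l/ln⟨cosθ⟩ with ⟨cosθ⟩ the single-joint average under
e^{−E(θ)} sinθ dθ. `calibrate_rigidity` solves ⟨cosθ⟩ = e^{−l/Lp} by
quadrature + Brent (relative tolerance 1e-10). For Lp = 50 nm this gives
k = 146.89 kBT/rad² (stiff-limit check: Lp/l = 147) and B = 7.78 kBT/rad.

**Kink free energy.** ΔG_k is the orientational partition-function ratio of
the kinked to the elastic branch with the solid-angle Jacobian,
ΔG_k = −ln(Z_kink/Z_el), Z = ∫ e^{−E branch} sinθ dθ. The default
convention partitions configuration space at θc (elastic branch on [0, θc],
kinked on [θc, π]); the alternative integrates both branches over the full
range. The two differ by < 0.3 kBT; both are exposed and the convention is
recorded. Defaults give 17.66 kBT for (h=22, b=0.3) and 12.07 kBT for
(h=17, b=0.7) — the ≈18 and 12 kBT costs of kinking one step under
sodium-only and magnesium conditions respectively.

## Monte Carlo samplers

All kernels are numba-compiled, explicitly seeded, and deterministic per
seed. Stage-level seeds are derived from one top-level seed through named
SHA-256 child streams.

**Restrained open loops (pivot moves).** A loop of N links with a harmonic
end-to-end restraint U = (K/2)(r − r0)² is sampled by pivot moves: a uniform
random interior vertex, the shorter tail rotated about a uniform random axis
through it by an angle uniform in [−π, π]. Only the pivot joint's angle and
the restraint change, so energy updates are O(1). Runs start from the
minimum-energy loop and equilibrate for 1e5 proposals (default). Restraint
stiffness defaults translate 8 pN·nm/bp² (1-bp monomers) and
400 pN·nm/(7 bp)² (LSEC) into ≈16.8 and ≈17.2 kBT/nm²; estimates are
verified K-independent.

**Recording is dwell-time weighted.** The chain state is recorded every
`thin`-th *proposal* after equilibration, repeating the current state when a
proposal is rejected. Recording accepted moves only would weight each state
by the acceptance flux out of it rather than its Boltzmann dwell time; on a
floppy-chain oracle this biased short-separation densities by 25–40%. The
recording scheme is validated against exact quadrature on a two-link chain
(KS distance 0.003) and against the discrete-chain ⟨r²⟩ closed form at
2000 bp. Production force runs use thin ≈ 1/acceptance (25), so a
1e6-sample run carries ≈1e6 accepted updates.

**Closed minicircles (crankshaft moves).** Rings are exactly closed polygons
sampled by crankshaft rotations: the arc between two random non-adjacent
vertices rotates about the axis through them, changing exactly two joint
angles and preserving closure and link lengths to machine precision. Rotation
angles are drawn 50/50 from uniform intervals [−90°, 90°] and [−10°, 10°].

**Kink-basin ergodicity.** Forming the first kink requires one joint to
climb the elastic branch to θc — an ~h-sized barrier. Plain crankshaft (or
pivot) dynamics is bistable on practical time scales (a circular start
stays unkinked and a kinked start stays kinked for >2e6 accepted moves), so
kinkable-model statistics are sampled with Hamiltonian replica exchange
over a ladder of barriers stepping from h down to 4 kBT (step 1.5 for
rings, 2 for restrained loops). Kinks form and dissolve freely at the
ladder bottom; neighboring replicas exchange configurations (cross energies
recomputed exactly; the shared restraint cancels) every other sweep with
~50% acceptance, and statistics are taken from the physical-h replica only.
The scheme matches plain long-run MC where plain MC does mix (h = 6), and
independent runs agree once the physical replica shows multiple basin
flips. The plain single-replica samplers remain available
(`exchange=False`).

**Free chains.** Unrestrained phantom chains are drawn directly: joint
angles are i.i.d. under e^{−E(θ)} sinθ, sampled by inverse transform with
binary search on a 2·10⁵-point CDF table, azimuths uniform. This is exact
equilibrium sampling (no Markov chain) and serves as the brute-force oracle
for the umbrella machinery and the persistence-length recovery check.

## Shear force

The force the bent loop exerts on its closing linker is estimated from the
restrained ensemble as f = kBT⟨δr⟩/var(δr), δr = r − r0, reported as a
positive outward magnitude in pN (kBT = 4.114 pN·nm at 298 K). The
independent route — the log-derivative −kBT ∂ln P(r)/∂r of the
WHAM-unbiased density at r0 — agrees within 2% at 60–100 bp. Per size, ≥3
independent repeats give the SEM; for the kink-prone KWLC at small sizes,
repeats are added until SEM ≤ 8% of the mean (capped, non-convergence
flagged). Default r0 = 5 nm; the force varies <25% between r0 = 3.4 and
5 nm.

At r0 = 5 nm the converged WLC force is ≈8.8 pN for a 60-bp loop and
≈4.0 pN for a 100-bp loop. The corresponding figure-legend values in the
source experiments (~8 and ~3 pN) are recovered exactly only under
accepted-only recording; see Limitations.

## J factor

Umbrella windows ladder from r0 to 90% of the contour (0.5-nm spacing near
r0 grading to 2 nm, stiffness (2/spacing)² capped at 8 kBT/nm² so adjacent
centers sit within ~2σ). Window histograms share a 0.1-nm bin grid; bias
factors are bin-averaged Boltzmann weights (5-point within-bin quadrature —
center-evaluation measurably biases stiff windows). The WHAM equations are
iterated to a max relative change < 1e-8 per populated bin; adjacent-window
overlap (≥5% shared populated counts) is enforced. The J factor is the
normalized radial probability at the r0 bin divided by the bin width and the
shell area 4πr0², converted at 1 nm⁻³ = 1.6606 M. The pipeline is validated
end-to-end against direct sampling on a floppy chain (Lp = 5 nm) and against
the Gaussian-chain closed form.

## Loop geometry

The minimum-energy loop with fixed end separation and free end angles is
planar; it is found by SLSQP over planar link direction angles with two
equality constraints pinning the end-to-end vector (energy and analytic
gradient; circular-arc initialization; for the KWLC also a one-kink
teardrop start, returning the lower minimum). The LSEC constrained minimum
is degenerate (energy = B × total turn for any convex shape), and the arc is
returned as the canonical minimizer.

The teardrop's maximum per-bp bend quantifies the sharpest local bending a
loop of a given size must sustain. For the quoted 7°/bp (60 bp) and 4°/bp
(100 bp) figures the gap is the 10-bp linker duplex span (3.4 nm) — the
physical closure of the assay's loops — giving 6.83 and 4.38°/bp; at a 5-nm
gap they would be 6.32 and 4.18. The deterministic elastica force law
−dE_min/dr0 (central difference, ±0.5 nm) tracks the Monte Carlo WLC force
within ~10–20% and serves as the noise-free generator default.

## Kinetic (Bell) analysis

Loop decay is first order, so per-size lifetimes come from the exponential
MLE τ = (total observed time)/(events) with exact χ² confidence intervals
(right-censored dwell times add observed time only); decay-count curves
N(t) are least-squares fitted with N0·e^{−t/τ} for parity with
survival-curve plots. Lifetime vs force is fitted as
log τ = log τ(0) − f·Δr0/kBT by iteratively reweighted least squares with
the bisquare influence function (tuning constant 4.685); Δr0 = −slope·kBT.

The softening transition is located by an RMSE range scan: for descending
lower cutoffs L_min, refit on sizes ≥ L_min and record the
dof-corrected residual RMSE; the plateau is the median RMSE over the larger
half of cutoffs, and the critical size is the smallest cutoff still below
(1 + 0.5) × plateau before the first jump (threshold configurable; "none"
when no cutoff jumps). Kink-barrier selection minimizes the summed squared
log-force discrepancy between a candidate model's force curve and a target
curve over a barrier grid.

## Synthetic data

The generator emulates the statistical structure of the single-molecule
unlooping assay: per loop size, n i.i.d. exponential dwell times with mean
τ(f(size)) from the Bell relationship under a configurable force law
(explicit table, model-derived elastica law, or Monte Carlo curve); optional
frame discretization, right-censoring at the observation window, and
per-size lognormal dispersion to stress the robust regression. Zero-force
dimer-dissociation controls are plain exponentials with mean τ(0). Defaults
mirror the study conditions: sizes 40–200 bp in 10-bp steps, 100 molecules
per size, τ(0) = 72.24 s and Δr0 = 1.10 nm (the 50 mM Na⁺ fit); presets for
other salts are placeholders flagged `paper_derived=False`.

What it does not emulate: photophysics (blinking, bleaching, intensity
noise), flow-exchange transients, molecule-to-molecule heterogeneity beyond
the optional lognormal dispersion, and any salt dependence beyond the
(τ0, Δr0) pair. Passing recovery tests therefore demonstrates correctness
of the estimators under the assumed kinetic model, not robustness to
photophysical artifacts.

## Problem sizes

Tests run reduced but honest simulations: forces from 1–4×10⁵ recorded
states × thin 8 (~3 independent repeats), minicircles from ~1.2×10⁵ recorded
sweeps × 3 repeats, window histograms from 4–6×10⁴ samples. The acceptance
script uses 10⁶ recorded states × thin 25 per force repeat (≈10⁶ accepted
updates, three repeats), 10⁵ free chains for persistence-length recovery,
and 6×10⁵ × thin 25 per repeat for the force-departure scan.

## Limitations and known discrepancies

* **100-bp shear force.** The converged estimator gives ≈4.0 pN where the
  source figure legend reads ~3 pN (and ≈8.8 vs ~8 at 60 bp). Both printed
  values are reproduced exactly under accepted-only recording, which is
  statistically biased; this package reports the correct dwell-weighted
  values.
* **Minicircle kinking probability.** At equilibrium, the h=17/b=0.7 chain
  kinks with probability ≈0.05 in a 70-bp circle, approaching unity only
  below ~45–50 bp; the properly closed one-kink 70-bp ring lies ≈5.6 kBT
  above the circle. The published claim of near-certain kinking at 70 bp is
  not reproducible as an equilibrium average of this Hamiltonian; plain
  crankshaft MC is strongly hysteretic at these sizes, so
  initialization-dependent metastability is the likely origin. The package
  reports converged equilibrium values.
* **KWLC forces near the softening size.** Even with barrier-ladder
  exchange, kink on/off switching dominates the variance of small-size KWLC
  force estimates (hence the SEM-controlled repeat rule). At r0 = 5 nm the
  equilibrium softening of the h=22/b=0.3 chain is modest — the KWLC force
  sits ~5-10% below the WLC at 40-50 bp and is indistinguishable at ≥55 bp
  — so the statistical significance of the departure accumulates slowly.
* The chain is a phantom (no excluded volume) without twist; J factors
  therefore lack helical-phase oscillations, appropriate for gapped-linker
  loops but not for covalently sealed, torsionally intact circles.
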