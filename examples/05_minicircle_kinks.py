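"""Kink statistics of closed DNA minicircles.

Closed rings of the kinkable chain are sampled by crankshaft Monte Carlo
with Hamiltonian replica exchange over a ladder of kink barriers (plain
crankshaft dynamics cannot cross between the kinked and unkinked basins at
feasible run lengths). A joint counts as kinked when its bend angle exceeds
the critical kink angle.
"""

import math

from kinkloop import BendingModel, SamplerConfig, critical_kink_angle, kink_probability

m = BendingModel.kwlc(17.0, 0.7)  # magnesium fit
print(f"critical kink angle: {math.degrees(critical_kink_angle(m)):.1f} deg\n")

cfg = SamplerConfig(n_equil=200_000, n_samples=120_000, seed=4)
for size in (45, 60, 100):
    stats = kink_probability(m, size, cfg, n_repeats=3)
    print(f"{size:4d} bp ring: P(>=1 kink) = {stats.p_kink:.3f} "
          f"(repeat SEM {stats.se_repeats:.3f}, mean kinks {stats.mean_kinks:.2f})")

print()
print("Kinking turns on sharply as the ring shrinks and the elastic bending")
print("stress approaches the kink barrier; with the h = 17 kBT magnesium")
print("barrier the equilibrium transition sits near 45-55 bp, while rings")
print("above ~100 bp essentially never kink.")
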