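"""Physical constants and unit conversions.

All internal energies are in units of kBT; forces cross to pN and lengths to nm
only at interfaces. The thermal energy defaults to 4.114 pN nm (T = 298 K).
"""

from __future__ import annotations

from dataclasses import dataclass

#: Thermal energy in pN nm at 298 K.
KBT_PNNM = 4.114

#: Helical rise per base pair, nm.
BP_RISE_NM = 0.34

#: LSEC monomer length in base pairs (coarse 7-bp segment).
LSEC_MONOMER_BP = 7

#: LSEC monomer length, nm.
LSEC_MONOMER_NM = LSEC_MONOMER_BP * BP_RISE_NM

#: Number-density to molar conversion: 1 chain / nm^3 = 1.6606 M
#: (10^24 nm^3 per litre / Avogadro's number).
MOLAR_PER_NM3 = 1.6606

#: Length of the annealed linker duplex, bp; its helical span (nm) is the
#: natural end-to-end gap of a loop closed by the linker.
LINKER_BP = 10
LINKER_SPAN_NM = LINKER_BP * BP_RISE_NM


@dataclass(frozen=True)
class ThermalConstants:
    """Energy/length unit conventions for a run."""

    kBT_pNnm: float = KBT_PNNM
    bp_rise: float = BP_RISE_NM

    def __post_init__(self) -> None:
        if self.kBT_pNnm <= 0 or self.bp_rise <= 0:
            raise ValueError("thermal constants must be positive")


def strong_bending_threshold_deg_per_bp(
    lp_nm: float = 50.0, bp_rise: float = BP_RISE_NM
) -> float:
    """Bend rate marking the strong-bending regime: one full helical turn
    (360 degrees of contour deflection) accumulated over one persistence
    length, expressed per base pair. For Lp = 50 nm this is ~2.4 deg/bp.
    """
    if lp_nm <= 0 or bp_rise <= 0:
        raise ValueError("lengths must be positive")
    return 360.0 / (lp_nm / bp_rise)
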