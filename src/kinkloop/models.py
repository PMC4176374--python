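"""Coarse-grained DNA bending-energy models.

Three discrete-chain models of double-stranded DNA bending are supported, each
assigning an energy (in kBT) to the bend angle theta between successive links:

* ``wlc`` — worm-like chain, E = (k/2) theta^2, one link per base pair.
* ``lsec`` — linear subelastic chain, E = B |theta|, one link per 7 bp;
  softer than the WLC at high curvature.
* ``kwlc`` — kinkable worm-like chain, E = min((k/2) theta^2, h + (theta-b)^6):
  the elastic branch of the WLC in series with a flat-bottomed "kinked" branch
  of barrier height h (kBT) and angular offset b (rad).

Rigidity constants (k or B) are never hard-coded: they are calibrated so the
single-step mean cosine under the Boltzmann weight with the solid-angle
Jacobian reproduces a target persistence length, Lp = -l / ln<cos theta>.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .constants import BP_RISE_NM, LSEC_MONOMER_NM

ModelKind = Literal["wlc", "lsec", "kwlc"]

_KIND_CODES = {"wlc": 0, "lsec": 1, "kwlc": 2}


@dataclass(frozen=True)
class BendingModel:
    """A bending-energy model with calibrated rigidity.

    Parameters
    ----------
    kind : {"wlc", "lsec", "kwlc"}
    k : float
        Bending rigidity, kBT/rad^2 (wlc/kwlc).
    B : float
        Linear bending constant, kBT/rad (lsec).
    h : float
        Kink energy barrier, kBT (kwlc).
    b : float
        Kink angle offset, rad (kwlc).
    l : float
        Monomer (link) length, nm: 0.34 for wlc/kwlc, 2.38 for lsec.
    lp_target : float
        Persistence length the rigidity was calibrated to, nm.
    """

    kind: ModelKind
    l: float
    lp_target: float
    k: float | None = None
    B: float | None = None
    h: float | None = None
    b: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KIND_CODES:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.l <= 0:
            raise ValueError("monomer length must be positive")
        if self.kind in ("wlc", "kwlc"):
            if self.k is None or self.k <= 0:
                raise ValueError("wlc/kwlc require k > 0")
        if self.kind == "lsec":
            if self.B is None or self.B <= 0:
                raise ValueError("lsec requires B > 0")
        if self.kind == "kwlc":
            if self.h is None or self.h < 0:
                raise ValueError("kwlc requires h >= 0")
            if self.b is None or self.b < 0:
                raise ValueError("kwlc requires b >= 0")

    # --- constructors -----------------------------------------------------

    @staticmethod
    def wlc(lp_target: float = 50.0, l: float = BP_RISE_NM) -> "BendingModel":
        return calibrate_rigidity("wlc", lp_target, l)

    @staticmethod
    def lsec(lp_target: float = 50.0, l: float = LSEC_MONOMER_NM) -> "BendingModel":
        return calibrate_rigidity("lsec", lp_target, l)

    @staticmethod
    def kwlc(
        h: float, b: float, lp_target: float = 50.0, l: float = BP_RISE_NM
    ) -> "BendingModel":
        base = calibrate_rigidity("wlc", lp_target, l)
        return replace(base, kind="kwlc", h=float(h), b=float(b))

    # --- numba kernel packing --------------------------------------------

    def pack(self) -> tuple[int, float, float, float, float]:
        """(code, k, B, h, b) scalars for the compiled MC kernels."""
        return (
            _KIND_CODES[self.kind],
            float(self.k or 0.0),
            float(self.B or 0.0),
            float(self.h or 0.0),
            float(self.b or 0.0),
        )

    @property
    def bp_per_link(self) -> float:
        return self.l / BP_RISE_NM

    # --- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "Lp_target": self.lp_target, "l_nm": self.l}
        if self.kind == "kwlc":
            d["h_kBT"] = self.h
            d["b_rad"] = self.b
        return d

    @staticmethod
    def from_dict(d: dict) -> "BendingModel":
        kind = d["kind"]
        lp = float(d.get("Lp_target", 50.0))
        l = d.get("l_nm")
        if l is None:
            l = LSEC_MONOMER_NM if kind == "lsec" else BP_RISE_NM
        if kind == "kwlc":
            return BendingModel.kwlc(float(d["h_kBT"]), float(d["b_rad"]), lp, float(l))
        return calibrate_rigidity(kind, lp, float(l))


def bend_energy(model: BendingModel, theta) -> np.ndarray | float:
    """Bending energy (kBT) of one link-link joint at angle ``theta`` (rad).

    Vectorized over theta; raises for angles outside [0, pi].
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0) or np.any(th > np.pi):
        raise ValueError("bend angle must lie in [0, pi]")
    if model.kind == "wlc":
        e = 0.5 * model.k * th**2
    elif model.kind == "lsec":
        e = model.B * np.abs(th)
    else:
        e = np.minimum(0.5 * model.k * th**2, model.h + (th - model.b) ** 6)
    return float(e) if np.isscalar(theta) else e


def _elastic_energy(model: BendingModel, th: float) -> float:
    if model.kind == "lsec":
        return model.B * abs(th)
    return 0.5 * model.k * th * th


def mean_step_cosine(model: BendingModel) -> float:
    """<cos theta> of a single joint under e^{-E(theta)} sin(theta) d theta."""
    e = lambda t: bend_energy(model, float(t))
    num = quad(lambda t: math.cos(t) * math.exp(-e(t)) * math.sin(t), 0, math.pi,
               limit=200)[0]
    den = quad(lambda t: math.exp(-e(t)) * math.sin(t), 0, math.pi, limit=200)[0]
    return num / den


def persistence_length(model: BendingModel) -> float:
    """Theoretical persistence length Lp = -l / ln<cos theta>, nm."""
    return -model.l / math.log(mean_step_cosine(model))


def calibrate_rigidity(kind: ModelKind, lp_target: float, l: float) -> BendingModel:
    """Solve for the rigidity constant reproducing ``lp_target``.

    The defining relation is the tangent-decorrelation identity of a chain
    with independent joints, Lp = -l / ln<cos theta>; the rigidity is the
    quadrature+bisection root of <cos theta> = exp(-l/Lp) to relative
    tolerance 1e-8.
    """
    if lp_target <= 0 or l <= 0:
        raise ValueError("lengths must be positive")
    if l >= lp_target:
        raise ValueError("monomer length must be below the persistence length")
    target = math.exp(-l / lp_target)

    def resid(c: float) -> float:
        if kind == "lsec":
            m = BendingModel("lsec", l=l, lp_target=lp_target, B=c)
        else:
            m = BendingModel("wlc", l=l, lp_target=lp_target, k=c)
        return mean_step_cosine(m) - target

    lo, hi = 1e-3, 10.0
    while resid(hi) < 0:
        hi *= 4.0
        if hi > 1e8:
            raise RuntimeError("rigidity calibration: no root in bracket")
    if resid(lo) > 0:
        raise RuntimeError("rigidity calibration: no root in bracket")
    c = brentq(resid, lo, hi, rtol=1e-10, xtol=1e-12)
    if kind == "lsec":
        return BendingModel("lsec", l=l, lp_target=lp_target, B=c)
    return BendingModel(kind, l=l, lp_target=lp_target, k=c)


def critical_kink_angle(model: BendingModel) -> float:
    """Angle theta_c (rad) where the elastic and kinked branches intersect.

    The smallest root of (k/2) theta^2 = h + (theta - b)^6 in (0, pi); a step
    bent beyond theta_c is assigned to the kinked branch. For h = 0 the
    branches meet at the origin.
    """
    if model.kind != "kwlc":
        raise ValueError("critical kink angle is defined only for kwlc")
    if model.h == 0 and model.b == 0:
        return 0.0
    if model.h == 0:
        return 0.0

    def g(t: float) -> float:
        return 0.5 * model.k * t * t - model.h - (t - model.b) ** 6

    # scan for the first sign change from below
    ts = np.linspace(1e-9, math.pi, 2000)
    vals = np.array([g(t) for t in ts])
    idx = np.nonzero((vals[:-1] < 0) & (vals[1:] >= 0))[0]
    if len(idx) == 0:
        raise RuntimeError("elastic branch never reaches the kink barrier")
    return brentq(g, ts[idx[0]], ts[idx[0] + 1], xtol=1e-10)


def kink_free_energy(
    model: BendingModel, partition_at_critical: bool = True
) -> float:
    """Free energy of kink formation per dinucleotide step, kBT.

    Orientational partition-function ratio of the kinked branch to the
    elastic branch with the solid-angle Jacobian:

        dG_k = -ln[ Z_kink / Z_elastic ],
        Z_branch = integral e^{-E_branch(theta)} sin(theta) d theta.

    With ``partition_at_critical`` (default) the integrals partition
    configuration space at the critical kink angle theta_c (elastic branch on
    [0, theta_c], kinked branch on [theta_c, pi]); otherwise both run over the
    full [0, pi] range. The two conventions differ by < 0.3 kBT for the
    parameter sets of interest.
    """
    if model.kind != "kwlc":
        raise ValueError("kink free energy is defined only for kwlc")
    if model.h is None or model.h <= 0:
        raise ValueError("kink free energy requires h > 0")
    k, h, b = model.k, model.h, model.b
    kink = lambda t: math.exp(-(h + (t - b) ** 6)) * math.sin(t)
    elastic = lambda t: math.exp(-0.5 * k * t * t) * math.sin(t)
    if partition_at_critical:
        tc = critical_kink_angle(model)
        z_kink = quad(kink, tc, math.pi, limit=400, epsabs=1e-12)[0]
        z_el = quad(elastic, 0, tc, limit=400, epsabs=1e-12)[0]
    else:
        z_kink = quad(kink, 0, math.pi, limit=400, epsabs=1e-12)[0]
        z_el = quad(elastic, 0, math.pi, limit=400, epsabs=1e-12)[0]
    return -math.log(z_kink / z_el)


def step_angle_cdf(model: BendingModel, n_grid: int = 200_001) -> np.ndarray:
    """CDF table of the single-joint angle density p(theta) ~ e^{-E(theta)}
    sin(theta) on a uniform grid over [0, pi], for exact inverse-transform
    sampling of unrestrained chains (the sampler binary-searches this table,
    so tail resolution is that of the theta grid itself)."""
    th = np.linspace(0.0, math.pi, n_grid)
    dens = np.exp(-np.asarray(bend_energy(model, th), dtype=float)) * np.sin(th)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]))])
    cdf /= cdf[-1]
    return cdf
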