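"""Minimum-energy (elastica-like) loop shapes.

The ground state of a bent loop with free end orientations is planar, so the
optimization is carried out over planar link direction angles psi_i with two
equality constraints fixing the end-to-end vector (length r0, orientation
along +x to remove the rotational degeneracy). The resulting "teardrop"
shape — a single curvature maximum opposite the gap — sets the maximum
per-base-pair bend of a loop of a given size, and initializes the restrained
Monte Carlo runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .conformation import ChainConformation, arc_directions, chain_from_directions
from .constants import BP_RISE_NM, LINKER_SPAN_NM
from .models import BendingModel, bend_energy


@dataclass
class MinEnergyLoop:
    conformation: ChainConformation
    energy: float  # kBT
    r0: float  # nm
    model: BendingModel

    @property
    def max_bend_deg_per_bp(self) -> float:
        return max_bend_per_bp(self)


def _optimize(model: BendingModel, psi0: np.ndarray, r0: float) -> tuple[np.ndarray, float]:
    l = model.l
    if model.kind == "lsec":
        # linear energy: sum B|dpsi| = B * total turn for any convex shape;
        # the initial arc is already a minimizer
        d = np.abs(np.diff(psi0))
        return psi0, float(model.B * d.sum())

    k, h, b = model.k, model.h, model.b

    def energy(psi: np.ndarray) -> float:
        d = np.abs(np.diff(psi))
        if model.kind == "wlc":
            return float(0.5 * k * np.sum(d * d))
        return float(np.sum(np.minimum(0.5 * k * d * d, h + (d - b) ** 6)))

    def grad(psi: np.ndarray) -> np.ndarray:
        d = np.diff(psi)
        ad = np.abs(d)
        if model.kind == "wlc":
            ge = k * d
        else:
            elastic = 0.5 * k * ad * ad <= h + (ad - b) ** 6
            ge = np.where(elastic, k * d, 6 * (ad - b) ** 5 * np.sign(d))
        g = np.zeros_like(psi)
        g[1:] += ge
        g[:-1] -= ge
        return g

    cons = [
        {
            "type": "eq",
            "fun": lambda p: np.sum(l * np.cos(p)) - r0,
            "jac": lambda p: -l * np.sin(p),
        },
        {
            "type": "eq",
            "fun": lambda p: np.sum(l * np.sin(p)),
            "jac": lambda p: l * np.cos(p),
        },
    ]
    res = minimize(
        energy, psi0, jac=grad, constraints=cons, method="SLSQP",
        options={"maxiter": 3000, "ftol": 1e-14},
    )
    if not res.success and res.status != 8:  # 8: positive directional derivative
        raise RuntimeError(f"loop optimization failed: {res.message}")
    return res.x, float(energy(res.x))


def _one_kink_directions(n_links: int, l: float, r0: float, theta_kink: float) -> np.ndarray:
    """Planar init with one sharp joint and a gentle arc elsewhere: the
    teardrop of a kinked loop. Built from an arc whose first joint turn is
    replaced by theta_kink, then rescaled to meet the chord constraint."""
    psi = arc_directions(n_links, l, r0)
    turns = np.diff(psi)
    total = turns.sum()
    # place the kink at the joint opposite the gap (middle of the chain)
    mid = n_links // 2
    remaining = total - theta_kink
    new_turns = np.full(n_links - 1, remaining / (n_links - 2))
    new_turns[mid] = theta_kink
    out = np.concatenate([[psi[0]], psi[0] + np.cumsum(new_turns)])
    return out


def min_energy_loop(model: BendingModel, n_links: int, r0: float) -> MinEnergyLoop:
    """Planar minimum of the total bending energy with the end separation
    fixed at ``r0`` and free end angles.

    Deterministic: initialized from a circular arc (and, for the KWLC model,
    additionally from a one-kink teardrop; the lower minimum is returned)
    and refined by SLSQP.
    """
    if n_links * model.l <= r0:
        raise ValueError("end separation unreachable for this contour length")
    psi0 = arc_directions(n_links, model.l, r0)
    psi, e = _optimize(model, psi0, r0)
    if model.kind == "kwlc":
        kink_angle = min(math.pi * 0.9, model.b + 0.5)
        try:
            psi_k0 = _one_kink_directions(n_links, model.l, r0, kink_angle)
            psi_k, e_k = _optimize(model, psi_k0, r0)
            if e_k < e:
                psi, e = psi_k, e_k
        except Exception:
            pass
    conf = chain_from_directions(psi, model.l)
    return MinEnergyLoop(conformation=conf, energy=e, r0=r0, model=model)


def max_bend_per_bp(loop: MinEnergyLoop) -> float:
    """Largest joint bend of the loop, degrees per base pair."""
    th = loop.conformation.bend_angles()
    return math.degrees(float(th.max())) / loop.model.bp_per_link


def circle_energy(model: BendingModel, n_links: int) -> float:
    """Bending energy of the regular N-gon (all joints at 2 pi / N), kBT."""
    return n_links * float(bend_energy(model, 2 * math.pi / n_links))


def one_kink_circle_energy(model: BendingModel, n_links: int) -> float:
    """Energy estimate of a closed one-kink teardrop: one joint on the kinked
    branch, the remaining N-1 joints sharing the residual turn elastically.
    Minimized over the kink angle."""
    if model.kind != "kwlc":
        raise ValueError("one-kink estimate requires the kwlc model")
    k, h, b = model.k, model.h, model.b

    def e(theta: float) -> float:
        rest = (2 * math.pi - theta) / (n_links - 1)
        return h + (theta - b) ** 6 + (n_links - 1) * 0.5 * k * rest * rest

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(e, bounds=(0.0, math.pi), method="bounded")
    return float(res.fun)


def teardrop_max_bend(
    model: BendingModel, size_bp: int, r0: float = LINKER_SPAN_NM
) -> float:
    """Maximum bend (deg/bp) of the minimum-energy loop of ``size_bp``.

    The default gap is the helical span of the ~10-bp linker duplex that
    closes the loop in the unlooping assay (3.4 nm).
    """
    n_links = round(size_bp / model.bp_per_link)
    return max_bend_per_bp(min_energy_loop(model, n_links, r0))
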