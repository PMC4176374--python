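"""Discrete chain conformations and their energies.

A chain of N rigid links is stored as N+1 ordered vertices (open chains) or N
vertices (closed rings, the last link returning to the first vertex). Bend
angles are measured between successive link vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .models import BendingModel, bend_energy


@dataclass
class ChainConformation:
    """Ordered 3D vertex positions (nm) of a discrete chain.

    ``closed`` rings store one vertex per link; open chains store N+1 vertices
    for N links.
    """

    vertices: np.ndarray
    link_length: float
    closed: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (M, 3) array")
        if self.link_length <= 0:
            raise ValueError("link length must be positive")

    @property
    def n_links(self) -> int:
        return len(self.vertices) if self.closed else len(self.vertices) - 1

    def link_vectors(self) -> np.ndarray:
        if self.closed:
            return np.roll(self.vertices, -1, axis=0) - self.vertices
        return np.diff(self.vertices, axis=0)

    def validate(self, rtol: float = 1e-9) -> None:
        """Raise if any link deviates from the nominal link length."""
        lens = np.linalg.norm(self.link_vectors(), axis=1)
        if not np.allclose(lens, self.link_length, rtol=rtol, atol=0):
            worst = float(np.abs(lens - self.link_length).max())
            raise ValueError(
                f"invalid conformation: link length deviates by {worst:.3e} nm"
            )

    def bend_angles(self) -> np.ndarray:
        """Angles between successive link vectors, rad, each in [0, pi].

        Open chains have N-1 joints; closed rings have N (cyclic).
        """
        t = self.link_vectors()
        if self.closed:
            a, b = t, np.roll(t, -1, axis=0)
        else:
            a, b = t[:-1], t[1:]
        c = np.einsum("ij,ij->i", a, b) / (self.link_length**2)
        return np.arccos(np.clip(c, -1.0, 1.0))

    @property
    def end_to_end(self) -> float:
        if self.closed:
            return 0.0
        return float(np.linalg.norm(self.vertices[-1] - self.vertices[0]))


@dataclass(frozen=True)
class RestraintSpec:
    """Harmonic end-to-end restraint U(r) = (K/2)(r - r0)^2.

    K in kBT/nm^2, r0 in nm.
    """

    K: float
    r0: float

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("restraint stiffness must be non-negative")
        if self.r0 <= 0:
            raise ValueError("restraint center must be positive")

    def energy(self, r: float) -> float:
        return 0.5 * self.K * (r - self.r0) ** 2


def total_energy(
    conf: ChainConformation,
    model: BendingModel,
    restraint: RestraintSpec | None = None,
) -> float:
    """Total energy (kBT): sum of joint bending energies plus the restraint."""
    conf.validate()
    e = float(np.sum(bend_energy(model, conf.bend_angles())))
    if restraint is not None and not conf.closed:
        e += restraint.energy(conf.end_to_end)
    return e


# --- constructors ---------------------------------------------------------


def straight_chain(n_links: int, link_length: float) -> ChainConformation:
    v = np.zeros((n_links + 1, 3))
    v[:, 0] = np.arange(n_links + 1) * link_length
    return ChainConformation(v, link_length)


def regular_polygon(n_links: int, link_length: float) -> ChainConformation:
    """Closed regular N-gon with the given side length (all joints 2*pi/N)."""
    if n_links < 3:
        raise ValueError("a closed polygon needs at least 3 links")
    R = link_length / (2.0 * math.sin(math.pi / n_links))
    ang = 2.0 * math.pi * np.arange(n_links) / n_links
    v = np.column_stack([R * np.cos(ang), R * np.sin(ang), np.zeros(n_links)])
    return ChainConformation(v, link_length, closed=True)


def arc_directions(n_links: int, link_length: float, r0: float) -> np.ndarray:
    """Planar link direction angles of a circular arc whose endpoints are r0
    apart, oriented with the end-to-end vector along +x. Used to initialize
    restrained loops and the teardrop optimizer.
    """
    if n_links * link_length <= r0:
        raise ValueError("chain too short to reach the requested end separation")

    def chord(T: float) -> float:
        psi = np.linspace(0.0, T, n_links)
        return math.hypot(
            float(np.sum(link_length * np.cos(psi))),
            float(np.sum(link_length * np.sin(psi))),
        )

    hi = 2.0 * math.pi * (1.0 - 1.0 / (2 * n_links))
    if chord(hi) > r0:
        T = hi  # cannot close further; near-closed arc
    else:
        T = brentq(lambda T: chord(T) - r0, 1e-9, hi, xtol=1e-12)
    psi = np.linspace(0.0, T, n_links)
    vx = float(np.sum(np.cos(psi)))
    vy = float(np.sum(np.sin(psi)))
    return psi - math.atan2(vy, vx)


def circular_arc(n_links: int, link_length: float, r0: float) -> ChainConformation:
    """Open chain bent into a circular arc with end separation ~r0."""
    psi = arc_directions(n_links, link_length, r0)
    v = np.zeros((n_links + 1, 3))
    v[1:, 0] = np.cumsum(link_length * np.cos(psi))
    v[1:, 1] = np.cumsum(link_length * np.sin(psi))
    return ChainConformation(v, link_length)


def chain_from_directions(psi: np.ndarray, link_length: float) -> ChainConformation:
    """Planar open chain from link direction angles."""
    psi = np.asarray(psi, dtype=float)
    v = np.zeros((len(psi) + 1, 3))
    v[1:, 0] = np.cumsum(link_length * np.cos(psi))
    v[1:, 1] = np.cumsum(link_length * np.sin(psi))
    return ChainConformation(v, link_length)
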