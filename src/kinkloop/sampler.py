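"""Monte Carlo chain sampling: restrained open loops, closed minicircles and
free chains.

The pivot sampler drives the umbrella simulations behind the shear-force and
J-factor calculations; the crankshaft sampler drives closed-minicircle kink
statistics. Unrestrained chains are drawn directly from the single-step
Boltzmann density (exact for a phantom chain), which serves both as the
persistence-length cross-check and as the brute-force oracle for the
umbrella machinery.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._mc import (
    crankshaft_kernel,
    free_chain_kernel,
    hladder_crankshaft_kernel,
    hladder_pivot_kernel,
    pivot_kernel,
)
from .conformation import (
    ChainConformation,
    RestraintSpec,
    circular_arc,
    regular_polygon,
    straight_chain,
)
from .models import BendingModel, critical_kink_angle, step_angle_cdf


def child_seed(seed: int, *names) -> int:
    """Deterministic child seed (< 2^31) for a named stage."""
    key = ":".join([str(seed), *map(str, names)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass(frozen=True)
class SamplerConfig:
    """Monte Carlo run lengths and proposal settings.

    ``crank_intervals`` are the two uniform proposal intervals (rad) for
    crankshaft rotations; defaults are [-90, 90] and [-10, 10] degrees.
    """

    n_equil: int = 100_000
    n_samples: int = 1_000_000
    thin: int = 1
    seed: int = 0
    crank_intervals: tuple[tuple[float, float], tuple[float, float]] = (
        (-math.pi / 2, math.pi / 2),
        (-math.pi / 18, math.pi / 18),
    )

    def __post_init__(self) -> None:
        if self.n_equil < 0 or self.n_samples < 0 or self.thin < 1:
            raise ValueError("invalid sampler configuration")


class SamplerStuckError(RuntimeError):
    pass


@dataclass
class RadialSampleSet:
    """End-to-end distances (nm) recorded from one restrained simulation."""

    r_values: np.ndarray
    restraint: RestraintSpec
    model: BendingModel
    n_links: int
    acceptance: float
    seed: int

    def __post_init__(self) -> None:
        self.r_values = np.asarray(self.r_values, dtype=float)
        if len(self.r_values) == 0:
            raise ValueError("empty sample set")
        if np.any(self.r_values < 0):
            raise ValueError("end-to-end distances must be non-negative")

    @property
    def delta_r(self) -> np.ndarray:
        return self.r_values - self.restraint.r0

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"sample_index": np.arange(len(self.r_values)), "r_nm": self.r_values}
        ).to_csv(path, index=False)
        meta = {
            "model": self.model.to_dict(),
            "K_kBT_nm2": self.restraint.K,
            "r0_nm": self.restraint.r0,
            "n_links": self.n_links,
            "acceptance": self.acceptance,
            "seed": self.seed,
        }
        Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=1))


def _initial_loop(model: BendingModel, n_links: int, restraint: RestraintSpec):
    """Starting conformation for a restrained run: the minimum-energy loop
    for quadratic-energy models, a circular arc for the LSEC model (whose
    constrained minimum is degenerate — any convex planar shape with the
    same total turn has equal energy)."""
    if model.kind == "lsec":
        return circular_arc(n_links, model.l, restraint.r0)
    from .loop_geometry import min_energy_loop

    return min_energy_loop(model, n_links, restraint.r0).conformation


def sample_restrained_chain(
    model: BendingModel,
    n_links: int,
    restraint: RestraintSpec | None,
    config: SamplerConfig,
    initial: ChainConformation | None = None,
    exchange: bool = False,
    h_ladder_step: float = 2.0,
    h_min: float = 4.0,
    swap_every: int = 2,
) -> RadialSampleSet:
    """Pivot-move Metropolis sampling of an open chain, recording the
    end-to-end distance of every ``thin``-th accepted conformation after
    ``n_equil`` equilibration proposals.

    Starts from the minimum-energy loop under the restraint (or a straight
    chain when unrestrained). Deterministic for a given config seed.
    """
    if n_links < 2:
        raise ValueError("need at least 2 links")
    if restraint is None:
        restraint = RestraintSpec(K=0.0, r0=n_links * model.l)
    if initial is None:
        if restraint.K == 0.0:
            initial = straight_chain(n_links, model.l)
        else:
            initial = _initial_loop(model, n_links, restraint)
    verts = np.array(initial.vertices, dtype=float)
    code, k, B, h, b = model.pack()
    max_props = config.n_equil + max(2_000_000, 2000 * config.n_samples * config.thin)
    if exchange and model.kind == "kwlc" and h > h_min + h_ladder_step:
        # kink nucleation in a stressed loop is a rare event under plain
        # pivot dynamics: exchange over a ladder of reduced barriers
        n_replicas = int(math.ceil((h - h_min) / h_ladder_step)) + 1
        hs = np.linspace(h, h_min, n_replicas)
        reps = np.repeat(verts[None, :, :], n_replicas, axis=0)
        r_out, n_rec, n_acc, n_props, _ = hladder_pivot_kernel(
            k, b, model.l, restraint.K, restraint.r0, hs, reps,
            config.n_equil, config.n_samples, config.thin, swap_every,
            config.seed, max_props,
        )
    else:
        r_out, n_rec, n_acc, n_props = pivot_kernel(
            code, k, B, h, b, model.l, restraint.K, restraint.r0, verts,
            config.n_equil, config.n_samples, config.thin, config.seed, max_props,
        )
    if n_rec < config.n_samples:
        raise SamplerStuckError(
            f"sampler stuck: {n_rec}/{config.n_samples} samples after "
            f"{n_props} proposals (acceptance {n_acc / max(n_props, 1):.2e})"
        )
    return RadialSampleSet(
        r_values=r_out,
        restraint=restraint,
        model=model,
        n_links=n_links,
        acceptance=n_acc / n_props,
        seed=config.seed,
    )


@dataclass
class MinicircleRun:
    """Angle statistics from one closed-ring crankshaft simulation."""

    n_links: int
    model: BendingModel
    theta_c: float
    n_recorded: int
    n_with_kink: int
    kink_sum: int
    min_energy: float
    acceptance: float
    angle_hist: np.ndarray  # counts over [0, pi)
    hist_conformations: int
    seed: int

    @property
    def p_kink(self) -> float:
        return self.n_with_kink / self.n_recorded

    @property
    def mean_kinks(self) -> float:
        return self.kink_sum / self.n_recorded

    def angle_density(self) -> tuple[np.ndarray, np.ndarray]:
        """(bin_centers, normalized density) of recorded joint angles."""
        nb = len(self.angle_hist)
        edges = np.linspace(0, np.pi, nb + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        total = self.angle_hist.sum()
        width = np.pi / nb
        return centers, self.angle_hist / max(total, 1) / width


def sample_minicircle(
    model: BendingModel,
    n_links: int,
    config: SamplerConfig,
    n_hist_bins: int = 360,
    exchange: bool = True,
    h_ladder_step: float = 1.5,
    h_min: float = 4.0,
    swap_every: int = 2,
) -> MinicircleRun:
    """Crankshaft Metropolis sampling of an exactly closed minicircle,
    starting from the regular polygon. All joint angles are tracked for every
    accepted conformation; a step counts as kinked when its angle exceeds
    the critical kink angle (non-KWLC models never kink).

    Kinked and unkinked rings are separated by a barrier of order the kink
    energy h, which plain crankshaft dynamics cannot cross at feasible run
    lengths; with ``exchange`` (default) the kinkable model therefore runs
    Hamiltonian replica exchange over a ladder of barriers stepping down
    from h to ``h_min`` in ``h_ladder_step`` increments. Kinks form and
    dissolve freely at the bottom of the ladder and equilibrated
    configurations percolate up; statistics come from the physical-h replica
    only. ``exchange=False`` gives the plain single-replica sampler.
    """
    if n_links < 4:
        raise ValueError("need at least 4 links to crankshaft a closed ring")
    ring = regular_polygon(n_links, model.l)
    theta_c = critical_kink_angle(model) if model.kind == "kwlc" else math.pi
    (lo1, hi1), (lo2, hi2) = config.crank_intervals
    code, k, B, h, b = model.pack()
    hist = np.zeros(n_hist_bins, dtype=np.int64)
    hist_max = config.n_samples  # histogram every recorded conformation
    use_ladder = exchange and model.kind == "kwlc" and h > h_min + h_ladder_step
    if not use_ladder:
        verts = np.array(ring.vertices, dtype=float)
        max_props = config.n_equil + max(2_000_000, 500 * config.n_samples)
        rec, with_kink, kink_sum, e_min, acc, props = crankshaft_kernel(
            code, k, B, h, b, model.l, verts, theta_c, config.n_equil,
            config.n_samples, lo1, hi1, lo2, hi2, config.seed, max_props,
            hist, hist_max,
        )
    else:
        n_replicas = int(math.ceil((h - h_min) / h_ladder_step)) + 1
        hs = np.linspace(h, h_min, n_replicas)
        verts = np.repeat(
            np.array(ring.vertices, dtype=float)[None, :, :], n_replicas, axis=0
        )
        max_sweeps = config.n_equil + max(2_000_000, 500 * config.n_samples)
        rec, with_kink, kink_sum, e_min, acc, props, _ = (
            hladder_crankshaft_kernel(
                k, b, model.l, hs, verts, theta_c, config.n_equil,
                config.n_samples, lo1, hi1, lo2, hi2, swap_every,
                config.seed, max_sweeps, hist, hist_max,
            )
        )
        verts = verts[0]
    if rec < config.n_samples:
        raise SamplerStuckError(
            f"minicircle sampler stuck: {rec}/{config.n_samples} after "
            f"{props} proposals"
        )
    final = ChainConformation(verts, model.l, closed=True)
    final.validate(rtol=1e-7)
    return MinicircleRun(
        n_links=n_links,
        model=model,
        theta_c=theta_c,
        n_recorded=rec,
        n_with_kink=with_kink,
        kink_sum=kink_sum,
        min_energy=e_min,
        acceptance=acc / props,
        angle_hist=hist,
        hist_conformations=min(rec, hist_max),
        seed=config.seed,
    )


# --- free chains ----------------------------------------------------------


def free_chain_distances(
    model: BendingModel, n_links: int, n_chains: int, seed: int
) -> np.ndarray:
    """End-to-end distances (nm) of unrestrained chains drawn directly from
    the equilibrium single-step density (exact, no Markov chain)."""
    cdf = step_angle_cdf(model)
    sep = np.empty(0, dtype=np.int64)
    _, _, r = free_chain_kernel(cdf, model.l, n_links, n_chains, seed, sep, 1)
    return r


def tangent_correlation(
    model: BendingModel,
    n_links: int,
    n_chains: int,
    seed: int,
    separations: np.ndarray | None = None,
    i_stride: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean tangent-tangent correlation <t_i . t_{i+s}> of free chains.

    Returns (contour separations in nm, correlations). Separations default
    to ~24 values spanning up to ~1.5 persistence lengths.
    """
    if separations is None:
        max_s = min(n_links - 1, max(4, int(1.5 * model.lp_target / model.l)))
        separations = np.unique(
            np.round(np.linspace(1, max_s, 24)).astype(np.int64)
        )
    separations = np.asarray(separations, dtype=np.int64)
    cdf = step_angle_cdf(model)
    corr, cnt, _ = free_chain_kernel(
        cdf, model.l, n_links, n_chains, seed, separations, i_stride
    )
    return separations * model.l, corr / cnt


def fit_persistence_length(sep_nm: np.ndarray, corr: np.ndarray) -> float:
    """Exponential-decay fit ln C(s) = const - s/Lp; returns Lp in nm."""
    mask = corr > 0
    slope, _ = np.polyfit(sep_nm[mask], np.log(corr[mask]), 1)
    if slope >= 0:
        raise RuntimeError("tangent correlation does not decay")
    return -1.0 / slope
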