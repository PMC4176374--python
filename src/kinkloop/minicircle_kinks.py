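"""Kink statistics of closed DNA minicircles under the KWLC energy.

A joint of a sampled minicircle counts as kinked when its bend angle exceeds
the critical kink angle (the intercept of the elastic and kinked energy
branches). The kinking probability of a circle is the fraction of accepted
conformations carrying at least one kink; it rises sharply as the circle
shrinks and the elastic bending stress approaches the kink barrier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import BendingModel, critical_kink_angle
from .sampler import MinicircleRun, SamplerConfig, child_seed, sample_minicircle


def count_kinks(angles: np.ndarray, theta_c: float) -> int:
    """Number of joints bent beyond the critical kink angle."""
    angles = np.asarray(angles, dtype=float)
    if np.any(angles < 0) or np.any(angles > np.pi):
        raise ValueError("angles must lie in [0, pi]")
    return int(np.sum(angles > theta_c))


@dataclass
class KinkStats:
    size_bp: float
    p_kink: float
    se_binomial: float
    se_repeats: float
    mean_kinks: float
    n_conformations: int
    theta_c: float
    n_repeats: int
    per_repeat: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_kink <= 1.0:
            raise ValueError("p_kink must lie in [0, 1]")


def kink_probability(
    model: BendingModel,
    size_bp: float,
    config: SamplerConfig = SamplerConfig(n_samples=1_000_000),
    n_repeats: int = 3,
) -> KinkStats:
    """Kinking probability of one minicircle size from independent repeats.

    Both error estimates the data allow are reported: the binomial standard
    error of the pooled fraction and the SEM over repeat runs.
    """
    if model.kind != "kwlc":
        raise ValueError("kink statistics require the kwlc model")
    n_links = round(size_bp / model.bp_per_link)
    runs: list[MinicircleRun] = []
    for rep in range(n_repeats):
        cfg = SamplerConfig(
            n_equil=config.n_equil,
            n_samples=config.n_samples,
            thin=config.thin,
            seed=child_seed(config.seed, "minicircle", size_bp, rep),
            crank_intervals=config.crank_intervals,
        )
        runs.append(sample_minicircle(model, n_links, cfg))
    per = [r.p_kink for r in runs]
    n_tot = sum(r.n_recorded for r in runs)
    p = sum(r.n_with_kink for r in runs) / n_tot
    se_bin = math.sqrt(max(p * (1 - p), 1.0 / n_tot) / n_tot)
    se_rep = (
        float(np.std(per, ddof=1) / math.sqrt(n_repeats)) if n_repeats > 1 else 0.0
    )
    return KinkStats(
        size_bp=size_bp,
        p_kink=p,
        se_binomial=se_bin,
        se_repeats=se_rep,
        mean_kinks=sum(r.kink_sum for r in runs) / n_tot,
        n_conformations=n_tot,
        theta_c=critical_kink_angle(model),
        n_repeats=n_repeats,
        per_repeat=per,
    )


def kink_probability_vs_size(
    model: BendingModel,
    sizes_bp,
    config: SamplerConfig = SamplerConfig(n_samples=1_000_000),
    n_repeats: int = 3,
) -> list[KinkStats]:
    """Kinking probability across minicircle sizes (>= 40 bp)."""
    out = []
    for size in sizes_bp:
        if size < 40:
            raise ValueError("minicircle sizes below 40 bp are not supported")
        out.append(kink_probability(model, size, config, n_repeats))
    return out


def kink_table(stats: list[KinkStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "size_bp": [s.size_bp for s in stats],
            "p_kink": [s.p_kink for s in stats],
            "se_binomial": [s.se_binomial for s in stats],
            "se_repeats": [s.se_repeats for s in stats],
            "mean_kinks": [s.mean_kinks for s in stats],
            "n_conformations": [s.n_conformations for s in stats],
        }
    )
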