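"""Kinetic analysis of loop unlooping: exponential survival fits, Bell-model
regression and softening-transition detection.

The linker duplex closing a DNA loop dissociates under the shear force f the
bent loop exerts on it; its lifetime follows the Bell relationship

    tau(f) = tau(0) exp(-f dr0 / kBT),

with dr0 the duplex elongation at the transition state. Fitting log tau
against the model-computed force over a range of loop sizes yields (tau(0),
dr0); scanning the lower end of the fit range with the regression RMSE
locates the loop size below which measured lifetimes stop following the
elastic force law — the softening transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit
from scipy.stats import chi2

from .constants import KBT_PNNM


# --- survival fitting -----------------------------------------------------


@dataclass
class ExponentialFit:
    tau: float  # s
    ci_low: float
    ci_high: float
    se: float
    n: int
    method: str


def fit_survival_exponential(
    dwell_times: np.ndarray | None = None,
    decay_curve: tuple[np.ndarray, np.ndarray] | None = None,
    censored: np.ndarray | None = None,
    ci_level: float = 0.95,
) -> ExponentialFit:
    """Single-exponential lifetime from dwell times or a decay-count curve.

    Raw dwell times use the exponential maximum-likelihood estimate
    tau = (total observed time) / (number of uncensored events), with the
    exact chi-square confidence interval; right-censored observations
    (observation window ended first) contribute their full observed time to
    the numerator only. Decay curves N(t) are least-squares fitted with
    N0 exp(-t / tau).
    """
    if (dwell_times is None) == (decay_curve is None):
        raise ValueError("provide exactly one of dwell_times or decay_curve")
    alpha = 1.0 - ci_level
    if dwell_times is not None:
        t = np.asarray(dwell_times, dtype=float)
        if len(t) < 10:
            raise ValueError("need at least 10 dwell times")
        if np.any(t <= 0):
            raise ValueError("dwell times must be positive")
        if np.all(t == t[0]):
            raise ValueError("degenerate dwell times (all equal)")
        cens = (
            np.zeros(len(t), dtype=bool)
            if censored is None
            else np.asarray(censored, dtype=bool)
        )
        n_events = int((~cens).sum())
        if n_events == 0:
            raise ValueError("no uncensored events")
        tau = float(t.sum()) / n_events
        lo = 2 * t.sum() / chi2.ppf(1 - alpha / 2, 2 * n_events)
        hi = 2 * t.sum() / chi2.ppf(alpha / 2, 2 * n_events)
        return ExponentialFit(tau, float(lo), float(hi),
                              tau / math.sqrt(n_events), n_events, "mle")
    t, counts = (np.asarray(a, dtype=float) for a in decay_curve)
    if len(t) < 5:
        raise ValueError("need at least 5 time points")
    if np.any(np.diff(counts) > 0):
        raise ValueError("decay counts must be non-increasing")
    n0 = counts[0]
    popt, pcov = curve_fit(
        lambda tt, N0, tau: N0 * np.exp(-tt / tau),
        t,
        counts,
        p0=(n0, max(t[-1] / 2.0, t[1])),
        maxfev=10_000,
    )
    tau = float(popt[1])
    se = float(np.sqrt(pcov[1, 1]))
    z = chi2.ppf(ci_level, 1) ** 0.5
    return ExponentialFit(tau, tau - z * se, tau + z * se, se, len(t), "curve")


# --- Bell model -----------------------------------------------------------


def bell_lifetime(
    tau0: float, delta_r0: float, f, kBT: float = KBT_PNNM
):
    """Bell lifetime tau = tau0 exp(-f dr0 / kBT); f in pN, dr0 in nm."""
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    out = tau0 * np.exp(-f * delta_r0 / kBT)
    return float(out) if out.ndim == 0 else out


@dataclass
class BellFit:
    delta_r0: float  # nm
    tau0: float  # s
    se_delta_r0: float
    se_tau0: float
    rmse: float
    fit_range_bp: tuple[float, float]
    n_points: int
    weights: np.ndarray = field(repr=False, default=None)


def fit_bell_robust(
    forces_pN: Sequence[float],
    lifetimes_s: Sequence[float],
    sizes_bp: Sequence[float] | None = None,
    kBT: float = KBT_PNNM,
) -> BellFit:
    """Robust linear regression of log tau on force.

    Iteratively reweighted least squares with the bisquare (Tukey biweight)
    influence function, tuning constant 4.685 — the conventional default of
    robust linear fitting. Slope -> dr0 = -slope * kBT; intercept -> tau(0).
    RMSE is the degrees-of-freedom-corrected root mean squared residual of
    the fit (on log lifetime).
    """
    f = np.asarray(forces_pN, dtype=float)
    tau = np.asarray(lifetimes_s, dtype=float)
    if len(f) != len(tau) or len(f) < 3:
        raise ValueError("need at least 3 (force, lifetime) pairs")
    if np.any(tau <= 0):
        raise ValueError("lifetimes must be positive")
    if np.allclose(f, f[0]):
        raise ValueError("degenerate design: all forces equal")
    y = np.log(tau)
    X = sm.add_constant(f)
    rlm = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
    res = rlm.fit()
    intercept, slope = res.params
    se_int, se_slope = res.bse
    resid = y - res.fittedvalues
    dof = max(len(f) - 2, 1)
    rmse = float(np.sqrt(np.sum(resid**2) / dof))
    sizes = np.asarray(sizes_bp, dtype=float) if sizes_bp is not None else None
    rng = (
        (float(sizes.min()), float(sizes.max()))
        if sizes is not None
        else (math.nan, math.nan)
    )
    return BellFit(
        delta_r0=-slope * kBT,
        tau0=float(np.exp(intercept)),
        se_delta_r0=se_slope * kBT,
        se_tau0=float(np.exp(intercept) * se_int),
        rmse=rmse,
        fit_range_bp=rng,
        n_points=len(f),
        weights=res.weights,
    )


# --- softening-transition scan -------------------------------------------


@dataclass
class TransitionReport:
    critical_size_bp: float | None
    rmse_curve: pd.DataFrame  # columns: cutoff_bp, rmse, n_points
    plateau_rmse: float
    jump_factor: float
    fits: dict  # cutoff -> BellFit


def rmse_transition_scan(
    sizes_bp: Sequence[float],
    forces_pN: Sequence[float],
    lifetimes_s: Sequence[float],
    jump_factor: float = 0.5,
    min_points: int = 3,
    kBT: float = KBT_PNNM,
) -> TransitionReport:
    """Locate the softening transition by scanning the lower fit cutoff.

    For each candidate lower cutoff L_min (descending through the observed
    sizes), the Bell model is refit on sizes >= L_min and the regression RMSE
    recorded. The plateau RMSE is the median over the larger half of the
    cutoffs; the critical size is the smallest cutoff whose RMSE still sits
    below (1 + jump_factor) * plateau before the first jump above it —
    lifetimes at smaller sizes deviate from the elastic force law. Returns
    ``critical_size_bp = None`` when no cutoff jumps.
    """
    sizes = np.asarray(sizes_bp, dtype=float)
    f = np.asarray(forces_pN, dtype=float)
    tau = np.asarray(lifetimes_s, dtype=float)
    if len(sizes) < 6:
        raise ValueError("need at least 6 sizes to scan")
    order = np.argsort(sizes)
    sizes, f, tau = sizes[order], f[order], tau[order]
    uniq = np.unique(sizes)
    cutoffs = [c for c in uniq if np.sum(sizes >= c) >= min_points]
    cutoffs = sorted(cutoffs, reverse=True)  # descending L_min
    rows = []
    fits = {}
    for c in cutoffs:
        mask = sizes >= c
        fit = fit_bell_robust(f[mask], tau[mask], sizes[mask], kBT)
        fits[c] = fit
        rows.append({"cutoff_bp": c, "rmse": fit.rmse, "n_points": int(mask.sum())})
    curve = pd.DataFrame(rows)
    # plateau from the large-size half of the scan, excluding the shortest
    # fits whose RMSE is unstable (few residuals after dof correction)
    stable = curve[curve["n_points"] >= max(min_points, 6)]
    upper_half = (stable if len(stable) else curve).iloc[
        : max(len(stable if len(stable) else curve) // 2, 1)
    ]
    plateau = float(upper_half["rmse"].median())
    threshold = (1.0 + jump_factor) * plateau + 1e-12
    # walk the stable fits only: short fits fluctuate too much to either set
    # the plateau or call the jump
    walk = curve[curve["n_points"] >= max(min_points, 6)]
    if not len(walk):
        walk = curve
    critical = None
    for _, row in walk.iterrows():
        if row["rmse"] > threshold:
            break
        critical = row["cutoff_bp"]
    # no jump ever happened -> no transition detected
    jumped = bool((walk["rmse"] > threshold).any())
    return TransitionReport(
        critical_size_bp=float(critical) if jumped and critical is not None else None,
        rmse_curve=curve,
        plateau_rmse=plateau,
        jump_factor=jump_factor,
        fits=fits,
    )


# --- KWLC parameter selection ---------------------------------------------


def select_kwlc_parameters(
    sizes_bp: Sequence[float],
    target_forces_pN: Sequence[float],
    h_candidates: Sequence[float],
    b: float,
    force_fn: Callable[[float, float, Sequence[float]], np.ndarray],
) -> tuple[float, pd.DataFrame]:
    """Pick the kink barrier h best matching a target force curve.

    ``force_fn(h, b, sizes) -> forces`` computes the candidate model's force
    curve; the score is the summed squared log-force discrepancy. Returns
    (best h, score table).
    """
    sizes = np.asarray(sizes_bp, dtype=float)
    target = np.asarray(target_forces_pN, dtype=float)
    if len(h_candidates) == 0:
        raise ValueError("empty candidate grid")
    if len(sizes) < 2:
        raise ValueError("need at least 2 sizes to discriminate candidates")
    rows = []
    for h in h_candidates:
        forces = np.asarray(force_fn(h, b, sizes), dtype=float)
        score = float(np.sum((np.log(forces) - np.log(target)) ** 2))
        rows.append({"h_kBT": h, "score": score})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["score"].idxmin(), "h_kBT"])
    return best, table
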