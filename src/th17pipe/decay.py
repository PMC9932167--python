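"""mRNA decay-rate and half-life estimation from transcription-shutoff
time courses.

Transcript abundance after transcription blockade (actinomycin D) is
modelled as first-order exponential decay, N(t) = N0 * exp(-k t). After
normalizing to the t = 0 point, ln N(t) is fitted by ordinary least
squares on time with a free intercept; t1/2 = ln 2 / k. The same
machinery serves short reporter-RNA time courses (0, 20, 40 min).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "DecaySeries",
    "HalfLifeEstimate",
    "normalize_to_t0",
    "normalize_to_control",
    "fit_half_life",
    "compare_decay",
]


@dataclass(frozen=True)
class DecaySeries:
    """A t0-normalized relative-abundance time course for one transcript."""

    series_id: str
    condition: str
    timepoints: tuple[float, ...]
    relative_abundance: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        y = np.asarray(self.relative_abundance, dtype=float)
        if len(t) != len(y):
            raise ValueError("timepoints and abundances differ in length")
        if len(t) == 0 or t[0] != 0:
            raise ValueError("timepoints must start at 0")
        if (np.diff(t) <= 0).any():
            raise ValueError("timepoints must be strictly increasing")
        if not np.isfinite(y).all() or (y <= 0).any():
            raise ValueError("abundances must be finite and > 0")
        if abs(y[0] - 1.0) > 1e-12:
            raise ValueError("abundance at t=0 must be 1 (normalize first)")


@dataclass(frozen=True)
class HalfLifeEstimate:
    """Fitted first-order decay: rate k (1/min), half-life (min), fit r^2."""

    series_id: str
    k: float
    t_half: float
    r_squared: float
    n_points: int
    k_se: float = float("nan")

    def summary(self) -> str:
        t = "inf" if math.isinf(self.t_half) else f"{self.t_half:.2f} min"
        return (
            f"{self.series_id}: k = {self.k:.5f} /min, t1/2 = {t}, "
            f"r^2 = {self.r_squared:.4f} ({self.n_points} points)"
        )


def normalize_to_t0(
    series_id: str,
    condition: str,
    timepoints: Sequence[float],
    raw: Sequence[float],
) -> DecaySeries:
    """Divide each raw quantity by the t=0 value.

    Non-positive later values are dropped with a warning (they cannot enter
    a log-linear fit); a non-positive t=0 value is an error.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(raw, dtype=float)
    if len(t) == 0 or t[0] != 0:
        raise ValueError("first timepoint must be 0")
    if y[0] <= 0:
        raise ValueError(f"{series_id}: abundance at t=0 must be > 0, got {y[0]}")
    norm = y / y[0]
    keep = norm > 0
    if not keep.all():
        logger.warning(
            "%s: dropped %d non-positive point(s)", series_id, int((~keep).sum())
        )
    return DecaySeries(series_id, condition, tuple(t[keep]), tuple(norm[keep]))


def normalize_to_control(target: Sequence[float], control: Sequence[float]) -> np.ndarray:
    """Divide target quantities by a same-length internal control (e.g. Gapdh)."""
    tg = np.asarray(target, dtype=float)
    ct = np.asarray(control, dtype=float)
    if tg.shape != ct.shape:
        raise ValueError("target and control must have the same length")
    if (ct <= 0).any():
        raise ValueError("control quantities must be > 0")
    return tg / ct


def fit_half_life(series: DecaySeries, nonlinear: bool = False) -> HalfLifeEstimate:
    """Fit ln(abundance) ~ time by OLS with free intercept; k = -slope.

    ``nonlinear=True`` refines by least squares of N0*exp(-k t) on the
    linear scale, seeded from the log-linear solution. Half-life is
    ln2/k for k > 0 and infinite otherwise.
    """
    t = np.asarray(series.timepoints, dtype=float)
    y = np.asarray(series.relative_abundance, dtype=float)
    if len(t) < 3:
        raise ValueError(f"{series.series_id}: need >= 3 points, got {len(t)}")
    res = stats.linregress(t, np.log(y))
    k = -res.slope
    k_se = res.stderr
    r2 = float(res.rvalue**2) if not np.isnan(res.rvalue) else 1.0
    if nonlinear:
        def model(tt, n0, kk):
            return n0 * np.exp(-kk * tt)

        popt, pcov = optimize.curve_fit(
            model, t, y, p0=[float(np.exp(res.intercept)), float(k)], maxfev=10000
        )
        k = float(popt[1])
        k_se = float(np.sqrt(pcov[1, 1]))
        resid = y - model(t, *popt)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    t_half = math.log(2) / k if k > 0 else math.inf
    return HalfLifeEstimate(
        series_id=series.series_id,
        k=float(k),
        t_half=float(t_half),
        r_squared=float(r2),
        n_points=len(t),
        k_se=float(k_se),
    )


def _pooled_fit(replicates: Sequence[DecaySeries], label: str) -> HalfLifeEstimate:
    """Log-linear fit pooling all replicate points of one condition."""
    t = np.concatenate([np.asarray(s.timepoints, dtype=float) for s in replicates])
    y = np.concatenate([np.asarray(s.relative_abundance, dtype=float) for s in replicates])
    res = stats.linregress(t, np.log(y))
    k = -res.slope
    t_half = math.log(2) / k if k > 0 else math.inf
    r2 = float(res.rvalue**2) if not np.isnan(res.rvalue) else 1.0
    return HalfLifeEstimate(label, float(k), float(t_half), r2, len(t), float(res.stderr))


def compare_decay(
    a: Sequence[DecaySeries],
    b: Sequence[DecaySeries],
    ci_level: float = 0.95,
) -> dict[str, object]:
    """Per-timepoint two-sided t-tests plus the ratio of fitted half-lives.

    Both arms must share timepoints. Testing needs >= 2 replicates per arm;
    with one replicate the tests are skipped but the half-life ratio (arm a
    over arm b) and its delta-method confidence interval are still returned.
    The ratio t_a/t_b equals k_b/k_a, whose log-scale variance is
    se(k_a)^2/k_a^2 + se(k_b)^2/k_b^2.
    """
    if not a or not b:
        raise ValueError("both condition arms must be non-empty")
    tps = a[0].timepoints
    for s in list(a) + list(b):
        if s.timepoints != tps:
            raise ValueError(
                f"mismatched timepoints: {s.series_id} has {s.timepoints}, expected {tps}"
            )
    tests: dict[float, dict[str, float]] = {}
    if len(a) >= 2 and len(b) >= 2:
        ya = np.array([s.relative_abundance for s in a])
        yb = np.array([s.relative_abundance for s in b])
        for i, t in enumerate(tps):
            if t == 0:
                continue  # both arms are 1 by construction
            va, vb = ya[:, i], yb[:, i]
            if va.std() == 0 and vb.std() == 0 and va.mean() == vb.mean():
                tests[float(t)] = {"t": 0.0, "p_value": 1.0}  # degenerate equal arms
                continue
            res = stats.ttest_ind(va, vb)
            tests[float(t)] = {"t": float(res.statistic), "p_value": float(res.pvalue)}
    fit_a = _pooled_fit(a, a[0].condition)
    fit_b = _pooled_fit(b, b[0].condition)
    ratio = fit_a.t_half / fit_b.t_half if math.isfinite(fit_a.t_half) and math.isfinite(fit_b.t_half) else float("nan")
    ci = (float("nan"), float("nan"))
    if np.isfinite(ratio) and ratio > 0:
        log_var = (fit_a.k_se / fit_a.k) ** 2 + (fit_b.k_se / fit_b.k) ** 2
        z = stats.norm.ppf(0.5 + ci_level / 2)
        ci = (
            float(ratio * np.exp(-z * np.sqrt(log_var))),
            float(ratio * np.exp(z * np.sqrt(log_var))),
        )
    return {
        "per_timepoint_tests": tests,
        "fit_a": fit_a,
        "fit_b": fit_b,
        "half_life_ratio": float(ratio),
        "ratio_ci": ci,
    }
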