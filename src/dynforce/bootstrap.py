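"""Bootstrap inference and routine motility/stall summaries.

Rupture-force distributions under a ramp are skewed, so uncertainty on mean
unbinding forces is quantified by a percentile bootstrap of the mean, and
differences between conditions by a shifted-null bootstrap test: bootstrap
the mean of each sample B times, difference the replicate means pairwise,
recenter that difference distribution to zero (the null of equal means), and
report the two-tailed tail fraction at the observed mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .rates import ForceSample, RateCurve, rate_curve
from .trap import TrapConfig

__all__ = [
    "CIResult",
    "TestResult",
    "boot_ci_mean",
    "boot_mean_diff_test",
    "boot_rate_ci",
    "gaussian_velocity_fit",
    "welch_t_test",
    "stall_summary",
]

_CHUNK = 10_000_000  # max resample-matrix entries held at once


@dataclass(frozen=True)
class CIResult:
    mean: float
    lo: float
    hi: float
    level: float = 0.95
    B: int = 4000

    def __contains__(self, value: float) -> bool:
        return self.lo <= value <= self.hi


@dataclass(frozen=True)
class TestResult:
    p_m: float
    observed_diff: float
    B: int
    seed: int | None = None


def _boot_means(x: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """B bootstrap replicate means of x, chunked to bound memory."""
    n = x.size
    out = np.empty(B)
    step = max(1, _CHUNK // n)
    for s in range(0, B, step):
        b = min(step, B - s)
        idx = rng.integers(0, n, size=(b, n))
        out[s : s + b] = x[idx].mean(axis=1)
    return out


def boot_ci_mean(
    sample,
    B: int = 4000,
    level: float = 0.95,
    seed: int | None = None,
    method: str = "percentile",
) -> CIResult:
    """Bootstrap confidence interval for the mean (percentile by default).

    ``method="bca"`` uses the bias-corrected accelerated interval via
    :func:`scipy.stats.bootstrap`.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError(f"boot_ci_mean needs at least 5 observations, got {x.size}")
    if B < 1000:
        raise ValueError(f"boot_ci_mean needs B >= 1000, got {B}")
    rng = np.random.default_rng(seed)
    if method == "percentile":
        means = _boot_means(x, B, rng)
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    elif method == "bca":
        res = stats.bootstrap(
            (x,), np.mean, n_resamples=B, confidence_level=level, method="BCa", rng=rng
        )
        lo, hi = res.confidence_interval.low, res.confidence_interval.high
    else:
        raise ValueError(f"unknown method {method!r}")
    m = float(x.mean())
    return CIResult(mean=m, lo=float(min(lo, m)), hi=float(max(hi, m)), level=level, B=B)


def boot_mean_diff_test(
    a,
    b,
    B: int = 100_000,
    seed: int | None = None,
    pairing: str = "paired",
) -> TestResult:
    """Shifted-null bootstrap test for a difference of means (two-tailed).

    Steps: bootstrap B replicate means per sample; difference them (paired
    draws by default, full cross-product with ``pairing="cross"``); subtract
    the mean of those differences so the distribution is centered on zero
    (consistent with the null of no difference); p_m is the fraction of
    recentered differences at least as large in magnitude as the observed
    mean difference, floored at 1/B.  Symmetric in argument order.
    """
    xa, xb = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    for name, x in (("a", xa), ("b", xb)):
        if x.size < 5:
            raise ValueError(f"sample {name} needs at least 5 observations, got {x.size}")
    rng = np.random.default_rng(seed)
    obs = abs(xa.mean() - xb.mean())
    ma = _boot_means(xa, B, rng)
    mb = _boot_means(xb, B, rng)
    if pairing == "paired":
        diffs = ma - mb
        shifted = diffs - diffs.mean()
        count = int(np.count_nonzero(np.abs(shifted) >= obs))
        total = B
    elif pairing == "cross":
        center = ma.mean() - mb.mean()
        count, total = 0, ma.size * mb.size
        step = max(1, _CHUNK // mb.size)
        for s in range(0, ma.size, step):
            block = ma[s : s + step, None] - mb[None, :] - center
            count += int(np.count_nonzero(np.abs(block) >= obs))
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    p = max(count / total, 1.0 / B)
    return TestResult(p_m=float(min(p, 1.0)), observed_diff=float(obs), B=B, seed=seed)


def boot_rate_ci(
    sample: ForceSample,
    trap: TrapConfig,
    B: int = 200,
    seed: int | None = None,
    level: float = 0.95,
    **rate_kwargs,
) -> RateCurve:
    """Pointwise percentile bands on the unbinding-rate curve.

    Forces are resampled with replacement and the full KDE-to-rate transform
    is recomputed per resample; bands are pointwise quantiles on the point
    estimate's force grid.  Grid points where a resample's curve is not
    reported (survival floor) are excluded pointwise; the per-point exclusion
    count is logged in ``meta["excluded"]``.
    """
    if sample.n < 50:
        raise ValueError(f"boot_rate_ci needs at least 50 forces, got {sample.n}")
    rng = np.random.default_rng(seed)
    point = rate_curve(sample, trap, **rate_kwargs)
    grid = point.f_grid
    reps = np.full((B, grid.size), np.nan)
    for i in range(B):
        forces = rng.choice(sample.forces, size=sample.n, replace=True)
        try:
            rc = rate_curve(
                ForceSample(forces, sample.direction, sample.condition), trap, **rate_kwargs
            )
        except ValueError:
            continue
        inside = (grid >= rc.f_grid[0]) & (grid <= rc.f_grid[-1])
        reps[i, inside] = np.interp(grid[inside], rc.f_grid, rc.rate)
    alpha = (1.0 - level) / 2.0
    with np.errstate(all="ignore"):
        lo = np.nanquantile(reps, alpha, axis=0)
        hi = np.nanquantile(reps, 1.0 - alpha, axis=0)
    point.ci_lo = np.minimum(lo, point.rate)
    point.ci_hi = np.maximum(hi, point.rate)
    point.meta["excluded"] = np.isnan(reps).sum(axis=0).tolist()
    point.meta["B"] = B
    point.meta["level"] = level
    return point


def gaussian_velocity_fit(velocities, bin_width: float = 10.0) -> tuple[float, float]:
    """Least-squares Gaussian fit to a binned velocity histogram.

    Returns ``(fitted mean, SEM)`` where SEM is the sample SD over sqrt(N)
    (the convention used for reporting single-molecule velocities).
    """
    v = np.asarray(velocities, dtype=float)
    if v.size < 20:
        raise ValueError(f"gaussian_velocity_fit needs at least 20 values, got {v.size}")
    lo = bin_width * np.floor(v.min() / bin_width)
    hi = bin_width * np.ceil(v.max() / bin_width)
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(v, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, amp, mu, sig):
        return amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)

    p0 = (counts.max(), v.mean(), max(v.std(ddof=1), bin_width / 2))
    popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10_000)
    sem = v.std(ddof=1) / np.sqrt(v.size)
    return float(popt[1]), float(sem)


def welch_t_test(a, b) -> float:
    """Unpaired Welch's t test (Satterthwaite df); returns the p-value."""
    xa, xb = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
        raise ValueError("Welch's t test is undefined for two zero-variance samples")
    return float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)


def stall_summary(forces) -> tuple[float, float]:
    """Arithmetic mean and sample SD of stall forces."""
    f = np.asarray(forces, dtype=float)
    if f.size < 2:
        raise ValueError("stall_summary needs at least 2 values")
    return float(f.mean()), float(f.std(ddof=1))
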