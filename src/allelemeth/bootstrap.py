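"""Nonparametric case-resampling bootstrap: BCa and bias-corrected intervals.

The BCa interval corrects the percentile bootstrap for median bias (z0,
estimated from the fraction of replicates below the point estimate) and for
skewness (acceleration a, estimated from the jackknife).  The bias-corrected
(BC) interval is the special case a = 0.  A bootstrap p-value is obtained by
interval inversion: the smallest alpha at which the (1 - alpha) interval
excludes zero, searched on an alpha grid (default resolution 0.001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["BootstrapCI", "bca_interval", "bca_from_replicates", "case_resample"]

_Z_CLIP = 8.0  # guard against infinite normal quantiles in degenerate cases


@dataclass
class BootstrapCI:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float | None
    method: str  # "bca" | "bc" | "percentile"
    B: int
    z0: float = 0.0
    accel: float = 0.0

    def __iter__(self):  # allows `low, high = ci.ci`-style unpacking in callers
        yield self.ci_low
        yield self.ci_high


def _rows(data):
    arr = np.asarray(data) if not hasattr(data, "iloc") else data
    n = arr.shape[0] if hasattr(arr, "shape") else len(arr)
    return arr, n


def _take(data, idx):
    if hasattr(data, "iloc"):
        return data.iloc[idx]
    return data[idx]


def case_resample(data, statistic_fn, B, rng):
    """B case-resampled replicates of ``statistic_fn`` (rows drawn with
    replacement)."""
    data, n = _rows(data)
    out = np.empty(B, dtype=float)
    for b in range(B):
        idx = rng.integers(0, n, n)
        out[b] = statistic_fn(_take(data, idx))
    return out


def _jackknife(data, statistic_fn):
    data, n = _rows(data)
    idx = np.arange(n)
    out = np.empty(n, dtype=float)
    for i in range(n):
        out[i] = statistic_fn(_take(data, np.delete(idx, i)))
    return out


def _acceleration(theta_jack) -> float:
    d = theta_jack.mean() - theta_jack
    denom = (d**2).sum() ** 1.5
    if denom == 0:
        return 0.0
    return float((d**3).sum() / (6.0 * denom))


def _adjusted_quantiles(z0, a, alphas):
    """BCa-adjusted percentile positions for two-sided (1-alpha) intervals."""
    z = sps.norm.ppf(np.column_stack([alphas / 2.0, 1.0 - alphas / 2.0]))
    num = z0 + z
    adj = sps.norm.cdf(z0 + num / (1.0 - a * num))
    return adj  # shape (len(alphas), 2)


def bca_from_replicates(
    theta_hat: float,
    theta_b: np.ndarray,
    theta_jack: np.ndarray | None = None,
    alpha: float = 0.05,
    compute_p: bool = True,
    p_resolution: float = 0.001,
) -> BootstrapCI:
    """Build a BCa (or BC when ``theta_jack`` is None) interval from
    precomputed bootstrap (and jackknife) replicates."""
    theta_b = np.asarray(theta_b, dtype=float)
    B = theta_b.size
    se = float(theta_b.std(ddof=1)) if B > 1 else 0.0
    if np.ptp(theta_b) == 0:
        warnings.warn("degenerate bootstrap: all replicates equal; percentile fallback")
        val = float(theta_b[0]) if B else theta_hat
        p = None
        if compute_p:
            p = 1.0 if val == 0 else p_resolution
        return BootstrapCI(theta_hat, se, val, val, p, "percentile", B)

    prop = ((theta_b < theta_hat).sum() + 0.5 * (theta_b == theta_hat).sum()) / B
    prop = min(max(prop, 0.5 / B), 1 - 0.5 / B)
    z0 = float(np.clip(sps.norm.ppf(prop), -_Z_CLIP, _Z_CLIP))
    a = _acceleration(np.asarray(theta_jack, float)) if theta_jack is not None else 0.0
    method = "bca" if theta_jack is not None else "bc"

    q = _adjusted_quantiles(z0, a, np.array([alpha]))[0]
    lo, hi = np.quantile(theta_b, q)

    p = None
    if compute_p:
        grid = np.arange(p_resolution, 1.0, p_resolution)
        qs = _adjusted_quantiles(z0, a, grid)
        lows = np.quantile(theta_b, qs[:, 0])
        highs = np.quantile(theta_b, qs[:, 1])
        excl = (lows > 0.0) | (highs < 0.0)
        p = float(grid[np.argmax(excl)]) if excl.any() else 1.0
    return BootstrapCI(float(theta_hat), se, float(lo), float(hi), p, method, B, z0, a)


def bca_interval(
    data,
    statistic_fn,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    accelerated: bool = True,
    compute_p: bool = True,
    p_resolution: float = 0.001,
) -> BootstrapCI:
    """BCa (default) or BC (``accelerated=False``) interval for
    ``statistic_fn(data)`` under case resampling of rows.

    ``statistic_fn`` must be deterministic given its input.  Requires
    n >= 10 rows.
    """
    _, n = _rows(data)
    if n < 10:
        raise ValueError(f"need at least 10 cases for the bootstrap, got {n}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    theta_hat = float(statistic_fn(data))
    theta_b = case_resample(data, statistic_fn, B, rng)
    theta_jack = _jackknife(data, statistic_fn) if accelerated else None
    return bca_from_replicates(
        theta_hat, theta_b, theta_jack, alpha=alpha,
        compute_p=compute_p, p_resolution=p_resolution,
    )
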