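"""Lognormality statistics for parcellation-unit volumes.

Fits a Gaussian to the natural log of region volumes, tests goodness of
fit with a one-sample Kolmogorov-Smirnov test against the fitted normal,
and produces QQ-plot coordinates.  All statistics are in natural-log
units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .fragmentation import InvalidInputError

__all__ = [
    "LognormalFit",
    "KSResult",
    "fit_log_gaussian",
    "ks_lognormality",
    "qq_points",
    "filter_volumes",
]


@dataclass(frozen=True)
class LognormalFit:
    """Gaussian fit to ln(volume): sample mean, sample sd (n-1), and n."""

    log_mean: float
    sigma: float
    n: int


@dataclass(frozen=True)
class KSResult:
    """Kolmogorov-Smirnov D statistic and p-value."""

    statistic: float
    p_value: float


def _as_positive_log(volumes) -> np.ndarray:
    v = np.asarray(volumes, dtype=float)
    if v.ndim != 1:
        v = v.ravel()
    if v.size < 2:
        raise InvalidInputError("need at least two volumes")
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise InvalidInputError("all volumes must be positive and finite")
    return np.log(v)


def fit_log_gaussian(volumes) -> LognormalFit:
    """Fit a normal distribution to ln(volumes).

    Returns the sample mean and the unbiased (n-1 denominator) sample
    standard deviation of the log volumes.  Zero or negative volumes are
    rejected; strip them first with :func:`filter_volumes`.
    """
    logv = _as_positive_log(volumes)
    return LognormalFit(
        log_mean=float(logv.mean()),
        sigma=float(logv.std(ddof=1)),
        n=logv.size,
    )


def ks_lognormality(
    volumes,
    lilliefors: bool = False,
    n_resamples: int = 1000,
    seed: int | None = None,
) -> KSResult:
    """One-sample KS test of ln(volumes) against the fitted normal.

    By default the classical KS p-value is returned even though the
    normal's parameters were estimated from the same sample; that p-value
    is then anti-conservative (the Lilliefors situation).  With
    ``lilliefors=True`` a parametric-bootstrap p-value is computed
    instead: ``n_resamples`` normal samples of the same size are drawn,
    each refit, and the p-value is the fraction whose KS D meets or
    exceeds the observed one.
    """
    logv = _as_positive_log(volumes)
    fit = LognormalFit(float(logv.mean()), float(logv.std(ddof=1)), logv.size)
    if fit.sigma == 0:
        raise InvalidInputError("degenerate sample: all volumes identical")
    d, p = sps.kstest(logv, "norm", args=(fit.log_mean, fit.sigma))
    if lilliefors:
        rng = np.random.default_rng(seed)
        n = logv.size
        exceed = 0
        for _ in range(n_resamples):
            x = rng.standard_normal(n)
            d_b, _ = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
            exceed += d_b >= d
        p = (exceed + 1) / (n_resamples + 1)
    return KSResult(statistic=float(d), p_value=float(p))


def qq_points(volumes) -> np.ndarray:
    """QQ-plot coordinates of ln(volumes) against the fitted normal.

    Returns an ``(n, 2)`` array: column 0 holds theoretical quantiles of
    the fitted normal at plotting positions ``(i - 0.5)/n``, column 1 the
    sorted observed log volumes.  A good lognormal fit puts the points on
    the identity line.
    """
    logv = _as_positive_log(volumes)
    obs = np.sort(logv)
    n = obs.size
    pos = (np.arange(1, n + 1) - 0.5) / n
    mu, sd = float(logv.mean()), float(logv.std(ddof=1))
    if sd == 0:
        theo = np.full(n, mu)
    else:
        theo = sps.norm.ppf(pos, loc=mu, scale=sd)
    return np.column_stack([theo, obs])


def filter_volumes(records) -> np.ndarray:
    """Extract the positive leaf volumes from region records.

    Accepts a pandas DataFrame with ``volume`` and (optionally)
    ``is_leaf`` columns, or an iterable of objects with ``volume`` and
    optionally ``is_leaf`` attributes.  Records that are not leaves, or
    whose volume is zero (atlas leaves without an assigned volume), are
    dropped; the number dropped is reported with a warning, and an empty
    result triggers its own warning rather than an error.
    """
    try:  # DataFrame path
        vol = np.asarray(records["volume"], dtype=float)
        leaf = (
            np.asarray(records["is_leaf"], dtype=bool)
            if "is_leaf" in records
            else np.ones(vol.shape, dtype=bool)
        )
    except (TypeError, IndexError, KeyError):
        vol = np.array([float(r.volume) for r in records])
        leaf = np.array([bool(getattr(r, "is_leaf", True)) for r in records])
    keep = leaf & (vol > 0)
    n_dropped = int(vol.size - keep.sum())
    if n_dropped:
        warnings.warn(
            f"filter_volumes dropped {n_dropped} of {vol.size} records "
            "(non-leaf or zero volume)",
            stacklevel=2,
        )
    out = vol[keep]
    if out.size == 0:
        warnings.warn("filter_volumes produced an empty vector", stacklevel=2)
    return out
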