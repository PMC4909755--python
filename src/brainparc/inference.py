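"""Simulation-based inference of the fragmentation bias exponent mu.

The dispersion of log PU volumes, sigma(ln v), decreases with mu: a
positive bias splits large regions preferentially and homogenises sizes.
Given a species' observed sigma and its PU count, mu is inferred by
inverting a simulated envelope: for each mu on a grid, many fragmentation
runs give the sampling distribution of sigma at that PU count; the band
between the q_low and q_high quantiles (defaults 0.05/0.95, a 90% band)
is intersected with the observed sigma, and the mu range where the
observation falls inside the band is the confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fragmentation import InvalidInputError, simulate_sigma

__all__ = ["SigmaEnvelope", "MuInterval", "sigma_envelope", "infer_mu_interval"]

DEFAULT_MU_GRID = np.round(np.arange(-0.8, 0.8 + 1e-9, 0.02), 10)
MACAQUE_N_PU = 91  # cortical areas in the macaque retrograde-tracing parcellation


@dataclass
class SigmaEnvelope:
    """Quantile bands of sigma(ln v) over a mu grid at fixed PU count."""

    mu_grid: np.ndarray
    n_pu: int
    n_sims: int
    q_low: float
    q_high: float
    lower_band: np.ndarray
    upper_band: np.ndarray
    median_band: np.ndarray

    def __post_init__(self) -> None:
        self.mu_grid = np.asarray(self.mu_grid, dtype=float)
        self.lower_band = np.asarray(self.lower_band, dtype=float)
        self.upper_band = np.asarray(self.upper_band, dtype=float)
        self.median_band = np.asarray(self.median_band, dtype=float)
        m = self.mu_grid.size
        if not (self.lower_band.size == self.upper_band.size
                == self.median_band.size == m):
            raise InvalidInputError("bands must align with mu_grid")
        if np.any(np.diff(self.mu_grid) <= 0):
            raise InvalidInputError("mu_grid must be strictly ascending")
        if np.any(self.lower_band > self.median_band + 1e-12) or np.any(
            self.median_band > self.upper_band + 1e-12
        ):
            raise InvalidInputError("bands must satisfy lower <= median <= upper")


@dataclass(frozen=True)
class MuInterval:
    """Inferred mu range; ``None`` endpoints mean the observed sigma never
    enters the envelope anywhere on the grid."""

    mu_low: float | None
    mu_high: float | None
    sigma_obs: float
    n_pu: int

    @property
    def contains_zero(self) -> bool:
        return (
            self.mu_low is not None
            and self.mu_high is not None
            and self.mu_low <= 0.0 <= self.mu_high
        )

    def contains(self, mu: float) -> bool:
        return (
            self.mu_low is not None
            and self.mu_high is not None
            and self.mu_low <= mu <= self.mu_high
        )


def sigma_envelope(
    n_pu: int,
    mu_grid=DEFAULT_MU_GRID,
    n_sims: int = 1000,
    noise_sd: float = 0.10,
    q_low: float = 0.05,
    q_high: float = 0.95,
    seed: int | None = None,
) -> SigmaEnvelope:
    """Simulate the sigma(ln v) quantile envelope over a mu grid.

    For each grid value, ``n_sims`` independent fragmentation runs to
    ``n_pu`` PUs are performed and the within-run sigma recorded; the
    bands are the empirical ``q_low``/``q_high`` quantiles and the
    median.  Each grid point gets an independent child RNG stream spawned
    from ``seed``, so results are reproducible and grid resolution does
    not perturb individual points.
    """
    mu_grid = np.asarray(mu_grid, dtype=float)
    if n_pu < 3:
        raise InvalidInputError("n_pu must be >= 3")
    if n_sims < 2:
        raise InvalidInputError("n_sims must be >= 2")
    if not (0.0 <= q_low < q_high <= 1.0):
        raise InvalidInputError("need 0 <= q_low < q_high <= 1")
    if np.any(np.diff(mu_grid) <= 0):
        raise InvalidInputError("mu_grid must be strictly ascending")
    children = np.random.SeedSequence(seed).spawn(mu_grid.size)
    lower = np.empty(mu_grid.size)
    upper = np.empty(mu_grid.size)
    median = np.empty(mu_grid.size)
    for k, (mu, child) in enumerate(zip(mu_grid, children)):
        s = simulate_sigma(mu, n_pu, n_sims, noise_sd=noise_sd,
                           rng=np.random.default_rng(child))
        lower[k] = np.quantile(s, q_low)
        upper[k] = np.quantile(s, q_high)
        median[k] = np.median(s)
    return SigmaEnvelope(
        mu_grid=mu_grid, n_pu=n_pu, n_sims=n_sims,
        q_low=q_low, q_high=q_high,
        lower_band=lower, upper_band=upper, median_band=median,
    )


def infer_mu_interval(sigma_obs: float, envelope: SigmaEnvelope) -> MuInterval:
    """Invert the envelope: the mu range where sigma_obs is inside the band.

    The bands are treated as piecewise-linear between grid points; on
    each grid segment the feasible set ``lower(mu) <= sigma_obs <=
    upper(mu)`` is a (possibly empty) subinterval found in closed form,
    and the union over segments gives the reported endpoints.  Every
    segment is scanned, so non-monotone (noisy) bands cannot silently
    truncate the interval.  If the observation never enters the band both
    endpoints are ``None``.
    """
    if not (sigma_obs > 0) or not np.isfinite(sigma_obs):
        raise InvalidInputError("sigma_obs must be positive and finite")
    grid = envelope.mu_grid
    lo_b, hi_b = envelope.lower_band, envelope.upper_band
    lo_best: float | None = None
    hi_best: float | None = None

    def _feasible_on_segment(k: int) -> tuple[float, float] | None:
        # constraints lower(mu) <= s and upper(mu) >= s, each linear in mu
        a, b = grid[k], grid[k + 1]
        seg_lo, seg_hi = a, b
        for band, sense in ((lo_b, "le"), (hi_b, "ge")):
            y0, y1 = band[k], band[k + 1]
            slope = (y1 - y0) / (b - a)
            if slope == 0.0:
                ok = y0 <= sigma_obs if sense == "le" else y0 >= sigma_obs
                if not ok:
                    return None
                continue
            # band(mu) = y0 + slope*(mu - a); crossing point of band == s
            x = a + (sigma_obs - y0) / slope
            if sense == "le":  # want band <= s
                if slope > 0:
                    seg_hi = min(seg_hi, x)
                else:
                    seg_lo = max(seg_lo, x)
            else:  # want band >= s
                if slope > 0:
                    seg_lo = max(seg_lo, x)
                else:
                    seg_hi = min(seg_hi, x)
        if seg_lo > seg_hi:
            return None
        return seg_lo, seg_hi

    if grid.size == 1:
        if lo_b[0] <= sigma_obs <= hi_b[0]:
            lo_best = hi_best = float(grid[0])
    else:
        for k in range(grid.size - 1):
            seg = _feasible_on_segment(k)
            if seg is None:
                continue
            lo_best = seg[0] if lo_best is None else min(lo_best, seg[0])
            hi_best = seg[1] if hi_best is None else max(hi_best, seg[1])
    if lo_best is None:
        return MuInterval(None, None, sigma_obs, envelope.n_pu)
    return MuInterval(float(lo_best), float(hi_best), sigma_obs, envelope.n_pu)
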