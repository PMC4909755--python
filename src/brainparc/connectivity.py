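"""Outer-product macroconnectome model and power-law scaling fits.

If a brain starts as a randomly wired pool of neurons (each pair
connected with probability f) and is then carved into regions by the
fragmentation process, the expected number of wires between regions i and
j is C_ij = f * rho^2 * v_i * v_j / 2 — a rank-one outer product of the
volume vector (rho is the neuron density, taken uniform).  Row-normalising
C by target gives the fraction of labeled neurons (FLN) measured by
retrograde tracing, which under the outer-product model depends on the
source volume alone: FLN_ij ∝ v_j, i.e., a power law with exponent 1.

Empirical macroconnectomes follow a steeper power law; this module fits
the exponent by ordinary least squares of log strength on log volume over
the non-zero connections, per target row (incoming, exponent eta), per
source column (outgoing, exponent kappa), or pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .fragmentation import InvalidInputError

__all__ = [
    "ConnectivityMatrix",
    "PowerLawFit",
    "InsufficientDataError",
    "DegenerateFitError",
    "outer_product_connectome",
    "normalize_fln",
    "fit_power_law",
    "fit_incoming",
    "fit_outgoing",
]


class InsufficientDataError(ValueError):
    """Fewer than three non-zero strengths: no meaningful log-log fit."""


class DegenerateFitError(ValueError):
    """Volume spread too small for a slope to be identified."""


@dataclass
class ConnectivityMatrix:
    """Region-to-region connection strengths; rows are targets, columns sources."""

    values: np.ndarray
    target_labels: list[str] = field(default_factory=list)
    source_labels: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("connectivity values must be a 2-D matrix")
        if np.any(self.values < 0) or np.any(~np.isfinite(self.values)):
            raise InvalidInputError("connectivity entries must be finite and >= 0")
        nt, ns = self.values.shape
        if not self.target_labels:
            self.target_labels = [f"T{i}" for i in range(nt)]
        if not self.source_labels:
            self.source_labels = [f"S{j}" for j in range(ns)]
        if len(self.target_labels) != nt or len(self.source_labels) != ns:
            raise InvalidInputError("labels must match matrix shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class PowerLawFit:
    """Log-log OLS fit: strength ∝ volume**exponent.

    ``intercept`` is in natural-log units; ``r`` is the Pearson
    correlation of the log-log scatter and ``r_squared = r**2``.
    """

    exponent: float
    intercept: float
    r: float
    r_squared: float
    n_points: int


def outer_product_connectome(
    volumes,
    f: float = 1.0,
    rho: float = 1.0,
    include_diagonal: bool = False,
) -> ConnectivityMatrix:
    """Rank-one connectome C_ij = f * rho^2 * v_i * v_j / 2.

    By default the diagonal (within-region wiring) is zeroed, matching
    how tracer studies report extrinsic connections; with
    ``include_diagonal=True`` the self-blocks are kept, which restores
    the total-count identity sum(C) = f * N^2 / 2 for N = rho * sum(v)
    neurons.
    """
    v = np.asarray(volumes, dtype=float)
    if v.size == 0 or np.any(v <= 0) or np.any(~np.isfinite(v)):
        raise InvalidInputError("volumes must be positive and finite")
    if not (0.0 <= f <= 1.0):
        raise InvalidInputError("connection probability f must lie in [0, 1]")
    if not (rho > 0):
        raise InvalidInputError("neuron density rho must be positive")
    C = f * rho**2 * np.outer(v, v) / 2.0
    if not include_diagonal:
        np.fill_diagonal(C, 0.0)
    return ConnectivityMatrix(values=C, normalized=False)


def normalize_fln(C: ConnectivityMatrix) -> ConnectivityMatrix:
    """Row-normalise to the fraction of labeled neurons (FLN).

    Every row with a positive sum is divided by that sum, so non-zero
    rows sum to one; all-zero rows are left at zero and reported with a
    warning.
    """
    if C.normalized:
        raise InvalidInputError("matrix is already FLN-normalized")
    rowsum = C.values.sum(axis=1)
    zero_rows = rowsum == 0
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} all-zero target rows left unnormalized",
            stacklevel=2,
        )
    safe = np.where(zero_rows, 1.0, rowsum)
    return ConnectivityMatrix(
        values=C.values / safe[:, None],
        target_labels=list(C.target_labels),
        source_labels=list(C.source_labels),
        normalized=True,
    )


def fit_power_law(strengths, volumes) -> PowerLawFit:
    """OLS of ln(strength) on ln(volume) over the non-zero strengths.

    Zero strengths are excluded, not floored: a floor would bias the
    exponent, and absent connections are a separate regime of the model.
    Requires at least three positive strengths and a volume spread
    (max/min) of at least 1.001 among them.
    """
    s = np.asarray(strengths, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if s.shape != v.shape:
        raise InvalidInputError("strengths and volumes must align")
    if np.any(s < 0) or np.any(~np.isfinite(s)):
        raise InvalidInputError("strengths must be finite and >= 0")
    if np.any(v <= 0) or np.any(~np.isfinite(v)):
        raise InvalidInputError("volumes must be positive and finite")
    mask = s > 0
    n = int(mask.sum())
    if n < 3:
        raise InsufficientDataError(
            f"need >= 3 non-zero strengths for a log-log fit, got {n}"
        )
    vv = v[mask]
    if vv.max() / vv.min() < 1.001:
        raise DegenerateFitError(
            "volume spread below 1.001: slope not identifiable"
        )
    res = sps.linregress(np.log(vv), np.log(s[mask]))
    return PowerLawFit(
        exponent=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r_squared=float(res.rvalue**2),
        n_points=n,
    )


def fit_incoming(
    C_fln: ConnectivityMatrix,
    volumes,
    target_ids=None,
    pooled: bool = False,
):
    """Incoming scaling: FLN of each target row against source volumes.

    Fits FLN_ij ∝ v_j**eta per target row (over that row's non-zero
    entries).  With ``pooled=True`` the selected rows' points are stacked
    into a single regression and one :class:`PowerLawFit` is returned;
    otherwise a dict keyed by target index.
    """
    if not C_fln.normalized:
        raise InvalidInputError("fit_incoming expects an FLN-normalized matrix")
    v = np.asarray(volumes, dtype=float)
    if v.size != C_fln.shape[1]:
        raise InvalidInputError("volumes must align with source columns")
    rows = list(range(C_fln.shape[0])) if target_ids is None else list(target_ids)
    if pooled:
        s = np.concatenate([C_fln.values[i] for i in rows])
        vv = np.concatenate([v for _ in rows])
        return fit_power_law(s, vv)
    return {i: fit_power_law(C_fln.values[i], v) for i in rows}


def fit_outgoing(C: ConnectivityMatrix, volumes, source_ids=None):
    """Outgoing scaling: each source column against target volumes.

    Fits C_ij ∝ v_i**kappa per source column j, regressing the column's
    non-zero entries on the volumes of the target regions.  Returns a
    dict keyed by source index.
    """
    v = np.asarray(volumes, dtype=float)
    if v.size != C.shape[0]:
        raise InvalidInputError("volumes must align with target rows")
    cols = list(range(C.shape[1])) if source_ids is None else list(source_ids)
    return {j: fit_power_law(C.values[:, j], v) for j in cols}
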