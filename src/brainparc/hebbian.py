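"""Multiplicative Hebbian plasticity for the macroconnectome.

Connection strengths between areas evolve under

    dC_ij/dt = eps1 * f_i**alpha * C_ij**beta * f_j**gamma - eps2 * C_ij

where f_i is the activity level of area i (taken proportional to its
volume), the first term models activity correlations and the second
uniform decay.  For beta < 1 the dynamics have an attracting non-trivial
fixed point

    C*_ij = (eps1/eps2)**(1/(1-beta)) * f_i**(alpha/(1-beta)) * f_j**(gamma/(1-beta)),

an outer-product power law in the activities — hence in the volumes —
with incoming exponent eta = gamma/(1-beta) and outgoing exponent
kappa = alpha/(1-beta).  C_ij = 0 is also a solution (for beta > 0), so
the rule accommodates absent connections.  For beta >= 1 the non-trivial
branch is repelling and the closed form is not an equilibrium of
interest; those parameters are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .fragmentation import InvalidInputError

__all__ = [
    "HebbianParams",
    "ActivityVector",
    "UnsupportedRegimeError",
    "ConvergenceError",
    "hebbian_rhs",
    "fixed_point",
    "integrate_to_equilibrium",
    "predicted_exponents",
]


class UnsupportedRegimeError(ValueError):
    """beta >= 1: the closed-form branch is not an attractor."""


class ConvergenceError(RuntimeError):
    """Integration did not reach the residual tolerance in max_time."""


@dataclass(frozen=True)
class HebbianParams:
    """Rule parameters: growth/decay rates eps1, eps2 and exponents alpha, beta, gamma."""

    alpha: float
    beta: float
    gamma: float
    eps1: float = 1.0
    eps2: float = 1.0

    def __post_init__(self) -> None:
        if not (self.eps1 > 0 and self.eps2 > 0):
            raise InvalidInputError("eps1 and eps2 must be positive")


@dataclass
class ActivityVector:
    """Per-area activity levels, strictly positive; by default f_i = v_i."""

    f: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 1 or self.f.size == 0:
            raise InvalidInputError("activity must be a non-empty 1-D vector")
        if np.any(self.f <= 0) or np.any(~np.isfinite(self.f)):
            raise InvalidInputError("activity levels must be positive and finite")

    @classmethod
    def from_volumes(cls, volumes) -> "ActivityVector":
        return cls(f=np.asarray(volumes, dtype=float))


def _as_activity(f) -> np.ndarray:
    return f.f if isinstance(f, ActivityVector) else ActivityVector(np.asarray(f)).f


def _growth_prefactor(f: np.ndarray, params: HebbianParams) -> np.ndarray:
    return params.eps1 * np.outer(f**params.alpha, f**params.gamma)


def hebbian_rhs(C, f, params: HebbianParams) -> np.ndarray:
    """Time derivative dC/dt of the Hebbian rule, entrywise.

    Zero entries have zero derivative when beta > 0, so absent
    connections stay absent.
    """
    C = np.asarray(C, dtype=float)
    fv = _as_activity(f)
    if C.shape != (fv.size, fv.size):
        raise InvalidInputError("C must be square and match the activity vector")
    if np.any(C < 0):
        raise InvalidInputError("connection strengths must be >= 0")
    with np.errstate(divide="ignore"):
        Cb = np.where(C > 0, C, 1.0) ** params.beta
        Cb = np.where(C > 0, Cb, 0.0 if params.beta != 0 else 1.0)
    return _growth_prefactor(fv, params) * Cb - params.eps2 * C


def fixed_point(f, params: HebbianParams) -> np.ndarray:
    """Closed-form non-trivial equilibrium of the Hebbian rule (beta < 1)."""
    if params.beta >= 1:
        raise UnsupportedRegimeError(
            "beta >= 1: non-trivial fixed point is repelling; closed form unsupported"
        )
    fv = _as_activity(f)
    e = 1.0 / (1.0 - params.beta)
    scale = (params.eps1 / params.eps2) ** e
    return scale * np.outer(fv ** (params.alpha * e), fv ** (params.gamma * e))


def integrate_to_equilibrium(
    C0,
    f,
    params: HebbianParams,
    tol: float = 1e-9,
    max_time: float = 1e4,
) -> np.ndarray:
    """Integrate the Hebbian ODE forward until the flow stalls.

    Convergence criterion: max |dC/dt| / max C < tol.  Entries starting
    at exactly zero are held at zero (they are equilibria of the rule for
    beta > 0).  Uses an implicit-capable stiff integrator internally; the
    contract is only the equilibrium, not the trajectory.
    """
    if params.beta >= 1:
        raise UnsupportedRegimeError("beta >= 1: no attracting equilibrium")
    C0 = np.asarray(C0, dtype=float)
    fv = _as_activity(f)
    if C0.shape != (fv.size, fv.size):
        raise InvalidInputError("C0 must be square and match the activity vector")
    if np.any(C0 < 0):
        raise InvalidInputError("C0 entries must be >= 0")
    free = C0 > 0
    if not free.any():
        return np.zeros_like(C0)
    g = _growth_prefactor(fv, params)[free]
    y0 = C0[free]

    def rhs(_t, y):
        y = np.maximum(y, 0.0)
        return g * y**params.beta - params.eps2 * y

    t, y = 0.0, y0
    # expected relaxation time ~ 1/((1-beta) eps2); chunked so we can stop early
    chunk = max(10.0 / ((1.0 - params.beta) * params.eps2), 1.0)
    while t < max_time:
        t_end = min(t + chunk, max_time)
        sol = solve_ivp(rhs, (t, t_end), y, method="LSODA",
                        rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise ConvergenceError(f"integrator failed: {sol.message}")
        t, y = sol.t[-1], np.maximum(sol.y[:, -1], 0.0)
        resid = np.abs(rhs(t, y)).max() / y.max()
        if resid < tol:
            out = np.zeros_like(C0)
            out[free] = y
            return out
    raise ConvergenceError(
        f"residual {resid:.3e} above tol {tol:.3e} after t = {max_time}"
    )


def predicted_exponents(params: HebbianParams) -> tuple[float, float]:
    """Equilibrium power-law exponents (eta, kappa) = (gamma, alpha)/(1 - beta)."""
    if params.beta == 1:
        raise ZeroDivisionError("beta = 1: exponents diverge")
    return (
        params.gamma / (1.0 - params.beta),
        params.alpha / (1.0 - params.beta),
    )
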