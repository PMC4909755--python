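"""Synthetic inputs for every analysis in the package.

Nothing here downloads or bundles atlas or tracer data: volume sets are
lognormal draws (matching the empirically observed shape of PU-size
distributions), hierarchy tables come from fragmentation runs dressed up
as an atlas-style parent-child table (including zero-volume leaves, which
real atlases contain), and connectivity matrices carry a planted
power-law dependence on source volume with multiplicative lognormal
scatter and missing-at-random zeros — the same structure the fitting
code is meant to recover.
"""

from __future__ import annotations

import numpy as np

from .connectivity import ConnectivityMatrix
from .fragmentation import InvalidInputError, ModelParams, run_fragmentation
from .io import HierarchyRecord, tree_to_records

__all__ = [
    "make_lognormal_volumes",
    "make_hierarchy_fixture",
    "make_power_law_fln",
]


def make_lognormal_volumes(
    n: int,
    log_mean: float = 0.0,
    sigma: float = 1.24,
    seed: int | None = None,
) -> np.ndarray:
    """Draw ``n`` lognormal volumes: exp(Normal(log_mean, sigma)).

    The default sigma of 1.24 natural-log units matches the dispersion
    scale reported for mammalian cortical parcellations.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if not (sigma >= 0):
        raise InvalidInputError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    return np.exp(log_mean + sigma * rng.standard_normal(n))


def make_hierarchy_fixture(
    n_leaves: int,
    zero_fraction: float = 0.0,
    seed: int | None = None,
    mu: float = 0.14,
    noise_sd: float = 0.10,
) -> list[HierarchyRecord]:
    """Atlas-style parent-child hierarchy table with some zero-volume leaves.

    A fragmentation run to ``n_leaves`` PUs (default bias mu = 0.14, the
    middle of the range consistent with real brains) provides the tree
    and volumes; ``floor(zero_fraction * n_leaves)`` randomly chosen
    leaves then get volume 0, mimicking atlas leaves without a volume
    annotation, so that downstream filtering is exercised.
    """
    if n_leaves < 2:
        raise InvalidInputError("n_leaves must be >= 2")
    if not (0.0 <= zero_fraction < 1.0):
        raise InvalidInputError("zero_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    sim_seed = int(rng.integers(2**31))
    tree = run_fragmentation(
        ModelParams(mu=mu, n_target=n_leaves, noise_sd=noise_sd, seed=sim_seed)
    )
    records = tree_to_records(tree)
    n_zero = int(np.floor(zero_fraction * n_leaves))
    if n_zero:
        leaf_pos = [k for k, r in enumerate(records) if r.is_leaf]
        for k in rng.choice(len(leaf_pos), size=n_zero, replace=False):
            rec = records[leaf_pos[k]]
            records[leaf_pos[k]] = HierarchyRecord(
                id=rec.id, parent_id=rec.parent_id, name=rec.name,
                volume=0.0, is_leaf=True, birth_step=rec.birth_step,
            )
    return records


def make_power_law_fln(
    volumes,
    exponent: float = 2.67,
    noise_sigma: float = 0.0,
    zero_fraction: float = 0.0,
    seed: int | None = None,
) -> ConnectivityMatrix:
    """FLN matrix with a planted power-law dependence on source volume.

    Each row gets entries proportional to ``v_j**exponent`` times
    independent lognormal noise exp(Normal(0, noise_sigma)); a random
    ``zero_fraction`` of off-diagonal entries is then zeroed
    (missing-at-random absent connections), the diagonal is zeroed, and
    rows are normalised to sum to one.  Row normalisation only shifts the
    log-log intercept, so the planted exponent is exactly recoverable
    when ``noise_sigma = 0``.
    """
    v = np.asarray(volumes, dtype=float)
    if v.size < 2 or np.any(v <= 0) or np.any(~np.isfinite(v)):
        raise InvalidInputError("volumes must be >= 2 positive finite values")
    if noise_sigma < 0:
        raise InvalidInputError("noise_sigma must be >= 0")
    if not (0.0 <= zero_fraction < 1.0):
        raise InvalidInputError("zero_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = v.size
    base = np.tile(v**exponent, (n, 1))
    noise = np.exp(noise_sigma * rng.standard_normal((n, n)))
    C = base * noise
    np.fill_diagonal(C, 0.0)
    if zero_fraction > 0:
        off = ~np.eye(n, dtype=bool)
        C[off & (rng.random((n, n)) < zero_fraction)] = 0.0
    rowsum = C.sum(axis=1)
    rowsum[rowsum == 0] = 1.0
    return ConnectivityMatrix(values=C / rowsum[:, None], normalized=True)
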