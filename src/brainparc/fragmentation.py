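"""Iterative biased fragmentation model of brain parcellation.

A brain starts as a single parcellation unit (PU) of volume ``root_volume``.
At every step one current leaf is chosen at random — with probability
proportional to ``volume**mu`` — and split into two daughters of roughly
equal size.  A multiplicative noise term (normal, mean 1, sd ``noise_sd``)
perturbs the 50/50 split while conserving the parent volume exactly, so
leaf volumes are not locked to powers of 1/2.  The process stops when the
target number of PUs is reached; evolutionary time is measured by the
current PU count.

Two implementations are provided:

* :func:`run_fragmentation` builds the full binary fragmentation history
  (:class:`ParcellationTree`), useful for hierarchy export and tree
  statistics.
* :func:`simulate_log_volumes` / :func:`simulate_sigma` track only the
  log leaf volumes for many replicate runs at once (vectorised over the
  replicate axis); this is the engine behind envelope-based inference,
  where tens of thousands of runs are needed.

Both paths draw from ``numpy.random.Generator`` streams and are
bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InvalidInputError",
    "InvalidOperationError",
    "PUnit",
    "ParcellationTree",
    "ModelParams",
    "split_probabilities",
    "split_leaf",
    "run_fragmentation",
    "simulate_log_volumes",
    "simulate_sigma",
]


class InvalidInputError(ValueError):
    """Raised when an argument violates a documented precondition."""


class InvalidOperationError(RuntimeError):
    """Raised when an operation is applied to an unsuitable tree node."""


# The split multiplier r ~ Normal(1, noise_sd) is redrawn outside this open
# interval so both daughter volumes stay strictly positive.  For the default
# noise_sd = 0.1 a redraw is a ~1e-22 event; the guard only matters for
# pathological user-set noise levels.
_R_LO = 0.02
_R_HI = 1.98


@dataclass
class PUnit:
    """One parcellation unit: a node of the fragmentation tree.

    Parameters
    ----------
    id : int
        Unique node identifier within its tree.
    volume : float
        Region volume, arbitrary units; strictly positive.
    parent_id : int or None
        Identifier of the parent node; ``None`` only for the root.
    birth_step : int
        Split index at which the node appeared (0 for the root).
    name : str or None
        Optional region name (used by atlas-style hierarchy tables).

    Simulated nodes always have strictly positive volume; volume 0 is
    tolerated only so that atlas tables with unannotated (zero-volume)
    leaves can be represented — such leaves are dropped by
    :func:`brainparc.stats.filter_volumes` before any statistics.
    """

    id: int
    volume: float
    parent_id: int | None = None
    birth_step: int = 0
    name: str | None = None

    def __post_init__(self) -> None:
        if self.volume < 0 or not np.isfinite(self.volume):
            raise InvalidInputError(
                f"PUnit volume must be non-negative and finite, got {self.volume!r}"
            )
        if self.birth_step < 0:
            raise InvalidInputError("birth_step must be non-negative")


class ParcellationTree:
    """Binary fragmentation history; current PUs are the leaves.

    Nodes are :class:`PUnit` instances keyed by id.  Internal nodes have
    exactly two children (the simulator only performs binary splits), and
    the sum of leaf volumes equals the root volume up to floating-point
    round-off, because every split conserves volume.

    Trees read from real atlas tables may be non-binary; see
    :meth:`validate` with ``require_binary=False``.
    """

    def __init__(self, root_volume: float = 1.0, root_name: str | None = None):
        root = PUnit(id=0, volume=float(root_volume), parent_id=None,
                     birth_step=0, name=root_name)
        self.nodes: dict[int, PUnit] = {0: root}
        self.root_id: int = 0
        self.leaf_ids: list[int] = [0]
        self.children: dict[int, list[int]] = {0: []}
        self._next_id: int = 1
        self._n_splits: int = 0

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_nodes(cls, nodes: list[PUnit]) -> "ParcellationTree":
        """Rebuild a tree from a flat node list (e.g., a hierarchy table).

        Raises
        ------
        InvalidInputError
            On duplicate ids, multiple/missing roots, dangling parents or
            cycles; the message names the offending node id.
        """
        if not nodes:
            raise InvalidInputError("empty node list")
        tree = cls.__new__(cls)
        tree.nodes = {}
        tree.children = {}
        roots = []
        for node in nodes:
            if node.id in tree.nodes:
                raise InvalidInputError(f"duplicate node id {node.id}")
            tree.nodes[node.id] = node
            tree.children.setdefault(node.id, [])
            if node.parent_id is None:
                roots.append(node.id)
        if len(roots) != 1:
            raise InvalidInputError(
                f"expected exactly one root, found {len(roots)}: {roots}"
            )
        tree.root_id = roots[0]
        for node in nodes:
            if node.parent_id is not None:
                if node.parent_id not in tree.nodes:
                    raise InvalidInputError(
                        f"node {node.id} references missing parent {node.parent_id}"
                    )
                tree.children[node.parent_id].append(node.id)
        # cycle check via traversal from the root
        seen: set[int] = set()
        stack = [tree.root_id]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise InvalidInputError(f"cycle detected at node {nid}")
            seen.add(nid)
            stack.extend(tree.children[nid])
        if len(seen) != len(tree.nodes):
            orphans = sorted(set(tree.nodes) - seen)
            raise InvalidInputError(
                f"nodes unreachable from root (cycle or detached): {orphans}"
            )
        tree.leaf_ids = [n.id for n in nodes if not tree.children[n.id]]
        tree._next_id = max(tree.nodes) + 1
        tree._n_splits = len(tree.nodes) - len(tree.leaf_ids)
        return tree

    # -- queries --------------------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def is_leaf(self, node_id: int) -> bool:
        return not self.children.get(node_id)

    def leaf_volumes(self) -> np.ndarray:
        """Volumes of the current PUs, in ``leaf_ids`` order."""
        return np.array([self.nodes[i].volume for i in self.leaf_ids])

    def depth(self, node_id: int) -> int:
        d = 0
        node = self.nodes[node_id]
        while node.parent_id is not None:
            node = self.nodes[node.parent_id]
            d += 1
        return d

    def leaf_depths(self) -> np.ndarray:
        return np.array([self.depth(i) for i in self.leaf_ids])

    def validate(self, require_binary: bool = True, rtol: float = 1e-9) -> None:
        """Check structural invariants; raise :class:`InvalidInputError` if violated."""
        for nid, kids in self.children.items():
            if kids and require_binary and len(kids) != 2:
                raise InvalidInputError(
                    f"internal node {nid} has {len(kids)} children (binary expected)"
                )
        root_v = self.nodes[self.root_id].volume
        leaf_sum = float(self.leaf_volumes().sum())
        if abs(leaf_sum - root_v) > rtol * root_v:
            raise InvalidInputError(
                f"leaf volumes sum to {leaf_sum}, root volume is {root_v}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParcellationTree):
            return NotImplemented
        def key(t: "ParcellationTree", i: int):
            n = t.nodes[i]
            return (n.id, n.parent_id, n.volume, n.birth_step)

        return (
            self.root_id == other.root_id
            and sorted(self.leaf_ids) == sorted(other.leaf_ids)
            and self.nodes.keys() == other.nodes.keys()
            and all(key(self, i) == key(other, i) for i in self.nodes)
        )


@dataclass
class ModelParams:
    """Parameters of one fragmentation run.

    ``mu`` biases leaf selection (0 = uniform; positive favours large PUs,
    homogenising sizes; negative favours small PUs, widening the size
    distribution).  ``n_target`` is both the final PU count and the
    evolutionary duration, since each step adds one PU.  ``noise_sd`` is
    the sd of the multiplicative split noise (default 10%).
    """

    mu: float = 0.0
    n_target: int = 100
    noise_sd: float = 0.10
    root_volume: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_target < 1:
            raise InvalidInputError("n_target must be >= 1")
        if not (0.0 <= self.noise_sd < 0.5):
            raise InvalidInputError("noise_sd must lie in [0, 0.5)")
        if not (self.root_volume > 0):
            raise InvalidInputError("root_volume must be positive")


def split_probabilities(leaf_volumes: np.ndarray, mu: float) -> np.ndarray:
    """Probability of each current PU being the next to split.

    ``p_i = v_i**mu / Z`` with ``Z`` normalising over all current leaves.
    Computed in log space with max-subtraction so that extreme ``mu * ln v``
    cannot overflow.

    Parameters
    ----------
    leaf_volumes : array-like of float
        Strictly positive volumes of the current leaves.
    mu : float
        Selection-bias exponent.

    Returns
    -------
    numpy.ndarray
        Probabilities, same length as the input, summing to one.
    """
    v = np.asarray(leaf_volumes, dtype=float)
    if v.size == 0:
        raise InvalidInputError("leaf_volumes must be non-empty")
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise InvalidInputError("all leaf volumes must be positive and finite")
    logw = mu * np.log(v)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def _draw_ratio(noise_sd: float, rng: np.random.Generator) -> float:
    """One truncated Normal(1, noise_sd) split multiplier."""
    if noise_sd == 0.0:
        return 1.0
    while True:
        r = rng.normal(1.0, noise_sd)
        if _R_LO < r < _R_HI:
            return float(r)


def split_leaf(
    tree: ParcellationTree,
    leaf_id: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> ParcellationTree:
    """Split a leaf into two daughters whose volumes sum exactly to the parent's.

    With parent volume ``v`` and multiplier ``r ~ Normal(1, noise_sd)``
    (truncated to keep both daughters positive), the daughters get
    ``v*r/2`` and ``v*(2-r)/2``.  The second daughter is assigned
    ``v - v*r/2`` so the sum is exact in floating point.  The tree is
    modified in place and returned.
    """
    if not tree.is_leaf(leaf_id):
        raise InvalidOperationError(f"node {leaf_id} is not a leaf")
    parent = tree.nodes[leaf_id]
    r = _draw_ratio(noise_sd, rng)
    v1 = parent.volume * r / 2.0
    v2 = parent.volume - v1
    tree._n_splits += 1
    step = tree._n_splits
    ids = (tree._next_id, tree._next_id + 1)
    tree._next_id += 2
    for cid, cv in zip(ids, (v1, v2)):
        tree.nodes[cid] = PUnit(id=cid, volume=cv, parent_id=leaf_id,
                                birth_step=step)
        tree.children[cid] = []
    tree.children[leaf_id] = list(ids)
    pos = tree.leaf_ids.index(leaf_id)
    tree.leaf_ids[pos:pos + 1] = ids
    return tree


def run_fragmentation(params: ModelParams) -> ParcellationTree:
    """Run the fragmentation process to ``params.n_target`` PUs.

    At each step the leaf to split is drawn from
    :func:`split_probabilities`; the RNG is consumed in a fixed order
    (one uniform for selection, then the noise multiplier), so a given
    seed reproduces the tree exactly.
    """
    rng = np.random.default_rng(params.seed)
    tree = ParcellationTree(root_volume=params.root_volume)
    while tree.n_leaves < params.n_target:
        p = split_probabilities(tree.leaf_volumes(), params.mu)
        u = rng.random()
        idx = int(np.searchsorted(np.cumsum(p), u))
        idx = min(idx, len(p) - 1)  # guard u landing on the rounded-up total
        split_leaf(tree, tree.leaf_ids[idx], params.noise_sd, rng)
    return tree


def simulate_log_volumes(
    mu: float,
    n_target: int,
    n_sims: int,
    noise_sd: float = 0.10,
    root_volume: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Log leaf volumes of many independent fragmentation runs.

    Runs ``n_sims`` replicates of the same process as
    :func:`run_fragmentation` but keeps only ``ln`` leaf volumes, with all
    replicates advanced one split at a time in lockstep (vectorised across
    the replicate axis).  Statistically equivalent to the tree simulator;
    the RNG stream differs, so individual runs are not bit-identical
    across the two paths.

    Returns
    -------
    numpy.ndarray of shape ``(n_sims, n_target)``
        Natural-log leaf volumes per run.
    """
    if n_target < 1:
        raise InvalidInputError("n_target must be >= 1")
    if n_sims < 1:
        raise InvalidInputError("n_sims must be >= 1")
    if not (0.0 <= noise_sd < 0.5):
        raise InvalidInputError("noise_sd must lie in [0, 0.5)")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    L = np.empty((n_sims, n_target))
    L[:, 0] = np.log(root_volume)
    rows = np.arange(n_sims)
    for k in range(1, n_target):
        a = mu * L[:, :k]
        w = np.exp(a - a.max(axis=1, keepdims=True))
        cw = np.cumsum(w, axis=1)
        u = rng.random(n_sims) * cw[:, -1]
        idx = np.minimum((cw < u[:, None]).sum(axis=1), k - 1)
        if noise_sd == 0.0:
            r = np.ones(n_sims)
        else:
            r = rng.normal(1.0, noise_sd, n_sims)
            bad = (r <= _R_LO) | (r >= _R_HI)
            while bad.any():
                r[bad] = rng.normal(1.0, noise_sd, int(bad.sum()))
                bad = (r <= _R_LO) | (r >= _R_HI)
        lp = L[rows, idx]
        L[rows, idx] = lp + np.log(r / 2.0)
        L[:, k] = lp + np.log((2.0 - r) / 2.0)
    return L


def simulate_sigma(
    mu: float,
    n_pu: int,
    n_sims: int,
    noise_sd: float = 0.10,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Within-run standard deviation of ln PU volume, per replicate run.

    The dispersion statistic sigma(ln v) (sample sd, n-1 denominator) for
    ``n_sims`` independent runs to ``n_pu`` PUs.
    """
    if n_pu < 2:
        raise InvalidInputError("n_pu must be >= 2 for a dispersion statistic")
    L = simulate_log_volumes(mu, n_pu, n_sims, noise_sd=noise_sd, rng=rng)
    return L.std(axis=1, ddof=1)
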