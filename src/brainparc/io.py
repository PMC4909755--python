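"""Reading and writing parcellation trees.

Two plain-text formats are supported:

* a flat CSV table (columns ``id, parent_id, name, volume, birth_step,
  is_leaf``; ``parent_id`` blank for the root) mirroring atlas
  structure-hierarchy tables, and
* Newick, with each node labelled ``id|volume``.  Volumes live in the
  labels rather than in branch lengths, because branch lengths
  conventionally encode time or divergence and the fragmentation model
  assigns no times to branches.

Real atlas hierarchies are not strictly binary; the CSV reader accepts
non-binary internal nodes (a multi-way branch point is read as a series
of duplications collapsed into one node) and emits a warning, since
simulator output is always binary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import pandas as pd

from .fragmentation import InvalidInputError, ParcellationTree, PUnit

__all__ = [
    "FormatError",
    "HierarchyRecord",
    "tree_to_records",
    "records_to_tree",
    "records_to_dataframe",
    "write_hierarchy_csv",
    "read_hierarchy_csv",
    "write_newick",
    "read_newick",
]


class FormatError(ValueError):
    """A structural problem in an input file; the message names the culprit."""


@dataclass(frozen=True)
class HierarchyRecord:
    """One row of a hierarchy table."""

    id: int
    parent_id: int | None
    name: str
    volume: float
    is_leaf: bool
    birth_step: int = 0


def tree_to_records(tree: ParcellationTree) -> list[HierarchyRecord]:
    """Flatten a tree to records, ordered by node id."""
    recs = []
    for nid in sorted(tree.nodes):
        node = tree.nodes[nid]
        recs.append(
            HierarchyRecord(
                id=node.id,
                parent_id=node.parent_id,
                name=node.name or f"region_{node.id}",
                volume=node.volume,
                is_leaf=tree.is_leaf(nid),
                birth_step=node.birth_step,
            )
        )
    return recs


def records_to_tree(records) -> ParcellationTree:
    """Rebuild a :class:`ParcellationTree` from hierarchy records."""
    nodes = [
        PUnit(id=r.id, volume=r.volume, parent_id=r.parent_id,
              birth_step=r.birth_step, name=r.name)
        for r in records
    ]
    try:
        tree = ParcellationTree.from_nodes(nodes)
    except InvalidInputError as exc:
        raise FormatError(str(exc)) from exc
    _warn_if_nonbinary(tree)
    return tree


def records_to_dataframe(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "parent_id": pd.array([r.parent_id for r in records], dtype="Int64"),
            "name": [r.name for r in records],
            "volume": [r.volume for r in records],
            "birth_step": [r.birth_step for r in records],
            "is_leaf": [r.is_leaf for r in records],
        }
    )


def _warn_if_nonbinary(tree: ParcellationTree) -> None:
    bad = [nid for nid, kids in tree.children.items() if len(kids) not in (0, 2)]
    if bad:
        warnings.warn(
            f"{len(bad)} internal nodes are non-binary (e.g. node {bad[0]}); "
            "accepted, but simulator output is always binary",
            stacklevel=3,
        )


def write_hierarchy_csv(tree: ParcellationTree, path) -> None:
    df = records_to_dataframe(tree_to_records(tree))
    # repr round-trips float64 exactly; pandas' default float formatting does not
    df["volume"] = [repr(float(v)) for v in df["volume"]]
    df.to_csv(path, index=False)


def read_hierarchy_csv(path) -> ParcellationTree:
    """Read a hierarchy CSV into a validated tree.

    Requires columns ``id, parent_id, volume`` (blank ``parent_id`` marks
    the root); ``name``, ``birth_step`` and ``is_leaf`` are optional.
    Duplicate ids, dangling parents, multiple roots and cycles raise
    :class:`FormatError` naming the offending row.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"id", "parent_id", "volume"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing required columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        pid = row["parent_id"]
        records.append(
            HierarchyRecord(
                id=int(row["id"]),
                parent_id=None if pd.isna(pid) else int(pid),
                name=str(row["name"]) if "name" in df.columns else f"region_{int(row['id'])}",
                volume=float(row["volume"]),
                is_leaf=bool(row["is_leaf"]) if "is_leaf" in df.columns else False,
                birth_step=int(row["birth_step"]) if "birth_step" in df.columns else 0,
            )
        )
    return records_to_tree(records)


# -- Newick -------------------------------------------------------------------

def _node_label(node: PUnit) -> str:
    return f"{node.id}|{node.volume!r}"


def write_newick(tree: ParcellationTree, path) -> None:
    """Write the tree as Newick with ``id|volume`` node labels."""
    dtree = dendropy.Tree()
    dmap = {tree.root_id: dtree.seed_node}
    dtree.seed_node.label = _node_label(tree.nodes[tree.root_id])
    stack = [tree.root_id]
    while stack:
        nid = stack.pop()
        for cid in tree.children[nid]:
            child = dmap[nid].new_child()
            child.label = _node_label(tree.nodes[cid])
            dmap[cid] = child
            stack.append(cid)
    text = dtree.as_string(
        schema="newick",
        suppress_leaf_node_labels=False,
        suppress_internal_node_labels=False,
        suppress_rooting=True,
        suppress_edge_lengths=True,
    )
    with open(path, "w") as fh:
        fh.write(text)


def _parse_label(label: str | None) -> tuple[int, float]:
    if not label or "|" not in label:
        raise FormatError(f"node label {label!r} is not of the form 'id|volume'")
    sid, svol = label.split("|", 1)
    try:
        return int(sid), float(svol)
    except ValueError as exc:
        raise FormatError(f"cannot parse node label {label!r}") from exc


def read_newick(path) -> ParcellationTree:
    """Read a Newick file written by :func:`write_newick`."""
    try:
        dtree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise FormatError(f"malformed Newick: {exc}") from exc
    nodes: list[PUnit] = []
    ids: dict[int, int] = {}  # dendropy node oid -> our id

    for dnode in dtree.preorder_node_iter():
        label = dnode.label if dnode.label else (
            dnode.taxon.label if dnode.taxon else None
        )
        nid, vol = _parse_label(label)
        ids[id(dnode)] = nid
        parent = dnode.parent_node
        parent_id = ids[id(parent)] if parent is not None else None
        nodes.append(PUnit(id=nid, volume=vol, parent_id=parent_id))
    try:
        tree = ParcellationTree.from_nodes(nodes)
    except InvalidInputError as exc:
        raise FormatError(str(exc)) from exc
    return tree
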