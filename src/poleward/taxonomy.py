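"""Rooted taxonomy trees for copy-number propagation and rank aggregation.

A taxonomy is a rooted tree of nodes ``(node_id, parent_id, rank, name)``;
the root points to itself (or carries a sentinel parent).  The tree supports
bottom-up attribute averaging (the rrnDB-style copy-number propagation),
nearest-valued-ancestor imputation, and lineage queries used by rank
aggregation of abundance tables.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import pandas as pd

from .errors import ImputationError, TaxonomyError

#: Rank order from the root side down.  Ranks not listed compare as unknown.
DEFAULT_RANK_ORDER: tuple[str, ...] = (
    "root",
    "domain",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


class Taxonomy:
    """Rooted tree of taxonomic nodes.

    Parameters
    ----------
    table:
        DataFrame with columns ``node_id``, ``parent_id``, ``rank``, ``name``.
        Exactly one node must be the root (``parent_id`` equal to its own
        ``node_id``, or empty/NA).
    rank_order:
        Root-to-leaf ordering of rank labels used when comparing depths.
    """

    def __init__(self, table: pd.DataFrame, rank_order: Iterable[str] = DEFAULT_RANK_ORDER):
        required = {"node_id", "parent_id", "rank", "name"}
        missing = required - set(table.columns)
        if missing:
            raise TaxonomyError(f"taxonomy table missing columns: {sorted(missing)}")
        table = table.astype({"node_id": str, "rank": str, "name": str})
        self._df = table.reset_index(drop=True)
        self.rank_order = tuple(rank_order)
        self._rank_pos = {r: i for i, r in enumerate(self.rank_order)}

        self.parent: dict[str, str | None] = {}
        self.rank: dict[str, str] = {}
        self.name: dict[str, str] = {}
        roots = []
        for row in self._df.itertuples(index=False):
            nid = str(row.node_id)
            if nid in self.parent:
                raise TaxonomyError(f"duplicate node id {nid!r}")
            pid = None if pd.isna(row.parent_id) else str(row.parent_id)
            if pid in (None, "", nid):
                roots.append(nid)
                pid = None
            self.parent[nid] = pid
            self.rank[nid] = row.rank
            self.name[nid] = row.name
        if len(roots) != 1:
            raise TaxonomyError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]

        self.children: dict[str, list[str]] = {nid: [] for nid in self.parent}
        for nid, pid in self.parent.items():
            if pid is not None:
                if pid not in self.parent:
                    raise TaxonomyError(f"node {nid!r} has unknown parent {pid!r}")
                self.children[pid].append(nid)
        self._check_acyclic()
        self._name_to_id = {}
        for nid, nm in self.name.items():
            self._name_to_id.setdefault(nm, nid)

    def _check_acyclic(self) -> None:
        seen_ok: set[str] = {self.root}
        for start in self.parent:
            path = []
            nid: str | None = start
            while nid is not None and nid not in seen_ok:
                if nid in path:
                    raise TaxonomyError(f"cycle detected at node {nid!r}")
                path.append(nid)
                nid = self.parent[nid]
            if nid is None and path:  # walked off the tree without hitting root
                raise TaxonomyError(f"node {start!r} is disconnected from the root")
            seen_ok.update(path)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.parent

    def __len__(self) -> int:
        return len(self.parent)

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def id_for_name(self, name: str) -> str:
        try:
            return self._name_to_id[name]
        except KeyError:
            raise TaxonomyError(f"no taxonomy node named {name!r}") from None

    def lineage(self, node_id: str) -> list[str]:
        """Node ids from ``node_id`` up to and including the root."""
        if node_id not in self.parent:
            raise TaxonomyError(f"unknown node id {node_id!r}")
        out = [node_id]
        nid = self.parent[node_id]
        while nid is not None:
            out.append(nid)
            nid = self.parent[nid]
        return out

    def rank_position(self, rank: str) -> int | None:
        return self._rank_pos.get(rank)

    def postorder(self) -> list[str]:
        """Children-before-parents traversal (iterative; deep trees safe)."""
        out: list[str] = []
        stack = [self.root]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(self.children[nid])
        out.reverse()
        return out


def propagate_attribute_up(
    taxonomy: Taxonomy, leaf_values: Mapping[str, float]
) -> dict[str, float]:
    """Fill internal nodes with the arithmetic mean of their children's values.

    Supplied values are authoritative for their own node; each unvalued
    internal node receives the mean of its children's (already propagated)
    values, bottom-up.  Nodes in subtrees with no valued descendant stay
    missing (absent from the result).

    This is the rrnDB-style procedure: strain-averaged species copy numbers
    are averaged upward through the lineage so every higher taxon carries a
    representative copy number.
    """
    for nid in leaf_values:
        if nid not in taxonomy:
            raise TaxonomyError(f"valued node {nid!r} is not in the taxonomy")
    values: dict[str, float] = {k: float(v) for k, v in leaf_values.items()}
    for nid in taxonomy.postorder():
        if nid in values:
            continue
        child_vals = [values[c] for c in taxonomy.children[nid] if c in values]
        if child_vals:
            values[nid] = sum(child_vals) / len(child_vals)
    return values


def impute_missing_attribute(
    taxonomy: Taxonomy,
    values: Mapping[str, float],
    target_nodes: Iterable[str],
) -> dict[str, float]:
    """Assign each valueless target the propagated value of its nearest valued ancestor.

    Mirrors taking "the average of closely related species from the above
    taxonomic level": values are first propagated up the tree, then each
    missing target takes its own propagated value (an internal node averages
    its valued descendants) or, failing that, walks toward the root until it
    meets a valued node.
    """
    propagated = propagate_attribute_up(taxonomy, values)
    out: dict[str, float] = {}
    for nid in target_nodes:
        if nid not in taxonomy:
            raise TaxonomyError(f"unknown target node {nid!r}")
        if nid in propagated:
            out[nid] = float(propagated[nid])
            continue
        assigned = None
        for anc in taxonomy.lineage(nid)[1:]:
            if anc in propagated:
                assigned = propagated[anc]
                break
        if assigned is None:
            raise ImputationError(f"node {nid!r} has no valued ancestor to impute from")
        out[nid] = assigned
    return out
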