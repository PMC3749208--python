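"""Ranked taxonomy trees for lowest-common-ancestor read placement.

A :class:`TaxonomyTree` is a single-rooted tree whose nodes carry a rank name
(e.g. ``phylum`` .. ``species``).  It backs both the synthetic reference
generator and the LCA assignment stage, and round-trips through a plain
nodes table (id, parent, rank, name) TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["TaxonomyNode", "TaxonomyTree"]


@dataclass(frozen=True)
class TaxonomyNode:
    id: str
    name: str
    rank: str
    parent_id: str | None  # None only for the root


class TaxonomyTree:
    """Single-rooted, acyclic taxonomy with one parent per non-root node."""

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self._nodes: dict[str, TaxonomyNode] = {}
        root = None
        for node in nodes:
            if node.id in self._nodes:
                raise ValueError(f"duplicate node id {node.id!r}")
            self._nodes[node.id] = node
            if node.parent_id is None:
                if root is not None:
                    raise ValueError("tree has more than one root")
                root = node.id
        if root is None:
            raise ValueError("tree has no root")
        self.root_id = root
        self._children: dict[str, list[str]] = {nid: [] for nid in self._nodes}
        for node in self._nodes.values():
            if node.parent_id is not None:
                if node.parent_id not in self._nodes:
                    raise ValueError(f"unknown parent {node.parent_id!r} of {node.id!r}")
                self._children[node.parent_id].append(node.id)
        # reject cycles / disconnected components: every node must reach root
        for nid in self._nodes:
            seen = set()
            cur: str | None = nid
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle involving node {nid!r}")
                seen.add(cur)
                cur = self._nodes[cur].parent_id
            if self.root_id not in seen:
                raise ValueError(f"node {nid!r} does not descend from the root")

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    @property
    def nodes(self) -> Mapping[str, TaxonomyNode]:
        return self._nodes

    def node(self, node_id: str) -> TaxonomyNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise KeyError(f"unknown taxonomy node {node_id!r}") from None

    def children(self, node_id: str) -> list[str]:
        return list(self._children[node_id])

    def parent(self, node_id: str) -> str | None:
        return self.node(node_id).parent_id

    def lineage(self, node_id: str) -> list[str]:
        """Node ids from the root down to (and including) ``node_id``."""
        path = []
        cur: str | None = node_id
        while cur is not None:
            path.append(cur)
            cur = self.node(cur).parent_id
        return path[::-1]

    def lineage_names(self, node_id: str, include_root: bool = False) -> list[str]:
        ids = self.lineage(node_id)
        if not include_root:
            ids = ids[1:]
        return [self._nodes[i].name for i in ids]

    def lca(self, node_ids: Iterable[str]) -> str:
        """Lowest common ancestor of a non-empty set of nodes."""
        ids = list(node_ids)
        if not ids:
            raise ValueError("lca of an empty node set is undefined")
        common = self.lineage(ids[0])
        for nid in ids[1:]:
            other = self.lineage(nid)
            n = 0
            for a, b in zip(common, other):
                if a != b:
                    break
                n += 1
            common = common[:n]
        return common[-1]

    def leaves(self) -> list[str]:
        return [nid for nid, kids in self._children.items() if not kids]

    # -- plain-table round trip -------------------------------------------
    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "id": n.id,
                "parent": "" if n.parent_id is None else n.parent_id,
                "rank": n.rank,
                "name": n.name,
            }
            for n in self._nodes.values()
        ]
        return pd.DataFrame(rows, columns=["id", "parent", "rank", "name"])

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "TaxonomyTree":
        nodes = [
            TaxonomyNode(
                id=str(r.id),
                name=str(r.name),
                rank=str(r.rank),
                parent_id=None if (pd.isna(r.parent) or r.parent == "") else str(r.parent),
            )
            for r in table.itertuples(index=False)
        ]
        return cls(nodes)

    def write_tsv(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TaxonomyTree":
        return cls.from_table(pd.read_csv(path, sep="\t", keep_default_na=False))
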