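"""Rooted timed species trees.

Thin wrapper around a dendropy tree providing the pieces the event
reconstruction needs: unique node labels used as edge identifiers (an
edge is named after its child node), pre-order traversal, MRCA queries,
and node ages in million years (MY) when branch lengths are present.
Node age is the maximum path length to a descendant leaf, so leaves have
age 0 and the intervals of a timed (ultrametric) tree are exact.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional

import dendropy

__all__ = ["SpeciesTree", "read_newick", "write_annotated_newick", "ROOT"]

#: Edge identifier for a gain at or above the root of the tree.
ROOT = "ROOT"


class SpeciesTree:
    """A rooted species tree with uniquely labelled nodes."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._label_nodes()
        self._nodes = {self._label(n): n for n in tree.preorder_node_iter()}
        self._preorder = [self._label(n) for n in tree.preorder_node_iter()]
        if len(self._nodes) != len(self._preorder):
            raise ValueError("node labels are not unique")
        for node in tree.preorder_internal_node_iter():
            if len(node.child_nodes()) == 1:
                raise ValueError(
                    f"internal node {self._label(node)!r} has a single child; "
                    "the tree must be rooted with >=2 children per internal node"
                )
        self._ages: Optional[dict[str, float]] = None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _label(node: dendropy.Node) -> str:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        return node.label or ""

    def _label_nodes(self) -> None:
        counter = 0
        for node in self._tree.preorder_node_iter():
            if not self._label(node):
                counter += 1
                node.label = f"N{counter}"

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                rooting="force-rooted",
                preserve_underscores=True,
                suppress_internal_node_taxa=False,
            )
        except dendropy.utility.error.DataParseError as exc:
            raise ValueError(f"invalid Newick input: {exc}") from exc
        return cls(tree)

    # -- basic queries -------------------------------------------------------

    @property
    def root(self) -> str:
        return self._label(self._tree.seed_node)

    def leaves(self) -> list[str]:
        return [self._label(n) for n in self._tree.leaf_node_iter()]

    def preorder(self) -> list[str]:
        return list(self._preorder)

    def has_node(self, label: str) -> bool:
        return label in self._nodes

    def children(self, label: str) -> list[str]:
        return [self._label(c) for c in self._nodes[label].child_nodes()]

    def parent(self, label: str) -> Optional[str]:
        p = self._nodes[label].parent_node
        return self._label(p) if p is not None else None

    def is_leaf(self, label: str) -> bool:
        return self._nodes[label].is_leaf()

    def edge_length(self, label: str) -> Optional[float]:
        return self._nodes[label].edge.length

    def has_branch_lengths(self) -> bool:
        return all(
            n.edge.length is not None
            for n in self._tree.preorder_node_iter()
            if n.parent_node is not None
        )

    def subtree_leaves(self, label: str) -> list[str]:
        return [self._label(n) for n in self._nodes[label].leaf_iter()]

    def mrca(self, labels: Iterable[str]) -> str:
        labels = list(labels)
        if not labels:
            raise ValueError("mrca of empty set")
        if len(labels) == 1:
            return labels[0]
        paths = []
        for lab in labels:
            node = self._nodes[lab]
            path = []
            while node is not None:
                path.append(self._label(node))
                node = node.parent_node
            paths.append(path[::-1])
        mrca = self.root
        for level in zip(*paths):
            if len(set(level)) == 1:
                mrca = level[0]
            else:
                break
        return mrca

    def is_ancestor(self, a: str, b: str) -> bool:
        """True if node ``a`` is a strict ancestor of node ``b``."""
        node = self._nodes[b].parent_node
        while node is not None:
            if self._label(node) == a:
                return True
            node = node.parent_node
        return False

    def path_to_root(self, label: str) -> list[str]:
        """Labels from ``label`` up to and including the root."""
        out = []
        node = self._nodes[label]
        while node is not None:
            out.append(self._label(node))
            node = node.parent_node
        return out

    # -- dating --------------------------------------------------------------

    def node_age(self, label: str) -> float:
        """Age in MY: maximum path length to a descendant leaf."""
        if not self.has_branch_lengths():
            raise ValueError("tree has no branch lengths; dating unavailable")
        if self._ages is None:
            ages: dict[str, float] = {}
            for node in self._tree.postorder_node_iter():
                lab = self._label(node)
                if node.is_leaf():
                    ages[lab] = 0.0
                else:
                    ages[lab] = max(
                        ages[self._label(c)] + c.edge.length
                        for c in node.child_nodes()
                    )
            self._ages = ages
        return self._ages[label]

    def root_age(self) -> float:
        return self.node_age(self.root)

    # -- serialization -------------------------------------------------------

    def to_newick(self, edge_comments: Optional[Mapping[str, str]] = None) -> str:
        """Newick string; ``edge_comments`` maps edge id (child label) to a
        bracketed comment appended after that edge's branch length."""
        comments = edge_comments or {}

        def render(node: dendropy.Node) -> str:
            lab = self._label(node)
            if node.is_leaf():
                s = lab
            else:
                inner = ",".join(render(c) for c in node.child_nodes())
                s = f"({inner}){lab}"
            if node.parent_node is not None and node.edge.length is not None:
                s += f":{node.edge.length:g}"
            if lab in comments:
                s += f"[{comments[lab]}]"
            return s

        return render(self._tree.seed_node) + ";"


def read_newick(path: str | Path) -> SpeciesTree:
    """Read a rooted Newick tree (internal labels and MY lengths kept)."""
    text = Path(path).read_text()
    return SpeciesTree.from_newick(text)


def write_annotated_newick(
    tree: SpeciesTree,
    events: Iterable,
    path: str | Path,
) -> Path:
    """Write the tree with gain/loss events as edge comments.

    Events are embedded as ``[&gain=GENE]`` / ``[&loss=GENE]`` comments on
    the affected edges; reading the file back recovers topology, labels
    and branch lengths unchanged (comments are ignored on read).
    """
    comments: dict[str, list[str]] = {}
    for ev in events:
        if ev.gain_branch and ev.gain_branch != ROOT:
            comments.setdefault(ev.gain_branch, []).append(f"&gain={ev.gene}")
        for edge in sorted(ev.loss_branches):
            comments.setdefault(edge, []).append(f"&loss={ev.gene}")
    merged = {k: ",".join(v) for k, v in comments.items()}
    out = Path(path)
    out.write_text(tree.to_newick(edge_comments=merged) + "\n")
    return out
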