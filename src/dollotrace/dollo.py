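"""Dollo-parsimony reconstruction of gene gain and loss on a species tree.

Under Dollo parsimony a gene arises exactly once and can only be lost
thereafter.  Given the presence/absence of a functional gene across the
leaves of a rooted tree, the most-parsimonious history places the gain
on the edge above the most recent common ancestor of all gene-bearing
species and one loss on each highest edge whose subtree contains a
species known to lack the gene and none known to carry it.  Species with
unknown state impose no constraint: they join whichever resolution needs
no extra event and never force a loss.  This reconstruction is unique,
so no tie-breaking is required.

A generalized Sankoff dynamic program over the two states (with explicit
gain and loss costs) is provided as a cross-check; with the regain cost
made prohibitive, cost_gain >= (1 + n_leaves) * cost_loss, its implied
events coincide with the Dollo reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .trees import ROOT, SpeciesTree

__all__ = [
    "PresenceMatrix",
    "EventSet",
    "dollo_reconstruct",
    "sankoff_reconstruct",
    "count_independent_losses",
    "date_event",
    "events_report",
    "DEFAULT_BINARIZATION",
]

STATES = ("INTACT", "PSEUDOGENE", "ABSENT", "UNKNOWN", "HOMOLOG_UNRESOLVED")

#: presence state -> {1 functional gene present, 0 none, "?" uninformative}
DEFAULT_BINARIZATION: dict[str, object] = {
    "INTACT": 1,
    "PSEUDOGENE": 0,
    "ABSENT": 0,
    "UNKNOWN": "?",
    "HOMOLOG_UNRESOLVED": "?",
}


@dataclass
class PresenceMatrix:
    """Species x gene table of presence states."""

    states: pd.DataFrame  # index: species, columns: genes, values from STATES
    binarization: Mapping[str, object] = field(
        default_factory=lambda: dict(DEFAULT_BINARIZATION)
    )

    def __post_init__(self) -> None:
        bad = set(self.states.values.ravel()) - set(STATES)
        if bad:
            raise ValueError(f"unknown presence states: {sorted(map(str, bad))}")

    @classmethod
    def from_tsv(cls, path: str | Path, **kw) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(states=df, **kw)

    def to_tsv(self, path: str | Path) -> None:
        self.states.to_csv(path, sep="\t")

    @property
    def species(self) -> list[str]:
        return list(self.states.index)

    @property
    def genes(self) -> list[str]:
        return list(self.states.columns)

    def column(self, gene: str) -> dict[str, object]:
        """Binarized states {species: 1|0|'?'} for one gene."""
        return {
            sp: self.binarization[s] for sp, s in self.states[gene].items()
        }


@dataclass
class EventSet:
    """Gain and loss events of one gene on a species tree.

    Edges are identified by their child node's label; ``gain_branch`` is
    ``ROOT`` for a gene already present at (or gained above) the root and
    ``None`` when the gene never appears in the matrix.  Time intervals
    are ``[older_bound, younger_bound]`` in MY.
    """

    gene: str
    gain_branch: Optional[str]
    loss_branches: frozenset[str] = frozenset()
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self, tree: SpeciesTree) -> None:
        losses = sorted(self.loss_branches)
        for a in losses:
            for b in losses:
                if a != b and tree.is_ancestor(a, b):
                    raise ValueError(f"nested losses: {a} is ancestral to {b}")
        if self.gain_branch not in (None, ROOT):
            for e in losses:
                if e != self.gain_branch and not tree.is_ancestor(self.gain_branch, e):
                    raise ValueError(
                        f"loss {e} not a strict descendant of gain {self.gain_branch}"
                    )


def _subtree_flags(
    tree: SpeciesTree, column: Mapping[str, object]
) -> tuple[dict[str, bool], dict[str, bool]]:
    """Per node: does the subtree contain a state-1 leaf / a known-0 leaf."""
    has_one: dict[str, bool] = {}
    has_zero: dict[str, bool] = {}
    for node in reversed(tree.preorder()):
        if tree.is_leaf(node):
            s = column.get(node, "?")
            has_one[node] = s == 1
            has_zero[node] = s == 0
        else:
            kids = tree.children(node)
            has_one[node] = any(has_one[c] for c in kids)
            has_zero[node] = any(has_zero[c] for c in kids)
    return has_one, has_zero


def dollo_reconstruct(
    column: Mapping[str, object],
    tree: SpeciesTree,
    gene: str = "gene",
    ancestral_at_root: bool = False,
) -> EventSet:
    """Reconstruct single-gain / irreversible-loss events for one gene.

    ``column`` maps each leaf to 1 (functional gene present), 0 (no
    functional gene) or "?" (uninformative).  The gain lands on the edge
    above the MRCA of all state-1 leaves (``ROOT`` if that MRCA is the
    root or ``ancestral_at_root`` forces it, e.g. for genes known to
    predate the clade in the matrix); losses land on the highest edges
    within the gain clade whose subtrees contain a known-0 leaf and no
    state-1 leaf.  The result is the unique minimum-loss history.
    """
    leaves = set(tree.leaves())
    for sp in column:
        if sp not in leaves:
            raise KeyError(f"species {sp!r} not a leaf of the tree")
    ones = [sp for sp, s in column.items() if s == 1]
    if not ones:
        return EventSet(gene=gene, gain_branch=None)

    gain_node = tree.root if ancestral_at_root else tree.mrca(sorted(ones))
    gain_branch = ROOT if gain_node == tree.root else gain_node

    has_one, has_zero = _subtree_flags(tree, column)

    losses: set[str] = set()

    def descend(node: str) -> None:
        for child in tree.children(node):
            if not has_one[child] and has_zero[child]:
                losses.add(child)  # highest qualifying edge; stop here
            elif has_one[child] or has_zero[child]:
                descend(child)
            # all-? subtree: gene retained, no event

    descend(gain_node)
    events = EventSet(gene=gene, gain_branch=gain_branch, loss_branches=frozenset(losses))
    events.validate(tree)
    if tree.has_branch_lengths():
        events.intervals = {
            edge: date_event(edge, tree)
            for edge in sorted(losses | ({gain_branch} if gain_branch != ROOT else set()))
        }
    return events


def sankoff_reconstruct(
    column: Mapping[str, object],
    tree: SpeciesTree,
    cost_gain: float,
    cost_loss: float,
    gene: str = "gene",
) -> tuple[float, dict[str, int], EventSet]:
    """Minimum-cost ancestral labelling under explicit gain/loss costs.

    Classic two-state Sankoff dynamic program: bottom-up cost vectors,
    top-down backtrace.  A root labelled 1 is charged ``cost_gain`` (the
    gain then sits on the stem above the root, reported as ``ROOT``).
    Ties are broken deterministically toward state 0, which delays gains
    to the latest and advances losses to the earliest cost-equivalent
    edge — the same convention the Dollo reconstruction uses.

    Returns (total cost, node labelling, implied EventSet).
    """
    if cost_gain <= 0 or cost_loss <= 0:
        raise ValueError("costs must be positive")
    leaves = set(tree.leaves())
    for sp in column:
        if sp not in leaves:
            raise KeyError(f"species {sp!r} not a leaf of the tree")

    INF = math.inf
    trans = {(0, 0): 0.0, (1, 1): 0.0, (0, 1): cost_gain, (1, 0): cost_loss}
    cost: dict[str, tuple[float, float]] = {}
    for node in reversed(tree.preorder()):
        if tree.is_leaf(node):
            s = column.get(node, "?")
            if s == 1:
                cost[node] = (INF, 0.0)
            elif s == 0:
                cost[node] = (0.0, INF)
            else:
                cost[node] = (0.0, 0.0)
        else:
            c0 = c1 = 0.0
            for child in tree.children(node):
                k0, k1 = cost[child]
                c0 += min(k0 + trans[(0, 0)], k1 + trans[(0, 1)])
                c1 += min(k0 + trans[(1, 0)], k1 + trans[(1, 1)])
            cost[node] = (c0, c1)

    root = tree.root
    r0, r1 = cost[root]
    r1 += cost_gain  # gain on the stem above the root
    total = min(r0, r1)
    labelling: dict[str, int] = {root: 0 if r0 <= r1 else 1}
    for node in tree.preorder():
        if node == root:
            continue
        p = labelling[tree.parent(node)]
        k0, k1 = cost[node]
        via0 = k0 + trans[(p, 0)]
        via1 = k1 + trans[(p, 1)]
        labelling[node] = 0 if via0 <= via1 else 1

    gains = [n for n in tree.preorder()
             if labelling[n] == 1 and (n == root or labelling[tree.parent(n)] == 0)]
    losses = {n for n in tree.preorder()
              if n != root and labelling[n] == 0 and labelling[tree.parent(n)] == 1}
    if not gains:
        events = EventSet(gene=gene, gain_branch=None)
    else:
        gain = ROOT if gains[0] == root else gains[0]
        events = EventSet(gene=gene, gain_branch=gain, loss_branches=frozenset(losses))
    return total, labelling, events


def count_independent_losses(
    events: EventSet,
    tree: Optional[SpeciesTree] = None,
    shared_groups: Optional[Iterable[Iterable[str]]] = None,
) -> int:
    """Number of independent loss events.

    Without extra evidence this is simply the number of loss branches.
    ``shared_groups`` (species groups whose pseudogenes share an aligned
    lesion, from :func:`dollotrace.orf.shared_lesion`) merge losses: a
    lesion inherited from a common ancestor collapses the member losses
    onto the edge above the group's MRCA, and any merged edge nested
    under another is dropped.
    """
    losses = set(events.loss_branches)
    if shared_groups:
        if tree is None:
            raise ValueError("tree required to merge shared-lesion groups")
        for group in shared_groups:
            group = sorted(set(group))
            if len(group) < 2:
                continue
            covering = {
                e for e in losses
                for sp in group
                if e == sp or tree.is_ancestor(e, sp)
            }
            if not covering:
                continue
            losses -= covering
            losses.add(tree.mrca(group))
        # drop edges nested under another merged edge
        losses = {
            e for e in losses
            if not any(o != e and tree.is_ancestor(o, e) for o in losses)
        }
    return len(losses)


def date_event(edge: str, tree: SpeciesTree) -> tuple[float, float]:
    """Time interval [older_bound, younger_bound] in MY for an event edge.

    The parsimony reconstruction resolves an event only to an edge, so
    the bounds are the ages of the edge's parent and child nodes.
    """
    if not tree.has_branch_lengths():
        raise ValueError("tree has no branch lengths; dating unavailable")
    if edge == ROOT:
        return (math.inf, tree.root_age())
    parent = tree.parent(edge)
    older = tree.node_age(parent) if parent is not None else math.inf
    return (older, tree.node_age(edge))


def events_report(
    matrix: PresenceMatrix,
    tree: SpeciesTree,
    ancestral_at_root: Iterable[str] = (),
) -> tuple[pd.DataFrame, dict[str, EventSet]]:
    """Per-gene gain/loss table over all columns of a presence matrix.

    Returns a tidy DataFrame (one row per event, genes in matrix order,
    edges in pre-order) and the underlying EventSet per gene.
    """
    force_root = set(ancestral_at_root)
    order = {n: i for i, n in enumerate(tree.preorder())}
    dated = tree.has_branch_lengths()
    rows = []
    all_events: dict[str, EventSet] = {}
    for gene in matrix.genes:
        ev = dollo_reconstruct(
            matrix.column(gene), tree, gene=gene,
            ancestral_at_root=gene in force_root,
        )
        all_events[gene] = ev
        if ev.gain_branch is None:
            continue
        gain_iv = date_event(ev.gain_branch, tree) if dated else (None, None)
        rows.append(
            dict(gene=gene, event="gain", edge=ev.gain_branch,
                 older_my=gain_iv[0], younger_my=gain_iv[1])
        )
        for edge in sorted(ev.loss_branches, key=lambda e: order[e]):
            iv = date_event(edge, tree) if dated else (None, None)
            rows.append(
                dict(gene=gene, event="loss", edge=edge,
                     older_my=iv[0], younger_my=iv[1])
            )
    df = pd.DataFrame(rows, columns=["gene", "event", "edge", "older_my", "younger_my"])
    return df, all_events
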