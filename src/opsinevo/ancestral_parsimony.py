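"""Parsimony reconstruction of ancestral copy numbers and habitats.

Copy numbers use Sankoff parsimony over the state space ``0..Nmax`` with a
linear cost ``|i - j|`` per branch (each gene gained or lost costs one).
Branches marked as whole-genome duplications (WGD) apply a deterministic,
zero-cost doubling ``i -> 2i`` at the branch start before the branch's
change cost is assessed; the WGD placement is taken from the tree, never
inferred.  Habitats use Fitch parsimony (equivalently Sankoff with 0/1
costs) with a bottom-up set pass and a top-down resolution preferring the
parent's state.

Tie-breaking everywhere prefers the smaller count (or the alphabetically
first habitat state); the full ambiguity set of each node is reported
alongside the resolved state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .io_formats import SpeciesTree

INF = float("inf")


@dataclass
class AncestralCounts:
    family: str
    node_count: dict[str, int]  # resolved (tie-broken) count per node
    ambiguity: dict[str, set[int]]  # all counts attaining the optimum
    total_cost: float
    wgd_branches: dict[str, str] = field(default_factory=dict)


def sankoff_counts(
    tree: SpeciesTree,
    leaf_counts: Mapping[str, int],
    cost: Callable[[int, int], float] | None = None,
    nmax: int | None = None,
    family: str = "",
) -> AncestralCounts:
    """Minimum-cost ancestral copy numbers by Sankoff's algorithm.

    ``leaf_counts`` maps every leaf label to its observed count;
    ``cost(i, j)`` is the per-branch cost of going from (post-doubling)
    parent state i to child state j (default ``|i - j|``).  On a WGD
    branch the parent state doubles (cost 0) before the branch cost.
    Ambiguity sets contain every state that occurs in at least one
    globally optimal labeling.
    """
    for lf, c in leaf_counts.items():
        if c < 0:
            raise ValueError(f"negative count for {lf}")
    missing = set(tree.leaf_labels) - set(leaf_counts)
    if missing:
        raise ValueError(f"leaf counts missing for {sorted(missing)}")
    if cost is None:
        cost = lambda i, j: abs(i - j)
    if nmax is None:
        nmax = max(leaf_counts.values(), default=0) + 2
    states = list(range(nmax + 1))
    wgd = tree.wgd_branches

    def branch_cost(parent_state: int, child_id: str, child_state: int) -> float:
        eff = 2 * parent_state if child_id in wgd else parent_state
        return cost(eff, child_state)

    # down-pass: D[node][s] = min cost of node's subtree given node state s
    D: dict[str, np.ndarray] = {}
    for nid in tree.node_ids("postorder"):
        nd = tree.node(nid)
        if nd.is_leaf():
            arr = np.full(len(states), INF)
            arr[leaf_counts[nid]] = 0.0
            D[nid] = arr
        else:
            arr = np.zeros(len(states))
            for cid in tree.children(nid):
                child = D[cid]
                arr += np.array(
                    [min(branch_cost(s, cid, t) + child[t] for t in states) for s in states]
                )
            D[nid] = arr

    # up-pass: U[node][s] = min cost of everything outside node's subtree,
    # given node state s (includes the branch above node)
    U: dict[str, np.ndarray] = {tree.root_id: np.zeros(len(states))}
    for nid in tree.node_ids("preorder"):
        for cid in tree.children(nid):
            sib_ids = [x for x in tree.children(nid) if x != cid]
            base = U[nid].copy()
            for sid in sib_ids:
                sib = D[sid]
                base += np.array(
                    [min(branch_cost(s, sid, t) + sib[t] for t in states) for s in states]
                )
            U[cid] = np.array(
                [
                    min(base[s] + branch_cost(s, cid, t) for s in states)
                    for t in states
                ]
            )

    total = float(min(D[tree.root_id]))
    ambiguity: dict[str, set[int]] = {}
    for nid in tree.node_ids("postorder"):
        full = D[nid] + U[nid]
        m = full.min()
        ambiguity[nid] = {s for s in states if full[s] <= m + 1e-9}

    # top-down resolution: prefer the parent's effective state, then smaller
    node_count: dict[str, int] = {}
    root_arr = D[tree.root_id]
    node_count[tree.root_id] = int(min(s for s in states if root_arr[s] <= total + 1e-9))
    for nid in tree.node_ids("preorder"):
        s = node_count[nid]
        for cid in tree.children(nid):
            child = D[cid]
            best = min(branch_cost(s, cid, t) + child[t] for t in states)
            opts = [t for t in states if branch_cost(s, cid, t) + child[t] <= best + 1e-9]
            eff = 2 * s if cid in wgd else s
            node_count[cid] = eff if eff in opts else min(opts)
    return AncestralCounts(
        family=family,
        node_count=node_count,
        ambiguity=ambiguity,
        total_cost=total,
        wgd_branches=dict(wgd),
    )


@dataclass
class RegimePainting:
    """Branch -> regime (habitat state of the branch's child node) plus the
    resolved node states and their Fitch ambiguity sets."""

    branch_regime: dict[str, str]
    node_state: dict[str, str]
    ambiguity: dict[str, set[str]]
    n_changes: int
    states: tuple[str, ...]

    @property
    def root_regime(self) -> str:
        # the root is the one node without a branch above it
        root = next(n for n in self.node_state if n not in self.branch_regime)
        return self.node_state[root]


def fitch_habitat(tree: SpeciesTree, leaf_states: Mapping[str, str]) -> RegimePainting:
    """Fitch parsimony habitat painting (bottom-up sets, top-down
    parent-preference resolution); every branch is painted by the state of
    its child node."""
    missing = set(tree.leaf_labels) - set(leaf_states)
    if missing:
        raise ValueError(f"leaf states missing for {sorted(missing)}; prune the tree first")
    states = tuple(sorted(set(leaf_states.values())))
    if not states:
        raise ValueError("no leaf states given")
    sets: dict[str, frozenset] = {}
    n_changes = 0
    for nid in tree.node_ids("postorder"):
        nd = tree.node(nid)
        if nd.is_leaf():
            sets[nid] = frozenset([leaf_states[nid]])
        else:
            child_sets = [sets[c] for c in tree.children(nid)]
            inter = frozenset.intersection(*child_sets)
            if inter:
                sets[nid] = inter
            else:
                sets[nid] = frozenset.union(*child_sets)
                n_changes += len(child_sets) - 1
    node_state: dict[str, str] = {}
    for nid in tree.node_ids("preorder"):
        parent = tree.parent(nid)
        if parent is None:
            node_state[nid] = min(sets[nid])
        else:
            p = node_state[parent]
            node_state[nid] = p if p in sets[nid] else min(sets[nid])
    branch_regime = {
        nid: node_state[nid] for nid in tree.node_ids() if tree.parent(nid) is not None
    }
    return RegimePainting(
        branch_regime=branch_regime,
        node_state=node_state,
        ambiguity={k: set(v) for k, v in sets.items()},
        n_changes=n_changes,
        states=states,
    )


@dataclass
class BranchEvent:
    branch: str
    event: str  # gain | loss | wgd_doubling
    magnitude: int


def branch_event_table(tree: SpeciesTree, counts: AncestralCounts) -> list[BranchEvent]:
    """Per-branch gain(k)/loss(k) events from resolved ancestral counts;
    on a WGD branch the doubling itself is reported and the change is
    measured against the doubled parent count."""
    events: list[BranchEvent] = []
    for nid in tree.node_ids("preorder"):
        parent = tree.parent(nid)
        if parent is None:
            continue
        p = counts.node_count[parent]
        c = counts.node_count[nid]
        if nid in counts.wgd_branches:
            events.append(BranchEvent(nid, "wgd_doubling", p))
            p = 2 * p
        if c > p:
            events.append(BranchEvent(nid, "gain", c - p))
        elif c < p:
            events.append(BranchEvent(nid, "loss", p - c))
    return events


def clamp_and_recount(
    tree: SpeciesTree,
    counts: AncestralCounts,
    clamped: Mapping[str, int],
    cost: Callable[[int, int], float] | None = None,
) -> AncestralCounts:
    """Optional constraint pass: clamp named internal nodes to counts
    implied by independent evidence (e.g. synteny), keep all other nodes
    at their resolved values, and recompute the total cost."""
    if cost is None:
        cost = lambda i, j: abs(i - j)
    node_count = dict(counts.node_count)
    node_count.update({k: int(v) for k, v in clamped.items()})
    total = 0.0
    for nid in tree.node_ids("preorder"):
        parent = tree.parent(nid)
        if parent is None:
            continue
        p = node_count[parent]
        if nid in counts.wgd_branches:
            p = 2 * p
        total += cost(p, node_count[nid])
    return AncestralCounts(
        family=counts.family,
        node_count=node_count,
        ambiguity={k: {v} if k in clamped else set(a) for k, (v, a) in
                   ((k, (node_count[k], counts.ambiguity.get(k, set()))) for k in node_count)},
        total_cost=total,
        wgd_branches=dict(counts.wgd_branches),
    )
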