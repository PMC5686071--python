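"""Opsin-centred synteny blocks and minimum-event inference.

A synteny block is the ordered gene context of one opsin run on a contig:
the sliding window holds ``6 + n`` genes (the n opsin genes plus three
flanking genes on each side), fewer near contig edges (flagged
edge-truncated).  Blocks are orientation-canonicalised so the same local
gene order reads identically from either strand.

Branch histories are explained with a unit-cost event vocabulary —
single-gene loss, loss of an opsin, tandem duplication of an opsin,
inversion of a contiguous segment, translocation of an opsin to a fresh
contig — and the minimum-cardinality event list between a parent and a
child state is found by iterative-deepening search (default depth 4) with
an admissible lower bound; ties are broken by event-type priority
(gene_loss < opsin_loss < tandem_duplication < inversion <
translocation).  An opsin appearing in a child block whose flanking genes
are all absent from the parent is explained as a translocation, mirroring
the rule that a new synteny implies a translocation event.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import SpeciesTree

Gene = tuple[str, int, bool]  # (name, orientation +1/-1, is_opsin)
BlockT = tuple[Gene, ...]
StateT = tuple[BlockT, ...]  # sorted multiset of canonical blocks

EVENT_PRIORITY = ("gene_loss", "opsin_loss", "tandem_duplication", "inversion", "translocation")


@dataclass
class SyntenyBlock:
    species: str
    contig: str
    genes: BlockT
    provenance: str = "full"  # full | edge_truncated

    def __post_init__(self) -> None:
        if not any(g[2] for g in self.genes):
            raise ValueError("a synteny block must contain at least one opsin")


@dataclass
class SyntenyEvent:
    branch: str
    event: str
    payload: str


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------


def extract_window(
    order: Sequence[Gene],
    opsin_positions: Sequence[int],
    species: str = "",
    contig: str = "",
    flank: int = 3,
) -> SyntenyBlock:
    """The ``6 + n`` sliding window around a run of opsins: the opsins plus
    up to ``flank`` genes on each side, edge-truncated at contig ends."""
    if not opsin_positions:
        raise ValueError("no opsin positions given")
    positions = sorted(opsin_positions)
    lo = max(0, positions[0] - flank)
    hi = min(len(order), positions[-1] + flank + 1)
    truncated = positions[0] - flank < 0 or positions[-1] + flank + 1 > len(order)
    return SyntenyBlock(
        species=species,
        contig=contig,
        genes=tuple(tuple(g) for g in order[lo:hi]),
        provenance="edge_truncated" if truncated else "full",
    )


def extract_windows(
    order: Sequence[Gene], species: str = "", contig: str = "", flank: int = 3, merge_gap: int = 2
) -> list[SyntenyBlock]:
    """All opsin windows on one contig; opsin runs separated by at most
    ``merge_gap`` non-opsin genes share a window."""
    opsins = [i for i, g in enumerate(order) if g[2]]
    if not opsins:
        return []
    clusters: list[list[int]] = [[opsins[0]]]
    for i in opsins[1:]:
        if i - clusters[-1][-1] - 1 <= merge_gap:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    return [extract_window(order, c, species, contig, flank) for c in clusters]


# ---------------------------------------------------------------------------
# canonical form
# ---------------------------------------------------------------------------


def _flip(genes: BlockT) -> BlockT:
    return tuple((n, -o, f) for n, o, f in reversed(genes))


def canonical_genes(genes: BlockT) -> BlockT:
    """Orientation-canonical gene tuple: the block or its reverse-flip,
    whichever reads lexicographically smaller by gene name; idempotent."""
    fwd = tuple(tuple(g) for g in genes)
    rev = _flip(fwd)
    return fwd if tuple(g[0] for g in fwd) <= tuple(g[0] for g in rev) else rev


def normalize_block(block: SyntenyBlock) -> SyntenyBlock:
    return SyntenyBlock(
        species=block.species,
        contig=block.contig,
        genes=canonical_genes(block.genes),
        provenance=block.provenance,
    )


def make_state(blocks: Iterable[BlockT | SyntenyBlock]) -> StateT:
    """Canonical multiset-of-blocks state used by the event search."""
    out = []
    for b in blocks:
        genes = b.genes if isinstance(b, SyntenyBlock) else b
        out.append(canonical_genes(genes))
    return tuple(sorted(out))


def _names(state: StateT) -> set[str]:
    return {g[0] for b in state for g in b}


def _opsin_count(state: StateT) -> int:
    return sum(1 for b in state for g in b if g[2])


# ---------------------------------------------------------------------------
# event search
# ---------------------------------------------------------------------------


def _successors(state: StateT, child: StateT | None):
    """All single-event successors, yielded in event-priority order as
    (event_type, payload, new_state)."""
    blocks = list(state)

    def rebuild(i: int, new_genes: BlockT | None) -> StateT:
        rest = blocks[:i] + blocks[i + 1 :]
        if new_genes is not None and any(g[2] for g in new_genes):
            rest = rest + [canonical_genes(new_genes)]
        return tuple(sorted(rest))

    # gene_loss
    for i, b in enumerate(blocks):
        for j, g in enumerate(b):
            if not g[2]:
                yield "gene_loss", g[0], rebuild(i, b[:j] + b[j + 1 :])
    # opsin_loss (block vanishes from the opsin universe if no opsin remains)
    for i, b in enumerate(blocks):
        for j, g in enumerate(b):
            if g[2]:
                yield "opsin_loss", g[0], rebuild(i, b[:j] + b[j + 1 :])
    # tandem duplication of an opsin
    for i, b in enumerate(blocks):
        for j, g in enumerate(b):
            if g[2]:
                yield "tandem_duplication", g[0], rebuild(i, b[: j + 1] + (g,) + b[j + 1 :])
    # inversion of a contiguous segment (length >= 1 flips orientation)
    for i, b in enumerate(blocks):
        L = len(b)
        for s in range(L):
            for e in range(s, L):
                if s == 0 and e == L - 1:
                    continue  # whole-block inversion is a no-op after canonicalisation
                seg = tuple((n, -o, f) for n, o, f in reversed(b[s : e + 1]))
                if seg == b[s : e + 1]:
                    continue
                yield "inversion", f"{s}:{e}", rebuild(i, b[:s] + seg + b[e + 1 :])
    # translocation of an opsin
    fresh_targets: list[BlockT] = []
    if child is not None:
        parent_names = _names(state)
        for cb in child:
            flanks = [g[0] for g in cb if not g[2]]
            # a translocation moves exactly one opsin, so only single-opsin
            # child blocks with entirely new flanks can be its landing site
            if (
                flanks
                and all(n not in parent_names for n in flanks)
                and sum(1 for g in cb if g[2]) == 1
            ):
                fresh_targets.append(cb)
    for i, b in enumerate(blocks):
        for j, g in enumerate(b):
            if g[2]:
                remainder = b[:j] + b[j + 1 :]
                rest = blocks[:i] + blocks[i + 1 :]
                if any(x[2] for x in remainder):
                    rest = rest + [canonical_genes(remainder)]
                # (a) opsin alone on a fresh, unobserved contig
                yield "translocation", g[0], tuple(sorted(rest + [canonical_genes((g,))]))
                # (b) opsin lands in a child block with entirely new flanks
                for tgt in fresh_targets:
                    if any(x[2] and x[0] == g[0] for x in tgt):
                        yield "translocation", g[0], tuple(sorted(rest + [tgt]))


def _unreachable(state: StateT, child: StateT) -> bool:
    """No move ever creates a new opsin name (duplication and
    translocation both preserve it), so a child opsin name absent from the
    state is impossible.  Non-opsin names are not checked: they can enter
    via fresh-flank landings, whose freshness is state-dependent."""
    parent_opsins = {g[0] for b in state for g in b if g[2]}
    return any(
        g[2] and g[0] not in parent_opsins for cb in child for g in cb
    )


def _make_bound(child: StateT):
    """Precompiled admissible lower bound against one goal state.

    Components: every event changes the total opsin count by at most one;
    each child block with entirely fresh flanks needs its own
    translocation; and every event rewrites at most two blocks (a
    translocation touches the source and the landing block, all other
    events touch one)."""
    child_ops = _opsin_count(child)
    child_counter = Counter(child)
    child_blockset = set(child)

    def bound(state: StateT) -> int:
        if state == child:
            return 0
        h = abs(_opsin_count(state) - child_ops)
        parent_names = {g[0] for b in state for g in b}
        fresh_needed = 0
        for cb in child_blockset:
            if cb in state:
                continue
            flanks = [g[0] for g in cb if not g[2]]
            if flanks and all(n not in parent_names for n in flanks):
                fresh_needed += 1
        sc = Counter(state)
        mismatched = sum((sc - child_counter).values()) + sum(
            (child_counter - sc).values()
        )
        return max(h, fresh_needed, (mismatched + 1) // 2, 1)

    return bound


def _lower_bound(state: StateT, child: StateT) -> int:
    return _make_bound(child)(state)


def infer_branch_events(
    parent_blocks: Iterable[BlockT | SyntenyBlock],
    child_blocks: Iterable[BlockT | SyntenyBlock],
    max_depth: int = 4,
    branch: str = "",
    min_depth: int = 1,
) -> list[SyntenyEvent] | None:
    """Minimum-cardinality event list transforming the parent block set
    into the child block set, or None if no explanation exists within
    ``max_depth`` events (flagged unresolved, never guessed).

    Iterative-deepening depth-first search; successor order follows the
    event-type priority so among equally short explanations the returned
    one is lexicographically first in that priority.  ``min_depth`` lets a
    caller resume deepening past depths already proven empty."""
    start = make_state(parent_blocks)
    goal = make_state(child_blocks)
    if start == goal:
        return []
    if _unreachable(start, goal):
        return None
    bound = _make_bound(goal)

    for depth in range(max(1, min_depth), max_depth + 1):
        seen: dict[StateT, int] = {}

        def dfs(state: StateT, budget: int, path: list) -> list | None:
            if bound(state) > budget or _unreachable(state, goal):
                return None
            if state == goal:
                return list(path)
            if budget == 0:
                return None
            if seen.get(state, -1) >= budget:
                return None
            seen[state] = budget
            # _successors already yields in event-type priority order, so
            # the first solution found respects the tie-break convention
            for ev, payload, nxt in _successors(state, goal):
                path.append((ev, payload))
                hit = dfs(nxt, budget - 1, path)
                if hit is not None:
                    return hit
                path.pop()
            return None

        found = dfs(start, depth, [])
        if found is not None:
            return [SyntenyEvent(branch=branch, event=e, payload=p) for e, p in found]
    return None


def event_distance(parent: StateT, child: StateT, max_depth: int = 4) -> float:
    ev = infer_branch_events(parent, child, max_depth=max_depth)
    return float(len(ev)) if ev is not None else float("inf")


# ---------------------------------------------------------------------------
# history reconstruction on a tree
# ---------------------------------------------------------------------------


@dataclass
class SyntenyHistory:
    node_states: dict[str, StateT]
    events: list[SyntenyEvent]
    total_cost: float
    unresolved: list[str] = field(default_factory=list)


def _candidate_pool(leaf_states: Sequence[StateT], max_depth: int) -> list[StateT]:
    """Ancestor candidates: the observed leaf states plus the intermediate
    states along a minimum event path between each pair of distinct leaf
    states (single-event modifications on parsimony paths)."""
    pool: list[StateT] = []
    for s in leaf_states:
        if s not in pool:
            pool.append(s)
    uniques = list(pool)
    for a in uniques:
        for b in uniques:
            if a == b:
                continue
            ev = infer_branch_events(a, b, max_depth=max_depth)
            if ev is None:
                continue
            state = a
            for e in ev[:-1]:
                nxt = _apply_named(state, b, e)
                if nxt is None:
                    break
                state = nxt
                if state not in pool:
                    pool.append(state)
    return pool


def _apply_named(state: StateT, goal: StateT, event: SyntenyEvent) -> StateT | None:
    for ev, payload, nxt in _successors(state, goal):
        if ev == event.event and payload == event.payload:
            return nxt
    return None


def reconstruct_synteny_history(
    tree: SpeciesTree,
    leaf_blocks: Mapping[str, Iterable[BlockT | SyntenyBlock]],
    max_depth: int = 4,
) -> SyntenyHistory:
    """Minimum-total-event ancestral block sets over the candidate pool.

    Bottom-up dynamic programme (Sankoff over the pool with the event
    distance as branch cost) followed by a top-down resolution; branches
    whose distance exceeds the search depth are flagged unresolved and
    excluded from the total.
    """
    leaf_states = {lf: make_state(leaf_blocks.get(lf, ())) for lf in tree.leaf_labels}
    pool = _candidate_pool(list(leaf_states.values()), max_depth)
    exact: dict[tuple[StateT, StateT], float] = {}
    # searched_to[(a, b)] = k means depths 1..k were proven empty (d > k)
    searched_to: dict[tuple[StateT, StateT], int] = {}

    def d_below(a: StateT, b: StateT, cap: float) -> float:
        """Exact distance if it is < cap (and <= max_depth), else inf.
        Failed search depths are cached and resumed, never repeated."""
        key = (a, b)
        if key in exact:
            dd = exact[key]
            return dd if dd < cap else float("inf")
        if a == b:
            exact[key] = 0.0
            return 0.0
        limit = int(min(max_depth, math.ceil(cap) - 1)) if cap != float("inf") else max_depth
        done = searched_to.get(key, 0)
        if limit <= done:
            return float("inf")
        ev = infer_branch_events(a, b, max_depth=limit, min_depth=done + 1)
        if ev is None:
            searched_to[key] = limit
            return float("inf")
        exact[key] = float(len(ev))
        return exact[key]

    def d(a: StateT, b: StateT) -> float:
        return d_below(a, b, float("inf"))

    BIG = 1e9
    bounds = {t: _make_bound(t) for t in pool}
    cost: dict[str, list[float]] = {}
    for nid in tree.node_ids("postorder"):
        if tree.node(nid).is_leaf():
            cost[nid] = [0.0 if s == leaf_states[nid] else BIG for s in pool]
        else:
            acc = [0.0] * len(pool)
            for cid in tree.children(nid):
                child_cost = cost[cid]
                for i, s in enumerate(pool):
                    # candidates in ascending optimistic cost; stop as soon
                    # as the optimistic bound cannot beat the incumbent
                    order = sorted(
                        (j for j in range(len(pool)) if child_cost[j] < BIG),
                        key=lambda j: (0 if pool[j] == s else bounds[pool[j]](s))
                        + child_cost[j],
                    )
                    best = BIG
                    for j in order:
                        t = pool[j]
                        optimistic = (0 if t == s else bounds[t](s)) + child_cost[j]
                        if optimistic >= best:
                            break
                        dd = d_below(s, t, best - child_cost[j])
                        if dd < float("inf"):
                            best = min(best, dd + child_cost[j])
                    acc[i] += best
            cost[nid] = acc

    node_states: dict[str, StateT] = {}
    root_costs = cost[tree.root_id]
    total = min(root_costs)
    # root ties resolved toward the smaller repertoire (fewest opsins, then
    # fewest genes), matching the copy-number tie-break convention
    tied = [i for i, c in enumerate(root_costs) if c <= total + 1e-9]
    best_i = min(
        tied,
        key=lambda i: (_opsin_count(pool[i]), sum(len(b) for b in pool[i]), pool[i]),
    )
    node_states[tree.root_id] = pool[best_i]
    events: list[SyntenyEvent] = []
    unresolved: list[str] = []
    for nid in tree.node_ids("preorder"):
        for cid in tree.children(nid):
            s = node_states[nid]
            child_cost = cost[cid]
            best_j, best_v = None, BIG
            order = sorted(
                (j for j in range(len(pool)) if child_cost[j] < BIG),
                key=lambda j: (0 if pool[j] == s else bounds[pool[j]](s)) + child_cost[j],
            )
            for j in order:
                t = pool[j]
                optimistic = (0 if t == s else bounds[t](s)) + child_cost[j]
                if best_j is not None and optimistic > best_v:
                    break
                dd = d(s, t)
                if dd == float("inf"):
                    continue
                v = dd + child_cost[j]
                # ties: keep the parent's state, then the smaller repertoire
                key = (v, t != s, _opsin_count(t), sum(len(b) for b in t))
                if best_j is None or key < (
                    best_v,
                    pool[best_j] != s,
                    _opsin_count(pool[best_j]),
                    sum(len(b) for b in pool[best_j]),
                ):
                    best_j, best_v = j, v
            if best_j is None:
                unresolved.append(cid)
                node_states[cid] = leaf_states.get(cid, s)
                continue
            node_states[cid] = pool[best_j]
            ev = infer_branch_events(s, pool[best_j], max_depth=max_depth, branch=cid)
            if ev is None:
                unresolved.append(cid)
            else:
                events.extend(ev)
    return SyntenyHistory(
        node_states=node_states,
        events=events,
        total_cost=float(total if total < BIG else float("inf")),
        unresolved=unresolved,
    )


def serialize_state(state: StateT) -> str:
    """Blocks joined by ';', genes by ',', each gene as signed name
    ('+g1' / '-g1', opsins upper-cased by convention of the caller)."""
    return ";".join(
        ",".join(("+" if o >= 0 else "-") + n for n, o, _ in b) for b in state
    )
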