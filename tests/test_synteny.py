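"""Window extraction, canonical forms, and event minima vs exhaustive BFS."""

import pytest

from opsinevo.synteny import (
    SyntenyBlock,
    _successors,
    canonical_genes,
    extract_window,
    extract_windows,
    infer_branch_events,
    make_state,
    normalize_block,
    reconstruct_synteny_history,
)
from opsinevo.io_formats import SpeciesTree
from opsinevo.synthetic_data import orders_to_contigs, simulate_gene_orders, simulate_tree


def bfs_min_events(parent, child, max_depth=4):
    """Exhaustive breadth-first enumeration of event sequences (no pruning,
    no heuristic): the independent minimality oracle."""
    start, goal = make_state(parent), make_state(child)
    if start == goal:
        return 0
    frontier = {start}
    seen = {start}
    for depth in range(1, max_depth + 1):
        nxt = set()
        for state in frontier:
            for _, _, succ in _successors(state, goal):
                if succ == goal:
                    return depth
                if succ not in seen:
                    seen.add(succ)
                    nxt.add(succ)
        frontier = nxt
    return None


def O(name):  # non-opsin gene
    return (name, 1, False)


def OPS(name="OPS"):
    return (name, 1, True)


class TestWindow:
    def test_single_opsin_seven_gene_window(self):
        order = [O(f"g{i}") for i in range(1, 5)] + [OPS()] + [O(f"g{i}") for i in range(5, 11)]
        block = extract_window(order, [4])
        assert len(block.genes) == 7
        assert [g[0] for g in block.genes] == ["g2", "g3", "g4", "OPS", "g5", "g6", "g7"]
        assert block.provenance == "full"

    def test_three_opsins_nine_gene_window(self):
        order = [O("a"), O("b"), O("c"), OPS("o1"), OPS("o2"), OPS("o3"), O("d"), O("e"), O("f")]
        block = extract_window(order, [3, 4, 5])
        assert len(block.genes) == 9

    def test_edge_truncation(self):
        order = [OPS(), O("a"), O("b"), O("c"), O("d")]
        block = extract_window(order, [0])
        assert len(block.genes) == 4
        assert block.provenance == "edge_truncated"

    def test_empty_positions_rejected(self):
        with pytest.raises(ValueError):
            extract_window([O("a")], [])

    def test_extract_windows_clusters_runs(self):
        order = [O("a"), OPS("o1"), O("b"), O("c"), O("d"), O("e"), OPS("o2"), O("f")]
        blocks = extract_windows(order)
        assert len(blocks) == 2


class TestNormalize:
    def test_reverse_flip_symmetric(self):
        genes = (O("z"), OPS(), O("a"))
        rev = tuple((n, -o, f) for n, o, f in reversed(genes))
        assert canonical_genes(genes) == canonical_genes(rev)

    def test_idempotent(self):
        b = SyntenyBlock("s", "c", (O("m"), OPS(), O("b")))
        once = normalize_block(b)
        assert normalize_block(once).genes == once.genes

    def test_random_blocks_idempotent(self, rng):
        names = [f"g{i}" for i in range(8)]
        for _ in range(50):
            k = int(rng.integers(2, 7))
            genes = tuple(
                (names[int(rng.integers(8))], int(rng.choice([-1, 1])), False)
                for _ in range(k)
            ) + ((f"OPS", 1, True),)
            c1 = canonical_genes(genes)
            assert canonical_genes(c1) == c1


class TestBranchEvents:
    def test_identical_is_empty(self):
        blocks = [(O("a"), OPS(), O("c"))]
        assert infer_branch_events(blocks, blocks) == []

    def test_single_gene_loss(self):
        parent = [(O("a"), O("b"), OPS(), O("c"))]
        child = [(O("a"), OPS(), O("c"))]
        ev = infer_branch_events(parent, child)
        assert [(e.event, e.payload) for e in ev] == [("gene_loss", "b")]

    def test_tandem_duplication(self):
        parent = [(O("a"), OPS(), O("c"))]
        child = [(O("a"), OPS(), OPS(), O("c"))]
        ev = infer_branch_events(parent, child)
        assert [(e.event, e.payload) for e in ev] == [("tandem_duplication", "OPS")]

    def test_translocation_to_new_flanks(self):
        parent = [(O("a"), O("b"), OPS(), O("c"))]
        child = [(O("z1"), OPS(), O("z2"))]
        ev = infer_branch_events(parent, child)
        assert [e.event for e in ev] == ["translocation"]

    def test_unresolvable_within_depth_returns_none(self):
        parent = [(O("a"), O("b"), O("c"), OPS(), O("d"), O("e"), O("f"))]
        child = [(OPS("Q"),)]  # different opsin name: unreachable
        assert infer_branch_events(parent, child, max_depth=2) is None

    def test_minima_match_bfs_oracle_on_random_instances(self, rng):
        template = (O("a"), O("b"), O("c"), OPS(), O("d"), O("e"), O("f"))
        checked = 0
        for seed in range(40):
            tree = SpeciesTree.from_newick("(X:1.0,Y:1.0);")
            sim = simulate_gene_orders(
                tree,
                template=template,
                loss_rate=0.6,
                dup_rate=0.4,
                inversion_rate=0.4,
                translocation_rate=0.2,
                seed=seed,
            )
            if not (1 <= len(sim.events) <= 4):
                continue
            child_blocks = []
            for contig in orders_to_contigs(sim.orders["X"]):
                child_blocks.extend(extract_windows(contig))
            if not child_blocks:
                continue
            ev = infer_branch_events([template], child_blocks)
            oracle = bfs_min_events([template], child_blocks)
            if oracle is None:
                assert ev is None
            else:
                assert ev is not None and len(ev) == oracle
            checked += 1
        assert checked >= 15


class TestHistory:
    def test_identical_leaves_zero_cost(self, balanced4):
        block = (O("a"), OPS(), O("b"))
        leaf_blocks = {lf: [block] for lf in balanced4.leaf_labels}
        hist = reconstruct_synteny_history(balanced4, leaf_blocks)
        assert hist.total_cost == 0
        assert hist.events == []
        assert all(s == make_state([block]) for s in hist.node_states.values())

    def test_single_terminal_loss(self, balanced4):
        full = (O("a"), O("b"), OPS(), O("c"))
        lost = (O("a"), OPS(), O("c"))
        leaf_blocks = {lf: [full] for lf in balanced4.leaf_labels}
        leaf_blocks["D"] = [lost]
        hist = reconstruct_synteny_history(balanced4, leaf_blocks)
        assert hist.total_cost == 1
        assert [(e.branch, e.event) for e in hist.events] == [("D", "gene_loss")]

    def test_matches_assignment_enumeration(self, rng):
        # brute force over every assignment of pool states to internal nodes
        import itertools

        template = (O("a"), O("b"), OPS(), O("c"), O("d"))
        for seed in (3, 11, 17):
            tree = simulate_tree(n_species=4, seed=seed, rescale_height=1.0)
            sim = simulate_gene_orders(
                tree, template=template, loss_rate=0.5, dup_rate=0.3, seed=seed
            )
            leaf_blocks = {}
            for lf in tree.leaf_labels:
                blocks = []
                for contig in orders_to_contigs(sim.orders[lf]):
                    blocks.extend(extract_windows(contig))
                leaf_blocks[lf] = blocks
            hist = reconstruct_synteny_history(tree, leaf_blocks)
            from opsinevo.synteny import _candidate_pool

            leaf_states = {lf: make_state(leaf_blocks[lf]) for lf in tree.leaf_labels}
            pool = _candidate_pool(list(leaf_states.values()), 4)
            internal = [n for n in tree.node_ids() if not tree.node(n).is_leaf()]
            best = float("inf")
            for combo in itertools.product(pool, repeat=len(internal)):
                assign = dict(zip(internal, combo))
                assign.update(leaf_states)
                total = 0.0
                for nid in tree.node_ids():
                    par = tree.parent(nid)
                    if par is None:
                        continue
                    d = bfs_min_events(assign[par], assign[nid])
                    if d is None:
                        total = float("inf")
                        break
                    total += d
                best = min(best, total)
            assert hist.total_cost == best

    def test_truth_recovery_at_low_rates(self):
        recovered = total = 0
        for seed in range(12):
            tree = simulate_tree(n_species=6, seed=seed, rescale_height=1.0)
            sim = simulate_gene_orders(
                tree, loss_rate=0.08, dup_rate=0.05, inversion_rate=0.04,
                translocation_rate=0.02, seed=seed,
            )
            leaf_blocks = {}
            for lf in tree.leaf_labels:
                blocks = []
                for contig in orders_to_contigs(sim.orders[lf]):
                    blocks.extend(extract_windows(contig))
                leaf_blocks[lf] = blocks
            hist = reconstruct_synteny_history(tree, leaf_blocks)
            inferred = {(e.branch, e.event) for e in hist.events}
            for e in sim.events:
                total += 1
                recovered += (e["branch"], e["type"]) in inferred
        assert total >= 10
        assert recovered / total >= 0.9
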