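"""Generators for every input the pipeline consumes.

Each generator emulates the statistical structure the downstream analysis
assumes — birth--death species trees with marked WGD branches, gene-count
histories with Poisson gains/losses and WGD doubling, Markov-evolved
habitats, exact BM/OU trait sampling, opsin-like coding sequences with
injected defects, and gene orders with rearrangement events — and returns
a machine-readable truth log sufficient to score the matching inference
stage.

Determinism: a single root seed fans out to independent per-stage
substreams (`substream`), so a stage can be regenerated on its own and a
fixed seed yields byte-identical files.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from dendropy.simulate import treesim

from .io_formats import GeneRecord, HabitatTable, SpeciesTree

STOP_CODONS = ("TAA", "TAG", "TGA")
_CODON_BY_AA: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    # one representative codon per amino acid (standard code), for building
    # coding sequences from protein templates
    if not _CODON_BY_AA:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in sorted(standard_dna_table.forward_table.items()):
            _CODON_BY_AA.setdefault(aa, codon)
    return _CODON_BY_AA


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible RNG substream for one generation stage.

    Uses a stable label digest (``hash`` is salted per interpreter run)."""
    digest = sum((i + 1) * ord(c) for i, c in enumerate(label)) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed, digest]))


_stable_substream = substream


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------


def simulate_tree(
    n_species: int | None = None,
    birth_rate: float = 0.15,
    death_rate: float = 0.0,
    max_time: float | None = None,
    fixed_newick: str | None = None,
    wgd_branches: Mapping[str, str] | None = None,
    seed: int = 0,
    rescale_height: float | None = None,
) -> SpeciesTree:
    """Birth--death species tree, or a fixed Newick passed through.

    Either ``n_species`` (condition on the number of extant tips) or
    ``max_time`` (run the process for a fixed duration) must be given.
    ``rescale_height`` linearly rescales branch lengths so the root-to-tip
    height matches a target age in Myr.  ``wgd_branches`` marks branches
    (by stable node id of the child node) as whole-genome duplications.
    """
    if fixed_newick is not None:
        tree = SpeciesTree.from_newick(fixed_newick)
    else:
        if birth_rate <= death_rate:
            raise ValueError("need birth_rate > death_rate >= 0")
        rng = random.Random(int(_stable_substream(seed, "tree").integers(2**31)))
        kwargs: dict = {"rng": rng}
        if n_species is not None:
            kwargs["num_extant_tips"] = n_species
            # general sampling approach: draw the tree at a uniform time while
            # the process holds n tips, avoiding zero-length terminal branches
            kwargs["gsa_ntax"] = 2 * n_species
        elif max_time is not None:
            kwargs["max_time"] = max_time
        else:
            raise ValueError("give n_species or max_time")
        dtree = treesim.birth_death_tree(birth_rate, death_rate, **kwargs)
        for i, leaf in enumerate(sorted(dtree.leaf_node_iter(), key=lambda x: x.taxon.label)):
            leaf.taxon.label = f"sp{i + 1:02d}"
        tree = SpeciesTree(dtree)
    if rescale_height is not None:
        h = tree.height()
        if h > 0:
            factor = rescale_height / h
            for nd in tree.dendropy_tree.preorder_node_iter():
                if nd.edge.length is not None:
                    nd.edge.length *= factor
    if wgd_branches:
        tree.wgd_branches.update(wgd_branches)
    return tree


# ---------------------------------------------------------------------------
# Copy-number histories
# ---------------------------------------------------------------------------


@dataclass
class CopyHistory:
    """True per-node counts and the branch event log for one gene family."""

    family: str
    node_counts: dict[str, int]
    events: list[dict] = field(default_factory=list)  # branch, type, detail

    def leaf_counts(self, tree: SpeciesTree) -> dict[str, int]:
        return {lf: self.node_counts[lf] for lf in tree.leaf_labels}


def simulate_copy_history(
    tree: SpeciesTree,
    family: str = "LWS",
    root_count: int = 1,
    gain_rate: float = 0.0,
    loss_rate: float = 0.0,
    wgd_retention: float = 0.5,
    seed: int = 0,
) -> CopyHistory:
    """Linear birth--death gene-count process along the tree.

    Along a branch of length t, gains and losses arrive as Poisson events
    with instantaneous rates ``gain_rate * n`` and ``loss_rate * n`` (n =
    current count); zero is absorbing.  On a WGD-marked branch the count
    doubles at the branch start, then each *duplicated* copy is retained
    with probability ``wgd_retention`` (retention 1 keeps the full
    doubling).
    """
    if root_count < 0:
        raise ValueError("root count must be >= 0")
    rng = _stable_substream(seed, f"copy:{family}")
    counts = {tree.root_id: root_count}
    events: list[dict] = []
    for nid in tree.node_ids(order="preorder"):
        if nid == tree.root_id:
            continue
        n = counts[tree.parent(nid)]
        if nid in tree.wgd_branches:
            retained = int(rng.binomial(n, wgd_retention)) if n else 0
            events.append(
                {"branch": nid, "type": "wgd_doubling", "detail": f"{n}->{n + retained}"}
            )
            n = n + retained
        t = tree.branch_length(nid)
        # Gillespie walk along the branch
        clock = 0.0
        while n > 0:
            total = (gain_rate + loss_rate) * n
            if total <= 0:
                break
            clock += rng.exponential(1.0 / total)
            if clock >= t:
                break
            if rng.random() < gain_rate / (gain_rate + loss_rate):
                n += 1
                events.append({"branch": nid, "type": "gain", "detail": "1"})
            else:
                n -= 1
                events.append({"branch": nid, "type": "loss", "detail": "1"})
        counts[nid] = n
    return CopyHistory(family=family, node_counts=counts, events=events)


# ---------------------------------------------------------------------------
# Habitats
# ---------------------------------------------------------------------------


def simulate_habitats(
    tree: SpeciesTree,
    q: float = 0.005,
    states: Sequence[str] = ("freshwater", "marine"),
    root_state: str | None = None,
    seed: int = 0,
) -> tuple[HabitatTable, dict[str, str]]:
    """Symmetric continuous-time Markov chain over habitat states.

    ``q`` is the per-Myr rate of jumping to *each* other state.  Returns a
    habitat table over the leaves (states land in the salinity column when
    they are the salinity pair, else in the depth column) plus the true
    state of every node.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    if len(states) < 2:
        raise ValueError("need at least two states")
    rng = _stable_substream(seed, "habitat")
    states = list(states)
    root = root_state if root_state is not None else states[int(rng.integers(len(states)))]
    node_states = {tree.root_id: root}
    for nid in tree.node_ids(order="preorder"):
        if nid == tree.root_id:
            continue
        s = node_states[tree.parent(nid)]
        t = tree.branch_length(nid)
        clock = 0.0
        total = q * (len(states) - 1)
        while total > 0:
            clock += rng.exponential(1.0 / total)
            if clock >= t:
                break
            others = [x for x in states if x != s]
            s = others[int(rng.integers(len(others)))]
        node_states[nid] = s
    leaf_states = {lf: node_states[lf] for lf in tree.leaf_labels}
    if set(states) <= {"freshwater", "marine"}:
        table = HabitatTable(salinity=leaf_states, depth_class={})
    elif set(states) <= {"above30", "below50", "unknown"}:
        table = HabitatTable(salinity={}, depth_class=leaf_states)
    else:
        # toy state labels: usable via the returned node states only
        table = HabitatTable(salinity={}, depth_class={})
    return table, node_states


# ---------------------------------------------------------------------------
# Continuous traits (BM / OU)
# ---------------------------------------------------------------------------


def simulate_trait(
    tree: SpeciesTree,
    model: str = "BM",
    sigma2: float = 1.0,
    root_value: float | None = None,
    alpha: float = 0.0,
    theta: Mapping[str, float] | float | None = None,
    painting: Mapping[str, str] | None = None,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Exact Gaussian trait simulation along the tree.

    BM: increment ~ Normal(0, sigma2 * t) per branch.  OU: transition mean
    ``x * exp(-a t) + theta_b * (1 - exp(-a t))``, variance
    ``sigma2 * (1 - exp(-2 a t)) / (2 a)`` with the branch's optimum
    ``theta_b`` taken from ``painting`` (branch id -> regime) and ``theta``
    (regime -> optimum), or a single shared optimum.  The root starts at
    ``root_value`` (default: 0 for BM, the root regime's optimum for OU).
    Returns (leaf values, all node values).
    """
    rng = _stable_substream(seed, "trait")
    if model not in {"BM", "OU"}:
        raise ValueError("model must be BM or OU")
    if model == "OU":
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        if isinstance(theta, (int, float)):
            theta_map = None
            theta_scalar = float(theta)
        else:
            theta_map = dict(theta or {})
            theta_scalar = None
            if painting is None:
                raise ValueError("multi-optimum OU needs a branch painting")

    def branch_theta(nid: str) -> float:
        if model != "OU":
            return 0.0
        if theta_map is None:
            return theta_scalar
        regime = painting[nid]
        return float(theta_map[regime])

    if root_value is None:
        if model == "BM":
            x0 = 0.0
        else:
            root_regime = painting.get(tree.root_id) if painting else None
            x0 = (
                theta_scalar
                if theta_map is None
                else float(theta_map[root_regime if root_regime is not None else next(iter(theta_map))])
            )
    else:
        x0 = float(root_value)

    values = {tree.root_id: x0}
    for nid in tree.node_ids(order="preorder"):
        if nid == tree.root_id:
            continue
        x = values[tree.parent(nid)]
        t = tree.branch_length(nid)
        if model == "BM":
            mean, var = x, sigma2 * t
        else:
            if alpha == 0:
                mean, var = x, sigma2 * t
            else:
                e = math.exp(-alpha * t)
                mean = x * e + branch_theta(nid) * (1 - e)
                var = sigma2 * (1 - e * e) / (2 * alpha)
        values[nid] = mean + math.sqrt(max(var, 0.0)) * rng.standard_normal()
    leaves = {lf: values[lf] for lf in tree.leaf_labels}
    return leaves, values


# ---------------------------------------------------------------------------
# Coding sequences with injected defects
# ---------------------------------------------------------------------------

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_family_references(
    families: Sequence[str] = ("LWS", "SWS1", "SWS2", "Rh2", "Rh1", "Exorh"),
    length_aa: int = 300,
    seed: int = 0,
) -> dict[str, str]:
    """Synthetic opsin-like protein references, one per family, pairwise
    ~50% divergent.  Purely synthetic stand-ins for curated reference sets."""
    rng = _stable_substream(seed, "refs")
    base = "".join(AA20[int(i)] for i in rng.integers(0, 20, size=length_aa))
    # canonical ancestral residues at the families' key tuning sites, so
    # injected tuning substitutions produce interpretable labels
    tuning_residues = {
        "LWS": {164: "S", 181: "H", 261: "Y", 269: "T", 292: "A"},
        "Rh2": {97: "S", 122: "E", 207: "M", 292: "A"},
        "Rh1": {83: "D", 122: "E", 261: "F", 292: "A"},
        "Exorh": {83: "D", 122: "E", 261: "F", 292: "A"},
        "SWS2": {94: "A", 97: "S", 118: "T", 265: "W"},
        "SWS1": {86: "F", 90: "S", 114: "A", 118: "S"},
    }
    refs = {}
    for fam in families:
        prot = list(base)
        idx = rng.choice(length_aa, size=length_aa // 2, replace=False)
        for i in idx:
            prot[i] = AA20[int(rng.integers(20))]
        for site, res in tuning_residues.get(fam, {}).items():
            if site <= length_aa:
                prot[site - 1] = res
        refs[fam] = "".join(prot)
    return refs


def protein_to_cds(protein: str, seed: int = 0, wobble: bool = True) -> str:
    """Back-translate with one representative codon per residue plus a stop."""
    table = _codon_table()
    rng = _stable_substream(seed, "cds")
    codons = [table[aa] for aa in protein]
    return "".join(codons) + "TAA"


@dataclass
class SimulatedCdsSet:
    gene_table: list[GeneRecord]
    cds: dict[str, str]
    proteins: dict[str, str]
    truth_status: dict[str, str]  # gene_id -> complete|pseudogene|truncated
    truth_family: dict[str, str]
    truth_substitutions: dict[str, list[tuple[int, str, str]]]  # (aa position, from, to)


def simulate_cds_set(
    species: Sequence[str],
    references: Mapping[str, str],
    divergence: float = 0.05,
    pseudogene_fraction: float = 0.1,
    truncated_fraction: float = 0.1,
    n_run_length: int = 150,
    substitutions: Mapping[str, Sequence[tuple[int, str, str]]] | None = None,
    expected_exons: Mapping[str, int] | None = None,
    seed: int = 0,
) -> SimulatedCdsSet:
    """Opsin-like CDS sets descended from family references.

    Per species and family: mutate the reference protein at rate
    ``divergence`` per site, apply any requested tuning-site substitutions
    (1-based protein position, from-residue, to-residue; error if the
    from-residue does not match), back-translate, then independently turn a
    ``pseudogene_fraction`` of genes into pseudogenes (in-frame premature
    stop) and a ``truncated_fraction`` into truncated genes (an N-run of
    ``n_run_length`` > 100).  Truth labels are returned for scoring.
    """
    rng = _stable_substream(seed, "cds_set")
    subs = substitutions or {}
    gene_table, cds_map, prot_map = [], {}, {}
    truth_status, truth_family, truth_subs = {}, {}, {}
    pos_cursor = 1000
    for sp in species:
        for fam, ref in references.items():
            gid = f"{sp}_{fam}"
            prot = list(ref)
            n_mut = int(rng.binomial(len(prot), divergence))
            for i in rng.choice(len(prot), size=n_mut, replace=False):
                prot[int(i)] = AA20[int(rng.integers(20))]
            applied = []
            for pos, frm, to in subs.get(fam, []):
                if pos < 1 or pos > len(prot):
                    raise ValueError(f"{gid}: substitution site {pos} outside reference")
                if ref[pos - 1] != frm:
                    raise ValueError(
                        f"{gid}: reference has {ref[pos - 1]} at {pos}, not {frm}"
                    )
                prot[pos - 1] = to
                applied.append((pos, frm, to))
            protein = "".join(prot)
            cds = protein_to_cds(protein)
            status = "complete"
            u = rng.random()
            if u < pseudogene_fraction:
                status = "pseudogene"
                codon = int(rng.integers(5, len(protein) - 5))
                cds = cds[: codon * 3] + "TAA" + cds[(codon + 1) * 3 :]
            elif u < pseudogene_fraction + truncated_fraction:
                status = "truncated"
                start = int(rng.integers(0, max(1, len(cds) - n_run_length)))
                cds = cds[:start] + "N" * n_run_length + cds[start + n_run_length :]
            n_exons = (expected_exons or {}).get(fam, 1)
            length = len(cds)
            exon_len = length // n_exons
            exons = []
            off = pos_cursor
            for k in range(n_exons):
                size = exon_len if k < n_exons - 1 else length - exon_len * (n_exons - 1)
                exons.append((off, off + size))
                off += size + 100
            gene_table.append(
                GeneRecord(
                    gene_id=gid,
                    species=sp,
                    contig=f"{sp}_contig1",
                    start=exons[0][0],
                    end=exons[-1][1],
                    strand="+",
                    exons=tuple(exons),
                    cds=cds,
                )
            )
            pos_cursor = off + 5000
            cds_map[gid] = cds
            prot_map[gid] = protein
            truth_status[gid] = status
            truth_family[gid] = fam
            truth_subs[gid] = applied
    return SimulatedCdsSet(gene_table, cds_map, prot_map, truth_status, truth_family, truth_subs)


# ---------------------------------------------------------------------------
# Gene orders / synteny histories
# ---------------------------------------------------------------------------


@dataclass
class SimulatedOrders:
    """Per-species gene orders plus the true branch event log."""

    orders: dict[str, list[tuple[str, int, bool]]]  # species -> [(name, orient, is_opsin)]
    node_orders: dict[str, list[tuple[str, int, bool]]]
    events: list[dict]  # branch, type, detail


def simulate_gene_orders(
    tree: SpeciesTree,
    template: Sequence[tuple[str, int, bool]] | None = None,
    loss_rate: float = 0.0,
    dup_rate: float = 0.0,
    inversion_rate: float = 0.0,
    translocation_rate: float = 0.0,
    seed: int = 0,
) -> SimulatedOrders:
    """Evolve a synteny template along the tree with Poisson-sampled events.

    Events: loss of one non-opsin gene; tandem duplication of an opsin;
    inversion of a contiguous segment; translocation of an opsin to a fresh
    contig (modelled as replacing its flanks with fresh gene names).  The
    template needs >= 1 opsin and >= 3 flanking genes per side.
    """
    if template is None:
        template = [
            ("g1", 1, False), ("g2", 1, False), ("g3", 1, False),
            ("OPS", 1, True),
            ("g4", 1, False), ("g5", 1, False), ("g6", 1, False),
        ]
    template = [tuple(x) for x in template]
    if not any(g[2] for g in template):
        raise ValueError("template needs at least one opsin")
    rng = _stable_substream(seed, "orders")
    rates = [
        ("gene_loss", loss_rate),
        ("tandem_duplication", dup_rate),
        ("inversion", inversion_rate),
        ("translocation", translocation_rate),
    ]
    total_rate = sum(r for _, r in rates)
    node_orders = {tree.root_id: list(template)}
    events: list[dict] = []
    fresh = [0]

    def apply_event(order: list, kind: str, branch: str) -> list:
        order = list(order)
        opsin_idx = [i for i, g in enumerate(order) if g[2]]
        nonop_idx = [i for i, g in enumerate(order) if not g[2]]
        if kind == "gene_loss" and nonop_idx:
            i = int(rng.choice(nonop_idx))
            events.append({"branch": branch, "type": "gene_loss", "detail": order[i][0]})
            del order[i]
        elif kind == "tandem_duplication" and opsin_idx:
            i = int(rng.choice(opsin_idx))
            events.append({"branch": branch, "type": "tandem_duplication", "detail": order[i][0]})
            order.insert(i + 1, order[i])
        elif kind == "inversion" and len(order) >= 2:
            i = int(rng.integers(0, len(order) - 1))
            j = int(rng.integers(i + 1, len(order)))
            seg = [(n, -o, f) for n, o, f in reversed(order[i : j + 1])]
            events.append({"branch": branch, "type": "inversion", "detail": f"{i}:{j}"})
            order[i : j + 1] = seg
        elif kind == "translocation" and opsin_idx:
            i = int(rng.choice(opsin_idx))
            ops = order[i]
            del order[i]
            fresh[0] += 1
            up = [(f"x{fresh[0]}u{k}", 1, False) for k in range(1, 4)]
            down = [(f"x{fresh[0]}d{k}", 1, False) for k in range(1, 4)]
            events.append({"branch": branch, "type": "translocation", "detail": ops[0]})
            # opsin lands on a fresh contig with entirely new flanks
            order = order + [("|", 0, False)] + up + [ops] + down
        return order

    for nid in tree.node_ids(order="preorder"):
        if nid == tree.root_id:
            continue
        order = list(node_orders[tree.parent(nid)])
        t = tree.branch_length(nid)
        n_events = int(rng.poisson(total_rate * t)) if total_rate > 0 else 0
        for _ in range(n_events):
            u = rng.random() * total_rate
            acc = 0.0
            for kind, r in rates:
                acc += r
                if u < acc:
                    order = apply_event(order, kind, nid)
                    break
        node_orders[nid] = order
    leaf_orders = {lf: node_orders[lf] for lf in tree.leaf_labels}
    return SimulatedOrders(orders=leaf_orders, node_orders=node_orders, events=events)


def orders_to_contigs(order: Sequence[tuple[str, int, bool]]) -> list[list[tuple[str, int, bool]]]:
    """Split a simulated order at contig separators ('|')."""
    contigs: list[list] = [[]]
    for g in order:
        if g[0] == "|":
            contigs.append([])
        else:
            contigs[-1].append(tuple(g))
    return [c for c in contigs if c]
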