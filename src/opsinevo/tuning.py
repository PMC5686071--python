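"""Spectral tuning sites: bovine numbering, ancestral residues, lambda-max.

Tuning sites are residue positions on the opsin--chromophore interface,
numbered by alignment to bovine rhodopsin (the field's shared coordinate
system).  Per site, ancestral residues are reconstructed by marginal
maximum likelihood on the species tree with the two-pass pruning
algorithm under an equal-exchangeability model with empirical residue
frequencies (an F81-style chain over the amino-acid alphabet, chosen for
exactness and oracle-testability; an empirical exchange matrix can be
dropped in).  Branch lengths are the time tree's, scaled by a single
substitution rate fitted by ML.

Spectral predictions are additive over a shipped, user-replaceable table
of experimentally measured shifts (|shift| >= 5 nm), except inside
declared interaction groups, whose combined measured shift replaces the
member sum.  The LWS lambda-max uses the five-sites rule: baseline 560 nm
for the ancestral genotype S164/H181/Y261/T269/A292 with a vitamin-A1
chromophore, plus the tabulated shift of each deviation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .io_formats import SpeciesTree, TuningShiftTable, read_tuning_shift_table
from .repertoire import _aligner, _as_protein, local_align_score

LWS_FIVE_SITES = (164, 181, 261, 269, 292)
LWS_BASELINE_GENOTYPE = {164: "S", 181: "H", 261: "Y", 269: "T", 292: "A"}
LWS_BASELINE_LAMBDA = 560.0  # nm, vitamin-A1 chromophore

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Exorh is the five-exon rod opsin; it shares the Rh1 tuning-site table.
FAMILY_ALIASES = {"Exorh": "Rh1"}


def default_shift_table() -> TuningShiftTable:
    with resources.as_file(
        resources.files("opsinevo.data").joinpath("tuning_shifts.tsv")
    ) as p:
        return read_tuning_shift_table(p)


def bovine_reference() -> str:
    text = resources.files("opsinevo.data").joinpath("bovine_rhodopsin.fasta").read_text()
    return "".join(ln.strip() for ln in text.splitlines() if not ln.startswith(">"))


# ---------------------------------------------------------------------------
# bovine numbering
# ---------------------------------------------------------------------------


def map_bovine_numbering(
    protein: str, reference: str | None = None, min_identity: float = 0.15
) -> dict[int, int]:
    """Map query positions to bovine-rhodopsin site numbers (both 1-based).

    Global alignment of the query against the bovine reference; each
    aligned column inherits the bovine index, gap columns stay unmapped.
    Queries aligning below ``min_identity`` are rejected as non-opsins.
    """
    ref = reference if reference is not None else bovine_reference()
    query = _as_protein(protein)
    if not query:
        raise ValueError("empty query protein")
    aln = _aligner("global").align(query, ref)[0]
    qa, ra = str(aln[0]), str(aln[1])
    matches = sum(1 for a, b in zip(qa, ra) if a == b and a != "-")
    aligned = sum(1 for a, b in zip(qa, ra) if a != "-" and b != "-")
    if aligned == 0 or matches / max(aligned, 1) < min_identity:
        raise ValueError(
            f"alignment identity {matches / max(aligned, 1):.2f} below {min_identity}: not an opsin"
        )
    mapping: dict[int, int] = {}
    qi = ri = 0
    for a, b in zip(qa, ra):
        if a != "-":
            qi += 1
        if b != "-":
            ri += 1
        if a != "-" and b != "-":
            mapping[qi] = ri
    return mapping


def residues_at_sites(
    protein: str, sites: Sequence[int], reference: str | None = None
) -> dict[int, str]:
    """Residues of a query protein at bovine-numbered sites (absent sites
    are skipped)."""
    mapping = map_bovine_numbering(protein, reference)
    inverse = {bovine: q for q, bovine in mapping.items()}
    prot = _as_protein(protein)
    return {s: prot[inverse[s] - 1] for s in sites if s in inverse}


def select_representative(
    candidates: Mapping[str, str], outgroup_protein: str
) -> str:
    """The family representative for ancestral reconstruction: the gene
    most similar to its basal-lineage counterpart (score argmax; ties by
    gene id order)."""
    if not candidates:
        raise ValueError("no candidate genes")
    out = _as_protein(outgroup_protein)
    best_id, best = None, -math.inf
    for gid in sorted(candidates):
        s = local_align_score(_as_protein(candidates[gid]), out)
        if s > best:
            best_id, best = gid, s
    return best_id


# ---------------------------------------------------------------------------
# ancestral state reconstruction (pruning algorithm)
# ---------------------------------------------------------------------------


@dataclass
class AncestralStates:
    site: int
    alphabet: str
    posterior: dict[str, np.ndarray]  # node id -> distribution over alphabet
    map_residue: dict[str, str]
    map_prob: dict[str, float]


def _f81_transition(freqs: np.ndarray, t: float) -> np.ndarray:
    """Closed-form transition matrix of the equal-exchangeability chain
    scaled to one expected substitution per unit branch length."""
    beta = 1.0 / (1.0 - float(freqs @ freqs))
    e = math.exp(-beta * t)
    k = len(freqs)
    return e * np.eye(k) + (1 - e) * np.tile(freqs, (k, 1))


def _empirical_freqs(leaf_residues: Mapping[str, str], alphabet: str) -> np.ndarray:
    counts = np.ones(len(alphabet))  # +1 pseudocount keeps the chain irreducible
    for r in leaf_residues.values():
        if r in alphabet:
            counts[alphabet.index(r)] += 1
    return counts / counts.sum()


def asr_sites(
    tree: SpeciesTree,
    leaf_residues: Mapping[str, str],
    site: int = 0,
    alphabet: str | None = None,
    freqs: Sequence[float] | None = None,
    rate: float = 1.0,
) -> AncestralStates:
    """Marginal ancestral residues at one site by the two-pass pruning
    algorithm (down-pass conditional likelihoods, up-pass marginals).

    Unknown leaf residues ('-', 'X' or absent from the alphabet) carry a
    flat partial likelihood.  ``rate`` scales the time-calibrated branch
    lengths into expected substitutions.
    """
    if alphabet is None:
        observed = sorted(set(leaf_residues.values()) & set(AA20))
        alphabet = "".join(observed) if observed else AA20
        if len(alphabet) < 2:
            alphabet = AA20
    k = len(alphabet)
    missing = set(tree.leaf_labels) - set(leaf_residues)
    if missing:
        raise ValueError(f"residues missing for {sorted(missing)}")
    if all(leaf_residues[lf] not in alphabet for lf in tree.leaf_labels):
        raise ValueError("site unknown at every leaf")
    f = (
        np.asarray(freqs, dtype=float)
        if freqs is not None
        else _empirical_freqs(leaf_residues, alphabet)
    )
    f = f / f.sum()

    P: dict[str, np.ndarray] = {}
    for nid in tree.node_ids():
        if tree.parent(nid) is not None:
            P[nid] = _f81_transition(f, rate * tree.branch_length(nid))

    down: dict[str, np.ndarray] = {}
    for nid in tree.node_ids("postorder"):
        nd = tree.node(nid)
        if nd.is_leaf():
            r = leaf_residues[nid]
            vec = np.ones(k) if r not in alphabet else np.eye(k)[alphabet.index(r)]
            down[nid] = vec
        else:
            vec = np.ones(k)
            for cid in tree.children(nid):
                vec = vec * (P[cid] @ down[cid])
            down[nid] = vec

    up: dict[str, np.ndarray] = {tree.root_id: f.copy()}
    for nid in tree.node_ids("preorder"):
        for cid in tree.children(nid):
            sib = np.ones(k)
            for sid in tree.children(nid):
                if sid != cid:
                    sib = sib * (P[sid] @ down[sid])
            up[cid] = (up[nid] * sib) @ P[cid]

    posterior, map_residue, map_prob = {}, {}, {}
    for nid in tree.node_ids():
        post = up[nid] * down[nid]
        total = post.sum()
        if total <= 0:
            raise ValueError("zero likelihood; check alphabet/frequencies")
        post = post / total
        posterior[nid] = post
        i = int(np.argmax(post))
        map_residue[nid] = alphabet[i]
        map_prob[nid] = float(post[i])
    return AncestralStates(site, alphabet, posterior, map_residue, map_prob)


def site_loglik(
    tree: SpeciesTree,
    leaf_residues: Mapping[str, str],
    alphabet: str,
    freqs: np.ndarray,
    rate: float,
) -> float:
    k = len(alphabet)
    down: dict[str, np.ndarray] = {}
    for nid in tree.node_ids("postorder"):
        nd = tree.node(nid)
        if nd.is_leaf():
            r = leaf_residues[nid]
            down[nid] = np.ones(k) if r not in alphabet else np.eye(k)[alphabet.index(r)]
        else:
            vec = np.ones(k)
            for cid in tree.children(nid):
                vec = vec * (_f81_transition(freqs, rate * tree.branch_length(cid)) @ down[cid])
            down[nid] = vec
    return float(np.log(freqs @ down[tree.root_id]))


def fit_rate(
    tree: SpeciesTree,
    site_columns: Mapping[int, Mapping[str, str]],
    alphabet: str = AA20,
    bounds: tuple[float, float] = (1e-6, 10.0),
) -> float:
    """Single ML rate scaling the time tree into substitution lengths,
    shared across sites."""
    cols = list(site_columns.values())
    pooled: dict[str, str] = {}
    counts = np.ones(len(alphabet))
    for col in cols:
        for lf, r in col.items():
            if r in alphabet:
                counts[alphabet.index(r)] += 1
    freqs = counts / counts.sum()

    def nll(log_rate: float) -> float:
        rate = math.exp(log_rate)
        return -sum(site_loglik(tree, col, alphabet, freqs, rate) for col in cols)

    res = optimize.minimize_scalar(
        nll, bounds=(math.log(bounds[0]), math.log(bounds[1])), method="bounded"
    )
    return float(math.exp(res.x))


# ---------------------------------------------------------------------------
# substitution labels
# ---------------------------------------------------------------------------


def label_substitutions(
    states_by_site: Mapping[int, AncestralStates], tree: SpeciesTree
) -> dict[str, list[dict]]:
    """Per-branch substitution labels "<from><site><to>" from the MAP
    residues; multiple sites on one branch are joined by '/' in ascending
    site order (see ``join_labels``).  Each label carries the parent and
    child MAP probabilities."""
    out: dict[str, list[dict]] = {}
    for nid in tree.node_ids("preorder"):
        parent = tree.parent(nid)
        if parent is None:
            continue
        labels = []
        for site in sorted(states_by_site):
            st = states_by_site[site]
            a, b = st.map_residue[parent], st.map_residue[nid]
            if a != b:
                labels.append(
                    {
                        "label": f"{a}{site}{b}",
                        "site": site,
                        "from": a,
                        "to": b,
                        "parent_prob": st.map_prob[parent],
                        "child_prob": st.map_prob[nid],
                    }
                )
        if labels:
            out[nid] = labels
    return out


def join_labels(labels: Sequence[Mapping]) -> str:
    return "/".join(l["label"] for l in sorted(labels, key=lambda l: l["site"]))


# ---------------------------------------------------------------------------
# spectral predictions
# ---------------------------------------------------------------------------

_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def _parse_sub(sub) -> tuple[str, int, str]:
    if isinstance(sub, str):
        m = _SUB_RE.match(sub)
        if not m:
            raise ValueError(f"bad substitution label {sub!r}")
        return m.group(1), int(m.group(2)), m.group(3)
    frm, site, to = sub
    return str(frm), int(site), str(to)


def predict_shift(
    family: str,
    substitutions: Sequence,
    table: TuningShiftTable | None = None,
) -> float:
    """Total lambda-max shift (nm, negative = blue) of a substitution set.

    Additive over the table's entries, except that when every member of an
    interaction group co-occurs the group's combined measured shift
    replaces the member sum.  A substitution absent from the table raises
    (never a silent zero).
    """
    table = table if table is not None else default_shift_table()
    family = FAMILY_ALIASES.get(family, family)
    subs = [_parse_sub(s) for s in substitutions]
    if not subs:
        return 0.0
    shifts = {}
    for frm, site, to in subs:
        try:
            shifts[(frm, site, to)] = table.lookup(family, site, frm, to)
        except KeyError as exc:
            raise KeyError(f"{family}: no tuning entry for {frm}{site}{to}") from exc
    total = 0.0
    consumed: set = set()
    for gid, rows in table.groups(family).items():
        members = [
            (r["from_res"], int(r["site"]), r["to_res"]) for _, r in rows.iterrows()
        ]
        if all(m in shifts for m in members):
            combined = rows["combined_shift"].dropna()
            if len(combined):
                total += float(combined.iloc[0])
                consumed.update(members)
    for key, val in shifts.items():
        if key not in consumed:
            total += val
    return total


def predict_lws_lambda(
    genotype: Mapping[int, str],
    table: TuningShiftTable | None = None,
    baseline: float = LWS_BASELINE_LAMBDA,
) -> float:
    """Five-sites-rule LWS lambda-max (nm, vitamin-A1 chromophore).

    ``genotype`` gives the residues at bovine sites 164, 181, 261, 269 and
    292; the ancestral teleost genotype S/H/Y/T/A sits at the 560 nm
    baseline, and every deviation adds its tabulated shift."""
    table = table if table is not None else default_shift_table()
    missing = [s for s in LWS_FIVE_SITES if s not in genotype]
    if missing:
        raise ValueError(f"five-sites genotype missing sites {missing}")
    lam = baseline
    for site in LWS_FIVE_SITES:
        base = LWS_BASELINE_GENOTYPE[site]
        obs = genotype[site]
        if obs != base:
            try:
                lam += table.lookup("LWS", site, base, obs)
            except KeyError as exc:
                raise KeyError(
                    f"no five-sites entry for {base}{site}{obs}"
                ) from exc
    return lam
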