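"""Bovine numbering, ancestral residues vs joint enumeration, labels and
spectral-shift predictions."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from opsinevo.io_formats import SpeciesTree
from opsinevo.tuning import (
    LWS_FIVE_SITES,
    asr_sites,
    bovine_reference,
    default_shift_table,
    fit_rate,
    join_labels,
    label_substitutions,
    map_bovine_numbering,
    predict_lws_lambda,
    predict_shift,
    residues_at_sites,
    select_representative,
)
from conftest import random_tree


class TestBovineNumbering:
    def test_identity_mapping_on_reference(self):
        ref = bovine_reference()
        mapping = map_bovine_numbering(ref)
        assert mapping == {i: i for i in range(1, len(ref) + 1)}

    def test_deletion_shifts_downstream_sites(self):
        ref = bovine_reference()
        query = ref[:49] + ref[50:]  # drop residue 50
        mapping = map_bovine_numbering(query)
        assert mapping[82] == 83  # site 83 now sits at query position 82

    def test_low_identity_rejected(self):
        with pytest.raises(ValueError, match="identity"):
            map_bovine_numbering("W" * 300)

    def test_residue_extraction(self):
        ref = bovine_reference()
        res = residues_at_sites(ref, [83, 122, 261, 292])
        assert res == {s: ref[s - 1] for s in (83, 122, 261, 292)}

    def test_representative_is_most_similar(self):
        ref = bovine_reference()
        near = ref[:300]
        far = ref[:150] + "A" * 100
        assert select_representative({"g_far": far, "g_near": near}, ref) == "g_near"


def enumeration_posteriors(tree, leaf_residues, alphabet, freqs, rate):
    """Joint enumeration over all internal-node assignments, with transition
    probabilities from the matrix exponential of the rate matrix (an
    independent route to the closed-form chain used by the implementation)."""
    k = len(alphabet)
    beta = 1.0 / (1.0 - float(freqs @ freqs))
    Q = beta * np.tile(freqs, (k, 1))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    P = {
        nid: expm(Q * rate * tree.branch_length(nid))
        for nid in tree.node_ids()
        if tree.parent(nid) is not None
    }
    internal = [n for n in tree.node_ids() if not tree.node(n).is_leaf()]
    post = {n: np.zeros(k) for n in tree.node_ids()}
    total = 0.0
    for combo in itertools.product(range(k), repeat=len(internal)):
        assign = dict(zip(internal, combo))
        for lf in tree.leaf_labels:
            assign[lf] = alphabet.index(leaf_residues[lf])
        prob = freqs[assign[tree.root_id]]
        for nid in tree.node_ids():
            parent = tree.parent(nid)
            if parent is not None:
                prob *= P[nid][assign[parent], assign[nid]]
        total += prob
        for nid in tree.node_ids():
            post[nid][assign[nid]] += prob
    return {n: v / total for n, v in post.items()}


class TestAsr:
    def test_uniform_leaves_confident_root(self, balanced4):
        # a conserved column under a realistically small fitted rate
        st = asr_sites(balanced4, {lf: "S" for lf in balanced4.leaf_labels},
                       alphabet="ST", rate=0.05)
        assert st.map_residue[balanced4.root_id] == "S"
        assert st.map_prob[balanced4.root_id] > 0.99

    def test_posteriors_sum_to_one(self, rng):
        tree = random_tree(rng, 6)
        residues = {lf: "ACD"[int(rng.integers(3))] for lf in tree.leaf_labels}
        st = asr_sites(tree, residues, alphabet="ACD")
        for nid in tree.node_ids():
            assert st.posterior[nid].sum() == pytest.approx(1.0, abs=1e-9)

    def test_three_leaf_toy_matches_enumeration(self):
        tree = SpeciesTree.from_newick("((A:1.0,B:1.0):1.0,C:2.0);")
        residues = {"A": "S", "B": "T", "C": "S"}
        freqs = np.array([0.5, 0.5])
        st = asr_sites(tree, residues, alphabet="ST", freqs=freqs, rate=0.6)
        oracle = enumeration_posteriors(tree, residues, "ST", freqs, 0.6)
        for nid in tree.node_ids():
            np.testing.assert_allclose(st.posterior[nid], oracle[nid], atol=1e-12)

    def test_matches_enumeration_on_random_instances(self, rng):
        for rep in range(12):
            n = int(rng.integers(3, 6))
            tree = random_tree(rng, n)
            k = int(rng.integers(2, 5))
            alphabet = "ACDE"[:k]
            residues = {lf: alphabet[int(rng.integers(k))] for lf in tree.leaf_labels}
            freqs = rng.uniform(0.5, 2.0, size=k)
            freqs = freqs / freqs.sum()
            rate = float(rng.uniform(0.2, 2.0))
            st = asr_sites(tree, residues, alphabet=alphabet, freqs=freqs, rate=rate)
            oracle = enumeration_posteriors(tree, residues, alphabet, freqs, rate)
            for nid in tree.node_ids():
                np.testing.assert_allclose(st.posterior[nid], oracle[nid], atol=1e-10)

    def test_all_unknown_rejected(self, balanced4):
        with pytest.raises(ValueError):
            asr_sites(balanced4, {lf: "X" for lf in balanced4.leaf_labels}, alphabet="ST")

    def test_fitted_rate_recovers_signal(self, rng):
        # many substitutions demand a higher rate than near-identity columns
        tree = random_tree(rng, 8, height=1.0)
        varied = {i: {lf: "AC"[int(rng.integers(2))] for lf in tree.leaf_labels}
                  for i in range(6)}
        constantish = {i: {lf: ("A" if j > 0 else "C") for j, lf in
                           enumerate(tree.leaf_labels)} for i in range(6)}
        assert fit_rate(tree, varied, alphabet="AC") > fit_rate(
            tree, constantish, alphabet="AC"
        )


class TestLabels:
    def test_parent_child_change_labelled(self, balanced4):
        st = asr_sites(balanced4, {"A": "N", "B": "N", "C": "D", "D": "D"},
                       alphabet="DN", site=83)
        labels = label_substitutions({83: st}, balanced4)
        flat = {b: [l["label"] for l in ls] for b, ls in labels.items()}
        assert any("83" in l for ls in flat.values() for l in ls)
        for ls in labels.values():
            for l in ls:
                assert 0 <= l["parent_prob"] <= 1 and 0 <= l["child_prob"] <= 1

    def test_no_change_no_labels(self, balanced4):
        st = asr_sites(balanced4, {lf: "S" for lf in balanced4.leaf_labels}, alphabet="ST")
        assert label_substitutions({164: st}, balanced4) == {}

    def test_multi_site_join_order(self):
        labels = [
            {"label": "S164A", "site": 164},
            {"label": "E122Q", "site": 122},
        ]
        assert join_labels(labels) == "E122Q/S164A"

    def test_injected_substitutions_recovered(self):
        # tuning substitutions injected on one clade must be labelled on
        # the branch subtending that clade
        from opsinevo.synthetic_data import simulate_tree

        recovered = total = 0
        for seed in range(20):
            tree = simulate_tree(n_species=8, seed=seed, rescale_height=1.0)
            # true interior branches only: a change on a root-child branch
            # is symmetric with the opposite root state and legitimately
            # ambiguous, like the near-root ties of parsimony.  Real
            # substitutions arise with probability proportional to branch
            # length, so vanishingly short branches (where ML rightly
            # prefers nearby placements) are not where changes land.
            root_children = set(tree.children(tree.root_id))
            internal = [n for n in tree.node_ids()
                        if not tree.node(n).is_leaf() and n != tree.root_id
                        and n not in root_children]
            lengths = {n: tree.branch_length(n) for n in internal}
            internal = [n for n in internal
                        if lengths[n] >= np.median(list(lengths.values()))]
            if not internal:
                continue
            branch = internal[seed % len(internal)]
            clade = tree._leafset_below(branch)
            residues = {lf: ("Q" if lf in clade else "E") for lf in tree.leaf_labels}
            st = asr_sites(tree, residues, alphabet="EQ", site=122, rate=0.1)
            labels = label_substitutions({122: st}, tree)
            total += 1
            recovered += branch in labels and labels[branch][0]["label"] == "E122Q"
        assert total >= 10
        assert recovered / total >= 0.9


class TestShiftPrediction:
    def test_empty_substitution_list_is_zero(self):
        assert predict_shift("Rh2", []) == 0.0

    def test_rh2_e122q_is_twenty_blue(self):
        assert predict_shift("Rh2", ["E122Q"]) == pytest.approx(-20.0)

    def test_exorh_aliases_rh1(self):
        assert predict_shift("Exorh", ["D83N"]) == pytest.approx(-6.0)

    def test_interaction_group_replaces_member_sum(self):
        table = default_shift_table()
        single = predict_shift("SWS2", ["A94C"], table) + predict_shift(
            "SWS2", ["W265Y"], table
        )
        combined = predict_shift("SWS2", ["A94C", "W265Y"], table)
        assert combined == pytest.approx(-32.0)
        assert abs(combined) < abs(single)  # smaller than the additive sum

    def test_additive_outside_interaction_groups(self):
        table = default_shift_table()
        a = predict_shift("LWS", ["S164A"], table)
        b = predict_shift("LWS", ["Y261F"], table)
        assert predict_shift("LWS", ["S164A", "Y261F"], table) == pytest.approx(a + b)

    def test_unknown_substitution_raises(self):
        with pytest.raises(KeyError, match="W99C"):
            predict_shift("Rh2", ["W99C"])

    def test_reversal_antisymmetry(self):
        table = default_shift_table()
        for _, row in table.df[table.df["reversible"] == 1].iterrows():
            fwd = table.lookup(row["family"], int(row["site"]), row["from_res"], row["to_res"])
            rev = table.lookup(row["family"], int(row["site"]), row["to_res"], row["from_res"])
            assert fwd == -rev


class TestLwsLambda:
    def test_ancestral_genotype_is_560(self):
        genotype = {164: "S", 181: "H", 261: "Y", 269: "T", 292: "A"}
        assert predict_lws_lambda(genotype) == pytest.approx(560.0)

    def test_single_deviation_adds_table_shift(self):
        table = default_shift_table()
        genotype = {164: "A", 181: "H", 261: "Y", 269: "T", 292: "A"}
        shift = table.lookup("LWS", 164, "S", "A")
        assert predict_lws_lambda(genotype, table) == pytest.approx(560.0 + shift)

    def test_missing_site_rejected(self):
        with pytest.raises(ValueError):
            predict_lws_lambda({164: "S"})

    def test_unknown_residue_rejected(self):
        genotype = {164: "W", 181: "H", 261: "Y", 269: "T", 292: "A"}
        with pytest.raises(KeyError):
            predict_lws_lambda(genotype)
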