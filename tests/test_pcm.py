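"""BM/OU likelihood closed forms, limits, invariances and model selection."""

import math

import numpy as np
import pytest
from scipy import stats

from opsinevo.ancestral_parsimony import fitch_habitat
from opsinevo.io_formats import SpeciesTree
from opsinevo.pcm import (
    FitError,
    ModelFit,
    bm_loglik,
    fit_model,
    ou_loglik,
    run_comparison,
    select_model,
)
from opsinevo.synthetic_data import simulate_habitats, simulate_trait, simulate_tree
from conftest import random_tree


def uniform_painting(tree, regime="r"):
    return {nid: regime for nid in tree.node_ids()}


class TestBmLoglik:
    def test_two_leaf_closed_form_identity_covariance(self):
        # star tree of depth 1: C = I, logL is a product of two unit normals
        t = SpeciesTree.from_newick("(A:1.0,B:1.0);")
        y = {"A": 0.3, "B": -0.7}
        expected = sum(stats.norm.logpdf(v, 0.0, 1.0) for v in y.values())
        assert bm_loglik(t, y, 1.0, 0.0) == pytest.approx(expected, abs=1e-10)

    def test_general_two_leaf_closed_form(self):
        t = SpeciesTree.from_newick("((A:1.0,B:1.0):0.5,C:1.5);")
        y = {"A": 0.2, "B": 0.9, "C": -0.4}
        sigma2, x0 = 1.7, 0.3
        cov = sigma2 * np.array([[1.5, 0.5, 0.0], [0.5, 1.5, 0.0], [0.0, 0.0, 1.5]])
        leaves = t.leaf_labels
        yv = np.array([y[lf] for lf in leaves])
        expected = stats.multivariate_normal.logpdf(yv, mean=np.full(3, x0), cov=cov)
        assert bm_loglik(t, y, sigma2, x0) == pytest.approx(expected, abs=1e-10)

    def test_invalid_sigma2(self):
        t = SpeciesTree.from_newick("(A:1.0,B:1.0);")
        with pytest.raises(ValueError):
            bm_loglik(t, {"A": 0, "B": 0}, 0.0, 0.0)

    def test_likelihood_consistency_under_simulation(self):
        # average logL at the generating parameters beats perturbed ones
        t = simulate_tree(n_species=16, seed=2, rescale_height=1.0)
        at_truth, at_perturbed = [], []
        for i in range(200):
            y, _ = simulate_trait(t, "BM", sigma2=1.0, root_value=0.0, seed=i)
            at_truth.append(bm_loglik(t, y, 1.0, 0.0))
            at_perturbed.append(bm_loglik(t, y, 2.5, 0.0))
        assert np.mean(at_truth) > np.mean(at_perturbed)


class TestOuLoglik:
    def test_bm_limit(self):
        t = SpeciesTree.from_newick("((A:1.0,B:1.0):1.0,C:2.0);")
        y = {"A": 0.5, "B": -0.2, "C": 1.1}
        ll_ou = ou_loglik(t, y, uniform_painting(t), 1e-8, 1.3, {"r": 0.4})
        ll_bm = bm_loglik(t, y, 1.3, 0.4)
        assert abs(ll_ou - ll_bm) < 1e-4

    def test_single_branch_transition_density(self):
        # two far-separated leaves: each is an independent OU transition
        # from the root optimum, so the closed form is a product of normals
        t = SpeciesTree.from_newick("(A:2.0,B:3.0);")
        alpha, sigma2, theta = 1.3, 0.8, 1.5
        y = {"A": 1.1, "B": 2.0}
        expected = 0.0
        for lf, tlen in (("A", 2.0), ("B", 3.0)):
            var = sigma2 * (1 - math.exp(-2 * alpha * tlen)) / (2 * alpha)
            expected += stats.norm.logpdf(y[lf], theta, math.sqrt(var))
        got = ou_loglik(t, y, uniform_painting(t), alpha, sigma2, {"r": theta})
        assert got == pytest.approx(expected, abs=1e-10)

    def test_unpainted_branch_rejected(self):
        t = SpeciesTree.from_newick("(A:1.0,B:1.0);")
        with pytest.raises(ValueError):
            ou_loglik(t, {"A": 0, "B": 0}, {"A": "r", t.root_id: "r"}, 1.0, 1.0, {"r": 0})

    def test_leaf_order_invariance(self, rng):
        t = random_tree(rng, 8)
        y = {lf: float(rng.normal()) for lf in t.leaf_labels}
        shuffled = dict(sorted(y.items(), reverse=True))
        p = uniform_painting(t)
        a = ou_loglik(t, y, p, 0.7, 1.0, {"r": 0.2})
        b = ou_loglik(t, shuffled, p, 0.7, 1.0, {"r": 0.2})
        assert a == pytest.approx(b, abs=1e-12)

    def test_degree_two_node_invariance(self):
        t1 = SpeciesTree.from_newick("(A:2.0,B:2.0);")
        t2 = SpeciesTree.from_newick("((A:1.0):1.0,B:2.0);")  # split A's branch
        y = {"A": 0.4, "B": -0.9}
        for alpha in (1e-8, 0.5, 2.0):
            a = ou_loglik(t1, y, uniform_painting(t1), alpha, 1.2, {"r": 0.1})
            b = ou_loglik(t2, y, uniform_painting(t2), alpha, 1.2, {"r": 0.1})
            assert a == pytest.approx(b, abs=1e-9)
        assert bm_loglik(t1, y, 1.2, 0.1) == pytest.approx(bm_loglik(t2, y, 1.2, 0.1))

    def test_swapped_optima_fit_worse_on_average(self):
        tree = simulate_tree(n_species=24, seed=4, rescale_height=1.0)
        _, node_states = simulate_habitats(tree, q=1.0, states=("F", "M"), seed=4)
        painting = fitch_habitat(tree, {l: node_states[l] for l in tree.leaf_labels})
        pm = dict(painting.branch_regime)
        pm[tree.root_id] = painting.root_regime
        theta = {"F": 0.0, "M": 2.0}
        swapped = {"F": 2.0, "M": 0.0}
        diffs = []
        for i in range(200):
            y, _ = simulate_trait(tree, "OU", sigma2=1.0, alpha=2.0, theta=theta,
                                  painting=pm, seed=i)
            diffs.append(
                ou_loglik(tree, y, pm, 2.0, 1.0, theta)
                - ou_loglik(tree, y, pm, 2.0, 1.0, swapped)
            )
        assert np.mean(diffs) > 0


class TestFit:
    def test_constant_trait_hits_sigma_floor(self, balanced4):
        fit = fit_model(balanced4, {lf: 2.0 for lf in balanced4.leaf_labels}, "BM")
        assert math.isfinite(fit.logL)
        assert fit.params["sigma2"] <= 1e-10

    def test_bm_fit_matches_analytic_gls(self, rng):
        t = random_tree(rng, 12)
        y = {lf: float(rng.normal()) for lf in t.leaf_labels}
        fit = fit_model(t, y, "BM")
        # profiled optimum is a stationary point: nudging parameters never helps
        for ds in (0.9, 1.1):
            assert bm_loglik(t, y, fit.params["sigma2"] * ds, fit.params["x0"]) <= fit.logL + 1e-9
            assert bm_loglik(t, y, fit.params["sigma2"], fit.params["x0"] + (ds - 1)) <= fit.logL + 1e-9

    def test_ou_fit_beats_grid_oracle(self, rng):
        # the 1-D profiled optimiser must dominate a brute parameter grid
        tree = simulate_tree(n_species=20, seed=6, rescale_height=1.0)
        y, _ = simulate_trait(tree, "OU", sigma2=1.0, alpha=1.5, theta=1.0,
                              painting=uniform_painting(tree), seed=9)
        fit = fit_model(tree, y, "OU1")
        best_grid = -np.inf
        for alpha in np.logspace(-2, 1.5, 20):
            for sigma2 in np.logspace(-1.5, 1.0, 20):
                for theta in np.linspace(-1, 3, 20):
                    ll = ou_loglik(tree, y, uniform_painting(tree), alpha, sigma2,
                                   {"r": theta})
                    best_grid = max(best_grid, ll)
        assert fit.logL >= best_grid - 1e-6

    def test_nesting_guaranteed(self, rng):
        # OU logL can never fall below BM: the alpha = 0 start is exact BM
        for seed in range(10):
            tree = simulate_tree(n_species=12, seed=seed, rescale_height=1.0)
            y, _ = simulate_trait(tree, "BM", sigma2=1.0, seed=seed)
            _, node_states = simulate_habitats(tree, q=1.5, states=("F", "M"), seed=seed)
            states = {l: node_states[l] for l in tree.leaf_labels}
            if len(set(states.values())) < 2:
                continue
            painting = fitch_habitat(tree, states)
            fits = {
                "BM": fit_model(tree, y, "BM"),
                "OU1": fit_model(tree, y, "OU1"),
                "OU2": fit_model(tree, y, "OU2", painting=painting),
                "OU3": fit_model(tree, y, "OU3", painting=painting),
            }
            assert fits["OU1"].logL >= fits["BM"].logL - 1e-6
            assert fits["OU2"].logL >= fits["BM"].logL - 1e-6
            assert fits["OU3"].logL >= fits["BM"].logL - 1e-6
            report = select_model(fits)  # must not raise

    def test_parameter_counts(self, balanced4):
        y = {"A": 1.0, "B": 2.0, "C": 0.5, "D": 1.5}
        painting = fitch_habitat(balanced4, {"A": "F", "B": "F", "C": "M", "D": "M"})
        assert fit_model(balanced4, y, "BM").k == 2
        assert fit_model(balanced4, y, "OU1").k == 3
        assert fit_model(balanced4, y, "OU2", painting=painting).k == 4
        assert fit_model(balanced4, y, "OU3", painting=painting).k == 5


class TestSelect:
    def test_identical_loglik_penalised_by_aic(self):
        f0 = ModelFit("BM", {}, -10.0, 2, 16)
        f1 = ModelFit("OU1", {}, -10.0, 3, 16)
        rep = select_model({"BM": f0, "OU1": f1})
        (c,) = rep.comparisons
        assert c.p == pytest.approx(1.0)
        assert c.delta_aic == pytest.approx(2.0)

    def test_chi_square_quantile(self):
        f0 = ModelFit("BM", {}, 0.0, 2, 16)
        f1 = ModelFit("OU1", {}, 3.84 / 2, 3, 16)
        rep = select_model({"BM": f0, "OU1": f1})
        assert rep.comparisons[0].lrt == pytest.approx(3.84)
        assert rep.comparisons[0].p == pytest.approx(0.05, abs=1e-3)

    def test_aic_bic_identities(self):
        f = ModelFit("OU2", {}, -12.5, 4, 32)
        assert f.aic == pytest.approx(2 * 4 - 2 * (-12.5))
        assert f.bic == pytest.approx(4 * math.log(32) - 2 * (-12.5))

    def test_optimisation_failure_detected(self):
        f0 = ModelFit("BM", {}, -5.0, 2, 16)
        f1 = ModelFit("OU1", {}, -6.0, 3, 16)
        with pytest.raises(FitError):
            select_model({"BM": f0, "OU1": f1})

    def test_verdict_follows_ou2_ou3_rule(self):
        fits = {
            "BM": ModelFit("BM", {}, -20.0, 2, 30),
            "OU2": ModelFit("OU2", {}, -12.0, 4, 30),  # LRT 16, df 2: significant
        }
        assert select_model(fits).significant_difference
        fits["OU2"] = ModelFit("OU2", {}, -19.5, 4, 30)
        assert not select_model(fits).significant_difference


class TestRunComparison:
    def test_unknown_depth_species_pruned(self):
        tree = simulate_tree(n_species=10, seed=3, rescale_height=1.0)
        leaves = tree.leaf_labels
        states = {lf: ("above30" if i % 2 else "below50") for i, lf in enumerate(leaves)}
        del states[leaves[0]]  # unknown: must be pruned, not guessed
        counts = {lf: float(i % 3) for i, lf in enumerate(leaves)}
        fits, report = run_comparison(tree, counts, states)
        assert fits["BM"].n == len(leaves) - 1
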