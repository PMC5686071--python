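"""Phylogenetic comparative tests of opsin copy number vs habitat.

Four Gaussian models of a continuous trait on a time-calibrated tree:

* **BM** — Brownian motion, drift only: covariance ``sigma2 * t_a`` where
  ``t_a`` is the shared root-to-MRCA path length; parameters sigma2 and the
  root value x0 (k = 2).  The null model.
* **OU1** — Ornstein--Uhlenbeck with one optimum theta shared by every
  branch (k = 3: alpha, sigma2, theta).
* **OU2** — OU with one optimum per habitat regime, branches painted by
  parsimony-reconstructed habitat (k = 4).
* **OU3** — OU2 with the ancestral habitat treated as unknown: terminal
  branches keep their habitat optimum, every internal branch (and the
  root) gets a third free optimum theta_anc (k = 5).

Under the default *fixed-root* policy the root sits at its regime's
optimum, which makes BM the exact alpha -> 0 limit of each OU model and
the ladder BM < OU1 < OU2 < OU3 properly nested for likelihood-ratio
tests.  A *stationary* root (variance sigma2 / (2 alpha)) is available as
an option.  Copy numbers are treated as continuous traits, as the BM/OU
framework requires.

Fitting maximises the likelihood over alpha only: given alpha, the optima
are profiled out by generalised least squares and sigma2 in closed form,
so the optimisation is one-dimensional, multi-started on a log-spaced
alpha grid (plus the exact BM limit alpha = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .ancestral_parsimony import RegimePainting
from .io_formats import SpeciesTree

LADDER = ("BM", "OU1", "OU2", "OU3")
ANC_REGIME = "anc"


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# paintings
# ---------------------------------------------------------------------------


def _painting_dict(tree: SpeciesTree, painting) -> dict[str, str]:
    """Branch id -> regime, with an entry for the root id giving the root
    regime.  Accepts a RegimePainting or a plain mapping."""
    if isinstance(painting, RegimePainting):
        out = dict(painting.branch_regime)
        out[tree.root_id] = painting.root_regime
        return out
    out = dict(painting)
    if tree.root_id not in out:
        raise ValueError("painting must include the root id (root regime)")
    return out


def ou3_painting(tree: SpeciesTree, painting) -> dict[str, str]:
    """OU3 regime map: terminal branches keep their habitat regime,
    internal branches and the root get the free ancestral optimum."""
    base = _painting_dict(tree, painting)
    leaves = set(tree.leaf_labels)
    return {
        nid: (base[nid] if nid in leaves else ANC_REGIME) for nid in base
    }


# ---------------------------------------------------------------------------
# covariance / design construction
# ---------------------------------------------------------------------------


def _leaf_order(tree: SpeciesTree, traits: Mapping[str, float]) -> list[str]:
    leaves = tree.leaf_labels
    missing = set(leaves) - set(traits)
    if missing:
        raise ValueError(f"trait values missing for {sorted(missing)}")
    return leaves


def _ou_cov(tree: SpeciesTree, alpha: float, root_policy: str) -> np.ndarray:
    """Unit-sigma2 covariance of leaf values under OU with rate alpha."""
    mrca, leaves = tree.mrca_depths()
    depth = np.diag(mrca).copy()
    if alpha == 0:
        if root_policy == "stationary":
            raise ValueError("stationary root undefined at alpha = 0")
        return mrca.copy()
    Ti = depth[:, None]
    Tj = depth[None, :]
    if root_policy == "fixed":
        return np.exp(-alpha * (Ti + Tj - 2 * mrca)) * (-np.expm1(-2 * alpha * mrca)) / (
            2 * alpha
        )
    if root_policy == "stationary":
        return np.exp(-alpha * (Ti + Tj - 2 * mrca)) / (2 * alpha)
    raise ValueError(f"unknown root policy {root_policy!r}")


def _ou_weights(
    tree: SpeciesTree, alpha: float, painting: Mapping[str, str], regimes: Sequence[str]
) -> np.ndarray:
    """Leaf x regime weight matrix W with E[y] = W theta.

    Root-to-tip recursion: w_child = w_parent * e^{-alpha t} +
    (1 - e^{-alpha t}) e_{regime(branch)}, starting from the root regime's
    unit vector (the root mean is its regime's optimum under both root
    policies)."""
    idx = {r: i for i, r in enumerate(regimes)}
    w: dict[str, np.ndarray] = {}
    root = tree.root_id
    w[root] = np.zeros(len(regimes))
    w[root][idx[painting[root]]] = 1.0
    for nid in tree.node_ids("preorder"):
        if nid == root:
            continue
        t = tree.branch_length(nid)
        e = math.exp(-alpha * t) if alpha > 0 else 1.0
        vec = w[tree.parent(nid)] * e
        vec = vec.copy()
        vec[idx[painting[nid]]] += 1.0 - e
        w[nid] = vec
    leaves = tree.leaf_labels
    return np.vstack([w[lf] for lf in leaves])


def _mvn_loglik(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    from scipy.linalg import solve_triangular

    n = len(y)
    L = np.linalg.cholesky(cov)
    r = solve_triangular(L, y - mean, lower=True)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return float(-0.5 * (n * math.log(2 * math.pi) + logdet + r @ r))


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------


def bm_loglik(tree: SpeciesTree, traits: Mapping[str, float], sigma2: float, x0: float) -> float:
    """Log-likelihood of leaf values under Brownian motion:
    multivariate normal with mean ``x0`` and covariance
    ``sigma2 * (shared path length to the MRCA)``."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    leaves = _leaf_order(tree, traits)
    y = np.array([traits[lf] for lf in leaves], dtype=float)
    mrca, _ = tree.mrca_depths()
    return _mvn_loglik(y, np.full(len(y), x0), sigma2 * mrca)


def ou_loglik(
    tree: SpeciesTree,
    traits: Mapping[str, float],
    painting,
    alpha: float,
    sigma2: float,
    theta: Mapping[str, float] | float,
    root_policy: str = "fixed",
) -> float:
    """Log-likelihood under an OU process with per-branch optima.

    ``painting`` maps every branch (child-node id) to a regime and the
    root id to the root regime; ``theta`` maps regime -> optimum (or a
    single shared optimum).  Root policies: "fixed" (root at its regime's
    optimum; the BM limit as alpha -> 0) or "stationary" (root drawn from
    the stationary distribution around its optimum)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    pmap = _painting_dict(tree, painting)
    missing = set(tree.node_ids()) - set(pmap)
    if missing:
        raise ValueError(f"unpainted branches: {sorted(missing)}")
    if isinstance(theta, (int, float)):
        theta = {r: float(theta) for r in set(pmap.values())}
    regimes = sorted(set(pmap.values()))
    leaves = _leaf_order(tree, traits)
    y = np.array([traits[lf] for lf in leaves], dtype=float)
    W = _ou_weights(tree, alpha, pmap, regimes)
    mean = W @ np.array([theta[r] for r in regimes], dtype=float)
    cov = sigma2 * _ou_cov(tree, alpha, root_policy)
    return _mvn_loglik(y, mean, cov)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

SIGMA2_FLOOR = 1e-12


@dataclass
class ModelFit:
    model: str
    params: dict
    logL: float
    k: int
    n: int
    root_policy: str = "fixed"

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.logL

    @property
    def bic(self) -> float:
        return self.k * math.log(self.n) - 2 * self.logL


def _profiled_loglik(
    y: np.ndarray, W: np.ndarray, V: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Maximise the Gaussian likelihood over the mean coefficients (GLS)
    and sigma2 (closed form) for a fixed correlation structure V."""
    from scipy.linalg import solve_triangular

    n = len(y)
    L = np.linalg.cholesky(V)
    yw = solve_triangular(L, y, lower=True)
    Ww = solve_triangular(L, W, lower=True)
    beta, *_ = np.linalg.lstsq(Ww, yw, rcond=None)
    r = yw - Ww @ beta
    s2 = float(r @ r) / n
    s2 = max(s2, SIGMA2_FLOOR)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    logL = -0.5 * (n * math.log(2 * math.pi * s2) + logdet + n * (float(r @ r) / n) / s2)
    return logL, beta, s2


def fit_model(
    tree: SpeciesTree,
    traits: Mapping[str, float],
    model: str,
    painting=None,
    root_policy: str = "fixed",
    n_starts: int = 8,
) -> ModelFit:
    """Maximum-likelihood fit of BM / OU1 / OU2 / OU3.

    OU2 requires a full habitat painting (e.g. from ``fitch_habitat``);
    OU3 derives its three-regime painting from the same input.  The search
    is one-dimensional in alpha (optima and sigma2 profiled out),
    multi-started on a log-spaced grid that always includes the exact BM
    limit alpha = 0, which guarantees logL(OU) >= logL(BM).
    """
    leaves = _leaf_order(tree, traits)
    y = np.array([traits[lf] for lf in leaves], dtype=float)
    n = len(y)
    mrca, _ = tree.mrca_depths()
    height = float(np.diag(mrca).max())

    if model == "BM":
        logL, beta, s2 = _profiled_loglik(y, np.ones((n, 1)), mrca)
        return ModelFit("BM", {"sigma2": s2, "x0": float(beta[0])}, logL, 2, n, root_policy)

    if model == "OU1":
        pmap = {nid: "all" for nid in tree.node_ids()}
    elif model == "OU2":
        if painting is None:
            raise ValueError("OU2 needs a habitat painting")
        pmap = _painting_dict(tree, painting)
    elif model == "OU3":
        if painting is None:
            raise ValueError("OU3 needs a habitat painting")
        pmap = ou3_painting(tree, painting)
    else:
        raise ValueError(f"unknown model {model!r}")
    regimes = sorted(set(pmap.values()))
    k = {"OU1": 3, "OU2": 4, "OU3": 5}[model]

    def eval_alpha(alpha: float) -> tuple[float, np.ndarray, float]:
        if alpha == 0 and root_policy == "stationary":
            return -np.inf, np.zeros(len(regimes)), SIGMA2_FLOOR
        V = _ou_cov(tree, alpha, root_policy)
        W = _ou_weights(tree, alpha, pmap, regimes)
        try:
            return _profiled_loglik(y, W, V)
        except np.linalg.LinAlgError:
            return -np.inf, np.zeros(len(regimes)), SIGMA2_FLOOR

    grid = list(np.exp(np.linspace(math.log(0.05 / height), math.log(30.0 / height), n_starts)))
    if root_policy == "fixed":
        grid = [0.0] + grid
    best = None
    for a in grid:
        logL, beta, s2 = eval_alpha(a)
        if best is None or logL > best[0]:
            best = (logL, a, beta, s2)
    # local refinement around the best grid point
    _, a_best, _, _ = best
    lo = max(a_best / 8, 1e-8 / height)
    hi = max(a_best * 8, 8e-8 / height)
    try:
        res = optimize.minimize_scalar(
            lambda a: -eval_alpha(a)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8 / height},
        )
        logL, beta, s2 = eval_alpha(float(res.x))
        if logL > best[0]:
            best = (logL, float(res.x), beta, s2)
    except Exception:
        pass
    logL, alpha, beta, s2 = best
    if not np.isfinite(logL):
        raise FitError(f"{model}: no finite likelihood found")
    params = {"alpha": alpha, "sigma2": s2}
    params.update({f"theta_{r}": float(b) for r, b in zip(regimes, beta)})
    return ModelFit(model, params, logL, k, n, root_policy)


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


@dataclass
class Comparison:
    null: str
    alt: str
    lrt: float
    df: int
    p: float
    delta_aic: float
    delta_bic: float


@dataclass
class SelectionReport:
    comparisons: list[Comparison]
    significant_difference: bool
    alpha_level: float = 0.05

    def as_rows(self) -> list[dict]:
        return [vars(c) for c in self.comparisons]


def select_model(
    fits: Mapping[str, ModelFit],
    pairs: Sequence[tuple[str, str]] | None = None,
    alpha_level: float = 0.05,
) -> SelectionReport:
    """Likelihood-ratio tests along the nested ladder BM < OU1 < OU2 < OU3
    plus AIC/BIC differences.

    The habitat groups are declared significantly different iff OU2 or OU3
    rejects the BM null at ``alpha_level`` (p <= 0.05 by default).
    """
    if pairs is None:
        present = [m for m in LADDER if m in fits]
        # OU2 and OU3 are not nested in either direction (OU3 frees the
        # internal branches but drops OU2's internal painting), so that
        # pair is compared by AIC/BIC only, never by LRT
        pairs = [
            (a, b)
            for i, a in enumerate(present)
            for b in present[i + 1 :]
            if (a, b) != ("OU2", "OU3")
        ]
    comps = []
    for null, alt in pairs:
        f0, f1 = fits[null], fits[alt]
        if f1.logL < f0.logL - 1e-6:
            raise FitError(
                f"logL({alt}) = {f1.logL:.6f} < logL({null}) = {f0.logL:.6f}: optimisation failure"
            )
        lrt = max(0.0, 2.0 * (f1.logL - f0.logL))
        df = f1.k - f0.k
        p = float(stats.chi2.sf(lrt, df)) if df > 0 else float("nan")
        comps.append(
            Comparison(
                null=null,
                alt=alt,
                lrt=lrt,
                df=df,
                p=p,
                delta_aic=f1.aic - f0.aic,
                delta_bic=f1.bic - f0.bic,
            )
        )
    significant = any(
        c.p <= alpha_level for c in comps if c.null == "BM" and c.alt in {"OU2", "OU3"}
    )
    return SelectionReport(comparisons=comps, significant_difference=significant,
                           alpha_level=alpha_level)


def run_comparison(
    tree: SpeciesTree,
    counts: Mapping[str, float],
    leaf_states: Mapping[str, str],
    models: Sequence[str] = LADDER,
    root_policy: str = "fixed",
) -> tuple[dict[str, ModelFit], SelectionReport]:
    """Full test for one family and one habitat comparison: prune the tree
    to species with known states, paint habitats by Fitch parsimony, fit
    the requested models and run the selection report."""
    from .ancestral_parsimony import fitch_habitat

    known = [lf for lf in tree.leaf_labels if lf in leaf_states and lf in counts]
    if len(known) < 3:
        raise ValueError("need at least three species with known state and count")
    sub = tree.prune_to(known) if set(known) != set(tree.leaf_labels) else tree
    painting = fitch_habitat(sub, {s: leaf_states[s] for s in sub.leaf_labels})
    traits = {s: float(counts[s]) for s in sub.leaf_labels}
    fits = {}
    for m in models:
        fits[m] = fit_model(sub, traits, m, painting=painting, root_policy=root_policy)
    report = select_model(fits)
    return fits, report
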