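"""Recursively partitioned beta-mixture modelling of methylation profiles.

Samples are clustered by recursively fitting a 2-class mixture of beta
distributions: each locus j in class k contributes an independent
Beta(a_jk, b_jk), class weights are a 2-simplex at every node, and a node
is split only when the 2-class BIC beats the 1-class BIC (BIC computed
with the node's effective sample size, the sum of the fractional sample
weights reaching it).  Recursion passes soft (responsibility-weighted)
sample weights down the tree, so class membership stays empirical-Bayes
throughout; a sample's posterior over the final leaves is the product of
branch responsibilities along its path.

Downstream of the fit:

* ``permutation_chisq`` tests class vs phenotype association with a
  Pearson chi-square statistic referred to a label-permutation null;
* ``class_auc`` scores how well locus j separates leaf k from the rest:
  the other leaves' fitted betas are pooled (prevalence-weighted) into a
  moment-matched normal G_jk, and AUC_jk = P(X_k > X_other) is computed
  by numerical integration of the class-k survival function against
  G_jk (truncated to [0, 1]), folded to max(AUC, 1-AUC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betainc, digamma, gammaln, logit, polygamma

from .datatypes import ValidationError

__all__ = [
    "BetaMixtureNode",
    "RPMMTree",
    "fit_two_class",
    "fit_one_class",
    "recursive_partition",
    "eb_membership",
    "permutation_chisq",
    "class_auc",
    "rank_loci_by_auc",
    "RPMM",
    "RPMMResults",
]

CLAMP = 1e-6
PARAM_FLOOR = 1e-3


def _clamp(X: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(X, dtype=float), CLAMP, 1.0 - CLAMP)


def _weighted_beta_mle(
    logx: np.ndarray, log1mx: np.ndarray, w: np.ndarray, mean: np.ndarray, var: np.ndarray
):
    """Weighted beta ML per locus via Newton on the digamma equations.

    ``logx``/``log1mx`` are (n, J); ``w`` is (n,) nonnegative weights.
    Initialised at weighted method-of-moments; shapes floored at 1e-3.
    """
    W = w.sum()
    s1 = (w[:, None] * logx).sum(axis=0) / W  # E[log x]
    s2 = (w[:, None] * log1mx).sum(axis=0) / W  # E[log(1-x)]
    var = np.maximum(var, 1e-6)
    common = np.maximum(mean * (1 - mean) / var - 1.0, 1e-2)
    a = np.maximum(mean * common, PARAM_FLOOR)
    b = np.maximum((1 - mean) * common, PARAM_FLOOR)
    for _ in range(60):
        dga, dgb, dgab = digamma(a), digamma(b), digamma(a + b)
        f1 = dga - dgab - s1
        f2 = dgb - dgab - s2
        ta, tb, tab = polygamma(1, a), polygamma(1, b), polygamma(1, a + b)
        # Jacobian [[ta - tab, -tab], [-tab, tb - tab]]
        det = (ta - tab) * (tb - tab) - tab**2
        det = np.where(np.abs(det) < 1e-12, np.sign(det) * 1e-12 + (det == 0) * 1e-12, det)
        da = ((tb - tab) * f1 - (-tab) * f2) / det
        db = (-(-tab) * f1 + (ta - tab) * f2) / det
        step = 1.0
        a_new = a - step * da
        b_new = b - step * db
        # damped step to stay positive
        bad = (a_new <= 0) | (b_new <= 0)
        while bad.any() and step > 1e-4:
            step /= 2.0
            a_new = np.where(bad, a - step * da, a_new)
            b_new = np.where(bad, b - step * db, b_new)
            bad = (a_new <= 0) | (b_new <= 0)
        a_new = np.maximum(a_new, PARAM_FLOOR)
        b_new = np.maximum(b_new, PARAM_FLOOR)
        if np.max(np.abs(a_new - a) + np.abs(b_new - b)) < 1e-10:
            a, b = a_new, b_new
            break
        a, b = a_new, b_new
    return a, b


def _beta_loglik_matrix(logx, log1mx, a, b) -> np.ndarray:
    """(n,) log-likelihood of each sample under per-locus Beta(a_j, b_j)."""
    const = (gammaln(a + b) - gammaln(a) - gammaln(b)).sum()
    return const + logx @ (a - 1.0) + log1mx @ (b - 1.0)


@dataclass
class BetaMixtureNode:
    """A fitted node: either a leaf (1-class) or a 2-class split."""

    eta: np.ndarray  # class weights, shape (K,)
    a: np.ndarray  # (K, J)
    b: np.ndarray  # (K, J)
    resp: np.ndarray  # (n, K) responsibilities of the samples reaching here
    loglik: float
    bic: float
    n_effective: float
    converged: bool = True
    n_iter: int = 0
    loglik_trace: np.ndarray | None = None
    children: list = field(default_factory=list)
    name: str = "root"

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        """Posterior class membership of arbitrary samples under this node."""
        Xc = _clamp(X)
        logx, log1mx = np.log(Xc), np.log1p(-Xc)
        ll = np.column_stack(
            [
                _beta_loglik_matrix(logx, log1mx, self.a[k], self.b[k])
                for k in range(len(self.eta))
            ]
        ) + np.log(self.eta)
        ll -= ll.max(axis=1, keepdims=True)
        r = np.exp(ll)
        return r / r.sum(axis=1, keepdims=True)


def fit_one_class(X: np.ndarray, weights: np.ndarray | None = None) -> BetaMixtureNode:
    """Weighted single-beta fit per locus (the no-split model)."""
    Xc = _clamp(X)
    n, J = Xc.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    W = w.sum()
    logx, log1mx = np.log(Xc), np.log1p(-Xc)
    mean = (w[:, None] * Xc).sum(axis=0) / W
    var = (w[:, None] * (Xc - mean) ** 2).sum(axis=0) / W
    a, b = _weighted_beta_mle(logx, log1mx, w, mean, var)
    ll = float(w @ _beta_loglik_matrix(logx, log1mx, a, b))
    bic = -2.0 * ll + 2 * J * np.log(max(W, 1.0))
    return BetaMixtureNode(
        eta=np.array([1.0]),
        a=a[None, :],
        b=b[None, :],
        resp=np.ones((n, 1)),
        loglik=ll,
        bic=bic,
        n_effective=W,
    )


def _initial_split(X: np.ndarray, weights: np.ndarray, seed: int) -> np.ndarray:
    """Seeded initial responsibilities from the first principal direction of
    the (weighted, centred) logit-beta matrix: samples above the weighted
    median score start at 0.9 in class 1."""
    Z = logit(_clamp(X))
    w = weights / weights.sum()
    Zc = Z - (w[:, None] * Z).sum(axis=0)
    rng = np.random.default_rng(seed)
    # power iteration for the first right singular vector (deterministic start)
    v = rng.standard_normal(Z.shape[1])
    v /= np.linalg.norm(v)
    for _ in range(50):
        u = (Zc * w[:, None]) @ v
        v_new = Zc.T @ u
        nv = np.linalg.norm(v_new)
        if nv == 0:
            break
        v_new /= nv
        if np.abs(v_new @ v) > 1 - 1e-12:
            v = v_new
            break
        v = v_new
    scores = Zc @ v
    order = np.argsort(scores)
    cum = np.cumsum(weights[order])
    med = scores[order[np.searchsorted(cum, cum[-1] / 2.0)]]
    r1 = np.where(scores > med, 0.9, 0.1)
    return np.column_stack([1.0 - r1, r1])


def fit_two_class(
    X: np.ndarray,
    weights: np.ndarray | None = None,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> BetaMixtureNode:
    """EM fit of the 2-class beta mixture with fractional sample weights.

    Loci are independent given class.  Runs until the relative change in
    weighted log-likelihood falls below ``tol`` or ``max_iter`` sweeps;
    the log-likelihood is nondecreasing every iteration (up to round-off).
    Non-convergence is reported on the node together with the trace.
    """
    Xc = _clamp(np.asarray(X, dtype=float))
    n, J = Xc.shape
    if n < 4:
        raise ValidationError("need at least 4 samples for a 2-class fit")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    logx, log1mx = np.log(Xc), np.log1p(-Xc)

    resp = _initial_split(Xc, w, seed)
    eta = np.array([0.5, 0.5])
    a = np.zeros((2, J))
    b = np.zeros((2, J))
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M-step
        for k in range(2):
            wk = w * resp[:, k]
            if wk.sum() <= 1e-10:
                wk = wk + 1e-10
            Wk = wk.sum()
            mean = (wk[:, None] * Xc).sum(axis=0) / Wk
            var = (wk[:, None] * (Xc - mean) ** 2).sum(axis=0) / Wk
            a[k], b[k] = _weighted_beta_mle(logx, log1mx, wk, mean, var)
        eta = np.array([(w * resp[:, k]).sum() for k in range(2)])
        eta = eta / eta.sum()
        eta = np.clip(eta, 1e-10, 1.0)
        eta = eta / eta.sum()
        # E-step
        ll_k = np.column_stack(
            [_beta_loglik_matrix(logx, log1mx, a[k], b[k]) for k in range(2)]
        ) + np.log(eta)
        mx = ll_k.max(axis=1)
        lse = mx + np.log(np.exp(ll_k - mx[:, None]).sum(axis=1))
        loglik = float(w @ lse)
        trace.append(loglik)
        resp = np.exp(ll_k - lse[:, None])
        if np.isfinite(prev) and abs(loglik - prev) <= tol * (abs(prev) + 1e-12):
            converged = True
            break
        prev = loglik

    W = w.sum()
    n_params = 4 * J + 1
    bic = -2.0 * trace[-1] + n_params * np.log(max(W, 1.0))
    return BetaMixtureNode(
        eta=eta,
        a=a.copy(),
        b=b.copy(),
        resp=resp,
        loglik=trace[-1],
        bic=bic,
        n_effective=W,
        converged=converged,
        n_iter=it,
        loglik_trace=np.array(trace),
    )


@dataclass
class RPMMTree:
    """The fitted recursive partition.

    ``leaves`` are BetaMixtureNode-like records carrying the per-locus
    beta parameters of the final classes; ``leaf_posterior`` is the n x L
    empirical-Bayes membership matrix (rows sum to 1) and ``assignment``
    the hard argmax labels.
    """

    root: BetaMixtureNode
    leaves: list
    leaf_params: list  # per leaf: dict(a=(J,), b=(J,), mass=float, name=str)
    leaf_posterior: np.ndarray
    assignment: np.ndarray
    locus_ids: list

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_params)

    def leaf_prevalence(self, phenotype: np.ndarray) -> np.ndarray:
        """Per-leaf soft prevalence of a 0/1 phenotype."""
        ph = np.asarray(phenotype, dtype=float)
        mass = self.leaf_posterior.sum(axis=0)
        return (self.leaf_posterior * ph[:, None]).sum(axis=0) / np.maximum(mass, 1e-12)


def _recurse(X, logx, log1mx, weights, seed, min_split_mass, depth, max_depth, name):
    node_1 = fit_one_class(X, weights)
    node_1.name = name
    if weights.sum() < min_split_mass or X.shape[0] < 4 or depth >= max_depth:
        return node_1
    node_2 = fit_two_class(X, weights, seed=seed)
    node_2.name = name
    if node_2.bic >= node_1.bic:
        return node_1
    children = []
    for k in range(2):
        child = _recurse(
            X, logx, log1mx, weights * node_2.resp[:, k],
            seed * 2 + k + 1, min_split_mass, depth + 1, max_depth, f"{name}{'LR'[k]}",
        )
        children.append(child)
    node_2.children = children
    return node_2


def _collect_leaves(node, path_resp, leaves, leaf_params):
    if node.is_leaf:
        leaves.append(node)
        leaf_params.append(
            {
                "a": node.a[0],
                "b": node.b[0],
                "mass": float(path_resp.sum()),
                "name": node.name,
            }
        )
        return [path_resp]
    out = []
    for k, child in enumerate(node.children):
        out.extend(_collect_leaves(child, path_resp * node.resp[:, k], leaves, leaf_params))
    return out


def recursive_partition(
    X,
    seed: int = 0,
    min_split_mass: float = 8.0,
    max_depth: int = 6,
    locus_ids=None,
) -> RPMMTree:
    """Recursively split while the 2-class BIC improves on the 1-class BIC.

    Sub-populations are weighted by responsibilities (soft split); a node
    is only considered for splitting when at least ``min_split_mass``
    effective samples reach it.  Returns a single-leaf tree when no split
    is accepted.
    """
    if hasattr(X, "columns"):
        locus_ids = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        locus_ids = list(locus_ids) if locus_ids is not None else list(range(X.shape[1]))
    Xc = _clamp(X)
    logx, log1mx = np.log(Xc), np.log1p(-Xc)
    weights = np.ones(X.shape[0])
    root = _recurse(Xc, logx, log1mx, weights, seed, min_split_mass, 0, max_depth, "r")
    leaves: list = []
    leaf_params: list = []
    cols = _collect_leaves(root, np.ones(X.shape[0]), leaves, leaf_params)
    post = np.column_stack(cols)
    post = post / post.sum(axis=1, keepdims=True)
    return RPMMTree(
        root=root,
        leaves=leaves,
        leaf_params=leaf_params,
        leaf_posterior=post,
        assignment=post.argmax(axis=1),
        locus_ids=locus_ids,
    )


def eb_membership(tree: RPMMTree, X) -> np.ndarray:
    """Empirical-Bayes posterior over leaves for (possibly new) samples:
    the product of branch responsibilities along each root-to-leaf path."""
    X = X.to_numpy(dtype=float) if hasattr(X, "to_numpy") else np.asarray(X, dtype=float)

    def walk(node, path_resp):
        if node.is_leaf:
            return [path_resp]
        r = node.responsibilities(X)
        out = []
        for k, child in enumerate(node.children):
            out.extend(walk(child, path_resp * r[:, k]))
        return out

    cols = walk(tree.root, np.ones(X.shape[0]))
    post = np.column_stack(cols)
    return post / post.sum(axis=1, keepdims=True)


def _pearson_chisq(table: np.ndarray) -> float:
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (table - expected) ** 2 / expected
    return float(np.nansum(terms))


def permutation_chisq(classes, phenotype, B: int = 10000, seed: int = 0) -> tuple[float, float]:
    """Pearson chi-square of the class x phenotype table with a
    label-permutation reference: p = (1 + #{null >= observed}) / (1 + B)."""
    cls, _ = pd.factorize(np.asarray(classes))
    ph, ph_levels = pd.factorize(np.asarray(phenotype))
    K, L = cls.max() + 1, ph.max() + 1
    if K < 2:
        raise ValidationError("need at least 2 classes")
    if L < 2:
        raise ValidationError("phenotype is constant (degenerate table)")
    idx = cls * L + ph
    observed = _pearson_chisq(np.bincount(idx, minlength=K * L).reshape(K, L).astype(float))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        perm = rng.permutation(ph)
        tab = np.bincount(cls * L + perm, minlength=K * L).reshape(K, L).astype(float)
        if _pearson_chisq(tab) >= observed - 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + B)
    return observed, p


def class_auc(tree: RPMMTree, j: int, k: int, grid_points: int = 10001) -> float:
    """AUC of locus j for separating leaf k from the pooled other leaves.

    The complement distribution G_jk is a normal moment-matched to the
    prevalence-weighted mixture of the other leaves' fitted betas at
    locus j, truncated to [0, 1] and renormalised; the class-k survival
    function is integrated against it on a uniform grid, and the result is
    folded to max(AUC, 1 - AUC).
    """
    if tree.n_leaves < 2:
        raise ValidationError("AUC undefined for a single-leaf tree")
    masses = np.array([lp["mass"] for lp in tree.leaf_params])
    others = [i for i in range(tree.n_leaves) if i != k]
    wts = masses[others] / masses[others].sum()
    mus = np.array(
        [tree.leaf_params[i]["a"][j] / (tree.leaf_params[i]["a"][j] + tree.leaf_params[i]["b"][j])
         for i in others]
    )
    vars_ = np.array(
        [
            tree.leaf_params[i]["a"][j] * tree.leaf_params[i]["b"][j]
            / ((tree.leaf_params[i]["a"][j] + tree.leaf_params[i]["b"][j]) ** 2
               * (tree.leaf_params[i]["a"][j] + tree.leaf_params[i]["b"][j] + 1.0))
            for i in others
        ]
    )
    mu = float(wts @ mus)
    var = float(wts @ (vars_ + mus**2) - mu**2)
    sd = max(np.sqrt(max(var, 0.0)), 1e-6)

    grid = np.linspace(0.0, 1.0, grid_points)
    g = stats.norm.pdf(grid, mu, sd)
    Z = np.trapezoid(g, grid)
    if Z <= 0:
        return 0.5
    g = g / Z
    a_k, b_k = tree.leaf_params[k]["a"][j], tree.leaf_params[k]["b"][j]
    sf_k = stats.beta.sf(grid, a_k, b_k)  # P(X_k > t)
    auc = float(np.trapezoid(sf_k * g, grid))
    return max(auc, 1.0 - auc)


def _class_auc_vector(tree: RPMMTree, k: int, grid_points: int) -> np.ndarray:
    """AUC_jk for every locus at once (same construction as class_auc)."""
    masses = np.array([lp["mass"] for lp in tree.leaf_params])
    others = [i for i in range(tree.n_leaves) if i != k]
    wts = masses[others] / masses[others].sum()
    a_o = np.stack([tree.leaf_params[i]["a"] for i in others])  # (O, J)
    b_o = np.stack([tree.leaf_params[i]["b"] for i in others])
    mus = a_o / (a_o + b_o)
    var_o = a_o * b_o / ((a_o + b_o) ** 2 * (a_o + b_o + 1.0))
    mu = wts @ mus
    var = wts @ (var_o + mus**2) - mu**2
    sd = np.maximum(np.sqrt(np.maximum(var, 0.0)), 1e-6)

    grid = np.linspace(0.0, 1.0, grid_points)[:, None]
    z = (grid - mu[None, :]) / sd[None, :]
    g = np.exp(-0.5 * z**2) / (sd[None, :] * np.sqrt(2.0 * np.pi))
    Z = np.trapezoid(g, axis=0, dx=1.0 / (grid_points - 1))
    g = g / np.maximum(Z, 1e-300)
    sf_k = 1.0 - betainc(
        tree.leaf_params[k]["a"][None, :], tree.leaf_params[k]["b"][None, :], grid
    )
    auc = np.trapezoid(sf_k * g, axis=0, dx=1.0 / (grid_points - 1))
    return np.maximum(auc, 1.0 - auc)


def rank_loci_by_auc(tree: RPMMTree, grid_points: int = 10001) -> pd.DataFrame:
    """Per-locus AUC_jk for every leaf plus the max over leaves.

    Columns: one AUC column per leaf (``auc_leaf<i>``), ``auc_max`` and
    ``best_leaf``.  Thresholding (0.75 for the intersection rule, 0.90 for
    within-model ranking) is left to the caller.
    """
    if tree.n_leaves < 2:
        raise ValidationError("AUC ranking undefined for a single-leaf tree")
    cols = {}
    for k in range(tree.n_leaves):
        cols[f"auc_leaf{k}"] = _class_auc_vector(tree, k, grid_points)
    out = pd.DataFrame(cols, index=pd.Index(tree.locus_ids, name="locus"))
    mat = out.to_numpy()
    out["auc_max"] = mat.max(axis=1)
    out["best_leaf"] = mat.argmax(axis=1)
    return out


class RPMM:
    """Recursively partitioned beta-mixture model of a beta matrix."""

    def __init__(self, beta, min_split_mass: float = 8.0, max_depth: int = 6):
        self.beta = beta
        self.min_split_mass = min_split_mass
        self.max_depth = max_depth

    def fit(self, seed: int = 0) -> "RPMMResults":
        tree = recursive_partition(
            self.beta, seed=seed, min_split_mass=self.min_split_mass,
            max_depth=self.max_depth,
        )
        return RPMMResults(model=self, tree=tree)


@dataclass
class RPMMResults:
    """Fitted RPMM: the tree, memberships, and the AUC locus ranking."""

    model: RPMM
    tree: RPMMTree
    _auc: pd.DataFrame | None = None

    @property
    def assignment(self) -> np.ndarray:
        return self.tree.assignment

    @property
    def n_classes(self) -> int:
        return self.tree.n_leaves

    def membership(self) -> np.ndarray:
        return self.tree.leaf_posterior

    def auc_ranking(self) -> pd.DataFrame:
        if self._auc is None:
            self._auc = rank_loci_by_auc(self.tree)
        return self._auc

    def phenotype_test(self, phenotype, B: int = 10000, seed: int = 0):
        return permutation_chisq(self.assignment, phenotype, B=B, seed=seed)

    def class_of_interest(self, phenotype) -> int:
        """Leaf with the highest (soft) prevalence of the phenotype."""
        return int(np.argmax(self.tree.leaf_prevalence(np.asarray(phenotype))))

    def summary(self) -> str:
        masses = [f"{lp['name']}: {lp['mass']:.1f}" for lp in self.tree.leaf_params]
        return (
            f"RPMM fit: {self.n_classes} methylation classes "
            f"(effective sizes {', '.join(masses)})"
        )

    def plot_class_heatmap(self, ax=None):
        from .plot import plot_class_heatmap

        return plot_class_heatmap(self, ax=ax)
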