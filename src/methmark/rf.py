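"""Random-forest screen: mtry tuning, OOB permutation test, importance.

A bagged ensemble of regression trees (per-split random subspace of size
m) is grown on y in {0, 1}.  Keeping the response numeric lets the
out-of-bag (OOB) error double as both a misclassification rate (threshold
the averaged OOB prediction at 0.5) and a mean-squared error, and lets
variable importance be reported as *percent increase in OOB MSE* when a
locus is permuted — the classical regression-forest importance.

The bespoke content here is the tuning loop over the mtry grid
[ceil(sqrt(M)/2), floor(2*sqrt(M))], the label-permutation null for the
OOB error, and the strict importance thresholding; the tree learner is
scikit-learn's, with bootstrap and OOB bookkeeping handled locally so the
per-tree OOB indices are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .datatypes import ValidationError

__all__ = [
    "RFConfig",
    "BaggedForest",
    "mtry_grid",
    "tune_mtry",
    "oob_permutation_test",
    "select_important",
    "external_error",
    "RandomForestScreen",
    "RFScreenResults",
]


@dataclass
class RFConfig:
    """Knobs of the random-forest screen.

    ``importance_cut`` is in percent change of OOB MSE; the discovery
    pipeline's default is 6 (the intersection rule), with 5 the
    within-screen reporting alternative.  ``max_grid_points`` thins the
    mtry grid to at most that many evenly spaced values.
    """

    n_trees: int = 500
    m: int | None = None
    n_perm: int = 100
    importance_cut: float = 6.0
    max_grid_points: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")


def mtry_grid(M: int, max_points: int | None = None) -> np.ndarray:
    """Candidate mtry values: [ceil(sqrt(M)/2), floor(2*sqrt(M))] inclusive,
    clipped to [1, M]; optionally thinned to ``max_points`` evenly spaced
    values (endpoints kept)."""
    if M < 1:
        raise ValidationError("M must be >= 1")
    r = np.sqrt(M)
    lo = max(1, int(np.ceil(r / 2.0)))
    hi = min(M, int(np.floor(2.0 * r)))
    hi = max(hi, lo)
    grid = np.arange(lo, hi + 1)
    if max_points is not None and len(grid) > max_points:
        idx = np.unique(np.round(np.linspace(0, len(grid) - 1, max_points)).astype(int))
        grid = grid[idx]
    return grid


def _misclassification(pred: np.ndarray, y: np.ndarray) -> float:
    err = ((pred > 0.5).astype(float) != y).astype(float)
    err[pred == 0.5] = 0.5
    return float(err.mean())


class BaggedForest:
    """Bagged regression trees with explicit bootstrap/OOB bookkeeping."""

    def __init__(self, n_trees: int, m: int, seed: int = 0):
        self.n_trees = n_trees
        self.m = m
        self.seed = seed
        self.trees: list[DecisionTreeRegressor] = []
        self.oob_masks: list[np.ndarray] = []
        self._y = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedForest":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=float)
        n = len(y)
        rng = np.random.default_rng(self.seed)
        self.trees, self.oob_masks = [], []
        self._y = y
        m = min(self.m, X.shape[1])
        for t in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            tree = DecisionTreeRegressor(
                max_features=m, random_state=int(rng.integers(0, 2**31 - 1))
            )
            tree.fit(X[idx], y[idx])
            self.trees.append(tree)
            self.oob_masks.append(oob)
        self._X = X
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        pred = np.zeros(X.shape[0])
        for tree in self.trees:
            pred += tree.predict(X)
        return pred / len(self.trees)

    def oob_prediction(self) -> np.ndarray:
        n = len(self._y)
        total = np.zeros(n)
        count = np.zeros(n)
        for tree, oob in zip(self.trees, self.oob_masks):
            if oob.any():
                total[oob] += tree.predict(self._X[oob])
                count[oob] += 1
        with np.errstate(invalid="ignore"):
            pred = total / count
        # samples in every bootstrap (rare): fall back to the full forest
        never = count == 0
        if never.any():
            pred[never] = self.predict(self._X[never])
        return pred

    def oob_error(self) -> float:
        """OOB misclassification rate (averaged OOB prediction cut at 0.5;
        a prediction exactly at 0.5 counts half an error, keeping the rate
        invariant under swapping the two class labels)."""
        pred = self.oob_prediction()
        return float(_misclassification(pred, self._y))

    def oob_mse(self) -> float:
        return float(((self.oob_prediction() - self._y) ** 2).mean())

    def importance(self) -> np.ndarray:
        """Permutation importance as percent change in OOB MSE.

        For each tree, the OOB MSE is recomputed with one feature's OOB
        values shuffled; per-tree baseline and permuted MSEs are averaged
        over the forest first, and the importance of feature j is
        100 * (mean permuted MSE_j - mean base MSE) / mean base MSE.
        Aggregating before taking the ratio keeps the statistic stable on
        trees whose OOB error happens to be zero.
        """
        n_feat = self._X.shape[1]
        rng = np.random.default_rng(self.seed + 1)
        perm_totals = np.zeros(n_feat)
        base_total = 0.0
        n_used = 0
        for tree, oob in zip(self.trees, self.oob_masks):
            n_oob = int(oob.sum())
            if n_oob < 2:
                continue
            Xo = self._X[oob]
            yo = self._y[oob]
            base = float(((tree.predict(Xo) - yo) ** 2).mean())
            base_total += base
            n_used += 1
            used = np.unique(tree.tree_.feature)
            used = used[used >= 0]
            perm = rng.permutation(n_oob)
            perm_totals += base  # unused features leave the prediction as is
            for j in used:
                Xp = Xo.copy()
                Xp[:, j] = Xo[perm, j]
                mse = float(((tree.predict(Xp) - yo) ** 2).mean())
                perm_totals[j] += mse - base
        if n_used == 0:
            return np.zeros(n_feat)
        base_mean = base_total / n_used
        perm_mean = perm_totals / n_used
        denom = max(base_mean, 1e-12)
        return 100.0 * (perm_mean - base_mean) / denom


def tune_mtry(X, y, config: RFConfig) -> tuple[int, dict[int, float]]:
    """Pick the mtry with the lowest OOB misclassification error over the
    grid; ties break toward the smallest m.  Deterministic given the seed."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("phenotype has a single class")
    grid = mtry_grid(X.shape[1], max_points=config.max_grid_points)
    curve: dict[int, float] = {}
    for m in grid:
        forest = BaggedForest(config.n_trees, int(m), seed=config.seed).fit(X, y)
        curve[int(m)] = forest.oob_error()
    best_m = min(curve, key=lambda m: (curve[m], m))
    return best_m, curve


def oob_permutation_test(
    X, y, config: RFConfig, m: int | None = None
) -> tuple[float, np.ndarray, float]:
    """Label-permutation null for the OOB error.

    The observed forest's OOB error is compared with ``n_perm`` forests
    grown on permuted phenotype labels (the tuned m is reused);
    p = (1 + #{null <= observed}) / (1 + n_perm).
    """
    y = np.asarray(y, dtype=float)
    m = m if m is not None else (config.m or max(1, int(np.sqrt(X.shape[1]))))
    observed = BaggedForest(config.n_trees, m, seed=config.seed).fit(X, y).oob_error()
    rng = np.random.default_rng(config.seed + 1000)
    null = np.empty(config.n_perm)
    for b in range(config.n_perm):
        y_perm = rng.permutation(y)
        null[b] = (
            BaggedForest(config.n_trees, m, seed=config.seed + 1 + b)
            .fit(X, y_perm)
            .oob_error()
        )
    p = (1.0 + float((null <= observed).sum())) / (1.0 + config.n_perm)
    return observed, null, p


def select_important(importances, cut: float) -> set:
    """Loci whose percent change in MSE strictly exceeds ``cut``."""
    try:
        items = importances.items()
    except AttributeError:
        items = enumerate(np.asarray(importances))
    return {k for k, v in items if v > cut}


def external_error(forest: BaggedForest, X2, y2) -> float:
    """Misclassification proportion of a fitted forest on a held-out series."""
    pred = forest.predict(np.asarray(X2, dtype=float))
    return _misclassification(pred, np.asarray(y2, dtype=float))


class RandomForestScreen:
    """Random-forest screen of invasive status from average-beta profiles."""

    def __init__(self, beta, invasive, config: RFConfig | None = None):
        try:
            self.locus_ids = list(beta.columns)
            self.X = beta.to_numpy(dtype=float)
        except AttributeError:
            self.X = np.asarray(beta, dtype=float)
            self.locus_ids = list(range(self.X.shape[1]))
        self.y = np.asarray(invasive, dtype=float)
        if len(self.y) != self.X.shape[0]:
            raise ValidationError("phenotype length != number of samples")
        self.config = config or RFConfig()

    def fit(self, run_permutation_test: bool = False) -> "RFScreenResults":
        cfg = self.config
        best_m, curve = tune_mtry(self.X, self.y, cfg)
        forest = BaggedForest(cfg.n_trees, best_m, seed=cfg.seed).fit(self.X, self.y)
        imp = forest.importance()
        importances = dict(zip(self.locus_ids, imp))
        observed = forest.oob_error()
        null = p = None
        if run_permutation_test:
            observed, null, p = oob_permutation_test(self.X, self.y, cfg, m=best_m)
        return RFScreenResults(
            model=self,
            forest=forest,
            best_m=best_m,
            oob_curve=curve,
            oob_error=observed,
            importances=importances,
            null_oob=null,
            permutation_p=p,
        )


@dataclass
class RFScreenResults:
    """Fitted screen: tuned mtry, OOB error, importances, optional null."""

    model: RandomForestScreen
    forest: BaggedForest
    best_m: int
    oob_curve: dict
    oob_error: float
    importances: dict
    null_oob: np.ndarray | None = None
    permutation_p: float | None = None
    external_err: float | None = None

    def select(self, cut: float | None = None) -> set:
        cut = self.model.config.importance_cut if cut is None else cut
        return select_important(self.importances, cut)

    def validate_external(self, beta2, y2) -> float:
        X2 = beta2.to_numpy(dtype=float) if hasattr(beta2, "to_numpy") else beta2
        self.external_err = external_error(self.forest, X2, y2)
        return self.external_err

    def summary(self) -> str:
        lines = [
            "Random-forest screen",
            f"  tuned mtry: {self.best_m}   OOB error: {self.oob_error:.3f}",
            f"  loci above importance cut "
            f"({self.model.config.importance_cut}% MSE): {len(self.select())}",
        ]
        if self.permutation_p is not None:
            lines.append(f"  permutation p (OOB vs {len(self.null_oob)} nulls): "
                         f"{self.permutation_p:.4g}")
        if self.external_err is not None:
            lines.append(f"  external validation error: {self.external_err:.3f}")
        return "\n".join(lines)
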