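"""Confirmation-series statistics on pyrosequencing percent methylation.

Covers the validation arm of the study: Spearman correlation between
adjacent CpG sites, per-sample gene means, Kruskal-Wallis and (protected)
Wilcoxon rank-sum comparisons across grade/stage groups, dichotomisation
of methylation extent at the median, 2x2 odds ratios with Woolf
confidence intervals, multivariable logistic regression (Wald CIs),
the all-three-genes additive exposure, the tumor-cell-fraction
sensitivity refit, and the Pfaffl efficiency-corrected qPCR fold change.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import ValidationError, validate_pyro_table

__all__ = [
    "site_correlations",
    "gene_mean",
    "kruskal_wallis",
    "ranksum",
    "RankSumResult",
    "dichotomize_median",
    "TwoByTwo",
    "or_from_2x2",
    "logistic_fit",
    "LogisticFit",
    "SeparationError",
    "additive_score",
    "tumor_fraction_sensitivity",
    "pfaffl_fold_change",
    "percent_cells",
]


def site_correlations(table: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Spearman rank-correlation matrix between the CpG sites of a gene."""
    validate_pyro_table(table)
    wide = (
        table[table["gene"] == gene]
        .pivot(index="sample_id", columns="site", values="percent")
        .sort_index(axis=1)
    )
    if wide.shape[1] == 0:
        raise ValidationError(f"no sites for gene {gene!r}")
    return wide.corr(method="spearman")


def gene_mean(table: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Per-sample mean percent methylation across a gene's observed sites.

    Missing sites are averaged over; ``n_sites`` records how many sites
    contributed for each sample.
    """
    validate_pyro_table(table)
    sub = table[table["gene"] == gene]
    if sub.empty:
        raise ValidationError(f"no rows for gene {gene!r}")
    g = sub.groupby("sample_id")["percent"]
    return pd.DataFrame({"mean_percent": g.mean(), "n_sites": g.count()})


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square(k-1) p-value."""
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.array_equal(arrays[0], arr) for arr in arrays[1:]):
        return 0.0, 1.0
    try:
        h, p = stats.kruskal(*arrays)
    except ValueError:  # all values identical across groups
        return 0.0, 1.0
    return float(h), float(p)


@dataclass
class RankSumResult:
    W: float | None
    p: float | None
    tested: bool = True
    exact: bool = False

    def __iter__(self):
        return iter((self.W, self.p))


def _ranksum_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exhaustive-enumeration two-sided rank-sum p (handles ties via midranks)."""
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    na = len(a)
    w_obs = float(ranks[:na].sum())
    mu = na * (len(combined) + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(combined)), na):
        w = float(ranks[list(comb)].sum())
        total += 1
        if abs(w - mu) >= dev_obs - 1e-9:
            count += 1
    return w_obs, count / total


def ranksum(a, b, protected_by: float | None = None, alpha: float = 0.05) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Uses exhaustive enumeration when min(n) <= 8, otherwise the normal
    approximation with tie correction and continuity correction.  When
    ``protected_by`` (an upstream Kruskal-Wallis p) is given, the
    comparison is only carried out if that p is below ``alpha``
    (a protected rank-sum test); otherwise ``tested`` is False.
    """
    if protected_by is not None and not protected_by < alpha:
        return RankSumResult(W=None, p=None, tested=False)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be nonempty")
    na, nb = len(a), len(b)
    if min(na, nb) <= 8 and max(na, nb) <= 12:
        w, p = _ranksum_exact(a, b)
        return RankSumResult(W=w, p=p, exact=True)
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    w = float(ranks[:na].sum())
    N = na + nb
    mu = na * (N + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1))
    var = na * nb / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return RankSumResult(W=w, p=1.0)
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return RankSumResult(W=w, p=min(p, 1.0))


def dichotomize_median(values) -> np.ndarray:
    """Binary exposure coding: 1 ('positive') iff strictly above the median
    of the analysed series; values at or below the median are 0."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("empty vector")
    return (v > np.median(v)).astype(int)


@dataclass
class TwoByTwo:
    """Exposure x outcome counts.

    ``a`` unexposed controls, ``b`` unexposed cases, ``c`` exposed
    controls, ``d`` exposed cases (cases = e.g. invasive tumors).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("counts must be nonnegative")
        arr = np.array([[self.a, self.b], [self.c, self.d]])
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            raise ValidationError("all 2x2 margins must be positive")


def or_from_2x2(t: TwoByTwo) -> tuple[float, tuple[float, float], bool]:
    """Cross-product odds ratio with Woolf (log-scale) 95% CI.

    A 0.5 continuity correction is applied to every cell iff any cell is
    zero; the returned flag says whether it was.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (d * a) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(orr) - 1.96 * se), np.exp(np.log(orr) + 1.96 * se)
    return float(orr), (float(lo), float(hi)), corrected


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE diverges."""


@dataclass
class LogisticFit:
    """Per-covariate logistic-regression estimates with Wald intervals."""

    params: pd.Series
    se: pd.Series
    odds_ratios: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    converged: bool
    llf: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.se,
                "OR": self.odds_ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def summary(self) -> str:
        return self.table().to_string(float_format=lambda v: f"{v:.3f}")


def logistic_fit(outcome, covariates: pd.DataFrame) -> LogisticFit:
    """Unconditional multivariable logistic regression (ML via IRLS/Newton,
    convergence 1e-8, at most 100 iterations) with Wald 95% CIs.

    Raises :class:`SeparationError` when the data are perfectly separated.
    """
    y = np.asarray(outcome, dtype=float)
    X = sm.add_constant(pd.DataFrame(covariates).astype(float), has_constant="add")
    try:
        res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100, tol=1e-8)
    except Exception as exc:  # statsmodels raises PerfectSeparationError or LinAlgError
        raise SeparationError(str(exc)) from exc
    if not res.mle_retvals.get("converged", True) or np.max(np.abs(res.params)) > 25:
        raise SeparationError("perfect separation detected (diverging coefficients)")
    params = pd.Series(res.params, index=X.columns)
    se = pd.Series(res.bse, index=X.columns)
    return LogisticFit(
        params=params,
        se=se,
        odds_ratios=np.exp(params),
        ci_low=np.exp(params - 1.96 * se),
        ci_high=np.exp(params + 1.96 * se),
        converged=True,
        llf=float(res.llf),
    )


def additive_score(gene_dichotomies: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Indicator of methylation above the median at *all three* genes
    (vs none, 1, or 2); feeds the additive logistic model."""
    arr = np.asarray(gene_dichotomies, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValidationError("expect exactly three gene dichotomies")
    return (arr.sum(axis=1) == 3).astype(int)


def tumor_fraction_sensitivity(
    outcome, covariates: pd.DataFrame, tumor_percent, collinearity_r: float = 0.999
) -> dict:
    """Refit the logistic model with a tumor-cell-percentage covariate and
    report the per-coefficient deltas; flags collinearity with any exposure."""
    covariates = pd.DataFrame(covariates).astype(float)
    tp = np.asarray(tumor_percent, dtype=float)
    flags = {}
    for col in covariates.columns:
        x = covariates[col].to_numpy()
        if np.std(x) > 0 and np.std(tp) > 0:
            r = abs(np.corrcoef(x, tp)[0, 1])
            if r > collinearity_r:
                flags[col] = r
    if np.std(tp) == 0:
        flags["tumor_percent"] = 1.0
    if flags:
        return {"collinear": flags, "deltas": None, "base": None, "adjusted": None}
    base = logistic_fit(outcome, covariates)
    adj = logistic_fit(outcome, covariates.assign(tumor_percent=tp))
    deltas = (adj.params.drop("tumor_percent") - base.params).to_dict()
    return {"collinear": {}, "deltas": deltas, "base": base, "adjusted": adj}


def pfaffl_fold_change(
    e_target: float, dct_target: float, e_ref: float, dct_ref: float
) -> float:
    """Efficiency-corrected relative expression ratio
    E_target^dCt(target) / E_ref^dCt(ref), dCt = Ct(control) - Ct(treated)."""
    if e_target <= 0 or e_ref <= 0:
        raise ValidationError("amplification efficiencies must be positive")
    return float(e_target**dct_target / e_ref**dct_ref)


def percent_cells(counts) -> np.ndarray:
    """Row percentages rounded to integers (round-half-even, the rounding
    that matches the demographic and odds-ratio tables' printed cells)."""
    arr = np.asarray(counts, dtype=float)
    row_tot = arr.sum(axis=-1, keepdims=True)
    return np.round(100.0 * arr / row_tot).astype(int)
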