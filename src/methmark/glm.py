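"""Locus-by-locus quasi-binomial screen of average beta vs invasive status.

Average beta values are proportions, so each locus is modelled with a
quasi-binomial GLM: logit link, binomial variance, and a free (non-unit)
scale parameter estimated from the Pearson chi-square.  With a single
binary covariate the fit is saturated — the fitted group means equal the
observed group means and the slope is exactly the difference of the
group-mean logits — so the whole screen is computed in closed form,
vectorised across loci.  The two-sided p-value uses a t reference with
n - 2 degrees of freedom and the Pearson dispersion, matching standard
quasi-likelihood practice.

Multiple testing across loci is handled with Storey q-values (pi0
estimated over a lambda grid with a cubic-smoother extrapolation); the
pi0 = 1 mode reduces exactly to Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.special import logit

from .datatypes import MethylationMatrix, ValidationError

__all__ = [
    "fit_quasibinomial",
    "compute_qvalues",
    "count_significant",
    "hcluster",
    "LocusGLMScreen",
    "LocusGLMResults",
    "EPS",
]

#: beta values are clamped to [EPS, 1-EPS] before the logit link
EPS = 1e-6


def _screen_arrays(beta: np.ndarray, invasive: np.ndarray):
    """Vectorised saturated quasi-binomial fit for every locus (column).

    Returns (slope, dispersion, p, degenerate flag) arrays.
    """
    y = np.clip(beta, EPS, 1.0 - EPS)
    g1 = invasive.astype(bool)
    g0 = ~g1
    n0, n1 = int(g0.sum()), int(g1.sum())
    if n0 == 0 or n1 == 0:
        raise ValidationError("both invasive and non-invasive groups must be nonempty")
    n = n0 + n1
    m0 = y[g0].mean(axis=0)
    m1 = y[g1].mean(axis=0)
    slope = logit(m1) - logit(m0)

    mu = np.where(g1[:, None], m1[None, :], m0[None, :])
    resid2 = (y - mu) ** 2 / (mu * (1.0 - mu))
    x2 = resid2.sum(axis=0)
    df = n - 2
    dispersion = x2 / df

    var_slope = dispersion * (1.0 / (n0 * m0 * (1.0 - m0)) + 1.0 / (n1 * m1 * (1.0 - m1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / np.sqrt(var_slope)
    p = 2.0 * stats.t.sf(np.abs(t), df)

    # degenerate loci: zero residual variation (all values identical, or a
    # group at a boundary with no variance); conservative rule slope 0, p 1
    # when the groups agree, p 0 when a perfect-fit separation remains
    degenerate = x2 <= 0
    same = degenerate & (np.abs(slope) < 1e-12)
    p = np.where(degenerate, np.where(same, 1.0, 0.0), p)
    slope = np.where(same, 0.0, slope)
    return slope, dispersion, p, degenerate


def fit_quasibinomial(beta_j, invasive) -> tuple[float, float, float]:
    """Quasi-binomial fit of one locus against a binary phenotype.

    Returns ``(slope, dispersion, p)``: the invasive-vs-non-invasive
    log-odds difference of mean beta, the Pearson dispersion (chi-square /
    (n-2)), and the two-sided t(n-2) p-value.
    """
    beta_j = np.asarray(beta_j, dtype=float).reshape(-1, 1)
    invasive = np.asarray(invasive)
    slope, dispersion, p, _ = _screen_arrays(beta_j, invasive)
    return float(slope[0]), float(dispersion[0]), float(p[0])


def compute_qvalues(p, pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    pi0 (the null proportion) is estimated over lambda = 0.05..0.95 step
    0.05 with a cubic polynomial smoother evaluated at the largest lambda,
    clipped to (0, 1].  Passing ``pi0=1`` reduces exactly to
    Benjamini-Hochberg.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
        pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
        if m < 100 or p.min() >= lambdas[-1]:
            pi0 = 1.0
        else:
            coef = np.polyfit(lambdas, pi0_l, 3)
            pi0 = float(np.polyval(coef, lambdas[-1]))
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m * pi0 / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def count_significant(table: pd.DataFrame, q_cut: float = 0.05) -> tuple[int, int]:
    """(n hypermethylated, n hypomethylated) at q < q_cut, split by slope sign."""
    sig = table["q"] < q_cut
    n_up = int((sig & (table["slope"] > 0)).sum())
    n_down = int((sig & (table["slope"] < 0)).sum())
    return n_up, n_down


def hcluster(m: MethylationMatrix | pd.DataFrame) -> np.ndarray:
    """Exploratory hierarchical clustering of samples: Manhattan metric,
    average linkage.  Returns a scipy linkage matrix."""
    beta = m.beta if isinstance(m, MethylationMatrix) else m
    if beta.shape[0] < 2:
        raise ValidationError("need at least two samples to cluster")
    return linkage(beta.to_numpy(), method="average", metric="cityblock")


class LocusGLMScreen:
    """Locus-wise quasi-binomial screen model.

    Parameters
    ----------
    beta : DataFrame or MethylationMatrix
        Samples x loci average-beta values.
    invasive : array-like of 0/1
        Phenotype, aligned to the rows of ``beta``.
    """

    def __init__(self, beta, invasive):
        if isinstance(beta, MethylationMatrix):
            beta = beta.beta
        self.beta = beta
        self.invasive = np.asarray(invasive)
        if len(self.invasive) != beta.shape[0]:
            raise ValidationError("phenotype length != number of samples")

    @classmethod
    def from_cohort(cls, matrix: MethylationMatrix, sheet: pd.DataFrame):
        return cls(matrix.beta, sheet.loc[matrix.beta.index, "invasive"].to_numpy())

    def fit(self, pi0: float | None = None) -> "LocusGLMResults":
        slope, disp, p, degen = _screen_arrays(self.beta.to_numpy(dtype=float), self.invasive)
        q = compute_qvalues(p, pi0=pi0)
        table = pd.DataFrame(
            {
                "slope": slope,
                "dispersion": disp,
                "p": p,
                "q": q,
                "direction": np.where(slope > 0, "+", np.where(slope < 0, "-", "0")),
                "degenerate": degen,
            },
            index=self.beta.columns.rename("locus"),
        )
        return LocusGLMResults(self, table)


@dataclass
class LocusGLMResults:
    """Fitted locus-wise screen: per-locus slope, dispersion, p and q."""

    model: LocusGLMScreen
    table: pd.DataFrame

    def count_significant(self, q_cut: float = 0.05) -> tuple[int, int]:
        return count_significant(self.table, q_cut=q_cut)

    def significant_loci(self, q_cut: float = 0.05) -> pd.Index:
        return self.table.index[self.table["q"] < q_cut]

    def summary(self, q_cut: float = 0.05) -> str:
        n_up, n_down = self.count_significant(q_cut)
        lines = [
            "Locus-wise quasi-binomial screen",
            f"  samples: {self.beta_shape[0]}   loci: {self.beta_shape[1]}",
            f"  significant at q<{q_cut:g}: {n_up} hypermethylated, "
            f"{n_down} hypomethylated",
            "",
            self.table.sort_values("q").head(10).to_string(),
        ]
        return "\n".join(lines)

    @property
    def beta_shape(self):
        return self.model.beta.shape

    def plot_invasive_scatter(self, ax=None):
        from .plot import plot_invasive_scatter

        return plot_invasive_scatter(self.model.beta, self.model.invasive, ax=ax)
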