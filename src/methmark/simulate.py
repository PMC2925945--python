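"""Synthetic GoldenGate-style cohorts and pyrosequencing tables.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without any external data:

* per-locus average-beta values drawn from beta distributions, optionally
  with latent sample classes (per-class per-locus shape parameters);
* a subset of loci differentially methylated by invasive status, with
  invasive tumors shifted upward — mimicking the general hypermethylation
  of invasive disease on the array;
* detection p-values with a configurable per-sample failure rate
  (passing measurements ~ Uniform(0, 1e-6), failures ~ Uniform(1e-5, 1),
  matching the operating points of the two QC thresholds);
* covariates (age, gender, TP53 IHC intensity) associated with
  invasiveness — TP53-high is sampled with a configurable odds ratio
  given invasive status so confounding-adjustment can be exercised;
* pyrosequencing percent-methylation tables with correlated adjacent CpG
  sites, generated through a Gaussian copula so the between-site Spearman
  correlation is tunable while values stay in [0, 100].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MethylationMatrix, ValidationError

__all__ = [
    "CohortConfig",
    "PyroConfig",
    "Cohort",
    "generate_cohort",
    "generate_pyro_table",
    "two_series_configs",
    "write_cohort",
]

_AUTOSOMES = [str(c) for c in range(1, 23)]


def _mean_precision_to_ab(mean: np.ndarray, precision: float | np.ndarray):
    """Convert (mean, precision) to beta shapes a = mu*s, b = (1-mu)*s."""
    mean = np.clip(np.asarray(mean, dtype=float), 1e-3, 1 - 1e-3)
    a = mean * precision
    b = (1.0 - mean) * precision
    return a, b


@dataclass
class CohortConfig:
    """Configuration of a synthetic array cohort.

    Beta parameters may be given explicitly per class and locus via ``a``
    and ``b`` (arrays of shape (n_classes, n_loci)), or compactly via
    per-locus baseline means plus a precision; in the compact scheme the
    optional ``class_mean_shift`` (n_classes, n_loci) offsets class means.

    ``differential_loci`` are shifted upward (or downward, for negative
    shifts) by ``differential_shift`` in invasive samples only.
    """

    n_samples: int = 150
    n_loci: int = 300
    n_classes: int = 1
    class_weights: np.ndarray | None = None
    a: np.ndarray | None = None
    b: np.ndarray | None = None
    locus_means: np.ndarray | None = None
    precision: float = 20.0
    class_mean_shift: np.ndarray | None = None
    invasive_fraction: float = 0.4
    class_invasive_fraction: np.ndarray | None = None
    frac_differential: float = 0.0
    differential_loci: np.ndarray | None = None
    differential_shift: float | np.ndarray = 0.12
    detection_fail_rate: float | np.ndarray = 0.0
    frac_sex_loci: float = 0.0
    tp53_odds_ratio: float = 7.0
    tp53_baseline_prob: float = 0.15
    male_fraction: float = 0.75
    age_mean: float = 63.0
    age_sd: float = 9.5
    age_invasive_shift: float = 2.0
    series: str = "series1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValidationError("n_classes must be >= 1")
        if self.class_weights is None:
            self.class_weights = np.full(self.n_classes, 1.0 / self.n_classes)
        self.class_weights = np.asarray(self.class_weights, dtype=float)
        if len(self.class_weights) != self.n_classes:
            raise ValidationError("class_weights length != n_classes")
        if (self.class_weights < 0).any() or abs(self.class_weights.sum() - 1.0) > 1e-9:
            raise ValidationError("class_weights must be a simplex vector")
        if self.a is not None or self.b is not None:
            self.a = np.atleast_2d(np.asarray(self.a, dtype=float))
            self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
            if self.a.shape != (self.n_classes, self.n_loci) or self.b.shape != self.a.shape:
                raise ValidationError("a/b must have shape (n_classes, n_loci)")
            if (self.a <= 0).any() or (self.b <= 0).any():
                raise ValidationError("beta parameters must be strictly positive")
        if not 0.0 <= self.invasive_fraction <= 1.0:
            raise ValidationError("invasive_fraction must be in [0, 1]")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ValidationError("frac_differential must be in [0, 1]")
        if self.differential_loci is not None:
            self.differential_loci = np.asarray(self.differential_loci, dtype=int)
            if len(self.differential_loci) and (
                self.differential_loci.min() < 0
                or self.differential_loci.max() >= self.n_loci
            ):
                raise ValidationError("differential loci must be a subset of loci")

    def beta_params(self, rng: np.random.Generator):
        """Per-class per-locus beta shapes (a_kj, b_kj), each (K, J)."""
        if self.a is not None:
            return self.a, self.b
        if self.locus_means is not None:
            means = np.asarray(self.locus_means, dtype=float)
            if means.shape != (self.n_loci,):
                raise ValidationError("locus_means must have length n_loci")
        else:
            # bimodal baseline typical of promoter CpG panels: mostly
            # unmethylated loci with a methylated minority
            hi = rng.random(self.n_loci) < 0.25
            means = np.where(
                hi, rng.beta(8.0, 3.0, self.n_loci), rng.beta(1.8, 9.0, self.n_loci)
            )
        means = np.tile(means, (self.n_classes, 1))
        if self.class_mean_shift is not None:
            means = means + np.asarray(self.class_mean_shift, dtype=float)
        return _mean_precision_to_ab(means, self.precision)


@dataclass
class Cohort:
    """A generated cohort: the array substrate, the sample sheet, and the
    hidden truth (latent classes, differential loci) used only by tests."""

    matrix: MethylationMatrix
    sheet: pd.DataFrame
    truth: dict


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a synthetic cohort; identical config and seed give identical output."""
    rng = np.random.default_rng(config.seed)
    n, J = config.n_samples, config.n_loci

    classes = rng.choice(config.n_classes, size=n, p=config.class_weights)
    if config.class_invasive_fraction is not None:
        p_inv = np.asarray(config.class_invasive_fraction, dtype=float)[classes]
    else:
        p_inv = np.full(n, config.invasive_fraction)
    invasive = (rng.random(n) < p_inv).astype(int)

    a, b = config.beta_params(rng)
    means = a / (a + b)
    precision = a + b
    sample_means = means[classes]  # (n, J)
    sample_prec = np.broadcast_to(precision[classes], sample_means.shape).copy()

    if config.differential_loci is not None:
        diff = config.differential_loci
    elif config.frac_differential > 0:
        n_diff = int(round(config.frac_differential * J))
        diff = rng.choice(J, size=n_diff, replace=False)
    else:
        diff = np.array([], dtype=int)
    shift = np.broadcast_to(np.asarray(config.differential_shift, dtype=float), diff.shape)
    inv_mask = invasive.astype(bool)
    if len(diff):
        shifted = sample_means[np.ix_(inv_mask, diff)] + shift
        sample_means[np.ix_(inv_mask, diff)] = np.clip(shifted, 1e-3, 1 - 1e-3)

    aa = sample_means * sample_prec
    bb = (1.0 - sample_means) * sample_prec
    beta_vals = rng.beta(aa, bb)

    fail_rate = np.broadcast_to(
        np.asarray(config.detection_fail_rate, dtype=float), (n,)
    )
    fails = rng.random((n, J)) < fail_rate[:, None]
    detp = rng.uniform(0.0, 1e-6, size=(n, J))
    detp[fails] = rng.uniform(1e-5, 1.0, size=int(fails.sum()))

    sample_ids = [f"{config.series}_S{i:04d}" for i in range(n)]
    locus_ids = [f"L{j:04d}" for j in range(J)]
    n_sex = int(round(config.frac_sex_loci * J))
    chroms = list(rng.choice(_AUTOSOMES, size=J - n_sex)) + list(
        rng.choice(["X", "Y"], size=n_sex)
    )
    genes = [f"GENE{j:04d}" for j in range(J)]
    annotation = pd.DataFrame(
        {"gene": genes, "chromosome": chroms}, index=pd.Index(locus_ids, name="locus")
    )

    matrix = MethylationMatrix(
        beta=pd.DataFrame(beta_vals, index=sample_ids, columns=locus_ids),
        detection_p=pd.DataFrame(detp, index=sample_ids, columns=locus_ids),
        annotation=annotation,
    )

    age = rng.normal(config.age_mean, config.age_sd, n) + config.age_invasive_shift * invasive
    gender = np.where(rng.random(n) < config.male_fraction, "M", "F")
    # TP53-high with configured odds ratio given invasive status
    p0 = config.tp53_baseline_prob
    odds1 = config.tp53_odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    tp53 = (rng.random(n) < np.where(invasive == 1, p1, p0)).astype(int)
    # grade: high grade (3) enriched in invasive tumors
    p_high = np.where(invasive == 1, 0.75, 0.14)
    grade = np.where(rng.random(n) < p_high, 3, rng.integers(1, 3, n))

    sheet = pd.DataFrame(
        {
            "age": np.round(age, 1),
            "gender": gender,
            "invasive": invasive,
            "grade": grade,
            "tp53_high": tp53,
            "series": config.series,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    truth = {
        "classes": classes.tolist(),
        "differential_loci": [locus_ids[j] for j in diff],
        "seed": config.seed,
    }
    return Cohort(matrix=matrix, sheet=sheet, truth=truth)


@dataclass
class PyroConfig:
    """Configuration of a synthetic pyrosequencing percent-methylation table.

    ``group_means`` maps gene -> {group label -> mean percent}; the grouping
    column of the sample sheet is named by ``group_col`` (values are matched
    after applying ``group_of``, by default identity).
    """

    genes: dict = field(default_factory=dict)  # gene -> n CpG sites
    group_col: str = "invasive"
    group_means: dict = field(default_factory=dict)  # gene -> {group: mean}
    site_rho: float = 0.0  # target between-site Spearman correlation
    noise_scale: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.site_rho < 1.0:
            raise ValidationError("site correlation must lie strictly inside (-1, 1)")
        for gene, gm in self.group_means.items():
            for g, m in gm.items():
                if not 0.0 <= m <= 100.0:
                    raise ValidationError(
                        f"group mean {m} for {gene}/{g} outside [0, 100]"
                    )


def generate_pyro_table(config: PyroConfig, sheet: pd.DataFrame) -> pd.DataFrame:
    """Long-format percent-methylation table with correlated adjacent sites.

    Sites within a gene share an equicorrelated Gaussian copula; the latent
    Pearson correlation is chosen as 2*sin(pi*rho_s/6) so the *Spearman*
    correlation between sites matches ``site_rho``.  Marginals are
    mean + noise * z, truncated to [0, 100].
    """
    if not config.genes:
        raise ValidationError("genes must be nonempty")
    if config.group_col not in sheet.columns:
        raise ValidationError(f"sample sheet lacks grouping column {config.group_col!r}")
    rng = np.random.default_rng(config.seed)
    rho_p = 2.0 * np.sin(np.pi * config.site_rho / 6.0)
    rows = []
    groups = sheet[config.group_col]
    for gene, n_sites in config.genes.items():
        gm = config.group_means.get(gene, {})
        cov = np.full((n_sites, n_sites), rho_p)
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(n_sites), cov, size=len(sheet), method="cholesky")
        means = groups.map(lambda g: gm.get(g, 50.0)).to_numpy(dtype=float)[:, None]
        vals = np.clip(means + config.noise_scale * z, 0.0, 100.0)
        for s in range(n_sites):
            for i, sid in enumerate(sheet.index):
                rows.append((sid, gene, s + 1, vals[i, s]))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "site", "percent"])


def two_series_configs(
    seed: int,
    n_series1: int = 80,
    n_series2: int = 150,
    n_loci: int = 300,
    n_spiked: int = 5,
    spiked_noninvasive_mean: float = 0.2,
    spiked_invasive_mean: float = 0.6,
    frac_class_loci: float = 0.4,
    class_shift: float = 0.22,
    class_weights: tuple = (0.6, 0.4),
    class_invasive_fraction: tuple = (0.08, 0.85),
    precision: float = 15.0,
) -> tuple[CohortConfig, CohortConfig]:
    """Two-series discovery scenario mirroring the study's structure.

    A latent hypermethylator class shifts a broad set of loci upward and is
    strongly enriched for invasive tumors — this is what drives the
    mixture-model split and the general invasive hypermethylation seen on
    the array — while a handful of spiked loci are shifted directly by
    invasive status (0.2 -> 0.6) in both series.  Only the spiked loci
    should survive the three-method, two-series intersection: the broad
    class loci are GLM/AUC-positive but carry little forest importance,
    and noise loci pass nothing.
    """
    rng = np.random.default_rng(seed)
    hi = rng.random(n_loci) < 0.25
    locus_means = np.where(hi, rng.beta(8.0, 3.0, n_loci), rng.beta(1.8, 9.0, n_loci))
    spiked = np.arange(n_spiked)
    locus_means[spiked] = spiked_noninvasive_mean
    n_class = int(round(frac_class_loci * n_loci))
    class_loci = rng.permutation(np.arange(n_spiked, n_loci))[:n_class]
    shift = np.zeros((2, n_loci))
    shift[1, class_loci] = class_shift
    common = dict(
        n_loci=n_loci,
        n_classes=2,
        class_weights=np.asarray(class_weights, dtype=float),
        class_invasive_fraction=np.asarray(class_invasive_fraction, dtype=float),
        locus_means=locus_means,
        precision=precision,
        class_mean_shift=shift,
        differential_loci=spiked,
        differential_shift=spiked_invasive_mean - spiked_noninvasive_mean,
    )
    cfg1 = CohortConfig(n_samples=n_series1, series="series1", seed=seed * 2 + 1, **common)
    cfg2 = CohortConfig(n_samples=n_series2, series="series2", seed=seed * 2 + 2, **common)
    return cfg1, cfg2


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the standard pipeline inputs (TSV/CSV) plus a truth sidecar.

    The sidecar (truth.json) is for test harnesses only and is never read
    by the pipeline.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.matrix.beta.to_csv(outdir / "beta.tsv", sep="\t", index_label="sample_id")
    cohort.matrix.detection_p.to_csv(outdir / "detp.tsv", sep="\t", index_label="sample_id")
    cohort.matrix.annotation.to_csv(outdir / "loci.tsv", sep="\t")
    cohort.sheet.to_csv(outdir / "samples.csv")
    (outdir / "truth.json").write_text(json.dumps(cohort.truth, indent=1))
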