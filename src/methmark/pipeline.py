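"""End-to-end two-series discovery pipeline.

Stages run in order qc -> (glm, rf, rpmm) per series -> intersection;
optionally followed by the pyrosequencing validation statistics.  All
randomness flows from one master seed: per-stage seeds are drawn from
``numpy.random.SeedSequence(master).spawn`` in a fixed order (series 1 rf,
series 1 rpmm, series 2 rf, series 2 rpmm, ...), so a rerun with the same
configuration is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import MethylationMatrix, QCReport, ValidationError
from .glm import LocusGLMScreen
from .qc import run_qc
from .rf import RFConfig, RandomForestScreen
from .rpmm import RPMM
from .selection import CandidateSet, SelectionThresholds, SeriesResults, intersect

__all__ = ["PipelineConfig", "SeriesStage", "PipelineResult", "run_pipeline"]


def _stage_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    """Thresholds and sizes for the discovery pipeline."""

    fail_p: float = 1e-5
    sample_fail_frac: float = 0.75
    med_p: float = 0.05
    thresholds: SelectionThresholds = field(default_factory=SelectionThresholds)
    rf: RFConfig = field(default_factory=lambda: RFConfig(n_trees=200, max_grid_points=8))
    rpmm_min_split_mass: float = 8.0
    rpmm_max_depth: int = 6
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load thresholds from a YAML (or JSON) mapping; every key named in
        the analysis (q_cut, importance_cut, auc_cut, fail_p,
        sample_fail_frac, med_p, rf.n_trees, rf.n_perm, seed, ...) defaults
        to its published value when omitted."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = SelectionThresholds(
            q_cut=raw.get("q_cut", 0.05),
            importance_cut=raw.get("importance_cut", 6.0),
            auc_cut=raw.get("auc_cut", 0.75),
        )
        rf_raw = raw.get("rf", {})
        rf = RFConfig(
            n_trees=rf_raw.get("n_trees", 200),
            n_perm=rf_raw.get("n_perm", 100),
            importance_cut=thr.importance_cut,
            max_grid_points=rf_raw.get("max_grid_points", 8),
        )
        return cls(
            fail_p=raw.get("fail_p", 1e-5),
            sample_fail_frac=raw.get("sample_fail_frac", 0.75),
            med_p=raw.get("med_p", 0.05),
            thresholds=thr,
            rf=rf,
            rpmm_min_split_mass=raw.get("rpmm_min_split_mass", 8.0),
            rpmm_max_depth=raw.get("rpmm_max_depth", 6),
            seed=raw.get("seed", 0),
        )


@dataclass
class SeriesStage:
    """Per-series intermediate artifacts."""

    matrix: MethylationMatrix
    qc_report: QCReport
    glm: object
    rf: object
    rpmm: object
    class_of_interest: int
    auc: pd.Series


@dataclass
class PipelineResult:
    series: list
    candidates: CandidateSet
    manifest: dict


def _run_series(matrix, sheet, config: PipelineConfig, ss) -> SeriesStage:
    filtered, report = run_qc(
        matrix, fail_p=config.fail_p, frac=config.sample_fail_frac, med_p=config.med_p
    )
    invasive = sheet.loc[filtered.beta.index, "invasive"].to_numpy()
    glm_res = LocusGLMScreen(filtered.beta, invasive).fit()

    rf_seed, rpmm_seed = ss.spawn(2)
    rf_cfg = RFConfig(
        n_trees=config.rf.n_trees,
        n_perm=config.rf.n_perm,
        importance_cut=config.thresholds.importance_cut,
        max_grid_points=config.rf.max_grid_points,
        seed=_stage_seed(rf_seed),
    )
    rf_res = RandomForestScreen(filtered.beta, invasive, rf_cfg).fit()

    rpmm_res = RPMM(
        filtered.beta,
        min_split_mass=config.rpmm_min_split_mass,
        max_depth=config.rpmm_max_depth,
    ).fit(seed=_stage_seed(rpmm_seed))
    if rpmm_res.n_classes >= 2:
        k = rpmm_res.class_of_interest(invasive)
        auc = rpmm_res.auc_ranking()[f"auc_leaf{k}"]
    else:
        k = 0
        auc = pd.Series(0.5, index=pd.Index(filtered.locus_ids, name="locus"))
    return SeriesStage(
        matrix=filtered,
        qc_report=report,
        glm=glm_res,
        rf=rf_res,
        rpmm=rpmm_res,
        class_of_interest=k,
        auc=auc,
    )


def run_pipeline(
    series: list[tuple[MethylationMatrix, pd.DataFrame]],
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run qc/glm/rf/rpmm on each (matrix, sheet) series, then intersect.

    When ``outdir`` is given, per-series locus tables, the candidate list
    and a manifest (package version, seed, thresholds) are written there.
    """
    config = config or PipelineConfig()
    if len(series) < 1:
        raise ValidationError("need at least one series")
    master = np.random.SeedSequence(config.seed)
    stage_seeds = master.spawn(len(series))
    stages: list[SeriesStage] = []
    for (matrix, sheet), ss in zip(series, stage_seeds):
        stages.append(_run_series(matrix, sheet, config, ss))

    series_results = [
        SeriesResults(
            glm=st.glm.table,
            rf=pd.Series(st.rf.importances).reindex(st.glm.table.index),
            auc=st.auc.reindex(st.glm.table.index),
        )
        for st in stages
    ]
    candidates = intersect(series_results, config.thresholds)

    manifest = {
        "methmark_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "q_cut": config.thresholds.q_cut,
            "importance_cut": config.thresholds.importance_cut,
            "auc_cut": config.thresholds.auc_cut,
            "fail_p": config.fail_p,
            "sample_fail_frac": config.sample_fail_frac,
            "med_p": config.med_p,
        },
        "series": [
            {
                "n_samples": st.matrix.n_samples,
                "n_loci": st.matrix.n_loci,
                "rf_best_m": st.rf.best_m,
                "rf_oob_error": st.rf.oob_error,
                "rpmm_classes": st.rpmm.n_classes,
                "class_of_interest": st.class_of_interest,
            }
            for st in stages
        ],
        "n_candidates": len(candidates.candidates),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, st in enumerate(stages, start=1):
            st.glm.table.to_csv(outdir / f"series{i}_locus_results.tsv", sep="\t")
            (outdir / f"series{i}_qc_report.json").write_text(
                json.dumps(st.qc_report.to_dict(), indent=1)
            )
        candidates.passfail.to_csv(outdir / "candidates.tsv", sep="\t")
        (outdir / "candidates.txt").write_text("\n".join(candidates.candidates) + "\n")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return PipelineResult(series=stages, candidates=candidates, manifest=manifest)
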