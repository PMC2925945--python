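"""The three-approach, two-series intersection rule.

A locus becomes a candidate only if, *within each series independently*,
it passes all three screens — quasi-binomial q < 0.05, random-forest
importance > 6% MSE, and AUC > 0.75 for the invasive-enriched methylation
class — and does so in both series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datatypes import ValidationError

__all__ = ["SelectionThresholds", "CandidateSet", "SeriesResults", "intersect"]


@dataclass(frozen=True)
class SelectionThresholds:
    q_cut: float = 0.05
    importance_cut: float = 6.0  # percent change in MSE
    auc_cut: float = 0.75


@dataclass
class SeriesResults:
    """One series' three screen outputs over a shared locus universe.

    ``glm`` is the locus result table (columns p, q, slope); ``rf`` maps
    locus -> importance (% MSE); ``auc`` maps locus -> AUC of the class of
    interest (the invasive-enriched leaf).
    """

    glm: pd.DataFrame
    rf: pd.Series
    auc: pd.Series

    def universe(self) -> set:
        return set(self.glm.index)

    def check(self) -> None:
        u = self.universe()
        for name, other in (("rf", set(self.rf.index)), ("auc", set(self.auc.index))):
            if other != u:
                diff = sorted(u.symmetric_difference(other))[:10]
                raise ValidationError(
                    f"{name} locus universe differs from glm universe: {diff}"
                )


@dataclass
class CandidateSet:
    """Candidates plus the per-series per-method pass/fail audit matrix."""

    candidates: list
    passfail: pd.DataFrame = field(default_factory=pd.DataFrame)


def intersect(
    series_results: list[SeriesResults] | tuple[SeriesResults, ...],
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> CandidateSet:
    """Intersect the three method hits within each series, then across series."""
    if len(series_results) < 1:
        raise ValidationError("need at least one series")
    universes = [sr.universe() for sr in series_results]
    if any(u != universes[0] for u in universes[1:]):
        diff = sorted(universes[0].symmetric_difference(set.union(*universes[1:])))[:10]
        raise ValidationError(f"series locus universes differ: {diff}")
    for sr in series_results:
        sr.check()

    loci = sorted(universes[0])
    cols = {}
    survivors = set(loci)
    for s, sr in enumerate(series_results, start=1):
        glm_pass = sr.glm["q"] < thresholds.q_cut
        rf_pass = sr.rf > thresholds.importance_cut
        auc_pass = sr.auc > thresholds.auc_cut
        cols[f"series{s}_glm"] = glm_pass.reindex(loci)
        cols[f"series{s}_rf"] = rf_pass.reindex(loci)
        cols[f"series{s}_auc"] = auc_pass.reindex(loci)
        series_hits = {
            l for l in loci if glm_pass.get(l, False) and rf_pass.get(l, False)
            and auc_pass.get(l, False)
        }
        survivors &= series_hits
    passfail = pd.DataFrame(cols, index=pd.Index(loci, name="locus"))
    passfail["candidate"] = passfail.index.isin(survivors)
    return CandidateSet(candidates=sorted(survivors), passfail=passfail)
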