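"""Core data containers for the array and pyrosequencing analysis stages.

The array substrate is a samples x loci matrix of *average beta* values
(methylated signal / total signal, a proportion in [0, 1]) together with a
matching matrix of detection p-values and a per-locus annotation table
(gene symbol, chromosome).  Phenotypes travel in a sample sheet; the
pyrosequencing confirmation data are a long table of percent-methylation
values per (sample, gene, CpG site).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "QCReport",
    "validate_sample_sheet",
    "validate_pyro_table",
    "SAMPLE_SHEET_COLUMNS",
    "PYRO_COLUMNS",
]

#: Expected columns of a sample sheet.  ``invasive`` is 0/1 (muscle-invasive
#: vs papillary/superficial), ``grade`` is the histologic grade (1-3),
#: ``tp53_high`` is 0/1 immunohistochemical p53 intensity (3+ vs <3),
#: ``series`` identifies the tumor series.
SAMPLE_SHEET_COLUMNS = ("age", "gender", "invasive", "grade", "tp53_high", "series")

#: Columns of a long-format pyrosequencing table.
PYRO_COLUMNS = ("sample_id", "gene", "site", "percent")


class ValidationError(ValueError):
    """Raised when an input table violates the documented contract."""


@dataclass
class MethylationMatrix:
    """Samples x loci average-beta matrix with detection p-values.

    Parameters
    ----------
    beta : DataFrame
        Rows are samples, columns are loci; values in [0, 1].
    detection_p : DataFrame
        Same shape/index/columns as ``beta``; per-measurement probability
        the signal is indistinguishable from background.
    annotation : DataFrame
        Indexed by locus id with columns ``gene`` and ``chromosome``.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if self.beta.shape != self.detection_p.shape:
            raise ValidationError(
                f"beta shape {self.beta.shape} != detection-p shape "
                f"{self.detection_p.shape}"
            )
        if not self.beta.index.equals(self.detection_p.index) or not self.beta.columns.equals(
            self.detection_p.columns
        ):
            raise ValidationError("beta and detection-p sample/locus ids differ")
        if self.beta.index.has_duplicates or self.beta.columns.has_duplicates:
            raise ValidationError("duplicate sample or locus ids")
        vals = self.beta.to_numpy()
        if np.isnan(vals).any():
            raise ValidationError("missing beta values")
        bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {vals[i, j]!r} out of [0, 1] at sample "
                f"{self.beta.index[i]!r}, locus {self.beta.columns[j]!r}"
            )
        missing = self.beta.columns.difference(self.annotation.index)
        if len(missing):
            raise ValidationError(f"loci missing from annotation: {list(missing[:5])}")
        for col in ("gene", "chromosome"):
            if col not in self.annotation.columns:
                raise ValidationError(f"annotation lacks column {col!r}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def locus_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_loci(self) -> int:
        return self.beta.shape[1]

    def subset_samples(self, keep: pd.Index | list) -> "MethylationMatrix":
        """Return the submatrix restricted to the given samples (no mutation)."""
        return MethylationMatrix(
            beta=self.beta.loc[keep],
            detection_p=self.detection_p.loc[keep],
            annotation=self.annotation,
        )

    def subset_loci(self, keep: pd.Index | list) -> "MethylationMatrix":
        """Return the submatrix restricted to the given loci (no mutation)."""
        return MethylationMatrix(
            beta=self.beta.loc[:, keep],
            detection_p=self.detection_p.loc[:, keep],
            annotation=self.annotation.loc[keep],
        )


@dataclass
class QCReport:
    """Record of what the quality filters removed and why."""

    dropped_samples: dict = field(default_factory=dict)  # sample id -> failing fraction
    dropped_loci: dict = field(default_factory=dict)  # locus id -> median detection p
    retained_samples: int = 0
    retained_loci: int = 0
    retained_autosomal_loci: int = 0

    def merge(self, other: "QCReport") -> "QCReport":
        overlap_s = set(self.dropped_samples) & set(other.dropped_samples)
        overlap_l = set(self.dropped_loci) & set(other.dropped_loci)
        if overlap_s or overlap_l:
            raise ValidationError("QC reports drop overlapping ids")
        return QCReport(
            dropped_samples={**self.dropped_samples, **other.dropped_samples},
            dropped_loci={**self.dropped_loci, **other.dropped_loci},
            retained_samples=other.retained_samples or self.retained_samples,
            retained_loci=other.retained_loci or self.retained_loci,
            retained_autosomal_loci=other.retained_autosomal_loci
            or self.retained_autosomal_loci,
        )

    def to_dict(self) -> dict:
        return {
            "dropped_samples": {str(k): float(v) for k, v in self.dropped_samples.items()},
            "dropped_loci": {str(k): float(v) for k, v in self.dropped_loci.items()},
            "retained_samples": int(self.retained_samples),
            "retained_loci": int(self.retained_loci),
            "retained_autosomal_loci": int(self.retained_autosomal_loci),
        }


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check a sample sheet has the documented columns and sane values."""
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    if sheet.index.has_duplicates:
        raise ValidationError("duplicate sample ids in sample sheet")
    if not set(pd.unique(sheet["invasive"])) <= {0, 1}:
        raise ValidationError("invasive must be coded 0/1")
    return sheet


def validate_pyro_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format pyrosequencing table: columns, range, no duplicates."""
    missing = [c for c in PYRO_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"pyro table missing columns: {missing}")
    vals = table["percent"].to_numpy(dtype=float)
    if ((vals < 0) | (vals > 100)).any():
        raise ValidationError("percent methylation outside [0, 100]")
    if table.duplicated(subset=["sample_id", "gene", "site"]).any():
        raise ValidationError("duplicate (sample, gene, site) rows in pyro table")
    return table
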