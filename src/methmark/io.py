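"""Reading and writing the pipeline's plain-text formats.

The analysis consumes exported average-beta values, never vendor binary
formats: a beta TSV (rows = samples, columns = loci), a detection-p TSV of
identical shape, a locus annotation TSV (locus, gene, chromosome), a
sample sheet CSV, and a long-format pyrosequencing CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    MethylationMatrix,
    ValidationError,
    validate_pyro_table,
    validate_sample_sheet,
)

__all__ = [
    "read_beta_matrix",
    "read_sample_sheet",
    "read_pyro_table",
    "write_matrix",
]


def _read_numeric_tsv(path: str | Path, lo: float, hi: float, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < lo) | (vals > hi)
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValidationError(
                f"{what} value {df.loc[row, col]!r} out of [{lo}, {hi}] at "
                f"row {row!r}, column {col!r} in {path}"
            )
        df[col] = vals
    return df


def read_beta_matrix(
    beta_path: str | Path,
    detp_path: str | Path,
    annot_path: str | Path,
) -> MethylationMatrix:
    """Read and validate the beta / detection-p / annotation triple.

    Errors name the first offending cell (row and column).
    """
    beta = _read_numeric_tsv(beta_path, 0.0, 1.0, "beta")
    detp = _read_numeric_tsv(detp_path, 0.0, 1.0, "detection p")
    if beta.shape != detp.shape:
        raise ValidationError(
            f"shape mismatch: beta {beta.shape} vs detection-p {detp.shape}"
        )
    annot = pd.read_csv(annot_path, sep="\t", index_col=0)
    return MethylationMatrix(beta=beta, detection_p=detp, annotation=annot)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, index_col=0))


def read_pyro_table(path: str | Path) -> pd.DataFrame:
    return validate_pyro_table(pd.read_csv(path))


def write_matrix(m: MethylationMatrix, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m.beta.to_csv(outdir / "beta.tsv", sep="\t", index_label="sample_id")
    m.detection_p.to_csv(outdir / "detp.tsv", sep="\t", index_label="sample_id")
    m.annotation.loc[m.locus_ids].to_csv(outdir / "loci.tsv", sep="\t")
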