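"""Array quality filters and the autosomal restriction.

Order of operations is fixed as samples -> loci -> autosomal: locus medians
are computed over the retained samples, and the sex-chromosome restriction
comes last so the retained-autosomal count refers to QC-passing loci.
"""

from __future__ import annotations

import re
import warnings

import numpy as np

from .datatypes import MethylationMatrix, QCReport, ValidationError

__all__ = ["filter_samples", "filter_loci", "restrict_autosomal", "run_qc"]

_CHROM_RE = re.compile(r"^(?:chr)?([0-9]{1,2}|[XYxy])$")


def filter_samples(
    m: MethylationMatrix, fail_p: float = 1e-5, frac: float = 0.75
) -> tuple[MethylationMatrix, QCReport]:
    """Drop samples for which strictly more than ``frac`` of loci have a
    detection p-value above ``fail_p``.

    A sample with exactly ``frac`` of loci failing is retained (the rule
    is a strict inequality).
    """
    if not (0 < fail_p < 1 and 0 < frac < 1):
        raise ValidationError("thresholds must lie in (0, 1)")
    if m.n_samples == 0 or m.n_loci == 0:
        raise ValidationError("empty methylation matrix")
    failing = (m.detection_p.to_numpy() > fail_p).mean(axis=1)
    drop = failing > frac
    dropped = {
        sid: float(f) for sid, f, d in zip(m.sample_ids, failing, drop) if d
    }
    kept = m.subset_samples(m.sample_ids[~drop]) if drop.any() else m
    report = QCReport(
        dropped_samples=dropped,
        retained_samples=kept.n_samples,
        retained_loci=kept.n_loci,
    )
    return kept, report


def filter_loci(
    m: MethylationMatrix, med_p: float = 0.05
) -> tuple[MethylationMatrix, QCReport]:
    """Drop loci whose median detection p-value across samples exceeds
    ``med_p`` (strictly); for even sample counts the median is the mean of
    the central pair.  A locus with median exactly at the threshold is
    retained."""
    if not 0 < med_p < 1:
        raise ValidationError("threshold must lie in (0, 1)")
    if m.n_samples == 0 or m.n_loci == 0:
        raise ValidationError("empty methylation matrix")
    med = np.median(m.detection_p.to_numpy(), axis=0)
    drop = med > med_p
    dropped = {lid: float(p) for lid, p, d in zip(m.locus_ids, med, drop) if d}
    kept = m.subset_loci(m.locus_ids[~drop]) if drop.any() else m
    report = QCReport(
        dropped_loci=dropped,
        retained_samples=kept.n_samples,
        retained_loci=kept.n_loci,
    )
    return kept, report


def _is_autosomal(chrom: str, locus: str) -> bool:
    m = _CHROM_RE.match(str(chrom).strip())
    if not m:
        raise ValidationError(f"unknown chromosome label {chrom!r} for locus {locus!r}")
    tag = m.group(1).upper()
    if tag in ("X", "Y"):
        return False
    if not 1 <= int(tag) <= 22:
        raise ValidationError(f"unknown chromosome label {chrom!r} for locus {locus!r}")
    return True


def restrict_autosomal(m: MethylationMatrix) -> MethylationMatrix:
    """Remove loci annotated on the X or Y chromosome.

    Chromosome labels {1..22, X, Y} are accepted with or without a ``chr``
    prefix; anything else raises naming the offending locus.
    """
    chroms = m.annotation.loc[m.locus_ids, "chromosome"]
    keep = np.array([_is_autosomal(c, l) for l, c in chroms.items()])
    if not keep.any():
        warnings.warn("no autosomal loci remain after restriction")
        return m.subset_loci(m.locus_ids[keep])
    if keep.all():
        return m
    return m.subset_loci(m.locus_ids[keep])


def run_qc(
    m: MethylationMatrix,
    fail_p: float = 1e-5,
    frac: float = 0.75,
    med_p: float = 0.05,
) -> tuple[MethylationMatrix, QCReport]:
    """Full QC pass: sample filter, locus filter, autosomal restriction."""
    m1, rep_s = filter_samples(m, fail_p=fail_p, frac=frac)
    m2, rep_l = filter_loci(m1, med_p=med_p)
    m3 = restrict_autosomal(m2)
    report = rep_s.merge(rep_l)
    report.retained_samples = m3.n_samples
    report.retained_loci = m2.n_loci
    report.retained_autosomal_loci = m3.n_loci
    return m3, report
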