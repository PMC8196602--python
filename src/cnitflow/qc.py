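"""Hybridization quality control and quantile normalization.

Arrays hybridized from archival FFPE tissue frequently carry degraded RNA,
so two per-sample QC statistics gate the cohort before any analysis:

* **percent present (%P)** — the fraction of non-control probesets called
  detectably expressed.  A probe is "present" in a sample when its log2
  intensity exceeds the median of the sample's negative-control probes by
  more than a margin (default 1.0 log2 unit, i.e. 2-fold above background).
  Samples pass at %P >= 50%; samples inside [35%, 65%) are additionally
  flagged "borderline" in the report.
* **GAPDH 3':5' ratio** — the linear-scale ratio of mean 3'-end to mean
  5'-end probe intensity of the GAPDH housekeeping transcript.  Ratios
  above 3 indicate RNA degradation and fail the sample.

Surviving samples are then quantile-normalized so every array shares one
empirical intensity distribution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from dataclasses import dataclass

from .types import ExpressionMatrix, ProbeAnnotation, Thresholds, ValidationError

logger = logging.getLogger(__name__)

BORDERLINE_BAND = (0.35, 0.65)  # the stated cutoff's +/- 15% uncertainty band


@dataclass
class QCReport:
    """Per-sample QC metrics and pass/fail calls.

    ``data`` columns: sample_id, percent_present, gapdh_ratio,
    pass_percent_present, pass_gapdh, pass, borderline.
    ``pass`` is the conjunction of the two component calls.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = [
            "sample_id",
            "percent_present",
            "gapdh_ratio",
            "pass_percent_present",
            "pass_gapdh",
            "pass",
        ]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"QC report missing columns: {missing}")
        pp = self.data["percent_present"]
        if ((pp < 0) | (pp > 1)).any():
            raise ValidationError("percent_present outside [0, 1]")
        conj = self.data["pass_percent_present"] & self.data["pass_gapdh"]
        if not (self.data["pass"] == conj).all():
            raise ValidationError("pass flag is not the conjunction of component calls")

    def write(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, lineterminator="\n")


def detection_call(
    matrix: ExpressionMatrix, annotation: ProbeAnnotation, margin: float = 1.0
) -> pd.DataFrame:
    """Present/absent call per probe and sample.

    Probe p is present in sample s iff value(p, s) strictly exceeds
    median(negative-control values in s) + margin (log2 units).

    Returns a boolean DataFrame shaped like the matrix.
    """
    neg = [p for p in annotation.probes_of_class("negative_control") if p in matrix.data.index]
    if not neg:
        raise ValidationError(
            "no negative-control probes found in the matrix; supply an annotation "
            "with control_class=negative_control rows matching matrix probe ids"
        )
    background = matrix.data.loc[neg].median(axis=0)  # per sample
    return matrix.data.gt(background + margin, axis=1)


def percent_present(
    calls: pd.DataFrame, annotation: ProbeAnnotation
) -> pd.Series:
    """Fraction of non-control probes called present, per sample."""
    ann = annotation.data.set_index("probe_id")["control_class"]
    ann = ann.reindex(calls.index).fillna("none")
    informative = calls.loc[ann == "none"]
    if informative.empty:
        raise ValidationError("no non-control probes to compute %P over")
    return informative.mean(axis=0)


def gapdh_ratio(
    matrix: ExpressionMatrix, annotation: ProbeAnnotation, qc_gene: str = "GAPDH"
) -> pd.Series:
    """Linear 3':5' intensity ratio of the housekeeping transcript, per sample.

    ratio = 2 ** (mean log2 of 3' probes - mean log2 of 5' probes).
    """
    ann = annotation.data
    p3 = ann.loc[
        (ann["control_class"] == "qc_3prime") & (ann["qc_gene"] == qc_gene), "probe_id"
    ]
    p5 = ann.loc[
        (ann["control_class"] == "qc_5prime") & (ann["qc_gene"] == qc_gene), "probe_id"
    ]
    p3 = [p for p in p3 if p in matrix.data.index]
    p5 = [p for p in p5 if p in matrix.data.index]
    if not p3 or not p5:
        raise ValidationError(
            f"need >=1 qc_3prime and >=1 qc_5prime probe for {qc_gene} in the matrix"
        )
    return np.exp2(matrix.data.loc[p3].mean(axis=0) - matrix.data.loc[p5].mean(axis=0))


def qc_report(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    thresholds: Thresholds | None = None,
    margin: float = 1.0,
) -> QCReport:
    """Compute both QC statistics on the raw (pre-normalization) matrix."""
    thresholds = thresholds or Thresholds.for_platform(matrix.platform)
    calls = detection_call(matrix, annotation, margin=margin)
    pp = percent_present(calls, annotation)
    ratio = gapdh_ratio(matrix, annotation)
    pass_pp = pp >= thresholds.percent_present_cutoff
    pass_gr = ratio <= thresholds.gapdh_ratio_cutoff
    borderline = (pp >= BORDERLINE_BAND[0]) & (pp < BORDERLINE_BAND[1])
    for s in matrix.sample_ids:
        if borderline[s]:
            logger.warning("sample %s has borderline %%P = %.3f", s, pp[s])
    df = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "percent_present": pp.values,
            "gapdh_ratio": ratio.values,
            "pass_percent_present": pass_pp.values,
            "pass_gapdh": pass_gr.values,
            "pass": (pass_pp & pass_gr).values,
            "borderline": borderline.values,
        }
    )
    return QCReport(df)


def apply_qc(
    matrix: ExpressionMatrix, report: QCReport, thresholds: Thresholds | None = None
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop failing samples; values of survivors are untouched.

    If ``thresholds`` is given, pass/fail is re-derived from the report's
    metrics under those cutoffs; otherwise the report's own calls are used.

    Returns (filtered matrix, dropped sample ids).  Raises if the report
    does not cover every sample or if no sample survives.
    """
    rep = report.data.set_index("sample_id")
    missing = [s for s in matrix.sample_ids if s not in rep.index]
    if missing:
        raise ValidationError(f"QC report missing samples: {missing}")
    if thresholds is not None:
        ok = (rep["percent_present"] >= thresholds.percent_present_cutoff) & (
            rep["gapdh_ratio"] <= thresholds.gapdh_ratio_cutoff
        )
    else:
        ok = rep["pass"]
    keep = [s for s in matrix.sample_ids if bool(ok[s])]
    dropped = [s for s in matrix.sample_ids if not bool(ok[s])]
    if not keep:
        raise ValidationError("all samples failed QC (empty cohort)")
    for s in dropped:
        logger.info("QC: dropping sample %s", s)
    return matrix.subset_samples(keep), dropped


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the shared empirical intensity distribution.

    The reference distribution is the across-sample mean of per-rank sorted
    values; tied values within a column receive the mean of the reference
    values at their tied ranks.  Idempotent, and rank order within each
    column is preserved.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    vals = matrix.data.to_numpy()
    n_probes, n_samples = vals.shape
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(n_samples):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty(n_probes)
        mapped[order] = reference
        # ties: average the reference values assigned within each tied block
        mapped = pd.Series(mapped).groupby(col).transform("mean").to_numpy()
        out[:, j] = mapped
    df = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(matrix.platform, df)
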