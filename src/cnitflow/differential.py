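"""Probeset-level two-group testing and gene-level collapse.

Each contrast (e.g. CNIT vs Normal) is a two-sample t-test per probeset on
log2 intensities, followed by Benjamini-Hochberg FDR adjustment within the
contrast, dual p/q thresholds plus a linear fold-change threshold, and a
many-probes-to-one-gene collapse into a signed differentially-expressed
gene set.

Conventions:

* pooled-variance Student t by default (the historical microarray choice);
  Welch available via ``welch=True``;
* fold change is geometric: 2**(difference of log2 group means);
* threshold strictness: p strictly < cutoff, q <= cutoff, |FC| >= cutoff;
* FDR is adjusted per contrast and per platform, not globally.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import fdrcorrection

from .types import (
    ContrastResult,
    DEGSet,
    ExpressionMatrix,
    ProbeAnnotation,
    Thresholds,
    ValidationError,
)

logger = logging.getLogger(__name__)


def probeset_test(
    matrix: ExpressionMatrix,
    group1: list[str],
    group2: list[str],
    contrast_id: str = "group1_vs_group2",
    welch: bool = False,
) -> ContrastResult:
    """Two-sample t-test per probeset; group1 minus group2.

    Degenerate probesets (zero pooled variance) follow the conventions:
    equal means -> t = 0, p = 1; unequal means -> p = 0 with a logged
    warning (the effect is infinitely many standard errors away).

    Returns a :class:`ContrastResult` with q_value/passes unset (NaN/False);
    run :func:`apply_thresholds` to finish.
    """
    g1, g2 = list(group1), list(group2)
    overlap = set(g1) & set(g2)
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("each group needs >= 2 samples")
    for s in g1 + g2:
        if s not in matrix.data.columns:
            raise ValidationError(f"sample {s!r} not in matrix")

    x1 = matrix.data[g1].to_numpy()
    x2 = matrix.data[g2].to_numpy()
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    diff = m1 - m2

    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = v1 / n1 + v2 / n2
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
            t = diff / np.sqrt(se2)
        else:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            df = np.full_like(diff, float(n1 + n2 - 2))
            t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * stats.t.sf(np.abs(t), df)

    zero_var = ~np.isfinite(t)
    if zero_var.any():
        same = zero_var & (diff == 0)
        differ = zero_var & (diff != 0)
        t[same], p[same] = 0.0, 1.0
        if differ.any():
            t[differ] = np.sign(diff[differ]) * np.inf
            p[differ] = 0.0
            for probe in np.asarray(matrix.probe_ids)[differ][:10]:
                logger.warning(
                    "probeset %s: zero pooled variance with unequal means (p set to 0)",
                    probe,
                )

    data = pd.DataFrame(
        {
            "mean_log2_diff": diff,
            "t_statistic": t,
            "p_value": p,
            "q_value": np.nan,
            "fold_change": np.exp2(diff),
            "direction": np.where(diff > 0, "up", "down"),
            "passes": False,
        },
        index=matrix.data.index,
    )
    return ContrastResult(contrast_id, matrix.platform, data)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    _, q = fdrcorrection(p, alpha=0.05, method="indep")
    return q


def apply_thresholds(result: ContrastResult, thresholds: Thresholds) -> ContrastResult:
    """Compute BH q within the contrast and set the pass flag.

    passes <=> p < p_cutoff AND q <= fdr_cutoff AND 2**|mean_log2_diff|
    >= fc_cutoff.
    """
    data = result.data.copy()
    data["q_value"] = bh_fdr(data["p_value"].to_numpy())
    abs_fc = np.exp2(np.abs(data["mean_log2_diff"].to_numpy()))
    data["passes"] = (
        (data["p_value"] < thresholds.p_cutoff)
        & (data["q_value"] <= thresholds.fdr_cutoff)
        & (abs_fc >= thresholds.fc_cutoff)
    )
    return ContrastResult(result.contrast_id, result.platform, data)


def run_contrast(
    matrix: ExpressionMatrix,
    group1: list[str],
    group2: list[str],
    thresholds: Thresholds,
    contrast_id: str = "group1_vs_group2",
    welch: bool = False,
) -> ContrastResult:
    """probeset_test followed by apply_thresholds."""
    return apply_thresholds(
        probeset_test(matrix, group1, group2, contrast_id=contrast_id, welch=welch),
        thresholds,
    )


def collapse_to_genes(result: ContrastResult, annotation: ProbeAnnotation) -> DEGSet:
    """Collapse passing probesets onto gene symbols.

    A gene is differentially expressed when at least one passing probeset
    maps to it.  Its direction is the majority sign among its passing
    probesets; ties go to the probeset with the largest |mean log2
    difference|.  Passing probesets without a gene symbol are kept in
    ``unmapped_passing`` and logged, never silently dropped.
    """
    gene_map = annotation.data.set_index("probe_id")["gene_symbol"]
    passing = result.passing
    directions: dict[str, str] = {}
    by_gene: dict[str, list[tuple[str, float]]] = {}
    unmapped: list[str] = []
    for probe, row in passing.iterrows():
        gene = gene_map.get(probe, "")
        if not gene:
            unmapped.append(probe)
            continue
        by_gene.setdefault(gene, []).append((row["direction"], row["mean_log2_diff"]))
    for gene, entries in by_gene.items():
        n_up = sum(1 for d, _ in entries if d == "up")
        n_down = len(entries) - n_up
        if n_up > n_down:
            directions[gene] = "up"
        elif n_down > n_up:
            directions[gene] = "down"
        else:  # tie: largest absolute effect wins
            best = max(entries, key=lambda e: abs(e[1]))
            directions[gene] = best[0]
    if unmapped:
        logger.info(
            "%s: %d passing probesets had no gene symbol", result.contrast_id, len(unmapped)
        )
    return DEGSet(
        contrast_id=result.contrast_id,
        directions=directions,
        passing_probesets=list(passing.index),
        unmapped_passing=unmapped,
    )


def write_contrast_result(result: ContrastResult, annotation: ProbeAnnotation | None, path) -> None:
    """Write the per-probeset table as TSV (with gene symbols if available)."""
    out = result.data.copy()
    out.insert(0, "probeset_id", out.index)
    if annotation is not None:
        gene_map = annotation.data.set_index("probe_id")["gene_symbol"]
        out.insert(1, "gene_symbol", [gene_map.get(p, "") for p in out.index])
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
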