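"""Directional gene-set and upstream-regulator enrichment.

Two statistics per set:

* **overlap p-value** — one-sided Fisher exact / hypergeometric upper
  tail P[X >= k] for the overlap k between the query gene list and the
  set, both restricted to a stated gene universe; BH-adjusted across the
  collection;
* **activation z-score** — for sets whose members carry an expected
  direction of change under activation: z = (N+ - N-) / sqrt(N+ + N-),
  where N+ counts query genes whose observed direction matches the
  expected sign and N- counts mismatches.  Positive z predicts activation
  of the set/regulator, negative z inhibition; |z| >= 2 is the
  conventional reporting threshold.  Unsigned members are ignored; with
  no signed overlapping member the score is undefined (NaN), which is
  distinct from z = 0.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .types import DEGSet, GeneSetCollection, Thresholds, ValidationError
from .differential import bh_fdr

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "set_name",
    "overlap_k",
    "set_size_in_universe",
    "query_size",
    "universe_size",
    "p_value",
    "q_value",
    "n_consistent",
    "n_inconsistent",
    "activation_z",
]

Z_CALL_THRESHOLD = 2.0


def _sign_of(direction: str) -> int:
    return 1 if direction == "up" else -1


def activation_z(query: DEGSet, signed_set: dict) -> float:
    """Consistency z-score of the query's directions against a signed set.

    Raises if the set has no signed member present in the query (the score
    is undefined there, not zero).
    """
    n_plus = n_minus = 0
    for gene, expected in signed_set.items():
        if expected == 0 or gene not in query.directions:
            continue
        if _sign_of(query.directions[gene]) == expected:
            n_plus += 1
        else:
            n_minus += 1
    total = n_plus + n_minus
    if total == 0:
        raise ValidationError("no signed set member overlaps the query: z undefined")
    return (n_plus - n_minus) / math.sqrt(total)


def fisher_enrichment(
    query: DEGSet,
    sets: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of each set in the query.

    Query genes outside the universe are logged and clipped before
    testing.  Returns one row per set (columns ``ENRICHMENT_COLUMNS``),
    with BH q computed across the whole collection and the activation
    z-score (NaN where undefined) from signed members.
    """
    if not universe:
        raise ValidationError("empty universe")
    uni = set(universe)
    if len(uni) != len(universe):
        raise ValidationError("universe contains duplicate symbols")
    outside = query.genes - uni
    if outside:
        logger.warning(
            "%d query genes outside the universe were clipped (e.g. %s)",
            len(outside),
            sorted(outside)[:3],
        )
    query_genes = query.genes & uni
    M = len(uni)
    N = len(query_genes)

    rows = []
    for name, members in sets:
        set_in_uni = {g for g in members if g in uni}
        n = len(set_in_uni)
        k = len(set_in_uni & query_genes)
        # P[X >= k], hypergeometric(M, n, N)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        p = min(p, 1.0)
        n_plus = n_minus = 0
        for gene, expected in members.items():
            if expected == 0 or gene not in query.directions:
                continue
            if _sign_of(query.directions[gene]) == expected:
                n_plus += 1
            else:
                n_minus += 1
        total_signed = n_plus + n_minus
        z = (n_plus - n_minus) / math.sqrt(total_signed) if total_signed else np.nan
        rows.append(
            {
                "set_name": name,
                "overlap_k": k,
                "set_size_in_universe": n,
                "query_size": N,
                "universe_size": M,
                "p_value": p,
                "q_value": np.nan,
                "n_consistent": n_plus,
                "n_inconsistent": n_minus,
                "activation_z": z,
            }
        )
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    if len(df):
        df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    return df


def upstream_regulators(
    query: DEGSet,
    regulators: GeneSetCollection,
    universe: list[str],
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Overlap p and activation z per putative upstream regulator.

    Same machinery as :func:`fisher_enrichment` over regulator target
    sets, plus two derived columns: ``reported`` (overlap p below the
    enrichment cutoff) and ``predicted_state`` ("activated" for z >= 2,
    "inhibited" for z <= -2, "" otherwise).
    """
    thresholds = thresholds or Thresholds()
    df = fisher_enrichment(query, regulators, universe)
    df["reported"] = df["p_value"] < thresholds.enrichment_p
    state = np.where(
        df["activation_z"] >= Z_CALL_THRESHOLD,
        "activated",
        np.where(df["activation_z"] <= -Z_CALL_THRESHOLD, "inhibited", ""),
    )
    state = np.where(np.isnan(df["activation_z"]), "", state)
    df["predicted_state"] = state
    return df


def write_enrichment(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
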