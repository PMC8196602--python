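"""miRNA-mRNA data integration.

Differentially expressed miRNAs (CNIT vs Normal) are paired with their
CNIT-specific target genes.  Because miRNAs repress their targets, only
pairs with **opposite** directions of change are biologically coherent
(an upregulated miRNA with a downregulated target, or vice versa), and
only **experimentally observed** target relationships are trusted.  A
candidate (miRNA, gene) edge is therefore retained iff:

1. its evidence class is ``experimentally_observed``;
2. the miRNA is differentially expressed and the gene is in the
   unique-CNIT gene list, with opposite directions.

Every rejected candidate carries exactly one reason, assigned in the
fixed priority order ``not_experimentally_observed`` > ``same_direction``
> ``target_not_in_unique_list`` > ``mirna_not_de``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .types import DEGSet, TargetPairTable, ValidationError

REJECTION_REASONS = (
    "not_experimentally_observed",
    "same_direction",
    "target_not_in_unique_list",
    "mirna_not_de",
)

RETAINED_COLUMNS = ["mirna_id", "mirna_direction", "gene_symbol", "gene_direction", "evidence"]


@dataclass
class IntegrationResult:
    """Retained miRNA:mRNA pairs plus a complete rejection audit.

    ``retained`` columns: mirna_id, mirna_direction, gene_symbol,
    gene_direction, evidence — sorted by (mirna_id, gene_symbol).
    ``rejected`` adds a ``reason`` column.  Every input candidate appears
    in exactly one of the two tables.
    """

    retained: pd.DataFrame
    rejected: pd.DataFrame

    @property
    def n_mirnas(self) -> int:
        return self.retained["mirna_id"].nunique()

    @property
    def n_genes(self) -> int:
        return self.retained["gene_symbol"].nunique()

    @property
    def n_pairs(self) -> int:
        return len(self.retained)

    def pairs_for(self, mirna_id: str) -> pd.DataFrame:
        return self.retained[self.retained["mirna_id"] == mirna_id]


def integrate(
    de_mirnas: DEGSet, unique_cnit: DEGSet, targets: TargetPairTable
) -> IntegrationResult:
    """Apply the three-predicate filter to every candidate target pair.

    Pure function of its inputs; output rows are sorted lexicographically
    by miRNA id then gene symbol.  An empty target table is an error
    (nothing to integrate); an empty *result* is a valid outcome.
    """
    if len(targets) == 0:
        raise ValidationError("target-pair table is empty: nothing to integrate")

    kept_rows = []
    rejected_rows = []
    for _, row in targets.data.iterrows():
        mirna, gene, evidence = row["mirna_id"], row["gene_symbol"], row["evidence"]
        m_dir = de_mirnas.directions.get(mirna)
        g_dir = unique_cnit.directions.get(gene)
        reason = None
        if evidence != "experimentally_observed":
            reason = "not_experimentally_observed"
        elif m_dir is not None and g_dir is not None and m_dir == g_dir:
            reason = "same_direction"
        elif g_dir is None:
            reason = "target_not_in_unique_list"
        elif m_dir is None:
            reason = "mirna_not_de"
        record = {
            "mirna_id": mirna,
            "mirna_direction": m_dir or "",
            "gene_symbol": gene,
            "gene_direction": g_dir or "",
            "evidence": evidence,
        }
        if reason is None:
            kept_rows.append(record)
        else:
            rejected_rows.append({**record, "reason": reason})

    retained = pd.DataFrame(kept_rows, columns=RETAINED_COLUMNS)
    rejected = pd.DataFrame(rejected_rows, columns=RETAINED_COLUMNS + ["reason"])
    retained = retained.sort_values(["mirna_id", "gene_symbol"], kind="mergesort").reset_index(
        drop=True
    )
    rejected = rejected.sort_values(["mirna_id", "gene_symbol"], kind="mergesort").reset_index(
        drop=True
    )
    return IntegrationResult(retained, rejected)


def write_integration(result: IntegrationResult, pairs_path, audit_path) -> None:
    result.retained.to_csv(pairs_path, sep="\t", index=False, lineterminator="\n")
    result.rejected.to_csv(audit_path, sep="\t", index=False, lineterminator="\n")
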