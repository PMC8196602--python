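"""Marker-specificity comparison across the three injury contrasts.

The CNIT signature is refined by comparing the differentially expressed
gene sets of CNIT vs Normal against the two positive-control injuries
(AR vs Normal, IFTA vs Normal): genes shared with the other injuries are
common allograft-damage markers, while genes found in exactly one contrast
are condition-specific.  Membership is by gene symbol only — a gene up in
one contrast and down in another still counts as shared.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import DEGSet, ValidationError

REGIONS = ("A", "B", "C", "AB", "AC", "BC", "ABC")
CONDITION_TO_SET = {"CNIT": "A", "AR": "B", "IFTA": "C"}


@dataclass
class VennPartition:
    """The seven disjoint regions of a three-set comparison.

    A = CNIT vs Normal, B = AR vs Normal, C = IFTA vs Normal.  Region keys:
    "A"/"B"/"C" (unique to one contrast), "AB"/"AC"/"BC" (exactly two),
    "ABC" (common to all three).
    """

    regions: dict[str, frozenset]
    sources: dict[str, DEGSet]  # "A"/"B"/"C" -> the input DEGSet

    def __post_init__(self) -> None:
        missing = [r for r in REGIONS if r not in self.regions]
        if missing:
            raise ValidationError(f"partition missing regions {missing}")
        all_regions = list(self.regions.values())
        for i in range(len(all_regions)):
            for j in range(i + 1, len(all_regions)):
                if all_regions[i] & all_regions[j]:
                    raise ValidationError("venn regions are not disjoint")
        for label in "ABC":
            rebuilt = frozenset().union(
                *(self.regions[r] for r in REGIONS if label in r)
            )
            if rebuilt != self.sources[label].genes:
                raise ValidationError(
                    f"regions containing {label} do not reproduce input set {label}"
                )

    @property
    def counts(self) -> dict[str, int]:
        return {r: len(self.regions[r]) for r in REGIONS}

    def set_size(self, label: str) -> int:
        return sum(len(self.regions[r]) for r in REGIONS if label in r)


def venn_partition(cnit: DEGSet, ar: DEGSet, ifta: DEGSet) -> VennPartition:
    """Exact three-way set algebra over gene symbols (directions ignored)."""
    a, b, c = cnit.genes, ar.genes, ifta.genes
    regions = {
        "A": frozenset(a - b - c),
        "B": frozenset(b - a - c),
        "C": frozenset(c - a - b),
        "AB": frozenset((a & b) - c),
        "AC": frozenset((a & c) - b),
        "BC": frozenset((b & c) - a),
        "ABC": frozenset(a & b & c),
    }
    return VennPartition(regions, {"A": cnit, "B": ar, "C": ifta})


def unique_genes(partition: VennPartition, condition: str) -> DEGSet:
    """Genes differentially expressed only in the given condition's contrast.

    Directions are inherited from that condition's input DEGSet.
    """
    if condition not in CONDITION_TO_SET:
        raise ValidationError(
            f"condition must be one of {sorted(CONDITION_TO_SET)}, got {condition!r}"
        )
    label = CONDITION_TO_SET[condition]
    source = partition.sources[label]
    members = partition.regions[label]
    return source.subset(members, contrast_id=f"unique_{condition}")


def common_genes(partition: VennPartition) -> frozenset:
    """Genes shared by all three contrasts (the triple intersection)."""
    return partition.regions["ABC"]


def write_partition(partition: VennPartition, out_dir) -> None:
    """One gene-list TSV per region plus a 7-row summary of counts."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for region in REGIONS:
        path = os.path.join(out_dir, f"region_{region}.tsv")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene_symbol\n")
            for gene in sorted(partition.regions[region]):
                fh.write(gene + "\n")
    with open(os.path.join(out_dir, "summary.tsv"), "w", encoding="utf-8", newline="\n") as fh:
        fh.write("region\tcount\n")
        for region in REGIONS:
            fh.write(f"{region}\t{len(partition.regions[region])}\n")
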