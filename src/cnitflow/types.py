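"""Shared domain types for the nephrotoxicity transcriptomics pipeline.

The pipeline compares kidney-allograft biopsy transcriptomes across four
histologic conditions — calcineurin-inhibitor nephrotoxicity (CNIT), normal
allograft, acute rejection (AR), and interstitial fibrosis / tubular atrophy
(IFTA) — on two microarray platforms (gene expression and miRNA).  All stages
exchange the validated containers defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

PLATFORMS = ("mRNA", "miRNA")
CONDITIONS = ("CNIT", "Normal", "AR", "IFTA")
CONTROL_CLASSES = ("none", "negative_control", "qc_5prime", "qc_3prime")
EVIDENCE_CLASSES = ("experimentally_observed", "predicted_high", "predicted_moderate")
DIRECTIONS = ("up", "down")


class ValidationError(ValueError):
    """Raised when a container or file violates a structural invariant."""


def _check_unique(values: Iterable, what: str) -> None:
    seen = set()
    for v in values:
        if v in seen:
            raise ValidationError(f"duplicate {what}: {v!r}")
        seen.add(v)


@dataclass
class ExpressionMatrix:
    """Log2-intensity matrix, probes (rows) by samples (columns).

    Parameters
    ----------
    platform : {"mRNA", "miRNA"}
        Array platform the probes belong to.
    data : pandas.DataFrame
        Finite float values; index = probe ids, columns = sample ids, both
        unique.  Values are log2 intensities by contract.
    """

    platform: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValidationError(
                f"platform must be one of {PLATFORMS}, got {self.platform!r}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        self.data = self.data.astype(float)
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.platform, self.data[ids].copy())


@dataclass
class SampleTable:
    """Sample metadata: one row per (sample, platform) with its condition."""

    data: pd.DataFrame  # columns: sample_id, condition, platform

    def __post_init__(self) -> None:
        required = ["sample_id", "condition", "platform"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"sample table missing columns: {missing}")
        bad_cond = set(self.data["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(
                f"unknown condition labels {sorted(bad_cond)}; accepted: {CONDITIONS}"
            )
        bad_plat = set(self.data["platform"]) - set(PLATFORMS)
        if bad_plat:
            raise ValidationError(f"unknown platforms {sorted(bad_plat)}")
        for plat, grp in self.data.groupby("platform"):
            _check_unique(grp["sample_id"], f"sample id on platform {plat}")

    def samples(self, condition: str, platform: str) -> list[str]:
        """Sample ids for one condition on one platform, file order preserved."""
        m = (self.data["condition"] == condition) & (self.data["platform"] == platform)
        return list(self.data.loc[m, "sample_id"])


@dataclass
class ProbeAnnotation:
    """Probe-to-gene map plus QC-control probe designations.

    ``control_class`` marks negative-control probes (used by the detection
    call) and the 5'/3' probes of housekeeping transcripts (used by the
    RNA-degradation ratio); ``qc_gene`` names the housekeeping gene for the
    latter (GAPDH on the study's platform).
    """

    data: pd.DataFrame  # columns: probe_id, gene_symbol, control_class, qc_gene

    def __post_init__(self) -> None:
        required = ["probe_id", "gene_symbol", "control_class", "qc_gene"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        _check_unique(self.data["probe_id"], "probe id")
        bad = set(self.data["control_class"]) - set(CONTROL_CLASSES)
        if bad:
            raise ValidationError(f"unknown control_class {sorted(bad)}")
        qc = self.data["control_class"].isin(["qc_5prime", "qc_3prime"])
        empty_qc = self.data.loc[qc, "qc_gene"].fillna("").eq("")
        if empty_qc.any():
            bad_probes = self.data.loc[qc, "probe_id"][empty_qc].tolist()
            raise ValidationError(f"qc probes without qc_gene: {bad_probes[:5]}")
        self.data = self.data.fillna({"gene_symbol": "", "qc_gene": ""})

    def probes_of_class(self, control_class: str) -> list[str]:
        return list(self.data.loc[self.data["control_class"] == control_class, "probe_id"])

    def gene_map(self) -> pd.Series:
        """probe_id -> gene_symbol ('' = unmapped), non-control probes only."""
        noctl = self.data[self.data["control_class"] == "none"]
        return noctl.set_index("probe_id")["gene_symbol"]


@dataclass
class Thresholds:
    """Significance and QC cutoffs, with the study's strictness conventions.

    A probeset is differentially expressed when p < ``p_cutoff`` (strict),
    BH q <= ``fdr_cutoff``, and linear |fold change| >= ``fc_cutoff``.
    Defaults are the gene-expression values; :meth:`mirna` gives the miRNA
    platform's (p < 0.005, FC >= 2).
    """

    p_cutoff: float = 0.001
    fdr_cutoff: float = 0.05
    fc_cutoff: float = 1.5
    enrichment_p: float = 0.05
    percent_present_cutoff: float = 0.50
    gapdh_ratio_cutoff: float = 3.0

    def __post_init__(self) -> None:
        for name in ("p_cutoff", "fdr_cutoff", "enrichment_p", "percent_present_cutoff"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.fc_cutoff < 1.0:
            raise ValidationError(f"fc_cutoff must be >= 1, got {self.fc_cutoff}")
        if self.gapdh_ratio_cutoff <= 0:
            raise ValidationError("gapdh_ratio_cutoff must be positive")

    @classmethod
    def mrna(cls) -> "Thresholds":
        return cls()

    @classmethod
    def mirna(cls) -> "Thresholds":
        return cls(p_cutoff=0.005, fc_cutoff=2.0)

    @classmethod
    def for_platform(cls, platform: str) -> "Thresholds":
        if platform == "mRNA":
            return cls.mrna()
        if platform == "miRNA":
            return cls.mirna()
        raise ValidationError(f"unknown platform {platform!r}")


@dataclass
class TargetPairTable:
    """miRNA -> target-gene edges with an evidence class per edge."""

    data: pd.DataFrame  # columns: mirna_id, gene_symbol, evidence, source

    def __post_init__(self) -> None:
        required = ["mirna_id", "gene_symbol", "evidence", "source"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"target table missing columns: {missing}")
        bad = set(self.data["evidence"]) - set(EVIDENCE_CLASSES)
        if bad:
            raise ValidationError(
                f"unknown evidence {sorted(bad)}; accepted: {EVIDENCE_CLASSES}"
            )
        pairs = list(zip(self.data["mirna_id"], self.data["gene_symbol"]))
        _check_unique(pairs, "(mirna, gene) pair")

    def __len__(self) -> int:
        return len(self.data)


class GeneSetCollection:
    """Named gene sets whose members carry an expected direction of change.

    ``expected_sign`` is +1/-1 for members whose up/down regulation is
    consistent with activation of the set (or of the upstream regulator the
    set represents), 0 for unsigned members.
    """

    def __init__(self, sets: Mapping[str, Mapping[str, int]]):
        self.sets: dict[str, dict[str, int]] = {}
        for name, members in sets.items():
            if name in self.sets:
                raise ValidationError(f"duplicate set name: {name!r}")
            clean: dict[str, int] = {}
            for gene, sign in members.items():
                if sign not in (-1, 0, 1):
                    raise ValidationError(
                        f"expected_sign must be -1/0/+1, got {sign} for {gene!r}"
                    )
                if gene in clean:
                    raise ValidationError(f"duplicate member {gene!r} in set {name!r}")
                clean[gene] = sign
            self.sets[name] = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> dict[str, int]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ContrastResult:
    """Per-probeset statistics for one two-group comparison.

    ``data`` is indexed by probeset id with columns mean_log2_diff,
    t_statistic, p_value, q_value, fold_change, direction, passes.
    ``fold_change`` is the geometric-mean linear fold change
    2**mean_log2_diff; ``direction`` is "up" iff mean_log2_diff > 0.
    """

    contrast_id: str
    platform: str
    data: pd.DataFrame

    COLUMNS = [
        "mean_log2_diff",
        "t_statistic",
        "p_value",
        "q_value",
        "fold_change",
        "direction",
        "passes",
    ]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"contrast result missing columns: {missing}")

    @property
    def passing(self) -> pd.DataFrame:
        return self.data[self.data["passes"]]


@dataclass
class DEGSet:
    """Gene-level signed differential-expression calls for one contrast."""

    contrast_id: str
    directions: dict[str, str]  # gene_symbol -> "up"/"down"
    passing_probesets: list[str] = field(default_factory=list)
    unmapped_passing: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = {d for d in self.directions.values()} - set(DIRECTIONS)
        if bad:
            raise ValidationError(f"directions must be up/down, got {sorted(bad)}")

    @property
    def genes(self) -> set[str]:
        return set(self.directions)

    def __len__(self) -> int:
        return len(self.directions)

    def __contains__(self, gene: str) -> bool:
        return gene in self.directions

    def subset(self, genes: Iterable[str], contrast_id: str | None = None) -> "DEGSet":
        keep = {g: d for g, d in self.directions.items() if g in set(genes)}
        return DEGSet(contrast_id or self.contrast_id, keep)


@dataclass
class QpcrTable:
    """qPCR cycle-threshold measurements, target vs a single reference gene.

    delta_ct = ct_target - ct_reference is appended on construction; lower
    delta_ct means higher expression of the target.
    """

    data: pd.DataFrame  # sample_id, condition, gene, ct_target, ct_reference
    reference_gene: str = "GAPDH"

    def __post_init__(self) -> None:
        required = ["sample_id", "condition", "gene", "ct_target", "ct_reference"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"qPCR table missing columns: {missing}")
        if self.data[["ct_target", "ct_reference"]].isna().any().any():
            raise ValidationError("missing Ct values in qPCR table")
        if (self.data[["ct_target", "ct_reference"]] <= 0).any().any():
            raise ValidationError("Ct values must be positive")
        self.data = self.data.assign(
            delta_ct=self.data["ct_target"] - self.data["ct_reference"]
        )
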