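"""Seeded synthetic cohorts and fixtures emulating the study design.

The generators reproduce the *structure* of the deposited dataset — a
38-sample gene-expression cohort (12 CNIT, 12 Normal, 7 AR, 7 IFTA) with
one CNIT array failing hybridization QC, and a 15-sample miRNA cohort
(10 CNIT, 5 Normal) — so every pipeline stage is testable without any
download.  Probe-level log2 intensities follow a per-probe baseline
~ Normal(8, 1.5) plus per-condition planted shifts plus Normal(0,
noise_sd) noise; negative-control probes sit at Normal(4, 0.5); GAPDH
5'/3' probes are generated to a configurable true degradation ratio; the
failure sample's informative probes are drawn near the control level so
its percent-present falls below 50%.

Three deterministic fixtures mirror the study's printed accounting:

* the **venn fixture** — three gene sets with region counts unique
  1245/418/107, pairwise-only 127/45/67, triple 66 (so the CNIT set has
  1483 genes, 714 of them up);
* the **integration fixture** — 20 DE miRNAs and a mixed-validity target
  table constructed so exactly 13 miRNAs retain pairs covering exactly 33
  distinct genes;
* the **collapse fixture** — 1837 passing probesets mapped many-to-one
  onto 1483 genes.

All generators are pure functions of their config/seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ContrastResult,
    DEGSet,
    ExpressionMatrix,
    GeneSetCollection,
    ProbeAnnotation,
    SampleTable,
    TargetPairTable,
    ValidationError,
)

# three-way region counts consistent with the printed set totals:
# |CNIT set| = 1245+127+45+66 = 1483, |AR set| = 678, |IFTA set| = 285
VENN_REGION_COUNTS = {
    "A": 1245,
    "B": 418,
    "C": 107,
    "AB": 127,
    "AC": 45,
    "BC": 67,
    "ABC": 66,
}
CNIT_UP_COUNT = 714  # of 1483
AR_UP_COUNT = 407  # 60% of 678
IFTA_UP_COUNT = 88  # 31% of 285


@dataclass
class PlantedEffect:
    """Per-condition differential-expression effect model."""

    n_probesets: int
    shift: float  # log2 units, magnitude of the planted group difference
    up_fraction: float = 0.5


@dataclass
class GeneratorConfig:
    """Everything that determines a synthetic cohort; seed-reproducible."""

    seed: int = 42
    platform: str = "mRNA"
    n_probes: int = 2000
    n_genes: int = 1600
    group_sizes: dict = field(
        default_factory=lambda: {"CNIT": 12, "Normal": 12, "AR": 7, "IFTA": 7}
    )
    effects: dict = field(
        default_factory=lambda: {
            "CNIT": PlantedEffect(200, 1.2),
            "AR": PlantedEffect(80, 1.2),
            "IFTA": PlantedEffect(40, 1.2),
        }
    )
    noise_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    n_negative_controls: int = 40
    control_mean: float = 4.0
    control_sd: float = 0.5
    n_gapdh_probes: int = 3  # per end
    gapdh_true_ratio: float = 1.5
    qc_failure_sample: str | None = "CNIT_12"
    qc_fail_mean: float = 4.5
    qc_fail_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.n_probes <= 0 or self.n_genes <= 0:
            raise ValidationError("n_probes and n_genes must be positive")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValidationError("group sizes must be positive")
        total_planted = sum(e.n_probesets for e in self.effects.values())
        if total_planted > self.n_probes:
            raise ValidationError(
                f"{total_planted} planted probesets exceed n_probes={self.n_probes}"
            )
        if self.n_genes > self.n_probes:
            raise ValidationError("n_genes cannot exceed n_probes")


def default_mirna_config(seed: int = 3) -> GeneratorConfig:
    """The 10 CNIT + 5 Normal miRNA cohort with planted miRNA effects."""
    return GeneratorConfig(
        seed=seed,
        platform="miRNA",
        n_probes=400,
        n_genes=400,
        group_sizes={"CNIT": 10, "Normal": 5},
        effects={"CNIT": PlantedEffect(60, 1.5, up_fraction=0.72)},
        noise_sd=0.4,
        qc_failure_sample=None,
    )


@dataclass
class Cohort:
    matrix: ExpressionMatrix
    samples: SampleTable
    annotation: ProbeAnnotation
    truth: pd.DataFrame  # planted effects: condition, probeset_id, gene_symbol, direction, shift
    qc_fail_sample: str | None


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Simulate one platform's probe-level cohort with planted effects."""
    rng = np.random.default_rng(config.seed)
    prefix = "miR-sim-" if config.platform == "miRNA" else "PS"
    probe_ids = [f"{prefix}{i:05d}_at" for i in range(config.n_probes)]
    gene_ids = [f"{'miRg' if config.platform == 'miRNA' else 'G'}{i:05d}" for i in range(config.n_genes)]
    # one probe per gene, then surplus probes assigned to random genes
    gene_of_probe = list(range(config.n_genes)) + list(
        rng.integers(0, config.n_genes, size=config.n_probes - config.n_genes)
    )

    sample_ids: list[str] = []
    conditions: list[str] = []
    for cond, n in config.group_sizes.items():
        for i in range(1, n + 1):
            sample_ids.append(f"{cond}_{i:02d}")
            conditions.append(cond)
    n_samples = len(sample_ids)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_probes)
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_probes, n_samples)
    )

    # planted effects: disjoint probeset blocks per condition
    shuffled = rng.permutation(config.n_probes)
    cursor = 0
    truth_rows = []
    cond_cols = {c: [j for j, cc in enumerate(conditions) if cc == c] for c in config.group_sizes}
    for cond, effect in config.effects.items():
        if cond not in cond_cols:
            raise ValidationError(f"effect condition {cond!r} not in group_sizes")
        idx = shuffled[cursor : cursor + effect.n_probesets]
        cursor += effect.n_probesets
        n_up = int(round(effect.up_fraction * effect.n_probesets))
        for rank, p in enumerate(idx):
            sign = 1.0 if rank < n_up else -1.0
            values[p, cond_cols[cond]] += sign * effect.shift
            truth_rows.append(
                {
                    "condition": cond,
                    "probeset_id": probe_ids[p],
                    "gene_symbol": gene_ids[gene_of_probe[p]],
                    "direction": "up" if sign > 0 else "down",
                    "shift": effect.shift,
                }
            )

    # hybridization-failure sample: informative signal collapses toward background
    if config.qc_failure_sample is not None:
        if config.qc_failure_sample not in sample_ids:
            raise ValidationError(
                f"qc_failure_sample {config.qc_failure_sample!r} not in cohort"
            )
        j = sample_ids.index(config.qc_failure_sample)
        values[:, j] = rng.normal(config.qc_fail_mean, config.qc_fail_sd, size=config.n_probes)

    # control probes
    neg_ids = [f"NEGCTRL_{i:03d}" for i in range(config.n_negative_controls)]
    neg_vals = rng.normal(
        config.control_mean, config.control_sd, size=(config.n_negative_controls, n_samples)
    )
    g5_ids = [f"GAPDH_5_{i}" for i in range(config.n_gapdh_probes)]
    g3_ids = [f"GAPDH_3_{i}" for i in range(config.n_gapdh_probes)]
    g5_level = 7.5
    g3_level = g5_level + np.log2(config.gapdh_true_ratio)
    g5_vals = g5_level + rng.normal(0, 0.05, size=(config.n_gapdh_probes, n_samples))
    g3_vals = g3_level + rng.normal(0, 0.05, size=(config.n_gapdh_probes, n_samples))

    all_ids = probe_ids + neg_ids + g5_ids + g3_ids
    all_vals = np.vstack([values, neg_vals, g5_vals, g3_vals])
    matrix = ExpressionMatrix(
        config.platform, pd.DataFrame(all_vals, index=all_ids, columns=sample_ids)
    )

    samples = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "condition": conditions,
                "platform": config.platform,
            }
        )
    )

    ann_rows = [
        {"probe_id": p, "gene_symbol": gene_ids[gene_of_probe[i]], "control_class": "none", "qc_gene": ""}
        for i, p in enumerate(probe_ids)
    ]
    ann_rows += [
        {"probe_id": p, "gene_symbol": "", "control_class": "negative_control", "qc_gene": ""}
        for p in neg_ids
    ]
    ann_rows += [
        {"probe_id": p, "gene_symbol": "GAPDH", "control_class": "qc_5prime", "qc_gene": "GAPDH"}
        for p in g5_ids
    ]
    ann_rows += [
        {"probe_id": p, "gene_symbol": "GAPDH", "control_class": "qc_3prime", "qc_gene": "GAPDH"}
        for p in g3_ids
    ]
    annotation = ProbeAnnotation(pd.DataFrame(ann_rows))

    truth = pd.DataFrame(
        truth_rows,
        columns=["condition", "probeset_id", "gene_symbol", "direction", "shift"],
    )
    return Cohort(matrix, samples, annotation, truth, config.qc_failure_sample)


def generate_venn_fixture() -> tuple[DEGSet, DEGSet, DEGSet]:
    """Three DEGSets whose three-way regions have the study's exact counts.

    Returns (CNIT vs Normal, AR vs Normal, IFTA vs Normal).  Deterministic;
    gene symbols are synthetic.
    """
    regions: dict[str, list[str]] = {}
    counter = 0
    for region in ("A", "B", "C", "AB", "AC", "BC", "ABC"):
        n = VENN_REGION_COUNTS[region]
        regions[region] = [f"VG{counter + i:04d}" for i in range(n)]
        counter += n

    def build(label: str, up_count: int, contrast_id: str) -> DEGSet:
        genes = [
            g
            for region in ("A", "B", "C", "AB", "AC", "BC", "ABC")
            if label in region
            for g in regions[region]
        ]
        directions = {
            g: ("up" if i < up_count else "down") for i, g in enumerate(genes)
        }
        return DEGSet(contrast_id, directions)

    return (
        build("A", CNIT_UP_COUNT, "CNIT_vs_Normal"),
        build("B", AR_UP_COUNT, "AR_vs_Normal"),
        build("C", IFTA_UP_COUNT, "IFTA_vs_Normal"),
    )


# miRNAs assigned validated target pairs in the integration fixture
TRUE_MIRNAS = [
    "miR-16-5p",
    "miR-24-3p",
    "miR-26a-5p",
    "miR-27a-3p",
    "miR-30a-5p",
    "miR-30c-5p",
    "miR-99a-5p",
    "miR-100-5p",
    "miR-125b-5p",
    "miR-145-5p",
    "miR-195-5p",
    "miR-204-5p",
    "miR-21-5p",
]
DECOY_MIRNAS = [f"miR-dec-{i}-3p" for i in range(1, 8)]
NAMED_TARGETS = ["CCND1", "SOD2", "APP", "AGO4", "MYC", "GFPT1", "GRB10", "TLR4", "SMAD4", "PNN"]


@dataclass
class IntegrationFixture:
    de_mirnas: DEGSet
    unique_cnit: DEGSet
    targets: TargetPairTable
    designed_rejections: pd.DataFrame  # mirna_id, gene_symbol, designed_reason


def generate_integration_fixture(seed: int = 42) -> IntegrationFixture:
    """20 DE miRNAs plus a target table of mixed validity.

    Constructed so that exactly the 13 true miRNAs retain >= 1 pair and the
    retained pairs cover exactly 33 distinct genes (no target shared between
    miRNAs); the 7 decoys and extra bad pairs on true miRNAs exercise every
    rejection reason.
    """
    rng = np.random.default_rng(seed)

    # 33 distinct retained targets: 10 study-named + 23 synthetic
    targets_33 = NAMED_TARGETS + [f"CNITG{i:03d}" for i in range(1, 24)]

    # miRNA directions: ~72% up, mirroring the DE-miRNA up fraction
    all_mirnas = TRUE_MIRNAS + DECOY_MIRNAS
    n_up = int(round(0.72 * len(all_mirnas)))
    up_flags = np.array([True] * n_up + [False] * (len(all_mirnas) - n_up))
    rng.shuffle(up_flags)
    mirna_dirs = {m: ("up" if f else "down") for m, f in zip(all_mirnas, up_flags)}
    de_mirnas = DEGSet("CNIT_vs_Normal_miRNA", dict(mirna_dirs))

    # distribute the 33 targets over the 13 true miRNAs: 7x3 + 6x2
    sizes = [3] * 7 + [2] * 6
    assignments: dict[str, list[str]] = {}
    pos = 0
    for m, k in zip(TRUE_MIRNAS, sizes):
        assignments[m] = targets_33[pos : pos + k]
        pos += k

    # unique-CNIT gene list: the 33 targets (directions opposite their miRNA)
    # plus background genes of both directions
    unique_dirs: dict[str, str] = {}
    for m, genes in assignments.items():
        opp = "down" if mirna_dirs[m] == "up" else "up"
        for g in genes:
            unique_dirs[g] = opp
    for i in range(1, 41):
        unique_dirs[f"UCG{i:03d}"] = "up" if i % 2 else "down"
    unique_cnit = DEGSet("unique_CNIT", unique_dirs)

    rows = []
    designed = []

    def add(mirna, gene, evidence, source, reason=None):
        rows.append(
            {"mirna_id": mirna, "gene_symbol": gene, "evidence": evidence, "source": source}
        )
        if reason is not None:
            designed.append(
                {"mirna_id": mirna, "gene_symbol": gene, "designed_reason": reason}
            )

    for m, genes in assignments.items():
        for g in genes:
            add(m, g, "experimentally_observed", "curated literature")

    # decoys: one failing pair each, cycling the reasons achievable for a
    # DE miRNA; two extra pairs from a non-DE miRNA cover mirna_not_de
    same_dir_pool = {
        "up": [g for g, d in unique_dirs.items() if d == "up" and g.startswith("UCG")],
        "down": [g for g, d in unique_dirs.items() if d == "down" and g.startswith("UCG")],
    }
    opp = {"up": "down", "down": "up"}
    cycle = ["not_experimentally_observed", "same_direction", "target_not_in_unique_list"]
    for i, m in enumerate(DECOY_MIRNAS):
        reason = cycle[i % len(cycle)]
        if reason == "not_experimentally_observed":
            gene = same_dir_pool[opp[mirna_dirs[m]]][i]  # would retain but for evidence
            add(m, gene, "predicted_high", "prediction", reason)
        elif reason == "same_direction":
            gene = same_dir_pool[mirna_dirs[m]][i]
            add(m, gene, "experimentally_observed", "curated literature", reason)
        else:
            add(m, f"OFFLIST{i:02d}", "experimentally_observed", "curated literature", reason)
    for i, gene in enumerate(["UCG001", "UCG002"]):
        add("miR-9999-3p", gene, "experimentally_observed", "curated literature", "mirna_not_de")

    # extra failing pairs on true miRNAs: per-pair filtering, not per-miRNA
    for i, m in enumerate(TRUE_MIRNAS[:3]):
        add(m, f"CNITG{30 + i:03d}", "predicted_moderate", "prediction", "not_experimentally_observed")
        same = same_dir_pool[mirna_dirs[m]][10 + i]
        add(m, same, "experimentally_observed", "curated literature", "same_direction")

    targets = TargetPairTable(pd.DataFrame(rows))
    designed_df = pd.DataFrame(designed, columns=["mirna_id", "gene_symbol", "designed_reason"])
    return IntegrationFixture(de_mirnas, unique_cnit, targets, designed_df)


def generate_collapse_fixture(seed: int = 42) -> tuple[ContrastResult, ProbeAnnotation]:
    """1837 passing probesets mapped many-to-one onto 1483 genes.

    354 genes carry two passing probesets each and 1129 carry one
    (354*2 + 1129 = 1837); 714 genes are up, 769 down, probesets of one
    gene agreeing in sign.  163 additional non-passing probesets map to
    separate genes, exercising the pass filter in the collapse.
    """
    rng = np.random.default_rng(seed)
    genes = [f"CG{i:04d}" for i in range(1483)]
    gene_dir = {g: ("up" if i < 714 else "down") for i, g in enumerate(genes)}
    # doubled genes interleaved across both direction blocks
    doubled = set(genes[:177]) | set(genes[714 : 714 + 177])

    probe_rows = []
    ann_rows = []
    k = 0

    def add_probe(gene, passes):
        nonlocal k
        pid = f"CPS{k:05d}_at"
        k += 1
        if passes:
            diff = float(rng.uniform(0.7, 2.0))
            if gene_dir[gene] == "down":
                diff = -diff
            p = float(rng.uniform(1e-8, 5e-4))
        else:
            diff = float(rng.uniform(-0.2, 0.2))
            p = float(rng.uniform(0.2, 1.0))
        probe_rows.append(
            {
                "probeset_id": pid,
                "mean_log2_diff": diff,
                "t_statistic": diff * 8.0,
                "p_value": p,
                "q_value": p,  # placeholder on the same side of the cutoff
                "fold_change": float(2.0**diff),
                "direction": "up" if diff > 0 else "down",
                "passes": passes,
            }
        )
        ann_rows.append(
            {"probe_id": pid, "gene_symbol": gene, "control_class": "none", "qc_gene": ""}
        )

    for g in genes:
        add_probe(g, True)
        if g in doubled:
            add_probe(g, True)
    for i in range(163):
        g = f"NPG{i:03d}"
        gene_dir[g] = "up"
        add_probe(g, False)

    data = pd.DataFrame(probe_rows).set_index("probeset_id")
    result = ContrastResult("CNIT_vs_Normal", "mRNA", data)
    annotation = ProbeAnnotation(pd.DataFrame(ann_rows))
    return result, annotation


def generate_regulator_fixture(seed: int = 11):
    """An unambiguously activated upstream regulator.

    Returns (query DEGSet, regulator GeneSetCollection, universe).  The
    regulator's ten signed targets are all in the query, nine with the
    consistent direction, so z = 8/sqrt(10) > 2 and the overlap p is far
    below 0.05.
    """
    rng = np.random.default_rng(seed)
    universe = [f"RU{i:03d}" for i in range(100)]
    targets = universe[:10]
    query_dirs = {}
    signs = {}
    for i, g in enumerate(targets):
        expected = 1 if rng.random() < 0.5 else -1
        signs[g] = expected
        observed = expected if i > 0 else -expected  # one inconsistent member
        query_dirs[g] = "up" if observed > 0 else "down"
    for g in universe[10:15]:
        query_dirs[g] = "up"
    query = DEGSet("CNIT_vs_Normal", query_dirs)
    regulators = GeneSetCollection({"REG1": signs})
    return query, regulators, universe


def generate_pathway_fixture():
    """A 109-member pathway with exactly 54 members in the query.

    Mirrors the study's top-pathway overlap (54/109 = 49.5%).  Returns
    (query DEGSet, GeneSetCollection, universe).
    """
    universe = [f"PWG{i:04d}" for i in range(1600)]
    pathway = universe[:109]
    query_genes = pathway[:54] + universe[200 : 200 + 1429]
    query = DEGSet(
        "CNIT_vs_Normal", {g: ("up" if i % 2 else "down") for i, g in enumerate(query_genes)}
    )
    sets = GeneSetCollection({"oxidative_phosphorylation": {g: -1 for g in pathway}})
    return query, sets, universe
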