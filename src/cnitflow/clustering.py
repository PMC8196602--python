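"""Supervised hierarchical clustering of samples and qPCR group comparison.

"Supervised" here means feature preselection: samples are clustered on the
differentially expressed probesets only (the clustering itself is ordinary
agglomerative clustering).  Defaults follow the microarray-heatmap
convention — distance = 1 - Pearson correlation between samples over the
selected features, average linkage — and both are configurable.

The qPCR comparison works on delta-Ct (target Ct minus reference-gene Ct;
lower delta-Ct = higher expression) with a pooled-variance two-sample t
and per-group 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .types import ExpressionMatrix, QpcrTable, SampleTable, ValidationError


@dataclass
class ClusteringResult:
    """Agglomerative clustering of samples over DE features.

    ``linkage_matrix`` is the scipy (n-1, 4) merge list; ``leaf_order`` a
    permutation of ``sample_ids``; ``cut_labels`` the two-cluster cut;
    ``agreement`` the best-mapping fraction of samples whose cluster
    matches their condition label.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    cut_labels: dict[str, int]
    agreement: float

    def __post_init__(self) -> None:
        if sorted(self.leaf_order) != sorted(self.sample_ids):
            raise ValidationError("leaf order is not a permutation of sample ids")
        heights = self.linkage_matrix[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValidationError("merge heights decrease")


def label_agreement(labels_a: dict[str, int], labels_b: dict[str, str]) -> float:
    """Best-permutation agreement between two labelings of the same samples.

    Maximizes, over injective mappings from cluster ids to condition
    labels, the fraction of samples on which the mapped labels coincide.
    Invariant under renaming of either side's labels.
    """
    samples = list(labels_a)
    clusters = sorted(set(labels_a.values()))
    conditions = sorted(set(labels_b[s] for s in samples))
    short, long_ = (clusters, conditions) if len(clusters) <= len(conditions) else (
        conditions,
        clusters,
    )
    best = 0
    for perm in permutations(long_, len(short)):
        if len(clusters) <= len(conditions):
            mapping = dict(zip(clusters, perm))
            hits = sum(1 for s in samples if mapping[labels_a[s]] == labels_b[s])
        else:
            mapping = dict(zip(perm, short))
            hits = sum(
                1 for s in samples if mapping.get(labels_a[s]) == labels_b[s]
            )
        best = max(best, hits)
    return best / len(samples)


def supervised_cluster(
    matrix: ExpressionMatrix,
    de_features: list[str],
    meta: SampleTable,
    method: str = "average",
    metric: str = "correlation",
) -> ClusteringResult:
    """Cluster samples on the given DE features and score the grouping.

    Raises if fewer than 2 features or 3 samples are available, or if a
    sample has zero variance over the selected features (correlation
    distance undefined), naming the sample.
    """
    feats = [f for f in de_features if f in matrix.data.index]
    if len(feats) < 2:
        raise ValidationError("need >= 2 DE features present in the matrix")
    if matrix.shape[1] < 3:
        raise ValidationError("need >= 3 samples to cluster")
    X = matrix.data.loc[feats].to_numpy().T  # samples x features
    if metric == "correlation":
        sds = X.std(axis=1)
        flat = np.flatnonzero(sds == 0)
        if flat.size:
            raise ValidationError(
                f"sample {matrix.sample_ids[flat[0]]!r} has zero variance over the "
                "selected features; correlation distance undefined"
            )
    d = pdist(X, metric=metric)
    Z = linkage(d, method=method)
    order = [matrix.sample_ids[i] for i in leaves_list(Z)]
    cut = fcluster(Z, t=2, criterion="maxclust")
    cut_labels = {s: int(c) for s, c in zip(matrix.sample_ids, cut)}
    meta_map = dict(zip(meta.data["sample_id"], meta.data["condition"]))
    missing = [s for s in matrix.sample_ids if s not in meta_map]
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing[:5]}")
    agreement = label_agreement(cut_labels, meta_map)
    return ClusteringResult(
        feature_ids=feats,
        sample_ids=matrix.sample_ids,
        linkage_matrix=Z,
        leaf_order=order,
        cut_labels=cut_labels,
        agreement=agreement,
    )


@dataclass
class QpcrComparison:
    gene: str
    group1: str
    group2: str
    mean_delta_ct: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    t_statistic: float
    p_value: float
    n: dict[str, int]


def qpcr_compare(table: QpcrTable, gene: str, group1: str, group2: str) -> QpcrComparison:
    """Compare delta-Ct of one gene between two condition groups.

    Pooled-variance two-sided Student t on delta-Ct; group means with
    95% t-based confidence intervals.  Lower delta-Ct means higher
    expression of the target gene.
    """
    df = table.data[table.data["gene"] == gene]
    values = {}
    for grp in (group1, group2):
        v = df.loc[df["condition"] == grp, "delta_ct"].to_numpy(dtype=float)
        if v.size < 2:
            raise ValidationError(f"group {grp!r} has < 2 measurements for {gene!r}")
        values[grp] = v
    x1, x2 = values[group1], values[group2]
    n1, n2 = len(x1), len(x2)
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    dof = n1 + n2 - 2
    if sp2 == 0:
        t_stat, p = (0.0, 1.0) if x1.mean() == x2.mean() else (np.inf, 0.0)
    else:
        t_stat = (x1.mean() - x2.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = float(2 * stats.t.sf(abs(t_stat), dof))
    ci = {}
    for grp, v in values.items():
        se = v.std(ddof=1) / np.sqrt(len(v))
        half = stats.t.ppf(0.975, len(v) - 1) * se
        ci[grp] = (float(v.mean() - half), float(v.mean() + half))
    return QpcrComparison(
        gene=gene,
        group1=group1,
        group2=group2,
        mean_delta_ct={g: float(v.mean()) for g, v in values.items()},
        ci95=ci,
        t_statistic=float(t_stat),
        p_value=p,
        n={g: len(v) for g, v in values.items()},
    )


def write_clustering(result: ClusteringResult, out_dir) -> None:
    """Emit leaf order and merge list as TSVs."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "leaf_order.tsv"), "w", encoding="utf-8", newline="\n") as fh:
        fh.write("position\tsample_id\tcluster\n")
        for i, s in enumerate(result.leaf_order):
            fh.write(f"{i}\t{s}\t{result.cut_labels[s]}\n")
    merge = pd.DataFrame(
        result.linkage_matrix, columns=["left", "right", "height", "size"]
    )
    merge.to_csv(os.path.join(out_dir, "merges.tsv"), sep="\t", index=False, lineterminator="\n")


def plot_heatmap(matrix: ExpressionMatrix, result: ClusteringResult, path) -> None:
    """Feature-by-sample heatmap with samples in dendrogram leaf order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.data.loc[result.feature_ids, result.leaf_order]
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * data.shape[1]), max(3, 0.05 * data.shape[0])))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="log2 intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
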