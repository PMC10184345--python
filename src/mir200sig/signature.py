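"""Supervised derivation of the anchor-microRNA gene signature.

Tumors are ranked by the anchor microRNA (miR-429 or the mean of the
chromosome-1 miR-200 cluster), the extreme tails are contrasted by Welch's
t, and the top differential genes are intersected with the most-variable
genes from the unsupervised analysis.  Hierarchical clustering on the
resulting signature yields the supervised classes (I = anchor-low,
IIA/IIB = anchor-high) whose I-vs-II split seeds the deconvolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterAssignment, hierarchical_cluster
from .io import DataFormatError, ExpressionMatrix, SampleAnnotations
from .preprocess import VariableGeneSet


@dataclass
class GeneSignature:
    """Derived gene list with per-gene contrast statistic and direction.

    ``table`` is indexed by gene with columns ``t`` (Welch statistic,
    positive = higher in anchor-high tumors) and ``direction``
    ("up" / "down"), ordered by |t| descending.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise DataFormatError("signature genes must be unique")
        if not np.isfinite(self.table["t"].to_numpy()).all():
            raise DataFormatError("signature statistics must be finite")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def extreme_groups(
    annotations: SampleAnnotations, n_extreme: int,
    anchor: pd.Series | None = None,
) -> tuple[list[str], list[str]]:
    """Bottom-n and top-n samples by anchor value.

    Ties at a group boundary are broken by lexicographic sample id (with a
    warning).  All-identical anchor values are rejected as a degenerate
    ranking.
    """
    values = annotations.anchor if anchor is None else anchor
    values = values.dropna()
    if len(values) < 2 * n_extreme:
        raise DataFormatError(
            f"need >= {2 * n_extreme} samples with known anchor values, "
            f"have {len(values)}"
        )
    if values.nunique() == 1:
        raise DataFormatError("degenerate anchor ranking: all anchor values identical")
    order = pd.DataFrame({"value": values, "sample": values.index})
    order = order.sort_values(["value", "sample"], ascending=[True, True])
    low = list(order["sample"].iloc[:n_extreme])
    high = list(order["sample"].iloc[-n_extreme:])
    v = order["value"].to_numpy()
    if len(v) > n_extreme:
        if v[n_extreme - 1] == v[n_extreme]:
            warnings.warn("anchor tie at the low-group boundary; broken by sample id")
        if v[-n_extreme] == v[-n_extreme - 1]:
            warnings.warn("anchor tie at the high-group boundary; broken by sample id")
    return low, high


def welch_t(
    matrix: ExpressionMatrix, group_a: list[str], group_b: list[str]
) -> pd.Series:
    """Per-gene Welch two-sample t, positive = higher in ``group_b``.

    Genes with zero variance in both groups get t = 0 when the means agree
    (with a warning); when the means differ, the standard error is replaced
    by the smallest positive one observed so the statistic stays finite.
    """
    a = matrix.values[group_a].to_numpy(dtype=float)
    b = matrix.values[group_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise DataFormatError("each group needs >= 2 samples")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se = np.sqrt(va / na + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / se
    zero = se == 0
    if zero.any():
        equal = zero & np.isclose(ma, mb)
        if equal.any():
            warnings.warn(
                f"{int(equal.sum())} gene(s) with zero variance in both groups; t set to 0"
            )
            t[equal] = 0.0
        unequal = zero & ~np.isclose(ma, mb)
        if unequal.any():
            fallback = se[se > 0].min() if (se > 0).any() else np.finfo(float).eps
            warnings.warn(
                f"{int(unequal.sum())} zero-variance gene(s) with differing means; "
                "smallest positive standard error substituted"
            )
            t[unequal] = (mb[unequal] - ma[unequal]) / fallback
    return pd.Series(t, index=matrix.values.index, name="t")


def rank_differential(
    matrix: ExpressionMatrix, group_a: list[str], group_b: list[str], n_de: int
) -> pd.DataFrame:
    """Top ``n_de`` genes by |Welch t| between the two groups.

    ``group_a`` is the anchor-low tail and ``group_b`` the anchor-high tail,
    so positive t marks genes up in anchor-high tumors.  Ties in |t| are
    broken by gene symbol.
    """
    if set(group_a) & set(group_b):
        raise DataFormatError("groups must be disjoint")
    t = welch_t(matrix, group_a, group_b)
    table = pd.DataFrame({"t": t, "abs_t": t.abs(), "gene": t.index})
    table = table.sort_values(["abs_t", "gene"], ascending=[False, True])
    table = table.head(n_de).drop(columns=["abs_t", "gene"])
    table["direction"] = np.where(table["t"] >= 0, "up", "down")
    return table


def derive_signature(
    de_table: pd.DataFrame, variable_set: VariableGeneSet, metadata: dict | None = None
) -> GeneSignature:
    """Intersect the differential list with the most-variable genes.

    Order (by |t|) and statistics come from the differential ranking; the
    result is the supervised signature (the study's 493-gene analogue).
    """
    if len(de_table) == 0 or len(variable_set.genes) == 0:
        raise DataFormatError("both gene lists must be non-empty")
    keep = de_table.index.isin(set(variable_set.genes))
    table = de_table.loc[keep]
    if len(table) == 0:
        raise DataFormatError("empty intersection between differential and variable genes")
    meta = {
        "n_de": len(de_table),
        "n_variable": variable_set.n_requested,
        "n_signature": len(table),
    }
    meta.update(metadata or {})
    return GeneSignature(table.copy(), meta)


def _class_names(k: int) -> list[str]:
    if k == 2:
        return ["I", "II"]
    if k == 3:
        return ["I", "IIA", "IIB"]
    return [f"C{i + 1}" for i in range(k)]


def cluster_on_signature(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    annotations: SampleAnnotations,
    k: int = 3,
    distance: str = "pearson",
    linkage: str = "ward",
) -> ClusterAssignment:
    """Hierarchical clustering restricted to signature genes.

    Clusters are named by mean anchor value ascending: the anchor-low
    cluster is "I"; for k = 3 the two anchor-high clusters are "IIA" and
    "IIB" (ascending anchor).
    """
    assignment = hierarchical_cluster(matrix, signature.genes, k, distance, linkage)
    anchor = annotations.anchor
    means = {
        label: anchor.reindex(assignment.members(label)).mean()
        for label in assignment.labels.unique()
    }
    ordered = sorted(means, key=lambda lb: (means[lb], lb))
    rename = dict(zip(ordered, _class_names(k)))
    labels = assignment.labels.map(rename).rename("cluster")
    return ClusterAssignment(labels, k, distance, linkage)


def mutation_enrichment(
    assignment: ClusterAssignment | pd.Series, annotations: SampleAnnotations
) -> pd.DataFrame:
    """Fisher exact enrichment of each mutation flag in each cluster.

    For every (cluster, gene) pair, tests mutant frequency inside the
    cluster against the rest of the cohort (samples with unknown status
    excluded).  Returns odds ratios and two-sided p-values.
    """
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) else assignment
    rows = []
    for gene in annotations.mutation_genes:
        flags = annotations.mutation_flags(gene).reindex(labels.index)
        known = flags != "unknown"
        for cluster in sorted(labels.unique()):
            inside = (labels == cluster) & known
            outside = (labels != cluster) & known
            a = int(((flags == "mutant") & inside).sum())
            b = int(((flags == "wild-type") & inside).sum())
            c = int(((flags == "mutant") & outside).sum())
            d = int(((flags == "wild-type") & outside).sum())
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {"cluster": cluster, "gene": gene, "n_mut_in": a, "n_wt_in": b,
                 "n_mut_out": c, "n_wt_out": d, "odds_ratio": odds, "p_value": p}
            )
    return pd.DataFrame(rows)
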