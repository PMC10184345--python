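"""Unsupervised expression subtyping.

Agglomerative clustering of samples on a gene subset (distance
1 - Pearson correlation, Ward linkage by default, the dominant convention
for expression heatmaps) and nearest-centroid assignment by correlation
against reference class profiles, the device used to match de-novo
clusters to published LUAD subtypes (TRU / PI / PP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .io import ClassCentroids, DataFormatError, ExpressionMatrix


@dataclass
class ClusterAssignment:
    """Sample -> cluster label for a k-group partition."""

    labels: pd.Series
    k: int
    distance: str
    linkage: str

    def __post_init__(self) -> None:
        n_nonempty = self.labels.nunique()
        if n_nonempty != self.k:
            raise DataFormatError(
                f"expected {self.k} non-empty clusters, found {n_nonempty}"
            )

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def partition(self) -> set[frozenset]:
        """Order-free view of the partition (for invariance checks)."""
        return {frozenset(self.members(lb)) for lb in self.labels.unique()}


@dataclass
class CentroidCorrelation:
    """Per-sample correlations with reference classes and argmax assignment."""

    correlations: pd.DataFrame  # samples x classes, values in [-1, 1]
    assigned: pd.Series


def _sample_distance(values: np.ndarray, distance: str, sample_ids: Sequence[str]) -> np.ndarray:
    """Condensed distance between sample columns of a genes x samples array."""
    if distance == "pearson":
        sd = values.std(axis=0)
        if (sd == 0).any():
            bad = sample_ids[int(np.argmax(sd == 0))]
            raise DataFormatError(
                f"sample {bad!r} has a constant profile; correlation undefined"
            )
        corr = np.corrcoef(values.T)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        return squareform(dist, checks=False)
    if distance == "euclidean":
        return pdist(values.T)
    raise DataFormatError(f"unknown distance {distance!r}")


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    k: int,
    distance: str = "pearson",
    linkage: str = "ward",
) -> ClusterAssignment:
    """Cut an agglomerative tree of samples into ``k`` groups.

    Labels ("C1", "C2", ...) are assigned by order of first appearance in
    the sample list, so the partition is deterministic given the input.
    """
    if not 2 <= k <= matrix.n_samples:
        raise DataFormatError(f"k={k} out of range for {matrix.n_samples} samples")
    sub = matrix.subset_genes(list(genes))
    cond = _sample_distance(sub.values.to_numpy(), distance, sub.sample_ids)
    tree = sch.linkage(cond, method=linkage)
    raw = sch.fcluster(tree, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        raise DataFormatError(
            f"tree cut produced {len(np.unique(raw))} clusters instead of {k}"
        )
    relabel: dict[int, str] = {}
    for r in raw:
        if r not in relabel:
            relabel[r] = f"C{len(relabel) + 1}"
    labels = pd.Series([relabel[r] for r in raw], index=sub.sample_ids, name="cluster")
    return ClusterAssignment(labels, k, distance, linkage)


def compute_centroids(
    matrix: ExpressionMatrix, assignment: ClusterAssignment | pd.Series,
    genes: Sequence[str] | None = None,
) -> ClassCentroids:
    """Per-class mean expression profiles over ``genes`` (default: all)."""
    labels = assignment.labels if isinstance(assignment, ClusterAssignment) else assignment
    missing = [s for s in labels.index if s not in matrix.values.columns]
    if missing:
        raise DataFormatError(f"assignment covers unknown samples: {missing[:5]}")
    sub = matrix if genes is None else matrix.subset_genes(list(genes))
    cols = {}
    for label in sorted(labels.unique()):
        members = labels.index[labels == label]
        if len(members) == 0:
            raise DataFormatError(f"class {label!r} is empty")
        cols[label] = sub.values[list(members)].mean(axis=1)
    return ClassCentroids(pd.DataFrame(cols))


def assign_by_centroid_correlation(
    matrix: ExpressionMatrix, reference: ClassCentroids
) -> CentroidCorrelation:
    """Pearson correlation of each sample with each reference class profile.

    Correlations are computed over the gene intersection; each sample is
    assigned the argmax class, breaking exact ties by class-name order
    (with a warning).
    """
    shared = [g for g in matrix.gene_ids if g in reference.profiles.index]
    if len(shared) < 2:
        raise DataFormatError(
            f"only {len(shared)} shared gene(s) between matrix and centroids"
        )
    x = matrix.values.loc[shared].to_numpy()  # genes x samples
    c = reference.profiles.loc[shared].to_numpy()  # genes x classes
    xs = x - x.mean(axis=0)
    cs = c - c.mean(axis=0)
    x_norm = np.sqrt((xs**2).sum(axis=0))
    c_norm = np.sqrt((cs**2).sum(axis=0))
    if (x_norm == 0).any():
        bad = matrix.sample_ids[int(np.argmax(x_norm == 0))]
        raise DataFormatError(f"sample {bad!r} has zero variance over shared genes")
    if (c_norm == 0).any():
        bad = reference.class_names[int(np.argmax(c_norm == 0))]
        raise DataFormatError(f"class {bad!r} has zero variance over shared genes")
    corr = (xs.T @ cs) / np.outer(x_norm, c_norm)
    corr_df = pd.DataFrame(corr, index=matrix.sample_ids, columns=reference.class_names)
    # argmax with deterministic ties: class-name order
    ordered = corr_df[sorted(corr_df.columns)]
    assigned = ordered.idxmax(axis=1)
    ties = (ordered.to_numpy() == ordered.max(axis=1).to_numpy()[:, None]).sum(axis=1) > 1
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} sample(s) with tied centroid correlations; "
            "assigned by class-name order"
        )
    return CentroidCorrelation(corr_df, assigned.rename("assigned_class"))
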