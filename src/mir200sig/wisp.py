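"""Centroid-based constrained mixture deconvolution (weighted in silico
pathology).

Each tumor is modelled as a convex mixture of two pure transcriptional
programs ("miR-200-sign-up" and "miR-200-sign-down").  The model is fitted
by alternating (1) pure-class centroid estimation over near-pure samples
and (2) per-sample weight estimation under non-negativity and sum-to-one
constraints; a sample's up-weight is its "impregnation" of the up program.

Identifiability note: the mixing scale is anchored by the purest samples,
so the purity threshold must sit close to 1 -- admitting samples that are
20% admixed into the "pure" sets shrinks the centroid separation and
stretches every estimated weight accordingly.  The default threshold is
0.95 (config-exposed; the approach's internal value is not published).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import CLASS_DOWN, CLASS_UP, ClassCentroids, DataFormatError, ExpressionMatrix
from .signature import welch_t


@dataclass
class MixtureWeights:
    """Per-sample non-negative class weights summing to one.

    ``weights`` is samples x classes; ``residual`` the per-sample Euclidean
    norm of the reconstruction error over the centroid panel.
    """

    weights: pd.DataFrame
    residual: pd.Series

    def __post_init__(self) -> None:
        w = self.weights.to_numpy()
        if (w < -1e-9).any() or (w > 1 + 1e-9).any():
            raise DataFormatError("mixture weights must lie in [0, 1]")
        if not np.allclose(w.sum(axis=1), 1.0, atol=1e-9):
            raise DataFormatError("mixture weights must sum to 1 per sample")
        if (self.residual < -1e-12).any():
            raise DataFormatError("residuals must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.weights.index)

    def up_weight(self) -> pd.Series:
        return self.weights[CLASS_UP]


@dataclass
class WispModel:
    """Fitted deconvolution model: panel centroids and convergence state."""

    centroids: ClassCentroids
    purity_threshold: float
    iterations: int
    pure_samples: dict[str, list[str]] = field(default_factory=dict)

    @property
    def panel(self) -> list[str]:
        return self.centroids.gene_ids


def select_centroid_panel(
    matrix: ExpressionMatrix, initial_labels: pd.Series, n_panel: int = 150
) -> list[str]:
    """Most class-discriminant genes for the centroid panel.

    Genes are ranked by |Welch t| between the two initial classes; the top
    ``n_panel`` are returned with each direction guaranteed at least 25% of
    the panel when enough genes of that direction exist.  Ties break by
    gene symbol; swapping the class names leaves the panel unchanged.
    """
    classes = sorted(initial_labels.unique())
    if len(classes) != 2:
        raise DataFormatError(f"expected two initial classes, got {classes}")
    group_a = list(initial_labels.index[initial_labels == classes[0]])
    group_b = list(initial_labels.index[initial_labels == classes[1]])
    if len(group_a) < 2 or len(group_b) < 2:
        raise DataFormatError("each initial class needs >= 2 samples")
    if n_panel >= matrix.n_genes:
        warnings.warn(
            f"panel size {n_panel} >= {matrix.n_genes} genes; returning all genes"
        )
        return sorted(matrix.gene_ids)
    t = welch_t(matrix, group_a, group_b)
    ranked = (
        pd.DataFrame({"t": t, "abs_t": t.abs(), "gene": t.index})
        .sort_values(["abs_t", "gene"], ascending=[False, True])
    )
    selected = ranked.head(n_panel)
    quota = int(np.ceil(0.25 * n_panel))
    for sign in (1, -1):
        same = selected["t"] * sign > 0
        short = quota - int(same.sum())
        if short <= 0:
            continue
        pool = ranked.iloc[n_panel:]
        candidates = pool[pool["t"] * sign > 0].head(short)
        if len(candidates) == 0:
            continue
        # drop the weakest genes of the over-represented direction
        droppable = selected[selected["t"] * sign <= 0].tail(len(candidates))
        selected = pd.concat([selected.drop(droppable.index), candidates])
        selected = selected.sort_values(["abs_t", "gene"], ascending=[False, True])
    return list(selected["gene"])


def _align(x: pd.Series, centroids: ClassCentroids, min_overlap: float = 0.5):
    shared = [g for g in centroids.profiles.index if g in x.index]
    if len(shared) < 2:
        raise DataFormatError("need >= 2 shared genes with the centroid panel")
    if len(shared) < min_overlap * len(centroids.profiles):
        raise DataFormatError(
            f"only {len(shared)}/{len(centroids.profiles)} panel genes present; "
            "refusing to score (weights would be corrupted)"
        )
    return shared


def estimate_weights(
    x: pd.Series, centroids: ClassCentroids
) -> tuple[pd.Series, float]:
    """Simplex-constrained least-squares weights for one sample profile.

    Solves ``min ||x - sum_k w_k c_k||^2`` (per-gene weighted when the
    centroids carry weights) subject to ``w_k >= 0`` and ``sum w_k = 1``.
    With two classes the solution is the clamped 1-D projection onto the
    segment between the centroids; with more classes, non-negative least
    squares followed by simplex renormalization (an approximation).
    """
    shared = _align(x, centroids)
    c = centroids.profiles.loc[shared]
    xs = x.loc[shared].to_numpy(dtype=float)
    cw = (
        np.ones(len(shared))
        if centroids.weights is None
        else centroids.weights.loc[shared].to_numpy(dtype=float)
    )
    sw = np.sqrt(cw)
    cm = c.to_numpy(dtype=float) * sw[:, None]
    xv = xs * sw
    names = centroids.class_names
    if cm.shape[1] == 2:
        c0, c1 = cm[:, 0], cm[:, 1]
        d = c1 - c0
        denom = float(d @ d)
        if denom == 0.0:
            raise DataFormatError("degenerate centroids: classes are identical")
        w1 = float(np.clip((xv - c0) @ d / denom, 0.0, 1.0))
        w = np.array([1.0 - w1, w1])
    else:
        if np.allclose(cm - cm[:, [0]], 0.0):
            raise DataFormatError("degenerate centroids: classes are identical")
        w, _ = nnls(cm, xv)
        total = w.sum()
        if total == 0:
            w = np.full(len(names), 1.0 / len(names))
        else:
            w = w / total
    residual = float(np.linalg.norm(xv - cm @ w))
    return pd.Series(w, index=names, name=x.name), residual


def estimate_weights_matrix(
    matrix: ExpressionMatrix, centroids: ClassCentroids
) -> MixtureWeights:
    """Vectorized :func:`estimate_weights` over all samples of a matrix."""
    shared = _align(pd.Series(index=matrix.values.index, dtype=float), centroids)
    names = centroids.class_names
    x = matrix.values.loc[shared].to_numpy(dtype=float)
    cw = (
        np.ones(len(shared))
        if centroids.weights is None
        else centroids.weights.loc[shared].to_numpy(dtype=float)
    )
    sw = np.sqrt(cw)[:, None]
    cm = centroids.profiles.loc[shared].to_numpy(dtype=float) * sw
    xv = x * sw
    if len(names) == 2:
        c0, c1 = cm[:, [0]], cm[:, [1]]
        d = (c1 - c0).ravel()
        denom = float(d @ d)
        if denom == 0.0:
            raise DataFormatError("degenerate centroids: classes are identical")
        w1 = np.clip((xv - c0).T @ d / denom, 0.0, 1.0)
        w = np.column_stack([1.0 - w1, w1])
    else:
        w = np.empty((matrix.n_samples, len(names)))
        for j in range(matrix.n_samples):
            ws, _ = estimate_weights(matrix.values.iloc[:, j], centroids)
            w[j] = ws.to_numpy()
    recon = cm @ w.T
    residual = np.linalg.norm(xv - recon, axis=0)
    return MixtureWeights(
        pd.DataFrame(w, index=matrix.sample_ids, columns=names),
        pd.Series(residual, index=matrix.sample_ids, name="residual"),
    )


def fit_model(
    matrix: ExpressionMatrix,
    initial_labels: pd.Series,
    n_panel: int = 150,
    purity_threshold: float = 0.95,
    max_iterations: int = 10,
    panel: list[str] | None = None,
) -> WispModel:
    """Fit pure-class centroids by iterative purity refinement.

    ``initial_labels`` maps every sample to one of the two class names
    (down = supervised cluster I, up = cluster II).  Iteration: centroids
    are per-class means over the current pure sets (initially all class
    members); weights are re-estimated for every sample; the pure sets
    become the samples whose top weight reaches the purity threshold.
    Stops when the pure sets are stable or ``max_iterations`` is reached.

    The centroid panel is chosen by :func:`select_centroid_panel` unless an
    explicit ``panel`` gene list is supplied (e.g. genes pre-ranked by their
    association with the anchor, which keeps the panel off side programs
    that merely co-vary with the class cut).
    """
    classes = sorted(initial_labels.unique())
    if len(classes) != 2:
        raise DataFormatError(f"expected two initial classes, got {classes}")
    if panel is None:
        panel = select_centroid_panel(matrix, initial_labels, n_panel)
    else:
        missing = [g for g in panel if g not in matrix.values.index]
        if missing:
            raise DataFormatError(f"panel genes not in matrix: {missing[:5]}")
    sub = matrix.subset_genes(panel)
    pure = {cl: sorted(initial_labels.index[initial_labels == cl]) for cl in classes}
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        cols = {cl: sub.values[pure[cl]].mean(axis=1) for cl in classes}
        centroids = ClassCentroids(pd.DataFrame(cols)[classes])
        weights = estimate_weights_matrix(sub, centroids)
        new_pure = {}
        for cl in classes:
            w = weights.weights[cl]
            new_pure[cl] = sorted(w.index[w >= purity_threshold])
            if not new_pure[cl]:
                raise DataFormatError(
                    f"class {cl!r} lost all pure samples at iteration {iterations}"
                )
        if new_pure == pure:
            pure = new_pure
            break
        pure = new_pure
    cols = {cl: sub.values[pure[cl]].mean(axis=1) for cl in classes}
    centroids = ClassCentroids(pd.DataFrame(cols)[classes])
    return WispModel(centroids, purity_threshold, iterations, pure)


def classify(weights: MixtureWeights, cutoff: float = 0.5) -> pd.Series:
    """Binary class from the up-weight: > cutoff is up, otherwise down.

    A weight exactly at the cutoff is conservatively assigned down, with a
    warning.
    """
    up = weights.up_weight()
    at_cutoff = up == cutoff
    if at_cutoff.any():
        warnings.warn(
            f"{int(at_cutoff.sum())} sample(s) exactly at the cutoff; assigned "
            f"{CLASS_DOWN!r}"
        )
    labels = np.where(up > cutoff, CLASS_UP, CLASS_DOWN)
    return pd.Series(labels, index=up.index, name="wisp_class")


def quartile_bins(weights: MixtureWeights) -> pd.Series:
    """Quartile bin (Q1 lowest up-weight .. Q4 highest) per sample.

    Samples are ordered by (up-weight, sample id) and split at empirical
    quartile ranks: sample at rank r of n lands in bin floor(4 r / n), so
    sizes differ by at most one and any remainder goes to the lower bins.
    """
    up = weights.up_weight()
    n = len(up)
    if n < 4:
        raise DataFormatError("need >= 4 samples for quartile binning")
    order = pd.DataFrame({"w": up, "sample": up.index}).sort_values(
        ["w", "sample"], ascending=[True, True]
    )
    ranks = np.arange(n)
    bins = ranks * 4 // n
    labels = pd.Series(
        [f"Q{b + 1}" for b in bins], index=order["sample"], name="quartile"
    )
    return labels.reindex(up.index)
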