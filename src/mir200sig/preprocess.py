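"""Normalization, sample QC and variable-gene selection.

Counts are converted to log2 counts-per-million with a prior count, samples
with low tumor-cell content are excluded (strict less-than threshold), and
the most variable genes (by per-gene variance of logCPM, or MAD) feed the
unsupervised clustering and the supervised signature intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DataFormatError, ExpressionMatrix, SampleAnnotations


@dataclass
class VariableGeneSet:
    """Ordered most-variable gene list with its dispersion statistic."""

    genes: list[str]
    statistic: pd.Series  # aligned with genes, non-increasing
    n_requested: int

    def __post_init__(self) -> None:
        stats = self.statistic.loc[self.genes].to_numpy()
        if np.any(np.diff(stats) > 1e-12):
            raise DataFormatError("variable-gene statistic must be non-increasing")


def counts_to_logcpm(matrix: ExpressionMatrix, prior_count: float = 0.5) -> ExpressionMatrix:
    """log2 CPM: value(g, s) = log2((count + c) / (libsize + 2c) * 1e6).

    The library-size offset of twice the prior count keeps the transform
    exact for a hypothetical gene carrying the whole library.
    """
    if matrix.unit != "counts":
        raise DataFormatError(f"expected counts matrix, got unit {matrix.unit!r}")
    counts = matrix.values.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = matrix.sample_ids[int(np.argmax(lib <= 0))]
        raise DataFormatError(f"zero library size for sample {bad!r}")
    c = float(prior_count)
    logcpm = np.log2((counts + c) / (lib + 2 * c) * 1e6)
    return ExpressionMatrix(
        pd.DataFrame(logcpm, index=matrix.values.index, columns=matrix.values.columns),
        unit="logCPM",
    )


def filter_by_tumor_content(
    annotations: SampleAnnotations, min_fraction: float = 0.20
) -> list[str]:
    """Samples retained after the tumor-cell-content QC.

    Exclusion is strict less-than (a sample exactly at the threshold is
    kept); samples with unknown content are retained with a warning.
    """
    tc = annotations.df["tumor_content"]
    unknown = tc.isna()
    if unknown.any():
        warnings.warn(
            f"{int(unknown.sum())} sample(s) with unknown tumor content retained"
        )
    keep = unknown | (tc >= min_fraction)
    return list(annotations.df.index[keep])


def select_most_variable(
    matrix: ExpressionMatrix, n: int, statistic: str = "variance"
) -> VariableGeneSet:
    """Top ``n`` genes by dispersion across samples (ties: lexicographic symbol)."""
    if matrix.unit != "logCPM":
        raise DataFormatError("variable-gene selection expects a logCPM matrix")
    if n < 1:
        raise DataFormatError("n must be >= 1")
    vals = matrix.values
    if statistic == "variance":
        stat = vals.var(axis=1, ddof=1)
    elif statistic == "mad":
        med = vals.median(axis=1)
        stat = (vals.sub(med, axis=0)).abs().median(axis=1)
    else:
        raise DataFormatError(f"unknown dispersion statistic {statistic!r}")
    if n > len(stat):
        warnings.warn(f"requested {n} genes but only {len(stat)} available")
        n = len(stat)
    # deterministic: sort by (-stat, symbol)
    order = pd.DataFrame({"stat": stat, "gene": stat.index})
    order = order.sort_values(["stat", "gene"], ascending=[False, True])
    top = order.head(n)
    return VariableGeneSet(list(top["gene"]), stat, n)
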