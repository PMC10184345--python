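"""EMT scores, marker-based immune scores, single-gene comparisons and
pre-ranked gene-set enrichment.

Three EMT scores are provided, with fixed sign conventions:

* ``emt_76gs`` -- correlation-weighted sum over a signature set, weights
  being each gene's Pearson correlation with an epithelial anchor gene
  (CDH1 by default); HIGHER = more epithelial.
* ``emt_ks`` -- signed two-sample Kolmogorov-Smirnov statistic between the
  per-sample expression distributions of an epithelial and a mesenchymal
  gene set; POSITIVE = more mesenchymal, so it is anticorrelated with
  ``emt_76gs`` by construction.
* ``emt_kgene`` -- mean of direction-signed per-gene z-scores over a small
  panel (e.g. a 7-gene panel); higher = more mesenchymal.

Marker scores are arithmetic means of logCPM over marker genes per cell
population (MCP-counter style).  Pre-ranked GSEA uses the weighted
running-sum statistic with a gene-set permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataFormatError, ExpressionMatrix, GeneSetCollection
from .wisp import MixtureWeights


# ---------------------------------------------------------------------------
# EMT scores
# ---------------------------------------------------------------------------

def emt_76gs(
    matrix: ExpressionMatrix, signature_set: Sequence[str], anchor_gene: str = "CDH1"
) -> pd.Series:
    """Correlation-weighted EMT score (higher = more epithelial).

    Each signature gene g gets weight w_g = corr(g, anchor) across samples
    (0, with a warning, if either profile is constant); the per-sample
    score is the w-weighted sum of expression, mean-centered across the
    cohort so per-gene offsets cancel.
    """
    if anchor_gene not in matrix.values.index:
        raise DataFormatError(f"anchor gene {anchor_gene!r} absent from matrix")
    genes = [g for g in signature_set if g in matrix.values.index]
    if len(genes) < 2:
        raise DataFormatError("need >= 2 signature genes present in the matrix")
    if matrix.n_samples < 3:
        raise DataFormatError("need >= 3 samples to estimate correlation weights")
    x = matrix.values.loc[genes].to_numpy(dtype=float)
    a = matrix.values.loc[anchor_gene].to_numpy(dtype=float)
    ac = a - a.mean()
    a_norm = np.sqrt((ac**2).sum())
    xc = x - x.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((xc**2).sum(axis=1))
    w = np.zeros(len(genes))
    ok = (x_norm > 0) & (a_norm > 0)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} constant profile(s); correlation weight set to 0"
        )
    if a_norm > 0:
        w[ok] = (xc[ok] @ ac) / (x_norm[ok] * a_norm)
    raw = w @ x
    score = raw - raw.mean()
    return pd.Series(score, index=matrix.sample_ids, name="emt_76gs")


def _signed_ks(epi: np.ndarray, mes: np.ndarray) -> float:
    """Signed two-sample KS: + when the mesenchymal set sits higher."""
    grid = np.sort(np.concatenate([epi, mes]))
    f_epi = np.searchsorted(np.sort(epi), grid, side="right") / len(epi)
    f_mes = np.searchsorted(np.sort(mes), grid, side="right") / len(mes)
    d_plus = float(np.max(f_epi - f_mes))  # mes shifted to higher values
    d_minus = float(np.max(f_mes - f_epi))
    if d_plus > d_minus:
        return d_plus
    if d_minus > d_plus:
        return -d_minus
    return 0.0  # equal maxima: sign undefined, score 0 keeps antisymmetry exact


def emt_ks(
    matrix: ExpressionMatrix,
    epithelial_set: Sequence[str],
    mesenchymal_set: Sequence[str],
) -> pd.Series:
    """Signed Kolmogorov-Smirnov EMT score in [-1, 1] (positive = mesenchymal).

    Per sample, compares the empirical distribution of expression over the
    epithelial genes with that over the mesenchymal genes; the score is the
    maximal ECDF separation, signed positive when the mesenchymal
    distribution dominates (sits at higher expression).
    """
    epi = [g for g in epithelial_set if g in matrix.values.index]
    mes = [g for g in mesenchymal_set if g in matrix.values.index]
    if len(epi) < 2 or len(mes) < 2:
        raise DataFormatError("both gene sets need >= 2 members present in the matrix")
    overlap = set(epi) & set(mes)
    if overlap:
        raise DataFormatError(f"sets overlap after intersection: {sorted(overlap)[:5]}")
    e = matrix.values.loc[epi].to_numpy(dtype=float)
    m = matrix.values.loc[mes].to_numpy(dtype=float)
    scores = [_signed_ks(e[:, j], m[:, j]) for j in range(matrix.n_samples)]
    return pd.Series(scores, index=matrix.sample_ids, name="emt_ks")


def emt_kgene(
    matrix: ExpressionMatrix, gene_list: Sequence[str], directions: Mapping[str, str]
) -> pd.Series:
    """Mean direction-signed z-score over a small gene panel.

    ``directions`` maps each gene to "epithelial" or "mesenchymal";
    epithelial genes enter with flipped sign so that higher = more
    mesenchymal.  Constant genes contribute 0 with a warning.
    """
    genes = [g for g in gene_list if g in matrix.values.index]
    if not genes:
        raise DataFormatError("no panel gene present in the matrix")
    for g in genes:
        if directions.get(g) not in ("epithelial", "mesenchymal"):
            raise DataFormatError(f"gene {g!r} needs direction epithelial|mesenchymal")
    x = matrix.values.loc[genes].to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant gene(s) contribute 0 to the score")
        sd[sd == 0] = 1.0
    z = (x - mu) / sd
    z[flat] = 0.0
    sign = np.array([-1.0 if directions[g] == "epithelial" else 1.0 for g in genes])
    score = (z * sign[:, None]).mean(axis=0)
    return pd.Series(score, index=matrix.sample_ids, name="emt_kgene")


# ---------------------------------------------------------------------------
# Marker scores and group comparisons
# ---------------------------------------------------------------------------

def marker_scores(
    matrix: ExpressionMatrix, marker_sets: GeneSetCollection
) -> pd.DataFrame:
    """Mean logCPM of present marker genes per population (samples x populations).

    Populations with no marker present are omitted with a warning.
    """
    cols = {}
    for name, members in marker_sets.sets.items():
        present = [g for g in members if g in matrix.values.index]
        if not present:
            warnings.warn(f"population {name!r}: no marker gene present; omitted")
            continue
        cols[name] = matrix.values.loc[present].mean(axis=0)
    if not cols:
        raise DataFormatError("no population has any marker gene in the matrix")
    return pd.DataFrame(cols, index=matrix.sample_ids)


def compare_gene_across_groups(
    matrix: ExpressionMatrix, gene: str, groups: Mapping[str, Sequence[str]]
) -> dict:
    """Per-group median/IQR of one gene plus a rank-based test.

    Two groups: two-sided Wilcoxon rank-sum (Mann-Whitney); more groups:
    Kruskal-Wallis.
    """
    if gene not in matrix.values.index:
        raise DataFormatError(f"gene {gene!r} absent from matrix")
    if len(groups) < 2:
        raise DataFormatError("need >= 2 groups")
    x = matrix.values.loc[gene]
    arrays, summary = [], {}
    for name, members in groups.items():
        vals = x.reindex(list(members)).dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            raise DataFormatError(f"group {name!r} needs >= 2 samples")
        arrays.append(vals)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        summary[name] = {"n": len(vals), "median": med, "iqr": (q1, q3)}
    if len(arrays) == 2:
        res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        test = "wilcoxon-rank-sum"
    else:
        res = stats.kruskal(*arrays)
        test = "kruskal-wallis"
    return {"gene": gene, "groups": summary, "test": test,
            "statistic": float(res.statistic), "p_value": float(res.pvalue)}


# ---------------------------------------------------------------------------
# Pre-ranked GSEA
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Enrichment of one gene set in a ranked gene list."""

    name: str
    es: float
    nes: float
    p_value: float
    n_permutations: int
    n_hits: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.es <= 1.0 + 1e-12:
            raise DataFormatError("|ES| must be <= 1")
        if not 0 < self.p_value <= 1:
            raise DataFormatError("p-value must lie in (0, 1]")


def _running_sum_es(stats_abs_p: np.ndarray, hit_mask: np.ndarray) -> float:
    """Signed maximal deviation of the weighted running sum."""
    n = len(stats_abs_p)
    n_hits = int(hit_mask.sum())
    hit_total = stats_abs_p[hit_mask].sum()
    steps = np.where(
        hit_mask,
        (stats_abs_p / hit_total) if hit_total > 0 else (1.0 / n_hits),
        -1.0 / (n - n_hits),
    )
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def rank_genes_by_weight_association(
    matrix: ExpressionMatrix, weights: MixtureWeights | pd.Series
) -> pd.DataFrame:
    """Genes ordered by Pearson correlation with the up-weight (descending).

    This is the ranking fed to :func:`preranked_gsea`, mirroring tumors
    ordered by their up-signature impregnation.  Constant genes get
    correlation 0 with a warning; ties break by gene symbol.
    """
    up = weights.up_weight() if isinstance(weights, MixtureWeights) else weights
    up = up.reindex(matrix.sample_ids)
    if up.isna().any():
        raise DataFormatError("weights must cover every matrix sample")
    x = matrix.values.to_numpy(dtype=float)
    w = up.to_numpy(dtype=float)
    wc = w - w.mean()
    w_norm = np.sqrt((wc**2).sum())
    xc = x - x.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((xc**2).sum(axis=1))
    r = np.zeros(matrix.n_genes)
    ok = (x_norm > 0) & (w_norm > 0)
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} constant gene(s); correlation set to 0")
    if w_norm > 0:
        r[ok] = (xc[ok] @ wc) / (x_norm[ok] * w_norm)
    table = pd.DataFrame({"r": r, "gene": matrix.gene_ids}, index=matrix.gene_ids)
    table = table.sort_values(["r", "gene"], ascending=[False, True])
    return table.drop(columns="gene")


def preranked_gsea(
    ranked: pd.DataFrame | pd.Series,
    gene_set: Sequence[str],
    name: str = "",
    p_exponent: float = 1.0,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> EnrichmentResult:
    """Weighted running-sum enrichment with a gene-set permutation null.

    Hits increment by |r|^p normalized over hits, misses decrement by
    1/(N - N_hits); ES is the signed maximal deviation.  The null permutes
    set membership uniformly over the ranking; the p-value is the
    exchangeable two-sided tail (1 + #{|ES_perm| >= |ES|}) / (n_perm + 1),
    with resolution 1/(n_perm + 1).  NES divides ES by the mean |ES| of
    same-sign permutations.
    """
    stats_series = ranked["r"] if isinstance(ranked, pd.DataFrame) else ranked
    genes = list(stats_series.index)
    n = len(genes)
    if n < 10:
        raise DataFormatError("ranking must cover >= 10 genes")
    hit_mask = np.isin(np.array(genes), np.array(list(gene_set)))
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise DataFormatError("gene set does not intersect the ranking")
    if n_hits == n:
        # every permutation is the set itself: ES = 1 deterministically
        return EnrichmentResult(name, 1.0, 1.0, 1.0, n_perm, n_hits)
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    weights_abs = np.abs(stats_series.to_numpy(dtype=float)) ** p_exponent
    if weights_abs.sum() == 0:
        warnings.warn("all ranking statistics are zero; hits weighted uniformly")
    es = _running_sum_es(weights_abs, hit_mask)
    perm_es = np.empty(n_perm)
    mask = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        mask[:] = False
        mask[gen.choice(n, size=n_hits, replace=False)] = True
        perm_es[i] = _running_sum_es(weights_abs, mask)
    p = (1 + int(np.sum(np.abs(perm_es) >= abs(es)))) / (n_perm + 1)
    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    if len(same_sign) == 0:
        warnings.warn("no same-sign permutation ES; NES undefined")
        nes = np.nan
    else:
        nes = es / np.mean(np.abs(same_sign))
    return EnrichmentResult(name, es, float(nes), p, n_perm, n_hits, seed)
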