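"""Synthetic lung-adenocarcinoma cohort generator with known ground truth.

Each tumor's logCPM expression is a convex mixture of two latent pure
programs (an anchor-miR-high "up"/epithelial program and an anchor-miR-low
"down"/mesenchymal program) plus i.i.d. Gaussian noise:

    x_s = p_s * C_up + (1 - p_s) * C_down + eps,   eps ~ N(0, noise_sd^2)

The anchor microRNA value is the true proportion plus noise, mutation flags
are Bernoulli with class-conditional probabilities (TP53 enriched in the
down class, EGFR/KRAS in the up class), and disease-free survival is
exponential with hazard h0 * exp(beta * (1 - p_s)), administratively
censored at a horizon with optional uniform dropout.

A secondary, KRAS-linked program (a block of genes shifted in KRAS-mutant
tumors, which concentrate in the up class) reproduces the substructure that
splits the anchor-high side of the cohort into two subclusters, so that a
three-group supervised clustering has the intended geometry.

A handful of planted genes carry canonical symbols (CDH1 and friends in the
up program, ZEB1/VIM/CD274 and friends in the down program, immune-marker
panels per population) so that EMT scores, marker scores and checkpoint-gene
comparisons can run on the synthetic cohort with their real-data defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CLASS_DOWN,
    CLASS_UP,
    AnalysisConfig,
    ClassCentroids,
    DataFormatError,
    ExpressionMatrix,
    GeneSetCollection,
    SampleAnnotations,
    write_annotations,
    write_centroids,
    write_expression,
    write_gmt,
    write_table,
)

# planted genes with canonical symbols, by program direction
EPITHELIAL_NAMED = ("CDH1", "ESRP1", "ESRP2", "GRHL2", "CLDN4", "EPCAM", "RAB25")
MESENCHYMAL_NAMED = ("ZEB1", "ZEB2", "VIM", "CDH2", "FN1", "SNAI2", "TWIST1", "CD274")

#: immune/stromal marker panels and the program side they are elevated on
MARKER_PANELS: dict[str, tuple[tuple[str, ...], str]] = {
    "LYMPHOCYTES": (("CD3E", "CD8A", "CD2", "CD3D", "CD3G", "IL7R"), "down"),
    "MONOCYTES": (("CD14", "CSF1R", "CD163", "MS4A7"), "down"),
    "FIBROBLASTS": (("COL1A1", "COL1A2", "PDGFRB", "FAP", "DCN"), "down"),
    "NEUTROPHILS": (("FCGR3B", "CXCR2", "CSF3R", "S100A8", "S100A9"), "up"),
    "ENDOTHELIAL": (("PECAM1", "VWF", "CDH5", "CLDN5"), "up"),
    "DENDRITIC": (("CD1C", "CLEC10A", "FCER1A", "CD1E"), "up"),
}

_STAGE_PROBS = {
    "IA": 0.26, "IB": 0.22, "IIA": 0.06, "IIB": 0.17,
    "IIIA": 0.22, "IIIB": 0.03, "IV": 0.04,
}


@dataclass
class SimulationParams:
    """Study conditions of the simulated cohort.

    Defaults mirror the modelled study: 107 tumors, a few hundred
    program genes with a 2-logCPM shift between pure programs, per-cell
    Gaussian noise of 0.5, an anchor read out at noise 0.05, uniform
    mixture proportions, class-conditional mutation probabilities strong
    enough for Fisher enrichment at n ~ 107, and a disease-free-survival
    hazard increasing in (1 - proportion) calibrated so the down-class
    median sits near 40 months while the up-class median exceeds the
    60-month administrative horizon.
    """

    n_samples: int = 107
    n_genes: int = 2000
    n_program_genes: int = 200
    n_secondary_genes: int = 100
    effect_size: float = 2.0
    secondary_effect: float = 2.0
    noise_sd: float = 0.5
    anchor_noise_sd: float = 0.05
    proportion_dist: str = "uniform"  # or "beta"
    proportion_beta: tuple[float, float] = (0.6, 0.6)
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    # per-gene Bernoulli mutation probabilities (P(mut | down), P(mut | up))
    mutation_probs: dict = field(
        default_factory=lambda: {
            "TP53": (0.60, 0.10),
            "KRAS": (0.10, 0.45),
            "EGFR": (0.05, 0.35),
            "STK11": (0.15, 0.10),
        }
    )
    # survival: hazard = baseline_hazard * exp(hazard_log_ratio * (1 - p));
    # baseline calibrated so the down-class (p < 0.5 mixture) median DFS sits
    # near 40 months while the up-class median exceeds the 60-month horizon
    hazard_log_ratio: float = 2.0
    baseline_hazard: float = 0.0037
    os_hazard_log_ratio: float = 0.9
    os_baseline_hazard: float = 0.0030
    censor_horizon: float = 60.0
    dropout_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_program_genes > self.n_genes:
            raise DataFormatError("n_program_genes must be <= n_genes")
        if self.n_program_genes + self.n_secondary_genes > self.n_genes:
            raise DataFormatError("program + secondary genes exceed n_genes")
        for v, name in ((self.noise_sd, "noise_sd"), (self.anchor_noise_sd, "anchor_noise_sd")):
            if v < 0:
                raise DataFormatError(f"{name} must be >= 0")
        if self.proportion_dist not in ("uniform", "beta"):
            raise DataFormatError(f"unknown proportion distribution {self.proportion_dist!r}")
        if not 0 <= self.dropout_fraction <= 1:
            raise DataFormatError("dropout_fraction must lie in [0, 1]")
        if self.baseline_hazard <= 0 or self.censor_horizon <= 0:
            raise DataFormatError("hazards and horizon must be positive")


@dataclass
class SyntheticCohort:
    """Generated cohort with full ground truth."""

    expression: ExpressionMatrix
    annotations: SampleAnnotations
    truth: pd.DataFrame  # per-sample true_proportion, true_class, secondary flag
    centroids: ClassCentroids  # true pure-program centroids over all genes
    program_genes: list[str]
    program_directions: pd.Series  # +1 up-program gene, -1 down-program gene
    secondary_genes: list[str]
    gene_sets: GeneSetCollection
    params: SimulationParams


def _gene_names(params: SimulationParams) -> tuple[list[str], np.ndarray, list[str]]:
    """Planted program genes (with directions), secondary genes, and null genes."""
    named_up = list(EPITHELIAL_NAMED)
    named_down = list(MESENCHYMAL_NAMED)
    for genes, side in MARKER_PANELS.values():
        (named_up if side == "up" else named_down).extend(genes)
    n_named = len(named_up) + len(named_down)
    if params.n_program_genes < n_named:
        raise DataFormatError(
            f"n_program_genes must be >= {n_named} to host the named gene panels"
        )
    n_extra = params.n_program_genes - n_named
    n_extra_up = (params.n_program_genes + 1) // 2 - len(named_up)
    n_extra_down = n_extra - n_extra_up
    if n_extra_up < 0 or n_extra_down < 0:
        raise DataFormatError("n_program_genes too small to balance directions")
    up = named_up + [f"PRGU{i:04d}" for i in range(n_extra_up)]
    down = named_down + [f"PRGD{i:04d}" for i in range(n_extra_down)]
    program = up + down
    directions = np.array([1] * len(up) + [-1] * len(down))
    secondary = [f"SEC{i:04d}" for i in range(params.n_secondary_genes)]
    n_null = params.n_genes - len(program) - len(secondary)
    null = [f"G{i:05d}" for i in range(n_null)]
    return program, directions, secondary + null


def simulate_cohort(params: SimulationParams | None = None) -> SyntheticCohort:
    """Draw a full cohort (expression, annotations, truth) from ``params``.

    The same seed always reproduces the same cohort.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    program, directions, rest = _gene_names(params)
    secondary = rest[: params.n_secondary_genes]
    genes = program + rest

    # true pure-program centroids
    base = rng.normal(params.baseline_mean, params.baseline_sd, size=len(genes))
    delta = np.zeros(len(genes))
    delta[: len(program)] = directions * params.effect_size
    c_up = base + delta / 2.0
    c_down = base - delta / 2.0

    # mixture proportions and classes
    if params.proportion_dist == "uniform":
        p = rng.uniform(0.0, 1.0, size=n)
    else:
        a, b = params.proportion_beta
        p = rng.beta(a, b, size=n)
    true_class = np.where(p > 0.5, CLASS_UP, CLASS_DOWN)

    # mutations (Bernoulli, class-conditional)
    mut = {}
    for gene, (p_down, p_up) in params.mutation_probs.items():
        probs = np.where(true_class == CLASS_UP, p_up, p_down)
        mut[gene] = rng.random(n) < probs

    # expression: convex mixture + secondary (KRAS-linked) program + noise
    x = np.outer(c_up, p) + np.outer(c_down, 1.0 - p)
    if secondary and "KRAS" in mut:
        sec_idx = [genes.index(g) for g in secondary]
        x[np.ix_(sec_idx, np.flatnonzero(mut["KRAS"]))] += params.secondary_effect
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, size=x.shape)

    anchor = p + rng.normal(0.0, params.anchor_noise_sd, size=n)

    # survival: exponential, administrative censoring + uniform dropout
    def draw_endpoint(h0: float, beta: float):
        hazard = h0 * np.exp(beta * (1.0 - p))
        t_event = rng.exponential(1.0 / hazard)
        censor = np.full(n, params.censor_horizon)
        dropout = rng.random(n) < params.dropout_fraction
        c_drop = rng.uniform(0.0, params.censor_horizon, size=n)
        censor = np.where(dropout, np.minimum(censor, c_drop), censor)
        time = np.minimum(t_event, censor)
        event = (t_event <= censor).astype(int)
        return time, event

    dfs_time, dfs_event = draw_endpoint(params.baseline_hazard, params.hazard_log_ratio)
    os_time, os_event = draw_endpoint(params.os_baseline_hazard, params.os_hazard_log_ratio)

    stage_levels = list(_STAGE_PROBS)
    stage = rng.choice(stage_levels, size=n, p=list(_STAGE_PROBS.values()))
    tumor_content = np.clip(rng.normal(0.55, 0.15, size=n), 0.20, 0.95)

    ann_df = pd.DataFrame(
        {
            "anchor_value": anchor,
            "dfs_time": dfs_time,
            "dfs_event": dfs_event,
            "os_time": os_time,
            "os_event": os_event,
            "stage": stage,
            "tumor_content": tumor_content,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for gene, flags in mut.items():
        ann_df[f"mut_{gene}"] = np.where(flags, "mutant", "wild-type")

    truth = pd.DataFrame(
        {
            "true_proportion": p,
            "true_class": true_class,
            "secondary_program": mut.get("KRAS", np.zeros(n, dtype=bool)).astype(int),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    expression = ExpressionMatrix(
        pd.DataFrame(x, index=genes, columns=sample_ids), unit="logCPM"
    )
    centroids = ClassCentroids(
        pd.DataFrame({CLASS_DOWN: c_down, CLASS_UP: c_up}, index=genes)
    )

    sets: dict[str, list[str]] = {
        "EMT_EPITHELIAL": list(EPITHELIAL_NAMED),
        "EMT_MESENCHYMAL": [g for g in MESENCHYMAL_NAMED if g != "CD274"],
        "PROGRAM_UP": [g for g, d in zip(program, directions) if d > 0],
        "PROGRAM_DOWN": [g for g, d in zip(program, directions) if d < 0],
    }
    if secondary:
        sets["SECONDARY_PROGRAM"] = list(secondary)
    for pop, (members, _) in MARKER_PANELS.items():
        sets[f"MARKERS_{pop}"] = list(members)
    descriptions = {k: "synthetic planted set" for k in sets}
    gene_sets = GeneSetCollection(sets, descriptions)

    return SyntheticCohort(
        expression=expression,
        annotations=SampleAnnotations(ann_df),
        truth=truth,
        centroids=centroids,
        program_genes=program,
        program_directions=pd.Series(directions, index=program),
        secondary_genes=list(secondary),
        gene_sets=gene_sets,
        params=params,
    )


def truth_report(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-sample ground-truth table for test harnesses."""
    return cohort.truth.copy()


def write_cohort(
    cohort: SyntheticCohort, outdir: str | Path, config: AnalysisConfig | None = None
) -> dict[str, Path]:
    """Write the pipeline input files plus the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "annotations": outdir / "annotations.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth": outdir / "truth.tsv",
        "true_centroids": outdir / "true_centroids.tsv",
    }
    write_expression(cohort.expression, paths["expression"], config)
    write_annotations(cohort.annotations, paths["annotations"], config)
    write_gmt(cohort.gene_sets, paths["gene_sets"])
    write_table(cohort.truth, paths["truth"], config, index_label="sample_id")
    write_centroids(cohort.centroids, paths["true_centroids"], config)
    return paths
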