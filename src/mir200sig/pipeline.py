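"""End-to-end pipeline: preprocess -> subtypes -> signature -> deconvolution
-> scores -> enrichment -> survival.

Stages communicate through in-memory objects; each stage's artifact is also
written to the configured output directory as a tab-delimited table stamped
with the config hash and seed.  Sample identifiers (never column positions)
carry meaning: inputs are re-indexed to sorted sample order on load so the
whole run is invariant to permuting input columns.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import (
    ClusterAssignment,
    assign_by_centroid_correlation,
    compute_centroids,
    hierarchical_cluster,
)
from .io import (
    CLASS_DOWN,
    CLASS_UP,
    AnalysisConfig,
    DataFormatError,
    ExpressionMatrix,
    GeneSetCollection,
    PipelineStageError,
    SampleAnnotations,
    read_annotations,
    read_expression,
    read_gmt,
    write_centroids,
    write_table,
)
from .preprocess import counts_to_logcpm, filter_by_tumor_content, select_most_variable
from .scoring import (
    compare_gene_across_groups,
    emt_76gs,
    emt_kgene,
    emt_ks,
    marker_scores,
    preranked_gsea,
    rank_genes_by_weight_association,
)
from .signature import (
    GeneSignature,
    cluster_on_signature,
    derive_signature,
    extreme_groups,
    mutation_enrichment,
    rank_differential,
)
from .survival import logrank_test, stratified_report
from .wisp import classify, estimate_weights_matrix, fit_model, quartile_bins

logger = logging.getLogger("mir200sig")


def _anchor_values(
    matrix: ExpressionMatrix, annotations: SampleAnnotations, config: AnalysisConfig
) -> pd.Series:
    """Anchor ranking values: annotation column, or mean of z-scored matrix rows."""
    if not config.anchor_rows:
        return annotations.anchor
    rows = matrix.values.loc[list(config.anchor_rows)]
    z = rows.sub(rows.mean(axis=1), axis=0).div(rows.std(axis=1, ddof=1), axis=0)
    return z.mean(axis=0)


def run_pipeline(
    config: AnalysisConfig,
    matrix: ExpressionMatrix | None = None,
    annotations: SampleAnnotations | None = None,
    gene_sets: GeneSetCollection | None = None,
) -> dict:
    """Run every stage and return the artifact bundle.

    Inputs may be passed in memory; otherwise they are read from the paths
    in ``config``.  Any stage failure propagates as
    :class:`PipelineStageError` naming the stage.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"config": config}

    def emit(name: str, df: pd.DataFrame, index_label: str) -> None:
        if outdir:
            write_table(df, outdir / f"{name}.tsv", config, index_label=index_label)

    # ---- load ------------------------------------------------------------
    stage = "load"
    try:
        if matrix is None:
            matrix = read_expression(config.expression_path, config.expression_unit)
        if annotations is None:
            annotations = read_annotations(config.annotations_path)
        if gene_sets is None and config.gene_sets_path:
            gene_sets = read_gmt(config.gene_sets_path)
        shared = sorted(set(matrix.sample_ids) & set(annotations.sample_ids))
        if len(shared) < 2:
            raise DataFormatError(
                f"expression and annotations share only {len(shared)} sample(s)"
            )
        matrix = matrix.subset_samples(shared)
        annotations = annotations.subset(shared)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- preprocess ------------------------------------------------------
    stage = "preprocess"
    try:
        if matrix.unit == "counts":
            matrix = counts_to_logcpm(matrix, config.prior_count)
        keep = filter_by_tumor_content(annotations, config.min_tumor_content)
        matrix = matrix.subset_samples(keep)
        annotations = annotations.subset(keep)
        variable = select_most_variable(
            matrix, config.n_variable_genes, config.variable_statistic
        )
        artifacts["variable_genes"] = variable
        emit(
            "variable_genes",
            pd.DataFrame({"statistic": variable.statistic.loc[variable.genes]}),
            "gene",
        )
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- unsupervised subtypes -------------------------------------------
    stage = "subtypes"
    try:
        subtypes = hierarchical_cluster(
            matrix, variable.genes, config.k_subtypes, config.distance, config.linkage
        )
        subtype_centroids = compute_centroids(matrix, subtypes, variable.genes)
        artifacts["subtypes"] = subtypes
        artifacts["subtype_centroids"] = subtype_centroids
        emit("subtypes", subtypes.labels.to_frame(), "sample_id")
        if outdir:
            write_centroids(subtype_centroids, outdir / "subtype_centroids.tsv", config)
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- supervised signature --------------------------------------------
    stage = "signature"
    try:
        anchor = _anchor_values(matrix, annotations, config)
        low, high = extreme_groups(annotations, config.n_extreme, anchor)
        de = rank_differential(matrix, low, high, config.n_de_genes)
        signature = derive_signature(
            de, variable, {"n_extreme": config.n_extreme, "anchor": "anchor_value"}
        )
        clusters = cluster_on_signature(
            matrix, signature, annotations, config.k_subtypes,
            config.distance, config.linkage,
        )
        # distill the anchor-coherent core of the signature: genes ranked by
        # the strength of their association with the anchor over ALL samples
        # (not just the extremes).  Side programs (e.g. mutation-linked
        # blocks) can pass the small extreme-group contrast together but
        # only track the anchor weakly across the cohort, so this ranking
        # keeps them out of the deconvolution basis.
        sig_expr = matrix.values.loc[signature.genes]
        sig_c = sig_expr.sub(sig_expr.mean(axis=1), axis=0)
        a_c = anchor.reindex(sig_expr.columns) - anchor.mean()
        denom = np.sqrt((sig_c**2).sum(axis=1)) * np.sqrt((a_c**2).sum())
        anchor_r = (sig_c @ a_c).where(denom > 0, 0.0) / denom.replace(0, 1.0)
        panel = (
            pd.DataFrame({"abs_r": anchor_r.abs(), "gene": anchor_r.index})
            .sort_values(["abs_r", "gene"], ascending=[False, True])
            .head(config.n_centroid_genes)["gene"]
            .tolist()
        )
        # the binary I-vs-II supervised call is anchored at the extremes:
        # each sample is assigned to the nearer (by Pearson correlation over
        # the panel) of the two extreme-group centroids.  Unlike a tree cut,
        # whose boundary on a proportion continuum wanders with the merge
        # order, the correlation flip point sits at the program midpoint.
        extreme_centroids = compute_centroids(
            matrix,
            pd.Series(
                ["I"] * len(low) + ["II"] * len(high), index=low + high
            ),
            panel,
        )
        binary_corr = assign_by_centroid_correlation(
            matrix.subset_genes(panel), extreme_centroids
        )
        binary = ClusterAssignment(
            binary_corr.assigned.rename("cluster"), 2, config.distance, "centroid"
        )
        enrichment_mut = mutation_enrichment(clusters, annotations)
        artifacts.update(
            signature=signature, supervised_clusters=clusters,
            supervised_binary=binary, mutation_enrichment=enrichment_mut,
            centroid_panel=panel,
        )
        emit("signature", signature.table, "gene")
        emit("supervised_clusters", clusters.labels.to_frame(), "sample_id")
        emit("supervised_binary", binary.labels.to_frame(), "sample_id")
        if len(enrichment_mut):
            emit("mutation_enrichment", enrichment_mut.set_index("cluster"), "cluster")
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- deconvolution ----------------------------------------------------
    stage = "deconvolution"
    try:
        initial = binary.labels.map(
            lambda lb: CLASS_DOWN if lb == "I" else CLASS_UP
        )
        model = fit_model(
            matrix.subset_genes(signature.genes), initial,
            config.n_centroid_genes, config.purity_threshold,
            config.max_iterations, panel=artifacts["centroid_panel"],
        )
        weights = estimate_weights_matrix(
            matrix.subset_genes(model.panel), model.centroids
        )
        classes = classify(weights, config.class_cutoff)
        quartiles = quartile_bins(weights)
        artifacts.update(
            wisp_model=model, weights=weights, classes=classes, quartiles=quartiles
        )
        wtab = weights.weights.copy()
        wtab["residual"] = weights.residual
        wtab["wisp_class"] = classes
        wtab["quartile"] = quartiles
        emit("mixture_weights", wtab, "sample_id")
        if outdir:
            write_centroids(model.centroids, outdir / "wisp_centroids.tsv", config)
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- EMT / immune scores ----------------------------------------------
    stage = "scores"
    try:
        score_cols: dict[str, pd.Series] = {}
        if gene_sets is not None:
            epi = gene_sets[config.epithelial_set] if config.epithelial_set in gene_sets else None
            mes = gene_sets[config.mesenchymal_set] if config.mesenchymal_set in gene_sets else None
            if epi and mes:
                if config.emt_anchor_gene in matrix.values.index:
                    score_cols["emt_76gs"] = emt_76gs(
                        matrix, sorted(set(epi) | set(mes)), config.emt_anchor_gene
                    )
                score_cols["emt_ks"] = emt_ks(matrix, epi, mes)
            if config.emt7_epithelial_genes or config.emt7_mesenchymal_genes:
                panel = list(config.emt7_epithelial_genes) + list(
                    config.emt7_mesenchymal_genes
                )
                dirs = {g: "epithelial" for g in config.emt7_epithelial_genes}
                dirs.update({g: "mesenchymal" for g in config.emt7_mesenchymal_genes})
                score_cols["emt_7g"] = emt_kgene(matrix, panel, dirs)
            marker_names = [
                n for n in gene_sets.names() if n.startswith(config.marker_set_prefix)
            ]
            if marker_names:
                markers = GeneSetCollection(
                    {n[len(config.marker_set_prefix):]: gene_sets[n] for n in marker_names}
                )
                mscores = marker_scores(matrix, markers)
                for col in mscores.columns:
                    score_cols[f"markers_{col.lower()}"] = mscores[col]
        if config.checkpoint_gene in matrix.values.index:
            score_cols[config.checkpoint_gene] = matrix.values.loc[config.checkpoint_gene]
            artifacts["checkpoint_comparison"] = compare_gene_across_groups(
                matrix,
                config.checkpoint_gene,
                {cl: list(classes.index[classes == cl]) for cl in sorted(classes.unique())},
            )
        scores = pd.DataFrame(score_cols, index=matrix.sample_ids)
        artifacts["scores"] = scores
        if len(scores.columns):
            emit("scores", scores, "sample_id")
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- gene-set enrichment ----------------------------------------------
    stage = "enrichment"
    try:
        enrichment_rows = []
        if gene_sets is not None and len(gene_sets):
            ranking = rank_genes_by_weight_association(matrix, weights)
            rng = np.random.default_rng(config.seed)
            for set_name in gene_sets.names():
                members = set(gene_sets[set_name]) & set(matrix.gene_ids)
                if not members:
                    continue
                res = preranked_gsea(
                    ranking, members, set_name, config.gsea_exponent,
                    config.gsea_permutations, rng,
                )
                enrichment_rows.append(
                    {"gene_set": res.name, "es": res.es, "nes": res.nes,
                     "p_value": res.p_value, "n_hits": res.n_hits}
                )
        enrichment = pd.DataFrame(enrichment_rows)
        artifacts["enrichment"] = enrichment
        if len(enrichment):
            emit("enrichment", enrichment.set_index("gene_set"), "gene_set")
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ---- survival ----------------------------------------------------------
    stage = "survival"
    try:
        surv: dict = {}
        endpoints = ["dfs"]
        if "os_time" in annotations.df.columns and annotations.df["os_time"].notna().any():
            endpoints.append("os")
        for endpoint in endpoints:
            surv[endpoint] = {
                "by_class": stratified_report(
                    classes, annotations, "stage", endpoint,
                    config.min_stratum_size, config.ties,
                ),
                "by_quartile": stratified_report(
                    quartiles, annotations, "stage", endpoint,
                    config.min_stratum_size, config.ties,
                ),
            }
        artifacts["survival"] = surv
        rows = []
        for endpoint in endpoints:
            pooled = surv[endpoint]["by_class"]["pooled"]
            for cls, curve in pooled["km"].items():
                rows.append(
                    {"endpoint": endpoint, "group": cls, "n": curve.n,
                     "median": curve.median if curve.median_reached else "",
                     "median_reached": int(curve.median_reached),
                     "logrank_p": pooled["logrank"].p_value if pooled["logrank"] else ""}
                )
        summary = pd.DataFrame(rows).set_index("endpoint")
        artifacts["survival_summary"] = summary
        emit("survival_summary", summary, "endpoint")
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    return artifacts
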