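# mir200sig

Anchor-microRNA transcriptome analysis for early-stage lung adenocarcinoma
(LUAD): derive a miR-200-supervised gene signature from bulk RNA-seq,
estimate each tumor's continuous mixture of a "miR-200-sign-up" (epithelial)
versus "miR-200-sign-down" (mesenchymal) transcriptional program by
constrained centroid deconvolution, score EMT state and immune infiltration,
test gene-set enrichment along the mixture gradient, and stratify
disease-free and overall survival by signature class and quartile.

The package is aimed at translational transcriptomics groups who have a
gene × sample expression matrix (counts or logCPM), per-tumor microRNA
measurements and clinical follow-up, and who want a continuous,
deconvolution-based readout of EMT heterogeneity rather than a discrete
cluster label. Because cohorts of this kind are rarely public, the package
ships a first-class synthetic-cohort generator with full ground truth, which
every stage of the pipeline is tested against.

## The model

Each tumor's logCPM profile over a panel of signature genes is modelled as a
convex mixture of two pure class centroids,

    x_s = w_s · c_up + (1 − w_s) · c_down + ε_s,      0 ≤ w_s ≤ 1,

and the per-sample weight ("impregnation" of the up-signature) is the
simplex-constrained least-squares solution

    ŵ_s = clamp( (x_s − c_down)·(c_up − c_down) / ‖c_up − c_down‖² , 0, 1 ).

Centroids are fitted by iterative purity refinement: starting from the
supervised binary classes, per-class means are computed over "pure" samples
(top weight ≥ 0.95), weights are re-estimated, and the pure sets updated
until stable. Tumors with ŵ > 0.5 are called miR-200-sign-up, the rest
miR-200-sign-down; quartiles of ŵ give the continuous stratification.

Upstream, the signature itself is supervised by the anchor microRNA
(miR-429 or the mean chromosome-1 miR-200 cluster): the 15 anchor-highest
versus 15 anchor-lowest tumors are contrasted by Welch's t, the top 1500
differential genes are intersected with the 1500 most variable genes, and
the 150 signature genes most associated with the anchor across the whole
cohort form the centroid panel. Downstream, the package provides
correlation-weighted (76GS-style, higher = epithelial) and
Kolmogorov–Smirnov (positive = mesenchymal) EMT scores, marker-mean immune
scores (MCP-counter style), pre-ranked GSEA against the weight gradient with
a permutation null, and Kaplan–Meier / log-rank / Cox (Breslow) survival
analysis with stage adjustment.

## Worked example

Simulate a 107-tumor cohort and run the full pipeline (all inputs are plain
TSV/GMT text files; `truth.tsv` records the generator's ground truth):

```bash
mir200sig --seed 11 --outdir sim simulate
cat > cfg.yaml <<EOF
expression_path: sim/expression.tsv
annotations_path: sim/annotations.tsv
gene_sets_path: sim/gene_sets.gmt
n_extreme: 15
n_de_genes: 300
n_variable_genes: 300
n_centroid_genes: 150
seed: 11
EOF
mir200sig --config cfg.yaml --outdir run run-all
```

which prints

```
classified 57 miR-200-sign-down / 50 miR-200-sign-up tumors
```

and writes, among other artifacts, the per-sample weight table

```
# mir200sig config_hash=c416f52a7e6c seed=11
sample_id  miR-200-sign-down  miR-200-sign-up  residual  wisp_class         quartile
S001       0.356927           0.643073         6.107272  miR-200-sign-up    Q3
S002       0.786212           0.213788         6.076467  miR-200-sign-down  Q2
```

(`miR-200-sign-up` is the estimated up-program weight ŵ; rows sum to one;
`residual` is the reconstruction error over the 150-gene panel) and the
survival summary

```
endpoint  group              n   median   median_reached  logrank_p
dfs       miR-200-sign-down  57  53.17    1               0.006688
dfs       miR-200-sign-up    50           0               0.006688
```

i.e. the down-class median disease-free survival is 53.2 months while the
up-class median is not reached within the follow-up horizon, with a
log-rank p of 0.0067 — the expected direction, since the generator links
the hazard to 1 − (true up-proportion). Every output table carries the
config hash and seed of the run in its header comment.

The same stages are available individually (`simulate`, `preprocess`,
`subtype`, `derive-signature`, `fit-centroids`, `score-mixture`,
`emt-scores`, `marker-scores`, `gsea`, `survival`), and everything is
importable as a library (`mir200sig.run_pipeline`, `mir200sig.fit_model`,
`mir200sig.estimate_weights`, ...).

## Layout

- `src/mir200sig/io.py` — data model (expression matrix, annotations, gene
  sets, centroids), TSV/GMT readers and writers, configuration
- `src/mir200sig/synthetic.py` — ground-truthed cohort generator
- `src/mir200sig/preprocess.py` — logCPM, tumor-content QC, variable genes
- `src/mir200sig/clustering.py` — hierarchical subtyping, centroid
  correlation
- `src/mir200sig/signature.py` — anchor-supervised signature derivation
- `src/mir200sig/wisp.py` — constrained mixture deconvolution
- `src/mir200sig/scoring.py` — EMT/immune scores, pre-ranked GSEA
- `src/mir200sig/survival.py` — Kaplan–Meier, log-rank, Cox PH
- `src/mir200sig/pipeline.py` — end-to-end orchestration
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
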