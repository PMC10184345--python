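# Methods

This note records the models, parameter choices and numerical conventions
behind `mir200sig`, and what the synthetic-cohort tests do and do not
establish about real data.

## Mixture model and deconvolution

A tumor's expression over the centroid panel is modelled as a convex
combination of two pure transcriptional programs plus noise,
`x = w·c_up + (1−w)·c_down + ε`. For two classes the simplex-constrained
least-squares weight has the closed form

    ŵ = clamp( (x − c_down)·(c_up − c_down) / ‖c_up − c_down‖², 0, 1 ),

optionally with per-gene weights applied as `√g`-scaling of both sides.
Three or more classes fall back to non-negative least squares followed by
renormalization onto the simplex — an approximation, flagged as such, since
the renormalized NNLS solution is not the exact simplex-constrained
minimizer.

**Centroid fitting and identifiability.** Centroids are estimated by
iterative purity refinement: per-class means over the current pure sets,
weight re-estimation for all samples, pure sets = samples with top weight
above the purity threshold, iterated until stable (≤ 10 iterations;
convergence is typically 5–8). The mixing scale of this model is
identified *only* by near-pure samples: any affine reparametrization of
(w, centroids) fits equally well, so if the "pure" sets admit samples that
are substantially admixed, the fitted centroids contract toward the middle
and every weight is stretched proportionally. Quantitatively, with
threshold t the pure-set boundary converges to `0.5/(1.5 − t)` under a
uniform proportion distribution: t = 0.8 anchors centroids at mean purity
≈ 0.86 (≈ 15% scale error), while t = 0.95 anchors at ≈ 0.955 (≈ 5%).
The default purity threshold is therefore **0.95**; it is config-exposed,
and cohorts without near-pure tumors will still return stretched (rank-
preserving but biased) weights — a structural limitation of any
centroid-anchored deconvolution, not a numerical one.

**Panel selection.** `select_centroid_panel` ranks genes by |Welch t|
between the two classes, with at least 25% of the panel per direction when
available. Inside `run_pipeline`, panel candidates are additionally
restricted to the derived signature and ranked by the strength of their
Pearson association with the anchor across *all* samples, not just the
extreme groups. The reason is confounding: a side program tied to a
mutation that is enriched in one class (the KRAS-like block in the
generator) moves as a correlated gene block and can pass a small
extreme-group contrast wholesale, yet tracks the anchor only weakly across
the cohort (r ≈ 0.3 versus ≈ 0.75 for true program genes). Ranking by
full-cohort anchor association keeps the deconvolution basis on the anchor
program; panels fed in from a centroid file are used as-is. Scoring a new
cohort refuses to proceed if fewer than half the panel genes are present.

**Supervised binary call.** The down/up call from the supervised side
(which seeds the centroid fit and is compared with the deconvolution
classes) assigns each sample to the nearer of the two extreme-group
centroids by Pearson correlation over the panel. A hierarchical tree cut
was considered and rejected for this purpose: on a continuum of mixture
proportions the Ward cut position has no anchor and drifts widely between
cohorts (observed 0.29–0.68 in true-proportion units), whereas the
correlation flip point sits at the program midpoint by symmetry. The
three-group signature clustering (I / IIA / IIB, named by ascending mean
anchor) is retained as the descriptive subtype structure; in synthetic
cohorts its IIA/IIB split tracks the planted mutation-linked program.

## Signature derivation

Tumors are ranked by the anchor value (an annotation column by default; a
config switch averages z-scored expression rows instead). The bottom and
top `n_extreme` (default 15) are contrasted by Welch's t on logCPM;
the top `n_de_genes` (default 1500) by |t| are intersected with the
`n_variable_genes` (default 1500) most variable genes, preserving |t|
order. Ties in any ranking break lexicographically by gene symbol so every
run is deterministic. Genes with zero variance in both groups get t = 0
(with a warning); zero-variance genes with differing means receive the
smallest positive standard error observed, keeping the statistic finite.
The choice of Welch's t (rather than a moderated statistic) and of variance
(rather than MAD, available by config) follows the principle of the
simplest deterministic statistic consistent with the design.

## Preprocessing

logCPM: `log2((count + c) / (libsize + 2c) × 1e6)` with prior count
c = 0.5 (the standard convention; the 2c library offset keeps the
transform exact for a gene carrying the whole library). No between-sample
scaling beyond library size is applied; TMM-style normalization is out of
scope. Tumor-content QC excludes samples strictly below 20% tumor cells;
unknown content is retained with a warning.

## Scores and enrichment

* **76GS-style score** — per-gene weights are Pearson correlations with an
  epithelial anchor gene (CDH1 by default) across samples; the score is the
  weighted expression sum, mean-centered; **higher = more epithelial**.
* **KS score** — per sample, the signed two-sample Kolmogorov–Smirnov
  separation between the expression distribution of the epithelial set and
  that of the mesenchymal set; **positive = mesenchymal**, so the two EMT
  scores are anticorrelated by construction. When the two one-sided maxima
  tie exactly the sign is undefined and the score is 0, which makes the
  antisymmetry under set exchange exact.
* **k-gene score** — mean of direction-signed per-gene z-scores (sample
  variance, ddof 1); the gene list and directions are configuration, no
  default panel is claimed.
* **Marker scores** — arithmetic mean logCPM of present marker genes per
  population; populations with no present marker are omitted with a warning.
* **Pre-ranked GSEA** — genes are ranked by Pearson correlation with the
  up-weight; the weighted running-sum statistic (hit increments ∝ |r|^p,
  p = 1 by default) gives the ES as the signed maximal deviation. The null
  permutes set membership uniformly over the ranking. The reported p-value
  is the exchangeable two-sided tail `(1 + #{|ES_perm| ≥ |ES|})/(n_perm+1)`,
  which is uniform under the null with resolution `1/(n_perm+1)`; a
  same-sign one-tailed count divided by the full permutation total was
  rejected because it is miscalibrated by roughly a factor of two. NES
  divides ES by the mean |ES| of same-sign permutations. Phenotype
  permutation (re-ranking per permutation) is out of scope.

## Survival

Kaplan–Meier curves and the log-rank statistic delegate to lifelines; the
median is the first event time with S(t) ≤ 0.5 and is reported with an
explicit "not reached" flag, never as infinity. The Cox model maximizes
the Breslow partial likelihood by Newton–Raphson (tolerance 1e-8, ≤ 50
iterations) with Wald intervals from the observed information; Efron tie
handling is available through lifelines. Non-convergence and suspected
separation (|β| > 15) are flagged, never silently reported. Stage enters
the adjusted model dummy-coded against IA; samples with unknown stage are
excluded from the adjusted model only. Strata smaller than 5 samples are
reported as "insufficient n". All times are months.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
107 tumors (default); 2000 genes of which 200 form the two-program
contrast (baseline N(7, 2²) logCPM, ±1 logCPM per pure program, i.e. a
2-logCPM shift between programs); per-cell Gaussian noise sd 0.5; uniform
mixture proportions; anchor = proportion + N(0, 0.05²); class-conditional
Bernoulli mutations (TP53 0.60/0.10 down/up, KRAS 0.10/0.45,
EGFR 0.05/0.35, STK11 0.15/0.10 — strong enough for Fisher enrichment at
n ≈ 107); and a 100-gene secondary program added in KRAS-mutant tumors
(+2 logCPM), which concentrates in the up class and reproduces the
IIA/IIB-style substructure. A subset of planted genes carries canonical
symbols (CDH1-side epithelial genes, ZEB1/VIM-side mesenchymal genes,
CD274, and per-population immune marker panels) so the scoring defaults
run unchanged on synthetic data.

Disease-free survival is exponential with hazard
`h0 · exp(β · (1 − p))`, β = 2.0 and h0 = 0.0037, calibrated so that the
*down-class mixture* (p < 0.5) has median DFS near 40 months while the
up-class median exceeds the 60-month administrative horizon; a 10% uniform
dropout adds random censoring. Overall survival uses a weaker log-ratio
(0.9), giving a trend rather than a strong effect. Stage is drawn from the
cohort's marginal stage distribution independently of the proportion, so
the simulated prognostic signal is wholly mediated by the mixture — stage
adjustment should (and does) leave it intact.

What the generator does **not** emulate: count-level (negative binomial)
noise, library-size variation, batch effects, gene–gene correlation beyond
the two planted programs, stage–biology dependence, or competing risks.
Passing tests therefore demonstrate correctness of the algorithms under
the stated model, not robustness to these real-data complications.

## Numerical conventions

Deterministic tie-breaks (gene symbol, then sample id) everywhere a
ranking is cut; sample identifiers, not column positions, carry meaning
(inputs are re-indexed to sorted sample order, making runs invariant to
column permutations); one `numpy` Generator seeded from the config drives
all pipeline randomness (GSEA permutations), so a fixed seed reproduces
score tables byte-for-byte; every output table is stamped with the config
hash and seed. Problem sizes in the test and acceptance harnesses are
scaled versions of the defaults (e.g. 300-gene rankings, 100-sample
cohorts, 20-cohort replications) chosen to exercise the same structure at
desk scale.

## Known limitations

* Two-class deconvolution only is exact; ≥ 3 classes use the NNLS
  approximation.
* Weight estimates are anchored by near-pure samples; cohorts confined to
  mid-range mixtures return systematically stretched weights.
* The log-rank and KM routines assume independent censoring; no competing
  risks.
* GSEA significance is per-set; no cross-collection FDR.
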