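# Methods

This note records the statistical model, the algorithmic and numerical
choices, the synthetic-data generator's design, and the known
limitations of the implementation.

## 1. Model

### 1.1 Two-stage regression

Stage 1 (CRE linkage). For gene *g* with transcription start site
(TSS) *t* on chromosome *c*, the candidate set is every peak whose
interval overlaps `[t − 500000, t + 500000)` (any overlap; half-open
coordinates throughout the package). The response is *g*'s expression
over pseudocells or cells; the design matrix is the raw, non-binarized
accessibility of the candidate peaks. Significant coefficients become
CRE→gene links annotated with the signed, strand-oriented TSS distance
of the peak midpoint and a promoter / gene-body / intergenic class
(promoter label: any overlap with ±2 kb of the TSS).

Stage 2 (TF linkage). A TF is nominated for gene *g* if one of its
motifs has a hit in a significant CRE of *g* or in a peak overlapping
*g*'s promoter — the strand-aware 2 kb immediately upstream of the TSS
(`[t − 2000, t)` on `+`, `[t + 1, t + 2001)` on `−`) — and the TF is
expressed in ≥ 1% of cells. The gene's expression is then regressed on
the nominated TFs' expression over single cells; self-loops are
removed. Significant coefficients are the edges of the network.

### 1.2 The adaptive elastic net

Both stages solve

    β̂ = (1 + λ₂/n) · argmin_β ‖y − Xβ‖² + λ₂‖β‖² + λ₁ Σⱼ ŵⱼ|βⱼ|

- Predictors are z-standardized internally; reported coefficients are
  back-transformed to the original scale. The `(1 + λ₂/n)` factor
  undoes the elastic net's double-shrinkage bias.
- Pass 1 (pilot) uses unit weights; pass 2 uses the adaptive weights
  ŵⱼ = |β̂ⱼ(pilot)|^(−γ) with γ = 1. Predictors with a zero pilot
  coefficient receive an infinite penalty and are excluded outright,
  which is what gives the adaptive estimator its selection-consistency
  (oracle) behavior.
- λ₁ is selected by 10-fold cross-validation (minimum-MSE rule; a
  one-standard-error rule is available) over a 50-point geometric path
  from λ_max = maxⱼ 2|cⱼ|/ŵⱼ (the smallest penalty with an all-zero
  solution, c = Xᵀy on standardized data) down to 10⁻³·λ_max.
- The ridge level is tied to the L1 level, λ₂ = l2_weight · λ₁, so a
  single CV sweep tunes both. l2_weight is 0.25 in the CRE stage and
  0.5 in the TF stage — the TF stage faces more collinear predictors
  (co-regulated TFs) and benefits from more grouping.

### 1.3 Bootstrap inference

At the selected (λ₁, ŵ), rows of (X, y) are resampled with replacement
(1,000 resamples in the CRE stage, 100 in the TF stage at full scale;
the validation suite scales these to 100/50 for runtime) and the model
is refit each time. The standard error is the across-resample standard
deviation; the p-value is two-sided normal, 2(1 − Φ(|β̂|/se)); links
with p ≥ 0.05 are dropped. A degenerate se < 10⁻¹² maps to p = 0 for a
nonzero coefficient and p = 1 otherwise.

Calibration caveat: this is inference *conditional on selection* at a
fixed penalty. Among predictors that survive pilot selection under a
global null, the pass rate is far above nominal (≈ 0.3 in our null
experiment) because selected coefficients are biased away from zero
(winner's curse); bootstrap refitting at the selected penalty does not
correct that. The quantity that is controlled near the nominal level is
the *marginal* false-link rate — significant links per candidate
predictor — which is ≈ 0.04 under the same null (200 null genes,
n = 100, p = 10). That marginal rate is what the network-level false
discovery proportion inherits, so it is the number we report; both
numbers appear in the acceptance JSON
(`null_false_link_fraction`, `null_conditional_pass_fraction`).

### 1.4 Depth normalization

Per-cell sequencing depth is a global multiplicative confounder: with
positive feature levels it induces positive correlation between *every*
pair of features, so an unrelated TF would predict every gene. The
package therefore estimates one depth factor per cell and divides it
out (`estimate_size_factors` + `library_size_normalize`). Factors are
row totals relative to the median cell, and they can be **pooled across
paired modalities**: with a small expression panel, a single feature's
own noise is a non-negligible share of its matrix's total (creating
compositional anti-correlation), while pooling the paired ATAC matrix's
thousands of peaks makes the estimate precise and nearly independent of
any single feature. The `fit-*` and `run-all` commands normalize by
pooled factors by default; already-normalized inputs can be passed with
`--no-normalize`. An optional log1p transform is available but off by
default, since the regression model is linear in the measured signal.

### 1.5 Pseudocells

Stage 1 can run on micropooled profiles: Louvain communities of the
cell–cell neighbor graph (or of a kNN graph built from an embedding,
k = 20) are each split by k-means into ⌈size / target⌉ pools, so pools
never mix communities. Typical targets are 10 cells for RNA and 100 for
ATAC. Aggregation is the within-pool mean; the size-weighted mean of
the pooled matrix equals the global cell mean to machine precision, and
a target of 1 reproduces the input exactly. Stage 2 stays on single
cells, where averaging would erase the regulatory heterogeneity the
model needs.

### 1.6 Motif scanning and enrichment

The scanner scores a peak sequence against a PFM's log₂-odds matrix
(pseudocount 10⁻³ per cell against a uniform background) on both
strands; a peak hits a motif iff the best window score, rescaled so the
worst achievable score maps to 0 and the best to 1, reaches 0.8.
Ambiguous bases score their background expectation, so a run of N can
never produce a hit. A stricter nomination mode keeps only TFs whose
motifs are over-represented in the gene's CRE set versus a GC-matched
background (deciles of GC content, sampled without replacement;
one-sided Fisher exact test, Benjamini–Hochberg across motifs at 0.05).
Enrichment-mode nominations are by construction a subset of
presence-mode nominations, and with small CRE sets many genes end up
with no enriched TF at all — the price of the stricter mode.

### 1.7 Scores, graph, perturbation, model comparison

- Axis score: score(TF) = mean_expr(TF) · Σ_g s_g β_{TF,g}, with
  s_g = ±1 the gene's direction in a two-state contrast; positive marks
  a stateA-promoting regulator. Reversing every s_g negates every
  score.
- Graph: directed TF→gene edges, weight |β| · mean TF expression, sign
  = sign(β). PageRank (damping 0.85) runs on the edge-reversed graph so
  that regulators accrue rank from their targets; betweenness uses
  distance = 1/weight.
- Perturbation: rules per TF (set to zero, scale, set to a quantile)
  produce X_perturb; every modeled gene is re-predicted as
  ŷ = X_perturb β̂. The baseline profile substitutes the *unperturbed
  predictions* for the same genes, so an identity perturbation yields
  exactly zero displacement and the reported displacement isolates the
  modeled effect. Profiles are projected through caller-supplied
  embedding loadings.
- Model comparison: AIC = −2ℓ + 2k with a Gaussian likelihood,
  σ̂² = max(RSS/n, 10⁻¹²) (floor keeps perfect fits finite), and k the
  number of nonzero slopes (the intercept is common to both models and
  excluded). ΔAIC = AIC_full − AIC_promoter < 0 favors the distal-CRE
  model; exp(ΔAIC/2) is the promoter model's relative probability.
  Jaccard overlap of two ranked sets defines |A∩B|/|A∪B| with two empty
  sets counted as identical (with a warning).

## 2. Numerical choices

- Solver: cyclic coordinate descent on the Gram system (G = XᵀX,
  c = Xᵀy), numba-compiled, warm-started along the λ path, tolerance
  10⁻¹² on the largest coordinate update. Per-coordinate update:
  βⱼ = S(cⱼ − Σ_{k≠j} G_{jk}β_k, λ₁ŵⱼ/2)/(G_{jj} + λ₂). On an
  orthonormal design this reduces to the closed form
  S(cⱼ, λ₁ŵⱼ/2)/(1 + λ₂), which the tests check to 10⁻⁸; on random
  problems the objective matches a 10,000-step proximal-gradient oracle
  to ~10⁻¹³ (tolerance 10⁻⁶).
- Cross-validation folds are standardized per training fold; the path
  index minimizing mean validation MSE is selected.
- Determinism: all randomness flows from `numpy.random.default_rng`
  seeds. Per-gene seeds are `(global_seed + crc32(gene_id)) mod 2³¹−1`,
  so results do not depend on gene order or scheduling. Floating-point
  I/O uses `%.17g`, which round-trips IEEE doubles exactly.
- Zero-variance predictors get a unit divisor during standardization
  and a zero coefficient (the CD kernel skips non-positive diagonals);
  constant responses return an all-zero model with a warning.

## 3. The synthetic generator

`simulate_multiome` emulates the causal chain the model assumes, with a
planted, checkable ground truth.

Generative chain (defaults: 2,000 cells, 50 genes × 50 candidate peaks,
30 TFs, 5 true CREs and 3 true TFs per gene, effects |β| ∈ [0.5, 2]
with a 30% repressive fraction, expression noise σ = 0.5, two states at
fraction 0.5, seed 7):

1. Cells split into two states; each cell draws a lognormal depth
   factor (sd 0.1) that multiplies *all* of its observed signals.
2. TFs split into **drivers** (first half), which carry a
   state-dependent mean shift and supply every planted regulator, and
   **bystanders**, which are state-independent noise and supply decoy
   motif placements. A decoy TF association is therefore a genuine
   false positive, not a variable confounded with the state.
3. Each gene's latent activity is a weighted sum of its true TFs'
   standardized expression; true-CRE accessibility is base level +
   0.4 × sign(β) × activity + Gaussian noise (sd 0.75); decoy peaks are
   independent noise. Accessibility is depth-scaled and clipped at 0.
4. Gene expression is **exactly linear in the observed accessibility**
   of its true CREs plus depth-scaled Gaussian noise — so stage 1 is
   well-specified by construction, and stage 2 is approximately linear
   through the TF→accessibility chain.
5. Motifs (one 8-bp near-consensus PFM per TF) are placed so every true
   TF has a hit in the target's promoter peak and in at least one true
   CRE (checked at generation time), plus decoy placements in true
   CREs/promoters and sparse background hits, so the false-positive
   nomination path is genuinely exercised.

Realism and limits:

- The depth factor reproduces the library-size confound of real data,
  which is why the pipeline's normalization step exists; with only ~80
  expression features the panel is far smaller than a real
  transcriptome, so precise depth estimation *requires* pooling the
  paired ATAC totals (Section 1.4). Real datasets with 20k genes are
  much more forgiving.
- Expression is exactly linear in accessibility — real enhancer–gene
  coupling is nonlinear and non-additive. The generator validates the
  estimator under its own assumptions; it cannot measure robustness to
  model misspecification.
- All peaks sit on one chromosome with well-separated genes, so
  candidate windows never overlap between genes; real cis landscapes
  share enhancers.
- Noise is Gaussian on continuous signals, not count noise; there is no
  batch structure, doublets, or ambient contamination.
- Problem sizes (50 genes, 2,500 peaks, 30 TFs, 2,000 cells) are chosen
  so the full two-stage pipeline with bootstrap inference runs in
  seconds on one CPU while keeping ≥ 150 planted TF edges and 250
  planted CRE links for stable recall/FDR estimates.

## 4. Design decisions

- **λ₂ tied to λ₁.** Parameterizing the ridge level as a fixed fraction
  of the L1 level (`l2_weight`) makes one CV sweep tune both and makes
  "ridge weight 0.25/0.5" statements meaningful across problems with
  different scales.
- **Estimator as a scikit-learn class.** The statistical core is
  `AdaptiveElasticNet(BaseEstimator, RegressorMixin)`; pipeline stages
  that operate on genomic domain objects (peaks, annotations, motif
  hits) remain plain functions over typed containers — a regressor
  interface fits the math, not the genomics plumbing.
- **Pooled-modality depth factors** (Section 1.4): the multiome pairing
  guarantees both assays share the cell, so its depth estimate may use
  both; each matrix can also be normalized by its own totals when no
  paired matrix is available.
- **Identity-preserving baselines.** The perturbation baseline uses
  model predictions (not observations) for modeled genes so that the
  identity perturbation is exactly null; pseudocell ids are ordered by
  numeric suffix so a pooling target of 1 is exactly the identity.
- **Strict I/O.** Readers validate dimensions, duplicate ids, interval
  sanity, and strand values at the boundary, so the in-memory
  containers can assume clean data.

## 5. Limitations

- Bootstrap p-values are not valid post-selection inference for the
  surviving coefficients (Section 1.3); treat per-link p-values as a
  ranking/filtering device, not as calibrated error statements about
  individual selected links.
- CRE candidacy is marginal per gene; a peak inside two genes' windows
  can be credited to both. No attempt is made to deconvolve shared
  enhancers.
- TF nomination depends entirely on motif presence; TFs acting without
  a detectable motif (cofactors, tethering) are invisible, and motif
  families with near-identical PFMs are not disambiguated.
- The perturbation model is one-step linear: no propagation through
  TF→TF cascades, no feedback, no re-equilibration.
- PageRank/betweenness use |β|-based weights; sign information is kept
  on the edges but not used by the centralities themselves.
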