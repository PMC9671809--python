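# Methods

This note documents the statistical machinery, the synthetic-cohort
generator it is validated against, and the design choices made where the
underlying methodology leaves room.

## Data model and preprocessing

All layers are sample × feature matrices (`OmicsLayer`) with a layer kind
that fixes validation rules: genotype dosages in [0, 2], microbiome
relative abundances in [0, 1] before transformation.

- **Metabolome**: natural-log transform (zeros shifted by half the
  smallest positive value), then OLS residualization on the configured
  covariate set (age, sex, smoking by default; per-stage sets are
  configurable — the microbiome scans add proton-pump-inhibitor and
  antibiotics flags, the mQTL scan can add BMI and further covariates).
  Residuals are exactly orthogonal to the covariates used (asserted to
  |r| < 1e−10 in tests).
- **Microbiome**: prevalence filter (features present in ≥ 10% of
  samples, inclusive at the boundary), closure renormalization, centered
  log-ratio transform with zeros replaced by half the global smallest
  nonzero relative abundance, then a rank-based inverse normal transform.
- **Rank-inverse normal**: Φ⁻¹((r − 3/8)/(n + 1/4)) with average ranks for
  ties (Blom offset). The offset choice is the package's own; alternative
  offsets differ negligibly and the choice is recorded in output headers.
- Missing values: correlations are pairwise-complete; samples with
  missing covariates are dropped per analysis with a logged count.

## Whole-metabolome PERMANOVA

The Gower-centered inner-product matrix G = −½ J D² J of a sample
dissimilarity matrix D (Euclidean on the transformed metabolome, chosen
to be consistent with the Euclidean PCoA used for the temporal shift) is
projected on the centered design of one factor; R² = tr(QᵀGQ)/tr(G) with
Q an orthonormal basis of the design. On a univariate Euclidean distance
this reduces *exactly* to the one-way ANOVA R² (oracle-tested to 1e−10,
and the pseudo-F is cross-checked against an independent PERMANOVA
implementation). Significance is by label permutation,
p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1), default 1,000 permutations.

Marginally significant factors (permutation FDR < 0.05) are de-collineared
by average-linkage clustering on D = 1 − r² cut at 0.70; each cluster is
represented by its medoid (greatest mean r² to cluster mates, ties broken
by feature id). The combined model enters representatives in descending
marginal-R² order and attributes each one's sequential sum of squares
(Gram–Schmidt increment tr(qᵀGq)) to its layer; a marginal mode is
available since the sequential/marginal choice is genuinely open, and the
entry order is recorded in outputs. Linkage method and medoid rule are
package choices, recorded in output metadata.

## Per-metabolite variance partitioning

Candidates per layer are the features associated with the metabolite at
BH FDR < 0.05 in the corresponding Spearman scan (for genetics, the mQTL
scan — study-wide hits are a subset of these). Per layer: predictors are
standardized; a lasso path over 100 log-spaced λ values is scored by
seeded 10-fold cross-validation; features with nonzero coefficients at
the minimum-mean-error λ are refit by OLS; adjusted
r² = 1 − (1 − r²)(n − 1)/(n − p − 1) and the F-test p are recorded; no
survivors ⇒ r² = 0, p = 1; more survivors than n/2 ⇒ truncation to the
top n/2 by |coefficient| (logged). Elastic net (mixing 0.5) is the
robustness variant and agrees with lasso within ±0.05 on the default
design (tested). BH q-values are computed across metabolites per layer;
the dominant factor is the layer with the strictly greatest adjusted r²
among layers with q < 0.05, 'none' on ties or no significance, with
negative adjusted r² floored at zero for the comparison.

Post-selection OLS p-values are anti-conservative in isolation; the
pipeline's null behaviour is controlled by the candidate pre-screen plus
the across-metabolite BH step, which is what the null tests exercise.

## mQTL mapping

Spearman correlation (p from the t-approximation
t = ρ√((n−2)/(1−ρ²)); all designs here have n ≥ 100, where the
approximation is accurate — an exact small-n mode was deliberately not
built) between each SNP dosage and each metabolite residual; monomorphic
SNPs are skipped. Study-wide significance divides the genome-wide
5.0 × 10⁻⁸ by the number of metabolites tested (1,183 tests give
4.2 × 10⁻¹¹). Greedy clumping sorts by ascending p (ties by chromosome,
position, id) and accepts a SNP iff no accepted SNP within ±500 kb has
dosage r² ≥ 0.05.

## Mendelian randomization

Per-SNP summary statistics come from simple linear regressions of the
(residualized) feature on dosage. Instruments: p < 10⁻⁵, clumped, ≥ 3
surviving; when follow-up statistics are available, instruments must
replicate with the same sign at p < 0.05 (forward) or p < 0.1 (reverse
direction). Estimators, all from first principles:

- Wald ratio β_out/β_exp with first-order delta SE se_out/|β_exp|.
- Fixed-effect IVW: β = Σwβ/Σw, se = (Σw)^−½, w = se⁻²; fixed effects
  because heterogeneous results are filtered by Q rather than modeled.
- Weighted median: cumulative-weight interpolation at 50%; SE by seeded
  parametric bootstrap (1,000 draws) — the SE method is a package choice.
- MR-Egger: WLS of outcome betas on exposure betas with intercept,
  weights se_out⁻², SNPs oriented so β_exp > 0; only the intercept is
  used for filtering (the slope is reported, never used for verdicts).
- Cochran's Q with J − 1 df; leave-one-out IVW re-estimates.

The verdict cascade, in order: `not_significant` (BH q of forward IVW
p-values ≥ 0.05, forward-only BH by default, switchable) →
`filtered_pleiotropy` (Egger intercept p < 0.05) →
`filtered_heterogeneity` (Q p < 0.05) → `filtered_loo` →
`filtered_reverse` (reverse IVW p < 0.05) → `causal_candidate`.
The leave-one-out exclusion is operationalized as the single-driver
signature: exactly one configuration non-significant while all others
stay significant. One-sample overlap (same samples for exposure and
outcome statistics) is accepted and documented; with no confounding in
the generator it does not bias the planted-effect recovery (mean IVW
estimate within 0.05 of a planted 0.3 over 200 replicates, tested).

A practical caveat surfaced by the planted reverse-causation scenario:
when instruments reach the exposure only through the outcome, their
exposure betas are noisy, and MR-Egger's no-measurement-error assumption
breaks first — weak reverse wiring tends to be flagged as pleiotropy or
heterogeneity before the reverse check fires. The reverse signature is
therefore exercised with a strong reverse path.

## Mediation

Mediator model m ~ x + covariates; outcome model y ~ x + m + x·m +
covariates, both OLS. Quasi-Bayesian inference (1,000 draws from the
estimated sampling distributions) computes counterfactual means with the
continuous treatment contrasted at mean vs mean + SD (the package's
choice for continuous exposures). ACME is averaged over the treated and
control mediator regimes (both components reported; they differ when the
interaction is nonzero), ADE likewise; total = ACME + ADE exactly in the
linear model. Two-sided p is the tail proportion of the ACME draws,
floored at 1/(n_sims + 1) and labeled when floored.

Direction verdict for a (treatment, a, b) triple: an ordering `mediates`
iff its (BH-adjusted, across all triples) ACME p < 0.05 while the inverse
ordering's p > 0.05; both → `ambiguous`, neither → `none`. Note a genuine
identification limit: in a linear Gaussian chain the inverse-ordering
mediation effect is nonzero (attenuated by b·σ²_m/(b²σ²_m + σ²_y), not
absent), so direction is resolvable only when the inverse effect falls
below noise — weak paths, a noisy outcome and a large n. The
direction-signature tests run in that regime (a = 0.12, b = 0.35,
σ_y = 3, n = 2,000) and use a majority vote over seeds.

## Temporal stability and diet score

Stability is the per-metabolite Spearman correlation across ≥ 30 paired
samples. The relation to explained variance is a Spearman correlation of
stability against per-layer and total adjusted r²; dominance groups are
compared by two-sided rank-sum tests (normal approximation, continuity
correction; groups under 5 skipped). The two-time-point shift uses a
pooled classical MDS (principal coordinates via eigendecomposition of the
Gower-centered matrix — coordinates reproduce Euclidean inputs exactly,
oracle-tested) with per-component paired signed-rank tests; an all-zero
difference vector reports p = 1 with a degeneracy flag rather than an
error.

The diet-quality model: Spearman screen at p < 0.05, lasso with 10-fold
CV λ, OLS refit on survivors; evaluation regresses the observed held-out
score on the predictions and reports adjusted r² and the F-test p. Under
a null score the model may still retain a chance feature (the screen
admits ~5% of features and CV-min λ is liberal), but it carries no
out-of-sample predictive power — that, not model emptiness, is the
tested null property.

## Synthetic cohort

The generator produces the structure the analysis assumes, with recorded
truth; defaults (800 samples, 200 metabolites, 500 SNPs, 80 taxa, 40 diet
items, 311 follow-up samples) keep every stage within minutes on one CPU.

- **Genotypes**: HWE dosages (sum of two Bernoulli(MAF) allele copies),
  MAF uniform in [0.05, 0.5]. LD within a block is an allele-copy Markov
  chain: each allele copy of SNP j+1 equals SNP j's copy with probability
  ld_rho, else a fresh draw — adjacent dosage correlation equals ld_rho
  directly (a latent-Gaussian copula was considered but its correlation
  attenuates at the binary allele level and cannot reach high dosage r²).
  Blocks sit > 500 kb apart so clumping windows separate them.
- **Microbiome**: zero-inflated log-normal abundances over ~4 orders of
  magnitude, closed to sum 1, internal 10%-prevalence floor. Zeros are
  *not* replaced here — they flow downstream so the CLR pseudocount rule
  is exercised.
- **Diet**: items load on a few latent factors plus item noise; the
  diet-quality score is a fixed linear combination of the latent factors
  and is the ground truth for the prediction stage (the real
  questionnaire-derived score is not reconstructible; alternative scores
  are further latent combinations, configurable).
- **Metabolites**: y = Σ_layer √f_layer · (standardized composite of a
  few layer features) + √f_noise · ε, composed from the standardized
  *analysis-scale* signals (CLR+INT taxa, standardized dosages/items), so
  the recorded fractions are exact on the scale the partitioning
  estimates and recovery is not attenuated by the compositional
  transform. Age/sex effects are added on top and recorded; fractions
  refer to the covariate-adjusted scale. Fraction designs emulate
  plausible population ranges (diet up to ~0.35, microbiome ~0.25,
  genetics ~0.28, ~15% pure-noise metabolites) with a ≥ 5-point dominance
  margin so dominance labels are well defined.
- **Follow-up**: follow-up = ρ·standardized baseline + √(1−ρ²)·innovation,
  rescaled to baseline moments; by default stability targets rise with a
  metabolite's explained fraction (0.15 + 0.8·explained, capped at 0.95),
  planting the stability-vs-variance signature.
- **Scenario generators** plant MR systems (instrument strengths,
  causal/pleiotropic/reverse wiring, including outcome-side instruments
  so reverse causation can contaminate a forward analysis) and mediation
  chains with chosen path coefficients.

What the generator does **not** emulate: phylogenetic correlation among
taxa, sequencing-depth noise, genotype imputation error, non-Gaussian
metabolite distributions beyond the log scale, and population structure.
Passing tests therefore demonstrate correctness of the estimators on
data satisfying their assumptions — not robustness to every failure mode
of real cohort data.

## Determinism and numerics

Every stochastic stage draws from a stream keyed by (global seed, CRC32
of the stage name), so adding or reordering stages never changes another
stage's results; two runs with equal config and inputs are byte-identical
(tested). Numeric text output is written at 12 significant digits.
Degenerate inputs: constant columns are preserved and flagged
(log-transform), mapped to zeros with a warning (rank-inverse), skipped
with a log entry (interaction products, monomorphic SNPs), or rejected
with located messages (all-zero compositions, collinear covariates).

## Problem sizes used in validation

Null-calibration checks use 500 replicates per test statistic (199
permutations per PERMANOVA replicate, where the attainable p-grid makes
the nominal 0.05 exact under exchangeability). Recovery checks use
n = 2,000 with 200 metabolites for variance partitioning, 200 replicates
at n = 1,000 for IVW, 200 replicates at n = 500 with 1,000 quasi-Bayesian
draws for ACME, and n = 311 pairs for stability. The acceptance script
runs the pipeline at 800 samples × 120 metabolites with 499 permutations.
These sizes were chosen so the whole validation cycle completes in
minutes on a single CPU while keeping Monte-Carlo error well inside the
stated tolerances.
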