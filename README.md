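# metabvar

**How much of the person-to-person variation in the plasma metabolome is
explained by diet, host genetics and the gut microbiome — and which links
are plausibly causal?**

`metabvar` is a Python library for population multi-omics studies that
measure plasma metabolites alongside genotypes, gut metagenomes and
food-frequency questionnaires. It implements, as tested and reusable
components:

- **Whole-metabolome attribution** by PERMANOVA: each candidate factor's
  share R² = SS(factor)/SS(total) of a sample dissimilarity matrix, with
  permutation p-values; collinear factors are reduced to representatives
  by average-linkage clustering of the 1 − r² correlation distance (cut at
  70% dissimilarity, medoid per cluster) before a combined sequential-SS
  partition.
- **Per-metabolite variance partitioning**: for each metabolite *y*, the
  FDR-significant features of each layer are screened by lasso
  (10-fold cross-validated λ at minimum mean error), survivors refit by
  OLS, and adjusted r² per layer recorded; the layer with the strictly
  greatest significant adjusted r² is the metabolite's **dominant factor**
  (diet, microbiome, genetics, or none). An elastic-net mode (mixing 0.5)
  is the robustness variant.
- **mQTL mapping**: Spearman correlation of SNP dosage against
  covariate-adjusted metabolite residuals, study-wide significance at
  5.0 × 10⁻⁸ / (number of metabolites), greedy LD clumping (r² < 0.05,
  500-kb window).
- **One-sample bi-directional Mendelian randomization**: instruments at
  p < 10⁻⁵ (≥ 3 after clumping, optional follow-up replication), per-SNP
  Wald ratios β_out/β_exp meta-analyzed by fixed-effect IVW
  (w_j = se_j⁻²), weighted-median estimator, MR-Egger intercept test,
  Cochran's Q, leave-one-out, and a verdict cascade ending with the
  reverse-direction check.
- **Bi-directional mediation** with treatment–mediator interaction
  (y = x + m + x·m): quasi-Bayesian ACME/ADE with the continuous
  treatment contrasted at mean vs mean + SD, and a direction verdict
  requiring the inverse ordering to be non-significant.
- **Temporal stability**: per-metabolite Spearman correlation across two
  time points, its relation to explained variance, dominance-group
  comparisons, and a joint principal-coordinates shift test.
- **Metabolome-based diet-quality prediction**: Spearman screen → lasso →
  OLS refit, evaluated by adjusted r² / F-test on held-out samples.
- A **synthetic-cohort generator** with recorded ground truth (variance
  fractions, causal chains, stability targets) so every stage is testable
  end-to-end without access-restricted cohort data.

## Worked example

```bash
python examples/05_full_pipeline.py
```

runs every stage on a 400-sample synthetic cohort (40 metabolites,
100 SNPs, 40 taxa, 20 dietary items) and prints:

```
whole-metabolome PERMANOVA shares (fractions of distance variance):
 total_r2  share_diet  share_microbiome  share_genotype
   0.2087      0.0651            0.0954          0.0482

dominant-factor counts:
diet          17
genetics      10
microbiome     8
none           5

diet-score model (validation = held-out 20% of samples):
 train_r2_adj  train_f_p  valid_r2_adj  valid_f_p  n_selected  n_valid
       0.3687        0.0        0.2678        0.0          14       80

stability vs explained variance:
variance_term    rho      p  n
         diet 0.6151 0.0000 40
        model 0.8479 0.0000 40
```

Reading the output: the three layers jointly explain ~21% of
whole-metabolome distance variance, with the microbiome the largest
single share in this cohort realization; 35 of 40 metabolites get a
dominant factor matching how they were generated; a 14-metabolite linear
model predicts the held-out diet-quality score with adjusted r² = 0.27;
and metabolites whose variance is better explained are more stable over
the follow-up interval (ρ = 0.85 against total explained variance).

Other examples cover the generator (`01`), per-metabolite partitioning
against ground truth (`02`), MR on a planted causal effect (`03`), and
mediation recovery of a planted a·b = 0.40 chain (`04`). A thin CLI
(`metabvar simulate|preprocess|associate|variance|mr|mediate|temporal|dietscore|run-all`)
wraps the same functions for shell use.

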