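"""Synthetic multi-omics cohort with known ground truth.

Generates the inputs the analysis stages assume: Hardy–Weinberg biallelic
dosages with block-wise linkage disequilibrium, zero-inflated compositional
taxa, correlated dietary items driven by latent factors, covariates, and
metabolites built as additive mixtures of layer signals with prescribed
variance fractions plus Gaussian noise.  Planted SNP->taxon->metabolite and
diet->mediator->outcome chains, plus a follow-up time point with chosen
per-metabolite temporal correlation, make every downstream stage testable
against recorded truth.

Metabolite mixtures are composed from the *standardized analysis-scale*
signals (CLR + inverse-rank taxa, standardized dosages and diet items), so
the recorded variance fractions are exact on the scale the variance
partitioning estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LayerKind, OmicsLayer, stage_rng
from .preprocess import transform_microbiome

__all__ = [
    "GenerativeTruth",
    "simulate_genotypes",
    "simulate_microbiome",
    "simulate_diet",
    "simulate_covariates",
    "simulate_metabolome",
    "simulate_followup",
    "simulate_mr_scenario",
    "simulate_mediation_scenario",
    "simulate_cohort",
]

LAYERS = ("diet", "genotype", "microbiome")


@dataclass
class GenerativeTruth:
    """Ground truth recorded while generating a cohort.

    ``fractions`` — per metabolite, the variance fraction contributed by
    each layer plus noise (rows sum to 1).  ``loadings`` — per metabolite,
    the contributing feature ids and weights per layer.  ``stability`` —
    per-metabolite temporal correlation targets.  ``chains`` — planted
    causal / mediation chains with their true effect sizes.
    """

    fractions: pd.DataFrame
    loadings: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    stability: pd.Series | None = None
    covariate_effects: pd.DataFrame | None = None
    chains: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        frac_cols = [c for c in self.fractions.columns]
        sums = self.fractions[frac_cols].sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-metabolite variance fractions must sum to 1")
        if (self.fractions[frac_cols].to_numpy() < -1e-12).any():
            raise ValueError("variance fractions must be non-negative")
        if self.stability is not None:
            s = self.stability.to_numpy(dtype=float)
            if (s < 0).any() or (s > 1).any():
                raise ValueError("stability targets must lie in [0, 1]")


# ---------------------------------------------------------------------------
# genotype layer


def simulate_genotypes(
    n_samples: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block_size: int = 5,
    ld_rho: float = 0.8,
    seed: int | np.random.Generator = 0,
) -> OmicsLayer:
    """HWE dosages in {0,1,2} with block-wise LD.

    Per SNP the MAF is uniform in ``maf_range`` (shared within an LD
    block) and dosage is the sum of two independent allele copies, so
    marginals follow Hardy–Weinberg proportions.  Within a block, each
    allele copy of SNP j+1 equals the corresponding copy of SNP j with
    probability ``ld_rho`` and is redrawn Bernoulli(MAF) otherwise, which
    makes the dosage correlation of adjacent block-mates ~``ld_rho`` (and
    ``ld_rho``^k at lag k) — directly tunable LD for clumping tests.
    Positions place distinct blocks more than 500 kb apart so clumping
    windows separate them.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    lo, hi = maf_range
    if lo < 0.05:
        raise ValueError("requested MAF below 0.05 violates the emulated genotype QC")
    if hi > 0.5:
        raise ValueError("MAF cannot exceed 0.5")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    mafs = np.empty(n_snps)
    dosage = np.empty((n_samples, n_snps), dtype=float)
    n_blocks = int(np.ceil(n_snps / ld_block_size))
    for b in range(n_blocks):
        j0, j1 = b * ld_block_size, min((b + 1) * ld_block_size, n_snps)
        maf = rng.uniform(lo, hi)
        mafs[j0:j1] = maf
        alleles = rng.uniform(size=(n_samples, 2)) < maf
        dosage[:, j0] = alleles.sum(axis=1)
        for j in range(j0 + 1, j1):
            copy = rng.uniform(size=(n_samples, 2)) < ld_rho
            fresh = rng.uniform(size=(n_samples, 2)) < maf
            alleles = np.where(copy, alleles, fresh)
            dosage[:, j] = alleles.sum(axis=1)

    snp_ids = [f"snp{j:04d}" for j in range(n_snps)]
    pos = np.empty(n_snps, dtype=int)
    for j in range(n_snps):
        b, off = divmod(j, ld_block_size)
        pos[j] = 1_000_000 + b * 600_000 + off * 2_000
    meta = pd.DataFrame(
        {"chrom": "1", "pos": pos, "effect_allele": "A", "maf": mafs},
        index=snp_ids,
    )
    data = pd.DataFrame(dosage, index=_sample_ids(n_samples), columns=snp_ids)
    return OmicsLayer(LayerKind.GENOTYPE, data, feature_meta=meta)


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# microbiome layer


def simulate_microbiome(
    n_samples: int,
    n_taxa: int,
    zero_inflation: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> OmicsLayer:
    """Zero-inflated log-normal relative abundances, closed to sum 1.

    Per-taxon mean log abundance spreads the taxa over ~4 orders of
    magnitude; a per-taxon Bernoulli mask (rate drawn around
    ``zero_inflation``) zeroes entries; rows are renormalized; taxa absent
    in more than 90% of samples are regenerated away by an internal
    prevalence floor so every emitted taxon is present in >= 10% of samples.
    """
    if not 0 <= zero_inflation < 0.9:
        raise ValueError("zero_inflation must be in [0, 0.9)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = rng.uniform(-4, 0, size=n_taxa)
    raw = np.exp(mu + rng.standard_normal((n_samples, n_taxa)))
    if zero_inflation > 0:
        # per-taxon zero rate jittered around the requested level, capped at 0.85
        rate = np.clip(rng.uniform(0.5, 1.5, size=n_taxa) * zero_inflation, 0, 0.85)
        mask = rng.uniform(size=raw.shape) < rate
        raw = np.where(mask, 0.0, raw)
    # ensure no all-zero sample
    dead = raw.sum(axis=1) == 0
    if dead.any():
        raw[dead, 0] = np.exp(mu[0])
    rel = raw / raw.sum(axis=1, keepdims=True)
    data = pd.DataFrame(rel, index=_sample_ids(n_samples),
                        columns=[f"taxon{j:03d}" for j in range(n_taxa)])
    # internal prevalence floor: drop taxa below 10% presence, re-close
    present = (data.to_numpy() > 0).mean(axis=0)
    data = data.loc[:, present >= 0.10]
    vals = data.to_numpy()
    data = pd.DataFrame(vals / vals.sum(axis=1, keepdims=True), index=data.index, columns=data.columns)
    return OmicsLayer(LayerKind.MICROBIOME_TAXA, data)


# ---------------------------------------------------------------------------
# diet layer


def simulate_diet(
    n_samples: int,
    n_items: int,
    n_latent: int = 4,
    item_noise: float = 0.6,
    seed: int | np.random.Generator = 0,
) -> tuple[OmicsLayer, pd.Series]:
    """Correlated dietary-habit items from latent factors, plus the latent
    diet-quality score.

    Each item loads on one latent factor with weight sqrt(1-item_noise^2)
    plus independent noise; the quality score is a fixed linear combination
    of the latent factors (equal weights, alternating sign) and is the
    ground truth for the diet-score prediction stage.
    """
    if n_latent > n_items:
        raise ValueError("n_latent must be <= n_items")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    F = rng.standard_normal((n_samples, n_latent))
    load = np.sqrt(max(0.0, 1 - item_noise**2))
    assign = np.arange(n_items) % n_latent
    items = load * F[:, assign] + item_noise * rng.standard_normal((n_samples, n_items))
    w = np.array([(-1.0) ** k for k in range(n_latent)]) / np.sqrt(n_latent)
    score = F @ w
    data = pd.DataFrame(items, index=_sample_ids(n_samples),
                        columns=[f"diet{j:03d}" for j in range(n_items)])
    return OmicsLayer(LayerKind.DIET, data), pd.Series(score, index=data.index, name="diet_quality")


# ---------------------------------------------------------------------------
# covariates


def simulate_covariates(n_samples: int, seed: int | np.random.Generator = 0) -> OmicsLayer:
    """Age, sex (0/1), BMI, smoking (0/1) and two medication flags."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = pd.DataFrame(
        {
            "age": rng.uniform(20, 70, n_samples),
            "sex": rng.integers(0, 2, n_samples).astype(float),
            "bmi": rng.normal(25, 4, n_samples),
            "smoking": (rng.uniform(size=n_samples) < 0.25).astype(float),
            "ppi": (rng.uniform(size=n_samples) < 0.1).astype(float),
            "antibiotics": (rng.uniform(size=n_samples) < 0.05).astype(float),
        },
        index=_sample_ids(n_samples),
    )
    return OmicsLayer(LayerKind.COVARIATES, data)


# ---------------------------------------------------------------------------
# metabolome


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def default_fraction_design(
    n_metabolites: int,
    rng: np.random.Generator,
    dominance_margin: float = 0.05,
) -> pd.DataFrame:
    """Variance-fraction targets emulating the study's reported ranges.

    Diet contributions span roughly 0–0.35, microbiome 0–0.25, genetics
    0–0.28; most metabolites are diet-dominant, a smaller set microbiome-
    or genetics-dominant, and ~15% are pure noise.  Dominant layers win by
    at least ``dominance_margin`` so dominance labels are well defined.
    """
    rows = []
    kinds = rng.choice(
        ["diet", "microbiome", "genotype", "none"],
        size=n_metabolites,
        p=[0.45, 0.25, 0.15, 0.15],
    )
    for kind in kinds:
        if kind == "none":
            f = {"diet": 0.0, "genotype": 0.0, "microbiome": 0.0}
        else:
            hi_range = {"diet": (0.12, 0.35), "microbiome": (0.12, 0.25), "genotype": (0.12, 0.28)}
            hi = rng.uniform(*hi_range[kind])
            f = {}
            for layer in LAYERS:
                if layer == kind:
                    f[layer] = hi
                else:
                    f[layer] = rng.uniform(0.0, max(0.0, hi - dominance_margin) * 0.6)
        noise = 1.0 - sum(f.values())
        rows.append({**f, "noise": noise})
    idx = [f"met{j:04d}" for j in range(n_metabolites)]
    return pd.DataFrame(rows, index=idx)


def simulate_metabolome(
    genotype: OmicsLayer,
    microbiome: OmicsLayer,
    diet: OmicsLayer,
    covariates: OmicsLayer,
    truth_design: pd.DataFrame,
    n_features_per_layer: int = 4,
    covariate_sd: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> tuple[OmicsLayer, GenerativeTruth]:
    """Metabolites as additive mixtures of layer signals plus noise.

    ``truth_design`` rows (index = metabolite ids) give the target variance
    fractions for columns diet/genotype/microbiome/noise, summing to 1.
    Per metabolite and contributing layer, ``n_features_per_layer`` features
    are drawn, combined with random weights, the composite standardized and
    scaled to sqrt(fraction) — so the empirical variance share of every
    generative component equals its target exactly (before covariate
    effects).  Age and sex effects of scale ``covariate_sd`` are added on
    top and recorded; the fractions refer to the covariate-adjusted scale.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frac_cols = ["diet", "genotype", "microbiome", "noise"]
    if not set(frac_cols) <= set(truth_design.columns):
        raise ValueError(f"truth_design must have columns {frac_cols}")
    sums = truth_design[frac_cols].sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise ValueError("per-metabolite fractions must sum to 1")

    n = genotype.n_samples
    micro_t = transform_microbiome(microbiome)
    signals = {
        "genotype": _standardize(genotype.values),
        "microbiome": _standardize(micro_t.to_numpy()),
        "diet": _standardize(diet.values),
    }
    ids = {
        "genotype": genotype.feature_ids,
        "microbiome": list(micro_t.columns),
        "diet": diet.feature_ids,
    }

    cov = covariates.data
    age_z = _standardize(cov[["age"]].to_numpy()).ravel()
    sex_z = _standardize(cov[["sex"]].to_numpy()).ravel()

    met = np.empty((n, len(truth_design)))
    loadings: dict[str, dict[str, dict[str, float]]] = {}
    cov_eff_rows = []
    for i, (mid, row) in enumerate(truth_design.iterrows()):
        y = np.zeros(n)
        loadings[mid] = {}
        for layer in LAYERS:
            f = float(row[layer])
            if f <= 0:
                continue
            nf = min(n_features_per_layer, signals[layer].shape[1])
            picks = rng.choice(signals[layer].shape[1], size=nf, replace=False)
            w = rng.normal(size=nf)
            comp = signals[layer][:, picks] @ w
            comp = _standardize(comp[:, None]).ravel()
            y = y + np.sqrt(f) * comp
            loadings[mid][layer] = {ids[layer][p]: float(wi) for p, wi in zip(picks, w)}
        fn = float(row["noise"])
        eps = _standardize(rng.standard_normal((n, 1))).ravel()
        y = y + np.sqrt(fn) * eps
        b_age, b_sex = rng.normal(0, covariate_sd, size=2)
        met[:, i] = y + b_age * age_z + b_sex * sex_z
        cov_eff_rows.append({"age": b_age, "sex": b_sex})

    data = pd.DataFrame(met, index=genotype.data.index, columns=truth_design.index)
    truth = GenerativeTruth(
        fractions=truth_design[frac_cols].copy(),
        loadings=loadings,
        covariate_effects=pd.DataFrame(cov_eff_rows, index=truth_design.index),
    )
    return OmicsLayer(LayerKind.METABOLOME, data), truth


# ---------------------------------------------------------------------------
# follow-up time point


def simulate_followup(
    baseline: OmicsLayer,
    stability_targets: pd.Series,
    seed: int | np.random.Generator = 0,
    n_followup: int | None = None,
) -> OmicsLayer:
    """Second time point with chosen per-metabolite temporal correlation.

    followup = rho * standardized(baseline) + sqrt(1-rho^2) * innovation,
    rescaled back to baseline mean and variance, for the first
    ``n_followup`` samples (all by default).
    """
    rho = stability_targets.reindex(baseline.feature_ids).to_numpy(dtype=float)
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("stability targets must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = baseline.data if n_followup is None else baseline.data.iloc[:n_followup]
    vals = df.to_numpy(dtype=float)
    mu, sd = vals.mean(axis=0), vals.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (vals - mu) / sd
    innov = rng.standard_normal(vals.shape)
    follow = rho * z + np.sqrt(1 - rho**2) * innov
    out = pd.DataFrame(follow * sd + mu, index=df.index, columns=df.columns)
    return OmicsLayer(LayerKind.METABOLOME, out)


# ---------------------------------------------------------------------------
# MR scenario


def simulate_mr_scenario(
    n_samples: int = 1000,
    n_instruments: int = 5,
    per_snp_exposure_r2: float = 0.02,
    causal_effect: float = 0.3,
    reverse_effect: float = 0.0,
    pleiotropy: float = 0.0,
    n_reverse_instruments: int = 0,
    per_snp_outcome_r2: float = 0.02,
    n_null_snps: int = 20,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Planted instrument->exposure->outcome system for the MR stage.

    ``n_instruments`` independent SNPs each explain ``per_snp_exposure_r2``
    of the exposure (a transformed taxon abundance stand-in); the outcome
    (a metabolite stand-in) is ``causal_effect * exposure`` plus noise, plus
    an optional constant ``pleiotropy`` direct effect of every instrument.
    ``n_reverse_instruments`` SNPs act on the outcome instead, and
    ``reverse_effect`` wires outcome -> exposure, letting reverse-causation
    scenarios be planted.  ``n_null_snps`` unassociated SNPs pad the panel.
    Returns a dict with genotype layer, exposure/outcome series and truth.
    """
    if n_instruments < 0 or per_snp_exposure_r2 <= 0 or per_snp_exposure_r2 > 0.2:
        raise ValueError("per_snp_exposure_r2 must be in (0, 0.2]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_snps = n_instruments + n_reverse_instruments + n_null_snps
    geno = simulate_genotypes(
        n_samples, n_snps, maf_range=(0.2, 0.5), ld_block_size=1, ld_rho=0.0, seed=rng
    )
    G = _standardize(geno.values)
    exp_idx = np.arange(n_instruments)
    rev_idx = np.arange(n_instruments, n_instruments + n_reverse_instruments)

    g_exp = np.sqrt(per_snp_exposure_r2) * G[:, exp_idx].sum(axis=1) if n_instruments else 0.0
    var_gexp = n_instruments * per_snp_exposure_r2
    g_out = np.sqrt(per_snp_outcome_r2) * G[:, rev_idx].sum(axis=1) if n_reverse_instruments else 0.0
    var_gout = n_reverse_instruments * per_snp_outcome_r2

    e_exp = rng.standard_normal(n_samples) * np.sqrt(max(1e-9, 1 - var_gexp))
    e_out = rng.standard_normal(n_samples) * np.sqrt(max(1e-9, 1 - var_gout))

    if reverse_effect != 0.0:
        outcome = g_out + e_out
        exposure = g_exp + reverse_effect * outcome + e_exp
        outcome = outcome + causal_effect * exposure  # usually 0 in reverse scenarios
    else:
        exposure = g_exp + e_exp
        outcome = causal_effect * exposure + g_out + e_out
    if pleiotropy != 0.0 and n_instruments:
        outcome = outcome + pleiotropy * G[:, exp_idx].sum(axis=1)

    idx = geno.data.index
    return {
        "genotype": geno,
        "exposure": pd.Series(exposure, index=idx, name="exposure"),
        "outcome": pd.Series(outcome, index=idx, name="outcome"),
        "truth": {
            "causal_effect": causal_effect,
            "reverse_effect": reverse_effect,
            "pleiotropy": pleiotropy,
            "instrument_ids": [geno.feature_ids[j] for j in exp_idx],
            "reverse_instrument_ids": [geno.feature_ids[j] for j in rev_idx],
        },
    }


# ---------------------------------------------------------------------------
# mediation scenario


def simulate_mediation_scenario(
    n_samples: int = 500,
    a: float = 0.8,
    b: float = 0.5,
    c_prime: float = 0.0,
    interaction: float = 0.0,
    direction: str = "metabolite_mediates",
    sigma_m: float = 1.0,
    sigma_y: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Planted treatment->mediator->outcome triple.

    mediator = a*treatment + e1;  outcome = c'*treatment + b*mediator +
    interaction*treatment*mediator + e2, with standard-normal treatment and
    Gaussian errors of SD ``sigma_m`` / ``sigma_y``.  ``direction`` labels
    which variable (metabolite or microbe) plays the mediator role in the
    bundle, so direction-verdict tests know the truth.
    """
    if direction not in ("metabolite_mediates", "microbe_mediates"):
        raise ValueError("direction must be metabolite_mediates or microbe_mediates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rng.standard_normal(n_samples)
    m = a * x + sigma_m * rng.standard_normal(n_samples)
    y = c_prime * x + b * m + interaction * x * m + sigma_y * rng.standard_normal(n_samples)
    idx = _sample_ids(n_samples)
    mediator_name = "metabolite" if direction == "metabolite_mediates" else "taxon"
    outcome_name = "taxon" if direction == "metabolite_mediates" else "metabolite"
    return {
        "treatment": pd.Series(x, index=idx, name="diet_item"),
        "mediator": pd.Series(m, index=idx, name=mediator_name),
        "outcome": pd.Series(y, index=idx, name=outcome_name),
        "truth": {
            "a": a, "b": b, "c_prime": c_prime, "interaction": interaction,
            "acme_unit_sd": a * b,  # per unit-SD treatment contrast, interaction = 0
            "direction": direction,
        },
    }


# ---------------------------------------------------------------------------
# full cohort bundle


def simulate_cohort(
    n_samples: int = 800,
    n_metabolites: int = 200,
    n_snps: int = 500,
    n_taxa: int = 80,
    n_diet_items: int = 40,
    n_followup: int = 311,
    seed: int = 0,
) -> dict:
    """Desk-scale cohort bundle: all layers, follow-up, and truth tables.

    Stability targets are wired to increase with a metabolite's total
    explained fraction (0.15 + 0.8 * explained, capped at 0.95), which is
    the qualitative signature the temporal stage should recover.
    """
    rngs = {s: stage_rng(seed, f"simulate/{s}") for s in
            ("genotype", "microbiome", "diet", "covariates", "metabolome", "followup")}
    geno = simulate_genotypes(n_samples, n_snps, seed=rngs["genotype"])
    micro = simulate_microbiome(n_samples, n_taxa, zero_inflation=0.3, seed=rngs["microbiome"])
    diet, diet_score = simulate_diet(n_samples, n_diet_items, seed=rngs["diet"])
    cov = simulate_covariates(n_samples, seed=rngs["covariates"])
    design = default_fraction_design(n_metabolites, rngs["metabolome"])
    met, truth = simulate_metabolome(geno, micro, diet, cov, design, seed=rngs["metabolome"])

    explained = 1.0 - truth.fractions["noise"]
    stability = (0.15 + 0.8 * explained).clip(0, 0.95)
    stability.name = "stability_target"
    truth.stability = stability
    follow = simulate_followup(met, stability, seed=rngs["followup"],
                               n_followup=min(n_followup, n_samples))
    return {
        "genotype": geno,
        "microbiome": micro,
        "diet": diet,
        "diet_score": diet_score,
        "covariates": cov,
        "metabolome": met,
        "metabolome_followup": follow,
        "truth": truth,
    }
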