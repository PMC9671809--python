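"""Seeded end-to-end orchestration of the analysis stages.

``run_pipeline`` sequences preprocessing, association scans, variance
attribution, interaction analysis, Mendelian randomization, mediation,
temporal stability and diet-score prediction over a bundle of layers,
writing each stage's record table as TSV with seed and stage provenance
in header comments.  Identical config and inputs give identical outputs:
every stochastic stage draws from its own stream keyed by stage name and
the global seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import association as assoc
from . import mediation as med
from . import mr as mrmod
from . import preprocess as prep
from . import temporal as temp
from . import variance as var
from .io import OmicsLayer, RunConfig, stage_rng, write_table

log = logging.getLogger("metabvar")

ALL_STAGES = (
    "preprocess",
    "association",
    "variance",
    "interaction",
    "mr",
    "mediation",
    "temporal",
    "dietscore",
)

STAGE_REQUIRES = {
    "preprocess": ["metabolome", "covariates"],
    "association": ["metabolome", "covariates"],
    "variance": ["metabolome", "covariates"],
    "interaction": ["metabolome", "covariates"],
    "mr": ["metabolome", "covariates", "genotype", "microbiome"],
    "mediation": ["metabolome", "covariates", "diet", "microbiome"],
    "temporal": ["metabolome", "metabolome_followup"],
    "dietscore": ["metabolome", "diet_score"],
}

__all__ = ["run_pipeline", "ALL_STAGES"]


def _require(layers: dict, stage: str) -> None:
    missing = [l for l in STAGE_REQUIRES[stage] if l not in layers or layers[l] is None]
    if missing:
        raise ValueError(f"stage {stage!r} requires missing layer(s): {missing}")


def run_pipeline(
    config: RunConfig,
    layers: dict,
    outdir: str | Path | None = None,
    stages: list[str] | None = None,
) -> dict:
    """Run the requested stages over a layer bundle.

    ``layers`` maps names (metabolome, genotype, microbiome, diet,
    covariates, metabolome_followup, diet_score) to layers/series.
    Returns a dict of result tables; also writes them under ``outdir``
    when given, each file carrying ``# seed=`` and ``# stage=`` comments.
    """
    stages = list(stages) if stages is not None else list(ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    for s in stages:
        _require(layers, s)
    thr = config.thresholds
    seed = config.seed
    results: dict = {}

    # --- preprocessing shared by most stages -----------------------------
    cov: OmicsLayer = layers["covariates"]
    met_resid = prep.residualize(layers["metabolome"], cov, config.covariate_names)
    diet_t = None
    if layers.get("diet") is not None:
        diet_int = prep.inverse_rank_transform(layers["diet"])
        diet_t = prep.residualize(diet_int, cov.data, config.covariate_names).data
    micro_t = None
    if layers.get("microbiome") is not None:
        micro_clr = prep.transform_microbiome(layers["microbiome"], thr["prevalence_min"])
        micro_cov = [c for c in config.covariate_names + ["ppi", "antibiotics"]
                     if c in cov.data.columns]
        micro_t = prep.residualize(micro_clr, cov.data, micro_cov).data
    results["metabolite_residuals"] = met_resid.data

    def emit(name: str, df: pd.DataFrame, stage: str) -> None:
        results[name] = df
        if outdir is not None:
            write_table(df, Path(outdir) / f"{name}.tsv",
                        header={"seed": seed, "stage": stage,
                                "regularization_mode": config.regularization_mode})

    if "preprocess" in stages:
        emit("metabolite_residuals_table", met_resid.data.reset_index(names="sample_id"),
             "preprocess")
        if diet_t is not None:
            emit("diet_transformed", diet_t.reset_index(names="sample_id"), "preprocess")
        if micro_t is not None:
            emit("microbiome_transformed", micro_t.reset_index(names="sample_id"),
                 "preprocess")

    diet_scan = micro_scan = mqtl = None
    if "association" in stages or "variance" in stages or "interaction" in stages \
            or "mediation" in stages or "mr" in stages:
        if diet_t is not None:
            diet_scan = assoc.spearman_scan(diet_t, met_resid.data)
            emit("associations_diet", diet_scan, "association")
        if micro_t is not None:
            micro_scan = assoc.spearman_scan(micro_t, met_resid.data)
            emit("associations_microbiome", micro_scan, "association")
        if layers.get("genotype") is not None:
            n_tests = int(thr["n_metabolite_tests"]) or layers["metabolome"].n_features
            cut = assoc.study_wide_threshold(thr["mqtl_alpha"], n_tests)
            mqtl = assoc.map_mqtls(layers["genotype"], met_resid, cut,
                                   clump_r2=thr["clump_r2"],
                                   window_bp=int(thr["clump_window_bp"]))
            emit("mqtl_records", mqtl, "association")

    if "variance" in stages:
        results.update(_variance_stage(config, layers, met_resid, diet_t, micro_t,
                                       diet_scan, micro_scan, mqtl, emit))
    if "interaction" in stages:
        _interaction_stage(config, met_resid, diet_t, micro_t, layers, diet_scan,
                           micro_scan, mqtl, emit)
    if "mr" in stages:
        _mr_stage(config, layers, met_resid, micro_t, micro_scan, emit)
    if "mediation" in stages:
        _mediation_stage(config, met_resid, diet_t, micro_t, diet_scan, micro_scan, emit)
    if "temporal" in stages:
        _temporal_stage(config, layers, results, emit)
    if "dietscore" in stages:
        _dietscore_stage(config, layers, emit)
    return results


def _candidates_for(mid: str, diet_scan, micro_scan, mqtl, diet_t, micro_t, geno,
                    fdr_level: float) -> dict[str, pd.DataFrame]:
    cand: dict[str, pd.DataFrame] = {}
    if diet_scan is not None:
        hits = diet_scan[(diet_scan["metabolite_id"] == mid) & (diet_scan["q"] < fdr_level)]
        if len(hits):
            cand["diet"] = diet_t[hits["feature_id"].tolist()]
    if micro_scan is not None:
        hits = micro_scan[(micro_scan["metabolite_id"] == mid) & (micro_scan["q"] < fdr_level)]
        if len(hits):
            cand["microbiome"] = micro_t[hits["feature_id"].tolist()]
    if mqtl is not None:
        # per-metabolite candidate SNPs follow the FDR rule used for the
        # other layers; study-wide hits are a subset of these
        hits = mqtl[(mqtl["metabolite_id"] == mid) & (mqtl["q"] < fdr_level)]
        if len(hits):
            from .association import ld_clump

            leads = ld_clump(hits, geno)
            cand["genotype"] = geno.data[leads]
    return cand


def _variance_stage(config, layers, met_resid, diet_t, micro_t, diet_scan, micro_scan,
                    mqtl, emit) -> dict:
    thr = config.thresholds
    seed = config.seed
    # whole-metabolome PERMANOVA on the Euclidean distance of residuals
    D = squareform(pdist(met_resid.values, metric="euclidean"))
    rng = stage_rng(seed, "variance/permanova")
    n_perm = int(thr["permanova_permutations"])
    candidates: list[tuple[str, str, pd.Series]] = []
    cov = layers["covariates"].data
    for c in cov.columns:
        candidates.append(("covariates", c, cov[c]))
    if diet_t is not None:
        for c in diet_t.columns:
            candidates.append(("diet", c, diet_t[c]))
    if micro_t is not None:
        for c in micro_t.columns:
            candidates.append(("microbiome", c, micro_t[c]))
    if mqtl is not None:
        lead_snps = mqtl.loc[mqtl["clump_lead"], "snp_id"].unique().tolist()
        for s in lead_snps:
            candidates.append(("genotype", s, layers["genotype"].data[s]))

    idx = met_resid.data.index
    marg_rows = []
    for layer, fid, series in candidates:
        res = var.permanova_r2(D, series.loc[idx], n_perm=n_perm, seed=rng)
        marg_rows.append({"layer": layer, "factor_id": fid, "r2": res.r2,
                          "pseudo_f": res.pseudo_f, "p_perm": res.p_perm,
                          "n_perm": res.n_perm})
    marg = pd.DataFrame(marg_rows)
    marg["q_perm"] = assoc.benjamini_hochberg(marg["p_perm"].to_numpy())
    emit("permanova_marginal", marg, "variance")

    kept = marg[marg["q_perm"] < thr["fdr_level"]]
    combined_row: dict = {"total_r2": 0.0}
    if len(kept):
        feats = {}
        layer_of = {}
        for _, r in kept.iterrows():
            _, fid, series = next(c for c in candidates if c[1] == r["factor_id"])
            feats[fid] = series.loc[idx]
            layer_of[fid] = r["layer"]
        fdf = pd.DataFrame(feats)
        reps, _ = var.select_representative_features(fdf, thr["dissimilarity_cut"])
        combined = var.combined_permanova(D, fdf[reps], layer_of, n_perm=n_perm, seed=rng)
        combined_row = {"total_r2": combined["total_r2"], **{
            f"share_{k}": v for k, v in combined["layer_shares"].items()}}
        emit("permanova_combined", pd.DataFrame([combined_row]), "variance")

    # per-metabolite partitioning
    fdr = thr["fdr_level"]
    cand_map = {
        mid: _candidates_for(mid, diet_scan, micro_scan, mqtl, diet_t, micro_t,
                             layers.get("genotype"), fdr)
        for mid in met_resid.data.columns
    }
    recs = var.partition_all_metabolites(
        met_resid.data, cand_map,
        cv_folds=int(thr["cv_folds"]),
        regularization_mode=config.regularization_mode,
        fdr_level=fdr,
        seed=seed,
    )
    emit("variance_records", recs, "variance")
    return {"variance_candidates": cand_map}


def _interaction_stage(config, met_resid, diet_t, micro_t, layers, diet_scan,
                       micro_scan, mqtl, emit) -> None:
    fdr = config.thresholds["fdr_level"]
    factors: dict[str, pd.Series] = {}
    pairs: list[tuple[str, str, str]] = []
    for mid in met_resid.data.columns:
        per_type: dict[str, list[str]] = {}
        if diet_scan is not None:
            hits = diet_scan[(diet_scan["metabolite_id"] == mid) & (diet_scan["q"] < fdr)]
            if len(hits):
                top = hits.sort_values("p").iloc[0]["feature_id"]
                per_type["diet"] = [top]
                factors[top] = diet_t[top]
        if micro_scan is not None:
            hits = micro_scan[(micro_scan["metabolite_id"] == mid) & (micro_scan["q"] < fdr)]
            if len(hits):
                top = hits.sort_values("p").iloc[0]["feature_id"]
                per_type["microbiome"] = [top]
                factors[top] = micro_t[top]
        if mqtl is not None:
            hits = mqtl[(mqtl["metabolite_id"] == mid) & mqtl["clump_lead"]]
            if len(hits):
                top = hits.sort_values("p").iloc[0]["snp_id"]
                per_type["genotype"] = [top]
                factors[top] = layers["genotype"].data[top]
        types = sorted(per_type)
        if len(types) < 2:
            continue  # interaction only for metabolites with >= 2 factor types
        for i, ta in enumerate(types):
            for tb in types[i + 1:]:
                pairs.append((mid, per_type[ta][0], per_type[tb][0]))
    out = assoc.interaction_scan(met_resid.data, pairs, factors)
    emit("interaction_records", out, "interaction")


def _mr_stage(config, layers, met_resid, micro_t, micro_scan, emit) -> None:
    thr = config.thresholds
    fdr = thr["fdr_level"]
    if micro_scan is None or micro_t is None:
        raise ValueError("MR stage requires the microbiome association scan")
    sig = micro_scan[micro_scan["q"] < fdr].sort_values("p")
    pairs = list(dict.fromkeys(zip(sig["feature_id"], sig["metabolite_id"])))[:20]
    if not pairs:
        emit("mr_records", pd.DataFrame(), "mr")
        return
    recs = mrmod.run_bidirectional_mr(
        pairs,
        exposures=micro_t,
        outcomes=met_resid.data,
        dosages=layers["genotype"],
        instrument_p=thr["instrument_p"],
        min_instruments=int(thr["min_instruments"]),
        clump_r2=thr["clump_r2"],
        clump_window_bp=int(thr["clump_window_bp"]),
        fdr_level=fdr,
        seed=config.seed,
    )
    emit("mr_records", recs, "mr")


def _mediation_stage(config, met_resid, diet_t, micro_t, diet_scan, micro_scan, emit) -> None:
    thr = config.thresholds
    fdr = thr["fdr_level"]
    if diet_scan is None or micro_scan is None:
        raise ValueError("mediation stage requires diet and microbiome scans")
    # eligible triples: diet-metabolite, taxon-metabolite and diet-taxon all FDR-significant
    diet_sig = diet_scan[diet_scan["q"] < fdr]
    micro_sig = micro_scan[micro_scan["q"] < fdr]
    dm = assoc.spearman_scan(diet_t, micro_t)
    dm_sig = dm[dm["q"] < fdr]
    dm_pairs = set(zip(dm_sig["feature_id"], dm_sig["metabolite_id"]))
    triples = []
    merged = diet_sig.merge(micro_sig, on="metabolite_id", suffixes=("_diet", "_micro"))
    for _, r in merged.iterrows():
        if (r["feature_id_diet"], r["feature_id_micro"]) in dm_pairs:
            triples.append((diet_t[r["feature_id_diet"]],
                            met_resid.data[r["metabolite_id"]],
                            micro_t[r["feature_id_micro"]]))
        if len(triples) >= 20:
            break
    recs = med.mediation_scan(triples, n_sims=int(thr["mediation_sims"]),
                              fdr_level=fdr, seed=config.seed)
    if not recs.empty:
        recs = recs.assign(acme_ci=[f"{lo:.6g},{hi:.6g}" for lo, hi in recs["acme_ci"]])
    emit("mediation_records", recs, "mediation")


def _temporal_stage(config, layers, results, emit) -> None:
    stab = temp.metabolite_stability(layers["metabolome"], layers["metabolome_followup"])
    emit("stability", stab, "temporal")
    if "variance_records" in results:
        sv = temp.stability_vs_variance(stab, results["variance_records"])
        emit("stability_vs_variance", sv, "temporal")
        grp = temp.compare_stability_groups(
            stab, results["variance_records"][["metabolite_id", "dominant"]])
        emit("stability_group_tests", grp, "temporal")
    shift = temp.metabolome_pca_shift(layers["metabolome"], layers["metabolome_followup"])
    emit("pca_shift", shift["shift_tests"], "temporal")


def _dietscore_stage(config, layers, emit) -> None:
    score = layers["diet_score"]
    met = layers["metabolome"].data
    n = len(met)
    n_train = int(round(n * 0.8))
    train_idx, valid_idx = met.index[:n_train], met.index[n_train:]
    model = temp.train_diet_score_model(met.loc[train_idx], score.loc[train_idx],
                                        cv_folds=int(config.thresholds["cv_folds"]),
                                        seed=config.seed)
    perf = temp.evaluate_diet_score(model, met.loc[valid_idx], score.loc[valid_idx])
    emit("dietscore_model", pd.DataFrame({
        "metabolite_id": model.selected,
        "coefficient": model.coefficients.to_numpy() if len(model.selected) else [],
    }), "dietscore")
    emit("dietscore_eval", pd.DataFrame([{
        "train_r2_adj": model.train_r2_adj, "train_f_p": model.train_f_p,
        "valid_r2_adj": perf["r2_adj"], "valid_f_p": perf["f_p"],
        "n_selected": len(model.selected), "n_valid": perf["n"],
    }]), "dietscore")
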