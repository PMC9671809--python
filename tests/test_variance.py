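import numpy as np
import pandas as pd
import pytest

from metabvar.variance import (
    assign_dominant_factor,
    combined_permanova,
    partition_metabolite_variance,
    permanova_r2,
    select_representative_features,
)


def _euclid(y):
    y = np.asarray(y, float)
    if y.ndim == 1:
        y = y[:, None]
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(y))


class TestPermanova:
    def test_univariate_equals_anova_r2(self):
        y = np.array([1, 2, 3, 10, 11, 12], float)
        res = permanova_r2(_euclid(y), np.array(list("AAABBB")), n_perm=99, seed=0)
        assert res.r2 == pytest.approx(121.5 / 125.5, abs=1e-10)

    def test_matches_reference_permanova_statistic(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 4))
        groups = np.repeat(list("abc"), 10)
        D = _euclid(X)
        ours = permanova_r2(D, groups, n_perm=99, seed=1)
        dm = skbio_dist.DistanceMatrix(D, ids=[str(i) for i in range(30)])
        theirs = skbio_dist.permanova(dm, grouping=list(groups), permutations=99)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-10)

    def test_minimum_p_is_one_over_nperm_plus_one(self, rng):
        y = np.arange(30.0)
        groups = np.array(["A"] * 15 + ["B"] * 15)
        res = permanova_r2(_euclid(y), groups, n_perm=199, seed=2)
        assert res.p_perm >= 1 / 200
        assert res.p_perm == pytest.approx(1 / 200)

    def test_null_p_roughly_uniform(self):
        ps = []
        for s in range(200):
            rng = np.random.default_rng(3000 + s)
            y = rng.normal(size=(40, 3))
            fac = rng.normal(size=40)
            ps.append(permanova_r2(_euclid(y), fac, n_perm=99, seed=s).p_perm)
        from scipy.stats import kstest

        # discrete grid blurs the KS test slightly; 0.01 level per contract
        stat, p = kstest(ps, "uniform")
        assert p > 0.01

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            permanova_r2(D, np.array([0.0, 1.0]), n_perm=9)


class TestRepresentativeSelection:
    def test_perfectly_correlated_pair_collapses(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        reps, labels = select_representative_features(df)
        assert len(reps) == 1
        assert labels["a"] == labels["b"]

    def test_uncorrelated_features_all_kept(self, rng):
        df = pd.DataFrame(rng.normal(size=(500, 5)), columns=list("abcde"))
        reps, _ = select_representative_features(df)
        assert sorted(reps) == list("abcde")

    def test_three_feature_medoid_deterministic(self, rng):
        x = rng.normal(size=300)
        df = pd.DataFrame({
            "a": x,
            "b": 0.97 * x + np.sqrt(1 - 0.97**2) * rng.normal(size=300),
            "c": rng.normal(size=300),
        })
        reps, labels = select_representative_features(df)
        assert len(reps) == 2
        assert "c" in reps
        assert labels["a"] == labels["b"] != labels["c"]
        # medoid of a 2-cluster is the id-ordered first on exact tie
        pair_rep = [r for r in reps if r != "c"][0]
        assert pair_rep == "a"


class TestCombinedPermanova:
    def test_single_representative_equals_marginal(self, rng):
        y = rng.normal(size=(60, 3))
        f = pd.DataFrame({"x": rng.normal(size=60)})
        D = _euclid(y)
        marg = permanova_r2(D, f["x"], n_perm=9, seed=0).r2
        comb = combined_permanova(D, f)
        assert comb["total_r2"] == pytest.approx(marg, abs=1e-10)

    def test_orthogonal_designs_additive(self):
        n = 64
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        rng = np.random.default_rng(4)
        y = 0.5 * a + 0.3 * b + rng.normal(size=n)
        D = _euclid(y)
        reps = pd.DataFrame({"a": a, "b": b})
        comb = combined_permanova(D, reps)
        marg_a = permanova_r2(D, a, n_perm=9).r2
        marg_b = permanova_r2(D, b, n_perm=9).r2
        assert comb["total_r2"] == pytest.approx(marg_a + marg_b, abs=1e-6)

    def test_generative_share_recovery(self):
        rng = np.random.default_rng(9)
        n, m = 500, 40
        diet = rng.normal(size=n)
        micro = rng.normal(size=n)
        geno = rng.normal(size=n)
        mets = np.empty((n, m))
        for j in range(m):
            mets[:, j] = (np.sqrt(0.10) * diet + np.sqrt(0.13) * micro
                          + np.sqrt(0.03) * geno + np.sqrt(0.74) * rng.normal(size=n))
        D = _euclid(mets)
        reps = pd.DataFrame({"diet": diet, "micro": micro, "geno": geno})
        comb = combined_permanova(D, reps, layer_of={"diet": "diet", "micro": "micro",
                                                     "geno": "geno"})
        assert comb["layer_shares"]["diet"] == pytest.approx(0.10, abs=0.04)
        assert comb["layer_shares"]["micro"] == pytest.approx(0.13, abs=0.04)
        assert comb["layer_shares"]["geno"] == pytest.approx(0.03, abs=0.04)


class TestPartition:
    def test_adjusted_r2_formula(self):
        # r2=0.5, n=101, p=10 -> 1 - 0.5*100/90 = 0.4444
        from metabvar.variance import _ols_fit

        rng = np.random.default_rng(12)
        # construct data with exact in-sample r2 = 0.5 via residual scaling
        n, p = 101, 10
        X = rng.normal(size=(n, p))
        beta = rng.normal(size=p)
        signal = X @ beta
        Q, _ = np.linalg.qr(np.column_stack([np.ones(n), X]))
        noise = rng.normal(size=n)
        noise -= Q @ (Q.T @ noise)  # orthogonal to the model space
        signal_c = signal - signal.mean()
        y = signal + noise * np.linalg.norm(signal_c) / np.linalg.norm(noise)
        r2, adj, _ = _ols_fit(y, X)
        assert r2 == pytest.approx(0.5, abs=1e-10)
        assert adj == pytest.approx(0.4444, abs=1e-4)

    def test_planted_diet_fraction_recovered(self):
        rng = np.random.default_rng(13)
        n = 2000
        X = pd.DataFrame(rng.normal(size=(n, 40)),
                         index=[f"s{i}" for i in range(n)],
                         columns=[f"d{j}" for j in range(40)])
        w = rng.normal(size=10)
        comp = X.iloc[:, :10].to_numpy() @ w
        comp = (comp - comp.mean()) / comp.std()
        y = pd.Series(np.sqrt(0.30) * comp + np.sqrt(0.70) * rng.standard_normal(n),
                      index=X.index, name="met")
        rec = partition_metabolite_variance(y, {"diet": X}, seed=1)
        assert rec["r2_adj_diet"] == pytest.approx(0.30, abs=0.05)
        assert rec["p_diet"] < 1e-10

    def test_pure_noise_metabolites_rarely_flagged(self):
        # faithful to the pipeline: candidates are FDR-significant hits of
        # a joint association scan, and significance is BH across
        # metabolites — under a global null almost nothing survives
        from metabvar.association import spearman_scan
        from metabvar.variance import partition_all_metabolites

        rng = np.random.default_rng(500)
        n, n_met = 300, 50
        idx = [f"s{i}" for i in range(n)]
        X = pd.DataFrame(rng.normal(size=(n, 20)), index=idx,
                         columns=[f"d{j}" for j in range(20)])
        Y = pd.DataFrame(rng.normal(size=(n, n_met)), index=idx,
                         columns=[f"m{j}" for j in range(n_met)])
        scan = spearman_scan(X, Y)
        cand_map = {}
        for mid in Y.columns:
            ids = scan.loc[(scan["metabolite_id"] == mid) & (scan["q"] < 0.05),
                           "feature_id"].tolist()
            cand_map[mid] = {"diet": X[ids]} if ids else {}
        recs = partition_all_metabolites(Y, cand_map, seed=1)
        flagged = ((recs["r2_adj_diet"] > 0.02) & (recs["q_diet"] < 0.05)).sum()
        assert flagged <= max(1, int(0.05 * n_met))

    def test_no_candidates_zero_variance(self, rng):
        y = pd.Series(rng.normal(size=100), name="met",
                      index=[f"s{i}" for i in range(100)])
        rec = partition_metabolite_variance(y, {}, seed=0)
        for layer in ("diet", "genotype", "microbiome"):
            assert rec[f"r2_adj_{layer}"] == 0.0
            assert rec[f"p_{layer}"] == 1.0

    def test_elastic_net_mode_close_to_lasso(self):
        rng = np.random.default_rng(77)
        n = 800
        X = pd.DataFrame(rng.normal(size=(n, 30)),
                         index=[f"s{i}" for i in range(n)],
                         columns=[f"d{j}" for j in range(30)])
        comp = X.iloc[:, :5].sum(axis=1).to_numpy()
        comp = (comp - comp.mean()) / comp.std()
        y = pd.Series(np.sqrt(0.25) * comp + np.sqrt(0.75) * rng.standard_normal(n),
                      index=X.index, name="met")
        lasso = partition_metabolite_variance(y, {"diet": X}, seed=2)
        enet = partition_metabolite_variance(y, {"diet": X}, seed=2,
                                             regularization_mode="elastic_net")
        assert abs(lasso["r2_adj_diet"] - enet["r2_adj_diet"]) < 0.05


class TestDominance:
    def test_clear_winner(self):
        rec = {"r2_adj_diet": 0.20, "q_diet": 0.01,
               "r2_adj_microbiome": 0.10, "q_microbiome": 0.01,
               "r2_adj_genotype": 0.05, "q_genotype": 0.2}
        assert assign_dominant_factor(rec) == "diet"

    def test_no_significant_layer(self):
        rec = {"r2_adj_diet": 0.20, "q_diet": 0.5,
               "r2_adj_microbiome": 0.10, "q_microbiome": 0.9,
               "r2_adj_genotype": 0.05, "q_genotype": 0.2}
        assert assign_dominant_factor(rec) == "none"

    def test_exact_tie_is_none(self):
        rec = {"r2_adj_diet": 0.20, "q_diet": 0.01,
               "r2_adj_microbiome": 0.20, "q_microbiome": 0.01,
               "r2_adj_genotype": 0.0, "q_genotype": 1.0}
        assert assign_dominant_factor(rec) == "none"

    def test_genotype_layer_labeled_genetics(self):
        rec = {"r2_adj_diet": 0.02, "q_diet": 0.5,
               "r2_adj_microbiome": 0.01, "q_microbiome": 0.5,
               "r2_adj_genotype": 0.15, "q_genotype": 0.001}
        assert assign_dominant_factor(rec) == "genetics"

    def test_negative_adjusted_r2_floored(self):
        rec = {"r2_adj_diet": -0.01, "q_diet": 0.01,
               "r2_adj_microbiome": -0.02, "q_microbiome": 0.01,
               "r2_adj_genotype": 0.0, "q_genotype": 1.0}
        assert assign_dominant_factor(rec) == "none"
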