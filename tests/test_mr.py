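import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabvar.mr import (
    apply_verdict_cascade,
    cochran_q,
    egger_regression,
    ivw_estimate,
    leave_one_out,
    mr_single_pair,
    run_bidirectional_mr,
    select_instruments,
    summary_associations,
    wald_ratio,
    weighted_median_estimate,
)
from metabvar.simulate import simulate_mr_scenario


class TestWaldRatio:
    def test_direct_evaluation(self):
        ratio, se = wald_ratio(0.5, 0.05, 0.2, 0.04)
        assert ratio == pytest.approx(0.4)
        assert se == pytest.approx(0.08)

    def test_zero_outcome_beta(self):
        assert wald_ratio(0.5, 0.1, 0.0, 0.1)[0] == 0.0

    def test_joint_sign_flip_invariance(self):
        r1, s1 = wald_ratio(0.5, 0.05, 0.2, 0.04)
        r2, s2 = wald_ratio(-0.5, 0.05, -0.2, 0.04)
        assert (r1, s1) == (r2, s2)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.1, 0.2, 0.1)


class TestIVW:
    def test_single_instrument_equals_wald_ratio(self):
        ratio, se = wald_ratio(0.4, 0.05, 0.24, 0.05)
        beta, se_ivw, _ = ivw_estimate(np.array([ratio]), np.array([se]))
        assert beta == pytest.approx(ratio, abs=1e-15)
        assert se_ivw == pytest.approx(se, abs=1e-15)

    def test_closed_form_two_instruments(self):
        beta, se, _ = ivw_estimate(np.array([0.4, 0.6]), np.array([0.1, 0.1]))
        assert beta == pytest.approx(0.5)
        assert se == pytest.approx(0.07071, abs=1e-4)

    def test_se_is_inverse_sqrt_weight_sum(self, rng):
        ses = rng.uniform(0.05, 0.3, size=6)
        _, se, _ = ivw_estimate(rng.normal(size=6), ses)
        assert se == pytest.approx((ses**-2).sum() ** -0.5)

    def test_null_size_calibrated(self):
        rejections = 0
        reps = 300
        rng = np.random.default_rng(99)
        for _ in range(reps):
            ses = np.full(5, 0.1)
            ratios = rng.normal(0.0, ses)
            _, _, p = ivw_estimate(ratios, ses)
            rejections += p < 0.05
        assert 0.02 < rejections / reps < 0.09


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        beta, _, _ = weighted_median_estimate(np.array([0.3, 0.5, 0.7]),
                                              np.array([0.1, 0.1, 0.1]), seed=1)
        assert beta == pytest.approx(0.5, abs=1e-10)

    def test_robust_to_one_pleiotropic_outlier(self):
        ratios = np.array([0.50, 0.49, 0.51, 0.50, 3.0])
        ses = np.full(5, 0.05)
        beta, _, _ = weighted_median_estimate(ratios, ses, seed=2)
        assert beta == pytest.approx(0.50, abs=0.05)

    def test_bootstrap_se_deterministic_given_seed(self):
        ratios, ses = np.array([0.2, 0.4, 0.6]), np.array([0.1, 0.2, 0.15])
        a = weighted_median_estimate(ratios, ses, seed=7)
        b = weighted_median_estimate(ratios, ses, seed=7)
        assert a == b


class TestEgger:
    def test_exact_proportionality_zero_intercept(self):
        bx = np.array([0.2, 0.4, 0.6, 0.8])
        by = 0.5 * bx
        slope, intercept, _ = egger_regression(bx, by, np.full(4, 0.1))
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert slope == pytest.approx(0.5, abs=1e-12)

    def test_constant_directional_pleiotropy_recovered(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.2, 0.8, size=20)
        by = 0.5 * bx + 0.3 + rng.normal(0, 0.01, size=20)
        slope, intercept, p = egger_regression(bx, by, np.full(20, 0.05))
        assert intercept == pytest.approx(0.3, abs=0.02)
        assert p < 1e-6

    def test_balanced_pleiotropy_null_size(self):
        rejections, reps = 0, 300
        rng = np.random.default_rng(4)
        for _ in range(reps):
            bx = rng.uniform(0.2, 0.8, size=8)
            by = 0.5 * bx + rng.normal(0, 0.1, size=8)
            _, _, p = egger_regression(bx, by, np.full(8, 0.1))
            rejections += p < 0.05
        assert 0.02 < rejections / reps < 0.09

    def test_orientation_invariance(self):
        bx = np.array([0.2, -0.4, 0.6])
        by = np.array([0.1, -0.2, 0.3])
        a = egger_regression(bx, by, np.full(3, 0.1))
        b = egger_regression(np.abs(bx), np.sign(bx) * by, np.full(3, 0.1))
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestCochranQ:
    def test_identical_ratios_zero_q(self):
        q, df, p = cochran_q(np.array([0.4, 0.4, 0.4]), np.array([0.1, 0.1, 0.1]))
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_closed_form_two_ratios(self):
        q, df, p = cochran_q(np.array([0.4, 0.6]), np.array([0.1, 0.1]))
        assert q == pytest.approx(2.0)
        assert df == 1
        assert p == pytest.approx(0.1573, abs=1e-4)

    def test_homogeneous_mean_near_df(self):
        rng = np.random.default_rng(5)
        qs = []
        for _ in range(300):
            ses = np.full(6, 0.1)
            ratios = rng.normal(0.5, ses)
            qs.append(cochran_q(ratios, ses)[0])
        assert np.mean(qs) == pytest.approx(5.0, abs=0.5)


class TestLeaveOneOut:
    def test_concordant_instruments_pass(self):
        ratios = np.array([0.5, 0.52, 0.48, 0.51, 0.49])
        ses = np.full(5, 0.05)
        loo, ok = leave_one_out(ratios, ses)
        assert ok
        assert (loo["p"] < 0.05).all()

    def test_single_driver_detected(self):
        # signal lives in one precise SNP; the rest are noise-only
        ratios = np.array([1.0, 0.0, 0.0, 0.0])
        ses = np.array([0.05, 1.0, 1.0, 1.0])
        loo, ok = leave_one_out(ratios, ses)
        assert not ok

    def test_minimum_three_instruments(self):
        loo, ok = leave_one_out(np.array([0.4, 0.5, 0.6]), np.full(3, 0.05))
        assert len(loo) == 3


class TestVerdictCascade:
    CASES = [
        (0.2, 0.5, 0.5, True, 0.5, "not_significant"),
        (0.01, 0.01, 0.5, True, 0.5, "filtered_pleiotropy"),
        (0.01, 0.5, 0.01, True, 0.5, "filtered_heterogeneity"),
        (0.01, 0.5, 0.5, False, 0.5, "filtered_loo"),
        (0.01, 0.5, 0.5, True, 0.01, "filtered_reverse"),
        (0.01, 0.5, 0.5, True, 0.5, "causal_candidate"),
        (0.01, 0.5, 0.5, True, None, "causal_candidate"),
    ]

    @pytest.mark.parametrize("q,egger_p,qc_p,loo,rev,expect", CASES)
    def test_rule_table(self, q, egger_p, qc_p, loo, rev, expect):
        assert apply_verdict_cascade(q, egger_p, qc_p, loo, rev) == expect

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        q=st.floats(0, 1), eg=st.floats(0, 1), qc=st.floats(0, 1),
        loo=st.booleans(), rev=st.one_of(st.none(), st.floats(0, 1)),
    )
    def test_matches_brute_force_rule_evaluator(self, q, eg, qc, loo, rev):
        def brute(q, eg, qc, loo, rev):
            if not q < 0.05:
                return "not_significant"
            if eg < 0.05:
                return "filtered_pleiotropy"
            if qc < 0.05:
                return "filtered_heterogeneity"
            if not loo:
                return "filtered_loo"
            if rev is not None and rev < 0.05:
                return "filtered_reverse"
            return "causal_candidate"

        assert apply_verdict_cascade(q, eg, qc, loo, rev) == brute(q, eg, qc, loo, rev)


class TestSummaryAssociations:
    def test_exact_linear_feature(self):
        from metabvar.simulate import simulate_genotypes

        g = simulate_genotypes(200, 3, ld_block_size=1, seed=1)
        feat = pd.Series(0.5 * g.data["snp0000"], index=g.data.index)
        stats_df = summary_associations(feat, g)
        row = stats_df.set_index("snp_id").loc["snp0000"]
        assert row["beta"] == pytest.approx(0.5, abs=1e-12)
        assert row["se"] < 1e-8

    def test_instrument_strength_detectable(self):
        ps = []
        for s in range(10):
            sc = simulate_mr_scenario(n_samples=1000, n_instruments=5,
                                      per_snp_exposure_r2=0.02, n_null_snps=0, seed=s)
            gw = summary_associations(sc["exposure"], sc["genotype"])
            ps.extend(gw["p"].tolist())
        assert np.median(ps) < 1e-3  # median instrument comfortably detectable


class TestSelectInstruments:
    def _scenario(self, seed=0, **kw):
        return simulate_mr_scenario(n_samples=1500, n_instruments=5,
                                    per_snp_exposure_r2=0.03, seed=seed, **kw)

    def test_planted_instruments_recovered(self):
        sc = self._scenario()
        gw = summary_associations(sc["exposure"], sc["genotype"])
        inst = select_instruments(gw, sc["genotype"], p_cut=1e-5)
        assert not isinstance(inst, str)
        assert set(sc["truth"]["instrument_ids"]) >= set(inst.snp_ids)
        assert len(inst.snp_ids) >= 3

    def test_too_few_instruments_rejected_with_reason(self):
        sc = simulate_mr_scenario(n_samples=300, n_instruments=1,
                                  per_snp_exposure_r2=0.2, n_null_snps=5, seed=3)
        gw = summary_associations(sc["exposure"], sc["genotype"])
        out = select_instruments(gw, sc["genotype"], p_cut=1e-5)
        assert isinstance(out, str)
        assert "fewer than 3" in out

    def test_followup_sign_flip_drops_snp(self):
        sc = self._scenario(seed=4)
        gw = summary_associations(sc["exposure"], sc["genotype"])
        fu = gw.copy()
        flip_id = sc["truth"]["instrument_ids"][0]
        fu.loc[fu["snp_id"] == flip_id, "beta"] *= -1
        fu["p"] = 1e-6
        inst = select_instruments(gw, sc["genotype"], followup_gwas=fu, p_cut=1e-5)
        if not isinstance(inst, str):
            assert flip_id not in inst.snp_ids


class TestBidirectionalMR:
    def test_planted_effect_yields_causal_candidate(self):
        # each sensitivity filter has ~5% false-positive rate, so ask for a
        # clear majority of clean verdicts plus an accurate pooled estimate
        verdicts, betas = [], []
        for s in range(5):
            sc = simulate_mr_scenario(n_samples=1500, n_instruments=6,
                                      per_snp_exposure_r2=0.03, causal_effect=0.3,
                                      n_null_snps=10, seed=100 + s)
            recs = run_bidirectional_mr([("exposure", "outcome")],
                                        sc["exposure"].to_frame(),
                                        sc["outcome"].to_frame(),
                                        sc["genotype"], n_boot=100, seed=1)
            verdicts.append(recs.iloc[0]["verdict"])
            betas.append(recs.iloc[0]["beta_ivw"])
        assert verdicts.count("causal_candidate") >= 3
        assert np.mean(betas) == pytest.approx(0.3, abs=0.1)

    def test_reverse_causation_filtered(self):
        # SNPs act on the outcome; outcome drives the exposure, so the
        # exposure GWAS inherits the outcome's instruments and the forward
        # estimate looks significant until the reverse check fires
        sc = simulate_mr_scenario(n_samples=3000, n_instruments=0,
                                  per_snp_exposure_r2=0.03, causal_effect=0.0,
                                  reverse_effect=1.2, n_reverse_instruments=6,
                                  per_snp_outcome_r2=0.08, n_null_snps=10, seed=11)
        recs = run_bidirectional_mr([("exposure", "outcome")],
                                    sc["exposure"].to_frame(), sc["outcome"].to_frame(),
                                    sc["genotype"], n_boot=200, seed=2)
        assert recs.iloc[0]["verdict"] == "filtered_reverse"

    def test_directional_pleiotropy_filtered(self):
        flagged = 0
        for s in range(3):
            sc = simulate_mr_scenario(n_samples=1500, n_instruments=8,
                                      per_snp_exposure_r2=0.03, causal_effect=0.3,
                                      pleiotropy=0.15, n_null_snps=0, seed=20 + s)
            recs = run_bidirectional_mr([("exposure", "outcome")],
                                        sc["exposure"].to_frame(),
                                        sc["outcome"].to_frame(),
                                        sc["genotype"], n_boot=100, seed=3)
            if recs.iloc[0]["verdict"] in ("filtered_pleiotropy", "filtered_heterogeneity"):
                flagged += 1
        assert flagged >= 1


def test_mr_single_pair_consistency_scenario():
    est = []
    for s in range(30):
        sc = simulate_mr_scenario(n_samples=1000, n_instruments=5,
                                  per_snp_exposure_r2=0.02, causal_effect=0.3,
                                  n_null_snps=0, seed=300 + s)
        gw_x = summary_associations(sc["exposure"], sc["genotype"])
        inst = select_instruments(gw_x, sc["genotype"], p_cut=1.0, min_snps=3)
        gw_y = summary_associations(sc["outcome"], sc["genotype"])
        res = mr_single_pair(inst, gw_y, n_boot=50, seed=s)
        est.append(res["beta_ivw"])
    assert abs(np.mean(est) - 0.3) < 0.05
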