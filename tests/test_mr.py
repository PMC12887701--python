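import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nexuslipid import mr
from nexuslipid.synthio import GwasSimConfig, simulate_gwas_pair

from conftest import make_pairs


def _sumstats(rows):
    return pd.DataFrame(rows, columns=["snp", "chr", "pos", "ea", "oa", "eaf",
                                       "beta", "se", "pval", "n"])


class TestSelectInstruments:
    def _ld(self, snps, r2):
        m = np.asarray(r2, dtype=float)
        return pd.DataFrame(m, index=snps, columns=snps)

    def test_greedy_hand_oracle(self):
        gwas = _sumstats([
            ("s1", "1", 1_000_000, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000),
            ("s2", "1", 1_100_000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000),
            ("s3", "1", 1_200_000, "A", "G", 0.3, 0.1, 0.01, 1e-8 * 0.99, 1000),
        ])
        ld = self._ld(["s1", "s2", "s3"],
                      [[1, 0.5, 0.0001], [0.5, 1, 0.0001], [0.0001, 0.0001, 1]])
        assert mr.select_instruments(gwas, ld) == ["s1", "s3"]

    def test_no_significant_candidates(self):
        gwas = _sumstats([("s1", "1", 1, "A", "G", 0.3, 0.1, 0.05, 1e-6, 1000)])
        assert mr.select_instruments(gwas, self._ld(["s1"], [[1.0]])) == []

    def test_window_rule(self):
        # 2 Mb apart with r2=0.9: both retained because outside the window
        gwas = _sumstats([
            ("s1", "1", 1_000_000, "A", "G", 0.3, 0.1, 0.01, 1e-10, 1000),
            ("s2", "1", 3_000_000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000),
        ])
        ld = self._ld(["s1", "s2"], [[1, 0.9], [0.9, 1]])
        assert mr.select_instruments(gwas, ld) == ["s1", "s2"]


class TestHarmonize:
    def test_sign_flip(self):
        exp = _sumstats([("s1", "1", 100, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000)])
        out = _sumstats([("s1", "1", 100, "G", "A", 0.7, -0.05, 0.01, 1e-5, 1000)])
        pairs = mr.harmonize(exp, out)
        assert pairs[0].beta_out == pytest.approx(0.05)
        assert pairs[0].flipped is True
        assert pairs[0].eaf_out == pytest.approx(0.3)

    def test_palindromic_dropped(self):
        exp = _sumstats([("s1", "1", 100, "A", "T", 0.5, 0.1, 0.01, 1e-9, 1000)])
        out = _sumstats([("s1", "1", 100, "A", "T", 0.5, 0.05, 0.01, 1e-5, 1000)])
        assert mr.harmonize(exp, out) == []

    def test_identical_coding_unchanged(self):
        exp = _sumstats([("s1", "1", 100, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000)])
        out = _sumstats([("s1", "1", 100, "A", "G", 0.3, 0.05, 0.01, 1e-5, 1000)])
        p = mr.harmonize(exp, out)[0]
        assert p.beta_out == pytest.approx(0.05) and p.flipped is False

    def test_no_overlap(self):
        exp = _sumstats([("s1", "1", 100, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000)])
        out = _sumstats([("s2", "1", 100, "A", "G", 0.3, 0.1, 0.01, 1e-9, 1000)])
        assert mr.harmonize(exp, out) == []


class TestIvw:
    def test_hand_fixture(self, ratio_fixture):
        est = mr.ivw(ratio_fixture)
        assert est.beta_hat == pytest.approx(0.46, abs=1e-10)
        assert est.se_hat == pytest.approx(1 / np.sqrt(125), abs=1e-10)
        q, df, _ = mr.cochran_q(ratio_fixture, est.beta_hat)
        assert q == pytest.approx(0.8, abs=1e-10) and df == 1
        # Q/df < 1 so RE SE equals the fixed-effect SE
        assert est.se_hat == pytest.approx(0.0894, abs=5e-4)

    def test_identical_ratios(self):
        pairs = make_pairs([1, 1, 1], [0.3, 0.3, 0.3], [0.1, 0.1, 0.1])
        est = mr.ivw(pairs)
        assert est.beta_hat == pytest.approx(0.3)
        q, _, qp = mr.cochran_q(pairs)
        assert q == pytest.approx(0.0, abs=1e-12) and qp == pytest.approx(1.0)

    def test_odds_ratio_definition(self):
        est = mr.MrEstimate("IVW", 0.131, 0.03, 1e-5, 10)
        assert est.or_ == pytest.approx(np.exp(0.131))
        assert est.or_ == pytest.approx(1.14, abs=0.005)
        assert est.ci_low < est.or_ < est.ci_high

    def test_matches_generic_wls_through_origin(self, rng):
        # invariant: IVW formula == origin-constrained weighted least squares
        for _ in range(25):
            k = int(rng.integers(2, 12))
            bexp = rng.normal(0.1, 0.03, k)
            bout = rng.normal(0.02, 0.02, k)
            seo = rng.uniform(0.005, 0.05, k)
            pairs = make_pairs(bexp, bout, seo)
            est = mr.ivw(pairs)
            w = 1.0 / seo**2
            beta_wls = np.sum(w * bexp * bout) / np.sum(w * bexp**2)
            assert est.beta_hat == pytest.approx(beta_wls, abs=1e-10)

    def test_zero_beta_exp_excluded(self):
        pairs = make_pairs([0.0, 1.0, 1.0], [0.1, 0.3, 0.3], [0.1, 0.1, 0.1])
        with pytest.warns(UserWarning, match="excluded"):
            est = mr.ivw(pairs)
        assert est.nsnp == 2

    def test_too_few_instruments(self):
        with pytest.raises(mr.InsufficientInstrumentsError):
            mr.ivw(make_pairs([1.0], [0.3], [0.1]))


class TestEgger:
    def test_exact_line(self):
        pairs = make_pairs([0.1, 0.2, 0.3], [0.07, 0.12, 0.17],
                           [0.01, 0.01, 0.01])
        est, intercept, p_int = mr.egger(pairs)
        assert est.beta_hat == pytest.approx(0.5, abs=1e-10)
        assert intercept == pytest.approx(0.02, abs=1e-10)

    def test_line_through_origin(self):
        pairs = make_pairs([0.1, 0.2, 0.3], [0.05, 0.10, 0.15],
                           [0.01, 0.01, 0.01])
        _, intercept, _ = mr.egger(pairs)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_requires_three(self):
        with pytest.raises(mr.InsufficientInstrumentsError, match="3"):
            mr.egger(make_pairs([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))

    def test_orientation_invariance(self):
        # flipping the sign of a pair leaves the Egger fit unchanged
        pairs = make_pairs([0.1, -0.2, 0.3], [0.07, -0.12, 0.17],
                           [0.01, 0.02, 0.01])
        flipped = make_pairs([0.1, 0.2, 0.3], [0.07, 0.12, 0.17],
                             [0.01, 0.02, 0.01])
        a = mr.egger(pairs)
        b = mr.egger(flipped)
        assert a[0].beta_hat == pytest.approx(b[0].beta_hat)
        assert a[1] == pytest.approx(b[1])

    def test_pleiotropy_power(self):
        # power oracle via the simulator: a constant direct effect shifts the
        # intercept, so rejection exceeds the 5% nominal null rate
        rejected = 0
        for seed in range(100):
            cfg = GwasSimConfig(n_instruments=30, beta_causal=0.1,
                                pleiotropy_mean=0.05, seed=seed)
            exp, out, _ = simulate_gwas_pair(cfg)
            _, _, p_int = mr.egger(mr.harmonize(exp, out))
            rejected += p_int < 0.05
        assert rejected / 100 > 0.3

    def test_slope_equals_ivw_without_intercept(self):
        # constrained-to-origin weighted regression reproduces the IVW beta
        pairs = make_pairs([0.1, 0.2, 0.3], [0.06, 0.13, 0.14],
                           [0.01, 0.02, 0.015])
        est = mr.ivw(pairs)
        x = np.array([p.beta_exp for p in pairs])
        y = np.array([p.beta_out for p in pairs])
        w = np.array([1 / p.se_out**2 for p in pairs])
        slope0 = np.sum(w * x * y) / np.sum(w * x * x)
        assert est.beta_hat == pytest.approx(slope0, abs=1e-10)


class TestCochranQ:
    def test_hand_sum(self, ratio_fixture):
        q, df, p = mr.cochran_q(ratio_fixture)
        assert q == pytest.approx(100 * 0.04**2 + 25 * 0.16**2, abs=1e-10)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(0.8, 1))

    def test_monotone_in_het_sd(self):
        def mean_q(het_sd):
            qs = []
            for seed in range(30):
                cfg = GwasSimConfig(n_instruments=30, beta_causal=0.1,
                                    het_sd=het_sd, seed=seed)
                exp, out, _ = simulate_gwas_pair(cfg)
                q, _, _ = mr.cochran_q(mr.harmonize(exp, out))
                qs.append(q)
            return np.mean(qs)

        assert mean_q(0.0) < mean_q(0.1) < mean_q(0.3)

    def test_single_pair_errors(self):
        with pytest.raises(mr.InsufficientInstrumentsError):
            mr.cochran_q(make_pairs([1.0], [0.3], [0.1]))


class TestLeaveOneOut:
    def test_identical_ratios_equal_full(self):
        pairs = make_pairs([1, 1, 1], [0.3, 0.3, 0.3], [0.1, 0.1, 0.1])
        table = mr.leave_one_out(pairs)
        full = mr.ivw(pairs)
        np.testing.assert_allclose(table["beta"], full.beta_hat)
        assert not table["influential"].any()

    def test_outlier_largest_delta(self):
        pairs = make_pairs([1, 1, 1, 1, 1], [0.3, 0.3, 0.3, 0.3, 1.5],
                           [0.1] * 5)
        table = mr.leave_one_out(pairs)
        worst = table.loc[table["delta_beta"].abs().idxmax(), "snp"]
        assert worst == "s4"

    def test_row_count(self):
        pairs = make_pairs([1] * 5, [0.3, 0.31, 0.29, 0.3, 0.32], [0.1] * 5)
        assert len(mr.leave_one_out(pairs)) == 5


class TestRadialOutliers:
    def test_homogeneous_empty(self):
        pairs = make_pairs([1, 1, 1], [0.3, 0.3, 0.3], [0.1, 0.1, 0.1])
        assert mr.radial_outliers(pairs) == frozenset()

    def test_displaced_snp_flagged(self):
        # one ratio displaced by 10 ratio-SEs among 10 concordant SNPs
        betas = [0.3] * 10 + [0.3 + 10 * 0.1]
        pairs = make_pairs([1] * 11, betas, [0.1] * 11)
        flagged = mr.radial_outliers(pairs)
        assert flagged == frozenset({"s10"})

    def test_bonferroni_threshold_monotonicity(self):
        betas = [0.3, 0.32, 0.28, 0.3, 0.55]
        pairs = make_pairs([1] * 5, betas, [0.1] * 5)
        loose = mr.radial_outliers(pairs, bonferroni=False)
        strict = mr.radial_outliers(pairs, bonferroni=True)
        assert strict <= loose


class TestSteiger:
    def test_forward_consistent_retained(self):
        pairs = make_pairs([0.14], [0.03], [0.01], ses_exp=[0.01])
        retained, removed = mr.steiger_filter(pairs, 1000, 1000)
        assert len(retained) == 1 and removed == frozenset()

    def test_reverse_removed(self):
        pairs = make_pairs([0.03], [0.14], [0.01], ses_exp=[0.01])
        retained, removed = mr.steiger_filter(pairs, 1000, 1000)
        assert retained == [] and removed == frozenset({"s0"})

    def test_missing_n_names_dataset(self):
        pairs = make_pairs([0.1], [0.03], [0.01])
        with pytest.raises(ValueError, match="exposure"):
            mr.steiger_filter(pairs, None, 1000)
        with pytest.raises(ValueError, match="outcome"):
            mr.steiger_filter(pairs, 1000, None)

    def test_outcome_first_architecture_removes_majority(self):
        # generative oracle: beta=0 with strong pleiotropy makes instruments
        # explain more variance in the outcome
        removed_frac = []
        for seed in range(20):
            cfg = GwasSimConfig(n_instruments=30, beta_causal=0.0,
                                pleiotropy_mean=0.2, seed=seed)
            exp, out, _ = simulate_gwas_pair(cfg)
            pairs = mr.harmonize(exp, out)
            _, removed = mr.steiger_filter(pairs, cfg.n_exposure, cfg.n_outcome)
            removed_frac.append(len(removed) / len(pairs))
        assert np.median(removed_frac) > 0.5

    def test_no_removal_when_exposure_dominates(self):
        fracs = []
        for seed in range(20):
            cfg = GwasSimConfig(n_instruments=30, beta_causal=0.2, seed=seed)
            exp, out, _ = simulate_gwas_pair(cfg)
            pairs = mr.harmonize(exp, out)
            _, removed = mr.steiger_filter(pairs, cfg.n_exposure, cfg.n_outcome)
            fracs.append(len(removed) / len(pairs))
        assert np.mean(fracs) <= 0.05


class TestQualify:
    def _assoc(self, p_ivw, p_int, p_q):
        est = mr.MrEstimate("IVW", 0.1, 0.02, p_ivw, 10)
        sens = mr.SensitivityReport(egger_intercept=0.0, egger_intercept_p=p_int,
                                    q_stat=5.0, q_df=9, q_p=p_q)
        return mr.qualify("X", "Y", "forward", est, sens)

    def test_all_criteria_pass(self):
        assert self._assoc(0.01, 0.5, 0.5).qualified

    def test_pleiotropy_fails(self):
        assert not self._assoc(0.01, 0.01, 0.5).qualified

    def test_ivw_not_significant_fails(self):
        assert not self._assoc(0.06, 0.5, 0.5).qualified

    def test_heterogeneity_fails(self):
        assert not self._assoc(0.01, 0.5, 0.01).qualified


class TestRunMr:
    def test_full_path_on_simulated_pair(self):
        cfg = GwasSimConfig(n_instruments=20, beta_causal=0.25, seed=11)
        exp, out, ld = simulate_gwas_pair(cfg)
        assoc = mr.run_mr(exp, out, ld, exposure_name="X", outcome_name="Y")
        assert assoc is not None
        assert assoc.qualified
        assert assoc.estimate.pval < 0.05
        assert len(assoc.instruments) == assoc.estimate.nsnp

    def test_returns_none_without_instruments(self):
        cfg = GwasSimConfig(n_instruments=5, beta_causal=0.0, seed=1,
                            gamma_range=(0.0001, 0.0002))
        exp, out, ld = simulate_gwas_pair(cfg)
        assert mr.run_mr(exp, out, ld) is None
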