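"""Moderated paired testing: formula oracles, limma cross-check, BH."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist

from exprot.differential import (
    ModerationHyperparams,
    bh_adjust,
    estimate_moderation,
    moderated_paired_test,
    paired_log_differences,
    paired_t_test,
    run_differential,
)


def _diff_frame(arr):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"SL{i:05d}" for i in range(arr.shape[0])],
        columns=[f"P{j:02d}" for j in range(arr.shape[1])],
    )


class TestPairedLogDifferences:
    def test_identity_and_doubling(self, tiny_study):
        study = tiny_study
        sheet = study.samples
        for intensity in ("moderate", "high"):
            pre = sheet[(sheet.intensity == intensity) & (sheet.timepoint == "pre")]
            post = sheet[(sheet.intensity == intensity) & (sheet.timepoint == "post")]
            for pr, po in zip(pre.sample_id, post.sample_id):
                study.abundance[po] = study.abundance[pr] * (
                    1.0 if intensity == "moderate" else 2.0
                )
        d_m = paired_log_differences(study, "moderate")
        d_h = paired_log_differences(study, "high")
        assert np.allclose(d_m.to_numpy(), 0.0)
        assert np.allclose(d_h.to_numpy(), 1.0)

    def test_matches_direct_log2_recomputation(self, small_study):
        study, _ = small_study
        diffs = paired_log_differences(study, "high")
        sheet = study.samples
        sub = diffs.columns[3]
        pre = sheet[
            (sheet.subject_id == sub)
            & (sheet.intensity == "high")
            & (sheet.timepoint == "pre")
        ]["sample_id"].item()
        post = sheet[
            (sheet.subject_id == sub)
            & (sheet.intensity == "high")
            & (sheet.timepoint == "post")
        ]["sample_id"].item()
        expected = np.log2(study.abundance[post]) - np.log2(study.abundance[pre])
        assert np.allclose(diffs[sub], expected)

    def test_missing_pair_names_subject(self, tiny_study):
        study = tiny_study
        study.samples = study.samples[study.samples.sample_id != "P02_H_post"]
        with pytest.raises(ValueError, match="P02"):
            paired_log_differences(study, "high")

    def test_nonpositive_abundance_rejected(self, tiny_study):
        study = tiny_study
        study.abundance.iloc[0, 0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            paired_log_differences(study, "moderate")


class TestEstimateModeration:
    def test_equal_variances_give_infinite_prior_df(self):
        from scipy.special import digamma

        hyper = estimate_moderation(np.full(20, 0.7), df=11)
        assert np.isinf(hyper.d0)
        # zero excess dispersion: s0^2 is the common value after undoing
        # the chi-square log bias E[log(chi2_d/d)] = digamma(d/2)-log(d/2)
        expected = 0.7 * np.exp(-(digamma(5.5) - np.log(5.5)))
        assert hyper.s0_sq == pytest.approx(expected, rel=1e-12)

    def test_recovers_known_prior_within_25pct(self):
        # variances from a scaled inverse-chi-square prior (d0=4, s0^2=1)
        d0_true, s0_true, n, df = 4.0, 1.0, 5000, 11
        errors = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sigma2 = d0_true * s0_true / rng.chisquare(d0_true, n)
            s2 = sigma2 * rng.chisquare(df, n) / df
            hyper = estimate_moderation(s2, df)
            errors.append(abs(hyper.d0 - d0_true) / d0_true)
        assert np.mean(errors) < 0.25

    def test_two_wildly_different_variances_give_finite_positive_d0(self):
        hyper = estimate_moderation(np.array([1e-4, 1e2]), df=11)
        assert 0 < hyper.d0 < np.inf

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError, match="positive variance"):
            estimate_moderation(np.zeros(10), df=11)


class TestModeratedPairedTest:
    def test_matches_step_by_step_formula_oracle(self):
        # 50 proteins x 12 subjects, fixed hyperparameters
        rng = np.random.default_rng(42)
        X = rng.normal(0.0, rng.uniform(0.1, 1.0, (50, 1)), (50, 12))
        d0, s0 = 3.0, 0.5
        res = moderated_paired_test(
            _diff_frame(X), ModerationHyperparams(d0=d0, s0_sq=s0)
        )
        n = 12
        dg = n - 1
        for g in range(50):
            mean = X[g].mean()
            s2 = X[g].var(ddof=1)
            s2_post = (d0 * s0 + dg * s2) / (d0 + dg)
            t_exp = mean / np.sqrt(s2_post / n)
            assert res["t"].iloc[g] == pytest.approx(t_exp, abs=1e-10)
            df_exp = min(d0 + dg, dg * 50)
            p_exp = 2 * t_dist.sf(abs(t_exp), df_exp)
            assert res["p_value"].iloc[g] == pytest.approx(p_exp, rel=1e-10)

    def test_d0_zero_equals_plain_paired_t(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (20, 8))
        res = moderated_paired_test(_diff_frame(X), ModerationHyperparams(0.0, 1.0))
        from scipy.stats import ttest_rel

        t_ref = ttest_rel(X.T, np.zeros_like(X.T)).statistic
        assert np.allclose(res["t"], t_ref, atol=1e-12)

    def test_null_protein_t_zero_p_one(self):
        X = np.vstack([np.zeros(6), np.random.default_rng(0).normal(0, 1, 6)])
        res = moderated_paired_test(_diff_frame(X), ModerationHyperparams(2.0, 0.3))
        assert res["t"].iloc[0] == 0.0
        assert res["p_value"].iloc[0] == 1.0

    def test_zero_posterior_variance_is_error_not_p0(self):
        X = np.zeros((3, 5))
        with pytest.raises(ValueError, match="posterior variance"):
            moderated_paired_test(_diff_frame(X), ModerationHyperparams(0.0, 1.0))

    def test_shrinkage_lies_between_sample_and_prior_variance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (100, 12))
        s2 = X.var(axis=1, ddof=1)
        s0 = 1.0
        prev_dist = None
        for d0 in (1.0, 5.0, 50.0):
            res = moderated_paired_test(
                _diff_frame(X), ModerationHyperparams(d0, s0)
            )
            s2_post = (X.mean(axis=1) / res["t"].to_numpy()) ** 2 * X.shape[1]
            lo, hi = np.minimum(s2, s0), np.maximum(s2, s0)
            assert ((s2_post >= lo - 1e-12) & (s2_post <= hi + 1e-12)).all()
            dist = np.abs(s2_post - s0).mean()
            if prev_dist is not None:
                assert dist < prev_dist  # larger d0 pulls harder toward s0
            prev_dist = dist

    def test_matches_limma_ebayes_oracle(self, tmp_path):
        """Independent cross-check against Bioconductor limma on the same
        difference matrix (paired analysis = intercept-only fit)."""
        rng = np.random.default_rng(7)
        sigma2 = 4.0 * 0.25 / rng.chisquare(4.0, 60)
        X = rng.normal(0.1, np.sqrt(sigma2)[:, None], (60, 12))
        diffs = _diff_frame(X)
        diffs.to_csv(tmp_path / "diffs.tsv", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            x <- as.matrix(read.delim('diffs.tsv', row.names=1))
            fit <- eBayes(lmFit(x, design=matrix(1, ncol(x), 1)))
            out <- data.frame(t=fit$t[,1], p=fit$p.value[,1])
            out$d0 <- fit$df.prior; out$s0 <- fit$s2.prior
            write.csv(format(out, digits=12), 'limma_out.csv')
            """
        )
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(
            ["Rscript", "oracle.R"], cwd=tmp_path, check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "limma_out.csv", index_col=0)
        res = moderated_paired_test(diffs)
        hyper = estimate_moderation(X.var(axis=1, ddof=1), 11)
        assert hyper.d0 == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-4)
        assert hyper.s0_sq == pytest.approx(float(ref["s0"].iloc[0]), rel=1e-4)
        assert np.allclose(res["t"], ref["t"].astype(float), rtol=1e-5)
        assert np.allclose(res["p_value"], ref["p"].astype(float), rtol=1e-4)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_run_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bounds_and_order_preservation(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 500)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 200))
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(bh_adjust(p), q_ref, atol=1e-12)

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestPairedTTest:
    def test_identity_gives_t0_p1(self):
        t, p = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_hand_formula(self):
        # differences (1,2,3,4): mean 2.5, sd 1.2910 -> t = 3.873
        t, p = paired_t_test([0.0, 0.0, 0.0, 0.0], [1.0, 2.0, 3.0, 4.0])
        assert t == pytest.approx(2.5 / (np.sqrt(5 / 3) / 2), rel=1e-6)
        assert t == pytest.approx(3.873, abs=1e-3)

    def test_swapping_flips_sign_keeps_p(self):
        rng = np.random.default_rng(2)
        pre, post = rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)
        t1, p1 = paired_t_test(pre, post)
        t2, p2 = paired_t_test(post, pre)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_constant_shift_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


class TestRunDifferential:
    def test_result_invariants(self, small_study):
        study, _ = small_study
        res = run_differential(study, "high")
        assert np.allclose(res["fold_change"], np.exp2(res["log2_fc"]))
        assert (res["q_value"] >= res["p_value"] - 1e-15).all()
        assert ((res["q_value"] < 0.05) == res["significant"]).all()
        up = res["direction"] == "up"
        assert (res.loc[up, "log2_fc"] >= 0).all()
        assert (res.loc[~up, "log2_fc"] < 0).all()

    def test_moderation_none_matches_scipy(self, small_study):
        from scipy.stats import ttest_rel

        study, _ = small_study
        res = run_differential(study, "moderate", moderation="none")
        diffs = paired_log_differences(study, "moderate").to_numpy()
        ref = ttest_rel(diffs.T, np.zeros_like(diffs.T))
        assert np.allclose(res["t"], ref.statistic, atol=1e-10)
        assert np.allclose(res["p_value"], ref.pvalue, atol=1e-12)
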