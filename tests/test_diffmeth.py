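import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ladomics.diffmeth import (
    BetaMatrix,
    ModerationPrior,
    ModeratedDifferentialMethylation,
    bh_adjust,
    estimate_moderation_prior,
    filter_probes,
    fit_moderated_f,
    welch_t,
)


def make_beta(values, probe_prefix="p", sample_prefix="s"):
    values = np.asarray(values, dtype=float)
    return BetaMatrix(
        pd.DataFrame(
            values,
            index=[f"{probe_prefix}{i}" for i in range(values.shape[0])],
            columns=[f"{sample_prefix}{j}" for j in range(values.shape[1])],
        )
    )


def make_sheet(n_case, n_control):
    ids = [f"s{j}" for j in range(n_case + n_control)]
    return pd.DataFrame(
        {"group": ["case"] * n_case + ["control"] * n_control},
        index=pd.Index(ids, name="sample_id"),
    )


class TestBetaMatrix:
    def test_bounds_and_duplicates(self):
        with pytest.raises(ValueError):
            make_beta([[1.2, 0.5]])
        df = pd.DataFrame([[0.5, 0.5]], index=["a"], columns=["x", "x"])
        with pytest.raises(ValueError):
            BetaMatrix(df)

    def test_nan_allowed_as_missing(self):
        bm = make_beta([[0.5, np.nan]])
        assert np.isnan(bm.values.iloc[0, 1])


class TestFilterProbes:
    def test_rules(self, small_sim):
        beta, det = small_sim["beta"], small_sim["detection"]
        annot = small_sim["genome"].probe_annot
        out, log = filter_probes(beta, det, annot)
        # removal rule: any sample above threshold, plus the three flags
        fail = (det > 0.01).any(axis=1)
        flagged = annot.loc[beta.probe_ids, ["sex_chromosome", "snp_affected", "cross_reactive"]].any(axis=1)
        expected_drop = (fail | flagged).sum()
        assert log["removed_total"] == expected_drop
        assert out.shape[0] == beta.shape[0] - expected_drop
        # retained values are untouched
        keep = out.probe_ids
        pd.testing.assert_frame_equal(out.values, beta.values.loc[keep])

    def test_single_failing_sample_removes_probe(self):
        beta = make_beta(np.full((2, 4), 0.5))
        det = pd.DataFrame(0.0, index=beta.probe_ids, columns=beta.sample_ids)
        det.iloc[0, 2] = 0.02
        annot = pd.DataFrame(
            {
                "chrom": "chr1", "pos": [10, 20],
                "sex_chromosome": False, "snp_affected": False,
                "cross_reactive": False, "solo_wcgw": False,
                "in_pmd": False, "in_hmd": True,
            },
            index=beta.probe_ids,
        )
        out, log = filter_probes(beta, det, annot)
        assert list(out.probe_ids) == ["p1"]
        assert log["high_detection_p"] == 1

    def test_misaligned_matrices_error(self):
        beta = make_beta(np.full((2, 3), 0.5))
        det = pd.DataFrame(0.0, index=["p0", "px"], columns=beta.sample_ids)
        with pytest.raises(ValueError, match="aligned"):
            filter_probes(beta, det, pd.DataFrame())


class TestModeratedF:
    def test_null_identity(self):
        vals = np.tile(np.linspace(0.2, 0.8, 10)[:, None], (1, 6))
        tab = fit_moderated_f(make_beta(vals), make_sheet(3, 3))
        assert (tab["F_statistic"] == 0).all()
        assert (tab["p_value"] == 1).all()

    def test_no_shrink_equals_anova(self, rng):
        vals = rng.uniform(0.1, 0.9, size=(200, 9))
        beta = make_beta(vals)
        tab = fit_moderated_f(beta, make_sheet(4, 5), shrink=False)
        for i in range(200):
            f, p = stats.f_oneway(vals[i, :4], vals[i, 4:])
            assert abs(tab["F_statistic"].iloc[i] - f) <= 1e-10 * max(f, 1e-30)
            assert abs(tab["p_value"].iloc[i] - p) <= 1e-10

    def test_shrinkage_formula_hand_value(self):
        # s_g^2 = 1, d_g = 13, d0 = 4, s0^2 = 2  ->  (4*2 + 13*1)/17 = 21/17
        prior = ModerationPrior(d0=4.0, s0_squared=2.0)
        s2_mod = (prior.d0 * prior.s0_squared + 13 * 1.0) / (prior.d0 + 13)
        assert s2_mod == pytest.approx(21 / 17, abs=1e-12)

    def test_moderated_variance_between_prior_and_residual(self, rng):
        vals = rng.uniform(0.1, 0.9, size=(500, 12))
        est = ModeratedDifferentialMethylation().fit(
            vals.T, np.array(["case"] * 6 + ["control"] * 6)
        )
        lo = np.minimum(est.residual_var_, est.prior_.s0_squared)
        hi = np.maximum(est.residual_var_, est.prior_.s0_squared)
        assert ((est.moderated_var_ >= lo - 1e-12) & (est.moderated_var_ <= hi + 1e-12)).all()

    def test_infinite_prior_uses_s0_only(self, rng):
        # equal-variance probes: excess log-variance spread is negative,
        # the prior degenerates to d0 = inf and s~^2 is constant
        base = rng.normal(0, 1, size=(2000, 10))
        est = ModeratedDifferentialMethylation().fit(
            base.T, np.array(["case"] * 5 + ["control"] * 5)
        )
        if est.prior_.is_infinite:
            assert np.allclose(est.moderated_var_, est.prior_.s0_squared)

    def test_prior_recovery_from_known_hyperparameters(self, rng):
        d0, s0, df = 6.0, 0.04, 10
        sigma2 = d0 * s0 / stats.chi2.rvs(d0, size=30000, random_state=3)
        s2 = sigma2 * stats.chi2.rvs(df, size=30000, random_state=4) / df
        prior = estimate_moderation_prior(s2, df)
        assert prior.d0 == pytest.approx(d0, rel=0.1)
        assert prior.s0_squared == pytest.approx(s0, rel=0.05)

    def test_matches_limma_ebayes(self, tmp_path, rng):
        """Independent oracle: R limma lmFit + eBayes on the same matrix."""
        m, n1, n2 = 300, 4, 6
        X = rng.normal(0, rng.uniform(0.5, 2.0, size=(m, 1)), size=(m, n1 + n2))
        X[:50, :n1] += 1.0
        path = tmp_path / "m.tsv"
        pd.DataFrame(X, index=[f"p{i}" for i in range(m)]).to_csv(path, sep="\t")
        out = tmp_path / "limma.tsv"
        script = f"""
        suppressMessages(library(limma))
        m <- as.matrix(read.table("{path}", header=TRUE, row.names=1, sep="\\t"))
        grp <- factor(c(rep("case", {n1}), rep("ctrl", {n2})), levels=c("ctrl", "case"))
        fit <- eBayes(lmFit(m, model.matrix(~grp)))
        write.table(data.frame(F=fit$t[,2]^2, p=fit$p.value[,2]),
                    "{out}", sep="\\t", quote=FALSE)
        """
        res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        ref = pd.read_csv(out, sep="\t")
        est = ModeratedDifferentialMethylation().fit(
            X.T, np.array(["case"] * n1 + ["control"] * n2)
        )
        np.testing.assert_allclose(est.f_statistic_, ref["F"].to_numpy(), rtol=1e-6)
        np.testing.assert_allclose(est.p_values_, ref["p"].to_numpy(), atol=1e-8)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            ModeratedDifferentialMethylation().fit(
                np.zeros((4, 5)), np.array(["case"] * 4)
            )

    def test_delta_sign_convention(self, rng):
        vals = np.array([[0.8, 0.8, 0.2, 0.2]] * 5) + rng.normal(0, 0.01, (5, 4))
        tab = fit_moderated_f(make_beta(np.clip(vals, 0, 1)), make_sheet(2, 2))
        assert (tab["delta_beta"] > 0).all()  # hypermethylated in cases


class TestBHAdjust:
    def test_hand_values(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04], atol=1e-12
        )

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestWelchT:
    def test_identical_samples(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res["t"] == 0 and res["p"] == 1

    def test_hand_example(self):
        res = welch_t([1, 2, 3], [3, 4, 5])
        assert res["t"] == pytest.approx(-2.449, abs=1e-3)
        assert res["df"] == pytest.approx(4.0)
        assert res["p"] == pytest.approx(2 * stats.t.sf(2.449489, 4), abs=1e-4)

    def test_degenerate_zero_variance(self):
        assert welch_t([2, 2], [2, 2])["p"] == 1
        with pytest.warns(UserWarning):
            assert welch_t([2, 2], [3, 3])["p"] == 0

    def test_null_calibration(self, rng):
        rejections = sum(
            welch_t(rng.normal(size=8), rng.normal(size=8))["p"] < 0.05
            for _ in range(4000)
        )
        lo, hi = stats.binom.interval(0.999, 4000, 0.05)
        assert lo <= rejections <= hi
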