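import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sepsisprot import (
    AbundanceMatrix,
    EBayesParams,
    PairedContrast,
    SampleRecord,
    UnpairedContrast,
    benjamini_hochberg,
    call_deps,
    estimate_ebayes_prior,
    fit_contrast,
    moderated_t,
    ordinary_t,
    run_de,
    signed_fold_change,
)


def _two_group_data(a_vals, b_vals):
    """One-protein matrix with explicit per-group values."""
    na, nb = len(a_vals), len(b_vals)
    sids = [f"A{i}" for i in range(na)] + [f"B{i}" for i in range(nb)]
    df = pd.DataFrame({"P1": list(a_vals) + list(b_vals)}, index=sids)
    records = [
        SampleRecord(sample_id=f"A{i}", subject_id=f"A{i}", group="SEPSIS", timepoint="D1")
        for i in range(na)
    ] + [SampleRecord(sample_id=f"B{i}", subject_id=f"B{i}", group="HC", timepoint="NA") for i in range(nb)]
    return AbundanceMatrix(df), records


D1_VS_HC = UnpairedContrast("SEPSIS", "D1", "HC", None)


class TestFitContrast:
    def test_constant_groups(self):
        matrix, records = _two_group_data([0, 0], [1, 1])
        fit = fit_contrast(matrix, records, D1_VS_HC)
        row = fit.loc["P1"]
        assert row["beta"] == -1.0 and row["s2"] == 0.0 and row["df"] == 2.0

    def test_pooled_variance_hand_example(self):
        """beta = 2-5 = -3; each group variance 1 on 2 df; v = 1/3+1/3."""
        matrix, records = _two_group_data([1, 2, 3], [4, 5, 6])
        row = fit_contrast(matrix, records, D1_VS_HC).loc["P1"]
        assert row["beta"] == -3.0
        assert row["s2"] == pytest.approx(1.0)
        assert row["df"] == 4.0
        assert row["v"] == pytest.approx(2 / 3)

    def test_paired_identity_gives_zero_effect(self):
        sids = ["S1_D1", "S2_D1", "S1_D3", "S2_D3"]
        df = pd.DataFrame({"P1": [3.0, 5.0, 3.0, 5.0], "P2": [1.0, 2.0, 1.0, 2.0]}, index=sids)
        records = [
            SampleRecord(sample_id=f"S{i}_{tp}", subject_id=f"S{i}", group="SEPSIS", timepoint=tp)
            for tp in ("D1", "D3")
            for i in (1, 2)
        ]
        fit = fit_contrast(AbundanceMatrix(df), records, PairedContrast("D3", "D1"))
        assert (fit["beta"] == 0).all()
        assert (fit["df"] == 1.0).all()

    def test_unmatched_pairs_listed(self):
        sids = ["S1_D1", "S2_D1", "S1_D3"]
        df = pd.DataFrame({"P1": [1.0, 2.0, 3.0]}, index=sids)
        records = [
            SampleRecord(sample_id="S1_D1", subject_id="S1", group="SEPSIS", timepoint="D1"),
            SampleRecord(sample_id="S2_D1", subject_id="S2", group="SEPSIS", timepoint="D1"),
            SampleRecord(sample_id="S1_D3", subject_id="S1", group="SEPSIS", timepoint="D3"),
        ]
        with pytest.raises(ValueError, match="S2"):
            fit_contrast(AbundanceMatrix(df), records, PairedContrast("D3", "D1"))

    def test_too_few_samples_rejected(self):
        matrix, records = _two_group_data([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match=">=2"):
            fit_contrast(matrix, records, D1_VS_HC)


class TestEBayesPrior:
    def test_identical_variances_give_infinite_d0(self):
        from scipy.special import digamma

        prior = estimate_ebayes_prior(np.full(50, 2.0), d=10)
        assert math.isinf(prior.d0)
        # complete shrinkage toward the moment-consistent scale, which is the
        # common s2 times the finite-d log-scale bias factor exp(log(d/2)-digamma(d/2))
        expected = 2.0 * math.exp(math.log(5.0) - digamma(5.0))
        assert prior.s0sq == pytest.approx(expected, rel=1e-9)

    def test_parametric_recovery(self):
        """Variances drawn from the scaled inverse-chi-square prior are re-estimated."""
        rng = np.random.default_rng(8)
        d0_true, s0_true, d = 4.0, 1.0, 6
        n = 5000
        # s2 | s0 ~ s0^2 * d0 / chi2(d0) (prior draw), then sampling: s2_hat ~ s2 * chi2(d)/d
        prior_draw = s0_true * d0_true / rng.chisquare(d0_true, size=n)
        s2 = prior_draw * rng.chisquare(d, size=n) / d
        est = estimate_ebayes_prior(s2, d=d)
        assert est.d0 == pytest.approx(d0_true, rel=0.15)
        assert est.s0sq == pytest.approx(s0_true, rel=0.15)

    def test_two_proteins_moment_solve(self):
        est = estimate_ebayes_prior([1.0, math.e], d=10)
        assert 0 < est.d0 < math.inf

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                estimate_ebayes_prior([0.0, 0.0, 0.0], d=4)


class TestModeratedT:
    def test_hand_arithmetic(self):
        """s~2 = (4*1 + 2*2)/6 = 4/3; t = 1/sqrt(4/3) = sqrt(3)/2; df = 6."""
        t, df, p = moderated_t(1.0, 2.0, d=2, v=1.0, prior=EBayesParams(d0=4, s0sq=1.0))
        assert t[0] == pytest.approx(math.sqrt(3) / 2)
        assert df == 6.0

    def test_no_shrinkage_limit_is_ordinary_t(self):
        rng = np.random.default_rng(9)
        beta, s2 = rng.normal(size=30), rng.chisquare(5, size=30)
        t_mod, df_mod, p_mod = moderated_t(beta, s2, d=8, v=0.25, prior=EBayesParams(d0=0.0, s0sq=1.0))
        t_ord, df_ord, p_ord = ordinary_t(beta, s2, d=8, v=0.25)
        np.testing.assert_allclose(t_mod, t_ord, rtol=1e-12)
        assert df_mod == df_ord
        np.testing.assert_allclose(p_mod, p_ord, rtol=1e-12)

    def test_infinite_d0_is_fixed_variance_z(self):
        from scipy import stats

        beta = np.array([1.0, -2.0])
        t, df, p = moderated_t(beta, np.array([5.0, 0.1]), d=8, v=1.0,
                               prior=EBayesParams(d0=math.inf, s0sq=4.0))
        np.testing.assert_allclose(t, beta / 2.0)
        assert math.isinf(df)
        np.testing.assert_allclose(p, 2 * stats.norm.sf(np.abs(beta / 2.0)))

    def test_zero_effect_gives_p_one(self):
        t, _, p = moderated_t(0.0, 1.0, d=4, v=1.0, prior=EBayesParams(d0=2, s0sq=1.0))
        assert t[0] == 0.0 and p[0] == 1.0

    def test_shrinkage_direction_monotone(self):
        """Low-variance proteins lose |t|, high-variance proteins gain, vs ordinary t."""
        prior = EBayesParams(d0=4.0, s0sq=1.0)
        beta = np.ones(2)
        s2 = np.array([0.2, 5.0])  # below and above s0sq
        t_mod, _, _ = moderated_t(beta, s2, d=6, v=0.5, prior=prior)
        t_ord, _, _ = ordinary_t(beta, s2, d=6, v=0.5)
        assert abs(t_mod[0]) <= abs(t_ord[0])
        assert abs(t_mod[1]) >= abs(t_ord[1])


def _bh_reject_oracle(p, alpha):
    """Largest k with p_(k) <= k*alpha/m defines the rejection set."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = np.asarray(p)[order]
    thresh = alpha * np.arange(1, m + 1) / m
    below = np.nonzero(sorted_p <= thresh)[0]
    k = below[-1] + 1 if below.size else 0
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return reject


class TestBenjaminiHochberg:
    def test_single_p_identity(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_manual_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    def test_monotone_and_order_preserving(self):
        rng = np.random.default_rng(10)
        p = rng.random(50)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        # adjusted values are non-decreasing in raw-p order
        assert (np.diff(adj[np.argsort(p, kind="mergesort")]) >= -1e-15).all()

    def test_rejections_match_step_up_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            adj = benjamini_hochberg(p)
            for alpha in (0.01, 0.05, 0.1, 0.25):
                np.testing.assert_array_equal(adj <= alpha, _bh_reject_oracle(p, alpha))


class TestDepCalling:
    @pytest.mark.parametrize(
        "log2fc,p_adj,status",
        [
            (1.0, 0.05, "up"),       # boundaries inclusive
            (0.9, 0.001, "ns"),
            (-1.5, 0.01, "down"),
            (2.0, 0.051, "ns"),
            (-1.0, 0.05, "down"),
        ],
    )
    def test_threshold_rule(self, log2fc, p_adj, status):
        table = pd.DataFrame({"log2fc": [log2fc], "p_adj": [p_adj]})
        assert call_deps(table).loc[0, "status"] == status

    @pytest.mark.parametrize("lfc,expected", [(1, 2.0), (-3, -8.0), (0, 1.0)])
    def test_signed_fold_change(self, lfc, expected):
        assert signed_fold_change(lfc) == expected

    def test_signed_fold_change_matches_printed_convention(self):
        assert signed_fold_change(5.5532) == pytest.approx(46.96, abs=0.01)

    @given(st.floats(-20, 20))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_signed_fold_change_magnitude_at_least_one(self, lfc):
        assert abs(signed_fold_change(lfc)) >= 1.0


class TestRunDE:
    def test_planted_deps_recovered(self, default_cohort):
        _, matrix, records, truth, _ = default_cohort
        table = run_de(matrix, records, D1_VS_HC)
        called = set(table.index[table["status"] != "ns"])
        planted = set(truth.dep_ids)
        sens = len(called & planted) / len(planted)
        assert sens >= 0.9
        fdr = len(called - planted) / max(len(called), 1)
        assert fdr <= 0.1

    def test_direction_matches_planted_sign(self, default_cohort):
        _, matrix, records, truth, _ = default_cohort
        table = run_de(matrix, records, D1_VS_HC)
        for pid, effect in truth.dep_effects.items():
            status = table.loc[pid, "status"]
            if status != "ns":
                assert status == ("up" if effect > 0 else "down")

    def test_sorted_by_adjusted_p(self, default_cohort):
        _, matrix, records, *_ = default_cohort
        table = run_de(matrix, records, D1_VS_HC)
        assert (np.diff(table["p_adj"].to_numpy()) >= -1e-15).all()
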