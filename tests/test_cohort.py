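import warnings
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from sepsisprot import (
    SampleRecord,
    association_matrix,
    chi_square,
    mann_whitney,
    pca_embedding,
    percent_of,
    summarize_cohort,
    summarize_continuous,
)
from sepsisprot.cohort import DegenerateDataWarning


class TestSummaries:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 2, 3, 4, 5], (3.0, 2.0, 4.0)),
            ([7], (7.0, 7.0, 7.0)),
            ([1, 1, 1, 1], (1.0, 1.0, 1.0)),
        ],
    )
    def test_median_and_interpolated_quartiles(self, values, expected):
        assert summarize_continuous(values) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_continuous([])

    @pytest.mark.parametrize(
        "count,total,expected",
        [(15, 23, 65), (0, 23, 0), (19, 23, 83), (21, 23, 91), (7, 23, 30), (17, 23, 74), (11, 23, 48)],
    )
    def test_percent_rounding_half_up(self, count, total, expected):
        assert percent_of(count, total) == expected

    def test_percent_invalid_inputs(self):
        with pytest.raises(ValueError):
            percent_of(1, 0)
        with pytest.raises(ValueError):
            percent_of(5, 3)


def _mwu_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    na = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    us = []
    for idx in combinations(range(len(pooled)), na):
        us.append(ranks[list(idx)].sum() - na * (na + 1) / 2)
    us = np.asarray(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_small_sample_exact_enumeration(self):
        """U = 0 with n = 2+2 gives exact two-sided p = 1/3 (2 of 6 arrangements)."""
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_multisets_give_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=6), rng.normal(size=5)
        assert mann_whitney(a, b)[1] == pytest.approx(mann_whitney(b, a)[1])

    def test_degenerate_constant_data_warns_p_one(self):
        with pytest.warns(DegenerateDataWarning):
            _, p = mann_whitney([2, 2], [2, 2, 2])
        assert p == 1.0

    def test_exact_branch_matches_full_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            na = int(rng.integers(2, 5))
            nb = int(rng.integers(2, 5))
            vals = rng.permutation(20)[: na + nb].astype(float)  # distinct, no ties
            a, b = vals[:na], vals[na:]
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(_mwu_exact_oracle(a, b), abs=1e-12)


class TestChiSquare:
    def test_perfect_independence(self):
        stat, p = chi_square([[5, 5], [5, 5]])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_perfect_association_hand_value(self):
        """Expected counts all 5; stat = sum (o-e)^2/e = 4 * 25/5 = 20 on 1 df."""
        stat, p = chi_square([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert p == pytest.approx(stats.chi2.sf(20.0, 1))

    def test_transpose_invariance(self):
        tab = [[8, 3], [2, 9]]
        assert chi_square(tab)[0] == pytest.approx(chi_square(np.transpose(tab))[0])

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square([[0, 0], [5, 5]])

    def test_matches_hand_2x2_formula_on_random_tables(self):
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 100:
            a, b, c, d = rng.integers(1, 40, size=4)
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, _ = chi_square([[a, b], [c, d]])
            assert stat == pytest.approx(expected, rel=1e-12)
            checked += 1


def _make_records(columns: dict) -> list:
    n = len(next(iter(columns.values())))
    return [
        SampleRecord(
            sample_id=f"S{i}", subject_id=f"S{i}", group="SEPSIS", timepoint="D1",
            clinical={k: v[i] for k, v in columns.items()},
        )
        for i in range(n)
    ]


class TestAssociationMatrix:
    def test_duplicated_variable_reaches_fdr_tier(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        records = _make_records({"a": x, "a_copy": x, "noise": rng.normal(size=30)})
        out = association_matrix(records)
        row = out[(out["var_a"] == "a") & (out["var_b"] == "a_copy")].iloc[0]
        assert row["tier"] == "fdr<alpha"

    def test_null_variables_calibrated(self):
        """Independent variables trigger the p<0.05 tier at roughly the nominal rate."""
        rng = np.random.default_rng(3)
        n_pairs, n_hits = 0, 0
        for _ in range(20):
            cols = {f"v{j}": rng.normal(size=50) for j in range(10)}
            out = association_matrix(_make_records(cols), variables=sorted(cols))
            n_pairs += len(out)
            n_hits += (out["p"] < 0.05).sum()
        frac = n_hits / n_pairs
        envelope = 2.576 * np.sqrt(0.05 * 0.95 / n_pairs)
        assert abs(frac - 0.05) <= envelope

    def test_constant_variable_tier_ns_with_warning(self):
        rng = np.random.default_rng(4)
        records = _make_records({"flat": np.ones(20), "x": rng.normal(size=20)})
        with pytest.warns(DegenerateDataWarning):
            out = association_matrix(records)
        assert (out["tier"] == "ns").all()

    def test_mixed_type_pairs_use_matching_tests(self):
        rng = np.random.default_rng(5)
        records = _make_records(
            {
                "cont": rng.normal(size=40),
                "cont2": rng.normal(size=40),
                "binary": rng.integers(0, 2, size=40).astype(float),
                "cat": np.array(list("ABC") * 14)[:40],
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = association_matrix(records)
        tests = out.set_index(["var_a", "var_b"])["test"]
        assert tests[("cont", "cont2")] == "pearson"
        assert tests[("cont", "binary")] == "mann_whitney"
        assert tests[("binary", "cat")] == "chi_square"
        assert tests[("cont", "cat")] == "kruskal_wallis"


class TestPCA:
    def test_duplicated_samples_identical_coordinates(self, small_cohort):
        _, matrix, *_ = small_cohort
        import pandas as pd
        from sepsisprot import AbundanceMatrix

        df = matrix.data.copy()
        dup = pd.concat([df, df.iloc[[0]].rename(index={df.index[0]: "DUP"})])
        scores = pca_embedding(AbundanceMatrix(dup))
        np.testing.assert_allclose(scores.loc["DUP"], scores.iloc[0], atol=1e-9)

    def test_component_variance_ordering(self, default_cohort):
        _, matrix, *_ = default_cohort
        scores = pca_embedding(matrix, k=2)
        assert scores["PC1"].var() >= scores["PC2"].var()

    def test_groups_separate_on_planted_signal(self, default_cohort):
        from sklearn.metrics import silhouette_score

        _, matrix, records, *_ = default_cohort
        keep = [r.sample_id for r in records if r.group == "HC" or r.timepoint == "D1"]
        labels = [0 if s.startswith("HC") else 1 for s in keep]
        sub_scores = pca_embedding(matrix).loc[keep]
        assert silhouette_score(sub_scores, labels) > 0

    def test_k_larger_than_dims_rejected(self, small_cohort):
        _, matrix, *_ = small_cohort
        with pytest.raises(ValueError, match="k="):
            pca_embedding(matrix, k=999)

    def test_sign_convention_deterministic(self, small_cohort):
        _, matrix, *_ = small_cohort
        s1 = pca_embedding(matrix)
        s2 = pca_embedding(matrix)
        np.testing.assert_array_equal(s1.to_numpy(), s2.to_numpy())


class TestSummarizeCohort:
    def test_summary_covers_both_kinds(self, default_cohort):
        _, _, records, *_ = default_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows = summarize_cohort(records, variables=["age_years", "sex"])
        kinds = {r.kind for r in rows}
        assert kinds == {"continuous", "categorical"}
        cont = next(r for r in rows if r.kind == "continuous")
        assert cont.q1 <= cont.median <= cont.q3
        cats = [r for r in rows if r.kind == "categorical"]
        assert all(r.percent == percent_of(r.count, sum(c.count for c in cats)) for r in cats)
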