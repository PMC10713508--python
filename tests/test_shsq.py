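"""Scoring, stratification and group-comparison behaviour of the data model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from shsnet.shsq import (
    CANONICAL_ITEMS,
    DOMAIN_SIZES,
    DegenerateSplitWarning,
    LikertResponseMatrix,
    RatingValidationError,
    SchemaError,
    cohens_d,
    compare_groups,
    effect_size_label,
    load_responses,
    median_split,
    pooled_t_from_summaries,
    shs_scores,
)


def _matrix(rows, covariates=None, ids=None):
    rows = np.asarray(rows, dtype=float)
    return LikertResponseMatrix(
        respondent_ids=ids or [f"r{i}" for i in range(len(rows))],
        items=list(CANONICAL_ITEMS),
        ratings=rows,
        covariates=covariates,
    )


class TestLoadResponses:
    def test_round_trip(self, tmp_path, canonical_matrix):
        path = tmp_path / "resp.csv"
        canonical_matrix.to_csv(path)
        loaded = load_responses(path)
        assert loaded.ratings.shape == (6, 25)
        np.testing.assert_array_equal(loaded.ratings, canonical_matrix.ratings)
        assert loaded.items == list(CANONICAL_ITEMS)

    def test_out_of_range_rating_names_cell(self, tmp_path, canonical_matrix):
        df = canonical_matrix.to_frame()
        df.iloc[1, df.columns.get_loc("FT4")] = 5
        df.to_csv(tmp_path / "bad.csv", index_label="respondent_id")
        with pytest.raises(RatingValidationError) as exc:
            load_responses(tmp_path / "bad.csv")
        assert ("r1", "FT4") in exc.value.offending

    def test_missing_item_column_named(self, tmp_path, canonical_matrix):
        df = canonical_matrix.to_frame().drop(columns=["MH7"])
        df.to_csv(tmp_path / "short.csv", index_label="respondent_id")
        with pytest.raises(SchemaError, match="MH7"):
            load_responses(tmp_path / "short.csv")


class TestScoring:
    def test_all_zero_row(self):
        st_ = shs_scores(_matrix(np.zeros((2, 25))))
        assert st_.total_score[0] == 0
        assert (st_.domain_scores.iloc[0] == 0).all()

    def test_all_four_row_hits_domain_maxima(self):
        st_ = shs_scores(_matrix(np.full((2, 25), 4)))
        assert st_.total_score[0] == 100
        expected = {dom: 4 * k for dom, k in DOMAIN_SIZES.items()}
        assert st_.domain_scores.iloc[0].to_dict() == expected

    def test_single_domain_contribution(self):
        row = np.zeros(25)
        ft_cols = [i for i, item in enumerate(CANONICAL_ITEMS) if item.startswith("FT")]
        row[ft_cols] = 2
        st_ = shs_scores(_matrix([row, row]))
        assert st_.total_score[0] == 18
        assert st_.domain_scores.iloc[0]["FT"] == 18

    def test_total_equals_domain_sum_and_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        ratings = rng.integers(0, 5, (10, 25))
        st_ = shs_scores(_matrix(ratings))
        np.testing.assert_array_equal(
            st_.total_score, st_.domain_scores.sum(axis=1).to_numpy()
        )
        perm = rng.permutation(10)
        st_p = shs_scores(_matrix(ratings[perm]))
        np.testing.assert_array_equal(st_p.total_score, st_.total_score[perm])

    def test_missing_strict_refuses_and_drop_warns(self):
        ratings = np.ones((3, 25))
        ratings[1, 4] = np.nan
        m = _matrix(ratings)
        with pytest.raises(ValueError, match="r1"):
            shs_scores(m)
        with pytest.warns(UserWarning, match="dropping"):
            st_ = shs_scores(m, missing="drop")
        assert len(st_.respondent_ids) == 2


class TestMedianSplit:
    def _scores(self, totals):
        rows = []
        for t in totals:  # spread the total over FT items, valid 0-4 each
            row = np.zeros(25)
            ft = [i for i, it in enumerate(CANONICAL_ITEMS) if it.startswith("FT")]
            q, r = divmod(int(t), len(ft))
            row[ft] = q
            row[ft[:r]] += 1
            rows.append(row)
        return shs_scores(_matrix(rows))

    def test_clean_split(self):
        st_ = median_split(self._scores([10, 20, 30, 36]))
        assert list(st_.status_label) == ["optimal", "optimal", "suboptimal", "suboptimal"]
        assert st_.median_cutoff == 25

    def test_ties_go_to_optimal_by_default(self):
        st_ = median_split(self._scores([10, 20, 20, 36]))
        assert list(st_.status_label) == ["optimal", "optimal", "optimal", "suboptimal"]

    def test_ties_configurable(self):
        st_ = median_split(self._scores([10, 20, 20, 36]), ties="suboptimal")
        assert list(st_.status_label) == [
            "optimal", "suboptimal", "suboptimal", "suboptimal",
        ]

    def test_degenerate_split_warns_all_optimal(self):
        with pytest.warns(DegenerateSplitWarning):
            st_ = median_split(self._scores([7, 7, 7]))
        assert set(st_.status_label) == {"optimal"}

    def test_group_sizes_differ_only_by_tie_count(self):
        totals = [5, 10, 15, 15, 20, 25]
        st_ = median_split(self._scores(totals))
        n_opt = (st_.status_label == "optimal").sum()
        n_sub = (st_.status_label == "suboptimal").sum()
        ties = sum(t == st_.median_cutoff for t in totals)
        assert abs(n_opt - n_sub) <= ties + len(totals) % 2


class TestCohensD:
    @pytest.mark.parametrize(
        "summaries, expected",
        [
            ((53.09, 7.57, 106, 57.02, 10.43, 111), 0.43),  # age
            ((142.06, 22.86, 106, 149.70, 25.31, 111), 0.32),  # systolic BP
        ],
    )
    def test_published_effect_sizes(self, summaries, expected):
        assert round(cohens_d(*summaries), 2) == expected

    def test_equal_means_give_zero(self):
        assert cohens_d(5.0, 1.0, 10, 5.0, 3.0, 12) == 0.0

    def test_zero_pooled_sd_with_unequal_means_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            cohens_d(1.0, 0.0, 5, 2.0, 0.0, 5)

    @given(
        m1=st.floats(-50, 50), m2=st.floats(-50, 50),
        s1=st.floats(0.1, 20), s2=st.floats(0.1, 20),
        n1=st.integers(2, 500), n2=st.integers(2, 500),
        c=st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_scale_invariance(self, m1, m2, s1, s2, n1, n2, c):
        d = cohens_d(m1, s1, n1, m2, s2, n2)
        d_swapped = cohens_d(m2, s2, n2, m1, s1, n1)
        d_scaled = cohens_d(c * m1, c * s1, n1, c * m2, c * s2, n2)
        assert d == pytest.approx(d_swapped, rel=1e-9)
        assert d == pytest.approx(d_scaled, rel=1e-6)

    def test_label_bands(self):
        assert effect_size_label(0.1) == "negligible"
        assert effect_size_label(0.43) == "small"
        assert effect_size_label(0.6) == "medium"
        assert effect_size_label(1.2) == "large"


class TestCompareGroups:
    def _with_covariates(self, values, status):
        n = len(values)
        rng = np.random.default_rng(0)
        ratings = rng.integers(0, 5, (n, 25))
        cov = pd.DataFrame({"v": values}, index=[f"r{i}" for i in range(n)])
        m = _matrix(ratings, covariates=cov)
        return m, pd.Series(status, index=cov.index)

    def test_published_age_comparison_from_raw_data(self):
        # construct raw groups whose summaries match the published ones
        rng = np.random.default_rng(5)

        def sample(mean, sd, n):
            x = rng.standard_normal(n)
            return mean + sd * (x - x.mean()) / x.std(ddof=1)

        a = sample(53.09, 7.57, 106)
        b = sample(57.02, 10.43, 111)
        m, status = self._with_covariates(
            np.concatenate([a, b]), ["optimal"] * 106 + ["suboptimal"] * 111
        )
        res = compare_groups(m, "v", status=status)
        assert res.statistic == pytest.approx(3.16, abs=0.01)
        assert res.df == 215
        assert res.p_value == pytest.approx(0.002, abs=5e-4)
        assert round(res.cohens_d, 2) == 0.43

    def test_gender_contingency_matches_hand_chi_square(self):
        # oracle: sum((O-E)^2/E) over the 2x2 published gender table
        table = np.array([[59.0, 47.0], [74.0, 37.0]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2_hand = float(((table - expected) ** 2 / expected).sum())

        values = (["F"] * 59 + ["M"] * 47) + (["F"] * 74 + ["M"] * 37)
        m, status = self._with_covariates(
            values, ["optimal"] * 106 + ["suboptimal"] * 111
        )
        res = compare_groups(m, "v", status=status)
        assert res.statistic == pytest.approx(chi2_hand, rel=1e-12)
        assert chi2_hand == pytest.approx(2.77, abs=0.01)
        assert res.p_value == pytest.approx(0.096, abs=5e-3)

    def test_identical_distributions_null_result(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        m, status = self._with_covariates(values, ["optimal"] * 3 + ["suboptimal"] * 3)
        res = compare_groups(m, "v", status=status)
        assert res.cohens_d == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_pooled_t_consistent_with_d(self):
        t, df, _ = pooled_t_from_summaries(53.09, 7.57, 106, 57.02, 10.43, 111)
        d = cohens_d(53.09, 7.57, 106, 57.02, 10.43, 111)
        assert abs(t) * np.sqrt(1 / 106 + 1 / 111) == pytest.approx(d, rel=1e-12)
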