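"""Normalization, differential testing, temporal and presence summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from trio_mirnet.expression import (
    classify_temporal_pattern,
    compute_fpkm,
    expression_membership,
    five_number_summary,
    log2fc_ddct,
    normalize_rpm,
    test_differential as run_differential,
    venn_region_counts,
)
from trio_mirnet.types import AbundanceMatrix, LibraryMeta, design_frame


def matrix_from_values(values: pd.DataFrame, metas=None) -> AbundanceMatrix:
    if metas is None:
        metas = [
            LibraryMeta(c, "TG", "CG", 5, i + 1) for i, c in enumerate(values.columns)
        ]
    return AbundanceMatrix(values=values, meta=design_frame(metas), unit="raw_count")


def welch_oracle(a, b):
    """Textbook Welch t-test: statistic, Satterthwaite df, two-sided p."""
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * stats.t.sf(abs(t), df)


class TestNormalization:
    def test_rpm_arithmetic(self):
        values = pd.DataFrame({"L1": [200, 1_999_800]}, index=["f1", "f2"])
        rpm = normalize_rpm(matrix_from_values(values))
        assert rpm.values.loc["f1", "L1"] == pytest.approx(100.0)
        assert rpm.unit == "RPM"

    def test_single_feature_library_gets_one_million(self):
        values = pd.DataFrame({"L1": [37]}, index=["f1"])
        rpm = normalize_rpm(matrix_from_values(values))
        assert rpm.values.loc["f1", "L1"] == pytest.approx(1e6)

    def test_rpm_column_sums_are_one_million(self, rng):
        values = pd.DataFrame(
            rng.integers(0, 500, size=(40, 6)) + 1,
            index=[f"f{i}" for i in range(40)],
            columns=[f"L{i}" for i in range(6)],
        )
        rpm = normalize_rpm(matrix_from_values(values))
        np.testing.assert_allclose(rpm.values.sum(axis=0), 1e6)

    def test_zero_total_library_raises_naming_it(self):
        values = pd.DataFrame({"L1": [1, 2], "L2": [0, 0]}, index=["f1", "f2"])
        with pytest.raises(ValueError, match="L2"):
            normalize_rpm(matrix_from_values(values))

    def test_fpkm_closed_form(self):
        values = pd.DataFrame({"L1": [100, 999_900]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 2000, "g2": 1000})
        fpkm = compute_fpkm(matrix_from_values(values), lengths)
        assert fpkm.values.loc["g1", "L1"] == pytest.approx(50.0)

    def test_fpkm_of_zero_count_is_zero(self):
        values = pd.DataFrame({"L1": [0, 10]}, index=["g1", "g2"])
        lengths = pd.Series({"g1": 500, "g2": 500})
        fpkm = compute_fpkm(matrix_from_values(values), lengths)
        assert fpkm.values.loc["g1", "L1"] == 0.0

    def test_missing_length_raises(self):
        values = pd.DataFrame({"L1": [1, 2]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="g2"):
            compute_fpkm(matrix_from_values(values), pd.Series({"g1": 100}))

    def test_five_number_summary_equals_order_statistics(self):
        col = [3.0, 1.0, 4.0, 1.5, 9.0]
        summary = five_number_summary(col)
        ordered = sorted(col)
        assert summary["min"] == ordered[0]
        assert summary["median"] == ordered[2]
        assert summary["max"] == ordered[-1]
        assert summary["q1"] == np.percentile(col, 25)
        assert summary["q3"] == np.percentile(col, 75)


class TestDifferential:
    def _matrix(self, rows: dict, n_per_group=3):
        metas = [LibraryMeta(f"A{r}", "TG", "WS", 5, r) for r in range(1, n_per_group + 1)]
        metas += [LibraryMeta(f"B{r}", "TG", "CG", 5, r) for r in range(1, n_per_group + 1)]
        values = pd.DataFrame(rows, index=[m.library_id for m in metas]).T
        return matrix_from_values(values, metas)

    def test_welch_p_matches_textbook_formula(self):
        matrix = self._matrix({"f": [10, 12, 11, 20, 22, 21]})
        res = run_differential(
            matrix,
            {"A": ["A1", "A2", "A3"], "B": ["B1", "B2", "B3"]},
            method="welch_t",
            log_transform=False,
        )
        expected = welch_oracle([10, 12, 11], [20, 22, 21])
        assert res["p_value"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_identical_groups_have_zero_log2fc(self):
        matrix = self._matrix({"f": [5, 9, 7, 5, 9, 7]})
        res = run_differential(
            matrix, {"A": ["A1", "A2", "A3"], "B": ["B1", "B2", "B3"]}
        )
        assert res["log2fc"].iloc[0] == 0.0

    def test_replicate_permutation_within_groups_leaves_p_unchanged(self, rng):
        rows = {f"f{i}": rng.poisson(50, 6) for i in range(30)}
        matrix = self._matrix(rows)
        groups = {"A": ["A1", "A2", "A3"], "B": ["B1", "B2", "B3"]}
        permuted = {"A": ["A3", "A1", "A2"], "B": ["B2", "B3", "B1"]}
        for method in ("moderated_t", "welch_t", "student_t"):
            r1 = run_differential(matrix, groups, method=method)
            r2 = run_differential(matrix, permuted, method=method)
            np.testing.assert_allclose(r1["p_value"], r2["p_value"])

    def test_all_zero_feature_gets_p_one_and_zero_fold_change(self, rng):
        rows = {"null": [0, 0, 0, 0, 0, 0]}
        rows.update({f"f{i}": rng.poisson(20, 6) for i in range(10)})
        matrix = self._matrix(rows)
        res = run_differential(
            matrix, {"A": ["A1", "A2", "A3"], "B": ["B1", "B2", "B3"]}
        ).set_index("feature_id")
        assert res.loc["null", "p_value"] == 1.0
        assert res.loc["null", "log2fc"] == 0.0

    def test_bh_q_values_bound_p_and_respect_rank_monotonicity(self, rng):
        rows = {f"f{i}": rng.poisson(40, 6) for i in range(60)}
        matrix = self._matrix(rows)
        res = run_differential(
            matrix, {"A": ["A1", "A2", "A3"], "B": ["B1", "B2", "B3"]}
        ).sort_values("p_value")
        assert (res["q_value"] >= res["p_value"] - 1e-12).all()
        assert (res["q_value"] <= 1.0).all()
        assert res["q_value"].is_monotonic_increasing

    def test_anova_used_for_more_than_two_groups(self):
        metas = [
            LibraryMeta(f"{t}{r}", "TG", t, 5, r)
            for t in ("CG", "WS", "HS")
            for r in (1, 2)
        ]
        values = pd.DataFrame(
            {"f": [1.0, 2.0, 8.0, 9.0, 1.5, 2.5]},
            index=[m.library_id for m in metas],
        ).T
        matrix = matrix_from_values(values, metas)
        res = run_differential(
            matrix,
            {"CG": ["CG1", "CG2"], "WS": ["WS1", "WS2"], "HS": ["HS1", "HS2"]},
        )
        assert res["test"].iloc[0] == "anova"
        assert res["log2fc"].iloc[0] == 0.0

    def test_single_replicate_group_raises(self):
        matrix = self._matrix({"f": [1, 2, 3, 4, 5, 6]})
        with pytest.raises(ValueError, match="<2 replicates"):
            run_differential(matrix, {"A": ["A1"], "B": ["B1", "B2"]})


class TestTemporalClassification:
    @pytest.mark.parametrize(
        "profile, expected",
        [
            ([100, 80, 60, 40, 20], "descending"),
            ([10, 20, 40, 80, 160], "ascending"),
            ([10, 50, 20, 5, 1], "peak_15"),
            ([1, 5, 50, 20, 10], "peak_25"),
            ([1, 5, 20, 50, 10], "peak_35"),
            ([5, 5, 5, 5, 5], "other"),
            ([100, 80, 60, 40, 60], "other"),
        ],
    )
    def test_pattern_examples(self, profile, expected):
        assert classify_temporal_pattern(profile) == expected

    def test_small_end_to_end_change_is_not_a_trend(self):
        # monotone but under the two-fold end-to-end change requirement
        assert classify_temporal_pattern([100, 95, 90, 85, 80]) == "other"

    @given(
        st.lists(
            st.floats(0.1, 1e6, allow_nan=False, allow_infinity=False),
            min_size=5,
            max_size=5,
        ),
        st.floats(0.001, 1000.0),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_scale_invariance(self, profile, factor):
        scaled = [v * factor for v in profile]
        assert classify_temporal_pattern(profile) == classify_temporal_pattern(scaled)

    def test_wrong_arity_raises(self):
        with pytest.raises(ValueError, match="5 values|expected 5"):
            classify_temporal_pattern([1, 2, 3])


class TestMembership:
    def _matrix(self):
        metas = [
            LibraryMeta(f"{t}{r}", "TG", t, 5, r)
            for t in ("CG", "WS", "HS", "WH")
            for r in (1, 2)
        ]
        # planted presence design: f_cg only in CG; f_all everywhere;
        # f_ws_hs in WS and HS; f_nowhere silent
        rows = {
            "f_cg": [5, 3, 0, 0, 0, 0, 0, 0],
            "f_all": [1, 1, 2, 2, 3, 3, 4, 4],
            "f_ws_hs": [0, 0, 7, 1, 2, 2, 0, 0],
            "f_nowhere": [0] * 8,
        }
        values = pd.DataFrame(rows, index=[m.library_id for m in metas]).T
        return matrix_from_values(values, metas)

    def test_membership_matches_planted_design(self):
        membership = expression_membership(self._matrix(), by="treatment")
        assert membership["f_cg"] == frozenset({"CG"})
        assert membership["f_all"] == frozenset({"CG", "WS", "HS", "WH"})
        assert membership["f_ws_hs"] == frozenset({"WS", "HS"})
        assert membership["f_nowhere"] == frozenset()

    def test_venn_region_counts_match_planted_design(self):
        counts = venn_region_counts(expression_membership(self._matrix()))
        assert counts[("CG",)] == 1
        assert counts[("CG", "HS", "WH", "WS")] == 1
        assert counts[("HS", "WS")] == 1
        assert sum(counts.values()) == 3  # silent features are not counted

    def test_presence_threshold_excludes_weak_signal(self):
        membership = expression_membership(
            self._matrix(), by="treatment", presence_threshold=4.0
        )
        assert membership["f_all"] == frozenset()
        assert membership["f_ws_hs"] == frozenset({"WS"})


class TestDdct:
    @pytest.mark.parametrize(
        "cts, expected",
        [
            ((20, 18, 22, 20), 0.0),  # ddCt = 0
            ((24, 20, 25, 20), 1.0),  # ddCt = -1 -> two-fold up
            ((26, 20, 25, 20), -1.0),  # ddCt = +1 -> two-fold down
        ],
    )
    def test_convention(self, cts, expected):
        assert log2fc_ddct(*cts) == pytest.approx(expected)

    def test_non_finite_ct_raises(self):
        with pytest.raises(ValueError):
            log2fc_ddct(float("nan"), 20, 25, 20)
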