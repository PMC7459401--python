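"""Student's t-test and the differential/significant selection cascade."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from tardilfq.select import (
    SelectionConfig,
    apply_strict_criteria,
    cascade_counts,
    classify_differential,
    normalize_to_untreated,
    select_significant,
    student_t_test,
    triplicate_filter,
)


def make_manifest():
    return pd.DataFrame(
        {
            "run": [f"{g}_{j}" for g in ("untreated", "vehicle", "treatment") for j in (1, 2, 3)],
            "group": [g for g in ("untreated", "vehicle", "treatment") for _ in (1, 2, 3)],
            "replicate": [1, 2, 3] * 3,
        }
    )


def make_matrix(rows: dict[str, list[float]]) -> pd.DataFrame:
    """Protein matrix from 9 values per protein (untreated, vehicle, treatment)."""
    cols = [f"{g}_{j}" for g in ("untreated", "vehicle", "treatment") for j in (1, 2, 3)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).rename_axis(
        "protein"
    )


class TestStudentT:
    def test_identical_groups(self):
        r = student_t_test([1, 1, 1], [1, 1, 1])
        assert r.statistic == 0.0
        assert r.pvalue == 1.0
        assert not r.degenerate

    def test_textbook_example(self):
        """(1,2,3) vs (4,5,6): t = -3/sqrt(2/3), df = 4, p ~ 0.0213."""
        r = student_t_test([1, 2, 3], [4, 5, 6])
        assert r.statistic == pytest.approx(-3.674234614, abs=1e-8)
        assert r.df == 4
        assert r.pvalue == pytest.approx(0.021311641, abs=1e-8)

    def test_degenerate_variance_unequal_means(self):
        r = student_t_test([1, 1, 1], [2, 2, 2])
        assert r.pvalue == 0.0
        assert r.degenerate

    def test_sample_too_small(self):
        with pytest.raises(ValueError):
            student_t_test([1.0], [1, 2, 3])

    def test_incomplete_beta_oracle(self):
        """p-values match the incomplete-beta closed form to 1e-8.

        For the equal-variance t with df degrees of freedom the two-sided
        p-value is I_{df/(df+t^2)}(df/2, 1/2) — an independent route
        through the regularized incomplete beta function.
        """
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            na, nb = rng.integers(2, 8, size=2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), size=na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), size=nb)
            r = student_t_test(a, b)
            p_oracle = special.betainc(r.df / 2, 0.5, r.df / (r.df + r.statistic**2))
            assert abs(r.pvalue - p_oracle) < 1e-8

    def test_welch_differs_under_unequal_variance(self):
        a = [1.0, 1.1, 0.9, 1.05]
        b = [2.0, 4.0, 0.5]
        assert student_t_test(a, b, welch=True).df != student_t_test(a, b).df


class TestTriplicateFilter:
    def test_fully_quantified_is_tested(self):
        m = make_matrix({"A": [1.0] * 9})
        assert triplicate_filter(m, make_manifest()).loc["A"]

    def test_one_missing_vehicle_rep_is_not_tested(self):
        vals = [1.0] * 9
        vals[4] = np.nan  # vehicle_2
        m = make_matrix({"A": vals})
        assert not triplicate_filter(m, make_manifest()).loc["A"]

    def test_mask_count_oracle_on_random_dropout(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0.5, 2.0, size=(40, 9))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        m = make_matrix({f"P{i}": list(vals[i]) for i in range(40)})
        mask = triplicate_filter(m, make_manifest())
        oracle = ~np.isnan(vals).any(axis=1)
        assert (mask.to_numpy() == oracle).all()


class TestClassification:
    def test_treatment_only_change_is_differential(self):
        m = make_matrix({"A": [1.0, 1.1, 0.9, 1.05, 0.95, 1.0, 3.0, 3.2, 2.8]})
        res = classify_differential(m, make_manifest())
        assert res.loc["A", "p_treatment"] < 0.05
        assert res.loc["A", "p_vehicle"] >= 0.05
        assert res.loc["A", "class"] == "differentially_regulated"

    def test_vehicle_also_significant_stays_tested(self):
        m = make_matrix({"A": [1.0, 1.1, 0.9, 3.1, 2.9, 3.0, 3.0, 3.2, 2.8]})
        res = classify_differential(m, make_manifest())
        assert res.loc["A", "p_vehicle"] < 0.05
        assert res.loc["A", "class"] == "tested"

    def test_fold_changes_are_mean_ratios(self):
        m = make_matrix({"A": [1.0, 1.0, 1.0, 1.2, 1.2, 1.2, 2.5, 2.5, 2.5]})
        res = classify_differential(m, make_manifest())
        assert res.loc["A", "fc_treatment"] == pytest.approx(2.5)
        assert res.loc["A", "fc_vehicle"] == pytest.approx(1.2)

    def test_untested_protein_has_no_pvalues(self):
        vals = [1.0] * 9
        vals[0] = np.nan
        m = make_matrix({"A": vals})
        res = classify_differential(m, make_manifest())
        assert res.loc["A", "class"] == "not_tested"
        assert np.isnan(res.loc["A", "p_treatment"])


class TestStrictCriteria:
    """Criteria act on classified rows: fold bounds + closed vehicle band."""

    @staticmethod
    def _row(fc_t, fc_v, cls="differentially_regulated"):
        return pd.DataFrame(
            {"fc_treatment": [fc_t], "fc_vehicle": [fc_v], "class": [cls]},
            index=pd.Index(["A"], name="protein"),
        )

    @pytest.mark.parametrize(
        "fc_t,fc_v,expected",
        [
            (2.5, 1.1, "significant_up"),
            (2.5, 1.3, "differentially_regulated"),  # vehicle outside band
            (0.3, 0.95, "significant_down"),
            (2.0, 1.0, "differentially_regulated"),  # 2-fold is strictly >
            (0.5, 1.0, "differentially_regulated"),  # and strictly <
            (2.5, 0.8, "significant_up"),  # band closed at both ends
            (0.4, 1.2, "significant_down"),
        ],
    )
    def test_threshold_logic(self, fc_t, fc_v, expected):
        res = apply_strict_criteria(self._row(fc_t, fc_v))
        assert res.loc["A", "class"] == expected

    def test_only_differential_rows_upgraded(self):
        res = apply_strict_criteria(self._row(3.0, 1.0, cls="tested"))
        assert res.loc["A", "class"] == "tested"

    def test_end_to_end_up_call(self):
        u = [1.0, 1.05, 0.95]
        m = make_matrix(
            {"A": u + [1.1 * x for x in u] + [2.5 * x for x in u]}
        )
        res = apply_strict_criteria(classify_differential(m, make_manifest()))
        assert res.loc["A", "p_vehicle"] >= 0.05
        assert res.loc["A", "class"] == "significant_up"

    def test_sorted_by_abs_log2_fold_change(self):
        u = [1.0, 1.02, 0.98]
        rows = {
            "UP": u + u + [2.6 * x for x in u],
            "DOWN": u + u + [0.2 * x for x in u],
        }
        res = apply_strict_criteria(
            classify_differential(make_matrix(rows), make_manifest())
        )
        sig = select_significant(res)
        assert list(sig.index) == ["DOWN", "UP"]  # |log2 0.2| > |log2 2.6|


class TestNormalizeToUntreated:
    def test_reference_group_reports_one_and_sds_rescale(self):
        m = make_matrix({"A": [2.0, 2.2, 1.8, 2.2, 2.42, 1.98, 4.0, 4.4, 3.6]})
        res = classify_differential(m, make_manifest())
        rel = normalize_to_untreated(res)
        assert rel.loc["A", "rel_mean_untreated"] == pytest.approx(1.0)
        assert rel.loc["A", "rel_mean_treatment"] == pytest.approx(2.0)
        ref_mean = res.loc["A", "mean_untreated"]
        assert rel.loc["A", "rel_sd_vehicle"] == pytest.approx(
            res.loc["A", "sd_vehicle"] / ref_mean
        )


class TestCascadeProperties:
    def _random_world(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.lognormal(0.0, 0.3, size=(80, 9))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        # a few planted effects of both kinds
        vals[:5, 6:] *= 4.0
        vals[5:8, 3:] *= 4.0
        return make_matrix({f"P{i}": list(vals[i]) for i in range(80)})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cascade_nesting(self, seed):
        m = self._random_world(seed)
        res = apply_strict_criteria(classify_differential(m, make_manifest()))
        c = cascade_counts(res)
        assert (
            c["significant"]
            <= c["differentially_regulated"]
            <= c["tested"]
            <= c["detected"]
        )
        cls = res["class"]
        sig = cls.isin(["significant_up", "significant_down"])
        assert (res.loc[sig, "p_treatment"] < 0.05).all()
        assert (res.loc[sig, "p_vehicle"] >= 0.05).all()

    def test_tightening_thresholds_never_adds_calls(self):
        m = self._random_world(3)
        base_cfg = SelectionConfig()
        base = apply_strict_criteria(classify_differential(m, make_manifest()), base_cfg)
        base_sig = set(select_significant(base).index)
        for cfg in (
            SelectionConfig(fc_threshold=3.0),
            SelectionConfig(vehicle_band=(0.9, 1.1)),
            SelectionConfig(fc_threshold=2.5, vehicle_band=(0.85, 1.15)),
        ):
            res = apply_strict_criteria(classify_differential(m, make_manifest(), cfg), cfg)
            assert set(select_significant(res).index) <= base_sig

    def test_invariant_to_run_relabeling_within_group(self):
        m = self._random_world(4)
        res_a = apply_strict_criteria(classify_differential(m, make_manifest()))
        # swap two untreated replicates and two treatment replicates
        swapped = m.rename(
            columns={
                "untreated_1": "untreated_2",
                "untreated_2": "untreated_1",
                "treatment_1": "treatment_3",
                "treatment_3": "treatment_1",
            }
        )
        res_b = apply_strict_criteria(classify_differential(swapped, make_manifest()))
        assert (res_a["class"] == res_b["class"]).all()
        pd.testing.assert_series_equal(res_a["p_treatment"], res_b["p_treatment"])


class TestSelectionConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0.0},
            {"alpha": 1.5},
            {"fc_threshold": 1.0},
            {"vehicle_band": (1.1, 1.2)},
            {"fc_method": "harmonic"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SelectionConfig(**kwargs)
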