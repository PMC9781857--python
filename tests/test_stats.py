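"""Factorial ANOVA, t-tests, Tukey post hoc, and the summary-statistics oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fgng.errors import DegenerateDataError, DesignError, DomainError
from fgng.stats import (
    AnimalRecord,
    anova_from_summary,
    independent_t_test,
    tukey_hsd,
    two_way_anova,
)

#: post-intervention per-cell summaries of the reference cohort (percent)
REFERENCE_POST_SUMMARY = pd.DataFrame(
    {
        "feeding": ["AL", "AL", "CR", "CR"],
        "injury": ["Con", "TBI", "Con", "TBI"],
        "mean": [62.64, 59.85, 79.83, 79.10],
        "sd": [6.33, 5.01, 4.43, 4.52],
        "n": [3, 6, 6, 5],
    }
)


def _frame(cells: dict[tuple[str, str], list[float]]) -> pd.DataFrame:
    rows = [
        {"feeding": f, "injury": i, "fgng": v}
        for (f, i), values in cells.items()
        for v in values
    ]
    return pd.DataFrame(rows)


def _random_unbalanced(rng: np.random.Generator) -> pd.DataFrame:
    ns = {"AL-Con": 3, "AL-TBI": 6, "CR-Con": 6, "CR-TBI": 5}
    return _frame(
        {
            (c.split("-")[0], c.split("-")[1]): rng.uniform(0.2, 0.9, n).tolist()
            for c, n in ns.items()
        }
    )


class TestTwoWayAnova:
    def test_additive_cell_means_have_zero_interaction(self):
        # means 0.2/0.4 along feeding plus 0/0.1 along injury, replicated
        df = _frame(
            {
                ("AL", "Con"): [0.2, 0.2],
                ("AL", "TBI"): [0.3, 0.3],
                ("CR", "Con"): [0.4, 0.4],
                ("CR", "TBI"): [0.5, 0.5],
            }
        )
        table = two_way_anova(df)
        assert table["interaction"].sum_sq == pytest.approx(0.0, abs=1e-12)

    def test_hand_decomposition_with_zero_residual(self):
        # factor A separates {0,0,0,0} from {1,1,1,1}: SS_A = 8 * 0.25 = 2
        df = _frame(
            {
                ("AL", "Con"): [0.0, 0.0],
                ("AL", "TBI"): [0.0, 0.0],
                ("CR", "Con"): [1.0, 1.0],
                ("CR", "TBI"): [1.0, 1.0],
            }
        )
        table = two_way_anova(df)
        assert table["feeding"].sum_sq == pytest.approx(2.0, abs=1e-12)
        assert table["residual"].sum_sq == pytest.approx(0.0, abs=1e-12)
        # boundary case: zero residual variance reported as F=inf, p=0
        assert np.isinf(table["feeding"].F)
        assert table["feeding"].p == 0.0

    def test_balanced_design_matches_cell_means_oracle(self, rng):
        df = _frame(
            {
                (f, i): rng.normal(0.5, 0.1, 4).tolist()
                for f in ("AL", "CR")
                for i in ("Con", "TBI")
            }
        )
        table = two_way_anova(df)
        # brute-force balanced decomposition from marginal means
        y = df["fgng"].to_numpy()
        ma = df.groupby("feeding")["fgng"].mean()
        mb = df.groupby("injury")["fgng"].mean()
        mab = df.groupby(["feeding", "injury"])["fgng"].mean()
        grand = y.mean()
        n_cell = 4
        ss_a = 2 * n_cell * float(((ma - grand) ** 2).sum())
        ss_b = 2 * n_cell * float(((mb - grand) ** 2).sum())
        ss_ab = n_cell * float(
            sum(
                (mab[(f, i)] - ma[f] - mb[i] + grand) ** 2
                for f in ("AL", "CR")
                for i in ("Con", "TBI")
            )
        )
        assert table["feeding"].sum_sq == pytest.approx(ss_a, abs=1e-9)
        assert table["injury"].sum_sq == pytest.approx(ss_b, abs=1e-9)
        assert table["interaction"].sum_sq == pytest.approx(ss_ab, abs=1e-9)
        # SS decomposition closes on the balanced design
        total = float(((y - grand) ** 2).sum())
        parts = (
            table["feeding"].sum_sq
            + table["injury"].sum_sq
            + table["interaction"].sum_sq
            + table["residual"].sum_sq
        )
        assert parts == pytest.approx(total, abs=1e-9)

    def test_empty_cell_raises_naming_the_cell(self):
        df = _frame(
            {
                ("AL", "Con"): [0.2, 0.3],
                ("AL", "TBI"): [0.3, 0.4],
                ("CR", "Con"): [0.5, 0.6],
            }
        )
        with pytest.raises(DesignError, match="CR.*TBI"):
            two_way_anova(df)

    def test_accepts_animal_records(self):
        records = [
            AnimalRecord(f"a{k}", f, i, "post", v)
            for k, (f, i, v) in enumerate(
                [
                    ("AL", "Con", 0.60),
                    ("AL", "Con", 0.65),
                    ("AL", "TBI", 0.58),
                    ("AL", "TBI", 0.62),
                    ("CR", "Con", 0.80),
                    ("CR", "Con", 0.78),
                    ("CR", "TBI", 0.79),
                    ("CR", "TBI", 0.81),
                ]
            )
        ]
        table = two_way_anova(records)
        assert table["feeding"].p < 0.001

    def test_record_vocabulary_enforced(self):
        with pytest.raises(DomainError):
            AnimalRecord("a", "ad-lib", "Con", "post", 0.5)


class TestIndependentTTest:
    def test_identical_groups(self):
        res = independent_t_test([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_hand_computed_pooled_t(self):
        # means 2 vs 5, pooled var 1, se = sqrt(2/3)
        res = independent_t_test([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3 / np.sqrt(2 / 3), rel=1e-12)
        assert res.df == 4
        assert res.p == pytest.approx(2 * sps.t.sf(3 / np.sqrt(2 / 3), 4), rel=1e-12)

    def test_zero_variance_unequal_means_raises(self):
        with pytest.raises(DegenerateDataError):
            independent_t_test([1.0, 1.0], [2.0, 2.0])

    def test_too_small_groups_raise(self):
        with pytest.raises(DegenerateDataError):
            independent_t_test([1.0], [2.0, 3.0])

    def test_welch_differs_under_variance_heterogeneity(self):
        a = [0.1, 0.2, 0.3, 0.4]
        b = [0.0, 1.0, 2.0]
        student = independent_t_test(a, b, variant="student")
        welch = independent_t_test(a, b, variant="welch")
        assert student.df == 5
        assert welch.df < student.df

    def test_t_squared_equals_one_way_f(self, rng):
        a = rng.normal(0.4, 0.05, 7)
        b = rng.normal(0.6, 0.05, 9)
        t = independent_t_test(a, b)
        f = sps.f_oneway(a, b)
        assert t.t**2 == pytest.approx(f.statistic, rel=1e-9)
        assert t.p == pytest.approx(f.pvalue, rel=1e-9)


class TestTukey:
    def test_identical_constant_cells_all_p_one(self):
        df = _frame({(f, i): [0.5, 0.5] for f in ("AL", "CR") for i in ("Con", "TBI")})
        out = tukey_hsd(df)
        assert (out["p_adj"] == 1.0).all()

    def test_separated_pair_significant_coincident_pair_not(self, rng):
        df = _frame(
            {
                ("AL", "Con"): (0.20 + rng.normal(0, 0.005, 5)).tolist(),
                ("AL", "TBI"): (0.20 + rng.normal(0, 0.005, 5)).tolist(),
                ("CR", "Con"): (0.80 + rng.normal(0, 0.005, 5)).tolist(),
                ("CR", "TBI"): (0.80 + rng.normal(0, 0.005, 5)).tolist(),
            }
        )
        out = tukey_hsd(df).set_index(["group1", "group2"])
        assert out.loc[("AL:Con", "CR:Con"), "p_adj"] < 0.001
        assert out.loc[("AL:Con", "AL:TBI"), "p_adj"] > 0.05
        assert not out.loc[("AL:Con", "AL:TBI"), "reject"]


class TestAnovaFromSummary:
    def test_roundtrip_matches_raw_two_way_anova(self, rng):
        """Summary-only route equals the raw-data route on unbalanced designs."""
        for _ in range(5):
            df = _random_unbalanced(rng)
            raw = two_way_anova(df)
            summ = (
                df.groupby(["feeding", "injury"])["fgng"]
                .agg(mean="mean", sd="std", n="count")
                .reset_index()
            )
            from_summary = anova_from_summary(summ)
            for effect in ("feeding", "injury", "interaction", "residual"):
                assert from_summary[effect].sum_sq == pytest.approx(
                    raw[effect].sum_sq, abs=1e-9
                )
                if raw[effect].p is not None:
                    assert from_summary[effect].p == pytest.approx(raw[effect].p, abs=1e-9)

    def test_equal_cell_means_give_zero_effect_ss(self):
        summ = pd.DataFrame(
            {
                "feeding": ["AL", "AL", "CR", "CR"],
                "injury": ["Con", "TBI", "Con", "TBI"],
                "mean": [0.5] * 4,
                "sd": [0.05] * 4,
                "n": [3, 6, 6, 5],
            }
        )
        table = anova_from_summary(summ)
        for effect in ("feeding", "injury", "interaction"):
            assert table[effect].sum_sq == pytest.approx(0.0, abs=1e-12)

    def test_reference_cell_summaries_show_feeding_effect(self):
        """The printed post-intervention summaries imply a strong feeding
        effect (p < 0.001) and no injury or interaction effect."""
        table = anova_from_summary(REFERENCE_POST_SUMMARY)
        assert table["feeding"].p < 0.001
        assert table["injury"].p > 0.05
        assert table["interaction"].p > 0.05

    def test_small_cells_raise(self):
        summ = REFERENCE_POST_SUMMARY.copy()
        summ.loc[0, "n"] = 1
        with pytest.raises(DegenerateDataError):
            anova_from_summary(summ)
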