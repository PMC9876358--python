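"""Productivity index, sensitivity ANOVA, repeatability ICC and rank tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from larvatray import (
    eta_squared,
    kruskal_dunn,
    productivity,
    productivity_table,
    repeatability_icc,
    sensitivity_analysis,
    simulated_productivity,
)
from larvatray.lifehistory import LifeHistoryError, SENSITIVITY_SCENARIOS
from larvatray.simulate import container_via_development_config, generate_lifehistory


class TestProductivity:
    def test_unit_log_argument_gives_zero(self):
        for d in (1.0, 5.0, 12.0):
            assert productivity(0.1, 0.1, d) == pytest.approx(0.0, abs=1e-12)  # 100*0.1*0.1 = 1

    def test_reference_value(self):
        assert productivity(80, 0.9, 9) == pytest.approx(math.log(7200) / 9, rel=1e-12)
        assert productivity(80, 0.9, 9) == pytest.approx(0.9869, abs=5e-5)

    def test_doubling_development_halves_pi(self):
        assert productivity(80, 0.9, 18) == pytest.approx(productivity(80, 0.9, 9) / 2)

    def test_alternative_formula_variant(self):
        assert productivity(80, 0.9, 9, formula="lnfs") == pytest.approx(
            math.log(72) / 9, rel=1e-12
        )

    def test_domain_errors_and_negative_warning(self):
        with pytest.raises(LifeHistoryError):
            productivity(0.0, 0.5, 9)
        with pytest.raises(LifeHistoryError):
            productivity(80, 0.9, 0)
        with pytest.warns(UserWarning):
            assert productivity(0.05, 0.1, 9) < 0  # 100*F*S = 0.5 < 1

    @given(
        f=st.floats(1.0, 300.0),
        s=st.floats(0.05, 1.0),
        d=st.floats(1.0, 30.0),
        bump=st.floats(0.01, 0.5),
    )
    def test_monotonicity(self, f, s, d, bump):
        """PI increases in F and S and decreases in D where 100*F*S > 1."""
        base = productivity(f, s, d)
        assert productivity(f * (1 + bump), s, d) > base
        if s * (1 + bump) <= 1:
            assert productivity(f, s * (1 + bump), d) > base
        assert productivity(f, s, d * (1 + bump)) < base


class TestProductivityTable:
    def test_single_tray(self):
        table = pd.DataFrame(
            {"Fecundity": [80.0], "Survival": [0.9], "Development": [9.0]}
        )
        out, errors = productivity_table(table)
        assert not errors
        assert out["PI"].iloc[0] == pytest.approx(0.9869, abs=5e-5)

    def test_identical_trays_identical_pi(self):
        table = pd.DataFrame(
            {"Fecundity": [70.0] * 4, "Survival": [0.8] * 4, "Development": [10.0] * 4}
        )
        out, _ = productivity_table(table)
        assert out["PI"].nunique() == 1

    def test_bad_rows_reported_and_skipped(self):
        table = pd.DataFrame(
            {
                "Fecundity": [80.0, np.nan, 70.0],
                "Survival": [0.9, 0.8, 0.7],
                "Development": [9.0, 9.0, -1.0],
            }
        )
        out, errors = productivity_table(table)
        assert {e["row"] for e in errors} == {1, 2}
        assert np.isnan(out["PI"].iloc[1]) and np.isnan(out["PI"].iloc[2])
        assert np.isfinite(out["PI"].iloc[0])


class TestEtaSquared:
    def test_ratio_arithmetic(self):
        assert eta_squared(91, 100) == pytest.approx(0.91)
        assert eta_squared(0, 100) == 0.0
        with pytest.raises(LifeHistoryError):
            eta_squared(1, 0)
        with pytest.raises(LifeHistoryError):
            eta_squared(101, 100)

    def test_two_group_eta_equals_squared_point_biserial(self, rng):
        """For a balanced two-group one-way layout, SS_between/SS_total equals
        the squared point-biserial correlation."""
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(1.0, 1.0, 20)
        values = np.concatenate([a, b])
        grand = values.mean()
        ss_between = 20 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
        ss_total = ((values - grand) ** 2).sum()
        r_pb = stats.pointbiserialr(np.repeat([0, 1], 20), values).statistic
        assert eta_squared(ss_between, ss_total) == pytest.approx(r_pb**2, rel=1e-9)


def _balanced_table(rng, n_rep=4):
    rows = []
    d_by_treat = {"Low": 9.0, "High": 12.0}
    for size in ("Small", "Medium", "Large"):
        for treat, d in d_by_treat.items():
            for rep in range(n_rep):
                rows.append(
                    (size, treat, rep + 1, d + rng.normal(0, 0.2), 0.85, 80.0)
                )
    return pd.DataFrame(
        rows, columns=["Size", "Density", "Replicate", "Development", "Survival", "Fecundity"]
    )


class TestSensitivity:
    def test_all_frozen_scenario_constant_pi_zero_eta(self, rng):
        table = _balanced_table(rng)
        pi = simulated_productivity(table, hold=("D", "S", "F"))
        assert pi.nunique() == 1
        report = sensitivity_analysis(table, scenarios={"DSF": ("D", "S", "F")})
        sub = report.table[report.table["scenario"] == "DSF"]
        assert (sub["eta_sq"] == 0).all()

    def test_treatment_effect_through_development_only(self, rng):
        """Only D differs by treatment: holding D kills the treatment effect,
        not holding it leaves a near-total treatment effect."""
        table = _balanced_table(rng)
        report = sensitivity_analysis(table)
        assert report.eta("none", "treatment") > 0.9
        assert report.eta("D", "treatment") < 0.05

    def test_unheld_scenario_matches_plain_anova_by_hand(self, rng):
        """η² of the unheld fit equals the sequential sums of squares computed
        directly from group means on a balanced design."""
        table = _balanced_table(rng)
        with_pi, _ = productivity_table(table)
        pi = with_pi["PI"].to_numpy()
        grand = pi.mean()
        ss_total = ((pi - grand) ** 2).sum()
        # balanced design: factor SS from cell/margin means
        ss_size = sum(
            (with_pi[with_pi["Size"] == s]["PI"].mean() - grand) ** 2 * 8
            for s in ("Small", "Medium", "Large")
        )
        ss_treat = sum(
            (with_pi[with_pi["Density"] == t]["PI"].mean() - grand) ** 2 * 12
            for t in ("Low", "High")
        )
        report = sensitivity_analysis(table)
        assert report.eta("none", "size") == pytest.approx(ss_size / ss_total, rel=1e-9)
        assert report.eta("none", "treatment") == pytest.approx(ss_treat / ss_total, rel=1e-9)

    def test_eta_decomposition_sums_to_one(self, rng):
        table = _balanced_table(rng)
        report = sensitivity_analysis(table)
        for scen in SENSITIVITY_SCENARIOS:
            sub = report.table[report.table["scenario"] == scen]
            total = sub["eta_sq"].sum()
            assert total == pytest.approx(1.0, rel=1e-9) or total == 0.0
            assert ((sub["eta_sq"] >= 0) & (sub["eta_sq"] <= 1)).all()

    def test_container_effect_via_development_collapses_when_d_held(self):
        """Container-size differences flowing only through development time
        vanish from the η² decomposition when D is frozen."""
        table = generate_lifehistory(container_via_development_config(seed=2))
        report = sensitivity_analysis(table)
        assert report.eta("none", "size") > 0.5
        assert report.eta("D", "size") < 0.05

    def test_empty_cell_rejected_by_name(self, rng):
        table = _balanced_table(rng)
        table = table[~((table["Size"] == "Small") & (table["Density"] == "High"))]
        with pytest.raises(LifeHistoryError, match="Small"):
            sensitivity_analysis(table)

    def test_summary_mentions_scenarios(self, rng):
        text = sensitivity_analysis(_balanced_table(rng)).summary()
        for scen in ("none", "'D'", "'SF'"):
            assert scen in text


class TestRepeatability:
    def test_pure_between_variance_gives_one(self):
        values = np.repeat([1.0, 5.0, 9.0, 13.0], 3)
        groups = np.repeat(np.arange(4), 3)
        res = repeatability_icc(values, groups, n_boot=50, seed=0)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_pure_within_noise_near_zero(self, rng):
        groups = np.repeat(np.arange(20), 3)
        values = rng.normal(0, 1, 60)
        res = repeatability_icc(values, groups, n_boot=50, seed=0)
        assert res.r < 0.25

    def test_variance_component_recovery(self):
        """Groups with between-variance 4 and within-variance 1 have true
        ICC 0.8; the estimate and its bootstrap CI recover it."""
        rng = np.random.default_rng(99)
        g, k = 40, 3
        means = rng.normal(0, 2.0, g)
        values = (means[:, None] + rng.normal(0, 1.0, (g, k))).ravel()
        groups = np.repeat(np.arange(g), k)
        res = repeatability_icc(values, groups, n_boot=500, seed=7)
        assert res.r == pytest.approx(0.8, abs=0.1)
        assert res.ci_low <= 0.8 <= res.ci_high

    def test_affine_invariance(self, rng):
        groups = np.repeat(np.arange(10), 3)
        values = rng.normal(0, 1, 30) + groups * 0.5
        r1 = repeatability_icc(values, groups, n_boot=20, seed=1).r
        r2 = repeatability_icc(3.7 * values - 11.0, groups, n_boot=20, seed=1).r
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_negative_estimate_clamped_and_flagged(self):
        # group means closer than chance: MSB < MSW
        values = np.array([0.0, 10.0, 0.1, 9.9, 0.05, 9.95])
        groups = np.array([0, 0, 1, 1, 2, 2])
        res = repeatability_icc(values, groups, n_boot=20, seed=0)
        assert res.r == 0.0 and res.clamped

    def test_matches_pingouin_icc1(self):
        """Cross-check the one-way ICC against pingouin's ICC1 on balanced data."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        g, k = 12, 3
        values = (rng.normal(0, 1.5, g)[:, None] + rng.normal(0, 1, (g, k))).ravel()
        groups = np.repeat(np.arange(g), k)
        df = pd.DataFrame(
            {"targets": groups, "raters": np.tile(np.arange(k), g), "ratings": values}
        )
        icc_table = pingouin.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="ratings"
        )
        icc1 = icc_table[icc_table["Type"].isin(["ICC1", "ICC(1,1)"])]["ICC"].iloc[0]
        ours = repeatability_icc(values, groups, n_boot=10, seed=0).r
        assert ours == pytest.approx(icc1, abs=1e-6)


class TestKruskalDunn:
    def test_fully_separated_rank_fixture(self):
        """Hand rank arithmetic: H = 12/(9·10)·(3·(2−5)² + 3·(5−5)² + 3·(8−5)²) = 7.2."""
        res = kruskal_dunn([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.h == pytest.approx(7.2, rel=1e-12)
        z = res.dunn.set_index(["group1", "group2"])["z"]
        assert z.loc[(0, 2)] == pytest.approx(-6 / math.sqrt(5), rel=1e-12)
        assert z.loc[(0, 1)] == pytest.approx(-3 / math.sqrt(5), rel=1e-12)

    def test_identical_groups_zero_z(self):
        res = kruskal_dunn([[1, 2, 3], [1, 2, 3]])
        assert res.dunn["z"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_all_values_identical_degenerate(self):
        res = kruskal_dunn([[5, 5], [5, 5], [5, 5]])
        assert res.h == 0.0 and res.p == 1.0

    def test_holm_adjustment_monotone(self):
        res = kruskal_dunn(
            [[1, 2, 3], [4, 5, 6], [7, 8, 9]], labels=["e", "i", "c"], adjust="holm"
        )
        assert (res.dunn["p_adj"] >= res.dunn["p"] - 1e-15).all()

    def test_permutation_null_type_one_error(self):
        """Permuting group labels preserves the null: asymptotic p < 0.05 in
        about 5% of 2000 permutations."""
        rng = np.random.default_rng(17)
        values = rng.normal(0, 1, 30)
        rejections = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(values)
            h, p = stats.kruskal(perm[:10], perm[10:20], perm[20:])
            rejections += p < 0.05
        assert abs(rejections / n_perm - 0.05) < 0.02
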