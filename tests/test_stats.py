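"""Statistics ladder: effect sizes, flags, routing, and report rendering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photoskin import stats

#: printed per-well means from the network and spreading tables, with the
#: annotation each pair carries (treated mean, reference mean, rounded %)
WORKED_EXAMPLES = [
    (259.69, 454.06, -43),   # network total length, stress vs untreated
    (0.356, 0.127, 180),     # trees per length, stress vs untreated
    (2.79, 8.79, -68),       # average tree length, stress vs untreated
    (1.33, 2.02, -34),       # average branch length, stress vs untreated
    (391.89, 259.69, 51),    # network total length, low dose vs stress
    (450.41, 259.69, 73),    # network total length, high dose vs stress
    (0.223, 0.356, -37),     # trees per length, low dose vs stress
    (0.190, 0.356, -47),     # trees per length, high dose vs stress
    (4.48, 2.79, 61),        # average tree length, low dose vs stress
    (5.40, 2.79, 94),        # average tree length, high dose vs stress
    (0.55, 0.68, -19),       # branches per length, low dose vs stress
    (1.72, 1.33, 29),        # average branch length, low dose vs stress
    (1886.6, 2088.71, -10),  # cell area, stress vs untreated
    (52.1, 69.96, -26),      # % spread cells, stress vs untreated
    (2257.17, 1886.6, 20),   # cell area, low dose vs stress
    (2239.48, 1886.6, 19),   # cell area, high dose vs stress
    (81.56, 52.1, 57),       # % spread cells, low dose vs stress
    (78.78, 52.1, 51),       # % spread cells, high dose vs stress
]


class TestPercentChange:
    @pytest.mark.parametrize("treated,reference,expected", WORKED_EXAMPLES)
    def test_worked_examples_from_well_means(self, treated, reference, expected):
        _, rounded = stats.percent_change(treated, reference)
        assert rounded == expected

    def test_identity_is_zero(self):
        assert stats.percent_change(3.7, 3.7) == (0.0, 0)

    def test_zero_reference_is_error(self):
        with pytest.raises(ValueError):
            stats.percent_change(1.0, 0.0)

    def test_half_rounds_away_from_zero(self):
        assert stats.percent_change(102.5, 100.0)[1] == 3
        assert stats.percent_change(97.5, 100.0)[1] == -3

    @given(
        st.floats(min_value=0.1, max_value=1e4),
        st.floats(min_value=0.1, max_value=1e4),
    )
    @settings(derandomize=True, max_examples=50)
    def test_antisymmetry(self, a, b):
        """If a vs b is +p%, then b vs a is -100 p / (100 + p) %."""
        p, _ = stats.percent_change(a, b)
        q, _ = stats.percent_change(b, a)
        assert q == pytest.approx(-100.0 * p / (100.0 + p), rel=1e-9)


class TestSignificanceFlag:
    @pytest.mark.parametrize(
        "p,flag",
        [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.07, "#"), (0.5, "ns"), (0.1, "ns")],
    )
    def test_thresholds(self, p, flag):
        assert stats.significance_flag(p) == flag

    def test_out_of_range_rejected(self):
        for p in (-0.1, 1.1):
            with pytest.raises(ValueError):
                stats.significance_flag(p)

    @given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_in_p(self, p1, p2):
        """A smaller p-value never earns a less significant flag."""
        order = ["***", "**", "*", "#", "ns"]
        lo, hi = min(p1, p2), max(p1, p2)
        assert order.index(stats.significance_flag(lo)) <= order.index(stats.significance_flag(hi))


class TestNormalityGate:
    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            stats.normality_gate({"a": [1.0, 2.0]})

    def test_constant_group_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            stats.normality_gate({"a": [1.0, 1.0, 1.0, 1.0]})

    def test_normal_data_parametric(self, rng):
        groups = {k: rng.normal(0, 1, 60) for k in "abc"}
        assert stats.normality_gate(groups) == "parametric"

    def test_heavy_skew_nonparametric(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            groups = {"a": np.exp(rng.normal(0, 1, 50))}
            hits += stats.normality_gate(groups) == "nonparametric"
        assert hits >= 49


class TestRouting:
    def test_two_groups_never_anova(self, rng):
        groups = {"a": rng.normal(0, 1, 20), "b": rng.normal(1, 1, 20)}
        res = stats.compare_groups(groups, reference="a")
        assert res[0].test in ("unpaired t-test", "Mann-Whitney U")
        assert "ANOVA" not in res[0].test

    def test_three_parametric_groups_use_dunnett(self, rng):
        groups = {k: rng.normal(0, 1, 30) for k in "abc"}
        res = stats.compare_groups(groups, reference="a", gate="parametric")
        assert all(r.test == "one-way ANOVA + Dunnett" for r in res)
        assert all(r.omnibus_p is not None for r in res)

    def test_nonparametric_unpaired_route(self, rng):
        groups = {k: rng.normal(0, 1, 12) for k in "abc"}
        res = stats.compare_groups(groups, reference="a", gate="nonparametric")
        assert all(r.test == "Kruskal-Wallis + Mann-Whitney U" for r in res)

    def test_nonparametric_paired_route(self, rng):
        groups = {"a": rng.normal(0, 1, 12), "b": rng.normal(0.5, 1, 12)}
        res = stats.compare_groups(groups, design="paired", reference="a", gate="nonparametric")
        assert res[0].test == "Wilcoxon signed-rank"

    def test_identical_groups_p_is_one(self, rng):
        x = rng.normal(0, 1, 10)
        res = stats.compare_groups({"a": x, "b": x.copy()}, reference="a", gate="nonparametric")
        assert res[0].p_value == 1.0

    def test_unknown_design_rejected(self, rng):
        with pytest.raises(ValueError):
            stats.compare_groups({"a": rng.normal(0, 1, 5), "b": rng.normal(0, 1, 5)}, design="weird", reference="a")

    def test_missing_reference_rejected(self, rng):
        with pytest.raises(ValueError):
            stats.compare_groups({"a": rng.normal(0, 1, 5)}, reference="zzz")

    def test_shifted_group_flagged_strongly(self):
        """A 3-SD shift at n = 30 earns *** in nearly every draw."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            groups = {
                "control": rng.normal(0, 1, 30),
                "same": rng.normal(0, 1, 30),
                "shifted": rng.normal(3, 1, 30),
            }
            res = stats.compare_groups(groups, reference="control", gate="parametric")
            flags = {r.group: r.flag for r in res}
            hits += flags["shifted"] == "***"
        assert hits >= 48


class TestRenderReport:
    def _example(self):
        means = pd.DataFrame(
            {"untreated": {"len": 454.06}, "stress": {"len": 259.69}}
        )
        comparisons = [
            stats.ComparisonResult(
                group="stress", reference="untreated", effect_percent_raw=-42.8,
                effect_percent=-43, test="unpaired t-test", p_value=1e-5,
                flag="***", design="unpaired", metric="len",
            )
        ]
        return means, comparisons

    def test_contains_percent_annotation(self):
        means, comparisons = self._example()
        text = stats.render_report(means, comparisons, reference="untreated")
        assert "(-43% *** vs. untreated)" in text

    def test_round_trip_recovers_values(self):
        means, comparisons = self._example()
        text = stats.render_report(means, comparisons, reference="untreated")
        parsed = stats.parse_report(text)
        assert parsed.loc["len", "untreated"] == means.loc["len", "untreated"]
        assert parsed.loc["len", "stress"] == means.loc["len", "stress"]

    def test_empty_comparisons_values_only(self):
        means, _ = self._example()
        text = stats.render_report(means, [], reference="untreated")
        assert "vs." not in text
        parsed = stats.parse_report(text)
        assert parsed.loc["len", "stress"] == 259.69

    def test_missing_reference_column_is_error(self):
        means, comparisons = self._example()
        with pytest.raises(ValueError):
            stats.render_report(means, comparisons, reference="placebo")
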