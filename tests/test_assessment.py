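"""Residual pipeline, ARE, bias classification, trends, group comparison."""

import numpy as np
import pytest

import mltkit as mk
from mltkit.assessment import CaseSpec, ResidualRecord, residuals_frame


def _records(values, indicator="q45_15", case="W1"):
    return [ResidualRecord(year=str(i), case=case, indicator=indicator,
                           observed=o, estimated=e)
            for i, (o, e) in enumerate(values)]


class TestCaseSpec:
    def test_all_ten_shorthands_round_trip(self):
        assert len(mk.ALL_CASES) == 10
        for name in mk.ALL_CASES:
            assert CaseSpec.from_shorthand(name).shorthand == name

    def test_exact_inputs_per_case(self):
        assert CaseSpec.from_shorthand("W1").exact_indicators == ("q5_0",)
        assert CaseSpec.from_shorthand("M2").exact_indicators == ("q5_0", "q45_15")
        assert CaseSpec.from_shorthand("W3").exact_indicators == ("q5_0", "e0")
        assert CaseSpec.from_shorthand("C2(level:45q15)").exact_indicators == ("q45_15",)
        assert CaseSpec.from_shorthand("C3").exact_indicators == ("e0",)

    def test_unknown_shorthand_rejected(self):
        with pytest.raises(ValueError, match="W4"):
            CaseSpec.from_shorthand("W4")


class TestRunCase:
    def test_self_generated_series_has_zero_residuals(self, clean_corpus):
        """W2 on a series drawn from the fitted system itself."""
        tables, _ = clean_corpus
        lq = mk.fit_logquad(tables)
        cfg = mk.SeriesConfig(adult_mult=1.0, old_mult=1.0,
                              female_deviation_extra=1.0, crossover=False)
        coeffs = {s: mk.default_truth_coefficients(s) for s in ("male", "female")}
        series = mk.generate_china_like_series(cfg, coeffs)
        recs = mk.run_case("W2", {"logquad": lq}, series["male"].labelled())
        assert max(abs(r.residual) for r in recs) < 1e-4

    def test_level_45q15_case_zeroes_q45_not_q5(self, calibrated_systems, china_series):
        recs = mk.run_case("C2(level:45q15)", calibrated_systems["male"],
                           china_series["male"].labelled())
        q45 = [abs(r.residual) for r in recs if r.indicator == "q45_15"]
        q5 = [abs(r.residual) for r in recs if r.indicator == "q5_0"]
        assert max(q45) < 1e-9
        assert max(q5) > 1e-4

    def test_deflated_adult_pattern_overestimated_by_level_only_case(
            self, calibrated_systems, china_series):
        recs = mk.run_case("W1", calibrated_systems["male"],
                           china_series["male"].labelled())
        q45 = [r.residual for r in recs if r.indicator == "q45_15"]
        assert all(r > 0 for r in q45)

    def test_frame_shape_and_exact_input_column(self, calibrated_systems, china_series):
        recs = mk.run_case("M2", calibrated_systems["female"],
                           china_series["female"].labelled())
        df = residuals_frame(recs)
        assert len(df) == 19 * 5  # years x indicators
        assert set(df["indicator"]) == {"q1_0", "q5_0", "q45_15", "q20_60", "e0"}


class TestARE:
    def test_hand_computed_example(self):
        res = mk.are(_records([(2, 1), (4, 5)]))
        assert res.are_percent == pytest.approx(37.5)
        assert res.n == 2

    def test_zero_when_exact(self):
        assert mk.are(_records([(2, 2), (4, 4)])).are_percent == 0.0

    def test_order_invariance(self, rng):
        vals = [(o, o * rng.uniform(0.8, 1.2)) for o in rng.uniform(1, 10, 12)]
        a1 = mk.are(_records(vals)).are_percent
        a2 = mk.are(_records(vals[::-1])).are_percent
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_zero_observation_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero observations"):
            res = mk.are(_records([(0, 1), (2, 3)]))
        assert res.n == 1

    def test_mixed_indicators_rejected(self):
        recs = _records([(2, 1)]) + _records([(2, 1)], indicator="e0")
        with pytest.raises(ValueError, match="mix"):
            mk.are(recs)


class TestClassifyBias:
    @pytest.mark.parametrize("series,expected", [
        ([0.01] * 5, "+"),
        ([-0.01] * 5, "-"),
        ([0.0] * 5, "0"),
        ([-3, -2, -1, 1, 2], "-+"),
        ([3, 2, 1, -1, -2], "+-"),
    ])
    def test_canonical_patterns(self, series, expected):
        assert mk.classify_bias(series).cls == expected

    def test_linear_trend_crossing_zero(self):
        """Residuals rising through zero over the years classify as -+."""
        resid = np.linspace(-0.02, 0.015, 19)
        assert mk.classify_bias(resid).cls == "-+"

    def test_majority_sign_with_scattered_noise(self):
        resid = [0.02, 0.03, -0.01, 0.04, 0.02, -0.005, 0.03, 0.05, 0.01, 0.02]
        assert mk.classify_bias(resid).cls == "+"

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            mk.classify_bias([0.1, 0.2])


class TestTrend:
    def test_equal_endpoints_give_zero(self):
        assert mk.annual_decrease_rate(0.03, 0.03, 10) == 0.0
        assert mk.annual_increase_age(70.0, 70.0, 10) == 0.0

    def test_halving_over_ten_intervals(self):
        rate = mk.annual_decrease_rate(0.04, 0.02, 11)
        assert rate == pytest.approx(100 * (1 - 2 ** (-1 / 10)), abs=1e-10)
        assert round(rate, 2) == 6.70

    def test_rate_inverts_exactly(self, rng):
        for _ in range(20):
            q1 = rng.uniform(0.01, 0.1)
            q2 = q1 * rng.uniform(0.05, 0.9)
            n = int(rng.integers(3, 60))
            r = mk.annual_decrease_rate(q1, q2, n)
            assert q1 * (1 - r / 100) ** (n - 1) == pytest.approx(q2, rel=1e-12)

    def test_e0_gain_convention_and_antisymmetry(self):
        assert mk.annual_increase_age(70, 72, 11) == pytest.approx(0.2)
        assert mk.annual_increase_age(72, 70, 11) == pytest.approx(-0.2)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mk.annual_decrease_rate(0.0, 0.01, 10)
        with pytest.raises(ValueError):
            mk.annual_decrease_rate(0.02, 0.01, 1)


class TestCompareGroups:
    def _ares(self, scale):
        out = []
        for case in ("W1", "M1"):
            for ind in ("q45_15", "e0"):
                out.append(mk.AREResult(indicator=ind, are_percent=scale * 10,
                                        n=19, case=case))
        return out

    def test_identical_groups_have_no_flags(self):
        df = mk.compare_groups({"male": self._ares(1.0), "female": self._ares(1.0)})
        assert not df["is_larger"].any()

    def test_larger_group_flagged(self):
        df = mk.compare_groups({"male": self._ares(1.0), "female": self._ares(2.0)})
        flagged = df[df["is_larger"]]
        assert set(flagged["sex" if "sex" in df else "group"]) == {"female"}
        assert len(flagged) == 4  # every case x indicator cell

    def test_layout_covers_cases_by_indicators_by_groups(self):
        df = mk.compare_groups({"a": self._ares(1.0), "b": self._ares(1.5)})
        assert len(df) == 2 * 2 * 2
        assert not df["absent"].any()

    def test_missing_cells_flagged_absent(self):
        df = mk.compare_groups({"a": self._ares(1.0), "b": self._ares(1.0)[:2]})
        assert df["absent"].sum() == 2
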