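"""Family/level system: clustering, assignment, level matching, envelope."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import mltkit as mk
from mltkit.logquad import CalibrationError, constrained_table_from_rates


@pytest.fixture(scope="module")
def separated_corpus():
    """Three well-separated adult-pattern families, mild noise."""
    patterns = mk.family_deviation_patterns(3, spread=0.25)
    cfg = mk.CorpusConfig(n_tables=120, k_bounds=(-0.03, 0.03), noise_sd=0.01,
                          family_patterns=patterns, seed=11)
    return mk.generate_corpus(cfg), patterns


@pytest.fixture(scope="module")
def ordered_system():
    """Noise-free k=0 corpus with 3 ordered adult patterns, fitted at K=3."""
    patterns = mk.family_deviation_patterns(3, spread=0.15)
    tables, truth = mk.generate_corpus(
        mk.CorpusConfig(n_tables=90, k_bounds=(0.0, 0.0), noise_sd=0.0,
                        family_patterns=patterns, seed=3))
    return mk.fit_families(tables, K=3, seed=1), patterns, truth


class TestFit:
    def test_separated_patterns_recovered(self, separated_corpus):
        (tables, truth), _ = separated_corpus
        system = mk.fit_families(tables, K=3, seed=0)
        assert adjusted_rand_score(truth["family"], system.labels) > 0.95

    def test_refit_with_same_seed_is_identical(self, separated_corpus):
        (tables, _), _ = separated_corpus
        l1 = mk.fit_families(tables, K=3, seed=0).labels
        l2 = mk.fit_families(tables, K=3, seed=0).labels
        np.testing.assert_array_equal(l1, l2)

    def test_single_family_reduces_to_pooled_logquad(self, clean_corpus):
        tables, _ = clean_corpus
        system = mk.fit_families(tables, K=1, seed=0)
        pooled = mk.fit_logquad(tables)
        t_fam = mk.predict_family(system, 0, "q5_0", 0.02)
        t_lq = mk.predict_logquad(pooled, 0.02, 0.0)
        np.testing.assert_allclose(t_fam.l, t_lq.l, rtol=1e-10)

    def test_corpus_too_small_for_k_rejected(self, clean_corpus):
        tables, _ = clean_corpus
        with pytest.raises(CalibrationError, match="too small"):
            mk.fit_families(tables[:20], K=5, seed=0)

    def test_every_table_assigned_to_exactly_one_family(self, separated_corpus):
        (tables, _), _ = separated_corpus
        system = mk.fit_families(tables, K=3, seed=0)
        assert system.labels.shape == (len(tables),)
        assert set(np.unique(system.labels)) <= set(range(system.K))


class TestAssign:
    def test_pair_on_family_curve_selects_that_family(self, ordered_system):
        system, _, _ = ordered_system
        for j in range(system.K):
            q45 = mk.indicators(mk.predict_family(system, j, "q5_0", 0.02)).q45_15
            assert mk.assign_family(system, 0.02, q45) == j

    def test_table_with_family_pattern_assigned_to_it(self, ordered_system):
        system, patterns, _ = ordered_system
        truth = mk.default_truth_coefficients()
        x = np.log10(0.015)
        for j in range(system.K):
            log_m = truth.a_coef + truth.b_coef * x + truth.c_coef * x * x + patterns[j]
            table = constrained_table_from_rates(truth.grid, 10.0 ** log_m, 0.015)
            assert mk.assign_family_from_table(system, table) == j

    def test_assignment_deterministic_and_in_range(self, ordered_system):
        system, _, _ = ordered_system
        fams = [mk.assign_family(system, q5) for q5 in (0.005, 0.02, 0.08)]
        assert all(0 <= f < system.K for f in fams)
        assert fams == [mk.assign_family(system, q5) for q5 in (0.005, 0.02, 0.08)]


class TestPredict:
    def test_level_q5_is_exact(self, ordered_system):
        system, _, _ = ordered_system
        out = mk.indicators(mk.predict_family(system, 1, "q5_0", 0.0173))
        assert out.q5_0 == pytest.approx(0.0173, abs=1e-10)

    @pytest.mark.parametrize("param,value,tol", [
        ("q45_15", 0.12, 1e-9), ("e0", 72.0, 1e-7)])
    def test_level_matching_residual_is_zero(self, ordered_system, param, value, tol):
        system, _, _ = ordered_system
        out = mk.indicators(mk.predict_family(system, 1, param, value))
        assert getattr(out, param) == pytest.approx(value, abs=tol)

    def test_level_45q15_output_q5_differs_from_observed(self, ordered_system):
        """The sign-flip mechanism: matching 45q15 moves 5q0 off the input."""
        system, _, _ = ordered_system
        obs = mk.indicators(mk.predict_family(system, 0, "q5_0", 0.02))
        # deflate adult mortality, then match family 1 on the new 45q15
        out = mk.indicators(mk.predict_family(system, 1, "q45_15",
                                              obs.q45_15 * 0.8))
        assert abs(out.q5_0 - 0.02) > 1e-4

    def test_generative_member_round_trip(self, ordered_system):
        system, patterns, truth = ordered_system
        base = mk.default_truth_coefficients()
        x = np.log10(0.012)
        j = 2
        log_m = base.a_coef + base.b_coef * x + base.c_coef * x * x + patterns[j]
        member = mk.indicators(constrained_table_from_rates(base.grid, 10.0 ** log_m, 0.012))
        est = mk.indicators(mk.predict_family(system, j, "q5_0", 0.012))
        assert est.q45_15 == pytest.approx(member.q45_15, rel=0.01)

    def test_level_is_monotone_within_family(self, ordered_system):
        system, _, _ = ordered_system
        for j in range(system.K):
            q45 = [mk.indicators(mk.predict_family(system, j, "q5_0", q5)).q45_15
                   for q5 in (0.005, 0.01, 0.02, 0.05)]
            assert np.all(np.diff(q45) > 0)


class TestRange:
    def test_envelope_matches_generative_extremes(self, ordered_system):
        system, patterns, _ = ordered_system
        base = mk.default_truth_coefficients()
        q5 = 0.02
        x = np.log10(q5)
        gen = []
        for j in range(3):
            log_m = base.a_coef + base.b_coef * x + base.c_coef * x * x + patterns[j]
            gen.append(mk.indicators(
                constrained_table_from_rates(base.grid, 10.0 ** log_m, q5)).q45_15)
        lo, hi = mk.range_45q15(system, q5)
        assert lo == pytest.approx(min(gen), abs=1e-6)
        assert hi == pytest.approx(max(gen), abs=1e-6)
        for j in range(3):
            mid = mk.indicators(mk.predict_family(system, j, "q5_0", q5)).q45_15
            assert lo - 1e-12 <= mid <= hi + 1e-12

    def test_single_family_envelope_degenerates(self, clean_corpus):
        tables, _ = clean_corpus
        system = mk.fit_families(tables, K=1, seed=0)
        lo, hi = mk.range_45q15(system, 0.02)
        assert lo == hi

    def test_diagnostic_counts_controlled_series(self, ordered_system):
        """12 of 19 points forced below the envelope give 63.2% below."""
        system, _, _ = ordered_system
        q5s = np.geomspace(0.006, 0.05, 19)
        pairs = []
        for i, q5 in enumerate(q5s):
            lo, hi = mk.range_45q15(system, q5)
            q45 = lo * 0.85 if i < 12 else 0.5 * (lo + hi)
            pairs.append((q5, q45))
        diag = mk.range_diagnostic(system, pairs)
        assert diag.percent_below == pytest.approx(100 * 12 / 19, abs=1e-9)
        assert diag.percent_above == 0.0
        assert diag.percent_outside == pytest.approx(63.2, abs=0.1)
        assert diag.are_below == pytest.approx(100 * (1 / 0.85 - 1), rel=1e-6)
        assert np.isnan(diag.are_above)

    def test_points_from_system_itself_all_within(self, ordered_system):
        system, _, _ = ordered_system
        pairs = []
        for q5 in np.geomspace(0.006, 0.05, 10):
            j = mk.assign_family(system, q5)
            pairs.append((q5, mk.indicators(
                mk.predict_family(system, j, "q5_0", q5)).q45_15))
        diag = mk.range_diagnostic(system, pairs)
        assert diag.percent_outside == 0.0

    def test_outside_decomposition_holds_on_random_series(self, ordered_system, rng):
        system, _, _ = ordered_system
        pairs = [(q5, rng.uniform(0.02, 0.4))
                 for q5 in rng.uniform(0.005, 0.06, 30)]
        diag = mk.range_diagnostic(system, pairs)
        assert diag.percent_outside == pytest.approx(
            diag.percent_below + diag.percent_above, abs=1e-12)
        assert 0 <= diag.percent_outside <= 100
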