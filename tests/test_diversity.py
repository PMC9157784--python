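"""Richness estimation, rarefaction, effort projection and similarity."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aquasurvey import (
    IncidenceCounts,
    chao2,
    chao2_ci,
    effort_to_census,
    effort_to_fraction,
    ice_cv,
    lowest_accumulation_percent,
    percent_detected,
    rarefy,
    rarefy_resample,
    select_variant,
    simplified_morisita,
    survey_report,
    tally_counts,
)

from conftest import counts_from_q, matrix_from_frequencies


class TestChao2:
    def test_bias_corrected_published_row(self):
        est = chao2(counts_from_q(39, 34, 3, 6), "bias_corrected")
        assert round(est.Sest, 1) == 34.4

    def test_classic_published_row(self):
        est = chao2(counts_from_q(59, 28, 6, 4), "classic")
        assert round(est.Sest, 1) == 32.4

    def test_zero_uniques_collapse_to_sobs(self):
        c = counts_from_q(10, 5, 0, 2)
        for v in ("classic", "bias_corrected"):
            assert chao2(c, v).Sest == pytest.approx(5.0)

    def test_classic_without_duplicates_falls_back(self, caplog):
        c = counts_from_q(10, 5, 3, 0)
        est = chao2(c, "classic")
        assert est.variant == "bias_corrected"

    def test_degenerate_counts_give_point_interval(self):
        est = chao2(counts_from_q(10, 4, 0, 0), "bias_corrected")
        assert (est.ci_low, est.ci_high) == (4.0, 4.0)

    def test_published_confidence_intervals(self):
        # log-transform CI reproduces the printed bounds to one decimal
        est = chao2(counts_from_q(39, 34, 3, 6), "bias_corrected")
        assert (round(est.ci_low, 1), round(est.ci_high, 1)) == (34.0, 39.5)
        est = chao2(counts_from_q(59, 28, 6, 4), "classic")
        assert (round(est.ci_low, 1), round(est.ci_high, 1)) == (28.8, 52.5)
        est = chao2(counts_from_q(73, 16, 6, 1), "bias_corrected")
        assert (round(est.ci_low, 1), round(est.ci_high, 1)) == (17.3, 58.0)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            chao2_ci(10, 12.0, -1.0)

    def test_ci_collapses_onto_sest_as_variance_vanishes(self):
        low, high = chao2_ci(10, 12.0, 1e-12)
        assert low == pytest.approx(12.0, abs=1e-4)
        assert high == pytest.approx(12.0, abs=1e-4)

    @settings(derandomize=True, max_examples=80)
    @given(
        m=st.integers(2, 60),
        sobs_extra=st.integers(0, 20),
        q1=st.integers(0, 10),
        q2=st.integers(0, 10),
    )
    def test_estimate_dominates_sobs_and_variant_order(self, m, sobs_extra, q1, q2):
        sobs = q1 + q2 + sobs_extra
        if sobs == 0:
            return
        needed = 3 if sobs_extra else (2 if q2 else 1)
        if needed > m:
            return
        c = counts_from_q(m, sobs, q1, q2)
        bc = chao2(c, "bias_corrected").Sest
        assert bc >= sobs - 1e-12
        if q1 >= 1 and q2 >= 1:
            cl = chao2(c, "classic").Sest
            assert cl >= sobs - 1e-12
            assert bc <= cl + 1e-12


class TestIceCV:
    def test_homogeneous_incidence_gives_zero_cv(self):
        c = counts_from_q(10, 5, 0, 5)  # every species detected exactly twice
        assert ice_cv(c) == pytest.approx(0.0)
        assert select_variant(0.0) == "bias_corrected"

    def test_threshold_rule(self):
        assert select_variant(0.51) == "classic"
        assert select_variant(0.5) == "bias_corrected"

    def test_gamma_formula_oracle(self):
        # frequencies {1,1,1,1,1,1,9,9} over m = 10 units, all infrequent:
        # n=24, Q1=6, C=1-6/24=0.75, S=8, sum k(k-1)Q_k = 2*9*8 = 144
        # gamma^2 = 8/0.75 * 10/9 * 144/24^2 - 1
        c = IncidenceCounts.from_frequencies([1, 1, 1, 1, 1, 1, 9, 9], 10)
        expected = math.sqrt(8 / 0.75 * (10 / 9) * 144 / 576 - 1)
        assert ice_cv(c) == pytest.approx(expected)

    def test_all_uniques_give_infinite_cv(self):
        c = IncidenceCounts.from_frequencies([1, 1, 1], 5)
        assert math.isinf(ice_cv(c))
        assert select_variant(ice_cv(c)) == "classic"


class TestRarefaction:
    def test_endpoints(self, matrix_factory):
        m = matrix_factory([3, 1, 1, 2], 5)
        curve = rarefy(m)
        counts = tally_counts(m)
        assert curve.expected_S[-1] == pytest.approx(counts.Sobs)
        assert curve.expected_S[0] == pytest.approx(counts.incidences / counts.m)

    def test_expectation_matches_exhaustive_enumeration(self, matrix_factory):
        mat = matrix_factory([2, 1, 3, 1], 4)
        pres = mat.presence.to_numpy()
        curve = rarefy(mat)
        for ti, t in enumerate(curve.t):
            vals = [
                pres[list(combo)].any(axis=0).sum()
                for combo in itertools.combinations(range(4), t)
            ]
            assert curve.expected_S[ti] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_curve_concave_nondecreasing(self, random_matrix):
        curve = rarefy(random_matrix(seed=5))
        diffs = np.diff(curve.expected_S)
        assert (diffs >= -1e-12).all()
        assert (np.diff(diffs) <= 1e-9).all()

    def test_resampling_agrees_with_analytic_mean(self, random_matrix):
        mat = random_matrix(m=8, s=6, seed=7)
        analytic = rarefy(mat)
        reps = 4000
        mc = rarefy_resample(mat, n_reps=reps, seed=11)
        se = mc.sd / math.sqrt(reps)
        assert (np.abs(mc.expected_S - analytic.expected_S) <= 3 * se + 1e-9).all()

    def test_t_out_of_range_rejected(self, random_matrix):
        with pytest.raises(ValueError):
            rarefy(random_matrix(m=5), t=[6])

    def test_lowest_accumulation_is_a_lower_envelope(self, random_matrix):
        mat = random_matrix(seed=9)
        est = chao2(tally_counts(mat), "bias_corrected")
        low = lowest_accumulation_percent(mat, 2, est.Sest, n_perm=500, seed=1)
        curve = rarefy(mat, t=[2])
        assert low <= 100 * curve.expected_S[0] / est.Sest + 1e-9


class TestEffortProjection:
    def test_published_s95_values(self):
        assert effort_to_fraction(counts_from_q(78, 43, 4, 3), 0.95).m_additional == 7
        assert effort_to_fraction(counts_from_q(59, 28, 6, 4), 0.95).m_additional == 44

    def test_zero_when_target_already_met(self):
        c = counts_from_q(78, 43, 4, 3)
        # classic Sest = 45.63 -> Sobs/Sest = 0.942
        assert effort_to_fraction(c, 0.90).m_additional == 0
        eps_above = effort_to_fraction(c, 0.9425).m_additional_exact
        assert 0 < eps_above < 5

    def test_monotone_in_g(self):
        c = counts_from_q(60, 41, 11, 4)
        e95 = effort_to_fraction(c, 0.95).m_additional_exact
        e99 = effort_to_fraction(c, 0.99).m_additional_exact
        census = effort_to_census(c).m_additional_exact
        assert e95 < e99 < census

    @settings(derandomize=True, max_examples=40)
    @given(g1=st.floats(0.75, 0.99), g2=st.floats(0.75, 0.99))
    def test_strictly_increasing_in_g(self, g1, g2):
        c = counts_from_q(60, 41, 11, 4)
        lo, hi = sorted((g1, g2))
        if hi - lo < 1e-6:
            return
        a = effort_to_fraction(c, lo).m_additional_exact
        b = effort_to_fraction(c, hi).m_additional_exact
        ratio = 41 / chao2(c, "classic").Sest
        if lo > ratio:
            assert a < b

    def test_no_duplicates_is_an_error(self):
        with pytest.raises(ValueError, match="bias-corrected"):
            effort_to_fraction(counts_from_q(10, 6, 3, 0), 0.95)

    def test_no_undetected_species_needs_no_effort(self):
        assert effort_to_census(counts_from_q(10, 5, 0, 2)).m_additional == 0

    def test_census_order_of_magnitude(self):
        # printed value 169; the census formula is only indicative
        m100 = effort_to_census(counts_from_q(78, 43, 4, 3)).m_additional
        assert 80 <= m100 <= 500


class TestPercentDetected:
    def test_published_percentages(self):
        est = chao2(counts_from_q(78, 43, 4, 3), "bias_corrected")
        assert percent_detected(est) == 97
        est = chao2(counts_from_q(60, 41, 11, 4), "classic")
        assert percent_detected(est) == 73

    def test_full_detection(self):
        est = chao2(counts_from_q(10, 5, 0, 0), "bias_corrected")
        assert percent_detected(est) == 100


class TestSimplifiedMorisita:
    def test_self_similarity_is_one(self):
        r = simplified_morisita({"a": 3, "b": 2}, {"a": 3, "b": 2})
        assert r.index == pytest.approx(1.0)
        assert r.shared_species == 2

    def test_disjoint_assemblages_are_zero(self):
        r = simplified_morisita({"a": 3}, {"b": 2})
        assert r.index == 0.0
        assert r.shared_species == 0

    def test_hand_computed_value(self):
        # x={a:2,b:1}, y={a:1,b:2}: 2*(2+2) / ((5/9+5/9)*9) = 8/10
        r = simplified_morisita({"a": 2, "b": 1}, {"a": 1, "b": 2})
        assert r.index == pytest.approx(0.8)

    @settings(derandomize=True, max_examples=50)
    @given(
        x=st.dictionaries(st.sampled_from("abcdef"), st.integers(0, 9), min_size=1),
        y=st.dictionaries(st.sampled_from("abcdef"), st.integers(0, 9), min_size=1),
    )
    def test_symmetry_and_bounds(self, x, y):
        if sum(x.values()) == 0 or sum(y.values()) == 0:
            return
        a = simplified_morisita(x, y)
        b = simplified_morisita(y, x)
        assert a.index == pytest.approx(b.index)
        assert 0 <= a.index <= 1 + 1e-9
        assert (a.index == 0) == (a.shared_species == 0)

    def test_relabelling_invariance(self):
        a = simplified_morisita({"a": 2, "b": 5}, {"a": 1, "b": 5})
        b = simplified_morisita({"q": 2, "z": 5}, {"q": 1, "z": 5})
        assert a.index == pytest.approx(b.index)

    def test_empty_assemblage_rejected(self):
        with pytest.raises(ValueError):
            simplified_morisita({"a": 0}, {"a": 1})


class TestSurveyReport:
    def test_published_rows_assemble(self):
        rep = survey_report(counts_from_q(73, 16, 6, 1), variant="bias_corrected")
        assert round(rep.sest, 1) == 23.4
        rep = survey_report(counts_from_q(60, 41, 11, 4), variant="classic")
        assert round(rep.sest, 1) == 55.9

    def test_degenerate_matrix_reports_zero_effort(self, matrix_factory):
        mat = matrix_factory([3, 3, 4], 5)  # Q1 = Q2 = 0
        rep = survey_report(mat)
        assert rep.sest == rep.sobs
        assert rep.s95_additional == 0 and rep.s100_additional == 0

    def test_auto_variant_follows_cv_rule(self, matrix_factory):
        mat = matrix_factory([1, 1, 1, 1, 1, 1, 9, 9], 10)
        rep = survey_report(mat)
        assert rep.cv_ice > 0.5
        assert rep.variant == "classic"
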