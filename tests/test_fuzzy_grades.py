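"""Membership functions, mean–min aggregation, flow rates and the
hierarchical decision objective."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from actd.fuzzy_grades import (
    MembershipSpec,
    decision_grade,
    deviation_grade,
    flow_rates,
    grade_max,
    grade_min,
    grade_two_sided,
    mean_min,
    two_sided_specs_from_template,
)
from actd.metnet_io import Metabolite, Reaction, StoichiometricModel


def min_spec(lb, ub):
    return MembershipSpec(kind="min_one_sided", LB=lb, UB=ub)


def max_spec(lb, ub):
    return MembershipSpec(kind="max_one_sided", LB=lb, UB=ub)


def ts_spec(lb, st_, ub):
    return MembershipSpec(kind="two_sided", LB=lb, UB=ub, ST=st_)


class TestOneSided:
    @pytest.mark.parametrize("fv,expected", [
        (2.0, 1.0), (6.0, 0.0), (5.0, 0.25), (1.0, 1.0), (7.0, 0.0),
    ])
    def test_min_ramp(self, fv, expected):
        assert grade_min(fv, min_spec(2, 6)) == pytest.approx(expected)

    def test_min_midpoint_linearity(self):
        assert grade_min(0.5, min_spec(0, 1)) == pytest.approx(0.5)

    @pytest.mark.parametrize("fv,expected", [
        (10.0, 1.0), (2.5, 0.25), (0.0, 0.0), (-1.0, 0.0), (12.0, 1.0),
    ])
    def test_max_ramp(self, fv, expected):
        assert grade_max(fv, max_spec(0, 10)) == pytest.approx(expected)

    def test_inverted_bounds_are_a_spec_error(self):
        with pytest.raises(ValueError, match="LB < UB"):
            min_spec(6, 2)

    @given(st.floats(-5, 15))
    def test_complement_identity_inside_the_band(self, fv):
        lo, hi = 0.0, 10.0
        if lo <= fv <= hi:
            total = grade_min(fv, min_spec(lo, hi)) + grade_max(fv, max_spec(lo, hi))
            assert total == pytest.approx(1.0)


class TestTwoSided:
    def test_unity_at_standard_level(self):
        assert grade_two_sided(4.0, ts_spec(0, 4, 10)) == 1.0

    @pytest.mark.parametrize("pb", [0.0, 10.0, -3.0, 12.0])
    def test_zero_at_and_beyond_the_ramp_ends(self, pb):
        assert grade_two_sided(pb, ts_spec(0, 4, 10)) == 0.0

    def test_right_ramp_value(self):
        assert grade_two_sided(7.0, ts_spec(0, 4, 10)) == pytest.approx(0.5)

    def test_degenerate_left_side_is_an_indicator(self):
        spec = ts_spec(0, 0, 2)  # ST == LB
        assert grade_two_sided(0.0, spec) == 1.0
        assert grade_two_sided(1.0, spec) == pytest.approx(0.5)

    def test_st_outside_band_is_a_spec_error(self):
        with pytest.raises(ValueError, match="ST"):
            MembershipSpec(kind="two_sided", LB=0, UB=1, ST=2)

    @given(
        st.floats(-100, 100), st.floats(0.1, 50), st.floats(0.1, 50),
        st.floats(-200, 200),
    )
    def test_always_clamped_to_unit_interval(self, st_, wl, wr, pb):
        spec = ts_spec(st_ - wl, st_, st_ + wr)
        assert 0.0 <= grade_two_sided(pb, spec) <= 1.0


class TestMeanMin:
    @pytest.mark.parametrize("grades,expected", [
        ((1.0, 0.0), 0.25),
        ((0.5, 0.5), 0.5),
        ((0.4, 0.6), 0.45),
    ])
    def test_published_worked_example(self, grades, expected):
        assert mean_min(grades) == pytest.approx(expected)

    def test_empty_list_is_a_domain_error(self):
        with pytest.raises(ValueError):
            mean_min([])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_never_exceeds_the_mean(self, grades):
        mm = mean_min(grades)
        mean = float(np.mean(grades))
        assert mm <= mean + 1e-12
        if len(set(grades)) > 1:
            assert mm < mean
        else:
            assert mm == pytest.approx(mean)


class TestFlowRates:
    def _model(self, reactions):
        mets = sorted({m for r in reactions for m in r.stoich})
        return StoichiometricModel(
            id="m",
            metabolites=[Metabolite.from_id(m) for m in mets],
            reactions=reactions,
            biomass_rxn_id=reactions[0].id,
            atp_rxn_id=reactions[0].id,
        )

    def test_single_producer(self):
        model = self._model([Reaction("r", {"A[c]": -1, "B[c]": 1}, 0, 10)])
        rates = flow_rates({"r": 2.0}, {"r": 0.0}, model)
        assert rates["B"] == pytest.approx(2.0)

    def test_reverse_flux_counts_as_production(self):
        # producer with N=2 at v_f=3 plus a reversible consumer (N=-1)
        # running backward at v_b=1 contributes |N| * v_b
        model = self._model([
            Reaction("p", {"A[c]": -1, "B[c]": 2}, 0, 10),
            Reaction("c", {"B[c]": -1, "C[c]": 1}, -10, 10),
        ])
        rates = flow_rates({"p": 3.0, "c": 0.0}, {"p": 0.0, "c": 1.0}, model)
        assert rates["B"] == pytest.approx(7.0)

    def test_compartment_copies_are_pooled(self):
        model = self._model([
            Reaction("pc", {"A[c]": 1}, 0, 10),
            Reaction("pm", {"A[m]": 1}, 0, 10),
        ])
        rates = flow_rates({"pc": 1.5, "pm": 0.5}, {"pc": 0.0, "pm": 0.0}, model)
        assert rates["A"] == pytest.approx(2.0)


class TestDeviationGrade:
    def _specs(self, values, alpha=1.0):
        return two_sided_specs_from_template(values, values.keys(), alpha=alpha)

    def test_ideal_side_effect_free_kill(self):
        # half-width 0.5*|ST| keeps the cancer bands clear of the healthy
        # values, so the dissimilarity grades saturate at 1
        ht = {"a": 2.0, "b": 4.0}
        ca = {"a": 20.0, "b": 40.0}
        ca_specs = self._specs(ca, alpha=0.5)
        ht_specs = self._specs(ht, alpha=0.5)
        out = deviation_grade(ht, ht, ca_specs, ht_specs, ca_specs, ht_specs)
        assert out == pytest.approx((1.0, 1.0, 1.0, 1.0, 1.0))

    def test_perturbed_equal_to_cancer_template_zeroes_the_min_term(self):
        ca = {"a": 2.0, "b": 4.0}
        ca_specs = self._specs(ca)
        ht_specs = self._specs({"a": 2.0, "b": 4.0})
        f_ca, m_ca, f_bl, m_bl, eta_md = deviation_grade(
            ca, ca, ca_specs, ht_specs, ca_specs, ht_specs
        )
        assert f_ca == m_ca == 0.0
        # the min term vanishes, so the aggregate is half the mean
        assert eta_md == pytest.approx(np.mean([f_ca, m_ca, f_bl, m_bl]) / 2)

    def test_four_grade_arithmetic(self):
        # mean-min of (0.8, 0.6, 1.0, 0.6) = 0.75/1 ... = (0.75 + 0.6) / 2
        assert mean_min([0.8, 0.6, 1.0, 0.6]) == pytest.approx(0.675)

    def test_similarity_and_dissimilarity_sum_to_one_per_element(self):
        values = {"a": 3.0}
        specs = self._specs(values)
        for pb in (0.0, 1.0, 2.5, 3.0, 4.4, 9.0):
            sim = grade_two_sided(pb, specs["a"])
            assert sim + (1.0 - sim) == pytest.approx(1.0)
            assert 0.0 <= sim <= 1.0

    def test_empty_universe_is_a_domain_error(self):
        with pytest.raises(ValueError, match="empty"):
            deviation_grade({}, {}, {}, {"a": ts_spec(0, 1, 2)}, {}, {})


class TestDecisionGrade:
    def test_published_one_target_row(self):
        # mortality is the smallest grade, so it dominates the hierarchy
        assert decision_grade(0.668, 0.751, 0.682) == pytest.approx(0.668)

    def test_all_equal_passes_through(self):
        assert decision_grade(0.4, 0.4, 0.4) == pytest.approx(0.4)

    def test_low_viability_pulls_the_average(self):
        assert decision_grade(0.9, 0.3, 0.8) == pytest.approx(0.6)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_bounded_by_mortality_and_monotone(self, tr, cv, md):
        d = decision_grade(tr, cv, md)
        assert 0.0 <= d <= tr + 1e-12
        assert decision_grade(tr, min(1.0, cv + 0.1), md) >= d - 1e-12
        assert decision_grade(tr, cv, min(1.0, md + 0.1)) >= d - 1e-12
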