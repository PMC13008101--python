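"""Decision-tree cascade: masses, costs, Bayes-conditioned starting strata."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibscreen import (
    build_initial_strata,
    classify_cohort,
    cost_per_true_positive,
    expected_screening_cost,
)
from fibscreen.cascade import (
    TREATED_FALSE,
    TREATED_TRUE,
    UNSCREENED,
    UndefinedRatioError,
)
from fibscreen.states import SIGNIFICANT_FIBROSIS, HealthState


def enumerate_tree(pi, stages):
    """Independent full-tree oracle.

    Enumerates screen? x true status x stage-1 result x attend-TE? x TE
    result and sums leaf probabilities into the cascade's six fractions.
    ``stages`` is a list of (uptake, sens, spec) tuples (1 or 2 entries).
    """
    fr = {k: 0.0 for k in (
        "unscreened", "step1_negative", "referred_not_attending_te",
        "te_negative", "treated_true_positive", "treated_false_positive")}
    statuses = [(True, pi), (False, 1.0 - pi)]
    if not stages:
        fr["unscreened"] = 1.0
    elif len(stages) == 1:
        (u, se, sp), = stages
        for diseased, p_status in statuses:
            fr["unscreened"] += (1 - u) * p_status
            p_pos = se if diseased else (1 - sp)
            for positive, p_res in ((True, p_pos), (False, 1 - p_pos)):
                leaf = u * p_status * p_res
                if not positive:
                    fr["te_negative"] += leaf
                elif diseased:
                    fr["treated_true_positive"] += leaf
                else:
                    fr["treated_false_positive"] += leaf
    else:
        (u1, se1, sp1), (u2, se2, sp2) = stages
        for diseased, p_status in statuses:
            fr["unscreened"] += (1 - u1) * p_status
            p1 = se1 if diseased else (1 - sp1)
            fr["step1_negative"] += u1 * p_status * (1 - p1)
            fr["referred_not_attending_te"] += u1 * p_status * p1 * (1 - u2)
            p2 = se2 if diseased else (1 - sp2)
            base = u1 * p_status * p1 * u2
            fr["te_negative"] += base * (1 - p2)
            if diseased:
                fr["treated_true_positive"] += base * p2
            else:
                fr["treated_false_positive"] += base * p2
    return fr


def _stages(ps, strategy):
    return [
        (ps[s.uptake_param], ps[s.sens_param], ps[s.spec_param])
        for s in strategy.stages
    ]


class TestClassifyCohort:
    def test_fib4_te_treated_true_mass(self, mets_ps):
        # 0.9 * 0.116 * 0.66 * 0.9 * 0.801
        c = classify_cohort(mets_ps, mets_ps.strategies["FIB4_TE"], 50)
        assert c.fractions[TREATED_TRUE] == pytest.approx(0.0496728936, abs=1e-10)

    def test_fib4_te_treated_false_mass(self, mets_ps):
        # 0.9 * 0.884 * 0.35 * 0.9 * 0.27
        c = classify_cohort(mets_ps, mets_ps.strategies["FIB4_TE"], 50)
        assert c.fractions[TREATED_FALSE] == pytest.approx(0.06766578, abs=1e-10)

    def test_no_disease_no_true_positives(self, mets_ps):
        ps = mets_ps.copy()
        ps.set("prev_sigfib_50", 0.0)
        for sid in ("FIB4_TE", "SAFE_TE", "TE_ALONE"):
            c = classify_cohort(ps, ps.strategies[sid], 50)
            assert c.fractions[TREATED_TRUE] == 0.0

    def test_no_screen_all_unscreened(self, mets_ps):
        c = classify_cohort(mets_ps, mets_ps.strategies["NO_SCREEN"], 50)
        assert c.fractions[UNSCREENED] == 1.0
        assert c.expected_screening_cost == 0.0

    @pytest.mark.parametrize("sid", ["NO_SCREEN", "FIB4_TE", "SAFE_TE", "TE_ALONE"])
    @pytest.mark.parametrize("population", ["mets", "obesity"])
    def test_matches_tree_enumeration(self, sid, population, mets_ps, obesity_ps):
        ps = mets_ps if population == "mets" else obesity_ps
        strategy = ps.strategies[sid]
        c = classify_cohort(ps, strategy, 50)
        oracle = enumerate_tree(ps.sigfib_prevalence(50), _stages(ps, strategy))
        for key, val in oracle.items():
            assert c.fractions[key] == pytest.approx(val, abs=1e-12), key

    def test_perfect_tests_full_uptake(self, mets_ps):
        ps = mets_ps.copy()
        for name in ("sens_fib4", "spec_fib4", "sens_te", "spec_te"):
            ps.set(name, 1.0 - 1e-12)
        for name in ("uptake_step1", "uptake_confirm"):
            ps.set(name, 1.0)
        c = classify_cohort(ps, ps.strategies["FIB4_TE"], 50)
        assert c.fractions[TREATED_TRUE] == pytest.approx(ps.sigfib_prevalence(50), abs=1e-9)
        assert c.fractions[TREATED_FALSE] == pytest.approx(0.0, abs=1e-9)

    def test_treated_true_monotone_in_sensitivity_and_uptake(self, mets_ps):
        base = classify_cohort(mets_ps, mets_ps.strategies["FIB4_TE"], 50)
        for name in ("sens_fib4", "sens_te", "uptake_step1", "uptake_confirm"):
            bumped = mets_ps.copy()
            bumped.set(name, min(1.0, mets_ps[name] + 0.05))
            c = classify_cohort(bumped, bumped.strategies["FIB4_TE"], 50)
            assert c.fractions[TREATED_TRUE] >= base.fractions[TREATED_TRUE]

    @settings(max_examples=60, deadline=None)
    @given(
        pi=st.floats(0.001, 0.6),
        u1=st.floats(0.0, 1.0),
        u2=st.floats(0.0, 1.0),
        se1=st.floats(0.0, 1.0),
        sp1=st.floats(0.0, 1.0),
    )
    def test_mass_conservation(self, mets_ps, pi, u1, u2, se1, sp1):
        ps = mets_ps.copy()
        ps.set("prev_sigfib_50", min(pi, 1.0 - 1e-9))
        ps.set("uptake_step1", u1)
        ps.set("uptake_confirm", u2)
        ps.set("sens_fib4", se1)
        ps.set("spec_fib4", sp1)
        for sid in ("FIB4_TE", "TE_ALONE", "NO_SCREEN"):
            c = classify_cohort(ps, ps.strategies[sid], 50)
            assert sum(c.fractions.values()) == pytest.approx(1.0, abs=1e-12)
            assert all(v >= -1e-15 for v in c.fractions.values())


class TestScreeningCost:
    def test_fib4_te_cost(self, mets_ps):
        strategy = mets_ps.strategies["FIB4_TE"]
        c = classify_cohort(mets_ps, strategy, 50)
        # 0.9*271 + 0.9*0.38596*0.9*2000
        assert expected_screening_cost(mets_ps, strategy, c) == pytest.approx(
            869.1552, abs=1e-4
        )

    def test_te_alone_cost(self, mets_ps):
        strategy = mets_ps.strategies["TE_ALONE"]
        c = classify_cohort(mets_ps, strategy, 50)
        assert expected_screening_cost(mets_ps, strategy, c) == pytest.approx(1600.0)

    def test_zero_uptake_zero_cost(self, mets_ps):
        ps = mets_ps.copy()
        for name in ("uptake_step1", "uptake_confirm", "uptake_te_alone"):
            ps.set(name, 0.0)
        for sid in ("FIB4_TE", "SAFE_TE", "TE_ALONE"):
            c = classify_cohort(ps, ps.strategies[sid], 50)
            assert c.expected_screening_cost == 0.0


class TestCostPerTruePositive:
    def test_screening_tests_convention(self, mets_ps):
        strategy = mets_ps.strategies["FIB4_TE"]
        c = classify_cohort(mets_ps, strategy, 50)
        value = cost_per_true_positive(mets_ps, strategy, c)
        assert value == pytest.approx(869.1552 / 0.0496728936, rel=1e-6)

    def test_homogeneous_in_unit_costs(self, mets_ps):
        doubled = mets_ps.copy()
        for name in ("cost_fib4", "cost_te"):
            doubled.set(name, 2 * mets_ps[name])
        strategy = mets_ps.strategies["FIB4_TE"]
        base = cost_per_true_positive(
            mets_ps, strategy, classify_cohort(mets_ps, strategy, 50))
        two = cost_per_true_positive(
            doubled, strategy, classify_cohort(doubled, strategy, 50))
        assert two == pytest.approx(2 * base, rel=1e-12)

    def test_perfect_te_limit(self, mets_ps):
        # Se_TE, Sp -> 1, uptakes -> 1 gives c1/pi + c_TE
        ps = mets_ps.copy()
        for name in ("sens_fib4", "spec_fib4", "sens_te", "spec_te"):
            ps.set(name, 1.0 - 1e-12)
        for name in ("uptake_step1", "uptake_confirm"):
            ps.set(name, 1.0)
        strategy = ps.strategies["FIB4_TE"]
        value = cost_per_true_positive(ps, strategy, classify_cohort(ps, strategy, 50))
        pi = ps.sigfib_prevalence(50)
        assert value == pytest.approx(271.0 / pi + 2000.0, rel=1e-6)

    def test_undefined_without_true_positives(self, mets_ps):
        ps = mets_ps.copy()
        ps.set("sens_te", 0.0)
        strategy = ps.strategies["FIB4_TE"]
        with pytest.raises(UndefinedRatioError):
            cost_per_true_positive(ps, strategy, classify_cohort(ps, strategy, 50))

    def test_all_conventions_reported(self, mets_ps):
        strategy = mets_ps.strategies["FIB4_TE"]
        c = classify_cohort(mets_ps, strategy, 50)
        tests = cost_per_true_positive(mets_ps, strategy, c, "tests")
        visits = cost_per_true_positive(mets_ps, strategy, c, "tests+visits")
        lifestyle = cost_per_true_positive(mets_ps, strategy, c, "tests+lifestyle")
        assert tests < visits and tests < lifestyle


class TestInitialStrata:
    def test_no_screen_single_stratum(self, mets_ps):
        strata = build_initial_strata(mets_ps, mets_ps.strategies["NO_SCREEN"], 50)
        assert len(strata) == 1
        assert strata[0].mass == pytest.approx(1.0)
        assert not strata[0].treated

    @pytest.mark.parametrize("sid", ["NO_SCREEN", "FIB4_TE", "SAFE_TE", "TE_ALONE"])
    def test_masses_and_distributions_normalised(self, mets_ps, sid):
        strata = build_initial_strata(mets_ps, mets_ps.strategies[sid], 50)
        assert sum(s.mass for s in strata) == pytest.approx(1.0, abs=1e-12)
        for s in strata:
            assert s.initial_distribution.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unconditional_state_mix_matches_prevalence(self, mets_ps):
        # mass-weighted initial distribution reproduces the population prior
        strata = build_initial_strata(mets_ps, mets_ps.strategies["FIB4_TE"], 50)
        mix = sum(s.mass * s.initial_distribution for s in strata)
        masld, pi = mets_ps.masld_prevalence(50), mets_ps.sigfib_prevalence(50)
        assert mix[HealthState.NO_MASLD] == pytest.approx(1 - masld, abs=1e-12)
        f01 = mix[HealthState.F0] + mix[HealthState.F1]
        assert f01 == pytest.approx(masld - pi, abs=1e-12)  # 0.348 - 0.116 = 0.232
        assert sum(mix[s] for s in SIGNIFICANT_FIBROSIS) == pytest.approx(pi, abs=1e-12)

    def test_treated_strata_flags(self, mets_ps):
        strata = build_initial_strata(mets_ps, mets_ps.strategies["TE_ALONE"], 50)
        by_label = {s.label: s for s in strata}
        tp = by_label["treated_true_positive_adherent"]
        fp = by_label["treated_false_positive"]
        assert tp.treated and tp.adherent and tp.incurs_lifestyle_cost
        assert fp.treated and not fp.adherent and fp.incurs_lifestyle_cost
        # true positives hold significant fibrosis; false positives none
        assert sum(tp.initial_distribution[s] for s in SIGNIFICANT_FIBROSIS) == pytest.approx(1.0)
        assert sum(fp.initial_distribution[s] for s in SIGNIFICANT_FIBROSIS) == 0.0

    def test_adherence_subsplit(self, mets_ps):
        ps = mets_ps.copy()
        ps.set("adherence", 0.7)
        strata = build_initial_strata(ps, ps.strategies["FIB4_TE"], 50)
        by_label = {s.label: s for s in strata}
        adh = by_label["treated_true_positive_adherent"]
        non = by_label["treated_true_positive_nonadherent"]
        assert adh.mass / (adh.mass + non.mass) == pytest.approx(0.7)
        assert non.incurs_lifestyle_cost and not non.adherent
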