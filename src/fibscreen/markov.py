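"""Markov cohort engine: lifetime disease progression with age-dependent mortality.

Annual cycles from the screening age to the model horizon.  Background
all-cause mortality comes from the life table, multiplied by the
population-level metabolic adjustment and by disease hazard ratios (1.29 in
non-cirrhotic MASLD, 3.13 in cirrhotic states); transplant-year and
post-transplant occupants use a dedicated annual mortality parameter.  Death
competes first: disease transitions apply to the surviving fraction, so rows
are stochastic by construction, and parameter combinations whose raw exits
exceed one raise an error instead of being renormalised silently.

In treated, adherent strata the three progression probabilities
F2->F3, F3->F4/CC and F4/CC->DC are multiplied by one minus the relative
risk reduction of the lifestyle intervention.

Costs and QALYs accumulate with annual discounting, first cycle undiscounted
(t = 0) and no half-cycle correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cascade import CohortStratum, build_initial_strata, classify_cohort
from .parameters import ParameterSet
from .states import (
    ADVANCED_STATES,
    CIRRHOTIC_STATES,
    DEATH_STATES,
    N_STATES,
    NONCIRRHOTIC_MASLD,
    PRE_DC_STATES,
    HealthState as S,
)

ROW_TOL = 1e-10


class InfeasibleParameterError(ValueError):
    """A state's exit probabilities sum above one."""


# ---------------------------------------------------------------------------
# transition matrices


def _death_probability(ps: ParameterSet, age: int) -> np.ndarray:
    """Per-state annual death probability at the given age."""
    q = ps.life_table.prob(age) * ps["metabolic_multiplier"]
    p = np.zeros(N_STATES)
    p[S.NO_MASLD] = q
    for s in NONCIRRHOTIC_MASLD:
        p[s] = q * ps["hr_noncirrhotic"]
    for s in CIRRHOTIC_STATES:
        p[s] = q * ps["hr_cirrhotic"]
    p[S.LT] = ps["mort_post_lt"]
    p[S.POST_LT] = ps["mort_post_lt"]
    return np.minimum(p, 1.0)


def _cause_split(ps: ParameterSet, state: S) -> tuple[float, float, float]:
    st = ps.settings
    if state == S.NO_MASLD:
        return st.cause_split_no_masld
    if state in NONCIRRHOTIC_MASLD:
        return st.cause_split_noncirrhotic
    if state in CIRRHOTIC_STATES:
        return st.cause_split_cirrhotic
    return st.cause_split_lt


def build_transition_matrix(
    ps: ParameterSet, age: int, treated_adherent: bool = False
) -> np.ndarray:
    """One annual transition matrix, tagged by age and treatment variant."""
    rrr_mult = (1.0 - ps["rrr"]) if treated_adherent else 1.0
    lt_open = age <= ps.settings.lt_age_limit

    exits: dict[S, dict[S, float]] = {
        S.NO_MASLD: {S.F0: ps["tp_no_masld_f0"]},
        S.F0: {S.NO_MASLD: ps["tp_f0_no_masld"], S.F1: ps["tp_f0_f1"]},
        S.F1: {S.F0: ps["tp_f1_f0"], S.F2: ps["tp_f1_f2"]},
        S.F2: {S.F1: ps["tp_f2_f1"], S.F3: ps["tp_f2_f3"] * rrr_mult},
        S.F3: {S.F2: ps["tp_f3_f2"], S.F4_CC: ps["tp_f3_f4"] * rrr_mult},
        S.F4_CC: {
            S.F3: ps["tp_f4_f3"],
            S.DC: ps["tp_f4_dc"] * rrr_mult,
            S.HCC: ps["tp_f4_hcc"],
        },
        S.DC: {S.HCC: ps["tp_dc_hcc"], S.LT: ps["tp_dc_lt"] if lt_open else 0.0},
        S.HCC: {S.LT: ps["tp_hcc_lt"] if lt_open else 0.0},
        S.LT: {S.POST_LT: 1.0},  # transplant year is a tunnel state
        S.POST_LT: {},
    }

    p_death = _death_probability(ps, age)
    mat = np.zeros((N_STATES, N_STATES))
    for state, moves in exits.items():
        total_exit = sum(moves.values())
        if total_exit > 1.0 + ROW_TOL:
            raise InfeasibleParameterError(
                f"state {state.name} at age {age}: exit probabilities sum to "
                f"{total_exit:.6f} > 1"
            )
        pd_ = p_death[state]
        survive = 1.0 - pd_
        cvd, liver, other = _cause_split(ps, state)
        mat[state, S.DEATH_CVD] = pd_ * cvd
        mat[state, S.DEATH_LIVER] = pd_ * liver
        mat[state, S.DEATH_OTHER] = pd_ * other
        for dest, prob in moves.items():
            mat[state, dest] = survive * prob
        mat[state, state] = survive * (1.0 - min(total_exit, 1.0))
    for d in DEATH_STATES:
        mat[d, d] = 1.0
    return mat


def transition_matrices(ps: ParameterSet) -> dict[bool, np.ndarray]:
    """All annual matrices for one parameter set.

    Returns ``{variant: array of shape (n_transitions, S, S)}`` for the
    untreated and treated-adherent variants, ages ``start_age`` to
    ``max_age - 1``.
    """
    ages = range(ps.start_age, ps.max_age)
    out = {}
    for variant in (False, True):
        out[variant] = np.stack(
            [build_transition_matrix(ps, a, variant) for a in ages]
        )
    return out


# ---------------------------------------------------------------------------
# cohort propagation


def run_cohort(initial: Sequence[float], mats: np.ndarray) -> np.ndarray:
    """Propagate an occupancy vector through the annual matrices.

    Returns the trajectory of shape ``(n_transitions + 1, n_states)``; row 0
    is the initial distribution.
    """
    init = np.asarray(initial, dtype=float)
    if init.shape != (N_STATES,):
        raise ValueError(f"initial occupancy must have length {N_STATES}")
    if abs(init.sum() - 1.0) > 1e-9:
        raise ValueError(f"initial occupancy sums to {init.sum()}, expected 1")
    traj = np.empty((mats.shape[0] + 1, N_STATES))
    traj[0] = init
    for t in range(mats.shape[0]):
        traj[t + 1] = traj[t] @ mats[t]
    return traj


# ---------------------------------------------------------------------------
# payoffs


def state_utility_vector(ps: ParameterSet) -> np.ndarray:
    u = np.zeros(N_STATES)
    u[S.NO_MASLD] = ps["u_no_masld"]
    for s in NONCIRRHOTIC_MASLD:
        u[s] = ps["u_f0_f3"]
    u[S.F4_CC] = ps["u_f4"]
    u[S.DC] = ps["u_dc"]
    u[S.HCC] = ps["u_hcc"]
    u[S.LT] = ps["u_lt"]
    u[S.POST_LT] = ps["u_post_lt"]
    return u


def state_cost_vector(ps: ParameterSet, incurs_lifestyle_cost: bool = False) -> np.ndarray:
    """Annual cost per state: medical management plus non-medical visit costs.

    The cost-to-charge ratio applies to the hospital-database-derived state
    costs (no-MASLD management, F0-F3, F4/CC).  Obesity-without-MASLD incurs
    no healthcare costs, medical or non-medical.  When
    ``incurs_lifestyle_cost`` the annual programme cost is added in every
    pre-decompensation alive state.
    """
    ctc = ps["cost_to_charge_ratio"]
    visit = ps["c_visit_food"] + ps["c_visit_transport"]
    v_pre = ps.settings.visits_per_year_pre_dc * visit
    v_adv = ps.settings.visits_per_year_advanced * visit

    c = np.zeros(N_STATES)
    c[S.NO_MASLD] = ps["c_no_masld"] * ctc
    for s in NONCIRRHOTIC_MASLD:
        c[s] = ps["c_f0_f3"] * ctc
    c[S.F4_CC] = ps["c_f4"] * ctc
    c[S.DC] = ps["c_dc"]
    c[S.HCC] = ps["c_hcc"]
    c[S.LT] = ps["c_lt"]
    c[S.POST_LT] = ps["c_post_lt"]

    for s in PRE_DC_STATES:
        c[s] += v_pre
    for s in ADVANCED_STATES:
        c[s] += v_adv
    if ps.population == "obesity":
        c[S.NO_MASLD] = 0.0  # no healthcare contact without MASLD

    if incurs_lifestyle_cost:
        for s in PRE_DC_STATES:
            c[s] += ps["cost_lifestyle"]
    return c


@dataclass
class LifetimeOutcome:
    """Discounted and undiscounted lifetime aggregates for one cohort run."""

    cost: float
    qaly: float
    life_years: float
    cost_undiscounted: float
    qaly_undiscounted: float

    def weighted(self, w: float) -> "LifetimeOutcome":
        return LifetimeOutcome(
            self.cost * w, self.qaly * w, self.life_years * w,
            self.cost_undiscounted * w, self.qaly_undiscounted * w,
        )

    def __add__(self, other: "LifetimeOutcome") -> "LifetimeOutcome":
        return LifetimeOutcome(
            self.cost + other.cost,
            self.qaly + other.qaly,
            self.life_years + other.life_years,
            self.cost_undiscounted + other.cost_undiscounted,
            self.qaly_undiscounted + other.qaly_undiscounted,
        )


def accumulate_outcomes(
    traj: np.ndarray,
    ps: ParameterSet,
    incurs_lifestyle_cost: bool = False,
) -> LifetimeOutcome:
    """Discounted cost/QALY aggregation of one trajectory (t = 0 undiscounted)."""
    if traj.size == 0:
        raise ValueError("trajectory is empty")
    d = ps["discount_rate"]
    t = np.arange(traj.shape[0])
    w = (1.0 + d) ** (-t.astype(float))

    utilities = state_utility_vector(ps)
    base_cost = state_cost_vector(ps, incurs_lifestyle_cost=False)
    per_cycle_q = traj @ utilities
    per_cycle_c = traj @ base_cost

    if incurs_lifestyle_cost:
        lifestyle = np.zeros(N_STATES)
        lifestyle[list(PRE_DC_STATES)] = ps["cost_lifestyle"]
        ls_cycle = traj @ lifestyle
        dur = ps.settings.lifestyle_duration
        if dur is not None:
            ls_cycle = np.where(t < dur, ls_cycle, 0.0)
        per_cycle_c = per_cycle_c + ls_cycle

    alive = 1.0 - traj[:, list(DEATH_STATES)].sum(axis=1)
    return LifetimeOutcome(
        cost=float(per_cycle_c @ w),
        qaly=float(per_cycle_q @ w),
        life_years=float(alive.sum()),
        cost_undiscounted=float(per_cycle_c.sum()),
        qaly_undiscounted=float(per_cycle_q.sum()),
    )


# ---------------------------------------------------------------------------
# strategy evaluation


@dataclass
class StrategyOutcome:
    """Lifetime outcome of one screening strategy (screening cost included)."""

    strategy_id: str
    population: str
    age: int
    cost: float
    qaly: float
    life_years: float
    cost_undiscounted: float
    qaly_undiscounted: float
    screening_cost: float
    strata: list[CohortStratum] = field(default_factory=list, repr=False)


def evaluate_strategy(
    ps: ParameterSet,
    strategy_id: str,
    mats: Optional[dict[bool, np.ndarray]] = None,
) -> StrategyOutcome:
    """Run the full cascade-plus-Markov pipeline for one strategy."""
    strategy = ps.strategies[strategy_id]
    if mats is None:
        mats = transition_matrices(ps)
    strata = build_initial_strata(ps, strategy, ps.start_age)
    cascade = classify_cohort(ps, strategy, ps.start_age)

    total = LifetimeOutcome(0.0, 0.0, 0.0, 0.0, 0.0)
    for stratum in strata:
        variant = stratum.treated and stratum.adherent
        traj = run_cohort(stratum.initial_distribution, mats[variant])
        out = accumulate_outcomes(
            traj, ps, incurs_lifestyle_cost=stratum.incurs_lifestyle_cost
        )
        total = total + out.weighted(stratum.mass)

    screen = cascade.expected_screening_cost  # incurred at t = 0, undiscounted
    return StrategyOutcome(
        strategy_id=strategy_id,
        population=ps.population,
        age=ps.start_age,
        cost=total.cost + screen,
        qaly=total.qaly,
        life_years=total.life_years,
        cost_undiscounted=total.cost_undiscounted + screen,
        qaly_undiscounted=total.qaly_undiscounted,
        screening_cost=screen,
        strata=strata,
    )


def evaluate_strategies(
    ps: ParameterSet,
    strategy_ids: Optional[Sequence[str]] = None,
    mats: Optional[dict[bool, np.ndarray]] = None,
) -> dict[str, StrategyOutcome]:
    """Evaluate several strategies sharing one set of transition matrices."""
    if strategy_ids is None:
        strategy_ids = list(ps.strategies)
    if mats is None:
        mats = transition_matrices(ps)
    return {sid: evaluate_strategy(ps, sid, mats) for sid in strategy_ids}


def natural_history_trajectory(ps: ParameterSet) -> np.ndarray:
    """Unscreened cohort trajectory from the population's prior state mix."""
    strata = build_initial_strata(ps, ps.strategies["NO_SCREEN"], ps.start_age)
    return run_cohort(strata[0].initial_distribution, transition_matrices(ps)[False])


def projected_masld_incidence(ps: ParameterSet) -> float:
    """Model-projected MASLD incidence, cases per 1,000 person-years.

    New cases per cycle are disease-free occupants times the incidence
    transition; person-years at risk are approximated mid-cycle among those
    starting the year disease-free.
    """
    traj = natural_history_trajectory(ps)
    mats = transition_matrices(ps)[False]
    at_risk = traj[:-1, S.NO_MASLD]
    p_new = mats[:, S.NO_MASLD, S.F0]
    stay = mats[:, S.NO_MASLD, S.NO_MASLD]
    cases = at_risk * p_new
    person_years = at_risk * (1.0 + stay) / 2.0
    return 1000.0 * float(cases.sum() / person_years.sum())


def trajectory_to_frame(traj: np.ndarray, start_age: int) -> pd.DataFrame:
    df = pd.DataFrame(traj, columns=[s.name for s in S])
    df.insert(0, "age", start_age + np.arange(traj.shape[0]))
    return df
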