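"""Decision-tree screening cascade.

Partitions the screened population into strata by test outcome, using each
test's sensitivity and specificity against the target condition (significant
fibrosis, histological stage >= 2), attaches expected screening costs, and
produces the initial state distributions the Markov engine starts from.

Step-1 scores and elastography are treated as conditionally independent given
true fibrosis status, since published accuracies carry no joint information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ParameterSet, StrategyDef, DomainError
from .states import N_STATES, HealthState

MASS_TOL = 1e-12

#: stratum labels, in tree order
UNSCREENED = "unscreened"
STEP1_NEGATIVE = "step1_negative"
NOT_ATTENDING_TE = "referred_not_attending_te"
TE_NEGATIVE = "te_negative"
TREATED_TRUE = "treated_true_positive"
TREATED_FALSE = "treated_false_positive"


class UndefinedRatioError(ZeroDivisionError):
    """Cost per true positive is undefined when no true positives are detected."""


@dataclass
class CascadeResult:
    """Per-stratum mass fractions and expected testing burden per person."""

    strategy_id: str
    fractions: dict[str, float]
    #: expected number of tests performed per person, keyed by test name
    tests_per_person: dict[str, float]
    expected_screening_cost: float
    #: probability a step-1 test (if any) reads positive
    step1_positive_rate: float
    sigfib_prevalence: float

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9 or any(v < -MASS_TOL for v in self.fractions.values()):
            raise ValueError(f"cascade fractions invalid (sum {total})")


@dataclass
class CohortStratum:
    """A decision-tree leaf feeding the Markov engine."""

    label: str
    mass: float
    initial_distribution: np.ndarray  # length N_STATES, sums to 1
    treated: bool = False
    adherent: bool = False
    incurs_lifestyle_cost: bool = False


def _stage_values(ps: ParameterSet, strategy: StrategyDef):
    """(uptake, sens, spec, cost) per stage."""
    return [
        (ps[s.uptake_param], ps[s.sens_param], ps[s.spec_param], ps[s.cost_param])
        for s in strategy.stages
    ]


def classify_cohort(ps: ParameterSet, strategy: StrategyDef, age: int) -> CascadeResult:
    """Partition a cohort of the given age by screening outcome.

    The disease-positive branch is the population significant-fibrosis
    prevalence ``pi`` for the age band; sensitivities act on that branch and
    false-positive rates on its complement.  Mass is conserved exactly.
    """
    pi = ps.sigfib_prevalence(age)
    stages = _stage_values(ps, strategy)
    fractions = {
        UNSCREENED: 0.0,
        STEP1_NEGATIVE: 0.0,
        NOT_ATTENDING_TE: 0.0,
        TE_NEGATIVE: 0.0,
        TREATED_TRUE: 0.0,
        TREATED_FALSE: 0.0,
    }
    tests: dict[str, float] = {}
    cost = 0.0
    step1_pos = 0.0

    if not stages:  # no screening
        fractions[UNSCREENED] = 1.0
    elif len(stages) == 1:  # TE alone
        u, se, sp, c = stages[0]
        fractions[UNSCREENED] = 1.0 - u
        fractions[TE_NEGATIVE] = u * (pi * (1.0 - se) + (1.0 - pi) * sp)
        fractions[TREATED_TRUE] = u * pi * se
        fractions[TREATED_FALSE] = u * (1.0 - pi) * (1.0 - sp)
        tests[strategy.stages[0].test] = u
        cost = u * c
    else:  # score followed by TE
        u1, se1, sp1, c1 = stages[0]
        u2, se2, sp2, c2 = stages[1]
        step1_pos = pi * se1 + (1.0 - pi) * (1.0 - sp1)
        fractions[UNSCREENED] = 1.0 - u1
        fractions[STEP1_NEGATIVE] = u1 * (pi * (1.0 - se1) + (1.0 - pi) * sp1)
        fractions[NOT_ATTENDING_TE] = u1 * step1_pos * (1.0 - u2)
        fractions[TE_NEGATIVE] = u1 * u2 * (
            pi * se1 * (1.0 - se2) + (1.0 - pi) * (1.0 - sp1) * sp2
        )
        fractions[TREATED_TRUE] = u1 * u2 * pi * se1 * se2
        fractions[TREATED_FALSE] = u1 * u2 * (1.0 - pi) * (1.0 - sp1) * (1.0 - sp2)
        tests[strategy.stages[0].test] = u1
        tests[strategy.stages[1].test] = u1 * step1_pos * u2
        cost = u1 * c1 + u1 * step1_pos * u2 * c2

    return CascadeResult(
        strategy_id=strategy.id,
        fractions=fractions,
        tests_per_person=tests,
        expected_screening_cost=cost,
        step1_positive_rate=step1_pos,
        sigfib_prevalence=pi,
    )


def expected_screening_cost(ps: ParameterSet, strategy: StrategyDef,
                            cascade: CascadeResult) -> float:
    """Expected screening-test spend per person offered screening (THB)."""
    if cascade.strategy_id != strategy.id:
        raise ValueError("cascade was produced by a different strategy")
    return cascade.expected_screening_cost


def cost_per_true_positive(
    ps: ParameterSet,
    strategy: StrategyDef,
    cascade: CascadeResult,
    components: str = "tests",
) -> float:
    """Programme cost per true positive case detected (THB).

    ``components`` selects the numerator convention:

    - ``"tests"``: screening-test costs only;
    - ``"tests+visits"``: adds one clinic visit's non-medical cost per test
      performed;
    - ``"tests+lifestyle"``: adds the first-year lifestyle-programme cost for
      every intervention recipient (true and false positives).
    """
    tp = cascade.fractions[TREATED_TRUE]
    if tp <= 0:
        raise UndefinedRatioError(
            f"strategy {strategy.id} detects no true positives at these inputs"
        )
    cost = cascade.expected_screening_cost
    if components == "tests":
        pass
    elif components == "tests+visits":
        visit = ps["c_visit_food"] + ps["c_visit_transport"]
        cost += visit * sum(cascade.tests_per_person.values())
    elif components == "tests+lifestyle":
        treated = tp + cascade.fractions[TREATED_FALSE]
        cost += ps["cost_lifestyle"] * treated
    else:
        raise ValueError(f"unknown component convention {components!r}")
    return cost / tp


def _conditional_distribution(ps: ParameterSet, age: int, diseased_mass: float,
                              healthy_mass: float) -> np.ndarray:
    """State distribution for a stratum mixing the two true-status branches.

    The disease-positive branch spreads over F2/F3/F4 by the configured
    split; the negative branch spreads over no-MASLD/F0/F1 by their prior
    proportions (Bayes' rule with test outcomes independent of stage within
    each branch).
    """
    masld = ps.masld_prevalence(age)
    pi = ps.sigfib_prevalence(age)
    f01_pool = max(masld - pi, 0.0)
    healthy_total = 1.0 - pi

    dist = np.zeros(N_STATES)
    total = diseased_mass + healthy_mass
    if total <= 0:
        raise ValueError("empty stratum has no state distribution")
    w_dis = diseased_mass / total
    w_hea = healthy_mass / total

    s2, s3, s4 = ps.settings.f2_f3_f4_split
    dist[HealthState.F2] = w_dis * s2
    dist[HealthState.F3] = w_dis * s3
    dist[HealthState.F4_CC] = w_dis * s4

    if healthy_total > 0:
        f0s, f1s = ps.settings.f0_f1_split
        dist[HealthState.NO_MASLD] = w_hea * (1.0 - masld) / healthy_total
        dist[HealthState.F0] = w_hea * f01_pool * f0s / healthy_total
        dist[HealthState.F1] = w_hea * f01_pool * f1s / healthy_total
    return dist


def build_initial_strata(ps: ParameterSet, strategy: StrategyDef,
                         age: int) -> list[CohortStratum]:
    """Decision-tree leaves with Bayes-conditioned initial state distributions.

    True positives on elastography split further into an adherent fraction
    (progression slowed by the treatment effect) and a non-adherent remainder
    that incurs programme costs without benefit, as do false positives.
    """
    pi = ps.sigfib_prevalence(age)
    stages = _stage_values(ps, strategy)
    cascade = classify_cohort(ps, strategy, age)
    fr = cascade.fractions
    adherence = ps["adherence"]

    # (diseased, healthy) un-normalised branch masses per stratum
    if not stages:
        branch = {UNSCREENED: (pi, 1.0 - pi)}
    elif len(stages) == 1:
        u, se, sp, _ = stages[0]
        branch = {
            UNSCREENED: ((1.0 - u) * pi, (1.0 - u) * (1.0 - pi)),
            TE_NEGATIVE: (u * pi * (1.0 - se), u * (1.0 - pi) * sp),
            TREATED_TRUE: (fr[TREATED_TRUE], 0.0),
            TREATED_FALSE: (0.0, fr[TREATED_FALSE]),
        }
    else:
        u1, se1, sp1, _ = stages[0]
        u2, se2, sp2, _ = stages[1]
        branch = {
            UNSCREENED: ((1.0 - u1) * pi, (1.0 - u1) * (1.0 - pi)),
            STEP1_NEGATIVE: (u1 * pi * (1.0 - se1), u1 * (1.0 - pi) * sp1),
            NOT_ATTENDING_TE: (
                u1 * pi * se1 * (1.0 - u2),
                u1 * (1.0 - pi) * (1.0 - sp1) * (1.0 - u2),
            ),
            TE_NEGATIVE: (
                u1 * u2 * pi * se1 * (1.0 - se2),
                u1 * u2 * (1.0 - pi) * (1.0 - sp1) * sp2,
            ),
            TREATED_TRUE: (fr[TREATED_TRUE], 0.0),
            TREATED_FALSE: (0.0, fr[TREATED_FALSE]),
        }

    strata: list[CohortStratum] = []
    for label, (dis, hea) in branch.items():
        mass = dis + hea
        if mass <= MASS_TOL:
            continue
        dist = _conditional_distribution(ps, age, dis, hea)
        if label == TREATED_TRUE:
            if adherence > 0:
                strata.append(CohortStratum(
                    label=f"{label}_adherent", mass=mass * adherence,
                    initial_distribution=dist, treated=True, adherent=True,
                    incurs_lifestyle_cost=True,
                ))
            if adherence < 1:
                strata.append(CohortStratum(
                    label=f"{label}_nonadherent", mass=mass * (1.0 - adherence),
                    initial_distribution=dist, treated=True, adherent=False,
                    incurs_lifestyle_cost=True,
                ))
        elif label == TREATED_FALSE:
            strata.append(CohortStratum(
                label=label, mass=mass, initial_distribution=dist,
                treated=True, adherent=False, incurs_lifestyle_cost=True,
            ))
        else:
            strata.append(CohortStratum(
                label=label, mass=mass, initial_distribution=dist,
            ))

    total = sum(s.mass for s in strata)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"strata masses sum to {total}, expected 1")
    return strata


def strata_to_frame(strata: list[CohortStratum]) -> pd.DataFrame:
    """Tabular export: one row per stratum, one column per starting state."""
    rows = []
    for s in strata:
        row = {
            "stratum": s.label,
            "mass": s.mass,
            "treated": s.treated,
            "adherent": s.adherent,
            "lifestyle_cost": s.incurs_lifestyle_cost,
        }
        row.update({st.name: s.initial_distribution[st] for st in HealthState})
        rows.append(row)
    return pd.DataFrame(rows)
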