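"""Synthetic inputs and independent oracles.

Everything the pipeline consumes from outside — an age-indexed life table and
a national population count — can be generated here so the whole analysis
runs with no downloads.  The module also provides the analytic toy scenario
(closed-form discounted-QALY anchors) and an individual-level
microsimulation that serves as an independent check on the cohort engine's
matrix algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence
import warnings

import numpy as np

from .parameters import LifeTable, ModelSettings, ParameterSet, base_parameters
from .states import DEATH_STATES, N_STATES, HealthState

#: Gompertz parameters of the frozen synthetic "Thailand-like" life table
#: (life expectancy 77.0 y at birth, 28.8 y at age 50)
GOMPERTZ_ALPHA = 4.9645e-05
GOMPERTZ_BETA = 0.09


def synth_life_table(
    alpha: float, beta: float, ages: Iterable[int], source: str = "synthetic-gompertz"
) -> LifeTable:
    """Gompertz life table: annual death probability ``1 - exp(-alpha e^{beta a})``.

    Monotone nondecreasing in age for nonnegative parameters.  Probabilities
    that would exceed ``1 - 1e-9`` are clipped with a warning.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be >= 0")
    ages = tuple(int(a) for a in ages)
    a_arr = np.asarray(ages, dtype=float)
    qx = -np.expm1(-alpha * np.exp(beta * a_arr))
    cap = 1.0 - 1e-9
    if np.any(qx > cap):
        warnings.warn("Gompertz death probability reached 1 before max age; clipped")
        qx = np.minimum(qx, cap)
    return LifeTable(ages, tuple(float(q) for q in qx), source=source)


def thai_like_life_table(max_age: int = 110) -> LifeTable:
    """The frozen synthetic life table used wherever a national table is absent."""
    return synth_life_table(
        GOMPERTZ_ALPHA, GOMPERTZ_BETA, range(0, max_age + 1),
        source="synthetic-thailand-like",
    )


def constant_mortality_life_table(p: float, max_age: int = 200) -> LifeTable:
    """Age-constant annual death probability (geometric survival)."""
    return LifeTable(
        tuple(range(max_age + 1)), tuple([float(p)] * (max_age + 1)),
        source=f"synthetic-constant-p{p}",
    )


# ---------------------------------------------------------------------------
# analytic toy scenario


@dataclass
class SyntheticScenario:
    """A reduced model with closed-form expected outcomes.

    ``expectations`` maps a label to ``(value, formula)`` where the value is
    reproducible from the stored formula string evaluated on the scenario
    parameters.
    """

    params: ParameterSet
    seed: int
    expectations: dict = field(default_factory=dict)


def toy_scenario(
    survival: float = 0.9,
    discount: float = 0.03,
    horizon: int = 400,
    seed: int = 0,
) -> SyntheticScenario:
    """Degenerate scenario whose discounted QALYs are a geometric series.

    All disease transitions are switched off, mortality is age-constant at
    ``1 - survival``, every utility is 1 and every cost 0, so discounted
    QALYs from an alive start equal ``sum_t (s/(1+d))^t``; over an
    effectively infinite horizon this is ``1 / (1 - s/(1+d))`` (7.9230... at
    s = 0.9, d = 0.03).
    """
    ps = base_parameters(
        population="mets",
        start_age=0,
        max_age=horizon,
        life_table=constant_mortality_life_table(1.0 - survival, max_age=horizon),
    )
    for name in list(ps.params):
        if name.startswith("tp_"):
            ps.set(name, 0.0)
        elif name.startswith(("u_",)):
            ps.set(name, 1.0)
        elif name.startswith(("c_", "cost_")):
            ps.set(name, 0.0)
    ps.set("hr_noncirrhotic", 1.0)
    ps.set("hr_cirrhotic", 1.0)
    ps.set("metabolic_multiplier", 1.0)
    ps.set("mort_post_lt", 1.0 - survival)
    ps.set("discount_rate", discount)
    x = survival / (1.0 + discount)
    n = horizon + 1
    scen = SyntheticScenario(params=ps, seed=seed)
    scen.expectations = {
        "discounted_qaly_infinite": (
            float("inf") if x >= 1.0 else 1.0 / (1.0 - x),
            "1 / (1 - s/(1+d))",
        ),
        "discounted_qaly_horizon": (
            float(n) if x == 1.0 else (1.0 - x**n) / (1.0 - x),
            "(1 - x**(horizon+1)) / (1 - x), x = s/(1+d)",
        ),
        "life_expectancy_horizon": (
            float(n) if survival == 1.0
            else (1.0 - survival**n) / (1.0 - survival),
            "(1 - s**(horizon+1)) / (1 - s)",
        ),
    }
    return scen


# ---------------------------------------------------------------------------
# microsimulation oracle


@dataclass
class MicrosimResult:
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    n: int


def microsim_oracle(
    ps: ParameterSet,
    initial_distribution: Sequence[float],
    n: int,
    seed,
    treated_adherent: bool = False,
    incurs_lifestyle_cost: bool = False,
) -> MicrosimResult:
    """Individual-level Monte Carlo check of the cohort engine.

    Simulates ``n`` individuals by categorical sampling from the same
    age-indexed transition rows the cohort engine uses, accumulating the same
    per-state discounted payoffs per individual, but sharing none of the
    occupancy-vector matrix algebra.  Returns means and Monte Carlo standard
    errors of discounted cost and QALYs.
    """
    from .markov import state_cost_vector, state_utility_vector, transition_matrices

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mats = transition_matrices(ps)[treated_adherent]  # (T-1, S, S)
    cum = np.cumsum(mats, axis=2)
    n_cycles = mats.shape[0] + 1

    utilities = state_utility_vector(ps)
    costs = state_cost_vector(ps, incurs_lifestyle_cost=False)
    lifestyle = state_cost_vector(ps, incurs_lifestyle_cost=True) - costs
    duration = ps.settings.lifestyle_duration
    d = ps["discount_rate"]

    init = np.asarray(initial_distribution, dtype=float)
    if abs(init.sum() - 1.0) > 1e-9:
        raise ValueError("initial distribution must sum to 1")
    states = rng.choice(N_STATES, size=n, p=init / init.sum())

    qaly = np.zeros(n)
    cost = np.zeros(n)
    for t in range(n_cycles):
        w = (1.0 + d) ** (-t)
        qaly += w * utilities[states]
        ct = costs[states]
        if incurs_lifestyle_cost and (duration is None or t < duration):
            ct = ct + lifestyle[states]
        cost += w * ct
        if t < n_cycles - 1:
            u = rng.random(n)
            nxt = (u[:, None] > cum[t][states]).sum(axis=1)
            states = np.minimum(nxt, N_STATES - 1)  # guard fp rounding in cumsum

    return MicrosimResult(
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        n=n,
    )
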