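"""Strategy comparison: ICERs, dominance frontier, NMB, age scenarios, thresholds.

Strategies are ranked by effectiveness (QALYs); simply dominated options
(costlier and no more effective than another) are excluded, then incremental
cost-effectiveness ratios are computed along the remaining ladder and any
strategy whose ICER exceeds that of a more effective one is excluded by
extended dominance, iterating until the frontier ICERs strictly increase.
All ratios use full-precision model outputs, never rounded table values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .markov import StrategyOutcome, evaluate_strategies, transition_matrices
from .parameters import ParameterSet, thb_to_usd

NONDOMINATED = "nondominated"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended_dominated"

#: ICER sign conventions: a negative ratio with positive incremental QALYs
#: means the comparator is dominant (cheaper and better).
DOMINANT = "dominant"
DOMINATED_VERDICT = "dominated"


class UndefinedICER(ArithmeticError):
    """Incremental QALYs are zero; the comparison is a dominance case."""


def compute_icer(reference: StrategyOutcome, comparator: StrategyOutcome) -> float:
    """Incremental cost per QALY gained of `comparator` over `reference`.

    Antisymmetric: swapping the arguments flips the sign of both increments,
    leaving the ratio's magnitude unchanged.
    """
    dq = comparator.qaly - reference.qaly
    if dq == 0.0:
        raise UndefinedICER(
            f"{comparator.strategy_id} vs {reference.strategy_id}: zero QALY difference"
        )
    return (comparator.cost - reference.cost) / dq


def net_monetary_benefit(
    outcome: StrategyOutcome, comparator: StrategyOutcome, wtp: float
) -> float:
    """NMB = wtp * incremental QALYs - incremental cost, vs the comparator."""
    return wtp * (outcome.qaly - comparator.qaly) - (outcome.cost - comparator.cost)


@dataclass
class FrontierEntry:
    strategy_id: str
    status: str
    icer_vs_next_cheaper: Optional[float] = None
    dominated_by: Optional[str] = None


def dominance_frontier(outcomes: Sequence[StrategyOutcome]) -> list[FrontierEntry]:
    """Simple and extended dominance over a strategy set (>= 2 entries).

    QALY ties resolve as simple dominance by lower cost; exact cost-and-QALY
    ties are reported jointly as nondominated with the cheaper-or-equal twin
    named, keeping output deterministic.
    """
    if len(outcomes) < 2:
        if len(outcomes) == 1:
            return [FrontierEntry(outcomes[0].strategy_id, NONDOMINATED)]
        raise ValueError("need at least one strategy")

    order = sorted(outcomes, key=lambda o: (o.qaly, -o.cost))
    entries: dict[str, FrontierEntry] = {}

    # simple dominance: costlier and not more effective than some other
    for o in outcomes:
        dominator = None
        for p in outcomes:
            if p is o:
                continue
            better = p.qaly >= o.qaly and p.cost <= o.cost
            strict = p.qaly > o.qaly or p.cost < o.cost
            if better and strict:
                dominator = p.strategy_id
                break
        if dominator is not None:
            entries[o.strategy_id] = FrontierEntry(o.strategy_id, DOMINATED,
                                                   dominated_by=dominator)

    survivors = [o for o in order if o.strategy_id not in entries]

    # extended dominance: drop survivors whose ladder ICER exceeds that of a
    # more effective survivor, until ICERs strictly increase
    while True:
        icers: list[Optional[float]] = [None]
        for prev, cur in zip(survivors, survivors[1:]):
            # exact cost-and-QALY ties survive jointly with no ladder ICER
            icers.append(None if cur.qaly == prev.qaly else compute_icer(prev, cur))
        removed = False
        for i in range(1, len(survivors) - 1):
            if icers[i] is not None and icers[i + 1] is not None and icers[i] >= icers[i + 1]:
                ext = survivors[i]
                entries[ext.strategy_id] = FrontierEntry(
                    ext.strategy_id, EXTENDED_DOMINATED,
                    dominated_by=survivors[i + 1].strategy_id,
                )
                survivors.pop(i)
                removed = True
                break
        if not removed:
            break

    for o, icer in zip(survivors, icers):
        entries[o.strategy_id] = FrontierEntry(o.strategy_id, NONDOMINATED,
                                               icer_vs_next_cheaper=icer)
    return [entries[o.strategy_id] for o in order]


@dataclass
class CEResult:
    """Full comparison table for one population/age."""

    outcomes: dict[str, StrategyOutcome]
    frontier: list[FrontierEntry]
    wtp: float
    comparator_id: str = "NO_SCREEN"

    def icer_vs_comparator(self, strategy_id: str) -> Optional[float]:
        if strategy_id == self.comparator_id:
            return None
        return compute_icer(self.outcomes[self.comparator_id],
                            self.outcomes[strategy_id])

    def cost_effective(self, strategy_id: str) -> bool:
        """WTP verdict from the frontier: on the frontier with ladder ICER <= wtp."""
        entry = next(e for e in self.frontier if e.strategy_id == strategy_id)
        if entry.status != NONDOMINATED:
            return False
        if entry.icer_vs_next_cheaper is None:
            return True
        return entry.icer_vs_next_cheaper <= self.wtp

    def to_frame(self, exchange_rate: float = 34.64) -> pd.DataFrame:
        rows = []
        for e in self.frontier:
            o = self.outcomes[e.strategy_id]
            icer0 = self.icer_vs_comparator(e.strategy_id)
            rows.append({
                "strategy": e.strategy_id,
                "life_expectancy_years": o.life_years,
                "total_cost_thb": o.cost,
                "total_cost_usd": thb_to_usd(o.cost, exchange_rate),
                "total_qalys": o.qaly,
                "icer_vs_no_screen_thb": icer0,
                "frontier_icer_thb": e.icer_vs_next_cheaper,
                "status": e.status,
                "dominated_by": e.dominated_by,
                "cost_effective_at_wtp": self.cost_effective(e.strategy_id),
            })
        return pd.DataFrame(rows)


def run_cea(ps: ParameterSet, strategy_ids: Optional[Sequence[str]] = None) -> CEResult:
    """Evaluate all strategies and assemble the comparison."""
    outcomes = evaluate_strategies(ps, strategy_ids)
    frontier = dominance_frontier(list(outcomes.values()))
    return CEResult(outcomes=outcomes, frontier=frontier, wtp=ps.settings.wtp)


def scenario_sweep(
    ps: ParameterSet, ages: Sequence[int] = (30, 40, 50, 60, 70, 80)
) -> pd.DataFrame:
    """ICERs versus no screening across screening ages.

    Age-banded prevalences are swapped in automatically via the band lookup;
    each age is a fresh lifetime evaluation from that start age.
    """
    rows = []
    for age in ages:
        aged = ps.copy()
        aged.start_age = int(age)
        res = run_cea(aged)
        for sid in aged.strategies:
            if sid == "NO_SCREEN":
                continue
            rows.append({
                "age": age,
                "strategy": sid,
                "icer_vs_no_screen_thb": res.icer_vs_comparator(sid),
                "qaly_gain": res.outcomes[sid].qaly - res.outcomes["NO_SCREEN"].qaly,
                "incremental_cost_thb": res.outcomes[sid].cost
                - res.outcomes["NO_SCREEN"].cost,
                "cost_effective_at_wtp": (
                    res.icer_vs_comparator(sid) is not None
                    and res.icer_vs_comparator(sid) <= ps.settings.wtp
                    and res.outcomes[sid].qaly > res.outcomes["NO_SCREEN"].qaly
                ),
            })
    return pd.DataFrame(rows)


@dataclass
class ThresholdResult:
    strategy_id: str
    verdict: str  # "critical_cost", "already_cost_effective", "never_cost_effective"
    critical_te_cost: Optional[float]
    icer_at_critical: Optional[float]


def threshold_te_cost(
    ps: ParameterSet,
    strategy_id: str,
    wtp: Optional[float] = None,
    rel_tol: float = 1e-6,
    max_iter: int = 200,
) -> ThresholdResult:
    """Maximum elastography unit cost keeping the strategy cost-effective.

    The ICER versus no screening is affine and increasing in the TE unit
    cost at fixed QALYs; bisection finds the cost where it crosses the
    willingness-to-pay threshold to relative tolerance ``rel_tol``.
    """
    if wtp is None:
        wtp = ps.settings.wtp
    base_cost = ps["cost_te"]
    mats = transition_matrices(ps)

    def icer_at(c: float) -> float:
        trial = ps.copy()
        trial.set("cost_te", c)
        outs = evaluate_strategies(trial, ["NO_SCREEN", strategy_id], mats)
        return compute_icer(outs["NO_SCREEN"], outs[strategy_id])

    icer_now = icer_at(base_cost)
    if icer_now <= wtp:
        return ThresholdResult(strategy_id, "already_cost_effective",
                               base_cost, icer_now)
    icer_zero = icer_at(0.0)
    if icer_zero >= wtp:
        return ThresholdResult(strategy_id, "never_cost_effective", None, None)

    lo, hi = 0.0, base_cost
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        icer_mid = icer_at(mid)
        if abs(icer_mid - wtp) / wtp < rel_tol:
            return ThresholdResult(strategy_id, "critical_cost", mid, icer_mid)
        if icer_mid > wtp:
            hi = mid
        else:
            lo = mid
    mid = 0.5 * (lo + hi)
    return ThresholdResult(strategy_id, "critical_cost", mid, icer_at(mid))
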