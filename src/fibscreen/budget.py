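"""Five-year open-cohort budget impact of the screening programme.

Payer perspective, direct screening-test costs only (no post-screening
management, treatment, or non-medical items), undiscounted.  Year 1 screens
the prevalent eligible pool; years 2-5 each add the new cases arising in the
condition pool at the published annual incidence, every person screened once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cascade import classify_cohort
from .parameters import ParameterSet, StrategyDef, thb_to_usd


@dataclass
class BIAInputs:
    """Inputs of one budget projection scenario."""

    population_count: float          # national adult population, eligible ages
    prevalence: float                # prevalent fraction with the condition
    incidence: float                 # annual new cases as fraction of the pool
    horizon_years: int = 5
    uptake_overrides: dict = field(default_factory=dict)  # param -> rate

    def __post_init__(self) -> None:
        if self.population_count <= 0:
            raise ValueError("population_count must be > 0")
        for name, v in (("prevalence", self.prevalence), ("incidence", self.incidence)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")


def bia_inputs_for(ps: ParameterSet, group: Optional[str] = None, **overrides) -> BIAInputs:
    """Build :class:`BIAInputs` from a parameter set's configured settings.

    ``group`` is ``mets``, ``obesity`` or ``both``; the joint-condition
    incidence is approximated as the average of the two published rates.
    """
    bia = ps.settings.bia
    group = group or ps.population
    prevalence = bia.prevalence[group]
    if group == "both":
        incidence = (bia.incidence["mets"] + bia.incidence["obesity"]) / 2.0
    else:
        incidence = bia.incidence[group]
    return BIAInputs(
        population_count=overrides.pop("population_count", bia.national_population),
        prevalence=overrides.pop("prevalence", prevalence),
        incidence=overrides.pop("incidence", incidence),
        horizon_years=overrides.pop("horizon_years", bia.horizon_years),
        **overrides,
    )


def project_eligible_population(inputs: BIAInputs) -> np.ndarray:
    """Newly eligible (never-screened) count per programme year.

    Year 1 is the prevalent pool; each later year adds the pool's incident
    growth (population x prevalence x incidence), so nobody is screened twice.
    """
    pool = inputs.population_count * inputs.prevalence
    eligible = np.full(inputs.horizon_years, pool * inputs.incidence)
    eligible[0] = pool
    return eligible


@dataclass
class BIAResult:
    strategy_id: str
    table: pd.DataFrame  # per-year eligibles, tests, costs; final row = total

    @property
    def total_cost_thb(self) -> float:
        return float(self.table.loc[self.table["year"] == "total", "cost_thb"].iloc[0])

    @property
    def average_annual_cost_thb(self) -> float:
        years = self.table[self.table["year"] != "total"]
        return float(years["cost_thb"].mean())


def compute_budget(
    ps: ParameterSet,
    strategy: StrategyDef,
    inputs: BIAInputs,
) -> BIAResult:
    """Undiscounted screening-test budget per year and over the horizon.

    Per eligible person the expected spend is the cascade's screening cost
    (step-1 uptake x unit cost, plus referral-rate-weighted elastography for
    stepwise strategies); the step-1 positivity rate uses the configured
    reference-age significant-fibrosis prevalence.
    """
    trial = ps
    if inputs.uptake_overrides:
        trial = ps.copy()
        for name, v in inputs.uptake_overrides.items():
            trial.set(name, v)
    cascade = classify_cohort(trial, strategy, trial.settings.bia.reference_age)

    eligible = project_eligible_population(inputs)
    fx = ps.settings.exchange_rate
    rows = []
    for year, n_el in enumerate(eligible, start=1):
        tests = {f"tests_{t}": n_el * per for t, per in cascade.tests_per_person.items()}
        cost = n_el * cascade.expected_screening_cost
        rows.append({
            "year": year, "eligible": n_el, **tests,
            "cost_thb": cost, "cost_usd": thb_to_usd(cost, fx),
        })
    df = pd.DataFrame(rows)
    total = {"year": "total", "eligible": df["eligible"].sum()}
    for col in df.columns:
        if col.startswith(("tests_", "cost_")):
            total[col] = df[col].sum()
    df = pd.concat([df, pd.DataFrame([total])], ignore_index=True).fillna(0.0)
    return BIAResult(strategy_id=strategy.id, table=df)


def budget_summary(
    ps: ParameterSet,
    group: Optional[str] = None,
    strategy_ids: Optional[list[str]] = None,
    **input_overrides,
) -> pd.DataFrame:
    """Average-annual and 5-year totals for each screening strategy."""
    inputs = bia_inputs_for(ps, group, **input_overrides)
    if strategy_ids is None:
        strategy_ids = [s for s in ps.strategies if ps.strategies[s].stages]
    rows = []
    for sid in strategy_ids:
        res = compute_budget(ps, ps.strategies[sid], inputs)
        rows.append({
            "strategy": sid,
            "eligible_total": float(
                res.table.loc[res.table["year"] == "total", "eligible"].iloc[0]
            ),
            "average_annual_cost_thb": res.average_annual_cost_thb,
            "average_annual_cost_usd": thb_to_usd(
                res.average_annual_cost_thb, ps.settings.exchange_rate
            ),
            "total_cost_thb": res.total_cost_thb,
            "total_cost_usd": thb_to_usd(res.total_cost_thb, ps.settings.exchange_rate),
        })
    return pd.DataFrame(rows)
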