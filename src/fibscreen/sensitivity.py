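"""Deterministic one-way sweeps and probabilistic sensitivity analysis.

One-way analysis re-evaluates the ICER at each parameter's bounds (95%
confidence interval for moment-specified inputs, the published range for
rate-type inputs, +/-25% for costs) holding everything else at base, sorted
into tornado order.  The probabilistic analysis draws full parameter sets
(common draw across strategies), evaluates every strategy per draw, and
summarises the draws as cost-effectiveness planes, probability-cost-effective
statistics versus no screening, and acceptability curves (CEAC) over the
competing screening strategies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .markov import InfeasibleParameterError, evaluate_strategies
from .parameters import ParameterSet, sample_parameter_set
from .cea import compute_icer

#: a PSA whose infeasible-draw resample rate exceeds this fraction is suspect
MAX_RESAMPLE_RATE = 0.05


# ---------------------------------------------------------------------------
# one-way deterministic sweeps


def one_way_sweep(
    ps: ParameterSet,
    strategy_id: str,
    comparator_id: str = "NO_SCREEN",
    parameters: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Tornado table of ICER sensitivity to each parameter's bounds.

    Returns one row per swept parameter with the ICER at its low and high
    bound and the absolute range, sorted descending by range.
    """
    if parameters is None:
        parameters = sorted(ps.params)

    def icer_with(name: Optional[str], value: Optional[float]) -> float:
        trial = ps.copy()
        if name is not None:
            trial.set(name, value)
        outs = evaluate_strategies(trial, [comparator_id, strategy_id])
        return compute_icer(outs[comparator_id], outs[strategy_id])

    rows = []
    base_icer = icer_with(None, None)
    for name in parameters:
        bounds = ps.params[name].owsa_bounds()
        if bounds is None:
            continue
        lo, hi = bounds
        icer_lo = icer_with(name, lo)
        icer_hi = icer_with(name, hi)
        rows.append({
            "parameter": name,
            "low": lo,
            "high": hi,
            "icer_low": icer_lo,
            "icer_high": icer_hi,
            "range": abs(icer_hi - icer_lo),
            "base_icer": base_icer,
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("range", ascending=False, ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PSADraw:
    index: int
    outcomes: dict[str, tuple[float, float]]  # strategy -> (cost, qaly)


@dataclass
class PSAResult:
    draws: list[PSADraw]
    n_resampled: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.draws:
            for sid, (cost, qaly) in d.outcomes.items():
                rows.append({"draw": d.index, "strategy": sid,
                             "cost_thb": cost, "qaly": qaly})
        return pd.DataFrame(rows)


def run_psa(
    ps: ParameterSet,
    n: int = 1000,
    seed: int = 0,
    strategy_ids: Optional[Sequence[str]] = None,
) -> PSAResult:
    """Monte Carlo PSA: ``n`` common-random-number draws over all strategies.

    Each draw samples one full parameter set (seeded by ``(seed, index)``,
    so any draw is reproducible in isolation) and evaluates every strategy on
    it.  Draws whose sampled transition rows are infeasible are resampled and
    counted; a resample rate above 5% raises, flagging a suspect
    parameterization.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if strategy_ids is None:
        strategy_ids = list(ps.strategies)
    draws: list[PSADraw] = []
    n_resampled = 0
    for i in range(n):
        for attempt in range(100):
            child_seed = np.random.SeedSequence(entropy=seed, spawn_key=(i, attempt))
            drawn = sample_parameter_set(ps, child_seed)
            try:
                outs = evaluate_strategies(drawn, strategy_ids)
            except InfeasibleParameterError:
                n_resampled += 1
                continue
            draws.append(PSADraw(
                index=i,
                outcomes={sid: (o.cost, o.qaly) for sid, o in outs.items()},
            ))
            break
        else:
            raise RuntimeError(f"draw {i}: could not find a feasible sample")
        if n_resampled > MAX_RESAMPLE_RATE * max(n, 1) + 10:
            raise RuntimeError(
                f"PSA resample rate exceeded {MAX_RESAMPLE_RATE:.0%}; "
                "parameterization suspect"
            )
    return PSAResult(draws=draws, n_resampled=n_resampled, seed=seed)


@dataclass
class PSASummary:
    ce_plane: pd.DataFrame         # draw-level increments vs the comparator
    prob_cost_effective: pd.DataFrame  # per strategy, at the reference wtp
    ceac: pd.DataFrame             # wtp grid x strategy optimality probabilities
    wtp: float


def psa_summaries(
    result: PSAResult,
    ps: ParameterSet,
    comparator_id: str = "NO_SCREEN",
    wtp_grid: Optional[Sequence[float]] = None,
    wtp: Optional[float] = None,
) -> PSASummary:
    """CE plane, probability-cost-effective, and acceptability curves.

    ``prob_cost_effective`` is the fraction of draws with positive net
    monetary benefit versus the comparator at the reference threshold (the
    cost-effectiveness-plane statistic).  The CEAC is computed among the
    screening strategies only, excluding the comparator: at each
    willingness-to-pay the probability that each strategy attains the
    highest NMB versus the comparator.  Probabilities sum to one at every
    grid point, and adding a constant cost to all strategies leaves the CEAC
    unchanged.
    """
    if not result.draws:
        raise ValueError("PSA result contains no draws")
    if wtp is None:
        wtp = ps.settings.wtp
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 300_001.0, 10_000.0)
    strategies = [s for s in result.draws[0].outcomes if s != comparator_id]

    n = len(result.draws)
    d_cost = {s: np.empty(n) for s in strategies}
    d_qaly = {s: np.empty(n) for s in strategies}
    for j, d in enumerate(result.draws):
        c0, q0 = d.outcomes[comparator_id]
        for s in strategies:
            c, q = d.outcomes[s]
            d_cost[s][j] = c - c0
            d_qaly[s][j] = q - q0

    plane_rows = []
    for s in strategies:
        for j in range(n):
            plane_rows.append({"draw": j, "strategy": s,
                               "delta_cost_thb": d_cost[s][j],
                               "delta_qaly": d_qaly[s][j]})
    ce_plane = pd.DataFrame(plane_rows)

    prob_ce = pd.DataFrame([
        {
            "strategy": s,
            "wtp": wtp,
            "prob_cost_effective": float(
                np.mean(wtp * d_qaly[s] - d_cost[s] > 0.0)
            ),
        }
        for s in strategies
    ])

    ceac_rows = []
    for lam in wtp_grid:
        nmb = np.stack([lam * d_qaly[s] - d_cost[s] for s in strategies])
        best = np.argmax(nmb, axis=0)
        row = {"wtp": float(lam)}
        for k, s in enumerate(strategies):
            row[s] = float(np.mean(best == k))
        ceac_rows.append(row)
    ceac = pd.DataFrame(ceac_rows)

    return PSASummary(ce_plane=ce_plane, prob_cost_effective=prob_ce,
                      ceac=ceac, wtp=wtp)
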