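"""Model parameter registry, conversions, configuration I/O and PSA sampling.

The full numeric state of the model lives in a :class:`ParameterSet`: a flat
registry of named :class:`Parameter` objects (each a current value plus its
uncertainty distribution and sweep bounds), together with the life table, the
screening-strategy definitions and the structural settings that are not
subject to uncertainty analysis.

The base-case values are the published Thai inputs: noninvasive-test accuracy
(FIB-4, SAFE, transient elastography against biopsy), age-banded MASLD and
significant-fibrosis prevalence for metabolic-syndrome and obesity
populations, annual fibrosis transition probabilities, state utilities and
2023-THB costs, the lifestyle-modification relative risk reduction, and the
economic settings (3% discounting, 160,000 THB/QALY willingness to pay,
34.64 THB/USD).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import yaml

from .distributions import DistributionSpec, build_distribution
from .states import HealthState

POPULATIONS = ("mets", "obesity")

THB_PER_USD = 34.64


class ValidationError(ValueError):
    """A configuration is structurally invalid (missing/blank mandatory field)."""


class DomainError(ValueError):
    """A supplied value lies outside its scientific domain."""


# ---------------------------------------------------------------------------
# unit conversions


def rate_to_annual_probability(rate: float) -> float:
    """Convert an event rate (per person-year) to an annual probability.

    Uses the constant-hazard identity ``p = 1 - exp(-rate)``; the result is
    always in ``[0, 1)``.
    """
    if rate < 0:
        raise DomainError(f"rate must be >= 0, got {rate}")
    return -math.expm1(-rate)


def probability_to_annual_rate(p: float) -> float:
    """Inverse of :func:`rate_to_annual_probability`."""
    if not (0.0 <= p < 1.0):
        raise DomainError(f"probability must be in [0,1), got {p}")
    return -math.log1p(-p)


def thb_to_usd(amount_thb: float, rate: float = THB_PER_USD) -> float:
    """Convert 2023 Thai baht to US dollars at the fixed study exchange rate."""
    return amount_thb / rate


# ---------------------------------------------------------------------------
# life table


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual all-cause death probabilities.

    ``ages`` must be consecutive integers; probabilities in [0, 1].
    """

    ages: tuple[int, ...]
    qx: tuple[float, ...]
    source: str = "unspecified"

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.qx) or not self.ages:
            raise ValidationError("life table needs equal-length, nonempty columns")
        if list(self.ages) != list(range(self.ages[0], self.ages[-1] + 1)):
            raise ValidationError("life-table ages must be consecutive integers")
        for a, q in zip(self.ages, self.qx):
            if not (0.0 <= q <= 1.0):
                raise DomainError(f"death probability at age {a} out of [0,1]: {q}")

    def prob(self, age: int) -> float:
        if not (self.ages[0] <= age <= self.ages[-1]):
            raise DomainError(
                f"life table covers ages {self.ages[0]}-{self.ages[-1]}, got {age}"
            )
        return self.qx[age - self.ages[0]]

    def life_expectancy(self, age: int) -> float:
        """Remaining person-years from `age` (survival-curve sum, no half-cycle)."""
        i = age - self.ages[0]
        if i < 0:
            raise DomainError(f"age {age} below life-table start {self.ages[0]}")
        surv = np.cumprod(1.0 - np.asarray(self.qx[i:]))
        return float(surv.sum())

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("age\tdeath_probability\n")
            for a, q in zip(self.ages, self.qx):
                fh.write(f"{a}\t{q:.10g}\n")

    @classmethod
    def read(cls, path: Union[str, Path]) -> "LifeTable":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline()
            if "age" not in header.lower():
                raise ValidationError(f"life table {path} missing header line")
            ages, qx = [], []
            for line in fh:
                if not line.strip():
                    continue
                a, q = line.split()[:2]
                ages.append(int(a))
                qx.append(float(q))
        return cls(tuple(ages), tuple(qx), source=str(path))


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class Parameter:
    """One named scalar model input.

    ``domain`` truncates one-way sweep bounds; ``owsa`` overrides the default
    bound rule (95% CI for moment-specified parameters, the printed range for
    range-specified ones, +/-25% for cost parameters).
    """

    value: float
    spec: DistributionSpec
    domain: tuple[float, float] = (-math.inf, math.inf)
    tags: frozenset = field(default_factory=frozenset)
    owsa: Optional[tuple[float, float]] = None

    def owsa_bounds(self) -> Optional[tuple[float, float]]:
        lo_d, hi_d = self.domain
        if self.owsa is not None:
            lo, hi = self.owsa
        elif self.spec.family == "uniform_range":
            lo, hi = self.spec.low, self.spec.high
        elif "cost" in self.tags:
            lo, hi = 0.75 * self.spec.mean, 1.25 * self.spec.mean
        elif self.spec.se > 0:
            lo = self.spec.mean - 1.96 * self.spec.se
            hi = self.spec.mean + 1.96 * self.spec.se
        else:
            return None
        lo, hi = max(lo, lo_d), min(hi, hi_d)
        if lo >= hi:
            return None
        return (lo, hi)


@dataclass(frozen=True)
class Stage:
    """One test in a screening cascade (name + registry keys)."""

    test: str
    cost_param: str
    sens_param: str
    spec_param: str
    uptake_param: str


@dataclass(frozen=True)
class StrategyDef:
    """A screening strategy: an ordered test sequence with uptake rates.

    ``cutoffs`` are descriptive metadata only (the tests are abstracted by
    sensitivity/specificity against biopsy-confirmed fibrosis stage >= 2).
    """

    id: str
    stages: tuple[Stage, ...] = ()
    cutoffs: str = ""

    def __post_init__(self) -> None:
        if len(self.stages) == 2 and self.stages[-1].test != "te":
            raise ValidationError(f"two-stage strategy {self.id} must end in TE")


STRATEGY_IDS = ("NO_SCREEN", "FIB4_TE", "SAFE_TE", "TE_ALONE")

_STAGE_FIB4 = Stage("fib4", "cost_fib4", "sens_fib4", "spec_fib4", "uptake_step1")
_STAGE_SAFE = Stage("safe", "cost_safe", "sens_safe", "spec_safe", "uptake_step1")
_STAGE_TE2 = Stage("te", "cost_te", "sens_te", "spec_te", "uptake_confirm")
_STAGE_TE1 = Stage("te", "cost_te", "sens_te", "spec_te", "uptake_te_alone")


def default_strategies() -> dict[str, StrategyDef]:
    return {
        "NO_SCREEN": StrategyDef("NO_SCREEN"),
        "FIB4_TE": StrategyDef(
            "FIB4_TE", (_STAGE_FIB4, _STAGE_TE2), "FIB-4 >= 1.3 then LSM >= 7.0 kPa"
        ),
        "SAFE_TE": StrategyDef(
            "SAFE_TE", (_STAGE_SAFE, _STAGE_TE2), "SAFE >= 0 then LSM >= 7.0 kPa"
        ),
        "TE_ALONE": StrategyDef("TE_ALONE", (_STAGE_TE1,), "LSM >= 7.0 kPa"),
    }


# ---------------------------------------------------------------------------
# structural settings


@dataclass
class BIASettings:
    """Budget-impact inputs: a national open cohort screened once each."""

    national_population: float = 20_000_000.0  # synthetic default, adults 50-79
    horizon_years: int = 5
    prevalence: dict = field(
        default_factory=lambda: {"mets": 0.180, "obesity": 0.334, "both": 0.152}
    )
    incidence: dict = field(
        default_factory=lambda: {"mets": 0.080, "obesity": 0.009}
    )
    reference_age: int = 50  # age band used for the step-1 positivity rate


@dataclass
class ModelSettings:
    """Structural choices not subject to parameter-uncertainty analysis."""

    wtp: float = 160_000.0
    exchange_rate: float = THB_PER_USD
    # split of the MASLD-without-significant-fibrosis pool across F0:F1
    f0_f1_split: tuple[float, float] = (0.5, 0.5)
    # split of the significant-fibrosis pool across F2:F3:F4
    f2_f3_f4_split: tuple[float, float, float] = (0.60, 0.25, 0.15)
    visits_per_year_pre_dc: float = 2.0
    visits_per_year_advanced: float = 4.0
    # cause-of-death attribution (CVD, liver, other) per state group;
    # placeholders — attribution only, never changes death totals
    cause_split_no_masld: tuple[float, float, float] = (0.30, 0.00, 0.70)
    cause_split_noncirrhotic: tuple[float, float, float] = (0.30, 0.05, 0.65)
    cause_split_cirrhotic: tuple[float, float, float] = (0.40, 0.40, 0.20)
    cause_split_lt: tuple[float, float, float] = (0.20, 0.60, 0.20)
    # lifestyle programme duration in years; None = lifelong
    lifestyle_duration: Optional[int] = None
    lt_age_limit: int = 70  # transplant entry permitted while age <= limit
    bia: BIASettings = field(default_factory=BIASettings)

    def validate(self) -> None:
        for name in ("f0_f1_split", "f2_f3_f4_split"):
            s = getattr(self, name)
            if abs(sum(s) - 1.0) > 1e-9 or any(x < 0 for x in s):
                raise ValidationError(f"{name} must be nonnegative and sum to 1")
        for name in (
            "cause_split_no_masld",
            "cause_split_noncirrhotic",
            "cause_split_cirrhotic",
            "cause_split_lt",
        ):
            s = getattr(self, name)
            if abs(sum(s) - 1.0) > 1e-9 or any(x < 0 for x in s):
                raise ValidationError(f"{name} must be nonnegative and sum to 1")
        if self.wtp < 0 or self.exchange_rate <= 0:
            raise DomainError("wtp must be >= 0 and exchange rate > 0")


# ---------------------------------------------------------------------------
# the parameter set


@dataclass
class ParameterSet:
    """The full numeric state of the model (possibly a PSA draw)."""

    population: str
    start_age: int
    max_age: int
    params: dict[str, Parameter]
    life_table: LifeTable
    strategies: dict[str, StrategyDef]
    settings: ModelSettings
    provenance: list[str] = field(default_factory=list)

    def __getitem__(self, name: str) -> float:
        return self.params[name].value

    def set(self, name: str, value: float) -> None:
        if name not in self.params:
            raise KeyError(name)
        self.params[name] = replace(self.params[name], value=float(value))

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # -- age-banded epidemiology ------------------------------------------

    def masld_prevalence(self, age: int) -> float:
        """Overall MASLD prevalence for the age band containing `age`.

        Floored at the significant-fibrosis prevalence so the residual F0/F1
        pool is never negative (the published age bands overlap imperfectly
        at older ages).
        """
        if age < 18:
            raise DomainError(f"no MASLD prevalence band below age 18 (got {age})")
        if age < 40:
            p = self["prev_masld_18"]
        elif age < 60:
            p = self["prev_masld_40"]
        else:
            p = self["prev_masld_60"]
        return max(p, self.sigfib_prevalence(age))

    def sigfib_prevalence(self, age: int) -> float:
        """Population prevalence of MASLD with significant fibrosis (>= F2)."""
        if age < 30:
            raise DomainError(
                f"no significant-fibrosis prevalence band below age 30 (got {age})"
            )
        band = min(int(age) // 10 * 10, 80)
        return self[f"prev_sigfib_{band}"]

    def validate(self) -> None:
        self.settings.validate()
        if self.population not in POPULATIONS:
            raise ValidationError(f"unknown population {self.population!r}")
        if not self.strategies:
            raise ValidationError("strategy list is empty")
        if not (self.life_table.ages[0] <= self.start_age < self.max_age):
            raise DomainError("start_age must lie in the life table and below max_age")
        if self.life_table.ages[-1] < self.max_age:
            raise DomainError(
                f"life table ends at {self.life_table.ages[-1]} < max_age {self.max_age}"
            )
        for name, p in self.params.items():
            lo, hi = p.domain
            if not (lo <= p.value <= hi):
                raise DomainError(
                    f"parameter {name} = {p.value} outside domain [{lo}, {hi}]"
                )
        for sid, strat in self.strategies.items():
            for st in strat.stages:
                for key in (st.cost_param, st.sens_param, st.spec_param, st.uptake_param):
                    if key not in self.params:
                        raise ValidationError(
                            f"strategy {sid} references undefined parameter {key}"
                        )


# ---------------------------------------------------------------------------
# base-case registry (published Table-of-inputs values)

_PROB = (0.0, 1.0)
_POS = (0.0, math.inf)


def _p(value, family, se=0.0, low=None, high=None, domain=_PROB, tags=(), owsa=None):
    return Parameter(
        value=float(value),
        spec=DistributionSpec(family, float(value), float(se), low, high),
        domain=domain,
        tags=frozenset(tags),
        owsa=owsa,
    )


def _base_param_table(population: str) -> dict[str, Parameter]:
    mets = population == "mets"
    t = {
        # --- test performance (vs biopsy, fibrosis stage >= 2) ---
        "sens_fib4": _p(0.660, "beta", 0.012, tags=("accuracy",)),
        "spec_fib4": _p(0.650, "beta", 0.014, tags=("accuracy",)),
        "sens_safe": _p(0.873, "beta", 0.008, tags=("accuracy",)),
        "spec_safe": _p(0.351, "beta", 0.014, tags=("accuracy",)),
        "sens_te": _p(0.801, "beta", 0.021, tags=("accuracy",)),
        "spec_te": _p(0.730, "beta", 0.026, tags=("accuracy",)),
        # --- screening uptake (ranges, no SE; uniform in PSA) ---
        "uptake_step1": _p(0.90, "uniform_range", low=0.50, high=1.00, tags=("uptake",)),
        "uptake_confirm": _p(0.90, "uniform_range", low=0.65, high=1.00, tags=("uptake",)),
        "uptake_te_alone": _p(0.80, "uniform_range", low=0.30, high=1.00, tags=("uptake",)),
        # --- epidemiology ---
        "prev_masld_18": _p(0.353, "beta", 0.013, tags=("epi",)),
        "prev_masld_40": _p(0.348, "beta", 0.002, tags=("epi",)),
        "prev_masld_60": _p(0.244, "beta", 0.004, tags=("epi",)),
        # annual MASLD incidence rate per person-year (converted to a
        # transition probability for the Markov engine)
        "incidence_masld": _p(
            0.0549 if mets else 0.0509,
            "beta",
            0.0169 if mets else 0.0033,
            tags=("epi",),
        ),
        # --- treatment effect ---
        "rrr": _p(0.204, "rr_lognormal", 0.124, domain=(0.0, 1.0), tags=("effect",)),
        "adherence": _p(1.0, "fixed", domain=_PROB, owsa=(0.60, 1.00)),
        # --- annual transition probabilities ---
        "tp_no_masld_f0": _p(0.055 if mets else 0.051, "beta", 0.017 if mets else 0.003,
                             tags=("transition",)),
        "tp_f0_no_masld": _p(0.024, "beta", 0.013, tags=("transition",)),
        "tp_f0_f1": _p(0.063, "beta", 0.025, tags=("transition",)),
        "tp_f1_f0": _p(0.025, "beta", 0.017, tags=("transition",)),
        "tp_f1_f2": _p(0.067, "beta", 0.025, tags=("transition",)),
        "tp_f2_f1": _p(0.045, "beta", 0.022, tags=("transition",)),
        "tp_f2_f3": _p(0.056, "beta", 0.024, tags=("transition",)),
        "tp_f3_f2": _p(0.058, "beta", 0.024, tags=("transition",)),
        "tp_f3_f4": _p(0.044, "beta", 0.021, tags=("transition",)),
        "tp_f4_f3": _p(0.046, "beta", 0.022, tags=("transition",)),
        "tp_f4_dc": _p(0.043, "beta", 0.041, tags=("transition",)),
        "tp_f4_hcc": _p(0.008, "beta", 0.017, tags=("transition",)),
        "tp_dc_hcc": _p(0.029, "beta", 0.045, tags=("transition",)),
        "tp_dc_lt": _p(0.003, "beta", 0.012, tags=("transition",)),
        "tp_hcc_lt": _p(0.012, "beta", 0.027, tags=("transition",)),
        # --- utilities ---
        "u_no_masld": _p(0.890 if mets else 0.908, "beta", 0.003 if mets else 0.004,
                         tags=("utility",)),
        "u_f0_f3": _p(0.840 if mets else 0.908, "beta", 0.071 if mets else 0.131,
                      tags=("utility",)),
        "u_f4": _p(0.748, "beta", 0.042, tags=("utility",)),
        "u_dc": _p(0.603, "beta", 0.022, tags=("utility",)),
        "u_hcc": _p(0.380, "beta", 0.015, tags=("utility",)),
        "u_lt": _p(0.570, "beta", 0.015, tags=("utility",)),
        "u_post_lt": _p(0.683, "beta", 0.015, tags=("utility",)),
        # --- costs (2023 THB) ---
        # FIB-4/SAFE screening costs are component lab-cost sums; SE taken in
        # quadrature over the components (AST/ALT/platelet [+globulin])
        "cost_fib4": _p(271.0, "gamma", 39.25, domain=_POS, tags=("cost", "screen_cost")),
        "cost_safe": _p(355.4, "gamma", 46.84, domain=_POS, tags=("cost", "screen_cost")),
        "cost_te": _p(2000.0, "gamma", 500.0, domain=_POS, tags=("cost", "screen_cost")),
        "cost_lifestyle": _p(1426.8, "gamma", 356.7, domain=_POS, tags=("cost",)),
        "c_no_masld": (
            _p(2668.5, "gamma", 667.1, domain=_POS, tags=("cost", "hospital"))
            if mets
            else _p(0.0, "fixed", domain=_POS, tags=("cost", "hospital"))
        ),
        "c_f0_f3": _p(8294.1 if mets else 14583.7, "gamma", 2073.5 if mets else 3645.9,
                      domain=_POS, tags=("cost", "hospital")),
        "c_f4": _p(38394.5 if mets else 37568.2, "gamma", 9598.6 if mets else 9392.0,
                   domain=_POS, tags=("cost", "hospital")),
        "c_dc": _p(151164.1, "gamma", 37791.0, domain=_POS, tags=("cost",)),
        "c_hcc": _p(184822.2, "gamma", 46205.5, domain=_POS, tags=("cost",)),
        "c_lt": _p(683432.3, "gamma", 170858.1, domain=_POS, tags=("cost",)),
        "c_post_lt": _p(110287.1, "gamma", 27571.8, domain=_POS, tags=("cost",)),
        # direct non-medical costs per clinic visit (tertiary hospital)
        "c_visit_food": _p(66.2, "gamma", 6.7, domain=_POS, tags=("cost",)),
        "c_visit_transport": _p(179.7, "gamma", 14.6, domain=_POS, tags=("cost",)),
        # --- mortality ---
        "hr_noncirrhotic": _p(1.29, "fixed", domain=_POS, owsa=(1.04, 1.59)),
        "hr_cirrhotic": _p(3.13, "fixed", domain=_POS, owsa=(1.08, 9.12)),
        "metabolic_multiplier": _p(1.0, "fixed", domain=_POS),
        "mort_post_lt": _p(0.05, "fixed", domain=_PROB),  # placeholder, overridable
        # --- economics ---
        "discount_rate": _p(0.03, "fixed", domain=(0.0, 1.0), owsa=(0.0, 0.06)),
        "cost_to_charge_ratio": _p(1.0, "fixed", domain=_POS, owsa=(0.6, 1.2)),
    }
    # population-specific significant-fibrosis prevalence by decade band
    sigfib = {
        "mets": {30: (0.174, 0.079), 40: (0.108, 0.038), 50: (0.116, 0.020),
                 60: (0.114, 0.020), 70: (0.105, 0.029), 80: (0.407, 0.095)},
        "obesity": {30: (0.250, 0.056), 40: (0.227, 0.043), 50: (0.241, 0.029),
                    60: (0.361, 0.028), 70: (0.324, 0.044), 80: (0.522, 0.104)},
    }[population]
    for band, (m, se) in sigfib.items():
        t[f"prev_sigfib_{band}"] = _p(m, "beta", se, tags=("epi",))
    return t


def base_parameters(
    population: str = "mets",
    start_age: int = 50,
    max_age: int = 100,
    life_table: Optional[LifeTable] = None,
    settings: Optional[ModelSettings] = None,
) -> ParameterSet:
    """Construct the base-case :class:`ParameterSet` for one population."""
    if population not in POPULATIONS:
        raise ValidationError(
            f"population must be one of {POPULATIONS}, got {population!r}"
        )
    if life_table is None:
        from .synthetic import thai_like_life_table

        life_table = thai_like_life_table(max_age=max(max_age, 100))
    ps = ParameterSet(
        population=population,
        start_age=start_age,
        max_age=max_age,
        params=_base_param_table(population),
        life_table=life_table,
        strategies=default_strategies(),
        settings=settings or ModelSettings(),
    )
    ps.validate()
    return ps


# ---------------------------------------------------------------------------
# PSA sampling


def sample_parameter_set(base: ParameterSet, seed) -> ParameterSet:
    """Draw one probabilistic parameter set.

    Each stochastic parameter is drawn independently from its configured
    distribution; deterministic parameters pass through unchanged.  The same
    seed always reproduces the same draw (parameters are sampled in sorted
    name order from a single ``numpy`` generator).
    """
    rng = np.random.default_rng(seed)
    out = base.copy()
    out.provenance = list(base.provenance)
    for name in sorted(base.params):
        p = base.params[name]
        if p.spec.stochastic:
            out.set(name, build_distribution(p.spec)(rng))
    return out


# ---------------------------------------------------------------------------
# configuration I/O (YAML)


def _spec_to_dict(spec: DistributionSpec) -> dict:
    d = {"family": spec.family, "mean": spec.mean, "se": spec.se}
    if spec.low is not None:
        d["low"] = spec.low
    if spec.high is not None:
        d["high"] = spec.high
    return d


def parameter_set_to_dict(ps: ParameterSet) -> dict:
    """Full serialization; ``load_parameters`` round-trips it identically."""
    return {
        "population": ps.population,
        "start_age": ps.start_age,
        "max_age": ps.max_age,
        "life_table": {
            "ages": list(ps.life_table.ages),
            "qx": list(ps.life_table.qx),
            "source": ps.life_table.source,
        },
        "economics": {
            "wtp": ps.settings.wtp,
            "exchange_rate": ps.settings.exchange_rate,
        },
        "structure": {
            "f0_f1_split": list(ps.settings.f0_f1_split),
            "f2_f3_f4_split": list(ps.settings.f2_f3_f4_split),
            "visits_per_year_pre_dc": ps.settings.visits_per_year_pre_dc,
            "visits_per_year_advanced": ps.settings.visits_per_year_advanced,
            "cause_split_no_masld": list(ps.settings.cause_split_no_masld),
            "cause_split_noncirrhotic": list(ps.settings.cause_split_noncirrhotic),
            "cause_split_cirrhotic": list(ps.settings.cause_split_cirrhotic),
            "cause_split_lt": list(ps.settings.cause_split_lt),
            "lifestyle_duration": ps.settings.lifestyle_duration,
            "lt_age_limit": ps.settings.lt_age_limit,
        },
        "bia": {
            "national_population": ps.settings.bia.national_population,
            "horizon_years": ps.settings.bia.horizon_years,
            "prevalence": dict(ps.settings.bia.prevalence),
            "incidence": dict(ps.settings.bia.incidence),
            "reference_age": ps.settings.bia.reference_age,
        },
        "strategies": sorted(ps.strategies),
        "overrides": {
            name: {**_spec_to_dict(p.spec), "value": p.value}
            for name, p in sorted(ps.params.items())
        },
    }


def save_parameters(ps: ParameterSet, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(parameter_set_to_dict(ps), fh, sort_keys=True)


def load_parameters(source: Union[str, Path, Mapping]) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a YAML file or mapping.

    Only ``population`` is mandatory; every other field falls back to the
    documented base case, and each applied default is recorded in the
    returned set's ``provenance`` list.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
        if cfg is None:
            raise ValidationError(f"config file {source} is empty")
    else:
        cfg = dict(source)
    if not isinstance(cfg, Mapping):
        raise ValidationError("config must be a mapping")
    if "population" not in cfg:
        raise ValidationError("missing mandatory field: population")

    provenance: list[str] = []

    def get(key, default):
        if key in cfg:
            return cfg[key]
        provenance.append(f"default applied: {key} = {default!r}")
        return default

    population = cfg["population"]
    start_age = int(get("start_age", 50))
    max_age = int(get("max_age", 100))

    lt_cfg = cfg.get("life_table")
    if lt_cfg is None:
        provenance.append("default applied: life_table = synthetic Gompertz table")
        life_table = None
    elif isinstance(lt_cfg, Mapping) and "gompertz" in lt_cfg:
        from .synthetic import synth_life_table

        g = lt_cfg["gompertz"]
        life_table = synth_life_table(
            g["alpha"], g["beta"], range(0, int(g.get("max_age", 110)) + 1)
        )
    elif isinstance(lt_cfg, Mapping):
        life_table = LifeTable(
            tuple(int(a) for a in lt_cfg["ages"]),
            tuple(float(q) for q in lt_cfg["qx"]),
            source=lt_cfg.get("source", "config-inline"),
        )
    else:
        life_table = LifeTable.read(lt_cfg)

    settings = ModelSettings()
    econ = cfg.get("economics", {})
    if "wtp" in econ:
        settings.wtp = float(econ["wtp"])
    if "exchange_rate" in econ:
        settings.exchange_rate = float(econ["exchange_rate"])
    struct = cfg.get("structure", {})
    for key in (
        "f0_f1_split",
        "f2_f3_f4_split",
        "cause_split_no_masld",
        "cause_split_noncirrhotic",
        "cause_split_cirrhotic",
        "cause_split_lt",
    ):
        if key in struct:
            setattr(settings, key, tuple(float(x) for x in struct[key]))
    if "visits_per_year_pre_dc" in struct:
        settings.visits_per_year_pre_dc = float(struct["visits_per_year_pre_dc"])
    if "visits_per_year_advanced" in struct:
        settings.visits_per_year_advanced = float(struct["visits_per_year_advanced"])
    if "lifestyle_duration" in struct:
        v = struct["lifestyle_duration"]
        settings.lifestyle_duration = None if v is None else int(v)
    if "lt_age_limit" in struct:
        settings.lt_age_limit = int(struct["lt_age_limit"])
    bia = cfg.get("bia", {})
    for key in ("national_population", "horizon_years", "reference_age"):
        if key in bia:
            setattr(settings.bia, key, type(getattr(settings.bia, key))(bia[key]))
    for key in ("prevalence", "incidence"):
        if key in bia:
            getattr(settings.bia, key).update(
                {k: float(v) for k, v in bia[key].items()}
            )

    ps = base_parameters(
        population=population,
        start_age=start_age,
        max_age=max_age,
        life_table=life_table,
        settings=settings,
    )

    wanted = get("strategies", sorted(ps.strategies))
    if not wanted:
        raise ValidationError("strategy list is empty")
    unknown = set(wanted) - set(ps.strategies)
    if unknown:
        raise ValidationError(f"unknown strategies in config: {sorted(unknown)}")
    ps.strategies = {k: v for k, v in ps.strategies.items() if k in wanted}

    for name, ov in (cfg.get("overrides") or {}).items():
        if name not in ps.params:
            raise ValidationError(f"override for unknown parameter {name!r}")
        p = ps.params[name]
        if isinstance(ov, Mapping):
            spec = DistributionSpec(
                ov.get("family", p.spec.family),
                float(ov.get("mean", p.spec.mean)),
                float(ov.get("se", p.spec.se)),
                ov.get("low", p.spec.low),
                ov.get("high", p.spec.high),
            )
            value = float(ov.get("value", spec.mean))
        else:
            # bare-number override changes the working value only, keeping
            # the documented uncertainty spec for sweeps and PSA
            spec = p.spec
            value = float(ov)
        ps.params[name] = replace(p, value=value, spec=spec)

    ps.provenance = provenance
    ps.validate()
    return ps
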