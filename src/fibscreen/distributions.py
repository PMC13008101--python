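"""Parameter-uncertainty distributions for deterministic and probabilistic runs.

Every uncertain model input carries a :class:`DistributionSpec` describing the
family used in probabilistic sensitivity analysis (PSA).  Families follow
standard health-economics practice: beta for probabilities (test accuracy,
transition probabilities, prevalences, utilities), gamma for costs, and a
lognormal on the relative risk for the treatment-effect relative risk
reduction (RRR).  Beta and gamma are parameterised by the method of moments
from the reported (mean, SE) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

FAMILIES = ("beta", "gamma", "lognormal", "rr_lognormal", "fixed", "uniform_range")

#: RRR draws are truncated to [0, 1 - _EPS]
_EPS = 1e-12


class ParameterizationError(ValueError):
    """A (mean, SE) pair is incompatible with the requested family."""


@dataclass(frozen=True)
class DistributionSpec:
    """Distribution family plus its reported moments / range.

    Parameters
    ----------
    family:
        One of ``beta``, ``gamma``, ``lognormal``, ``rr_lognormal``,
        ``fixed`` or ``uniform_range``.  ``rr_lognormal`` denotes the
        relative-risk-reduction convention: the relative risk ``RR = 1 - mean``
        is sampled lognormally (moment matched with the same SE) and the draw
        returned as ``1 - RR`` truncated to ``[0, 1)``, keeping the progression
        multiplier ``1 - RRR`` positive.
    mean, se:
        Reported base-case value and standard error.
    low, high:
        Range bounds for ``uniform_range`` parameters (reported as e.g.
        "50-100%" with no SE); also usable as explicit sweep bounds.
    """

    family: str
    mean: float
    se: float = 0.0
    low: Optional[float] = None
    high: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterizationError(f"unknown distribution family {self.family!r}")
        if self.se < 0:
            raise ParameterizationError("se must be >= 0")
        if self.family == "beta" and not (0.0 < self.mean < 1.0):
            raise ParameterizationError(f"beta requires mean in (0,1), got {self.mean}")
        if self.family == "gamma" and self.mean <= 0:
            raise ParameterizationError(f"gamma requires mean > 0, got {self.mean}")
        if self.family == "fixed" and self.se != 0:
            raise ParameterizationError("fixed requires se = 0")
        if self.family == "uniform_range":
            if self.low is None or self.high is None:
                raise ParameterizationError("uniform_range requires low and high")
            if not (self.low <= self.mean <= self.high):
                raise ParameterizationError(
                    f"uniform_range requires low <= mean <= high, got "
                    f"{self.low} <= {self.mean} <= {self.high}"
                )

    @property
    def stochastic(self) -> bool:
        if self.family == "fixed":
            return False
        if self.family == "uniform_range":
            return self.low != self.high
        return self.se > 0


def beta_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments (alpha, beta) shape pair for a beta distribution."""
    var = se * se
    nu = mean * (1.0 - mean) / var - 1.0
    if nu <= 0:
        raise ParameterizationError(
            f"beta with mean {mean} needs se^2 < mean(1-mean); got se={se}"
        )
    return mean * nu, (1.0 - mean) * nu


def gamma_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments (shape, scale) pair for a gamma distribution."""
    var = se * se
    return mean * mean / var, var / mean


def lognormal_moments(mean: float, se: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SE."""
    if mean <= 0:
        raise ParameterizationError("lognormal requires mean > 0")
    sigma2 = np.log1p((se / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


Sampler = Callable[[np.random.Generator], float]


def build_distribution(spec: DistributionSpec) -> Sampler:
    """Return a ``sampler(rng) -> float`` for one parameter.

    A degenerate spec (``fixed``, or zero SE / zero-width range) always
    returns the mean, so deterministic parameters pass through PSA untouched.
    """
    if not spec.stochastic:
        return lambda rng: spec.mean

    if spec.family == "beta":
        a, b = beta_moments(spec.mean, spec.se)
        return lambda rng: float(rng.beta(a, b))

    if spec.family == "gamma":
        shape, scale = gamma_moments(spec.mean, spec.se)
        return lambda rng: float(rng.gamma(shape, scale))

    if spec.family == "lognormal":
        mu, sigma = lognormal_moments(spec.mean, spec.se)
        return lambda rng: float(rng.lognormal(mu, sigma))

    if spec.family == "rr_lognormal":
        # sample the relative risk RR = 1 - RRR on the log scale; the SE is
        # carried over unchanged (var(RR) = var(RRR))
        mu, sigma = lognormal_moments(1.0 - spec.mean, spec.se)
        return lambda rng: float(
            np.clip(1.0 - rng.lognormal(mu, sigma), 0.0, 1.0 - _EPS)
        )

    # uniform_range
    lo, hi = spec.low, spec.high
    return lambda rng: float(rng.uniform(lo, hi))
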