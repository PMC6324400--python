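"""Hospital reference intervals and their parametric instantiation.

A hospital reference interval is, by convention, the central 95% of a
laboratory test's values in a healthy reference population.  To compare an
ICU cohort's distribution against that interval with density-overlap and
standardized-mean-difference statistics, the interval is instantiated as a
parametric "healthy cohort" distribution whose central 95% reproduces the
interval bounds exactly.  A normal family is the canonical reading of how
reference intervals are constructed; a log-normal option exists for strictly
positive analytes whose normal instantiation would place appreciable mass
below zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import ConfigurationError

__all__ = [
    "Z_COVERAGE_95",
    "ReferenceInterval",
    "LabSpec",
    "ReferenceDistribution",
    "interval_to_distribution",
    "sample_reference",
]

#: 0.975 standard-normal quantile used to map a central-95% interval onto
#: a normal distribution's parameters.
Z_COVERAGE_95: float = float(sps.norm.ppf(0.975))

_DIRECTIONS = ("minimum", "maximum")


@dataclass(frozen=True)
class ReferenceInterval:
    """Central-coverage interval of a healthy reference population.

    Parameters
    ----------
    lower, upper : float
        Interval bounds in the test's units; ``lower < upper`` is required.
    coverage : float, default 0.95
        Central probability mass the interval represents.
    """

    lower: float
    upper: float
    coverage: float = 0.95

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ConfigurationError("reference interval bounds must be finite")
        if not self.lower < self.upper:
            raise ConfigurationError(
                f"reference interval requires lower < upper, got "
                f"({self.lower}, {self.upper})"
            )
        if not 0.0 < self.coverage < 1.0:
            raise ConfigurationError("coverage must lie strictly in (0, 1)")

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class LabSpec:
    """One panel entry: test identity, units, worst-value direction(s) and
    the hospital reference interval.

    ``directions`` states which first-day extreme(s) are clinically "worst"
    for the analyte — e.g. the minimum for albumin, the maximum for lactate,
    both for sodium.  ``nonnegative`` marks analytes whose physical support
    is bounded below by zero; density estimates and the instantiated
    reference density are then clipped at zero and renormalized.
    """

    test_id: str
    reference: ReferenceInterval
    directions: tuple[str, ...] = ("minimum", "maximum")
    name: str = ""
    units: str = ""
    nonnegative: bool = False

    def __post_init__(self) -> None:
        if not self.test_id:
            raise ConfigurationError("test_id must be non-empty")
        dirs = tuple(self.directions)
        if not dirs:
            raise ConfigurationError(f"{self.test_id}: directions must be non-empty")
        for d in dirs:
            if d not in _DIRECTIONS:
                raise ConfigurationError(
                    f"{self.test_id}: unknown direction {d!r}; "
                    f"expected one of {_DIRECTIONS}"
                )
        object.__setattr__(self, "directions", dirs)
        if not self.name:
            object.__setattr__(self, "name", self.test_id)

    @property
    def support_floor(self) -> float | None:
        return 0.0 if self.nonnegative else None


@dataclass(frozen=True)
class ReferenceDistribution:
    """Parametric instantiation of a reference interval.

    For the ``"normal"`` family ``mean``/``sd`` are the natural-scale
    parameters; for ``"lognormal"`` they parameterize the distribution of the
    log, so the central 95% interval is ``exp(mean ± z*sd)``.
    """

    mean: float
    sd: float
    family: str = "normal"
    z_coverage: float = field(default=Z_COVERAGE_95)

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if not (math.isfinite(self.mean) and math.isfinite(self.sd)):
            raise ConfigurationError("distribution parameters must be finite")
        if self.sd <= 0:
            raise ConfigurationError("sd must be positive")

    @property
    def _frozen(self):
        if self.family == "normal":
            return sps.norm(loc=self.mean, scale=self.sd)
        return sps.lognorm(s=self.sd, scale=math.exp(self.mean))

    @property
    def natural_mean(self) -> float:
        """Mean on the measurement scale."""
        if self.family == "normal":
            return self.mean
        return math.exp(self.mean + self.sd**2 / 2)

    @property
    def natural_sd(self) -> float:
        """Standard deviation on the measurement scale."""
        if self.family == "normal":
            return self.sd
        m = self.natural_mean
        return m * math.sqrt(math.exp(self.sd**2) - 1.0)

    def pdf(self, x) -> np.ndarray:
        return np.asarray(self._frozen.pdf(np.asarray(x, dtype=float)))

    def ppf(self, q) -> np.ndarray:
        return np.asarray(self._frozen.ppf(q))

    def central_interval(self, coverage: float = 0.95) -> tuple[float, float]:
        tail = (1.0 - coverage) / 2.0
        lo, hi = self._frozen.ppf([tail, 1.0 - tail])
        return float(lo), float(hi)


def interval_to_distribution(
    ref: ReferenceInterval, family: str = "normal"
) -> ReferenceDistribution:
    """Map a reference interval onto the distribution whose central
    ``ref.coverage`` interval equals the interval bounds.

    With ``z`` the appropriate standard-normal quantile: the normal family
    gets ``mean = (lower+upper)/2`` and ``sd = (upper-lower)/(2z)``; the
    log-normal family applies the same mapping to the log-bounds (and
    requires ``lower > 0``).
    """
    if not ref.lower < ref.upper:  # frozen dataclass already checks; belt+braces
        raise ConfigurationError("degenerate interval")
    z = float(sps.norm.ppf(0.5 + ref.coverage / 2.0))
    if family == "normal":
        mean = (ref.lower + ref.upper) / 2.0
        sd = ref.width / (2.0 * z)
    elif family == "lognormal":
        if ref.lower <= 0:
            raise ConfigurationError(
                "lognormal instantiation requires a strictly positive lower bound"
            )
        llo, lhi = math.log(ref.lower), math.log(ref.upper)
        mean = (llo + lhi) / 2.0
        sd = (lhi - llo) / (2.0 * z)
    else:
        raise ConfigurationError(f"unknown family {family!r}")
    return ReferenceDistribution(mean=mean, sd=sd, family=family, z_coverage=z)


def sample_reference(dist: ReferenceDistribution, n: int, seed) -> np.ndarray:
    """Draw ``n`` seeded values from an instantiated reference distribution."""
    if n <= 0:
        raise ValueError(f"n must be a positive integer, got {n}")
    rng = np.random.default_rng(seed)
    if dist.family == "normal":
        return rng.normal(dist.mean, dist.sd, size=n)
    return np.exp(rng.normal(dist.mean, dist.sd, size=n))
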