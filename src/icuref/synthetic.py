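"""Synthetic ICU cohort generator with known ground truth.

Emulates the structure of a deidentified critical-care database export that
the downstream pipeline consumes: per-patient ICU stays with in/out times
and an ICU-death flag, timestamped lab events with repeated same-day
measurements, per-test missingness (some analytes are ordered for only a
minority of patients), group-conditional location shifts between survivors
and non-survivors, right-skewed length of stay, and optionally the masked
ages (> 300 years) that deidentification produces for very old patients.

Because every analyte's per-outcome-group distribution is configured
explicitly, the generator provides a ground-truth record (true group
locations and true standardized mean differences) against which every
downstream estimate can be checked.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import OUTCOME_GROUPS, survivor_quartiles
from .exceptions import ConfigurationError
from .stats import analytic_normal_ovl  # re-export: closed-form OVL oracle

__all__ = [
    "SyntheticAnalyte",
    "SyntheticConfig",
    "GroundTruth",
    "AnalyteTruth",
    "default_analytes",
    "generate",
    "analytic_normal_ovl",
]

_FAMILIES = ("normal", "lognormal")

#: Masked-age value used for patients whose true age is suppressed.
MASKED_AGE = 308.0

_BASE_TIME = pd.Timestamp("2140-01-01 00:00:00")


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent RNG stream derived from (seed, label) so that adding an
    analyte never perturbs the draws of another."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


@dataclass(frozen=True)
class SyntheticAnalyte:
    """One simulated lab test.

    ``loc``/``scale`` parameterize the baseline measurement distribution:
    natural units for the normal family, log-space for the log-normal.
    ``group_shifts`` moves each outcome group's location by a multiple of
    ``scale`` — i.e. the configured shift *is* the true SMD of that group
    against baseline (equal variances).  ``missingness`` is the fraction of
    patients for whom the test is never ordered.
    """

    test_id: str
    loc: float
    scale: float
    family: str = "normal"
    group_shifts: dict[str, float] = field(default_factory=dict)
    missingness: float = 0.0
    severity_monotone: bool = False

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"{self.test_id}: unknown family {self.family!r}")
        if not np.isfinite(self.loc) or not np.isfinite(self.scale):
            raise ConfigurationError(f"{self.test_id}: non-finite parameters")
        if self.scale <= 0:
            raise ConfigurationError(f"{self.test_id}: scale must be positive")
        if not 0.0 <= self.missingness <= 1.0:
            raise ConfigurationError(f"{self.test_id}: missingness must be in [0, 1]")
        for g, s in self.group_shifts.items():
            if g not in OUTCOME_GROUPS:
                raise ConfigurationError(f"{self.test_id}: unknown group {g!r}")
            if not np.isfinite(s):
                raise ConfigurationError(f"{self.test_id}: non-finite shift for {g}")
        if self.severity_monotone:
            worst = abs(self.group_shifts.get("DIED_WORST", 0.0))
            best = abs(self.group_shifts.get("Q1_BEST", 0.0))
            if worst < best:
                raise ConfigurationError(
                    f"{self.test_id}: severity-monotone analyte requires "
                    f"|death shift| >= |best-survivor shift| "
                    f"({worst:.3g} < {best:.3g})"
                )

    def group_loc(self, group: str) -> float:
        return self.loc + self.scale * self.group_shifts.get(group, 0.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic cohort draw.

    Defaults emulate a large adult ICU population: ~8% ICU mortality,
    log-normal LOS with median ≈ 2 days, about three measurements of each
    ordered test during the first day, and 12% of survivors given a decoy
    later stay that downstream first-stay selection must discard.
    """

    n_patients: int
    seed: int = 0
    death_probability: float = 0.08
    los_median_days: float = 2.0
    los_log_sigma: float = 0.9
    panel: tuple[SyntheticAnalyte, ...] = ()
    events_per_first_day: float = 3.0
    multi_stay_fraction: float = 0.12
    mask_age_fraction: float = 0.0
    age_range: tuple[float, float] = (18.0, 89.0)

    def __post_init__(self) -> None:
        if self.n_patients < 0 or int(self.n_patients) != self.n_patients:
            raise ConfigurationError("n_patients must be a non-negative integer")
        for name in ("death_probability", "multi_stay_fraction", "mask_age_fraction"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a fraction in [0, 1]")
        if not (np.isfinite(self.los_median_days) and self.los_median_days > 0):
            raise ConfigurationError("los_median_days must be positive")
        if not (np.isfinite(self.los_log_sigma) and self.los_log_sigma > 0):
            raise ConfigurationError("los_log_sigma must be positive")
        if not (np.isfinite(self.events_per_first_day) and self.events_per_first_day >= 1):
            raise ConfigurationError("events_per_first_day must be >= 1")
        if self.age_range[0] >= self.age_range[1] or self.age_range[0] < 0:
            raise ConfigurationError("age_range must be an increasing pair of ages")
        if not self.panel:
            object.__setattr__(self, "panel", tuple(default_analytes()))
        else:
            object.__setattr__(self, "panel", tuple(self.panel))

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class AnalyteTruth:
    """True measurement-level parameters of one simulated analyte."""

    test_id: str
    family: str
    loc: float
    scale: float
    missingness: float
    group_loc: dict[str, float]
    #: true SMD of each group's measurement distribution vs baseline
    true_smd: dict[str, float]


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    analytes: dict[str, AnalyteTruth]
    groups: pd.Series  # stay_id -> true outcome group of the first stay
    death_count: int


def default_analytes() -> list[SyntheticAnalyte]:
    """Six analytes whose group-shift patterns mimic the qualitative
    divergence structure seen in ICU cohorts: albumin depressed (most in
    non-survivors), lactate and creatinine elevated and right-skewed,
    hemoglobin mildly depressed, sodium nearly centred, glucose elevated.

    Missingness mirrors ordering frequency: albumin ordered for a minority
    of patients (59% missing), lactate for 60% of patients, the rest nearly
    universal.
    """
    return [
        SyntheticAnalyte(
            "albumin", loc=3.1, scale=0.65, missingness=0.59,
            group_shifts={"Q1_BEST": 0.55, "Q2": 0.30, "Q3": 0.05,
                          "Q4": -0.20, "DIED_WORST": -0.85},
            severity_monotone=True,
        ),
        SyntheticAnalyte(
            "lactate", loc=float(np.log(1.9)), scale=0.50, family="lognormal",
            missingness=0.40,
            group_shifts={"Q1_BEST": -0.35, "Q2": -0.15, "Q3": 0.0,
                          "Q4": 0.20, "DIED_WORST": 1.00},
            severity_monotone=True,
        ),
        SyntheticAnalyte(
            "hemoglobin", loc=10.6, scale=1.9, missingness=0.02,
            group_shifts={"Q1_BEST": 0.30, "Q2": 0.10, "Q3": 0.0,
                          "Q4": -0.10, "DIED_WORST": -0.45},
            severity_monotone=True,
        ),
        SyntheticAnalyte(
            "sodium", loc=137.5, scale=3.2, missingness=0.02,
            group_shifts={"Q1_BEST": -0.05, "Q2": 0.0, "Q3": 0.0,
                          "Q4": 0.05, "DIED_WORST": 0.15},
            severity_monotone=True,
        ),
        SyntheticAnalyte(
            "creatinine", loc=0.0, scale=0.45, family="lognormal",
            missingness=0.03,
            group_shifts={"Q1_BEST": -0.30, "Q2": -0.10, "Q3": 0.0,
                          "Q4": 0.25, "DIED_WORST": 0.80},
            severity_monotone=True,
        ),
        SyntheticAnalyte(
            "glucose", loc=135.0, scale=38.0, missingness=0.05,
            group_shifts={"Q1_BEST": -0.20, "Q2": -0.10, "Q3": 0.0,
                          "Q4": 0.15, "DIED_WORST": 0.50},
            severity_monotone=True,
        ),
    ]


def _empty_outputs() -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    stays = pd.DataFrame(
        columns=["subject_id", "stay_id", "intime", "outtime", "age_years",
                 "icu_death", "los_days"]
    )
    events = pd.DataFrame(
        columns=["subject_id", "stay_id", "test_id", "charttime", "value"]
    )
    truth = GroundTruth(
        analytes={},
        groups=pd.Series([], dtype=object, name="outcome_group",
                         index=pd.Index([], name="stay_id")),
        death_count=0,
    )
    return stays, events, truth


def _draw_values(rng: np.random.Generator, analyte: SyntheticAnalyte,
                 locs: np.ndarray) -> np.ndarray:
    draws = rng.normal(locs, analyte.scale)
    if analyte.family == "lognormal":
        return np.exp(draws)
    return draws


def generate(config: SyntheticConfig):
    """Draw a synthetic cohort.

    Returns ``(stays, events, truth)``: a stay table (one first stay per
    patient plus decoy later stays for a ``multi_stay_fraction`` of
    survivors), a lab-event table whose first-day events follow each
    patient's group-conditional distribution, and the :class:`GroundTruth`
    record.  Identical config + seed gives byte-identical tables.
    """
    n = int(config.n_patients)
    if n == 0:
        return _empty_outputs()

    rng = _substream(config.seed, "__cohort__")
    subject_ids = np.array([f"S{i:06d}" for i in range(n)])
    stay_ids = np.array([f"T{i:06d}" for i in range(n)])
    died = rng.random(n) < config.death_probability

    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, n)
    if config.mask_age_fraction > 0:
        masked = rng.random(n) < config.mask_age_fraction
        ages = np.where(masked, MASKED_AGE, ages)

    los = np.exp(rng.normal(np.log(config.los_median_days), config.los_log_sigma, n))
    start_offsets = rng.uniform(0, 3 * 365 * 86400, n).astype(np.int64)
    intime = _BASE_TIME + pd.to_timedelta(start_offsets, unit="s")
    outtime = intime + pd.to_timedelta(np.round(los * 86400).astype(np.int64), unit="s")
    los_days = (outtime - intime).to_numpy() / np.timedelta64(1, "D")

    # True outcome groups (same deterministic rank rule the pipeline uses)
    labels = np.empty(n, dtype=object)
    labels[died] = "DIED_WORST"
    surv_idx = np.flatnonzero(~died)
    if surv_idx.size >= 4:
        q = survivor_quartiles(los_days[surv_idx], stay_ids[surv_idx])
        labels[surv_idx] = np.array(["Q1_BEST", "Q2", "Q3", "Q4"], dtype=object)[q - 1]
    else:
        labels[surv_idx] = "Q1_BEST"

    stays = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "stay_id": stay_ids,
            "intime": intime,
            "outtime": outtime,
            "age_years": np.round(ages, 2),
            "icu_death": died,
            "los_days": los_days,
        }
    )

    # Decoy later stays for a fraction of survivors; their events must be
    # discarded by first-stay selection downstream.
    rng_decoy = _substream(config.seed, "__decoy__")
    n_decoy = int(round(config.multi_stay_fraction * surv_idx.size))
    decoy_idx = np.sort(rng_decoy.permutation(surv_idx)[:n_decoy])
    decoy_stays = None
    if n_decoy > 0:
        gap = rng_decoy.uniform(2, 60, n_decoy)
        dlos = np.exp(
            rng_decoy.normal(np.log(config.los_median_days), config.los_log_sigma, n_decoy)
        )
        d_in = outtime[decoy_idx] + pd.to_timedelta(
            np.round(gap * 86400).astype(np.int64), unit="s"
        )
        d_out = d_in + pd.to_timedelta(np.round(dlos * 86400).astype(np.int64), unit="s")
        decoy_stays = pd.DataFrame(
            {
                "subject_id": subject_ids[decoy_idx],
                "stay_id": np.array([f"D{i:06d}" for i in decoy_idx]),
                "intime": d_in,
                "outtime": d_out,
                "age_years": np.round(ages[decoy_idx], 2),
                "icu_death": np.zeros(n_decoy, dtype=bool),
                "los_days": (d_out - d_in).to_numpy() / np.timedelta64(1, "D"),
            }
        )
        stays = pd.concat([stays, decoy_stays], ignore_index=True)

    stays = stays.sort_values("stay_id", kind="mergesort").reset_index(drop=True)

    # Lab events: per-analyte substreams, first-day window of the true stay
    frames = []
    analyte_truth: dict[str, AnalyteTruth] = {}
    for analyte in config.panel:
        rng_a = _substream(config.seed, analyte.test_id)
        measured = rng_a.random(n) < (1.0 - analyte.missingness)
        counts = 1 + rng_a.poisson(max(config.events_per_first_day - 1.0, 0.0), n)
        counts = np.where(measured, counts, 0)
        total = int(counts.sum())
        if total > 0:
            offsets = rng_a.uniform(0, 24 * 3600, total).astype(np.int64)
            locs = np.repeat(
                np.array([analyte.group_loc(g) for g in labels]), counts
            )
            vals = _draw_values(rng_a, analyte, locs)
            rep = np.repeat(np.arange(n), counts)
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": subject_ids[rep],
                        "stay_id": stay_ids[rep],
                        "test_id": analyte.test_id,
                        "charttime": intime[rep] + pd.to_timedelta(offsets, unit="s"),
                        "value": np.round(vals, 6),
                    }
                )
            )
        # decoy-stay events: drawn off-baseline so leakage is detectable
        if n_decoy > 0:
            rng_d = _substream(config.seed, f"__decoy__:{analyte.test_id}")
            d_counts = 1 + rng_d.poisson(
                max(config.events_per_first_day - 1.0, 0.0), n_decoy
            )
            d_total = int(d_counts.sum())
            d_offsets = rng_d.uniform(0, 24 * 3600, d_total).astype(np.int64)
            d_locs = np.full(d_total, analyte.loc + 2.5 * analyte.scale)
            d_vals = _draw_values(rng_d, analyte, d_locs)
            d_rep = np.repeat(np.arange(n_decoy), d_counts)
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": decoy_stays["subject_id"].to_numpy()[d_rep],
                        "stay_id": decoy_stays["stay_id"].to_numpy()[d_rep],
                        "test_id": analyte.test_id,
                        "charttime": decoy_stays["intime"].to_numpy()[d_rep]
                        + pd.to_timedelta(d_offsets, unit="s"),
                        "value": np.round(d_vals, 6),
                    }
                )
            )

        group_loc = {g: analyte.group_loc(g) for g in OUTCOME_GROUPS}
        analyte_truth[analyte.test_id] = AnalyteTruth(
            test_id=analyte.test_id,
            family=analyte.family,
            loc=analyte.loc,
            scale=analyte.scale,
            missingness=analyte.missingness,
            group_loc=group_loc,
            true_smd={g: analyte.group_shifts.get(g, 0.0) for g in OUTCOME_GROUPS},
        )

    if frames:
        events = pd.concat(frames, ignore_index=True)
        events = events.sort_values(
            ["subject_id", "charttime", "test_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        events = _empty_outputs()[1]

    truth = GroundTruth(
        analytes=analyte_truth,
        groups=pd.Series(
            labels, index=pd.Index(stay_ids, name="stay_id"), name="outcome_group"
        ),
        death_count=int(died.sum()),
    )
    return stays, events, truth
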