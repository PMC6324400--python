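"""Cohort construction: first-ICU-stay selection, worst first-day lab value
extraction, and five-level outcome stratification.

Outcome stratification follows the mortality/length-of-stay scheme: stays
ending in ICU death form the worst group; survivors are split into LOS
quartiles, the shortest-stay quartile being the best outcome.  Lab values
enter the analysis as the per-stay, per-test clinical extremes (minimum
and/or maximum, per the panel's direction configuration) observed during the
first day of the stay.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputDataError
from .reference import LabSpec

__all__ = [
    "OUTCOME_GROUPS",
    "AGE_MASK_SENTINEL",
    "outcome_categorical",
    "select_first_stays",
    "extract_worst_first_day",
    "assign_outcome_groups",
    "build_cohort_table",
    "worst_value_column",
]

#: Ordinal outcome levels, best to worst: survivor LOS quartiles Q1-Q4
#: (shortest stays first), then ICU deaths.
OUTCOME_GROUPS = ("Q1_BEST", "Q2", "Q3", "Q4", "DIED_WORST")

#: Deidentified source databases mask ages of very old patients by shifting
#: them to implausible values; anything above this is treated as "adult,
#: age masked" rather than an error.
AGE_MASK_SENTINEL = 300.0

_STAY_COLUMNS = ("subject_id", "stay_id", "intime", "outtime", "age_years", "icu_death")
_EVENT_COLUMNS = ("subject_id", "test_id", "charttime", "value")


def outcome_categorical(values: Iterable[str]) -> pd.Categorical:
    """Wrap labels as the ordered 5-level outcome categorical."""
    return pd.Categorical(values, categories=list(OUTCOME_GROUPS), ordered=True)


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputDataError(f"{what} table is missing column(s) {missing}")


def _validate_stays(stays: pd.DataFrame) -> pd.DataFrame:
    _require_columns(stays, _STAY_COLUMNS, "stay")
    out = stays.copy()
    if out["stay_id"].duplicated().any():
        dups = out.loc[out["stay_id"].duplicated(), "stay_id"].unique()[:5]
        raise InputDataError(f"duplicate stay_id values, e.g. {list(dups)}")
    out["intime"] = pd.to_datetime(out["intime"])
    out["outtime"] = pd.to_datetime(out["outtime"])
    if not (out["outtime"] > out["intime"]).all():
        bad = out.loc[~(out["outtime"] > out["intime"]), "stay_id"].tolist()[:5]
        raise InputDataError(f"outtime must exceed intime; offending stays {bad}")
    if "los_days" not in out.columns:
        out["los_days"] = (
            (out["outtime"] - out["intime"]).dt.total_seconds() / 86400.0
        )
    return out


def select_first_stays(stays: pd.DataFrame, adult_age_min: float = 18.0) -> pd.DataFrame:
    """Keep exactly one stay per subject — the earliest ``intime``, ties
    broken by smallest ``stay_id`` — then drop stays younger than
    ``adult_age_min`` years (masked-age sentinels above 300 are retained as
    adults)."""
    stays = _validate_stays(stays)
    ordered = stays.sort_values(
        ["subject_id", "intime", "stay_id"], kind="mergesort"
    )
    first = ordered.drop_duplicates("subject_id", keep="first")
    adult = first[
        (first["age_years"] >= adult_age_min)
        | (first["age_years"] > AGE_MASK_SENTINEL)
    ]
    return adult.reset_index(drop=True)


def extract_worst_first_day(
    events: pd.DataFrame,
    stays: pd.DataFrame,
    panel: list[LabSpec],
    window_hours: float = 24.0,
) -> pd.DataFrame:
    """Per-stay, per-test, per-direction worst values within the first-day
    window ``[intime, intime + window_hours)``.

    Events are matched to a stay by ``stay_id`` when present, falling back to
    ``subject_id`` plus the time window otherwise.  A stay with no in-window
    event for a test simply yields no record for that test (per-test
    missingness: the stay still participates in every other analyte's
    analysis).

    Returns a long table with columns ``stay_id, test_id, direction, value``,
    at most one row per (stay, test, direction).
    """
    if window_hours <= 0:
        raise ConfigurationError("window_hours must be positive")
    if not panel:
        raise ConfigurationError("panel must be non-empty")
    stays = _validate_stays(stays)
    _require_columns(events, _EVENT_COLUMNS, "event")

    ev = events.copy()
    ev["charttime"] = pd.to_datetime(ev["charttime"])
    values = pd.to_numeric(ev["value"], errors="coerce")
    bad = values.isna() & ev["value"].notna()
    if bad.any():
        rows = ev.index[bad].tolist()[:5]
        raise InputDataError(f"non-numeric lab values at input rows {rows}")
    ev["value"] = values
    ev = ev[ev["value"].notna() & ev["charttime"].notna()]

    panel_ids = [s.test_id for s in panel]
    absent = sorted(set(panel_ids) - set(ev["test_id"].unique()))
    if absent:
        warnings.warn(
            f"panel test(s) with no events at all: {absent}", stacklevel=2
        )
    ev = ev[ev["test_id"].isin(panel_ids)]

    window = pd.to_timedelta(window_hours, unit="h")
    stay_info = stays[["stay_id", "subject_id", "intime"]]

    has_sid = ev["stay_id"].notna() if "stay_id" in ev.columns else pd.Series(
        False, index=ev.index
    )
    by_stay = ev[has_sid].merge(stay_info[["stay_id", "intime"]], on="stay_id")
    by_subj = (
        ev[~has_sid]
        .drop(columns=["stay_id"], errors="ignore")
        .merge(stay_info, on="subject_id")
    )
    matched = pd.concat([by_stay, by_subj], ignore_index=True)
    in_window = (matched["charttime"] >= matched["intime"]) & (
        matched["charttime"] < matched["intime"] + window
    )
    matched = matched[in_window]

    if matched.empty:
        return pd.DataFrame(columns=["stay_id", "test_id", "direction", "value"])

    agg = matched.groupby(["stay_id", "test_id"], sort=True)["value"].agg(
        ["min", "max"]
    )
    directions = {s.test_id: s.directions for s in panel}
    rows = []
    for (stay_id, test_id), row in agg.iterrows():
        for direction in directions[test_id]:
            rows.append(
                (
                    stay_id,
                    test_id,
                    direction,
                    row["min"] if direction == "minimum" else row["max"],
                )
            )
    return pd.DataFrame(rows, columns=["stay_id", "test_id", "direction", "value"])


def survivor_quartiles(los_days, stay_ids) -> np.ndarray:
    """Quartile labels 1..4 for survivors ranked by (LOS, stay_id) ascending;
    rank r of n maps to ⌈4r/n⌉, so Q1 holds the shortest stays."""
    los = np.asarray(los_days, dtype=float)
    ids = np.asarray(stay_ids)
    n = los.size
    order = np.lexsort((ids, los))
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    return np.ceil(4.0 * ranks / n).astype(int)


def assign_outcome_groups(stays: pd.DataFrame) -> pd.Series:
    """Map each stay to its outcome level: ICU deaths to ``DIED_WORST``,
    survivors to LOS quartiles ``Q1_BEST``..``Q4`` via the deterministic
    ⌈4r/n⌉ rank rule with stay_id tie-break.

    Returns a Series indexed by ``stay_id`` holding the ordered categorical.
    """
    if stays.empty:
        raise InputDataError("cannot stratify an empty stay table")
    stays = _validate_stays(stays)
    died = stays["icu_death"].astype(bool).to_numpy()
    n_surv = int((~died).sum())
    if n_surv < 4:
        raise InputDataError(
            f"only {n_surv} survivor(s): too few for LOS quartiles; merge "
            "groups or enlarge the cohort"
        )
    labels = np.empty(len(stays), dtype=object)
    labels[died] = "DIED_WORST"
    surv = stays[~died]
    q = survivor_quartiles(surv["los_days"].to_numpy(), surv["stay_id"].to_numpy())
    qlabels = np.array(["Q1_BEST", "Q2", "Q3", "Q4"], dtype=object)[q - 1]
    labels[~died] = qlabels
    return pd.Series(
        outcome_categorical(labels),
        index=pd.Index(stays["stay_id"], name="stay_id"),
        name="outcome_group",
    )


def worst_value_column(test_id: str, direction: str) -> str:
    """Wide-table column name for a (test, direction) worst value."""
    return f"{test_id}_{'min' if direction == 'minimum' else 'max'}"


def build_cohort_table(
    stays: pd.DataFrame,
    records: pd.DataFrame,
    groups: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Materialize the wide analysis table: one row per selected stay with
    its outcome group, LOS, demographics, optional covariates, and one
    column per (test, direction) worst value (missing values preserved)."""
    stays = _validate_stays(stays)
    base = stays[["stay_id", "subject_id", "age_years", "icu_death", "los_days"]].copy()
    base = base.set_index("stay_id")
    base["outcome_group"] = groups.reindex(base.index)
    if base["outcome_group"].isna().any():
        missing = base.index[base["outcome_group"].isna()].tolist()[:5]
        raise InputDataError(f"stays without an outcome group, e.g. {missing}")

    if covariates is not None:
        base = base.join(covariates, how="left")

    if not records.empty:
        unknown = set(records["stay_id"]) - set(base.index)
        if unknown:
            raise InputDataError(
                f"worst-value records reference unknown stays, e.g. "
                f"{sorted(unknown)[:5]}"
            )
        wide = records.assign(
            column=[
                worst_value_column(t, d)
                for t, d in zip(records["test_id"], records["direction"])
            ]
        ).pivot(index="stay_id", columns="column", values="value")
        wide = wide[sorted(wide.columns)]
        base = base.join(wide, how="left")
    return base.reset_index()
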