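"""Model/Results interface for the outcome-stratified lab divergence
analysis.

:class:`LabDivergenceModel` is built from a stay table, a lab-event table
and a panel configuration; :meth:`LabDivergenceModel.fit` runs the whole
procedure — first-stay selection, worst first-day extraction, five-level
outcome stratification, KDE/OVL/SMD divergence of the all-ICU, best- and
worst-outcome cohorts against the instantiated hospital reference
distribution, trimmed central intervals, and outcome-proportion profiles —
and returns a :class:`LabDivergenceResults` carrying the estimates with a
``summary()`` table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import cohort as _cohort
from . import profiles as _profiles
from . import stats as _stats
from .exceptions import InputDataError
from .panel import demo_panel
from .reference import LabSpec, interval_to_distribution, sample_reference

__all__ = ["LabDivergenceModel", "LabDivergenceResults"]

#: Comparison labels in the divergence table.
COMPARISONS = (
    "all_vs_reference",
    "best_vs_reference",
    "worst_vs_reference",
    "best_vs_worst",
)

_MIN_GROUP_N = 6  # smallest cohort slice worth a density/Wilcoxon row


class LabDivergenceModel:
    """Outcome-stratified divergence of ICU lab values from hospital
    reference intervals.

    Parameters
    ----------
    stays : DataFrame
        Stay table (``subject_id, stay_id, intime, outtime, age_years,
        icu_death``; ``los_days`` derived if absent).
    events : DataFrame
        Lab events (``subject_id, stay_id, test_id, charttime, value``).
    panel : list of LabSpec, optional
        Analyte panel with reference intervals; defaults to the demo panel.
    window_hours : float
        First-day window ``[intime, intime + window_hours)``.
    adult_age_min : float
        Minimum age (years) for inclusion; masked-age sentinels pass.
    covariates : DataFrame indexed by stay_id, optional
        Extra per-stay columns (e.g. sex, vasopressor/ventilation flags,
        a severity score) carried into the cohort table and summaries.
    """

    def __init__(
        self,
        stays: pd.DataFrame,
        events: pd.DataFrame,
        panel: list[LabSpec] | None = None,
        *,
        window_hours: float = 24.0,
        adult_age_min: float = 18.0,
        covariates: pd.DataFrame | None = None,
    ) -> None:
        self.stays = stays
        self.events = events
        self.panel = list(panel) if panel is not None else demo_panel()
        self.window_hours = float(window_hours)
        self.adult_age_min = float(adult_age_min)
        self.covariates = covariates
        self.ground_truth = None  # populated by from_synthetic

    @classmethod
    def from_synthetic(cls, config, panel: list[LabSpec] | None = None, **kwargs):
        """Build the model from a :class:`~icuref.synthetic.SyntheticConfig`,
        keeping the generator's ground truth on the model."""
        from .synthetic import generate

        stays, events, truth = generate(config)
        model = cls(stays, events, panel=panel, **kwargs)
        model.ground_truth = truth
        return model

    @classmethod
    def from_csv(cls, stays_path, events_path, panel=None, column_map=None, **kwargs):
        """Build the model from stay/event CSV (or parquet) exports."""
        from .io import read_events, read_stays

        stays = read_stays(stays_path, column_map=column_map)
        events = read_events(events_path, column_map=column_map)
        return cls(stays, events, panel=panel, **kwargs)

    def fit(
        self,
        *,
        trim: float = 0.025,
        profile_trim: float = 0.05,
        n_bins: int = 20,
        grid_points: int = 512,
        bandwidth_rule="silverman",
        reference_mode: str = "analytic",
        reference_n: int = 100_000,
        seed: int = 0,
    ) -> "LabDivergenceResults":
        """Run the full analysis.

        ``reference_mode="analytic"`` evaluates the instantiated reference
        distribution exactly (density on the grid, exact mean) — the default,
        which removes one layer of Monte-Carlo noise; ``"sampled"`` draws
        ``reference_n`` seeded values instead, for parity checks.
        """
        if reference_mode not in ("analytic", "sampled"):
            raise ValueError("reference_mode must be 'analytic' or 'sampled'")

        first = _cohort.select_first_stays(self.stays, self.adult_age_min)
        if first.empty:
            raise InputDataError("no stays remain after first-stay/adult selection")
        groups = _cohort.assign_outcome_groups(first)
        records = _cohort.extract_worst_first_day(
            self.events, first, self.panel, self.window_hours
        )
        cohort_table = _cohort.build_cohort_table(
            first, records, groups, self.covariates
        )

        rows: list[_stats.DivergenceResult] = []
        intervals: list[dict] = []
        profile_map: dict[tuple[str, str], _profiles.OutcomeProfile] = {}
        densities: dict[tuple[str, str], dict[str, _stats.DensityEstimate]] = {}

        indexed = cohort_table.set_index("stay_id")
        grp = indexed["outcome_group"]

        for spec in self.panel:
            dist = interval_to_distribution(spec.reference)
            floor = spec.support_floor
            for direction in spec.directions:
                col = _cohort.worst_value_column(spec.test_id, direction)
                if col not in indexed.columns:
                    continue
                values = indexed[col]
                x_all = values.dropna().to_numpy(dtype=float)
                if np.unique(x_all).size < 2 or x_all.size < _MIN_GROUP_N:
                    warnings.warn(
                        f"{col}: too few values ({x_all.size}); skipped",
                        stacklevel=2,
                    )
                    continue

                slices = {
                    "all": x_all,
                    "best": values[grp == "Q1_BEST"].dropna().to_numpy(dtype=float),
                    "worst": values[grp == "DIED_WORST"].dropna().to_numpy(dtype=float),
                }
                dens: dict[str, _stats.DensityEstimate] = {}
                for label, x in slices.items():
                    if np.unique(x).size >= 2 and x.size >= _MIN_GROUP_N:
                        dens[label] = _stats.estimate_density(
                            x, bandwidth_rule, grid_points, support_floor=floor
                        )
                if reference_mode == "analytic":
                    ref_sample = None
                    dens["reference"] = _stats.reference_density(
                        dist, grid_points, support_floor=floor
                    )
                else:
                    ref_sample = sample_reference(dist, reference_n, seed)
                    dens["reference"] = _stats.estimate_density(
                        ref_sample, bandwidth_rule, grid_points, support_floor=floor
                    )
                densities[(spec.test_id, direction)] = dens

                for label in ("all", "best", "worst"):
                    if label not in dens:
                        continue
                    x = slices[label]
                    if ref_sample is None:
                        smd = _stats.smd_vs_reference(x, dist)
                        n2 = 0
                    else:
                        smd = _stats.standardized_mean_difference(
                            x, ref_sample, pooling="balanced"
                        )
                        n2 = ref_sample.size
                    ovl = _stats.overlap_coefficient(dens[label], dens["reference"])
                    p = _stats.location_shift_test(x, dist)
                    rows.append(
                        _stats.DivergenceResult(
                            test_id=spec.test_id,
                            direction=direction,
                            comparison=f"{label}_vs_reference",
                            ovl=ovl,
                            smd=smd,
                            effect_band=_stats.classify_effect_size(smd),
                            p_value=p,
                            n1=x.size,
                            n2=n2,
                        )
                    )

                if "best" in dens and "worst" in dens:
                    xb, xw = slices["best"], slices["worst"]
                    smd = _stats.standardized_mean_difference(xb, xw)
                    _, p = _stats.group_comparison([xb, xw], kind="continuous")
                    rows.append(
                        _stats.DivergenceResult(
                            test_id=spec.test_id,
                            direction=direction,
                            comparison="best_vs_worst",
                            ovl=_stats.overlap_coefficient(dens["best"], dens["worst"]),
                            smd=smd,
                            effect_band=_stats.classify_effect_size(smd),
                            p_value=p,
                            n1=xb.size,
                            n2=xw.size,
                        )
                    )

                for label, x in slices.items():
                    if x.size == 0:
                        continue
                    ci = _stats.central_interval(x, trim)
                    intervals.append(
                        {
                            "test_id": spec.test_id,
                            "direction": direction,
                            "cohort": label,
                            "lower": ci.lower,
                            "upper": ci.upper,
                            "trim_fraction": trim,
                            "n": x.size,
                        }
                    )

                profile_map[(spec.test_id, direction)] = _profiles.outcome_proportions(
                    values,
                    grp,
                    n_bins=n_bins,
                    trim_fraction=profile_trim,
                    test_id=spec.test_id,
                    direction=direction,
                )

        divergence = pd.DataFrame([r.__dict__ for r in rows])
        central = pd.DataFrame(intervals)
        return LabDivergenceResults(
            model=self,
            cohort=cohort_table,
            groups=groups,
            divergence=divergence,
            central_intervals=central,
            profiles=profile_map,
            densities=densities,
        )


class LabDivergenceResults:
    """Fitted results: the cohort table, the divergence estimates and the
    outcome profiles, with summary/plotting helpers.

    Attributes
    ----------
    cohort : DataFrame
        One row per included first stay; outcome group, LOS, demographics,
        covariates and worst-value columns.
    divergence : DataFrame
        Long table: (test_id, direction, comparison) → OVL, SMD, effect
        band, p-value, group sizes.
    central_intervals : DataFrame
        Trimmed central-95% bounds per (test, direction, cohort slice).
    profiles : dict
        (test_id, direction) → :class:`~icuref.profiles.OutcomeProfile`.
    densities : dict
        (test_id, direction) → {cohort slice → DensityEstimate}.
    """

    def __init__(self, model, cohort, groups, divergence, central_intervals,
                 profiles, densities):
        self.model = model
        self.cohort = cohort
        self.groups = groups
        self.divergence = divergence
        self.central_intervals = central_intervals
        self.profiles = profiles
        self.densities = densities

    # ------------------------------------------------------------------ #
    @property
    def group_sizes(self) -> pd.Series:
        return self.groups.value_counts().reindex(list(_cohort.OUTCOME_GROUPS))

    def missingness(self) -> pd.Series:
        """Per-(test, direction) missing fraction: 1 − non-missing/cohort rows."""
        n = len(self.cohort)
        out = {}
        for spec in self.model.panel:
            for direction in spec.directions:
                col = _cohort.worst_value_column(spec.test_id, direction)
                present = self.cohort[col].notna().sum() if col in self.cohort else 0
                out[col] = 1.0 - present / n if n else 1.0
        return pd.Series(out, name="missingness")

    def divergence_wide(self) -> pd.DataFrame:
        """Divergence table in the three-reference-comparison layout: one
        row per (test, direction) with OVL/SMD for all/best/worst vs the
        reference, best-vs-worst OVL/SMD, and p-values.  Full precision
        plus 2-decimal display columns."""
        if self.divergence.empty:
            return pd.DataFrame()
        short = {
            "all_vs_reference": "all",
            "best_vs_reference": "best",
            "worst_vs_reference": "worst",
            "best_vs_worst": "best_worst",
        }
        d = self.divergence.assign(tag=self.divergence["comparison"].map(short))
        wide = d.pivot(index=["test_id", "direction"], columns="tag",
                       values=["ovl", "smd", "p_value"])
        wide.columns = [f"{a}_{b}" for a, b in wide.columns]
        order = [
            c
            for c in (
                "ovl_all", "smd_all", "ovl_best", "smd_best",
                "ovl_worst", "smd_worst", "ovl_best_worst", "smd_best_worst",
                "p_value_all", "p_value_best", "p_value_worst",
                "p_value_best_worst",
            )
            if c in wide.columns
        ]
        wide = wide[order].reset_index()
        for col in order:
            if col.startswith(("ovl", "smd")):
                wide[f"{col}_display"] = wide[col].round(2)
        return wide

    def ovl_summary(self) -> dict:
        """Mean and IQR of the OVL across the reference comparisons."""
        mask = self.divergence["comparison"].str.endswith("_vs_reference")
        ovl = self.divergence.loc[mask, "ovl"]
        q25, q75 = (np.quantile(ovl, [0.25, 0.75]) if len(ovl) else (np.nan, np.nan))
        return {
            "mean": float(ovl.mean()) if len(ovl) else float("nan"),
            "iqr": (float(q25), float(q75)),
            "n_comparisons": int(len(ovl)),
        }

    def summarize_best_worst(self) -> pd.DataFrame:
        """Baseline-characteristics comparison of the best and worst outcome
        groups: median (IQR) and Kruskal-Wallis p for continuous columns,
        counts (%) and χ² p for boolean/categorical covariates.  A column
        entirely missing in a group is flagged, not fatal."""
        best = self.cohort[self.cohort["outcome_group"] == "Q1_BEST"]
        worst = self.cohort[self.cohort["outcome_group"] == "DIED_WORST"]
        if best.empty or worst.empty:
            raise InputDataError("cohort lacks best and/or worst outcome rows")

        skip = {"stay_id", "subject_id", "outcome_group", "icu_death"}
        rows = []
        for col in self.cohort.columns:
            if col in skip:
                continue
            b, w = best[col], worst[col]
            if pd.api.types.is_bool_dtype(self.cohort[col]):
                tb, tw = int(b.sum()), int(w.sum())
                table = [[tb, len(b) - tb], [tw, len(w) - tw]]
                try:
                    _, p = _stats.group_comparison(table, kind="categorical")
                except InputDataError:
                    p = np.nan
                rows.append(
                    {
                        "variable": col, "kind": "categorical",
                        "best": f"{tb} ({100 * tb / max(len(b), 1):.1f}%)",
                        "worst": f"{tw} ({100 * tw / max(len(w), 1):.1f}%)",
                        "p_value": p, "note": "",
                    }
                )
            elif pd.api.types.is_numeric_dtype(self.cohort[col]):
                bv, wv = b.dropna(), w.dropna()
                if bv.empty or wv.empty:
                    rows.append(
                        {
                            "variable": col, "kind": "continuous",
                            "best": _fmt_median_iqr(bv),
                            "worst": _fmt_median_iqr(wv),
                            "p_value": np.nan,
                            "note": "entirely missing in a group",
                        }
                    )
                    continue
                _, p = _stats.group_comparison([bv, wv], kind="continuous")
                rows.append(
                    {
                        "variable": col, "kind": "continuous",
                        "best": _fmt_median_iqr(bv),
                        "worst": _fmt_median_iqr(wv),
                        "p_value": p, "note": "",
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary in the spirit of a fitted-model report."""
        sizes = self.group_sizes
        ovl = self.ovl_summary()
        lines = [
            "Outcome-stratified ICU lab divergence",
            "=" * 54,
            f"Included first stays: {len(self.cohort)}",
            "Outcome groups (best -> worst): "
            + ", ".join(f"{g}={int(sizes[g])}" for g in sizes.index),
            f"Panel analytes: {len(self.model.panel)}; "
            f"first-day window: {self.model.window_hours:g} h",
            f"Mean OVL vs reference: {ovl['mean']:.2f} "
            f"(IQR {ovl['iqr'][0]:.2f}-{ovl['iqr'][1]:.2f}, "
            f"{ovl['n_comparisons']} comparisons)",
            "",
        ]
        wide = self.divergence_wide()
        if not wide.empty:
            cols = [
                c
                for c in (
                    "test_id", "direction", "ovl_all", "smd_all",
                    "ovl_best", "smd_best", "ovl_worst", "smd_worst",
                )
                if c in wide.columns
            ]
            lines.append(
                wide[cols].to_string(
                    index=False, float_format=lambda v: f"{v:.2f}"
                )
            )
        return "\n".join(lines)

    # plotting ---------------------------------------------------------- #
    def plot_density(self, test_id: str, direction: str, ax=None):
        from .plotting import plot_density_comparison

        return plot_density_comparison(self, test_id, direction, ax=ax)

    def plot_profile(self, test_id: str, direction: str, ax=None):
        from .plotting import plot_outcome_profile

        return plot_outcome_profile(self, test_id, direction, ax=ax)


def _fmt_median_iqr(values: pd.Series) -> str:
    if values.empty:
        return "–"
    q25, med, q75 = np.quantile(values.to_numpy(dtype=float), [0.25, 0.5, 0.75])
    return f"{med:.2f} ({q25:.2f}-{q75:.2f})"
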