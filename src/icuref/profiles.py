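"""Outcome-probability profiles along the lab-value axis.

For one analyte/direction, the worst first-day values of all stays are
binned (after excluding a small fraction of extreme values where estimates
would be unstable) and, within each bin, the relative proportions of the
five outcome groups are computed.  Stacked, these proportions visualize how
the likelihood of each outcome changes across the range of a lab test —
e.g. the share of non-survivors rising sharply once lactate exceeds a few
mmol/L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import OUTCOME_GROUPS
from .exceptions import InputDataError
from .stats import _clean_values

__all__ = ["OutcomeProfile", "trim_extreme_support", "outcome_proportions"]


@dataclass(frozen=True)
class OutcomeProfile:
    """Binned outcome-proportion profile for one (test, direction).

    ``counts`` is bins × 5 (group order best → worst); ``proportions`` holds
    NaN rows for empty bins (they are reported, not dropped, so bin edges
    stay stable); ``kept_range`` is the value range after extreme-value
    exclusion.
    """

    test_id: str
    direction: str
    bin_edges: np.ndarray
    counts: np.ndarray
    proportions: np.ndarray
    kept_range: tuple[float, float]

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        props = np.asarray(self.proportions, dtype=float)
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin_edges must be strictly increasing")
        if counts.shape != (edges.size - 1, len(OUTCOME_GROUPS)):
            raise ValueError("counts must be (n_bins, 5)")
        if props.shape != counts.shape:
            raise ValueError("proportions must match counts shape")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "proportions", props)

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per bin with edges, counts and
        proportions per outcome group."""
        df = pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "n": self.counts.sum(axis=1),
            }
        )
        for j, g in enumerate(OUTCOME_GROUPS):
            df[f"count_{g}"] = self.counts[:, j]
        for j, g in enumerate(OUTCOME_GROUPS):
            df[f"prop_{g}"] = self.proportions[:, j]
        return df


def trim_extreme_support(values, fraction: float = 0.05) -> tuple[float, float]:
    """Value range after excluding ``fraction`` total probability mass,
    split evenly between the two tails (linear-interpolation quantiles).

    ``fraction=0`` keeps the full observed range.
    """
    x = _clean_values(values)
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    lo, hi = np.quantile(x, [fraction / 2.0, 1.0 - fraction / 2.0], method="linear")
    return float(lo), float(hi)


def outcome_proportions(
    values: pd.Series,
    groups: pd.Series,
    n_bins: int = 20,
    trim_fraction: float = 0.05,
    test_id: str = "",
    direction: str = "",
) -> OutcomeProfile:
    """Bin per-stay worst values and tally outcome-group proportions.

    Parameters
    ----------
    values : Series indexed by stay_id
        Worst first-day values (NaN = missing; those stays are skipped).
    groups : Series indexed by stay_id
        Outcome group per stay; every valued stay must have one.
    n_bins : int
        Number of equal-width bins over the kept range; the final bin is
        right-closed, all others half-open.
    trim_fraction : float
        Total extreme mass excluded before binning (split per tail).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    vals = values.dropna()
    if vals.empty:
        raise InputDataError("no non-missing values to profile")
    g = groups.reindex(vals.index)
    if g.isna().any():
        missing = vals.index[g.isna()].tolist()[:5]
        raise InputDataError(f"valued stays without an outcome group, e.g. {missing}")

    x = vals.to_numpy(dtype=float)
    lo, hi = trim_extreme_support(x, trim_fraction)
    if hi > lo:
        edges = np.linspace(lo, hi, n_bins + 1)
    else:  # all kept values identical: centre a degenerate range
        edges = np.linspace(lo - 0.5, hi + 0.5, n_bins + 1)

    keep = (x >= lo) & (x <= hi)
    xk = x[keep]
    gk = np.asarray(g.astype(str))[keep]

    idx = np.clip(np.searchsorted(edges, xk, side="right") - 1, 0, n_bins - 1)
    counts = np.zeros((n_bins, len(OUTCOME_GROUPS)), dtype=np.int64)
    gcode = {name: j for j, name in enumerate(OUTCOME_GROUPS)}
    codes = np.array([gcode[name] for name in gk])
    np.add.at(counts, (idx, codes), 1)

    totals = counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        proportions = np.where(totals > 0, counts / totals, np.nan)

    return OutcomeProfile(
        test_id=test_id,
        direction=direction,
        bin_edges=edges,
        counts=counts,
        proportions=proportions,
        kept_range=(lo, hi),
    )
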