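"""Statistical core: kernel density estimates, trimmed central intervals,
the overlapping coefficient (OVL), Cohen's standardized mean difference
(SMD), and the nonparametric hypothesis tests used in the cohort summaries.

OVL is the integral of the pointwise minimum of two probability densities
(0 = disjoint, 1 = identical); SMD is the difference of two group means in
units of their pooled standard deviation.  Together they quantify how far an
ICU cohort's lab-value distribution sits from the hospital reference
interval, and from one outcome group to another.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import InputDataError
from .reference import ReferenceDistribution

__all__ = [
    "DensityEstimate",
    "CentralInterval",
    "DivergenceResult",
    "silverman_bandwidth",
    "estimate_density",
    "reference_density",
    "central_interval",
    "overlap_coefficient",
    "standardized_mean_difference",
    "smd_vs_reference",
    "classify_effect_size",
    "location_shift_test",
    "group_comparison",
    "analytic_normal_ovl",
]


@dataclass(frozen=True)
class DensityEstimate:
    """A probability density evaluated on a strictly increasing grid.

    ``density`` is renormalized so its trapezoidal integral over ``grid`` is
    1; ``bandwidth`` is the Gaussian kernel standard deviation (NaN for an
    analytic curve), ``n`` the sample size behind the estimate.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n: int

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        if grid.ndim != 1 or grid.shape != dens.shape:
            raise ValueError("grid and density must be 1-D arrays of equal length")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(dens < 0):
            raise ValueError("density must be non-negative")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "density", dens)

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass(frozen=True)
class CentralInterval:
    """Trimmed central interval (``trim_fraction`` excluded per tail)."""

    lower: float
    upper: float
    trim_fraction: float = 0.025

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower must not exceed upper")


@dataclass(frozen=True)
class DivergenceResult:
    """The (OVL, SMD, p-value) triple for one distribution comparison."""

    test_id: str
    direction: str
    comparison: str
    ovl: float
    smd: float
    effect_band: str
    p_value: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (np.isnan(self.ovl) or 0.0 <= self.ovl <= 1.0):
            raise ValueError("ovl must lie in [0, 1]")
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def _clean_values(values, min_distinct: int = 1) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise InputDataError("empty value list")
    if not np.all(np.isfinite(x)):
        raise InputDataError("non-finite values in input")
    if np.unique(x).size < min_distinct:
        raise InputDataError(f"need at least {min_distinct} distinct values")
    return x


def silverman_bandwidth(values) -> float:
    """Rule-of-thumb Gaussian-kernel bandwidth 0.9·min(s, IQR/1.34)·n^(-1/5).

    Falls back to the sample SD when the IQR degenerates to zero.
    """
    x = _clean_values(values, min_distinct=2)
    s = float(np.std(x, ddof=1))
    q25, q75 = np.quantile(x, [0.25, 0.75])
    iqr = float(q75 - q25)
    spread = min(s, iqr / 1.34) if iqr > 0 else s
    return 0.9 * spread * x.size ** (-0.2)


def estimate_density(
    values,
    bandwidth_rule="silverman",
    grid_points: int = 512,
    support_floor: float | None = None,
) -> DensityEstimate:
    """Gaussian-kernel KDE on an even grid spanning [min−3h, max+3h].

    The grid is clipped at ``support_floor`` (e.g. 0 for analytes that cannot
    be negative) and the density renormalized to integrate to 1 on the grid,
    which removes any kernel mass that would spill outside the support.

    Parameters
    ----------
    bandwidth_rule : {"silverman", "scott"}, float, or callable
        Bandwidth selector; a float fixes h directly, a callable receives the
        sample and returns h.
    """
    x = _clean_values(values, min_distinct=2)
    if grid_points < 2:
        raise ValueError("grid_points must be >= 2")
    if bandwidth_rule == "silverman":
        h = silverman_bandwidth(x)
    elif bandwidth_rule == "scott":
        h = 1.06 * float(np.std(x, ddof=1)) * x.size ** (-0.2)
    elif callable(bandwidth_rule):
        h = float(bandwidth_rule(x))
    else:
        h = float(bandwidth_rule)
    if not (h > 0 and math.isfinite(h)):
        raise ValueError(f"bandwidth must be positive and finite, got {h}")

    lo = float(x.min()) - 3.0 * h
    hi = float(x.max()) + 3.0 * h
    if support_floor is not None:
        lo = max(lo, float(support_floor))
    if hi <= lo:
        hi = lo + 6.0 * h
    grid = np.linspace(lo, hi, grid_points)

    # gaussian_kde's kernel sd is factor * sample sd (ddof=1)
    kde = sps.gaussian_kde(x, bw_method=h / float(np.std(x, ddof=1)))
    dens = kde(grid)
    dens = np.clip(dens, 0.0, None)
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise InputDataError("degenerate density estimate")
    return DensityEstimate(grid=grid, density=dens / area, bandwidth=h, n=x.size)


def reference_density(
    dist: ReferenceDistribution,
    grid_points: int = 512,
    support_floor: float | None = None,
    span: float = 4.0,
) -> DensityEstimate:
    """Evaluate an instantiated reference distribution on a grid spanning
    ``span`` standard deviations around its centre, clipped at
    ``support_floor`` and renormalized (the truncated-at-zero reading of a
    normal reference for non-negative analytes)."""
    tail = sps.norm.cdf(-span)
    lo, hi = dist.ppf([tail, 1.0 - tail])
    lo, hi = float(lo), float(hi)
    if support_floor is not None:
        lo = max(lo, float(support_floor))
    grid = np.linspace(lo, hi, grid_points)
    dens = dist.pdf(grid)
    area = np.trapezoid(dens, grid)
    return DensityEstimate(grid=grid, density=dens / area, bandwidth=float("nan"), n=0)


def central_interval(values, trim: float = 0.025) -> CentralInterval:
    """Central interval after excluding ``trim`` probability mass per tail,
    using linear-interpolation quantiles on the order statistics (position
    1 + p·(n−1))."""
    x = _clean_values(values)
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")
    lo, hi = np.quantile(x, [trim, 1.0 - trim], method="linear")
    return CentralInterval(lower=float(lo), upper=float(hi), trim_fraction=trim)


def overlap_coefficient(d1: DensityEstimate, d2: DensityEstimate) -> float:
    """OVL = ∫ min(f1, f2), by trapezoid on the union of the two grids.

    Each density is linearly interpolated on the union grid and treated as 0
    outside its own grid; the result is clipped to [0, 1].
    """
    grid = np.union1d(d1.grid, d2.grid)
    f1 = np.interp(grid, d1.grid, d1.density, left=0.0, right=0.0)
    f2 = np.interp(grid, d2.grid, d2.density, left=0.0, right=0.0)
    ovl = float(np.trapezoid(np.minimum(f1, f2), grid))
    return min(max(ovl, 0.0), 1.0)


def standardized_mean_difference(x1, x2, pooling: str = "pooled") -> float:
    """Cohen's d: (mean(x1) − mean(x2)) / pooled SD.

    ``pooling="pooled"`` uses the classic sample-size-weighted formula
    sqrt(((n1−1)s1² + (n2−1)s2²)/(n1+n2−2)); ``"balanced"`` weights the two
    variances equally, sqrt((s1²+s2²)/2) — their common value at n1 = n2,
    and the convention used against an (effectively infinite) analytic
    reference so the two routes agree regardless of reference sample size.

    Sign convention: group 1 is the cohort of interest (e.g. the ICU
    population), group 2 the comparator.
    """
    a = _clean_values(x1)
    b = _clean_values(x2)
    if a.size < 2 or b.size < 2:
        raise InputDataError("each group needs at least 2 values")
    s1, s2 = np.var(a, ddof=1), np.var(b, ddof=1)
    if pooling == "pooled":
        pooled = math.sqrt(
            ((a.size - 1) * s1 + (b.size - 1) * s2) / (a.size + b.size - 2)
        )
    elif pooling == "balanced":
        pooled = math.sqrt((s1 + s2) / 2.0)
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    if pooled == 0:
        raise InputDataError("pooled standard deviation is zero (degenerate groups)")
    return float((a.mean() - b.mean()) / pooled)


def smd_vs_reference(x, dist: ReferenceDistribution) -> float:
    """SMD of a sample against an analytic reference distribution.

    Uses balanced pooling sqrt((s² + sd_ref²)/2), the equal-group-size limit
    of the pooled-SD formula, with the reference's natural-scale moments, so
    it agrees with the sampled-reference route at matched n.
    """
    a = _clean_values(x, min_distinct=2)
    s = float(np.std(a, ddof=1))
    pooled = math.sqrt((s**2 + dist.natural_sd**2) / 2.0)
    return float((a.mean() - dist.natural_mean) / pooled)


def classify_effect_size(smd: float) -> str:
    """Band |SMD|: < 0.2 small; 0.2–0.8 moderate; > 0.8 large."""
    if not math.isfinite(smd):
        raise ValueError("SMD must be finite")
    a = abs(smd)
    if a < 0.2:
        return "small"
    if a <= 0.8:
        return "moderate"
    return "large"


def location_shift_test(x, ref) -> float:
    """One-sample Wilcoxon signed-rank test of a cohort against the
    reference centre.

    ``ref`` may be a ReferenceDistribution (its natural-scale mean is used)
    or a number.  Zero differences are dropped; ties take mid-ranks; the
    tie-corrected normal approximation is used for n > 25 or when ties are
    present, the exact distribution otherwise.  Two-sided p.
    """
    mu = ref.natural_mean if isinstance(ref, ReferenceDistribution) else float(ref)
    a = _clean_values(x)
    if a.size < 6:
        raise InputDataError(f"need at least 6 observations, got {a.size}")
    d = a - mu
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn(
            "all differences from the reference mean are zero; p = 1", stacklevel=2
        )
        return 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "approx" if (d.size > 25 or has_ties) else "exact"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=False, method=method)
    return float(res.pvalue)


def group_comparison(groups, kind: str = "continuous") -> tuple[float, float]:
    """Omnibus comparison across ≥ 2 groups.

    ``kind="continuous"``: Kruskal-Wallis H with tie correction on a sequence
    of value arrays.  ``kind="categorical"``: Pearson χ² without continuity
    correction on a groups × categories contingency table.

    Returns ``(statistic, p_value)``.
    """
    if kind == "continuous":
        arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
        if len(arrays) < 2:
            raise InputDataError("need at least 2 groups")
        for g in arrays:
            if g.size == 0:
                raise InputDataError("a group has zero observations")
        pooled = np.concatenate(arrays)
        if np.unique(pooled).size == 1:
            return 0.0, 1.0  # identical constants carry no rank information
        stat, p = sps.kruskal(*arrays)
        return float(stat), float(p)
    if kind == "categorical":
        table = np.asarray(groups, dtype=float)
        if table.ndim != 2 or table.shape[0] < 2:
            raise InputDataError("contingency table must be 2-D with >= 2 groups")
        if np.any(table.sum(axis=1) == 0):
            raise InputDataError("a group has zero observations")
        res = sps.chi2_contingency(table, correction=False)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown kind {kind!r}")


def analytic_normal_ovl(mu1: float, mu2: float, sigma: float) -> float:
    """Exact overlap of two equal-variance normal densities: 2Φ(−|Δμ|/(2σ)).

    Serves as the closed-form oracle against which the KDE-path OVL is
    checked.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return float(2.0 * sps.norm.cdf(-abs(mu1 - mu2) / (2.0 * sigma)))
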