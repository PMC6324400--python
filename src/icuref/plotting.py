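"""Plots: density comparisons against the reference interval, and stacked
outcome-proportion profiles."""

from __future__ import annotations

import numpy as np

from .cohort import OUTCOME_GROUPS

__all__ = ["plot_density_comparison", "plot_outcome_profile"]

_COHORT_STYLE = {
    "all": dict(color="tab:orange", label="All ICU"),
    "best": dict(color="black", label="Best outcome"),
    "worst": dict(color="tab:red", label="Worst outcome"),
    "reference": dict(color="tab:blue", label="Reference", linestyle="--"),
}

# best -> worst, light -> dark
_GROUP_COLORS = ("#d9f0d3", "#a6dba0", "#fee08b", "#f46d43", "#54278f")


def _spec_for(results, test_id):
    for spec in results.model.panel:
        if spec.test_id == test_id:
            return spec
    raise KeyError(f"unknown panel test {test_id!r}")


def plot_density_comparison(results, test_id: str, direction: str, ax=None):
    """Cohort densities with the hospital reference interval as vertical
    dotted lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    dens = results.densities[(test_id, direction)]
    for label, d in dens.items():
        ax.plot(d.grid, d.density, **_COHORT_STYLE.get(label, {"label": label}))
    spec = _spec_for(results, test_id)
    for bound in (spec.reference.lower, spec.reference.upper):
        ax.axvline(bound, color="black", linestyle=":", linewidth=1)
    ax.set_xlabel(f"{spec.name} ({spec.units})" if spec.units else spec.name)
    ax.set_ylabel("Density")
    ax.set_title(f"{spec.name} — {direction}")
    ax.legend(frameon=False)
    return ax


def plot_outcome_profile(results, test_id: str, direction: str, ax=None):
    """Stacked outcome-group proportions across the lab-value axis, group
    order fixed best → worst."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    prof = results.profiles[(test_id, direction)]
    centers = 0.5 * (prof.bin_edges[:-1] + prof.bin_edges[1:])
    props = np.nan_to_num(prof.proportions, nan=0.0)
    bottom = np.zeros_like(centers)
    width = np.diff(prof.bin_edges)
    for j, g in enumerate(OUTCOME_GROUPS):
        ax.bar(centers, props[:, j], bottom=bottom, width=width,
               color=_GROUP_COLORS[j], label=g, edgecolor="none")
        bottom += props[:, j]
    spec = _spec_for(results, test_id)
    ax.set_xlabel(f"{spec.name} ({spec.units})" if spec.units else spec.name)
    ax.set_ylabel("Proportion of outcome group")
    ax.set_ylim(0, 1)
    ax.set_title(f"{spec.name} — {direction}")
    ax.legend(frameon=False, fontsize="small")
    return ax
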