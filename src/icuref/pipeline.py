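"""End-to-end orchestration: configuration, the run pipeline, and the
table/figure-shaped output files.

A run consumes either a synthetic-cohort configuration or stay/event table
paths, fits :class:`~icuref.model.LabDivergenceModel`, and writes a
deterministic set of artifacts: the resolved configuration, the cohort
table, a baseline-characteristics (best vs worst) summary, the divergence
table, per-analyte density curves and central intervals, outcome-profile
tables, optional plots, and a JSON manifest with a configuration hash, seed,
row counts and per-test missingness.  Identical config + seed reproduces
every CSV/JSON byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .model import LabDivergenceModel
from .panel import demo_panel, load_panel, panel_to_mapping
from .synthetic import SyntheticAnalyte, SyntheticConfig, generate

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("icuref")

STAGES = ("synth", "cohort", "divergence", "profiles")


@dataclass
class RunConfig:
    """Resolved run configuration.

    Exactly one input source is required: ``synthetic`` (a
    :class:`SyntheticConfig`) or both ``stays_path`` and ``events_path``.
    """

    synthetic: SyntheticConfig | None = None
    stays_path: str | None = None
    events_path: str | None = None
    panel: list = field(default_factory=demo_panel)
    column_map: dict | None = None
    window_hours: float = 24.0
    adult_age_min: float = 18.0
    trim: float = 0.025
    profile_trim: float = 0.05
    n_bins: int = 20
    grid_points: int = 512
    bandwidth_rule: str = "silverman"
    reference_mode: str = "analytic"
    reference_n: int = 100_000
    seed: int = 0
    plots: bool = False

    def __post_init__(self) -> None:
        has_files = self.stays_path is not None and self.events_path is not None
        if (self.synthetic is None) == (not has_files):
            raise ConfigurationError(
                "config needs either a 'synthetic' block or both "
                "'stays_path' and 'events_path'"
            )
        for name in ("trim", "profile_trim"):
            v = getattr(self, name)
            if not 0.0 <= v < 0.5:
                raise ConfigurationError(f"{name} must lie in [0, 0.5)")

    # ------------------------------------------------------------------ #
    @classmethod
    def from_mapping(cls, mapping: dict, base_dir: Path | None = None) -> "RunConfig":
        m = dict(mapping)
        synth = m.pop("synthetic", None)
        if synth is not None:
            analytes = synth.pop("analytes", None)
            if analytes is not None:
                synth["panel"] = tuple(
                    SyntheticAnalyte(**a) for a in analytes
                )
            synth = SyntheticConfig(**synth)
        panel_src = m.pop("panel", None)
        if isinstance(panel_src, str) and base_dir is not None:
            panel_src = str((base_dir / panel_src).resolve())
        panel = load_panel(panel_src) if panel_src is not None else demo_panel()
        for key in ("stays_path", "events_path"):
            if m.get(key) and base_dir is not None:
                m[key] = str((base_dir / m[key]).resolve())
        return cls(synthetic=synth, panel=panel, **m)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
        return cls.from_mapping(mapping, base_dir=path.parent)

    # ------------------------------------------------------------------ #
    def resolved(self) -> dict:
        """JSON-serializable view of every scientific parameter (output
        locations excluded, so the hash is location-independent)."""
        d: dict = {
            "window_hours": self.window_hours,
            "adult_age_min": self.adult_age_min,
            "trim": self.trim,
            "profile_trim": self.profile_trim,
            "n_bins": self.n_bins,
            "grid_points": self.grid_points,
            "bandwidth_rule": self.bandwidth_rule,
            "reference_mode": self.reference_mode,
            "reference_n": self.reference_n,
            "seed": self.seed,
            "panel": panel_to_mapping(self.panel),
        }
        if self.synthetic is not None:
            s = dataclasses.asdict(self.synthetic)
            s["panel"] = [dataclasses.asdict(a) for a in self.synthetic.panel]
            d["synthetic"] = s
        else:
            d["stays_path"] = self.stays_path
            d["events_path"] = self.events_path
            d["column_map"] = self.column_map
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _iso(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    return out


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    _iso(df).to_csv(path, index=False, lineterminator="\n")


def run_pipeline(config: RunConfig, out_dir, seed: int | None = None,
                 stages=None) -> dict:
    """Run the requested stages and write artifacts under ``out_dir``.

    ``stages`` is a subset of ``("synth", "cohort", "divergence",
    "profiles")``; ``None`` runs everything.  Returns the manifest dict.
    """
    stages = set(STAGES if stages is None else stages)
    unknown = stages - set(STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stage(s) {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
        if config.synthetic is not None:
            config = dataclasses.replace(
                config, synthetic=config.synthetic.with_seed(int(seed))
            )

    outputs: list[str] = []

    def _record(path: Path) -> None:
        outputs.append(str(path.relative_to(out)))

    cfg_path = out / "resolved_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config.resolved(), fh, sort_keys=True)
    _record(cfg_path)

    truth = None
    if config.synthetic is not None:
        log.info("generating synthetic cohort: n=%d seed=%d",
                 config.synthetic.n_patients, config.synthetic.seed)
        stays, events, truth = generate(config.synthetic)
        if "synth" in stages:
            _write_csv(stays, out / "stays.csv")
            _record(out / "stays.csv")
            _write_csv(events, out / "events.csv")
            _record(out / "events.csv")
    else:
        from .io import read_events, read_stays

        stays = read_stays(config.stays_path, column_map=config.column_map)
        events = read_events(config.events_path, column_map=config.column_map)

    model = LabDivergenceModel(
        stays,
        events,
        panel=config.panel,
        window_hours=config.window_hours,
        adult_age_min=config.adult_age_min,
    )
    model.ground_truth = truth
    log.info("fitting divergence model on %d stays / %d events",
             len(stays), len(events))
    results = model.fit(
        trim=config.trim,
        profile_trim=config.profile_trim,
        n_bins=config.n_bins,
        grid_points=config.grid_points,
        bandwidth_rule=config.bandwidth_rule,
        reference_mode=config.reference_mode,
        reference_n=config.reference_n,
        seed=config.seed,
    )

    if "cohort" in stages:
        _write_csv(results.cohort, out / "cohort.csv")
        _record(out / "cohort.csv")
        _write_csv(results.summarize_best_worst(), out / "table1_best_worst.csv")
        _record(out / "table1_best_worst.csv")

    if "divergence" in stages:
        _write_csv(results.divergence_wide(), out / "table2_divergence.csv")
        _record(out / "table2_divergence.csv")
        _write_csv(results.central_intervals, out / "central_intervals.csv")
        _record(out / "central_intervals.csv")
        for (test_id, direction), dens in sorted(results.densities.items()):
            frames = [
                pd.DataFrame(
                    {"cohort": label, "grid": d.grid, "density": d.density}
                )
                for label, d in dens.items()
            ]
            path = out / "densities" / f"{test_id}_{direction}.csv"
            _write_csv(pd.concat(frames, ignore_index=True), path)
            _record(path)

    if "profiles" in stages:
        for (test_id, direction), prof in sorted(results.profiles.items()):
            path = out / "profiles" / f"{test_id}_{direction}.csv"
            _write_csv(prof.to_frame(), path)
            _record(path)

    if config.plots and ("divergence" in stages or "profiles" in stages):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        plot_dir = out / "plots"
        plot_dir.mkdir(exist_ok=True)
        for (test_id, direction) in sorted(results.densities):
            fig, axes = plt.subplots(1, 2, figsize=(11, 4))
            results.plot_density(test_id, direction, ax=axes[0])
            results.plot_profile(test_id, direction, ax=axes[1])
            fig.tight_layout()
            path = plot_dir / f"{test_id}_{direction}.png"
            fig.savefig(path, dpi=110)
            plt.close(fig)
            _record(path)

    missing = results.missingness()
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": sorted(stages),
        "n_stays_input": int(len(stays)),
        "n_first_stays": int(len(results.cohort)),
        "group_sizes": {
            str(k): int(v) for k, v in results.group_sizes.items()
        },
        "missingness": {k: float(v) for k, v in missing.items()},
        "ovl_vs_reference": results.ovl_summary(),
        "outputs": sorted(outputs),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
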