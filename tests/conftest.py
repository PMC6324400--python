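import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from icuref.synthetic import SyntheticConfig, generate

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

BASE = pd.Timestamp("2140-01-01")


def make_stays(rows):
    """Build a stay table from (subject, stay, intime_day, los_days, age,
    died) tuples."""
    recs = []
    for subject, stay, day, los, age, died in rows:
        intime = BASE + pd.Timedelta(days=day)
        recs.append(
            {
                "subject_id": subject,
                "stay_id": stay,
                "intime": intime,
                "outtime": intime + pd.Timedelta(days=los),
                "age_years": age,
                "icu_death": died,
            }
        )
    return pd.DataFrame(recs)


def make_events(rows):
    """Build an event table from (subject, stay_or_None, test, hours, value)
    tuples; hours is the offset from BASE."""
    return pd.DataFrame(
        [
            {
                "subject_id": subject,
                "stay_id": stay,
                "test_id": test,
                "charttime": BASE + pd.Timedelta(hours=hours),
                "value": value,
            }
            for subject, stay, test, hours, value in rows
        ]
    )


def brute_force_worst(events, stays, panel, window_hours=24.0):
    """Independent per-event scan: the oracle for worst first-day
    extraction."""
    window = pd.Timedelta(hours=window_hours)
    specs = {s.test_id: s.directions for s in panel}
    collected: dict[tuple, list] = {}
    for st in stays.itertuples():
        lo, hi = st.intime, st.intime + window
        for ev in events.itertuples():
            if ev.test_id not in specs:
                continue
            sid = getattr(ev, "stay_id", None)
            if sid is not None and not pd.isna(sid):
                matched = sid == st.stay_id
            else:
                matched = ev.subject_id == st.subject_id
            if matched and lo <= ev.charttime < hi:
                collected.setdefault((st.stay_id, ev.test_id), []).append(ev.value)
    rows = []
    for (stay_id, test_id), vals in collected.items():
        for direction in specs[test_id]:
            worst = min(vals) if direction == "minimum" else max(vals)
            rows.append((stay_id, test_id, direction, float(worst)))
    return pd.DataFrame(rows, columns=["stay_id", "test_id", "direction", "value"])


def random_extraction_fixture(seed, panel, n_stays=20, n_events=200):
    """Random stays (with non-first decoys) and events (in/out of window,
    some without stay_id) for extraction-oracle checks."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_stays):
        rows.append(
            (f"P{i:03d}", f"A{i:03d}", float(rng.uniform(0, 10)),
             float(rng.uniform(0.5, 6)), float(rng.uniform(18, 90)),
             bool(rng.random() < 0.2))
        )
    stays = make_stays(rows)
    # decoy later stays for some subjects (must be ignored after selection)
    decoys = make_stays(
        [
            (f"P{i:03d}", f"Z{i:03d}", float(30 + rng.uniform(0, 5)),
             float(rng.uniform(0.5, 3)), 50.0, False)
            for i in range(0, n_stays, 3)
        ]
    )
    all_stays = pd.concat([stays, decoys], ignore_index=True)

    tests = [s.test_id for s in panel]
    ev_rows = []
    for _ in range(n_events):
        st = all_stays.iloc[int(rng.integers(len(all_stays)))]
        offset = float(rng.uniform(-12, 60))  # some events fall out of window
        hours = (st.intime - BASE).total_seconds() / 3600 + offset
        stay_ref = st.stay_id if rng.random() < 0.7 else None
        ev_rows.append(
            (st.subject_id, stay_ref, tests[int(rng.integers(len(tests)))],
             hours, float(np.round(rng.normal(10, 3), 3)))
        )
    return all_stays, make_events(ev_rows)


@pytest.fixture(scope="session")
def small_cohort():
    """A reusable synthetic cohort with defaults at modest size."""
    cfg = SyntheticConfig(n_patients=1000, seed=42)
    stays, events, truth = generate(cfg)
    return cfg, stays, events, truth
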