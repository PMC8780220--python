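"""Shared fixtures: small simulated worlds and hand-built tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aviarytrack.decoder import close_durations, decode_stream
from aviarytrack.layout import SignalParams, build_default_layout
from aviarytrack.movement import DwellParams, simulate_movement
from aviarytrack.signals import simulate_receptions

NOISELESS_DURATION = 2 * 3600.0


@pytest.fixture(scope="session")
def noiseless_chain():
    """One pen, 4 tags, 2 h, zero RSS noise, no weak spots: the regime in
    which the decoder must reproduce the ground truth exactly."""
    layouts = build_default_layout(1, seed=11)
    truth = simulate_movement(layouts, 4, NOISELESS_DURATION, DwellParams(), seed=12)
    sp = SignalParams(rss_noise_sd=0.0)
    recs = simulate_receptions(truth, layouts[0], sp, seed=13)
    regs = close_durations(decode_stream(recs), NOISELESS_DURATION)
    return {
        "layout": layouts[0],
        "truth": truth,
        "receptions": recs,
        "registrations": regs,
        "duration": NOISELESS_DURATION,
        "sp": sp,
    }


def make_registrations(rows):
    """Build a registration table from (tag, zone, t_start, duration) or
    (tag, zone, t_start, duration, rss, zone2, rss2, zone3exist) tuples."""
    full = []
    for r in rows:
        tag, zone, t0, dur = r[:4]
        rss, zone2, rss2, z3 = (r[4:] + (80.0, None, np.nan, 0))[:4] if len(r) > 4 else (
            80.0,
            None,
            np.nan,
            0,
        )
        full.append((tag, "pen1", "station1", zone, t0, dur, rss, zone2, rss2, z3))
    return pd.DataFrame(
        full,
        columns=[
            "tag_id",
            "pen_id",
            "station_id",
            "zone",
            "t_start",
            "duration",
            "rss",
            "zone2",
            "rss2",
            "zone3exist",
        ],
    )


def make_truth(rows):
    """Build a truth table from (tag, zone, t_start, t_end) tuples."""
    return pd.DataFrame(
        [(tag, "pen1", zone, t0, t1, 1.0, 0.5) for tag, zone, t0, t1 in rows],
        columns=["tag_id", "pen_id", "zone", "t_start", "t_end", "x", "y"],
    )


def random_reception_stream(rng, n=50, tag="tagA"):
    """A random (unphysical) reception stream for decoder oracle checks."""
    times = np.cumsum(rng.uniform(0.2, 3.0, n))
    zones = ["TOP_TIER", "NEST_BOX", "LOWER_TIER", "LITTER", "WINTER_GARDEN"]
    markers = rng.integers(0, 5, n)
    rss = rng.normal(70.0, 8.0, n)
    return pd.DataFrame(
        {
            "tag_id": tag,
            "pen_id": "pen1",
            "station_id": "station1",
            "time": times,
            "marker_zone": [zones[m] for m in markers],
            "rss": rss,
        }
    )
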