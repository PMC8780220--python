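"""Tag-side decoding of LF receptions into zone registrations.

The tag re-evaluates its zone at every reception: a transition to a zone is
registered when, among the receptions of the last 10 s, a single marker
holds the strongest signal and supplies at least two receptions that each
exceed every other marker's strongest signal — and that marker's zone
differs from the last registered zone.  Requiring two dominating receptions
makes one spurious strong burst insufficient to switch zones.

Each registration carries the window's signal metadata used downstream as
classifier features: the strongest RSS, the runner-up marker's zone and
RSS, and whether at least three distinct zones were heard in the window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit

from .zones import ZONES

#: registration table columns; duration is NaN until close_durations is run
REGISTRATION_COLUMNS = [
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
]

DEFAULT_WINDOW_S = 10.0


@njit(cache=True)
def _decode_tag(times, markers, rss, window):  # pragma: no cover - numba
    n = len(times)
    out_idx = np.empty(n, dtype=np.int64)
    out_marker = np.empty(n, dtype=np.int64)
    out_rss = np.empty(n, dtype=np.float64)
    out_zone2 = np.empty(n, dtype=np.int64)
    out_rss2 = np.empty(n, dtype=np.float64)
    out_z3 = np.empty(n, dtype=np.int64)
    n_out = 0
    last_zone = -1
    j0 = 0
    n_markers = 5
    best = np.empty(n_markers, dtype=np.float64)
    first_at = np.empty(n_markers, dtype=np.int64)
    for i in range(n):
        while times[j0] <= times[i] - window:
            j0 += 1
        # per-marker strongest signal in the half-open window (t-W, t]
        for m in range(n_markers):
            best[m] = -np.inf
            first_at[m] = -1
        n_distinct = 0
        for j in range(j0, i + 1):
            m = markers[j]
            if first_at[m] < 0:
                n_distinct += 1
            if rss[j] > best[m]:
                best[m] = rss[j]
                first_at[m] = j
            elif first_at[m] < 0:
                first_at[m] = j
        mx = -np.inf
        for m in range(n_markers):
            if best[m] > mx:
                mx = best[m]
        # pick the top marker; ties resolve toward the registered zone,
        # then toward the marker whose maximum was heard first
        m_star = -1
        for m in range(n_markers):
            if best[m] == mx:
                if m == last_zone:
                    m_star = m
                    break
                if m_star < 0 or first_at[m] < first_at[m_star]:
                    m_star = m
        best_other = -np.inf
        m2 = -1
        for m in range(n_markers):
            if m != m_star and best[m] > best_other:
                best_other = best[m]
                m2 = m
        # receptions of the top marker that dominate every other marker
        n_dom = 0
        for j in range(j0, i + 1):
            if markers[j] == m_star and rss[j] > best_other:
                n_dom += 1
        if n_dom >= 2 and m_star != last_zone:
            out_idx[n_out] = i
            out_marker[n_out] = m_star
            out_rss[n_out] = mx
            out_zone2[n_out] = m2
            out_rss2[n_out] = best_other if m2 >= 0 else np.nan
            out_z3[n_out] = 1 if n_distinct >= 3 else 0
            n_out += 1
            last_zone = m_star
    return (
        out_idx[:n_out],
        out_marker[:n_out],
        out_rss[:n_out],
        out_zone2[:n_out],
        out_rss2[:n_out],
        out_z3[:n_out],
    )


def decode_stream(
    receptions: pd.DataFrame, window: float = DEFAULT_WINDOW_S
) -> pd.DataFrame:
    """Decode a reception table into a registration table.

    Receptions must be strictly time-ordered within each tag.  Durations
    are left NaN; run :func:`close_durations` once the observation end is
    known.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if receptions.empty:
        return pd.DataFrame(columns=REGISTRATION_COLUMNS)

    zone_code = {z.value: i for i, z in enumerate(ZONES)}
    frames = []
    for tag_id, grp in receptions.groupby("tag_id", sort=False):
        times = grp["time"].to_numpy(float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"receptions of tag {tag_id} are not strictly ordered")
        markers = grp["marker_zone"].map(zone_code).to_numpy(np.int64)
        rss = grp["rss"].to_numpy(float)
        idx, m_star, r, z2, r2, z3 = _decode_tag(times, markers, rss, float(window))
        if len(idx) == 0:
            continue
        first = grp.iloc[0]
        frames.append(
            pd.DataFrame(
                {
                    "tag_id": tag_id,
                    "pen_id": first["pen_id"],
                    "station_id": first["station_id"],
                    "zone": [ZONES[m].value for m in m_star],
                    "t_start": times[idx],
                    "duration": np.nan,
                    "rss": r,
                    "zone2": [ZONES[m].value if m >= 0 else None for m in z2],
                    "rss2": r2,
                    "zone3exist": z3,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=REGISTRATION_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def close_durations(regs: pd.DataFrame, observation_end: float) -> pd.DataFrame:
    """Fill stay durations: each registration lasts until the next one of
    the same tag; the last lasts until ``observation_end``."""
    if regs.empty:
        return regs.copy()
    out = regs.copy()
    for _, idx in out.groupby("tag_id", sort=False).groups.items():
        starts = out.loc[idx, "t_start"].to_numpy(float)
        if np.any(np.diff(starts) < 0):
            raise ValueError("registrations must be ordered per tag")
        if observation_end < starts[-1]:
            raise ValueError("observation_end precedes the last registration")
        ends = np.append(starts[1:], observation_end)
        out.loc[idx, "duration"] = ends - starts
    return out
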