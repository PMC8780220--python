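"""LF reception stream: marker emission grids, path loss, noise, weak spots.

Each zone's marker emits a 50-ms burst on its own transmission-interval
grid (1.6-2.1 s, random phase).  A tag hears a burst iff its stay position
lies within the marker's range (2-3 m from the antenna cable), with

    rss = marker_power - 10 * ple * log10(max(d, 0.1) / 1 m) + noise   [dB]

Bursts from two markers that overlap in time at a tag are both dropped
(overlapping LF signals cannot be demodulated).  Weak spots add an RSS
boost to a spoofed marker near a fixed position, and an optional hourly
weather series inflates the noise SD in cold or dry hours.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .layout import WEAK_SPOT_RADIUS, PenLayout, SignalParams
from .zones import ZONES, Zone

#: reception table columns (time in seconds, rss in dB)
RECEPTION_COLUMNS = ["tag_id", "pen_id", "station_id", "time", "marker_zone", "rss"]

#: weather table columns; hour_start in seconds from the simulation origin
WEATHER_COLUMNS = ["hour_start", "temperature_c", "humidity_pct"]


def simulate_receptions(
    stays: pd.DataFrame,
    layout: PenLayout,
    sp: SignalParams,
    weather: pd.DataFrame | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the reception stream for one pen's ground-truth stays.

    Returns a reception table sorted by (tag_id, time).  ``weather`` rows
    (``hour_start, temperature_c, humidity_pct``) inflate the RSS noise SD
    by ``weather_noise_coeff`` dB per unit of standardized humidity deficit
    plus standardized temperature deficit within the matching hour.
    """
    if sp.max_range <= 0:
        raise ValueError("max_range must be positive")
    if stays.empty:
        return pd.DataFrame(columns=RECEPTION_COLUMNS)
    if not (stays["pen_id"] == layout.pen_id).all():
        raise ValueError("stays do not belong to this pen")

    rng = np.random.default_rng(seed)
    t_max = float(stays["t_end"].max())
    emission_times = {
        zone: _emission_grid(sp.tx_interval[zone], t_max, rng) for zone in ZONES
    }
    noise_sd = _noise_sd_fn(sp, weather)

    frames: list[pd.DataFrame] = []
    for tag_id, tag_stays in stays.groupby("tag_id", sort=False):
        recs = _tag_receptions(tag_stays, layout, sp, emission_times, noise_sd, rng)
        if recs is None:
            continue
        times, markers, rss = recs
        frames.append(
            pd.DataFrame(
                {
                    "tag_id": tag_id,
                    "pen_id": layout.pen_id,
                    "station_id": layout.station_id,
                    "time": times,
                    "marker_zone": [ZONES[m].value for m in markers],
                    "rss": rss,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=RECEPTION_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["tag_id", "time"], kind="stable").reset_index(drop=True)


def simulate_weather(duration_s: float, seed: int = 0) -> pd.DataFrame:
    """Hourly outdoor weather with diurnal cycles plus noise.

    Temperature follows a 12 +/- 6 degC cycle peaking mid-afternoon;
    humidity moves opposite to it around 70%.
    """
    rng = np.random.default_rng(seed)
    hours = np.arange(0.0, duration_s, 3600.0)
    hod = (hours / 3600.0) % 24
    phase = np.sin(2 * np.pi * (hod - 9) / 24.0)
    temperature = 12.0 + 6.0 * phase + rng.normal(0, 2.0, len(hours))
    humidity = np.clip(
        70.0 - 15.0 * phase + rng.normal(0, 5.0, len(hours)), 5.0, 100.0
    )
    return pd.DataFrame(
        {
            "hour_start": hours,
            "temperature_c": temperature,
            "humidity_pct": humidity,
        }
    )


def _emission_grid(interval: float, t_max: float, rng: np.random.Generator):
    phase = rng.uniform(0.0, interval)
    n = max(int((t_max - phase) // interval) + 1, 0)
    return phase + interval * np.arange(n)


def _noise_sd_fn(sp: SignalParams, weather: pd.DataFrame | None):
    """Map reception times to noise SDs, optionally weather-inflated."""
    if weather is None or weather.empty or sp.weather_noise_coeff == 0.0:
        return lambda times: np.full(len(times), sp.rss_noise_sd)
    w = weather.sort_values("hour_start")
    starts = w["hour_start"].to_numpy(float)
    for col in ("humidity_pct", "temperature_c"):
        vals = w[col].to_numpy(float)
        sd = vals.std()
        w[col + "_deficit"] = (vals.mean() - vals) / sd if sd > 0 else 0.0
    deficit = (w["humidity_pct_deficit"] + w["temperature_c_deficit"]).to_numpy()
    sds = np.maximum(sp.rss_noise_sd + sp.weather_noise_coeff * deficit, 0.0)

    def fn(times: np.ndarray) -> np.ndarray:
        idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(sds) - 1)
        return sds[idx]

    return fn


def _tag_receptions(tag_stays, layout, sp, emission_times, noise_sd, rng):
    times_parts: list[np.ndarray] = []
    marker_parts: list[np.ndarray] = []
    clean_parts: list[np.ndarray] = []
    for stay in tag_stays.itertuples(index=False):
        x, y = stay.x, stay.y
        boost = {z: 0.0 for z in ZONES}
        forced = set()
        for ws in layout.weak_spots:
            if math.hypot(x - ws.x, y - ws.y) <= WEAK_SPOT_RADIUS:
                boost[ws.spoofed_zone] += ws.rss_boost
                forced.add(ws.spoofed_zone)  # distortion carries it into range
        for mi, zone in enumerate(ZONES):
            d = layout.loop_distance(zone, x, y)
            if d > sp.max_range and zone not in forced:
                continue
            grid = emission_times[zone]
            lo = np.searchsorted(grid, stay.t_start, side="left")
            hi = np.searchsorted(grid, stay.t_end, side="left")
            if hi <= lo:
                continue
            t = grid[lo:hi]
            rss0 = (
                layout.marker_power[zone]
                - 10.0 * sp.path_loss_exponent * math.log10(max(d, 0.1))
                + boost[zone]
            )
            times_parts.append(t)
            marker_parts.append(np.full(len(t), mi, dtype=np.int64))
            clean_parts.append(np.full(len(t), rss0))
    if not times_parts:
        return None
    times = np.concatenate(times_parts)
    markers = np.concatenate(marker_parts)
    clean = np.concatenate(clean_parts)
    order = np.argsort(times, kind="stable")
    times, markers, clean = times[order], markers[order], clean[order]

    keep = _drop_collisions(times, markers, sp.burst_duration)
    times, markers, clean = times[keep], markers[keep], clean[keep]
    if len(times) == 0:
        return None
    sds = noise_sd(times)
    rss = clean + rng.normal(0.0, 1.0, len(times)) * sds
    return times, markers, rss


def _drop_collisions(times: np.ndarray, markers: np.ndarray, burst: float):
    """Drop every burst overlapping a different marker's burst in time."""
    keep = np.ones(len(times), dtype=bool)
    if len(times) > 1:
        close = np.diff(times) < burst
        differs = markers[1:] != markers[:-1]
        bad = close & differs
        keep[1:] &= ~bad
        keep[:-1] &= ~bad
    return keep
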