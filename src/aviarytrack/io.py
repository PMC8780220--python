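"""CSV/JSON readers and writers for the pipeline's table schemas.

On-disk column names carry units (``t_start_s``, ``rss_db``); in-memory
frames use the bare names.  Weather hours are written as ISO timestamps
relative to a nominal origin so the files are readable outside the
package.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .layout import PenLayout, SignalParams, WeakSpot
from .zones import Zone

#: nominal wall-clock origin of simulation time zero
TIME_ORIGIN = pd.Timestamp("2021-01-01T00:00:00")

_TRUTH_MAP = {"t_start": "t_start_s", "t_end": "t_end_s", "x": "x_m", "y": "y_m"}
_RECEPTION_MAP = {"time": "time_s", "rss": "rss_db"}
_REGISTRATION_MAP = {
    "t_start": "t_start_s",
    "duration": "duration_s",
    "rss": "rss_db",
    "rss2": "rss2_db",
}

_FLOAT_FORMAT = "%.6f"


def _write(df: pd.DataFrame, path, mapping: dict) -> None:
    df.rename(columns=mapping).to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def _read(path, mapping: dict) -> pd.DataFrame:
    inverse = {v: k for k, v in mapping.items()}
    return pd.read_csv(path).rename(columns=inverse)


def write_truth(df: pd.DataFrame, path) -> None:
    _write(df, path, _TRUTH_MAP)


def read_truth(path) -> pd.DataFrame:
    return _read(path, _TRUTH_MAP)


def write_receptions(df: pd.DataFrame, path) -> None:
    _write(df, path, _RECEPTION_MAP)


def read_receptions(path) -> pd.DataFrame:
    return _read(path, _RECEPTION_MAP)


def write_registrations(df: pd.DataFrame, path) -> None:
    _write(df, path, _REGISTRATION_MAP)


def read_registrations(path) -> pd.DataFrame:
    return _read(path, _REGISTRATION_MAP)


def write_weather(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["hour_start_iso"] = (
        TIME_ORIGIN + pd.to_timedelta(out.pop("hour_start"), unit="s")
    ).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out = out[["hour_start_iso", "temperature_c", "humidity_pct"]]
    out.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["hour_start"] = (
        pd.to_datetime(df.pop("hour_start_iso")) - TIME_ORIGIN
    ).dt.total_seconds()
    return df[["hour_start", "temperature_c", "humidity_pct"]]


def layout_to_dict(layout: PenLayout) -> dict:
    return {
        "pen_id": layout.pen_id,
        "station_id": layout.station_id,
        "zone_regions": {z.value: list(r) for z, r in layout.zone_regions.items()},
        "marker_loops": {z.value: list(s) for z, s in layout.marker_loops.items()},
        "marker_power": {z.value: p for z, p in layout.marker_power.items()},
        "weak_spots": [
            {
                "x": w.x,
                "y": w.y,
                "spoofed_zone": w.spoofed_zone.value,
                "rss_boost": w.rss_boost,
            }
            for w in layout.weak_spots
        ],
        "pophole_open_hours": list(layout.pophole_open_hours),
    }


def layout_from_dict(d: dict) -> PenLayout:
    return PenLayout(
        pen_id=d["pen_id"],
        station_id=d["station_id"],
        zone_regions={Zone(z): tuple(r) for z, r in d["zone_regions"].items()},
        marker_loops={Zone(z): tuple(s) for z, s in d["marker_loops"].items()},
        marker_power={Zone(z): p for z, p in d["marker_power"].items()},
        weak_spots=[
            WeakSpot(w["x"], w["y"], Zone(w["spoofed_zone"]), w["rss_boost"])
            for w in d["weak_spots"]
        ],
        pophole_open_hours=tuple(d["pophole_open_hours"]),
    )


def write_layouts(layouts: list[PenLayout], path) -> None:
    Path(path).write_text(
        json.dumps([layout_to_dict(la) for la in layouts], indent=1)
    )


def read_layouts(path) -> list[PenLayout]:
    return [layout_from_dict(d) for d in json.loads(Path(path).read_text())]


def signal_params_to_dict(sp: SignalParams) -> dict:
    return {
        "tx_interval": {z.value: v for z, v in sp.tx_interval.items()},
        "burst_duration": sp.burst_duration,
        "max_range": sp.max_range,
        "path_loss_exponent": sp.path_loss_exponent,
        "rss_noise_sd": sp.rss_noise_sd,
        "weather_noise_coeff": sp.weather_noise_coeff,
    }


def signal_params_from_dict(d: dict) -> SignalParams:
    d = dict(d)
    d["tx_interval"] = {Zone(z): v for z, v in d["tx_interval"].items()}
    return SignalParams(**d)
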