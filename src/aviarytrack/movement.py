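"""Ground-truth hen movement: zone stays with adjacency and pop-hole gating.

Stands in for the video-observed gold standard: each tag's day is a
contiguous sequence of zone stays, moves happen only between bordering
zones, and the winter garden is reachable only while the pop hole is open.
Within a stay the hen is treated as stationary at a position drawn
uniformly inside the zone region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import PenLayout
from .zones import ADJACENCY, ZONES, Zone, as_zone

DAY_S = 86400.0

#: truth table columns (times in seconds from the simulation origin)
TRUTH_COLUMNS = ["tag_id", "pen_id", "zone", "t_start", "t_end", "x", "y"]


@dataclass
class DwellParams:
    """Shifted-exponential dwell-time distributions, per zone.

    A stay in zone z lasts ``minimum[z] + Exp(mean[z] - minimum[z])``
    seconds.  The 15-s floor keeps every stay long enough for the tag to
    hear its zone's marker several times (momentary pass-throughs are not
    zone visits), while still producing sub-minute visits that a duration
    threshold filter wrongly removes; the exponential tail gives the
    irregular, heavy-tailed visit pattern of aviary hens.
    """

    mean: dict[Zone, float] = field(
        default_factory=lambda: {
            Zone.TOP_TIER: 1500.0,
            Zone.NEST_BOX: 1200.0,
            Zone.LOWER_TIER: 600.0,
            Zone.LITTER: 900.0,
            Zone.WINTER_GARDEN: 600.0,
        }
    )
    minimum: dict[Zone, float] = field(
        default_factory=lambda: {z: 15.0 for z in ZONES}
    )

    def __post_init__(self) -> None:
        for z in self.mean:
            if self.mean[z] <= 0 or self.minimum[z] < 0:
                raise ValueError("dwell distributions need positive support")
            if self.mean[z] < self.minimum[z]:
                raise ValueError(f"mean dwell below minimum for {z}")

    def sample(self, zone: Zone, rng: np.random.Generator) -> float:
        scale = self.mean[zone] - self.minimum[zone]
        extra = rng.exponential(scale) if scale > 0 else 0.0
        return self.minimum[zone] + extra


def _pophole_open(t: float, open_hours: tuple[float, float]) -> bool:
    hour = (t % DAY_S) / 3600.0
    return open_hours[0] <= hour < open_hours[1]


def _seconds_until_close(t: float, open_hours: tuple[float, float]) -> float:
    return open_hours[1] * 3600.0 - (t % DAY_S)


def simulate_movement(
    layouts: list[PenLayout],
    n_tags_per_pen: int,
    duration: float,
    dwell: DwellParams | None = None,
    seed: int = 0,
    start_zone: Zone | str | None = None,
) -> pd.DataFrame:
    """Simulate per-tag ground-truth stays over ``[0, duration)``.

    Returns a truth table (one row per stay) with columns
    ``tag_id, pen_id, zone, t_start, t_end, x, y``; stays of one tag are
    contiguous, consecutive zones are adjacent, and winter-garden stays lie
    inside the pop-hole opening hours.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if n_tags_per_pen < 0:
        raise ValueError("n_tags_per_pen must be >= 0")
    dwell = dwell if dwell is not None else DwellParams()
    forced_start = as_zone(start_zone) if start_zone is not None else None

    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    for layout in layouts:
        for k in range(n_tags_per_pen):
            tag_id = f"{layout.pen_id}-t{k:02d}"
            rows.extend(
                _simulate_tag(tag_id, layout, duration, dwell, rng, forced_start)
            )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def _simulate_tag(
    tag_id: str,
    layout: PenLayout,
    duration: float,
    dwell: DwellParams,
    rng: np.random.Generator,
    forced_start: Zone | None,
) -> list[tuple]:
    open_hours = layout.pophole_open_hours
    indoor = [z for z in ZONES if z is not Zone.WINTER_GARDEN]
    if forced_start is None:
        zone = indoor[rng.integers(len(indoor))]
    else:
        zone = forced_start
        if zone is Zone.WINTER_GARDEN and not _pophole_open(0.0, open_hours):
            raise ValueError("cannot start in WINTER_GARDEN while pop hole is closed")

    rows: list[tuple] = []
    t = 0.0
    while t < duration:
        length = dwell.sample(zone, rng)
        t_end = min(t + length, duration)
        if zone is Zone.WINTER_GARDEN:
            # hens are shooed back inside when the pop hole closes
            t_end = min(t_end, t + _seconds_until_close(t, open_hours))
        x, y = _sample_position(layout, zone, rng)
        rows.append((tag_id, layout.pen_id, zone.value, t, t_end, x, y))
        t = t_end
        if t >= duration:
            break
        zone = _next_zone(zone, t, dwell, open_hours, rng)
    return rows


def _next_zone(
    zone: Zone,
    t: float,
    dwell: DwellParams,
    open_hours: tuple[float, float],
    rng: np.random.Generator,
) -> Zone:
    options = list(ADJACENCY[zone])
    if Zone.WINTER_GARDEN in options:
        # enter only if a minimum-length stay fits before the pop hole closes
        if not (
            _pophole_open(t, open_hours)
            and _seconds_until_close(t, open_hours)
            > dwell.minimum[Zone.WINTER_GARDEN]
        ):
            options.remove(Zone.WINTER_GARDEN)
    return options[rng.integers(len(options))]


def _sample_position(
    layout: PenLayout, zone: Zone, rng: np.random.Generator
) -> tuple[float, float]:
    x0, y0, x1, y1 = layout.zone_regions[zone]
    eps = 0.02  # keep positions off the exact region border
    return (
        float(rng.uniform(x0 + eps, x1 - eps)),
        float(rng.uniform(y0 + eps, y1 - eps)),
    )
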