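"""Pen geometry, marker placement and LF signal parameters.

The simulated pen is a 2-D cross-section (width x height, metres).  The four
indoor zones are stacked 1-m-tall rectangles over the full 3-m pen width;
the winter garden is a rectangle horizontally adjacent to the litter, behind
the pop hole at x = 3 m:

          y
        4 +---------------+
          |   TOP_TIER    |
        3 +---------------+
          |   NEST_BOX    |
        2 +---------------+
          |  LOWER_TIER   |
        1 +---------------+----------------+
          |    LITTER     | WINTER_GARDEN  |
        0 +---------------+----------------+
          0               3               5.5   x

Each zone holds one LF marker whose antenna cable is modelled as a line
segment along the zone's mid-line.  Received signal strength follows a
log-distance path-loss law from the point-to-segment distance, so inside a
zone the zone's own marker is always the strongest in the absence of noise,
while points near zone borders have small dB margins — these are the
"critical locations" used for calibration and where noise-induced false
registrations arise.

"Weak spots" are localized positions where field distortion makes a wrong
marker appear strongest; the simulator models them as an RSS boost applied
to a spoofed zone's marker whenever the tag sits within 0.3 m of the spot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .zones import ZONES, Zone

#: (x0, y0, x1, y1) axis-aligned rectangle, metres.
Rect = tuple[float, float, float, float]
#: (x1, y1, x2, y2) line segment, metres.
Segment = tuple[float, float, float, float]

PEN_WIDTH = 3.0
WG_WIDTH = 2.5
TIER_HEIGHT = 1.0
#: cable segments are inset from the zone's horizontal extent
LOOP_INSET = 0.2
#: radius within which a weak spot distorts the field
WEAK_SPOT_RADIUS = 0.3

DEFAULT_ZONE_REGIONS: dict[Zone, Rect] = {
    Zone.LITTER: (0.0, 0.0, PEN_WIDTH, 1.0),
    Zone.LOWER_TIER: (0.0, 1.0, PEN_WIDTH, 2.0),
    Zone.NEST_BOX: (0.0, 2.0, PEN_WIDTH, 3.0),
    Zone.TOP_TIER: (0.0, 3.0, PEN_WIDTH, 4.0),
    Zone.WINTER_GARDEN: (PEN_WIDTH, 0.0, PEN_WIDTH + WG_WIDTH, 1.0),
}

#: transmission interval per zone, seconds; distinct per zone so that
#: 50-ms bursts from different markers only rarely collide
DEFAULT_TX_INTERVALS: dict[Zone, float] = {
    Zone.TOP_TIER: 1.6,
    Zone.NEST_BOX: 1.7,
    Zone.LOWER_TIER: 1.85,
    Zone.LITTER: 1.95,
    Zone.WINTER_GARDEN: 2.1,
}

DEFAULT_MARKER_POWER_DB = 80.0


def _default_marker_loops() -> dict[Zone, Segment]:
    loops: dict[Zone, Segment] = {}
    for zone, (x0, y0, x1, y1) in DEFAULT_ZONE_REGIONS.items():
        ym = 0.5 * (y0 + y1)
        loops[zone] = (x0 + LOOP_INSET, ym, x1 - LOOP_INSET, ym)
    return loops


@dataclass(frozen=True)
class WeakSpot:
    """A localized field distortion spoofing another zone's marker."""

    x: float
    y: float
    spoofed_zone: Zone
    rss_boost: float  # dB added to the spoofed marker near the spot


@dataclass
class SignalParams:
    """LF transmission and propagation parameters.

    tx_interval
        Per-zone emission period, seconds; must lie in [1.6, 2.1].
    burst_duration
        Length of one LF burst, seconds (50 ms by default).
    max_range
        Maximum marker range in metres (2-3 m for these markers).
    path_loss_exponent
        Exponent of the log-distance path-loss law.
    rss_noise_sd
        Gaussian RSS noise, dB.
    weather_noise_coeff
        dB of extra noise SD per unit of standardized humidity plus
        temperature deficit (noise grows in cold, dry hours).
    """

    tx_interval: dict[Zone, float] = field(
        default_factory=lambda: dict(DEFAULT_TX_INTERVALS)
    )
    burst_duration: float = 0.05
    max_range: float = 2.5
    path_loss_exponent: float = 2.0
    rss_noise_sd: float = 0.75
    weather_noise_coeff: float = 1.0

    def __post_init__(self) -> None:
        for zone, iv in self.tx_interval.items():
            if not 1.6 <= iv <= 2.1:
                raise ValueError(
                    f"tx_interval[{zone}]={iv} outside [1.6, 2.1] s"
                )
        if self.burst_duration <= 0:
            raise ValueError("burst_duration must be > 0")
        if not 2.0 <= self.max_range <= 3.0:
            raise ValueError("max_range must lie in [2, 3] m")


@dataclass
class PenLayout:
    """Geometry and marker configuration of one pen."""

    pen_id: str
    station_id: str
    zone_regions: dict[Zone, Rect] = field(
        default_factory=lambda: dict(DEFAULT_ZONE_REGIONS)
    )
    marker_loops: dict[Zone, Segment] = field(default_factory=_default_marker_loops)
    marker_power: dict[Zone, float] = field(
        default_factory=lambda: {z: DEFAULT_MARKER_POWER_DB for z in ZONES}
    )
    weak_spots: list[WeakSpot] = field(default_factory=list)
    pophole_open_hours: tuple[float, float] = (10.0, 16.0)

    def __post_init__(self) -> None:
        if set(self.marker_loops) != set(ZONES):
            raise ValueError("one marker loop per zone is required")
        regions = list(self.zone_regions.items())
        for i, (_, a) in enumerate(regions):
            for _, b in regions[i + 1 :]:
                if _rects_overlap(a, b):
                    raise ValueError("zone regions must be disjoint")
        for ws in self.weak_spots:
            if self.zone_at(ws.x, ws.y) is None:
                raise ValueError("weak spot outside every zone region")

    def zone_at(self, x: float, y: float) -> Zone | None:
        """Zone whose region contains (x, y), or None."""
        for zone, (x0, y0, x1, y1) in self.zone_regions.items():
            if x0 <= x < x1 and y0 <= y < y1:
                return zone
        return None

    def loop_distance(self, zone: Zone, x: float, y: float) -> float:
        """Distance (m) from a point to the zone's antenna cable segment."""
        return point_segment_distance(x, y, *self.marker_loops[zone])

    def model_rss(self, zone: Zone, x: float, y: float,
                  path_loss_exponent: float = 2.0) -> float:
        """Noise-free RSS (dB) of ``zone``'s marker at a point."""
        d = self.loop_distance(zone, x, y)
        return self.marker_power[zone] - 10.0 * path_loss_exponent * math.log10(
            max(d, 0.1)
        )


def _rects_overlap(a: Rect, b: Rect) -> bool:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


def point_segment_distance(px: float, py: float,
                           x1: float, y1: float, x2: float, y2: float) -> float:
    """Euclidean distance from point (px, py) to segment (x1,y1)-(x2,y2)."""
    dx, dy = x2 - x1, y2 - y1
    den = dx * dx + dy * dy
    if den == 0.0:
        return math.hypot(px - x1, py - y1)
    t = ((px - x1) * dx + (py - y1) * dy) / den
    t = min(1.0, max(0.0, t))
    return math.hypot(px - (x1 + t * dx), py - (y1 + t * dy))


def build_default_layout(
    n_pens: int,
    seed: int,
    n_weak_spots_per_pen: int = 0,
    weak_spot_boost: float = 18.0,
    pophole_open_hours: tuple[float, float] = (10.0, 16.0),
) -> list[PenLayout]:
    """Build ``n_pens`` default pens grouped into stations of 2-3 pens.

    Weak spots, when requested, are placed uniformly inside a random indoor
    zone and spoof a different indoor zone's marker with ``weak_spot_boost``
    dB of gain — emulating field distortions that make a wrong marker
    appear strongest at a fixed physical location.
    """
    if n_pens < 1:
        raise ValueError("n_pens must be >= 1")
    rng = np.random.default_rng(seed)
    station_of_pen = _group_into_stations(n_pens)
    indoor = [z for z in ZONES if z is not Zone.WINTER_GARDEN]
    layouts = []
    for p in range(n_pens):
        spots: list[WeakSpot] = []
        for _ in range(n_weak_spots_per_pen):
            zone = indoor[rng.integers(len(indoor))]
            x0, y0, x1, y1 = DEFAULT_ZONE_REGIONS[zone]
            x = rng.uniform(x0 + 0.1, x1 - 0.1)
            y = rng.uniform(y0 + 0.1, y1 - 0.1)
            others = [z for z in indoor if z is not zone]
            spoofed = others[rng.integers(len(others))]
            spots.append(WeakSpot(x, y, spoofed, weak_spot_boost))
        layouts.append(
            PenLayout(
                pen_id=f"pen{p + 1}",
                station_id=f"station{station_of_pen[p] + 1}",
                weak_spots=spots,
                pophole_open_hours=pophole_open_hours,
            )
        )
    return layouts


def _group_into_stations(n_pens: int) -> list[int]:
    """Assign pens to stations of 2-3 pens (single-pen station only if n=1)."""
    sizes: list[int] = []
    remaining = n_pens
    while remaining > 0:
        if remaining in (1, 2, 4):
            # take a 2 (or a final 1) to avoid leaving a lone pen
            take = min(2, remaining)
        else:
            take = 3
        sizes.append(take)
        remaining -= take
    out: list[int] = []
    for s, size in enumerate(sizes):
        out.extend([s] * size)
    return out
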