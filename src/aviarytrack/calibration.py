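"""Automatic marker-power calibration against critical reference positions.

Manual calibration of an LF zone-tracking system is slow: a tag is placed
at tens of critical locations per pen (typically where zones border) and
marker powers are hand-tuned until every location decodes to its true
zone.  The automatic procedure emulated here runs a 10-s evaluation cycle:
reference tags at fixed per-zone positions report the RSS of every marker;
each zone's *margin* is the smallest difference, across its reference
tags, between its own marker's signal and the strongest other marker.  If
the worst zone's margin does not exceed 1 dB, that zone's marker power is
raised one step.  Calibration completes once 100 consecutive cycles induce
no adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .layout import PenLayout, SignalParams
from .zones import ZONES, Zone

MARGIN_LIMIT_DB = 1.0
COMPLETE_AFTER_QUIET_RUNS = 100
#: inset (m) of near-border reference positions from the zone border
BORDER_INSET = 0.04


@dataclass
class CalibrationState:
    marker_power: dict[Zone, float]
    margin_table: dict[Zone, float]
    runs_without_adjustment: int = 0


@dataclass
class Adjustment:
    cycle: int
    zone: Zone
    old_power: float
    new_power: float
    margin: float


@dataclass
class CalibrationResult:
    layout: PenLayout
    converged: bool
    n_cycles: int
    adjustments: list[Adjustment] = field(default_factory=list)
    final_margins: dict[Zone, float] = field(default_factory=dict)


def default_reference_positions(
    layout: PenLayout,
) -> dict[Zone, list[tuple[float, float]]]:
    """44 critical measurement points per pen.

    Rows of points hug every zone border (inset 4 cm, where dB margins are
    smallest) plus a few interior points per zone; four extra points flank
    the pop hole between litter and winter garden.
    """
    xs = [0.4, 1.2, 2.0, 2.8]
    ref: dict[Zone, list[tuple[float, float]]] = {z: [] for z in ZONES}
    ref[Zone.TOP_TIER] += [(x, 3.0 + BORDER_INSET) for x in xs]
    ref[Zone.TOP_TIER] += [(x, 3.5) for x in xs]
    ref[Zone.NEST_BOX] += [(x, 3.0 - BORDER_INSET) for x in xs]
    ref[Zone.NEST_BOX] += [(x, 2.0 + BORDER_INSET) for x in xs]
    ref[Zone.LOWER_TIER] += [(x, 2.0 - BORDER_INSET) for x in xs]
    ref[Zone.LOWER_TIER] += [(x, 1.0 + BORDER_INSET) for x in xs]
    ref[Zone.LITTER] += [(x, 1.0 - BORDER_INSET) for x in xs]
    ref[Zone.LITTER] += [(3.0 - BORDER_INSET, y) for y in (0.3, 0.5, 0.7)]
    ref[Zone.LITTER] += [(1.5, 0.5)]
    ref[Zone.WINTER_GARDEN] += [(3.0 + BORDER_INSET, y) for y in (0.3, 0.5, 0.7)]
    ref[Zone.WINTER_GARDEN] += [(x, 0.5) for x in (3.8, 4.4, 5.0)]
    ref[Zone.WINTER_GARDEN] += [(4.1, 0.25), (4.7, 0.75)]
    # pop-hole flanks
    ref[Zone.LITTER] += [(2.9, 0.2), (2.9, 0.8)]
    ref[Zone.WINTER_GARDEN] += [(3.1, 0.2), (3.1, 0.8)]
    assert sum(len(v) for v in ref.values()) == 44
    return ref


def measure_margins(
    layout: PenLayout,
    ref_positions: dict[Zone, list[tuple[float, float]]],
    sp: SignalParams,
    rng: np.random.Generator | None = None,
) -> dict[Zone, float]:
    """Per-zone worst-case dB margin over the zone's reference tags.

    A marker out of range contributes no signal; if no competing marker is
    audible at a position, that position imposes no constraint.
    """
    margins: dict[Zone, float] = {}
    for zone, positions in ref_positions.items():
        worst = math.inf
        for (x, y) in positions:
            rss = {}
            for z in ZONES:
                d = layout.loop_distance(z, x, y)
                if d > sp.max_range:
                    continue
                val = layout.marker_power[z] - 10.0 * sp.path_loss_exponent * (
                    math.log10(max(d, 0.1))
                )
                if rng is not None and sp.rss_noise_sd > 0:
                    val += rng.normal(0.0, sp.rss_noise_sd)
                rss[z] = val
            own = rss.get(zone, -math.inf)
            others = [v for z, v in rss.items() if z is not zone]
            if not others:
                continue
            worst = min(worst, own - max(others))
        margins[zone] = worst
    return margins


def auto_calibrate(
    layout: PenLayout,
    sp: SignalParams,
    ref_positions: dict[Zone, list[tuple[float, float]]] | None = None,
    step_db: float = 0.5,
    max_runs: int = 5000,
    seed: int = 0,
    allow_decrease: bool = False,
) -> CalibrationResult:
    """Run the automatic calibration loop on a copy of ``layout``.

    Each cycle measures the margins at the reference positions, raises the
    worst zone's marker power by ``step_db`` when its margin is at most
    1 dB, and completes after 100 consecutive quiet cycles (or gives up
    after ``max_runs``).  ``allow_decrease`` instead lowers the strongest
    competing marker when the worst zone is already at its power cap —
    not used by default.
    """
    if step_db <= 0:
        raise ValueError("step_db must be > 0")
    if ref_positions is None:
        ref_positions = default_reference_positions(layout)
    if any(len(v) == 0 for v in ref_positions.values()):
        raise ValueError("need at least one reference position per zone")
    rng = np.random.default_rng(seed)

    from copy import deepcopy

    cal = deepcopy(layout)
    state = CalibrationState(marker_power=cal.marker_power, margin_table={})
    adjustments: list[Adjustment] = []
    converged = False
    n_cycles = 0
    while n_cycles < max_runs:
        n_cycles += 1
        margins = measure_margins(cal, ref_positions, sp, rng)
        state.margin_table = margins
        worst_zone = min(margins, key=lambda z: margins[z])
        if margins[worst_zone] <= MARGIN_LIMIT_DB:
            old = cal.marker_power[worst_zone]
            new = old + step_db
            if allow_decrease and margins[worst_zone] < -10.0:
                # gross miscalibration: pull the dominating competitor down
                competitor = _strongest_competitor(
                    cal, ref_positions[worst_zone], worst_zone, sp
                )
                cal.marker_power[competitor] -= step_db
            cal.marker_power[worst_zone] = new
            adjustments.append(
                Adjustment(n_cycles, worst_zone, old, new, margins[worst_zone])
            )
            state.runs_without_adjustment = 0
        else:
            state.runs_without_adjustment += 1
            if state.runs_without_adjustment >= COMPLETE_AFTER_QUIET_RUNS:
                converged = True
                break
    final = measure_margins(cal, ref_positions, sp, rng=None)
    return CalibrationResult(cal, converged, n_cycles, adjustments, final)


def _strongest_competitor(layout, positions, zone, sp) -> Zone:
    best_zone, best = zone, -math.inf
    for (x, y) in positions:
        for z in ZONES:
            if z is zone:
                continue
            val = layout.model_rss(z, x, y, sp.path_loss_exponent)
            if val > best:
                best, best_zone = val, z
    return best_zone
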