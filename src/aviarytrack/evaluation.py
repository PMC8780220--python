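"""Scoring registration datasets against ground truth.

Two complementary views, mirroring how zone-tracking data are used:

* presence/absence — per-second categorical zone series (carry-forward
  from registrations), scored by accuracy and macro-averaged
  precision/recall across zones;
* movement — the number of transitions into each zone per observation
  batch, scored by the explained-variance score
  ``EV = 1 - Var(y_gs - y_hat) / Var(y_gs)`` (population variances) and
  the mean absolute error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .zones import ZONES

DEFAULT_BATCH_HOURS = 2.0


class CoverageError(ValueError):
    """A tag has no registration at or before the evaluation start."""


class UndefinedEVError(ValueError):
    """Explained variance is undefined for zero-variance ground truth."""


@dataclass
class ZoneSeries:
    """Per-second zone occupancy of one tag over [t0, t1)."""

    tag_id: str
    t0: float
    values: np.ndarray  # zone codes, int8, one per second

    def zones(self) -> np.ndarray:
        return np.array([ZONES[v].value for v in self.values], dtype=object)


def to_zone_series(
    regs: pd.DataFrame, t0: float, t1: float
) -> dict[str, ZoneSeries]:
    """Carry-forward per-second zone series per tag over ``[t0, t1)``.

    Second ``s`` holds the zone of the last registration with
    ``t_start <= s``.  Works for registration tables and ground-truth stay
    tables alike.  Every tag needs a registration at or before ``t0``.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    n = int(np.floor(t1 - t0))
    seconds = t0 + np.arange(n, dtype=float)
    zone_code = {z.value: i for i, z in enumerate(ZONES)}
    out: dict[str, ZoneSeries] = {}
    for tag_id, grp in regs.groupby("tag_id", sort=False):
        starts = grp["t_start"].to_numpy(float)
        codes = grp["zone"].map(zone_code).to_numpy(np.int8)
        idx = np.searchsorted(starts, seconds, side="right") - 1
        if idx[0] < 0:
            raise CoverageError(
                f"tag {tag_id} has no registration at or before t0={t0}"
            )
        out[tag_id] = ZoneSeries(tag_id, t0, codes[idx])
    return out


def drop_startup_registrations(
    regs: pd.DataFrame, settle_window: float = 15.0
) -> pd.DataFrame:
    """Drop each tag's pre-settling registrations.

    Until a tag's own marker has delivered two bursts, a bordering marker
    with an earlier emission phase can register first, so the opening
    seconds of a stream may contain spurious start-up registrations even
    without noise.  Per tag, only the last registration inside
    ``settle_window`` (the settled origin zone) and everything after it
    are kept.  The window default matches the shortest possible true stay,
    so no real transition can be dropped.
    """
    if regs.empty:
        return regs.copy()
    parts = []
    for _, grp in regs.groupby("tag_id", sort=False):
        in_window = grp["t_start"].to_numpy(float) <= settle_window
        start = int(in_window.sum()) - 1 if in_window.any() else 0
        parts.append(grp.iloc[max(start, 0):])
    return pd.concat(parts).reset_index(drop=True)


@dataclass
class OccupancyMetrics:
    accuracy: float
    macro_precision: float
    macro_recall: float
    zones_used: list = field(default_factory=list)
    zones_skipped: list = field(default_factory=list)


def occupancy_metrics(
    pred: dict[str, ZoneSeries] | ZoneSeries,
    truth: dict[str, ZoneSeries] | ZoneSeries,
) -> OccupancyMetrics:
    """Per-second accuracy and macro precision/recall over aligned series.

    Macro averages run over the zones present in the ground truth (zones
    absent from both series are skipped and reported).
    """
    p = _concat(pred)
    t = _concat(truth)
    if len(p) != len(t):
        raise ValueError("pred and truth series have different lengths")
    present_truth = np.unique(t)
    accuracy = float((p == t).mean())
    precisions, recalls, used = [], [], []
    for z in present_truth:
        tp = float(((p == z) & (t == z)).sum())
        fp = float(((p == z) & (t != z)).sum())
        fn = float(((p != z) & (t == z)).sum())
        precisions.append(tp / (tp + fp) if tp + fp > 0 else 0.0)
        recalls.append(tp / (tp + fn))
        used.append(ZONES[z].value)
    skipped = [
        ZONES[int(z)].value
        for z in range(len(ZONES))
        if z not in present_truth and not (p == z).any()
    ]
    return OccupancyMetrics(
        accuracy=accuracy,
        macro_precision=float(np.mean(precisions)),
        macro_recall=float(np.mean(recalls)),
        zones_used=used,
        zones_skipped=skipped,
    )


def _concat(series) -> np.ndarray:
    if isinstance(series, ZoneSeries):
        return series.values
    keys = sorted(series)
    return np.concatenate([series[k].values for k in keys])


def transitions_per_batch(
    data: pd.DataFrame,
    batches: list[tuple[float, float]],
    zones=None,
) -> pd.DataFrame:
    """Count entries into each zone per batch.

    ``data`` is a registration table or a ground-truth stay table; an
    entry is a row's ``t_start`` falling in the half-open batch
    ``[start, end)``.  Each tag's first row is not an entry (the stay in
    place at the origin is not a transition).
    """
    zones = [z.value for z in ZONES] if zones is None else list(zones)
    bounds = sorted(batches)
    for (s0, e0), (s1, _) in zip(bounds, bounds[1:]):
        if s1 < e0:
            raise ValueError("batches overlap")
    first = data.groupby("tag_id", sort=False).cumcount() == 0
    entries = data.loc[~first]
    rows = []
    for b, (start, end) in enumerate(batches):
        in_batch = entries[
            (entries["t_start"] >= start) & (entries["t_start"] < end)
        ]
        counts = in_batch.groupby("zone").size()
        for z in zones:
            rows.append((b, z, int(counts.get(z, 0))))
    return pd.DataFrame(rows, columns=["batch", "zone", "count"])


def explained_variance(y_gs, y_hat) -> float:
    """Explained-variance score 1 - Var(y_gs - y_hat)/Var(y_gs), using
    population variances; invariant to constant shifts of ``y_hat``."""
    y_gs = np.asarray(y_gs, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y_gs) != len(y_hat) or len(y_gs) < 2:
        raise ValueError("need equal-length vectors of length >= 2")
    denom = np.var(y_gs)
    if denom == 0:
        raise UndefinedEVError("ground-truth counts have zero variance")
    return float(1.0 - np.var(y_gs - y_hat) / denom)


def mean_absolute_error(y_gs, y_hat) -> float:
    """Mean absolute difference between count vectors."""
    y_gs = np.asarray(y_gs, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y_gs) != len(y_hat) or len(y_gs) == 0:
        raise ValueError("need equal-length non-empty vectors")
    return float(np.mean(np.abs(y_gs - y_hat)))


@dataclass
class EvalReport:
    """Full comparison of a registration dataset against ground truth."""

    accuracy: float
    macro_precision: float
    macro_recall: float
    ev: float
    mae: float
    per_batch_zone_counts: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "ev": self.ev,
            "mae": self.mae,
        }


def make_batches(t0: float, t1: float, batch_hours: float = DEFAULT_BATCH_HOURS):
    """Consecutive half-open batches of ``batch_hours`` covering [t0, t1)."""
    step = batch_hours * 3600.0
    edges = np.arange(t0, t1, step)
    return [(float(s), float(min(s + step, t1))) for s in edges]


def evaluate(
    regs: pd.DataFrame,
    truth: pd.DataFrame,
    t0: float,
    t1: float,
    batch_hours: float = DEFAULT_BATCH_HOURS,
) -> EvalReport:
    """Score a registration dataset against ground-truth stays on
    [t0, t1): per-second occupancy metrics plus transition-count EV/MAE
    over ``batch_hours`` batches."""
    pred_series = to_zone_series(regs, t0, t1)
    truth_series = to_zone_series(truth, t0, t1)
    occ = occupancy_metrics(pred_series, truth_series)
    batches = make_batches(t0, t1, batch_hours)
    gs = transitions_per_batch(truth, batches)
    hat = transitions_per_batch(regs, batches)
    merged = gs.merge(hat, on=["batch", "zone"], suffixes=("_truth", "_pred"))
    ev = explained_variance(merged["count_truth"], merged["count_pred"])
    mae = mean_absolute_error(merged["count_truth"], merged["count_pred"])
    counts = merged.rename(
        columns={"count_truth": "count_truth", "count_pred": "count_pred"}
    )
    return EvalReport(
        accuracy=occ.accuracy,
        macro_precision=occ.macro_precision,
        macro_recall=occ.macro_recall,
        ev=ev,
        mae=mae,
        per_batch_zone_counts=counts,
    )
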