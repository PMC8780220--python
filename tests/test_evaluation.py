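"""Zone-series construction, occupancy metrics, transition counts, EV/MAE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sklearn.metrics as skm

from aviarytrack.evaluation import (
    CoverageError,
    UndefinedEVError,
    ZoneSeries,
    explained_variance,
    make_batches,
    mean_absolute_error,
    occupancy_metrics,
    to_zone_series,
    transitions_per_batch,
)
from aviarytrack.zones import ZONES
from conftest import make_registrations, make_truth

ZNAME = [z.value for z in ZONES]


def series(codes):
    return ZoneSeries("a", 0.0, np.asarray(codes, dtype=np.int8))


class TestToZoneSeries:
    def test_constant_series(self):
        regs = make_registrations([("a", "LITTER", 0.0, 100.0)])
        out = to_zone_series(regs, 0.0, 50.0)
        assert (out["a"].zones() == "LITTER").all()
        assert len(out["a"].values) == 50

    def test_forced_carry_forward(self):
        regs = make_registrations(
            [("a", "LITTER", 0.0, 10.0), ("a", "LOWER_TIER", 10.0, 10.0)]
        )
        out = to_zone_series(regs, 0.0, 20.0)
        zones = out["a"].zones()
        assert (zones[:10] == "LITTER").all()
        assert (zones[10:] == "LOWER_TIER").all()

    def test_matches_per_second_brute_force(self):
        rng = np.random.default_rng(3)
        rows, t = [], 0.0
        prev = None
        for _ in range(25):
            z = rng.choice([z for z in ZNAME[:4] if z != prev])
            d = float(rng.uniform(3, 40))
            rows.append(("a", z, t, d))
            t += d
            prev = z
        regs = make_registrations(rows)
        t0, t1 = 5.0, t - 1
        out = to_zone_series(regs, t0, t1)["a"].zones()
        for k, s in enumerate(np.arange(t0, np.floor(t1 - t0) + t0)):
            last = [r for r in rows if r[2] <= s][-1]
            assert out[k] == last[1]

    def test_missing_coverage_raises(self):
        regs = make_registrations([("a", "LITTER", 10.0, 100.0)])
        with pytest.raises(CoverageError, match="a"):
            to_zone_series(regs, 0.0, 50.0)


class TestOccupancyMetrics:
    def test_identical_series_all_ones(self):
        s = series([0, 1, 2, 3, 0, 1])
        m = occupancy_metrics(s, s)
        assert (m.accuracy, m.macro_precision, m.macro_recall) == (1.0, 1.0, 1.0)

    def test_eight_of_ten_matching(self):
        t = series([0] * 10)
        p = series([0] * 8 + [1, 1])
        assert occupancy_metrics(p, t).accuracy == pytest.approx(0.8)

    def test_hand_computed_three_zone_confusion(self):
        t = series([0, 0, 0, 1, 1, 2, 2, 2, 2, 2])
        p = series([0, 0, 1, 1, 1, 2, 2, 2, 0, 0])
        m = occupancy_metrics(p, t)
        # zone0: tp=2 fp=2 fn=1; zone1: tp=2 fp=1 fn=0; zone2: tp=3 fp=0 fn=2
        assert m.accuracy == pytest.approx(0.7)
        assert m.macro_precision == pytest.approx((2 / 4 + 2 / 3 + 1.0) / 3)
        assert m.macro_recall == pytest.approx((2 / 3 + 1.0 + 3 / 5) / 3)

    def test_agrees_with_sklearn_macro_scores(self):
        rng = np.random.default_rng(11)
        t = series(rng.integers(0, 4, 500))
        p = series(rng.integers(0, 4, 500))
        m = occupancy_metrics(p, t)
        labels = np.unique(t.values)
        assert m.macro_precision == pytest.approx(
            skm.precision_score(
                t.values, p.values, labels=labels, average="macro",
                zero_division=0,
            )
        )
        assert m.macro_recall == pytest.approx(
            skm.recall_score(
                t.values, p.values, labels=labels, average="macro",
                zero_division=0,
            )
        )

    def test_accuracy_equals_micro_recall(self):
        rng = np.random.default_rng(12)
        t = series(rng.integers(0, 5, 300))
        p = series(rng.integers(0, 5, 300))
        m = occupancy_metrics(p, t)
        assert m.accuracy == pytest.approx(
            skm.recall_score(t.values, p.values, average="micro")
        )

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            occupancy_metrics(series([0, 1]), series([0]))


class TestTransitionsPerBatch:
    def test_empty_batch_all_zero(self):
        regs = make_registrations([("a", "LITTER", 0.0, 100.0)])
        out = transitions_per_batch(regs, [(200.0, 300.0)])
        assert (out["count"] == 0).all()

    def test_origin_entry_not_counted(self):
        truth = make_truth(
            [
                ("a", "LITTER", 0.0, 100.0),
                ("a", "LOWER_TIER", 100.0, 200.0),
                ("a", "LITTER", 200.0, 300.0),
            ]
        )
        out = transitions_per_batch(truth, [(0.0, 300.0)])
        counts = out.set_index("zone")["count"]
        assert counts["LOWER_TIER"] == 1
        assert counts["LITTER"] == 1
        assert counts["TOP_TIER"] == 0

    def test_totals_conserve_registration_count(self):
        rng = np.random.default_rng(4)
        rows = []
        for tag in ("a", "b", "c"):
            t, prev = 0.0, None
            for _ in range(20):
                z = rng.choice([z for z in ZNAME if z != prev])
                d = float(rng.uniform(60, 600))
                rows.append((tag, z, t, d))
                t += d
                prev = z
        regs = make_registrations(rows)
        horizon = regs["t_start"].max() + 1
        batches = make_batches(0.0, horizon, batch_hours=2.0)
        out = transitions_per_batch(regs, batches)
        assert out["count"].sum() == len(regs) - 3  # minus one origin per tag

    def test_overlapping_batches_rejected(self):
        regs = make_registrations([("a", "LITTER", 0.0, 100.0)])
        with pytest.raises(ValueError):
            transitions_per_batch(regs, [(0.0, 100.0), (50.0, 150.0)])


class TestEVAndMAE:
    def test_perfect_prediction(self):
        assert explained_variance([0, 2, 4], [0, 2, 4]) == 1.0
        assert mean_absolute_error([1, 2], [1, 2]) == 0.0

    def test_constant_shift_gives_ev_one(self):
        assert explained_variance([0, 2, 4], [3, 5, 7]) == pytest.approx(1.0)

    def test_hand_computed_values(self):
        # population variances: var([0,1,2]) = 2/3, var([0,2,4]) = 8/3
        assert explained_variance([0, 2, 4], [0, 1, 2]) == pytest.approx(0.75)
        assert mean_absolute_error([1, 2], [0, 4]) == pytest.approx(1.5)

    def test_agrees_with_sklearn_explained_variance(self):
        rng = np.random.default_rng(6)
        y = rng.poisson(10, 40).astype(float)
        yh = y + rng.normal(0, 2, 40)
        assert explained_variance(y, yh) == pytest.approx(
            skm.explained_variance_score(y, yh)
        )

    def test_zero_variance_truth_raises(self):
        with pytest.raises(UndefinedEVError):
            explained_variance([3, 3, 3], [1, 2, 3])

    def test_mae_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert mean_absolute_error(a, b) == mean_absolute_error(b, a) >= 0.0

    @settings(max_examples=50, deadline=None)
    @given(
        y=st.lists(st.integers(0, 50), min_size=3, max_size=20),
        shift=st.integers(-10, 10),
    )
    def test_ev_invariant_to_constant_shift_and_bounded(self, y, shift):
        if np.var(y) == 0:
            return
        yh = [v + shift for v in y]
        assert explained_variance(y, yh) == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        noisy = [v + rng.integers(-5, 5) for v in y]
        assert explained_variance(y, noisy) <= 1.0
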