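# aviarytrack

Zone-level tracking of laying hens in commercial aviaries, end to end:
simulation of a low-frequency (LF) marker system, tag-side decoding of zone
registrations, false-registration filtering, and evaluation against ground
truth.

## The problem

Active LF tracking systems divide an aviary pen into a handful of
resource zones — top tier, nest box, lower tier, littered floor, and an
outdoor winter garden behind a pop hole — each enclosed by a marker cable
that emits short identification bursts. A backpack tag decodes its zone
from the strongest received signal (RSS): it reports a transition whenever
one marker supplies the absolute strongest signal twice within 10 s and
that marker's zone differs from the last registered zone.

Such systems locate birds very accurately second-by-second, but they
overestimate *movement*: signal noise and localized field distortions
("weak spots") create false registrations (FR) that inflate transition
counts. Two filters address this:

- **SD method** — remove every stay shorter than a threshold (60 s);
- **ML method** — remove registrations that a gradient-boosted tree
  classifier, trained on 13 registration features (zones, durations and
  signal metadata of a record and its neighbours), predicts to be FR;
  winter-garden records, for which no labelled training data exist, fall
  back to the SD rule.

Filtered datasets are scored against ground truth per second (accuracy,
macro precision/recall over zones) and per movement, via transition counts
per batch and zone with the explained-variance score and mean absolute
error:

```
EV  = 1 − Var(y_GS − ŷ) / Var(y_GS)          MAE = (1/n) Σ |y_GS,i − ŷ_i|
```

This package implements the whole chain against a synthetic aviary — a 2-D
pen cross-section with distance-based RSS, per-zone transmission intervals
(1.6–2.1 s), burst collisions, weak spots and pop-hole-gated winter-garden
access — plus two companion analyses:

- **error-rate factor analysis**: classifier-identified FR rates per
  pen-zone area, and a binomial-logit mixed model (pen nested in station)
  of hourly FR odds on temperature, humidity and hour of day;
- **significance-loss simulation**: the downstream cost of a weaker
  filter, measured as the probability that a movement–health correlation
  test (true Pearson r between 0.15 and 0.40) is significant when the
  movement proxy retains 99% of the metric's variance but not when it
  retains 91%;
- **automatic calibration**: an iterative loop that raises the marker
  power of the zone with the smallest dB margin at critical reference
  positions until every margin exceeds 1 dB for 100 consecutive 10-s
  cycles.

## Worked example

```python
from aviarytrack import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=7, n_pens=10, n_tags_per_pen=5,
                                duration_s=24 * 3600))
for name, report in result.reports.items():
    print(f"{name:12s} EV={report.ev:6.3f}  MAE={report.mae:6.2f} "
          f"accuracy={report.accuracy:.3f}")
```

prints (one day, 50 hens, 10 pens, two weak spots per pen):

```
unprocessed  EV= 0.264  MAE= 17.78 accuracy=0.973
sd           EV= 0.972  MAE=  3.95 accuracy=0.973
ml           EV= 0.990  MAE=  1.65 accuracy=0.973
```

Per-second presence/absence is excellent even unprocessed, but the raw
data explain only ~26% of the variance in true transition counts; the
one-minute filter recovers most of it, and the classifier filter recovers
the most while making a third of the SD filter's absolute count error.
The same three-way pattern (99%/91%/23% EV on real barn data) motivates
the whole processing chain.

The command line mirrors the library:

```
aviarytrack run --config cfg.yaml --out rundir --seed 7
aviarytrack sigloss --rho 0.25 --n 80 --sims 10000 --seed 1
aviarytrack calibrate --layout layouts.json --out calibrated.json --log audit.csv
```

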