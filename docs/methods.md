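# Methods

This note documents the models behind `aviarytrack`: what the simulator
emulates, how the decoder and filters are defined, the numerical and
design choices that were genuinely open, and what the package's tests do
and do not establish about real barn data.

## The simulated aviary

A pen is a 2-D cross-section. Four indoor zones are stacked 1-m-tall,
3-m-wide rectangles (litter, lower tier, nest box, top tier, bottom to
top); the winter garden is a 2.5-m-wide rectangle beside the litter,
reachable through the pop hole at x = 3 m. Zone adjacency is therefore the
path graph top tier – nest box – lower tier – litter – winter garden.
Pens are grouped into stations of two or three (a station is one tracking
system installation serving its pens).

Each zone's marker cable is a horizontal line segment along the zone's
mid-line, inset 0.2 m from the walls. The signal model is log-distance
path loss from the point-to-segment distance `d`:

```
rss(d) = P_z − 10 · γ · log10(max(d, 0.1 m) / 1 m) + ε,   ε ~ N(0, σ²)
```

with reference power `P_z` = 80 dB for every zone, exponent γ = 2, and a
0.1-m near-field clamp. With equal powers and mid-line cables, the
occupied zone's marker is strictly the nearest (hence strongest) marker at
every interior point, so the σ = 0 world decodes exactly; near zone
borders the dB margin between own and neighbouring marker shrinks toward
zero, which is where noise produces false registrations — mirroring the
real system, whose calibration effort concentrates on border locations.

Markers emit 50-ms bursts on per-zone periods of 1.6, 1.7, 1.85, 1.95 and
2.1 s (distinct per zone, random phase per run). Two bursts that overlap
in time at a tag are both dropped, as overlapping LF signals cannot be
demodulated; distinct periods make such collisions sporadic rather than
persistent. Marker range is 2.5 m, so a tag typically hears two to four
markers — the nominal five to six bursts per marker per 10 s minus range
and collision losses. (The stated burst counts and the 2.1-s period are
mutually inconsistent at the upper end; the simulator follows the interval
range.)

**Weak spots** model localized field distortions (metal furnishing
reflecting or absorbing the field): within 0.3 m of a weak spot, a
designated wrong zone's marker gains a fixed RSS boost and is received
regardless of range. A hen sitting on a strong weak spot is registered in
the spoofed zone for the whole stay — the long false registrations that a
duration threshold cannot remove.

**Movement.** A tag's day is a continuous-time walk on the zone graph.
Dwell times are shifted exponentials, `15 s + Exp(mean − 15 s)`, with
per-zone means of 25 min (top tier), 20 min (nest box), 10 min (lower
tier, winter garden) and 15 min (litter). The 15-s floor keeps every stay
long enough to be decodable (two bursts of the new zone's marker plus
expiry of the previous zone's strongest burst from the 10-s window take at
most ~12 s), while retaining sub-minute stays whose removal is the real
cost of the one-minute filter. The winter garden is entered only while
the pop hole is open (10:00–16:00, the six-hour daily access) and with
enough time left for a minimum stay; hens still inside at closing exit to
the litter. The tag position is resampled uniformly inside the zone
rectangle once per stay: zone-level tracking does not require within-stay
trajectories, and a stationary hen is exactly the regime in which weak
spots matter.

**Noise calibration.** The defaults — σ = 0.75 dB RSS noise, 18-dB weak
spot boost, two weak spots per pen — were chosen so that the synthetic
world reproduces the documented operating regime of such systems: a false
registration fraction around 5–20% of records, near-perfect per-second
presence/absence, and unprocessed data explaining only a small fraction
(~0.2–0.5) of the variance in transition counts. Larger noise drives the
simulator into a churn regime (FR fractions ≥ 40%) unlike anything
observed on real hardware. An optional hourly weather series inflates σ
by 1 dB per unit of standardized humidity-plus-temperature deficit, making
cold, dry hours noisier.

## Tag decoder

The decoder re-evaluates at every reception, over the half-open 10-s
window ending at that reception: let m\* be the marker holding the single
maximum RSS in the window. A transition to zone(m\*) is registered iff
m\* supplies **at least two** receptions that each exceed every other
marker's maximum in the window, and zone(m\*) differs from the last
registered zone. Requiring two *dominating* receptions (not merely the
top marker twice) is the strictest reading of "absolute strongest signal
value twice"; it makes a single spurious strong burst insufficient to
switch zones. The registration timestamp is the reception at which the
rule is first satisfied; RSS ties break toward the currently registered
zone, then toward the earlier reception. Each registration carries the
window's strongest RSS, the runner-up marker's zone and RSS, and a flag
for three or more distinct zones heard — the signal metadata used as
classifier features. Durations are closed afterwards: each stay lasts
until the tag's next registration, the last until the observation end.

Two consequences worth noting. *Detection lag*: after a true transition,
the previous zone's strongest burst must leave the 10-s window before the
new zone can dominate, so reconstruction trails truth by up to
window + 2 periods (≈ 14 s). *Start-up*: before a tag's own marker has
delivered two bursts, a bordering marker with an earlier phase can
register first, even without noise. Both are properties of the decoding
rule, not implementation artifacts; evaluation utilities provide a settle
exclusion (`drop_startup_registrations`) and the exactness checks on
noiseless runs exclude the post-transition lag seconds.

## Labels, features, filters

A registration is **CR** when the registered zone equals the true zone at
its timestamp, else **FR**. A CR is **transitional** when it is the first
registration inside its enclosing true stay ("associated with a true
transition" — made parameter-free by the first-in-stay rule), otherwise
**corrected**. A true stay (after a tag's first) containing no
registration at all yields one **missed transition** row. Missed
transitions are diagnostics; they have no decoder fields.

The feature table has exactly 13 columns per registration: previous /
current / next zone, strongest RSS, station identity, previous / current /
next duration, runner-up zone and its RSS, the ≥3-zones flag, and two
binary features marking whether the neighbouring record's runner-up zone
equals the current zone (the signature of a stationary hen flip-flopping
between two markers). Edge records take a `NONE` zone category and NaN
durations.

The **SD filter** removes stays shorter than 60 s; the **ML filter**
removes indoor registrations predicted FR by a gradient-boosted tree
ensemble (`HistGradientBoostingClassifier`, native categorical and NaN
handling), applying the SD rule to winter-garden records, which are
excluded from training for lack of labels. In both filters a removed
interval is absorbed by *extending the preceding registration* — the tag
is presumed to remain in its last registered zone until re-registered,
matching the decoder's carry-forward semantics — then consecutive
same-zone stays are merged and durations recomputed. A tag's first
registration is never removed (it has no predecessor). Hyperparameters
come from a 3-fold cross-validated grid over depth {3, 6}, learning rate
{0.1, 0.3} and ensemble size {100, 200}; any tree ensemble satisfies the
contract, as the three learners compared on the real data performed
indistinguishably. Feature importances are permutation importances on the
held-out split, clipped at zero and normalized to sum to one. Classifier
pairs are compared with McNemar's test — exact binomial below 25
discordant predictions, continuity-corrected chi-square otherwise.

## Evaluation

Per-second occupancy series are carry-forward: second *s* holds the zone
of the last registration at or before *s*. Accuracy is the matching
fraction; macro precision/recall average one-vs-rest scores over the zones
present in the ground truth (zones absent from both series are skipped and
reported — evaluation batches often lack winter-garden visits). Movement
is summarized as transition counts per batch and zone: a row's entry time
falling in the half-open batch, with each tag's first record excluded
(being somewhere at the origin is not a transition; a stay straddling a
batch boundary counts once, in its entry batch). EV uses population
variances, matching the usual explained-variance score, and is undefined
(an error) for zero-variance ground truth; MAE is per batch-zone cell.
The default batch is two hours, the length of the video-observation
batches such datasets are validated against.

## Error-rate factors

Without video, the classifier's FR predictions (IFR) proxy the truth. The
estimated error rate is each hen's IFR count over its registration count;
pen-zone areas report mean ± SD across hens (1 when everything was
filtered, 0 when nothing). Winter-garden registrations timed while the
pop hole is closed are dropped first, since the zone is then unreachable
and such records would inflate the rate.

Hourly weather effects are estimated by a binomial-logit mixed model on
per-(pen, hour) counts of IFR vs other registrations, with fixed effects
temperature (°C), humidity/10 (so the odds ratio refers to a
10-percentage-point change) and hour-of-day as a categorical (daily
management and behaviour rhythms are a confounder, not a smooth trend),
and random intercepts for pen nested in station. The fit uses lme4's
`glmer` via Rscript (`nAGQ = 0`, adequate for binomial counts of this
size); when R is unavailable or the random-effect structure degenerates,
a binomial GLM with station and pen fixed intercepts is used and flagged.
Wald 95% intervals on the exponentiated coefficients are reported.
Aggregation is per (pen, hour) rather than per (hen, hour), keeping the
table small; the hen-level option is a trivial change of grouping by the
caller. The companion generator draws from this model's own likelihood
(Gaussian station/pen intercepts of SD 0.15, diurnal temperature and
humidity cycles with noise, Poisson+1 registrations per pen-hour,
intercept −2 giving a ~12% baseline error rate) for parameter-recovery
testing.

## Significance-loss simulation

M (movement metric) and H (health outcome) are standard normal with true
Pearson correlation ρ ∈ [0.15, 0.40]. A pipeline recovering a fraction v
of M's variance yields the proxy `M'_v = √v·M + √(1−v)·ε`. For
v_hi = 0.99 and v_lo = 0.91 — the variance fractions recovered by the
classifier and the duration filter — the simulation reports the fraction
of replicates in which the two-sided Pearson test of proxy against H is
significant (α = 0.05) at v_hi but not at v_lo, over 10,000 replicates.

By default each variance fraction is evaluated on its **own independently
drawn sample** — two studies of identical design run with different
pipelines — giving ≈ 26% at (n=80, ρ=0.25) and ≈ 25–26% at (n=120,
ρ=0.2), essentially power(v_hi)·(1 − power(v_lo)). A paired mode
(`paired=True`) evaluates both proxies on one shared (M, H) draw with
independent noise; it answers a different question — "would *this*
study's conclusion have changed?" — and yields much smaller fractions
(≈ 7%), because the two proxies are almost perfectly correlated. The
Monte-Carlo SE at 10,000 replicates is ≈ 0.4 percentage points.

## Automatic calibration

Reference tags sit at 44 critical positions per pen: rows hugging every
zone border at 4 cm inset (where margins are ~1.4 dB, just above the
limit), a few interior points, and four points flanking the pop hole.
Every 10-s cycle measures each zone's margin — the smallest difference,
over the zone's reference tags, between the own marker's RSS and the
strongest other marker (out-of-range markers are silent; a tag hearing no
competitor imposes no constraint). If the worst margin does not exceed
1 dB, that zone's marker power is raised by `step_db` (default 0.5 dB;
conservative steps avoid oscillation between bordering zones, to which the
small nest-box zone is particularly prone). Calibration completes after
100 consecutive cycles without adjustment. Adjustment is increase-only by
default: raising the under-detected marker restores its margins and
returns neighbours to their baseline, whereas decreases can ping-pong; a
decrease path exists behind `allow_decrease` for gross miscalibration.
The audit log (cycle, zone, old/new power, margin) replays exactly to the
final state.

## Problem sizes and numerical conventions

Time is float seconds from the simulation origin; intervals are half-open
`[t_start, t_end)`. All randomness flows from one root seed through named
`SeedSequence` substreams per pipeline stage, so identical configurations
reproduce identical outputs. The decoder's inner loop is numba-compiled;
a 50-tag day (~5 million receptions) decodes in about a second.

The test suite exercises the chain at the sizes a desk machine handles in
minutes: the noiseless exactness checks on one pen × 4 tags × 2 h; the
filter-ordering property on ten simulations of 10 pens × 5 tags × 24 h
(classifier trained on half the tags, scored on the held-out half);
weather-model recovery on 50 tables of 12 pens × 7 days; the
significance-loss figures at the full 10,000 replicates.

## Limitations

The simulator is a caricature sufficient for the pipeline's contracts,
not a calibrated twin of any barn: geometry is 2-D, hens are stationary
within stays and move as a memoryless walk, RSS noise is Gaussian and
independent across bursts, weak spots are disks with a constant boost,
and inter-pen interference, tag power management and the UHF reader
back-channel are not modelled. Passing tests therefore demonstrate the
correctness and internal consistency of the decoding, labeling, filtering
and evaluation logic under controlled conditions — they do not certify
error rates on real hardware, where propagation is far messier. The
classifier's advantage over the duration threshold depends on the
existence of long false stays and short true stays; in a barn without
weak spots the two filters converge, as the significance-loss analysis
quantifies.
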