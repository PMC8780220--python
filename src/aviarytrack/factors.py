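"""Error-rate factor analysis: pen-zone areas and weather covariates.

Without video, the trained classifier's FR predictions (identified false
registrations, IFR) proxy the truth.  Two analyses:

* the estimated error rate — per-hen IFR count over total registrations,
  aggregated as mean +/- SD across hens for each pen-zone area; and
* a mixed-effects logistic (binomial-logit) regression of hourly IFR odds
  on external temperature (degC), humidity rescaled to 10%-units, and hour
  of day (categorical), with pen nested in station as random intercepts.

The regression is fitted with lme4's ``glmer`` through Rscript (the
standard tool for nested binomial GLMMs); if R is unavailable or the
random-effect structure is degenerate, a binomial GLM with station and
pen fixed intercepts is used instead and flagged in the result.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .zones import Zone

HOURLY_TABLE_COLUMNS = [
    "pen_id",
    "station_id",
    "hour",
    "ifr_count",
    "cr_count",
    "temperature_c",
    "humidity_rescaled",
    "hour_of_day",
]


def estimated_error_rate(
    flagged: pd.DataFrame,
    wg_open_hours: tuple[float, float] = (10.0, 16.0),
) -> pd.DataFrame:
    """Per pen-zone estimated error rate, mean +/- SD across individuals.

    ``flagged`` is a registration table with a boolean ``ifr`` column.
    Winter-garden registrations timed outside the pop-hole opening hours
    are dropped before counting (they would otherwise inflate the rate
    while the zone is unreachable).  Returns columns
    ``pen_id, zone, mean_rate, sd_rate, n_individuals``.
    """
    df = flagged.copy()
    hour = (df["t_start"].to_numpy(float) % 86400.0) / 3600.0
    closed_wg = (df["zone"] == Zone.WINTER_GARDEN.value) & ~(
        (hour >= wg_open_hours[0]) & (hour < wg_open_hours[1])
    )
    df = df.loc[~closed_wg]
    per_hen = (
        df.groupby(["pen_id", "zone", "tag_id"])["ifr"]
        .mean()
        .rename("rate")
        .reset_index()
    )
    agg = (
        per_hen.groupby(["pen_id", "zone"])["rate"]
        .agg(mean_rate="mean", sd_rate="std", n_individuals="size")
        .reset_index()
    )
    agg["sd_rate"] = agg["sd_rate"].fillna(0.0)
    return agg


def build_hourly_error_table(
    flagged: pd.DataFrame, weather: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate flagged registrations into the hourly binomial table.

    ``weather`` rows are (hour_start [s], temperature_c, humidity_pct);
    humidity is rescaled by dividing by 10 so its odds ratio refers to a
    10-percentage-point change.
    """
    df = flagged.copy()
    df["hour"] = (df["t_start"].to_numpy(float) // 3600.0).astype(int)
    counts = (
        df.groupby(["pen_id", "station_id", "hour"])["ifr"]
        .agg(ifr_count="sum", total="size")
        .reset_index()
    )
    counts["ifr_count"] = counts["ifr_count"].astype(int)
    counts["cr_count"] = counts["total"] - counts["ifr_count"]
    w = weather.copy()
    w["hour"] = (w["hour_start"].to_numpy(float) // 3600.0).astype(int)
    out = counts.merge(
        w[["hour", "temperature_c", "humidity_pct"]], on="hour", how="inner"
    )
    out["humidity_rescaled"] = out["humidity_pct"] / 10.0
    out["hour_of_day"] = out["hour"] % 24
    return out[HOURLY_TABLE_COLUMNS]


@dataclass
class WeatherModelResult:
    """Exponentiated coefficients of the hourly IFR-odds model."""

    odds_ratios: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    backend: str  # 'lme4' or 'glm_fixed'
    fallback: bool = False
    random_effect_sd: dict[str, float] = field(default_factory=dict)


_R_SCRIPT = r"""
suppressMessages(library(lme4))
args <- commandArgs(trailingOnly = TRUE)
fits <- lapply(args, function(path) {
  d <- read.csv(path)
  d$hour_of_day <- factor(d$hour_of_day)
  m <- glmer(cbind(ifr_count, cr_count) ~ temperature_c + humidity_rescaled +
               hour_of_day + (1 | station_id / pen_id),
             data = d, family = binomial(link = "logit"), nAGQ = 0)
  fe <- fixef(m)
  se <- sqrt(diag(as.matrix(vcov(m))))
  vc <- as.data.frame(VarCorr(m))
  list(names = names(fe), coef = unname(fe), se = unname(se),
       re_names = vc$grp, re_sd = vc$sdcor)
})
cat(jsonlite::toJSON(fits, digits = 12))
"""


def fit_weather_model(
    table: pd.DataFrame, backend: str = "lme4"
) -> WeatherModelResult:
    """Fit the binomial-logit weather model on the hourly error table.

    Returns odds ratios with Wald 95% CIs for temperature,
    humidity_rescaled and the hour-of-day contrasts.
    """
    missing = set(HOURLY_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"hourly table missing columns: {sorted(missing)}")
    if backend == "lme4":
        try:
            return _fit_lme4(table)
        except (OSError, RuntimeError, subprocess.SubprocessError):
            pass  # fall through to the fixed-intercept GLM
        backend_used, fallback = "glm_fixed", True
    elif backend == "glm_fixed":
        backend_used, fallback = "glm_fixed", False
    else:
        raise ValueError(f"unknown backend {backend!r}")
    res = _fit_glm_fixed(table)
    res.backend = backend_used
    res.fallback = fallback
    return res


def _fit_lme4(table: pd.DataFrame) -> WeatherModelResult:
    return fit_weather_models([table])[0]


def fit_weather_models(tables: list[pd.DataFrame]) -> list[WeatherModelResult]:
    """Fit the lme4 binomial GLMM to several hourly tables in one R call.

    Useful for simulation studies: the R interpreter start-up is paid once
    for the whole batch.
    """
    with tempfile.TemporaryDirectory() as tmp:
        r_path = Path(tmp) / "fit.R"
        r_path.write_text(_R_SCRIPT)
        csv_paths = []
        for i, table in enumerate(tables):
            p = Path(tmp) / f"hourly{i}.csv"
            table.to_csv(p, index=False)
            csv_paths.append(str(p))
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(r_path), *csv_paths],
            capture_output=True,
            text=True,
            timeout=60 + 120 * len(tables),
        )
    if proc.returncode != 0:
        raise RuntimeError(f"lme4 fit failed: {proc.stderr[-500:]}")
    results = []
    for payload in json.loads(proc.stdout):
        names = [_tidy_name(n) for n in payload["names"]]
        coefs = dict(zip(names, map(float, payload["coef"])))
        ses = dict(zip(names, map(float, payload["se"])))
        results.append(
            _assemble_result(
                coefs,
                ses,
                backend="lme4",
                re_sd=dict(
                    zip(
                        payload.get("re_names", []),
                        map(float, payload.get("re_sd", [])),
                    )
                ),
            )
        )
    return results


def _fit_glm_fixed(table: pd.DataFrame) -> WeatherModelResult:
    import statsmodels.api as sm

    d = table.copy()
    endog = d[["ifr_count", "cr_count"]].to_numpy(float)
    exog = pd.get_dummies(
        d[["temperature_c", "humidity_rescaled"]].join(
            d[["hour_of_day", "station_id", "pen_id"]].astype(str)
        ),
        columns=["hour_of_day", "station_id", "pen_id"],
        drop_first=True,
        dtype=float,
    )
    exog.insert(0, "Intercept", 1.0)
    fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    names = [_tidy_name(n) for n in fit.params.index]
    coefs = dict(zip(names, fit.params.to_numpy(float)))
    ses = dict(zip(names, fit.bse.to_numpy(float)))
    return _assemble_result(coefs, ses, backend="glm_fixed")


def _tidy_name(name: str) -> str:
    name = name.replace("(Intercept)", "Intercept")
    if name.startswith("hour_of_day") and not name.startswith("hour_of_day_"):
        return "hour_of_day_" + name[len("hour_of_day") :]
    return name


def _assemble_result(coefs, ses, backend, re_sd=None) -> WeatherModelResult:
    z = 1.959963984540054
    keep = {
        n: c
        for n, c in coefs.items()
        if n in ("temperature_c", "humidity_rescaled")
        or n.startswith("hour_of_day_")
    }
    ors = {n: float(np.exp(c)) for n, c in keep.items()}
    cis = {
        n: (
            float(np.exp(c - z * ses[n])),
            float(np.exp(c + z * ses[n])),
        )
        for n, c in keep.items()
    }
    return WeatherModelResult(
        odds_ratios=ors,
        conf_int=cis,
        coefficients={n: float(c) for n, c in coefs.items()},
        std_errors={n: float(s) for n, s in ses.items()},
        backend=backend,
        random_effect_sd=re_sd or {},
    )


def simulate_hourly_error_table(
    n_pens: int = 12,
    n_days: int = 10,
    or_humidity: float = 0.96,
    or_temperature: float = 0.97,
    intercept: float = -2.0,
    sd_station: float = 0.15,
    sd_pen: float = 0.15,
    mean_registrations_per_hour: float = 25.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate an hourly error table from the binomial-logit model itself.

    Used for parameter-recovery checks: hourly humidity/temperature follow
    smooth diurnal cycles with noise, station and pen intercepts are
    Gaussian, hour-of-day has no effect, and IFR counts are binomial with
    logit-linear probabilities.  Registration volume per pen-hour is
    Poisson (plus one, so every cell is populated).
    """
    from .layout import _group_into_stations

    rng = np.random.default_rng(seed)
    station_of_pen = _group_into_stations(n_pens)
    n_stations = max(station_of_pen) + 1
    b_station = rng.normal(0.0, sd_station, n_stations)
    b_pen = rng.normal(0.0, sd_pen, n_pens)

    hours = np.arange(n_days * 24)
    hod = hours % 24
    temperature = (
        12.0 + 6.0 * np.sin(2 * np.pi * (hod - 9) / 24.0)
        + rng.normal(0, 2.0, len(hours))
    )
    humidity = np.clip(
        70.0 - 15.0 * np.sin(2 * np.pi * (hod - 9) / 24.0)
        + rng.normal(0, 5.0, len(hours)),
        5.0,
        100.0,
    )
    beta_h = np.log(or_humidity)
    beta_t = np.log(or_temperature)
    rows = []
    for p in range(n_pens):
        s = station_of_pen[p]
        eta = (
            intercept
            + b_station[s]
            + b_pen[p]
            + beta_t * temperature
            + beta_h * humidity / 10.0
        )
        prob = 1.0 / (1.0 + np.exp(-eta))
        total = rng.poisson(mean_registrations_per_hour, len(hours)) + 1
        ifr = rng.binomial(total, prob)
        for h in range(len(hours)):
            rows.append(
                (
                    f"pen{p + 1}",
                    f"station{s + 1}",
                    int(hours[h]),
                    int(ifr[h]),
                    int(total[h] - ifr[h]),
                    float(temperature[h]),
                    float(humidity[h] / 10.0),
                    int(hod[h]),
                )
            )
    return pd.DataFrame(rows, columns=HOURLY_TABLE_COLUMNS)
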