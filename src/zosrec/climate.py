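"""Bottom-water temperature hindcast and monthly atmospheric summaries.

Historical bottom-water temperatures at a shallow estuarine site are rarely
recorded, but oceanic sea-surface temperature (SST) from nearby buoys is.
The hindcast regresses the *offset* between measured site bottom temperature
and oceanic SST on three meteorological drivers of local heating/cooling —
the air-sea temperature differential (degC), wind chill (W/m^2), and mean
wind speed of the previous three days (m/s) — in a fully saturated linear
model (all interactions through the three-way term).  The fitted offset is
then added back to SST to reconstruct a daily site series over any span the
predictors cover.

Daily temperatures are summarized per month as *threshold exceedance*: the
proportion of days whose mean fell within each of six bands (<0, <5, <10,
10-20 ["optimal"], >20, >25 degC).  The central three bands partition the
line; the outer bands are nested tails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "OffsetModel",
    "ExceedanceSpec",
    "ZONES",
    "wind_components",
    "wind_chill",
    "fit_offset_model",
    "hindcast_bottom_temperature",
    "smooth_series",
    "exceedance_summary",
    "monthly_atmos_summary",
    "read_offset_table",
]

# band label -> membership predicate on daily mean temperature
ZONES = {
    "0C": lambda t: t < 0.0,
    "5C": lambda t: t < 5.0,
    "10C": lambda t: t < 10.0,
    "optimal": lambda t: (t >= 10.0) & (t <= 20.0),
    "20C": lambda t: t > 20.0,
    "25C": lambda t: t > 25.0,
}


@dataclass(frozen=True)
class ExceedanceSpec:
    """The six temperature bands.  Boundary rule: ``optimal`` is closed
    [10, 20]; ``10C`` and ``20C`` are strict, so {10C, optimal, 20C}
    partition the line; 0C, 5C and 25C are strict nested tails."""

    zones: tuple[str, ...] = tuple(ZONES)


@dataclass
class OffsetModel:
    """Fully saturated OLS of (site bottom temp - oceanic SST).

    Predictors: ``airsea`` (air - SST, degC), ``chill`` (wind chill, W/m^2),
    ``wind3`` (mean wind speed of the previous 3 days, m/s), all two-way
    interactions and the three-way term, plus intercept: 8 coefficients.
    """

    params: pd.Series
    cov: pd.DataFrame
    adj_r2: float
    f_pvalue: float
    resid_var: float
    nobs: int

    TERMS = (
        "Intercept", "airsea", "chill", "wind3",
        "airsea:chill", "airsea:wind3", "chill:wind3", "airsea:chill:wind3",
    )

    def design(self, airsea, chill, wind3) -> pd.DataFrame:
        a = np.asarray(airsea, dtype=float)
        c = np.asarray(chill, dtype=float)
        w = np.asarray(wind3, dtype=float)
        return pd.DataFrame({
            "Intercept": np.ones_like(a), "airsea": a, "chill": c, "wind3": w,
            "airsea:chill": a * c, "airsea:wind3": a * w, "chill:wind3": c * w,
            "airsea:chill:wind3": a * c * w,
        })

    def predict_offset(self, airsea, chill, wind3) -> np.ndarray:
        X = self.design(airsea, chill, wind3)[list(self.TERMS)]
        return X.to_numpy() @ self.params[list(self.TERMS)].to_numpy()


def wind_components(directions) -> tuple[float, float]:
    """Mean eastness/northness of meteorological 'from' bearings (degrees).

    eastness = mean sin(theta), northness = mean cos(theta).  Calm/variable
    observations must be excluded upstream.  Empty input yields (nan, nan)
    with a warning.
    """
    d = np.asarray(directions, dtype=float)
    if d.size == 0:
        warnings.warn("no direction observations; eastness/northness missing")
        return float("nan"), float("nan")
    rad = np.deg2rad(d)
    return float(np.mean(np.sin(rad))), float(np.mean(np.cos(rad)))


def wind_chill(air_temp, speed):
    """Siple-Passel wind chill (W/m^2): 1.163 (10 sqrt(v) + 10.45 - v)(33 - Ta).

    The classic heat-loss index with v in m/s and Ta in degC; the 1.163
    factor converts kcal/(m^2 h) to W/m^2.  Zero when Ta = 33 degC.
    """
    v = np.asarray(speed, dtype=float)
    ta = np.asarray(air_temp, dtype=float)
    if np.any(v < 0):
        raise ValueError("wind speed must be non-negative")
    return 1.163 * (10.0 * np.sqrt(v) + 10.45 - v) * (33.0 - ta)


def smooth_series(x: pd.Series, window: int = 7) -> pd.Series:
    """Centered running mean; edges average over the available partial window."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    return x.rolling(window, center=True, min_periods=1).mean()


def _previous3_wind(wind: pd.Series) -> pd.Series:
    """Mean wind speed over the trailing 3-day window ending today; the first
    two days of a span are undefined (insufficient lookback)."""
    return wind.rolling(3, min_periods=3).mean()


def fit_offset_model(
    site_temp: pd.Series, sst: pd.Series, air: pd.Series, wind: pd.Series,
    presmoothed: bool = False,
) -> OffsetModel:
    """Fit the saturated offset model on overlapping days (>= 60 required).

    ``site_temp`` is smoothed with a 7-pt running mean first unless
    ``presmoothed``; wind chill is computed from daily air temperature and
    wind speed; ``wind3`` honors the 3-day lookback.
    """
    if not presmoothed:
        site_temp = smooth_series(site_temp)
    df = pd.DataFrame({
        "offset": site_temp - sst,
        "airsea": air - sst,
        "chill": wind_chill(air, wind),
        "wind3": _previous3_wind(wind),
    }).dropna()
    if len(df) < 60:
        raise ValueError(f"need >= 60 overlapping days, got {len(df)}")
    X = OffsetModel(pd.Series(dtype=float), pd.DataFrame(), 0, 0, 0, 0).design(
        df["airsea"], df["chill"], df["wind3"]
    )
    X.index = df.index
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            "rank-deficient saturated design; near-collinear columns among "
            f"{list(X.columns)}"
        )
    res = sm.OLS(df["offset"], X).fit()
    return OffsetModel(
        params=res.params, cov=res.cov_params(), adj_r2=float(res.rsquared_adj),
        f_pvalue=float(res.f_pvalue), resid_var=float(res.mse_resid), nobs=int(res.nobs),
    )


def hindcast_bottom_temperature(
    model: OffsetModel, sst: pd.Series, air: pd.Series, wind: pd.Series,
    span: pd.DatetimeIndex | None = None,
    validation: pd.Series | None = None,
    gap_limit: int = 7,
) -> tuple[pd.Series, dict]:
    """Daily site temperature = SST + predicted offset over ``span``.

    The first two days of the span are missing (3-day wind lookback).  Gaps
    longer than ``gap_limit`` days in the predictors are flagged in the
    report, never interpolated.  If ``validation`` observations are given,
    the report carries the fraction within 1 degC.
    """
    if span is None:
        span = sst.index
    sst, air, wind = (s.reindex(span) for s in (sst, air, wind))
    offset = model.predict_offset(air - sst, wind_chill(air, wind), _previous3_wind(wind))
    site = pd.Series(offset, index=span) + sst

    gaps = []
    isna = site.isna()
    if isna.any():
        grp = (isna != isna.shift()).cumsum()
        for _, block in site[isna].groupby(grp[isna]):
            if len(block) > gap_limit:
                gaps.append((block.index[0], block.index[-1], len(block)))
    report: dict = {"long_gaps": gaps}
    if validation is not None:
        both = pd.DataFrame({"obs": validation, "hind": site}).dropna()
        report["n_validation"] = len(both)
        report["frac_within_1C"] = (
            float(np.mean(np.abs(both["obs"] - both["hind"]) <= 1.0)) if len(both) else np.nan
        )
    return site, report


def exceedance_summary(temp: pd.Series, spec: ExceedanceSpec | None = None) -> pd.DataFrame:
    """Month x zone proportions of days within each temperature band.

    Months with partial data use the available-day denominator; wholly
    missing months are linearly interpolated (per zone) from the adjacent
    months; missing months at the series ends stay NaN (flagged).
    Returns a tidy frame (year, month, zone, proportion).
    """
    spec = spec or ExceedanceSpec()
    temp = temp.dropna()
    months = pd.period_range(temp.index.min(), temp.index.max(), freq="M")
    per = pd.PeriodIndex(temp.index, freq="M")
    flags = pd.DataFrame({z: ZONES[z](temp.to_numpy()) for z in spec.zones}, index=per)
    wide = flags.groupby(level=0).mean().astype(float).reindex(months)
    missing = wide.isna().all(axis=1)
    if missing.any():
        interp = wide.astype(float)
        interp.index = months.to_timestamp()
        interp = interp.interpolate(method="time", limit_area="inside")
        interp.index = months
        wide = interp
        still = wide.isna().all(axis=1)
        if still.any():
            warnings.warn(f"months {list(wide.index[still])} missing at series end; left NaN")
    out = wide.reset_index(names="period").melt(
        id_vars="period", var_name="zone", value_name="proportion")
    out["year"] = out["period"].map(lambda p: p.year)
    out["month"] = out["period"].map(lambda p: p.month)
    return out[["year", "month", "zone", "proportion"]]


def monthly_atmos_summary(winds: pd.DataFrame, rain: pd.Series | None = None) -> pd.DataFrame:
    """Monthly atmospheric table: rain (tenths of mm, monthly total),
    eastness, northness, mWindSpd (m/s).

    Calm/variable wind observations are excluded from both the speed mean
    and the direction components; an all-calm month yields missing values
    with a warning.
    """
    t = pd.PeriodIndex(pd.DatetimeIndex(winds["time"]), freq="M")
    rows = []
    for m in sorted(set(t)):
        sub = winds.loc[(t == m) & (~winds["calm"].astype(bool))]
        if len(sub) == 0:
            warnings.warn(f"month {m}: all observations calm/variable; wind summaries missing")
            east = north = spd = np.nan
        else:
            east, north = wind_components(sub["direction"].to_numpy())
            spd = float(sub["speed"].mean())
        rows.append({"year": m.year, "month": m.month,
                     "eastness": east, "northness": north, "mWindSpd": spd})
    out = pd.DataFrame(rows)
    if rain is not None:
        rm = rain.groupby(pd.PeriodIndex(rain.index, freq="M")).sum(min_count=1)
        out["rain"] = [rm.get(pd.Period(f"{r.year}-{r.month:02d}", freq="M"), np.nan)
                       for r in out.itertuples()]
    return out


def read_offset_table(path) -> pd.DataFrame:
    """Read the raw daily table used to fit the offset model (XLSX or CSV).

    Expected columns (case-insensitive match on prefixes): date, site
    bottom temperature, oceanic SST, air temperature, wind speed.
    """
    sp = str(path)
    df = pd.read_excel(sp) if sp.endswith((".xlsx", ".xls")) else pd.read_csv(sp)
    cols = {c.lower().strip(): c for c in df.columns}

    def find(*prefixes):
        for key, orig in cols.items():
            if any(key.startswith(p) for p in prefixes):
                return orig
        raise KeyError(f"no column matching {prefixes} in {list(df.columns)}")

    out = pd.DataFrame({
        "date": pd.to_datetime(df[find("date", "day")]),
        "site_temp": df[find("site", "bottom")],
        "sst": df[find("sst", "ocean", "sea")],
        "air": df[find("air")],
        "wind": df[find("wind")],
    }).set_index("date")
    return out
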