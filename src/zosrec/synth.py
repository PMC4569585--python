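"""Synthetic wind, climate, bathymetry and landscape histories.

The generator emulates the study conditions of a shallow, westerly-dominated
backbarrier lagoon: Weibull wind speeds with seasonal von Mises directions
(meteorological "from" convention, NW in winter swinging to SSW in summer),
sinusoidal air/sea temperatures with AR(1) noise, gamma-distributed monthly
rainfall, a shoaling bathymetric ramp inside a land rim, and an annual
landscape history in which patch recruitment follows a *known* log-linear
function of lagged climate.  Because the true coefficients, placement rules
(naked seeds within a few meters of reproductively mature seagrass, rafted
seeds spatially random over distant bare space) and radial patch growth
(13-46 cm/yr) are all recorded, every downstream stage — census, lag
features, model search, forecasting — can be tested for parameter recovery
without any external data.

All randomness flows through one explicitly passed ``numpy.random.Generator``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

from . import climate as _climate
from . import lagfeat as _lagfeat
from .census import MapSeries, SeagrassMap
from .waves import BathymetryGrid

__all__ = [
    "SynthConfig",
    "LandscapeHistory",
    "gen_wind_series",
    "gen_climate_series",
    "gen_bathymetry",
    "gen_monthly_environment",
    "draw_recruit_counts",
    "gen_landscape_history",
]

# seasonal 'from' direction regimes: winter NW, shoulder W, summer SSW
_DEFAULT_DIR = {1: 330, 2: 330, 3: 330, 4: 270, 5: 270, 6: 210,
                7: 210, 8: 210, 9: 210, 10: 270, 11: 330, 12: 330}
# mild seasonal modulation of the Weibull scale (stronger winter winds)
_SCALE_MOD = {1: 1.12, 2: 1.15, 3: 1.10, 4: 1.0, 5: 0.95, 6: 0.85,
              7: 0.80, 8: 0.80, 9: 0.90, 10: 1.0, 11: 1.05, 12: 1.12}


@dataclass
class SynthConfig:
    """Study conditions of the synthetic system."""

    years: int = 8  # census years
    seed: int = 0
    wind_weibull: tuple[float, float] = (2.0, 5.0)  # shape, scale m/s
    wind_dir_mixture: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {m: (mu, 1.0) for m, mu in _DEFAULT_DIR.items()}
    )  # month -> (von Mises mu deg-from, kappa)
    calm_fraction: float = 0.05
    temp_sinusoid: tuple[float, float, float, float] = (12.0, 10.0, 205.0, 1.0)
    # (mean degC, amplitude degC, phase day-of-year of maximum, AR1 sigma degC)
    sst_amp_ratio: float = 0.8  # SST amplitude relative to air amplitude
    yearly_anomaly_sigma: float = 1.0  # degC; warm/cold years shift both series
    rain_gamma: tuple[float, float] = (2.0, 400.0)  # shape, scale (tenths of mm / month)
    rain_days: int = 10  # wet days per month over which the total is spread
    grid: tuple[int, int, float, tuple[float, float]] = (60, 40, 100.0, (0.25, 4.0))
    # (nx, ny, cell m, (shallow depth, deep depth) south->north ramp)
    truth_beta: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "nsd": {"Intercept": 5.0, "rain_p2yJDN": 0.002, "eastness_pFeb": 9.0},
        "rsd": {"Intercept": 11.0, "mWindSpd_pMay": -1.6},
    })
    overdispersion_sigma: float = 0.25  # lognormal environmental noise on the intensity
    nsd_kernel_scale: float = 2.0  # m, exponential offset of naked seeds
    patch_growth: float = 30.0  # cm/yr radial spread
    site: tuple[float, float] = (250.0, 225.0)  # site extent m (x, y)
    patch_radius: tuple[float, float] = (0.35, 0.8)  # m, first-observation size

    def __post_init__(self) -> None:
        if self.years < 4:
            raise ValueError("need at least 4 census years")
        if not (13.0 <= self.patch_growth <= 46.0):
            raise ValueError("patch_growth must lie in [13, 46] cm/yr")
        if self.grid[2] <= 0:
            raise ValueError("grid cell must be positive")
        for v in (*self.wind_weibull, *self.rain_gamma, self.nsd_kernel_scale):
            if v <= 0:
                raise ValueError("all scale parameters must be positive")


def _check_span(span: pd.DatetimeIndex | tuple) -> tuple[pd.Timestamp, pd.Timestamp]:
    if isinstance(span, (tuple, list)):
        start, end = pd.Timestamp(span[0]), pd.Timestamp(span[1])
    else:
        start, end = span[0], span[-1]
    if end < start + pd.DateOffset(months=36):
        raise ValueError(
            "span must cover at least 36 months: the lag engine reaches back "
            "three years from the first census")
    return start, end


def gen_wind_series(cfg: SynthConfig, span, rng: np.random.Generator) -> pd.DataFrame:
    """Hourly wind record: time, speed (m/s), direction (deg 'from'), calm flag."""
    start, end = _check_span(span)
    t = pd.date_range(start, end, freq="h")
    month = t.month.to_numpy()
    shape, scale = cfg.wind_weibull
    speed = scale * np.array([_SCALE_MOD[m] for m in month]) * rng.weibull(shape, len(t))
    mus = np.array([cfg.wind_dir_mixture[m][0] for m in month])
    kappas = np.array([cfg.wind_dir_mixture[m][1] for m in month])
    direction = np.rad2deg(rng.vonmises(np.deg2rad(mus), kappas)) % 360.0
    calm = rng.random(len(t)) < cfg.calm_fraction
    return pd.DataFrame({"time": t, "speed": speed, "direction": direction, "calm": calm})


def gen_climate_series(
    cfg: SynthConfig, span, rng: np.random.Generator, missing_fraction: float = 0.0,
) -> pd.DataFrame:
    """Daily air temperature, SST and rainfall (tenths of mm).

    SST follows the air sinusoid with damped amplitude, a ~2-week phase lag
    and smaller AR(1) noise (the ocean integrates).  Monthly rainfall totals
    are gamma draws spread over a fixed number of wet days.
    """
    start, end = _check_span(span)
    t = pd.date_range(start, end, freq="D")
    mean, amp, phase, sigma = cfg.temp_sinusoid
    doy = t.dayofyear.to_numpy()

    def ar1(n, s, rho=0.8):
        from scipy.signal import lfilter

        e = rng.normal(0, s, n)
        return lfilter([np.sqrt(1 - rho**2)], [1, -rho], e)

    # interannual anomalies (anomalously warm/cold years) shared by air and sea
    anom = {y: rng.normal(0, cfg.yearly_anomaly_sigma) for y in np.unique(t.year)}
    yearly = np.array([anom[y] for y in t.year])
    air = mean + amp * np.cos(2 * np.pi * (doy - phase) / 365.25) + yearly + ar1(len(t), sigma)
    sst = (mean + cfg.sst_amp_ratio * amp
           * np.cos(2 * np.pi * (doy - phase - 14) / 365.25)
           + 0.8 * yearly + ar1(len(t), sigma * 0.5))

    rain = np.zeros(len(t))
    per = pd.PeriodIndex(t, freq="M")
    for m in per.unique():
        idx = np.nonzero(per == m)[0]
        total = rng.gamma(cfg.rain_gamma[0], cfg.rain_gamma[1])
        wet = rng.choice(idx, size=min(cfg.rain_days, len(idx)), replace=False)
        rain[wet] = total / len(wet)

    df = pd.DataFrame({"air": air, "sst": sst, "rain": rain}, index=t)
    if missing_fraction > 0:
        drop = rng.random(len(df)) < missing_fraction
        df.loc[drop, ["air", "sst"]] = np.nan
    return df


def gen_bathymetry(cfg: SynthConfig) -> BathymetryGrid:
    """Shoaling basin: linear south-to-north depth ramp inside a land rim."""
    nx, ny, cell, (d0, d1) = cfg.grid
    depth = np.tile(np.linspace(d0, d1, ny)[:, None], (1, nx))
    depth[0, :] = np.nan
    depth[-1, :] = np.nan
    depth[:, 0] = np.nan
    depth[:, -1] = np.nan
    return BathymetryGrid(depth, cell)


def gen_monthly_environment(
    cfg: SynthConfig, start_year: int, end_year: int, rng: np.random.Generator,
) -> pd.DataFrame:
    """Wide monthly predictor table (PeriodIndex x variables).

    Temperature-band exceedances come from a full daily synthetic series
    through :func:`zosrec.climate.exceedance_summary`; rainfall, wind speed
    and direction components are drawn at the monthly level from the same
    seasonal regimes the hourly generator uses (a fast path for many-replicate
    studies; the hourly route is exercised separately).
    """
    span = (f"{start_year}-01-01", f"{end_year}-12-31")
    daily = gen_climate_series(cfg, span, rng)
    exc = _climate.exceedance_summary(daily["sst"])
    wide = exc.pivot_table(index=["year", "month"], columns="zone", values="proportion")
    wide.index = pd.PeriodIndex(
        [pd.Period(f"{y}-{m:02d}", freq="M") for y, m in wide.index], freq="M")

    months = wide.index
    mnum = months.month.to_numpy()
    shape, scale = cfg.wind_weibull
    from scipy.special import gamma as gammafn

    wmean = scale * np.array([_SCALE_MOD[m] for m in mnum]) * gammafn(1 + 1 / shape)
    wide["mWindSpd"] = wmean + rng.normal(0, 0.35, len(months))
    kappas = np.array([cfg.wind_dir_mixture[m][1] for m in mnum])
    mus = np.deg2rad([cfg.wind_dir_mixture[m][0] for m in mnum])
    # mean resultant length of a von Mises sample: I1(k)/I0(k)
    from scipy.special import i0, i1

    rbar = i1(kappas) / i0(kappas)
    wide["eastness"] = np.clip(rbar * np.sin(mus) + rng.normal(0, 0.06, len(months)), -1, 1)
    wide["northness"] = np.clip(rbar * np.cos(mus) + rng.normal(0, 0.06, len(months)), -1, 1)
    wide["rain"] = rng.gamma(cfg.rain_gamma[0], cfg.rain_gamma[1], len(months))
    return wide.sort_index()


def draw_recruit_counts(
    beta: dict[str, float], features: pd.DataFrame, rng: np.random.Generator,
    overdispersion_sigma: float = 0.0,
) -> pd.Series:
    """Poisson counts with log-mean = Intercept + beta . features per year.

    ``overdispersion_sigma`` adds lognormal environmental noise to the
    yearly intensity (counts are Poisson conditional on that intensity) —
    the usual representation of unmodeled year-to-year stochasticity in
    recruitment data.
    """
    eta = np.full(len(features), beta.get("Intercept", 0.0))
    for name, b in beta.items():
        if name == "Intercept":
            continue
        if name not in features.columns:
            raise KeyError(f"truth predictor {name!r} missing from feature table")
        eta = eta + b * features[name].to_numpy(dtype=float)
    if overdispersion_sigma > 0:
        eta = eta + rng.normal(0.0, overdispersion_sigma, len(eta))
    if np.nanmax(eta) > 20:
        raise ValueError(f"recruitment log-mean exceeds 20 (max {np.nanmax(eta):.2f}); "
                         "intensity overflow")
    return pd.Series(rng.poisson(np.exp(eta)), index=features.index)


@dataclass
class LandscapeHistory:
    """Dated synthetic maps plus the generating truth."""

    maps: MapSeries
    truth: pd.DataFrame  # per census year: nsd, rsd + generating predictor values
    site: Polygon

    def __post_init__(self) -> None:
        if (self.truth[["nsd", "rsd"]] < 0).any().any():
            raise ValueError("truth counts must be non-negative")


def _place_disc(center, radius) -> Polygon:
    return Point(center).buffer(radius, quad_segs=12)


def gen_landscape_history(
    cfg: SynthConfig, predictors: pd.DataFrame, rng: np.random.Generator,
    max_attempts: int = 2000,
) -> LandscapeHistory:
    """Annual landscape history with known recruitment truth.

    ``predictors`` is a census-year x lag-feature table covering every
    census year and every predictor named in ``cfg.truth_beta``.  Each year:
    existing patches dilate radially by ``patch_growth``; NSD recruits are
    discs whose boundary lies within 6 m (exponential kernel) of seagrass
    mapped two springs prior; RSD recruits fall uniformly over bare space
    beyond that band.  Placement keeps new discs disjoint from all prior
    coverage so a census of the generated maps recovers the truth exactly.
    """
    years = list(predictors.index)
    nsd_counts = draw_recruit_counts(cfg.truth_beta["nsd"], predictors, rng,
                                     cfg.overdispersion_sigma)
    rsd_counts = draw_recruit_counts(cfg.truth_beta["rsd"], predictors, rng,
                                     cfg.overdispersion_sigma)

    sx, sy = cfg.site
    site = box(0, 0, sx, sy)
    window = box(20.0 + 1.0, 0, sx - 20.0 - 1.0, sy)  # inside the east-west buffer
    growth = cfg.patch_growth / 100.0
    r_lo, r_hi = cfg.patch_radius

    # three pre-census springs of founder coverage so two-springs-prior
    # references are never empty
    y0 = years[0] - 3
    founders = []
    for _ in range(6):
        c = (rng.uniform(40, sx - 40), rng.uniform(20, sy - 20))
        founders.append(_place_disc(c, rng.uniform(1.0, 2.0)))
    coverage = unary_union(founders)
    spring_maps: dict[int, SeagrassMap] = {}
    for y in (y0, y0 + 1, y0 + 2):
        spring_maps[y] = SeagrassMap(pd.Timestamp(year=y, month=4, day=15), coverage)
        coverage = coverage.buffer(growth, quad_segs=8)

    truth_rows = []
    for y in years:
        ref = spring_maps[y - 2].geometry
        new_discs = []

        def try_place(kind: str) -> Polygon | None:
            for _ in range(max_attempts):
                r0 = rng.uniform(r_lo, r_hi)
                if kind == "nsd":
                    u = rng.uniform(0, ref.boundary.length)
                    anchor = ref.boundary.interpolate(u)
                    d_b = min(0.8 + rng.exponential(cfg.nsd_kernel_scale), 5.0)
                    theta = rng.uniform(0, 2 * np.pi)
                    c = (anchor.x + (d_b + r0) * np.cos(theta),
                         anchor.y + (d_b + r0) * np.sin(theta))
                    cand = _place_disc(c, r0)
                    if cand.distance(ref) > 5.0 or cand.distance(ref) <= 0.05:
                        continue
                else:
                    c = (rng.uniform(window.bounds[0], window.bounds[2]),
                         rng.uniform(window.bounds[1], window.bounds[3]))
                    cand = _place_disc(c, r0)
                    if cand.distance(ref) <= 6.5:
                        continue
                if not cand.within(window):
                    continue
                blocked = coverage.union(unary_union(new_discs)) if new_discs else coverage
                if cand.distance(blocked) <= 0.2:
                    continue
                return cand
            return None

        n_nsd = n_rsd = 0
        for _ in range(int(nsd_counts[y])):
            disc = try_place("nsd")
            if disc is not None:
                new_discs.append(disc)
                n_nsd += 1
        for _ in range(int(rsd_counts[y])):
            disc = try_place("rsd")
            if disc is not None:
                new_discs.append(disc)
                n_rsd += 1

        this_spring = unary_union([coverage, *new_discs]) if new_discs else coverage
        spring_maps[y] = SeagrassMap(pd.Timestamp(year=y, month=4, day=15), this_spring)
        coverage = this_spring.buffer(growth, quad_segs=8)
        row = {"year": y, "nsd": n_nsd, "rsd": n_rsd,
               "nsd_drawn": int(nsd_counts[y]), "rsd_drawn": int(rsd_counts[y])}
        for name in set().union(*(set(b) for b in cfg.truth_beta.values())) - {"Intercept"}:
            row[name] = predictors.loc[y, name]
        truth_rows.append(row)

    series = MapSeries([spring_maps[y] for y in sorted(spring_maps)])
    truth = pd.DataFrame(truth_rows).set_index("year")
    return LandscapeHistory(maps=series, truth=truth, site=site)


def write_truth_json(history: LandscapeHistory, path) -> None:
    with open(path, "w") as fh:
        json.dump(json.loads(history.truth.reset_index().to_json(orient="records")), fh)
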