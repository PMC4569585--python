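"""Recruit census from dated seagrass polygon maps.

Sexual recruits are isolated patches that first appear in a spring map and
cannot be explained by prior coverage: every location mapped as seagrass up
to the preceding December is masked out, and new patches within an internal
east-west edge buffer are discarded (they could stem from unmapped lateral
seed sources).  Surviving patches are classified by their minimum distance
to seagrass mapped *two springs prior* — the stand that produced the seeds —
as naked-seed dispersal (NSD, <= 6 m) or rafted-seed dispersal (RSD, > 6 m).

Raw counts are standardized to rates: each class's count is divided by the
bare space (m^2) available in its distance class at the time of seed
dehiscence, and NSD — being locally produced — is further divided by the
source seagrass area (m^2) inside a 14-m east-west-buffered site at seed
production.  All geometry is planar (meters, single projected frame).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, box, mapping, shape
from shapely.ops import unary_union

__all__ = [
    "CensusConfig",
    "SeagrassMap",
    "MapSeries",
    "RecruitRecord",
    "RecruitmentSeries",
    "build_presence_mask",
    "detect_recruits",
    "classify_recruits",
    "standardize_rates",
    "run_census",
    "read_geojson_maps",
    "write_geojson_maps",
]


@dataclass(frozen=True)
class CensusConfig:
    """Distances (m) and calendar rules of the census."""

    nsd_threshold: float = 6.0
    ew_buffer: float = 20.0
    source_buffer: float = 14.0
    spring_months: tuple[int, ...] = (3, 4, 5)
    area_warn: float = 4.0  # m^2; larger first-observation patches are suspect

    def __post_init__(self) -> None:
        if min(self.nsd_threshold, self.ew_buffer, self.source_buffer) <= 0:
            raise ValueError("all distances must be positive")
        if self.nsd_threshold >= self.ew_buffer:
            raise ValueError("nsd_threshold must be smaller than ew_buffer")


@dataclass
class SeagrassMap:
    """One dated presence map: a union of seagrass polygons."""

    date: pd.Timestamp
    geometry: Polygon | MultiPolygon

    def __post_init__(self) -> None:
        self.date = pd.Timestamp(self.date)
        if not self.geometry.is_valid:
            raise ValueError(f"map dated {self.date.date()} has invalid geometry")


@dataclass
class MapSeries:
    """Strictly date-increasing sequence of presence maps."""

    maps: list[SeagrassMap]

    def __post_init__(self) -> None:
        dates = [m.date for m in self.maps]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("maps must be strictly increasing in date")

    def __iter__(self):
        return iter(self.maps)

    def __len__(self) -> int:
        return len(self.maps)

    def through(self, cutoff) -> list[SeagrassMap]:
        cutoff = pd.Timestamp(cutoff)
        return [m for m in self.maps if m.date <= cutoff]

    def spring_map(self, year: int, cfg: CensusConfig) -> SeagrassMap | None:
        """First available map in the Mar-May window of a census year."""
        cand = [m for m in self.maps
                if m.date.year == year and m.date.month in cfg.spring_months]
        return cand[0] if cand else None

    def at_or_before(self, cutoff) -> SeagrassMap | None:
        prior = self.through(cutoff)
        return prior[-1] if prior else None


@dataclass
class RecruitRecord:
    year: int
    patch_id: int
    centroid: tuple[float, float]
    area: float
    distance: float  # min boundary-to-boundary distance to two-springs-prior seagrass
    klass: str  # "NSD" | "RSD"

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("patch area must be positive")
        if self.klass not in ("NSD", "RSD"):
            raise ValueError(f"class must be NSD or RSD, got {self.klass!r}")


def build_presence_mask(maps: MapSeries, cutoff) -> Polygon | MultiPolygon:
    """Union of all seagrass polygons dated at or before ``cutoff``.
    Idempotent; an empty history yields an empty mask."""
    prior = maps.through(cutoff)
    if not prior:
        return Polygon()
    return unary_union([m.geometry for m in prior])


def _ew_shrunk(site_boundary: Polygon, buffer: float) -> Polygon:
    """Site boundary shrunk by ``buffer`` on the east and west edges only."""
    minx, miny, maxx, maxy = site_boundary.bounds
    if maxx - minx <= 2 * buffer:
        raise ValueError("east-west buffer consumes the whole site")
    return site_boundary.intersection(box(minx + buffer, miny, maxx - buffer, maxy))


def _components(geom) -> list[Polygon]:
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    return [g for g in geom.geoms if isinstance(g, Polygon) and not g.is_empty]


def detect_recruits(
    spring_map: SeagrassMap, mask, site_boundary: Polygon, cfg: CensusConfig | None = None,
) -> list[Polygon]:
    """Connected components of spring seagrass that (a) do not intersect the
    presence mask and (b) lie wholly inside the east-west-buffered site."""
    cfg = cfg or CensusConfig()
    if spring_map.date.month not in cfg.spring_months:
        raise ValueError(
            f"spring map must be dated Mar-May, got {spring_map.date.date()}")
    window = _ew_shrunk(site_boundary, cfg.ew_buffer)
    patches = []
    for comp in _components(spring_map.geometry):
        if comp.intersects(mask):
            continue  # pre-existing or regrowing coverage
        if not comp.within(window):
            continue  # clipped by the lateral-transport buffer
        patches.append(comp)
    return patches


def classify_recruits(
    patches: list[Polygon], reference_map, cfg: CensusConfig | None = None, year: int = 0,
) -> list[RecruitRecord]:
    """Classify patches by minimum Euclidean distance to the two-springs-prior
    seagrass: <= nsd_threshold -> NSD (6.0 m exactly is NSD), else RSD.
    An empty reference makes every patch RSD (no local source anywhere)."""
    cfg = cfg or CensusConfig()
    ref = reference_map.geometry if isinstance(reference_map, SeagrassMap) else reference_map
    if ref is None:
        raise ValueError("reference map missing and no fallback provided")
    records = []
    for k, patch in enumerate(patches):
        if ref.is_empty:
            dist = np.inf
        else:
            dist = patch.distance(ref)
        if patch.area >= cfg.area_warn:
            warnings.warn(
                f"recruit {k} ({year}): first-observation area {patch.area:.1f} m^2 "
                f">= {cfg.area_warn} m^2; may not be a new recruit")
        records.append(RecruitRecord(
            year=year, patch_id=k, centroid=(patch.centroid.x, patch.centroid.y),
            area=patch.area,
            distance=float(dist),
            klass="NSD" if dist <= cfg.nsd_threshold else "RSD",
        ))
    return records


@dataclass
class RecruitmentSeries:
    """Per census year: raw counts and standardized NSD/RSD rates."""

    table: pd.DataFrame  # index census year; columns nsd, rsd, nsd_rate, rsd_rate, ...

    def __post_init__(self) -> None:
        t = self.table
        if (t[["nsd", "rsd"]] < 0).any().any():
            raise ValueError("counts must be non-negative")


def standardize_rates(
    records_by_year: dict[int, list[RecruitRecord]],
    maps: MapSeries,
    site_boundary: Polygon,
    cfg: CensusConfig | None = None,
) -> RecruitmentSeries:
    """Standardize raw NSD/RSD counts into rates.

    For census year Y: the two-springs-prior reference R (spring map of
    Y-2, falling back to Y-3's distributions when unavailable) splits the
    east-west-buffered site into the NSD band (within 6 m of R) and the RSD
    remainder.  Bare space is each band's area minus seagrass mapped at the
    dehiscence epoch (latest map on or before July 1 of Y-1, same fallback).
    nsd_rate = n_NSD / (bare6 * source_area) with source_area the seagrass
    coverage inside the 14-m east-west-buffered site at seed production
    (the dehiscence-epoch map); rsd_rate = n_RSD / bare_beyond.
    """
    cfg = cfg or CensusConfig()
    window = _ew_shrunk(site_boundary, cfg.ew_buffer)
    source_window = _ew_shrunk(site_boundary, cfg.source_buffer)
    rows = []
    for year in sorted(records_by_year):
        recs = records_by_year[year]
        n_nsd = sum(r.klass == "NSD" for r in recs)
        n_rsd = sum(r.klass == "RSD" for r in recs)

        ref, fallback_ref = None, False
        for back in (2, 3):
            m = maps.spring_map(year - back, cfg)
            if m is not None:
                ref, fallback_ref = m.geometry, back != 2
                break
        if ref is None:
            raise ValueError(f"no reference map within reach of census year {year}")

        deh, fallback_deh = None, False
        for back in (1, 2):
            m = maps.at_or_before(pd.Timestamp(year=year - back, month=7, day=1))
            if m is not None:
                deh, fallback_deh = m.geometry, back != 1
                break
        if deh is None:
            raise ValueError(f"no dehiscence-epoch map for census year {year}")

        band6 = ref.buffer(cfg.nsd_threshold).intersection(window)
        beyond = window.difference(band6)
        bare6 = band6.difference(deh).area
        bare_beyond = beyond.difference(deh).area
        source_area = deh.intersection(source_window).area

        if n_nsd > 0 and (bare6 <= 0 or source_area <= 0):
            raise ValueError(
                f"census {year}: {n_nsd} NSD recruits but no bare space/source area")
        if n_rsd > 0 and bare_beyond <= 0:
            raise ValueError(f"census {year}: {n_rsd} RSD recruits but no bare space")

        rows.append({
            "year": year, "nsd": n_nsd, "rsd": n_rsd, "total": n_nsd + n_rsd,
            "bare6_m2": bare6, "bare_beyond_m2": bare_beyond, "source_m2": source_area,
            "nsd_rate": n_nsd / (bare6 * source_area) if n_nsd else 0.0,
            "rsd_rate": n_rsd / bare_beyond if n_rsd else 0.0,
            "fallback_reference": fallback_ref, "fallback_dehiscence": fallback_deh,
        })
    return RecruitmentSeries(pd.DataFrame(rows).set_index("year"))


def run_census(
    maps: MapSeries, site_boundary: Polygon, years: list[int],
    cfg: CensusConfig | None = None,
) -> tuple[RecruitmentSeries, dict[int, list[RecruitRecord]]]:
    """Full census: detect, classify and standardize for each requested year.
    Years with no spring map are skipped with a warning."""
    cfg = cfg or CensusConfig()
    records: dict[int, list[RecruitRecord]] = {}
    for year in years:
        spring = maps.spring_map(year, cfg)
        if spring is None:
            warnings.warn(f"census year {year}: no spring map; skipped")
            continue
        mask = build_presence_mask(maps, pd.Timestamp(year=year - 1, month=12, day=31))
        patches = detect_recruits(spring, mask, site_boundary, cfg)
        ref = None
        for back in (2, 3):
            m = maps.spring_map(year - back, cfg)
            if m is not None:
                ref = m
                break
        if ref is None:
            ref = SeagrassMap(pd.Timestamp(year=year - 2, month=4, day=1), Polygon())
        records[year] = classify_recruits(patches, ref, cfg, year=year)
    return standardize_rates(records, maps, site_boundary, cfg), records


# ---------------------------------------------------------------------------
# GeoJSON I/O (FeatureCollection with a `date` property per feature)
# ---------------------------------------------------------------------------

def read_geojson_maps(path) -> MapSeries:
    with open(path) as fh:
        fc = json.load(fh)
    by_date: dict[str, list] = {}
    for feat in fc["features"]:
        by_date.setdefault(feat["properties"]["date"], []).append(shape(feat["geometry"]))
    maps = [SeagrassMap(pd.Timestamp(d), unary_union(geoms))
            for d, geoms in sorted(by_date.items())]
    return MapSeries(maps)


def write_geojson_maps(series: MapSeries, path) -> None:
    feats = []
    for m in series:
        feats.append({
            "type": "Feature",
            "properties": {"date": str(m.date.date())},
            "geometry": mapping(m.geometry),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def recruits_to_csv(records_by_year: dict[int, list[RecruitRecord]], path) -> None:
    rows = [{
        "year": r.year, "id": r.patch_id, "x": r.centroid[0], "y": r.centroid[1],
        "area_m2": r.area, "dist_m": r.distance, "class": r.klass,
    } for recs in records_by_year.values() for r in recs]
    pd.DataFrame(rows).to_csv(path, index=False)
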