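"""Census-anchored time-lagged predictor windows and their naming grammar.

Annual recruit censuses happen in spring; the environmental conditions that
plausibly forced them span the preceding three years of the recruit life
history (floral induction through patch development).  Each predictor is
therefore an arithmetic mean of one monthly environmental variable over a
window of whole calendar months counted *backward from the May census*:
offset 1 = April of the census year, offset 12 = May of the previous year,
offset 36 = June three years back.

Four window families are enumerated per variable:

1. the 12 single-month offsets (``rain_pFeb`` = February of the census year,
   ``rain_pMay`` = May of the previous year);
2. expanding windows anchored at offset 1, out to one full previous year
   (``eastness_pAprToNov`` = November of the previous year through April);
3. the full 24- and 36-month means (``eastness_p36mo``);
4. every contiguous 3-month window reaching back 3 years, written with a
   year index (calendar years between the census and the window's oldest
   month) and backward month initials: ``10C_p1yNOS`` = September-November
   of the previous year, ``rain_p2yJDN`` = the second previous November
   through the following January.

Labels are bijective with the canonical window representation: the initial
triples of three contiguous backward months are all distinct (JDN, FJD,
MFJ, AMF, MAM, JMA, JJM, AJJ, SAJ, OSA, NOS, DNO), and the year index pins
the repeat.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LagSpec",
    "enumerate_lag_specs",
    "summarize",
    "parse_label",
    "format_label",
    "build_feature_table",
    "CENSUS_MONTH",
    "MAX_OFFSET",
]

CENSUS_MONTH = 5  # May: spring census anchor
MAX_OFFSET = 36  # whole months; the third previous August boundary

_MON3 = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
         "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]
_INITIAL = [m[0] for m in _MON3]

# backward triple of initials, keyed by the most recent month (1-based)
_TRIPLES = {m: "".join(_INITIAL[(m - 1 - i) % 12] for i in range(3)) for m in range(1, 13)}
_TRIPLE_TO_END = {v: k for k, v in _TRIPLES.items()}


def _month_at(offset: int) -> int:
    """Calendar month number at a backward offset from the census anchor."""
    return (CENSUS_MONTH - offset - 1) % 12 + 1


@dataclass(frozen=True)
class LagSpec:
    """One lagged predictor: a variable, a backward window, the mean."""

    variable: str
    start_offset: int  # oldest month, inclusive
    end_offset: int  # most recent month, inclusive

    def __post_init__(self) -> None:
        if not (1 <= self.end_offset <= self.start_offset <= MAX_OFFSET):
            raise ValueError(
                f"window must satisfy 1 <= end <= start <= {MAX_OFFSET}, "
                f"got ({self.start_offset}, {self.end_offset})"
            )

    @property
    def window(self) -> tuple[int, int]:
        return (self.start_offset, self.end_offset)

    @property
    def label(self) -> str:
        return format_label(self)

    def months(self, census_year: int) -> pd.PeriodIndex:
        anchor = pd.Period(f"{census_year}-{CENSUS_MONTH:02d}", freq="M")
        return pd.PeriodIndex(
            [anchor - o for o in range(self.start_offset, self.end_offset - 1, -1)], freq="M"
        )


def _canonical_windows() -> list[tuple[int, int]]:
    seen: list[tuple[int, int]] = []
    for o in range(1, 13):  # single months
        seen.append((o, o))
    for k in range(2, 13):  # expanding from offset 1 ((1,1) is the single)
        seen.append((k, 1))
    seen += [(24, 1), (36, 1)]
    for s in range(4, 37):  # 3-month windows ((3,1) is expanding k=3)
        seen.append((s, s - 2))
    return seen


def enumerate_lag_specs(variable: str) -> list[LagSpec]:
    """All canonical lagged windows (58 after duplicate removal) for one variable."""
    return [LagSpec(variable, s, e) for s, e in _canonical_windows()]


def format_label(spec: LagSpec) -> str:
    """Canonical grammar label ``<var>_p...`` of an enumerated window."""
    s, e = spec.window
    if s == e:
        if s > 12:
            raise ValueError(f"single-month window {spec.window} beyond offset 12 has no label")
        suffix = _MON3[_month_at(s) - 1]
    elif e == 1 and 2 <= s <= 12:
        suffix = f"{_MON3[_month_at(1) - 1]}To{_MON3[_month_at(s) - 1]}"
    elif (s, e) in {(24, 1), (36, 1)}:
        suffix = f"{s}mo"
    elif s - e == 2:
        k = _year_offset_years(s)
        suffix = f"{k}y{_TRIPLES[_month_at(e)]}"
    else:
        raise ValueError(f"window {spec.window} is not in the canonical label grammar")
    return f"{spec.variable}_p{suffix}"


def _year_offset_years(start_offset: int) -> int:
    """Calendar years between the census year and the window's oldest month."""
    p0 = pd.Period(f"2000-{CENSUS_MONTH:02d}", freq="M")
    return 2000 - (p0 - start_offset).year


_LABEL_RE = re.compile(
    r"^(?P<var>.+)_p(?:"
    r"(?P<nmo>\d+)mo|"
    r"(?P<ky>\d+)y(?P<triple>[A-Z]{3})|"
    r"(?P<endmon>[A-Z][a-z]{2})To(?P<startmon>[A-Z][a-z]{2})|"
    r"(?P<mon>[A-Z][a-z]{2})"
    r")$"
)

_GRAMMAR = (
    "<var>_p(<Mon> | <Mon>To<Mon> | <N>mo | <k>y<backward month initials>), "
    "e.g. rain_pFeb, d16000_pAprToNov, eastness_p36mo, 10C_p1yNOS"
)


def _offset_of_month(mon: int, at_least: int = 1) -> int:
    for o in range(at_least, at_least + 12):
        if _month_at(o) == mon:
            return o
    raise ValueError(f"no offset >= {at_least} for month {mon}")


def parse_label(label: str) -> LagSpec:
    """Parse a grammar label into its canonical window."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"label {label!r} does not match the lag grammar: {_GRAMMAR}")
    var = m["var"]
    if m["nmo"]:
        n = int(m["nmo"])
        if n not in (24, 36):
            raise ValueError(f"only 24- and 36-month means are defined, got {n} in {label!r}")
        return LagSpec(var, n, 1)
    if m["ky"]:
        triple = m["triple"]
        if triple not in _TRIPLE_TO_END:
            raise ValueError(
                f"{triple!r} is not a backward triple of contiguous month initials "
                f"({sorted(_TRIPLE_TO_END)}); label {label!r}"
            )
        end_mon = _TRIPLE_TO_END[triple]
        k = int(m["ky"])
        start_mon = (end_mon - 3) % 12 + 1
        for s in (_offset_of_month(start_mon), _offset_of_month(start_mon) + 12,
                  _offset_of_month(start_mon) + 24):
            if s <= MAX_OFFSET and _year_offset_years(s) == k:
                return LagSpec(var, s, s - 2)
        raise ValueError(f"year index {k} in {label!r} places the window outside 36 months")
    if m["endmon"]:
        end = _offset_of_month(_MON3.index(m["endmon"]) + 1)
        start = _offset_of_month(_MON3.index(m["startmon"]) + 1, at_least=end)
        return LagSpec(var, start, end)
    return LagSpec(var, (o := _offset_of_month(_MON3.index(m["mon"]) + 1)), o)


def summarize(spec: LagSpec, monthly_table: pd.DataFrame, census_year: int) -> float:
    """Mean of the variable over the window's months; NaN if any month is missing.

    ``monthly_table`` is wide: a monthly ``PeriodIndex`` and one column per
    variable (the tidy CSV layout converts via ``pivot``).
    """
    months = spec.months(census_year)
    if spec.variable not in monthly_table.columns:
        raise KeyError(f"variable {spec.variable!r} not in monthly table")
    col = monthly_table[spec.variable]
    vals = col.reindex(months)
    if vals.isna().any():
        return float("nan")
    return float(vals.mean())


def build_feature_table(
    monthly_table: pd.DataFrame,
    census_years: list[int],
    variables: list[str] | None = None,
    specs: list[LagSpec] | None = None,
) -> pd.DataFrame:
    """Census-year x lagged-predictor matrix with grammar labels as columns.

    Columns that are constant across years are dropped (they cannot enter
    screening); windows with missing months yield NaN cells.
    """
    if specs is None:
        variables = variables if variables is not None else list(monthly_table.columns)
        specs = [sp for v in variables for sp in enumerate_lag_specs(v)]

    # windowed means via prefix sums over a gap-free monthly grid
    full = pd.period_range(monthly_table.index.min(), monthly_table.index.max(), freq="M")
    grid = monthly_table.reindex(full)
    vals = grid.to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    csum = np.vstack([np.zeros(vals.shape[1]), np.nancumsum(np.where(ok, vals, 0.0), axis=0)])
    ccnt = np.vstack([np.zeros(vals.shape[1]), np.cumsum(ok, axis=0)])
    col_of = {v: j for j, v in enumerate(grid.columns)}
    pos_of = {p: i for i, p in enumerate(full)}

    def window_mean(spec: LagSpec, year: int) -> float:
        anchor = pd.Period(f"{year}-{CENSUS_MONTH:02d}", freq="M")
        lo, hi = anchor - spec.start_offset, anchor - spec.end_offset
        if lo not in pos_of or hi not in pos_of:
            return float("nan")
        a, b = pos_of[lo], pos_of[hi] + 1
        j = col_of[spec.variable]
        length = b - a
        if ccnt[b, j] - ccnt[a, j] < length:
            return float("nan")  # any missing month voids the window
        return float((csum[b, j] - csum[a, j]) / length)

    data = {sp.label: [window_mean(sp, y) for y in census_years] for sp in specs}
    tbl = pd.DataFrame(data, index=pd.Index(census_years, name="census_year"))
    nunique = tbl.nunique(dropna=True)
    return tbl.loc[:, nunique > 1]


def tidy_to_wide(tidy: pd.DataFrame) -> pd.DataFrame:
    """Convert the tidy monthly CSV layout (variable, year, month, value)
    into the wide PeriodIndex table ``summarize`` consumes."""
    tidy = tidy.copy()
    tidy["period"] = pd.PeriodIndex(
        [pd.Period(f"{y}-{m:02d}", freq="M") for y, m in zip(tidy["year"], tidy["month"])],
        freq="M",
    )
    return tidy.pivot(index="period", columns="variable", values="value").sort_index()
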