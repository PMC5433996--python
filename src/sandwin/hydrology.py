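"""Daily discharge records: containers, readers/writers, climatology, peak extraction.

All discharges are cubic metres per second (m³/s) internally; unit conversion
(cfs → m³/s) happens only at I/O time.  Gaps in a record are represented by
absent dates — never by zeros — and every value carries a provenance flag
(``observed`` / ``estimated`` / ``merged``) so that record-extension output can
be distinguished from gauge observations downstream.
"""

from __future__ import annotations

import datetime as dt
import io
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CFS_TO_CMS",
    "DailyFlowSeries",
    "AnnualHydrograph",
    "FlowDataError",
    "CoverageWarning",
    "read_daily_flows",
    "mean_annual_hydrograph",
    "habitat_forming_discharge",
    "fill_gaps",
]

#: Exact conversion factor, 1 cubic foot = 0.3048**3 m³.
CFS_TO_CMS = 0.028316846592

OBSERVED = "observed"
ESTIMATED = "estimated"
MERGED = "merged"
_PROVENANCE = frozenset({OBSERVED, ESTIMATED, MERGED})

#: Value codes NWIS daily-values tables use for missing/unusable observations.
_RDB_MISSING = frozenset({"", "ice", "eqp", "rat", "dis", "mnt", "***", "bkw", "ssn"})


class FlowDataError(ValueError):
    """Malformed or insufficient daily-flow data."""


class CoverageWarning(UserWarning):
    """A computation proceeded on a window with incomplete data coverage."""


@dataclass
class DailyFlowSeries:
    """A dated mean-daily-discharge record for one gage or reach.

    Parameters
    ----------
    station_id
        Gage or reach identifier (free text; USGS site numbers fit here).
    data
        ``pandas.Series`` of discharge in m³/s with a strictly increasing,
        duplicate-free ``DatetimeIndex`` at daily (midnight) resolution.
        Missing days are simply absent from the index.
    provenance
        Optional per-record flag aligned with ``data``; defaults to
        ``observed`` everywhere.
    """

    station_id: str
    data: pd.Series
    provenance: pd.Series | None = None

    def __post_init__(self) -> None:
        s = pd.Series(self.data, dtype=float)
        if not isinstance(s.index, pd.DatetimeIndex):
            s.index = pd.DatetimeIndex(s.index)
        s.index = s.index.normalize()
        if s.index.has_duplicates:
            dup = s.index[s.index.duplicated()][0]
            raise FlowDataError(f"duplicate date in series: {dup.date()}")
        if not s.index.is_monotonic_increasing:
            s = s.sort_index()
        if s.isna().any():
            raise FlowDataError("NaN discharge in series; represent gaps as absent dates")
        if (s.values < 0).any():
            bad = s.index[s.values < 0][0]
            raise FlowDataError(f"negative discharge at {bad.date()}")
        self.data = s
        if self.provenance is None:
            prov = pd.Series(OBSERVED, index=s.index, dtype=object)
        else:
            prov = pd.Series(self.provenance, dtype=object).reindex(s.index)
            prov = prov.fillna(OBSERVED)
            unknown = set(prov.unique()) - _PROVENANCE
            if unknown:
                raise FlowDataError(f"unknown provenance flags: {sorted(unknown)}")
        self.provenance = prov

    # -- basic views ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def window(self, start, end) -> "DailyFlowSeries":
        """Sub-series over ``[start, end]`` inclusive."""
        sub = self.data.loc[pd.Timestamp(start): pd.Timestamp(end)]
        return DailyFlowSeries(self.station_id, sub, self.provenance.loc[sub.index])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.data.index.strftime("%Y-%m-%d"),
                "discharge_cms": self.data.to_numpy(),
                "provenance": self.provenance.to_numpy(),
            }
        )

    # -- I/O -----------------------------------------------------------------

    def write_csv(self, path) -> None:
        """Write as CSV (date, discharge_cms, provenance); full float precision."""
        self.to_frame().to_csv(path, index=False)

    def write_rdb(self, path) -> None:
        """Write in the USGS daily-values RDB dialect (values in cfs)."""
        lines = [
            "# Synthetic daily-values table, NWIS RDB dialect",
            f"# station {self.station_id}",
            "agency_cd\tsite_no\tdatetime\t00060_00003\t00060_00003_cd",
            "5s\t15s\t20d\t14n\t10s",
        ]
        for ts, q, flag in zip(self.data.index, self.data.to_numpy(), self.provenance):
            code = "A" if flag == OBSERVED else "A:e"
            lines.append(
                f"USGS\t{self.station_id}\t{ts.strftime('%Y-%m-%d')}\t{float(q / CFS_TO_CMS)!r}\t{code}"
            )
        text = "\n".join(lines) + "\n"
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w") as fh:
                fh.write(text)


@dataclass
class AnnualHydrograph:
    """Day-of-year climatology (mean annual hydrograph), Feb 29 folded into day 59."""

    mean_discharge: np.ndarray  # length 365, indexed by day-of-year 1..365
    n_years: int

    def __post_init__(self) -> None:
        self.mean_discharge = np.asarray(self.mean_discharge, dtype=float)
        if self.mean_discharge.shape != (365,):
            raise FlowDataError("climatology must have exactly 365 day-of-year values")

    @property
    def doy(self) -> np.ndarray:
        return np.arange(1, 366)


# ---------------------------------------------------------------------------
# readers


def _open_text(source):
    if hasattr(source, "read"):
        return source, False
    return open(source, "r"), True


def read_daily_flows(
    source,
    dialect: str = "csv",
    *,
    unit: str | None = None,
    station_id: str | None = None,
) -> DailyFlowSeries:
    """Read a daily mean-discharge record from CSV or USGS RDB.

    ``unit`` is ``"cfs"`` or ``"cms"``; defaults to cfs for RDB (the NWIS
    convention for parameter 00060) and cms for CSV.  Missing-value codes map
    to gaps.  Duplicate dates with conflicting values are a hard error.
    """
    if dialect == "rdb":
        return _read_rdb(source, unit=unit or "cfs", station_id=station_id)
    if dialect == "csv":
        return _read_csv(source, unit=unit or "cms", station_id=station_id)
    raise FlowDataError(f"unknown dialect {dialect!r}; expected 'rdb' or 'csv'")


def _finish_series(dates, values, prov, station_id):
    df = pd.DataFrame({"date": dates, "q": values, "prov": prov})
    df = df.dropna(subset=["q"])
    # exact duplicates collapse; conflicting duplicates are an error
    for date, grp in df.groupby("date"):
        if len(grp) > 1 and grp["q"].nunique() > 1:
            raise FlowDataError(f"conflicting duplicate values on {pd.Timestamp(date).date()}")
    df = df.drop_duplicates(subset="date").sort_values("date")
    data = pd.Series(df["q"].to_numpy(), index=pd.DatetimeIndex(df["date"]))
    provenance = pd.Series(df["prov"].to_numpy(), index=data.index, dtype=object)
    return DailyFlowSeries(station_id or "unknown", data, provenance)


def _read_csv(source, *, unit, station_id):
    fh, close = _open_text(source)
    try:
        df = pd.read_csv(fh)
    finally:
        if close:
            fh.close()
    cols = {c.lower(): c for c in df.columns}
    date_col = cols.get("date") or cols.get("datetime")
    if date_col is None:
        raise FlowDataError("CSV needs a 'date' column")
    qcol = None
    for name in ("discharge_cms", "discharge_cfs", "discharge", "flow", "q"):
        if name in cols:
            qcol = cols[name]
            break
    if qcol is None:
        raise FlowDataError("CSV needs a discharge column (e.g. 'discharge_cms')")
    if qcol.lower() == "discharge_cfs":
        unit = "cfs"
    factor = CFS_TO_CMS if unit == "cfs" else 1.0
    values = pd.to_numeric(df[qcol], errors="coerce") * factor
    prov = df[cols["provenance"]] if "provenance" in cols else OBSERVED
    return _finish_series(pd.to_datetime(df[date_col]), values, prov, station_id)


_DISCHARGE_COL = re.compile(r"(?:\d+_)?00060(?:_\d+)?$")
_FORMAT_CELL = re.compile(r"^\d+[sdn]$")


def _read_rdb(source, *, unit, station_id):
    fh, close = _open_text(source)
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()
    header = None
    qidx = didx = None
    sid = station_id
    dates, values, prov = [], [], []
    factor = CFS_TO_CMS if unit == "cfs" else 1.0
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            try:
                didx = header.index("datetime")
            except ValueError as exc:
                raise FlowDataError(f"line {lineno}: RDB header lacks 'datetime'") from exc
            matches = [i for i, c in enumerate(header) if _DISCHARGE_COL.match(c)]
            if not matches:
                raise FlowDataError(f"line {lineno}: no 00060 discharge column in RDB header")
            qidx = matches[0]
            continue
        if all(_FORMAT_CELL.match(p) for p in parts if p):
            continue  # the 5s/15s/20d format-specifier row
        if len(parts) <= max(didx, qidx):
            raise FlowDataError(f"line {lineno}: too few columns")
        raw = parts[qidx].strip()
        if raw.lower() in _RDB_MISSING:
            continue
        try:
            q = float(raw) * factor
        except ValueError as exc:
            raise FlowDataError(f"line {lineno}: unparseable discharge {raw!r}") from exc
        try:
            date = pd.Timestamp(parts[didx])
        except ValueError as exc:
            raise FlowDataError(f"line {lineno}: unparseable date {parts[didx]!r}") from exc
        if sid is None and len(parts) > 1:
            sid = parts[1]
        dates.append(date)
        values.append(q)
        prov.append(OBSERVED)
    if header is None:
        raise FlowDataError("no header row found in RDB input")
    return _finish_series(pd.DatetimeIndex(dates), np.array(values, float), prov, sid)


# ---------------------------------------------------------------------------
# climatology and peaks


def folded_doy(index: pd.DatetimeIndex) -> np.ndarray:
    """Day-of-year 1..365 with 29 Feb folded into day 59 (28 Feb)."""
    doy = index.dayofyear.to_numpy()
    leap = index.is_leap_year
    return np.where(leap & (doy > 59), doy - 1, doy)


def mean_annual_hydrograph(
    series: DailyFlowSeries, period: tuple[int, int] | None = None
) -> AnnualHydrograph:
    """Mean discharge for each day-of-year across all years in ``period``.

    Requires at least one complete calendar year so every day-of-year has a
    value; Feb 29 observations are folded into day 59 rather than dropped.
    """
    data = series.data
    if period is not None:
        y0, y1 = period
        data = data[(data.index.year >= y0) & (data.index.year <= y1)]
    if data.empty:
        raise FlowDataError("no data within the requested period")
    per_year = data.groupby(data.index.year).size()
    years = data.index.year.to_numpy()
    expected = np.where(pd.DatetimeIndex([f"{y}-12-31" for y in per_year.index]).is_leap_year, 366, 365)
    if not (per_year.to_numpy() >= expected).any():
        raise FlowDataError("need at least one complete calendar year for a climatology")
    doy = folded_doy(data.index)
    means = pd.Series(data.to_numpy()).groupby(doy).mean()
    out = np.full(365, np.nan)
    out[means.index.to_numpy() - 1] = means.to_numpy()
    return AnnualHydrograph(out, n_years=int(len(np.unique(years))))


def habitat_forming_discharge(
    series: DailyFlowSeries,
    analysis_year: int,
    *,
    coverage_threshold: float = 0.5,
    include_end: bool = True,
) -> float:
    """Maximum mean daily discharge from 1 Jan of the prior year through 1 Jul.

    This 1.5-year maximum is taken to be the discharge that controlled sandbar
    height going into the ``analysis_year`` nesting season (sandbars persist
    through two seasons).  The window is closed on both ends by default;
    ``include_end=False`` excludes 1 July itself.
    """
    start = pd.Timestamp(analysis_year - 1, 1, 1)
    end = pd.Timestamp(analysis_year, 7, 1)
    sub = series.data.loc[start:end]
    if not include_end:
        sub = sub.loc[sub.index < end]
    if sub.empty:
        raise FlowDataError(
            f"no flow data in the habitat-forming window for {analysis_year}"
        )
    n_expected = (end - start).days + (1 if include_end else 0)
    coverage = len(sub) / n_expected
    if coverage < coverage_threshold:
        warnings.warn(
            f"habitat-forming window for {analysis_year} covers only "
            f"{100 * coverage:.0f}% of days",
            CoverageWarning,
            stacklevel=2,
        )
    return float(sub.max())


def fill_gaps(series: DailyFlowSeries, max_gap: int) -> DailyFlowSeries:
    """Linearly interpolate interior gaps of length ≤ ``max_gap`` days.

    Interpolated values are flagged ``estimated``; longer gaps are untouched.
    """
    if max_gap < 0:
        raise FlowDataError("max_gap must be ≥ 0")
    if max_gap == 0 or len(series) == 0:
        return series
    full = pd.date_range(series.dates[0], series.dates[-1], freq="D")
    data = series.data.reindex(full)
    prov = series.provenance.reindex(full)
    missing = data.isna().to_numpy()
    if not missing.any():
        return series
    # locate runs of missing days
    padded = np.concatenate(([0], missing.astype(int), [0]))
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    interp = data.interpolate(method="time", limit_area="inside")
    for s, e in zip(starts, ends):
        if e - s <= max_gap:
            data.iloc[s:e] = interp.iloc[s:e]
            prov.iloc[s:e] = ESTIMATED
    keep = data.notna()
    return DailyFlowSeries(series.station_id, data[keep], prov[keep])
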