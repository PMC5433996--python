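"""Nesting phenology metrics and fledge-ratio arithmetic.

Nest-record summaries (counts, first/median/last initiation, hatch and fledge
dates, the 5th–95th percentile initiation window) pool records across years
on a day-of-year basis.  The demography side converts a frequency of years
with any reproductive potential into the average fledge ratio a subpopulation
would need in those years to meet an annual maintenance target
(1.13 fledglings/pair for piping plover, 0.70 for least tern).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .sandbar import SpeciesProfile, SuccessSummary

__all__ = [
    "NestRecord",
    "DemographyTargets",
    "initiation_window",
    "season_length",
    "success_period",
    "required_fledge_ratio",
    "p_success_from_summary",
    "phenology_summary",
    "round_ratio",
    "read_nest_csv",
    "write_nest_csv",
]


@dataclass(frozen=True)
class NestRecord:
    """One monitored nest: a scrape with ≥ 1 egg and its subsequent fates."""

    species: str
    initiation_date: dt.date
    hatch_date: dt.date | None = None
    fledge_date: dt.date | None = None
    habitat_type: str = "on-channel"  # on-channel | off-channel

    def __post_init__(self):
        if self.hatch_date is not None and self.hatch_date < self.initiation_date:
            raise ValueError("hatch before initiation")
        if self.fledge_date is not None:
            ref = self.hatch_date or self.initiation_date
            if self.fledge_date < ref:
                raise ValueError("fledge before hatch/initiation")


@dataclass(frozen=True)
class DemographyTargets:
    """Annual fledge ratios needed for stable-to-growing subpopulations."""

    plover_target: float = 1.13  # fledglings per pair per year
    tern_target: float = 0.70

    def __post_init__(self):
        if self.plover_target <= 0 or self.tern_target <= 0:
            raise ValueError("targets must be positive")


def _doy(dates) -> np.ndarray:
    idx = pd.DatetimeIndex(pd.to_datetime(list(dates)))
    return idx.dayofyear.to_numpy()


def _date_from_doy(doy: float, year: int) -> dt.date:
    return (dt.date(year, 1, 1) + dt.timedelta(days=round(doy) - 1))


def initiation_window(dates, lower: float = 0.05, upper: float = 0.95) -> tuple[dt.date, dt.date]:
    """Empirical (lower, upper) quantile window of initiation day-of-year.

    Trims the disproportionate influence of a few very early or late nests on
    the apparent season.  Quantiles use linear interpolation between order
    statistics; fractional days round to the nearest calendar day in the year
    of the earliest record.
    """
    dates = list(dates)
    if len(dates) < 2:
        raise ValueError("need ≥ 2 initiation dates")
    if not (0 <= lower < upper <= 1):
        raise ValueError("need 0 ≤ lower < upper ≤ 1")
    doy = _doy(dates)
    lo, hi = np.quantile(doy, [lower, upper], method="linear")
    ref_year = min(pd.Timestamp(d).year for d in dates)
    return _date_from_doy(float(lo), ref_year), _date_from_doy(float(hi), ref_year)


def season_length(first: dt.date, last: dt.date) -> int:
    """Inclusive day count from first to last (same day → 1)."""
    if last < first:
        raise ValueError("last date precedes first date")
    return (pd.Timestamp(last) - pd.Timestamp(first)).days + 1


def success_period(profile: SpeciesProfile) -> int:
    """Laying + incubation + brooding days for a species profile."""
    return profile.success_period


def round_ratio(value: float, places: int = 2) -> float:
    """Half-up decimal rounding, matching how reported ratios are printed."""
    if math.isinf(value):
        return value
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def required_fledge_ratio(target: float, p_success: float) -> float:
    """Fledge ratio needed in successful years to average ``target`` annually.

    With reproductive potential in only a fraction ``p_success`` of years, the
    long-run annual average equals ``ratio × p_success``; hence
    ``ratio = target / p_success``.  ``p_success = 0`` is reported as
    ``inf`` — maintenance is unattainable, not an error.
    """
    if target <= 0:
        raise ValueError("target must be positive")
    if not (0 <= p_success <= 1):
        raise ValueError("p_success must lie in [0, 1]")
    if p_success == 0:
        return float("inf")
    return target / p_success


def p_success_from_summary(summary: SuccessSummary) -> float:
    """Fraction of years with any success window: 1 − pct_no_window/100."""
    return 1.0 - summary.pct_no_window / 100.0


def phenology_summary(nests, profile: SpeciesProfile) -> dict:
    """Table of phenology metrics for one species' nest records.

    Hatch/fledge metrics use only records where those dates exist; the counts
    of contributing records are reported alongside.  Dates are summarised on
    pooled day-of-year and reported in the earliest record's year.
    """
    nests = [n for n in nests if n.species == profile.name]
    if not nests:
        raise ValueError(f"no nest records for species {profile.name!r}")
    init = [n.initiation_date for n in nests]
    ref_year = min(d.year for d in init)
    out = {"species": profile.name, "nest_count": len(nests)}

    def _stats(dates, prefix):
        doy = _doy(dates)
        out[f"first_{prefix}"] = _date_from_doy(int(doy.min()), ref_year)
        out[f"median_{prefix}"] = _date_from_doy(float(np.median(doy)), ref_year)
        out[f"last_{prefix}"] = _date_from_doy(int(doy.max()), ref_year)

    _stats(init, "initiation")
    hatch = [n.hatch_date for n in nests if n.hatch_date is not None]
    fledge = [n.fledge_date for n in nests if n.fledge_date is not None]
    out["hatch_count"] = len(hatch)
    out["fledge_count"] = len(fledge)
    if hatch:
        _stats(hatch, "hatch")
    if fledge:
        _stats(fledge, "fledge")
    if len(init) >= 2:
        lo, hi = initiation_window(init)
        out["initiation_window"] = (lo, hi)
        out["initiation_window_days"] = season_length(lo, hi)
    out["season_length_days"] = profile.season_length
    out["success_period_days"] = profile.success_period
    return out


# -- nest record I/O ----------------------------------------------------------

_COLUMNS = ["species", "init_date", "hatch_date", "fledge_date", "habitat_type"]


def write_nest_csv(nests, path) -> None:
    rows = [
        {
            "species": n.species,
            "init_date": n.initiation_date.isoformat(),
            "hatch_date": n.hatch_date.isoformat() if n.hatch_date else "",
            "fledge_date": n.fledge_date.isoformat() if n.fledge_date else "",
            "habitat_type": n.habitat_type,
        }
        for n in nests
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_nest_csv(path) -> list[NestRecord]:
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"nest CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            NestRecord(
                species=row["species"],
                initiation_date=dt.date.fromisoformat(row["init_date"]),
                hatch_date=dt.date.fromisoformat(row["hatch_date"]) if row["hatch_date"] else None,
                fledge_date=dt.date.fromisoformat(row["fledge_date"]) if row["fledge_date"] else None,
                habitat_type=row["habitat_type"] or "on-channel",
            )
        )
    return records
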