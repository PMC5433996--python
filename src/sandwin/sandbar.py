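"""Emergent-sandbar habitat model: per-year nesting success windows.

The model chain for each analysis year and species:

1. ``DISCH_HAB`` — maximum mean daily discharge from 1 Jan of the prior year
   through 1 Jul of the analysis year (the habitat-forming discharge assumed
   to control sandbar height).
2. ``STAGE_HAB`` — stage of that discharge from the reach rating curve.
3. ``STAGE_BAR`` — sandbar stage: ``STAGE_HAB`` minus the bar-height-below-
   peak-stage parameter (medians 0.46 m for the central Platte reach, 0.61 m
   for the lower Platte).
4. Daily stage over the species nesting season from daily discharge.
5. A day is *emergent* iff daily stage is strictly below ``STAGE_BAR``
   (a tie counts as inundated — conservative).
6. Maximum contiguous run of emergent days within the season.
7. Success window = max(0, run − success period), where the success period is
   laying + incubation + brooding (64 d piping plover, 45 d least tern).

Summaries across years report the median window, the percent of years with no
window, and the percent of years in which the whole season was emergent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hydraulics import RatingCurve, RatingCurveError
from .hydrology import CoverageWarning, DailyFlowSeries, habitat_forming_discharge

__all__ = [
    "SpeciesProfile",
    "PLOVER",
    "TERN",
    "ReachConfig",
    "HabitatYearResult",
    "SuccessSummary",
    "sandbar_stage",
    "daily_emergence",
    "max_contiguous",
    "success_window",
    "run_reach",
    "summarize",
    "results_to_frame",
]


@dataclass(frozen=True)
class SpeciesProfile:
    """Nesting phenology constants defining a species' season and success period.

    Seasons are month-day bounds applied to every year (neither species nests
    across the new year, so season length is constant across leap years).
    """

    name: str
    season_start: tuple[int, int]  # (month, day), inclusive
    season_end: tuple[int, int]  # (month, day), inclusive
    laying_days: int
    incubation_days: int
    brooding_days: int

    def __post_init__(self):
        if self.season_start >= self.season_end:
            raise ValueError("season_start must precede season_end")
        for d in (self.laying_days, self.incubation_days, self.brooding_days):
            if d < 0:
                raise ValueError("phenology durations must be ≥ 0")

    @property
    def success_period(self) -> int:
        """Days needed to initiate, incubate, hatch and fledge without loss."""
        return self.laying_days + self.incubation_days + self.brooding_days

    def season_dates(self, year: int) -> pd.DatetimeIndex:
        start = pd.Timestamp(year, *self.season_start)
        end = pd.Timestamp(year, *self.season_end)
        return pd.date_range(start, end, freq="D")

    @property
    def season_length(self) -> int:
        """Inclusive season length in days (constant across years)."""
        return len(self.season_dates(2001))


#: Piping plover: season 1 May – 26 Aug (118 d), success period 8+28+28 = 64 d.
PLOVER = SpeciesProfile("piping_plover", (5, 1), (8, 26), 8, 28, 28)
#: Least tern: season 28 May – 30 Aug (95 d), success period 3+21+21 = 45 d.
TERN = SpeciesProfile("least_tern", (5, 28), (8, 30), 3, 21, 21)


@dataclass
class ReachConfig:
    """Everything the habitat model needs for one river reach."""

    name: str
    rating_curve: RatingCurve
    bar_height_below_peak: float  # m below peak (habitat-forming) stage
    flow_series: DailyFlowSeries
    analysis_years: range | tuple[int, int]

    def __post_init__(self):
        if self.bar_height_below_peak < 0:
            raise ValueError("bar height below peak stage must be ≥ 0")
        if isinstance(self.analysis_years, tuple):
            y0, y1 = self.analysis_years
            self.analysis_years = range(y0, y1 + 1)


@dataclass
class HabitatYearResult:
    """Model outputs for one reach, species and analysis year."""

    year: int
    species: str
    disch_hab: float  # habitat-forming discharge, m³/s
    stage_hab: float  # its stage, m
    stage_bar: float  # sandbar stage, m
    inundating_discharge: float  # discharge whose stage equals stage_bar (NaN if below table)
    max_contiguous_emergent: int
    success_window: int
    season_long: bool  # every season day emergent
    coverage_ok: bool


@dataclass
class SuccessSummary:
    """Cross-year summary of success windows (one reach × species)."""

    median_window: float
    pct_no_window: float
    pct_season_long: float
    n_years: int


def sandbar_stage(stage_hab: float, bar_height: float) -> float:
    """Sandbar stage: peak (habitat-forming) stage minus bar height below peak."""
    if bar_height < 0:
        raise ValueError("bar height must be ≥ 0")
    return stage_hab - bar_height


def daily_emergence(
    flows: DailyFlowSeries,
    curve: RatingCurve,
    stage_bar: float,
    season: pd.DatetimeIndex,
    *,
    return_present: bool = False,
):
    """Boolean emergence sequence over ``season``.

    A day is emergent iff its stage is strictly below ``stage_bar``; a stage
    exactly at the sandbar stage counts as inundated.  Missing season days are
    conservatively scored not-emergent (and reported via ``return_present``).
    Zero-flow days take the stage of the lowest tabulated discharge, per the
    below-table clamping policy.
    """
    if len(flows) == 0 or season[-1] < flows.dates[0] or season[0] > flows.dates[-1]:
        raise ValueError("season lies outside the flow record")
    q = flows.data.reindex(season)
    present = q.notna().to_numpy()
    stage = np.full(len(season), np.inf)
    qv = q.to_numpy()
    ok = present.copy()
    low = present & (qv <= 0)
    if low.any():
        stage[low] = curve.stage[0]
        ok &= ~low
    if ok.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # clamping handled above; peaks may extrapolate
            stage[ok] = curve.stage_at(qv[ok])
    emergent = stage < stage_bar
    if return_present:
        return emergent, present
    return emergent


def max_contiguous(emergent) -> int:
    """Length of the longest run of True in a boolean sequence."""
    a = np.asarray(emergent, dtype=bool)
    if a.size == 0:
        return 0
    padded = np.concatenate(([False], a, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    if starts.size == 0:
        return 0
    return int((ends - starts).max())


def success_window(max_contiguous_days: int, success_period: int) -> int:
    """Days a nest could start and still fledge: max(0, run − success period)."""
    if max_contiguous_days < 0 or success_period < 0:
        raise ValueError("day counts must be ≥ 0")
    return max(0, max_contiguous_days - success_period)


def run_reach(
    reach: ReachConfig,
    species: SpeciesProfile,
    *,
    min_coverage: float = 0.95,
    coverage_threshold: float = 0.5,
) -> list[HabitatYearResult]:
    """Run the full seven-step model chain for every analysis year.

    Years whose season coverage falls below ``min_coverage`` are flagged
    (``coverage_ok=False``) and excluded from :func:`summarize`.
    """
    curve = reach.rating_curve
    results: list[HabitatYearResult] = []
    for year in reach.analysis_years:
        disch_hab = habitat_forming_discharge(
            reach.flow_series, year, coverage_threshold=coverage_threshold
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stage_hab = curve.stage_at(disch_hab)
        stage_bar = sandbar_stage(stage_hab, reach.bar_height_below_peak)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                inundating = curve.discharge_at(stage_bar)
        except RatingCurveError:
            inundating = float("nan")
        season = species.season_dates(year)
        emergent, present = daily_emergence(
            reach.flow_series, curve, stage_bar, season, return_present=True
        )
        coverage = float(present.mean())
        if coverage < min_coverage:
            warnings.warn(
                f"{reach.name} {year}: season coverage {100 * coverage:.0f}% "
                f"< {100 * min_coverage:.0f}%; year excluded from summaries",
                CoverageWarning,
                stacklevel=2,
            )
        run = max_contiguous(emergent)
        results.append(
            HabitatYearResult(
                year=year,
                species=species.name,
                disch_hab=disch_hab,
                stage_hab=float(stage_hab),
                stage_bar=float(stage_bar),
                inundating_discharge=float(inundating),
                max_contiguous_emergent=run,
                success_window=success_window(run, species.success_period),
                season_long=bool(emergent.all()),
                coverage_ok=coverage >= min_coverage,
            )
        )
    return results


def summarize(results: list[HabitatYearResult]) -> SuccessSummary:
    """Median window, % no-window years and % season-long years over included years.

    Median uses the mean-of-central-pair rule for even year counts.
    """
    included = [r for r in results if r.coverage_ok]
    if not included:
        raise ValueError("no years with adequate coverage to summarize")
    windows = np.array([r.success_window for r in included], dtype=float)
    season_long = np.array([r.season_long for r in included])
    return SuccessSummary(
        median_window=float(np.median(windows)),
        pct_no_window=float(100.0 * np.mean(windows == 0)),
        pct_season_long=float(100.0 * np.mean(season_long)),
        n_years=len(included),
    )


def results_to_frame(results: list[HabitatYearResult]) -> pd.DataFrame:
    """Tabulate per-year results (one row per year) for CSV output."""
    return pd.DataFrame(
        {
            "year": [r.year for r in results],
            "species": [r.species for r in results],
            "disch_hab_cms": [r.disch_hab for r in results],
            "stage_hab_m": [r.stage_hab for r in results],
            "stage_bar_m": [r.stage_bar for r in results],
            "inundating_discharge_cms": [r.inundating_discharge for r in results],
            "max_contiguous_emergent_days": [r.max_contiguous_emergent for r in results],
            "success_window_days": [r.success_window for r in results],
            "season_long": [r.season_long for r in results],
            "coverage_ok": [r.coverage_ok for r in results],
        }
    )
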