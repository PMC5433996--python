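"""Synthetic hydrology, rating curves and nest records for testing the pipeline.

The generators reproduce the statistical structure the analysis assumes about
Platte-like rivers, so every downstream stage is testable without gage
downloads:

* daily hydrographs with a bimodal annual shape — an early (Feb–Mar) snowmelt
  rise and a larger mid-June rise — plus multiplicative lognormal AR(1) noise
  and lognormal inter-annual scaling of pulse amplitudes (which naturally
  produces the multi-year sequences of declining peaks that favour nesting);
* monotone power-law rating curves ``stage = c · Q^e`` tabulated at
  geometrically spaced discharges;
* nest records with initiation dates normal around a species' median
  initiation day-of-year, truncated to the nesting season.

Everything is seeded and bit-reproducible: the same seed always yields the
same output.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hydraulics import RatingCurve
from .hydrology import DailyFlowSeries
from .phenology import NestRecord
from .sandbar import SpeciesProfile

__all__ = [
    "HydrographParams",
    "generate_daily_hydrograph",
    "generate_rating_curve",
    "generate_nest_records",
]


@dataclass(frozen=True)
class HydrographParams:
    """Parameters of the bimodal synthetic annual hydrograph.

    Defaults describe a mid-sized sand-bed river: ~30 m³/s baseflow, a modest
    early-March rise (day 65) and a dominant mid-June rise (day 166), daily
    lognormal noise of σ = 0.3 with strong day-to-day persistence, and 40%
    inter-annual variability in pulse amplitude.
    """

    baseflow: float = 30.0  # m³/s
    early_rise_peak: float = 100.0  # m³/s above baseflow at pulse centre
    early_rise_doy: float = 65.0
    late_rise_peak: float = 200.0
    late_rise_doy: float = 166.0  # mid-June
    rise_width_days: float = 15.0  # Gaussian σ of each pulse
    noise_sigma: float = 0.3  # lognormal σ of multiplicative daily noise
    noise_rho: float = 0.85  # AR(1) coefficient of the log-noise
    interannual_cv: float = 0.4  # CV of the yearly lognormal amplitude factor

    def __post_init__(self):
        if self.baseflow <= 0:
            raise ValueError("baseflow must be positive")
        if self.early_rise_peak < 0 or self.late_rise_peak < 0:
            raise ValueError("pulse peaks must be ≥ 0")
        for doy in (self.early_rise_doy, self.late_rise_doy):
            if not 1 <= doy <= 366:
                raise ValueError("pulse centres must be day-of-year 1..366")
        if self.rise_width_days <= 0:
            raise ValueError("rise width must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be ≥ 0")
        if not 0 <= self.noise_rho < 1:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        if self.interannual_cv < 0:
            raise ValueError("inter-annual CV must be ≥ 0")


def _pulse_shape(doy: np.ndarray, year_len: np.ndarray, center: float, width: float) -> np.ndarray:
    """Gaussian pulse in day-of-year, wrapped at the year boundary."""
    out = np.zeros_like(doy, dtype=float)
    for k in (-1.0, 0.0, 1.0):
        out += np.exp(-0.5 * ((doy - center + k * year_len) / width) ** 2)
    return out


def generate_daily_hydrograph(
    params: HydrographParams, start_year: int, n_years: int, seed: int
) -> DailyFlowSeries:
    """Generate ``n_years`` calendar years of synthetic mean daily discharge.

    With ``noise_sigma = 0`` and ``interannual_cv = 0`` the series is exactly
    baseflow plus the two Gaussian pulses (the deterministic skeleton used by
    tests); otherwise each year's pulse amplitudes share a lognormal factor
    with the stated CV and days carry multiplicative lognormal AR(1) noise
    with stationary log-variance ``noise_sigma²`` (median 1).
    """
    if n_years < 1:
        raise ValueError("n_years must be ≥ 1")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(
        dt.date(start_year, 1, 1), dt.date(start_year + n_years - 1, 12, 31), freq="D"
    )
    doy = dates.dayofyear.to_numpy().astype(float)
    year = dates.year.to_numpy()
    year_len = np.where(dates.is_leap_year, 366.0, 365.0)

    # Inter-annual amplitude factor (one per calendar year, both pulses).
    if params.interannual_cv > 0:
        sig2 = np.log1p(params.interannual_cv**2)
        amp_by_year = rng.lognormal(mean=-sig2 / 2.0, sigma=np.sqrt(sig2), size=n_years)
    else:
        amp_by_year = np.ones(n_years)
    amp = amp_by_year[year - start_year]

    early = params.early_rise_peak * _pulse_shape(
        doy, year_len, params.early_rise_doy, params.rise_width_days
    )
    late = params.late_rise_peak * _pulse_shape(
        doy, year_len, params.late_rise_doy, params.rise_width_days
    )
    q = params.baseflow + amp * (early + late)

    if params.noise_sigma > 0:
        z = rng.standard_normal(len(dates))
        e = np.empty(len(dates))
        e[0] = z[0] * params.noise_sigma
        scale = params.noise_sigma * np.sqrt(1.0 - params.noise_rho**2)
        for i in range(1, len(dates)):
            e[i] = params.noise_rho * e[i - 1] + scale * z[i]
        q = q * np.exp(e)

    return DailyFlowSeries("synthetic", pd.Series(q, index=dates))


def generate_rating_curve(
    coefficient: float,
    exponent: float,
    q_min: float,
    q_max: float,
    n_points: int = 40,
) -> RatingCurve:
    """Tabulate the power-law rating ``stage = coefficient · Q^exponent``.

    Discharges are geometrically spaced from ``q_min`` to ``q_max`` so the
    log-discharge interpolation grid is uniform.
    """
    if coefficient <= 0:
        raise ValueError("coefficient must be positive")
    if not 0 < exponent < 1.5:
        raise ValueError("exponent must lie in (0, 1.5)")
    if q_min <= 0:
        raise ValueError("q_min must be positive")
    if q_min >= q_max:
        raise ValueError("q_min must be less than q_max")
    if n_points < 2:
        raise ValueError("need at least 2 tabulated points")
    q = np.geomspace(q_min, q_max, n_points)
    return RatingCurve(q, coefficient * q**exponent, source="synthetic")


def generate_nest_records(
    species: SpeciesProfile,
    n: int,
    median_doy: float,
    sd_days: float,
    seed: int,
    *,
    years: tuple[int, ...] = (2001,),
    off_channel_fraction: float = 0.0,
) -> list[NestRecord]:
    """Draw ``n`` nest records with initiation ~ Normal(median_doy, sd_days).

    Initiation dates are truncated (clipped) to the species season; hatch and
    fledge dates follow deterministically from the profile's laying,
    incubation and brooding durations.  ``sd_days = 0`` collapses every nest
    onto the median date.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if sd_days < 0:
        raise ValueError("sd_days must be ≥ 0")
    rng = np.random.default_rng(seed)
    year_arr = rng.choice(np.asarray(years), size=n)
    doy = median_doy + sd_days * rng.standard_normal(n)
    records = []
    for y, d in zip(year_arr, doy):
        y = int(y)
        start = dt.date(y, *species.season_start)
        end = dt.date(y, *species.season_end)
        init = dt.date(y, 1, 1) + dt.timedelta(days=int(round(d)) - 1)
        init = min(max(init, start), end)
        hatch = init + dt.timedelta(days=species.laying_days + species.incubation_days)
        fledge = hatch + dt.timedelta(days=species.brooding_days)
        habitat = "off-channel" if rng.random() < off_channel_fraction else "on-channel"
        records.append(NestRecord(species.name, init, hatch, fledge, habitat))
    return records
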