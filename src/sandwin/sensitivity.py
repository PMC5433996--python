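"""Monte Carlo sensitivity of the median success window.

Two inputs are perturbed with independent triangular distributions, mirroring
the conventions of spreadsheet risk-analysis tools:

* stage-per-unit-discharge scale factor (default range 0.7–1.3 of the base
  rating curve), applied about a pivot discharge so only the stage *rise*
  scales; and
* sandbar height below peak stage (default: observed median ± 0.46 m).

Each trial rebuilds the reach with the perturbed curve and bar height, runs
the habitat model over all analysis years, and records the median success
window.  Sensitivity is attributed by *contribution to variance*: the squared
Spearman rank correlation of each input with the output, normalized across
inputs to sum to 100%.

The per-trial evaluation exploits the fact that scaling stage rise by ``f``
is affine in stage: a season day is emergent iff
``f · (STAGE_HAB − STAGE_DAILY) > bar_height``, so base stages are computed
once per year and each trial reduces to vectorised comparisons.  This is
exactly equivalent to rebuilding the scaled curve trial by trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sandbar import ReachConfig, SpeciesProfile, success_window
from .hydrology import habitat_forming_discharge, FlowDataError

__all__ = [
    "TriangularSpec",
    "SensitivityResult",
    "sample_triangular",
    "contribution_to_variance",
    "run_sensitivity",
]


@dataclass(frozen=True)
class TriangularSpec:
    """min ≤ mode ≤ max triangular distribution (units of the target input)."""

    minimum: float
    mode: float
    maximum: float

    def __post_init__(self):
        if not (self.minimum <= self.mode <= self.maximum):
            raise ValueError("need minimum ≤ mode ≤ maximum")
        if not self.minimum < self.maximum:
            raise ValueError("need minimum < maximum (use a constant otherwise)")

    @property
    def mean(self) -> float:
        return (self.minimum + self.mode + self.maximum) / 3.0


@dataclass
class SensitivityResult:
    n_trials: int
    contributions: dict[str, float]  # percent, sums to 100 unless degenerate
    trials: pd.DataFrame  # stage_scale, bar_height_m, median_window_days
    degenerate: bool  # output constant across trials


def sample_triangular(spec: TriangularSpec, n: int, seed) -> np.ndarray:
    """n i.i.d. triangular draws; ``seed`` may be an int or a Generator."""
    if n < 1:
        raise ValueError("n must be ≥ 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.triangular(spec.minimum, spec.mode, spec.maximum, size=n)


def contribution_to_variance(inputs: dict[str, np.ndarray], output) -> dict[str, float]:
    """Percent contribution of each sampled input to output variance.

    Squared Spearman rank correlation per input, normalized to sum to 100%.
    A constant output (or all-zero correlations) yields all-zero
    contributions — the caller should treat that as degenerate.
    """
    out = np.asarray(output, dtype=float)
    if len(inputs) < 1:
        raise ValueError("need at least one input")
    if out.size < 10:
        raise ValueError("need ≥ 10 trials for a rank-correlation attribution")
    if np.ptp(out) == 0:
        return {k: 0.0 for k in inputs}
    sq = {}
    for name, vals in inputs.items():
        rho = stats.spearmanr(np.asarray(vals, float), out).statistic
        sq[name] = 0.0 if np.isnan(rho) else float(rho) ** 2
    total = sum(sq.values())
    if total == 0:
        return {k: 0.0 for k in inputs}
    return {k: 100.0 * v / total for k, v in sq.items()}


def _max_run_rows(emergent: np.ndarray) -> np.ndarray:
    """Longest run of True per row of a 2-D boolean array."""
    n, m = emergent.shape
    best = np.zeros(n, dtype=np.int64)
    cur = np.zeros(n, dtype=np.int64)
    for j in range(m):
        cur = np.where(emergent[:, j], cur + 1, 0)
        np.maximum(best, cur, out=best)
    return best


def run_sensitivity(
    reach: ReachConfig,
    species: SpeciesProfile,
    stage_spec: TriangularSpec,
    bar_spec: TriangularSpec,
    n_trials: int = 10_000,
    seed: int = 0,
    *,
    min_coverage: float = 0.95,
) -> SensitivityResult:
    """Monte Carlo sensitivity of the median success window for one reach/species."""
    if n_trials < 100:
        raise ValueError("n_trials must be ≥ 100")
    curve = reach.rating_curve
    rng = np.random.default_rng(seed)

    # Per-year base quantities (independent of the perturbations).
    reliefs = []  # STAGE_HAB − STAGE_DAILY per season day; −inf marks missing days
    for year in reach.analysis_years:
        try:
            disch_hab = habitat_forming_discharge(reach.flow_series, year)
        except FlowDataError as exc:
            raise FlowDataError(f"{reach.name} year {year}: {exc}") from exc
        season = species.season_dates(year)
        q = reach.flow_series.data.reindex(season)
        present = q.notna().to_numpy()
        if present.mean() < min_coverage:
            continue
        qv = q.to_numpy()
        stage_daily = np.full(len(season), np.inf)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stage_hab = float(curve.stage_at(disch_hab))
            low = present & (qv <= 0)
            stage_daily[low] = curve.stage[0]
            ok = present & ~low
            if ok.any():
                stage_daily[ok] = curve.stage_at(qv[ok])
        reliefs.append(stage_hab - stage_daily)  # missing days → −inf → never emergent
    if not reliefs:
        raise FlowDataError("no analysis years with adequate coverage")
    relief = np.vstack(reliefs)  # (n_years, season_len)

    f = sample_triangular(stage_spec, n_trials, rng)
    b = sample_triangular(bar_spec, n_trials, rng)
    b = np.maximum(b, 0.0)  # bars cannot sit above peak stage

    windows = np.empty((relief.shape[0], n_trials), dtype=np.int64)
    for i, rel in enumerate(relief):
        emergent = f[:, None] * rel[None, :] > b[:, None]  # tie → inundated
        runs = _max_run_rows(emergent)
        windows[i] = np.maximum(runs - species.success_period, 0)
    median_window = np.median(windows, axis=0)

    inputs = {"stage_discharge": f, "bar_height": b}
    contributions = contribution_to_variance(inputs, median_window)
    degenerate = float(np.ptp(median_window)) == 0.0
    trials = pd.DataFrame(
        {
            "stage_scale": f,
            "bar_height_m": b,
            "median_window_days": median_window,
        }
    )
    return SensitivityResult(
        n_trials=n_trials,
        contributions=contributions,
        trials=trials,
        degenerate=degenerate,
    )
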