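# Methods

This note documents the models, parameter choices and numerical conventions
behind `sandwin`, and what the synthetic test battery does and does not
establish about behaviour on real gage data.

## The emergent-sandbar habitat model

The model is deliberately simple and deterministic. Its core assumptions:

* **Sandbar height is set by the habitat-forming discharge.** The maximum
  mean daily discharge over the 1.5-year window from 1 January of the prior
  year through 1 July of the analysis year is assumed to have built the bars
  available in the analysis season. The window is closed on both ends;
  `habitat_forming_discharge(..., include_end=False)` excludes 1 July itself
  for users who prefer the half-open reading.
* **Bars sit a fixed depth below the peak water surface.** The
  bar-height-below-peak-stage parameter (field medians: 0.46 m for the
  central Platte reach, 0.61 m for the lower Platte) is subtracted from the
  stage of the habitat-forming discharge to get the sandbar stage. Setting
  it to 0 reproduces the older assumption that bars build to the peak water
  surface — an assumption the model exists to challenge: with any positive
  bar depth the predicted inundating discharge falls strictly below the
  habitat-forming peak, so nest losses occur at flows far smaller than the
  flows that built the habitat.
* **Inundation is binary and daily.** A season day is emergent iff its stage
  is *strictly* below the sandbar stage; a stage exactly at bar height
  counts as inundated. This conservative tie rule reflects field evidence
  that even surveyed bar heights overpredict the discharge needed to flood
  nests. There is no partial-day hydraulics and no within-reach spatial
  variation in bar height.
* **Seasons are month-day windows.** Piping plover 1 May–26 Aug (118 days,
  success period 8+28+28 = 64); least tern 28 May–30 Aug (95 days, success
  period 3+21+21 = 45). Both are configurable via `SpeciesProfile`. The
  component durations (laying, incubation, brooding) sum to the success
  period by construction; where a published operational description instead
  quotes 49 days for the tern, the component sum (45) is used because it is
  internally consistent with the per-stage durations. Neither season spans
  February, so season length is leap-year invariant.

Missing season days count as inundated (conservative), and a year whose
season coverage falls below 95% (configurable) is flagged and excluded from
cross-year summaries rather than interpolated across. Cross-year summaries
use the mean-of-central-pair median. Note one boundary subtlety: with that
median rule, "median window = 0 iff ≥ 50% of years have no window" holds in
the strict directions only (e.g. windows {0, 4} give median 2 with exactly
50% zero years).

## Hydrology and units

All discharges are m³/s internally ("cm"/"cms" in the regional literature);
cfs → m³/s conversion (× 0.028316846592) happens only when reading NWIS RDB
or cfs-labelled CSV files. Gaps are represented by absent dates, never
zeros; `fill_gaps` linearly interpolates only gaps up to a caller-set length
and flags the values `estimated`. Day-of-year climatologies fold 29 February
into day 59 rather than dropping it.

## Record extension (MOVE.1) and validation

Short records are extended from a correlated donor gage by Maintenance of
Variance Extension type 1: the transfer line matches the concurrent-period
means and standard deviations exactly, `t(ŷ) = m_y + (s_y/s_x)(t(x) − m_x)`,
rather than minimising squared error — ordinary regression would deflate the
variance of the extended record and bias the frequency of habitat-forming
peaks. The transform defaults to log10 (standard for streamflow); zero-flow
days require a positive offset (suggested 0.01 m³/s) and raise a loud error
otherwise. Concurrent alignment is by exact date with no lag search.
Validation uses the Nash–Sutcliffe Coefficient of Efficiency computed on
*untransformed* flows over the common dates; ≥ 0.70 is the conventional
satisfactory threshold for daily flow. Observed values always take
precedence over estimated ones when records are merged, and provenance flags
survive the merge.

## Rating curves

Rating tables are interpolated with stage linear in log-discharge, a good
approximation for near-power-law curves while tolerating the negative stages
produced by re-datuming; a fully linear mode is available. Above the table
the terminal segment is extended with a warning (habitat-forming peaks can
exceed the rated range); below the lowest tabulated discharge stage clamps
to the first point with a warning, and zero-flow days inherit that clamped
stage. Inversion is exact on the tabulated range (round-trip within 1e-9
relative) and refuses stages below the bottom of the table. Curves are
strictly increasing in both columns; a flat segment is rejected at
construction because it would make inundating-discharge back-prediction
ill-posed.

Sensitivity scaling multiplies the stage *rise* about a pivot discharge:
`s'(Q) = s(p) + f·(s(Q) − s(p))`. The pivot defaults to the normalization
reference (else the lowest tabulated discharge); the emergence decision is
in fact pivot-independent, since it reduces to
`f · (STAGE_HAB − STAGE_DAILY) > bar_height`. A consequence worth stating
because intuition can run the other way: success windows are weakly
*increasing* in `f`. Flattening the curve (f < 1) shrinks the stage relief
between the peak that built the bars and ordinary season flows, while the
bars still sit a fixed depth below that (now lower) peak stage — so flat,
wide channels drown fixed-depth bars more easily. This is the hydraulic
reason the wide historical channel performs worst in the reach comparison.

## Monte Carlo sensitivity

Inputs are drawn independently from triangular distributions — the
stage-per-discharge factor over (0.7, 1.0, 1.3) and bar height over the
observed median ± 0.46 m, floored at 0 — mirroring spreadsheet risk-analysis
conventions. Each trial's output is the median success window across all
analysis years. Contribution to variance is the squared Spearman rank
correlation of each input with the output, normalised to sum to 100%; this
is the convention of the spreadsheet tools that popularised the statistic
(which do not publish a formula), documented here as an interpretation. A
constant output across trials is flagged degenerate with all-zero
contributions rather than an error — it is the correct answer for, e.g., a
reach where the plover window is 0 in every trial. Because stage scaling is
affine in stage, per-trial evaluation precomputes each year's base stages
once and reduces every trial to vectorised comparisons; a test verifies this
path agrees exactly with literally rebuilding the scaled curve per trial.
Default 10,000 trials; the acceptance script uses 1,000, where the
attribution is already stable to a few percent.

## Phenology and demography

Initiation windows are empirical 5th–95th percentile windows of pooled
day-of-year, with linear interpolation between order statistics (one pinned
quantile rule, since several are in common use); fractional days round to
the nearest calendar day in the earliest record's year. Required fledge
ratios divide the annual maintenance target (1.13 fledglings/pair for
plover, 0.70 for tern) by the fraction of years with any success window;
`p = 0` returns an infinite-requirement sentinel rather than an error.
When reproducing printed ratios the rounded percentages are used as inputs
and results are rounded half-up to 2 decimals (1.13/0.16 = 7.06,
0.70/0.32 = 2.19, 0.70/0.71 = 0.99, 0.70/0.83 = 0.84); pipeline mode keeps
unrounded fractions. One published inconsistency is preserved rather than
silently corrected: the contemporary-reach plover ratios 1.95 and 2.40
appear with reach labels swapped relative to the no-window percentages they
derive from (1.13/0.47 = 2.40 matches the central reach's 53%, 1.13/0.58 =
1.95 the lower reach's 42%); this package computes from the fractions.

## Synthetic data: what it emulates, and what it does not

The generators encode the study conditions the analysis assumes:

* **Hydrographs** — baseflow plus two Gaussian day-of-year pulses (early
  rise centred day 65, late rise day 166 ≈ mid-June, σ = 15 d), wrapped at
  the year boundary; multiplicative lognormal AR(1) daily noise (σ = 0.3,
  ρ = 0.85, median 1); one lognormal amplitude factor per year (CV = 0.4)
  shared by both pulses, which naturally produces the multi-year declining-
  peak sequences that open long success windows. The pulse form, noise and
  inter-annual parameters are this package's choices of realistic values —
  no published characterisation of daily-flow noise exists to estimate them
  from — and they are deliberately not tuned to any particular gage.
* **Rating curves** — power laws `s = c·Qᵉ` tabulated geometrically, so the
  log-discharge interpolation grid is uniform.
* **Nest records** — initiation day-of-year normal around the species median
  (plover 15 May, tern 10 June), clipped to the season; hatch and fledge
  dates follow deterministically from the stage durations.

The demo configuration contrasts three reaches by construction: a
"historical" reach with big rises but a flat rating curve (exponent 0.32),
a reservoir-damped "contemporary" reach (0.45), and a high-flow "lower"
reach (0.55). The qualitative hierarchy that emerges — lower ≥ contemporary
≥ historical windows, plover always worse than tern, > 90% of window
variance attributable to bar height — matches the published field analysis.

What passing tests do **not** show: the synthetic river has no flow routing,
no ice or regulation artefacts, no heteroscedastic gage error, no
vegetation encroachment, and bar heights enter only as a scalar depth below
peak stage (no height distributions, no bar area). Numerical agreement with
published reach-specific medians therefore cannot be claimed from synthetic
runs; only directions, orderings and arithmetic identities are verified
offline.

## Reproducing the external analysis

With network access, the published comparison can be re-run end to end:
retrieve NWIS daily values for gages 06770500 (Grand Island) and 06805500
(Louisville) for 1954–2012 (`read_daily_flows(..., dialect="rdb")`), supply
the corresponding USGS rating tables as two-column CSVs, set bar heights
0.46 m and 0.61 m, and run `sandwin run --years 1954:2012`. The historical
record at Overton (06768000) is extended back to 1895 with `sandwin extend`
from the North Platte donor gages; NSCE against the observed 1902–1906
Overton flows should exceed 0.70. These steps require third-party downloads
and are intentionally outside the test suite.

## Problem sizes

Defaults chosen for the bundled analyses: 30-year demo records, 100-scenario
monotonicity sweeps, 1,000-trial sensitivity in the acceptance script
(10,000 by default in the API), 500-year climatology in the generator test.
These sizes give stable medians and attributions while keeping the full
offline suite fast.
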