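# sandwin

**Emergent-sandbar nesting-habitat success windows from river hydrology.**

Interior least terns (*Sternula antillarum athalassos*) and piping plovers
(*Charadrius melodus*) nest on barren riverine sandbars. On sand-bed rivers
like the Platte (Nebraska, USA), sandbars are built by high flows and then
drowned by the next ones: a nest succeeds only if it is initiated, incubated
and the chicks fledged during a stretch of days when the bars stand above the
water. `sandwin` implements a deterministic emergent-sandbar habitat model
that turns daily discharge records, stage–discharge rating curves and sandbar
heights into per-year *success windows* — the number of days a nest could
have been started and still fledged chicks without inundation — and the
demographic arithmetic that converts success-year frequencies into the fledge
ratios needed to sustain a subpopulation.

It is written for quantitative ecologists and ecohydrologists comparing the
reproductive potential of river reaches or management scenarios.

## The model

For each analysis year and reach:

1. **DISCH_HAB** — the habitat-forming discharge: the maximum mean daily
   discharge from 1 January of the prior year through 1 July of the analysis
   year (sandbars persist through two nesting seasons).
2. **STAGE_HAB** = stage(DISCH_HAB) from the reach rating curve.
3. **STAGE_BAR** = STAGE_HAB − *bar height below peak stage* (observed
   medians: 0.46 m central Platte, 0.61 m lower Platte).
4. Daily stage over the species nesting season (piping plover 1 May–26 Aug,
   least tern 28 May–30 Aug) from daily discharge.
5. A day is *emergent* iff daily stage < STAGE_BAR (ties count as inundated).
6. Take the maximum contiguous run of emergent days.
7. **Success window** = max(0, run − success period), with success period =
   laying + incubation + brooding = 64 d (plover) or 45 d (tern).

Summaries across years report the median window, the percent of years with
no window, and the percent of years in which the entire season was emergent.
Supporting stages include MOVE.1 streamflow record extension (variance-
preserving transfer from a donor gage) with Nash–Sutcliffe validation, Monte
Carlo sensitivity with triangular input distributions and contribution-to-
variance attribution, nesting-phenology metrics (5th–95th percentile
initiation windows), and seeded synthetic generators (bimodal hydrographs,
power-law rating curves, nest records) so the whole pipeline runs and is
tested entirely offline.

## Worked example

Run the built-in synthetic three-reach comparison (a wide, hydraulically flat
"historical" reach; a reservoir-damped "contemporary" reach; a steep-rated
high-flow "lower" reach):

```python
from sandwin import make_demo_config, run_full_analysis

bundle = run_full_analysis(make_demo_config(seed=1, n_years=30), "demo_out")
print(bundle["reaches"]["LPR"]["least_tern"])
print(bundle["reaches"]["historical_AHR"]["piping_plover"])
```

prints (seed 1):

```
{'median_window_days': 25.0, 'pct_no_window': 0.0, 'pct_season_long': 30.0,
 'n_years': 30, 'p_success': 1.0, 'required_fledge_ratio': 0.7}
{'median_window_days': 0.0, 'pct_no_window': 100.0, 'pct_season_long': 0.0,
 'n_years': 30, 'p_success': 0.0, 'required_fledge_ratio': None}
```

Read: on the synthetic lower-river reach a least tern pair finds a usable
nesting window in every year (median 25 days wide), so the ordinary
maintenance target of 0.70 fledglings/pair suffices. On the flat historical
reach the mid-June rise tops the bars every year, piping plovers get no
window at all, and no finite fledge ratio could sustain an on-channel
subpopulation (`required_fledge_ratio` is `None`, i.e. unattainable). The
same arithmetic applied to published no-window frequencies (84% and 68% of
years) gives the required ratios 7.06 and 2.19 fledglings/pair — far above
anything observed in the field.

The same pipeline runs from the shell:

```sh
sandwin demo --seed 1 --out-dir demo_out
sandwin run --flows flows.csv --rating rating.csv --bar-height 0.46 \
            --species both --years 1954:2012 --out reach
sandwin sensitivity --flows flows.csv --rating rating.csv --bar-height 0.46 \
            --species plover --years 1954:2012 --trials 10000 --seed 1 --out sens
```

Real USGS NWIS daily-values files (tab-delimited RDB) are read directly with
`read_daily_flows(path, dialect="rdb")`; discharges are converted from cfs
and kept in m³/s throughout.

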