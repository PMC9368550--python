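# ecocrit

Delineation, change typing and driver attribution of **ecologically
critical areas (ECA)** on raster landscapes.

Ecological barrier zones — large mountainous regions managed for soil
conservation, water retention and biodiversity — contain cells whose loss
would disproportionately damage regional ecological security.  `ecocrit`
implements a complete, reproducible pipeline for identifying those cells on
a common analysis grid (1 km by default), tracking how the critical set
expands or degrades between survey dates, and attributing that change to
environmental and socioeconomic drivers.  It is written for landscape
ecologists and spatial analysts who have (or want to simulate) co-registered
land-cover, ecosystem-service and driver rasters.

## The model

Each grid cell *i* receives an **ecological critical index**

```
ECI_i = MESLI_i × LESSI_i
```

* **MESLI** (multiple ecosystem services landscape index) is the sum of
  min–max normalised ecosystem-service values, `Σ_s (x_si − min_s)/(max_s −
  min_s)`, over the service layers (carbon sequestration, water yield, soil
  conservation, habitat quality); range `[0, n_services]`.
* **LESSI** (landscape ecological structure security index) scores each
  analysis unit (county) by `1 − [(PD + ED) × 2.5 V]` with
  `V = 0.5·AWMSI + 0.3·F + 0.2·D`, built from FRAGSTATS-standard
  class-level metrics: patch density PD, edge density ED, area-weighted
  mean shape index AWMSI, fractal dimension F and division D, min–max
  rescaled across units so `LESSI ∈ [0, 1]`.

The ECA threshold **T** is the centre of the **last peak** of the smoothed
ECI frequency distribution; cells with `ECI > T` form the ECA mask.
Two-date change splits into *expansion* (non-ECA → ECA) and *degradation*
(ECA → non-ECA).  Changed cells whose 1-km buffers overlap form patches,
each located by the **landscape expansion index**

```
LEI = 100 · A0 / (AE − AP)     ∈ [0, 100]
```

(`AP` patch area, `AE` patch-plus-buffer area, `A0` reference ECA inside the
buffer), which classifies the six evolution types: *isolation / spread /
infilling* for expansion (`LEI = 0`, `0 < LEI ≤ 50`, `50 < LEI ≤ 100`) and
*departed / atrophy / disintegration* for degradation.  Finally a
Gini-impurity random forest attributes unit-level evolution modes and types
to twelve drivers (terrain, climate, land-cover shares, GDP, population,
nightlight, distances from impervious/cropland), reporting percent
contributions `P(r)` (summing to 100) graded I–VI on geometric intervals.

Because no public dataset accompanies this kind of analysis, the package
ships a first-class synthetic-landscape generator that produces seeded
multi-period inputs with exactly known ground truth (planted edge,
isolated and interior change; a planted driver effect), so every stage is
testable end to end.

## Worked example

```python
import ecocrit

report = ecocrit.run_pipeline(ecocrit.ScenarioConfig(seed=1))

for period, row in report["periods"].items():
    print(period, row["eca_count"], round(row["threshold"], 3))
print("overall change %:", report["overall_change_pct"])
print("2005-2010 expansion share %:",
      report["pairs"]["2005-2010"]["summary"]["expansion"]["proportion_pct"])
top = max(report["drivers"]["mode"]["contributions_pct"].items(),
          key=lambda kv: kv[1])
print("top driver:", top)
```

prints

```
2005 11166 1.28
2010 11049 1.28
2015 11173 1.28
2019 11023 1.28
overall change %: 1.28
2005-2010 expansion share %: 22.01
top driver: ('precipitation', 39.4992)
```

Read: the scenario's critical set shrinks, grows, then shrinks again
(net −1.28 % of cells) under a stable extracted threshold, the 2005–2010
interval is degradation-dominated (expansion only 22 % of changed cells),
and the planted driver
(precipitation, shifted between expansion- and degradation-prone counties)
is correctly recovered as the dominant contribution.  The per-pair summary
also carries the six type counts, areas and proportions, and
`report["truth_audit"]` scores the detected ECA against the generator's
ground truth.

A `ecocrit` command-line interface exposes the same stages
(`simulate`, `metrics`, `eci`, `identify`, `evolve`, `drivers`, `run`) over
ESRI ASCII grid rasters, CSV tables and JSON reports.

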