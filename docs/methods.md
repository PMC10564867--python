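# Methods

## Model overview

`thermodiv` couples two components.

**Niche pool and ensemble.** A pseudo-species is an interval
[t_low, t_high] on the temperature axis; it is present wherever the local
mean-annual upper-ocean temperature lies inside the closed interval (ties at
either bound count as presence, which maximizes continuity of richness in
temperature). The pool enumerates every interval on a regular double grid:
positions t_low = t_min + iΔ and breadths n = n_min + jΔ with
t_low + n ≤ t_max, with defaults t_min = −1.8 °C (seawater freezing),
t_max = 44 °C (modern ceiling for metazoan reproduction), n_min = 1 °C,
Δ = 0.1 °C. This yields 101,025 niches (449·450/2), with breadths from 1 to
45.8 °C. Published applications of this model family report 101,397 niches
for the same bounds; the exact enumeration scheme behind that count is not
recoverable from its description, and the regular double grid is adopted as
the transparent, reproducible choice — the two counts differ by 0.4%, far
below any effect studied here. The increment is a configuration parameter,
so alternative schemes can be explored.

Ensembles draw 10,000 pseudo-species uniformly without replacement from the
pool, repeated 100 times; per-cell richness is the **mean** of the per-draw
counts (medians are reserved for spatial aggregation). Draw substreams are
spawned deterministically from one seed, so results are bit-reproducible and
the same ensemble can be reused across time slices. Uniformity matters:
skewing the niche distribution toward warm temperatures would pack and
overlap niches there, conflicting with competitive exclusion, and is
deliberately unsupported.

Richness evaluation uses sorted-bound counting,
`count(t_low ≤ T) − count(t_high < T)`, which is exactly the per-niche scan
but O(n log n); the equivalence is asserted in tests. Cell temperatures are
clamped at −1.8 °C before occupancy, so freezing cells can still host niches
whose lower bound is −1.8 °C. Invalid cells carry NaN, never 0 — zero is a
legitimate richness.

## Synthetic paleoclimate

The generator stands in for an ocean-atmosphere GCM. Its defaults define the
study conditions; they were fixed at design time and are configurable.

**Time slices and forcing.** Seven slices, 490–430 Ma at 10-Myr steps. The
`proxy-cooling` scenario fixes tropical SST at 45 °C (490 Ma) and 30 °C
(430 Ma) — the end members of the proxy-derived Ordovician cooling trend —
with the packaged monotone interpolation
{480: 42.5, 470: 40, 460: 37, 450: 33, 440: 31} °C in between (only the
endpoints are externally anchored; the table can be overridden, and
unlisted ages interpolate linearly). `constant-30` and `constant-40` hold
tropical SST fixed, isolating the effect of continental drift.

**Zonal profile with polar amplification.** Temperature is
`T(lat) = p + (t_trop − p)·cos(lat)^e`, clamped at −1.8 °C, with the pole
anchor and exponent functions of the climate state:

* pole anchor `p = max(−1.8, 0.8·(t_trop − 30))` °C,
* exponent `e = 1 + 0.1·(45 − t_trop)`.

Hothouse states therefore have a warm pole and a flat gradient
(490 Ma: p = 12 °C, e = 1), cool states a freezing pole and a steep gradient
(430 Ma: p = 0 °C ice-marginal, e = 2.5). This is the textbook polar-
amplification structure of GCM ensembles and is load-bearing here: a fixed
−1.8 °C pole with a plain cosine puts every shelf temperature of the *cool*
reference climate on the flat top of the richness–temperature curve, so the
reference loses its latitudinal structure and the thermal-ceiling sweep
(below) inverts. With the amplified profile the cool world exhibits a proper
modern-type LBG and the sweep reproduces the expected structure — correlation
with the cool reference is maximal for ceilings near 65–68 °C and collapses
rapidly below ~62 °C — as an emergent result rather than a tuned one. The
coefficients (0.8 °C pole warming per tropical degree; exponent slope
0.1/°C) are round values chosen once to give a hothouse pole ≈ 10–15 °C and
a coolhouse 55°S shelf ≈ 5–8 °C, both within the envelope of published
deep-time GCM simulations.

**Paleogeography.** Five rectangular continental blocks drift along a
piecewise-linear track (interpolated for off-table ages): a wide polar
Gondwana with a broad (3-cell) shelf fringe retreating poleward through the
period; Baltica drifting monotonically north from mid-southern latitudes
toward the equator (so that it tracks a climate belt — the regional-analysis
edge case); tropical Laurentia, Siberia and South China drifting slowly
north. Shelves are one dilation ring (per-block fringe width in degrees)
around the land cells; merging fringes of neighbouring blocks are allowed on
coarse grids, overlapping land is an error. Region labels cover each block's
land and fringe. Positions are schematic — chosen so the emulated world
reproduces the qualitative Ordovician story (inverted-to-modern LBG
transition, rising-then-stable global curve, muted Baltica trend) — and are
not reconstructions; the true paleogeographies are not re-derived.

**Grid and noise.** Default 64 × 128 cell-centered grid (≈ 2.8°, emulating a
GCM ocean at reduced cost; minimum 8 × 8). Optional noise is a seeded,
Gaussian-smoothed (σ = 2 cells) perturbation scaled to a target standard
deviation, default 0.5 °C when requested; the pipeline and all acceptance
computations run with noise off, so their results are deterministic. All
"area-weighted" means use cos(latitude) weights.

With noise off the tropical-band (|lat| ≤ 10°) mean SST sits 0.2–0.5 °C
below the nominal tropical value (44.79 vs 45, 29.54 vs 30, 39.70 vs 40 °C)
because the band average of cos^e over ±10° is slightly below one; this is
within the "ca." precision of the nominal values and left uncorrected.

**NetCDF ingest.** Real GCM output is read from CF-style NetCDF (classic
format): 2-D fields pass through; 3-D (depth, lat, lon) fields are averaged
over levels with center depth ≤ 100 m, weighted by layer thickness (layer
interfaces at midpoints between centers, top interface at 0 m). Units are
validated (°C accepted, Kelvin converted, anything else is an error; a
missing units attribute is assumed °C). Bathymetry (positive depths) defines
ocean (depth > 0) and shelf (depth ≤ 250 m); without a bathymetry variable
every finite-temperature cell is treated as shelf.

## Analysis conventions

* **Domain.** Valid = ocean ∧ shelf ∧ |lat| ≤ 60°, with switches for
  global-ocean and polar robustness runs. The polar cutoff excludes the grid
  row centered at 60.47°, so the most poleward valid row on the default grid
  is 57.66°.
* **Global curve.** Median and standard deviation over valid cells,
  unweighted (an area-weighted option exists, off by default). The spatial
  standard deviation is the envelope; ensemble spread is much smaller and is
  not plotted.
* **LBG.** Zonal medians on native grid rows by default, optionally in wider
  bands; empty rows are flagged NaN. Peak latitude is the argmax row,
  optionally restricted to one hemisphere.
* **Regional series.** Median ± std over valid cells carrying one block's
  region label; ages where a region has no valid cells (e.g. Gondwana once
  its margin retreats poleward of 60°) are flagged missing, not zero-filled.
* **Normalization.** Min–max over the displayed age range, for co-plotting
  against normalized fossil compilations (which are ingested as CSV for
  plotting only; no quantitative model–data statistic is computed).
* **Taylor statistics.** Pearson correlation, population standard
  deviations, and *centered* (anomaly) pattern RMSD over jointly valid
  cells, with the bias (mean difference) reported alongside but excluded
  from the diagram geometry — the standard Taylor convention. Zero variance
  in either field raises an explicit error. The thermal-ceiling sweep uses
  the 460 Ma geography, compares each warm-climate (constant-40) map against
  the cool-climate (constant-30) t_max = 44 reference over shelf cells only,
  regenerates the pool per ceiling on the grid
  {50, 53, 56, 59, 62, 65, 68, 71, 74, 78} °C (anchored at the four named
  values 50, 65, 68, 78, evenly filled, configurable), keeps t_min, minimum
  breadth and increment fixed, lets the maximum breadth extend to the new
  span, and resamples the ensemble under the same seed policy. Sweep
  statistics are reported for ensemble-scale richness, so members with
  larger pools (which dilute 10,000 species over more niches) have smaller
  standard deviations.

## Problem sizes and determinism

Default runs use the full published problem size — 101,025-niche pool,
10,000 × 100 ensemble, 64 × 128 grid, 7 time slices — because bound counting
makes each richness map take ~20 ms; the whole pipeline runs in well under a
second and the acceptance script in ~1 s. The test suite uses the same
defaults for the headline checks and reduced pools/grids elsewhere. All
randomness flows from explicit seeds; reruns are bit-identical.

## Known limitations

* The biodiversity–temperature relationship is assumed constant over
  geological time; only temperature limits ecology (no dispersal, no
  interactions beyond niche exclusivity, no seasonality, no oxygen or sea
  level, no mass extinction).
* The synthetic world is zonally symmetric up to noise: longitudinal
  structure (boundary currents, upwelling) that shapes real GCM richness
  maps is absent, so passing qualitative tests here demonstrates the
  machinery and the mid-domain mechanism, not GCM fidelity.
* The number of pseudo-species is an index of habitat suitability, not an
  absolute species count; only relative/temporal patterns are meaningful.
* Zonal medians on a coarse grid quantize the LBG peak to ~2.8°; reported
  peak latitudes inherit that resolution.
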