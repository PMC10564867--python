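# thermodiv

Thermal-niche pseudo-species modelling of Ordovician marine biodiversity on
gridded paleoclimate temperature fields.

## The problem

The Great Ordovician Biodiversification Event (GOBE, ca. 490–430 Ma) is the
largest sustained rise in marine animal diversity of the Phanerozoic, and
long-term global cooling — tropical sea-surface temperatures falling from
ca. 45 °C in the late Cambrian to ca. 30 °C by the early Silurian — is a
leading candidate driver. `thermodiv` implements a macroecological model that
makes this hypothesis quantitative: it couples gridded mean-annual upper-ocean
(0–100 m) temperature fields with a pool of *pseudo-species*, virtual taxa
defined solely by a thermal tolerance interval, and asks what global, zonal
and regional biodiversity trajectories emerge.

It is written for paleoclimate and macroecology researchers who want to run
niche-based biodiversity reconstructions without a general circulation model:
a synthetic forcing generator emulates the GCM (drifting continental blocks
with fringing shelves, a cooling-dependent zonal temperature profile with
polar amplification), and real GCM output can be ingested from NetCDF.

## The model

A niche pool is enumerated on a regular grid of positions and breadths: every
interval [t_low, t_low + n] with

* t_min = −1.8 °C ≤ t_low, the freezing point of seawater,
* t_low + n ≤ t_max = 44 °C, the modern upper limit for metazoan reproduction,
* breadth n from 1 °C (stenotherms) to the full span 45.8 °C (universal
  eurytherms), at 0.1 °C increments,

giving 101,025 unique niches. An ensemble draws 10,000 pseudo-species without
replacement, repeated 100 times. At each ocean grid cell with mean-annual
upper-100 m temperature T, richness is the ensemble-mean count of sampled
niches containing T. Because niches are bounded between fixed limits, more
intervals overlap intermediate temperatures: richness against temperature
peaks mid-domain, near 21 °C — the thermal mid-domain effect that converts
cooling of an overheated tropical ocean into biodiversification.

The analysis domain is the continental shelf (depth ≤ 250 m) within 60° of
the equator, matching where the fossil record is dense. Headline products:

* **Global curve** — median richness over valid shelf cells per time slice,
  ± the spatial standard deviation.
* **Latitudinal biodiversity gradient (LBG)** — zonal medians per time slice.
* **Regional series** — the same statistics per paleocontinent
  (Gondwana, Laurentia, Baltica, Siberia, South China).
* **Thermal-ceiling sensitivity** — a Taylor-diagram sweep of t_max from 50
  to 78 °C comparing warm-climate richness patterns against a cool-climate
  reference, testing how extreme an ectotherm physiology would be needed to
  suppress the cooling-driven biodiversification. The diagram's correlation
  r, centered pattern RMSD and standard deviations obey
  `crmsd² = σ_sim² + σ_ref² − 2 σ_sim σ_ref r`.

## Worked example

```python
import thermodiv as td

pool = td.generate_niche_pool()                    # 101,025 thermal niches
ens = td.sample_ensemble(pool, n_species=10_000, n_reps=100, seed=1)
scenario = td.build_scenario("proxy-cooling")

for age in (490.0, 450.0):
    field = td.generate_climate_field(scenario, age, noise_sd=0.0)
    rmap = td.richness_map(ens, field)
    median, std = td.global_summary(rmap)
    peak = td.zonal_lbg(rmap).peak_latitude()
    print(f"{age:.0f} Ma: median shelf richness {median:7.1f} +/- {std:6.1f}, "
          f"LBG peak at {peak:+.1f} deg")
```

prints

```
490 Ma: median shelf richness  1738.2 +/- 1696.0, LBG peak at -57.7 deg
450 Ma: median shelf richness  4554.7 +/-  491.0, LBG peak at -38.0 deg
```

At 490 Ma the tropics are lethally hot, so diversity concentrates at high
southern latitudes (an inverted LBG) and the global median is low with a huge
spatial spread. By 450 Ma cooling has opened the low-latitude shelves: the
richness peak has migrated to within 40° of the equator (a modern-type LBG)
and the global median has roughly tripled.

The same pipeline is scriptable from the shell:

```bash
thermodiv simulate --scenario proxy-cooling --seed 1 --out run/
thermodiv sweep-tmax --seed 1 --out run/
```

which writes per-age richness maps, the global curve, the LBG table, regional
series and the Taylor sweep as CSV (with provenance headers), plus optional
NetCDF fields.

## Limitations

The synthetic forcing is schematic: zonally symmetric temperatures (plus
optional smooth noise) and rectangular drifting blocks, not a reconstruction.
No dispersal, species interactions, seasonality, sea level or anoxia are
modelled, and the Late Ordovician Mass Extinction is outside the model's
scope. See `docs/methods.md` for the full model description and the
reasoning behind each default.
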