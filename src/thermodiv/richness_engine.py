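"""Per-cell pseudo-species richness from an ensemble and a climate field.

Richness at a grid cell is the number of sampled pseudo-species whose thermal
niche overlaps the cell's mean annual temperature, averaged over the
ensemble's repetitions. The analysis domain follows the paleontological
sampling domain: continental-shelf cells (depth <= 250 m) within 60 degrees
of the equator, with switches for global-ocean robustness runs.

The main path counts niches by sorted-bound bisection
(``count(t_low <= T) - count(t_high < T)``), which is exactly equivalent to a
per-niche scan but runs in O(n log n).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .niche_model import Ensemble, NichePool
from .synthetic_paleoclimate import SEAWATER_FREEZING_C, ClimateField, GridSpec

__all__ = [
    "DomainMaskSpec",
    "RichnessMap",
    "EmptyDomainError",
    "build_domain_mask",
    "richness_curve",
    "richness_map",
]


class EmptyDomainError(ValueError):
    """No valid cells remain after masking; the message names the culprit."""


@dataclass(frozen=True)
class DomainMaskSpec:
    """Which cells enter the analysis domain.

    Defaults reproduce the shelf-only domain: ocean cells on the continental
    shelf (depth <= 250 m) with |latitude| <= 60 degrees. ``global_ocean_mode``
    (or ``include_deep_ocean``) admits all ocean cells regardless of depth;
    ``include_polar`` lifts the latitude cutoff.
    """

    shelf_depth_cutoff: float = 250.0
    polar_latitude_cutoff: float = 60.0
    include_deep_ocean: bool = False
    include_polar: bool = False
    global_ocean_mode: bool = False

    def __post_init__(self) -> None:
        if self.shelf_depth_cutoff <= 0 or self.polar_latitude_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


def build_domain_mask(field: ClimateField, spec: DomainMaskSpec | None = None
                      ) -> np.ndarray:
    """Boolean validity mask: ocean AND (shelf OR deep-ocean switch) AND
    (|lat| within the polar cutoff unless lifted)."""
    spec = spec or DomainMaskSpec()
    lat2, _ = field.grid.mesh()
    depth_ok = field.shelf_mask | spec.global_ocean_mode | spec.include_deep_ocean
    lat_ok = spec.include_polar | (np.abs(lat2) <= spec.polar_latitude_cutoff)
    return field.ocean_mask & depth_ok & lat_ok


@dataclass
class RichnessMap:
    """Per-cell ensemble-mean pseudo-species richness.

    Invalid cells carry NaN, never 0 (zero is a legitimate richness).
    ``region_codes``/``region_names`` are carried through from the climate
    field for regional aggregation; the pool's thermal ceiling, ensemble size
    and scenario tag are kept as provenance.
    """

    grid: GridSpec
    age: float
    richness: np.ndarray
    valid_mask: np.ndarray
    n_species: int
    n_reps: int
    t_max: float
    scenario: str = "custom"
    region_codes: np.ndarray | None = None
    region_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        vals = self.richness[self.valid_mask]
        if vals.size and (np.nanmin(vals) < -1e-9
                          or np.nanmax(vals) > self.n_species + 1e-9):
            raise ValueError("richness outside [0, n_species] on valid cells")

    def values_at_valid(self) -> np.ndarray:
        return self.richness[self.valid_mask]

    def region_values(self, name: str) -> np.ndarray:
        if self.region_codes is None or not self.region_names:
            raise ValueError("map carries no region labels")
        if name not in self.region_names:
            raise KeyError(
                f"unknown region {name!r}; known: {', '.join(self.region_names)}"
            )
        code = self.region_names.index(name) + 1
        return self.richness[self.valid_mask & (self.region_codes == code)]

    def to_csv(self, path: str | Path) -> None:
        """(lat, lon, richness) rows for valid cells."""
        lat2, lon2 = self.grid.mesh()
        v = self.valid_mask
        pd.DataFrame({
            "lat": lat2[v], "lon": lon2[v], "richness": self.richness[v],
        }).to_csv(path, index=False)

    def to_netcdf(self, path: str | Path) -> None:
        import xarray as xr

        xr.Dataset(
            {"richness": (("lat", "lon"), self.richness),
             "valid_mask": (("lat", "lon"), self.valid_mask.astype("i1"))},
            coords={"lat": self.grid.latitudes, "lon": self.grid.longitudes},
            attrs={"age_ma": self.age, "scenario": self.scenario,
                   "n_species": self.n_species, "n_reps": self.n_reps,
                   "t_max": self.t_max},
        ).to_netcdf(path, engine="scipy")


def _bounds_of(niche_set) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(niche_set, NichePool):
        return niche_set.t_low, niche_set.t_high
    t_low, t_high = niche_set
    return np.asarray(t_low, float), np.asarray(t_high, float)


def richness_curve(niche_set, temperature_axis) -> np.ndarray:
    """Number of niches overlapping each temperature of a sorted axis.

    ``niche_set`` is a :class:`NichePool` or a ``(t_low, t_high)`` pair of
    arrays. With niches bounded between fixed limits, the curve peaks at
    mid-domain temperatures (the thermal mid-domain effect).
    """
    t_low, t_high = _bounds_of(niche_set)
    axis = np.asarray(temperature_axis, dtype=float)
    if not np.all(np.isfinite(axis)):
        raise ValueError("temperature axis must be finite")
    lo = np.sort(t_low)
    hi = np.sort(t_high)
    return (np.searchsorted(lo, axis, side="right")
            - np.searchsorted(hi, axis, side="left"))


def richness_map(
    ensemble: Ensemble,
    field: ClimateField,
    mask_spec: DomainMaskSpec | None = None,
) -> RichnessMap:
    """Ensemble-mean richness on the valid domain of a climate field.

    Cell temperatures are clamped at the seawater freezing point before
    occupancy is evaluated. The per-cell value is the mean over the
    ensemble's repetitions of the count of sampled niches containing the
    cell temperature; by linearity this equals the average of the per-draw
    richness maps.
    """
    mask_spec = mask_spec or DomainMaskSpec()
    valid = build_domain_mask(field, mask_spec)
    if not valid.any():
        culprit = _diagnose_empty(field, mask_spec)
        raise EmptyDomainError(f"no valid cells: {culprit}")
    temps = np.maximum(field.temperature[valid], SEAWATER_FREEZING_C)
    uniq, inverse = np.unique(temps, return_inverse=True)
    acc = np.zeros(uniq.size, dtype=float)
    for rep in range(ensemble.n_reps):
        lo, hi = ensemble.draw_bounds(rep)
        acc += (np.searchsorted(lo, uniq, side="right")
                - np.searchsorted(hi, uniq, side="left"))
    mean_counts = acc / ensemble.n_reps
    richness = np.full(field.grid.shape, np.nan)
    richness[valid] = mean_counts[inverse]
    return RichnessMap(
        grid=field.grid, age=field.age, richness=richness, valid_mask=valid,
        n_species=ensemble.n_species, n_reps=ensemble.n_reps,
        t_max=ensemble.pool.spec.t_max, scenario=field.scenario,
        region_codes=field.region_codes, region_names=field.region_names,
    )


def _diagnose_empty(field: ClimateField, spec: DomainMaskSpec) -> str:
    if not field.ocean_mask.any():
        return "the land mask covers the whole grid"
    if not (field.ocean_mask & (field.shelf_mask | spec.global_ocean_mode
                                | spec.include_deep_ocean)).any():
        return (f"the shelf mask (depth <= {spec.shelf_depth_cutoff} m) "
                "removed every ocean cell")
    return (f"the polar cutoff (|lat| <= {spec.polar_latitude_cutoff} deg) "
            "removed every shelf cell")
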