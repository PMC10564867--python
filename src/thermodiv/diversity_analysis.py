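"""Aggregation of richness maps into biodiversity trajectories.

Three headline products: the global biodiversification curve (median richness
over valid shelf cells per time slice, with the spatial standard deviation as
an envelope), the latitudinal biodiversity gradient (zonal medians), and
regional time series for individual paleocontinents. Medians and standard
deviations are unweighted across valid cells; an area-weighted option exists
but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .richness_engine import RichnessMap

__all__ = [
    "DiversityCurve",
    "LatitudinalGradient",
    "global_summary",
    "global_curve",
    "zonal_lbg",
    "regional_series",
    "normalize_curve",
    "read_fossil_curve",
]


@dataclass(frozen=True)
class DiversityCurve:
    """Median richness +/- spatial std per age for one domain (global shelf
    or one region). Ages where the domain is empty carry NaN and are flagged
    in ``missing``."""

    ages: np.ndarray
    median: np.ndarray
    std: np.ndarray
    scenario: str = "custom"
    domain: str = "global-shelf"
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.missing is None:
            object.__setattr__(self, "missing", ~np.isfinite(self.median))
        if not (len(self.ages) == len(self.median) == len(self.std)):
            raise ValueError("ages, median, std must have equal length")
        finite_std = self.std[np.isfinite(self.std)]
        if finite_std.size and finite_std.min() < 0:
            raise ValueError("std must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age": self.ages, "median": self.median, "std": self.std,
            "scenario": self.scenario, "domain": self.domain,
        })


@dataclass(frozen=True)
class LatitudinalGradient:
    """Zonal medians of richness: one row per latitude band; bands with no
    valid cells are NaN (flagged, never zero-filled)."""

    band_centers: np.ndarray
    median: np.ndarray
    n_cells: np.ndarray
    age: float = float("nan")

    def peak_latitude(self, hemisphere: str | None = None) -> float:
        """Latitude of the maximum zonal median, optionally restricted to one
        hemisphere ('south' or 'north')."""
        med = self.median.copy()
        if hemisphere == "south":
            med[self.band_centers > 0] = np.nan
        elif hemisphere == "north":
            med[self.band_centers < 0] = np.nan
        elif hemisphere is not None:
            raise ValueError("hemisphere must be 'south', 'north' or None")
        if not np.isfinite(med).any():
            raise ValueError("no populated latitude band in that hemisphere")
        return float(self.band_centers[np.nanargmax(med)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age": self.age, "lat_band": self.band_centers,
            "median": self.median, "n_cells": self.n_cells,
        })


def global_summary(rmap: RichnessMap, area_weighted: bool = False
                   ) -> tuple[float, float]:
    """Median and spatial standard deviation of richness over valid cells.

    The median is robust to outliers in the spatial domain; the std
    summarizes the spread of values found in the time slice.
    """
    vals = rmap.values_at_valid()
    if vals.size == 0:
        raise ValueError("richness map has no valid cells")
    if area_weighted:
        w = rmap.grid.area_weights()[rmap.valid_mask]
        order = np.argsort(vals)
        cw = np.cumsum(w[order])
        med = float(vals[order][np.searchsorted(cw, 0.5 * cw[-1])])
        mean = np.sum(w * vals) / w.sum()
        std = float(np.sqrt(np.sum(w * (vals - mean) ** 2) / w.sum()))
        return med, std
    return float(np.median(vals)), float(np.std(vals))


def global_curve(maps_by_age: Mapping[float, RichnessMap],
                 scenario: str | None = None,
                 domain: str = "global-shelf") -> DiversityCurve:
    """Assemble the global biodiversification curve from per-age maps,
    ordered oldest first."""
    ages = np.array(sorted(maps_by_age, reverse=True), dtype=float)
    med = np.empty(ages.size)
    std = np.empty(ages.size)
    for i, a in enumerate(ages):
        med[i], std[i] = global_summary(maps_by_age[a])
    tag = scenario or next(iter(maps_by_age.values())).scenario
    return DiversityCurve(ages=ages, median=med, std=std,
                          scenario=tag, domain=domain)


def zonal_lbg(rmap: RichnessMap, band_width: float | None = None
              ) -> LatitudinalGradient:
    """Latitudinal biodiversity gradient: median richness per latitude band.

    ``band_width=None`` uses native grid rows; otherwise rows are grouped
    into bands of the given width (degrees), centered on the equator.
    """
    if not rmap.valid_mask.any():
        raise ValueError("richness map has no valid cells")
    lats = rmap.grid.latitudes
    if band_width is None:
        centers = lats
        index = np.arange(lats.size)
    else:
        edges = np.arange(-90.0, 90.0 + band_width, band_width)
        centers = 0.5 * (edges[:-1] + edges[1:])
        index = np.clip(np.digitize(lats, edges) - 1, 0, centers.size - 1)
    med = np.full(centers.size, np.nan)
    n = np.zeros(centers.size, dtype=int)
    for band in np.unique(index):
        rows = np.where(index == band)[0]
        sel = rmap.valid_mask[rows, :]
        if sel.any():
            med[band] = np.median(rmap.richness[rows, :][sel])
            n[band] = int(sel.sum())
    return LatitudinalGradient(band_centers=centers, median=med,
                               n_cells=n, age=rmap.age)


def regional_series(maps_by_age: Mapping[float, RichnessMap],
                    region_label: str) -> DiversityCurve:
    """Median +/- spatial std over the valid cells carrying one
    paleocontinent's label, per age; ages where the region has no valid
    cells are flagged as missing."""
    ages = np.array(sorted(maps_by_age, reverse=True), dtype=float)
    med = np.full(ages.size, np.nan)
    std = np.full(ages.size, np.nan)
    seen = False
    for i, a in enumerate(ages):
        vals = maps_by_age[a].region_values(region_label)  # raises if unknown
        if vals.size:
            med[i] = np.median(vals)
            std[i] = np.std(vals)
            seen = True
    if not seen:
        raise ValueError(f"region {region_label!r} has no valid cells at any age")
    scen = next(iter(maps_by_age.values())).scenario
    return DiversityCurve(ages=ages, median=med, std=std,
                          scenario=scen, domain=region_label)


def normalize_curve(curve) -> np.ndarray:
    """Min-max normalization of a series to [0, 1], for co-plotting model
    output against normalized fossil-diversity compilations."""
    vals = curve.median if isinstance(curve, DiversityCurve) else np.asarray(
        curve, dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size < 2 or np.max(finite) == np.min(finite):
        raise ValueError("cannot normalize a constant (or near-empty) series")
    lo, hi = np.min(finite), np.max(finite)
    return (vals - lo) / (hi - lo)


def read_fossil_curve(path: str | Path) -> pd.DataFrame:
    """Read a digitized fossil-diversity curve CSV with columns
    (age, value[, source]); used for co-plotting only."""
    df = pd.read_csv(path, comment="#")
    missing = {"age", "value"} - set(df.columns)
    if missing:
        raise IOError(f"{path}: fossil curve lacks columns {sorted(missing)}")
    return df
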