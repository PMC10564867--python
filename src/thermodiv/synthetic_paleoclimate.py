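"""Synthetic paleoclimate forcing: gridded upper-ocean temperature fields and
paleogeography masks for the Ordovician time slices (490-430 Ma), plus ingest
of real GCM output from NetCDF.

The generator emulates the forcing a coupled ocean-atmosphere GCM would
provide: a zonal mean-annual temperature profile whose equator-pole gradient
steepens as the climate cools (polar amplification), drifting continental
blocks with fringing shallow shelves, and an optional seeded smooth
perturbation. Temperatures are mean-annual upper-ocean (0-100 m average)
values in degrees Celsius, clamped below at the freezing point of seawater
(-1.8 degC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "SEAWATER_FREEZING_C",
    "GridSpec",
    "ScenarioConfig",
    "ClimateField",
    "BlockTrack",
    "PaleogeographyTable",
    "ConfigurationError",
    "build_scenario",
    "zonal_profile",
    "generate_climate_field",
    "default_paleogeography",
    "read_gcm_field",
    "write_climate_field",
    "load_climate_field",
    "DEFAULT_AGES",
    "DEFAULT_TROPICAL_SST",
    "REGION_NAMES",
]

#: Freezing point of seawater (degC); hard lower bound for all temperatures.
SEAWATER_FREEZING_C = -1.8

#: Time slices, Ma, oldest first (10-Myr steps through the Ordovician).
DEFAULT_AGES: tuple[float, ...] = (490.0, 480.0, 470.0, 460.0, 450.0, 440.0, 430.0)

#: Tropical mean SST (degC) per time slice under the proxy-derived cooling
#: trajectory. The 490 and 430 Ma endpoints (45 and 30 degC) anchor the
#: trajectory; intermediate values are a smooth monotone interpolation.
DEFAULT_TROPICAL_SST: dict[float, float] = {
    490.0: 45.0,
    480.0: 42.5,
    470.0: 40.0,
    460.0: 37.0,
    450.0: 33.0,
    440.0: 31.0,
    430.0: 30.0,
}

REGION_NAMES: tuple[str, ...] = (
    "Gondwana", "Laurentia", "Baltica", "Siberia", "SouthChina",
)

_SCENARIO_NAMES = ("proxy-cooling", "constant-30", "constant-40", "custom")


class ConfigurationError(ValueError):
    """Raised for invalid scenario, grid, or paleogeography configuration."""


@dataclass(frozen=True)
class GridSpec:
    """Regular latitude-longitude grid, cell-center convention.

    Latitude centers run strictly increasing in (-90, 90); longitude centers
    in [0, 360). The default 64 x 128 grid emulates a GCM ocean resolution
    at reduced cost.
    """

    n_lat: int = 64
    n_lon: int = 128

    def __post_init__(self) -> None:
        if self.n_lat < 8 or self.n_lon < 8:
            raise ConfigurationError(
                f"grid must be at least 8 x 8, got {self.n_lat} x {self.n_lon}"
            )

    @property
    def latitudes(self) -> np.ndarray:
        return -90.0 + (np.arange(self.n_lat) + 0.5) * (180.0 / self.n_lat)

    @property
    def longitudes(self) -> np.ndarray:
        return (np.arange(self.n_lon) + 0.5) * (360.0 / self.n_lon)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """2-D (lat, lon) center coordinates, shape ``(n_lat, n_lon)``."""
        return np.meshgrid(self.latitudes, self.longitudes, indexing="ij")

    def area_weights(self) -> np.ndarray:
        """cos(latitude) weights broadcast to the grid shape."""
        w = np.cos(np.deg2rad(self.latitudes))
        return np.repeat(w[:, None], self.n_lon, axis=1)


@dataclass(frozen=True)
class ScenarioConfig:
    """A climate forcing trajectory.

    ``tropical_sst_by_age`` gives the tropical (equatorial) mean SST per time
    slice. The pole anchor and the shape exponent of the zonal profile are
    functions of the tropical SST, emulating polar amplification: hothouse
    states have a warm pole and a flat gradient, cool states a freezing pole
    and a steep gradient.

    Parameters
    ----------
    pole_sst : float
        Lower bound for the polar anchor temperature (degC); the cold-state
        pole value.
    polar_amplification : float
        Pole warming per degree of tropical warming above the 30 degC
        cool-state reference.
    profile_exponent : float
        Exponent of the cos(latitude) profile in the warmest (45 degC
        tropical) reference state.
    exponent_cooling_slope : float
        Increase of the profile exponent per degree of tropical cooling
        below 45 degC (gradient steepening).
    """

    name: str
    ages: tuple[float, ...]
    tropical_sst_by_age: Mapping[float, float]
    pole_sst: float = SEAWATER_FREEZING_C
    polar_amplification: float = 0.8
    profile_exponent: float = 1.0
    exponent_cooling_slope: float = 0.1

    def __post_init__(self) -> None:
        if not self.ages:
            raise ConfigurationError("scenario needs at least one age")
        for a in self.ages:
            if not 430.0 <= a <= 490.0:
                raise ConfigurationError(f"age {a} Ma outside [430, 490]")
            if a not in self.tropical_sst_by_age:
                raise ConfigurationError(f"no tropical SST configured for {a} Ma")
        if self.profile_exponent <= 0:
            raise ConfigurationError("profile_exponent must be positive")
        for a, t in self.tropical_sst_by_age.items():
            if t <= self.pole_sst:
                raise ConfigurationError(
                    f"tropical SST {t} at {a} Ma must exceed pole SST {self.pole_sst}"
                )

    def tropical_sst(self, age: float) -> float:
        try:
            return float(self.tropical_sst_by_age[age])
        except KeyError:
            raise ConfigurationError(
                f"age {age} Ma not configured for scenario {self.name!r}"
            ) from None

    def pole_anchor(self, age: float) -> float:
        """Polar anchor temperature (degC) for the given time slice."""
        trop = self.tropical_sst(age)
        return max(self.pole_sst, self.polar_amplification * (trop - 30.0))

    def exponent(self, age: float) -> float:
        """Zonal-profile exponent for the given time slice (>= 0.1)."""
        trop = self.tropical_sst(age)
        return max(0.1, self.profile_exponent
                   + self.exponent_cooling_slope * (45.0 - trop))


def build_scenario(name: str, ages: Sequence[float] | None = None) -> ScenarioConfig:
    """Build one of the named forcing scenarios.

    ``proxy-cooling`` follows the proxy-derived trajectory from 45 degC
    tropical SST at 490 Ma down to 30 degC at 430 Ma; ``constant-30`` and
    ``constant-40`` hold tropical SST fixed (sensitivity tests isolating
    continental drift). Ages not in the packaged table are linearly
    interpolated.
    """
    if name not in _SCENARIO_NAMES or name == "custom":
        raise ConfigurationError(
            f"unknown scenario {name!r}; expected one of "
            f"{', '.join(n for n in _SCENARIO_NAMES if n != 'custom')} "
            "(build a ScenarioConfig directly for custom trajectories)"
        )
    ages_t = tuple(float(a) for a in (ages if ages is not None else DEFAULT_AGES))
    if not ages_t:
        raise ConfigurationError("ages must be non-empty")
    if name == "proxy-cooling":
        table_ages = np.array(sorted(DEFAULT_TROPICAL_SST))
        table_sst = np.array([DEFAULT_TROPICAL_SST[a] for a in table_ages])
        sst = {a: float(np.interp(a, table_ages, table_sst)) for a in ages_t}
    else:
        const = 30.0 if name == "constant-30" else 40.0
        sst = {a: const for a in ages_t}
    return ScenarioConfig(name=name, ages=ages_t, tropical_sst_by_age=sst)


def zonal_profile(
    tropical_sst: float,
    pole_sst: float = SEAWATER_FREEZING_C,
    exponent: float = 1.0,
    latitude: float | np.ndarray = 0.0,
) -> float | np.ndarray:
    """Zonal mean-annual temperature at a latitude (degC).

    ``T(lat) = pole_sst + (tropical_sst - pole_sst) * cos(lat)**exponent``,
    clamped below at the seawater freezing point. Symmetric about the
    equator and non-increasing in ``|lat|``.
    """
    if exponent <= 0:
        raise ConfigurationError(f"exponent must be positive, got {exponent}")
    if tropical_sst <= pole_sst:
        raise ConfigurationError(
            f"tropical_sst {tropical_sst} must exceed pole_sst {pole_sst}"
        )
    lat = np.asarray(latitude, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    t = pole_sst + (tropical_sst - pole_sst) * np.cos(np.deg2rad(lat)) ** exponent
    out = np.maximum(t, SEAWATER_FREEZING_C)
    return float(out) if np.isscalar(latitude) else out


@dataclass(frozen=True)
class BlockTrack:
    """One continental block's drift track: per-age center and half-extents
    (degrees) of a rectangular cap, plus its shelf fringe width (degrees)."""

    name: str
    ages: tuple[float, ...]
    center_lat: tuple[float, ...]
    center_lon: tuple[float, ...]
    half_lat: tuple[float, ...]
    half_lon: tuple[float, ...]
    fringe_deg: float = 2.8125

    def bounds(self, age: float) -> tuple[float, float, float, float]:
        """(lat_min, lat_max, lon_min, lon_max) at ``age``, linearly
        interpolated between table ages (ages stored oldest-first)."""
        a = np.array(self.ages)[::-1]  # np.interp wants increasing x
        cla = float(np.interp(age, a, np.array(self.center_lat)[::-1]))
        clo = float(np.interp(age, a, np.array(self.center_lon)[::-1]))
        hla = float(np.interp(age, a, np.array(self.half_lat)[::-1]))
        hlo = float(np.interp(age, a, np.array(self.half_lon)[::-1]))
        return cla - hla, cla + hla, clo - hlo, clo + hlo


@dataclass(frozen=True)
class PaleogeographyTable:
    """Drift tracks for all continental blocks."""

    blocks: tuple[BlockTrack, ...]

    def block(self, name: str) -> BlockTrack:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(f"unknown block {name!r}")

    def rasterize(
        self, grid: GridSpec, age: float
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Land mask, shelf mask and region-code array at ``age``.

        Region codes: 0 = open ocean, i+1 = ``REGION_NAMES[i]``; a block's
        code covers its land cells and its fringing shelf. Overlapping land
        is an error; merging shelf fringes of neighbouring blocks are allowed
        (the first block in table order keeps the contested cells).
        """
        lat2, lon2 = grid.mesh()
        cell_lat = 180.0 / grid.n_lat
        rasters = []
        land = np.zeros(grid.shape, dtype=bool)
        for b in self.blocks:
            la0, la1, lo0, lo1 = b.bounds(age)
            cells = (lat2 >= la0) & (lat2 <= la1) & (lon2 >= lo0) & (lon2 <= lo1)
            if not cells.any():
                continue
            if (cells & land).any():
                raise ConfigurationError(
                    f"continental blocks overlap on the grid at {age} Ma "
                    f"(near {b.name})"
                )
            land |= cells
            n_fringe = max(1, int(round(b.fringe_deg / cell_lat)))
            rasters.append((b.name, cells, _dilate_wrap(cells, n_fringe)))
        shelf = np.zeros(grid.shape, dtype=bool)
        region = np.zeros(grid.shape, dtype=np.int8)
        for name, cells, footprint in rasters:
            shelf |= footprint & ~land
            code = REGION_NAMES.index(name) + 1 if name in REGION_NAMES else 0
            region[footprint & (region == 0)] = code
        return land, shelf, region


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _dilate_wrap(mask: np.ndarray, iterations: int) -> np.ndarray:
    """Binary dilation with a 4-neighbour cross, periodic in longitude."""
    pad = iterations
    wide = np.concatenate([mask[:, -pad:], mask, mask[:, :pad]], axis=1)
    wide = ndimage.binary_dilation(wide, structure=_CROSS, iterations=iterations)
    return wide[:, pad:-pad]


def default_paleogeography() -> PaleogeographyTable:
    """Schematic Ordovician drift tracks for the five continental blocks.

    Gondwana is a wide polar block with a broad shelf fringe, retreating
    poleward through the period; Baltica drifts northward monotonically from
    mid-southern latitudes toward the equator; Laurentia, Siberia and South
    China sit in the tropics and drift slowly north. Positions are schematic,
    not reconstructions.
    """
    def track(name, rects, fringe):
        ages, cla, clo, hla, hlo = [], [], [], [], []
        for age, (la0, la1, lo0, lo1) in rects.items():
            ages.append(age)
            cla.append((la0 + la1) / 2)
            clo.append((lo0 + lo1) / 2)
            hla.append((la1 - la0) / 2)
            hlo.append((lo1 - lo0) / 2)
        return BlockTrack(name, tuple(ages), tuple(cla), tuple(clo),
                          tuple(hla), tuple(hlo), fringe)

    gondwana = {
        490.0: (-78, -50, 15, 75), 480.0: (-80, -56, 15, 75),
        470.0: (-82, -59, 15, 75), 460.0: (-84, -60, 15, 75),
        450.0: (-86, -67, 15, 75), 440.0: (-86, -67.5, 15, 75),
        430.0: (-87, -68, 15, 75),
    }
    laurentia = {
        490.0: (-8, 12, 200, 245), 480.0: (-6, 14, 200, 245),
        470.0: (-4, 16, 200, 245), 460.0: (-2, 18, 200, 245),
        450.0: (0, 20, 200, 245), 440.0: (2, 22, 200, 245),
        430.0: (4, 24, 200, 245),
    }
    siberia = {
        490.0: (2, 22, 150, 185), 480.0: (3, 23, 150, 185),
        470.0: (5, 25, 150, 185), 460.0: (6.5, 26.5, 150, 185),
        450.0: (8, 28, 150, 185), 440.0: (9, 29, 150, 185),
        430.0: (10, 30, 150, 185),
    }
    south_china = {
        490.0: (-25, -5, 255, 285), 480.0: (-24, -4, 255, 285),
        470.0: (-23, -3, 255, 285), 460.0: (-21, -1, 255, 285),
        450.0: (-20, 0, 255, 285), 440.0: (-18, 1, 255, 285),
        430.0: (-16, 3, 255, 285),
    }
    baltica = {
        490.0: (-54, -40, 300, 330), 480.0: (-50, -36, 300, 330),
        470.0: (-46, -32, 300, 330), 460.0: (-42, -28, 300, 330),
        450.0: (-36, -23, 300, 330), 440.0: (-28, -16, 300, 330),
        430.0: (-20, -8, 300, 330),
    }
    return PaleogeographyTable(blocks=(
        track("Gondwana", gondwana, fringe=3 * 2.8125),
        track("Laurentia", laurentia, fringe=2.8125),
        track("Siberia", siberia, fringe=2.8125),
        track("SouthChina", south_china, fringe=2.8125),
        track("Baltica", baltica, fringe=2.8125),
    ))


@dataclass
class ClimateField:
    """One time slice: gridded mean-annual upper-100 m temperature plus
    land / shelf / region masks."""

    grid: GridSpec
    age: float
    temperature: np.ndarray
    land_mask: np.ndarray
    shelf_mask: np.ndarray
    region_codes: np.ndarray
    scenario: str = "custom"
    region_names: tuple[str, ...] = REGION_NAMES

    def __post_init__(self) -> None:
        for name in ("temperature", "land_mask", "shelf_mask", "region_codes"):
            arr = getattr(self, name)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
        if (self.shelf_mask & self.land_mask).any():
            raise ValueError("shelf_mask must be disjoint from land_mask")
        ocean_t = self.temperature[self.ocean_mask]
        if ocean_t.size and (np.min(ocean_t) < SEAWATER_FREEZING_C - 1e-9
                             or not np.all(np.isfinite(ocean_t))):
            raise ValueError("ocean temperatures must be finite and >= -1.8 degC")

    @property
    def ocean_mask(self) -> np.ndarray:
        return ~self.land_mask

    def region_mask(self, name: str) -> np.ndarray:
        """Boolean mask of cells labelled with a continental block's region."""
        if name not in self.region_names:
            raise KeyError(
                f"unknown region {name!r}; known: {', '.join(self.region_names)}"
            )
        return self.region_codes == (self.region_names.index(name) + 1)


def generate_climate_field(
    scenario: ScenarioConfig,
    age: float,
    grid: GridSpec | None = None,
    paleogeo: PaleogeographyTable | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
    noise_smoothing_cells: float = 2.0,
) -> ClimateField:
    """Generate the synthetic temperature field and masks for one time slice.

    The temperature is the scenario's zonal profile plus, when
    ``noise_sd > 0``, a seeded Gaussian-smoothed perturbation with the given
    standard deviation (degC), clamped at the seawater freezing point. The
    result is deterministic given ``(scenario, age, grid, seed)``.
    """
    if age not in scenario.ages:
        raise ConfigurationError(
            f"age {age} Ma not in scenario {scenario.name!r} ages {scenario.ages}"
        )
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    grid = grid or GridSpec()
    paleogeo = paleogeo or default_paleogeography()
    lat2, _ = grid.mesh()
    temp = zonal_profile(
        scenario.tropical_sst(age),
        scenario.pole_anchor(age),
        scenario.exponent(age),
        lat2,
    )
    if noise_sd > 0:
        rng = np.random.default_rng([int(seed), int(round(age * 10))])
        white = rng.standard_normal(grid.shape)
        smooth = ndimage.gaussian_filter(
            white, sigma=noise_smoothing_cells, mode=("reflect", "wrap")
        )
        smooth *= noise_sd / smooth.std()
        temp = np.maximum(temp + smooth, SEAWATER_FREEZING_C)
    land, shelf, region = paleogeo.rasterize(grid, age)
    return ClimateField(
        grid=grid, age=float(age), temperature=temp, land_mask=land,
        shelf_mask=shelf, region_codes=region, scenario=scenario.name,
    )


def tropical_band_mean(field: ClimateField, band_deg: float = 10.0) -> float:
    """cos(latitude)-weighted mean ocean temperature within ``|lat| <= band``."""
    lat2, _ = field.grid.mesh()
    sel = (np.abs(lat2) <= band_deg) & field.ocean_mask
    if not sel.any():
        raise ValueError("no ocean cells in the tropical band")
    w = field.grid.area_weights()[sel]
    return float(np.sum(field.temperature[sel] * w) / np.sum(w))


# ---------------------------------------------------------------------------
# NetCDF plumbing


def write_climate_field(field: ClimateField, path) -> None:
    """Export a ClimateField to NetCDF (classic format)."""
    import xarray as xr

    ds = xr.Dataset(
        {
            "temperature": (("lat", "lon"), field.temperature.astype("f8"),
                            {"units": "degC",
                             "long_name": "mean annual upper-100m ocean temperature"}),
            "land_mask": (("lat", "lon"), field.land_mask.astype("i1")),
            "shelf_mask": (("lat", "lon"), field.shelf_mask.astype("i1")),
            "region": (("lat", "lon"), field.region_codes.astype("i1"),
                       {"flag_values": list(range(len(field.region_names) + 1)),
                        "flag_meanings": "ocean " + " ".join(field.region_names)}),
        },
        coords={"lat": ("lat", field.grid.latitudes, {"units": "degrees_north"}),
                "lon": ("lon", field.grid.longitudes, {"units": "degrees_east"})},
        attrs={"age_ma": field.age, "scenario": field.scenario},
    )
    ds.to_netcdf(path, engine="scipy")


def load_climate_field(path) -> ClimateField:
    """Re-read a ClimateField written by :func:`write_climate_field`."""
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        n_lat, n_lon = ds["temperature"].shape
        grid = GridSpec(n_lat=n_lat, n_lon=n_lon)
        return ClimateField(
            grid=grid,
            age=float(ds.attrs["age_ma"]),
            temperature=np.asarray(ds["temperature"].values, dtype=float),
            land_mask=np.asarray(ds["land_mask"].values, dtype=bool),
            shelf_mask=np.asarray(ds["shelf_mask"].values, dtype=bool),
            region_codes=np.asarray(ds["region"].values, dtype=np.int8),
            scenario=str(ds.attrs.get("scenario", "custom")),
        )


_CELSIUS_UNITS = {"degc", "deg_c", "celsius", "degrees_celsius", "c", "°c"}
_KELVIN_UNITS = {"k", "kelvin", "degk"}


def read_gcm_field(
    path,
    temp_var: str = "temp",
    bathy_var: str = "bathymetry",
    depth_average_m: float = 100.0,
    shelf_depth_m: float = 250.0,
    age: float = 0.0,
    scenario: str = "ingested",
) -> ClimateField:
    """Ingest a GCM temperature field from a CF-style NetCDF file.

    The temperature variable may be 2-D ``(lat, lon)`` or 3-D
    ``(depth, lat, lon)``; 3-D input is averaged over the levels whose center
    depth is within ``depth_average_m``, weighted by layer thickness (layer
    interfaces at midpoints between level centers, top interface at 0).
    Bathymetry (positive depths, meters) defines the land and shelf masks:
    ocean where depth > 0, shelf where depth <= ``shelf_depth_m``.
    """
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        if temp_var not in ds:
            raise IOError(f"{path}: no variable {temp_var!r} "
                          f"(found: {', '.join(ds.data_vars)})")
        da = ds[temp_var]
        temp = _to_celsius(np.asarray(da.values, dtype=float),
                           str(da.attrs.get("units", "")), temp_var)
        if temp.ndim == 3:
            depth_dim = da.dims[0]
            depths = np.asarray(ds[depth_dim].values, dtype=float)
            temp = _depth_average(temp, depths, depth_average_m)
        elif temp.ndim != 2:
            raise IOError(f"{temp_var!r} must be (lat, lon) or (depth, lat, lon), "
                          f"got dims {da.dims}")
        n_lat, n_lon = temp.shape
        grid = GridSpec(n_lat=n_lat, n_lon=n_lon)
        if bathy_var in ds:
            bathy = np.asarray(ds[bathy_var].values, dtype=float)
            if bathy.shape != temp.shape:
                raise IOError(
                    f"bathymetry grid {bathy.shape} inconsistent with "
                    f"temperature grid {temp.shape}"
                )
            ocean = np.isfinite(bathy) & (bathy > 0)
            shelf = ocean & (bathy <= shelf_depth_m)
        else:
            ocean = np.isfinite(temp)
            shelf = ocean.copy()
        land = ~ocean
        temp = np.where(ocean, np.maximum(temp, SEAWATER_FREEZING_C), np.nan)
        temp = np.where(land, SEAWATER_FREEZING_C, temp)  # placeholder on land
        return ClimateField(
            grid=grid, age=float(age), temperature=temp, land_mask=land,
            shelf_mask=shelf, region_codes=np.zeros(grid.shape, dtype=np.int8),
            scenario=scenario,
        )


def _to_celsius(values: np.ndarray, units: str, var: str) -> np.ndarray:
    u = units.strip().lower()
    if u in _CELSIUS_UNITS or u == "":
        return values
    if u in _KELVIN_UNITS:
        return values - 273.15
    raise IOError(f"variable {var!r} has unknown temperature units {units!r}")


def _depth_average(temp3d: np.ndarray, depths: np.ndarray, max_depth: float
                   ) -> np.ndarray:
    """Thickness-weighted vertical mean over levels with center depth within
    ``max_depth``. Interfaces at midpoints between centers; top interface 0;
    the bottom layer extends symmetrically below its center."""
    order = np.argsort(depths)
    depths = depths[order]
    temp3d = temp3d[order]
    sel = depths <= max_depth
    if not sel.any():
        raise IOError(
            f"no vertical levels within 0-{max_depth} m "
            f"(shallowest level at {depths.min():g} m)"
        )
    mids = 0.5 * (depths[:-1] + depths[1:])
    upper = np.concatenate([[0.0], mids])
    lower = np.concatenate([mids, [depths[-1] + (depths[-1] - upper[-1])]])
    thick = (lower - upper)[sel]
    return np.tensordot(thick, temp3d[sel], axes=(0, 0)) / thick.sum()
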