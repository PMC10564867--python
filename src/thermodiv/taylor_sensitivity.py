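"""Sensitivity of biodiversity patterns to the niche pool's thermal ceiling,
summarized with Taylor-diagram statistics.

The sweep regenerates the niche pool for a range of upper thermal limits
(t_max), computes the richness pattern each pool produces under a warm
climate (tropical SST ca. 40 degC), and compares it against a reference
pattern: the standard pool (t_max = 44 degC) under a cool climate (tropical
SST ca. 30 degC), both on the same fixed mid-Ordovician (460 Ma) geography.
The closer a sweep member sits to the reference on the Taylor diagram, the
weaker the impact of climate cooling on biodiversity under that thermal
ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .niche_model import NichePoolSpec, generate_niche_pool, sample_ensemble
from .richness_engine import DomainMaskSpec, RichnessMap, richness_map
from .synthetic_paleoclimate import (
    GridSpec,
    PaleogeographyTable,
    build_scenario,
    default_paleogeography,
    generate_climate_field,
)

__all__ = [
    "TaylorStats",
    "SweepSpec",
    "DegenerateFieldError",
    "taylor_statistics",
    "tmax_sweep",
    "taylor_diagram_coordinates",
]

#: Sweep grid anchored at the four named values 50, 65, 68, 78 degC,
#: evenly filled to ten members.
DEFAULT_TMAX_VALUES: tuple[float, ...] = (50., 53., 56., 59., 62.,
                                          65., 68., 71., 74., 78.)


class DegenerateFieldError(ValueError):
    """A compared field has zero variance: correlation undefined."""


@dataclass(frozen=True)
class TaylorStats:
    """Pattern-similarity statistics between a simulated and a reference
    richness map over their jointly valid cells.

    The centered RMSD, the two (population) standard deviations and the
    Pearson correlation satisfy the law-of-cosines identity
    ``crmsd^2 = sigma_sim^2 + sigma_ref^2 - 2 sigma_sim sigma_ref r``.
    The mean difference (bias) is reported separately; it does not enter the
    diagram geometry.
    """

    r: float
    centered_rmsd: float
    sigma_sim: float
    sigma_ref: float
    bias: float
    n_cells: int

    def identity_residual(self) -> float:
        """Relative residual of the law-of-cosines identity."""
        lhs = self.centered_rmsd ** 2
        rhs = (self.sigma_sim ** 2 + self.sigma_ref ** 2
               - 2 * self.sigma_sim * self.sigma_ref * self.r)
        scale = max(lhs, rhs, 1e-300)
        return abs(lhs - rhs) / scale


@dataclass(frozen=True)
class SweepSpec:
    """Configuration of the thermal-ceiling sweep."""

    t_max_values: tuple[float, ...] = DEFAULT_TMAX_VALUES
    reference_t_max: float = 44.0
    warm_scenario: str = "constant-40"
    cool_scenario: str = "constant-30"
    age: float = 460.0

    def __post_init__(self) -> None:
        if not self.t_max_values:
            raise ValueError("sweep needs at least one t_max value")
        bad = [t for t in self.t_max_values if t <= self.reference_t_max]
        if bad:
            raise ValueError(
                f"sweep t_max values must exceed the reference "
                f"{self.reference_t_max}: {bad}"
            )


def taylor_statistics(sim_map: RichnessMap | np.ndarray,
                      ref_map: RichnessMap | np.ndarray) -> TaylorStats:
    """Pearson correlation, population standard deviations, centered pattern
    RMSD and bias between two richness maps (or plain value arrays).

    Maps must share grid shape; statistics run over jointly valid cells.
    """
    sim, ref = _joint_values(sim_map, ref_map)
    if sim.size < 3:
        raise ValueError(f"need >= 3 jointly valid cells, got {sim.size}")
    s_mean, r_mean = sim.mean(), ref.mean()
    s_anom, r_anom = sim - s_mean, ref - r_mean
    sigma_sim = float(np.sqrt(np.mean(s_anom ** 2)))
    sigma_ref = float(np.sqrt(np.mean(r_anom ** 2)))
    if sigma_sim == 0.0 or sigma_ref == 0.0:
        raise DegenerateFieldError(
            "zero variance in "
            + ("simulated" if sigma_sim == 0.0 else "reference")
            + " field: correlation undefined"
        )
    r = float(np.mean(s_anom * r_anom) / (sigma_sim * sigma_ref))
    crmsd = float(np.sqrt(np.mean((s_anom - r_anom) ** 2)))
    return TaylorStats(r=r, centered_rmsd=crmsd, sigma_sim=sigma_sim,
                       sigma_ref=sigma_ref, bias=float(s_mean - r_mean),
                       n_cells=int(sim.size))


def _joint_values(sim, ref) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(sim, RichnessMap) and isinstance(ref, RichnessMap):
        if sim.grid.shape != ref.grid.shape:
            raise ValueError("maps are on different grids")
        joint = sim.valid_mask & ref.valid_mask
        return sim.richness[joint], ref.richness[joint]
    sim = np.asarray(sim, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if sim.shape != ref.shape:
        raise ValueError("value arrays differ in length")
    ok = np.isfinite(sim) & np.isfinite(ref)
    return sim[ok], ref[ok]


def tmax_sweep(
    sweep: SweepSpec | None = None,
    n_species: int = 10_000,
    n_reps: int = 100,
    seed: int = 0,
    grid: GridSpec | None = None,
    paleogeo: PaleogeographyTable | None = None,
    mask_spec: DomainMaskSpec | None = None,
    pool_spec: NichePoolSpec | None = None,
) -> pd.DataFrame:
    """Run the thermal-ceiling sweep and return one row per t_max.

    For each sweep value the pool is regenerated with that upper limit (same
    lower bound, minimum breadth and grid increment; the maximum breadth
    extends to the new span), the ensemble is resampled under the same seed
    policy, richness is computed under the warm field, and the map is
    compared to the cool-climate reference. The reference row (t_max of the
    reference pool, compared to itself, r = 1) is included.
    """
    sweep = sweep or SweepSpec()
    grid = grid or GridSpec()
    paleogeo = paleogeo or default_paleogeography()
    base = pool_spec or NichePoolSpec(t_max=sweep.reference_t_max)

    warm = generate_climate_field(
        build_scenario(sweep.warm_scenario, [sweep.age]), sweep.age,
        grid=grid, paleogeo=paleogeo, noise_sd=0.0, seed=seed)
    cool = generate_climate_field(
        build_scenario(sweep.cool_scenario, [sweep.age]), sweep.age,
        grid=grid, paleogeo=paleogeo, noise_sd=0.0, seed=seed)

    def run(t_max: float, field) -> RichnessMap:
        try:
            spec = NichePoolSpec(
                t_min=base.t_min, t_max=t_max, breadth_min=base.breadth_min,
                breadth_max=None, grid_increment=base.grid_increment)
            ens = sample_ensemble(generate_niche_pool(spec),
                                  n_species=n_species, n_reps=n_reps, seed=seed)
            return richness_map(ens, field, mask_spec)
        except Exception as exc:
            raise RuntimeError(f"sweep member t_max={t_max} failed: {exc}") from exc

    ref = run(sweep.reference_t_max, cool)
    rows = []
    for t_max, fld in [(sweep.reference_t_max, None)] + [
            (t, warm) for t in sweep.t_max_values]:
        stats = taylor_statistics(ref if fld is None else run(t_max, fld), ref)
        rows.append({
            "t_max": t_max, "r": stats.r, "centered_rmsd": stats.centered_rmsd,
            "sigma_sim": stats.sigma_sim, "sigma_ref": stats.sigma_ref,
            "bias": stats.bias, "is_reference": fld is None, "seed": seed,
        })
    return pd.DataFrame(rows)


def taylor_diagram_coordinates(stats: TaylorStats) -> tuple[float, float]:
    """Polar Taylor-diagram coordinates ``(radial, angle)``.

    radial = sigma_sim / sigma_ref, angle = arccos(r) in radians; the
    Euclidean distance from the point to the reference at (1, 0) equals
    ``centered_rmsd / sigma_ref``.
    """
    if stats.sigma_ref <= 0:
        raise ValueError("sigma_ref must be positive")
    if not -1.0 <= stats.r <= 1.0:
        raise ValueError(f"correlation {stats.r} outside [-1, 1]")
    return stats.sigma_sim / stats.sigma_ref, math.acos(stats.r)


def plot_taylor_diagram(sweep_table: pd.DataFrame, path=None):
    """Optional polar rendering of a sweep table (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="polar")
    ax.set_thetamin(0)
    ax.set_thetamax(180)
    for _, row in sweep_table.iterrows():
        radial = row["sigma_sim"] / row["sigma_ref"]
        angle = math.acos(np.clip(row["r"], -1, 1))
        if row.get("is_reference", False):
            ax.plot([angle], [radial], "r*", markersize=12)
        else:
            ax.annotate(f"{row['t_max']:.0f}", (angle, radial), fontsize=8)
            ax.plot([angle], [radial], "ko", markersize=3)
    ax.set_title("Pattern similarity vs. thermal ceiling")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
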