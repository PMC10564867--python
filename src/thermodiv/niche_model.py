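"""Thermal-niche pool enumeration and pseudo-species ensemble sampling.

A pseudo-species is defined solely by its thermal tolerance interval
``[t_low, t_high]`` (its niche, sensu Hutchinson). The pool enumerates every
niche on a regular grid of positions and breadths between the freezing point
of seawater (t_min = -1.8 degC) and the upper thermal limit for metazoan
reproduction (t_max = 44 degC by default, overridable for sensitivity
sweeps). Niches are uniformly distributed along the temperature axis; no
distributional skew is supported, consistent with competitive exclusion.

Monte-Carlo ensembles draw a fixed number of pseudo-species (default 10,000)
without replacement from the pool, repeated (default 100 times); biodiversity
statistics average over the repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_paleoclimate import SEAWATER_FREEZING_C, ConfigurationError

__all__ = [
    "ThermalNiche",
    "NichePoolSpec",
    "NichePool",
    "Ensemble",
    "pool_size",
    "generate_niche_pool",
    "sample_ensemble",
    "is_present",
]

_GRID_TOL = 1e-9


@dataclass(frozen=True)
class ThermalNiche:
    """One pseudo-species' tolerance interval on the temperature axis (degC).

    Both bounds are inclusive: the species is present wherever
    ``t_low <= T <= t_high``.
    """

    t_low: float
    t_high: float

    @property
    def breadth(self) -> float:
        """Niche breadth ``n = t_high - t_low`` (degC): stenothermy (small n)
        to eurythermy (large n)."""
        return self.t_high - self.t_low


@dataclass(frozen=True)
class NichePoolSpec:
    """Enumeration grid for the niche pool.

    Parameters
    ----------
    t_min, t_max : float
        Temperature bounds of the pool (degC). Defaults -1.8 (seawater
        freezing) and 44 (modern upper limit for metazoan reproduction).
    breadth_min, breadth_max : float
        Range of niche breadths (degC). ``breadth_max`` defaults to the full
        span ``t_max - t_min`` (the universal eurythermic species).
    grid_increment : float
        Step (degC) applied to both niche position and breadth; default 0.1.
    """

    t_min: float = SEAWATER_FREEZING_C
    t_max: float = 44.0
    breadth_min: float = 1.0
    breadth_max: float | None = None
    grid_increment: float = 0.1

    def __post_init__(self) -> None:
        if self.t_min >= self.t_max:
            raise ConfigurationError("t_min must be < t_max")
        if self.grid_increment <= 0:
            raise ConfigurationError("grid_increment must be positive")
        bmax = self.effective_breadth_max
        if not (0 < self.breadth_min <= bmax + _GRID_TOL
                and bmax <= self.span + _GRID_TOL):
            raise ConfigurationError(
                f"need 0 < breadth_min <= breadth_max <= {self.span}, got "
                f"[{self.breadth_min}, {bmax}]"
            )

    @property
    def span(self) -> float:
        return self.t_max - self.t_min

    @property
    def effective_breadth_max(self) -> float:
        return self.span if self.breadth_max is None else self.breadth_max


def _n_steps(length: float, step: float) -> int:
    """Number of grid points in [0, length] at spacing ``step`` (inclusive,
    with tolerance for floating-point grid rounding); 0 if length < 0."""
    if length < -_GRID_TOL:
        return 0
    return int(np.floor(length / step + _GRID_TOL)) + 1


def pool_size(spec: NichePoolSpec) -> int:
    """Closed-form niche count for a spec: the triangular sum over breadths
    of the number of admissible positions per breadth."""
    d = spec.grid_increment
    n_b = _n_steps(spec.effective_breadth_max - spec.breadth_min, d)
    breadths = spec.breadth_min + d * np.arange(n_b)
    lengths = spec.span - breadths
    counts = np.floor(lengths / d + _GRID_TOL).astype(np.int64) + 1
    return int(counts[lengths >= -_GRID_TOL].sum())


@dataclass(frozen=True)
class NichePool:
    """The enumerated niche pool.

    ``t_low``/``t_high`` are parallel arrays in a deterministic order:
    ascending breadth, then ascending lower bound, so index-based ensemble
    draws are reproducible across platforms.
    """

    spec: NichePoolSpec
    t_low: np.ndarray
    t_high: np.ndarray

    def __len__(self) -> int:
        return self.t_low.size

    @property
    def breadth(self) -> np.ndarray:
        return self.t_high - self.t_low

    def niche(self, index: int) -> ThermalNiche:
        return ThermalNiche(float(self.t_low[index]), float(self.t_high[index]))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "index": np.arange(len(self)),
            "t_low": self.t_low,
            "t_high": self.t_high,
            "breadth": self.breadth,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, spec: NichePoolSpec | None = None
                 ) -> "NichePool":
        df = pd.read_csv(path)
        return cls(spec=spec or NichePoolSpec(),
                   t_low=df["t_low"].to_numpy(float),
                   t_high=df["t_high"].to_numpy(float))


def generate_niche_pool(spec: NichePoolSpec | None = None) -> NichePool:
    """Enumerate all niches on the spec's regular grid.

    Every ``(t_low, breadth)`` pair with ``t_low`` on the position grid,
    breadth on the breadth grid and ``t_low + breadth <= t_max`` (inclusive
    up to grid-rounding tolerance) yields one niche. The count equals
    :func:`pool_size`.
    """
    spec = spec or NichePoolSpec()
    d = spec.grid_increment
    n_b = _n_steps(spec.effective_breadth_max - spec.breadth_min, d)
    lows, highs = [], []
    for j in range(n_b):
        b = spec.breadth_min + d * j
        n_pos = _n_steps(spec.span - b, d)
        if n_pos == 0:
            continue
        tl = spec.t_min + d * np.arange(n_pos)
        lows.append(tl)
        highs.append(tl + b)
    if not lows:
        raise ConfigurationError(f"spec admits no niche: {spec}")
    return NichePool(
        spec=spec,
        t_low=np.concatenate(lows),
        t_high=np.minimum(np.concatenate(highs), spec.t_max),
    )


@dataclass(frozen=True)
class Ensemble:
    """Repeated random draws of pseudo-species from a pool.

    ``draws`` has shape ``(n_reps, n_species)``; each row holds distinct pool
    indices (sampling without replacement), reproducible from ``seed`` via
    per-draw spawned substreams.
    """

    pool: NichePool
    n_species: int
    n_reps: int
    seed: int
    draws: np.ndarray

    def draw_bounds(self, rep: int) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (t_low, t_high) arrays of one draw, for bound counting."""
        idx = self.draws[rep]
        return np.sort(self.pool.t_low[idx]), np.sort(self.pool.t_high[idx])

    def to_csv(self, path: str | Path) -> None:
        """Compact index-list export: one row per repetition."""
        with open(path, "w") as fh:
            fh.write(f"# n_species={self.n_species} n_reps={self.n_reps} "
                     f"seed={self.seed} pool_size={len(self.pool)}\n")
            for rep in range(self.n_reps):
                fh.write(",".join(map(str, self.draws[rep])) + "\n")


def sample_ensemble(
    pool: NichePool,
    n_species: int = 10_000,
    n_reps: int = 100,
    seed: int = 0,
) -> Ensemble:
    """Draw ``n_reps`` independent samples of ``n_species`` distinct niches."""
    if n_species > len(pool):
        raise ValueError(
            f"cannot draw {n_species} species from a pool of {len(pool)}"
        )
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    draws = np.empty((n_reps, n_species), dtype=np.int64)
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        draws[rep] = rng.choice(len(pool), size=n_species, replace=False)
    return Ensemble(pool=pool, n_species=n_species, n_reps=n_reps,
                    seed=seed, draws=draws)


def is_present(niche: ThermalNiche, temperature: float) -> bool:
    """Whether a pseudo-species occurs at a temperature (closed interval:
    ties at either bound count as presence)."""
    if not np.isfinite(temperature):
        raise ValueError("temperature must be finite")
    return bool(niche.t_low <= temperature <= niche.t_high)
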