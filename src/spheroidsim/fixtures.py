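"""Deterministic synthetic spheroids and nutrient fields with known ground
truth, so the quantification layer can be exercised (and benchmarked)
without running full simulations.

The annulus fixture mirrors the three-region structure of a mature
spheroid: a colour-mixed proliferative rim, a red-only arrested shell and
an empty necrotic core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
import pandas as pd

from .agents import LETTER_PHASE, Phase
from .nutrient import Grid, NutrientField

__all__ = [
    "AnnulusFixtureSpec",
    "SyntheticPopulation",
    "make_annulus_spheroid",
    "make_radial_field",
    "population_to_table",
    "population_from_table",
]

#: reference cell density of the initial in-silico spheroid [cells/um^3]
#: (30000 agents in a 245-um ball)
REFERENCE_DENSITY = 30_000 / (4.0 / 3.0 * np.pi * 245.0 ** 3)


@dataclass(frozen=True)
class AnnulusFixtureSpec:
    """Three-region synthetic spheroid with known radii.

    ``0 <= r_necrotic <= r_arrested < r_outer`` [um]; the outer region
    [r_arrested, r_outer) is colour-mixed with the given red/yellow/green
    fractions, the middle region [r_necrotic, r_arrested) is red-only and
    flagged as nutrient-starved, and the core r < r_necrotic is empty.
    """

    r_necrotic: float = 50.0
    r_arrested: float = 100.0
    r_outer: float = 200.0
    density_outer: float = 2.0 * REFERENCE_DENSITY
    density_middle: float = 2.0 * REFERENCE_DENSITY
    mix: Tuple[float, float, float] = (0.60, 0.10, 0.30)
    c_outer: float = 1.0
    c_middle: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.r_necrotic <= self.r_arrested < self.r_outer):
            raise ValueError("need 0 <= r_necrotic <= r_arrested < r_outer")
        if abs(sum(self.mix) - 1.0) > 1e-9 or min(self.mix) < 0:
            raise ValueError("mix fractions must be non-negative and sum to 1")


@dataclass
class SyntheticPopulation:
    """Array-backed agent collection (duck-compatible with the analysis
    layer's use of SimulationState views)."""

    positions: np.ndarray
    phases: np.ndarray
    local_c: np.ndarray
    dead_positions: np.ndarray = field(
        default_factory=lambda: np.empty((0, 3)))
    time: float = 0.0
    field: Optional[NutrientField] = None


def _sample_shell(rng: np.random.Generator, n: int, r_in: float,
                  r_out: float) -> np.ndarray:
    """Volume-uniform points in the spherical shell [r_in, r_out)."""
    u = rng.random(n)
    r = (r_in ** 3 + u * (r_out ** 3 - r_in ** 3)) ** (1.0 / 3.0)
    cos_t = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    return np.column_stack([r * sin_t * np.cos(phi),
                            r * sin_t * np.sin(phi), r * cos_t])


def make_annulus_spheroid(spec: AnnulusFixtureSpec) -> SyntheticPopulation:
    """Generate the three-region population; bit-reproducible from the spec."""
    rng = np.random.default_rng(spec.seed)

    def shell_count(r_in, r_out, density):
        vol = 4.0 / 3.0 * np.pi * (r_out ** 3 - r_in ** 3)
        return int(round(vol * density))

    n_out = shell_count(spec.r_arrested, spec.r_outer, spec.density_outer)
    n_mid = shell_count(spec.r_necrotic, spec.r_arrested, spec.density_middle)

    pos_out = _sample_shell(rng, n_out, spec.r_arrested, spec.r_outer)
    phases_out = rng.choice([Phase.RED, Phase.YELLOW, Phase.GREEN],
                            size=n_out, p=list(spec.mix)).astype(np.int8)
    pos_mid = _sample_shell(rng, n_mid, spec.r_necrotic, spec.r_arrested)
    phases_mid = np.full(n_mid, Phase.RED, dtype=np.int8)

    return SyntheticPopulation(
        positions=np.vstack([pos_out, pos_mid]) if n_out + n_mid else np.empty((0, 3)),
        phases=np.concatenate([phases_out, phases_mid]),
        local_c=np.concatenate([np.full(n_out, spec.c_outer),
                                np.full(n_mid, spec.c_middle)]),
    )


def make_radial_field(profile: Callable[[np.ndarray], np.ndarray],
                      grid: Grid) -> NutrientField:
    """Nodal field ``c(x) = profile(|x|)``; profile values must lie in [0, 1]."""
    x = grid.nodes
    r = np.sqrt(x[:, None, None] ** 2 + x[None, :, None] ** 2
                + x[None, None, :] ** 2)
    vals = np.asarray(profile(r), dtype=float)
    if vals.shape != r.shape:
        vals = np.broadcast_to(vals, r.shape).copy()
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError("profile values must lie in [0, 1]")
    return NutrientField(grid, vals)


def population_to_table(pop: SyntheticPopulation,
                        time: float = 0.0) -> pd.DataFrame:
    """Standard agent table: id, time_h, x_um, y_um, z_um, phase, status."""
    n = len(pop.positions)
    nd = len(pop.dead_positions)
    letters = np.array(["R", "Y", "G"])
    live = pd.DataFrame(dict(
        id=np.arange(n), time_h=time,
        x_um=pop.positions[:, 0], y_um=pop.positions[:, 1],
        z_um=pop.positions[:, 2],
        phase=letters[np.asarray(pop.phases, dtype=int)], status="alive"))
    if nd:
        dead = pd.DataFrame(dict(
            id=np.arange(n, n + nd), time_h=time,
            x_um=pop.dead_positions[:, 0], y_um=pop.dead_positions[:, 1],
            z_um=pop.dead_positions[:, 2], phase="R", status="dead"))
        live = pd.concat([live, dead], ignore_index=True)
    return live


def population_from_table(table: pd.DataFrame) -> SyntheticPopulation:
    alive = table[table["status"] == "alive"]
    dead = table[table["status"] == "dead"]
    return SyntheticPopulation(
        positions=alive[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
        phases=alive["phase"].map(lambda s: int(LETTER_PHASE[s])).to_numpy(np.int8),
        local_c=np.ones(len(alive)),
        dead_positions=dead[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
        time=float(table["time_h"].iloc[0]) if len(table) else 0.0,
    )
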