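"""Agent state, FUCCI phase logic and the nutrient-dependent rate laws.

A cell is a point agent with a position, a FUCCI phase (red = G1,
yellow = early S, green = S/G2/M) and a cached local nutrient value,
sampled from the most recent quasi-steady field. Five per-capita rates
govern the dynamics:

* red -> yellow (cycle entry): ``Rr_max * c^eta1 / (c_a^eta1 + c^eta1)``,
  an increasing Hill function of nutrient — cells commit to the cycle
  only where nutrient is plentiful;
* yellow -> green: constant ``Ry``;
* green -> red (mitosis): constant ``Rg``; the parent is replaced by two
  red daughters dispersed ``sigma`` apart;
* migration: ``(m_max - m_min) * c^eta2 / (c_m^eta2 + c^eta2) + m_min``,
  a step of length ``mu`` in a uniformly random direction;
* death: ``(d_max - d_min) * (1 - c^eta3 / (c_d^eta3 + c^eta3)) + d_min``,
  decreasing in nutrient with a sharp rise below ``c_d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Tuple

import numpy as np

from .params import ModelParameters

__all__ = [
    "Phase",
    "AgentState",
    "DeathRecord",
    "BoundaryBreachError",
    "rate_red_to_yellow",
    "rate_yellow_to_green",
    "rate_green_to_red",
    "rate_migration",
    "rate_death",
    "random_unit_direction",
    "apply_migration",
    "apply_mitosis",
    "is_arrested",
]


class Phase(IntEnum):
    """FUCCI cell-cycle phase (the integer codes are used in agent arrays)."""

    RED = 0      # G1
    YELLOW = 1   # early S
    GREEN = 2    # S/G2/M


PHASE_LETTER = {Phase.RED: "R", Phase.YELLOW: "Y", Phase.GREEN: "G"}
LETTER_PHASE = {v: k for k, v in PHASE_LETTER.items()}


class BoundaryBreachError(RuntimeError):
    """An agent left the cubic domain.

    The domain side L is meant to be chosen large enough that this never
    happens; a breach therefore aborts the simulation with a diagnostic
    rather than clamping or reflecting the position.
    """


@dataclass
class AgentState:
    """One cell: position [um] relative to the domain centre, phase, and the
    nutrient concentration cached at the last field update."""

    position: np.ndarray
    phase: Phase
    cached_c: float = 1.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class DeathRecord:
    """Location [um] and time [h] of one death event."""

    position: np.ndarray
    time: float


def _check_c(c):
    c = np.asarray(c, dtype=float)
    if np.any(c < 0.0) or np.any(c > 1.0):
        raise ValueError("nutrient concentration must lie in [0, 1]")
    return c


def _hill(c, K: float, eta: float):
    ce = c ** eta
    return ce / (K ** eta + ce)


def rate_red_to_yellow(c, p: ModelParameters):
    """Nutrient-dependent G1 -> eS entry rate [1/h]; zero at c = 0 and
    half-maximal at the arrest concentration ``c_a``."""
    return p.Rr_max * _hill(_check_c(c), p.c_a, p.eta1)


def rate_yellow_to_green(p: ModelParameters) -> float:
    """Constant eS -> S/G2/M rate Ry [1/h]."""
    return p.Ry


def rate_green_to_red(p: ModelParameters) -> float:
    """Constant S/G2/M -> G1 (mitosis) rate Rg [1/h]."""
    return p.Rg


def rate_migration(c, p: ModelParameters):
    """Migration rate [1/h], rising from ``m_min`` at c = 0 towards
    ``m_max``, half-way at ``c_m``."""
    return (p.m_max - p.m_min) * _hill(_check_c(c), p.c_m, p.eta2) + p.m_min


def rate_death(c, p: ModelParameters):
    """Death rate [1/h], falling from ``d_max`` at c = 0 towards ``d_min``,
    half-way at ``c_d``."""
    return (p.d_max - p.d_min) * (1.0 - _hill(_check_c(c), p.c_d, p.eta3)) + p.d_min


def random_unit_direction(rng: np.random.Generator, size: int | None = None):
    """Unit vector(s) drawn uniformly on the sphere.

    The azimuthal angle is uniform on [0, 2*pi) and cos(theta) uniform on
    [-1, 1], so directions carry no polar bias. With ``size=None`` a single
    3-vector is returned, otherwise an array of shape ``(size, 3)``.
    """
    n = 1 if size is None else size
    cos_t = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    out = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    return out[0] if size is None else out


def _check_inside(position: np.ndarray, p: ModelParameters) -> None:
    if np.any(np.abs(position) >= p.L / 2.0):
        raise BoundaryBreachError(
            f"agent at {np.asarray(position)} left the domain [-L/2, L/2]^3 "
            f"with L = {p.L}; enlarge L")


def apply_migration(a: AgentState, direction: np.ndarray,
                    p: ModelParameters) -> AgentState:
    """Displace the agent a distance ``mu`` along *direction* (unit vector);
    phase and cached nutrient are unchanged."""
    new_pos = a.position + p.mu * np.asarray(direction, dtype=float)
    _check_inside(new_pos, p)
    return AgentState(new_pos, a.phase, a.cached_c)


def apply_mitosis(a: AgentState, direction: np.ndarray, p: ModelParameters,
                  nutrient_field=None) -> Tuple[AgentState, AgentState]:
    """Replace a green agent by two red daughters at ``position +- sigma/2 *
    direction``.

    Each daughter samples its cached nutrient from *nutrient_field* (the
    field frozen at the last update) at its own birth position; if no field
    is given the parent's cached value is inherited.
    """
    if a.phase != Phase.GREEN:
        raise ValueError(f"mitosis requires a GREEN agent, got {a.phase!r}")
    d = np.asarray(direction, dtype=float)
    pos1 = a.position + 0.5 * p.sigma * d
    pos2 = a.position - 0.5 * p.sigma * d
    _check_inside(pos1, p)
    _check_inside(pos2, p)
    if nutrient_field is not None:
        from .nutrient import sample_at
        c1, c2 = sample_at(np.vstack([pos1, pos2]), nutrient_field)
    else:
        c1 = c2 = a.cached_c
    return AgentState(pos1, Phase.RED, float(c1)), AgentState(pos2, Phase.RED, float(c2))


def is_arrested(a, p: ModelParameters):
    """True for red (G1) agents whose local nutrient is below the arrest
    concentration ``c_a``.

    The model has no explicit arrested state; a red cell is called arrested
    when its cycle-entry rate has fallen below half-maximum, i.e. when its
    cached nutrient is below ``c_a``. Accepts a single :class:`AgentState`
    or ``(phases, cached_c)`` arrays.
    """
    if isinstance(a, AgentState):
        return a.phase == Phase.RED and a.cached_c < p.c_a
    phases, cached_c = a
    return (np.asarray(phases) == int(Phase.RED)) & (np.asarray(cached_c) < p.c_a)
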