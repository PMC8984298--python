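"""Spheroid initialization and the hybrid simulation loop.

A run alternates exact Gillespie event resolution over windows of duration
``t_star`` with a density re-bin and a warm-started quasi-steady nutrient
solve; after each solve every living agent re-samples its local nutrient
by trilinear interpolation and keeps that value frozen for the next window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import _kernel
from .agents import BoundaryBreachError, Phase
from .nutrient import (Grid, NutrientField, QuasiSteadySolver, bin_density,
                       sample_at)
from .params import ModelParameters, validate

__all__ = ["SimulationState", "initialize", "gillespie_window", "run",
           "seed_event_rng"]

log = logging.getLogger(__name__)

EVENT_NAMES = ("red_to_yellow", "yellow_to_green", "mitosis", "migration", "death")


def seed_event_rng(seed: int) -> None:
    """Seed the Gillespie kernel's RNG (done automatically by
    :func:`initialize`; call directly only for hand-built states)."""
    _kernel.seed_rng(int(seed) % 2 ** 31)


@dataclass
class SimulationState:
    """Full mutable state of one realization.

    Agents occupy slots ``0..n_slots-1`` of flat arrays; dead agents keep
    their slot with ``alive = False`` (their final position is also in the
    death ledger). Convenience views (``positions``, ``phases`` ...) expose
    living agents only.
    """

    time: float
    pos: np.ndarray          # (cap, 3) float64
    phase: np.ndarray        # (cap,) int8
    alive: np.ndarray        # (cap,) bool
    cached_c: np.ndarray     # (cap,) float64
    n_slots: int
    grid: Grid
    field: NutrientField
    death_pos: np.ndarray    # (cap, 3)
    death_time: np.ndarray   # (cap,)
    n_death: int
    counts: np.ndarray       # (5,) int64 event counters
    tree: np.ndarray = field(repr=False, default=None)
    last_solver_iterations: int = 0

    # -- living-agent views -------------------------------------------------
    @property
    def living(self) -> np.ndarray:
        return self.alive[: self.n_slots]

    @property
    def positions(self) -> np.ndarray:
        return self.pos[: self.n_slots][self.living]

    @property
    def phases(self) -> np.ndarray:
        return self.phase[: self.n_slots][self.living]

    @property
    def local_c(self) -> np.ndarray:
        return self.cached_c[: self.n_slots][self.living]

    @property
    def dead_positions(self) -> np.ndarray:
        return self.death_pos[: self.n_death]

    @property
    def dead_times(self) -> np.ndarray:
        return self.death_time[: self.n_death]

    @property
    def n_living(self) -> int:
        return int(np.count_nonzero(self.living))

    def phase_counts(self) -> tuple[int, int, int]:
        ph = self.phases
        return (int(np.sum(ph == Phase.RED)), int(np.sum(ph == Phase.YELLOW)),
                int(np.sum(ph == Phase.GREEN)))

    def n_arrested(self, p: ModelParameters) -> int:
        ph = self.phases
        return int(np.sum((ph == Phase.RED) & (self.local_c < p.c_a)))

    def _grow(self, extra: int) -> None:
        cap = self.pos.shape[0]
        new_cap = cap + max(extra, cap // 2)
        for name in ("pos", "death_pos"):
            arr = getattr(self, name)
            out = np.zeros((new_cap, 3))
            out[:cap] = arr
            setattr(self, name, out)
        for name, dtype in (("phase", np.int8), ("alive", bool),
                            ("cached_c", np.float64), ("death_time", np.float64)):
            arr = getattr(self, name)
            out = np.zeros(new_cap, dtype=dtype)
            out[:cap] = arr
            setattr(self, name, out)
        self.tree = None  # must be rebuilt at the new capacity


def _sample_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Volume-uniform positions in the centred ball (radius ~ U^(1/3))."""
    cos_t = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    return np.column_stack([r * sin_t * np.cos(phi),
                            r * sin_t * np.sin(phi),
                            r * cos_t])


def initialize(p: ModelParameters, seed: Optional[int] = None,
               solver: Optional[QuasiSteadySolver] = None,
               solve_nutrient: bool = True) -> SimulationState:
    """Seed the in-silico spheroid.

    ``N0`` agents are placed volume-uniformly in the ball of radius
    ``ro_init`` centred at the origin; exactly ``Nr0``/``Ny0``/``Ng0``
    agents receive the red/yellow/green label via a uniformly random
    permutation. The initial nutrient field is solved from the initial
    density and every agent caches its interpolated local value
    (``solve_nutrient=False`` skips the solve and caches c = 1, useful
    when only the initial composition or geometry is needed).
    """
    validate(p)
    seed = p.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    seed_event_rng(seed + 1)

    n0 = p.N0
    cap = max(2 * n0, n0 + 1024)
    state = SimulationState(
        time=0.0,
        pos=np.zeros((cap, 3)),
        phase=np.zeros(cap, dtype=np.int8),
        alive=np.zeros(cap, dtype=bool),
        cached_c=np.ones(cap),
        n_slots=n0,
        grid=Grid.from_params(p),
        field=NutrientField.uniform(Grid.from_params(p), 1.0),
        death_pos=np.zeros((cap, 3)),
        death_time=np.zeros(cap),
        n_death=0,
        counts=np.zeros(5, dtype=np.int64),
    )
    state.pos[:n0] = _sample_ball(rng, n0, p.ro_init)
    labels = np.repeat(np.array([Phase.RED, Phase.YELLOW, Phase.GREEN], dtype=np.int8),
                       [p.Nr0, p.Ny0, p.Ng0])
    state.phase[:n0] = rng.permutation(labels)
    state.alive[:n0] = True

    if solve_nutrient:
        solver = solver or QuasiSteadySolver(state.grid)
        v = bin_density(state.pos[:n0], state.grid)
        state.field = solver.solve(v, p.alpha)
        state.last_solver_iterations = solver.last_iterations
        state.cached_c[:n0] = sample_at(state.pos[:n0], state.field)
    return state


def gillespie_window(state: SimulationState, p: ModelParameters,
                     window_end: float, log_capacity: int = 0):
    """Resolve all agent events from ``state.time`` to *window_end* with
    per-agent rates frozen at the cached nutrient values.

    Returns ``(event_times, event_types)`` arrays when *log_capacity* > 0
    (types indexed as in :data:`EVENT_NAMES`), else ``None``.
    """
    if window_end < state.time:
        raise ValueError("window_end precedes current time")
    P = _kernel.pack_params(p)
    # headroom so the kernel essentially never pauses mid-window
    margin = state.n_slots + max(1024, state.n_living // 2)
    if margin > state.pos.shape[0]:
        state._grow(margin - state.pos.shape[0])
    if state.tree is None or state.tree.shape[0] != state.pos.shape[0] + 1:
        state.tree = np.zeros(state.pos.shape[0] + 1)
    _kernel.build_tree(state.tree, state.phase, state.alive, state.cached_c,
                       state.n_slots, P)
    log_t = np.zeros(log_capacity)
    log_k = np.zeros(log_capacity, dtype=np.int8)
    n_log = 0
    t = state.time
    while True:
        status, t, state.n_slots, state.n_death, n_log = _kernel.run_window(
            t, float(window_end), state.pos, state.phase, state.alive,
            state.cached_c, state.tree, state.n_slots, state.field.values, P,
            state.death_pos, state.death_time, state.n_death, state.counts,
            log_t, log_k, n_log)
        if status == _kernel.OK:
            break
        if status == _kernel.GROW:
            state._grow(max(1024, state.n_living // 2))
            state.tree = np.zeros(state.pos.shape[0] + 1)
            _kernel.build_tree(state.tree, state.phase, state.alive,
                               state.cached_c, state.n_slots, P)
            continue
        raise BoundaryBreachError(
            f"an agent reached the domain boundary at t = {t:.3f} h "
            f"(L = {p.L} um is too small for this run)")
    state.time = float(window_end)
    if log_capacity:
        return log_t[:n_log], log_k[:n_log]
    return None


Observer = Callable[[SimulationState, ModelParameters], None]


def run(p: ModelParameters, observers: Sequence[Observer] = (),
        seed: Optional[int] = None) -> SimulationState:
    """Simulate one realization from t = 0 to t = T.

    Loops M = T/t_star times: Gillespie events to the next window edge,
    then density binning, a warm-started quasi-steady nutrient solve, and a
    cached-nutrient refresh for every living agent. Observers are invoked
    with ``(state, p)`` at t = 0 and after every window.
    """
    validate(p)
    solver = QuasiSteadySolver(Grid.from_params(p))
    state = initialize(p, seed=seed, solver=solver)
    for obs in observers:
        obs(state, p)
    for w in range(1, p.M + 1):
        gillespie_window(state, p, w * p.t_star)
        v = bin_density(state.positions, state.grid)
        state.field = solver.solve(v, p.alpha, warm_start=state.field)
        state.last_solver_iterations = solver.last_iterations
        living = state.living
        state.cached_c[: state.n_slots][living] = sample_at(
            state.pos[: state.n_slots][living], state.field)
        log.info("t=%6.1f h  living=%d dead=%d  events=%s  cg_iters=%d",
                 state.time, state.n_living, state.n_death,
                 state.counts.tolist(), solver.last_iterations)
        for obs in observers:
            obs(state, p)
    return state
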