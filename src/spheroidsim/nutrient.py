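"""Quasi-steady nutrient field: density binning, finite-volume solve,
trilinear sampling.

The nutrient obeys ``0 = lap(c) - alpha * v * c`` on the cubic domain with
``c = 1`` on the boundary, where ``v`` is the local agent density
[cells/um^3] estimated by counting agents in the h-cube control volume
around each mesh node. The equation is discretized with the standard
7-point second-order stencil on the uniform node grid; boundary nodes are
eliminated, leaving a symmetric positive-definite M-matrix system solved
with Jacobi-preconditioned conjugate gradients, warm-started from the
previous window's field. The discrete maximum principle guarantees
0 < c <= 1.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "Grid",
    "DensityField",
    "NutrientField",
    "SolverError",
    "bin_density",
    "QuasiSteadySolver",
    "solve_quasi_steady",
    "sample_at",
    "export_equatorial_csv",
]


class SolverError(RuntimeError):
    """The linear solve did not converge within the iteration cap."""


@dataclass(frozen=True)
class Grid:
    """Uniform I x I x I node grid spanning [-L/2, L/2] per axis."""

    I: int
    L: float

    @property
    def h(self) -> float:
        return self.L / (self.I - 1)

    @property
    def nodes(self) -> np.ndarray:
        """Node coordinates along one axis [um]."""
        return np.linspace(-self.L / 2.0, self.L / 2.0, self.I)

    @classmethod
    def from_params(cls, p) -> "Grid":
        return cls(I=p.I, L=p.L)


@dataclass
class DensityField:
    """Per-node agent density [cells/um^3]; values * h^3 sums to the count."""

    grid: Grid
    values: np.ndarray  # (I, I, I)


@dataclass
class NutrientField:
    """Per-node non-dimensional concentration c in [0, 1]."""

    grid: Grid
    values: np.ndarray  # (I, I, I)

    @classmethod
    def uniform(cls, grid: Grid, c0: float = 1.0) -> "NutrientField":
        return cls(grid, np.full((grid.I,) * 3, float(c0)))


def _positions_array(agents) -> np.ndarray:
    """Accept an (N, 3) array, an object with .positions, or AgentState list."""
    if hasattr(agents, "positions"):
        return np.asarray(agents.positions, dtype=float)
    agents = list(agents) if not isinstance(agents, np.ndarray) else agents
    if isinstance(agents, np.ndarray):
        return agents.reshape(-1, 3).astype(float)
    if len(agents) == 0:
        return np.empty((0, 3))
    return np.asarray([a.position for a in agents], dtype=float)


def bin_density(agents, grid: Grid) -> DensityField:
    """Count agents in the h-cube control volume of the nearest node.

    Each agent contributes ``1/h^3`` to exactly one node, so
    ``sum(v) * h^3`` equals the number of agents.
    """
    pos = _positions_array(agents)
    values = np.zeros((grid.I,) * 3)
    if len(pos):
        if np.any(np.abs(pos) > grid.L / 2.0):
            raise ValueError("agent positions must lie inside the domain")
        idx = np.rint((pos + grid.L / 2.0) / grid.h).astype(np.int64)
        np.clip(idx, 0, grid.I - 1, out=idx)
        flat = (idx[:, 0] * grid.I + idx[:, 1]) * grid.I + idx[:, 2]
        counts = np.bincount(flat, minlength=grid.I ** 3)
        values = counts.reshape((grid.I,) * 3) / grid.h ** 3
    return DensityField(grid, values)


@functools.lru_cache(maxsize=4)
def _interior_operator(I: int):
    """Scaled 7-point Laplacian (times -h^2) on the (I-2)^3 interior nodes,
    plus the Dirichlet boundary load ``b = A0 @ 1`` for boundary value 1."""
    m = I - 2
    T = sp.diags_array([-np.ones(m - 1), 2.0 * np.ones(m), -np.ones(m - 1)],
                       offsets=[-1, 0, 1], format="csr")
    E = sp.eye_array(m, format="csr")
    A0 = (sp.kron(sp.kron(T, E), E) + sp.kron(sp.kron(E, T), E)
          + sp.kron(sp.kron(E, E), T)).tocsr()
    b = np.asarray(A0 @ np.ones(m ** 3))
    return A0, b


class QuasiSteadySolver:
    """Reusable solver for one grid; keeps the assembled Laplacian and the
    previous solution for warm starts."""

    def __init__(self, grid: Grid, rtol: float = 1e-8, maxiter: int = 20_000):
        self.grid = grid
        self.rtol = rtol
        self.maxiter = maxiter
        self.last_iterations = 0

    def solve(self, v: DensityField, alpha: float,
              warm_start: NutrientField | None = None) -> NutrientField:
        grid = self.grid
        if v.grid != grid:
            raise ValueError("density field grid does not match solver grid")
        if alpha < 0:
            raise ValueError("alpha must be non-negative")
        if np.any(v.values < 0):
            raise ValueError("agent density must be non-negative")
        if alpha == 0 or not np.any(v.values):
            self.last_iterations = 0
            return NutrientField.uniform(grid, 1.0)

        I, h = grid.I, grid.h
        A0, b = _interior_operator(I)
        v_int = v.values[1:-1, 1:-1, 1:-1].reshape(-1)
        diag_extra = alpha * h * h * v_int
        A = A0 + sp.diags_array(diag_extra, format="csr")

        x0 = None
        if warm_start is not None and warm_start.grid == grid:
            x0 = warm_start.values[1:-1, 1:-1, 1:-1].reshape(-1).copy()

        inv_diag = 1.0 / (A0.diagonal() + diag_extra)
        M = spla.LinearOperator(A.shape, matvec=lambda r: inv_diag * r)
        niter = 0

        def _count(_):
            nonlocal niter
            niter += 1

        x, info = spla.cg(A, b, x0=x0, rtol=self.rtol, atol=0.0, M=M,
                          maxiter=self.maxiter, callback=_count)
        self.last_iterations = niter
        if info != 0:
            res = np.linalg.norm(A @ x - b) / np.linalg.norm(b)
            raise SolverError(
                f"CG failed to reach rtol={self.rtol} in {self.maxiter} "
                f"iterations (relative residual {res:.3e})")

        # The maximum principle bounds the exact solution in (0, 1]; allow
        # only round-off-sized excursions before clipping.
        slack = max(10.0 * self.rtol, 1e-6)
        if x.min() < -slack or x.max() > 1.0 + slack:
            raise SolverError(
                f"solution violates the maximum principle beyond round-off: "
                f"min={x.min():.3e}, max={x.max():.3e}")
        c = np.ones((I,) * 3)
        c[1:-1, 1:-1, 1:-1] = np.clip(x, 0.0, 1.0).reshape((I - 2,) * 3)
        return NutrientField(grid, c)


def solve_quasi_steady(v: DensityField, alpha: float,
                       warm_start: NutrientField | None = None,
                       rtol: float = 1e-8) -> NutrientField:
    """One-shot quasi-steady solve; see :class:`QuasiSteadySolver`."""
    return QuasiSteadySolver(v.grid, rtol=rtol).solve(v, alpha, warm_start)


def export_equatorial_csv(field: NutrientField, path) -> None:
    """Write the z = 0 plane of the field as x_um,y_um,c rows (for quick
    plotting of nutrient cross-sections)."""
    grid = field.grid
    mid = grid.I // 2
    x, y = np.meshgrid(grid.nodes, grid.nodes, indexing="ij")
    out = np.column_stack([x.ravel(), y.ravel(),
                           field.values[:, :, mid].ravel()])
    np.savetxt(path, out, delimiter=",", header="x_um,y_um,c", comments="")


def sample_at(positions, field: NutrientField) -> np.ndarray:
    """Trilinear interpolation of the nodal field at agent positions.

    Positions must lie inside the domain; results are convex combinations
    of the 8 surrounding node values and hence stay in [0, 1].
    """
    grid = field.grid
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.shape[-1] != 3:
        raise ValueError("positions must have shape (N, 3)")
    if np.any(np.abs(pos) > grid.L / 2.0):
        raise ValueError("positions must lie inside the domain")
    g = (pos + grid.L / 2.0) / grid.h
    i0 = np.clip(np.floor(g).astype(np.int64), 0, grid.I - 2)
    f = g - i0
    vals = field.values
    out = np.zeros(len(pos))
    for dx in (0, 1):
        wx = f[:, 0] if dx else 1.0 - f[:, 0]
        for dy in (0, 1):
            wy = f[:, 1] if dy else 1.0 - f[:, 1]
            for dz in (0, 1):
                wz = f[:, 2] if dz else 1.0 - f[:, 2]
                out += wx * wy * wz * vals[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    return out
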