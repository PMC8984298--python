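"""Quantification layer: cross-section rasterization, radii estimation,
periphery-referenced radial profiles, and ensemble statistics.

The radii pipeline mirrors how experimental confocal slices are analysed:
agent positions in a thin slab around a chosen plane are drawn as 12-um
discs on a 1 um/pixel image, the living-cell union is binarized, and three
radii are read off: the outer radius ro (edge of the whole spheroid), the
arrested radius ra (outer edge of the region where yellow/green cycling
activity has vanished) and the necrotic radius rn (central region devoid
of living cells), with ro > ra >= rn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .agents import Phase
from .nutrient import NutrientField
from .params import ModelParameters

__all__ = [
    "RadiiEstimate",
    "RadialProfileSet",
    "EstimationError",
    "rasterize_cross_section",
    "estimate_radii",
    "radii_from_state",
    "radial_profiles",
    "TimeSeriesObserver",
    "RadiiObserver",
    "ensemble_stats",
]

CHANNELS = ("red", "yellow", "green", "dead")
AGENT_DIAMETER_PX = 12        # drawn cell size, 1 um/pixel
SLAB_HALF_WIDTH = 6.0         # um; half a cell diameter either side of the plane
N_RAYS = 360
RING_WIDTH = 12.0             # um; width of the coverage rings used for ra
RA_COVER_FRACTION = 0.10      # ring counts as cycling-free below 10% of rim cover


class EstimationError(RuntimeError):
    """Radii could not be estimated (e.g. empty cross-section image)."""


@dataclass
class RadiiEstimate:
    """Outer / arrested / necrotic radii [um] of one cross-section.

    ``ra`` is NaN when no cycling-free region is detected (early times),
    ``rn`` is 0 when there is no central void.
    """

    time: float
    ro: float
    ra: float
    rn: float
    cross_section: str = "equator"


@dataclass
class RadialProfileSet:
    """Periphery-referenced profiles at one time.

    ``densities[name]`` holds the ensemble-mean relative density per bin of
    depth p = ro - r for the agent subpopulations (red_cycling, red_arrested,
    yellow, green; shared normalization) and the shell-averaged nutrient
    concentration (reported as-is). ``sd[name]`` is the across-realization
    standard deviation.
    """

    time: float
    p_centres: np.ndarray
    densities: Dict[str, np.ndarray]
    sd: Dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# rasterization


def _disc_offsets(diameter: int) -> Tuple[np.ndarray, np.ndarray]:
    r = diameter // 2
    dx, dy = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dx * dx + dy * dy <= r * r
    return dx[keep], dy[keep]


_DISC_DX, _DISC_DY = _disc_offsets(AGENT_DIAMETER_PX)


def _plane_z(plane: str, positions: np.ndarray) -> float:
    if plane == "equator":
        return 0.0
    r = np.linalg.norm(positions, axis=1)
    ro_hint = float(np.quantile(r, 0.99)) if len(r) else 0.0
    if plane == "upper":
        return ro_hint / 2.0
    if plane == "lower":
        return -ro_hint / 2.0
    raise ValueError(f"unknown cross-section plane {plane!r}; "
                     "expected 'equator', 'upper' or 'lower'")


def rasterize_cross_section(positions: np.ndarray, phases: np.ndarray,
                            plane: str, p: ModelParameters,
                            dead_positions: Optional[np.ndarray] = None,
                            z_plane: Optional[float] = None) -> np.ndarray:
    """Draw the agents of a thin slab as 12-um discs on a 1 um/px image.

    Returns a boolean array of shape ``(L+1, L+1, 4)`` with channels
    red/yellow/green/dead; pixel (0, 0) maps to the domain corner
    (-L/2, -L/2) in the cutting plane, axis 0 being x and axis 1 being y.
    The slab contains agents with ``|z - z_plane| <= 6`` um; the equator
    plane is z = 0 and the upper/lower planes sit at +- ro/2 (ro estimated
    from the positions) unless *z_plane* is given explicitly.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    phases = np.asarray(phases).reshape(-1)
    size = int(round(p.L)) + 1
    img = np.zeros((size, size, 4), dtype=bool)
    if z_plane is None:
        z_plane = _plane_z(plane, positions)
    elif plane not in ("equator", "upper", "lower"):
        raise ValueError(f"unknown cross-section plane {plane!r}")

    def _draw(pos2d: np.ndarray, channel: int) -> None:
        if not len(pos2d):
            return
        px = np.rint(pos2d[:, 0] + p.L / 2.0).astype(np.int64)
        py = np.rint(pos2d[:, 1] + p.L / 2.0).astype(np.int64)
        xs = (px[:, None] + _DISC_DX[None, :]).ravel()
        ys = (py[:, None] + _DISC_DY[None, :]).ravel()
        keep = (xs >= 0) & (xs < size) & (ys >= 0) & (ys < size)
        img[xs[keep], ys[keep], channel] = True

    in_slab = np.abs(positions[:, 2] - z_plane) <= SLAB_HALF_WIDTH
    for ch, phase in enumerate((Phase.RED, Phase.YELLOW, Phase.GREEN)):
        _draw(positions[in_slab & (phases == phase)], ch)
    if dead_positions is not None and len(dead_positions):
        dead_positions = np.asarray(dead_positions, dtype=float).reshape(-1, 3)
        dead_slab = np.abs(dead_positions[:, 2] - z_plane) <= SLAB_HALF_WIDTH
        _draw(dead_positions[dead_slab], 3)
    return img


# ---------------------------------------------------------------------------
# radii estimation


def _ray_samples(mask: np.ndarray, cx: float, cy: float):
    """Sample *mask* along N_RAYS rays from (cx, cy); returns (values, radii)."""
    size = mask.shape[0]
    rmax = int(min(cx, cy, size - 1 - cx, size - 1 - cy))
    if rmax < 2:
        raise EstimationError("cross-section centroid too close to the image edge")
    ang = np.linspace(0.0, 2.0 * np.pi, N_RAYS, endpoint=False)
    rr = np.arange(rmax + 1)
    xs = np.rint(cx + rr[None, :] * np.cos(ang)[:, None]).astype(np.int64)
    ys = np.rint(cy + rr[None, :] * np.sin(ang)[:, None]).astype(np.int64)
    return mask[xs, ys], rr


def estimate_radii(img: np.ndarray, time: float = float("nan"),
                   cross_section: str = "equator") -> RadiiEstimate:
    """Estimate (ro, ra, rn) from a rasterized cross-section.

    Procedure: the living-channel union is closed with a 6-px disc (the
    rasterized point agents cover only part of the tissue area, and the
    closing bridges sub-cell-scale gaps); rays are cast from the living
    centroid at 360 evenly spaced angles. ro is the median outermost
    foreground crossing, rn the median innermost crossing (0 if below one
    cell diameter, i.e. no genuine void). ra is found from yellow+green
    coverage in 12-um-wide rings: scanning inward from the rim, the first
    ring whose coverage falls below 10% of the rim value marks the arrested
    boundary; NaN if no such ring exists. The ordering ro > ra >= rn is
    enforced on the returned estimate.
    """
    img = np.asarray(img)
    living = img[:, :, 0] | img[:, :, 1] | img[:, :, 2]
    if not living.any():
        raise EstimationError("no living agents in the cross-section image")
    closed = _euclidean_closing(living, AGENT_DIAMETER_PX // 2)
    xs, ys = np.nonzero(closed)
    cx, cy = float(xs.mean()), float(ys.mean())
    vals, rr = _ray_samples(closed, cx, cy)
    hit = vals.any(axis=1)
    if not hit.any():
        raise EstimationError("no foreground along any ray")
    outer = (vals * (rr + 1)).max(axis=1) - 1          # last True per ray
    ro = float(np.median(outer[hit]))
    first = np.argmax(vals, axis=1)                     # first True per ray
    rn = float(np.median(first[hit]))
    if rn < AGENT_DIAMETER_PX:
        rn = 0.0

    ra = _arrested_radius(img, cx, cy, ro)
    if not math.isnan(ra):
        ra = min(max(ra, rn), max(ro - 1.0, rn))
    return RadiiEstimate(time=time, ro=ro, ra=ra, rn=rn,
                         cross_section=cross_section)


def _euclidean_closing(mask: np.ndarray, radius: float) -> np.ndarray:
    """Morphological closing with a Euclidean disc via two distance
    transforms (much faster than footprint-based closing at 1 um/px)."""
    dilated = distance_transform_edt(~mask) <= radius
    return distance_transform_edt(dilated) > radius


def _arrested_radius(img: np.ndarray, cx: float, cy: float, ro: float) -> float:
    cycling = img[:, :, 1] | img[:, :, 2]              # yellow + green
    size = img.shape[0]
    gx, gy = np.ogrid[:size, :size]
    dist = np.sqrt((gx - cx) ** 2 + (gy - cy) ** 2)
    step = 2.0
    # radial pixel histograms in 2-um bins; ring coverage is a sliding sum
    rbin = (dist / step).astype(np.int64)
    nbin = int(rbin.max()) + 1
    area_h = np.bincount(rbin.ravel(), minlength=nbin).astype(float)
    cyc_h = np.bincount(rbin[cycling], minlength=nbin).astype(float)
    edges = np.arange(ro, RING_WIDTH - 1e-9, -step)[::-1]   # ring outer edges
    if len(edges) < 3:
        return float("nan")
    width_bins = int(round(RING_WIDTH / step))
    cum_a = np.concatenate([[0.0], np.cumsum(area_h)])
    cum_c = np.concatenate([[0.0], np.cumsum(cyc_h)])
    cover = np.empty(len(edges))
    for k, e in enumerate(edges):
        hi = min(int(round(e / step)), nbin)
        lo = max(hi - width_bins, 0)
        area = cum_a[hi] - cum_a[lo]
        cover[k] = (cum_c[hi] - cum_c[lo]) / area if area else 0.0
    rim = cover[-2:].max()
    if rim <= 0:
        return float("nan")
    below = cover < RA_COVER_FRACTION * rim
    below[-2:] = False                                  # the rim itself never counts
    idx = np.nonzero(below)[0]
    if not len(idx):
        return float("nan")
    return float(edges[idx[-1]])                        # outermost qualifying ring


def radii_from_state(state, p: ModelParameters, plane: str = "equator",
                     include_dead: bool = True) -> RadiiEstimate:
    """Rasterize a simulation state and estimate its radii."""
    img = rasterize_cross_section(
        state.positions, state.phases, plane, p,
        dead_positions=state.dead_positions if include_dead else None)
    return estimate_radii(img, time=state.time, cross_section=plane)


# ---------------------------------------------------------------------------
# radial profiles


_SUBPOPS = ("red_cycling", "red_arrested", "yellow", "green")


def _shell_counts(state, p: ModelParameters, edges_p: np.ndarray,
                  ro: float) -> Dict[str, np.ndarray]:
    """Counts per depth shell (p = ro - r, clamped at 0) per subpopulation."""
    r = np.linalg.norm(state.positions, axis=1)
    depth = np.clip(ro - r, 0.0, None)
    ph = state.phases
    arrested = (ph == Phase.RED) & (state.local_c < p.c_a)
    sel = {
        "red_cycling": (ph == Phase.RED) & ~arrested,
        "red_arrested": arrested,
        "yellow": ph == Phase.YELLOW,
        "green": ph == Phase.GREEN,
    }
    return {k: np.histogram(depth[m], bins=edges_p)[0].astype(float)
            for k, m in sel.items()}


def _shell_volumes(edges_p: np.ndarray, ro: float) -> np.ndarray:
    r_out = np.clip(ro - edges_p[:-1], 0.0, None)
    r_in = np.clip(ro - edges_p[1:], 0.0, None)
    return np.maximum(4.0 / 3.0 * np.pi * (r_out ** 3 - r_in ** 3), 1e-12)


def _nutrient_shell_average(field: NutrientField, edges_p: np.ndarray,
                            ro: float) -> np.ndarray:
    grid = field.grid
    x = grid.nodes
    r = np.sqrt(x[:, None, None] ** 2 + x[None, :, None] ** 2
                + x[None, None, :] ** 2)
    depth = ro - r
    out = np.full(len(edges_p) - 1, np.nan)
    for k in range(len(edges_p) - 1):
        m = (depth >= edges_p[k]) & (depth < edges_p[k + 1])
        if m.any():
            out[k] = field.values[m].mean()
    return out


def radial_profiles(ensembles_by_time: Dict[float, Sequence],
                    p: ModelParameters, bin_width: float = 10.0,
                    radii: Optional[Dict[float, Sequence[float]]] = None,
                    ) -> List[RadialProfileSet]:
    """Periphery-referenced relative density profiles.

    Parameters
    ----------
    ensembles_by_time
        Mapping time -> list of :class:`~spheroidsim.engine.SimulationState`
        (identically prepared realizations at that time).
    bin_width
        Depth-shell width [um].
    radii
        Optional mapping time -> per-realization outer radii ro; by default
        each realization uses its 99th-percentile agent radius.

    All agent profiles share one normalization: the maximum mean density
    over every subpopulation, bin and requested time point, so relative
    abundances are comparable across times. The nutrient profile is the
    shell-averaged concentration, reported without renormalization.
    """
    raw: List[Tuple[float, Dict[str, np.ndarray], Dict[str, np.ndarray],
                    np.ndarray, np.ndarray]] = []
    for t in sorted(ensembles_by_time):
        states = list(ensembles_by_time[t])
        if not states:
            continue
        ro_list = (list(radii[t]) if radii is not None else
                   [float(np.quantile(np.linalg.norm(s.positions, axis=1), 0.99))
                    for s in states])
        p_max = max(ro_list)
        edges = np.arange(0.0, p_max + bin_width, bin_width)
        per_real = {k: [] for k in _SUBPOPS}
        nut = []
        for s, ro in zip(states, ro_list):
            counts = _shell_counts(s, p, edges, ro)
            vols = _shell_volumes(edges, ro)
            for k in _SUBPOPS:
                per_real[k].append(counts[k] / vols)
            fld = getattr(s, "field", None)
            nut.append(_nutrient_shell_average(fld, edges, ro)
                       if fld is not None else np.full(len(edges) - 1, np.nan))
        means = {k: np.mean(per_real[k], axis=0) for k in _SUBPOPS}
        sds = {k: (np.std(per_real[k], axis=0, ddof=1) if len(states) > 1
                   else np.zeros(len(edges) - 1)) for k in _SUBPOPS}
        nut = np.asarray(nut, dtype=float)
        raw.append((t, means, sds, edges,
                    np.vstack([nut.mean(axis=0) if len(nut) else nut,
                               np.std(nut, axis=0, ddof=1) if len(states) > 1
                               else np.zeros(len(edges) - 1)])))

    norm = max((m[k].max() for (_, m, _, _, _) in raw for k in _SUBPOPS
                if len(m[k])), default=0.0)
    norm = norm if norm > 0 else 1.0
    out = []
    for t, means, sds, edges, nut in raw:
        centres = 0.5 * (edges[:-1] + edges[1:])
        dens = {k: means[k] / norm for k in _SUBPOPS}
        sd = {k: sds[k] / norm for k in _SUBPOPS}
        dens["nutrient"] = nut[0]
        sd["nutrient"] = nut[1]
        out.append(RadialProfileSet(time=t, p_centres=centres,
                                    densities=dens, sd=sd))
    return out


# ---------------------------------------------------------------------------
# time series and ensemble statistics


def profiles_table(profile_sets: Sequence[RadialProfileSet]) -> pd.DataFrame:
    """Long-format table of profile sets: time_h, p_um, subpopulation,
    mean, sd."""
    rows = []
    for ps in profile_sets:
        for name, dens in ps.densities.items():
            sd = ps.sd[name]
            for pc, m, s in zip(ps.p_centres, dens, sd):
                rows.append(dict(time_h=ps.time, p_um=pc,
                                 subpopulation=name, mean=m, sd=s))
    return pd.DataFrame(rows)


class TimeSeriesObserver:
    """Engine observer recording subpopulation counts after every window.

    Columns: time_h, N, N_dead, N_red, N_yellow, N_green, N_arrested,
    N_cycling_red; with N_red = N_arrested + N_cycling_red and
    N = N_red + N_yellow + N_green.
    """

    def __init__(self):
        self.rows: List[dict] = []

    def __call__(self, state, p: ModelParameters) -> None:
        nr, ny, ng = state.phase_counts()
        na = state.n_arrested(p)
        self.rows.append(dict(time_h=state.time, N=state.n_living,
                              N_dead=state.n_death, N_red=nr, N_yellow=ny,
                              N_green=ng, N_arrested=na, N_cycling_red=nr - na))

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


class RadiiObserver:
    """Engine observer estimating cross-section radii on a fixed cadence."""

    def __init__(self, every: float = 24.0, plane: str = "equator"):
        self.every = every
        self.plane = plane
        self.estimates: List[RadiiEstimate] = []

    def __call__(self, state, p: ModelParameters) -> None:
        if abs(state.time / self.every - round(state.time / self.every)) > 1e-9:
            return
        self.estimates.append(radii_from_state(state, p, self.plane))

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(time_h=e.time, cross_section=e.cross_section,
                  ro_um=e.ro, ra_um=e.ra, rn_um=e.rn) for e in self.estimates])


def ensemble_stats(tables: Sequence[pd.DataFrame],
                   time_column: str = "time_h") -> pd.DataFrame:
    """Pointwise mean and (n-1)-denominator sd across aligned realizations.

    Returns a frame indexed like the inputs with ``<col>_mean`` and
    ``<col>_sd`` for every numeric column; raises if time grids differ.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 realizations")
    base = tables[0][time_column].to_numpy()
    for t in tables[1:]:
        if len(t) != len(base) or not np.allclose(t[time_column].to_numpy(), base):
            raise ValueError("realization time grids are not aligned")
    out = pd.DataFrame({time_column: base})
    cols = [c for c in tables[0].columns
            if c != time_column and pd.api.types.is_numeric_dtype(tables[0][c])]
    for c in cols:
        stack = np.vstack([t[c].to_numpy(dtype=float) for t in tables])
        out[f"{c}_mean"] = stack.mean(axis=0)
        out[f"{c}_sd"] = stack.std(axis=0, ddof=1)
    return out
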