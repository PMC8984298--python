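"""Model constants and run configuration.

All quantities are kept in the units used throughout the package:
micrometres for lengths, hours for times and rates, cells for counts.
The nutrient concentration is non-dimensional (c in [0, 1]).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Union

__all__ = [
    "ModelParameters",
    "ParameterError",
    "default_parameters",
    "desk_preset",
    "load_config",
    "save_config",
    "validate",
]


class ParameterError(ValueError):
    """A model parameter violates one of its constraints."""


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set for one spheroid simulation.

    Attributes
    ----------
    N0, Nr0, Ny0, Ng0 : int
        Initial number of agents in total and in the red (G1), yellow
        (early S) and green (S/G2/M) FUCCI phases. ``N0 = Nr0 + Ny0 + Ng0``.
    L : float
        Side length of the cubic domain [um]. Chosen large enough that no
        agent reaches the boundary during a run.
    I : int
        Number of mesh nodes per axis; the nutrient grid has I^3 nodes and
        spacing ``h = L / (I - 1)``.
    ro_init : float
        Initial spheroid radius [um].
    sigma : float
        Mitotic dispersal distance between the two daughters [um].
    mu : float
        Migration step length [um].
    T : float
        Total simulated time [h].
    t_star : float
        Interval between quasi-steady nutrient field updates [h];
        ``T / t_star`` must be a positive integer (the window count M).
    Rr_max : float
        Maximum red-to-yellow (G1 to eS) transition rate [1/h]; the actual
        rate is a Hill function of the local nutrient concentration.
    Ry, Rg : float
        Constant yellow-to-green and green-to-red (mitosis) rates [1/h].
    d_max, d_min : float
        Death rate [1/h] at zero and saturating nutrient, respectively.
    m_max, m_min : float
        Migration rate [1/h] at saturating and zero nutrient, respectively.
    eta1, eta2, eta3 : float
        Hill indices for the arrest, migration and death rate laws.
    c_a, c_m, c_d : float
        Inflection (half-maximum) nutrient concentrations of the arrest,
        migration and death rate laws; ``c_a`` doubles as the arrest
        threshold when classifying red agents as arrested.
    alpha : float
        Consumption-to-diffusion ratio kappa/D [um per cell] in the
        quasi-steady nutrient equation ``0 = lap(c) - alpha * v * c``.
    seed : int
        Master RNG seed for one realization; ensembles derive the seed of
        realization k as ``seed + k``.
    """

    N0: int = 30_000
    Nr0: int = 20_911
    Ny0: int = 995
    Ng0: int = 8_094
    L: float = 4000.0
    I: int = 201
    ro_init: float = 245.0
    sigma: float = 12.0
    mu: float = 12.0
    T: float = 240.0
    t_star: float = 1.0
    Rr_max: float = 0.047
    Ry: float = 0.50
    Rg: float = 0.062
    d_max: float = 2.0
    d_min: float = 0.0005
    m_max: float = 0.12
    m_min: float = 0.06
    eta1: float = 5.0
    eta2: float = 5.0
    eta3: float = 15.0
    c_a: float = 0.4
    c_m: float = 0.5
    c_d: float = 0.1
    alpha: float = 0.15
    seed: int = 0

    @property
    def h(self) -> float:
        """Mesh node spacing L / (I - 1) [um]."""
        return self.L / (self.I - 1)

    @property
    def M(self) -> int:
        """Number of nutrient-update windows, T / t_star (always derived)."""
        return int(round(self.T / self.t_star))

    def validated(self) -> "ModelParameters":
        validate(self)
        return self

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)


def validate(p: ModelParameters) -> None:
    """Raise :class:`ParameterError` naming the first violated constraint."""

    def req(cond: bool, msg: str) -> None:
        if not cond:
            raise ParameterError(msg)

    req(p.N0 == p.Nr0 + p.Ny0 + p.Ng0,
        f"N0 must equal Nr0 + Ny0 + Ng0 ({p.N0} != {p.Nr0}+{p.Ny0}+{p.Ng0})")
    req(min(p.Nr0, p.Ny0, p.Ng0) >= 0, "phase counts must be non-negative")
    req(p.d_max > p.d_min >= 0, f"need d_max > d_min >= 0 (got {p.d_max}, {p.d_min})")
    req(p.m_max > p.m_min >= 0, f"need m_max > m_min >= 0 (got {p.m_max}, {p.m_min})")
    req(p.Rr_max > 0, "Rr_max must be positive")
    req(p.Ry > 0, "Ry must be positive")
    req(p.Rg > 0, "Rg must be positive")
    for name in ("c_d", "c_a", "c_m"):
        v = getattr(p, name)
        req(0 < v <= 1, f"{name} must lie in (0, 1] (got {v})")
    for name in ("eta1", "eta2", "eta3"):
        req(getattr(p, name) > 0, f"{name} must be positive")
    req(p.alpha >= 0, f"alpha must be non-negative (got {p.alpha})")
    req(p.ro_init > 0, "ro_init must be positive")
    req(p.L > 2 * p.ro_init,
        f"L must exceed 2*ro_init so the spheroid fits (got L={p.L}, ro_init={p.ro_init})")
    req(p.I >= 3, f"I must be at least 3 (got {p.I})")
    req(p.T > 0, "T must be positive")
    req(p.t_star > 0, "t_star must be positive")
    m = p.T / p.t_star
    req(abs(m - round(m)) < 1e-9 and round(m) >= 1,
        f"T/t_star must be a positive integer (got {m})")
    req(p.sigma >= 0 and p.mu >= 0, "sigma and mu must be non-negative")


def default_parameters() -> ModelParameters:
    """The published parameter set for the WM793B melanoma spheroids."""
    return ModelParameters().validated()


def desk_preset() -> ModelParameters:
    """Reduced-domain preset: L = 1500 um, I = 76 (h = 20 um preserved).

    All biological parameters keep their defaults; only the domain and mesh
    shrink so a full 240 h run fits on a single workstation core. The
    Dirichlet boundary sits nearer the spheroid than with the default
    L = 4000 um domain, which raises the nutrient concentration slightly
    (see docs/methods.md).
    """
    return ModelParameters(L=1500.0, I=76).validated()


_INT_FIELDS = {f.name for f in fields(ModelParameters) if f.type in ("int", int)}


def save_config(p: ModelParameters, path: Union[str, Path]) -> None:
    """Write a flat ``key = value`` configuration file ('#' starts a comment)."""
    lines = ["# spheroidsim run configuration"]
    for f in fields(ModelParameters):
        lines.append(f"{f.name} = {getattr(p, f.name)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: Union[str, Path]) -> ModelParameters:
    """Read a ``key = value`` file; unspecified keys fall back to defaults.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ParameterError
        On unknown keys, malformed lines, or any violated invariant.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"configuration file not found: {path}")
    known = {f.name for f in fields(ModelParameters)}
    overrides: dict = {}
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParameterError(f"{path}:{ln}: expected 'key = value', got {raw!r}")
        key, _, val = (s.strip() for s in line.partition("="))
        if key not in known:
            raise ParameterError(f"{path}:{ln}: unknown parameter {key!r}")
        try:
            overrides[key] = int(val) if key in _INT_FIELDS else float(val)
        except ValueError as exc:
            raise ParameterError(f"{path}:{ln}: cannot parse {key} = {val!r}") from exc
    return ModelParameters(**overrides).validated()
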