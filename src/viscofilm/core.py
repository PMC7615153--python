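"""Grids, parameter containers, finite-difference operators and result types.

The axial domain is ``0 <= z <= L`` (lengths in tube-radius units) with
symmetry boundary conditions at both ends: fields such as the layer height and
surfactant concentration are even about each boundary, while fluxes vanish
there (odd extension).  All spatial derivatives are second-order central
differences evaluated with ghost nodes supplied by the appropriate parity
extension, so no one-sided stencils are needed and derivative operators retain
uniform second-order accuracy up to the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Grid",
    "ThinFilmParams",
    "LongWaveParams",
    "DimensionalParams",
    "ConservationReport",
    "SimulationResult",
    "make_grid",
    "d1",
    "d2",
    "d3",
    "integral",
]

# |pz| below this is treated as exactly zero when selecting yield-surface and
# flux branches; the clipped formulas are continuous there so the exact value
# is uncritical.
PZ_FLOOR = 1e-30


@dataclass(frozen=True)
class Grid:
    """Uniform node-centred grid on [0, L] including both endpoints."""

    z: np.ndarray
    L: float
    N: int

    @property
    def dz(self) -> float:
        return self.L / (self.N - 1)


def make_grid(L: float, N: int) -> Grid:
    """Build a uniform grid of ``N`` nodes covering ``[0, L]`` inclusive."""
    if not L > 0:
        raise ValueError(f"domain length must be positive, got L={L}")
    if N < 8:
        raise ValueError(f"need at least 8 grid nodes, got N={N}")
    z = np.linspace(0.0, float(L), int(N))
    return Grid(z=z, L=float(L), N=int(N))


@dataclass(frozen=True)
class ThinFilmParams:
    """Dimensionless groups of the thin-film model.

    B is the scaled capillary Bingham number (yield stress over the capillary
    stress scale, divided by the square of the thickness ratio) and M the
    scaled Marangoni number.  ``A`` is the initial perturbation amplitude,
    ``L`` the domain length and ``Y_min`` the yield-surface regularisation
    floor.
    """

    B: float
    M: float
    A: float = 0.2
    L: float = 2 * np.pi
    Y_min: float = 1e-8

    def __post_init__(self):
        if self.B < 0:
            raise ValueError("B must be non-negative")
        if self.M < 0:
            raise ValueError("M must be non-negative")
        if not 0 <= self.A < 1:
            raise ValueError("A must lie in [0, 1)")
        if not self.Y_min > 0:
            raise ValueError("Y_min must be positive")


@dataclass(frozen=True)
class LongWaveParams:
    """Dimensionless groups of the long-wave model.

    ``cB`` and ``cM`` are the unscaled capillary Bingham and Marangoni
    numbers; ``eps`` is the mean layer thickness over the tube radius.  The
    thin-film groups are recovered as B = cB/eps**2, M = cM/eps**2.
    """

    cB: float
    cM: float
    eps: float
    A: float = 0.2
    L: float = 2 * np.pi
    Y_min: float = 1e-8

    def __post_init__(self):
        if self.cB < 0:
            raise ValueError("cB must be non-negative")
        if self.cM < 0:
            raise ValueError("cM must be non-negative")
        if not 0 < self.eps < 1:
            raise ValueError("eps must lie in (0, 1)")
        if not self.Y_min > 0:
            raise ValueError("Y_min must be positive")

    @property
    def B(self) -> float:
        """Thin-film-scaled capillary Bingham number."""
        return self.cB / self.eps**2

    @property
    def M(self) -> float:
        """Thin-film-scaled Marangoni number."""
        return self.cM / self.eps**2


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional quantities for unit conversion.

    tube_radius in m, base_surface_tension in N/m, viscosity in Pa s,
    yield_stress in Pa, surfactant_elasticity (K*Gamma0) in N/m.  The viscous
    capillary time unit is a*eta/sigma0.
    """

    tube_radius: float
    base_surface_tension: float
    viscosity: float
    yield_stress: float = 0.0
    surfactant_elasticity: Optional[float] = None

    def __post_init__(self):
        for name in ("tube_radius", "base_surface_tension", "viscosity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.yield_stress < 0:
            raise ValueError("yield_stress must be non-negative")

    @property
    def capillary_bingham(self) -> float:
        """cB = a * tau_y / sigma0."""
        return self.tube_radius * self.yield_stress / self.base_surface_tension

    @property
    def marangoni(self) -> float:
        """cM = K * Gamma0 / sigma0."""
        if self.surfactant_elasticity is None:
            return 0.0
        return self.surfactant_elasticity / self.base_surface_tension

    @property
    def time_unit(self) -> float:
        """Viscous capillary time a*eta/sigma0 in seconds."""
        return self.tube_radius * self.viscosity / self.base_surface_tension


def _extend(f: np.ndarray, parity: str, width: int) -> np.ndarray:
    """Pad ``f`` with ``width`` ghost nodes on each side by parity reflection.

    ``even``: f(-z) = f(z) about both endpoints (symmetric fields);
    ``odd``:  f(-z) = -f(z), used for fluxes that vanish at the boundaries.
    """
    f = np.asarray(f, dtype=float)
    left = f[1 : width + 1][::-1]
    right = f[-width - 1 : -1][::-1]
    if parity == "even":
        return np.concatenate([left, f, right])
    if parity == "odd":
        return np.concatenate([-left, f, -right])
    raise ValueError(f"unknown parity {parity!r}")


def _check_field(field: np.ndarray, grid: Grid) -> np.ndarray:
    field = np.asarray(field, dtype=float)
    if field.shape != (grid.N,):
        raise ValueError(
            f"field of shape {field.shape} does not match grid with N={grid.N}"
        )
    return field


def d1(field: np.ndarray, grid: Grid, parity: str = "even") -> np.ndarray:
    """Second-order central first derivative with parity ghost extension."""
    f = _extend(_check_field(field, grid), parity, 1)
    return (f[2:] - f[:-2]) / (2.0 * grid.dz)


def d2(field: np.ndarray, grid: Grid, parity: str = "even") -> np.ndarray:
    """Second-order central second derivative with parity ghost extension."""
    f = _extend(_check_field(field, grid), parity, 1)
    return (f[2:] - 2.0 * f[1:-1] + f[:-2]) / grid.dz**2


def d3(field: np.ndarray, grid: Grid, parity: str = "even") -> np.ndarray:
    """Second-order central third derivative (5-point stencil, ghost values)."""
    f = _extend(_check_field(field, grid), parity, 2)
    return (-f[:-4] + 2.0 * f[1:-3] - 2.0 * f[3:-1] + f[4:]) / (2.0 * grid.dz**3)


def integral(field: np.ndarray, grid: Grid) -> float:
    """Composite trapezoidal quadrature of ``field`` over [0, L]."""
    return float(np.trapezoid(_check_field(field, grid), dx=grid.dz))


@dataclass
class ConservationReport:
    """Worst relative drift of each conserved integral over a trajectory."""

    max_drift: dict = field(default_factory=dict)
    worst_time: dict = field(default_factory=dict)

    @property
    def worst(self) -> float:
        return max(self.max_drift.values(), default=0.0)


@dataclass
class SimulationResult:
    """Time series of states from one model run.

    ``profile`` holds H (thin-film) or R (long-wave), one row per output time;
    ``Gamma`` the surfactant concentration.  Long-wave times are stored in the
    unscaled time unit; ``t_scaled`` reports them multiplied by eps**3 so both
    models share the thin-film time scale.
    """

    model: str
    params: object
    grid: Grid
    times: np.ndarray
    profile: np.ndarray
    Gamma: np.ndarray
    plug_formed: bool = False
    t_p: Optional[float] = None
    stop_reason: str = "t_end"
    conservation_report: ConservationReport = field(default_factory=ConservationReport)
    nfev: int = 0
    njev: int = 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("output times must be strictly increasing")
        if self.plug_formed and self.t_p is not None and t.size:
            if self.t_p > t[-1] + 1e-9 * max(1.0, abs(t[-1])):
                raise ValueError("plugging time exceeds the last output time")

    @property
    def time_scale(self) -> float:
        """Factor converting stored times to thin-film time units."""
        if self.model == "long_wave":
            return self.params.eps**3
        return 1.0

    @property
    def t_scaled(self) -> np.ndarray:
        return np.asarray(self.times) * self.time_scale

    @property
    def t_p_scaled(self) -> Optional[float]:
        if self.t_p is None:
            return None
        return self.t_p * self.time_scale

    @property
    def min_R(self) -> np.ndarray:
        """min_z R per output time (long-wave runs only)."""
        if self.model != "long_wave":
            raise AttributeError("min_R is defined for long-wave runs")
        return self.profile.min(axis=1)

    @property
    def max_height(self) -> np.ndarray:
        """max_z of the layer height (H, or (1-R)/eps for long-wave runs)."""
        if self.model == "long_wave":
            return (1.0 - self.profile.min(axis=1)) / self.params.eps
        return self.profile.max(axis=1)
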