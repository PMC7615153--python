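"""Long-wave evolution system for a thick surfactant-laden Bingham layer.

The interface sits at radius R(z, t) in a unit-radius tube; the exact
interface curvature is retained and the surface tension depends on the
surfactant concentration, ``sigma = 1 + cM*(1 - Gamma)``.  The layer evolves
through

    R_t = Q_z / R,        (R*Gamma)_t + (ws * R * Gamma)_z = 0,

with zero flux at both symmetry boundaries, so the liquid volume
``integral(1 - R^2) dz`` and total surfactant ``integral(R*Gamma) dz`` are
conserved discretely.  The flux Q and surface velocity ws are assembled from
the auxiliaries F1-F4 and G1-G4, piecewise in the same stress-ratio branches
that select the yield surfaces Psi-+.

Also provided are the strong-surfactant (cM >> 1) diagnostics: the
leading-order spatially uniform concentration G0(t) and surface velocity
W0(z, t), deducible from stored R profiles alone, independent of the fluid
rheology and of the equation of state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PZ_FLOOR, Grid, LongWaveParams, d1, d2, integral
from .yield_structure import YieldSurfacesLW, lw_yield_surfaces, regularise_lw

__all__ = [
    "LongWaveState",
    "LongWaveFields",
    "LargeMDiagnostics",
    "lw_curvature",
    "lw_pressure",
    "lw_fields",
    "lw_flux",
    "lw_surface_velocity",
    "lw_wall_stress",
    "lw_rhs",
    "lw_largeM_diagnostics",
]


@dataclass
class LongWaveState:
    """Interface radius and surfactant concentration at one time instant.

    ``t`` is the unscaled time; multiply by eps**3 for thin-film time units.
    """

    t: float
    R: np.ndarray
    Gamma: np.ndarray


@dataclass
class LongWaveFields:
    """Derived fields of the long-wave system at one instant."""

    kappa: np.ndarray
    p: np.ndarray
    pz: np.ndarray
    Q: np.ndarray
    ws: np.ndarray
    tau_w: np.ndarray
    surfaces: YieldSurfacesLW


@dataclass
class LargeMDiagnostics:
    """Strong-surfactant leading-order fields from stored R profiles."""

    times: np.ndarray
    G0: np.ndarray  # uniform concentration, one value per time
    I_field: np.ndarray  # integrand, (n_times, N)
    W0: np.ndarray  # surface velocity, (n_times, N)


def lw_curvature(R: np.ndarray, grid: Grid) -> np.ndarray:
    """Exact interface curvature from R and its central-difference derivatives."""
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("interface radius must be positive")
    Rz = d1(R, grid)
    Rzz = d2(R, grid)
    g = 1.0 + Rz**2
    return (1.0 / R - Rzz / g) / np.sqrt(g)


def lw_pressure(R, Gamma, cM: float, grid: Grid) -> np.ndarray:
    """Capillary pressure ``p = -kappa * (1 + cM*(1 - Gamma))``."""
    sigma = 1.0 + cM * (1.0 - np.asarray(Gamma, dtype=float))
    return -lw_curvature(R, grid) * sigma


def _F_terms(R, Pm, Pp):
    logt = np.log(R * Pp / Pm)
    F1 = (
        Pm**4
        - 4.0 * R**2 * Pm**2
        + R**4 * (3.0 - 4.0 * logt)
        - Pp**4
        + 4.0 * R**2 * Pp**2
        - 4.0 * R**2
        + 1.0
    )
    F2 = Pm**2 - R**2 - Pp**2 + 1.0 + 2.0 * R**2 * logt
    F3 = (Pp - 1.0) * (-3.0 * R**2 + 1.0 + Pp + Pp**2)
    F4 = Pm**3 - 3.0 * R**2 * Pm + 2.0 * R**3
    return F1, F2, F3, F4, logt


def lw_fields(R, Gamma, params: LongWaveParams, grid: Grid,
              classify: bool = True) -> LongWaveFields:
    """All derived long-wave fields with boundary fluxes pinned to zero."""
    R = np.asarray(R, dtype=float)
    Gamma = np.asarray(Gamma, dtype=float)
    cB, cM = params.cB, params.cM

    kappa = lw_curvature(R, grid)
    p = -kappa * (1.0 + cM * (1.0 - Gamma))
    pz = d1(p, grid)
    MGz = cM * d1(Gamma, grid)

    surfaces = lw_yield_surfaces(R, pz, MGz, cB, classify=classify)
    reg = regularise_lw(surfaces, params.Y_min)
    Pm, Pp = reg.Psi_minus, reg.Psi_plus
    F1, F2, F3, F4, logt = _F_terms(R, Pm, Pp)
    G1 = -F2  # R^2 + Pp^2 - Pm^2 - 1 - 2 R^2 log(R Pp / Pm)
    G2 = logt
    G3 = 1.0 - Pp
    G4 = R - Pm

    nz = np.abs(pz) > PZ_FLOOR
    pz_safe = np.where(nz, pz, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = 2.0 * MGz / (R * pz_safe)
    sgn_p = np.sign(pz)
    # yield-stress terms change sign with the branch of the stress ratio
    branch = np.where(s < 1.0, 1.0, -1.0)

    Q = (
        -pz * F1 / 16.0
        - 0.25 * R * MGz * F2
        - (cB / 6.0) * sgn_p * (F3 + branch * F4)
    )
    ws = 0.25 * pz * G1 + R * MGz * G2 + cB * sgn_p * (G3 + branch * G4)

    z0 = ~nz
    if np.any(z0):
        sgn_g = np.sign(MGz[z0])
        Q[z0] = (-0.25 * R * MGz * F2)[z0] + (cB / 6.0) * sgn_g * F4[z0]
        ws[z0] = (R * MGz * G2)[z0] - cB * sgn_g * G4[z0]

    Q[0] = Q[-1] = 0.0
    ws[0] = ws[-1] = 0.0
    tau_w = 0.5 * pz * (1.0 - R**2) + R * MGz
    return LongWaveFields(kappa, p, pz, Q, ws, tau_w, surfaces)


def lw_flux(R, Gamma, params: LongWaveParams, grid: Grid) -> np.ndarray:
    """Axial volume flux Q (zero at both boundaries)."""
    return lw_fields(R, Gamma, params, grid).Q


def lw_surface_velocity(R, Gamma, params: LongWaveParams, grid: Grid) -> np.ndarray:
    """Surface velocity ws (zero at both boundaries)."""
    return lw_fields(R, Gamma, params, grid).ws


def lw_wall_stress(R, Gamma, params: LongWaveParams, grid: Grid) -> np.ndarray:
    """Stress exerted on the tube wall, ``pz*(1-R^2)/2 + R*cM*Gamma_z``."""
    p = lw_pressure(R, Gamma, params.cM, grid)
    return 0.5 * d1(p, grid) * (1.0 - R**2) + R * params.cM * d1(Gamma, grid)


# Hard floor/ceiling on R inside the right-hand side.  The plug event stops
# physical trajectories at min R = 0.3, well above the floor, so the clip is
# only ever active on predictor/Newton trial states of the implicit
# integrator, which must evaluate to something finite.
_R_FLOOR = 0.02
_R_CEIL = 1.0 - 1e-9


def lw_rhs(state: LongWaveState, params: LongWaveParams, grid: Grid):
    """Tendencies (dR/dt, d(R*Gamma)/dt) in conservative form."""
    R = np.clip(state.R, _R_FLOOR, _R_CEIL)
    fields = lw_fields(R, state.Gamma, params, grid, classify=False)
    dR = d1(fields.Q, grid, parity="odd") / R
    gflux = fields.ws * R * state.Gamma
    gflux[0] = gflux[-1] = 0.0
    dS = -d1(gflux, grid, parity="odd")
    return dR, dS


def lw_largeM_diagnostics(
    R_series: np.ndarray, times: np.ndarray, grid: Grid
) -> LargeMDiagnostics:
    """Leading-order uniform concentration G0(t) and surface velocity W0(z, t).

    ``G0(t) = integral(R|t=0) / integral(R)``; W0 follows from the difference
    between the local rate of change of R and its global average, integrated
    from the symmetry boundary.  The time derivative of R is taken by finite
    differencing the stored profiles, so at least two are required.
    """
    R_series = np.asarray(R_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if R_series.ndim != 2 or R_series.shape[0] < 2:
        raise ValueError("need at least two stored profiles for time differencing")

    intR = np.trapezoid(R_series, dx=grid.dz, axis=1)
    G0 = intR[0] / intR

    dRdt = np.gradient(R_series, times, axis=0)
    int_dRdt = np.trapezoid(dRdt, dx=grid.dz, axis=1)
    I = (
        R_series * int_dRdt[:, None] - dRdt * intR[:, None]
    ) / intR[:, None]
    # cumulative integral from z = 0 (trapezoidal)
    cum = np.concatenate(
        [
            np.zeros((I.shape[0], 1)),
            np.cumsum(0.5 * (I[:, 1:] + I[:, :-1]) * grid.dz, axis=1),
        ],
        axis=1,
    )
    W0 = cum / R_series
    return LargeMDiagnostics(times, G0, I, W0)
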