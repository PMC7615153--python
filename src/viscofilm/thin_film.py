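"""Thin-film evolution system for a surfactant-laden Bingham layer.

Scaled variables: layer thickness H(z, t~) (mean 1), surfactant concentration
Gamma(z, t~) (mean 1), with t~ the thin-film time.  The capillary pressure
gradient is ``pz = -Hz - Hzzz`` (linearised curvature), and the layer evolves
through the conservative pair

    H_t + q_z = 0,        Gamma_t + (ws * Gamma)_z = 0,

with zero flux at both symmetry boundaries, so the discrete integrals of H and
Gamma are conserved to round-off.  The flux q and surface velocity ws are
piecewise-polynomial in the regularised yield surfaces Y-+, which makes the
right-hand side smooth enough for stiff multistep integration.

Also provided is the strong-surfactant (M -> infinity) limit equation, in
which the interface is immobilised and a single evolution equation for H
remains; it maps exactly onto the surfactant-free problem with the capillary
Bingham number doubled and time slowed four-fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PZ_FLOOR, Grid, ThinFilmParams, d1, d3
from .yield_structure import YieldSurfacesTF, regularise_tf, tf_yield_surfaces

__all__ = [
    "ThinFilmState",
    "ThinFilmFields",
    "tf_pressure_gradient",
    "tf_fields",
    "tf_flux",
    "tf_surface_velocity",
    "tf_wall_stress",
    "tf_rhs",
    "tf_largeM_rhs",
]


@dataclass
class ThinFilmState:
    """Layer thickness and surfactant concentration at one time instant."""

    t_tilde: float
    H: np.ndarray
    Gamma: np.ndarray


@dataclass
class ThinFilmFields:
    """Derived fields of the thin-film system at one instant."""

    pz_tilde: np.ndarray
    q: np.ndarray
    ws_tilde: np.ndarray
    tau_w: np.ndarray
    surfaces: YieldSurfacesTF


def tf_pressure_gradient(H: np.ndarray, grid: Grid) -> np.ndarray:
    """Capillary pressure gradient ``pz = -Hz - Hzzz`` (vanishes at z=0, L)."""
    return -d1(H, grid) - d3(H, grid)


def _flux_velocity(H, Gamma, params: ThinFilmParams, grid: Grid,
                   classify: bool = True):
    """Flux q, surface velocity ws and the supporting fields, unpinned."""
    pz = tf_pressure_gradient(H, grid)
    MGz = params.M * d1(Gamma, grid)
    surfaces = tf_yield_surfaces(H, pz, MGz, params.B, classify=classify)
    reg = regularise_tf(surfaces, params.Y_min)
    Ym, Yp = reg.Y_minus, reg.Y_plus
    B = params.B

    nz = np.abs(pz) > PZ_FLOOR
    sgn = np.where(nz, np.sign(pz), 0.0)
    hm = H - Ym
    hp = H - Yp

    q = (
        -pz * (H**3 + hp**3 - hm**3) / 3.0
        - 0.5 * MGz * (H**2 - hm**2 + hp**2)
        + 0.5 * B * sgn * (H**2 - hm**2 - hp**2)
    )
    ws = (
        -0.5 * pz * (H**2 + hp**2 - hm**2)
        - MGz * (H + Ym - Yp)
        - B * sgn * (H - Ym - Yp)
    )

    # pz == 0: purely Marangoni-driven branch
    z0 = ~nz
    if np.any(z0):
        drive = np.abs(MGz[z0]) - B
        sgn_g = np.sign(MGz[z0])
        act = drive > 0
        q[z0] = np.where(act, -0.5 * sgn_g * H[z0] ** 2 * drive, 0.0)
        ws[z0] = np.where(act, -sgn_g * H[z0] * drive, 0.0)

    return pz, MGz, surfaces, q, ws


def tf_fields(H, Gamma, params: ThinFilmParams, grid: Grid,
              classify: bool = True) -> ThinFilmFields:
    """All derived fields (pressure gradient, flux, surface velocity, wall
    stress, yield surfaces) with boundary fluxes pinned to zero."""
    pz, MGz, surfaces, q, ws = _flux_velocity(H, Gamma, params, grid, classify)
    q[0] = q[-1] = 0.0
    ws[0] = ws[-1] = 0.0
    return ThinFilmFields(pz, q, ws, H * pz + MGz, surfaces)


def tf_flux(H, Gamma, params: ThinFilmParams, grid: Grid) -> np.ndarray:
    """Scaled axial volume flux q (zero at both boundaries)."""
    return tf_fields(H, Gamma, params, grid).q


def tf_surface_velocity(H, Gamma, params: ThinFilmParams, grid: Grid) -> np.ndarray:
    """Scaled surface velocity ws (zero at both boundaries)."""
    return tf_fields(H, Gamma, params, grid).ws_tilde


def tf_wall_stress(H, Gamma, params: ThinFilmParams, grid: Grid) -> np.ndarray:
    """Wall shear stress ``tau_w = H*pz + M*Gamma_z``."""
    pz = tf_pressure_gradient(H, grid)
    return H * pz + params.M * d1(Gamma, grid)


def tf_rhs(state: ThinFilmState, params: ThinFilmParams, grid: Grid):
    """Tendencies (dH/dt~, dGamma/dt~) in conservative form.

    Fluxes are differenced with the odd-parity central operator so that the
    trapezoidal integrals of both tendencies vanish to round-off.
    """
    fields = tf_fields(state.H, state.Gamma, params, grid, classify=False)
    dH = -d1(fields.q, grid, parity="odd")
    gflux = fields.ws_tilde * state.Gamma
    gflux[0] = gflux[-1] = 0.0
    dG = -d1(gflux, grid, parity="odd")
    return dH, dG


def tf_largeM_rhs(state: ThinFilmState, params: ThinFilmParams, grid: Grid):
    """Strong-surfactant limit: immobilised interface, H evolves alone.

    ``H_t + [pz * Y^2 * (2Y - 3H) / 6]_z = 0`` with
    ``Y = max(0, H/2 - B/|pz|)`` (floored at ``Y_min``); Gamma is not evolved.
    """
    H = state.H
    pz = tf_pressure_gradient(H, grid)
    nz = np.abs(pz) > PZ_FLOOR
    pz_safe = np.where(nz, np.abs(pz), 1.0)
    Y = np.where(nz, H / 2.0 - params.B / pz_safe, 0.0)
    Y = np.maximum(Y, params.Y_min)
    flux = pz * Y**2 * (2.0 * Y - 3.0 * H) / 6.0
    flux[0] = flux[-1] = 0.0
    return -d1(flux, grid, parity="odd")
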