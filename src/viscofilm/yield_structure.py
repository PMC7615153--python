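"""Yield surfaces and yielding-type classification.

A Bingham layer sheared by capillary (``pz``) and Marangoni (``M*Gamma_z``)
stresses splits, across its depth, into fully-yielded shear regions and
plug-like regions where the shear stress is below the yield stress.  The
internal boundaries are the yield surfaces: heights ``Y-`` (wall side) and
``Y+`` (interface side) above the wall in the thin-film model, radii ``Psi-``
and ``Psi+`` in the long-wave model (plug-like flow in ``Psi- <= r <= Psi+``).

Each axial station is classified into one of five yielding types:

I   internal pseudo-plug       (0 < Y- < Y+ < H)
II  surface pseudo-plug        (0 < Y- < Y+ = H)
III fully yielded              (Y- = Y+, no plug-like region)
IV  near-wall rigid plug       (0 = Y- < Y+ < H)
V   fully rigid                (Y- = 0, Y+ = H)

Labels are diagnostics only: fluxes never branch on them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import PZ_FLOOR, Grid

__all__ = [
    "YieldSurfacesTF",
    "YieldSurfacesLW",
    "tf_yield_surfaces",
    "lw_yield_surfaces",
    "classify_regime",
    "regime_map",
    "regularise_tf",
    "regularise_lw",
    "REGIME_LABELS",
]

REGIME_LABELS = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V"}

# relative tolerance absorbing round-off when testing boundary equalities
_TIE_TOL = 1e-12


@dataclass
class YieldSurfacesTF:
    """Thin-film yield surfaces: heights above the wall, per node."""

    Y_minus: np.ndarray
    Y_plus: np.ndarray
    y_minus: np.ndarray  # unclipped
    y_plus: np.ndarray
    regime: np.ndarray  # int codes 1..5


@dataclass
class YieldSurfacesLW:
    """Long-wave yield surfaces: radial positions in [R, 1], per node."""

    Psi_minus: np.ndarray
    Psi_plus: np.ndarray
    psi_minus: np.ndarray  # unclipped
    psi_plus: np.ndarray
    regime: np.ndarray


def classify_regime(Y_minus, Y_plus, H) -> np.ndarray:
    """Classify each station into yielding types I-V (integer codes 1-5).

    Boundary equalities are detected with tolerance ``1e-12 * H``; exact ties
    are labelled by the adjacent lower-numbered type (III before IV/V).
    """
    Ym = np.atleast_1d(np.asarray(Y_minus, dtype=float))
    Yp = np.atleast_1d(np.asarray(Y_plus, dtype=float))
    H = np.broadcast_to(np.asarray(H, dtype=float), Ym.shape)
    tol = _TIE_TOL * np.maximum(H, 1e-300)
    if np.any(Ym < -tol) or np.any(Yp > H + tol) or np.any(Yp < Ym - tol):
        raise ValueError("yield surfaces violate 0 <= Y- <= Y+ <= H")

    out = np.empty(Ym.shape, dtype=int)
    plugless = Yp - Ym <= tol
    at_wall = Ym <= tol
    at_surf = Yp >= H - tol
    out[...] = 1  # internal pseudo-plug by default
    out[at_surf] = 2
    out[at_wall] = 4
    out[at_wall & at_surf] = 5
    out[plugless] = 3
    return out


def tf_yield_surfaces(H, pz, MGz, B, classify: bool = True) -> YieldSurfacesTF:
    """Thin-film yield surfaces from H, pressure gradient and Marangoni stress.

    For ``pz != 0``, ``y_pm = H + MGz/pz +- B/|pz|`` clipped to ``[0, H]``.
    For ``pz == 0`` the layer is fully yielded (type III) iff ``|MGz| > B``,
    otherwise fully rigid with ``(Y-, Y+) = (0, H)``.

    ``classify=False`` skips the (strict) regime labelling; used on the hot
    right-hand-side path where an implicit integrator may probe states
    slightly outside the physical domain.
    """
    H = np.atleast_1d(np.asarray(H, dtype=float))
    pz = np.broadcast_to(np.asarray(pz, dtype=float), H.shape)
    MGz = np.broadcast_to(np.asarray(MGz, dtype=float), H.shape)
    if classify and np.any(H < 0):
        raise ValueError("layer height must be non-negative")
    if B < 0:
        raise ValueError("B must be non-negative")
    H = np.maximum(H, 0.0)

    ym = np.zeros_like(H)
    yp = np.zeros_like(H)
    nz = np.abs(pz) > PZ_FLOOR
    with np.errstate(divide="ignore", invalid="ignore"):
        base = np.where(nz, H + MGz / pz, 0.0)
        half = np.where(nz, B / np.abs(pz), 0.0)
    ym[nz] = (base - half)[nz]
    yp[nz] = (base + half)[nz]

    Ym = np.clip(ym, 0.0, H)
    Yp = np.clip(yp, 0.0, H)

    # pz == 0 branch: rigid if |MGz| <= B, else fully yielded
    z0 = ~nz
    rigid = z0 & (np.abs(MGz) <= B)
    sheared = z0 & ~rigid
    Ym[rigid], Yp[rigid] = 0.0, H[rigid]
    ym[rigid], yp[rigid] = 0.0, H[rigid]
    Ym[sheared] = Yp[sheared] = 0.0
    ym[sheared] = yp[sheared] = 0.0

    regime = classify_regime(Ym, Yp, H) if classify else None
    return YieldSurfacesTF(Ym, Yp, ym, yp, regime)


def lw_yield_surfaces(R, pz, MGz, cB, classify: bool = True) -> YieldSurfacesLW:
    """Long-wave yield surfaces from R, pressure gradient and Marangoni stress.

    The unclipped radii follow a three-branch formula selected by the stress
    ratio ``s = 2*MGz/(R*pz)`` with thresholds 1 and ``1 + cB^2/(R*pz)^2``;
    the clipped surfaces ``Psi_pm = max[R, min(1, psi_pm)]`` are continuous
    across the branch switches and at ``pz -> 0``.
    """
    R = np.atleast_1d(np.asarray(R, dtype=float))
    pz = np.broadcast_to(np.asarray(pz, dtype=float), R.shape).copy()
    MGz = np.broadcast_to(np.asarray(MGz, dtype=float), R.shape)
    if classify and (np.any(R <= 0) or np.any(R >= 1)):
        raise ValueError("interface radius must lie in (0, 1)")
    if cB < 0:
        raise ValueError("cB must be non-negative")
    R = np.clip(R, 1e-9, 1.0 - 1e-12)

    # default to the rigid configuration so unmatched (non-finite) stress
    # inputs cannot leave uninitialised entries
    pm = R.copy()
    pp = np.ones_like(R)
    nz = np.abs(pz) > PZ_FLOOR
    pz_safe = np.where(nz, pz, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        s = 2.0 * MGz / (R * pz_safe)
        disc = (cB / pz_safe) ** 2 + R**2 - 2.0 * R * MGz / pz_safe
        sq = np.sqrt(np.maximum(disc, 0.0))
        half = cB / np.abs(pz_safe)
        s_hi = 1.0 + cB**2 / (R * pz_safe) ** 2

    b1 = nz & (s < 1.0)
    b2 = nz & (s >= 1.0) & (s <= s_hi)
    b3 = nz & (s > s_hi)
    pm[b1] = (-half + sq)[b1]
    pp[b1] = (half + sq)[b1]
    pm[b2] = (half - sq)[b2]
    pp[b2] = (half + sq)[b2]
    pm[b3] = R[b3]
    pp[b3] = R[b3]

    z0 = ~nz
    if np.any(z0):
        if cB > 0:
            pm[z0] = (R * np.abs(MGz) / cB)[z0]
        else:
            pm[z0] = np.where(np.abs(MGz)[z0] > 0, 1.0, R[z0])
        pp[z0] = 1.0

    Pm = np.clip(pm, R, 1.0)
    Pp = np.clip(pp, R, 1.0)
    regime = classify_regime(1.0 - Pp, 1.0 - Pm, 1.0 - R) if classify else None
    return YieldSurfacesLW(Pm, Pp, pm, pp, regime)


def regularise_tf(surfaces: YieldSurfacesTF, Y_min: float) -> YieldSurfacesTF:
    """Floor the clipped thin-film surfaces at ``Y_min`` (flux evaluation only)."""
    return replace(
        surfaces,
        Y_minus=np.maximum(surfaces.Y_minus, Y_min),
        Y_plus=np.maximum(surfaces.Y_plus, Y_min),
    )


def regularise_lw(surfaces: YieldSurfacesLW, Y_min: float) -> YieldSurfacesLW:
    """Cap the clipped long-wave surfaces at ``1 - Y_min`` away from the wall."""
    return replace(
        surfaces,
        Psi_minus=np.minimum(surfaces.Psi_minus, 1.0 - Y_min),
        Psi_plus=np.minimum(surfaces.Psi_plus, 1.0 - Y_min),
    )


def regime_map(model: str, R_or_H: float, axis_p, axis_m) -> np.ndarray:
    """Yielding-type map over a plane of stress ratios.

    ``model == "thin_film"``: axes are ``H*pz/B`` and ``M*Gamma_z/B`` (the map
    is computed at H = 1, B = 1 and is scale-invariant in both).
    ``model == "long_wave"``: axes are ``pz/cB`` and ``cM*Gamma_z/cB`` at
    fixed interface radius ``R_or_H``.

    Returns an integer-coded matrix with shape (len(axis_m), len(axis_p)).
    """
    axis_p = np.asarray(axis_p, dtype=float)
    axis_m = np.asarray(axis_m, dtype=float)
    P, Mg = np.meshgrid(axis_p, axis_m)
    if model == "thin_film":
        H = float(R_or_H) if R_or_H else 1.0
        surf = tf_yield_surfaces(
            np.full(P.size, H), P.ravel() / H, Mg.ravel(), 1.0
        )
    elif model == "long_wave":
        R = float(R_or_H)
        surf = lw_yield_surfaces(np.full(P.size, R), P.ravel(), Mg.ravel(), 1.0)
    else:
        raise ValueError(f"unknown model {model!r}")
    return surf.regime.reshape(P.shape)
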