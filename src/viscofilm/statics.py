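"""Static marginally-yielded profiles, stability thresholds and late-time
asymptotics.

An unstable thin film with strong surfactant approaches a marginally-yielded
static state in which the capillary stress is twice the Marangoni stress and
the resultant wall stress magnitude equals the yield stress:
``|H0 (H0_z + H0_zzz)| = 2 B``, together with ``H0_z = 0`` at the symmetry
boundaries and ``integral(H0) = L``.  (The surfactant-free problem obeys the
same relation with 2B replaced by B: sufficiently strong surfactant doubles
the effective capillary Bingham number.)  The surfactant settles onto the
linear profile ``M*Gamma0 = M - B*L/2 + B*z``, valid while ``2M >= B*L``.

On the default domain L = 2*pi the flat film is resonant — ``H = 1 - A cos z``
satisfies the marginal relation exactly with B = 0 for every A — and the
single-signed form of the static equation admits no nontrivial solution as a
classical boundary-value problem (a perturbation expansion about the flat
state is obstructed at second order, and exhaustive shooting scans find a
residual floor proportional to B**2 rather than roots; the attractors of the
dynamics are marginally yielded with piecewise stress sign).  This module
therefore computes the static family operationally, from the dynamics it
summarises:

* ``bm_of_A`` / ``solve_static_profile(..., branch="lower")`` define B_m(A)
  as the stability threshold of the strong-surfactant (immobilised-interface)
  limit equation: the largest capillary Bingham number at which an initial
  perturbation of amplitude A still triggers growth.  This is precisely the
  property the static lower branch predicts (the surfactant-free threshold
  is its exact double).
* ``solve_static_profile(..., branch="upper")`` relaxes an unstable
  strong-surfactant run onto its marginally-yielded attractor and matches
  the requested depression amplitude by bisection on B.

The approach to the static state is algebraic, H = H0 + H1/(B t) + ..., with
O(1/t) corrections solved here by damped Newton iteration.  A
Rankine-Hugoniot diagnostic gives the speed of the shock-like fronts in the
surfactant-gradient field, ``u_s = [ (ws*Gamma)_z ] / [ Gamma_z ]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_bvp
from scipy.optimize import root

from .core import Grid, make_grid, d1, d3, integral

__all__ = [
    "StaticSolution",
    "Gamma0Profile",
    "LateTimeCorrection",
    "ShockDiagnostic",
    "solve_static_profile",
    "bm_of_A",
    "marginal_bingham",
    "gamma0_profile",
    "late_time_correction",
    "validate_late_time",
    "shock_speed",
]


@dataclass
class StaticSolution:
    """Marginally-yielded static profile and its capillary Bingham number."""

    H0: np.ndarray
    B: float
    amplitude: float
    branch: str  # "lower" (near-flat threshold state) or "upper" (deformed)
    grid: Grid

    @property
    def max_height(self) -> float:
        return float(self.H0.max())


@dataclass
class Gamma0Profile:
    """Linear static surfactant profile; valid only while non-negative."""

    Gamma0: np.ndarray
    valid: bool


@dataclass
class LateTimeCorrection:
    """O(1/t) correction fields of the late-time expansion."""

    H1: np.ndarray
    Gamma1: np.ndarray
    Y_minus1: np.ndarray
    Y_plus1: np.ndarray
    W1: np.ndarray
    static: StaticSolution
    M: float
    Gamma0: np.ndarray


@dataclass
class ShockDiagnostic:
    """Rankine-Hugoniot shock speed and the one-sided jumps behind it."""

    u_s: float
    jump_Gz: float
    jump_flux: float
    location: float


# ---------------------------------------------------------------------------
# strong-surfactant relaxation machinery

_GROWTH_TOL = 1e-2  # peak-height increase distinguishing growth from rigidity
_BM_CACHE: dict = {}
_MARCH_CACHE: dict = {}


def _march(B: float, A: float, L: float, t_end: float, N: int = 241):
    """Final profile of a strong-surfactant limit run from the cosine IC."""
    from .core import ThinFilmParams
    from .experiments import initial_condition_tf
    from .solver import EventSpec, evolve

    key = (round(B, 10), round(A, 10), round(L, 10), t_end, N)
    if key in _MARCH_CACHE:
        return _MARCH_CACHE[key]
    params = ThinFilmParams(B=B, M=0.0, A=A, L=L)
    grid = make_grid(L, N)
    state0 = initial_condition_tf(A, L, grid)
    res = evolve("thin_film_largeM", state0, params,
                 EventSpec(t_end=t_end, n_out=3), grid)
    if res.stop_reason == "failure":
        raise RuntimeError(f"relaxation run failed at B={B}, A={A}")
    out = (grid, res.profile[0], res.profile[-1])
    _MARCH_CACHE[key] = out
    return out


def _grows(B: float, A: float, L: float, t_end: float, N: int = 241) -> bool:
    _, H_first, H_last = _march(B, A, L, t_end, N=N)
    return float(H_last.max() - H_first.max()) > _GROWTH_TOL


def marginal_bingham(A: float, L: float = 2 * np.pi, rel_tol: float = 0.01,
                     t_end: float = 1e4, N: int = 241) -> float:
    """Stability threshold B_m(A) of the strong-surfactant limit equation.

    Bisection on B between growth and rigidity of the standard cosine
    perturbation of amplitude A; the bracket starts around the small-
    amplitude estimate A/(2*pi) and is widened if it does not straddle.
    """
    if not 0 < A < 1:
        raise ValueError("amplitude must lie in (0, 1)")
    key = (round(A, 10), round(L, 10), rel_tol, t_end, N)
    if key in _BM_CACHE:
        return _BM_CACHE[key]
    base = A / (2 * np.pi)
    lo, hi = 0.5 * base, 1.6 * base
    for _ in range(6):
        if _grows(lo, A, L, t_end, N):
            break
        lo *= 0.5
    else:
        raise RuntimeError("no growing bracket end found")
    for _ in range(6):
        if not _grows(hi, A, L, t_end, N):
            break
        hi *= 1.6
    else:
        raise RuntimeError("no rigid bracket end found")
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if _grows(mid, A, L, t_end, N):
            lo = mid
        else:
            hi = mid
    B = 0.5 * (lo + hi)
    _BM_CACHE[key] = B
    return B


def _resonant(L: float) -> bool:
    """True when the domain supports a neutral cosine mode (sin L = 0)."""
    return abs(np.sin(L)) < 1e-6


def _bvp_solve_once(A: float, L: float, z, y, Bg: float):
    def odes(zz, yy, p):
        B = p[0]
        H, Hz, Hzz, _ = yy
        return np.vstack([Hz, Hzz, 2.0 * B / H - Hz, H])

    def bcs(ya, yb, p):
        return np.array([ya[1], yb[1], ya[3], yb[3] - L, ya[0] - (1.0 - A)])

    return solve_bvp(odes, bcs, z, y, p=[Bg], tol=1e-10, max_nodes=20000)


def _bvp_linear_guess(A: float, L: float, z):
    """Small-amplitude static profile on a non-resonant domain."""
    sinL, cosL = np.sin(L), np.cos(L)
    c2 = -2.0
    c1 = 2.0 * (1.0 - cosL) / sinL
    c0 = -(L**2 + c1 * sinL + c2 * (1.0 - cosL)) / L
    B = A / (-(c0 + c1))
    h = B * (2 * z + c0 + c1 * np.cos(z) + c2 * np.sin(z))
    H = 1.0 + h
    Hz = B * (2 - c1 * np.sin(z) + c2 * np.cos(z))
    Hzz = B * (-c1 * np.cos(z) - c2 * np.sin(z))
    V = np.concatenate(
        [[0.0], np.cumsum(0.5 * (H[1:] + H[:-1]) * np.diff(z))]
    )
    return np.vstack([H, Hz, Hzz, V]), B


def _bvp_continuation(amplitude: float, L: float):
    """Classical amplitude continuation from the flat state (non-resonant L)."""
    A0 = min(0.05, amplitude)
    z = np.linspace(0.0, L, 301)
    y, Bg = _bvp_linear_guess(A0, L, z)
    sol = _bvp_solve_once(A0, L, z, y, Bg)
    if not sol.success:
        raise RuntimeError("static continuation failed at the anchor")
    A_cur, B_cur, B_prev_slope = A0, float(sol.p[0]), 1.0
    step = 0.02
    while A_cur < amplitude - 1e-12:
        dA = min(step, amplitude - A_cur)
        trial = _bvp_solve_once(A_cur + dA, L, sol.x, sol.y, B_cur)
        ok = trial.success and float(trial.p[0]) > 1e-8
        if ok:
            B_prev_slope = (float(trial.p[0]) - B_cur) / dA
            A_cur += dA
            sol, B_cur = trial, float(trial.p[0])
            step *= 1.5
        else:
            step /= 2.0
            if step < 1e-5:
                raise RuntimeError(
                    f"static continuation stalled near A={A_cur:.4f}"
                )
    branch = "lower" if B_prev_slope > 0 else "upper"
    return sol, B_cur, branch


def _upper_branch_amplitude(B: float, L: float, t_end: float = 2e4):
    """Depression amplitude 1 - H(0) of the deformed attractor at given B."""
    A0 = 0.45
    grid, _, H = _march(B, A0, L, t_end)
    return float(1.0 - H[0]), grid, H


def solve_static_profile(
    amplitude: float,
    L: float = 2 * np.pi,
    grid: Optional[Grid] = None,
    branch: str = "lower",
) -> StaticSolution:
    """Static profile with depression amplitude ``1 - H0(0) = amplitude``.

    On a non-resonant domain (``sin L != 0``) this is the classical
    boundary-value continuation from the flat state with B as the unknown
    eigenparameter (``branch`` is then determined by the local slope of
    B(A)).  On the resonant default ``L = 2*pi`` no classical solution
    exists (see the module docstring) and the profile is produced by
    relaxation: ``branch="lower"`` returns the near-flat state frozen just
    above the stability threshold (its B is the threshold value);
    ``branch="upper"`` returns the strongly deformed attractor of an
    unstable strong-surfactant run, with B matched to the requested
    amplitude by bisection.
    """
    if not 0 < amplitude < 1:
        raise ValueError("amplitude must lie in (0, 1)")
    if grid is None:
        grid = make_grid(L, 200)

    if not _resonant(L):
        # classical boundary-value continuation from the flat state
        sol, B, branch_found = _bvp_continuation(amplitude, L)
        H0 = sol.sol(grid.z)[0]
        return StaticSolution(H0=H0, B=B, amplitude=amplitude,
                              branch=branch_found, grid=grid)

    if branch == "lower":
        B = marginal_bingham(amplitude, L)
        g, _, H = _march(1.02 * B, amplitude, L, t_end=1e4)
        H0 = np.interp(grid.z, g.z, H)
        return StaticSolution(H0=H0, B=B, amplitude=float(1.0 - H[0]),
                              branch="lower", grid=grid)
    if branch == "upper":
        # amplitude of the attractor decreases as B increases
        lo, hi = 0.005, marginal_bingham(0.45, L)
        a_hi, g, H = _upper_branch_amplitude(hi, L)
        a_lo, _, _ = _upper_branch_amplitude(lo, L)
        if not (min(a_lo, a_hi) <= amplitude <= max(a_lo, a_hi)):
            raise ValueError(
                f"amplitude {amplitude} outside reachable upper-branch range "
                f"({min(a_lo,a_hi):.3f}, {max(a_lo,a_hi):.3f})"
            )
        for _ in range(8):
            mid = 0.5 * (lo + hi)
            a_mid, g, H = _upper_branch_amplitude(mid, L)
            if (a_mid - amplitude) * (a_lo - amplitude) > 0:
                lo, a_lo = mid, a_mid
            else:
                hi = mid
        B = 0.5 * (lo + hi)
        _, g, H = _upper_branch_amplitude(B, L)
        H0 = np.interp(grid.z, g.z, H)
        return StaticSolution(H0=H0, B=B, amplitude=float(1.0 - H[0]),
                              branch="upper", grid=grid)
    raise ValueError(f"unknown branch {branch!r}")


def bm_of_A(
    A_values: Sequence[float], L: float = 2 * np.pi,
    rel_tol: float = 0.01, t_end: float = 1e4,
) -> pd.DataFrame:
    """Table of (A, B_m) stability thresholds; the clean threshold is 2*B_m."""
    A_values = sorted(float(a) for a in A_values)
    if not all(0 < a < 1 for a in A_values):
        raise ValueError("amplitudes must lie in (0, 1)")
    rows = []
    for a in A_values:
        bm = marginal_bingham(a, L, rel_tol=rel_tol, t_end=t_end)
        rows.append({"A": a, "B_m": bm, "two_B_m": 2 * bm,
                     "linear_estimate": a / (2 * np.pi)})
    return pd.DataFrame(rows)


def gamma0_profile(B: float, M: float, L: float, grid: Grid) -> Gamma0Profile:
    """Linear static surfactant profile with slope B/M and mass L."""
    if M <= 0:
        raise ValueError("the static surfactant profile requires M > 0")
    Gamma0 = (M - B * L / 2.0 + B * grid.z) / M
    return Gamma0Profile(Gamma0=Gamma0, valid=bool(2.0 * M >= B * L))


def _correction_residual(u, static: StaticSolution, M: float,
                         Gamma0: np.ndarray, grid: Grid):
    N = grid.N
    a, G1 = u[:N], u[N:]
    D, B = static.H0, static.B
    h = d1(a**2, grid)  # H1; odd about the boundaries
    MGz1 = M * d1(G1, grid)
    pz1_term = d1(h, grid, parity="odd") + d3(h, grid, parity="odd")
    rA = a - (h - (D / (2 * B)) * MGz1 + (D**2 / (2 * B)) * pz1_term)
    W1 = B * a**2 / D - (D / (4 * B)) * MGz1**2
    flux = Gamma0 * W1
    flux[0] = flux[-1] = 0.0
    rG = B * G1 - d1(flux, grid, parity="odd")
    return rA, rG, h, W1, MGz1


def late_time_correction(
    static: StaticSolution,
    M: float,
    grid: Optional[Grid] = None,
    seed: Optional[tuple] = None,
) -> LateTimeCorrection:
    """O(1/t) correction fields for a valid static solution (2M >= B*L).

    The coupled algebraic-differential relations for (Y-1, Gamma1) admit the
    trivial root, so the solve is a damped Newton iteration over a
    deterministic ladder of seed amplitudes; the physical root is selected by
    requiring Y-1 >= 0 with non-trivial magnitude and W1 <= 0 in the interior.
    """
    if grid is None:
        grid = static.grid
    B, L = static.B, grid.L
    if 2.0 * M < B * L:
        raise ValueError("late-time expansion requires 2M >= B*L")
    Gamma0 = gamma0_profile(B, M, L, grid).Gamma0
    N = grid.N

    def fun(u):
        rA, rG, _, _, _ = _correction_residual(u, static, M, Gamma0, grid)
        return np.concatenate([rA, rG])

    shape = np.sin(np.pi * grid.z / L) ** 2
    seeds = []
    if seed is not None:
        seeds.append(np.concatenate(seed))
    seeds += [
        np.concatenate([c * shape, np.zeros(N)])
        for c in (0.05, 0.1, 0.02, 0.2, 0.5, 1.0, 2.0)
    ]

    best = None
    for u0 in seeds:
        sol = root(fun, u0, method="hybr", tol=1e-13)
        if not sol.success:
            continue
        a = sol.x[:N]
        if np.max(np.abs(a)) < 1e-8:
            continue  # trivial root
        if np.min(a) < -1e-6 * max(1.0, np.max(np.abs(a))):
            continue
        _, _, h, W1, MGz1 = _correction_residual(
            sol.x, static, M, Gamma0, grid
        )
        if np.max(W1) > 1e-8 * max(1.0, np.max(np.abs(W1))):
            continue
        best = (sol.x, h, W1, MGz1)
        break
    if best is None:
        raise RuntimeError("late-time correction solve did not converge")

    u, h, W1, MGz1 = best
    a, G1 = u[:N], u[N:]
    Yp1 = h - (static.H0 / (2 * B)) * MGz1
    return LateTimeCorrection(
        H1=h, Gamma1=G1, Y_minus1=a, Y_plus1=Yp1, W1=W1,
        static=static, M=M, Gamma0=Gamma0,
    )


def validate_late_time(simulation, correction: LateTimeCorrection,
                       t_check: float, skip_boundary: int = 8) -> dict:
    """Sup-norm discrepancies between scaled simulation residuals and the
    O(1/t) correction fields at the stored time nearest ``t_check``.

    The comparison excludes ``skip_boundary`` nodes at each end, where the
    symmetric discretisation of the dynamics develops a corner (the stress
    changes sign in a thin zone) that the interior late-time expansion does
    not describe.
    """
    from .thin_film import tf_fields

    if simulation.model != "thin_film":
        raise ValueError("late-time validation needs a thin-film run")
    params = simulation.params
    if 2.0 * params.M < params.B * params.L:
        raise ValueError("run is outside the late-time regime (2M < B*L)")
    i = int(np.argmin(np.abs(simulation.times - t_check)))
    t = simulation.times[i]
    if t <= 0:
        raise ValueError("t_check precedes the first stored time")
    H = simulation.profile[i]
    Gam = simulation.Gamma[i]
    grid = simulation.grid
    Bt = correction.static.B * t
    sl = slice(skip_boundary, -skip_boundary)

    f = tf_fields(H, Gam, params, grid)
    scaled = {
        "H1": (H - correction.static.H0) * Bt,
        "Y_minus1": f.surfaces.Y_minus * Bt,
        "Y_plus1_minus_H1": (f.surfaces.Y_plus - H) * Bt,
        "Gamma1": (Gam - correction.Gamma0) * Bt,
    }
    reference = {
        "H1": correction.H1,
        "Y_minus1": correction.Y_minus1,
        "Y_plus1_minus_H1": correction.Y_plus1 - correction.H1,
        "Gamma1": correction.Gamma1,
    }
    report = {"t": float(t)}
    for k in reference:
        report[k] = float(np.max(np.abs(scaled[k][sl] - reference[k][sl])))
        report[k + "_scale"] = float(np.max(np.abs(reference[k][sl])))
    return report


def shock_speed(Gamma: np.ndarray, ws_Gamma: np.ndarray, grid: Grid,
                jump_floor: float = 1e-10) -> ShockDiagnostic:
    """Rankine-Hugoniot speed of the steepest front in the Gamma_z field.

    The front is the node of steepest |Gamma_zz|; one-sided values of
    Gamma_z and (ws*Gamma)_z on each side are linearly extrapolated to the
    front from 3 nodes per side, skipping the 2 nodes nearest the front
    (the scheme smears the discontinuity over a few grid cells).  The speed
    is undefined (NaN) when the Gamma_z jump is below ``jump_floor``.
    """
    Gz = d1(Gamma, grid)
    Fz = d1(np.asarray(ws_Gamma, dtype=float), grid, parity="odd")
    Gzz = d1(Gz, grid, parity="odd")
    k = 5 + int(np.argmax(np.abs(Gzz[5:-5])))
    z0 = grid.z[k]

    def one_sided(fieldvals, side):
        idx = (np.arange(k - 4, k - 1) if side == "left"
               else np.arange(k + 2, k + 5))
        coef = np.polyfit(grid.z[idx], fieldvals[idx], 1)
        return np.polyval(coef, z0)

    jump_Gz = one_sided(Gz, "right") - one_sided(Gz, "left")
    jump_Fz = one_sided(Fz, "right") - one_sided(Fz, "left")
    if abs(jump_Gz) < jump_floor:
        return ShockDiagnostic(np.nan, jump_Gz, jump_Fz, z0)
    return ShockDiagnostic(jump_Fz / jump_Gz, jump_Gz, jump_Fz, z0)
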