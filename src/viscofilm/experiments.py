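"""Initial conditions, dimensional conversion, sweep drivers and file I/O.

The built-in initial states are a single-mode cosine perturbation of the
interface with uniform surfactant: for the thin film
``H = 1 - A*cos(pi*z/L)`` and for the long-wave model
``R = sqrt((1-eps)^2 - eps^2*A^2/2) - eps*A*cos(pi*z/L)``, whose constant
term keeps the liquid volume independent of the perturbation amplitude A.
With the default L = 2*pi this perturbation is the one unstable Fourier mode
of the Newtonian problem that fits the domain.

Named presets reproduce the package's reference experiments; sweep drivers
emit tidy DataFrames (one simulation per row) for the stability and critical
thickness maps.
"""

from __future__ import annotations

from dataclasses import asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    DimensionalParams,
    Grid,
    LongWaveParams,
    SimulationResult,
    ThinFilmParams,
    make_grid,
)
from .long_wave import LongWaveState
from .solver import EventSpec, epsilon_crit_search, evolve
from .thin_film import ThinFilmState

__all__ = [
    "initial_condition_tf",
    "initial_condition_lw",
    "dimensional_time",
    "run_thin_film",
    "run_long_wave",
    "sweep_final_peak",
    "sweep_ecrit",
    "summary_frame",
    "save_result",
    "load_result",
    "PRESETS",
]


def initial_condition_tf(A: float, L: float, grid: Grid) -> ThinFilmState:
    """Cosine-perturbed flat film, uniform surfactant: H = 1 - A*cos(pi z/L)."""
    if not 0 <= A < 1:
        raise ValueError("perturbation amplitude must lie in [0, 1)")
    H = 1.0 - A * np.cos(np.pi * grid.z / L)
    return ThinFilmState(0.0, H, np.ones(grid.N))


def initial_condition_lw(A: float, eps: float, L: float, grid: Grid) -> LongWaveState:
    """Volume-preserving cosine perturbation of an annular layer of mean
    thickness ratio ``eps``; the square-root constant keeps
    ``integral(R^2) dz = (1-eps)^2 * L`` for every A."""
    if not 0 < eps < 1:
        raise ValueError("eps must lie in (0, 1)")
    if A < 0:
        raise ValueError("perturbation amplitude must be non-negative")
    const = (1.0 - eps) ** 2 - eps**2 * A**2 / 2.0
    if const <= 0:
        raise ValueError("perturbation too large for this eps")
    R = np.sqrt(const) - eps * A * np.cos(np.pi * grid.z / L)
    if np.any(R <= 0) or np.any(R >= 1):
        raise ValueError("initial interface radius leaves (0, 1)")
    return LongWaveState(0.0, R, np.ones(grid.N))


def dimensional_time(t_tilde, eps: float, dims: DimensionalParams):
    """Convert thin-film time(s) t~ to seconds: t* = t~ * a*eta/(sigma0*eps^3)."""
    if not 0 < eps < 1:
        raise ValueError("eps must lie in (0, 1)")
    return np.asarray(t_tilde, dtype=float) * dims.time_unit / eps**3


def run_thin_film(
    params: ThinFilmParams,
    event_spec: Optional[EventSpec] = None,
    N: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    large_M: bool = False,
) -> SimulationResult:
    """One thin-film simulation from the standard initial condition."""
    if event_spec is None:
        event_spec = EventSpec()
    grid = make_grid(params.L, N)
    state0 = initial_condition_tf(params.A, params.L, grid)
    model = "thin_film_largeM" if large_M else "thin_film"
    return evolve(model, state0, params, event_spec, grid, rtol=rtol, atol=atol)


def run_long_wave(
    params: LongWaveParams,
    event_spec: Optional[EventSpec] = None,
    N: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SimulationResult:
    """One long-wave simulation from the standard initial condition."""
    if event_spec is None:
        event_spec = EventSpec()
    grid = make_grid(params.L, N)
    state0 = initial_condition_lw(params.A, params.eps, params.L, grid)
    return evolve("long_wave", state0, params, event_spec, grid,
                  rtol=rtol, atol=atol)


# Reference experiment presets (thin-film groups B, M or long-wave cB, cM).
PRESETS = {
    "tf-reference": ThinFilmParams(B=0.04, M=0.2, A=0.2),
    "tf-partial-yield": ThinFilmParams(B=0.04, M=0.08, A=0.2),
    "lw-clean-plug": LongWaveParams(cB=0.001, cM=0.0, eps=0.14, A=0.2),
    "lw-surfactant-plug": LongWaveParams(cB=0.001, cM=0.02, eps=0.14, A=0.2),
    "lw-strong-surfactant": LongWaveParams(cB=0.001, cM=10.0, eps=0.14, A=0.25),
}


def sweep_final_peak(
    B_values: Sequence[float],
    M_values: Sequence[float],
    A: float = 0.2,
    event_spec: Optional[EventSpec] = None,
    N: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Thin-film stability sweep: final peak height over a B x M grid.

    Adds the reference quantities 2M/(B*L) (surface-yielding boundary) per
    row; rows carry the full configuration so any entry is regenerable.
    """
    rows = []
    for B in B_values:
        for M in M_values:
            params = ThinFilmParams(B=float(B), M=float(M), A=A)
            res = run_thin_film(params, event_spec, N=N, rtol=rtol, atol=atol)
            rows.append(
                {
                    "B": B,
                    "M": M,
                    "A": A,
                    "final_peak": float(res.profile[-1].max()),
                    "growth": float(res.profile[-1].max() - res.profile[0].max()),
                    "two_M_over_BL": (2 * M / (B * params.L)) if B > 0 else np.inf,
                    "stop_reason": res.stop_reason,
                    "max_drift": res.conservation_report.worst,
                }
            )
    return pd.DataFrame(rows)


def sweep_ecrit(
    cB_values: Sequence[float],
    cM: float,
    A: float = 0.25,
    bracket: tuple = (0.1, 0.25),
    tol: float = 0.001,
    event_spec: Optional[EventSpec] = None,
    N: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Critical thickness for plug formation along an axis of cB values."""
    rows = []
    for cB in cB_values:
        base = LongWaveParams(cB=float(cB), cM=float(cM), eps=0.14, A=A)
        eps_crit = epsilon_crit_search(
            base, bracket, tol=tol, event_spec=event_spec, N=N,
            rtol=rtol, atol=atol,
        )
        rows.append({"cB": cB, "cM": cM, "A": A, "eps_crit": eps_crit,
                     "tol": tol})
    return pd.DataFrame(rows)


def summary_frame(result: SimulationResult) -> pd.DataFrame:
    """Tabular per-time summary: peak height, min R, wall stress, conserved
    integrals."""
    from .long_wave import lw_fields
    from .thin_film import tf_fields

    rows = []
    for i, t in enumerate(result.times):
        prof = result.profile[i]
        gam = result.Gamma[i]
        row = {"t": t, "t_scaled": t * result.time_scale}
        if result.model == "long_wave":
            f = lw_fields(prof, gam, result.params, result.grid)
            row.update(
                min_R=float(prof.min()),
                max_height=float((1 - prof.min()) / result.params.eps),
                max_abs_wall_stress=float(np.abs(f.tau_w).max()),
                volume=float(np.trapezoid(1 - prof**2, dx=result.grid.dz)),
                surfactant=float(np.trapezoid(prof * gam, dx=result.grid.dz)),
            )
        elif result.model == "thin_film":
            f = tf_fields(prof, gam, result.params, result.grid)
            row.update(
                max_height=float(prof.max()),
                max_abs_wall_stress=float(np.abs(f.tau_w).max()),
                mass=float(np.trapezoid(prof, dx=result.grid.dz)),
                surfactant=float(np.trapezoid(gam, dx=result.grid.dz)),
            )
        else:
            row.update(
                max_height=float(prof.max()),
                mass=float(np.trapezoid(prof, dx=result.grid.dz)),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def save_result(result: SimulationResult, directory) -> None:
    """Write a run as summary CSV plus an array container (.npz)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    summary_frame(result).to_csv(directory / "summary.csv", index=False)
    np.savez(
        directory / "arrays.npz",
        z=result.grid.z,
        times=result.times,
        profile=result.profile,
        Gamma=result.Gamma,
        model=np.array(result.model),
        t_p=np.array(np.nan if result.t_p is None else result.t_p),
        plug_formed=np.array(result.plug_formed),
        stop_reason=np.array(result.stop_reason),
        params=np.array(repr(result.params)),
    )


def load_result(directory) -> dict:
    """Read back the array container written by :func:`save_result`."""
    with np.load(Path(directory) / "arrays.npz") as data:
        return {k: data[k] for k in data.files}
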