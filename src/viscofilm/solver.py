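"""Method-of-lines time integration, plug detection and critical thickness.

Both model systems are stiff (the capillary term carries a fourth spatial
derivative, so the spectral radius scales as dz**-4); they are integrated with
the variable-order implicit multistep BDF method from scipy, supplied with a
banded Jacobian sparsity pattern so the finite-difference Jacobian costs a few
right-hand-side evaluations per update.  Long-wave runs stop early at the plug
event, min_z R <= 0.3, which is the operational criterion for imminent plug
formation; the stopping time is the plugging time t_p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .core import (
    ConservationReport,
    Grid,
    LongWaveParams,
    SimulationResult,
    ThinFilmParams,
    integral,
    make_grid,
)
from .long_wave import LongWaveState, lw_rhs
from .thin_film import ThinFilmState, tf_largeM_rhs, tf_rhs
from .yield_structure import (
    YieldSurfacesLW,
    YieldSurfacesTF,
    regularise_lw,
    regularise_tf,
)

__all__ = [
    "EventSpec",
    "regularise_surfaces",
    "evolve",
    "detect_plug",
    "epsilon_crit_search",
]


@dataclass(frozen=True)
class EventSpec:
    """Stopping rules and output schedule (times in thin-film t~ units)."""

    plug_threshold: float = 0.3
    t_end: float = 1e4
    n_out: int = 201
    output_times: Optional[Sequence[float]] = None

    def __post_init__(self):
        if not 0 < self.plug_threshold < 1:
            raise ValueError("plug_threshold must lie in (0, 1)")
        if not self.t_end > 0:
            raise ValueError("t_end must be positive")

    def schedule(self) -> np.ndarray:
        """Output times: t=0 plus a geometric ladder up to t_end."""
        if self.output_times is not None:
            t = np.asarray(self.output_times, dtype=float)
        else:
            t = np.geomspace(self.t_end * 1e-4, self.t_end, self.n_out)
        if t[0] > 0:
            t = np.concatenate([[0.0], t])
        return t


def regularise_surfaces(surfaces, Y_min: float):
    """Apply the yield-surface regularisation floor/cap before flux evaluation."""
    if isinstance(surfaces, YieldSurfacesTF):
        return regularise_tf(surfaces, Y_min)
    if isinstance(surfaces, YieldSurfacesLW):
        return regularise_lw(surfaces, Y_min)
    raise TypeError(f"unsupported surfaces type {type(surfaces).__name__}")


def _band_sparsity(N: int, n_fields: int, halfwidth: int = 4) -> sparse.csr_matrix:
    offsets = range(-halfwidth, halfwidth + 1)
    band = sparse.diags([np.ones(N)] * len(list(offsets)),
                        list(range(-halfwidth, halfwidth + 1)),
                        shape=(N, N))
    return sparse.csr_matrix(
        sparse.kron(np.ones((n_fields, n_fields)), band)
    )


def evolve(
    model: str,
    state0,
    params,
    event_spec: EventSpec,
    grid: Grid,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
    max_step: Optional[float] = None,
) -> SimulationResult:
    """Integrate one model from ``state0`` until plugging, t_end or failure.

    ``model`` is one of ``thin_film``, ``thin_film_largeM`` or ``long_wave``.
    Long-wave runs integrate in unscaled time internally; ``event_spec`` times
    are always thin-film t~ units.
    """
    N = grid.N
    if model == "long_wave":
        if not isinstance(params, LongWaveParams):
            raise TypeError("long_wave model needs LongWaveParams")
        scale = params.eps**3  # t~ = eps^3 * t
        # With no surfactant coupling (cM = 0) the concentration field is
        # dynamically inert: it does not feed back on the flow and nothing
        # depends on it, so it is held at its initial value and only R is
        # integrated (this is the surfactant-free model).
        passive = params.cM == 0.0
        if passive:
            y0 = np.asarray(state0.R, dtype=float).copy()
            Gamma0_frozen = np.asarray(state0.Gamma, dtype=float).copy()

            def fun(t, y):
                Rsafe = np.clip(y, 0.02, 1.0 - 1e-9)
                dR, _ = lw_rhs(
                    LongWaveState(t, Rsafe, Gamma0_frozen), params, grid
                )
                return dR

            def plug_event(t, y):
                return np.min(y) - event_spec.plug_threshold

            n_fields = 1
        else:
            y0 = np.concatenate([state0.R, state0.R * state0.Gamma])

            def fun(t, y):
                R, S = y[:N], y[N:]
                Rsafe = np.clip(R, 0.02, 1.0 - 1e-9)
                dR, dS = lw_rhs(LongWaveState(t, R, S / Rsafe), params, grid)
                return np.concatenate([dR, dS])

            def plug_event(t, y):
                return np.min(y[:N]) - event_spec.plug_threshold

            n_fields = 2
        plug_event.terminal = True
        plug_event.direction = -1
        events = [plug_event]
    elif model in ("thin_film", "thin_film_largeM"):
        if not isinstance(params, ThinFilmParams):
            raise TypeError(f"{model} model needs ThinFilmParams")
        scale = 1.0
        y0 = np.concatenate([state0.H, state0.Gamma])
        events = None
        if model == "thin_film":
            if params.M == 0.0:
                # surfactant-free: Gamma is inert, evolve H alone
                y0 = np.asarray(state0.H, dtype=float).copy()
                Gamma0_frozen = np.asarray(state0.Gamma, dtype=float).copy()

                def fun(t, y):
                    dH, _ = tf_rhs(
                        ThinFilmState(t, y, Gamma0_frozen), params, grid
                    )
                    return dH

                n_fields = 1
            else:

                def fun(t, y):
                    dH, dG = tf_rhs(
                        ThinFilmState(t, y[:N], y[N:]), params, grid
                    )
                    return np.concatenate([dH, dG])

                n_fields = 2
        else:
            y0 = np.asarray(state0.H, dtype=float).copy()

            def fun(t, y):
                return tf_largeM_rhs(ThinFilmState(t, y, None), params, grid)

            n_fields = 1
    else:
        raise ValueError(f"unknown model {model!r}")

    t_out = event_spec.schedule() / scale
    T = t_out[-1]
    kwargs = {}
    if max_step is not None:
        kwargs["max_step"] = max_step / scale

    try:
        sol = solve_ivp(
            fun,
            (0.0, T),
            y0,
            method=method,
            rtol=rtol,
            atol=atol,
            t_eval=t_out,
            jac_sparsity=_band_sparsity(N, n_fields),
            events=events,
            **kwargs,
        )
    except (FloatingPointError, RuntimeError):
        sol = None

    if sol is None or (sol.status == -1 and sol.t.size == 0):
        g0 = np.asarray(state0.Gamma, dtype=float) if hasattr(state0, "Gamma") \
            and state0.Gamma is not None else np.ones(N)
        return SimulationResult(
            model=model, params=params, grid=grid,
            times=np.array([0.0]),
            profile=y0[None, :N].copy(),
            Gamma=g0[None, :].copy(),
            stop_reason="failure",
        )

    times = sol.t
    Y = sol.y.T
    plug_formed = False
    t_p = None
    stop_reason = {0: "t_end", 1: "plugged", -1: "failure"}[sol.status]
    if sol.status == 1 and sol.t_events and sol.t_events[0].size:
        plug_formed = True
        t_p = float(sol.t_events[0][0])
        ye = sol.y_events[0][0]
        if times.size == 0 or t_p > times[-1] * (1 + 1e-12):
            times = np.append(times, t_p)
            Y = np.vstack([Y, ye])

    if model == "long_wave":
        profile = Y[:, :N]
        conserved = {
            "volume": np.trapezoid(1.0 - profile**2, dx=grid.dz, axis=1),
        }
        if n_fields == 2:
            Gamma = Y[:, N:] / profile
            conserved["surfactant"] = np.trapezoid(Y[:, N:], dx=grid.dz, axis=1)
        else:
            Gamma = np.tile(Gamma0_frozen, (Y.shape[0], 1))
    elif model == "thin_film":
        profile = Y[:, :N]
        conserved = {"mass": np.trapezoid(profile, dx=grid.dz, axis=1)}
        if n_fields == 2:
            Gamma = Y[:, N:]
            conserved["surfactant"] = np.trapezoid(Gamma, dx=grid.dz, axis=1)
        else:
            Gamma = np.tile(Gamma0_frozen, (Y.shape[0], 1))
    else:
        profile = Y
        Gamma = np.ones_like(Y)
        conserved = {"mass": np.trapezoid(profile, dx=grid.dz, axis=1)}

    report = ConservationReport()
    for name, series in conserved.items():
        drift = np.abs(series - series[0]) / max(abs(series[0]), 1e-300)
        report.max_drift[name] = float(drift.max())
        report.worst_time[name] = float(times[int(drift.argmax())])

    return SimulationResult(
        model=model,
        params=params,
        grid=grid,
        times=times,
        profile=profile,
        Gamma=Gamma,
        plug_formed=plug_formed,
        t_p=t_p,
        stop_reason=stop_reason,
        conservation_report=report,
        nfev=sol.nfev,
        njev=sol.njev,
    )


def detect_plug(result: SimulationResult, event_spec: EventSpec) -> Optional[float]:
    """First time min_z R crosses the plug threshold, in t~ units.

    Located by monotone (PCHIP) interpolation of the stored min-R series and
    bracketed root refinement; returns None if the threshold is never reached.
    """
    if result.model != "long_wave":
        return None
    minR = result.min_R
    thr = event_spec.plug_threshold
    below = np.nonzero(minR <= thr)[0]
    if below.size == 0:
        if result.plug_formed and result.t_p is not None:
            # the terminal event located the crossing, but interpolation of
            # the stored state can leave the final sample a hair above the
            # threshold; the event time is the crossing itself
            return float(result.t_p * result.time_scale)
        return None
    k = below[0]
    if k == 0:
        return float(result.times[0] * result.time_scale)
    interp = PchipInterpolator(result.times, minR)
    t_cross = brentq(
        lambda t: interp(t) - thr, result.times[k - 1], result.times[k]
    )
    return float(t_cross * result.time_scale)


def epsilon_crit_search(
    params_base: LongWaveParams,
    bracket: tuple,
    tol: float = 0.001,
    event_spec: Optional[EventSpec] = None,
    N: int = 200,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Bisection on the thickness ratio eps for the plug/no-plug transition.

    ``bracket = (eps_lo, eps_hi)`` must straddle the transition: the thinner
    layer must remain open to t_end while the thicker one plugs.  Returns the
    midpoint of the final bracket, certified to +- tol.
    """
    from dataclasses import replace

    from .experiments import initial_condition_lw

    if event_spec is None:
        event_spec = EventSpec()
    lo, hi = float(bracket[0]), float(bracket[1])
    if not 0 < lo < hi < 1:
        raise ValueError("bracket must satisfy 0 < eps_lo < eps_hi < 1")

    def plugs(eps: float) -> bool:
        params = replace(params_base, eps=eps)
        grid = make_grid(params.L, N)
        state0 = initial_condition_lw(params.A, eps, params.L, grid)
        res = evolve("long_wave", state0, params, event_spec, grid,
                     rtol=rtol, atol=atol)
        return res.plug_formed

    if plugs(lo) or not plugs(hi):
        raise ValueError(
            "bracket does not straddle the plugging transition "
            f"(eps_lo={lo}, eps_hi={hi})"
        )
    while hi - lo > 2 * tol:
        mid = 0.5 * (lo + hi)
        if plugs(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
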