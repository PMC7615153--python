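"""Long-wave curvature, fluxes, tendencies and strong-surfactant diagnostics."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from viscofilm.core import LongWaveParams, ThinFilmParams, d1, integral, make_grid
from viscofilm.long_wave import (
    LongWaveState,
    lw_curvature,
    lw_fields,
    lw_largeM_diagnostics,
    lw_pressure,
    lw_rhs,
    lw_wall_stress,
)
from viscofilm.thin_film import tf_fields
from viscofilm.yield_structure import lw_yield_surfaces


def annular_profile_oracle(R, pz, MGz, cB):
    """Flux and surface velocity by quadrature of the annular Bingham profile.

    Shear stress tau(r) = (pz/2)(r - R^2/r) + (R/r)*MGz; Bingham closure
    dw/dr = tau - cB*sgn(tau) where |tau| > cB, no slip at the tube wall.
    """

    def wr(r):
        t = (pz / 2) * (r - R**2 / r) + (R / r) * MGz
        if abs(t) <= cB:
            return 0.0
        return t - cB * np.sign(t)

    sol = solve_ivp(lambda r, w: [wr(r)], (1.0, R), [0.0], method="DOP853",
                    rtol=1e-11, atol=1e-14, dense_output=True)
    ws = sol.y[0, -1]
    q, _ = quad(lambda r: sol.sol(r)[0] * r, R, 1, limit=400)
    return q, ws


class TestCurvature:
    def test_uniform_interface(self):
        g = make_grid(2 * np.pi, 100)
        assert np.allclose(lw_curvature(np.full(g.N, 0.86), g), 1 / 0.86)
        assert lw_curvature(np.full(g.N, 0.86), g)[0] == pytest.approx(
            1.1628, abs=2e-4
        )

    def test_against_symbolic_evaluation(self):
        import sympy as sp

        zs = sp.symbols("z")
        Rs = 0.9 - 0.05 * sp.cos(zs / 2)
        Rz, Rzz = sp.diff(Rs, zs), sp.diff(Rs, zs, 2)
        kappa_s = (1 / Rs - Rzz / (1 + Rz**2)) / sp.sqrt(1 + Rz**2)
        f = sp.lambdify(zs, kappa_s, "numpy")

        g = make_grid(2 * np.pi, 400)
        R = 0.9 - 0.05 * np.cos(g.z / 2)
        kap = lw_curvature(R, g)
        assert np.abs(kap[5:-5] - f(g.z[5:-5])).max() < 5e-5

    def test_nonpositive_radius_rejected(self):
        g = make_grid(2 * np.pi, 64)
        with pytest.raises(ValueError):
            lw_curvature(np.zeros(g.N), g)


class TestPressure:
    def test_surfactant_neutral_cases(self):
        g = make_grid(2 * np.pi, 64)
        R = np.full(g.N, 0.8)
        assert np.allclose(lw_pressure(R, np.ones(g.N), 5.0, g), -1 / 0.8)
        assert np.allclose(
            lw_pressure(R, 0.3 * np.ones(g.N), 0.0, g), -1 / 0.8
        )

    def test_reduced_concentration_raises_tension(self):
        g = make_grid(2 * np.pi, 64)
        R = np.full(g.N, 0.8)
        p = lw_pressure(R, np.full(g.N, 0.9), 0.02, g)
        assert np.allclose(p, -1.002 / 0.8)


class TestFluxAndVelocity:
    def test_rigid_layer(self):
        g = make_grid(2 * np.pi, 100)
        params = LongWaveParams(cB=10.0, cM=0.02, eps=0.14)
        R = 0.86 - 0.001 * np.cos(np.pi * g.z / g.L)
        f = lw_fields(R, np.ones(g.N), params, g)
        assert np.abs(f.Q).max() < 1e-7
        assert np.abs(f.ws).max() < 1e-7

    def test_against_velocity_profile_quadrature(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            R = rng.uniform(0.35, 0.95)
            pz = rng.choice([-1, 1]) * rng.uniform(0.05, 1.0)
            MGz = rng.uniform(-0.3, 0.3)
            cB = rng.uniform(0.0, 0.12)
            q_o, ws_o = annular_profile_oracle(R, pz, MGz, cB)
            from viscofilm.long_wave import _F_terms

            surf = lw_yield_surfaces([R], [pz], [MGz], cB)
            Pm, Pp = surf.Psi_minus, surf.Psi_plus
            F1, F2, F3, F4, logt = _F_terms(np.array([R]), Pm, Pp)
            s = 2 * MGz / (R * pz)
            br = 1.0 if s < 1 else -1.0
            sgn = np.sign(pz)
            Q = (-pz * F1[0] / 16 - 0.25 * R * MGz * F2[0]
                 - (cB / 6) * sgn * (F3[0] + br * F4[0]))
            ws = (0.25 * pz * (-F2[0]) + R * MGz * logt[0]
                  + cB * sgn * ((1 - Pp[0]) + br * (R - Pm[0])))
            assert Q == pytest.approx(q_o, rel=2e-6, abs=1e-9)
            assert ws == pytest.approx(ws_o, rel=2e-6, abs=1e-9)

    def test_thin_film_limit_of_fluxes(self):
        g = make_grid(2 * np.pi, 300)
        H = 1 - 0.2 * np.cos(np.pi * g.z / g.L)
        Gam = 1 + 0.05 * np.cos(np.pi * g.z / g.L)
        B, M = 0.04, 0.2
        ftf = tf_fields(H, Gam, ThinFilmParams(B=B, M=M), g)
        errs_q, errs_w = [], []
        for eps in (1e-2, 1e-3):
            params = LongWaveParams(cB=B * eps**2, cM=M * eps**2, eps=eps)
            flw = lw_fields(1 - eps * H, Gam, params, g)
            errs_q.append(np.max(np.abs(flw.Q / eps**4 - ftf.q))
                          / np.max(np.abs(ftf.q)))
            errs_w.append(np.max(np.abs(flw.ws / eps**3 - ftf.ws_tilde))
                          / np.max(np.abs(ftf.ws_tilde)))
        # relative error is O(eps)
        assert errs_q[1] < 10 * 1e-3 and errs_w[1] < 10 * 1e-3
        assert errs_q[1] < 0.3 * errs_q[0]


class TestWallStress:
    def test_uniform_state(self):
        g = make_grid(2 * np.pi, 64)
        params = LongWaveParams(cB=0.001, cM=0.02, eps=0.14)
        tw = lw_wall_stress(np.full(g.N, 0.86), np.ones(g.N), params, g)
        assert np.abs(tw).max() < 1e-12

    def test_rigid_nodes_below_yield(self, surfactant_plug_run):
        # wherever the layer is classified fully rigid the wall stress must
        # not exceed the yield stress (internal consistency of Psi with tau_w)
        res = surfactant_plug_run
        params, g = res.params, res.grid
        i = len(res.times) // 2
        f = lw_fields(res.profile[i], res.Gamma[i], params, g)
        rigid = f.surfaces.regime == 5
        if rigid.any():
            assert np.abs(f.tau_w[rigid]).max() <= params.cB * (1 + 1e-6)


class TestTendencies:
    def test_equilibrium_state(self):
        g = make_grid(2 * np.pi, 100)
        params = LongWaveParams(cB=0.001, cM=0.02, eps=0.14)
        dR, dS = lw_rhs(
            LongWaveState(0.0, np.full(g.N, 0.86), np.ones(g.N)), params, g
        )
        assert np.abs(dR).max() < 1e-12
        assert np.abs(dS).max() < 1e-12

    def test_discrete_conservation(self):
        g = make_grid(2 * np.pi, 200)
        params = LongWaveParams(cB=0.001, cM=0.02, eps=0.14)
        R = 0.86 - 0.03 * np.cos(np.pi * g.z / g.L)
        Gam = 1 + 0.1 * np.cos(np.pi * g.z / g.L)
        dR, dS = lw_rhs(LongWaveState(0.0, R, Gam), params, g)
        # volume: d/dt integral(1 - R^2) = -2 integral(R * dR)
        assert abs(integral(2 * R * dR, g)) < 1e-13
        assert abs(integral(dS, g)) < 1e-13


class TestLargeMDiagnostics:
    def test_static_profiles(self):
        g = make_grid(2 * np.pi, 64)
        R = 0.86 - 0.03 * np.cos(np.pi * g.z / g.L)
        series = np.tile(R, (4, 1))
        d = lw_largeM_diagnostics(series, np.array([0.0, 1, 2, 3.0]), g)
        assert np.allclose(d.G0, 1.0)
        assert np.abs(d.W0).max() < 1e-12

    def test_initial_concentration_is_unity(self):
        g = make_grid(2 * np.pi, 64)
        series = np.vstack([np.full(g.N, 0.9), np.full(g.N, 0.85)])
        d = lw_largeM_diagnostics(series, np.array([0.0, 1.0]), g)
        assert d.G0[0] == pytest.approx(1.0)
        assert d.G0[1] == pytest.approx(0.9 / 0.85)

    def test_uniform_shrinkage_induces_no_surface_flow(self):
        # spatially uniform d/dt R means no redistribution is needed
        g = make_grid(2 * np.pi, 64)
        t = np.linspace(0, 1, 5)
        series = np.array([np.full(g.N, 0.9 - 0.05 * tt) for tt in t])
        d = lw_largeM_diagnostics(series, t, g)
        assert np.abs(d.W0).max() < 1e-12

    def test_needs_two_profiles(self):
        g = make_grid(2 * np.pi, 64)
        with pytest.raises(ValueError):
            lw_largeM_diagnostics(np.ones((1, g.N)), np.array([0.0]), g)

    def test_agreement_with_strong_surfactant_run(
        self, strong_surfactant_plug_run
    ):
        # numerical Gamma is near-uniform and close to G0, and ws is close
        # to the leading-order surface velocity, in the cM=10 plug run
        res = strong_surfactant_plug_run
        g = res.grid
        d = lw_largeM_diagnostics(res.profile, res.times, g)
        i = len(res.times) - 2
        gam = res.Gamma[i]
        assert gam.max() - gam.min() < 0.05 * gam.mean()
        assert gam.mean() == pytest.approx(d.G0[i], rel=0.01)
        f = lw_fields(res.profile[i], gam, res.params, g)
        scale = np.abs(d.W0[i]).max()
        if scale > 0:
            assert np.abs(f.ws - d.W0[i]).max() < 0.5 * scale
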