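"""Thin-film fluxes, tendencies and the strong-surfactant limit equation."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from viscofilm.core import ThinFilmParams, d1, integral, make_grid
from viscofilm.experiments import initial_condition_tf, run_thin_film
from viscofilm.solver import EventSpec
from viscofilm.thin_film import (
    ThinFilmState,
    tf_fields,
    tf_largeM_rhs,
    tf_pressure_gradient,
    tf_rhs,
    tf_wall_stress,
)


def bingham_profile_oracle(H, pz, MGz, B):
    """Flux and surface velocity by direct quadrature of the velocity profile.

    The shear stress across the film is tau(y) = pz*(H - y) + MGz (y measured
    from the wall toward the interface, where the Marangoni stress acts);
    Bingham closure gives dw/dy = -(tau - B*sgn(tau)) where |tau| > B and
    zero otherwise, with no slip at the wall.
    """

    def wy(y):
        tau = pz * (H - y) + MGz
        if abs(tau) <= B:
            return 0.0
        return -(tau - B * np.sign(tau))

    sol = solve_ivp(lambda y, w: [wy(y)], (0, H), [0.0], method="DOP853",
                    rtol=1e-11, atol=1e-13, dense_output=True)
    ws = sol.y[0, -1]
    q, _ = quad(lambda y: sol.sol(y)[0], 0, H, limit=200)
    return q, ws


class TestPressureGradient:
    def test_flat_film(self):
        g = make_grid(2 * np.pi, 100)
        assert np.abs(tf_pressure_gradient(np.ones(g.N), g)).max() < 1e-12

    def test_single_mode_closed_form(self):
        # H = 1 - a*cos(kz): pz = -a*k*(1 - k^2)*sin(kz)
        g = make_grid(2 * np.pi, 400)
        a, k = 0.2, 0.5
        H = 1 - a * np.cos(k * g.z)
        expected = -a * k * (1 - k**2) * np.sin(k * g.z)
        err = tf_pressure_gradient(H, g) - expected
        assert np.abs(err).max() < 5e-4

    def test_neutral_wavenumber(self):
        # k = 1 has cancelling capillary terms
        g = make_grid(2 * np.pi, 400)
        H = 1 - 0.2 * np.cos(g.z)
        assert np.abs(tf_pressure_gradient(H, g)).max() < 2e-3


class TestFluxAndVelocity:
    def test_newtonian_reduction(self):
        g = make_grid(2 * np.pi, 200)
        H = 1 - 0.2 * np.cos(np.pi * g.z / g.L)
        params = ThinFilmParams(B=0.0, M=0.0)
        f = tf_fields(H, np.ones(g.N), params, g)
        expected = -f.pz_tilde * H**3 / 3.0
        expected[0] = expected[-1] = 0.0
        assert np.allclose(f.q, expected, atol=1e-10)

    def test_newtonian_with_marangoni(self):
        g = make_grid(2 * np.pi, 200)
        H = 1 - 0.2 * np.cos(np.pi * g.z / g.L)
        Gam = 1 + 0.05 * np.cos(np.pi * g.z / g.L)
        params = ThinFilmParams(B=0.0, M=0.3)
        f = tf_fields(H, Gam, params, g)
        MGz = params.M * d1(Gam, g)
        q_exp = -f.pz_tilde * H**3 / 3.0 - MGz * H**2 / 2.0
        ws_exp = -f.pz_tilde * H**2 / 2.0 - MGz * H
        q_exp[0] = q_exp[-1] = ws_exp[0] = ws_exp[-1] = 0.0
        assert np.allclose(f.q, q_exp, atol=1e-10)
        assert np.allclose(f.ws_tilde, ws_exp, atol=1e-10)

    def test_against_velocity_profile_quadrature(self):
        # the closed-form flux and surface velocity match direct integration
        # of the Bingham velocity profile in every yielding regime
        rng = np.random.default_rng(11)
        g = make_grid(1.0, 8)  # container only; fields supplied pointwise
        for _ in range(25):
            H = rng.uniform(0.3, 2.5)
            pz = rng.uniform(-1, 1)
            MGz = rng.uniform(-0.3, 0.3)
            B = rng.uniform(0.0, 0.15)
            q_o, ws_o = bingham_profile_oracle(H, pz, MGz, B)
            from viscofilm.thin_film import _flux_velocity

            params = ThinFilmParams(B=B, M=1.0, Y_min=1e-13)
            from viscofilm.yield_structure import regularise_tf, tf_yield_surfaces

            surf = regularise_tf(
                tf_yield_surfaces([H], [pz], [MGz], B), 1e-13
            )
            Ym, Yp = surf.Y_minus[0], surf.Y_plus[0]
            hm, hp = H - Ym, H - Yp
            sgn = np.sign(pz)
            q = (-pz * (H**3 + hp**3 - hm**3) / 3.0
                 - 0.5 * MGz * (H**2 - hm**2 + hp**2)
                 + 0.5 * B * sgn * (H**2 - hm**2 - hp**2))
            ws = (-0.5 * pz * (H**2 + hp**2 - hm**2)
                  - MGz * (H + Ym - Yp)
                  - B * sgn * (H - Ym - Yp))
            assert q == pytest.approx(q_o, rel=1e-6, abs=1e-9)
            assert ws == pytest.approx(ws_o, rel=1e-6, abs=1e-9)

    def test_rigid_layer_has_no_flux(self):
        g = make_grid(2 * np.pi, 100)
        H = 1 - 0.01 * np.cos(np.pi * g.z / g.L)  # too weak to yield
        params = ThinFilmParams(B=0.5, M=0.0)
        f = tf_fields(H, np.ones(g.N), params, g)
        assert np.abs(f.q).max() < 1e-7
        assert np.abs(f.ws_tilde).max() < 1e-7
        assert np.all(f.surfaces.regime == 5)

    def test_immobilised_interface(self):
        # wherever H*pz = -2*M*Gamma_z the surface velocity vanishes
        B = 0.05
        for pz, H in ((-1.2, 1.0), (0.8, 1.5)):
            MGz = -H * pz / 2
            from viscofilm.yield_structure import tf_yield_surfaces

            surf = tf_yield_surfaces([H], [pz], [MGz], B)
            Ym, Yp = surf.Y_minus[0], surf.Y_plus[0]
            ws = (-0.5 * pz * (H**2 + (H - Yp)**2 - (H - Ym)**2)
                  - MGz * (H + Ym - Yp) - B * np.sign(pz) * (H - Ym - Yp))
            assert ws == pytest.approx(0.0, abs=1e-12)


class TestWallStress:
    def test_flat_uniform_state(self):
        g = make_grid(2 * np.pi, 64)
        params = ThinFilmParams(B=0.04, M=0.2)
        tw = tf_wall_stress(np.ones(g.N), np.ones(g.N), params, g)
        assert np.abs(tw).max() < 1e-12

    def test_static_balance_value(self):
        # at (H*pz/B, M*Gz/B) = (-2, 1) the wall stress equals -B
        H, B, M = 1.0, 0.04, 0.2
        pz, MGz = -2 * B / H, B
        assert H * pz + MGz == pytest.approx(-B)


class TestTendencies:
    def test_equilibrium_state(self):
        g = make_grid(2 * np.pi, 100)
        params = ThinFilmParams(B=0.04, M=0.2)
        dH, dG = tf_rhs(
            ThinFilmState(0.0, np.ones(g.N), np.ones(g.N)), params, g
        )
        assert np.abs(dH).max() < 1e-12
        assert np.abs(dG).max() < 1e-12

    def test_discrete_conservation(self):
        g = make_grid(2 * np.pi, 200)
        params = ThinFilmParams(B=0.04, M=0.2)
        state = ThinFilmState(
            0.0,
            1 - 0.2 * np.cos(np.pi * g.z / g.L),
            1 + 0.1 * np.cos(2 * np.pi * g.z / g.L),
        )
        dH, dG = tf_rhs(state, params, g)
        assert abs(integral(dH, g)) < 1e-14
        assert abs(integral(dG, g)) < 1e-14

    def test_initial_yielding_confined_to_centre(self):
        # the standard perturbation first yields away from the domain ends
        g = make_grid(2 * np.pi, 200)
        params = ThinFilmParams(B=0.04, M=0.2, A=0.2)
        state = initial_condition_tf(0.2, g.L, g)
        f = tf_fields(state.H, state.Gamma, params, g)
        yielded = f.surfaces.regime != 5
        assert yielded.any()
        assert not yielded[:10].any() and not yielded[-10:].any()


class TestStrongSurfactantLimit:
    def test_newtonian_quarter_mobility(self):
        # B = 0: the immobilised-interface flux is -pz*H^3/12
        g = make_grid(2 * np.pi, 200)
        H = 1 - 0.2 * np.cos(np.pi * g.z / g.L)
        params = ThinFilmParams(B=0.0, M=0.0)
        dH = tf_largeM_rhs(ThinFilmState(0.0, H, None), params, g)
        pz = tf_pressure_gradient(H, g)
        flux = -pz * H**3 / 12.0
        flux[0] = flux[-1] = 0.0
        expected = -d1(flux, g, parity="odd")
        assert np.allclose(dH, expected, atol=1e-9)

    def test_rigid_when_subcritical(self):
        g = make_grid(2 * np.pi, 100)
        H = 1 - 0.01 * np.cos(np.pi * g.z / g.L)
        params = ThinFilmParams(B=0.5, M=0.0)
        dH = tf_largeM_rhs(ThinFilmState(0.0, H, None), params, g)
        assert np.abs(dH).max() < 1e-8

    def test_factor_four_doubled_B_equivalence(self):
        # strong-surfactant trajectories at (B, t) match surfactant-free
        # trajectories at (2B, t/4)
        spec_lm = EventSpec(t_end=400.0, n_out=5)
        spec_cl = EventSpec(t_end=100.0, n_out=5)
        lm = run_thin_film(ThinFilmParams(B=0.02, M=0.0, A=0.2), spec_lm,
                           N=150, large_M=True)
        cl = run_thin_film(ThinFilmParams(B=0.04, M=0.0, A=0.2), spec_cl,
                           N=150)
        for frac in (0.5, 1.0):
            i = np.argmin(np.abs(lm.times - 400 * frac))
            j = np.argmin(np.abs(cl.times - 100 * frac))
            assert lm.profile[i].max() == pytest.approx(
                cl.profile[j].max(), rel=1e-3
            )
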