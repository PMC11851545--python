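"""Flow solver oracles: Poiseuille, Womersley, conservation, symmetry."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as sla

from hemano import (
    AXISYMMETRIC,
    PLANAR,
    FluidProperties,
    MeshResolution,
    VesselGeometry,
    Waveform,
    build_mesh,
    extract_wss,
    solve_pulsatile,
    solve_steady,
)
from hemano.exceptions import ContractError, SolverError
from tests.conftest import TUBE_INFLOW, TUBE_RADIUS, WOM_AMP, WOM_MEAN, WOM_RADIUS


def womersley_profile_bvp(r_eval, R, omega, nu, n=2000):
    """Independent oracle: oscillatory tube-flow profile with unit mean.

    Solves the complex two-point BVP i*w*u = P + nu*(u'' + u'/r) with
    u(R) = 0, u'(0) = 0 and the unknown pressure amplitude P fixed by the
    unit-mean constraint, by direct finite differences at high resolution.
    """
    r = np.linspace(0, R, n + 1)
    dr = r[1] - r[0]
    rows, cols, vals = [], [], []
    rhs = np.zeros(n + 2, dtype=complex)

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(1, n):
        add(i, i, 1j * omega + nu * 2 / dr**2)
        add(i, i - 1, -nu * (1 / dr**2 - 1 / (2 * r[i] * dr)))
        add(i, i + 1, -nu * (1 / dr**2 + 1 / (2 * r[i] * dr)))
        add(i, n + 1, -1.0)
    add(0, 0, 1.0)
    add(0, 1, -1.0)
    add(n, n, 1.0)
    w = np.zeros(n + 1)
    w[1:] += 0.5 * dr
    w[:-1] += 0.5 * dr
    w *= r * 2 / R**2
    for j in range(n + 1):
        add(n + 1, j, w[j])
    rhs[n + 1] = 1.0
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n + 2, n + 2), dtype=complex)
    u = sla.spsolve(A.tocsc(), rhs)[: n + 1]
    return np.interp(r_eval, r, u.real) + 1j * np.interp(r_eval, r, u.imag)


class TestSteadyTube:
    def test_wss_matches_hagen_poiseuille(self, steady_tube_flow):
        # tau = 4 mu U / R = 0.28 Pa for mu=0.0035, U=0.2, R=10 mm
        tau = steady_tube_flow.wss["upper"][0]
        exact = 4 * 0.0035 * TUBE_INFLOW / TUBE_RADIUS
        assert exact == pytest.approx(0.28)
        mid = tau[len(tau) // 2]
        assert mid == pytest.approx(exact, rel=0.02)
        # uniform along the tube away from the ends
        assert np.ptp(tau[5:-5]) / exact < 0.02

    def test_centerline_velocity(self, steady_tube_flow):
        uz, ur = steady_tube_flow.velocity(0)
        assert uz[30, 0] == pytest.approx(2 * TUBE_INFLOW, rel=0.01)
        assert np.abs(ur).max() < 1e-3 * uz.max()

    def test_viscosity_doubling_doubles_wss(self, tube_mesh, steady_tube_flow):
        thick = FluidProperties(viscosity=0.007)
        sol2 = solve_steady(tube_mesh, thick, TUBE_INFLOW)
        ratio = sol2.wss["upper"][0][30] / steady_tube_flow.wss["upper"][0][30]
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_mass_conservation_and_divergence(self, steady_tube_flow):
        Q = steady_tube_flow.flux(0)
        assert Q == pytest.approx(np.pi * TUBE_RADIUS**2 * TUBE_INFLOW, rel=1e-9)
        assert steady_tube_flow.divergence_max(0) < 1e-18

    def test_no_slip_at_wall(self, steady_tube_flow):
        uz, _ = steady_tube_flow.velocity(0)
        assert np.abs(uz[:, -1]).max() < 0.02 * uz.max()

    def test_grid_convergence_of_wss_error(self, fluid):
        geom = VesselGeometry(axial_length=0.04, inlet_radius=0.01)
        exact = 4 * fluid.viscosity * TUBE_INFLOW / 0.01
        errs = []
        mesh = build_mesh(geom, MeshResolution(n_axial=16, n_lumen=10, n_wall=4), AXISYMMETRIC)
        for _ in range(3):
            sol = solve_steady(mesh, fluid, TUBE_INFLOW)
            tau = sol.wss["upper"][0]
            errs.append(abs(tau[len(tau) // 2] - exact) / exact)
            mesh = mesh.refine(1.5)
        assert errs[0] > errs[1] > errs[2]

    def test_zero_inflow_rejected(self, tube_mesh, fluid):
        with pytest.raises(ContractError):
            solve_steady(tube_mesh, fluid, 0.0)


class TestPlanarChannel:
    def test_wss_matches_plane_poiseuille_on_both_walls(self, fluid):
        # tau = 3 mu U / h for a channel of half-width h
        geom = VesselGeometry(axial_length=0.06, inlet_radius=0.01)
        mesh = build_mesh(geom, MeshResolution(n_axial=40, n_lumen=26, n_wall=5), PLANAR)
        sol = solve_steady(mesh, fluid, 0.2)
        exact = 3 * fluid.viscosity * 0.2 / 0.01
        for side in ("lower", "upper"):
            assert sol.wss[side][0][20] == pytest.approx(exact, rel=0.02)


class TestPulsatile:
    def test_constant_waveform_matches_steady(self, tube_mesh, fluid, steady_tube_flow):
        sol = solve_pulsatile(
            tube_mesh, fluid, Waveform.constant(TUBE_INFLOW), cycles=1, steps_per_cycle=20
        )
        tau_p = sol.wss["upper"][-1]
        tau_s = steady_tube_flow.wss["upper"][0]
        assert np.allclose(tau_p[3:-3], tau_s[3:-3], rtol=0.02)

    def test_womersley_oracle(self, womersley_flow, fluid):
        """Centerline amplitude and phase vs an independent BVP solution."""
        idx = womersley_flow.final_cycle_indices()
        t = womersley_flow.times[idx]
        uc = np.array([womersley_flow.velocity(k)[0][20, 0] for k in idx])
        F0 = womersley_profile_bvp(np.array([0.0]), WOM_RADIUS, 2 * np.pi, fluid.nu)[0]
        ck = -1j * WOM_AMP
        exact = 2 * WOM_MEAN + np.real(ck * F0 * np.exp(1j * 2 * np.pi * t))
        assert np.abs(uc - exact).max() / np.abs(exact).max() < 0.05
        amp = (uc.max() - uc.min()) / 2
        amp_e = (exact.max() - exact.min()) / 2
        assert amp == pytest.approx(amp_e, rel=0.05)

    def test_womersley_wall_shear(self, womersley_flow, fluid):
        """Wall-shear series vs the derivative of the BVP oracle profile."""
        idx = womersley_flow.final_cycle_indices()
        t = womersley_flow.times[idx]
        tau = womersley_flow.wss["upper"][idx][:, 20]
        eps = WOM_RADIUS * 1e-4
        re = np.array([WOM_RADIUS - eps, WOM_RADIUS])
        prof = womersley_profile_bvp(re, WOM_RADIUS, 2 * np.pi, fluid.nu)
        dudr_harm = (prof[1] - prof[0]) / eps
        mu = fluid.viscosity
        tau_exact = (
            4 * mu * WOM_MEAN / WOM_RADIUS
            + np.real(-1j * WOM_AMP * (-mu * dudr_harm) * np.exp(1j * 2 * np.pi * t))
        )
        scale = np.abs(tau_exact).max()
        assert np.abs(tau - tau_exact).max() / scale < 0.05

    def test_periodicity_reached_by_final_cycle(self, womersley_flow):
        tau = womersley_flow.wss["upper"]
        cyc = womersley_flow.cycle
        m_prev = np.abs(tau[cyc == cyc[-1] - 1]).mean()
        m_last = np.abs(tau[cyc == cyc[-1]]).mean()
        assert abs(m_last - m_prev) / m_prev < 0.01

    def test_reversed_inflow_flips_wss_sign(self, fluid):
        geom = VesselGeometry(axial_length=0.04, inlet_radius=0.006)
        mesh = build_mesh(geom, MeshResolution(n_axial=24, n_lumen=16, n_wall=4), AXISYMMETRIC)
        fwd = solve_pulsatile(mesh, fluid, Waveform.constant(0.2), cycles=1, steps_per_cycle=16)
        rev = solve_pulsatile(mesh, fluid, Waveform.constant(-0.2), cycles=1, steps_per_cycle=16)
        tf, tr = fwd.wss["upper"][-1], rev.wss["upper"][-1]
        assert np.all(tf[2:-2] > 0) and np.all(tr[2:-2] < 0)
        assert np.allclose(tf[2:-2], -tr[2:-2], rtol=0.02)

    def test_cfl_guard_names_step_size(self, tube_mesh, fluid):
        with pytest.raises(SolverError, match="dt="):
            solve_pulsatile(
                tube_mesh,
                fluid,
                Waveform.constant(2.0),
                cycles=1,
                steps_per_cycle=10,
                max_cfl=0.1,
            )

    def test_extract_wss_structure(self, womersley_flow):
        w = extract_wss(womersley_flow)
        assert set(w) == {"upper"}
        assert w["upper"]["tau"].shape == (len(womersley_flow.times), 41)
        assert np.all(np.diff(w["upper"]["s"]) > 0)


class TestBulge:
    def test_stokes_regime_wss_symmetric_about_bulge(self, fluid):
        """Creeping flow in a symmetric bulge has fore-aft symmetric WSS."""
        geom = VesselGeometry(
            axial_length=0.1,
            inlet_radius=0.009,
            bulge_amplitude=0.006,
            bulge_center=0.05,
            bulge_width=0.012,
        )
        mesh = build_mesh(geom, MeshResolution(n_axial=64, n_lumen=24, n_wall=5), AXISYMMETRIC)
        sol = solve_steady(mesh, fluid, 1e-4)
        tau = sol.wss["upper"][0]
        assert np.abs(tau - tau[::-1]).max() / np.abs(tau).max() < 0.05
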