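"""NO transport: production law, reaction kinetics, transport oracles."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from hemano import (
    TransportParameters,
    lumen_reaction,
    mesh_independence_study,
    production_rate,
    solve_no,
    wall_slab_profile,
)
from hemano import VesselGeometry, MeshResolution
from hemano.exceptions import ContractError
from hemano.no_transport import MeshIndependenceReport


class TestProductionLaw:
    def test_zero_shear_gives_basal_rate(self, transport):
        assert production_rate(0.0, transport) == pytest.approx(2.13, abs=1e-12)

    def test_half_saturation_at_b(self, transport):
        # tau = b -> Rbasal + Rmax/2 = 2.13 + 228.75 = 230.88 nM/s
        assert production_rate(3.5, transport) == pytest.approx(230.88, abs=1e-10)

    def test_saturation_asymptote(self, transport):
        # tau -> inf: Rbasal + Rmax = 459.63 nM/s
        assert production_rate(1e12, transport) == pytest.approx(459.63, abs=1e-4)

    def test_sign_insensitive(self, transport):
        assert production_rate(-2.0, transport) == production_rate(2.0, transport)

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_shear_magnitude(self, t1, t2):
        p = TransportParameters()
        lo, hi = sorted((t1, t2))
        assert production_rate(lo, p) <= production_rate(hi, p) + 1e-12

    def test_nonfinite_rejected(self, transport):
        with pytest.raises(ContractError):
            production_rate(np.nan, transport)


class TestLumenReaction:
    def test_zero_concentration_no_consumption(self, transport):
        assert lumen_reaction(0.0, transport) == 0.0

    def test_one_nanomolar(self, transport):
        # koxgen + kery = 7.56e-6 + 2.3 at cl = 1 nM
        assert lumen_reaction(1.0, transport) == pytest.approx(2.3000076, abs=1e-7)

    def test_negative_concentration_rejected(self, transport):
        with pytest.raises(ContractError):
            lumen_reaction(-1.0, transport)

    def test_well_mixed_decay_matches_exponential(self):
        """dc/dt = -R(c) with negligible oxidation: c(1 s)/c0 = e^-2.3."""
        p = TransportParameters(koxgen=1e-30)
        sol = solve_ivp(
            lambda t, c: -lumen_reaction(max(c[0], 0.0), p),
            (0, 1.0),
            [1.0],
            rtol=1e-10,
            atol=1e-12,
        )
        assert sol.y[0, -1] == pytest.approx(np.exp(-2.3), rel=1e-6)
        assert sol.y[0, -1] == pytest.approx(0.1003, abs=2e-4)


class TestWallSlab:
    def test_decay_profile_matches_closed_form(self, transport):
        """cosh((W-x)/L)/cosh(W/L) with L = sqrt(Dw/kw) = 0.291 mm."""
        L = transport.wall_decay_length
        assert L == pytest.approx(0.291e-3, abs=1e-6)
        W = 2.0e-3
        xc, c = wall_slab_profile(transport, thickness=W, c0=1.0)
        exact = np.cosh((W - xc) / L) / np.cosh(W / L)
        assert np.abs(c - exact).max() < 0.01
        # one-decay-length checkpoint: c(L)/c0 = 0.368 (far-wall limit)
        assert np.interp(L, xc, c) == pytest.approx(np.exp(-1.0), abs=0.005)


class TestCoupledSteadyTube:
    def test_nonnegative_and_physiological(self, steady_tube_no):
        assert steady_tube_no.min_concentration() >= -1e-6
        ci = steady_tube_no.interface_tacno("upper")
        assert np.all(ci > 0)
        assert 1.0 <= ci.mean() <= 1000.0  # physiological nM window

    def test_interface_concentrations_continuous(self, steady_tube_no):
        """The implied interface value lies between the adjacent cells'
        lumen and wall concentrations (flux continuity with a source can
        exceed both only at the source itself)."""
        sys_ = steady_tube_no._system
        c = steady_tube_no.c[0].ravel()
        f = sys_.ifaces["upper"]
        ci = steady_tube_no.interface["upper"][0]
        lo = np.minimum(c[f["lum_cell"]], c[f["wall_cell"]])
        assert np.all(ci > lo - 1e-12)

    def test_conservation_audit_closes(self, steady_tube_no):
        rep = steady_tube_no.balance_report()
        assert rep["closure_defect"] < 0.01
        assert rep["production"] > 0
        assert rep["lumen_sink"] > rep["wall_sink"] > 0

    def test_zero_production_limit_gives_zero_field(self, tube_mesh, steady_tube_flow):
        tiny = TransportParameters(Rbasal=1e-30, Rmax=1e-30)
        sol = solve_no(tube_mesh, steady_tube_flow, tiny)
        assert np.abs(sol.c).max() < 1e-25


class TestMonotonicity:
    def test_kery_increase_decreases_interface_no(self, tube_mesh, steady_tube_flow, steady_tube_no, transport):
        fast = dataclasses.replace(transport, kery=23.0)
        sol = solve_no(tube_mesh, steady_tube_flow, fast)
        assert np.all(
            sol.interface_tacno("upper") < steady_tube_no.interface_tacno("upper")
        )

    def test_uniformly_higher_shear_raises_tacno_pointwise(
        self, tube_mesh, steady_tube_flow, steady_tube_no, transport
    ):
        boosted = dataclasses.replace(
            steady_tube_flow, wss={s: 1.5 * t for s, t in steady_tube_flow.wss.items()}
        )
        boosted._system = steady_tube_flow._system
        sol = solve_no(tube_mesh, boosted, transport)
        assert np.all(
            sol.interface_tacno("upper") >= steady_tube_no.interface_tacno("upper") - 1e-12
        )


class TestMeshIndependence:
    GEOM = VesselGeometry(axial_length=0.06, inlet_radius=0.01)

    def test_protocol_accepts_on_default_tube(self):
        rep = mesh_independence_study(self.GEOM, inflow=0.2)
        assert isinstance(rep, MeshIndependenceReport)
        assert rep.accepted
        assert rep.deltas[-1] < 0.05
        assert rep.accepted_resolution is not None

    def test_fine_start_accepted_in_one_comparison(self):
        rep = mesh_independence_study(
            self.GEOM,
            base_resolution=MeshResolution(n_axial=80, n_lumen=30, n_wall=12),
            inflow=0.2,
        )
        assert rep.accepted and len(rep.averages) == 2

    def test_zero_threshold_never_accepts(self):
        rep = mesh_independence_study(
            self.GEOM,
            base_resolution=MeshResolution(n_axial=20, n_lumen=8, n_wall=4),
            inflow=0.2,
            threshold=0.0,
            max_refinements=2,
        )
        assert not rep.accepted
        assert rep.accepted_resolution is None
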