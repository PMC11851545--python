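"""Pulsatile incompressible Newtonian flow in the lumen.

The solver uses a streamfunction–vorticity formulation on the mapped
structured lumen grid: incompressibility is then satisfied exactly (the
volumetric flux between two streamlines is the streamfunction difference),
the no-slip wall enters through a Thom-type wall-vorticity closure, and each
implicit (backward-Euler) time step solves a linearized vorticity transport
equation followed by the streamfunction Poisson equation.  Advection is
first-order upwind, which keeps the transport matrix an M-matrix and the
scheme robust across flow reversal.

Inlet boundary condition: a fully developed profile reconstructed from the
waveform's Fourier harmonics (Poiseuille/parabolic for the mean, the
oscillatory laminar closed form per harmonic).  Outlet: zero axial gradient
with the wall streamline pinned, so the instantaneous flow rate is imposed
exactly at every cross-section.  Walls are rigid and no-slip.

Blood: density 1056 kg/m^3, viscosity 0.0035 Pa·s (Newtonian defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.special import jv

from ._operators import GridOperators
from .exceptions import ContractError, SolverError
from .geometry import AXISYMMETRIC, Mesh
from .waveform import Waveform


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood properties (SI)."""

    density: float = 1056.0
    viscosity: float = 0.0035

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ContractError("density and viscosity must be positive")

    @property
    def nu(self) -> float:
        return self.viscosity / self.density


# --------------------------------------------------------------------------
# developed-profile closed forms (inlet boundary condition / initialization)
# --------------------------------------------------------------------------


def _axisym_harmonic_shape(r, R, omega_k, nu):
    """Oscillatory tube-flow velocity shape with unit cross-section mean."""
    alpha = R * np.sqrt(omega_k / nu)
    lam = 1j**1.5 * alpha
    num = 1.0 - jv(0, lam * np.asarray(r) / R) / jv(0, lam)
    den = 1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam))
    return num / den


def _planar_harmonic_shape(yhat, h, omega_k, nu):
    """Oscillatory channel-flow velocity shape with unit mean (half-width h)."""
    lam = np.sqrt(1j * omega_k / nu)
    num = 1.0 - np.cosh(lam * np.asarray(yhat)) / np.cosh(lam * h)
    den = 1.0 - np.tanh(lam * h) / (lam * h)
    return num / den


class _InletColumn:
    """Developed-flow profiles (u, psi, omega) on one grid column.

    Precomputes, per waveform harmonic, the complex velocity / streamfunction
    / vorticity profiles at the column's transverse nodes; evaluation at a
    time t is then a small complex dot product.
    """

    def __init__(self, y: np.ndarray, waveform: Waveform, nu: float, axisym: bool):
        self.y = y
        self.wf = waveform
        self.axisym = axisym
        K = waveform.n_harmonics
        w0 = 2.0 * np.pi / waveform.period
        ck = waveform.complex_coefficients()
        if axisym:
            R = y[-1]
            self.u_mean = 2.0 * (1.0 - (y / R) ** 2)  # Poiseuille, unit mean
            self.psi_mean = y**2 - y**4 / (2.0 * R**2)  # integral of u*r
            self.psi_wall_mean = R**2 / 2.0
        else:
            h = 0.5 * (y[-1] - y[0])
            ymid = 0.5 * (y[-1] + y[0])
            yh = y - ymid
            self.u_mean = 1.5 * (1.0 - (yh / h) ** 2)
            self.psi_mean = 1.5 * (yh - yh**3 / (3.0 * h**2)) + h
            self.psi_wall_mean = 2.0 * h
        self.U = np.zeros((K, len(y)), dtype=complex)
        self.P = np.zeros((K, len(y)), dtype=complex)
        for k in range(1, K + 1):
            if abs(ck[k - 1]) == 0.0:
                continue
            if axisym:
                F = _axisym_harmonic_shape(y, y[-1], k * w0, nu)
                prof = _cumtrapz(F * y, y)
                exact = y[-1] ** 2 / 2.0
            else:
                h = 0.5 * (y[-1] - y[0])
                F = _planar_harmonic_shape(y - 0.5 * (y[-1] + y[0]), h, k * w0, nu)
                prof = _cumtrapz(F, y)
                exact = 2.0 * h
            # normalize the numerically integrated streamfunction so the wall
            # value carries exactly the harmonic's flux
            prof *= exact / prof[-1]
            self.U[k - 1] = ck[k - 1] * F
            self.P[k - 1] = ck[k - 1] * prof
        self.k_omega = w0 * np.arange(1, K + 1)

    def _phases(self, t: float) -> np.ndarray:
        return np.exp(1j * self.k_omega * t)

    def u(self, t: float) -> np.ndarray:
        ph = self._phases(t)
        return self.wf.a0 * self.u_mean + np.real(ph @ self.U)

    def psi(self, t: float) -> np.ndarray:
        ph = self._phases(t)
        return self.wf.a0 * self.psi_mean + np.real(ph @ self.P)

    def psi_wall(self, t: float) -> float:
        return float(self.wf(t)) * self.psi_wall_mean

    def omega(self, t: float) -> np.ndarray:
        """Vorticity of the developed profile (= -du/dy at the inlet)."""
        return -np.gradient(self.u(t), self.y, edge_order=2)


def _cumtrapz(f, x):
    out = np.zeros(len(x), dtype=np.result_type(f, float))
    out[1:] = np.cumsum(0.5 * (f[1:] + f[:-1]) * np.diff(x))
    return out


# --------------------------------------------------------------------------
# solution container
# --------------------------------------------------------------------------


@dataclass
class FlowSolution:
    """Velocity/pressure/WSS time series on the lumen grid.

    ``psi`` holds the streamfunction snapshots (n_t, ni, nj_lumen_nodes);
    velocity fields are reconstructed on demand.  ``wss[side]`` is the signed
    (streamwise-positive) wall shear stress at the interface nodes, Pa.
    """

    mesh: Mesh
    props: FluidProperties
    waveform: Waveform | None
    times: np.ndarray
    cycle: np.ndarray
    psi: np.ndarray
    wss: dict
    steady: bool = False
    residual_history: np.ndarray | None = field(default=None, repr=False)

    _system: object = field(default=None, repr=False)

    @property
    def sides(self):
        return sorted(self.wss.keys())

    @property
    def steps_per_cycle(self) -> int:
        if self.steady:
            return 1
        return int(np.sum(self.cycle == self.cycle[-1])) - 1

    def final_cycle_indices(self) -> np.ndarray:
        """Snapshot indices spanning exactly the last simulated cycle
        (inclusive of both endpoints)."""
        if self.steady:
            return np.array([0])
        last = self.cycle[-1]
        return np.nonzero(self.cycle == last)[0]

    def velocity(self, k: int):
        """(u_axial, u_transverse) node fields for snapshot k."""
        return self._system.velocities(self.psi[k])

    def cycle_averaged_psi(self) -> np.ndarray:
        idx = self.final_cycle_indices()
        t = self.times[idx]
        return np.trapezoid(self.psi[idx], t, axis=0) / (t[-1] - t[0])

    def flux(self, k: int) -> float:
        """Volumetric flow rate at snapshot k (exact from psi)."""
        dpsi = self.psi[k, 0, -1] - self.psi[k, 0, 0]
        return float(2.0 * np.pi * dpsi if self.mesh.mode == AXISYMMETRIC else dpsi)

    def divergence_max(self, k: int) -> float:
        """Max |net volumetric flux| over all lumen cells at snapshot k.

        Zero to round-off by construction of the streamfunction formulation;
        kept as an explicit audit of the continuity equation.
        """
        p = self.psi[k]
        div = (
            (p[1:, 1:] - p[1:, :-1])
            - (p[:-1, 1:] - p[:-1, :-1])
            + (p[:-1, 1:] - p[1:, 1:])
            - (p[:-1, :-1] - p[1:, :-1])
        )
        return float(np.abs(div).max())

    def wss_final_cycle(self, side: str):
        """(times, tau) for the final cycle on one wall side."""
        idx = self.final_cycle_indices()
        return self.times[idx], self.wss[side][idx]

    def save(self, path) -> None:
        """Persist the solution (npz) for later pipeline stages."""
        data = dict(
            times=self.times,
            cycle=self.cycle,
            psi=self.psi,
            steady=np.array(self.steady),
            flow_grading=np.array(self._system.flow_grading),
        )
        for side, tau in self.wss.items():
            data[f"wss_{side}"] = tau
        np.savez_compressed(path, **data)

    @classmethod
    def load(cls, path, mesh, props, waveform=None) -> "FlowSolution":
        """Rebuild a solution saved with :meth:`save` on the same mesh."""
        with np.load(path) as d:
            wss = {
                k[4:]: d[k] for k in d.files if k.startswith("wss_")
            }
            sol = cls(
                mesh=mesh,
                props=props,
                waveform=waveform,
                times=d["times"],
                cycle=d["cycle"],
                psi=d["psi"],
                wss=wss,
                steady=bool(d["steady"]),
            )
            grading = float(d["flow_grading"])
        sol._system = _FlowSystem(mesh, props, grading)
        return sol

    def pressure_axial(self, k: int) -> np.ndarray:
        """Reduced axial pressure profile p(z) at snapshot k (Pa, outlet 0).

        Integrates the axial momentum balance along a mid-lumen grid line;
        the transverse pressure variation is neglected (long-wave estimate,
        not used by any downstream index).
        """
        return self._system.pressure_axial(self, k)


def extract_wss(solution: FlowSolution) -> dict:
    """Signed wall-shear-stress series per wall side.

    Returns ``{side: {"s": arc-length (m), "t": times (s), "tau": (n_t, n_s)
    Pa}}``; positive tau points streamwise (+z).
    """
    if not solution.mesh.j_interfaces:
        raise ContractError("mesh has no labelled endothelial interface")
    out = {}
    for side in solution.sides:
        out[side] = {
            "s": solution.mesh.interface_arclength(side),
            "t": solution.times,
            "tau": solution.wss[side],
        }
    return out


# --------------------------------------------------------------------------
# the solver
# --------------------------------------------------------------------------


class _FlowSystem:
    """Discrete streamfunction–vorticity operators for one mesh.

    The flow is solved on its own mildly graded transverse node distribution
    (``flow_grading``) spanning the same lumen cross-sections as the mesh:
    the transport mesh's aggressive near-endothelium grading (built for the
    ~40 um NO boundary layer) would make the Thom wall-vorticity closure
    ill-conditioned, while the viscous boundary layer only needs ~0.1 mm
    resolution.  The streamfunction is interpolated back onto the transport
    mesh nodes; because advective fluxes are streamfunction differences,
    pointwise interpolation keeps the discrete velocity exactly
    divergence-free on the transport mesh as well.
    """

    def __init__(self, mesh: Mesh, props: FluidProperties, flow_grading: float = 1.05):
        from .geometry import _graded_unit_spacings

        self.mesh = mesh
        self.props = props
        self.flow_grading = flow_grading
        self.axisym = mesh.mode == AXISYMMETRIC
        j0, j1 = mesh.j_lumen
        self.j0, self.j1 = j0, j1
        n_lum = mesh.resolution.n_lumen
        ni_nodes = mesh.Y.shape[0]
        if self.axisym:
            t = np.concatenate(
                [[0.0], np.cumsum(_graded_unit_spacings(n_lum, flow_grading, "end"))]
            )
            r_up = mesh.Y[:, j1]
            self.Y = np.outer(r_up, t)
        else:
            t = np.concatenate(
                [[0.0], np.cumsum(_graded_unit_spacings(n_lum, flow_grading, "both"))]
            )
            y_lo = mesh.Y[:, j0]
            y_up = mesh.Y[:, j1]
            self.Y = y_lo[:, None] + np.outer(y_up - y_lo, t)
        self.zs = mesh.zs
        self.ops = GridOperators(self.zs, self.Y)
        ni, nj = self.ops.ni, self.ops.nj
        self.ni, self.nj = ni, nj
        n = ni * nj

        r = self.Y
        self.r = r
        if self.axisym:
            with np.errstate(divide="ignore"):
                inv_r = np.where(r > 0, 1.0 / np.maximum(r, 1e-300), 0.0)
        else:
            inv_r = np.zeros_like(r)
        self.inv_r = inv_r

        # --- node classification -----------------------------------------
        interior = np.ones((ni, nj), dtype=bool)
        interior[0, :] = interior[-1, :] = False
        interior[:, 0] = interior[:, -1] = False
        self.interior = interior
        is_wall_lo = np.zeros((ni, nj), dtype=bool)
        is_wall_up = np.zeros((ni, nj), dtype=bool)
        is_wall_up[:, -1] = True
        if not self.axisym:
            is_wall_lo[:, 0] = True
        self.is_axis = np.zeros((ni, nj), dtype=bool)
        if self.axisym:
            self.is_axis[:, 0] = True
        self.is_wall_lo, self.is_wall_up = is_wall_lo, is_wall_up
        inlet = np.zeros((ni, nj), dtype=bool)
        inlet[0, 1:-1] = True
        outlet = np.zeros((ni, nj), dtype=bool)
        outlet[-1, 1:-1] = True
        self.is_inlet, self.is_outlet = inlet, outlet

        mask = interior.ravel().astype(float)
        self.mask = mask
        Dmask = sp.diags(mask)
        flat = np.arange(n).reshape(ni, nj)

        def bc_matrix(dirichlet_mask):
            rows, cols, vals = [], [], []
            for idx in flat[dirichlet_mask].ravel():
                rows.append(idx)
                cols.append(idx)
                vals.append(1.0)
            for i, j in zip(*np.nonzero(outlet)):
                rows += [flat[i, j], flat[i, j]]
                cols += [flat[i, j], flat[i - 1, j]]
                vals += [1.0, -1.0]
            return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

        # psi rows: Dirichlet on inlet, walls and axis; zero-gradient outlet
        A_bc_psi = bc_matrix(is_wall_lo | is_wall_up | self.is_axis | inlet)
        # omega rows: Dirichlet on inlet and axis; wall rows get the implicit
        # Thom closure (identity on omega_w, psi coupling in a separate block)
        A_bc_om = bc_matrix(is_wall_lo | is_wall_up | self.is_axis | inlet)
        self.A_bc_psi, self.A_bc_om = A_bc_psi, A_bc_om

        ops = self.ops
        if self.axisym:
            # radial parts in chi = r^2: E^2 psi = 4 chi psi_cc + psi_zz and
            # D^2 omega = r (4 chi s'' + 8 s') + omega_zz with s = omega / r.
            # This avoids the near-axis cancellation of psi_rr - psi_r / r,
            # and is exact for the Poiseuille profile.  Columns are
            # constant-z lines, so these are plain tridiagonals in j.
            R_psi, R_om = self._radial_ops_axisym()
            L_psi = ops.Dzz + R_psi
            L_om = ops.Dzz + R_om
        else:
            L_psi = ops.lap
            L_om = ops.lap
        self.L_om_masked = (Dmask @ L_om).tocsr()
        self.A_psi = (Dmask @ L_psi + A_bc_psi).tocsc()
        self.lu_psi = splu(self.A_psi)
        # psi-equation coupling to omega: E^2 psi + r omega = 0
        rdiag = self.r.ravel() if self.axisym else np.ones(n)
        self.A_psi_om = sp.diags(mask * rdiag).tocsr()

        # --- upwind advection stencil pattern ------------------------------
        ii, jj = np.nonzero(interior)
        ctr = flat[ii, jj]
        self._adv_idx = dict(
            ctr=ctr,
            west=flat[ii - 1, jj],
            east=flat[ii + 1, jj],
            south=flat[ii, jj - 1],
            north=flat[ii, jj + 1],
            ii=ii,
            jj=jj,
        )
        self._n = n

        # cubic-Lagrange interpolation of psi onto the transport-mesh lumen
        # node rows (precomputed sparse weights; geometry is static)
        tgtY = mesh.Y[:, self.j0 : self.j1 + 1]
        nt, nf = tgtY.shape[1], nj
        rws, cls, wts = [], [], []
        for i in range(ni):
            xs, xt = self.Y[i], tgtY[i]
            k = np.clip(np.searchsorted(xs, xt) - 2, 0, nf - 4)
            idx = k[:, None] + np.arange(4)[None, :]
            xsm = xs[idx]  # (nt, 4)
            w = np.ones((nt, 4))
            for m in range(4):
                for l in range(4):
                    if l == m:
                        continue
                    w[:, m] *= (xt - xsm[:, l]) / (xsm[:, m] - xsm[:, l])
            rws.append(np.repeat(i * nt + np.arange(nt), 4))
            cls.append((i * nf + idx).ravel())
            wts.append(w.ravel())
        self._W_transport = sp.csr_matrix(
            (np.concatenate(wts), (np.concatenate(rws), np.concatenate(cls))),
            shape=(ni * nt, n),
        )
        self._nt_transport = nt

        # wall-normal spacing for the Thom closure (corrected for wall slope)
        self.thom = {}
        for side, jw, jn, sgn in self._wall_rows():
            dyn = np.abs(self.Y[:, jw] - self.Y[:, jn])
            slope = np.gradient(self.Y[:, jw], self.zs, edge_order=2)
            dn = dyn * np.cos(np.arctan(slope))
            rw = self.Y[:, jw] if self.axisym else np.ones(ni)
            self.thom[side] = (jw, jn, dn, rw, sgn)

        # implicit Thom closure: wall row  omega_w - c (psi_w - psi_n) = 0
        rows, cols, vals = [], [], []
        for side, (jw, jn, dn, rw, _sgn) in self.thom.items():
            c = 2.0 / (rw * dn**2)
            rows.extend(flat[:, jw])
            cols.extend(flat[:, jw])
            vals.extend(-c)
            rows.extend(flat[:, jw])
            cols.extend(flat[:, jn])
            vals.extend(c)
        self.T_thom = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def psi_on_transport(self, psi: np.ndarray) -> np.ndarray:
        """psi interpolated to the transport mesh's lumen node rows."""
        return (self._W_transport @ psi.ravel()).reshape(self.ni, self._nt_transport)

    def _radial_ops_axisym(self):
        """Tridiagonal radial operators in chi = r^2 (see __init__)."""
        ni, nj = self.ni, self.nj
        n = ni * nj
        chi = self.Y**2
        r = self.Y
        flat = np.arange(n).reshape(ni, nj)

        def lagrange_d1_d2(x0, xa, xb, xc):
            da = (2 * x0 - xb - xc) / ((xa - xb) * (xa - xc))
            db = (2 * x0 - xa - xc) / ((xb - xa) * (xb - xc))
            dc = (2 * x0 - xa - xb) / ((xc - xa) * (xc - xb))
            sa = 2.0 / ((xa - xb) * (xa - xc))
            sb = 2.0 / ((xb - xa) * (xb - xc))
            sc = 2.0 / ((xc - xa) * (xc - xb))
            return (da, db, dc), (sa, sb, sc)

        rows_p, cols_p, vals_p = [], [], []
        rows_o, cols_o, vals_o = [], [], []
        for j in range(1, nj - 1):
            x0 = chi[:, j]
            # psi: centered stencil (the axis node carries psi = 0)
            ka, kb, kc = j - 1, j, j + 1
            _d1, d2 = lagrange_d1_d2(x0, chi[:, ka], chi[:, kb], chi[:, kc])
            for k, c2 in zip((ka, kb, kc), d2):
                rows_p.extend(flat[:, j])
                cols_p.extend(flat[:, k])
                vals_p.extend(4.0 * x0 * c2)
            # omega: avoid the axis node (omega/r is 0/0 there)
            if j == 1:
                ka, kb, kc = 1, 2, 3
            d1, d2 = lagrange_d1_d2(x0, chi[:, ka], chi[:, kb], chi[:, kc])
            for k, c1, c2 in zip((ka, kb, kc), d1, d2):
                coeff = r[:, j] * (4.0 * x0 * c2 + 8.0 * c1) / r[:, k]
                rows_o.extend(flat[:, j])
                cols_o.extend(flat[:, k])
                vals_o.extend(coeff)
        R_psi = sp.csr_matrix(
            (vals_p, (rows_p, cols_p)), shape=(n, n)
        )
        R_om = sp.csr_matrix((vals_o, (rows_o, cols_o)), shape=(n, n))
        return R_psi, R_om

    def _wall_rows(self):
        """(side, wall row, neighbor row, streamwise-sign of mu*omega)."""
        out = [("upper", self.nj - 1, self.nj - 2, +1.0)]
        if not self.axisym:
            out.append(("lower", 0, 1, -1.0))
        return out

    # -------------------------------------------------------------- fields
    def velocities(self, psi):
        ops = self.ops
        dpsi_dy = ops.apply(ops.Dy, psi)
        dpsi_dz = ops.apply(ops.Dz, psi)
        if self.axisym:
            # u_z = (1/r) dpsi/dr = 2 dpsi/d(r^2); differencing in r^2 avoids
            # the 1/r error amplification near the axis
            chi = self.Y**2
            uz = np.empty_like(psi)
            uz[:, 1:-1] = (
                2.0 * (psi[:, 2:] - psi[:, :-2]) / (chi[:, 2:] - chi[:, :-2])
            )
            uz[:, 0] = 2.0 * psi[:, 1] / chi[:, 1]
            uz[:, -1] = 2.0 * (psi[:, -1] - psi[:, -2]) / (chi[:, -1] - chi[:, -2])
            ur = -dpsi_dz * self.inv_r
            ur[:, 0] = 0.0
            return uz, ur
        return dpsi_dy, -dpsi_dz

    def thom_vorticity(self, psi):
        out = {}
        for side, (jw, jn, dn, rw, _s) in self.thom.items():
            out[side] = 2.0 * (psi[:, jw] - psi[:, jn]) / (rw * dn**2)
        return out

    def wall_shear(self, omega):
        """Signed streamwise WSS (Pa) per wall side from wall vorticity."""
        mu = self.props.viscosity
        out = {}
        for side, (jw, _jn, _dn, _rw, sgn) in self.thom.items():
            out[side] = sgn * mu * omega[:, jw]
        return out

    # ---------------------------------------------------------- assembly
    def advection_matrix(self, uz, ur, dt, max_cfl):
        a = self.ops.metric_a
        y_eta = self.ops.y_eta
        dz = self.ops.dz
        vxi = uz
        veta = ur / y_eta - uz * a
        if max_cfl is not None:
            cfl = np.abs(vxi) * dt / dz + np.abs(veta) * dt
            worst = float(cfl.max())
            if worst > max_cfl:
                raise SolverError(
                    f"advective CFL {worst:.1f} exceeds limit {max_cfl} at "
                    f"time step dt={dt:.3e} s; reduce the step size"
                )
        vxi_p, vxi_m = np.maximum(vxi, 0), np.minimum(vxi, 0)
        veta_p, veta_m = np.maximum(veta, 0), np.minimum(veta, 0)
        idx = self._adv_idx
        ii, jj = idx["ii"], idx["jj"]
        cp, cm = vxi_p[ii, jj] / dz, vxi_m[ii, jj] / dz
        ep, em = veta_p[ii, jj], veta_m[ii, jj]
        center = cp - cm + ep - em
        if self.axisym:  # vortex-stretch term -(u_r / r) omega
            center = center - ur[ii, jj] * self.inv_r[ii, jj]
        rows = np.concatenate([idx["ctr"]] * 5)
        cols = np.concatenate(
            [idx["ctr"], idx["west"], idx["east"], idx["south"], idx["north"]]
        )
        vals = np.concatenate([center, -cp, cm, -ep, em])
        return sp.csr_matrix((vals, (rows, cols)), shape=(self._n, self._n))

    def boundary_values(self, field_kind, t, inlet: _InletColumn):
        """Dirichlet/BC right-hand-side vector for psi or omega rows."""
        ni, nj = self.ni, self.nj
        vals = np.zeros((ni, nj))
        if field_kind == "psi":
            prof = inlet.psi(t)
            vals[0, :] = prof
            pw = inlet.psi_wall(t)
            vals[self.is_wall_up] = pw
            if not self.axisym:
                vals[self.is_wall_lo] = 0.0
            vals[self.is_axis] = 0.0
            vals[-1, 1:-1] = 0.0  # zero-gradient row rhs
            # wall rows override the inlet corners
            vals[0, -1] = pw
            vals[0, 0] = 0.0
        else:
            vals[0, :] = inlet.omega(t)
            # wall rows carry the homogeneous implicit Thom closure
            for _side, (jw, *_rest) in self.thom.items():
                vals[:, jw] = 0.0
            vals[self.is_axis] = 0.0
            vals[-1, 1:-1] = 0.0
        return vals.ravel()

    def solve_psi(self, omega, t, inlet):
        rhs_int = -omega if not self.axisym else -self.r * omega
        rhs = self.mask * rhs_int.ravel() + self.boundary_values("psi", t, inlet)
        return self.lu_psi.solve(rhs).reshape(self.ni, self.nj)

    def step(
        self,
        omega,
        psi,
        t_new,
        dt,
        inlet: _InletColumn,
        max_cfl=None,
        theta: float = 1.0,
    ):
        """One implicit step of the coupled vorticity/streamfunction system.

        Vorticity transport (advection linearized at the previous step),
        the streamfunction Poisson equation and the Thom wall closure are
        solved monolithically, which is unconditionally stable in dt.
        """
        uz, ur = self.velocities(psi)
        Adv = self.advection_matrix(uz, ur, dt, max_cfl)
        nu = self.props.nu
        L = (Adv - nu * self.L_om_masked).tocsr()
        A11 = sp.diags(self.mask / dt) + theta * L + self.A_bc_om
        A = sp.bmat([[A11, self.T_thom], [self.A_psi_om, self.A_psi]], format="csc")
        rhs_om = self.mask * (omega.ravel() / dt)
        if theta < 1.0:
            rhs_om = rhs_om - (1.0 - theta) * (L @ omega.ravel())
        rhs = np.concatenate(
            [
                rhs_om + self.boundary_values("omega", t_new, inlet),
                self.boundary_values("psi", t_new, inlet),
            ]
        )
        x = splu(A).solve(rhs)
        n = self._n
        return x[:n].reshape(self.ni, self.nj), x[n:].reshape(self.ni, self.nj)

    # -------------------------------------------------- initialization
    def developed_fields(self, waveform, t=0.0):
        """Column-by-column developed flow (exact in a straight tube)."""
        ni, nj = self.ni, self.nj
        psi = np.zeros((ni, nj))
        omega = np.zeros((ni, nj))
        nu = self.props.nu
        for i in range(ni):
            col = _InletColumn(self.Y[i], waveform, nu, self.axisym)
            u = col.u(t)
            psi[i] = col.psi(t)
            omega[i] = -np.gradient(u, self.Y[i], edge_order=2)
        return omega, psi

    def pressure_axial(self, sol: FlowSolution, k: int) -> np.ndarray:
        jm = self.nj // 2
        uz, ur = self.velocities(sol.psi[k])
        if sol.steady or k == 0:
            dudt = np.zeros_like(uz)
        else:
            uz_prev, _ = self.velocities(sol.psi[k - 1])
            dudt = (uz - uz_prev) / (sol.times[k] - sol.times[k - 1])
        ops = self.ops
        lap_u = ops.apply(ops.lap, uz)
        if self.axisym:
            lap_u += self.inv_r * ops.apply(ops.Dy, uz)
        conv = uz * ops.apply(ops.Dz, uz) + ur * ops.apply(ops.Dy, uz)
        mu, rho = self.props.viscosity, self.props.density
        dpdz = (mu * lap_u - rho * (dudt + conv))[:, jm]
        p = np.concatenate([[0.0], np.cumsum(0.5 * (dpdz[1:] + dpdz[:-1]) * np.diff(self.zs))])
        return p - p[-1]


def _inlet_for(system: _FlowSystem, waveform: Waveform) -> _InletColumn:
    return _InletColumn(system.Y[0], waveform, system.props.nu, system.axisym)


def solve_pulsatile(
    mesh: Mesh,
    props: FluidProperties,
    waveform: Waveform,
    cycles: int = 5,
    steps_per_cycle: int = 200,
    max_cfl: float = 40.0,
    theta: float = 0.5,
    init: str = "developed",
    flow_grading: float = 1.05,
) -> FlowSolution:
    """Integrate the pulsatile flow over ``cycles`` cardiac cycles.

    All snapshots are retained, tagged with their cycle index; downstream
    analysis uses the final cycle only (periodicity is reached by then, which
    the test suite checks through the cycle-to-cycle WSS drift).
    """
    if cycles < 1:
        raise ContractError("cycles must be >= 1")
    if steps_per_cycle < 8:
        raise ContractError("steps_per_cycle must be >= 8")
    system = _FlowSystem(mesh, props, flow_grading)
    inlet = _inlet_for(system, waveform)
    dt = waveform.period / steps_per_cycle
    if init == "developed":
        omega, psi = system.developed_fields(waveform, t=0.0)
    elif init == "zero":
        omega = np.zeros((system.ni, system.nj))
        psi = system.solve_psi(omega, 0.0, inlet)
    else:
        raise ContractError(f"unknown init {init!r}")

    n_t = cycles * steps_per_cycle + 1
    times = dt * np.arange(n_t)
    cyc = np.minimum(np.arange(n_t) // steps_per_cycle, cycles - 1)
    psis = np.empty((n_t, system.ni, system.nj))
    psis[0] = psi
    wss = {side: np.empty((n_t, system.ni)) for side, *_ in system._wall_rows()}
    for side, tau in system.wall_shear(omega).items():
        wss[side][0] = tau
    for n in range(1, n_t):
        omega, psi = system.step(
            omega, psi, times[n], dt, inlet, max_cfl=max_cfl, theta=theta
        )
        psis[n] = psi
        for side, tau in system.wall_shear(omega).items():
            wss[side][n] = tau
    sol = FlowSolution(
        mesh=mesh,
        props=props,
        waveform=waveform,
        times=times,
        cycle=cyc,
        psi=psis,
        wss=wss,
        steady=False,
    )
    sol._system = system
    return sol


def solve_steady(
    mesh: Mesh,
    props: FluidProperties,
    inflow: float,
    tol: float = 1e-5,
    dt_pseudo: float = 0.5,
    max_steps: int = 400,
    flow_grading: float = 1.05,
) -> FlowSolution:
    """Steady flow at constant mean inlet velocity ``inflow`` (m/s).

    Pseudo-time marching of the transient solver until the relative
    streamfunction change per step drops below ``tol``; raises
    :class:`SolverError` with the residual history on non-convergence.
    """
    if inflow == 0:
        raise ContractError("inflow must be non-zero")
    system = _FlowSystem(mesh, props, flow_grading)
    waveform = Waveform.constant(inflow)
    inlet = _inlet_for(system, waveform)
    omega, psi = system.developed_fields(waveform, t=0.0)
    hist = []
    scale = max(abs(psi).max(), 1e-300)
    for _ in range(max_steps):
        omega, psi_new = system.step(omega, psi, 0.0, dt_pseudo, inlet, max_cfl=None)
        res = float(np.abs(psi_new - psi).max() / scale)
        hist.append(res)
        psi = psi_new
        if res < tol:
            break
    else:
        raise SolverError(
            f"steady flow did not converge below {tol} in {max_steps} pseudo-steps "
            f"(last residual {hist[-1]:.3e})",
            residual_history=np.array(hist),
        )
    wss = {side: tau[None, :] for side, tau in system.wall_shear(omega).items()}
    sol = FlowSolution(
        mesh=mesh,
        props=props,
        waveform=waveform,
        times=np.array([0.0]),
        cycle=np.array([0]),
        psi=psi[None, :, :],
        wss=wss,
        steady=True,
        residual_history=np.array(hist),
    )
    sol._system = system
    return sol
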