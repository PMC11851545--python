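"""Coupled lumen/wall nitric-oxide transport with shear-modulated production.

Model
-----
NO is produced by the endothelium at the lumen-wall interface at a rate
controlled by the hyperbolic shear-response law

    R_NO(tau_w) = R_basal + R_max |tau_w| / (|tau_w| + b),

released over an endothelial layer of thickness ``delta_en`` (the interface
therefore carries a surface flux R_NO * delta_en).  In the lumen NO is
advected by the blood, diffuses, and is consumed by oxidation (pseudo-second
order) and by red blood cells (first order):

    dc_l/dt + u . grad c_l = D_l lap c_l - (k_oxgen c_l^2 + k_ery c_l).

In the wall convection is negligible and consumption is first order:

    dc_w/dt = D_w lap c_w - k_w c_w.

Discretization
--------------
Cell-centered finite volumes on the structured two-domain mesh.  Advective
face fluxes are streamfunction differences taken from the flow solution, so
the discrete velocity field is exactly divergence-free and the scheme is
conservative to round-off; first-order upwinding plus implicit (backward
Euler) stepping keeps the system an M-matrix, so concentrations stay
non-negative without clipping.  The endothelial source enters at interface
faces, split between the adjacent lumen and wall cells in proportion to
their face conductances (this is the discrete form of concentration + flux
continuity with a surface source; the implied interface concentration is
recoverable and is what TAcNO surface averages use).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .exceptions import ContractError, SolverError
from .flow import FlowSolution, FluidProperties, solve_steady
from .geometry import AXISYMMETRIC, Mesh, MeshResolution, VesselGeometry, build_mesh


@dataclass(frozen=True)
class TransportParameters:
    """NO transport constants (defaults: aortic endothelium, SI + nM).

    ``koxgen`` is the pseudo-second-order oxidation rate; the second-order
    form of the lumen sink requires units nM^-1 s^-1.  ``delta_en`` converts
    the volumetric endothelial production rate (nM/s) into a well-posed
    interface flux.
    """

    Dl: float = 3.3e-9  # m^2/s, NO diffusivity in blood
    koxgen: float = 7.56e-6  # nM^-1 s^-1, oxidation by oxygen
    kery: float = 2.3  # s^-1, scavenging by red blood cells
    Dw: float = 8.48e-10  # m^2/s, NO diffusivity in the arterial wall
    kw: float = 0.01  # s^-1, wall consumption
    Rbasal: float = 2.13  # nM/s, basal endothelial production
    Rmax: float = 457.5  # nM/s, saturable shear-driven production
    b: float = 3.5  # Pa, half-saturation shear stress
    delta_en: float = 2.5e-6  # m, endothelium thickness

    def __post_init__(self):
        for name in ("Dl", "koxgen", "kery", "Dw", "kw", "Rbasal", "Rmax", "b", "delta_en"):
            if getattr(self, name) <= 0:
                raise ContractError(f"transport parameter {name} must be positive")

    @property
    def wall_decay_length(self) -> float:
        """Reaction-diffusion decay length sqrt(Dw/kw) in the wall (m)."""
        return float(np.sqrt(self.Dw / self.kw))


def production_rate(tau_w, params: TransportParameters = TransportParameters()):
    """Endothelial NO production rate (nM/s) for wall shear stress tau_w (Pa).

    Hyperbolic saturation law; monotone nondecreasing in |tau_w|, equal to
    ``Rbasal`` at zero shear and approaching ``Rbasal + Rmax`` at high shear.
    """
    tau = np.abs(np.asarray(tau_w, dtype=float))
    if not np.all(np.isfinite(tau)):
        raise ContractError("tau_w must be finite")
    r = params.Rbasal + params.Rmax * tau / (tau + params.b)
    return float(r) if r.ndim == 0 else r


def lumen_reaction(cl, params: TransportParameters = TransportParameters()):
    """Lumen consumption rate (nM/s): koxgen*cl^2 + kery*cl, for cl >= 0."""
    c = np.asarray(cl, dtype=float)
    if np.any(c < 0):
        raise ContractError("lumen concentration must be non-negative")
    r = params.koxgen * c**2 + params.kery * c
    return float(r) if r.ndim == 0 else r


# --------------------------------------------------------------------------
# solution container
# --------------------------------------------------------------------------


@dataclass
class NOSolution:
    """NO concentration fields (nM) on the two-domain mesh.

    ``c`` holds cell-centered snapshots of the final simulated cycle
    (n_t, n_axial, nj); ``interface`` maps each wall side to the implied
    interface concentration series (n_t, n_axial faces); ``production`` maps
    each side to the endothelial production-rate trace R_NO (nM/s).
    """

    mesh: Mesh
    params: TransportParameters
    times: np.ndarray
    c: np.ndarray
    interface: dict
    production: dict
    steady: bool = False
    cycle_trace: np.ndarray | None = None  # per-step mean concentration, all cycles
    _system: object = field(default=None, repr=False)

    @property
    def sides(self):
        return sorted(self.interface.keys())

    def lumen_mask(self) -> np.ndarray:
        return self.mesh.cell_domain() == "lumen"

    def min_concentration(self) -> float:
        return float(self.c.min())

    def time_averaged_field(self) -> np.ndarray:
        """Cell field averaged over the final cycle (trapezoid in time)."""
        if self.steady:
            return self.c[0]
        T = self.times[-1] - self.times[0]
        return np.trapezoid(self.c, self.times, axis=0) / T

    def interface_tacno(self, side: str) -> np.ndarray:
        """Per-face time-averaged interface concentration (nM)."""
        ci = self.interface[side]
        if self.steady:
            return ci[0]
        T = self.times[-1] - self.times[0]
        return np.trapezoid(ci, self.times, axis=0) / T

    def face_positions(self) -> np.ndarray:
        """Axial midpoints (m) of the interface faces."""
        zs = self.mesh.zs
        return 0.5 * (zs[:-1] + zs[1:])

    def domain_average(self, domain: str | None = None) -> float:
        """Volume-weighted average concentration of the final snapshot."""
        V = self.mesh.cell_volumes()
        cbar = self.c[-1]
        if domain is None:
            return float((cbar * V).sum() / V.sum())
        m = self.mesh.cell_domain() == domain
        return float((cbar[m] * V[m]).sum() / V[m].sum())

    def save(self, path) -> None:
        """Persist the solution (npz) for later pipeline stages."""
        data = dict(
            times=self.times,
            c=self.c,
            steady=np.array(self.steady),
        )
        if self.cycle_trace is not None:
            data["cycle_trace"] = self.cycle_trace
        for s in self.interface:
            data[f"interface_{s}"] = self.interface[s]
            data[f"production_{s}"] = self.production[s]
        np.savez_compressed(path, **data)

    @classmethod
    def load(cls, path, mesh, params) -> "NOSolution":
        with np.load(path) as d:
            sol = cls(
                mesh=mesh,
                params=params,
                times=d["times"],
                c=d["c"],
                interface={k[10:]: d[k] for k in d.files if k.startswith("interface_")},
                production={k[11:]: d[k] for k in d.files if k.startswith("production_")},
                steady=bool(d["steady"]),
                cycle_trace=d["cycle_trace"] if "cycle_trace" in d.files else None,
            )
        return sol

    def balance_report(self) -> dict:
        """Discrete steady-state source/sink audit (nM * m^3 / s terms)."""
        if not self.steady:
            raise ContractError("balance audit is defined for steady solutions")
        psiT, tau = self._system._audit_inputs
        return self._system.balance(self.c[0], psiT, tau)


# --------------------------------------------------------------------------
# finite-volume machinery
# --------------------------------------------------------------------------


class _TransportSystem:
    """Cell-centered FV discretization of the two-domain transport model."""

    def __init__(self, mesh: Mesh, params: TransportParameters):
        self.mesh = mesh
        self.params = params
        self.axisym = mesh.mode == AXISYMMETRIC
        fac = 2.0 * np.pi if self.axisym else 1.0
        self.fac = fac
        zs, Y = mesh.zs, mesh.Y
        nci, ncj = mesh.n_axial, mesh.nj
        self.nci, self.ncj = nci, ncj
        self.n = nci * ncj
        self.V = mesh.cell_volumes().ravel()
        dom = mesh.cell_domain()
        self.lumen = (dom == "lumen").ravel()
        j0, j1 = mesh.j_lumen  # lumen cell rows are j0..j1-1
        self.j_lum = (j0, j1)

        Cz = 0.5 * (zs[:-1] + zs[1:])[:, None] * np.ones((1, ncj))
        Cy = 0.25 * (Y[:-1, :-1] + Y[1:, :-1] + Y[:-1, 1:] + Y[1:, 1:])
        self.Cz, self.Cy = Cz, Cy
        flat = np.arange(self.n).reshape(nci, ncj)
        D_of_row = np.where(
            (np.arange(ncj) >= j0) & (np.arange(ncj) < j1), params.Dl, params.Dw
        )

        # ---------------- internal vertical faces (axial neighbors) -------
        i, j = np.meshgrid(np.arange(nci - 1), np.arange(ncj), indexing="ij")
        yb = Y[i + 1, j]
        yt = Y[i + 1, j + 1]
        A = (yt - yb) * (fac * 0.5 * (yt + yb) if self.axisym else 1.0)
        d = np.hypot(Cz[i + 1, j] - Cz[i, j], Cy[i + 1, j] - Cy[i, j])
        G = D_of_row[j] * A / d
        self.vf_a = flat[i, j].ravel()
        self.vf_b = flat[i + 1, j].ravel()
        self.vf_G = G.ravel()
        self.vf_lumen = self.lumen[self.vf_a] & self.lumen[self.vf_b]
        self.vf_node_col = (i + 1).ravel()  # psi node column of the face
        self.vf_cell_row = j.ravel()

        # ---------------- internal horizontal faces (transverse) ----------
        i, j = np.meshgrid(np.arange(nci), np.arange(ncj - 1), indexing="ij")
        # face at node row j+1, from node (i, j+1) to (i+1, j+1)
        dzf = zs[i + 1] - zs[i]
        dyf = Y[i + 1, j + 1] - Y[i, j + 1]
        length = np.hypot(dzf, dyf)
        rbar = 0.5 * (Y[i, j + 1] + Y[i + 1, j + 1])
        A = length * (fac * rbar if self.axisym else 1.0)
        zmid = 0.5 * (zs[i] + zs[i + 1])
        ymid = 0.5 * (Y[i, j + 1] + Y[i + 1, j + 1])
        d_lo = np.hypot(Cz[i, j] - zmid, Cy[i, j] - ymid)
        d_hi = np.hypot(Cz[i, j + 1] - zmid, Cy[i, j + 1] - ymid)
        lum_lo = self.lumen.reshape(nci, ncj)[i, j]
        lum_hi = self.lumen.reshape(nci, ncj)[i, j + 1]
        is_iface = lum_lo != lum_hi
        D_lo = np.where(lum_lo, params.Dl, params.Dw)
        D_hi = np.where(lum_hi, params.Dl, params.Dw)
        k_lo = D_lo * A / d_lo
        k_hi = D_hi * A / d_hi
        G = k_lo * k_hi / (k_lo + k_hi)  # series conductance
        self.hf_a = flat[i, j].ravel()
        self.hf_b = flat[i, j + 1].ravel()
        self.hf_G = G.ravel()
        self.hf_lumen = (lum_lo & lum_hi).ravel()
        self.hf_node_row = (j + 1).ravel()
        self.hf_node_col = i.ravel()

        # interface faces: source split proportional to conductances
        self.ifaces = {}
        for side, jn in mesh.j_interfaces.items():
            m = (j + 1 == jn)  # faces sitting on interface node row jn
            assert np.all(is_iface[m])
            a = flat[i, j][m]  # cell below
            b = flat[i, j + 1][m]
            frac_lo = (k_lo / (k_lo + k_hi))[m]
            to_lumen_is_lo = lum_lo[m]
            lum_cell = np.where(to_lumen_is_lo, a, b)
            wall_cell = np.where(to_lumen_is_lo, b, a)
            f_lum = np.where(to_lumen_is_lo, frac_lo, 1.0 - frac_lo)
            order = np.argsort(i[m])  # by axial face index
            self.ifaces[side] = dict(
                lum_cell=lum_cell[order],
                wall_cell=wall_cell[order],
                f_lum=f_lum[order],
                area=A[m][order],
                k_lum=np.where(to_lumen_is_lo, k_lo[m], k_hi[m])[order],
                k_wall=np.where(to_lumen_is_lo, k_hi[m], k_lo[m])[order],
            )

        # ---------------- diffusion matrix (constant) ----------------------
        rows = np.concatenate([self.vf_a, self.vf_a, self.vf_b, self.vf_b,
                               self.hf_a, self.hf_a, self.hf_b, self.hf_b])
        cols = np.concatenate([self.vf_a, self.vf_b, self.vf_b, self.vf_a,
                               self.hf_a, self.hf_b, self.hf_b, self.hf_a])
        vg, hg = self.vf_G, self.hf_G
        vals = np.concatenate([vg, -vg, vg, -vg, hg, -hg, hg, -hg])
        K = sp.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

        # inlet Dirichlet (c = 0) diffusive closure for lumen cells
        jl = np.arange(j0, j1)
        cells = flat[0, jl]
        yb = Y[0, jl]
        yt = Y[0, jl + 1]
        Ain = (yt - yb) * (fac * 0.5 * (yt + yb) if self.axisym else 1.0)
        din = Cz[0, jl] - zs[0]
        Gin = params.Dl * Ain / din
        K = K + sp.csr_matrix(
            (Gin, (cells, cells)), shape=(self.n, self.n)
        )
        self.inlet_cells = cells
        self.inlet_G = Gin
        self.K = K.tocsr()

        # first-order reaction diagonal (implicit part)
        react = np.where(self.lumen, params.kery, params.kw) * self.V
        self.react = react

        # boundary advective bookkeeping (outward-positive fluxes)
        self._flat = flat

    # ------------------------------------------------------------------
    def face_fluxes(self, psiT: np.ndarray):
        """(internal vertical Q, internal horizontal Q, inlet Qo, outlet Qo).

        ``psiT`` is the streamfunction at the transport-mesh lumen nodes,
        shape (n_axial+1, n_lumen+1).  Fluxes are volumetric (include the
        2*pi factor in axisymmetric mode) and exactly telescoping.
        """
        j0, j1 = self.j_lum
        fac = self.fac
        nci, ncj = self.nci, self.ncj
        Qv = np.zeros(len(self.vf_a))
        m = self.vf_lumen
        jl = self.vf_cell_row[m] - j0
        ic = self.vf_node_col[m]
        Qv[m] = fac * (psiT[ic, jl + 1] - psiT[ic, jl])
        Qh = np.zeros(len(self.hf_a))
        m = self.hf_lumen
        jn = self.hf_node_row[m] - j0
        ic = self.hf_node_col[m]
        Qh[m] = fac * (psiT[ic, jn] - psiT[ic + 1, jn])
        jl = np.arange(j1 - j0)
        Q_in_outward = -fac * (psiT[0, jl + 1] - psiT[0, jl])
        Q_out_outward = fac * (psiT[-1, jl + 1] - psiT[-1, jl])
        return Qv, Qh, Q_in_outward, Q_out_outward

    def advection_matrix(self, psiT: np.ndarray) -> sp.csr_matrix:
        Qv, Qh, Qin, Qout = self.face_fluxes(psiT)
        rows, cols, vals = [], [], []
        for (a, b, Q) in ((self.vf_a, self.vf_b, Qv), (self.hf_a, self.hf_b, Qh)):
            qp = np.maximum(Q, 0.0)
            qm = np.minimum(Q, 0.0)
            rows.extend([a, a, b, b])
            cols.extend([a, b, b, a])
            vals.extend([qp, qm, -qm, -qp])
        j0, j1 = self.j_lum
        for col_cells, Qo in (
            (self._flat[0, j0:j1], Qin),
            (self._flat[-1, j0:j1], Qout),
        ):
            rows.append(col_cells)
            cols.append(col_cells)
            vals.append(np.maximum(Qo, 0.0))
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def source_vector(self, tau_nodes: dict) -> tuple[np.ndarray, dict]:
        """Endothelial production RHS from wall-node WSS per side.

        Returns (rhs vector, {side: R_NO per face}).
        """
        S = np.zeros(self.n)
        trace = {}
        for side, f in self.ifaces.items():
            tau = tau_nodes[side]
            tau_face = 0.5 * (tau[:-1] + tau[1:])
            R = production_rate(tau_face, self.params)
            trace[side] = R
            src = R * self.params.delta_en * f["area"]
            np.add.at(S, f["lum_cell"], src * f["f_lum"])
            np.add.at(S, f["wall_cell"], src * (1.0 - f["f_lum"]))
        return S, trace

    def interface_concentration(self, c: np.ndarray, tau_nodes: dict) -> dict:
        """Implied interface concentration per side (length n_axial)."""
        out = {}
        cf = c.ravel()
        for side, f in self.ifaces.items():
            tau = tau_nodes[side]
            tau_face = 0.5 * (tau[:-1] + tau[1:])
            R = production_rate(tau_face, self.params)
            S = R * self.params.delta_en * f["area"]
            out[side] = (
                f["k_lum"] * cf[f["lum_cell"]] + f["k_wall"] * cf[f["wall_cell"]] + S
            ) / (f["k_lum"] + f["k_wall"])
        return out

    # ------------------------------------------------------------------
    def steady_matrix(self, psiT, c_lag=None):
        A = self.advection_matrix(psiT) + self.K + sp.diags(self.react)
        if c_lag is not None:
            A = A + sp.diags(
                np.where(self.lumen, self.params.koxgen * np.maximum(c_lag, 0.0), 0.0)
                * self.V
            )
        return A.tocsc()

    def solve_steady(self, psiT, tau_nodes=None, S=None, picard: int = 2) -> np.ndarray:
        if S is None:
            S, _ = self.source_vector(tau_nodes)
        c = np.zeros(self.n)
        for _ in range(picard):
            A = self.steady_matrix(psiT, c_lag=c)
            c = splu(A).solve(S)
        return c.reshape(self.nci, self.ncj)

    def balance(self, c_field: np.ndarray, psiT: np.ndarray, tau_nodes: dict) -> dict:
        """Steady source/sink closure audit.

        Returns production, lumen/wall consumption, net boundary losses and
        the relative closure defect (zero to solver precision by
        construction of the finite-volume scheme).
        """
        c = c_field.ravel()
        p = self.params
        S, _ = self.source_vector(tau_nodes)
        production = float(S.sum())
        lum_sink = float(((p.kery * c + p.koxgen * c**2) * self.V)[self.lumen].sum())
        wall_sink = float((p.kw * c * self.V)[~self.lumen].sum())
        _qv, _qh, Qin, Qout = self.face_fluxes(psiT)
        j0, j1 = self.j_lum
        cin = c[self._flat[0, j0:j1]]
        cout = c[self._flat[-1, j0:j1]]
        outflow = float(
            (np.maximum(Qin, 0.0) * cin).sum() + (np.maximum(Qout, 0.0) * cout).sum()
        )
        inlet_diffusion = float((self.inlet_G * cin).sum())
        total_loss = lum_sink + wall_sink + outflow + inlet_diffusion
        return dict(
            production=production,
            lumen_sink=lum_sink,
            wall_sink=wall_sink,
            advective_outflow=outflow,
            inlet_diffusive_loss=inlet_diffusion,
            closure_defect=abs(production - total_loss) / production,
        )


def _psi_series_on_transport(flow: FlowSolution):
    """Final-cycle streamfunction snapshots on the transport mesh nodes."""
    idx = flow.final_cycle_indices()
    sys_ = flow._system
    return np.array([sys_.psi_on_transport(flow.psi[k]) for k in idx]), idx


def solve_no(
    mesh: Mesh,
    flow: FlowSolution,
    params: TransportParameters = TransportParameters(),
    cycles: int = 5,
    negative_tol: float = 1e-6,
) -> NOSolution:
    """Integrate NO transport over ``cycles`` cardiac cycles.

    The flow's final (periodic) cycle drives every NO cycle; the run is
    initialized from the converged steady NO field at the cycle-averaged
    flow, and the final NO cycle is returned for analysis.
    """
    if flow.mesh is not mesh and flow.mesh.Y.shape != mesh.Y.shape:
        raise ContractError("flow solution was computed on a different mesh")
    if cycles < 1:
        raise ContractError("cycles must be >= 1")
    system = _TransportSystem(mesh, params)
    if flow.steady:
        psiT = flow._system.psi_on_transport(flow.psi[0])
        tau = {side: flow.wss[side][0] for side in flow.sides}
        c = system.solve_steady(psiT, tau)
        _check_nonneg(c, negative_tol)
        system._audit_inputs = (psiT, tau)
        sol = NOSolution(
            mesh=mesh,
            params=params,
            times=np.array([0.0]),
            c=c[None, ...],
            interface={s: v[None, :] for s, v in system.interface_concentration(c, tau).items()},
            production={s: production_rate(0.5 * (t[:-1] + t[1:]), params)[None, :] for s, t in tau.items()},
            steady=True,
        )
        sol._system = system
        return sol

    psis, idx = _psi_series_on_transport(flow)
    t_cycle = flow.times[idx]
    dt = np.diff(t_cycle)
    spc = len(idx) - 1
    taus = {side: flow.wss[side][idx] for side in flow.sides}

    # initialization: steady NO at the cycle-averaged flow, driven by the
    # cycle-averaged production rate (production is nonlinear in tau, so
    # averaging R_NO rather than tau puts the slow wall domain much closer
    # to its periodic state)
    T = t_cycle[-1] - t_cycle[0]
    psi_bar = np.trapezoid(psis, t_cycle, axis=0) / T
    S_steps = np.array(
        [system.source_vector({s: taus[s][m] for s in taus})[0] for m in range(len(t_cycle))]
    )
    S_bar = np.trapezoid(S_steps, t_cycle, axis=0) / T
    c = system.solve_steady(psi_bar, S=S_bar).ravel()

    n_store = spc + 1
    c_store = np.empty((n_store, system.nci, system.ncj))
    iface_store = {s: np.empty((n_store, system.nci)) for s in taus}
    prod_store = {s: np.empty((n_store, system.nci)) for s in taus}
    trace = []
    koxV = np.where(system.lumen, params.koxgen, 0.0) * system.V

    step_total = cycles * spc
    for n in range(step_total + 1):
        m = n % spc if n < step_total else spc  # index within the cycle
        if n > 0:
            dtm = dt[(n - 1) % spc]
            tau_m = {s: taus[s][m] for s in taus}
            S, prod = system.source_vector(tau_m)
            A = (
                sp.diags(system.V / dtm)
                + system.advection_matrix(psis[m])
                + system.K
                + sp.diags(system.react)
            ).tocsc()
            rhs = system.V * c / dtm + S - koxV * c**2
            c = splu(A).solve(rhs)
        trace.append(float(c.mean()))
        if n >= (cycles - 1) * spc:
            k = n - (cycles - 1) * spc
            tau_m = {s: taus[s][m] for s in taus}
            cf = c.reshape(system.nci, system.ncj)
            c_store[k] = cf
            ci = system.interface_concentration(cf, tau_m)
            _, prod = system.source_vector(tau_m)
            for s in taus:
                iface_store[s][k] = ci[s]
                prod_store[s][k] = prod[s]
    _check_nonneg(c, negative_tol)
    sol = NOSolution(
        mesh=mesh,
        params=params,
        times=t_cycle - t_cycle[0],
        c=c_store,
        interface=iface_store,
        production=prod_store,
        steady=False,
        cycle_trace=np.array(trace),
    )
    sol._system = system
    return sol


def _check_nonneg(c, tol):
    cmin = float(np.min(c))
    if cmin < -tol:
        raise SolverError(
            f"concentration fell to {cmin:.3e} nM, below the -{tol} scheme "
            "tolerance; the scheme should be positivity-preserving"
        )


def solve_no_steady(
    mesh: Mesh,
    flow: FlowSolution,
    params: TransportParameters = TransportParameters(),
) -> NOSolution:
    """Steady NO solve driven by a steady flow solution."""
    if not flow.steady:
        raise ContractError("solve_no_steady requires a steady flow solution")
    return solve_no(mesh, flow, params)


def wall_slab_profile(
    params: TransportParameters = TransportParameters(),
    thickness: float = 2.0e-3,
    c0: float = 1.0,
    n_cells: int = 14,
    grading: float = 1.15,
):
    """Steady 1D diffusion-reaction profile across a wall slab.

    Solves D_w c'' = k_w c with c(0) = c0 (endothelial face) and zero flux at
    x = thickness, on the same graded finite-volume discretization the wall
    domain uses (finest cells at the endothelium).  Returns (cell centres x,
    concentrations).  Closed form: c0 cosh((W-x)/L)/cosh(W/L), L=sqrt(Dw/kw).
    """
    from .geometry import _graded_unit_spacings

    dx = thickness * _graded_unit_spacings(n_cells, grading, "start")
    xf = np.concatenate([[0.0], np.cumsum(dx)])
    xc = 0.5 * (xf[:-1] + xf[1:])
    D, k = params.Dw, params.kw
    G = np.zeros(n_cells + 1)  # conductance per unit area at faces
    G[0] = D / xc[0]
    G[1:-1] = D / np.diff(xc)
    A = sp.lil_matrix((n_cells, n_cells))
    rhs = np.zeros(n_cells)
    for i in range(n_cells):
        A[i, i] = k * dx[i]
        if i == 0:
            A[i, i] += G[0]
            rhs[i] += G[0] * c0
        else:
            A[i, i] += G[i]
            A[i, i - 1] -= G[i]
        if i < n_cells - 1:
            A[i, i] += G[i + 1]
            A[i, i + 1] -= G[i + 1]
    c = np.linalg.solve(A.toarray(), rhs)
    return xc, c


@dataclass
class MeshIndependenceReport:
    """Trace of the steady-state grid refinement protocol."""

    resolutions: list
    averages: list
    deltas: list
    accepted: bool
    refinement_factor: float
    threshold: float

    @property
    def accepted_resolution(self):
        return self.resolutions[-1] if self.accepted else None


def mesh_independence_study(
    geom: VesselGeometry,
    base_resolution: MeshResolution = MeshResolution(n_axial=40, n_lumen=14, n_wall=6),
    mode: str = AXISYMMETRIC,
    props: FluidProperties = FluidProperties(),
    params: TransportParameters = TransportParameters(),
    inflow: float = 0.2,
    refinement_factor: float = 1.1,
    threshold: float = 0.05,
    max_refinements: int = 8,
) -> MeshIndependenceReport:
    """Grid-refinement protocol on the steady NO field.

    Starting from ``base_resolution``, refine all directions by
    ``refinement_factor`` until the volume-averaged NO concentration changes
    by less than ``threshold`` (relative) between consecutive meshes.  A
    non-positive threshold can never be met and yields a failure-flagged
    report after ``max_refinements``.
    """
    res = base_resolution
    resolutions, averages, deltas = [], [], []
    prev = None
    accepted = False
    for _ in range(max_refinements + 1):
        mesh = build_mesh(geom, res, mode)
        fsol = solve_steady(mesh, props, inflow)
        nsol = solve_no(mesh, fsol, params)
        avg = nsol.domain_average()
        resolutions.append(res)
        averages.append(avg)
        if prev is not None:
            delta = abs(avg - prev) / abs(prev)
            deltas.append(delta)
            if delta < threshold:
                accepted = True
                break
        prev = avg
        res = res.scaled(refinement_factor)
    return MeshIndependenceReport(
        resolutions=resolutions,
        averages=averages,
        deltas=deltas,
        accepted=accepted,
        refinement_factor=refinement_factor,
        threshold=threshold,
    )
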