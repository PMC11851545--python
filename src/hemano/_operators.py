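"""Sparse finite-difference operators on a mapped structured grid.

The lumen block of a :class:`~hemano.geometry.Mesh` is logically rectangular:
index i runs along the axis (uniform physical spacing dz) and index j across
the vessel with physical transverse coordinate y = Y[i, j] (graded).  All
physical derivatives are expressed in the index coordinates (xi = z, eta = j):

    f_y  = f_eta / y_eta
    f_yy = f_etaeta / y_eta^2 - f_eta * y_etaeta / y_eta^3
    f_z  = f_xi - a f_eta,               a = y_xi / y_eta
    f_zz = f_xixi - 2 a f_xieta + a^2 f_etaeta + (a a_eta - a_xi) f_eta

Metric coefficients are evaluated from the node coordinates with second-order
differences.  Boundary rows of the returned matrices use second-order
one-sided stencils; equation assembly replaces those rows with boundary
conditions anyway, but first-derivative operators stay usable up to the edge
(needed to evaluate velocities at walls).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def d1_uniform(n: int, h: float = 1.0) -> sp.csr_matrix:
    """Second-order first derivative on a uniform 1D grid."""
    D = sp.lil_matrix((n, n))
    for k in range(1, n - 1):
        D[k, k - 1], D[k, k + 1] = -0.5, 0.5
    D[0, 0], D[0, 1], D[0, 2] = -1.5, 2.0, -0.5
    D[n - 1, n - 3], D[n - 1, n - 2], D[n - 1, n - 1] = 0.5, -2.0, 1.5
    return (D / h).tocsr()


def d2_uniform(n: int, h: float = 1.0) -> sp.csr_matrix:
    """Second-order second derivative on a uniform 1D grid."""
    D = sp.lil_matrix((n, n))
    for k in range(1, n - 1):
        D[k, k - 1], D[k, k], D[k, k + 1] = 1.0, -2.0, 1.0
    # one-sided (first-order) second differences at the edges; these rows are
    # always replaced by boundary conditions in assembled equations
    D[0, 0], D[0, 1], D[0, 2] = 1.0, -2.0, 1.0
    D[n - 1, n - 3], D[n - 1, n - 2], D[n - 1, n - 1] = 1.0, -2.0, 1.0
    return (D / h**2).tocsr()


class GridOperators:
    """Derivative matrices for a mapped structured block of nodes.

    Parameters
    ----------
    zs : (ni,) uniform axial node coordinates
    Y : (ni, nj) transverse node coordinates
    """

    def __init__(self, zs: np.ndarray, Y: np.ndarray):
        self.zs = np.asarray(zs, dtype=float)
        self.Y = np.asarray(Y, dtype=float)
        ni, nj = self.Y.shape
        self.ni, self.nj = ni, nj
        self.n = ni * nj
        dz = float(zs[1] - zs[0])
        self.dz = dz

        Ii, Ij = sp.identity(ni, format="csr"), sp.identity(nj, format="csr")
        Dxi = sp.kron(d1_uniform(ni, dz), Ij, format="csr")
        Deta = sp.kron(Ii, d1_uniform(nj, 1.0), format="csr")
        D2xi = sp.kron(d2_uniform(ni, dz), Ij, format="csr")
        D2eta = sp.kron(Ii, d2_uniform(nj, 1.0), format="csr")
        Dxieta = (Dxi @ Deta).tocsr()

        y_eta = np.gradient(self.Y, axis=1, edge_order=2)
        # y_etaeta must be the same 3-point stencil as D2eta, otherwise the
        # two terms of f_yy stop cancelling for linear f on graded grids
        y_etaeta = np.empty_like(self.Y)
        y_etaeta[:, 1:-1] = self.Y[:, 2:] - 2.0 * self.Y[:, 1:-1] + self.Y[:, :-2]
        y_etaeta[:, 0] = y_etaeta[:, 1]
        y_etaeta[:, -1] = y_etaeta[:, -2]
        y_xi = np.gradient(self.Y, dz, axis=0, edge_order=2)
        a = y_xi / y_eta
        a_eta = np.gradient(a, axis=1, edge_order=2)
        a_xi = np.gradient(a, dz, axis=0, edge_order=2)

        def dg(arr):
            return sp.diags(arr.ravel())

        self.y_eta = y_eta
        self.metric_a = a
        self.Dy = (dg(1.0 / y_eta) @ Deta).tocsr()
        self.Dyy = (dg(1.0 / y_eta**2) @ D2eta - dg(y_etaeta / y_eta**3) @ Deta).tocsr()
        self.Dz = (Dxi - dg(a) @ Deta).tocsr()
        self.Dzz = (
            D2xi
            - 2.0 * dg(a) @ Dxieta
            + dg(a**2) @ D2eta
            + dg(a * a_eta - a_xi) @ Deta
        ).tocsr()
        self.Deta = Deta
        self.lap = (self.Dzz + self.Dyy).tocsr()

    def apply(self, M: sp.spmatrix, f: np.ndarray) -> np.ndarray:
        return (M @ f.ravel()).reshape(self.ni, self.nj)
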