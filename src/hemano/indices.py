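"""Wall-based hemodynamic indices and time-averaged NO summaries.

All time integrals are taken over exactly one (the final) cardiac cycle with
the uniform trapezoid rule:

    TAWSS  = (1/T) int |tau_w| dt
    OSI    = 0.5 (1 - |int tau_w dt| / int |tau_w| dt)     in [0, 0.5]
    RRT    = 1 / ((1 - 2 OSI) TAWSS)
    ECAP   = OSI / TAWSS
    TAWSSG = (1/T) int |d tau_w / ds| dt   (surface-tangential gradient)
    TAcNO  = time average, then spatial average, of the NO concentration

In 2D the spatial WSS gradient reduces to the derivative along the wall arc
length s; a steady solution is treated as a constant-in-time cycle (OSI = 0,
RRT = 1/TAWSS).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import ContractError
from .flow import FlowSolution
from .no_transport import NOSolution


def _check_series(t, x):
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size == 0 or x.shape[0] != t.size:
        raise ContractError("empty or mismatched time series")
    return t, x


def tawss(t, tau):
    """Time-averaged |WSS| (Pa) over one cycle; constant for steady input."""
    t, tau = _check_series(t, tau)
    if t.size == 1:
        return np.abs(tau[0]) if tau.ndim > 0 else float(abs(tau))
    T = t[-1] - t[0]
    return np.trapezoid(np.abs(tau), t, axis=0) / T


def osi(t, tau):
    """Oscillatory shear index in [0, 0.5]; NaN (with a warning) where the
    WSS series is identically zero."""
    t, tau = _check_series(t, tau)
    if t.size == 1:
        return np.zeros(np.shape(tau[0])) if tau.ndim > 1 else 0.0
    num = np.abs(np.trapezoid(tau, t, axis=0))
    den = np.trapezoid(np.abs(tau), t, axis=0)
    zero = den == 0
    if np.any(zero):
        warnings.warn("OSI undefined for identically zero WSS series")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 0.5 * (1.0 - num / den)
    out = np.where(zero, np.nan, out)
    return np.clip(out, 0.0, 0.5) if np.ndim(out) else float(np.clip(out, 0.0, 0.5))


def rrt(tawss_val, osi_val):
    """Relative residence time 1/((1-2 OSI) TAWSS); +inf where OSI = 0.5."""
    tw = np.asarray(tawss_val, dtype=float)
    os_ = np.asarray(osi_val, dtype=float)
    if np.any(tw <= 0):
        raise ContractError("RRT requires TAWSS > 0")
    with np.errstate(divide="ignore"):
        out = 1.0 / ((1.0 - 2.0 * os_) * tw)
    return float(out) if out.ndim == 0 else out


def ecap(tawss_val, osi_val):
    """Endothelial cell activation potential OSI / TAWSS (Pa^-1)."""
    tw = np.asarray(tawss_val, dtype=float)
    if np.any(tw <= 0):
        raise ContractError("ECAP requires TAWSS > 0")
    out = np.asarray(osi_val, dtype=float) / tw
    return float(out) if out.ndim == 0 else out


def tawssg(t, tau, s):
    """Time-averaged magnitude of the tangential WSS gradient (Pa/m).

    ``tau`` has shape (n_t, n_s); ``s`` is the wall arc-length coordinate.
    """
    t = np.asarray(t, dtype=float)
    tau = np.atleast_2d(np.asarray(tau, dtype=float))
    s = np.asarray(s, dtype=float)
    if s.size < 2:
        raise ContractError("TAWSSG needs at least two interface points")
    grad = np.abs(np.gradient(tau, s, axis=1))
    if t.size == 1:
        return grad[0]
    T = t[-1] - t[0]
    return np.trapezoid(grad, t, axis=0) / T


def tacno(t, c, weights=None):
    """Time-average then spatial average of an NO concentration series.

    ``c`` may be (n_t,) for a point, or (n_t, n_pts) for a region; optional
    ``weights`` give the spatial quadrature weights of the region.
    """
    t, c = _check_series(t, c)
    if t.size == 1:
        cbar = c[0]
    else:
        T = t[-1] - t[0]
        cbar = np.trapezoid(c, t, axis=0) / T
    cbar = np.atleast_1d(cbar)
    if cbar.size == 0:
        raise ContractError("empty region for TAcNO")
    if weights is None:
        return float(np.mean(cbar))
    w = np.asarray(weights, dtype=float)
    return float(np.sum(w * cbar) / np.sum(w))


def compute_index_field(
    flow: FlowSolution, no: NOSolution | None = None, side: str = "upper"
) -> pd.DataFrame:
    """Per-interface-point index table for one wall side.

    Columns: s_mm, z_mm, TAWSS (Pa), OSI, RRT (1/Pa), ECAP (1/Pa),
    TAWSSG (Pa/m), and TAcNO (nM) when an NO solution is supplied (interface
    face values interpolated to the wall nodes).
    """
    if side not in flow.wss:
        raise ContractError(f"flow solution has no wall side {side!r}")
    tcyc, tau = flow.wss_final_cycle(side)
    s = flow.mesh.interface_arclength(side)
    z = flow.mesh.zs
    tw = tawss(tcyc, tau)
    os_ = osi(tcyc, tau) if not flow.steady else np.zeros_like(tw)
    os_ = np.atleast_1d(os_)
    df = pd.DataFrame(
        {
            "s_mm": s * 1e3,
            "z_mm": z * 1e3,
            "TAWSS": np.atleast_1d(tw),
            "OSI": os_,
            "RRT": rrt(tw, os_),
            "ECAP": ecap(tw, os_),
            "TAWSSG": np.atleast_1d(tawssg(tcyc, tau, s)),
        }
    )
    df.attrs["side"] = side
    if no is not None:
        zf = no.face_positions()
        tac = no.interface_tacno(side)
        df["TAcNO"] = np.interp(z, zf, tac)
    return df


def check_index_invariants(df: pd.DataFrame, atol: float = 1e-10) -> None:
    """Raise if the exact algebraic identities between indices fail."""
    osi_v = df["OSI"].to_numpy()
    tw = df["TAWSS"].to_numpy()
    rrt_v = df["RRT"].to_numpy()
    ecap_v = df["ECAP"].to_numpy()
    ok = np.isfinite(rrt_v)
    if np.any((osi_v < -atol) | (osi_v > 0.5 + atol)):
        raise AssertionError("OSI outside [0, 0.5]")
    if not np.allclose((rrt_v * (1 - 2 * osi_v) * tw)[ok], 1.0, atol=1e-9):
        raise AssertionError("RRT identity violated")
    if not np.allclose(ecap_v * tw, osi_v, atol=1e-12):
        raise AssertionError("ECAP identity violated")
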