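"""Intraluminal thrombus (ILT) sectioning, averaging and correlation.

Protocol
--------
Cross-sections of the analyzed segment are taken every 5 mm and labelled ILT
or non-ILT by the presence of thrombus (max thickness > 0.1 mm, a tolerance
against numerical noise in generated maps).  Per ILT section the thrombus
area and the surface-averaged time-averaged NO concentration (TAcNO) feed an
ordinary least-squares fit (area regressed on TAcNO) with R^2 and an F test.
Three representative sections 20 mm apart support the directional analysis:
line-averaged TAcNO along each wall direction's radial chord, compared
between the thickest- and thinnest-thrombus directions.

The idealized 2D geometries provide one (axisymmetric) or two (planar) wall
directions; thrombus areas use the annular-sector formula per direction, so
the same bookkeeping generalizes to more directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import ContractError, DataError
from .geometry import AXISYMMETRIC, VesselGeometry, radius_profile
from .no_transport import NOSolution

#: thrombus thinner than this (m) counts as absent when labelling sections
ILT_THICKNESS_THRESHOLD = 0.1e-3

ILT_CSV_COLUMNS = ("z_mm", "direction_label", "thickness_mm")


@dataclass
class ILTMap:
    """Thrombus thickness h >= 0 (m) over wall positions (z x direction)."""

    z: np.ndarray  # (n_z,), axial positions (m)
    directions: tuple  # direction labels, e.g. ("lower", "upper")
    thickness: np.ndarray  # (n_z, n_dir), m

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.thickness = np.atleast_2d(np.asarray(self.thickness, dtype=float))
        self.directions = tuple(self.directions)
        if self.thickness.shape != (len(self.z), len(self.directions)):
            raise ContractError("thickness must have shape (n_z, n_directions)")
        if np.any(self.thickness < 0):
            raise DataError("thrombus thickness must be non-negative")

    def thickness_at(self, z, direction: str) -> np.ndarray:
        if direction not in self.directions:
            raise ContractError(f"unknown direction {direction!r}")
        k = self.directions.index(direction)
        return np.interp(np.asarray(z, dtype=float), self.z, self.thickness[:, k])

    def max_thickness_at(self, z) -> np.ndarray:
        vals = np.stack(
            [self.thickness_at(z, d) for d in self.directions], axis=-1
        )
        return vals.max(axis=-1)

    def sanity_check(self, geom: VesselGeometry) -> None:
        """Thrombus cannot be thicker than the local lumen radius."""
        for d in self.directions:
            side = d if d in ("lower", "upper") else "upper"
            r = radius_profile(geom, np.clip(self.z, 0, geom.axial_length), side)
            if np.any(self.thickness_at(self.z, d) > r + 1e-12):
                raise DataError(
                    f"ILT thickness exceeds the lumen radius on side {d!r}"
                )

    # ---------------------------------------------------------------- I/O
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, d in enumerate(self.directions):
            for zi, hi in zip(self.z, self.thickness[:, k]):
                rows.append((zi * 1e3, d, hi * 1e3))
        return pd.DataFrame(rows, columns=list(ILT_CSV_COLUMNS))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ILTMap":
        df = pd.read_csv(path)
        missing = [c for c in ILT_CSV_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(
                f"ILT CSV {path} is missing column(s) {missing}; expected "
                f"header {list(ILT_CSV_COLUMNS)}"
            )
        dirs = tuple(sorted(df["direction_label"].unique()))
        zs = np.sort(df["z_mm"].unique()) * 1e-3
        h = np.zeros((len(zs), len(dirs)))
        for k, d in enumerate(dirs):
            sub = df[df["direction_label"] == d].sort_values("z_mm")
            h[:, k] = np.interp(zs, sub["z_mm"].to_numpy() * 1e-3,
                                sub["thickness_mm"].to_numpy() * 1e-3)
        return cls(z=zs, directions=dirs, thickness=h)

    @classmethod
    def zero(cls, geom: VesselGeometry, directions=("lower", "upper"), n_z: int = 41):
        z = np.linspace(0.0, geom.axial_length, n_z)
        return cls(z=z, directions=directions, thickness=np.zeros((n_z, len(directions))))


@dataclass
class FitResult:
    """Simple linear regression summary (area ~ TAcNO)."""

    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {
            "slope_mm2_per_nM": self.slope,
            "intercept_mm2": self.intercept,
            "r_squared": self.r_squared,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "n": self.n,
        }


def section_positions(geom: VesselGeometry, spacing: float = 5e-3) -> np.ndarray:
    """Section locations z = 0, spacing, 2*spacing, ... within the segment."""
    if spacing > geom.axial_length:
        raise ContractError("section spacing exceeds the segment length")
    n = int(np.floor(geom.axial_length / spacing + 1e-9)) + 1
    return spacing * np.arange(n)


def section_geometry(
    geom: VesselGeometry,
    ilt: ILTMap,
    spacing: float = 5e-3,
    threshold: float = ILT_THICKNESS_THRESHOLD,
) -> pd.DataFrame:
    """Section skeleton: axial position and ILT / non-ILT group label."""
    if ilt.z.min() > 1e-9 or ilt.z.max() < geom.axial_length - 1e-9:
        raise ContractError("ILT map does not cover the analyzed segment")
    zs = section_positions(geom, spacing)
    groups = np.where(ilt.max_thickness_at(zs) > threshold, "ILT", "non-ILT")
    return pd.DataFrame({"z_mm": zs * 1e3, "group": groups})


def _direction_side(direction: str) -> str:
    return direction if direction in ("lower", "upper") else "upper"


def thrombus_area(
    z: float, geom: VesselGeometry, ilt: ILTMap
) -> float:
    """Thrombus cross-section area (m^2) at axial position z.

    Annular-sector model: each of the n directions occupies an equal angular
    sector of the cross-section; the thrombus fills the annulus between the
    lumen radius r_d and r_d + h_d within its sector:

        area = sum_d (pi / n) [ (r_d + h_d)^2 - r_d^2 ].
    """
    if not 0 <= z <= geom.axial_length:
        raise ContractError("section outside the segment")
    ilt.sanity_check(geom)
    n = len(ilt.directions)
    area = 0.0
    for d in ilt.directions:
        r = radius_profile(geom, z, _direction_side(d))
        h = float(ilt.thickness_at(z, d))
        area += (np.pi / n) * ((r + h) ** 2 - r**2)
    return float(area)


def thickness_for_area(area: float, r) -> np.ndarray:
    """Uniform thrombus thickness giving ``area`` over directions with lumen
    radii ``r`` (inverse of the annular-sector formula)."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    n = len(r)
    # area = (pi/n) sum ((r+h)^2 - r^2) = (pi/n)(n h^2 + 2 h sum r)
    sr = r.sum()
    disc = sr**2 + n * area * n / np.pi
    h = (-sr + np.sqrt(disc)) / n
    return np.full(n, max(h, 0.0))


def section_tacno(
    no: NOSolution, z, average: str = "perimeter"
) -> np.ndarray:
    """Surface-averaged TAcNO (nM) of the section(s) at axial position z.

    ``perimeter``: mean of the endothelial interface TAcNO over the wall
    sides at that z (the lumen-surface average of the protocol).
    ``area``: volume-weighted average over the section's lumen cells.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    zf = no.face_positions()
    if average == "perimeter":
        vals = np.mean(
            [np.interp(z, zf, no.interface_tacno(s)) for s in no.sides], axis=0
        )
        return vals
    if average == "area":
        cbar = no.time_averaged_field()
        V = no.mesh.cell_volumes()
        lum = no.lumen_mask()
        out = np.empty(len(z))
        for k, zk in enumerate(z):
            i = int(np.clip(np.searchsorted(zf, zk), 0, len(zf) - 1))
            w = np.where(lum[i], V[i], 0.0)
            out[k] = float((cbar[i] * w).sum() / w.sum())
        return out
    raise ContractError(f"unknown averaging mode {average!r}")


def section_table(
    geom: VesselGeometry,
    ilt: ILTMap,
    no: NOSolution,
    spacing: float = 5e-3,
    average: str = "perimeter",
    threshold: float = ILT_THICKNESS_THRESHOLD,
) -> pd.DataFrame:
    """Full per-section table: group, thrombus area (mm^2), TAcNO (nM)."""
    skel = section_geometry(geom, ilt, spacing, threshold)
    zs = skel["z_mm"].to_numpy() * 1e-3
    areas = np.array([thrombus_area(z, geom, ilt) for z in zs])
    skel["thrombus_area_mm2"] = areas * 1e6
    skel["tacno_nM"] = section_tacno(no, zs, average)
    return skel


def correlate_area_no(table: pd.DataFrame, ilt_only: bool = True) -> FitResult:
    """OLS fit of thrombus area (mm^2) against section TAcNO (nM).

    The slope therefore carries mm^2 per nM; R^2 and the regression F test
    (two-sided p) quantify the strength of the association.
    """
    df = table[table["group"] == "ILT"] if ilt_only else table
    if len(df) < 3:
        raise ContractError("need at least 3 sections in scope for the fit")
    x = df["tacno_nM"].to_numpy()
    y = df["thrombus_area_mm2"].to_numpy()
    if np.ptp(x) == 0 or np.var(x) == 0:
        raise ContractError("degenerate fit: TAcNO has no variance across sections")
    if np.var(y) == 0:  # constant response: no association by definition
        return FitResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0,
            f_stat=0.0, p_value=1.0, n=len(y),
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return FitResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_stat=float(model.fvalue),
        p_value=float(model.f_pvalue),
        n=int(model.nobs),
    )


def compare_ilt_groups(table: pd.DataFrame) -> dict:
    """Group means of section TAcNO for ILT vs non-ILT sections.

    Returns a partial (flagged) result when one group is empty.
    """
    out = {}
    for g in ("ILT", "non-ILT"):
        sub = table[table["group"] == g]["tacno_nM"]
        out[g] = dict(mean_tacno_nM=float(sub.mean()) if len(sub) else np.nan,
                      n=int(len(sub)))
    complete = out["ILT"]["n"] > 0 and out["non-ILT"]["n"] > 0
    out["difference_nM"] = (
        out["ILT"]["mean_tacno_nM"] - out["non-ILT"]["mean_tacno_nM"]
        if complete
        else np.nan
    )
    out["complete"] = bool(complete)
    return out


def line_averaged_tacno(no: NOSolution, z: float, direction: str) -> float:
    """Line-averaged TAcNO along the radial chord of one wall direction.

    The chord runs from the endothelial interface inward to the vessel
    centerline (full lumen radius at that direction), weighted by radial
    extent.
    """
    cbar = no.time_averaged_field()
    mesh = no.mesh
    zf = no.face_positions()
    i = int(np.clip(np.searchsorted(zf, z), 0, len(zf) - 1))
    j0, j1 = mesh.j_lumen
    Cy = 0.25 * (
        mesh.Y[:-1, :-1] + mesh.Y[1:, :-1] + mesh.Y[:-1, 1:] + mesh.Y[1:, 1:]
    )
    dy = np.abs(np.diff(0.5 * (mesh.Y[i] + mesh.Y[i + 1])))
    if mesh.mode == AXISYMMETRIC:
        jsel = np.arange(j0, j1)
    elif direction == "upper":
        jsel = np.array([j for j in range(j0, j1) if Cy[i, j] >= 0.0])
    elif direction == "lower":
        jsel = np.array([j for j in range(j0, j1) if Cy[i, j] < 0.0])
    else:
        raise ContractError(f"unknown direction {direction!r}")
    if len(jsel) == 0:
        raise ContractError("zero-length averaging line")
    w = dy[jsel]
    return float((cbar[i, jsel] * w).sum() / w.sum())


def directional_analysis(
    no: NOSolution,
    geom: VesselGeometry,
    ilt: ILTMap,
    sections: np.ndarray | None = None,
    spacing: float = 20e-3,
    threshold: float = ILT_THICKNESS_THRESHOLD,
) -> dict:
    """Thickest- vs thinnest-thrombus direction comparison of line TAcNO.

    Three representative sections ``spacing`` apart (default centred on the
    bulge) must lie inside the ILT-bearing region.  Per section, the thrombus
    thickness per direction picks the thickest and thinnest directions; the
    line-averaged TAcNO of those directions is reported per section and
    averaged over sections.
    """
    if sections is None:
        support = ilt.z[ilt.max_thickness_at(ilt.z) > threshold]
        if len(support) == 0:
            raise ContractError("ILT map has no thrombus-bearing region")
        zc = 0.5 * (support.min() + support.max())
        sections = np.array([zc - spacing, zc, zc + spacing])
    sections = np.asarray(sections, dtype=float)
    if len(sections) < 1:
        raise ContractError("need at least one representative section")
    support = ilt.max_thickness_at(sections) > threshold
    if not np.all(support):
        raise ContractError(
            f"representative sections {sections[~support] * 1e3} mm lie outside "
            "the ILT-bearing region"
        )
    dirs = [d for d in ilt.directions]
    rows = []
    for z in sections:
        h = {d: float(ilt.thickness_at(z, d)) for d in dirs}
        tac = {d: line_averaged_tacno(no, z, d) for d in dirs}
        thickest = max(dirs, key=lambda d: h[d])
        thinnest = min(dirs, key=lambda d: h[d])
        rows.append(
            dict(
                z_mm=z * 1e3,
                thickest=thickest,
                thinnest=thinnest,
                tacno_thickest=tac[thickest],
                tacno_thinnest=tac[thinnest],
                **{f"h_{d}_mm": h[d] * 1e3 for d in dirs},
                **{f"tacno_{d}": tac[d] for d in dirs},
            )
        )
    df = pd.DataFrame(rows)
    return dict(
        per_section=df,
        mean_tacno_thickest=float(df["tacno_thickest"].mean()),
        mean_tacno_thinnest=float(df["tacno_thinnest"].mean()),
    )
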