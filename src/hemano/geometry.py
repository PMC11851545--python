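"""Idealized two-domain vessel geometries and structured meshes.

The lumen of a (possibly bulged, possibly asymmetric) vessel segment is
described parametrically: a straight tube of radius ``inlet_radius`` carrying
a Gaussian fusiform dilation of amplitude ``bulge_amplitude`` centred at
``bulge_center``.  The arterial wall is the lumen surface offset outward by a
uniform ``wall_thickness`` (2 mm by default, the standard aortic value used
throughout).  Two mesh modes are supported:

``axisymmetric-2d``
    meridional (z, r) half-plane of a body of revolution; requires an
    axisymmetric bulge (``asymmetry == 0``).

``planar-2d``
    a planar channel with two distinct wall sides (``lower``/``upper``) so a
    bulge, thrombus and NO field can differ between sides.  The two sides
    stand in for the anatomical directions of a 3D aneurysm.

Meshes are structured quadrilateral grids with geometric near-wall grading so
the thin concentration boundary layers at the endothelium are resolved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ContractError, GeometryError

AXISYMMETRIC = "axisymmetric-2d"
PLANAR = "planar-2d"
MODES = (AXISYMMETRIC, PLANAR)

#: wall-side tags; for axisymmetric meshes only ``upper`` is meaningful.
SIDES = ("lower", "upper")


@dataclass(frozen=True)
class VesselGeometry:
    """Parametric lumen + wall description of an idealized vessel segment.

    All lengths are in metres (SI internally; mm only at I/O boundaries).

    Parameters
    ----------
    axial_length : float
        Length of the segment along the vessel axis.
    inlet_radius : float
        Lumen radius of the undilated tube.
    bulge_amplitude : float
        Peak radial excursion of the Gaussian bulge (0 = straight tube).
    bulge_center : float
        Axial position of the bulge peak; defaults to mid-segment.
    bulge_width : float
        Gaussian standard deviation of the bulge shape.
    asymmetry : float
        0 = axisymmetric bulge, 1 = bulge entirely on the upper wall side.
        The side factors are ``1 + asymmetry`` (upper) and ``1 - asymmetry``
        (lower) so that they always average to one.
    wall_thickness : float
        Uniform outward offset of the outer wall (default 2 mm).
    """

    axial_length: float
    inlet_radius: float
    bulge_amplitude: float = 0.0
    bulge_center: float | None = None
    bulge_width: float = 0.01
    asymmetry: float = 0.0
    wall_thickness: float = 2.0e-3

    def __post_init__(self):
        if self.axial_length <= 0:
            raise ContractError("axial_length must be positive")
        if self.inlet_radius <= 0:
            raise ContractError("inlet_radius must be positive")
        if self.bulge_amplitude < 0:
            raise ContractError("bulge_amplitude must be >= 0")
        if self.bulge_width <= 0:
            raise ContractError("bulge_width must be positive")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ContractError("asymmetry must lie in [0, 1]")
        if self.wall_thickness <= 0:
            raise ContractError("wall_thickness must be positive")
        if self.bulge_center is None:
            object.__setattr__(self, "bulge_center", 0.5 * self.axial_length)

    def side_factor(self, side: str) -> float:
        if side not in SIDES:
            raise ContractError(f"unknown wall side {side!r}; expected one of {SIDES}")
        return 1.0 + self.asymmetry if side == "upper" else 1.0 - self.asymmetry


def radius_profile(geom: VesselGeometry, z, side: str = "upper"):
    """Lumen radius r(z) on one wall side.

    r(z) = inlet_radius + bulge_amplitude * s(side) * exp(-(z-z_c)^2/(2 w^2))
    with s(upper) = 1 + asymmetry, s(lower) = 1 - asymmetry.

    ``z`` may be a scalar or array; values must lie inside the segment.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < -1e-12) or np.any(z > geom.axial_length + 1e-12):
        raise ContractError(
            f"axial position outside segment [0, {geom.axial_length}] m"
        )
    s = geom.side_factor(side)
    r = geom.inlet_radius + geom.bulge_amplitude * s * np.exp(
        -((z - geom.bulge_center) ** 2) / (2.0 * geom.bulge_width**2)
    )
    return float(r) if r.ndim == 0 else r


@dataclass(frozen=True)
class MeshResolution:
    """Cells-per-direction specification with near-wall grading.

    ``grading`` is the geometric ratio between adjacent cell sizes moving away
    from the endothelial interface (default 1.15; the finest cells sit at the
    interface on both the lumen and the wall side).
    """

    n_axial: int = 120
    n_lumen: int = 36
    n_wall: int = 14
    grading: float = 1.15

    def __post_init__(self):
        if min(self.n_axial, self.n_lumen, self.n_wall) < 2:
            raise ContractError("resolution counts must all be >= 2")
        if self.grading < 1.0:
            raise ContractError("grading ratio must be >= 1")

    def scaled(self, factor: float) -> "MeshResolution":
        if factor <= 1.0:
            raise ContractError("refinement factor must be > 1")
        return replace(
            self,
            n_axial=math.ceil(factor * self.n_axial),
            n_lumen=math.ceil(factor * self.n_lumen),
            n_wall=math.ceil(factor * self.n_wall),
        )


def _graded_unit_spacings(n: int, grading: float, fine_end: str) -> np.ndarray:
    """n spacings summing to 1, geometrically graded; finest at ``fine_end``."""
    ratios = grading ** np.arange(n, dtype=float)
    if fine_end == "start":
        pass  # smallest first
    elif fine_end == "end":
        ratios = ratios[::-1]
    elif fine_end == "both":
        k = np.arange(n, dtype=float)
        ratios = grading ** np.minimum(k, n - 1 - k)
    else:  # pragma: no cover - internal
        raise ValueError(fine_end)
    return ratios / ratios.sum()


@dataclass
class Mesh:
    """Structured two-domain quadrilateral mesh.

    Nodes are indexed (i, j): i along the axis (uniform z spacing), j across
    the vessel.  ``Y[i, j]`` is the transverse coordinate (radius r in
    axisymmetric mode, y in planar mode).  Row layout:

    axisymmetric-2d: j = 0 (axis) .. n_lumen (interface) .. n_lumen+n_wall
                     (outer wall); single interface row, side tag ``upper``.
    planar-2d:       j = 0 (lower outer wall) .. n_wall (lower interface)
                     .. n_wall+n_lumen (upper interface)
                     .. n_wall+n_lumen+n_wall (upper outer wall).
    """

    mode: str
    geom: VesselGeometry
    resolution: MeshResolution
    zs: np.ndarray  # (n_axial+1,)
    Y: np.ndarray  # (n_axial+1, nj+1)
    j_interfaces: dict = field(default_factory=dict)  # side -> node row index
    j_lumen: tuple = (0, 0)  # inclusive node-row range of the lumen block

    # ------------------------------------------------------------------ info
    @property
    def n_axial(self) -> int:
        return len(self.zs) - 1

    @property
    def nj(self) -> int:
        """Number of cell rows across the vessel."""
        return self.Y.shape[1] - 1

    def cell_domain(self) -> np.ndarray:
        """(n_axial, nj) array of 'lumen'/'wall' labels."""
        lab = np.full((self.n_axial, self.nj), "wall", dtype=object)
        j0, j1 = self.j_lumen
        lab[:, j0:j1] = "lumen"
        return lab

    def node_coords(self):
        """(Z, Y) node coordinate arrays, each (n_axial+1, nj+1)."""
        Z = np.repeat(self.zs[:, None], self.Y.shape[1], axis=1)
        return Z, self.Y

    # -------------------------------------------------------------- measures
    def cell_areas(self) -> np.ndarray:
        """Planar (meridional) area of each cell via the shoelace formula."""
        Z, Y = self.node_coords()
        x00, y00 = Z[:-1, :-1], Y[:-1, :-1]
        x10, y10 = Z[1:, :-1], Y[1:, :-1]
        x11, y11 = Z[1:, 1:], Y[1:, 1:]
        x01, y01 = Z[:-1, 1:], Y[:-1, 1:]
        a = 0.5 * (
            (x00 * y10 - x10 * y00)
            + (x10 * y11 - x11 * y10)
            + (x11 * y01 - x01 * y11)
            + (x01 * y00 - x00 * y01)
        )
        return a

    def cell_volumes(self) -> np.ndarray:
        """Cell measure used for integrals: area (planar) or volume of
        revolution per radian-free convention 2*pi*r_bar*area (axisymmetric).
        """
        a = self.cell_areas()
        if self.mode == AXISYMMETRIC:
            Y = self.Y
            rbar = 0.25 * (Y[:-1, :-1] + Y[1:, :-1] + Y[1:, 1:] + Y[:-1, 1:])
            return 2.0 * np.pi * rbar * a
        return a

    def domain_measure(self, domain: str) -> float:
        """Total measure (area or volume of revolution) of one domain."""
        vol = self.cell_volumes()
        mask = self.cell_domain() == domain
        return float(vol[mask].sum())

    def interface_arclength(self, side: str) -> np.ndarray:
        """Arc-length coordinate s of the interface nodes on ``side``."""
        j = self.j_interfaces[side]
        dz = np.diff(self.zs)
        dy = np.diff(self.Y[:, j])
        return np.concatenate([[0.0], np.cumsum(np.hypot(dz, dy))])

    # ----------------------------------------------------------------- audit
    def assert_valid(self):
        if np.any(self.cell_areas() <= 0):
            raise GeometryError("mesh contains inverted or degenerate cells")
        # outer wall offset check: node distance interface->outer along column
        t = self.geom.wall_thickness
        for side, j in self.j_interfaces.items():
            if side == "upper":
                jout = self.Y.shape[1] - 1
            else:
                jout = 0
            off = np.abs(self.Y[:, jout] - self.Y[:, j])
            if not np.allclose(off, t, rtol=1e-9, atol=1e-12):
                raise GeometryError("outer wall is not a uniform offset")

    def refine(self, factor: float) -> "Mesh":
        """Rebuild with per-direction node counts scaled by ``factor``."""
        return build_mesh(self.geom, self.resolution.scaled(factor), self.mode)


def build_mesh(
    geom: VesselGeometry,
    resolution: MeshResolution = MeshResolution(),
    mode: str = AXISYMMETRIC,
) -> Mesh:
    """Build a structured two-domain mesh for ``geom``.

    Raises :class:`GeometryError` for degenerate geometry (non-positive lumen
    radius anywhere) and :class:`ContractError` when an axisymmetric mesh is
    requested for an asymmetric bulge.
    """
    if mode not in MODES:
        raise ContractError(f"unsupported mesh mode {mode!r}; expected {MODES}")
    if mode == AXISYMMETRIC and geom.asymmetry > 0:
        raise ContractError(
            "axisymmetric-2d mode is meaningless for asymmetry > 0; "
            "use planar-2d"
        )
    res = resolution
    zs = np.linspace(0.0, geom.axial_length, res.n_axial + 1)
    r_up = radius_profile(geom, zs, "upper")
    r_lo = radius_profile(geom, zs, "lower")
    if np.any(r_up <= 0) or np.any(r_lo <= 0):
        raise GeometryError("lumen radius profile is non-positive")

    t_wall = np.concatenate(
        [[0.0], np.cumsum(_graded_unit_spacings(res.n_wall, res.grading, "start"))]
    )

    if mode == AXISYMMETRIC:
        t_lum = np.concatenate(
            [[0.0], np.cumsum(_graded_unit_spacings(res.n_lumen, res.grading, "end"))]
        )
        Y = np.empty((res.n_axial + 1, res.n_lumen + res.n_wall + 1))
        Y[:, : res.n_lumen + 1] = np.outer(r_up, t_lum)
        Y[:, res.n_lumen :] = r_up[:, None] + geom.wall_thickness * t_wall[None, :]
        mesh = Mesh(
            mode=mode,
            geom=geom,
            resolution=res,
            zs=zs,
            Y=Y,
            j_interfaces={"upper": res.n_lumen},
            j_lumen=(0, res.n_lumen),
        )
    else:
        t_lum = np.concatenate(
            [[0.0], np.cumsum(_graded_unit_spacings(res.n_lumen, res.grading, "both"))]
        )
        nw, nl = res.n_wall, res.n_lumen
        Y = np.empty((res.n_axial + 1, nl + 2 * nw + 1))
        # lower wall block: from -r_lo - t to -r_lo, finest at interface (top)
        Y[:, : nw + 1] = (
            -r_lo[:, None] - geom.wall_thickness * t_wall[None, ::-1]
        )
        # lumen block: -r_lo .. +r_up with double-sided grading
        width = r_lo + r_up
        Y[:, nw : nw + nl + 1] = -r_lo[:, None] + np.outer(width, t_lum)
        # upper wall block
        Y[:, nw + nl :] = r_up[:, None] + geom.wall_thickness * t_wall[None, :]
        mesh = Mesh(
            mode=mode,
            geom=geom,
            resolution=res,
            zs=zs,
            Y=Y,
            j_interfaces={"lower": nw, "upper": nw + nl},
            j_lumen=(nw, nw + nl),
        )
    mesh.assert_valid()
    return mesh


def refine(mesh: Mesh, factor: float) -> Mesh:
    """Functional alias for :meth:`Mesh.refine`."""
    return mesh.refine(factor)


def analytic_lumen_measure(geom: VesselGeometry, mode: str, n_quad: int = 20001):
    """High-order quadrature of the exact lumen measure (oracle helper).

    Axisymmetric: volume of revolution pi * integral r(z)^2 dz.
    Planar: area integral (r_lower(z) + r_upper(z)) dz.
    """
    z = np.linspace(0.0, geom.axial_length, n_quad)
    if mode == AXISYMMETRIC:
        return float(np.pi * np.trapezoid(radius_profile(geom, z, "upper") ** 2, z))
    return float(
        np.trapezoid(
            radius_profile(geom, z, "upper") + radius_profile(geom, z, "lower"), z
        )
    )
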