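"""Parametric left atrium / left atrial appendage geometry.

The fluid domain is an implicit solid: an ellipsoidal atrial body, four
pulmonary-vein (PV) inlet tubes, one mitral-valve (MV) outlet tube and a
tapered, blind appendage (LAA) attached through a circular ostium.  The solid
is voxelized onto a uniform Cartesian grid with staircase boundaries; a
triangulated surface (for STL export and watertightness checks) is obtained
by marching cubes on the same implicit function.

All geometric quantities are millimetres.  Coordinates are right-handed and
cell/face masks are 0-based with half-open extents.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

# cell classification codes
SOLID = 0
FLUID = 1
DEVICE = 2
INLET0 = 3          # inlet caps are INLET0 + pv index (0..3)
OUTLET = 7
SEALED = 8          # fluid pocket sealed off by a device; treated as stagnant

PV_NAMES = ("lupv", "llpv", "rupv", "rlpv")

# face classification codes (per axis face arrays)
FACE_INACTIVE = 0
FACE_INTERIOR = 1
FACE_WALL = 2
FACE_INLET0 = 3     # 3..6
FACE_OUTLET = 7


class GeometryError(ValueError):
    """Invalid or degenerate anatomical configuration."""


class ResolutionError(ValueError):
    """Grid spacing too coarse for the narrowest feature."""


class ConfigurationError(ValueError):
    """Inconsistent run configuration (e.g. empty ROI)."""


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise GeometryError("zero-length direction vector")
    return v / n


@dataclass(frozen=True)
class Tube:
    """A straight cylindrical tube grafted onto the chamber wall.

    ``direction`` points outward from the chamber centre; ``length`` is
    measured from the chamber surface to the capped end.
    """

    direction: tuple
    radius: float
    length: float
    name: str = "tube"


def _default_pv_tubes() -> tuple:
    dirs = {
        "lupv": (-0.78, 0.52, 0.34),
        "llpv": (-0.78, 0.52, -0.34),
        "rupv": (0.78, 0.52, 0.34),
        "rlpv": (0.78, 0.52, -0.34),
    }
    return tuple(Tube(direction=d, radius=6.0, length=30.0, name=n)
                 for n, d in dirs.items())


@dataclass
class AnatomyParams:
    """Parameters of the synthetic LA/LAA anatomy.

    Defaults are sized so the LAA ostium is ~24 mm and the appendage neck
    lumen is ~21.4 mm, i.e. a 24 mm deployed plug seats with ~11% compression
    (within the 8-20% release criterion).
    """

    chamber_radii: tuple = (24.0, 21.0, 19.0)
    pv_tubes: tuple = field(default_factory=_default_pv_tubes)
    # the outlet tube is short (10 mm) and mitral-annulus sized; a narrower
    # outlet cannot pass physiologic flow at laminar Reynolds numbers
    mv_tube: Tube = field(default_factory=lambda: Tube(
        direction=(0.0, -0.47, -0.88), radius=13.0, length=10.0, name="mv"))
    # the appendage sits antero-laterally, between the LUPV (ridge) and the
    # mitral outflow, so the 40 mm ROI sphere overlaps the MV approach flow
    laa_axis: tuple = (-0.68, -0.42, -0.10)
    laa_ostium_diameter: float = 24.0
    laa_depth: float = 45.0
    laa_neck_drop: float = 1.3     # mm of rapid lumen narrowing behind the ostium
    laa_neck_scale: float = 2.0    # e-folding depth of the neck narrowing (mm)
    laa_taper: float = 0.86        # apex/ostium radius ratio of the linear taper
    wall_resolution: float = 1.5   # target surface edge length (mm)

    def validate(self) -> None:
        radii = np.asarray(self.chamber_radii, dtype=float)
        if radii.shape != (3,) or np.any(radii <= 0):
            raise GeometryError("chamber_radii must be three positive lengths")
        if self.laa_depth <= 0:
            raise GeometryError("appendage degenerate: laa_depth must be > 0")
        if self.laa_ostium_diameter <= 0:
            raise GeometryError("laa_ostium_diameter must be > 0")
        if self.laa_ostium_diameter >= 2 * radii.min():
            raise GeometryError("laa_ostium_diameter must be < 2*min(chamber_radii)")
        if not (0 < self.laa_taper <= 1):
            raise GeometryError("laa_taper must lie in (0, 1]")
        if len(self.pv_tubes) != 4:
            raise GeometryError("exactly four PV tubes required")
        for t in list(self.pv_tubes) + [self.mv_tube]:
            if t.radius <= 0 or t.length <= 0:
                raise GeometryError(f"tube {t.name}: radius and length must be > 0")
        if self.wall_resolution <= 0:
            raise GeometryError("wall_resolution must be > 0")


def _surface_exit_distance(direction: np.ndarray, radii: np.ndarray) -> float:
    """Distance from the origin to the ellipsoid surface along ``direction``."""
    d = _unit(direction)
    return 1.0 / np.sqrt(np.sum((d / radii) ** 2))


class Anatomy:
    """Implicit LA/LAA solid with labelled openings.

    Construct via :func:`build_anatomy`.
    """

    TUBE_INSET = 4.0   # tube start recessed into the chamber so unions connect
    LAA_BLEND = 3.0    # proximal overshoot of the appendage solid into the body

    def __init__(self, params: AnatomyParams):
        params.validate()
        self.params = params
        self.radii = np.asarray(params.chamber_radii, dtype=float)
        self.laa_axis = _unit(params.laa_axis)
        t = _surface_exit_distance(self.laa_axis, self.radii)
        self.ostium_center = t * self.laa_axis
        self.ostium_radius = params.laa_ostium_diameter / 2.0

        self.tubes = list(params.pv_tubes) + [params.mv_tube]
        self.tube_starts = []
        for tube in self.tubes:
            d = _unit(tube.direction)
            surf = _surface_exit_distance(d, self.radii) * d
            self.tube_starts.append(surf - self.TUBE_INSET * d)

        # apex cap radius of the linear taper
        self._slope = (1.0 - params.laa_taper) * self.ostium_radius / params.laa_depth
        self._r_apex = self._profile_linear(params.laa_depth)
        if self._r_apex <= 0:
            raise GeometryError("appendage taper closes before laa_depth")
        self.laa_end = params.laa_depth + self._r_apex

        # LUPV ridge anchor: ostium rim point nearest the LUPV entry
        lupv = self.tubes[0]
        p_lupv = _surface_exit_distance(_unit(lupv.direction), self.radii) * _unit(lupv.direction)
        v = p_lupv - self.ostium_center
        v_perp = v - np.dot(v, self.laa_axis) * self.laa_axis
        self._ridge_dir = _unit(v_perp)          # in ostium plane, toward LUPV
        self.lupv_anchor = self.ostium_center + self.ostium_radius * self._ridge_dir
        self.ridge_plane_normal = _unit(np.cross(self.laa_axis, self._ridge_dir))

        self._check_clearance()

    # ---- appendage lumen profile -------------------------------------------------

    def _profile_linear(self, s):
        p = self.params
        return (self.ostium_radius
                - p.laa_neck_drop * (1.0 - np.exp(-np.maximum(s, 0.0) / p.laa_neck_scale))
                - self._slope * np.maximum(s, 0.0))

    def lumen_radius(self, s):
        """Appendage lumen radius (mm) at depth ``s`` along the LAA axis."""
        s = np.asarray(s, dtype=float)
        r_lin = self._profile_linear(np.clip(s, 0.0, self.params.laa_depth))
        over = s - self.params.laa_depth
        cap = np.sqrt(np.maximum(self._r_apex ** 2 - np.maximum(over, 0.0) ** 2, 0.0))
        r = np.where(s <= self.params.laa_depth, r_lin, cap)
        return np.where(s < 0, self.ostium_radius, r)

    def lumen_diameter(self, s):
        return 2.0 * self.lumen_radius(s)

    # ---- implicit solid ----------------------------------------------------------

    def _sdf_ellipsoid(self, pts):
        k0 = np.linalg.norm(pts / self.radii, axis=-1)
        k1 = np.linalg.norm(pts / self.radii ** 2, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = k0 * (k0 - 1.0) / np.where(k1 > 0, k1, 1.0)
        return np.where(k1 > 0, d, -self.radii.min())

    def _tube_coords(self, pts, i):
        tube = self.tubes[i]
        d = _unit(tube.direction)
        rel = pts - self.tube_starts[i]
        s = rel @ d
        rho = np.linalg.norm(rel - s[..., None] * d, axis=-1)
        return s, rho

    def _tube_total_length(self, i):
        return self.TUBE_INSET + self.tubes[i].length

    def _sdf_tube(self, pts, i):
        s, rho = self._tube_coords(pts, i)
        L = self._tube_total_length(i)
        return np.maximum(rho - self.tubes[i].radius, np.maximum(-s, s - L))

    def laa_coords(self, pts):
        rel = pts - self.ostium_center
        s = rel @ self.laa_axis
        rho = np.linalg.norm(rel - s[..., None] * self.laa_axis, axis=-1)
        return s, rho

    def _sdf_laa(self, pts):
        s, rho = self.laa_coords(pts)
        r = self.lumen_radius(np.clip(s, 0.0, self.laa_end))
        return np.maximum(rho - r, np.maximum(-(s + self.LAA_BLEND), s - self.laa_end))

    def sdf(self, pts) -> np.ndarray:
        """Approximate signed distance (mm); negative inside the blood pool."""
        pts = np.asarray(pts, dtype=float)
        d = self._sdf_ellipsoid(pts)
        for i in range(len(self.tubes)):
            d = np.minimum(d, self._sdf_tube(pts, i))
        return np.minimum(d, self._sdf_laa(pts))

    def contains(self, pts) -> np.ndarray:
        return self.sdf(pts) < 0.0

    def in_laa(self, pts, margin: float = 2.0) -> np.ndarray:
        """Cells belonging to the appendage region (distal of the ostium plane)."""
        s, rho = self.laa_coords(np.asarray(pts, dtype=float))
        return (s > 0) & (s <= self.laa_end) & (rho <= self.lumen_radius(np.clip(s, 0, self.laa_end)) + margin)

    def bounds(self):
        lo = -self.radii.copy()
        hi = self.radii.copy()
        for i, tube in enumerate(self.tubes):
            d = _unit(tube.direction)
            end = self.tube_starts[i] + (self._tube_total_length(i) + 6.0) * d
            lo = np.minimum(lo, end - tube.radius - 2.0)
            hi = np.maximum(hi, end + tube.radius + 2.0)
        apex = self.ostium_center + self.laa_end * self.laa_axis
        lo = np.minimum(lo, apex - self.ostium_radius - 2.0)
        hi = np.maximum(hi, apex + self.ostium_radius + 2.0)
        return lo, hi

    # ---- validity ---------------------------------------------------------------

    def _check_clearance(self):
        """The external runs of the five tubes and the appendage must not
        merge.  Openings may share a rim on the chamber wall (ostium beside
        the MV, ridge beside the LUPV), so sampling starts a few millimetres
        outside the surface."""
        START = 4.0
        trunks = []
        for i, tube in enumerate(self.tubes):
            d = _unit(tube.direction)
            s = np.arange(self.TUBE_INSET + START, self._tube_total_length(i), 2.0)
            pts = self.tube_starts[i] + s[:, None] * d
            trunks.append((tube.name, tube.radius, pts))
        s = np.arange(START, self.laa_end, 2.0)
        pts = self.ostium_center + s[:, None] * self.laa_axis
        trunks.append(("laa", self.ostium_radius, pts))
        for a in range(len(trunks)):
            for b in range(a + 1, len(trunks)):
                na, ra, pa = trunks[a]
                nb, rb, pb = trunks[b]
                dmin = np.min(np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1))
                if dmin < ra + rb:
                    raise GeometryError(
                        f"self-intersecting configuration: {na} and {nb} "
                        f"(clearance {dmin:.1f} mm < {ra + rb:.1f} mm)")

    # ---- surface ----------------------------------------------------------------

    def surface(self, resolution: float | None = None):
        """Triangulated boundary surface with per-face patch labels.

        Returns ``(mesh, labels)`` where ``mesh`` is a watertight
        :class:`trimesh.Trimesh` and ``labels[f]`` is 0 for wall, ``1+k`` for
        PV cap ``k`` and 5 for the MV cap.
        """
        import trimesh
        from skimage import measure

        h = float(resolution or self.params.wall_resolution)
        lo, hi = self.bounds()
        lo = lo - 2 * h
        hi = hi + 2 * h
        nx, ny, nz = [int(np.ceil((hi[i] - lo[i]) / h)) + 1 for i in range(3)]
        xs = lo[0] + h * np.arange(nx)
        ys = lo[1] + h * np.arange(ny)
        zs = lo[2] + h * np.arange(nz)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
        vol = self.sdf(pts).reshape(nx, ny, nz)
        verts, faces, _, _ = measure.marching_cubes(vol, level=0.0, spacing=(h, h, h))
        verts = verts + lo
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
        # marching cubes can shed sub-voxel satellite shells; keep the chamber
        parts = mesh.split(only_watertight=False)
        if len(parts) > 1:
            mesh = max(parts, key=lambda m: abs(m.volume))
        labels = self.label_surface(mesh.triangles_center, tol=h)
        return mesh, labels

    def label_surface(self, centroids, tol: float = 1.0) -> np.ndarray:
        """Patch label per surface point: 0 wall, 1..4 PV caps, 5 MV cap."""
        centroids = np.asarray(centroids, dtype=float)
        labels = np.zeros(len(centroids), dtype=int)
        for i, tube in enumerate(self.tubes):
            s, rho = self._tube_coords(centroids, i)
            L = self._tube_total_length(i)
            on_cap = (s > L - 0.75 * tol) & (rho < tube.radius + 0.5 * tol)
            labels[on_cap] = i + 1
        return labels

    def enclosed_volume(self, spacing: float = 1.0) -> float:
        """Voxel-counting estimate of the enclosed volume (mm^3)."""
        grid = discretize(self, spacing)
        return grid.fluid_volume


def build_anatomy(params: AnatomyParams | None = None) -> Anatomy:
    """Validate parameters and construct the implicit LA/LAA solid."""
    return Anatomy(params or AnatomyParams())


# ---- discretization -------------------------------------------------------------


@dataclass
class DomainGrid:
    """Uniform Cartesian voxelization of the fluid domain.

    ``cell_class`` holds SOLID/FLUID/DEVICE/SEALED plus inlet/outlet cap ghost
    layers behind the tube end planes.  Faces are classified lazily.
    """

    spacing: float
    origin: np.ndarray
    cell_class: np.ndarray
    anatomy: Anatomy | None = None
    _faces: dict = field(default_factory=dict, repr=False)

    @property
    def shape(self):
        return self.cell_class.shape

    def axes(self):
        h = self.spacing
        return tuple(self.origin[a] + h * (np.arange(self.shape[a]) + 0.5)
                     for a in range(3))

    def cell_centers(self, mask=None) -> np.ndarray:
        xs, ys, zs = self.axes()
        if mask is None:
            X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
            return np.stack([X, Y, Z], axis=-1)
        idx = np.argwhere(mask)
        return np.column_stack([xs[idx[:, 0]], ys[idx[:, 1]], zs[idx[:, 2]]])

    @property
    def fluid_mask(self):
        return self.cell_class == FLUID

    @property
    def cell_volume(self) -> float:
        return self.spacing ** 3

    @property
    def fluid_volume(self) -> float:
        return float(np.count_nonzero(self.fluid_mask)) * self.cell_volume

    def cap_mask(self, code: int):
        return self.cell_class == code

    def invalidate_faces(self):
        self._faces.clear()

    def face_classes(self):
        """Per-axis face type arrays (shape +1 along the face-normal axis)."""
        if self._faces:
            return self._faces
        C = self.cell_class
        for a in range(3):
            shape = list(C.shape)
            shape[a] += 1
            ftype = np.zeros(shape, dtype=np.uint8)
            low_fluid = np.zeros(shape, dtype=bool)
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[a] = slice(0, C.shape[a] - 1)
            sl_hi[a] = slice(1, C.shape[a])
            A = C[tuple(sl_lo)]
            B = C[tuple(sl_hi)]
            inner = [slice(None)] * 3
            inner[a] = slice(1, C.shape[a])
            fa = A == FLUID
            fb = B == FLUID
            blocked_a = (A == SOLID) | (A == DEVICE) | (A == SEALED)
            blocked_b = (B == SOLID) | (B == DEVICE) | (B == SEALED)
            ft = np.zeros_like(A, dtype=np.uint8)
            ft[fa & fb] = FACE_INTERIOR
            ft[(fa & blocked_b) | (fb & blocked_a)] = FACE_WALL
            for k in range(4):
                cap_a = A == INLET0 + k
                cap_b = B == INLET0 + k
                ft[(fa & cap_b) | (fb & cap_a)] = FACE_INLET0 + k
            out_a = A == OUTLET
            out_b = B == OUTLET
            ft[(fa & out_b) | (fb & out_a)] = FACE_OUTLET
            ftype[tuple(inner)] = ft
            low_fluid[tuple(inner)] = fa
            self._faces[a] = (ftype, low_fluid)
        return self._faces

    def wall_face_table(self):
        """Flat table of wall/device faces for shear-stress evaluation.

        Returns a dict of arrays: ``axis``, ``centroid`` (mm), ``normal``
        (unit, outward from the fluid), ``fluid_cell`` (i,j,k), ``area`` (mm^2)
        and ``is_device``.
        """
        faces = self.face_classes()
        C = self.cell_class
        h = self.spacing
        xs, ys, zs = self.axes()
        ax_list, cent, norm, cells, isdev = [], [], [], [], []
        for a in range(3):
            ftype, low_fluid = faces[a]
            idx = np.argwhere(ftype == FACE_WALL)
            if len(idx) == 0:
                continue
            lf = low_fluid[tuple(idx.T)]
            # fluid cell index along axis a: face index-1 if fluid below, else face index
            fcell = idx.copy()
            fcell[:, a] = idx[:, a] - lf.astype(int)
            scell = idx.copy()
            scell[:, a] = idx[:, a] - (~lf).astype(int)
            n = np.zeros((len(idx), 3))
            n[:, a] = np.where(lf, 1.0, -1.0)       # outward: fluid -> solid
            c = np.column_stack([xs[idx[:, 0]], ys[idx[:, 1]], zs[idx[:, 2]]])
            c[:, a] -= h / 2.0                      # face plane, not cell centre
            ax_list.append(np.full(len(idx), a))
            cent.append(c)
            norm.append(n)
            cells.append(fcell)
            isdev.append(C[tuple(scell.T)] == DEVICE)
        return {
            "axis": np.concatenate(ax_list),
            "centroid": np.concatenate(cent),
            "normal": np.concatenate(norm),
            "fluid_cell": np.concatenate(cells),
            "area": np.full(sum(len(x) for x in ax_list), h * h),
            "is_device": np.concatenate(isdev),
        }

    def check_tube_resolution(self):
        if self.anatomy is None:
            return
        for tube in self.anatomy.tubes:
            if 2.0 * tube.radius / self.spacing < 3.0:
                raise ResolutionError(
                    f"tube {tube.name}: fewer than 3 cells across its "
                    f"{2 * tube.radius:.0f} mm lumen at spacing {self.spacing} mm")


class ImplicitSolid:
    """Minimal implicit-solid adapter (``contains`` + ``bounds``) for tests
    and for externally supplied shapes."""

    def __init__(self, contains: Callable, bounds):
        self._contains = contains
        self._bounds = (np.asarray(bounds[0], float), np.asarray(bounds[1], float))

    def contains(self, pts):
        return self._contains(np.asarray(pts, dtype=float))

    def bounds(self):
        return self._bounds


def discretize(source, spacing: float) -> DomainGrid:
    """Voxelize a watertight solid onto a uniform grid.

    ``source`` may be an :class:`Anatomy` (implicit path, openings become
    inlet/outlet cap ghost layers), an :class:`ImplicitSolid`, or a
    ``trimesh.Trimesh`` (STL import path; all boundaries become walls).
    """
    import trimesh

    h = float(spacing)
    if h <= 0:
        raise ResolutionError("spacing must be > 0")

    if isinstance(source, trimesh.Trimesh):
        lo, hi = source.bounds
        contains = source.contains
        anatomy = None
    else:
        lo, hi = source.bounds()
        contains = source.contains
        anatomy = source if isinstance(source, Anatomy) else None

    lo = np.asarray(lo, float) - 2 * h
    hi = np.asarray(hi, float) + 2 * h
    shape = tuple(int(np.ceil((hi[a] - lo[a]) / h)) for a in range(3))
    grid = DomainGrid(spacing=h, origin=lo, cell_class=np.zeros(shape, dtype=np.uint8),
                      anatomy=anatomy)
    pts = grid.cell_centers().reshape(-1, 3)
    inside = np.asarray(contains(pts), dtype=bool).reshape(shape)
    grid.cell_class[inside] = FLUID

    if anatomy is not None:
        grid.check_tube_resolution()
        # cap ghost layers behind each tube end plane
        for i, tube in enumerate(anatomy.tubes):
            s, rho = anatomy._tube_coords(pts, i)
            L = anatomy._tube_total_length(i)
            cap = (s > L) & (s <= L + 2.5 * h) & (rho < tube.radius)
            cap = cap.reshape(shape) & (~inside)
            code = OUTLET if tube.name == "mv" else INLET0 + i
            grid.cell_class[cap] = code
        _prune_disconnected(grid)
    return grid


def _prune_disconnected(grid: DomainGrid):
    """Drop fluid not face-connected to the outlet cap (pre-device there
    should be exactly one component)."""
    live = (grid.cell_class == FLUID) | (grid.cell_class >= INLET0)
    lab, n = ndimage.label(live)
    out_labels = np.unique(lab[grid.cell_class == OUTLET])
    out_labels = out_labels[out_labels > 0]
    keep = np.isin(lab, out_labels)
    drop = (grid.cell_class == FLUID) & ~keep
    grid.cell_class[drop] = SOLID
    grid.invalidate_faces()


# ---- region of interest ---------------------------------------------------------


@dataclass
class RoiSpec:
    """Spherical region of interest centred on the ostium midpoint.

    Default diameter 40 mm; in occluded models the appendage distal to the
    device is excluded.
    """

    center: np.ndarray
    diameter: float = 40.0
    mask: np.ndarray | None = None

    @property
    def radius(self):
        return self.diameter / 2.0


def build_roi(grid: DomainGrid, exclusion=None, diameter: float = 40.0,
              center=None) -> RoiSpec:
    """ROI mask: fluid cells inside the sphere, minus the appendage region
    distal to the device's closure surface.

    ``exclusion`` is ``None`` (pre-occlusion) or ``(anchor, axis, distal_s)``:
    appendage cells with ``(x - anchor) . axis > distal_s`` are excluded.
    """
    if center is None:
        if grid.anatomy is None:
            raise ConfigurationError("ROI centre required when no anatomy is attached")
        center = grid.anatomy.ostium_center
    center = np.asarray(center, dtype=float)
    if diameter <= 0:
        raise ConfigurationError("ROI diameter must be > 0")
    pts = grid.cell_centers().reshape(-1, 3)
    in_sphere = np.linalg.norm(pts - center, axis=1) <= diameter / 2.0
    mask = in_sphere.reshape(grid.shape) & grid.fluid_mask
    if exclusion is not None:
        anchor, axis, distal_s = exclusion
        anchor = np.asarray(anchor, float)
        axis = _unit(axis)
        s = (pts - anchor) @ axis
        distal = (s > distal_s).reshape(grid.shape)
        if grid.anatomy is not None:
            distal &= grid.anatomy.in_laa(pts).reshape(grid.shape)
        mask &= ~distal
    if not mask.any():
        raise ConfigurationError("ROI is empty")
    return RoiSpec(center=center, diameter=diameter, mask=mask)
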