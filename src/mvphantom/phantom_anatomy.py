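"""Parametric anatomy: saddle annulus, bileaflet valve mesh, labeled thorax.

The anatomy that a patient CT segmentation would normally provide is replaced
by geometric primitives: a saddle-shaped annular ellipse (the classic
``cos 2θ`` bileaflet saddle), two leaflet sheets lofted from the annulus
halves toward smooth free edges, and ellipsoid/tube primitives for the
surrounding thoracic entities. Every downstream computation (closure
dynamics, image simulation, annotation, quantification) consumes only the
interfaces defined here, so the substitution is transparent.

Coordinates are world millimetres, right-handed; voxel indices are 0-based
and the affine maps voxel index (i, j, k, 1) to world mm.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import triangle_areas, unit
from .errors import (
    ConfigError,
    InsufficientLandmarksError,
    InvalidFrameError,
    OutOfBoundsError,
    ParameterError,
)

__all__ = [
    "AnnulusModel",
    "ValveMesh",
    "LabelVolume",
    "LandmarkSet",
    "ThoraxConfig",
    "generate_annulus",
    "generate_valve_mesh",
    "free_edge_curves",
    "landmark_align",
    "rasterize_surface",
    "generate_thorax",
    "DEFAULT_LABEL_MAP",
]

# Fixed integer ids for every entity of the intensity table, plus background 0.
DEFAULT_LABEL_MAP = {
    "mitral_valve": 1,
    "la_wall": 2,
    "la_cavity": 3,
    "lv_myocardium": 4,
    "lv_cavity": 5,
    "ra_wall": 6,
    "ra_cavity": 7,
    "rv_wall": 8,
    "rv_cavity": 9,
    "aorta": 10,
    "bones": 11,
    "liver": 12,
    "kidney": 13,
    "lung": 14,
    "bronchi": 15,
}

_LEFT_HEART = ("mitral_valve", "la_wall", "la_cavity", "lv_myocardium", "lv_cavity")
_RIGHT_HEART = ("ra_wall", "ra_cavity", "rv_wall", "rv_cavity")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class AnnulusModel:
    """Saddle-shaped annular ellipse.

    Parameters
    ----------
    center : (3,) world mm.
    radii : (a, b) semi-axes of the annular ellipse, a >= b > 0, mm.
    saddle_height : out-of-plane saddle amplitude h >= 0, mm.  The sampled
        curve spans ``2 h`` along the axis (``cos 2θ`` ranges over [-1, 1]).
    axis_frame : orthonormal 3x3 with rows (e1, e2, e3); e1/e2 span the
        annular plane, e3 is the valve axis (toward the atrium).  det = +1.
    n_samples : number of curve samples (closure implicit, no duplicate).
    """

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radii: tuple[float, float] = (20.0, 15.0)
    saddle_height: float = 3.0
    axis_frame: np.ndarray = field(default_factory=lambda: np.eye(3))
    n_samples: int = 360

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.axis_frame = np.asarray(self.axis_frame, dtype=float).reshape(3, 3)
        a, b = self.radii
        if not (a >= b > 0):
            raise ParameterError(f"annulus radii must satisfy a >= b > 0, got {self.radii}")
        if self.saddle_height < 0:
            raise ParameterError("saddle_height must be >= 0")
        if self.n_samples < 3:
            raise ParameterError("n_samples must be >= 3")
        F = self.axis_frame
        if not np.allclose(F @ F.T, np.eye(3), atol=1e-8) or np.linalg.det(F) < 0.5:
            raise InvalidFrameError("axis_frame must be orthonormal with det = +1")

    @property
    def e1(self):
        return self.axis_frame[0]

    @property
    def e2(self):
        return self.axis_frame[1]

    @property
    def e3(self):
        return self.axis_frame[2]


@dataclass
class ValveMesh:
    """Triangulated bileaflet surface with marked boundaries.

    ``annulus_vertex_ids`` index vertices lying exactly on the annulus curve;
    ``free_edge_vertex_ids`` maps leaflet name -> vertex ids on the free
    (orifice) edge.  ``face_leaflet`` assigns every face to one leaflet.
    """

    vertices: np.ndarray
    faces: np.ndarray
    annulus_vertex_ids: np.ndarray
    free_edge_vertex_ids: dict[str, np.ndarray]
    face_leaflet: np.ndarray  # array of leaflet names, one per face

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        self.annulus_vertex_ids = np.asarray(self.annulus_vertex_ids, dtype=int)
        self.free_edge_vertex_ids = {
            k: np.asarray(v, dtype=int) for k, v in self.free_edge_vertex_ids.items()
        }
        self.face_leaflet = np.asarray(self.face_leaflet)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def triangles(self) -> np.ndarray:
        """Face corner coordinates, shape (M, 3, 3)."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        return triangle_areas(self.vertices, self.faces)

    def mean_face_area(self) -> float:
        return float(self.face_areas().mean())

    def edges(self) -> np.ndarray:
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        return np.sort(e, axis=1)

    def nonmanifold_edge_count(self) -> int:
        _, counts = np.unique(self.edges(), axis=0, return_counts=True)
        return int((counts > 2).sum())

    def boundary_edges(self) -> np.ndarray:
        uniq, counts = np.unique(self.edges(), axis=0, return_counts=True)
        return uniq[counts == 1]

    def with_vertices(self, vertices: np.ndarray) -> "ValveMesh":
        """Same topology with replaced vertex positions."""
        return ValveMesh(
            vertices=np.asarray(vertices, dtype=float),
            faces=self.faces,
            annulus_vertex_ids=self.annulus_vertex_ids,
            free_edge_vertex_ids=self.free_edge_vertex_ids,
            face_leaflet=self.face_leaflet,
        )


@dataclass
class LabelVolume:
    """3D integer label grid with voxel->world affine and a name->id map."""

    labels: np.ndarray
    affine: np.ndarray
    label_map: dict[str, int]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ParameterError("labels must be a 3D array")
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ParameterError("affine must be invertible")
        if np.any(self.spacing <= 0):
            raise ParameterError("voxel size must be strictly positive")
        present = set(np.unique(self.labels)) - {0}
        known = set(self.label_map.values())
        if not present <= known:
            raise ParameterError(f"labels {sorted(present - known)} missing from label_map")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self):
        return self.labels.shape

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def name_of(self, label_id: int) -> str:
        for k, v in self.label_map.items():
            if v == label_id:
                return k
        return f"label_{label_id}"

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.labels.copy(), self.affine.copy(), dict(self.label_map))


@dataclass
class LandmarkSet:
    """Named anatomical landmarks (world mm)."""

    points: dict[str, np.ndarray]

    def __post_init__(self):
        self.points = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}

    def __len__(self):
        return len(self.points)

    @classmethod
    def default(cls) -> "LandmarkSet":
        """Ten landmarks: four valve centers, apex, septum center and four
        aorta-centerline markers, placed consistently with the default thorax."""
        return cls(points={
            "mitral_valve_center": (0.0, 0.0, 0.0),
            "aortic_valve_center": (-32.0, 10.0, 8.0),
            "tricuspid_valve_center": (44.0, 0.0, 0.0),
            "pulmonary_valve_center": (30.0, 14.0, 8.0),
            "apex": (0.0, 0.0, -64.0),
            "septum_center": (22.0, 0.0, -28.0),
            "aorta_1": (-32.0, 10.0, 0.0),
            "aorta_2": (-32.0, 10.0, 25.0),
            "aorta_3": (-32.0, 10.0, 50.0),
            "aorta_4": (-32.0, 10.0, 75.0),
        })

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "LandmarkSet":
        return LandmarkSet({k: R @ p + np.asarray(t, dtype=float) for k, p in self.points.items()})


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def generate_annulus(model: AnnulusModel, n_samples: int | None = None) -> np.ndarray:
    """Sample the saddle annulus curve.

    Point k is ``center + a cosθ e1 + b sinθ e2 + h cos2θ e3`` with
    ``θ = 2πk/n``; points run counter-clockwise about e3 and the closure is
    implicit (no duplicated endpoint).
    """
    n = int(n_samples if n_samples is not None else model.n_samples)
    theta = 2.0 * np.pi * np.arange(n) / n
    a, b = model.radii
    h = model.saddle_height
    return (model.center
            + np.outer(a * np.cos(theta), model.e1)
            + np.outer(b * np.sin(theta), model.e2)
            + np.outer(h * np.cos(2 * theta), model.e3))


def _leaflet_grid(model: AnnulusModel, theta: np.ndarray, s: np.ndarray,
                  leaflet_depth: float, gap_half: float,
                  commissure_depth: float) -> np.ndarray:
    """Vertex grid of one leaflet sheet, shape (n_theta, n_s, 3).

    The sheet interpolates from the annulus (s=0) to the free edge (s=1).
    The free edge is the ellipse-like loop ``(a cosθ, g sinθ)`` in plan view
    so the orifice bounded by the two free edges is smooth and closed; its
    depth below the annular plane grows from ``commissure_depth`` at the
    commissures (real commissural leaflet tissue is 5-8 mm tall) to
    ``leaflet_depth`` at the leaflet belly.
    """
    a, b = model.radii
    h = model.saddle_height
    T, S = np.meshgrid(theta, s, indexing="ij")
    x = a * np.cos(T)
    y = ((1.0 - S) * b + S * gap_half) * np.sin(T)
    depth = commissure_depth + (leaflet_depth - commissure_depth) * np.abs(np.sin(T))
    z = (1.0 - S) * h * np.cos(2 * T) - S * depth
    pts = (x[..., None] * model.e1 + y[..., None] * model.e2 + z[..., None] * model.e3)
    return pts + model.center


def free_edge_curves(model: AnnulusModel, leaflet_depth: float = 18.0,
                     orifice_gap: float = 16.0, state: float = 0.0,
                     commissure_depth: float = 6.0,
                     n: int = 720) -> dict[str, np.ndarray]:
    """Dense parametric free-edge curves (ground truth orifice boundary)."""
    g = 0.5 * orifice_gap * (1.0 - state)
    out = {}
    for name, (t0, t1) in (("anterior", (0.0, np.pi)), ("posterior", (np.pi, 2 * np.pi))):
        theta = np.linspace(t0, t1, n)
        a, _ = model.radii
        x = a * np.cos(theta)
        y = g * np.sin(theta)
        z = -(commissure_depth
              + (leaflet_depth - commissure_depth) * np.abs(np.sin(theta)))
        out[name] = (model.center + np.outer(x, model.e1)
                     + np.outer(y, model.e2) + np.outer(z, model.e3))
    return out


def _build_valve(model, leaflet_depth, gap_half, commissure_depth, n_theta, n_s) -> ValveMesh:
    verts, faces, face_leaf = [], [], []
    annulus_ids, free_ids = [], {}
    offset = 0
    s = np.linspace(0.0, 1.0, n_s + 1)
    for name, (t0, t1) in (("anterior", (0.0, np.pi)), ("posterior", (np.pi, 2 * np.pi))):
        theta = np.linspace(t0, t1, n_theta + 1)
        grid = _leaflet_grid(model, theta, s, leaflet_depth, gap_half, commissure_depth)
        nt, ns3 = grid.shape[0], grid.shape[1]
        idx = offset + np.arange(nt * ns3).reshape(nt, ns3)
        verts.append(grid.reshape(-1, 3))
        a00 = idx[:-1, :-1].ravel()
        a10 = idx[1:, :-1].ravel()
        a11 = idx[1:, 1:].ravel()
        a01 = idx[:-1, 1:].ravel()
        f = np.concatenate([np.stack([a00, a10, a11], axis=1),
                            np.stack([a00, a11, a01], axis=1)])
        faces.append(f)
        face_leaf.extend([name] * len(f))
        annulus_ids.append(idx[:, 0])
        free_ids[name] = idx[:, -1]
        offset += nt * ns3
    return ValveMesh(
        vertices=np.concatenate(verts),
        faces=np.concatenate(faces),
        annulus_vertex_ids=np.concatenate(annulus_ids),
        free_edge_vertex_ids=free_ids,
        face_leaflet=np.asarray(face_leaf),
    )


def _ellipse_perimeter(a: float, b: float) -> float:
    # Ramanujan approximation; only used to seed the grid resolution.
    return np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))


def generate_valve_mesh(annulus: AnnulusModel, leaflet_depth: float = 18.0,
                        orifice_gap: float = 16.0, target_face_area: float = 0.55,
                        state: float = 0.0,
                        commissure_depth: float = 6.0) -> ValveMesh:
    """Loft two leaflet sheets from the annulus halves toward their free edges.

    ``state`` interpolates the free-edge separation: the peak gap is
    ``orifice_gap * (1 - state)`` so ``state=1`` is the fully closed valve.
    The grid resolution is iterated so the mean triangle area lands within a
    few percent of ``target_face_area`` (default 0.55 mm², the density of a
    segmentation-derived valve surface at ~1 mm imaging scale).
    """
    if target_face_area <= 0:
        raise ParameterError("target_face_area must be > 0")
    if leaflet_depth <= 0:
        raise ParameterError("leaflet_depth must be > 0")
    if not (0.0 <= state <= 1.0):
        raise ParameterError("state must be in [0, 1]")
    if annulus.saddle_height <= 0:
        raise ParameterError(
            "saddle_height must be > 0 for mesh generation "
            "(flat annulus collapses the commissure columns)")
    gap_half = 0.5 * orifice_gap * (1.0 - state)
    # seed resolution from the annulus arc length and mean sheet depth
    cell = np.sqrt(2.0 * target_face_area)
    n_theta = max(8, int(round(0.5 * _ellipse_perimeter(*annulus.radii) / cell)))
    n_s = max(3, int(round(leaflet_depth / cell)))
    mesh = _build_valve(annulus, leaflet_depth, gap_half, commissure_depth, n_theta, n_s)
    for _ in range(4):
        ratio = mesh.mean_face_area() / target_face_area
        if abs(ratio - 1.0) < 0.05:
            break
        scale = np.sqrt(ratio)
        n_theta = max(8, int(round(n_theta * scale)))
        n_s = max(3, int(round(n_s * scale)))
        mesh = _build_valve(annulus, leaflet_depth, gap_half, commissure_depth, n_theta, n_s)
    return mesh


def landmark_align(moving: LandmarkSet, fixed: LandmarkSet):
    """Closed-form rigid alignment of named landmark pairs.

    Minimizes sum ||R m_i + t - f_i||^2 over proper rotations (orthogonal
    Procrustes / Kabsch).  With known correspondences the iterative
    closest-point loop collapses to this single step.

    Returns
    -------
    (R, t, rmsd) : rotation (3,3), translation (3,), residual RMSD in mm.
    """
    names = sorted(set(moving.points) & set(fixed.points))
    if len(names) < 3:
        raise InsufficientLandmarksError(
            f"need >= 3 matched landmarks, got {len(names)}")
    M = np.array([moving.points[n] for n in names])
    F = np.array([fixed.points[n] for n in names])
    Mc, Fc = M - M.mean(axis=0), F - F.mean(axis=0)
    if np.linalg.matrix_rank(Mc, tol=1e-9 * max(1.0, np.abs(Mc).max())) < 2:
        raise InsufficientLandmarksError("landmarks are collinear")
    H = Mc.T @ Fc
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = F.mean(axis=0) - R @ M.mean(axis=0)
    res = M @ R.T + t - F
    rmsd = float(np.sqrt((res ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def rasterize_surface(mesh: ValveMesh, template: LabelVolume, thickness: float = 1.0,
                      label: int | None = None, overwrite: str | set = "cavities",
                      label_name: str = "mitral_valve") -> LabelVolume:
    """Stamp the valve surface into a label volume as a thin slab.

    A voxel receives ``label`` when its center lies within ``thickness/2`` of
    the surface (exact point-triangle distance, not scan conversion).  The
    overwrite policy protects surrounding structures: by default the valve
    wins over background and blood-pool cavities only.
    """
    if thickness <= 0:
        raise ParameterError("thickness must be > 0")
    out = template.copy()
    if label is None:
        label = template.label_map.get(label_name)
        if label is None:
            label = max(template.label_map.values(), default=0) + 1
    out.label_map.setdefault(label_name, label)
    if len(mesh.faces) == 0:
        return out

    vox = template.world_to_voxel(mesh.vertices)
    shape = np.array(template.shape)
    bad = np.any((vox < -0.5) | (vox > shape - 0.5), axis=1)
    if np.any(bad):
        ids = np.nonzero(bad)[0]
        raise OutOfBoundsError(
            f"{len(ids)} mesh vertices outside the template volume "
            f"(first few ids: {ids[:10].tolist()})", vertex_ids=ids)

    if overwrite == "all":
        allowed = None
    elif overwrite == "cavities":
        allowed = {0} | {v for k, v in template.label_map.items() if k.endswith("_cavity")}
    else:
        allowed = {int(v) for v in overwrite}

    spacing = template.spacing
    pad = thickness / 2.0 / spacing + 0.51
    tris_w = mesh.triangles()
    tris_v = template.world_to_voxel(tris_w.reshape(-1, 3)).reshape(-1, 3, 3)
    mask = np.zeros(template.shape, dtype=bool)
    half = thickness / 2.0
    from ._geometry import _point_triangle_distance_block
    for tw, tv in zip(tris_w, tris_v):
        lo = np.maximum(np.ceil(tv.min(axis=0) - pad).astype(int), 0)
        hi = np.minimum(np.floor(tv.max(axis=0) + pad).astype(int), shape - 1)
        if np.any(hi < lo):
            continue
        ii, jj, kk = np.meshgrid(*(np.arange(l, h + 1) for l, h in zip(lo, hi)),
                                 indexing="ij")
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        centers = template.voxel_to_world(idx)
        d = _point_triangle_distance_block(centers, tw[0:1], tw[1:2], tw[2:3])[:, 0]
        sel = d <= half
        if np.any(sel):
            s = idx[sel]
            mask[s[:, 0], s[:, 1], s[:, 2]] = True

    if allowed is None:
        writable = mask
    else:
        writable = mask & np.isin(out.labels, list(allowed))
    out.labels = out.labels.copy()
    out.labels[writable] = label
    return out


# --------------------------------------------------------------------------
# thorax generator
# --------------------------------------------------------------------------

@dataclass
class ThoraxConfig:
    """Configuration of the parametric thorax label volume.

    The default places the mitral annulus center at the world origin with the
    valve axis along +z (toward the left atrium), 1 mm isotropic voxels and a
    160 mm cube field of view.
    """

    shape: tuple[int, int, int] = (160, 160, 160)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    entities: tuple[str, ...] | None = None  # None -> all known entities

    def __post_init__(self):
        if self.entities is not None:
            unknown = set(self.entities) - set(DEFAULT_LABEL_MAP)
            if unknown:
                raise ConfigError(f"unknown entities in config: {sorted(unknown)}")


def _ellipsoid(X, Y, Z, center, semi):
    cx, cy, cz = center
    sx, sy, sz = semi
    return ((X - cx) / sx) ** 2 + ((Y - cy) / sy) ** 2 + ((Z - cz) / sz) ** 2 <= 1.0


def _zcyl(X, Y, Z, center_xy, radii_xy, zlo, zhi):
    cx, cy = center_xy
    rx, ry = radii_xy
    return (((X - cx) / rx) ** 2 + ((Y - cy) / ry) ** 2 <= 1.0) & (Z >= zlo) & (Z <= zhi)


def _xcyl(X, Y, Z, center_yz, radius, xlo, xhi):
    cy, cz = center_yz
    return ((Y - cy) ** 2 + (Z - cz) ** 2 <= radius ** 2) & (X >= xlo) & (X <= xhi)


def generate_thorax(config: ThoraxConfig | None = None) -> LabelVolume:
    """Build the multi-label thorax/heart volume from geometric primitives.

    Entities follow the intensity table: left/right heart walls and cavities,
    aorta, bones (rib rings + spine), liver, kidney, lungs and bronchi.  The
    mitral valve label is reserved in the map but painted separately by
    :func:`rasterize_surface`.  A blood-filled mitral ostium channel joins the
    LA and LV cavities so the valve always sits in blood pool.
    """
    cfg = config or ThoraxConfig()
    entities = set(cfg.entities) if cfg.entities is not None else set(DEFAULT_LABEL_MAP)
    shape = np.asarray(cfg.shape, dtype=int)
    spacing = np.asarray(cfg.spacing, dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = -(shape - 1) / 2.0 * spacing  # world origin at volume center

    labels = np.zeros(tuple(shape), dtype=np.int16)
    label_map = dict(DEFAULT_LABEL_MAP)
    if not entities:
        return LabelVolume(labels, affine, label_map)

    idx = np.indices(tuple(shape), dtype=float)
    X = idx[0] * spacing[0] + affine[0, 3]
    Y = idx[1] * spacing[1] + affine[1, 3]
    Z = idx[2] * spacing[2] + affine[2, 3]

    def paint(name, mask):
        if name in entities:
            labels[mask] = label_map[name]

    # painted back-to-front; later structures win
    paint("lung", _ellipsoid(X, Y, Z, (-52, -8, 5), (24, 36, 58))
          | _ellipsoid(X, Y, Z, (52, -8, 5), (24, 36, 58)))
    paint("bronchi", _xcyl(X, Y, Z, (-8, 55), 4.0, -40, 40)
          | _zcyl(X, Y, Z, (0, -8), (5, 5), 55, 1e9))
    ribs = np.zeros_like(labels, dtype=bool)
    r2 = X ** 2 + Y ** 2
    shell = (r2 >= 70.0 ** 2) & (r2 <= 76.0 ** 2)
    for zc in range(-72, 73, 18):
        ribs |= shell & (np.abs(Z - zc) <= 2.5)
    spine = _zcyl(X, Y, Z, (0, -62), (12, 12), -1e9, 1e9)
    paint("bones", ribs | spine)
    paint("liver", _ellipsoid(X, Y, Z, (25, 25, -62), (34, 28, 16)))
    paint("kidney", _ellipsoid(X, Y, Z, (50, -40, -68), (9, 11, 14)))
    paint("aorta", _zcyl(X, Y, Z, (-32, 10), (10, 10), -20, 1e9))
    paint("rv_wall", _ellipsoid(X, Y, Z, (44, 0, -28), (16, 22, 28)))
    paint("ra_wall", _ellipsoid(X, Y, Z, (44, 0, 14), (13, 15, 13)))
    paint("lv_myocardium", _ellipsoid(X, Y, Z, (0, 0, -30), (33, 29, 34)))
    paint("la_wall", _ellipsoid(X, Y, Z, (0, 0, 20), (26, 22, 20)))
    paint("rv_cavity", _ellipsoid(X, Y, Z, (44, 0, -28), (12, 18, 24)))
    paint("ra_cavity", _ellipsoid(X, Y, Z, (44, 0, 14), (10, 12, 10)))
    paint("lv_cavity", _ellipsoid(X, Y, Z, (0, 0, -28), (27, 23, 28))
          | _zcyl(X, Y, Z, (0, 0), (23, 18), -18, 0))
    paint("la_cavity", _ellipsoid(X, Y, Z, (0, 0, 21), (22, 18, 16))
          | _zcyl(X, Y, Z, (0, 0), (23, 18), 0, 6))
    return LabelVolume(labels, affine, label_map)
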