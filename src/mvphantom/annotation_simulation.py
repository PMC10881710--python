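"""Simulated expert annotators.

Ground truth comes from exact mesh-plane intersections; an annotator is
modeled as that ground truth perturbed by in-plane Gaussian click noise
(through-plane uncertainty is induced implicitly by the slice geometry: a
point annotated on a slice lives on that slice's plane, wherever the true
structure sits inside the slab).  On radial LAX planes the annotator places
two annulus points, two leaflet-end (orifice) points and a variable number
of leaflet-contour points per plane; on SAX slices the valve is annotated
with spline contours (ordered control points).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import polyline_length, resample_polyline
from .errors import ParameterError
from .image_simulation import PlaneGeometry
from .phantom_anatomy import ValveMesh

__all__ = [
    "CrossSection",
    "PlaneAnnotation",
    "AnnotationSet",
    "intersect_valve_plane",
    "simulate_annotator",
]


@dataclass
class CrossSection:
    """One connected mesh-plane intersection polyline."""

    points: np.ndarray         # (k, 3) ordered world mm
    leaflet: str
    closed: bool
    endpoint_tags: tuple | None  # (tag_first, tag_last) for open polylines

    def length(self) -> float:
        return polyline_length(self.points, closed=self.closed)


@dataclass
class PlaneAnnotation:
    """Annotated points of one image plane (world mm, plane-embedded)."""

    plane_index: int
    plane: PlaneGeometry
    annulus_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    orifice_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    leaflet_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    contour_points: list = field(default_factory=list)  # SAX spline control points


@dataclass
class AnnotationSet:
    """All plane annotations of one simulated annotator."""

    annotator_id: str
    strategy: str
    records: list

    def pooled(self, kind: str) -> np.ndarray:
        """Pool 'annulus' | 'orifice' | 'leaflet' | 'contour' points across planes."""
        chunks = []
        for rec in self.records:
            if kind == "contour":
                chunks.extend(rec.contour_points)
            else:
                chunks.append(getattr(rec, f"{kind}_points"))
        chunks = [c for c in chunks if len(c)]
        return np.concatenate(chunks) if chunks else np.empty((0, 3))


# --------------------------------------------------------------------------

def _boundary_tag(edge, mesh: ValveMesh) -> str:
    ann = set(mesh.annulus_vertex_ids.tolist())
    free = set(np.concatenate(list(mesh.free_edge_vertex_ids.values())).tolist())
    i, j = edge
    if i in ann and j in ann:
        return "annulus"
    if i in free and j in free:
        return "orifice"
    return "leaflet"


def intersect_valve_plane(mesh: ValveMesh, plane: PlaneGeometry) -> list:
    """Exact mesh cross-section with the central plane of a slab.

    Returns connected polylines; open-polyline endpoints are tagged by the
    mesh boundary they touch (annulus attachment, free edge = orifice, or a
    lateral leaflet boundary).  No intersection yields an empty list.
    """
    V = mesh.vertices
    d = (V - plane.origin) @ plane.normal
    d = np.where(d == 0.0, 1e-12, d)  # nudge exact-on-plane vertices

    segments = {}   # face index -> (edge_key_a, edge_key_b)
    crossing_point = {}
    for fi, f in enumerate(mesh.faces):
        keys = []
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            if d[a] * d[b] < 0:
                key = (min(a, b), max(a, b))
                if key not in crossing_point:
                    t = d[a] / (d[a] - d[b])
                    crossing_point[key] = V[a] + t * (V[b] - V[a])
                keys.append(key)
        if len(keys) == 2:
            segments[fi] = tuple(keys)

    if not segments:
        return []

    # adjacency between edge-crossings through shared faces
    adj = {}
    for fi, (ka, kb) in segments.items():
        adj.setdefault(ka, []).append((kb, fi))
        adj.setdefault(kb, []).append((ka, fi))

    boundary = {tuple(e) for e in mesh.boundary_edges()}
    visited_faces = set()
    sections = []

    def walk(start_key):
        chain = [start_key]
        while True:
            nxt = [(k, fi) for k, fi in adj[chain[-1]] if fi not in visited_faces]
            if not nxt:
                return chain, False
            k, fi = nxt[0]
            visited_faces.add(fi)
            if k == chain[0]:
                return chain, True
            chain.append(k)

    # open chains first (start at degree-1 crossings = boundary edges)
    starts = [k for k, lst in adj.items() if len(lst) == 1]
    for s in starts:
        if all(fi in visited_faces for _, fi in adj[s]):
            continue
        chain, closed = walk(s)
        pts = np.array([crossing_point[k] for k in chain])
        leaf = str(mesh.face_leaflet[[fi for _, fi in adj[chain[0]]][0]])
        tags = (_boundary_tag(chain[0], mesh) if chain[0] in boundary else "interior",
                _boundary_tag(chain[-1], mesh) if chain[-1] in boundary else "interior")
        sections.append(CrossSection(points=pts, leaflet=leaf, closed=closed,
                                     endpoint_tags=None if closed else tags))
    # remaining cycles
    for fi, (ka, _kb) in segments.items():
        if fi in visited_faces:
            continue
        chain, _closed = walk(ka)
        pts = np.array([crossing_point[k] for k in dict.fromkeys(chain)])
        sections.append(CrossSection(points=pts, leaflet=str(mesh.face_leaflet[fi]),
                                     closed=True, endpoint_tags=None))
    return sections


def _inplane_noise(points: np.ndarray, plane: PlaneGeometry, sigma: float,
                   rng: np.random.Generator) -> np.ndarray:
    if len(points) == 0 or sigma == 0:
        return points.copy()
    n = rng.standard_normal((len(points), 2)) * sigma
    return points + np.outer(n[:, 0], plane.u) + np.outer(n[:, 1], plane.v)


def _keep(points: np.ndarray, miss_rate: float, rng) -> np.ndarray:
    if miss_rate == 0 or len(points) == 0:
        return points
    return points[rng.random(len(points)) >= miss_rate]


def simulate_annotator(mesh: ValveMesh, planes: list, strategy: str,
                       noise_sigma_mm: float = 1.5,
                       detection_miss_rate: float = 0.0,
                       seed: int = 0, n_annotators: int = 3,
                       n_leaflet_points: int = 4,
                       sax_n_control: int = 12) -> list:
    """Produce ``n_annotators`` independent AnnotationSets.

    Radial LAX planes: the two annulus endpoints and the two free-edge
    (orifice) endpoints of the plane's cross-sections plus a few
    leaflet-contour points, each perturbed by in-plane Gaussian noise and
    independently missed with ``detection_miss_rate``.  SAX planes: the
    cross-section contours resampled to spline control points, snapped to
    the slice-center plane, then perturbed.
    """
    if noise_sigma_mm < 0:
        raise ParameterError("noise_sigma_mm must be >= 0")
    if not (0.0 <= detection_miss_rate < 1.0):
        raise ParameterError("detection_miss_rate must be in [0, 1): "
                             "1 leaves no annotatable points")
    is_sax = strategy.upper() == "SAX"
    sections_per_plane = [intersect_valve_plane(mesh, pl) for pl in planes]
    if not any(sections_per_plane):
        raise ParameterError("no plane intersects the valve: nothing to annotate")

    streams = np.random.SeedSequence(seed).spawn(n_annotators)
    out = []
    for a, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        records = []
        for pi, (pl, sections) in enumerate(zip(planes, sections_per_plane)):
            rec = PlaneAnnotation(plane_index=pi, plane=pl)
            if not sections:
                records.append(rec)
                continue
            if is_sax:
                ctrls = []
                for sec in sections:
                    if len(sec.points) < 2:
                        continue
                    n_ctrl = min(sax_n_control, max(3, len(sec.points)))
                    c = resample_polyline(sec.points, n_ctrl, closed=sec.closed)
                    # annotation lives on the displayed slice, not the true depth
                    w = (c - pl.origin) @ pl.normal
                    c = c - np.outer(w, pl.normal)
                    ctrls.append(_inplane_noise(c, pl, noise_sigma_mm, rng))
                rec.contour_points = ctrls
            else:
                ann, ori, leaf = [], [], []
                for sec in sections:
                    if sec.closed or sec.endpoint_tags is None:
                        continue
                    for tag, pt in zip(sec.endpoint_tags, (sec.points[0], sec.points[-1])):
                        (ann if tag == "annulus" else ori if tag == "orifice" else leaf
                         ).append(pt)
                    if len(sec.points) >= 2 and n_leaflet_points > 0:
                        interior = resample_polyline(sec.points, n_leaflet_points + 2)[1:-1]
                        leaf.extend(interior)
                for attr, pts in (("annulus_points", ann), ("orifice_points", ori),
                                  ("leaflet_points", leaf)):
                    arr = np.asarray(pts, dtype=float).reshape(-1, 3)
                    arr = _keep(arr, detection_miss_rate, rng)
                    setattr(rec, attr, _inplane_noise(arr, pl, noise_sigma_mm, rng))
            records.append(rec)
        out.append(AnnotationSet(annotator_id=f"annotator_{a + 1}",
                                 strategy=strategy, records=records))
    return out
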