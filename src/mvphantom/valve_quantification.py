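"""Clinically established valve quantification and evaluation metrics.

Annulus diameters and height come from a PCA of the annular points: the
maximum diameter is the extent along the first principal component, the
minimum diameter the extent along the second, and the height the extent
along the third (the annular-plane normal).  Annulus and orifice areas are
2D shoelace areas after projecting the points to the annular plane.  Per
annotator and parameter the bias is the mean signed difference to the
ground-truth value, BIAS = sum_i (a_case,i - a_GT) / N.

Contour accuracy is the asymmetric shortest distance from each annotated
point to the ground-truth contour polyline; surface accuracy the exact
point-to-triangle distance to the ground-truth leaflet surface.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import (
    min_distance_to_polyline,
    orthonormal_basis,
    point_triangle_distance,
    shoelace_area,
    unit,
)
from .annotation_simulation import AnnotationSet, simulate_annotator
from .errors import GeometryError, InsufficientAnnotationError, ParameterError
from .phantom_anatomy import ValveMesh

__all__ = [
    "QuantParams",
    "AnnularFrame",
    "DistanceReport",
    "annulus_pca_params",
    "projected_area",
    "quantify",
    "bias",
    "contour_distance",
    "point_to_surface_distance",
    "sax_boundary_estimates",
    "replicate_study",
    "StudyReport",
]

PARAM_NAMES = ("d_max", "d_min", "height", "annulus_area", "orifice_area")


@dataclass
class AnnularFrame:
    """Centroid and principal axes (rows PC1, PC2, PC3) of the annulus."""

    centroid: np.ndarray
    axes: np.ndarray  # (3, 3), rows ordered by descending variance


@dataclass
class QuantParams:
    """The five clinical parameters of one valve model."""

    d_max: float
    d_min: float
    height: float
    annulus_area: float
    orifice_area: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in PARAM_NAMES}


@dataclass
class DistanceReport:
    """Per-point shortest distances with boxplot-style summary statistics."""

    distances: np.ndarray

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float).ravel()
        if len(self.distances) == 0:
            raise ParameterError("empty distance set")
        if np.any(self.distances < 0):
            raise ParameterError("distances must be >= 0")

    def summary(self) -> dict:
        d = self.distances
        q1, q2, q3 = np.percentile(d, [25, 50, 75])
        iqr = q3 - q1
        outliers = d[(d < q1 - 1.5 * iqr) | (d > q3 + 1.5 * iqr)]
        return {
            "n": int(len(d)), "min": float(d.min()), "p25": float(q1),
            "p50": float(q2), "p75": float(q3), "mean": float(d.mean()),
            "sd": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
            "max": float(d.max()), "outliers": outliers.tolist(),
        }


# --------------------------------------------------------------------------

def annulus_pca_params(points: np.ndarray):
    """PCA-based annulus diameters and height.

    Returns (d_max, d_min, height, AnnularFrame).  Principal components are
    ordered by descending eigenvalue with deterministic signs; extents are
    max - min of the centered projections, which is invariant to sign and to
    the tie ordering of equal eigenvalues.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 4:
        raise GeometryError(f"need >= 4 annular points, got {len(pts)}")
    centroid = pts.mean(axis=0)
    X = pts - centroid
    cov = (X.T @ X) / len(X)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]  # descending; eigh's own order breaks ties
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] < 1e-10 * max(evals[0], 1.0):
        raise GeometryError("annular points are collinear (rank < 2)")
    axes = evecs.T
    for i in range(3):  # deterministic sign: largest |component| positive
        if axes[i, np.argmax(np.abs(axes[i]))] < 0:
            axes[i] = -axes[i]
    proj = X @ axes.T
    ext = proj.max(axis=0) - proj.min(axis=0)
    return float(ext[0]), float(ext[1]), float(ext[2]), AnnularFrame(centroid, axes)


def _self_intersects(poly: np.ndarray) -> bool:
    """Naive O(n^2) proper-crossing test for a small closed 2D polygon."""
    n = len(poly)
    a = poly
    b = np.roll(poly, -1, axis=0)
    for i in range(n):
        p, r = a[i], b[i] - a[i]
        q = a[i + 2:n - (1 if i == 0 else 0)]
        s = b[i + 2:n - (1 if i == 0 else 0)] - q
        if len(q) == 0:
            continue
        denom = r[0] * s[:, 1] - r[1] * s[:, 0]
        ok = np.abs(denom) > 1e-12
        if not np.any(ok):
            continue
        qp = q - p
        t = (qp[:, 0] * s[:, 1] - qp[:, 1] * s[:, 0]) / np.where(ok, denom, 1.0)
        u = (qp[:, 0] * r[1] - qp[:, 1] * r[0]) / np.where(ok, denom, 1.0)
        if np.any(ok & (t > 1e-9) & (t < 1 - 1e-9) & (u > 1e-9) & (u < 1 - 1e-9)):
            return True
    return False


def projected_area(points: np.ndarray, frame: AnnularFrame | None = None,
                   ordered: bool = False) -> float:
    """2D area of the point loop after projection to the annular plane.

    Points are projected onto (PC1, PC2); unordered points are sorted by
    angle about the centroid before the shoelace sum.  When ``frame`` is
    omitted it is derived from the points themselves.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise GeometryError(f"need >= 3 points for an area, got {len(pts)}")
    if frame is None:
        _, _, _, frame = annulus_pca_params(pts)
    xy = (pts - frame.centroid) @ frame.axes[:2].T
    if not ordered:
        ang = np.arctan2(xy[:, 1] - xy[:, 1].mean(), xy[:, 0] - xy[:, 0].mean())
        xy = xy[np.argsort(ang, kind="stable")]
    if len(xy) <= 600 and _self_intersects(xy):
        warnings.warn("projected polygon self-intersects; shoelace value returned",
                      stacklevel=2)
    return shoelace_area(xy)


def sax_boundary_estimates(contour_points: np.ndarray, axis: np.ndarray,
                           center: np.ndarray, n_sectors: int = 36):
    """Annulus / orifice contour estimates from pooled SAX spline points.

    SAX contours have no labeled annulus or leaflet-end points; the annulus
    is estimated as the radially outermost annotated point per angular
    sector about the valve axis, the orifice boundary as the innermost.
    """
    pts = np.asarray(contour_points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise InsufficientAnnotationError("no SAX contour points")
    r1, r2 = orthonormal_basis(unit(axis))
    d = pts - np.asarray(center, dtype=float)
    x, y = d @ r1, d @ r2
    r = np.hypot(x, y)
    sector = ((np.arctan2(y, x) + np.pi) / (2 * np.pi) * n_sectors).astype(int) % n_sectors
    outer, inner = [], []
    for s in range(n_sectors):
        m = sector == s
        if not np.any(m):
            continue
        idx = np.nonzero(m)[0]
        outer.append(pts[idx[np.argmax(r[idx])]])
        inner.append(pts[idx[np.argmin(r[idx])]])
    return np.asarray(outer), np.asarray(inner)


def quantify(source, valve_axis: np.ndarray | None = None,
             valve_center: np.ndarray | None = None) -> QuantParams:
    """Compute the five clinical parameters for a ground-truth mesh or an
    annotation set.

    Ground truth: annulus = the mesh's annulus boundary vertices, orifice =
    its free-edge vertices.  rLAX annotations: annulus/leaflet-end points
    pooled across planes.  SAX annotations: sector-extreme estimates from
    the spline contours (needs ``valve_axis``/``valve_center``).
    """
    if isinstance(source, ValveMesh):
        ann_pts = source.vertices[source.annulus_vertex_ids]
        ori_pts = np.concatenate([source.vertices[v]
                                  for v in source.free_edge_vertex_ids.values()])
    elif isinstance(source, AnnotationSet):
        if source.strategy.upper() == "SAX":
            pooled = source.pooled("contour")
            if valve_axis is None or valve_center is None:
                if len(pooled) < 4:
                    raise InsufficientAnnotationError("too few SAX contour points")
                from .image_simulation import compute_valve_axis
                valve_axis, valve_center = compute_valve_axis(pooled)
            ann_pts, ori_pts = sax_boundary_estimates(pooled, valve_axis, valve_center)
        else:
            ann_pts = source.pooled("annulus")
            ori_pts = source.pooled("orifice")
    else:
        raise TypeError(f"cannot quantify {type(source).__name__}")

    if len(ann_pts) < 4:
        raise InsufficientAnnotationError(
            f"{len(ann_pts)} annulus points; at least 4 (>= 2 planes) required")
    d_max, d_min, height, frame = annulus_pca_params(ann_pts)
    ann_area = projected_area(ann_pts, frame)
    ori_area = projected_area(ori_pts, frame) if len(ori_pts) >= 3 else float("nan")
    return QuantParams(d_max=d_max, d_min=d_min, height=height,
                       annulus_area=ann_area, orifice_area=ori_area)


def bias(case_values, gt_value: float) -> float:
    """Mean signed difference of annotator values from ground truth."""
    vals = np.asarray(case_values, dtype=float)
    if vals.size == 0:
        raise ParameterError("no case values")
    return float(np.mean(vals - gt_value))


def contour_distance(annotated: np.ndarray, gt_contour: np.ndarray,
                     closed: bool = True) -> DistanceReport:
    """Asymmetric annotated-to-ground-truth contour distances.

    Exact point-to-segment minimum over every ground-truth polyline segment.
    """
    pts = np.asarray(annotated, dtype=float).reshape(-1, 3)
    gt = np.asarray(gt_contour, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ParameterError("no annotated points")
    if len(gt) < 2:
        raise ParameterError("ground-truth contour needs >= 2 points")
    return DistanceReport(min_distance_to_polyline(pts, gt, closed=closed))


def point_to_surface_distance(points: np.ndarray, mesh: ValveMesh) -> DistanceReport:
    """Exact unsigned shortest distance of each point to the leaflet surface."""
    if len(mesh.faces) == 0:
        raise ParameterError("empty mesh")
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ParameterError("no points")
    return DistanceReport(point_triangle_distance(pts, mesh.triangles()))


# --------------------------------------------------------------------------
# full study replication
# --------------------------------------------------------------------------

@dataclass
class StudyReport:
    """Tables of the full simulated study (one synthetic case)."""

    quant: pd.DataFrame      # case, strategy, annotator, parameter, value
    bias_table: pd.DataFrame  # strategy, parameter, bias, gt_value
    contour: pd.DataFrame    # strategy, annotator, contour, mean, sd, ...
    surface: pd.DataFrame    # strategy, annotator, mean, sd, ...
    gt_params: QuantParams = None
    annotations: dict = field(default_factory=dict)

    def save(self, out_dir):
        import json
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.quant.to_csv(out / "quant_params.csv", index=False)
        self.bias_table.to_csv(out / "bias.csv", index=False)
        self.contour.to_csv(out / "contour_distances.csv", index=False)
        self.surface.to_csv(out / "surface_distances.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump({"gt_params": self.gt_params.as_dict() if self.gt_params else None,
                       "bias": self.bias_table.to_dict(orient="records")}, fh, indent=1)
        self._boxplot(out / "contour_boxplot.png")

    def _boxplot(self, path):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for ax, name in zip(axes, ("annulus", "orifice")):
            sub = self.contour[self.contour["contour"] == name]
            strategies = sub["strategy"].unique()
            data = [sub[sub["strategy"] == s]["mean"].to_numpy() for s in strategies]
            ax.boxplot(data, tick_labels=list(strategies))
            ax.set_title(f"{name} contour distance")
            ax.set_ylabel("mm")
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)


def replicate_study(seed: int = 0, strategies=("SAX", "rLAX6", "rLAX9", "rLAX18"),
                    annulus=None, leaflet_depth: float = 18.0,
                    orifice_gap: float = 16.0, noise_sigma_mm: float = 1.5,
                    detection_miss_rate: float = 0.0, n_frames: int = 180,
                    n_timesteps: int = 10, annotate_timestep: int = 0,
                    n_sax_slices: int = 5, make_images: bool = False,
                    out_dir=None) -> StudyReport:
    """Run the full sampling-strategy comparison on one synthetic case.

    Phantom construction, closure simulation, temporal sampling, plane
    definition per strategy, three simulated annotators, quantification with
    per-parameter bias, and annulus/orifice contour plus point-to-surface
    distance reports.  With ``make_images`` the pixel stacks are rendered as
    well (the distance metrics depend only on the annotation geometry).
    """
    from .image_simulation import compute_valve_axis, planes_for_strategy
    from .phantom_anatomy import AnnulusModel, generate_annulus, generate_valve_mesh
    from .valve_dynamics import PBDConfig, simulate_closure, temporal_downsample

    model = annulus or AnnulusModel()
    mesh = generate_valve_mesh(model, leaflet_depth=leaflet_depth,
                               orifice_gap=orifice_gap)
    seq = simulate_closure(mesh, PBDConfig(n_frames=n_frames))
    sampled = temporal_downsample(seq, n_timesteps)
    gt_mesh = sampled.mesh_at(annotate_timestep)
    gt_params = quantify(gt_mesh)
    axis, center = compute_valve_axis(gt_mesh, atrial_reference=model.center + model.e3)

    gt_annulus = generate_annulus(model, 2000)
    gt_orifice = np.concatenate([gt_mesh.vertices[gt_mesh.free_edge_vertex_ids[k]]
                                 for k in sorted(gt_mesh.free_edge_vertex_ids)])

    if make_images:
        from .image_simulation import simulate_study
        from .phantom_anatomy import generate_thorax
        template = generate_thorax()
        simulate_study(sampled, template, strategies=strategies, seed=seed)

    rows_q, rows_b, rows_c, rows_s = [], [], [], []
    annotations = {}
    strat_seeds = np.random.SeedSequence(seed).generate_state(len(strategies))
    for strat, sseed in zip(strategies, strat_seeds):
        planes = planes_for_strategy(strat, axis, center, n_sax_slices=n_sax_slices)
        ann_sets = simulate_annotator(
            gt_mesh, planes, strategy=strat, noise_sigma_mm=noise_sigma_mm,
            detection_miss_rate=detection_miss_rate, seed=int(sseed) % (2 ** 31))
        annotations[strat] = ann_sets
        per_param_vals = {p: [] for p in PARAM_NAMES}
        for aset in ann_sets:
            qp = quantify(aset, valve_axis=axis, valve_center=center)
            for p in PARAM_NAMES:
                v = qp.as_dict()[p]
                per_param_vals[p].append(v)
                rows_q.append({"case": "synthetic_1", "strategy": strat,
                               "annotator": aset.annotator_id, "parameter": p,
                               "value": v})
            if strat.upper() == "SAX":
                ann_pts, ori_pts = sax_boundary_estimates(aset.pooled("contour"),
                                                          axis, center)
                all_pts = aset.pooled("contour")
            else:
                ann_pts = aset.pooled("annulus")
                ori_pts = aset.pooled("orifice")
                all_pts = np.concatenate([aset.pooled(k)
                                          for k in ("annulus", "orifice", "leaflet")])
            for cname, pts, gt in (("annulus", ann_pts, gt_annulus),
                                   ("orifice", ori_pts, gt_orifice)):
                if len(pts) == 0:
                    continue
                rep = contour_distance(pts, gt, closed=True).summary()
                rep.pop("outliers")
                rows_c.append({"strategy": strat, "annotator": aset.annotator_id,
                               "contour": cname, **rep})
            srep = point_to_surface_distance(all_pts, gt_mesh).summary()
            srep.pop("outliers")
            rows_s.append({"strategy": strat, "annotator": aset.annotator_id, **srep})
        for p in PARAM_NAMES:
            vals = [v for v in per_param_vals[p] if np.isfinite(v)]
            if vals:
                rows_b.append({"strategy": strat, "parameter": p,
                               "bias": bias(vals, gt_params.as_dict()[p]),
                               "gt_value": gt_params.as_dict()[p]})

    report = StudyReport(quant=pd.DataFrame(rows_q), bias_table=pd.DataFrame(rows_b),
                         contour=pd.DataFrame(rows_c), surface=pd.DataFrame(rows_s),
                         gt_params=gt_params, annotations=annotations)
    if out_dir is not None:
        report.save(out_dir)
    return report
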