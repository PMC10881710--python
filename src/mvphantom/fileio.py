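"""File formats: NIfTI label volumes, ASCII PLY/OBJ meshes with JSON
sidecars, motion-sequence manifests, annotation JSON/CSV.

NIfTI is used for both the 3D label model and the oblique slice stacks (the
affine fully encodes plane geometry, which DICOM writing would not without
far more machinery).  Mesh boundary markings (annulus / free-edge vertex
ids) travel in a JSON sidecar next to the PLY/OBJ file.
"""
from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .annotation_simulation import AnnotationSet, PlaneAnnotation
from .image_simulation import PlaneGeometry, SliceStack
from .phantom_anatomy import LabelVolume, ValveMesh

__all__ = [
    "save_label_volume", "load_label_volume",
    "save_mesh", "load_mesh",
    "save_motion_sequence", "load_motion_sequence",
    "save_annotations", "load_annotations", "annotations_to_csv",
    "save_slice_stack",
]


# -- NIfTI ------------------------------------------------------------------

def save_label_volume(volume: LabelVolume, path) -> None:
    img = nib.Nifti1Image(volume.labels.astype(np.int16), volume.affine)
    img.header.set_data_dtype(np.int16)
    nib.save(img, str(path))
    with open(str(path) + ".labels.json", "w") as fh:
        json.dump(volume.label_map, fh, indent=1)


def load_label_volume(path) -> LabelVolume:
    img = nib.load(str(path))
    sidecar = Path(str(path) + ".labels.json")
    label_map = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    labels = np.asarray(img.get_fdata(), dtype=np.int16)
    if not label_map:
        label_map = {f"label_{i}": int(i) for i in np.unique(labels) if i != 0}
    return LabelVolume(labels=labels, affine=img.affine, label_map=label_map)


def save_slice_stack(stack: SliceStack, path) -> None:
    """Slices stacked along the 3rd axis; oblique affine encodes geometry."""
    imgs = np.stack(stack.images, axis=-1)
    pl = stack.planes[0]
    A = np.eye(4)
    A[:3, 0] = pl.u * pl.pixel_spacing
    A[:3, 1] = pl.v * pl.pixel_spacing
    # SAX: true inter-slice step; radial fans share one origin, so the affine
    # can only encode the first plane — per-slice geometry goes to the sidecar
    step = (stack.planes[1].origin - pl.origin if len(stack.planes) > 1
            else np.zeros(3))
    if np.linalg.norm(step) < 1e-9:
        step = pl.normal * pl.thickness
    A[:3, 2] = step
    nu, nv = imgs.shape[:2]
    A[:3, 3] = pl.origin - pl.u * (nu - 1) / 2 * pl.pixel_spacing \
        - pl.v * (nv - 1) / 2 * pl.pixel_spacing
    nib.save(nib.Nifti1Image(imgs.astype(np.float32), A), str(path))
    with open(str(path) + ".json", "w") as fh:
        json.dump({"strategy": stack.strategy, "timeframe": stack.timeframe,
                   "thickness": pl.thickness, "pixel_spacing": stack.pixel_spacing,
                   "n_slices": len(stack.images),
                   "planes": [_plane_doc(p) for p in stack.planes]}, fh, indent=1)


# -- meshes -----------------------------------------------------------------

def _sidecar(mesh: ValveMesh) -> dict:
    return {
        "annulus_vertex_ids": mesh.annulus_vertex_ids.tolist(),
        "free_edge_vertex_ids": {k: v.tolist()
                                 for k, v in mesh.free_edge_vertex_ids.items()},
        "face_leaflet": mesh.face_leaflet.tolist(),
    }


def save_mesh(mesh: ValveMesh, path) -> None:
    """ASCII PLY or OBJ by extension, plus a JSON sidecar with boundary ids."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(mesh.vertices)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write(f"element face {len(mesh.faces)}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for v in mesh.vertices:
                fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    elif path.suffix.lower() == ".obj":
        with open(path, "w") as fh:
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            for f in mesh.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")
    with open(str(path) + ".json", "w") as fh:
        json.dump(_sidecar(mesh), fh)


def load_mesh(path) -> ValveMesh:
    path = Path(path)
    verts, faces = [], []
    if path.suffix.lower() == ".ply":
        with open(path) as fh:
            n_v = n_f = 0
            for line in fh:
                line = line.strip()
                if line.startswith("element vertex"):
                    n_v = int(line.split()[-1])
                elif line.startswith("element face"):
                    n_f = int(line.split()[-1])
                elif line == "end_header":
                    break
            for _ in range(n_v):
                verts.append([float(x) for x in next(fh).split()[:3]])
            for _ in range(n_f):
                parts = next(fh).split()
                faces.append([int(x) for x in parts[1:1 + int(parts[0])]])
    elif path.suffix.lower() == ".obj":
        with open(path) as fh:
            for line in fh:
                t = line.split()
                if not t:
                    continue
                if t[0] == "v":
                    verts.append([float(x) for x in t[1:4]])
                elif t[0] == "f":
                    faces.append([int(x.split("/")[0]) - 1 for x in t[1:4]])
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    faces = np.asarray(faces, dtype=int)
    return ValveMesh(
        vertices=np.asarray(verts, dtype=float),
        faces=faces,
        annulus_vertex_ids=np.asarray(meta.get("annulus_vertex_ids", []), dtype=int),
        free_edge_vertex_ids={k: np.asarray(v, dtype=int)
                              for k, v in meta.get("free_edge_vertex_ids", {}).items()},
        face_leaflet=np.asarray(meta.get("face_leaflet", ["anterior"] * len(faces))),
    )


# -- motion sequences -------------------------------------------------------

def save_motion_sequence(seq, out_dir, config_repr: str = "") -> None:
    """One PLY per frame plus a JSON manifest (frame times, config hash)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for i in range(seq.n_frames):
        name = f"frame_{i:04d}.ply"
        save_mesh(seq.mesh_at(i), out / name)
        names.append(name)
    manifest = {
        "frames": names,
        "frame_times": np.asarray(seq.frame_times).tolist(),
        "config_hash": hashlib.sha256(config_repr.encode()).hexdigest()[:16],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_motion_sequence(out_dir):
    from .valve_dynamics import MotionSequence
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    meshes = [load_mesh(out / n) for n in manifest["frames"]]
    return MotionSequence(frames=[m.vertices for m in meshes],
                          frame_times=np.asarray(manifest["frame_times"]),
                          mesh=meshes[0])


# -- annotations ------------------------------------------------------------

def _plane_doc(pl: PlaneGeometry) -> dict:
    return {"origin": pl.origin.tolist(), "u": pl.u.tolist(), "v": pl.v.tolist(),
            "normal": pl.normal.tolist(), "extent": list(pl.extent),
            "pixel_spacing": pl.pixel_spacing, "thickness": pl.thickness}


def save_annotations(ann_sets: list, path) -> None:
    doc = []
    for aset in ann_sets:
        recs = []
        for r in aset.records:
            recs.append({
                "plane_index": r.plane_index,
                "plane": _plane_doc(r.plane),
                "annulus_points": np.asarray(r.annulus_points).tolist(),
                "orifice_points": np.asarray(r.orifice_points).tolist(),
                "leaflet_points": np.asarray(r.leaflet_points).tolist(),
                "contour_points": [np.asarray(c).tolist() for c in r.contour_points],
            })
        doc.append({"annotator_id": aset.annotator_id, "strategy": aset.strategy,
                    "records": recs})
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_annotations(path) -> list:
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for aset in doc:
        records = []
        for r in aset["records"]:
            pl = PlaneGeometry(origin=r["plane"]["origin"], u=r["plane"]["u"],
                               v=r["plane"]["v"], normal=r["plane"]["normal"],
                               extent=tuple(r["plane"]["extent"]),
                               pixel_spacing=r["plane"]["pixel_spacing"],
                               thickness=r["plane"]["thickness"])
            records.append(PlaneAnnotation(
                plane_index=r["plane_index"], plane=pl,
                annulus_points=np.asarray(r["annulus_points"]).reshape(-1, 3),
                orifice_points=np.asarray(r["orifice_points"]).reshape(-1, 3),
                leaflet_points=np.asarray(r["leaflet_points"]).reshape(-1, 3),
                contour_points=[np.asarray(c).reshape(-1, 3)
                                for c in r["contour_points"]]))
        out.append(AnnotationSet(annotator_id=aset["annotator_id"],
                                 strategy=aset["strategy"], records=records))
    return out


def annotations_to_csv(ann_sets: list, path) -> None:
    """Long-format per-point export: annotator, plane, kind, x, y, z."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["annotator", "strategy", "plane", "kind", "x", "y", "z"])
        for aset in ann_sets:
            for r in aset.records:
                groups = [("annulus", r.annulus_points), ("orifice", r.orifice_points),
                          ("leaflet", r.leaflet_points)]
                for ci, c in enumerate(r.contour_points):
                    groups.append((f"contour_{ci}", c))
                for kind, pts in groups:
                    for p in np.asarray(pts).reshape(-1, 3):
                        w.writerow([aset.annotator_id, aset.strategy, r.plane_index,
                                    kind, f"{p[0]:.4f}", f"{p[1]:.4f}", f"{p[2]:.4f}"])
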