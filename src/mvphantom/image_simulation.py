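"""Synthetic multi-slice MR-style image generation.

Three-step workflow on the labeled 4D model:

1. intensities and temporal sampling — per-tissue Gaussian intensity draws
   (observation-based table), temporal sampling to 10 timesteps/closure,
   additive zero-mean Gaussian noise (sigma = 38, the largest per-tissue sd
   among the heart entities) and a Gaussian reconstruction-filter smoothing;
2. plane definition — the valve axis is the minimum principal component of
   the valve surface; SAX stacks are perpendicular to it (6 mm thickness,
   6 mm center-to-center spacing), radial LAX fans contain it (6/9/18 planes
   over 180 degrees);
3. in-plane sampling — slab averaging across the slice thickness followed by
   two consecutive resamplings, box-average to the acquired 1.4 mm grid then
   interpolation to the reconstructed 0.87 mm grid.
"""
from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._geometry import orthonormal_basis, rotation_about_axis, unit
from .errors import ConfigError, GeometryError, ParameterError
from .phantom_anatomy import LabelVolume, ValveMesh, rasterize_surface

__all__ = [
    "IntensityModel",
    "PlaneGeometry",
    "SliceStack",
    "DEFAULT_INTENSITIES",
    "assign_intensities",
    "add_noise",
    "smooth",
    "compute_valve_axis",
    "define_sax_planes",
    "define_rlax_planes",
    "sample_slab",
    "resample_inplane",
    "simulate_study",
]

# Observed per-tissue cine-MRI intensity distributions (mean, sd).
DEFAULT_INTENSITIES = {
    "mitral_valve": (266.0, 25.0),
    "la_wall": (100.0, 38.0),
    "la_cavity": (357.0, 14.0),
    "lv_myocardium": (75.0, 8.0),
    "lv_cavity": (344.0, 23.0),
    "ra_wall": (88.0, 32.0),
    "ra_cavity": (405.0, 26.0),
    "rv_wall": (71.0, 25.0),
    "rv_cavity": (356.0, 15.0),
    "aorta": (330.0, 22.0),
    "bones": (157.0, 72.0),
    "liver": (119.0, 47.0),
    "kidney": (126.0, 14.0),
    "lung": (8.0, 4.0),
    "bronchi": (389.0, 42.0),
    "background": (0.0, 0.0),
}

# default additive noise: max sd among the heart entities above
DEFAULT_NOISE_SIGMA = 38.0


@dataclass
class IntensityModel:
    """Per-tissue (mean, sd) intensity pairs.

    ``distribution`` selects the per-voxel sampling law.  A Rician model is
    available for completeness but the Gaussian is the default: the fitted
    Gaussian and Rician distributions differ only marginally on cine MRI
    blood pool and myocardium.
    """

    entries: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES))
    distribution: str = "gaussian"

    def __post_init__(self):
        if self.distribution not in ("gaussian", "rician"):
            raise ParameterError(f"unknown distribution {self.distribution!r}")
        for name, (_, sd) in self.entries.items():
            if sd < 0:
                raise ParameterError(f"negative sd for entity {name!r}")

    def lookup_tables(self, volume: LabelVolume) -> tuple[np.ndarray, np.ndarray]:
        """(mean, sd) lookup arrays indexed by integer label."""
        n = max(volume.label_map.values(), default=0) + 1
        means = np.zeros(n)
        sds = np.zeros(n)
        bg = self.entries.get("background", (0.0, 0.0))
        means[0], sds[0] = bg
        present = set(np.unique(volume.labels)) - {0}
        for name, lab in volume.label_map.items():
            if name in self.entries:
                means[lab], sds[lab] = self.entries[name]
            elif lab in present:
                raise ConfigError(f"intensity model has no entry for label {name!r}")
        return means, sds

    # -- serialization (JSON and a two-column CSV mirroring the table) ------
    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"distribution": self.distribution,
                       "entries": {k: list(v) for k, v in self.entries.items()}}, fh,
                      indent=1)

    @classmethod
    def from_json(cls, path) -> "IntensityModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(entries={k: (float(m), float(s)) for k, (m, s) in doc["entries"].items()},
                   distribution=doc.get("distribution", "gaussian"))

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["entity", "mean", "sd"])
            for name, (m, s) in self.entries.items():
                w.writerow([name, m, s])

    @classmethod
    def from_csv(cls, path) -> "IntensityModel":
        entries = {}
        with open(path) as fh:
            for row in csv.DictReader(fh):
                entries[row["entity"]] = (float(row["mean"]), float(row["sd"]))
        return cls(entries=entries)


@dataclass
class PlaneGeometry:
    """Oriented imaging slab.

    origin is the plane (and image) center; {u, v, normal} is a right-handed
    orthonormal triad; extent = (width, height) mm; pixel_spacing and
    thickness in mm.
    """

    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    normal: np.ndarray
    extent: tuple[float, float] = (120.0, 120.0)
    pixel_spacing: float = 0.5
    thickness: float = 6.0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.u = np.asarray(self.u, dtype=float).reshape(3)
        self.v = np.asarray(self.v, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        if self.thickness <= 0 or self.pixel_spacing <= 0:
            raise ParameterError("thickness and pixel_spacing must be > 0")
        M = np.stack([self.u, self.v, self.normal])
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-9):
            raise ParameterError("{u, v, normal} must be orthonormal")
        if np.linalg.det(M) < 0:
            raise ParameterError("{u, v, normal} must be right-handed")

    @property
    def n_pixels(self) -> tuple[int, int]:
        w, h = self.extent
        return (max(1, int(round(w / self.pixel_spacing))),
                max(1, int(round(h / self.pixel_spacing))))

    def pixel_centers(self, offset_mm: float = 0.0) -> np.ndarray:
        """World coordinates of pixel centers on a sub-plane, shape (nu, nv, 3)."""
        nu, nv = self.n_pixels
        xs = (np.arange(nu) - (nu - 1) / 2.0) * self.pixel_spacing
        ys = (np.arange(nv) - (nv - 1) / 2.0) * self.pixel_spacing
        Xg, Yg = np.meshgrid(xs, ys, indexing="ij")
        return (self.origin + offset_mm * self.normal
                + Xg[..., None] * self.u + Yg[..., None] * self.v)

    def project(self, points: np.ndarray) -> np.ndarray:
        """(u, v, w) plane coordinates of world points."""
        d = np.asarray(points, dtype=float) - self.origin
        return np.stack([d @ self.u, d @ self.v, d @ self.normal], axis=-1)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Whether points fall within the slab (|through-plane| <= t/2)."""
        return np.abs((np.asarray(points, dtype=float) - self.origin)
                      @ self.normal) <= self.thickness / 2.0


@dataclass
class SliceStack:
    """Per-timeframe set of simulated slices of one sampling strategy."""

    images: list  # list of 2D arrays
    planes: list  # list of PlaneGeometry (post-reconstruction spacing)
    strategy: str  # SAX | rLAX6 | rLAX9 | rLAX18
    timeframe: int = 0
    pixel_spacing: float = 0.87


# --------------------------------------------------------------------------
# step 1: intensities, noise, smoothing
# --------------------------------------------------------------------------

def assign_intensities(volume: LabelVolume, model: IntensityModel | None = None,
                       seed: int | np.random.Generator | None = 0) -> np.ndarray:
    """Draw per-voxel intensities from the per-tissue distributions."""
    model = model or IntensityModel()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    means, sds = model.lookup_tables(volume)
    mean_v = means[volume.labels]
    sd_v = sds[volume.labels]
    if model.distribution == "gaussian":
        out = mean_v + sd_v * rng.standard_normal(volume.labels.shape)
    else:  # rician: magnitude of a complex Gaussian with offset nu = mean
        n1 = rng.standard_normal(volume.labels.shape)
        n2 = rng.standard_normal(volume.labels.shape)
        out = np.sqrt((mean_v + sd_v * n1) ** 2 + (sd_v * n2) ** 2)
    return out


def add_noise(volume: np.ndarray, sigma: float = DEFAULT_NOISE_SIGMA,
              seed: int | np.random.Generator | None = 0) -> np.ndarray:
    """Additive independent zero-mean Gaussian noise."""
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if sigma == 0:
        return np.asarray(volume, dtype=float).copy()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    vol = np.asarray(volume, dtype=float)
    return vol + sigma * rng.standard_normal(vol.shape)


def smooth(volume: np.ndarray, kernel_sigma_mm: float = 0.7,
           spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Gaussian reconstruction-filter smoothing; sigma given in mm."""
    if kernel_sigma_mm < 0:
        raise ParameterError("kernel_sigma_mm must be >= 0")
    vol = np.asarray(volume, dtype=float)
    if kernel_sigma_mm == 0:
        return vol.copy()
    sig_vox = kernel_sigma_mm / np.asarray(spacing, dtype=float)
    return ndimage.gaussian_filter(vol, sigma=sig_vox, mode="nearest")


# --------------------------------------------------------------------------
# step 2: plane families
# --------------------------------------------------------------------------

def compute_valve_axis(mesh: ValveMesh | np.ndarray,
                       atrial_reference: np.ndarray | None = None):
    """Valve axis and center from PCA of the valve surface vertices.

    The axis is the eigenvector of the vertex covariance with the smallest
    eigenvalue (the surface's thin direction), the center the vertex
    centroid.  The sign is fixed to point toward ``atrial_reference`` when
    given, otherwise toward the largest-magnitude component being positive.
    """
    pts = mesh.vertices if isinstance(mesh, ValveMesh) else np.asarray(mesh, dtype=float)
    if len(pts) < 3:
        raise GeometryError("need >= 3 points")
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-10 * max(evals[-1], 1.0):
        raise GeometryError("degenerate (collinear) point set")
    axis = evecs[:, 0]  # smallest eigenvalue
    if atrial_reference is not None:
        if np.dot(axis, np.asarray(atrial_reference, dtype=float) - center) < 0:
            axis = -axis
    elif axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return unit(axis), center


def define_sax_planes(axis: np.ndarray, center: np.ndarray, n_slices: int = 5,
                      thickness_mm: float = 6.0, spacing_mm: float = 6.0,
                      extent=(120.0, 120.0), pixel_spacing: float = 0.5):
    """Parallel short-axis stack perpendicular to the valve axis.

    Slice centers sit at ``center + axis * (k - (n-1)/2) * spacing_mm``; the
    6 mm thickness / 6 mm center-to-center spacing default mimics a standard
    contiguous cine SAX acquisition.
    """
    if n_slices < 1:
        raise ParameterError("n_slices must be >= 1")
    n_hat = unit(axis)
    u, v = orthonormal_basis(n_hat)
    planes = []
    for k in range(n_slices):
        off = (k - (n_slices - 1) / 2.0) * spacing_mm
        planes.append(PlaneGeometry(origin=np.asarray(center, dtype=float) + off * n_hat,
                                    u=u, v=v, normal=n_hat, extent=tuple(extent),
                                    pixel_spacing=pixel_spacing, thickness=thickness_mm))
    return planes


def define_rlax_planes(axis: np.ndarray, center: np.ndarray, n_planes: int = 18,
                       thickness_mm: float = 6.0, extent=(120.0, 120.0),
                       pixel_spacing: float = 0.5,
                       reference_angle_deg: float | None = None,
                       span_deg: float = 180.0):
    """Radial long-axis fan: every plane contains the valve axis and center.

    Plane k is rotated by ``k * span/n`` about the axis from a reference
    in-plane direction.  The default reference offsets the fan by a quarter
    increment so no plane is tangent to the valve at the commissures.
    """
    if n_planes < 1:
        raise ParameterError("n_planes must be >= 1")
    n_hat = unit(axis)
    r1, r2 = orthonormal_basis(n_hat)
    step = np.deg2rad(span_deg / n_planes)
    phi0 = np.deg2rad(reference_angle_deg) if reference_angle_deg is not None else 0.25 * step
    planes = []
    for k in range(n_planes):
        phi = phi0 + k * step
        d = np.cos(phi) * r1 + np.sin(phi) * r2  # in-plane direction
        normal = np.cross(d, n_hat)
        planes.append(PlaneGeometry(origin=np.asarray(center, dtype=float),
                                    u=d, v=n_hat, normal=unit(normal),
                                    extent=tuple(extent), pixel_spacing=pixel_spacing,
                                    thickness=thickness_mm))
    return planes


# --------------------------------------------------------------------------
# step 3: slab sampling and in-plane resampling
# --------------------------------------------------------------------------

def sample_slab(volume: np.ndarray, affine: np.ndarray, plane: PlaneGeometry,
                n_sublayers: int = 5, fill_value: float = 0.0) -> np.ndarray:
    """Average trilinear samples over sub-planes across the slab thickness.

    Emulates through-plane partial volume: ``n_sublayers`` equally spaced
    parallel sub-planes spanning [-t/2, +t/2] are each sampled at the pixel
    world positions and averaged.  Out-of-volume samples take
    ``fill_value`` (with a warning).
    """
    if n_sublayers < 1 or n_sublayers % 2 == 0:
        raise ParameterError("n_sublayers must be odd and >= 1")
    vol = np.asarray(volume, dtype=float)
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    offsets = (np.array([0.0]) if n_sublayers == 1
               else np.linspace(-plane.thickness / 2.0, plane.thickness / 2.0, n_sublayers))
    acc = None
    warned = False
    for off in offsets:
        world = plane.pixel_centers(off)
        ijk = world @ inv[:3, :3].T + inv[:3, 3]
        coords = np.moveaxis(ijk, -1, 0)
        outside = np.any((coords < -0.5) | (coords > np.array(vol.shape)[:, None, None] - 0.5),
                         axis=0)
        if np.any(outside) and not warned:
            warnings.warn("plane extends outside the volume; background fill used",
                          stacklevel=2)
            warned = True
        img = ndimage.map_coordinates(vol, coords, order=1, mode="constant",
                                      cval=fill_value)
        acc = img if acc is None else acc + img
    return acc / len(offsets)


def _box_average_axis(img: np.ndarray, axis: int, n_out: int) -> np.ndarray:
    """Exact mean over n_out equal contiguous boxes along one axis
    (integral-image with linear interpolation at fractional box edges)."""
    img = np.moveaxis(np.asarray(img, dtype=float), axis, 0)
    n = img.shape[0]
    cum = np.concatenate([np.zeros((1,) + img.shape[1:]), np.cumsum(img, axis=0)])
    edges = np.linspace(0.0, n, n_out + 1)
    lo = np.floor(edges).astype(int).clip(0, n)
    frac = edges - lo
    vals = cum[lo] + frac.reshape((-1,) + (1,) * (img.ndim - 1)) * (
        cum[np.minimum(lo + 1, n)] - cum[lo])
    out = (vals[1:] - vals[:-1]) / np.diff(edges).reshape((-1,) + (1,) * (img.ndim - 1))
    return np.moveaxis(out, 0, axis)


def resample_inplane(image: np.ndarray, from_spacing: float,
                     to_spacing_acquired: float = 1.4,
                     to_spacing_reconstructed: float = 0.87):
    """Two-step in-plane resampling: acquisition then reconstruction.

    Box-average down to the acquired grid (partial-volume mixing at the
    acquisition resolution), then bilinear interpolation up to the
    reconstructed grid.  Returns (image, reconstructed_spacing).
    """
    if min(from_spacing, to_spacing_acquired, to_spacing_reconstructed) <= 0:
        raise ParameterError("spacings must be > 0")
    img = np.asarray(image, dtype=float)
    extent = np.array(img.shape) * from_spacing
    n_acq = np.maximum(1, np.round(extent / to_spacing_acquired).astype(int))
    acq = _box_average_axis(img, 0, n_acq[0])
    acq = _box_average_axis(acq, 1, n_acq[1])
    acq_spacing = extent / n_acq
    n_rec = np.maximum(1, np.round(extent / to_spacing_reconstructed).astype(int))
    rec_spacing = extent / n_rec
    ci = ((np.arange(n_rec[0]) + 0.5) * rec_spacing[0]) / acq_spacing[0] - 0.5
    cj = ((np.arange(n_rec[1]) + 0.5) * rec_spacing[1]) / acq_spacing[1] - 0.5
    CI, CJ = np.meshgrid(ci, cj, indexing="ij")
    rec = ndimage.map_coordinates(acq, np.stack([CI, CJ]), order=1, mode="nearest")
    return rec, float(rec_spacing.mean())


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------

_STRATEGY_PLANES = {"SAX": None, "rLAX6": 6, "rLAX9": 9, "rLAX18": 18}


def planes_for_strategy(strategy: str, axis, center, extent=(120.0, 120.0),
                        pixel_spacing: float = 0.5, n_sax_slices: int = 5,
                        thickness_mm: float = 6.0, sax_spacing_mm: float = 6.0):
    if strategy not in _STRATEGY_PLANES:
        raise ConfigError(f"unknown strategy {strategy!r}")
    if strategy == "SAX":
        return define_sax_planes(axis, center, n_slices=n_sax_slices,
                                 thickness_mm=thickness_mm, spacing_mm=sax_spacing_mm,
                                 extent=extent, pixel_spacing=pixel_spacing)
    return define_rlax_planes(axis, center, n_planes=_STRATEGY_PLANES[strategy],
                              thickness_mm=thickness_mm, extent=extent,
                              pixel_spacing=pixel_spacing)


def simulate_study(motion, template: LabelVolume,
                   intensity_model: IntensityModel | None = None,
                   strategies=("SAX", "rLAX6", "rLAX9", "rLAX18"),
                   seed: int = 0, n_timesteps: int = 10,
                   noise_sigma: float = DEFAULT_NOISE_SIGMA,
                   smooth_sigma_mm: float = 0.7, valve_thickness: float = 1.0,
                   temporal_mode: str = "decimate", extent=(120.0, 120.0),
                   base_pixel_spacing: float = 0.5, n_sax_slices: int = 5,
                   n_sublayers: int = 5,
                   to_spacing_acquired: float = 1.4,
                   to_spacing_reconstructed: float = 0.87) -> dict:
    """End-to-end synthetic study: 4D model -> slice stacks per strategy.

    Temporal sampling (10 timesteps/closure) happens first, then per
    timeframe: valve rasterization into the template, intensity assignment,
    additive noise, smoothing, plane definition per strategy, slab sampling
    and the two-step in-plane resampling.  All randomness derives from
    ``seed`` through per-timeframe substreams, so a fixed seed reproduces the
    output bit-for-bit.
    """
    from .valve_dynamics import MotionSequence, temporal_downsample

    model = intensity_model or IntensityModel()
    if isinstance(motion, MotionSequence):
        seq = (temporal_downsample(motion, n_timesteps, mode=temporal_mode)
               if motion.n_frames != n_timesteps else motion)
        frames = [seq.mesh_at(i) for i in range(seq.n_frames)]
    else:  # a single static mesh
        frames = [motion]

    axis, center = compute_valve_axis(frames[0])
    streams = np.random.SeedSequence(seed).spawn(len(frames))
    out = {s: [] for s in strategies}
    for t, (mesh_t, ss) in enumerate(zip(frames, streams)):
        rng = np.random.default_rng(ss)
        labeled = rasterize_surface(mesh_t, template, thickness=valve_thickness)
        vol = assign_intensities(labeled, model, seed=rng)
        vol = add_noise(vol, sigma=noise_sigma, seed=rng)
        vol = smooth(vol, kernel_sigma_mm=smooth_sigma_mm, spacing=labeled.spacing)
        for strat in strategies:
            planes = planes_for_strategy(strat, axis, center, extent=extent,
                                         pixel_spacing=base_pixel_spacing,
                                         n_sax_slices=n_sax_slices)
            images, rec_planes = [], []
            for pl in planes:
                img = sample_slab(vol, labeled.affine, pl, n_sublayers=n_sublayers)
                rec, rec_sp = resample_inplane(img, pl.pixel_spacing,
                                               to_spacing_acquired,
                                               to_spacing_reconstructed)
                images.append(rec)
                rec_planes.append(PlaneGeometry(
                    origin=pl.origin, u=pl.u, v=pl.v, normal=pl.normal,
                    extent=pl.extent, pixel_spacing=rec_sp, thickness=pl.thickness))
            out[strat].append(SliceStack(images=images, planes=rec_planes,
                                         strategy=strat, timeframe=t,
                                         pixel_spacing=rec_sp))
    return out
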