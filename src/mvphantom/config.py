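"""Study configuration and the end-to-end pipeline driver."""
from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError

__all__ = ["StudyConfig", "load_config", "save_config", "run_pipeline"]


@dataclass
class StudyConfig:
    """Validated parameters of one simulated acquisition study.

    Defaults reproduce the reference use case: 180-frame closure sampled to
    10 timesteps, additive noise sigma 38, 6 mm slices, 1.4 mm acquired and
    0.87 mm reconstructed in-plane spacing, all four sampling strategies and
    three annotators.
    """

    seed: int = 0
    out_dir: str = "mvphantom_out"
    # phantom
    annulus_radii: tuple = (20.0, 15.0)
    saddle_height: float = 3.0
    leaflet_depth: float = 18.0
    orifice_gap: float = 16.0
    target_face_area: float = 0.55
    thorax_shape: tuple = (160, 160, 160)
    thorax_spacing: tuple = (1.0, 1.0, 1.0)
    # dynamics
    n_frames: int = 180
    solver_iterations: int = 30
    # imaging
    n_timesteps: int = 10
    temporal_mode: str = "decimate"
    noise_sigma: float = 38.0
    smooth_sigma_mm: float = 0.7
    valve_thickness: float = 1.0
    slice_thickness: float = 6.0
    sax_spacing: float = 6.0
    n_sax_slices: int = 5
    acquired_spacing: float = 1.4
    reconstructed_spacing: float = 0.87
    plane_extent: tuple = (120.0, 120.0)
    strategies: tuple = ("SAX", "rLAX6", "rLAX9", "rLAX18")
    intensity_model_path: str | None = None
    make_images: bool = True
    # annotators
    annotator_noise_mm: float = 1.5
    detection_miss_rate: float = 0.0
    n_annotators: int = 3

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def load_config(path) -> StudyConfig:
    """Read and validate a JSON study config; unknown keys are rejected."""
    with open(path) as fh:
        doc = json.load(fh)
    known = set(StudyConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = StudyConfig(**doc)
    for name in ("noise_sigma", "smooth_sigma_mm", "valve_thickness",
                 "slice_thickness", "acquired_spacing", "reconstructed_spacing"):
        if getattr(cfg, name) < 0:
            raise ConfigError(f"config key {name!r} must be >= 0")
    if cfg.n_frames < 2 or cfg.n_timesteps < 2:
        raise ConfigError("n_frames and n_timesteps must be >= 2")
    if not isinstance(cfg.seed, int):
        raise ConfigError("seed must be an integer (mandatory for stochastic runs)")
    return cfg


def save_config(cfg: StudyConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=1, default=list)


def run_pipeline(cfg: StudyConfig) -> int:
    """Execute the full workflow and write a deterministic artifact tree.

    model + closure -> temporal sampling -> (optional) image stacks ->
    annotations -> quantification report, plus a provenance record with the
    config hash, seed and library versions.
    """
    from . import __version__, fileio
    from .image_simulation import IntensityModel, simulate_study
    from .phantom_anatomy import (AnnulusModel, ThoraxConfig, generate_thorax,
                                  generate_valve_mesh, rasterize_surface)
    from .valve_dynamics import PBDConfig, simulate_closure, temporal_downsample
    from .valve_quantification import replicate_study

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    model = AnnulusModel(radii=tuple(cfg.annulus_radii),
                         saddle_height=cfg.saddle_height)
    mesh = generate_valve_mesh(model, leaflet_depth=cfg.leaflet_depth,
                               orifice_gap=cfg.orifice_gap,
                               target_face_area=cfg.target_face_area)
    fileio.save_mesh(mesh, out / "valve_mesh.ply")

    seq = simulate_closure(mesh, PBDConfig(n_frames=cfg.n_frames,
                                           solver_iterations=cfg.solver_iterations))
    sampled = temporal_downsample(seq, cfg.n_timesteps, mode=cfg.temporal_mode)
    fileio.save_motion_sequence(sampled, out / "motion", config_repr=cfg.config_hash())

    template = generate_thorax(ThoraxConfig(shape=tuple(cfg.thorax_shape),
                                            spacing=tuple(cfg.thorax_spacing)))
    labeled = rasterize_surface(sampled.mesh_at(0), template,
                                thickness=cfg.valve_thickness)
    fileio.save_label_volume(labeled, out / "phantom_labels.nii.gz")

    if cfg.make_images:
        imodel = (IntensityModel.from_json(cfg.intensity_model_path)
                  if cfg.intensity_model_path else IntensityModel())
        stacks = simulate_study(
            sampled, template, intensity_model=imodel, strategies=cfg.strategies,
            seed=cfg.seed, n_timesteps=cfg.n_timesteps, noise_sigma=cfg.noise_sigma,
            smooth_sigma_mm=cfg.smooth_sigma_mm, valve_thickness=cfg.valve_thickness,
            temporal_mode=cfg.temporal_mode, n_sax_slices=cfg.n_sax_slices,
            extent=tuple(cfg.plane_extent),
            to_spacing_acquired=cfg.acquired_spacing,
            to_spacing_reconstructed=cfg.reconstructed_spacing)
        for strat, stacks_t in stacks.items():
            fileio.save_slice_stack(stacks_t[0], out / f"stack_{strat}_t0.nii.gz")

    report = replicate_study(
        seed=cfg.seed, strategies=tuple(cfg.strategies), annulus=model,
        leaflet_depth=cfg.leaflet_depth, orifice_gap=cfg.orifice_gap,
        noise_sigma_mm=cfg.annotator_noise_mm,
        detection_miss_rate=cfg.detection_miss_rate, n_frames=cfg.n_frames,
        n_timesteps=cfg.n_timesteps, n_sax_slices=cfg.n_sax_slices,
        make_images=False, out_dir=out / "report")
    for strat, ann_sets in report.annotations.items():
        fileio.save_annotations(ann_sets, out / f"annotations_{strat}.json")

    provenance = {
        "config": cfg.to_dict(), "config_hash": cfg.config_hash(),
        "seed": cfg.seed, "mvphantom": __version__,
        "numpy": np.__version__, "python": platform.python_version(),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, default=list)
    return 0
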