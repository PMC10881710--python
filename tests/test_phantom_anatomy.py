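import numpy as np
import pytest

from mvphantom import AnnulusModel, generate_annulus, generate_valve_mesh, landmark_align
from mvphantom._geometry import polyline_length, random_rotation
from mvphantom.errors import (
    ConfigError,
    InsufficientLandmarksError,
    InvalidFrameError,
    OutOfBoundsError,
    ParameterError,
)
from mvphantom.phantom_anatomy import (
    DEFAULT_LABEL_MAP,
    LandmarkSet,
    ThoraxConfig,
    ValveMesh,
    generate_thorax,
    rasterize_surface,
)
from conftest import make_label_volume


# ---------------------------------------------------------------- annulus --

class TestAnnulusCurve:
    def test_planar_circle_diameter(self):
        """A flat circular annulus has a maximum pairwise distance of 2r."""
        model = AnnulusModel(radii=(15.0, 15.0), saddle_height=0.0)
        pts = generate_annulus(model, 360)
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        assert d.max() == pytest.approx(30.0, abs=1e-6)
        assert np.allclose(pts[:, 2], 0.0)

    def test_saddle_axis_extent(self):
        """cos 2θ spans [-1, 1], so the curve spans 2h along the axis."""
        model = AnnulusModel(radii=(20.0, 15.0), saddle_height=3.0)
        pts = generate_annulus(model, 360)
        z = pts @ model.e3
        assert z.max() - z.min() == pytest.approx(6.0, abs=1e-9)

    def test_length_against_dense_polyline_oracle(self):
        """Curve length converges to the brute-force dense polyline sum."""
        model = AnnulusModel(radii=(20.0, 15.0), saddle_height=3.0)
        dense = polyline_length(generate_annulus(model, 100_000), closed=True)
        coarse = polyline_length(generate_annulus(model, 360), closed=True)
        assert coarse == pytest.approx(dense, rel=1e-4)

    def test_saddle_projection_reproduces_flat_ellipse(self):
        """Dropping the e3 coordinate of the saddle gives the h=0 ellipse."""
        flat = AnnulusModel(radii=(20.0, 15.0), saddle_height=0.0)
        saddle = AnnulusModel(radii=(20.0, 15.0), saddle_height=3.0)
        p_flat = generate_annulus(flat, 256)
        p_saddle = generate_annulus(saddle, 256)
        p_saddle[:, 2] = 0.0
        np.testing.assert_allclose(p_saddle, p_flat, atol=1e-12)

    def test_invalid_frame_rejected(self):
        frame = np.eye(3)
        frame[0, 0] = 2.0
        with pytest.raises(InvalidFrameError):
            AnnulusModel(axis_frame=frame)

    def test_invalid_radii_rejected(self):
        with pytest.raises(ParameterError):
            AnnulusModel(radii=(10.0, 15.0))


# ------------------------------------------------------------------- mesh --

class TestValveMesh:
    def test_mean_face_area_near_target(self, valve_mesh):
        """Default remeshing density reproduces ~0.55 mm² mean face area."""
        assert 0.55 * 0.85 <= valve_mesh.mean_face_area() <= 0.55 * 1.15

    def test_annulus_vertices_lie_on_curve(self, valve_mesh, annulus_model):
        a, b = annulus_model.radii
        h = annulus_model.saddle_height
        pts = valve_mesh.vertices[valve_mesh.annulus_vertex_ids]
        theta = np.arctan2(pts[:, 1] / b, pts[:, 0] / a)
        rec = np.stack([a * np.cos(theta), b * np.sin(theta),
                        h * np.cos(2 * theta)], axis=1)
        assert np.abs(pts - rec).max() < 1e-9

    def test_closed_state_free_edges_meet(self, annulus_model):
        mesh = generate_valve_mesh(annulus_model, state=1.0)
        fa = mesh.vertices[mesh.free_edge_vertex_ids["anterior"]]
        fp = mesh.vertices[mesh.free_edge_vertex_ids["posterior"]]
        dmin = np.linalg.norm(fa[:, None] - fp[None], axis=-1).min()
        assert dmin <= 1.0  # within one rasterization voxel

    def test_manifold_and_disk_topology(self, valve_mesh):
        """No non-manifold edges; each leaflet is a topological disk."""
        assert valve_mesh.nonmanifold_edge_count() == 0
        for name in ("anterior", "posterior"):
            faces = valve_mesh.faces[valve_mesh.face_leaflet == name]
            vids = np.unique(faces)
            edges = np.unique(np.sort(np.vstack(
                [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1), axis=0)
            euler = len(vids) - len(edges) + len(faces)
            assert euler == 1

    def test_open_state_leaflets_disjoint(self, valve_mesh):
        fa = valve_mesh.vertices[valve_mesh.free_edge_vertex_ids["anterior"]]
        fp = valve_mesh.vertices[valve_mesh.free_edge_vertex_ids["posterior"]]
        # interior free-edge points are separated by the orifice gap
        assert np.linalg.norm(fa[len(fa) // 2] - fp[len(fp) // 2]) > 10.0

    @pytest.mark.parametrize("kwargs", [dict(target_face_area=-1.0),
                                        dict(leaflet_depth=-2.0),
                                        dict(state=1.5)])
    def test_parameter_errors(self, annulus_model, kwargs):
        with pytest.raises(ParameterError):
            generate_valve_mesh(annulus_model, **kwargs)


# -------------------------------------------------------------- alignment --

class TestLandmarkAlign:
    def test_identity(self):
        lm = LandmarkSet.default()
        R, t, rmsd = landmark_align(lm, lm)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t, 0.0, atol=1e-12)
        assert rmsd < 1e-12

    def test_recovers_known_rigid_transform(self, rng):
        """Applying (R0, t0) then aligning back recovers the transform."""
        fixed = LandmarkSet.default()
        for _ in range(10):
            R0 = random_rotation(rng)
            t0 = rng.uniform(-50, 50, 3)
            moving = fixed.transformed(R0, t0)
            R, t, rmsd = landmark_align(moving, fixed)
            assert rmsd < 1e-6
            np.testing.assert_allclose(R @ R0, np.eye(3), atol=1e-9)
            recovered = moving.transformed(R, t)
            for k in fixed.points:
                np.testing.assert_allclose(recovered.points[k], fixed.points[k],
                                           atol=1e-6)

    def test_collinear_landmarks_rejected(self):
        a = LandmarkSet({"p1": (0, 0, 0), "p2": (1, 0, 0), "p3": (2, 0, 0)})
        with pytest.raises(InsufficientLandmarksError):
            landmark_align(a, a)

    def test_too_few_pairs_rejected(self):
        a = LandmarkSet({"p1": (0, 0, 0), "p2": (1, 0, 0)})
        with pytest.raises(InsufficientLandmarksError):
            landmark_align(a, a)

    def test_reflection_corrected_to_proper_rotation(self, rng):
        """Even noisy (non-exact) correspondences yield det(R) = +1."""
        fixed = LandmarkSet.default()
        pts = {k: v + rng.normal(0, 5.0, 3) for k, v in fixed.points.items()}
        R, _, _ = landmark_align(LandmarkSet(pts), fixed)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


# ----------------------------------------------------------- rasterization --

def _flat_square_mesh(side=20.0, n=21, z=0.0):
    xs = np.linspace(-side / 2, side / 2, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    verts = np.stack([X.ravel(), Y.ravel(), np.full(n * n, z)], axis=1)
    idx = np.arange(n * n).reshape(n, n)
    f1 = np.stack([idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(), idx[1:, 1:].ravel()], axis=1)
    f2 = np.stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()], axis=1)
    return ValveMesh(vertices=verts, faces=np.concatenate([f1, f2]),
                     annulus_vertex_ids=np.array([], dtype=int),
                     free_edge_vertex_ids={}, face_leaflet=np.array(["anterior"] * (
                         2 * (n - 1) ** 2)))


class TestRasterize:
    @staticmethod
    def _interior_count(volume, half=8.0):
        """Labeled voxels away from the sheet border (no edge-halo effects)."""
        idx = np.argwhere(volume.labels == 1)
        w = volume.voxel_to_world(idx)
        return int(((np.abs(w[:, 0]) <= half) & (np.abs(w[:, 1]) <= half)).sum())

    def test_slab_volume_matches_analytic(self):
        """A flat sheet at 1 mm thickness labels ~ area*t/voxel_volume voxels."""
        mesh = _flat_square_mesh()
        template = make_label_volume(np.zeros((80, 80, 40), dtype=np.int16), spacing=0.5,
                                     label_map={"mitral_valve": 1})
        out = rasterize_surface(mesh, template, thickness=1.0, label=1)
        expected = 16.0 * 16.0 * 1.0 / 0.5 ** 3  # 16x16 interior window
        assert abs(self._interior_count(out) - expected) / expected < 0.10

    def test_count_scales_linearly_with_thickness(self):
        mesh = _flat_square_mesh()
        template = make_label_volume(np.zeros((80, 80, 60), dtype=np.int16), spacing=0.5,
                                     label_map={"mitral_valve": 1})
        counts = {t: self._interior_count(
            rasterize_surface(mesh, template, thickness=t, label=1))
            for t in (1.0, 2.0, 4.0)}
        assert abs(counts[2.0] / counts[1.0] - 2.0) < 0.2
        assert abs(counts[4.0] / counts[2.0] - 2.0) < 0.2

    def test_overwrite_policy(self):
        """The valve overwrites cavity and background but not wall labels."""
        mesh = _flat_square_mesh()
        labels = np.zeros((80, 80, 20), dtype=np.int16)
        labels[:40] = 4   # lv_myocardium: protected
        labels[40:] = 5   # lv_cavity: writable
        template = make_label_volume(labels, spacing=0.5, label_map={
            "mitral_valve": 1, "lv_myocardium": 4, "lv_cavity": 5})
        out = rasterize_surface(mesh, template, thickness=1.0, label=1)
        assert (out.labels[:40] == 4).all()
        assert (out.labels == 1).sum() > 0
        out_all = rasterize_surface(mesh, template, thickness=1.0, label=1,
                                    overwrite="all")
        assert (out_all.labels == 1).sum() > (out.labels == 1).sum()

    def test_empty_mesh_is_identity(self):
        template = make_label_volume(np.zeros((10, 10, 10), dtype=np.int16),
                                     label_map={"mitral_valve": 1})
        empty = ValveMesh(vertices=np.empty((0, 3)), faces=np.empty((0, 3), dtype=int),
                          annulus_vertex_ids=np.array([], dtype=int),
                          free_edge_vertex_ids={}, face_leaflet=np.array([]))
        out = rasterize_surface(empty, template, label=1)
        np.testing.assert_array_equal(out.labels, template.labels)

    def test_out_of_bounds_reports_vertices(self):
        mesh = _flat_square_mesh(side=100.0)
        template = make_label_volume(np.zeros((20, 20, 20), dtype=np.int16),
                                     label_map={"mitral_valve": 1})
        with pytest.raises(OutOfBoundsError) as exc:
            rasterize_surface(mesh, template, label=1)
        assert len(exc.value.vertex_ids) > 0


# ----------------------------------------------------------------- thorax --

class TestThorax:
    def test_default_label_map_covers_intensity_table(self, small_thorax):
        required = {"mitral_valve", "la_wall", "la_cavity", "lv_myocardium",
                    "lv_cavity", "ra_wall", "ra_cavity", "rv_wall", "rv_cavity",
                    "aorta", "bones", "liver", "kidney", "lung", "bronchi"}
        assert required <= set(small_thorax.label_map)

    def test_empty_entity_list_gives_background(self):
        vol = generate_thorax(ThoraxConfig(shape=(20, 20, 20), entities=()))
        assert (vol.labels == 0).all()

    def test_left_heart_only_excludes_right_heart(self):
        vol = generate_thorax(ThoraxConfig(
            shape=(120, 120, 120),
            entities=("la_wall", "la_cavity", "lv_myocardium", "lv_cavity")))
        present = set(np.unique(vol.labels))
        right = {DEFAULT_LABEL_MAP[k] for k in ("ra_wall", "ra_cavity",
                                                "rv_wall", "rv_cavity")}
        assert not (present & right)
        assert DEFAULT_LABEL_MAP["lv_cavity"] in present

    def test_unknown_entity_rejected(self):
        with pytest.raises(ConfigError):
            ThoraxConfig(entities=("spleen",))

    def test_valve_region_is_blood_pool(self, small_thorax, annulus_model):
        """The annulus ring sits in cavity so rasterization can paint it."""
        ring = generate_annulus(annulus_model, 64)
        vox = np.round(small_thorax.world_to_voxel(ring)).astype(int)
        vals = small_thorax.labels[vox[:, 0], vox[:, 1], vox[:, 2]]
        cav = {small_thorax.label_map["la_cavity"], small_thorax.label_map["lv_cavity"]}
        assert set(vals.tolist()) <= cav
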