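import numpy as np
import pytest
from scipy import ndimage

from mvphantom import (
    AnnulusModel,
    IntensityModel,
    add_noise,
    assign_intensities,
    compute_valve_axis,
    define_rlax_planes,
    define_sax_planes,
    generate_valve_mesh,
    resample_inplane,
    sample_slab,
    simulate_study,
    smooth,
)
from mvphantom._geometry import random_rotation
from mvphantom.errors import ConfigError, GeometryError, ParameterError
from mvphantom.image_simulation import PlaneGeometry
from conftest import make_label_volume


def _two_label_volume(n=40):
    labels = np.zeros((n, n, n), dtype=np.int16)
    labels[: n // 2] = 1   # mitral_valve
    labels[n // 2:] = 3    # la_cavity
    return make_label_volume(labels, label_map={"mitral_valve": 1, "la_cavity": 3})


class TestIntensities:
    def test_region_means_match_table(self):
        """Homogeneous regions reproduce the observed tissue means."""
        vol = _two_label_volume(50)
        img = assign_intensities(vol, IntensityModel(), seed=0)
        n = (vol.labels == 1).sum()
        mv_mean = img[vol.labels == 1].mean()
        la_mean = img[vol.labels == 3].mean()
        assert abs(mv_mean - 266.0) < 3 * 25.0 / np.sqrt(n)
        assert abs(la_mean - 357.0) < 3 * 14.0 / np.sqrt(n)

    def test_region_sds_match_table(self):
        vol = _two_label_volume(50)  # >= 1e4 voxels per region
        img = assign_intensities(vol, IntensityModel(), seed=1)
        assert abs(img[vol.labels == 1].std() / 25.0 - 1) < 0.05
        assert abs(img[vol.labels == 3].std() / 14.0 - 1) < 0.05

    def test_zero_sd_gives_exact_means(self):
        vol = _two_label_volume(16)
        model = IntensityModel(entries={"mitral_valve": (266.0, 0.0),
                                        "la_cavity": (357.0, 0.0),
                                        "background": (0.0, 0.0)})
        img = assign_intensities(vol, model, seed=0)
        assert (img[vol.labels == 1] == 266.0).all()
        assert (img[vol.labels == 3] == 357.0).all()

    def test_missing_label_entry_raises(self):
        vol = _two_label_volume(8)
        model = IntensityModel(entries={"mitral_valve": (266.0, 25.0)})
        with pytest.raises(ConfigError, match="la_cavity"):
            assign_intensities(vol, model, seed=0)

    def test_rician_distribution_positive(self):
        vol = _two_label_volume(16)
        img = assign_intensities(vol, IntensityModel(distribution="rician"), seed=0)
        assert (img >= 0).all()


class TestNoise:
    def test_zero_sigma_identity(self):
        v = np.full((10, 10, 10), 5.0)
        np.testing.assert_array_equal(add_noise(v, 0.0, seed=0), v)

    def test_default_sigma_statistics(self):
        """sigma=38 on 1e6 voxels: sd within [37.8, 38.2], mean near 0."""
        v = np.zeros((100, 100, 100))
        out = add_noise(v, seed=42)
        assert 37.8 <= out.std() <= 38.2
        assert abs(out.mean()) <= 3 * 38.0 / 1000.0

    def test_negative_sigma_rejected(self):
        with pytest.raises(ParameterError):
            add_noise(np.zeros((2, 2, 2)), -1.0)


class TestSmoothing:
    def test_zero_sigma_and_constant_are_fixed_points(self):
        v = np.full((12, 12, 12), 7.0)
        np.testing.assert_array_equal(smooth(v, 0.0), v)
        np.testing.assert_allclose(smooth(v, 1.0), v, atol=1e-9)

    def test_noise_reduction_matches_kernel_weights(self):
        """Post-smoothing sd of white noise follows sqrt(sum w_i^2)."""
        rng = np.random.default_rng(7)
        v = rng.normal(0, 38.0, (64, 64, 64))
        sig_mm, spacing = 0.7, (1.0, 1.0, 1.0)
        out = smooth(v, sig_mm, spacing)
        # discrete kernel weights via impulse response
        imp = np.zeros((31, 31, 31))
        imp[15, 15, 15] = 1.0
        w = ndimage.gaussian_filter(imp, sigma=sig_mm)
        expected_sd = 38.0 * np.sqrt((w ** 2).sum())
        inner = out[8:-8, 8:-8, 8:-8]
        assert expected_sd < 38.0
        assert abs(inner.std() / expected_sd - 1) < 0.05


class TestValveAxis:
    def test_flat_mesh_axis_and_center(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(-10, 10, 200),
                               rng.uniform(-10, 10, 200),
                               np.full(200, 5.0)])
        axis, center = compute_valve_axis(pts)
        np.testing.assert_allclose(np.abs(axis), [0, 0, 1], atol=1e-9)
        assert center[2] == pytest.approx(5.0)

    def test_rotation_equivariance(self, valve_mesh, rng):
        axis0, _ = compute_valve_axis(valve_mesh)
        R = random_rotation(rng)
        axis_r, _ = compute_valve_axis(valve_mesh.vertices @ R.T)
        assert min(np.linalg.norm(axis_r - R @ axis0),
                   np.linalg.norm(axis_r + R @ axis0)) < 1e-9

    def test_saddle_valve_axis_matches_construction_frame(self, valve_mesh,
                                                          annulus_model):
        axis, _ = compute_valve_axis(valve_mesh,
                                     atrial_reference=annulus_model.center
                                     + annulus_model.e3)
        cosang = abs(np.dot(axis, annulus_model.e3))
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 2.0

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(10.0), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError):
            compute_valve_axis(pts)


class TestPlaneFamilies:
    def test_sax_single_plane(self):
        (pl,) = define_sax_planes([0, 0, 1], [1, 2, 3], n_slices=1)
        np.testing.assert_allclose(pl.origin, [1, 2, 3])
        np.testing.assert_allclose(pl.normal, [0, 0, 1])

    def test_sax_center_spacing(self):
        planes = define_sax_planes([0, 0, 1], [0, 0, 0], n_slices=5, spacing_mm=6.0)
        centers = np.array([p.origin for p in planes])
        gaps = np.linalg.norm(np.diff(centers, axis=0), axis=1)
        np.testing.assert_allclose(gaps, 6.0, atol=1e-12)
        # stack centered on the valve center
        np.testing.assert_allclose(centers.mean(axis=0), 0.0, atol=1e-12)

    def test_plane_orthonormality(self):
        for pl in define_sax_planes([0.3, -0.5, 0.8], [1, 1, 1], n_slices=3):
            assert abs(np.dot(pl.normal, pl.u)) < 1e-12
            assert abs(np.dot(pl.normal, pl.v)) < 1e-12

    @pytest.mark.parametrize("n,expected_step", [(18, 10.0), (9, 20.0), (6, 30.0)])
    def test_rlax_angular_increment(self, n, expected_step):
        planes = define_rlax_planes([0, 0, 1], [0, 0, 0], n_planes=n)
        for a, b in zip(planes[:-1], planes[1:]):
            cosang = np.clip(abs(np.dot(a.normal, b.normal)), -1, 1)
            assert np.degrees(np.arccos(cosang)) == pytest.approx(expected_step,
                                                                  abs=1e-9)

    def test_rlax_planes_contain_axis(self):
        axis = np.array([0.2, 0.3, 0.9]) / np.linalg.norm([0.2, 0.3, 0.9])
        for pl in define_rlax_planes(axis, [5, 5, 5], n_planes=9):
            assert abs(np.dot(axis, pl.normal)) < 1e-12
            assert abs(np.dot(pl.origin - [5, 5, 5], pl.normal)) < 1e-12

    def test_rlax_single_plane(self):
        (pl,) = define_rlax_planes([0, 0, 1], [0, 0, 0], n_planes=1)
        assert abs(np.dot(pl.normal, [0, 0, 1])) < 1e-12


class TestSlabSampling:
    def _axial_plane(self, z=0.0, thickness=6.0):
        return PlaneGeometry(origin=[0, 0, z], u=[1, 0, 0], v=[0, 1, 0],
                             normal=[0, 0, 1], extent=(20, 20),
                             pixel_spacing=1.0, thickness=thickness)

    def test_constant_volume(self):
        vol = make_label_volume(np.zeros((40, 40, 40), dtype=np.int16))
        img = sample_slab(np.full((40, 40, 40), 3.5), vol.affine, self._axial_plane())
        np.testing.assert_allclose(img, 3.5, atol=1e-12)

    def test_linear_field_slab_mean(self):
        """f(x,y,z)=z averaged symmetrically across the slab equals z_center."""
        vol = make_label_volume(np.zeros((40, 40, 40), dtype=np.int16))
        idx = np.indices((40, 40, 40), dtype=float)
        zw = idx[2] + vol.affine[2, 3]  # world z (spacing 1)
        for zc in (0.0, 3.25):
            img = sample_slab(zw, vol.affine, self._axial_plane(z=zc), n_sublayers=5)
            np.testing.assert_allclose(img, zc, atol=1e-9)

    def test_single_sublayer_equals_plane_resample(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(30, 30, 30))
        vol = make_label_volume(np.zeros((30, 30, 30), dtype=np.int16))
        pl = self._axial_plane(z=0.25, thickness=2.0)
        img1 = sample_slab(data, vol.affine, pl, n_sublayers=1)
        ijk = vol.world_to_voxel(pl.pixel_centers(0.0).reshape(-1, 3))
        ref = ndimage.map_coordinates(data, ijk.T, order=1).reshape(img1.shape)
        np.testing.assert_allclose(img1, ref, atol=1e-12)

    def test_even_sublayers_rejected(self):
        vol = make_label_volume(np.zeros((10, 10, 10), dtype=np.int16))
        with pytest.raises(ParameterError):
            sample_slab(np.zeros((10, 10, 10)), vol.affine, self._axial_plane(),
                        n_sublayers=4)

    def test_outside_plane_warns_and_fills(self):
        vol = make_label_volume(np.ones((10, 10, 10)))
        pl = PlaneGeometry(origin=[0, 0, 200.0], u=[1, 0, 0], v=[0, 1, 0],
                           normal=[0, 0, 1], extent=(20, 20), pixel_spacing=1.0,
                           thickness=2.0)
        with pytest.warns(UserWarning, match="outside"):
            img = sample_slab(np.ones((10, 10, 10)), vol.affine, pl,
                              fill_value=-1.0)
        assert (img == -1.0).all()


class TestInplaneResampling:
    def test_identity_spacings(self):
        rng = np.random.default_rng(5)
        img = rng.normal(size=(64, 64))
        out, sp = resample_inplane(img, 0.5, 0.5, 0.5)
        np.testing.assert_allclose(out, img, atol=1e-9)
        assert sp == pytest.approx(0.5)

    def test_constant_exact(self):
        img = np.full((50, 50), 2.25)
        out, _ = resample_inplane(img, 0.5)
        np.testing.assert_allclose(out, 2.25, atol=1e-12)

    def test_checkerboard_variance_reduced(self):
        """Box averaging to the acquired grid mixes fine structure."""
        n = 80
        img = (np.add.outer(np.arange(n), np.arange(n)) % 2).astype(float)
        out, _ = resample_inplane(img, 0.5)
        assert out.var() < img.var() * 0.2

    def test_output_geometry(self):
        img = np.zeros((100, 100))
        out, sp = resample_inplane(img, 0.5, 1.4, 0.87)
        # 50 mm extent -> 36 acquired -> 57 reconstructed pixels
        assert out.shape == (57, 57)
        assert sp == pytest.approx(50.0 / 57)


@pytest.fixture(scope="module")
def tiny_study(small_thorax, annulus_model):
    mesh = generate_valve_mesh(annulus_model)
    return simulate_study(mesh, small_thorax, strategies=("rLAX6",),
                          seed=11, extent=(60.0, 60.0), base_pixel_spacing=1.0)


class TestStudyPipeline:
    def test_noise_free_pipeline_preserves_label_mean(self):
        """Without noise and smoothing, slab samples deep inside one tissue
        equal the tissue mean exactly (Fig.-style workflow identity)."""
        labels = np.zeros((40, 40, 40), dtype=np.int16)
        labels[:] = 3  # one homogeneous tissue
        vol = make_label_volume(labels, label_map={"la_cavity": 3})
        model = IntensityModel(entries={"la_cavity": (357.0, 0.0),
                                        "background": (0.0, 0.0)})
        img = assign_intensities(vol, model, seed=0)
        img = add_noise(img, 0.0, seed=0)
        img = smooth(img, 0.0)
        pl = PlaneGeometry(origin=[0, 0, 0], u=[1, 0, 0], v=[0, 1, 0],
                           normal=[0, 0, 1], extent=(10, 10), pixel_spacing=1.0,
                           thickness=6.0)
        out = sample_slab(img, vol.affine, pl)
        np.testing.assert_allclose(out, 357.0, atol=1e-9)

    def test_stack_structure(self, tiny_study):
        stacks = tiny_study["rLAX6"]
        assert len(stacks) == 1  # single static frame
        assert len(stacks[0].images) == 6
        assert stacks[0].pixel_spacing == pytest.approx(0.87, rel=0.05)

    def test_seeded_rerun_is_bit_identical(self, tiny_study, small_thorax,
                                           annulus_model):
        mesh = generate_valve_mesh(annulus_model)
        again = simulate_study(mesh, small_thorax, strategies=("rLAX6",),
                               seed=11, extent=(60.0, 60.0), base_pixel_spacing=1.0)
        for a, b in zip(tiny_study["rLAX6"][0].images, again["rLAX6"][0].images):
            assert np.array_equal(a, b)

    def test_valve_brighter_than_myocardium_in_image(self, tiny_study):
        """The thin bright valve must survive the resampling chain."""
        img = tiny_study["rLAX6"][0].images[0]
        assert img.max() > 250.0
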