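"""Ray transform, canonical relation, visibility and sinogram truths."""

import numpy as np
import pytest

from shearwf.errors import InvalidConfigError, ShapeError
from shearwf.phantoms import Ellipse, PhantomConfig, rasterize, sample_head_phantom
from shearwf.tomo import (
    Sinogram,
    SinogramGeometry,
    SinogramWFElement,
    back_projection,
    canonical_forward,
    canonical_inverse,
    embed_sinogram_periodic,
    fold_extended_rows,
    ray_transform,
    sinogram_set_to_image_set,
    sinogram_wavefront_truth,
    visible_wavefront,
)
from shearwf.wavefront import DigitalWavefrontSet, wavefront_mse


@pytest.fixture(scope="module")
def phantom8():
    cfg = PhantomConfig(image_size=64, n_orientations=8, n_small=(3, 6))
    return sample_head_phantom(cfg, rng_seed=1)


class TestGeometry:
    def test_uniform_constructor(self):
        g = SinogramGeometry.parallel(64, angle_step_deg=6, n_det=64)
        assert g.n_angles == 30
        assert g.offsets[0] == pytest.approx(-np.sqrt(2))

    def test_invalid_grids_rejected(self):
        with pytest.raises(InvalidConfigError):
            SinogramGeometry(angles=np.array([0.5, 0.1]), offsets=np.linspace(-1.5, 1.5, 8),
                             image_size=64)
        with pytest.raises(InvalidConfigError):
            SinogramGeometry(angles=np.array([0.0, 0.1]), offsets=np.linspace(-0.5, 0.5, 8),
                             image_size=64)

    def test_json_round_trip(self, tmp_path):
        g = SinogramGeometry.parallel(64, n_angles=20, n_det=32)
        g.to_json(tmp_path / "g.json")
        g2 = SinogramGeometry.from_json(tmp_path / "g.json")
        assert np.allclose(g2.angles, g.angles) and g2.image_size == 64


class TestRayTransform:
    def test_zero_image_zero_sinogram(self):
        g = SinogramGeometry.parallel(64, n_angles=10, n_det=32)
        assert np.all(ray_transform(np.zeros((64, 64)), g).data == 0)

    def test_linearity(self, rng):
        g = SinogramGeometry.parallel(64, n_angles=12, n_det=48)
        i1, i2 = rng.standard_normal((2, 64, 64))
        combined = ray_transform(2 * i1 - 3 * i2, g).data
        assert np.allclose(combined, 2 * ray_transform(i1, g).data - 3 * ray_transform(i2, g).data)

    def test_disk_chord_length(self):
        """Central column of a disk sinogram equals the chord 2r within 1%."""
        M, r = 256, 0.4
        img = rasterize([Ellipse((0, 0), (r, r), 0.0, 1.0)], M, 2)
        g = SinogramGeometry.parallel(M, n_angles=30, n_det=129)
        sino = ray_transform(img, g)
        j0 = int(np.argmin(np.abs(g.offsets)))
        chord = 2 * np.sqrt(r ** 2 - g.offsets[j0] ** 2)
        assert np.abs(sino.data[:, j0] - chord).max() / chord < 0.01

    def test_radial_symmetry_gives_angle_constant_columns(self):
        M = 128
        img = rasterize([Ellipse((0, 0), (0.5, 0.5), 0.0, 1.0, edge_width=0.05)], M, 2)
        g = SinogramGeometry.parallel(M, n_angles=24, n_det=96)
        sino = ray_transform(img, g)
        assert np.abs(sino.data - sino.data.mean(axis=0)).max() < 1e-2

    def test_mass_preservation_every_angle(self, phantom8):
        M = 64
        g = SinogramGeometry.parallel(M, n_angles=18, n_det=128)
        sino = ray_transform(phantom8.image, g)
        mass = phantom8.image.sum() * (2.0 / M) ** 2
        line_mass = sino.data.sum(axis=1) * g.offset_spacing
        assert np.abs(line_mass - mass).max() / abs(mass) < 0.01

    def test_back_projection_is_exact_adjoint(self, rng):
        g = SinogramGeometry.parallel(32, n_angles=10, n_det=24)
        image = rng.standard_normal((32, 32))
        data = rng.standard_normal((10, 24))
        lhs = np.sum(ray_transform(image, g).data * data)
        rhs = np.sum(image * back_projection(Sinogram(data, g)))
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_shape_mismatch_raises(self):
        g = SinogramGeometry.parallel(64, n_angles=10, n_det=32)
        with pytest.raises(ShapeError):
            ray_transform(np.zeros((32, 32)), g)


class TestCanonicalRelation:
    def test_center_pixel_maps_to_zero_offset_and_slope(self):
        M = 64
        g = SinogramGeometry.parallel(M, n_angles=64, n_det=65)
        # center pixel has domain coordinates (1/M, 1/M), i.e. within half a
        # pixel of the origin; p and q must digitize to the central indices
        els = canonical_forward((M // 2, M // 2), 2, g, 8)
        assert len(els) == 1
        el = els[0]
        assert abs(g.offsets[el.offset_index]) < g.offset_spacing
        assert abs(el.slope) < 2.0 / M + 1e-9

    def test_full_angle_geometry_is_total(self, phantom8):
        g = SinogramGeometry.parallel(64, n_angles=64, n_det=64)
        for (r, c), bins in phantom8.truth.elements.items():
            for b in bins:
                assert len(canonical_forward((r, c), b, g, 8)) == 1

    def test_circle_boundary_offset_is_center_projection_plus_radius(self):
        """p0 = c.omega(alpha) + r for the boundary point with normal angle alpha."""
        M, r = 128, 0.35
        center = (0.15, -0.1)
        g = SinogramGeometry.parallel(M, n_angles=180, n_det=257)
        n_or = 180
        for alpha_deg in [0, 30, 75, 120]:
            alpha = np.radians(alpha_deg)
            x = (center[0] + r * np.cos(alpha), center[1] + r * np.sin(alpha))
            col = int(round((x[0] + 1) * M / 2 - 0.5))
            row = int(round((x[1] + 1) * M / 2 - 0.5))
            bin_ = int(alpha_deg % 180)
            els = canonical_forward((row, col), bin_, g, n_or)
            assert len(els) == 1
            p0 = g.offsets[els[0].offset_index]
            expected = center[0] * np.cos(alpha) + center[1] * np.sin(alpha) + r
            assert p0 == pytest.approx(expected, abs=2 * g.offset_spacing)

    def test_forward_inverse_round_trip(self, phantom8):
        g = SinogramGeometry.parallel(64, n_angles=64, n_det=64)
        for (r, c), bins in phantom8.truth.elements.items():
            for b in bins:
                (el,) = canonical_forward((r, c), b, g, 8)
                (rr, cc), bb = canonical_inverse(el, g, 8)
                assert abs(rr - r) <= 1 and abs(cc - c) <= 1
                assert min(abs(bb - b), 8 - abs(bb - b)) <= 1

    def test_inverse_forward_on_grid_aligned_elements(self):
        g = SinogramGeometry.parallel(64, n_angles=32, n_det=64)
        rng = np.random.default_rng(5)
        for _ in range(50):
            el = SinogramWFElement(
                angle_index=int(rng.integers(0, 32)),
                offset_index=int(rng.integers(10, 54)),
                slope=float(rng.uniform(-0.7, 0.7)),
            )
            mapped = canonical_inverse(el, g, 180)
            if mapped is None:
                continue
            (r, c), b = mapped
            els = canonical_forward((r, c), b, g, 180)
            if els:
                assert abs(els[0].angle_index - el.angle_index) <= 1
                assert abs(els[0].offset_index - el.offset_index) <= 1

    def test_zero_offset_zero_slope_inverts_to_origin(self):
        g = SinogramGeometry.parallel(64, n_angles=16, n_det=65)
        el = SinogramWFElement(angle_index=4, offset_index=32, slope=0.0)
        (r, c), b = canonical_inverse(el, g, 8)
        assert abs(r - 31.5) <= 1 and abs(c - 31.5) <= 1


class TestVisibility:
    def test_full_angle_grid_keeps_everything(self, phantom8):
        g = SinogramGeometry.parallel(64, n_angles=180, n_det=64)
        assert visible_wavefront(phantom8.truth, g) == phantom8.truth

    def test_empty_angle_handling(self, phantom8):
        g = SinogramGeometry(angles=np.array([0.3]), offsets=np.linspace(-1.5, 1.5, 16),
                             image_size=64)
        vis = visible_wavefront(phantom8.truth, g, angle_tolerance=1e-6)
        assert len(vis) < len(phantom8.truth)

    def test_six_degree_stride_keeps_half_of_circle_truth(self):
        from shearwf.phantoms import analytic_wavefront_set

        truth = analytic_wavefront_set([Ellipse((0, 0), (0.6, 0.6), 0.0, 1.0)], 256, 180)
        g = SinogramGeometry.parallel(256, angle_step_deg=6, n_det=256)
        vis = visible_wavefront(truth, g, angle_tolerance=np.radians(1.5))
        assert len(vis) / len(truth) == pytest.approx(0.5, abs=0.05)

    def test_more_angles_see_more(self, phantom8):
        coarse = SinogramGeometry.parallel(64, angle_step_deg=12, n_det=64)
        fine = SinogramGeometry.parallel(64, angle_step_deg=6, n_det=64)
        vc = visible_wavefront(phantom8.truth, coarse, angle_tolerance=np.radians(1.5))
        vf = visible_wavefront(phantom8.truth, fine, angle_tolerance=np.radians(1.5))
        assert len(vc) <= len(vf)
        for (pix, bins) in vc.elements.items():
            assert bins <= vf.elements[pix]


class TestSinogramTruth:
    def test_empty_phantom_empty_truth(self):
        from shearwf.phantoms import Phantom

        g = SinogramGeometry.parallel(64, n_angles=16, n_det=32)
        ph = Phantom(image=np.zeros((64, 64)), ellipses=[],
                     truth=DigitalWavefrontSet((64, 64), n_orientations=8))
        assert sinogram_wavefront_truth(ph, g).is_empty()

    def test_point_like_ellipse_traces_sinusoid(self):
        cfg_center = (0.4, 0.2)
        e = Ellipse(center=cfg_center, semi_axes=(0.04, 0.04), rotation=0.0, intensity=1.0)
        from shearwf.phantoms import Phantom, analytic_wavefront_set

        M = 64
        ph = Phantom(image=rasterize([e], M, 2), ellipses=[e],
                     truth=analytic_wavefront_set([e], M, 180))
        g = SinogramGeometry.parallel(M, n_angles=60, n_det=64)
        st = sinogram_wavefront_truth(ph, g, n_orientations=180)
        assert not st.is_empty()
        radius = 0.04
        for (i, j) in st.elements:
            theta = g.angles[i]
            expected_p = cfg_center[0] * np.cos(theta) + cfg_center[1] * np.sin(theta)
            assert abs(g.offsets[j] - expected_p) <= radius + 2 * g.offset_spacing

    def test_inverse_mapping_lands_on_image_truth(self, phantom8):
        g = SinogramGeometry.parallel(64, n_angles=64, n_det=64)
        st = sinogram_wavefront_truth(phantom8, g, n_orientations=8)
        back = sinogram_set_to_image_set(st, g, 8)
        vis = visible_wavefront(phantom8.truth, g)
        assert wavefront_mse(back, vis, penalty_cap=100.0) < 8.0


class TestPeriodicEmbedding:
    def test_embedding_rows_repeat_with_flip(self):
        g = SinogramGeometry.parallel(64, angle_step_deg=6, n_det=64)
        data = np.arange(30 * 64, dtype=float).reshape(30, 64)
        square = embed_sinogram_periodic(Sinogram(data, g), 64)
        assert square.shape == (64, 64)
        assert np.array_equal(square[:30], data)
        assert np.array_equal(square[30], data[0, ::-1])

    def test_fold_maps_flipped_copy_back(self):
        g = SinogramGeometry.parallel(64, angle_step_deg=6, n_det=64)
        ext = DigitalWavefrontSet((64, 64), n_orientations=8)
        ext.add(5, 10, 3)       # direct copy
        ext.add(35, 10, 3)      # flipped copy of row 5
        folded = fold_extended_rows(ext, g)
        assert (5, 10) in folded.elements and 3 in folded.elements[(5, 10)]
        assert (5, 53) in folded.elements and 4 in folded.elements[(5, 53)]
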