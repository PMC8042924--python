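"""Segmentation, skeleton metrics, thickness and height measurement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon

from rufflekit.errors import (
    InsufficientDataError,
    InvalidParameterError,
    UnmeasurableProfileError,
)
from rufflekit.morphometry import (
    max_intensity_projection,
    measure_height_profile,
    measure_thickness,
    segment_ruffles,
    skeletonize_and_measure,
    thickness_along_path,
    longest_skeleton_path,
)

PX = 0.1  # um per pixel used throughout


def rotated_bar_mask(angle_deg, length_px=100, width_px=5, shape=(200, 200)):
    a = math.radians(angle_deg)
    d = np.array([math.cos(a), math.sin(a)])
    n = np.array([-d[1], d[0]])
    c0 = np.array([60.0, 50.0])
    corners = [
        c0 + n * width_px / 2,
        c0 - n * width_px / 2,
        c0 + d * length_px - n * width_px / 2,
        c0 + d * length_px + n * width_px / 2,
    ]
    rr, cc = polygon([p[0] for p in corners], [p[1] for p in corners], shape)
    mask = np.zeros(shape, dtype=np.int32)
    mask[rr, cc] = 1
    return mask


class TestMaxIntensityProjection:
    def test_single_plane_is_identity(self, rng):
        vol = rng.random((1, 8, 9))
        assert np.array_equal(max_intensity_projection(vol, 0), vol[0])

    def test_disjoint_bright_pixels_union(self):
        vol = np.zeros((2, 4, 4))
        vol[0, 1, 1] = 5.0
        vol[1, 2, 3] = 7.0
        mip = max_intensity_projection(vol, 0)
        assert mip[1, 1] == 5.0 and mip[2, 3] == 7.0

    @given(arrays(np.float64, (4, 6, 5), elements=st.floats(0, 100)))
    @settings(max_examples=25, deadline=None)
    def test_projection_dominates_every_plane(self, vol):
        mip = max_intensity_projection(vol, 0)
        for z in range(vol.shape[0]):
            assert np.all(mip >= vol[z])

    def test_axis_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            max_intensity_projection(np.zeros((2, 2, 2)), 3)


class TestSegmentation:
    def test_single_bright_bar_gives_one_label(self):
        img = np.zeros((60, 60))
        img[20:26, 10:50] = 100.0
        labels = segment_ruffles(img, pixel_size=PX)
        assert labels.max() == 1

    def test_blank_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="blank"):
            labels = segment_ruffles(np.full((32, 32), 7.0), pixel_size=PX)
        assert labels.max() == 0

    def test_five_ruffle_scene_yields_five_labels(self, default_scene):
        params, series, truth = default_scene
        dz = params.voxel_size[2]
        z0 = int(math.ceil((params.base_z + 0.3) / dz))
        mip = max_intensity_projection(series.intensities[0, 0][z0:], axis=0)
        labels = segment_ruffles(mip, pixel_size=params.voxel_size[0])
        assert labels.max() == len(truth.ruffles) == 5


class TestSkeletonMetrics:
    def test_straight_bar_length_and_single_branch(self):
        mask = np.zeros((60, 140), dtype=np.int32)
        mask[30:35, 20:120] = 1  # 100 px long, 5 px wide
        rec = skeletonize_and_measure(mask, PX).iloc[0]
        assert 9.9 <= rec.L_um <= 10.0
        assert rec.Ree_um == pytest.approx(rec.L_um, rel=0.02)
        assert rec.n_branches == 1

    def test_y_shape_has_three_branches(self):
        mask = np.zeros((100, 100), dtype=np.int32)
        mask[50:53, 10:60] = 1
        for i in range(30):
            mask[50 - i : 53 - i, 58 + i] = 1
            mask[50 + i : 53 + i, 58 + i] = 1
        rec = skeletonize_and_measure(mask, PX).iloc[0]
        assert rec.n_branches == 3

    def test_quarter_circle_arc_geometry(self):
        yy, xx = np.mgrid[0:120, 0:120]
        r = np.hypot((yy - 10) * PX, (xx - 10) * PX)
        ang = np.arctan2(yy - 10, xx - 10)
        mask = ((np.abs(r - 5.0) < 0.25) & (ang >= 0) & (ang <= math.pi / 2)).astype(
            np.int32
        )
        rec = skeletonize_and_measure(mask, PX).iloc[0]
        assert rec.L_um == pytest.approx(math.pi * 5.0 / 2.0, rel=0.05)
        assert rec.Ree_um == pytest.approx(5.0 * math.sqrt(2.0), rel=0.05)

    def test_contour_length_rotation_invariant(self):
        l0 = skeletonize_and_measure(rotated_bar_mask(0), PX).iloc[0].L_um
        l37 = skeletonize_and_measure(rotated_bar_mask(37), PX).iloc[0].L_um
        assert abs(l37 - l0) / l0 < 0.03

    def test_single_pixel_label_flagged_degenerate(self):
        mask = np.zeros((10, 10), dtype=np.int32)
        mask[5, 5] = 1
        rec = skeletonize_and_measure(mask, PX).iloc[0]
        assert rec.degenerate and rec.L_um == 0.0

    def test_ree_never_exceeds_contour_length(self, default_scene):
        params, series, truth = default_scene
        dz = params.voxel_size[2]
        z0 = int(math.ceil((params.base_z + 0.3) / dz))
        mip = max_intensity_projection(series.intensities[0, 0][z0:], axis=0)
        labels = segment_ruffles(mip, pixel_size=params.voxel_size[0])
        table = skeletonize_and_measure(labels, params.voxel_size[0])
        assert (table.Ree_um <= table.L_um + 1e-9).all()


class TestThickness:
    @staticmethod
    def slab_image(width_um, sigma_um=0.0, ny=80, nx=60, amplitude=500.0, offset=0.0):
        """Vertical slab of given width, optionally blurred; rows are the profile axis."""
        y = (np.arange(ny) + 0.5) * PX
        centre = ny * PX / 2
        profile = ((y >= centre - width_um / 2) & (y < centre + width_um / 2)).astype(
            float
        )
        img = np.tile(profile[:, None], (1, nx)) * amplitude
        if sigma_um > 0:
            img = gaussian_filter(img, (sigma_um / PX, 0))
        return img + offset, centre

    def test_unblurred_slab_measures_box_width(self):
        img, centre = self.slab_image(0.8)
        line = ((2.0, 30.0), (78.0, 30.0))
        assert measure_thickness(img, line, PX) == pytest.approx(0.8, abs=PX / 4)

    def test_blurred_slab_against_numeric_convolution_oracle(self):
        # oracle: FWHM of box(0.83) * gaussian(0.1) computed on a fine 1D grid
        width, sigma = 0.83, 0.1
        x = np.linspace(-5, 5, 20001)
        from scipy.stats import norm

        oracle_profile = norm.cdf((x + width / 2) / sigma) - norm.cdf(
            (x - width / 2) / sigma
        )
        above = oracle_profile >= oracle_profile.max() / 2
        oracle_fwhm = x[above][-1] - x[above][0]
        img, _ = self.slab_image(width, sigma_um=sigma)
        line = ((2.0, 30.0), (78.0, 30.0))
        measured_fwhm = measure_thickness(img, line, PX, psf_sigma=0.0)
        assert measured_fwhm == pytest.approx(oracle_fwhm, abs=0.03)
        corrected = measure_thickness(img, line, PX, psf_sigma=sigma)
        assert corrected == pytest.approx(width, rel=0.10)

    def test_point_like_structure_corrects_to_zero(self):
        img, _ = self.slab_image(0.1, sigma_um=0.1)
        line = ((2.0, 30.0), (78.0, 30.0))
        corrected = measure_thickness(img, line, PX, psf_sigma=0.1)
        assert corrected < 0.12

    def test_correction_is_monotone_and_clipped(self):
        img1, _ = self.slab_image(0.6, sigma_um=0.1)
        img2, _ = self.slab_image(0.9, sigma_um=0.1)
        line = ((2.0, 30.0), (78.0, 30.0))
        t1 = measure_thickness(img1, line, PX, psf_sigma=0.1)
        t2 = measure_thickness(img2, line, PX, psf_sigma=0.1)
        assert 0.0 <= t1 < t2

    def test_flat_profile_unmeasurable(self):
        img = np.full((40, 40), 5.0)
        with pytest.raises(UnmeasurableProfileError):
            measure_thickness(img, ((2.0, 20.0), (38.0, 20.0)), PX)

    def test_thickness_along_rendered_sheet(self, straight_sheet_scene):
        params, series, truth = straight_sheet_scene
        dz = params.voxel_size[2]
        vol = series.intensities[0, 0]
        plane = vol[int((params.base_z + 1.0) / dz)]
        z0 = int(math.ceil((params.base_z + 0.3) / dz))
        mip = max_intensity_projection(vol[z0:], axis=0)
        labels = segment_ruffles(mip, pixel_size=params.voxel_size[0])
        path, _, _ = longest_skeleton_path(labels == 1)
        values = thickness_along_path(
            plane, path, params.voxel_size[0], psf_sigma=params.psf_sigma[0]
        )
        assert len(values) >= 20
        assert np.mean(values) == pytest.approx(params.thickness, rel=0.10)


class TestHeightProfile:
    def test_constant_height_recovered_with_subpixel_precision(
        self, straight_sheet_scene
    ):
        params, series, truth = straight_sheet_scene
        vol = series.intensities[0, 0]
        dz = params.voxel_size[2]
        z0 = int(math.ceil((params.base_z + 0.3) / dz))
        mip = max_intensity_projection(vol[z0:], axis=0)
        labels = segment_ruffles(mip, pixel_size=params.voxel_size[0])
        hp = measure_height_profile(
            vol, labels == 1, base_z=params.base_z, voxel_size=params.voxel_size
        )
        assert hp.arclength[-1] >= 5.0  # several micrometres of ruffle
        assert hp.mean == pytest.approx(3.0, abs=0.15)
        # sub-pixel edge localization: spread well below one 0.1 um voxel
        assert hp.sd <= 0.11

    def test_linear_ramp_slope_recovered(self):
        from rufflekit.volume_synth import SceneParams, apply_psf_noise, render_sheet
        from rufflekit.wlc_sim import ChainConformation

        n = 201
        backbone = ChainConformation(
            points=np.column_stack((np.linspace(3, 13, n), np.full(n, 3.0))),
            step=0.05,
            _validate=False,
        )
        params = SceneParams(volume_shape=(160, 60, 60), psf_sigma=(0.1, 0.1))
        profile = np.array([[0.0, 1.0], [10.0, 4.0]])
        vol = render_sheet(backbone, profile, 0.83, 1.0, params)
        counts = apply_psf_noise(
            vol, params.psf_sigma, 500.0, 100.0, seed=3, voxel_size=params.voxel_size
        )
        mask = max_intensity_projection(counts[13:], 0) > 200
        hp = measure_height_profile(
            counts, mask, base_z=1.0, voxel_size=params.voxel_size
        )
        good = ~hp.flags & (hp.arclength > 1.0) & (hp.arclength < 9.0)
        slope = np.polyfit(hp.arclength[good], hp.height[good], 1)[0]
        assert abs(slope) == pytest.approx(0.3, rel=0.05)

    def test_zero_height_region_flagged(self):
        vol = np.zeros((20, 30, 30))
        mask = np.zeros((30, 30), dtype=bool)
        mask[15, 5:25] = True
        vol[2, :, :] = 300.0  # only signal below base_z
        hp = measure_height_profile(
            vol, mask, base_z=1.0, voxel_size=(0.1, 0.1, 0.1), threshold=200.0
        )
        assert np.all(hp.height[hp.flags] == 0.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(InsufficientDataError):
            measure_height_profile(
                np.zeros((10, 10, 10)), np.zeros((10, 10), dtype=bool), base_z=0.5
            )
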