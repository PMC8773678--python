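"""Intensity transformation, skull/CSF elimination and Gaussian smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctinfarct.preprocess import (ContractError, EmptyInputError,
                                  FWHM_PER_SIGMA, eliminate_skull_csf,
                                  fwhm_to_sigma_voxels,
                                  inverse_transform_intensity, smooth_gaussian,
                                  transform_intensity)
from ctinfarct.volume import BinaryMask, CTVolume


def _vol(values, unit="HU", voxel=(1.0, 1.0, 1.0)):
    arr = np.atleast_1d(np.asarray(values, dtype=np.float64)).reshape(-1, 1, 1)
    return CTVolume(data=arr, voxel_size_mm=voxel, space="native", unit=unit)


class TestIntensityTransform:
    @pytest.mark.parametrize("hu,expected", [
        (-1000, 0), (-100, 900),          # lower segment endpoints
        (-99, 911), (0, 2000), (25, 2275), (35, 2385), (100, 3100),  # middle
        (101, 3101), (1000, 4000),        # upper segment endpoints
    ])
    def test_piecewise_map_values(self, hu, expected):
        out = transform_intensity(_vol([hu]))
        assert out.unit == "transformed"
        assert out.data.ravel()[0] == expected

    @pytest.mark.parametrize("hu,expected", [(-1024, 0), (-2000, 0), (3071, 4000)])
    def test_out_of_range_inputs_clamped(self, hu, expected):
        assert transform_intensity(_vol([hu])).data.ravel()[0] == expected

    def test_inverse_recovers_every_integer_hu(self):
        hu = np.arange(-1000, 1001, dtype=np.float64)
        back = inverse_transform_intensity(transform_intensity(_vol(hu)))
        assert back.unit == "HU"
        np.testing.assert_array_equal(back.data.ravel(), hu)

    def test_strictly_monotone_on_integer_hu(self):
        out = transform_intensity(_vol(np.arange(-1000, 1001))).data.ravel()
        assert np.all(np.diff(out) > 0)

    @given(st.lists(st.floats(-1000, 1000, allow_nan=False), min_size=1, max_size=50))
    @settings(deadline=None, derandomize=True)
    def test_inverse_composition_identity_on_reals(self, values):
        back = inverse_transform_intensity(transform_intensity(_vol(values)))
        np.testing.assert_allclose(back.data.ravel(), values, atol=1e-9)

    @pytest.mark.parametrize("inverse_value,expected", [(0, -1000), (3100, 100), (2000, 0)])
    def test_inverse_endpoint_values(self, inverse_value, expected):
        out = inverse_transform_intensity(_vol([inverse_value], unit="transformed"))
        assert out.data.ravel()[0] == pytest.approx(expected)

    def test_unit_tag_contracts(self):
        with pytest.raises(ContractError):
            transform_intensity(_vol([0], unit="transformed"))
        with pytest.raises(ContractError):
            inverse_transform_intensity(_vol([0], unit="HU"))
        with pytest.raises(ContractError):
            inverse_transform_intensity(_vol([4001], unit="transformed"))


class TestEliminateSkullCsf:
    def test_degenerate_sd_zero_keeps_all_positive_voxels(self):
        data = np.zeros((4, 4, 4))
        data[1:3, 1:3, 1:3] = 2300.0
        out, seg = eliminate_skull_csf(CTVolume(data, unit="transformed"))
        assert seg.sd == 0.0
        assert seg.parenchyma_mask.count() == 8
        assert seg.ventricle_mask.count() == 0 and seg.skull_mask.count() == 0
        np.testing.assert_array_equal(out.data, data)

    def test_planted_outliers_removed_per_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        values = rng.normal(2300.0, 30.0, size=1000)
        values[:5] = 4000.0   # planted skull-like voxels
        values[5:10] = 500.0  # planted fluid-like voxels
        vol = CTVolume(values.reshape(10, 10, 10), unit="transformed")
        out, seg = eliminate_skull_csf(vol)
        # independent oracle: plain mean/sample-sd over the positive values
        mean, sd = values.mean(), values.std(ddof=1)
        assert seg.mean == pytest.approx(mean)
        assert seg.sd == pytest.approx(sd)
        flat_skull = seg.skull_mask.data.ravel()
        flat_vent = seg.ventricle_mask.data.ravel()
        assert flat_skull[:5].all() and flat_vent[5:10].all()
        np.testing.assert_array_equal(flat_skull, values > mean + 2 * sd)
        np.testing.assert_array_equal(flat_vent, values < mean - 2 * sd)

    def test_masks_partition_the_positive_voxels(self):
        rng = np.random.default_rng(8)
        data = rng.normal(2300, 400, size=(8, 8, 8))
        data[data < 0] = 0.0
        data[0, 0, :] = 0.0  # some background
        _, seg = eliminate_skull_csf(CTVolume(data, unit="transformed"))
        p, v, s = seg.parenchyma_mask.data, seg.ventricle_mask.data, seg.skull_mask.data
        assert not (p & v).any() and not (p & s).any() and not (v & s).any()
        np.testing.assert_array_equal(p | v | s, data > 0)

    def test_output_zero_exactly_off_parenchyma(self):
        rng = np.random.default_rng(9)
        data = np.abs(rng.normal(2300, 600, size=(6, 6, 6)))
        out, seg = eliminate_skull_csf(CTVolume(data, unit="transformed"))
        assert (np.asarray(out.data)[~seg.parenchyma_mask.data] == 0).all()
        np.testing.assert_array_equal(
            np.asarray(out.data)[seg.parenchyma_mask.data],
            data[seg.parenchyma_mask.data])

    def test_no_positive_voxels_is_an_error(self):
        with pytest.raises(EmptyInputError):
            eliminate_skull_csf(CTVolume(np.zeros((3, 3, 3)), unit="transformed"))

    def test_requires_transformed_unit(self):
        with pytest.raises(ContractError):
            eliminate_skull_csf(CTVolume(np.ones((3, 3, 3)), unit="HU"))


class TestSmoothing:
    def test_fwhm_zero_is_identity(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(7, 7, 7))
        out = smooth_gaussian(CTVolume(data, unit="transformed"), fwhm_mm=0.0)
        np.testing.assert_array_equal(np.asarray(out.data), data)

    def test_sigma_conversion_for_5mm_fwhm_on_1mm_voxels(self):
        sigma = fwhm_to_sigma_voxels(5.0, (1.0, 1.0, 1.0))
        assert sigma == pytest.approx((2.1233, 2.1233, 2.1233), abs=1e-4)
        assert FWHM_PER_SIGMA == pytest.approx(2.3548, abs=1e-4)

    def test_impulse_mass_conserved_and_half_maximum_at_half_fwhm(self):
        n = 33
        data = np.zeros((n, n, n))
        data[n // 2, n // 2, n // 2] = 1.0
        vol = CTVolume(data, voxel_size_mm=(1, 1, 1), unit="transformed")
        out = np.asarray(smooth_gaussian(vol, fwhm_mm=5.0,
                                         mask=np.ones(data.shape, bool)).data)
        assert out.sum() == pytest.approx(1.0, rel=1e-6)
        peak = out[n // 2, n // 2, n // 2]
        # linear interpolation at 2.5 voxels (= FWHM/2) from the peak
        half = 0.5 * (out[n // 2 + 2, n // 2, n // 2] + out[n // 2 + 3, n // 2, n // 2])
        assert half / peak == pytest.approx(0.5, rel=0.05)

    def test_constant_field_preserved_exactly_on_full_mask(self):
        data = np.full((10, 10, 10), 3.7)
        out = smooth_gaussian(CTVolume(data, unit="transformed"), fwhm_mm=5.0,
                              mask=np.ones(data.shape, bool))
        np.testing.assert_allclose(np.asarray(out.data), 3.7, rtol=1e-12)

    def test_masked_exterior_does_not_dilute_interior(self):
        # constant value on an interior block, zero outside: normalized
        # smoothing must keep the block at its value right up to its edge
        data = np.zeros((16, 16, 16))
        data[4:12, 4:12, 4:12] = 2275.0
        vol = CTVolume(data, unit="transformed")
        out = np.asarray(smooth_gaussian(vol, fwhm_mm=5.0).data)
        inside = data > 0
        np.testing.assert_allclose(out[inside], 2275.0, rtol=1e-9)
        assert (out[~inside] == 0).all()

    def test_translation_equivariance_away_from_boundary(self):
        rng = np.random.default_rng(4)
        base = np.zeros((40, 12, 12))
        base[8:16, 4:8, 4:8] = rng.normal(10, 2, size=(8, 4, 4))
        shifted = np.roll(base, 5, axis=0)
        full = np.ones(base.shape, bool)
        a = np.asarray(smooth_gaussian(CTVolume(base, unit="transformed"),
                                       5.0, mask=full).data)
        b = np.asarray(smooth_gaussian(CTVolume(shifted, unit="transformed"),
                                       5.0, mask=full).data)
        np.testing.assert_allclose(np.roll(a, 5, axis=0)[12:28], b[12:28], atol=1e-10)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ContractError):
            smooth_gaussian(CTVolume(np.ones((3, 3, 3)), unit="transformed"), -1.0)

    def test_anisotropic_voxels_scale_sigma_per_axis(self):
        sigma = fwhm_to_sigma_voxels(5.0, (0.5, 1.0, 5.0))
        assert sigma[0] == pytest.approx(2 * sigma[1])
        assert sigma[2] == pytest.approx(sigma[1] / 5)
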