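import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctdenoise.ct_io import (
    ConstantImageError,
    CTImage,
    DomainTag,
    PatchSamplingError,
    compute_roi_mask,
    denormalize,
    minmax_normalize,
    read_image,
    sample_patch,
    write_image,
)
from ctdenoise.dicom import read_dicom, write_dicom


def make_image(pixels, **kw):
    return CTImage(pixels=np.asarray(pixels, dtype=float), **kw)


class TestMinMaxNormalize:
    def test_three_point_example(self):
        img = make_image([[-2048.0, 0.0, 2048.0]])
        out = minmax_normalize(img)
        assert np.allclose(out.pixels, [[0.0, 0.5, 1.0]])
        assert out.normalized
        assert out.norm_min == -2048.0 and out.norm_max == 2048.0

    def test_unit_span_is_identity(self):
        pixels = np.array([[0.0, 0.25], [0.75, 1.0]])
        out = minmax_normalize(make_image(pixels))
        assert np.allclose(out.pixels, pixels)

    def test_output_spans_unit_interval(self, rng):
        out = minmax_normalize(make_image(rng.normal(size=(16, 16)) * 500))
        assert out.pixels.min() == 0.0
        assert out.pixels.max() == 1.0

    def test_constant_image_raises(self):
        with pytest.raises(ConstantImageError):
            minmax_normalize(make_image(np.full((4, 4), 7.0)))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-3000, 3000), min_size=4, max_size=16, unique=True))
    def test_monotone(self, values):
        pixels = np.asarray(values).reshape(1, -1)
        out = minmax_normalize(make_image(pixels))
        order_in = np.argsort(pixels[0], kind="stable")
        # weakly monotone: outputs sorted by input order are non-decreasing
        assert np.all(np.diff(out.pixels[0][order_in]) >= 0)


class TestDenormalize:
    def test_round_trip(self, rng):
        pixels = rng.normal(size=(32, 32)) * 1000
        img = make_image(pixels)
        back = denormalize(minmax_normalize(img))
        assert np.abs(back.pixels - pixels).max() < 1e-6

    def test_explicit_range(self):
        img = CTImage(pixels=np.array([[0.0, 0.5, 1.0]]), normalized=True)
        out = denormalize(img, -2048.0, 2048.0)
        assert np.allclose(out.pixels, [[-2048.0, 0.0, 2048.0]])

    def test_constant_zero_maps_to_min(self):
        img = CTImage(pixels=np.zeros((3, 3)), normalized=True)
        out = denormalize(img, -100.0, 100.0)
        assert np.all(out.pixels == -100.0)

    def test_degenerate_range_raises(self):
        img = CTImage(pixels=np.zeros((2, 2)), normalized=True)
        with pytest.raises(ValueError):
            denormalize(img, 5.0, 5.0)

    def test_unnormalized_input_raises(self):
        with pytest.raises(ValueError):
            denormalize(make_image(np.eye(3) * 100), 0.0, 1.0)


class TestRoiMask:
    def test_all_background(self):
        img = make_image(np.full((8, 8), -2048.0))
        assert not compute_roi_mask(img).any()

    def test_disk_area_within_two_percent(self, disk_image):
        img, r = disk_image
        mask = compute_roi_mask(img)
        assert abs(mask.sum() - np.pi * r ** 2) / (np.pi * r ** 2) < 0.02

    def test_infinite_tol_all_false(self, disk_image):
        img, _ = disk_image
        assert not compute_roi_mask(img, tol=np.inf).any()

    def test_normalized_input_rejected(self, disk_image):
        img, _ = disk_image
        with pytest.raises(ValueError):
            compute_roi_mask(minmax_normalize(img))


class TestSamplePatch:
    def test_all_foreground_first_attempt(self, rng):
        img = make_image(np.ones((64, 64)))
        mask = np.ones((64, 64), dtype=bool)
        patch = sample_patch(img, mask, size=16, min_foreground_frac=1.0,
                             rng=rng, max_attempts=1)
        assert patch.foreground_fraction == 1.0

    def test_unique_admissible_block(self):
        # only one 16x16 block of foreground; full coverage forces its corner
        img = make_image(np.zeros((64, 64)))
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:26, 30:46] = True
        for seed in range(5):
            patch = sample_patch(img, mask, size=16, min_foreground_frac=1.0,
                                 rng=np.random.default_rng(seed),
                                 max_attempts=20000)
            assert patch.origin == (10, 30)

    def test_all_background_raises(self, rng):
        img = make_image(np.zeros((32, 32)))
        mask = np.zeros((32, 32), dtype=bool)
        with pytest.raises(PatchSamplingError, match="foreground fraction"):
            sample_patch(img, mask, size=8, min_foreground_frac=0.5,
                         rng=rng, max_attempts=10)

    def test_seed_reproducible(self, disk_image):
        img, _ = disk_image
        mask = compute_roi_mask(img)
        p1 = sample_patch(img, mask, size=16, min_foreground_frac=0.5,
                          rng=np.random.default_rng(3))
        p2 = sample_patch(img, mask, size=16, min_foreground_frac=0.5,
                          rng=np.random.default_rng(3))
        assert p1.origin == p2.origin
        assert np.array_equal(p1.pixels, p2.pixels)

    def test_oversized_patch_rejected(self, disk_image):
        img, _ = disk_image
        with pytest.raises(ValueError):
            sample_patch(img, compute_roi_mask(img), size=128,
                         min_foreground_frac=0.0)


class TestFileIO:
    def test_npz_round_trip(self, tmp_path, rng):
        pixels = rng.normal(size=(32, 32)) * 1000
        img = make_image(pixels)
        path = tmp_path / "slice.npz"
        write_image(img, path)
        back = read_image(path)
        assert np.array_equal(back.pixels, pixels)

    def test_png_16bit_depth(self, tmp_path, rng):
        pixels = np.round(rng.uniform(0, 65535, size=(16, 16)))
        img = make_image(pixels)
        path = tmp_path / "slice.png"
        write_image(img, path, png_bits=16)
        back = read_image(path)
        # 16-bit quantization of the [min,max] range
        span = pixels.max() - pixels.min()
        rescaled = back.pixels / 65535.0 * span + pixels.min()
        assert np.abs(rescaled - pixels).max() <= span / 65535.0 + 1e-6

    def test_dicom_rescale_applied(self, tmp_path):
        # stored value 0 with slope 1, intercept -1024 reads back as -1024
        path = tmp_path / "slice.dcm"
        write_dicom(path, np.full((8, 8), -1024.0), slope=1.0, intercept=-1024.0)
        pixels, info = read_dicom(path)
        assert info["intercept"] == -1024.0
        assert np.all(pixels == -1024.0)

    def test_dicom_round_trip_hu(self, tmp_path, rng):
        pixels = np.round(rng.uniform(-2048, 3000, size=(16, 16)))
        path = tmp_path / "ct.dcm"
        write_dicom(path, pixels)
        back, _ = read_dicom(path)
        assert np.array_equal(back, pixels)

    def test_read_image_dicom(self, tmp_path):
        path = tmp_path / "ct.dcm"
        write_dicom(path, np.arange(64, dtype=float).reshape(8, 8) - 1000)
        img = read_image(path)
        assert img.pixels[0, 0] == -1000.0

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_image(tmp_path / "nope.npz")

    def test_color_png_rejected(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "rgb.png"
        iio.imwrite(path, np.zeros((4, 4, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="grayscale"):
            read_image(path)


class TestCTImageInvariants:
    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            make_image([[1.0, np.nan]])

    def test_normalized_range_enforced(self):
        with pytest.raises(ValueError):
            CTImage(pixels=np.array([[0.0, 1.5]]), normalized=True)

    def test_domain_tag_coerced_from_string(self):
        img = CTImage(pixels=np.zeros((2, 2)), domain_tag="generated")
        assert img.domain_tag is DomainTag.GENERATED
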