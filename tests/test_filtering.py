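import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cropheight import (
    convolve,
    directional_kernel,
    laplacian_kernel,
    modified_kernel,
)
from cropheight.filtering import kernel_to_text


def brute_force_correlate(img, k):
    """Nested-loop correlation with edge replication; the oracle."""
    H, W = img.shape
    kh, kw = k.shape
    ry, rx = kh // 2, kw // 2
    out = np.zeros((H, W))
    for y in range(H):
        for x in range(W):
            acc = 0.0
            for dy in range(-ry, ry + 1):
                for dx in range(-rx, rx + 1):
                    yy = min(max(y + dy, 0), H - 1)
                    xx = min(max(x + dx, 0), W - 1)
                    acc += img[yy, xx] * k[dy + ry, dx + rx]
            out[y, x] = acc
    return out


class TestLaplacian:
    @pytest.mark.parametrize("neighbors", [4, 8])
    def test_zero_sum_3x3(self, neighbors):
        k = laplacian_kernel(neighbors)
        assert k.shape == (3, 3)
        assert k.sum() == 0

    @pytest.mark.parametrize("neighbors", [0, 6, 5])
    def test_rejects_other_neighbor_counts(self, neighbors):
        with pytest.raises(ValueError):
            laplacian_kernel(neighbors)

    def test_constant_image_gives_zero(self):
        img = np.full((6, 6), 42.0)
        assert not convolve(img, laplacian_kernel(4)).any()

    def test_single_bright_pixel_matches_second_difference_loop(self):
        """Response equals the discrete d2/dx2 + d2/dy2 computed directly."""
        img = np.zeros((5, 5))
        img[2, 2] = 9.0
        got = convolve(img, laplacian_kernel(4))
        # brute-force second differences (interior; edges replicate)
        expected = np.zeros((5, 5))
        for y in range(1, 4):
            for x in range(1, 4):
                expected[y, x] = (
                    img[y, x - 1] + img[y, x + 1] + img[y - 1, x] + img[y + 1, x]
                    - 4 * img[y, x]
                )
        assert np.array_equal(got[1:4, 1:4], expected[1:4, 1:4])


class TestDirectional:
    def test_constant_along_x_gives_zero(self):
        img = np.tile(np.arange(6.0)[:, None], (1, 7))  # varies only in y
        assert not convolve(img, directional_kernel("x")).any()

    def test_step_edge_peaks_at_step_column(self):
        img = np.zeros((5, 8))
        img[:, 4:] = 10.0
        resp = np.abs(convolve(img, directional_kernel("x")))
        peak_cols = resp.argmax(axis=1)
        assert set(peak_cols) <= {3, 4}

    def test_y_kernel_is_transpose_of_x(self):
        assert np.array_equal(directional_kernel("y"), directional_kernel("x").T)

    def test_unknown_axis(self):
        with pytest.raises(ValueError):
            directional_kernel("z")


class TestModifiedKernel:
    @pytest.mark.parametrize("width,size", [(3, 7), (5, 11), (7, 15)])
    def test_side_length_is_twice_width_plus_one(self, width, size):
        assert modified_kernel(width).shape == (size, size)

    @pytest.mark.parametrize("width", [2, 4, 1, -3, 0])
    def test_rejects_even_or_small_widths(self, width):
        with pytest.raises(ValueError):
            modified_kernel(width)

    @pytest.mark.parametrize("width", [3, 5, 7, 9])
    def test_structure(self, width):
        k = modified_kernel(width)
        size = 2 * width + 1
        flank = (width + 1) // 2
        # every row sums to zero, every column is constant
        assert np.allclose(k.sum(axis=1), 0)
        assert (k == k[0]).all()
        # central `width` columns negative, flanks positive, mirror symmetric
        signs = np.sign(k[0])
        assert (signs[flank : flank + width] == -1).all()
        assert (signs[:flank] == 1).all() and (signs[-flank:] == 1).all()
        assert np.array_equal(k, k[:, ::-1])
        assert (signs < 0).sum() == width
        assert size - width == 2 * flank

    def test_dark_stripe_response_peaks_at_stripe_center(self):
        """A dark bar of width w on a bright field lights up at its centre."""
        w = 5
        img = np.full((40, 60), 200.0)
        center = 30
        img[:, center - w // 2 : center + w // 2 + 1] = -150.0
        resp = convolve(img, modified_kernel(w))
        interior = resp[w : -w or None]
        assert (interior.argmax(axis=1) == center).all()


class TestConvolve:
    def test_identity_kernel(self, rng):
        img = rng.normal(size=(6, 7))
        k = np.zeros((3, 3))
        k[1, 1] = 1.0
        assert np.allclose(convolve(img, k), img)

    def test_zero_sum_kernel_on_constant_image(self):
        img = np.full((8, 8), 3.5)
        assert not convolve(img, modified_kernel(3)).any()

    @given(
        img=arrays(np.float64, (4, 4), elements=st.floats(-10, 10)),
        k=arrays(np.float64, (3, 3), elements=st.floats(-2, 2)),
    )
    @settings(max_examples=25, derandomize=True)
    def test_matches_brute_force_oracle(self, img, k):
        assert np.allclose(convolve(img, k), brute_force_correlate(img, k))

    def test_kernel_larger_than_image(self):
        with pytest.raises(ValueError, match="larger than image"):
            convolve(np.zeros((5, 5)), modified_kernel(3))

    @given(
        img=arrays(np.float64, (8, 8), elements=st.floats(-50, 50)),
        c=st.floats(-100, 100),
    )
    @settings(max_examples=25, derandomize=True)
    def test_offset_invariance_of_zero_sum_kernels(self, img, c):
        """Adding a constant to every pixel leaves the response unchanged."""
        for k in (modified_kernel(3), laplacian_kernel(4)):
            assert np.allclose(convolve(img + c, k), convolve(img, k), atol=1e-8)


def test_kernel_text_round_trips():
    k = modified_kernel(3)
    parsed = np.array(
        [[float(v) for v in line.split()] for line in kernel_to_text(k).splitlines()]
    )
    assert np.array_equal(parsed, k)
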