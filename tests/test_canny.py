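import numpy as np
import pytest
from scipy import ndimage as ndi

from sfnet.canny import (
    DegenerateInputError,
    GradientField,
    ImprovedCannyEdgeDetector,
    MedianFilterSpec,
    ThresholdPair,
    adaptive_thresholds,
    count_isolated_edge_pixels,
    hysteresis,
    improved_canny,
    median_filter,
    non_max_suppression,
    sobel_gradients,
)
from sfnet.image_io import ValidationError
from sfnet.synthetic import PhantomSpec, generate_phantom


# ---------------------------------------------------------------- oracles


def median_oracle(img, m, n):
    """Per-pixel sort-based median with edge replication."""
    padded = np.pad(img, ((m // 2, m // 2), (n // 2, n // 2)), mode="edge")
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            window = np.sort(padded[i : i + m, j : j + n].ravel())
            out[i, j] = window[window.size // 2]
    return out


def nms_oracle(field):
    """Exhaustive per-pixel re-derivation: quantize theta to a sector, compare
    against the two neighbors along it with >=; borders suppressed."""
    mag, theta = field.magnitude, field.theta
    h, w = mag.shape
    keep = np.zeros((h, w), dtype=bool)
    offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]
    for i in range(1, h - 1):
        for j in range(1, w - 1):
            if mag[i, j] <= 0:
                continue
            ang = theta[i, j] % np.pi
            sector = int((ang + np.pi / 8) // (np.pi / 4)) % 4
            dy, dx = offsets[sector]
            if mag[i, j] >= mag[i + dy, j + dx] and mag[i, j] >= mag[i - dy, j - dx]:
                keep[i, j] = True
    return keep


def hysteresis_oracle(candidates, mag, low, high):
    """Flood fill from strong seeds through weak/strong candidates."""
    strong = candidates & (mag >= high)
    weak = candidates & (mag >= low)
    out = np.zeros_like(strong)
    stack = list(zip(*np.where(strong)))
    while stack:
        i, j = stack.pop()
        if out[i, j]:
            continue
        out[i, j] = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                y, x = i + di, j + dj
                if 0 <= y < out.shape[0] and 0 <= x < out.shape[1]:
                    if weak[y, x] and not out[y, x]:
                        stack.append((y, x))
    return out


# ---------------------------------------------------------------- median


class TestMedianFilter:
    def test_constant_unchanged(self):
        img = np.full((8, 8), 0.5)
        assert np.array_equal(median_filter(img), img)

    def test_salt_pixel_removed(self):
        img = np.zeros((7, 7))
        img[3, 3] = 1.0
        assert np.all(median_filter(img) == 0)

    def test_center_of_printed_patch(self):
        patch = np.array([[1, 2, 3], [4, 100, 6], [7, 8, 9]]) / 255.0
        out = median_filter(patch)
        assert out[1, 1] == pytest.approx(6 / 255.0)

    def test_matches_sort_oracle_random(self):
        rng = np.random.default_rng(11)
        img = rng.random((12, 10))
        assert np.allclose(median_filter(img), median_oracle(img, 3, 3))

    def test_never_leaves_input_range(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            img = rng.random((9, 9))
            out = median_filter(img)
            assert out.min() >= img.min() and out.max() <= img.max()

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            MedianFilterSpec(4, 3)


# ---------------------------------------------------------------- sobel


class TestSobelGradients:
    def test_constant_image_zero_gradients(self):
        f = sobel_gradients(np.full((6, 6), 0.3))
        assert np.all(f.gx == 0) and np.all(f.gy == 0) and np.all(f.magnitude == 0)

    def test_vertical_step_response(self):
        img = np.zeros((8, 8))
        img[:, 4:] = 1.0
        f = sobel_gradients(img)
        # at the two columns flanking the step, away from borders:
        # kernel [-1 0 1; -2 0 2; -1 0 1] on a 0->255 step sums to 1020
        assert np.all(np.abs(f.gx[2:6, 3:5]) == 1020)
        assert np.all(f.gy[2:6, 3:5] == 0)

    def test_horizontal_step_is_transpose(self):
        img = np.zeros((8, 8))
        img[4:, :] = 1.0
        f = sobel_gradients(img)
        assert np.all(np.abs(f.gy[3:5, 2:6]) == 1020)
        assert np.all(f.gx[3:5, 2:6] == 0)

    def test_magnitude_identity(self):
        rng = np.random.default_rng(5)
        f = sobel_gradients(rng.random((10, 10)))
        assert np.allclose(f.magnitude, np.hypot(f.gx, f.gy))
        assert np.all(f.magnitude >= 0)

    def test_too_small_rejected(self):
        with pytest.raises(ValidationError):
            sobel_gradients(np.zeros((2, 5)))


# ---------------------------------------------------------------- thresholds


class TestAdaptiveThresholds:
    def test_flat_magnitudes_degenerate(self):
        with pytest.raises(DegenerateInputError):
            adaptive_thresholds(np.zeros((8, 8)))
        with pytest.raises(DegenerateInputError):
            adaptive_thresholds(np.full((8, 8), 3.0))

    def test_bimodal_threshold_between_modes(self):
        rng = np.random.default_rng(21)
        background = rng.normal(20, 3, size=4000)
        edges = rng.normal(200, 10, size=500)
        mags = np.abs(np.concatenate([background, edges]))
        t = adaptive_thresholds(mags)
        assert 20 < t.high < 200
        assert t.low == pytest.approx(0.5 * t.high)

    def test_scaling_property(self):
        rng = np.random.default_rng(22)
        mags = np.abs(np.concatenate([rng.normal(10, 2, 2000), rng.normal(90, 5, 300)]))
        t1 = adaptive_thresholds(mags)
        for c in (2.0, 7.5, 0.25):
            t2 = adaptive_thresholds(c * mags)
            assert t2.high == pytest.approx(c * t1.high, rel=1e-9)
            assert t2.low == pytest.approx(c * t1.low, rel=1e-9)

    def test_invalid_pair_rejected(self):
        with pytest.raises(ValidationError):
            ThresholdPair(low=2.0, high=1.0)


# ---------------------------------------------------------------- NMS


class TestNonMaxSuppression:
    def test_matches_bruteforce_oracle_on_random_fields(self):
        rng = np.random.default_rng(33)
        for _ in range(5):
            gx = rng.normal(size=(16, 16)) * 100
            gy = rng.normal(size=(16, 16)) * 100
            field = GradientField(gx=gx, gy=gy, magnitude=np.hypot(gx, gy),
                                  theta=np.arctan2(gy, gx))
            assert np.array_equal(non_max_suppression(field), nms_oracle(field))

    def test_ideal_ridge_survives(self):
        # one-pixel-wide vertical ridge: gradient points across it (x)
        mag = np.zeros((10, 10))
        mag[:, 5] = 100.0
        field = GradientField(gx=mag.copy(), gy=np.zeros_like(mag),
                              magnitude=mag, theta=np.zeros_like(mag))
        keep = non_max_suppression(field)
        assert np.all(keep[1:-1, 5])
        assert not keep[:, :5].any() and not keep[:, 6:].any()

    def test_constant_plateau_kept_by_tie_rule(self):
        mag = np.full((8, 8), 5.0)
        field = GradientField(gx=mag.copy(), gy=np.zeros_like(mag),
                              magnitude=mag, theta=np.zeros_like(mag))
        keep = non_max_suppression(field)
        assert np.all(keep[1:-1, 1:-1])  # interior plateau survives (>= ties)
        assert not keep[0].any() and not keep[-1].any()  # borders suppressed


# ---------------------------------------------------------------- hysteresis


class TestHysteresis:
    def test_no_strong_pixels_empty(self):
        cand = np.ones((6, 6), bool)
        mag = np.full((6, 6), 1.0)
        out = hysteresis(cand, mag, ThresholdPair(low=0.5, high=2.0))
        assert not out.any()

    def test_isolated_strong_pixel_survives_alone(self):
        cand = np.zeros((6, 6), bool)
        mag = np.zeros((6, 6))
        cand[3, 3] = True
        mag[3, 3] = 10.0
        out = hysteresis(cand, mag, ThresholdPair(low=2.0, high=5.0))
        assert out.sum() == 1 and out[3, 3]

    def test_weak_chain_needs_strong_contact(self):
        cand = np.zeros((8, 8), bool)
        mag = np.zeros((8, 8))
        # weak 5-pixel chain touching one strong pixel
        for j in range(1, 6):
            cand[2, j] = True
            mag[2, j] = 3.0
        cand[2, 6] = True
        mag[2, 6] = 10.0
        # identical weak chain with no strong contact
        for j in range(1, 6):
            cand[5, j] = True
            mag[5, j] = 3.0
        out = hysteresis(cand, mag, ThresholdPair(low=2.0, high=5.0))
        assert out[2, 1:7].all() and out.sum() == 6
        assert not out[5].any()

    def test_matches_floodfill_oracle_random(self):
        rng = np.random.default_rng(44)
        for _ in range(5):
            cand = rng.random((16, 16)) < 0.4
            mag = rng.random((16, 16)) * 10
            t = ThresholdPair(low=3.0, high=7.0)
            assert np.array_equal(
                hysteresis(cand, mag, t), hysteresis_oracle(cand, mag, 3.0, 7.0)
            )

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            ThresholdPair(low=5.0, high=5.0)


# ---------------------------------------------------------------- pipeline


class TestImprovedCanny:
    def test_flat_image_empty_map(self):
        assert not improved_canny(np.full((32, 32), 0.4)).any()

    def test_rectangle_edges_trace_the_boundary(self, rect_image):
        em = improved_canny(rect_image)
        # true boundary ring of the 24x32 rectangle, dilated by 1 px; the
        # 4-sector NMS breaks the ring at sharp corners, so the honest
        # contract is: few boundary-hugging segments and nothing elsewhere
        boundary = np.zeros_like(em)
        boundary[20:44, 16:48] = True
        boundary &= ~ndi.binary_erosion(boundary, iterations=2)
        band = ndi.binary_dilation(boundary, iterations=1)
        assert em.sum() > 80
        assert np.all(band[em])  # every edge pixel on the boundary band
        labels, n = ndi.label(em, structure=np.ones((3, 3), int))
        assert 1 <= n <= 4

    def test_deterministic(self, rect_image):
        assert np.array_equal(improved_canny(rect_image), improved_canny(rect_image))

    def test_edge_subset_chain(self, rect_image):
        from sfnet.canny import median_filter as mf

        sm = mf(rect_image)
        field = sobel_gradients(sm)
        cand = non_max_suppression(field)
        em = improved_canny(rect_image)
        assert np.all(cand[em])  # EdgeMap subset of NMS candidates
        assert np.all(field.magnitude[cand] > 0)  # candidates have G1 > 0

    def test_fracture_gap_adds_edges_in_gap_band(self, phantom_pair):
        from sfnet.synthetic import gap_mask

        frac, healthy = phantom_pair
        spec = PhantomSpec(side=96, fracture=True, seed=7, noise_sigma=0.02)
        ef, eh = improved_canny(frac), improved_canny(healthy)
        band = gap_mask(spec)
        assert ef[band].sum() > eh[band].sum()

    def test_transformer_batches_and_params(self, rect_image):
        det = ImprovedCannyEdgeDetector(window=3, ratio=0.5)
        out = det.fit_transform(np.stack([rect_image, rect_image]))
        assert out.shape == (2, 64, 64) and out.dtype == bool
        assert det.get_params() == {"window": 3, "ratio": 0.5, "n_bins": 256}
        assert det.set_params(ratio=0.4).ratio == 0.4


class TestMedianVsGaussianRobustness:
    def test_median_prefilter_fewer_isolated_points(self):
        from sfnet.synthetic import add_salt_pepper

        total_median = total_gauss = 0
        for seed in range(5):
            img, _ = generate_phantom(
                PhantomSpec(side=96, fracture=True, seed=seed, noise_sigma=0.02)
            )
            noisy = add_salt_pepper(img, 0.02, seed=100 + seed)
            total_median += count_isolated_edge_pixels(improved_canny(noisy))
            total_gauss += count_isolated_edge_pixels(
                improved_canny(noisy, prefilter="gaussian")
            )
        assert total_median < total_gauss
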