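import numpy as np
import pytest
from scipy import ndimage

from isletquant import ContourSet, SectionImage, auto_threshold, binarize, \
    build_tissue_mask, subtract_background
from isletquant.preprocess import ThresholdSpec, load_thresholds, save_thresholds


def square(x0, y0, x1, y1):
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


def section_1000():
    ch = np.zeros((1000, 1000), dtype=np.float32)
    return SectionImage({"nuclei": ch, "insulin": ch.copy()}, pixel_size=1.0)


def ball_opening_background(img: np.ndarray, radius: int) -> np.ndarray:
    """Independent oracle: grayscale opening with a ball structuring element,
    computed by explicit min/max loops (out-of-frame treated as +/- inf)."""
    h, w = img.shape
    offsets = [(dy, dx, np.sqrt(radius**2 - dx**2 - dy**2))
               for dy in range(-radius, radius + 1)
               for dx in range(-radius, radius + 1)
               if dx**2 + dy**2 <= radius**2]
    eroded = np.empty_like(img, dtype=float)
    for y in range(h):
        for x in range(w):
            eroded[y, x] = min(
                img[y + dy, x + dx] - hgt
                for dy, dx, hgt in offsets
                if 0 <= y + dy < h and 0 <= x + dx < w)
    bg = np.empty_like(eroded)
    for y in range(h):
        for x in range(w):
            bg[y, x] = max(
                eroded[y + dy, x + dx] + hgt
                for dy, dx, hgt in offsets
                if 0 <= y + dy < h and 0 <= x + dx < w)
    return bg


class TestBackgroundSubtraction:
    def test_constant_image_goes_to_zero(self):
        out = subtract_background(np.full((40, 40), 37.0), radius=5)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_bright_pixel_retained(self):
        img = np.zeros((64, 64))
        img[32, 32] = 100.0
        out = subtract_background(img, radius=15)
        assert out[32, 32] == pytest.approx(100.0, rel=0.01)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.ones((8, 8)), radius=0)

    def test_matches_ball_opening_oracle(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 50, (26, 30)) + 30 * np.linspace(0, 1, 30)[None, :]
        radius = 4
        expected = img - ball_opening_background(img, radius)
        out = subtract_background(img, radius)
        np.testing.assert_allclose(out, np.clip(expected, 0, None), atol=1e-9)

    def test_bounds_invariant(self):
        rng = np.random.default_rng(8)
        for radius in (3, 20, 50):  # 20 and 50 exercise the downscaled path
            img = rng.uniform(0, 200, (120, 90))
            out = subtract_background(img, radius)
            assert (out >= 0).all()
            assert (out <= img + 1e-9).all()


class TestTissueMask:
    def test_full_frame_outline(self):
        section = section_1000()
        contours = ContourSet(pancreas_outline=[square(0, 0, 1000, 1000)])
        tm = build_tissue_mask(section, contours)
        assert tm.pancreas_area == pytest.approx(1_000_000)
        assert tm.applied_exclusions == []

    def test_small_exclusion_ignored(self):
        # 400 px = 0.04% of the outline: at or below the >0.05% rule, kept in tissue
        section = section_1000()
        contours = ContourSet(
            pancreas_outline=[square(0, 0, 1000, 1000)],
            exclusions=[square(100, 100, 120, 120)],  # 400 px
        )
        tm = build_tissue_mask(section, contours)
        assert tm.pancreas_area == pytest.approx(1_000_000)
        assert tm.applied_exclusions == []
        assert tm.excluded_area == 0.0

    def test_boundary_exclusion_exactly_at_threshold_ignored(self):
        # exactly 0.05% (500 px) is not "> 0.05%": ignored
        section = section_1000()
        contours = ContourSet(
            pancreas_outline=[square(0, 0, 1000, 1000)],
            exclusions=[square(100, 100, 125, 120)],  # 25 x 20 = 500 px
        )
        tm = build_tissue_mask(section, contours)
        assert tm.applied_exclusions == []

    def test_large_exclusion_applied(self):
        section = section_1000()
        contours = ContourSet(
            pancreas_outline=[square(0, 0, 1000, 1000)],
            exclusions=[square(200, 200, 300, 300)],  # 10000 px = 1%
        )
        tm = build_tissue_mask(section, contours)
        assert tm.pancreas_area == pytest.approx(990_000)
        assert tm.applied_exclusions == [0]
        assert tm.excluded_area == pytest.approx(10_000)

    def test_area_monotone_in_applied_exclusions(self):
        section = section_1000()
        exclusions = [square(100 * i, 100, 100 * i + 50, 200) for i in range(1, 6)]
        areas = []
        for k in range(len(exclusions) + 1):
            contours = ContourSet(pancreas_outline=[square(0, 0, 1000, 1000)],
                                  exclusions=exclusions[:k])
            areas.append(build_tissue_mask(section, contours).pancreas_area)
        assert all(a1 >= a2 for a1, a2 in zip(areas, areas[1:]))

    def test_outline_outside_frame_rejected(self):
        section = section_1000()
        contours = ContourSet(pancreas_outline=[square(2000, 2000, 2100, 2100)])
        with pytest.raises(ValueError, match="zero pixels"):
            build_tissue_mask(section, contours)


def brute_force_otsu(values: np.ndarray) -> float:
    """Exhaustive between-class-variance maximization over all candidates."""
    candidates = np.unique(values)
    best_t, best_var = candidates[0], -1.0
    for t in candidates[1:]:
        lo, hi = values[values < t], values[values >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        var = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestAutoThreshold:
    def test_bimodal_threshold_between_modes(self):
        img = np.concatenate([np.full(900, 10.0), np.full(100, 200.0)])
        thr = auto_threshold(img.reshape(20, 50))
        assert 10 < thr.value < 200
        assert thr.provenance == "automatic"

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError):
            auto_threshold(np.full((10, 10), 7.0))

    def test_two_gaussian_mixture(self):
        rng = np.random.default_rng(2)
        img = np.concatenate([rng.normal(20, 10, 5000), rng.normal(180, 10, 5000)])
        thr = auto_threshold(img.reshape(100, 100))
        assert 50 < thr.value < 150

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_on_discrete_images(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 40, (40, 40)).astype(np.uint8)
        thr = auto_threshold(img)
        brute = brute_force_otsu(img.ravel())
        # same partition: every pixel classified identically (the library
        # threshold sits strictly between the classes, the brute-force one is
        # the lowest upper-class value)
        np.testing.assert_array_equal(img > thr.value, img >= brute)


class TestBinarize:
    def make_tissue(self, shape=(20, 20)):
        section = SectionImage({"nuclei": np.zeros(shape),
                                "insulin": np.zeros(shape)}, pixel_size=1.0)
        contours = ContourSet(pancreas_outline=[square(0, 0, shape[1], shape[0])])
        return build_tissue_mask(section, contours)

    def test_threshold_below_min_gives_tissue_mask(self):
        tissue = self.make_tissue()
        img = np.full((20, 20), 50.0)
        mask = binarize(img, ThresholdSpec(10.0), tissue)
        np.testing.assert_array_equal(mask.data, tissue.mask.data)

    def test_threshold_above_max_gives_empty(self):
        tissue = self.make_tissue()
        mask = binarize(np.full((20, 20), 50.0), ThresholdSpec(60.0), tissue)
        assert mask.count() == 0

    def test_checkerboard_half_positive(self):
        tissue = self.make_tissue()
        img = np.indices((20, 20)).sum(axis=0) % 2 * 255.0
        mask = binarize(img, ThresholdSpec(128.0), tissue)
        assert mask.count() == 200

    def test_threshold_is_inclusive(self):
        tissue = self.make_tissue()
        mask = binarize(np.full((20, 20), 128.0), ThresholdSpec(128.0), tissue)
        assert mask.count() == 400

    def test_outside_tissue_always_zero(self):
        section = SectionImage({"nuclei": np.zeros((20, 20)),
                                "insulin": np.zeros((20, 20))}, pixel_size=1.0)
        contours = ContourSet(pancreas_outline=[square(0, 0, 10, 20)])
        tissue = build_tissue_mask(section, contours)
        mask = binarize(np.full((20, 20), 9.0), ThresholdSpec(1.0), tissue)
        assert mask.data[:, 10:].sum() == 0

    def test_shape_mismatch_rejected(self):
        tissue = self.make_tissue()
        with pytest.raises(ValueError, match="mismatch"):
            binarize(np.zeros((5, 5)), ThresholdSpec(1.0), tissue)


def test_threshold_file_round_trip(tmp_path):
    specs = {"insulin": ThresholdSpec(120.5, "manual"),
             "nuclei": ThresholdSpec(80.0, "automatic")}
    path = tmp_path / "thresholds.txt"
    save_thresholds(specs, path)
    back = load_thresholds(path)
    assert back["insulin"].value == 120.5
    assert back["nuclei"].provenance == "automatic"
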