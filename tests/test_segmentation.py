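"""Soft-target encoding, normalization and watershed post-processing."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from paraloc import segmentation as seg


def _disk_mask(shape, center, radius, label=1):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = np.zeros(shape, dtype=np.uint16)
    mask[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2] = label
    return mask


class TestEncodeTarget:
    def test_background_is_exactly_zero(self):
        mask = _disk_mask((80, 80), (40, 40), 15)
        target = seg.encode_target(mask)
        assert (target[mask == 0] == 0).all()

    def test_deep_interior_saturates_at_one(self):
        # pixel >= 20 px inside a large object: 0.8 + 0.2 * 1.0 = 1.0
        mask = _disk_mask((100, 100), (50, 50), 35)
        target = seg.encode_target(mask, clip=20.0, w=0.8)
        assert target[50, 50] == pytest.approx(1.0)

    def test_eroded_border_sits_near_w(self):
        # border pixels of the eroded stencil: 0.8 + 0.2 * (1/20) = 0.81
        mask = _disk_mask((100, 100), (50, 50), 30)
        target = seg.encode_target(mask, clip=20.0, w=0.8)
        eroded = ndi.binary_erosion(mask > 0, structure=seg.CROSS)
        border = eroded & ~ndi.binary_erosion(eroded, structure=seg.CROSS)
        vals = target[border]
        assert np.all(vals >= 0.8) and np.all(vals <= 0.82)

    def test_foreground_floor_and_monotone_toward_center(self):
        mask = _disk_mask((100, 100), (50, 50), 30)
        target = seg.encode_target(mask)
        fg = target[target > 0]
        assert fg.min() >= 0.8
        # values along a ray increase toward the center
        ray = target[50, 22:51]
        assert np.all(np.diff(ray[ray > 0]) >= 0)

    def test_touching_instances_separated_by_zeros(self):
        mask = np.zeros((40, 40), dtype=np.uint16)
        mask[10:30, 5:20] = 1
        mask[10:30, 20:35] = 2
        target = seg.encode_target(mask)
        # erosion of each stencil leaves a 2-px zero gap at the shared border
        assert (target[:, 19:21] == 0).all()

    def test_empty_mask_gives_all_zero_target(self):
        assert seg.encode_target(np.zeros((10, 10), dtype=np.uint16)).sum() == 0

    def test_parameter_validation(self):
        mask = _disk_mask((20, 20), (10, 10), 5)
        with pytest.raises(ValueError):
            seg.encode_target(mask, clip=0)
        with pytest.raises(ValueError):
            seg.encode_target(mask, w=1.0)


class TestBackground:
    def test_median_of_identical_images_is_that_image(self):
        rng = np.random.default_rng(0)
        im = rng.integers(0, 1000, (30, 30)).astype(float)
        bg = seg.estimate_background([im, im, im])
        assert np.array_equal(bg, im)
        assert seg.subtract_background(im, bg).sum() == 0

    def test_per_pixel_median_by_hand(self):
        ims = [np.full((4, 4), v, dtype=float) for v in (1, 2, 9)]
        assert (seg.estimate_background(ims) == 2).all()

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError):
            seg.estimate_background([])

    def test_shape_mismatch_raises(self):
        with pytest.raises(seg.ShapeMismatchError):
            seg.estimate_background([np.zeros((4, 4)), np.zeros((5, 5))])

    def test_subtraction_clips_at_zero(self):
        im = np.full((3, 3), 5.0)
        bg = np.full((3, 3), 7.0)
        assert (seg.subtract_background(im, bg) == 0).all()


class TestNormalizeImage:
    def test_standardization_identity(self):
        rng = np.random.default_rng(1)
        im = rng.gamma(2.0, 100.0, (64, 64))
        norm = seg.normalize_image(im)
        assert abs(norm.pixels.mean()) < 1e-6
        assert abs(norm.pixels.std() - 1.0) < 1e-6

    def test_log_base_e(self):
        # pixel of value e - 1 maps to exactly 1 before standardization
        im = np.zeros((10, 10))
        im[0, 0] = np.e - 1.0
        norm = seg.normalize_image(im)
        assert norm.pixels[0, 0] * norm.sigma + norm.mu == pytest.approx(1.0)

    def test_constant_image_flagged(self):
        with pytest.raises(seg.ConstantImageError):
            seg.normalize_image(np.zeros((8, 8)))

    def test_reflection_padding_roundtrip(self):
        im = np.arange(100 * 100, dtype=float).reshape(100, 100)
        padded, pad = seg.pad_to_divisible(im, 32)
        assert padded.shape == (128, 128)
        assert np.array_equal(seg.crop_padding(padded, pad), im)


def _bump(shape, center, radius, peak):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(rr - center[0], cc - center[1])
    return np.clip(peak * (1 - (d / radius) ** 2), 0, None)


class TestInstancesFromProbability:
    def test_uniform_zero_map_yields_no_instances(self):
        assert seg.instances_from_probability(np.zeros((64, 64))).max() == 0

    def test_two_peaks_with_valley_split_into_two(self):
        # two bumps peaking at 0.95 joined across a ~0.6 valley must give
        # exactly two instances (flood-fill of the 0.8 seeds finds two)
        prob = np.maximum(
            _bump((100, 140), (50, 45), 42, 0.95), _bump((100, 140), (50, 95), 42, 0.95)
        )
        assert 0.5 < prob[50, 70] < 0.8  # valley between the peaks
        mask = seg.instances_from_probability(prob)
        assert mask.max() == 2
        n_seeds = ndi.label(prob >= 0.8)[1]  # independent component count oracle
        assert mask.max() == n_seeds

    def test_small_and_large_objects_removed(self):
        prob = np.zeros((200, 200))
        prob[10:20, 10:30] = 1.0  # area 200 < 256 -> removed
        prob[50:150, 50:150] = 1.0  # area 10000 > 8192 -> removed
        assert seg.instances_from_probability(prob).max() == 0

    def test_areas_within_filter_bounds(self):
        rng = np.random.default_rng(2)
        prob = np.zeros((300, 300))
        for c in [(50, 50), (150, 150), (250, 80)]:
            prob = np.maximum(prob, _bump((300, 300), c, rng.uniform(18, 40), 1.0))
        mask = seg.instances_from_probability(prob)
        areas = np.bincount(mask.ravel())[1:]
        assert all(256 <= a <= 8192 for a in areas if a > 0)

    def test_labels_partition_and_are_consecutive(self):
        prob = np.maximum(
            _bump((100, 140), (50, 45), 40, 0.95), _bump((100, 140), (50, 95), 40, 0.95)
        )
        mask = seg.instances_from_probability(prob)
        labels = np.unique(mask)[1:]
        assert np.array_equal(labels, np.arange(1, len(labels) + 1))
        # instances are disjoint subsets of the boundary-thresholded foreground
        assert ((mask > 0) <= (prob >= 0.5)).all()

    def test_threshold_order_validated(self):
        with pytest.raises(ValueError):
            seg.instances_from_probability(np.zeros((10, 10)), seed_thr=0.4, boundary_thr=0.5)


@pytest.fixture(scope="module")
def fixture_screen():
    from paraloc import synthetic as syn

    design = syn.ScreenDesign(
        pairs=(("T1", "T2"),),
        n_replicates=1,
        n_fields=4,
        cells_per_field=(40, 55),
        image_size=(384, 384),
        clump_fraction=0.15,
    )
    truth = syn.default_truth(design, 0)
    images, _ = syn.generate_screen(design, truth, seed=21)
    bg = seg.estimate_background([im.pixels for im in images])
    norms = [seg.normalize_image(seg.subtract_background(im.pixels, bg)) for im in images]
    return images, norms


class TestTrainedSegmenter:
    def test_probability_map_contract(self, fixture_screen):
        images, norms = fixture_screen
        model = seg.train_segmenter(norms[:3], [seg.encode_target(im.mask) for im in images[:3]])
        prob = model.predict_proba_map(norms[3])
        assert prob.shape == norms[3].pixels.shape
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_heldout_pixel_auc_above_095(self, fixture_screen):
        from sklearn.metrics import roc_auc_score

        images, norms = fixture_screen
        model = seg.train_segmenter(norms[:3], [seg.encode_target(im.mask) for im in images[:3]])
        prob = model.predict_proba_map(norms[3])
        truth_bin = (images[3].mask > 0).ravel()
        assert roc_auc_score(truth_bin, prob.ravel()) > 0.95

    def test_end_to_end_count_recovery_within_10pct(self, fixture_screen):
        images, norms = fixture_screen
        model = seg.train_segmenter(norms[:3], [seg.encode_target(im.mask) for im in images[:3]])
        for im, norm in zip(images[2:], norms[2:]):
            recovered = seg.segment_image(norm, model).max()
            truth_n = im.mask.max()
            assert abs(int(recovered) - int(truth_n)) <= 0.1 * truth_n

    def test_unpaired_data_rejected(self, fixture_screen):
        images, norms = fixture_screen
        with pytest.raises(ValueError):
            seg.train_segmenter(norms[:2], [seg.encode_target(images[0].mask)])

    def test_nonsquare_input_shape_preserved(self, fixture_screen):
        images, norms = fixture_screen
        model = seg.train_segmenter(norms[:2], [seg.encode_target(im.mask) for im in images[:2]])
        crop = seg.NormalizedImage(norms[3].pixels[:100, :100], norms[3].mu, norms[3].sigma)
        assert model.predict_proba_map(crop).shape == (100, 100)

    def test_untrained_fallback_contract(self, fixture_screen):
        _, norms = fixture_screen
        prob = seg.IntensitySegmenter().predict_proba_map(norms[0])
        assert prob.shape == norms[0].pixels.shape
        assert 0.0 <= prob.min() and prob.max() <= 1.0
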