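"""The synthetic cohort generator: determinism, geometry and class cues."""

import numpy as np
import pytest

from lesioncam import synthdata
from lesioncam.synthdata import (CLASSES, LabeledImage, LesionParams,
                                 generate_cohort, generate_lesion_mask,
                                 render_image, write_cohort)


class TestLesionMask:
    def test_same_seed_bitwise_identical(self):
        p = LesionParams()
        m1 = generate_lesion_mask(64, p, np.random.default_rng(9))
        m2 = generate_lesion_mask(64, p, np.random.default_rng(9))
        assert np.array_equal(m1, m2)

    def test_zero_irregularity_is_exact_ellipse(self):
        p = LesionParams(boundary_irregularity=0.0)
        rng = np.random.default_rng(4)
        mask = generate_lesion_mask(64, p, rng)
        # recover the ellipse from the foreground: it must be convex and
        # match the analytic ellipse equation fitted from its extents
        ys, xs = np.nonzero(mask)
        cy, cx = ys.mean(), xs.mean()
        # second moments of a filled ellipse give the semi-axes
        ry = 2 * np.sqrt(((ys - cy) ** 2).mean())
        rx = 2 * np.sqrt(((xs - cx) ** 2).mean())
        yy, xx = np.mgrid[0:64, 0:64]
        inside = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1
        # discretisation: allow mismatch only on a thin boundary band
        assert (mask ^ inside).sum() <= 0.15 * mask.sum()

    def test_area_bounds_over_many_draws(self):
        p = LesionParams(base_radius_fraction=0.15)
        rng = np.random.default_rng(0)
        fracs = [generate_lesion_mask(64, p, rng).mean() for _ in range(1000)]
        assert min(fracs) >= 0.01 and max(fracs) <= 0.40

    def test_single_connected_component(self):
        from skimage import measure
        p = LesionParams(boundary_irregularity=0.5)
        rng = np.random.default_rng(1)
        for _ in range(50):
            mask = generate_lesion_mask(48, p, rng)
            assert measure.label(mask, connectivity=2).max() == 1

    def test_parameter_validation(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            generate_lesion_mask(64, LesionParams(base_radius_fraction=0.7), rng)
        with pytest.raises(ValueError):
            generate_lesion_mask(8, LesionParams(), rng)


class TestRenderImage:
    def test_nonegc_has_no_mask(self):
        im = render_image("nonEGC", None, LesionParams(),
                          np.random.default_rng(0), image_side=32)
        assert im.lesion_mask is None
        assert im.class_label == "nonEGC"

    def test_invisible_lesion_when_all_cues_zero(self):
        p = LesionParams(texture_contrast=0.0, rim_strength=0.0, color_shift=0.0)
        diffs = []
        rng = np.random.default_rng(3)
        for _ in range(30):
            mask = generate_lesion_mask(64, p, rng)
            im = render_image("T1a", mask, p, rng)
            diffs.append(im.pixels[mask].mean() - im.pixels[~mask].mean())
        # no cue: in/out means agree within sampling noise
        assert abs(np.mean(diffs)) < 0.01

    def test_t1b_rim_brighter_than_interior(self):
        from scipy.ndimage import binary_dilation, binary_erosion
        p = LesionParams(rim_strength=0.5, texture_contrast=0.0, color_shift=0.0)
        rng = np.random.default_rng(5)
        mask = generate_lesion_mask(64, p, rng)
        im = render_image("T1b", mask, p, rng)
        interior = binary_erosion(mask, iterations=3)
        boundary = binary_dilation(mask) & ~binary_erosion(mask)
        assert im.pixels[boundary].mean() > im.pixels[interior].mean()

    def test_mask_class_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        mask = generate_lesion_mask(32, LesionParams(), rng)
        with pytest.raises(ValueError):
            render_image("nonEGC", mask, LesionParams(), rng)
        with pytest.raises(ValueError):
            render_image("T1a", None, LesionParams(), rng, image_side=32)


class TestCohort:
    def test_exact_counts(self):
        coh = generate_cohort(10, class_mix=(0.4, 0.3, 0.3),
                              images_per_patient=(2, 2), image_side=32, seed=1)
        assert len(coh.images) == 20
        assert len(coh.patients) == 10
        all_ids = [iid for ids in coh.patients.values() for iid in ids]
        assert len(all_ids) == len(set(all_ids)) == 20

    def test_degenerate_mix_all_nonegc(self):
        coh = generate_cohort(6, class_mix=(1.0, 0.0, 0.0),
                              images_per_patient=(2, 3), image_side=32, seed=2)
        assert all(im.class_label == "nonEGC" and im.lesion_mask is None
                   for im in coh.images)

    def test_mask_class_coupling(self, small_cohort):
        for im in small_cohort.images:
            assert (im.lesion_mask is not None) == (im.class_label != "nonEGC")

    def test_labels_table_reproducible_byte_for_byte(self, tmp_path):
        kw = dict(n_patients=8, class_mix=(0.4, 0.3, 0.3),
                  images_per_patient=(2, 3), image_side=32, seed=7)
        d1 = write_cohort(generate_cohort(**kw), tmp_path / "a")
        d2 = write_cohort(generate_cohort(**kw), tmp_path / "b")
        assert (d1 / "labels.csv").read_bytes() == (d2 / "labels.csv").read_bytes()

    def test_pixels_reproducible(self):
        c1 = generate_cohort(6, images_per_patient=(2, 2), image_side=32, seed=11)
        c2 = generate_cohort(6, images_per_patient=(2, 2), image_side=32, seed=11)
        for a, b in zip(c1.images, c2.images):
            assert np.array_equal(a.pixels, b.pixels)

    def test_round_trip(self, tmp_path):
        coh = generate_cohort(6, class_mix=(0.4, 0.3, 0.3),
                              images_per_patient=(2, 2), image_side=32, seed=3)
        write_cohort(coh, tmp_path)
        back = synthdata.read_cohort(tmp_path)
        assert len(back.images) == len(coh.images)
        orig = {im.image_id: im for im in coh.images}
        for im in back.images:
            o = orig[im.image_id]
            assert im.class_label == o.class_label
            assert np.abs(im.pixels - o.pixels).max() <= 1 / 255 + 1e-9
            if o.lesion_mask is not None:
                assert np.array_equal(im.lesion_mask, o.lesion_mask)

    def test_mix_validation(self):
        with pytest.raises(ValueError):
            generate_cohort(6, class_mix=(0.5, 0.5, 0.5), image_side=32, seed=0)
        with pytest.raises(ValueError):
            generate_cohort(3, image_side=32, seed=0)


def _contrast_statistic(images):
    """Mean in-mask minus out-of-mask local variance (3x3 windows)."""
    from scipy.ndimage import uniform_filter
    vals = []
    for im in images:
        lum = im.pixels.mean(axis=2)
        local_var = uniform_filter(lum ** 2, 3) - uniform_filter(lum, 3) ** 2
        vals.append(local_var[im.lesion_mask].mean()
                    - local_var[~im.lesion_mask].mean())
    return float(np.mean(vals))


def test_contrast_statistic_monotone_in_texture_contrast():
    """The planted texture cue grows monotonically with its amplitude."""
    stats = []
    for tc in (0.1, 0.3, 0.6):
        p = LesionParams(texture_contrast=tc)
        rng = np.random.default_rng(42)
        images = []
        for _ in range(100):
            mask = generate_lesion_mask(32, p, rng)
            images.append(render_image("T1a", mask, p, rng))
        stats.append(_contrast_statistic(images))
    assert stats[0] < stats[1] < stats[2]
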