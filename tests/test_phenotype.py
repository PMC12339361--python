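import numpy as np
import pytest

from nisseq import (
    LabelImage,
    PipelineParams,
    collapse_z,
    local_background_subtract,
    speck_score,
    translocation_score,
)


def disc_labels(shape, centers_radii):
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for k, (r, c, rad) in enumerate(centers_radii, start=1):
        labels[(yy - r) ** 2 + (xx - c) ** 2 <= rad**2] = k
    return LabelImage.from_labels(labels)


class TestCollapseZ:
    def test_single_plane_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(collapse_z(img[None]), img)

    def test_two_plane_average(self):
        img = np.ones((4, 4))
        np.testing.assert_array_equal(collapse_z(np.stack([2 * img, 0 * img])), img)

    def test_matches_elementwise_mean_oracle(self):
        rng = np.random.default_rng(0)
        planes = rng.random((3, 16, 16))
        np.testing.assert_allclose(collapse_z(planes), planes.mean(axis=0))

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            collapse_z(np.zeros((2,)))


def oracle_background_subtract(image, f=8, w=9):
    """Direct per-pixel implementation of the downsample/local-min rule."""
    H, W = image.shape
    ph, pw = (-H) % f, (-W) % f
    padded = np.pad(image, ((0, ph), (0, pw)), mode="edge")
    hd, wd = padded.shape[0] // f, padded.shape[1] // f
    ds = padded.reshape(hd, f, wd, f).mean(axis=(1, 3))
    out = np.empty_like(image, dtype=float)
    half = w // 2
    for r in range(H):
        for c in range(W):
            br, bc = r // f, c // f
            r0, r1 = max(br - half, 0), min(br + half + 1, hd)
            c0, c1 = max(bc - half, 0), min(bc + half + 1, wd)
            out[r, c] = image[r, c] - ds[r0:r1, c0:c1].min()
    return np.clip(out, 0, None)


class TestLocalBackgroundSubtract:
    def test_constant_image_becomes_zero(self):
        out = local_background_subtract(np.full((64, 64), 13.0))
        assert np.allclose(out, 0)

    def test_impulse_on_constant_survives(self):
        img = np.full((128, 128), 10.0)
        img[64, 64] += 500.0
        out = local_background_subtract(img)
        assert out[64, 64] == pytest.approx(500.0, rel=0.05)

    def test_matches_direct_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.random((70, 90)) * 50 + 10
        np.testing.assert_allclose(
            local_background_subtract(img), oracle_background_subtract(img)
        )

    def test_never_increases_and_never_negative(self):
        rng = np.random.default_rng(2)
        ramp = np.linspace(0, 100, 96)[None, :] * np.ones((96, 1))
        img = ramp + rng.random((96, 96))
        out = local_background_subtract(img)
        assert (out <= img + 1e-9).all()
        assert (out >= 0).all()


def translocation_scene(nuclear_fraction, shape=(96, 96), radius=9, seed=0):
    """One cell: nucleus disc inside a cytosol disc; reporter split by fraction.

    A seeded speckle texture breaks the two-level degeneracy so the Pearson
    correlation responds continuously to the nuclear fraction.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    nucleus = (yy - 48) ** 2 + (xx - 48) ** 2 <= radius**2
    cell = (yy - 48) ** 2 + (xx - 48) ** 2 <= (2.5 * radius) ** 2
    nuclear_img = np.where(nucleus, 100.0, 0.0) + 1.0
    reporter = np.where(nucleus, nuclear_fraction * 100, 0.0)
    reporter += np.where(cell & ~nucleus, (1 - nuclear_fraction) * 30, 0.0)
    reporter = np.clip(reporter + rng.normal(0, 5, shape), 0, None)
    labels = LabelImage.from_labels(cell.astype(np.int32))
    return labels, nuclear_img, reporter


class TestTranslocation:
    def test_reporter_equal_to_nuclear_gives_r_1(self):
        labels, nuclear, _ = translocation_scene(0.5)
        df = translocation_score(labels, nuclear, nuclear.copy())
        assert df["translocation_r"].iloc[0] == pytest.approx(1.0)

    def test_anticorrelated_reporter_negative(self):
        labels, nuclear, _ = translocation_scene(0.5)
        df = translocation_score(labels, nuclear, nuclear.max() - nuclear)
        assert df["translocation_r"].iloc[0] < 0

    def test_translocated_cells_score_above_cytosolic(self):
        for f_hi, f_lo in [(0.9, 0.1), (0.8, 0.2), (0.7, 0.3)]:
            lab, nuc, rep_hi = translocation_scene(f_hi)
            _, _, rep_lo = translocation_scene(f_lo)
            r_hi = translocation_score(lab, nuc, rep_hi)["translocation_r"].iloc[0]
            r_lo = translocation_score(lab, nuc, rep_lo)["translocation_r"].iloc[0]
            assert r_hi > r_lo

    def test_affine_rescaling_invariance(self):
        labels, nuclear, reporter = translocation_scene(0.7)
        r1 = translocation_score(labels, nuclear, reporter)["translocation_r"]
        r2 = translocation_score(labels, 3 * nuclear + 7, 0.5 * reporter + 2)[
            "translocation_r"
        ]
        np.testing.assert_allclose(r1, r2, rtol=1e-9)

    def test_zero_variance_cell_gets_missing_score(self):
        labels = disc_labels((64, 64), [(32, 32, 8)])
        df = translocation_score(labels, np.ones((64, 64)), np.ones((64, 64)))
        assert np.isnan(df["translocation_r"].iloc[0])


def speck_scene(with_speck, shape=(128, 128)):
    import scipy.ndimage as ndi

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cell = (yy - 64) ** 2 + (xx - 64) ** 2 <= 20**2
    # diffuse reporter with soft edges, as real cytosolic signal has
    reporter = ndi.gaussian_filter(np.where(cell, 50.0, 0.0), 8)
    if with_speck:
        reporter += 3000.0 * np.exp(
            -((yy - 70) ** 2 + (xx - 70) ** 2) / (2 * 1.5**2)
        )
    labels = LabelImage.from_labels(cell.astype(np.int32))
    return labels, reporter


class TestSpeckScore:
    def test_flat_cell_interior_near_zero(self):
        labels, reporter = speck_scene(False)
        df = speck_score(labels, reporter)
        assert df["speck_ratio"].iloc[0] < 0.05

    def test_punctum_raises_ratio_tenfold(self):
        labels, rep_flat = speck_scene(False)
        _, rep_speck = speck_scene(True)
        flat = speck_score(labels, rep_flat)["speck_ratio"].iloc[0]
        speck = speck_score(labels, rep_speck)["speck_ratio"].iloc[0]
        assert speck > 10 * max(flat, 1e-6)

    def test_scale_invariance(self):
        labels, reporter = speck_scene(True)
        a = speck_score(labels, reporter)["speck_ratio"].iloc[0]
        b = speck_score(labels, 17.0 * reporter)["speck_ratio"].iloc[0]
        assert a == pytest.approx(b, rel=1e-9)

    def test_perfect_auroc_on_planted_populations(self):
        ratios, truth = [], []
        for k in range(10):
            has = k % 2 == 0
            labels, reporter = speck_scene(has)
            ratios.append(speck_score(labels, reporter)["speck_ratio"].iloc[0])
            truth.append(has)
        pos = [r for r, t in zip(ratios, truth) if t]
        neg = [r for r, t in zip(ratios, truth) if not t]
        assert min(pos) > max(neg)  # AUROC = 1

    def test_zero_reporter_cell_excluded(self):
        labels = disc_labels((64, 64), [(32, 32, 8)])
        df = speck_score(labels, np.zeros((64, 64)))
        assert df["excluded_low_expression"].iloc[0]
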