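"""Distance-map feature behaviour against independent oracles."""

import numpy as np
import pytest

from distmap_ema import (
    DataError,
    DistanceMap,
    compute_distance_map,
    featurize_model,
    map_to_image,
)
from distmap_ema.map_features import (
    CONSENSUS_FEATURE,
    DIST_FEATURES,
    PRESETS,
    MapImage,
    contact_match,
    dist_gist,
    dist_orb_num,
    dist_pearson,
    dist_phash,
    dist_precl2,
    dist_psnr,
    dist_recall,
    dist_rmse,
    dist_ssim,
    gist_descriptor,
    masked_pairs,
    perceptual_hash,
    preset_columns,
)
from distmap_ema.structio import Contact, ContactList

from conftest import random_distance_map


def random_image(seed, size=16):
    rng = np.random.default_rng(seed)
    return MapImage((rng.random((size, size)) * 255).astype(np.uint8), size)


class TestMaskedPairs:
    def test_separation_filter_count(self):
        a = random_distance_map(10, 0)
        b = random_distance_map(10, 1)
        va, vb = masked_pairs(a, b, min_sep=6)
        assert len(va) == 10  # pairs (i,j), j-i >= 6 in a 10-residue chain

    def test_missing_residue_excluded(self):
        a = random_distance_map(10, 0)
        b = random_distance_map(10, 1)
        b.observed[0, :] = False
        b.observed[:, 0] = False
        va, _ = masked_pairs(a, b, min_sep=6)
        assert len(va) == 6  # the 4 pairs containing residue 1 are gone

    def test_min_sep_one(self):
        a = random_distance_map(3, 0)
        va, _ = masked_pairs(a, a, min_sep=1)
        assert len(va) == 3

    def test_size_mismatch(self):
        with pytest.raises(DataError, match="mismatch"):
            masked_pairs(random_distance_map(4, 0), random_distance_map(5, 0))


class TestPearsonRmse:
    def test_self_correlation(self):
        m = random_distance_map(12, 5)
        assert dist_pearson(m, m) == pytest.approx(1.0)
        assert dist_rmse(m, m) == 0.0

    def test_affine_invariance(self):
        m = random_distance_map(12, 5)
        m2 = DistanceMap.full(2.0 * m.values + 1.0)
        np.fill_diagonal(m2.values, 0.0)
        assert dist_pearson(m, m2) == pytest.approx(1.0)

    def test_pearson_matches_textbook_formula(self):
        a = random_distance_map(12, 7)
        b = random_distance_map(12, 8)
        va, vb = masked_pairs(a, b)
        cov = np.mean(va * vb) - va.mean() * vb.mean()
        expected = cov / (va.std() * vb.std())
        assert dist_pearson(a, b) == pytest.approx(expected, abs=1e-12)

    def test_rmse_constant_offset(self):
        a = random_distance_map(12, 9)
        b = DistanceMap.full(a.values + 2.0)
        np.fill_diagonal(b.values, 0.0)
        assert dist_rmse(a, b) == pytest.approx(2.0)

    def test_rmse_matches_direct_sum(self):
        a = random_distance_map(12, 10)
        b = random_distance_map(12, 11)
        va, vb = masked_pairs(a, b)
        expected = min(np.sqrt(sum((x - y) ** 2 for x, y in zip(va, vb)) / len(va)), 16.0)
        assert dist_rmse(a, b) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_sentinels(self):
        tiny = random_distance_map(4, 1)  # no pairs at separation >= 6
        assert dist_pearson(tiny, tiny) == 0.0
        assert dist_rmse(tiny, tiny) == 16.0


class TestMapToImage:
    def test_intensity_formula(self):
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = 8.0
        values[0, 2] = values[2, 0] = 16.0
        values[1, 2] = values[2, 1] = 40.0
        img = map_to_image(DistanceMap.full(values), size=3)
        assert img.pixels[0, 0] == 255  # d = 0
        assert img.pixels[0, 1] == 128  # d = 8 -> 127.5, round half up
        assert img.pixels[0, 2] == 0    # d = 16 (cap)
        assert img.pixels[1, 2] == 0    # beyond cap

    def test_unobserved_renders_black(self):
        dmap = random_distance_map(5, 2, missing=1)
        img = map_to_image(dmap, size=5)
        assert (img.pixels[~dmap.observed] == 0).all()

    def test_identity_resize_and_determinism(self):
        dmap = random_distance_map(128, 3)
        img1 = map_to_image(dmap)
        img2 = map_to_image(dmap)
        assert np.array_equal(img1.pixels, img2.pixels)
        direct = np.floor(255 * (1 - np.minimum(dmap.values, 16.0) / 16.0) + 0.5)
        assert np.array_equal(img1.pixels, direct.astype(np.uint8))


class TestSsim:
    def test_identical_images(self):
        img = random_image(0, 64)
        assert dist_ssim(img, img) == pytest.approx(1.0)

    def test_constant_images(self):
        a = MapImage(np.full((32, 32), 100, dtype=np.uint8), 32)
        b = MapImage(np.full((32, 32), 100, dtype=np.uint8), 32)
        assert dist_ssim(a, b) == pytest.approx(1.0)

    def test_matches_direct_windowed_formula(self):
        # independent oracle: explicit Gaussian-weighted sliding windows over
        # the interior (the library crops the filter border the same way)
        a, b = random_image(1), random_image(2)
        r, sigma, R = 5, 1.5, 255.0
        x = np.arange(-r, r + 1)
        g = np.exp(-x ** 2 / (2 * sigma ** 2)); g /= g.sum()
        w = np.outer(g, g)
        C1, C2 = (0.01 * R) ** 2, (0.03 * R) ** 2
        pa, pb = a.pixels.astype(float), b.pixels.astype(float)
        vals = []
        for i in range(r, 16 - r):
            for j in range(r, 16 - r):
                wa = pa[i - r:i + r + 1, j - r:j + r + 1]
                wb = pb[i - r:i + r + 1, j - r:j + r + 1]
                mua, mub = (w * wa).sum(), (w * wb).sum()
                va = (w * wa * wa).sum() - mua ** 2
                vb = (w * wb * wb).sum() - mub ** 2
                cov = (w * wa * wb).sum() - mua * mub
                vals.append(((2 * mua * mub + C1) * (2 * cov + C2))
                            / ((mua ** 2 + mub ** 2 + C1) * (va + vb + C2)))
        expected = (np.mean(vals) + 1.0) / 2.0
        assert dist_ssim(a, b) == pytest.approx(expected, abs=1e-10)


class TestPsnr:
    def test_identical_images_capped(self):
        img = random_image(3)
        assert dist_psnr(img, img) == 1.0

    def test_unit_mse_closed_form(self):
        a = MapImage(np.full((16, 16), 100, dtype=np.uint8), 16)
        b = MapImage(np.full((16, 16), 101, dtype=np.uint8), 16)
        assert dist_psnr(a, b) == pytest.approx(20 * np.log10(255) / 100.0)

    def test_noise_monotonicity_in_expectation(self):
        base = random_image(4, 32)
        means = []
        for amplitude in (2, 8, 32):
            vals = []
            for seed in range(50):
                rng = np.random.default_rng(seed)
                noisy = np.clip(base.pixels.astype(int)
                                + rng.integers(-amplitude, amplitude + 1, base.pixels.shape),
                                0, 255).astype(np.uint8)
                vals.append(dist_psnr(base, MapImage(noisy, 32)))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestPhash:
    def test_identical_and_deterministic(self):
        img = random_image(5)
        assert dist_phash(img, img) == 1.0
        assert np.array_equal(perceptual_hash(img), perceptual_hash(img))
        assert len(perceptual_hash(img)) == 64

    def test_feature_is_hamming_complement(self):
        a, b = random_image(6), random_image(7)
        ha, hb = perceptual_hash(a), perceptual_hash(b)
        expected = 1.0 - np.count_nonzero(ha != hb) / 64.0
        assert dist_phash(a, b) == pytest.approx(expected)
        # a single flipped bit costs exactly 1/64
        hb2 = ha.copy(); hb2[17] = ~hb2[17]
        assert 1.0 - np.count_nonzero(ha != hb2) / 64.0 == pytest.approx(63 / 64)


class TestOrb:
    def test_identical_images_all_matched(self, small_pool):
        img = map_to_image(small_pool["mdm_native"])
        feature = dist_orb_num(img, img)
        from distmap_ema.map_features import _orb_descriptors
        k = len(_orb_descriptors(img.pixels))
        assert feature == pytest.approx(k / 500.0)

    def test_featureless_images(self):
        a = MapImage(np.full((64, 64), 7, dtype=np.uint8), 64)
        assert dist_orb_num(a, a) == 0.0

    def test_roughly_symmetric(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            a = random_image(seed, 128)
            b = random_image(seed + 100, 128)
            ab = dist_orb_num(a, b)
            ba = dist_orb_num(b, a)
            assert abs(ab - ba) <= 2 / 500.0 + 1e-12


class TestGist:
    def test_identity_and_length(self):
        img = random_image(8, 64)
        assert dist_gist(img, img) == pytest.approx(1.0)
        assert gist_descriptor(img).shape == (512,)

    def test_intensity_scaling_invariance(self):
        rng = np.random.default_rng(9)
        half = MapImage(rng.integers(0, 128, (64, 64)).astype(np.uint8), 64)
        double = MapImage((2 * half.pixels).astype(np.uint8), 64)
        assert dist_gist(half, double) == pytest.approx(1.0, abs=1e-6)

    def test_blank_images_sentinels(self):
        blank = MapImage(np.zeros((64, 64), dtype=np.uint8), 64)
        other = MapImage(np.zeros((64, 64), dtype=np.uint8), 64)
        other.pixels = other.pixels.copy()
        assert dist_gist(blank, other) == 1.0


class TestRecallPrecision:
    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("long_only", [False, True])
    def test_recall_matches_enumeration(self, seed, long_only):
        pdm = random_distance_map(30, seed)
        mdm = random_distance_map(30, seed + 50, missing=seed % 3)
        num = den = 0
        for i in range(30):
            for j in range(i + 1, 30):
                sep = j - i
                if long_only and sep < 24:
                    continue
                if not long_only and sep < 6:
                    continue
                if pdm.values[i, j] < 8.0 and pdm.observed[i, j] and mdm.observed[i, j]:
                    den += 1
                    if mdm.values[i, j] < 8.0:
                        num += 1
        expected = num / den if den else 0.0
        assert dist_recall(pdm, mdm, long_only=long_only) == pytest.approx(expected)

    def test_recall_perfect_and_empty(self):
        pdm = random_distance_map(30, 3)
        assert dist_recall(pdm, pdm) == 1.0
        far = DistanceMap.full(np.full((30, 30), 30.0) - 30.0 * np.eye(30))
        assert dist_recall(far, far) == 0.0  # nothing predicted

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("long_only", [False, True])
    def test_precl2_matches_sort_and_count(self, seed, long_only):
        L = 30
        pdm = random_distance_map(L, seed + 200)
        mdm = random_distance_map(L, seed + 300, missing=seed % 3)
        min_sep = 24 if long_only else 6
        cands = [(pdm.values[i, j], i, j)
                 for i in range(L) for j in range(i + min_sep, L)
                 if pdm.observed[i, j] and mdm.observed[i, j]]
        cands.sort()
        top = cands[: int(np.ceil(L / 2))]
        expected = (sum(1 for _, i, j in top if mdm.values[i, j] < 8.0) / len(top)
                    if top else 0.0)
        assert dist_precl2(pdm, mdm, long_only=long_only) == pytest.approx(expected)

    def test_precl2_uses_all_when_few_candidates(self):
        L = 30
        pdm = random_distance_map(L, 4)
        mdm = random_distance_map(L, 5)
        # only 3 long-range candidate pairs survive masking
        mdm.observed[:, :] = False
        for i, j in [(0, 25), (1, 27), (2, 29)]:
            mdm.observed[i, j] = mdm.observed[j, i] = True
        expected = np.mean([mdm.values[i, j] < 8.0 for i, j in [(0, 25), (1, 27), (2, 29)]])
        assert dist_precl2(pdm, mdm, long_only=True) == pytest.approx(expected)


class TestContactMatch:
    def test_fraction_realized(self):
        values = np.full((40, 40), 20.0)
        np.fill_diagonal(values, 0.0)
        for i, j in [(0, 30), (1, 32), (2, 34)]:
            values[i, j] = values[j, i] = 6.0
        mdm = DistanceMap.full(values)
        contacts = ContactList([
            Contact(1, 31, 0.9, "long"), Contact(2, 33, 0.9, "long"),
            Contact(3, 35, 0.9, "long"), Contact(4, 36, 0.9, "long"),
        ])
        assert contact_match(contacts, mdm, "long") == pytest.approx(0.75)

    def test_missing_residues_excluded(self):
        values = np.full((40, 40), 6.0)
        np.fill_diagonal(values, 0.0)
        mdm = DistanceMap.full(values)
        mdm.observed[35, :] = mdm.observed[:, 35] = False
        contacts = ContactList([
            Contact(1, 31, 0.9, "long"), Contact(2, 36, 0.9, "long"),
        ])
        # the (2, 36) pair touches a missing residue: denominator is 1
        assert contact_match(contacts, mdm, "long") == 1.0

    def test_empty_class(self):
        mdm = random_distance_map(40, 1)
        assert contact_match(ContactList([]), mdm, "short") == 0.0


class TestFeaturize:
    def test_dist_preset_column_set(self, small_pool):
        externals = {c: 0.5 for c in PRESETS["dist"]["external"]}
        fv = featurize_model(small_pool["target"], small_pool["native"],
                             small_pool["pdm"], preset="dist", externals=externals)
        expected = set(DIST_FEATURES) | set(PRESETS["dist"]["external"])
        assert set(fv.values) == expected
        assert len(fv.values) == 17

    def test_self_comparison_maximality(self, small_pool):
        native = small_pool["native"]
        pdm = DistanceMap.full(small_pool["mdm_native"].values)
        fv = featurize_model(small_pool["target"], native, pdm, preset="dist",
                             allow_missing_externals=True)
        for name in ("dist_pearson", "dist_ssim", "dist_psnr", "dist_phash",
                     "dist_gist", "dist_recall", "dist_recall_long"):
            assert fv.values[name] == pytest.approx(1.0, abs=1e-9), name
        assert fv.values["dist_rmse"] == 0.0

    def test_deterministic(self, small_pool):
        args = (small_pool["target"], small_pool["decoys"][0], small_pool["pdm"])
        kw = dict(contacts=small_pool["contacts"], preset="deep",
                  allow_missing_externals=True)
        assert featurize_model(*args, **kw).values == featurize_model(*args, **kw).values

    def test_missing_externals_error_lists_columns(self, small_pool):
        with pytest.raises(DataError, match="voronota"):
            featurize_model(small_pool["target"], small_pool["native"],
                            small_pool["pdm"], preset="dist")

    def test_bounded_features(self, small_pool):
        fv = featurize_model(small_pool["target"], small_pool["decoys"][-1],
                             small_pool["pdm"], contacts=small_pool["contacts"],
                             preset="deep", allow_missing_externals=True)
        for name, value in fv.values.items():
            if name == "dist_rmse":
                assert 0.0 <= value <= 16.0
            else:
                assert 0.0 <= value <= 1.0 or name == "dist_pearson" and -1 <= value <= 1

    def test_unknown_preset(self, small_pool):
        with pytest.raises(ValueError, match="valid presets"):
            preset_columns("bogus")


class TestPresetTables:
    @pytest.mark.parametrize("preset,n_columns", [
        ("cluster", 19), ("construct", 18), ("ai", 18),
        ("hybrid", 30), ("deep", 29), ("dist", 17),
    ])
    def test_preset_sizes(self, preset, n_columns):
        # multi-model presets carry one consensus column in place of the
        # three original multi-model score columns
        assert len(preset_columns(preset)) == n_columns

    def test_multi_model_presets_have_consensus(self):
        for preset in ("cluster", "construct", "ai", "hybrid"):
            assert CONSENSUS_FEATURE in preset_columns(preset)
        for preset in ("deep", "dist"):
            assert CONSENSUS_FEATURE not in preset_columns(preset)
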