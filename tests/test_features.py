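import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippopix.features import (
    FEATURE_COLUMNS,
    fit_standardizer,
    gaussian_window,
    hu_first_two,
    log_sign,
    pixel_feature,
    standardize,
    unstandardize,
    weighted_patch,
    window_stats,
    window_stats_batch,
)
from hippopix.imageprep import GreyImage


def grey(arr, stage="enhanced"):
    return GreyImage(np.asarray(arr, dtype=float), stage=stage)


def brute_window_stats(pixels, x, y, w):
    """Independent oracle: explicit loop over the reflect-padded window."""
    half = w // 2
    padded = np.pad(pixels, half, mode="reflect")
    vals = []
    for dy in range(-half, half + 1):
        for dx in range(-half, half + 1):
            vals.append(padded[y + half + dy, x + half + dx])
    vals = np.array(vals)
    c = pixels[y, x]
    return (c - vals.min(), vals.max() - c, c - vals.mean(), vals.std(), c)


class TestWindowStats:
    def test_constant_window(self):
        img = grey(np.full((30, 30), 7.0))
        assert window_stats(img, 15, 15) == (0.0, 0.0, 0.0, 0.0, 7.0)

    def test_simple_hand_case(self):
        # centre 10, min 2, max 20 -> f1=8, f2=10
        px = np.full((30, 30), 10.0)
        px[12, 12] = 2.0
        px[18, 18] = 20.0
        f1, f2, f3, f4, f5 = window_stats(grey(px), 15, 15)
        assert (f1, f2, f5) == (8.0, 10.0, 10.0)
        assert f3 == pytest.approx(10.0 - px[11:20, 11:20].mean())

    def test_matches_bruteforce_on_many_seeded_pixels(self, rng):
        """1,000 random (image, x, y) triples against the 81-pixel loop."""
        for _ in range(10):
            pixels = np.floor(rng.uniform(0, 256, size=(60, 70)))
            img = grey(pixels)
            xs = rng.integers(0, 70, size=100)
            ys = rng.integers(0, 60, size=100)
            got = window_stats_batch(img, xs, ys, w=9)
            for k in range(100):
                exp = brute_window_stats(pixels, xs[k], ys[k], 9)
                assert got[k, 0] == exp[0] and got[k, 1] == exp[1] and got[k, 4] == exp[4]
                assert got[k, 2] == pytest.approx(exp[2], abs=1e-9)
                assert got[k, 3] == pytest.approx(exp[3], abs=1e-9)

    def test_range_identity_f1_plus_f2(self, rng):
        pixels = rng.uniform(0, 255, size=(50, 50))
        img = grey(pixels)
        xs = rng.integers(0, 50, size=1000)
        ys = rng.integers(0, 50, size=1000)
        got = window_stats_batch(img, xs, ys, w=9)
        half = 4
        padded = np.pad(pixels, half, mode="reflect")
        for k in range(1000):
            win = padded[ys[k] : ys[k] + 9, xs[k] : xs[k] + 9]
            assert got[k, 0] + got[k, 1] == pytest.approx(np.ptp(win), abs=1e-12)
            assert got[k, 0] >= 0 and got[k, 1] >= 0 and got[k, 3] >= 0

    def test_even_window_rejected(self, random_grey):
        with pytest.raises(ValueError):
            window_stats(random_grey, 5, 5, w=8)


class TestGaussianWindow:
    def test_peak_symmetry_and_mass(self):
        G = gaussian_window(17, 1.7)
        assert G.weights[8, 8] == 1.0
        assert G.weights.max() == 1.0
        # 8-fold symmetry
        assert G.weights[8 + 3, 8 + 4] == pytest.approx(G.weights[8 + 4, 8 + 3])
        assert G.weights[8 + 3, 8 + 4] == pytest.approx(G.weights[8 - 3, 8 - 4])
        # central 9x9 carries ~98.6% of the weight (localization claim)
        assert G.central_mass_fraction(9) == pytest.approx(0.986, abs=0.002)
        assert G.central_mass_fraction(9) > 0.95

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            gaussian_window(16)


class TestWeightedPatch:
    def test_annihilation_scaling_and_oracle(self, rng):
        G = gaussian_window()
        z = grey(np.zeros((40, 40)))
        assert np.all(weighted_patch(z, 20, 20, G) == 0)
        c = grey(np.full((40, 40), 255.0))
        assert np.allclose(weighted_patch(c, 20, 20, G), 255.0 * G.weights)
        pixels = rng.uniform(0, 255, size=(40, 40))
        img = grey(pixels)
        got = weighted_patch(img, 20, 20, G)
        for i in range(17):
            for j in range(17):
                assert got[i, j] == pixels[20 - 8 + i, 20 - 8 + j] * G.weights[i, j]


def brute_hu(patch):
    """Independent oracle: explicit moment sums."""
    s = patch.shape[0]
    m00 = m10 = m01 = 0.0
    for i in range(s):
        for j in range(s):
            m00 += patch[i, j]
            m10 += i * patch[i, j]
            m01 += j * patch[i, j]
    if m00 == 0:
        return 0.0, 0.0
    ci, cj = m10 / m00, m01 / m00
    mu20 = mu02 = mu11 = 0.0
    for i in range(s):
        for j in range(s):
            mu20 += (i - ci) ** 2 * patch[i, j]
            mu02 += (j - cj) ** 2 * patch[i, j]
            mu11 += (i - ci) * (j - cj) * patch[i, j]
    eta20, eta02, eta11 = mu20 / m00**2, mu02 / m00**2, mu11 / m00**2
    return eta20 + eta02, (eta20 - eta02) ** 2 + 4 * eta11**2


class TestHuInvariants:
    def test_zero_mass_and_point_mass(self):
        assert hu_first_two(np.zeros((17, 17))) == (0.0, 0.0)
        p = np.zeros((17, 17))
        p[8, 8] = 42.0
        phi1, phi2 = hu_first_two(p)
        assert phi1 == pytest.approx(0.0, abs=1e-12)
        assert phi2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            patch = rng.uniform(0, 255, size=(17, 17))
            got = hu_first_two(patch)
            exp = brute_hu(patch)
            assert got[0] == pytest.approx(exp[0], rel=1e-12)
            assert got[1] == pytest.approx(exp[1], rel=1e-12)

    def test_rotation_and_transpose_invariance(self, rng):
        """phi1, phi2 unchanged under 90-degree rotations and transposition."""
        for seed in range(100):
            r = np.random.default_rng(seed)
            patch = r.uniform(0, 255, size=(17, 17))
            ref = np.array(hu_first_two(patch))
            for variant in (
                np.rot90(patch),
                np.rot90(patch, 2),
                np.rot90(patch, 3),
                patch.T,
            ):
                got = np.array(hu_first_two(np.ascontiguousarray(variant)))
                assert np.allclose(got, ref, rtol=1e-9, atol=1e-15)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            hu_first_two(np.full((17, 17), -1.0))


class TestLogSign:
    @pytest.mark.parametrize(
        "phi,expected",
        [(0.0, 0.0), (1.0, 0.0), (np.e, 1.0), (-np.e, -1.0), (1e-40, 0.0)],
    )
    def test_known_values(self, phi, expected):
        assert log_sign(phi) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-20, max_value=1e20))
    def test_antisymmetry(self, phi):
        assert log_sign(-phi) == pytest.approx(-log_sign(phi), rel=1e-12)


class TestPixelFeature:
    def test_zero_images_and_channel_independence(self, rng):
        z = grey(np.zeros((40, 40)))
        nv = grey(rng.uniform(0, 255, size=(40, 40)), stage="negated")
        assert np.all(pixel_feature(z, grey(np.zeros((40, 40)), "negated"), 20, 20) == 0)
        F = pixel_feature(z, nv, 20, 20)
        assert np.all(F[:7] == 0)
        assert not np.all(F[7:] == 0)

    def test_composition_matches_stage_functions(self, rng):
        from hippopix.features import hu_first_two as hu
        from hippopix.features import log_sign as ls

        ihe = grey(rng.uniform(0, 255, size=(50, 50)))
        inv = grey(rng.uniform(0, 255, size=(50, 50)), stage="negated")
        G = gaussian_window()
        for x, y in [(25, 25), (3, 40), (49, 0)]:
            F = pixel_feature(ihe, inv, x, y, G)
            for img, base in [(ihe, 0), (inv, 7)]:
                assert np.allclose(F[base : base + 5], window_stats(img, x, y))
                phi = hu(weighted_patch(img, x, y, G))
                assert F[base + 5] == pytest.approx(ls(phi[0]), abs=1e-12)
                assert F[base + 6] == pytest.approx(ls(phi[1]), abs=1e-12)

    def test_translation_invariance(self, rng):
        content = rng.uniform(0, 255, size=(30, 30))
        big = np.zeros((80, 80))
        a, b = big.copy(), big.copy()
        a[10:40, 10:40] = content
        b[20:50, 25:55] = content
        nv = grey(np.zeros((80, 80)), "negated")
        Fa = pixel_feature(grey(a), nv, 25, 25)
        Fb = pixel_feature(grey(b), nv, 40, 35)
        assert np.allclose(Fa[:7], Fb[:7], atol=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pixel_feature(
                grey(np.zeros((40, 40))), grey(np.zeros((30, 30)), "negated"), 5, 5
            )


class TestStandardization:
    def test_hand_case_population_sigma(self):
        X = np.array([[0.0] * 14, [2.0] * 14])
        p = fit_standardizer(X)
        assert np.allclose(p.mu, 1.0)
        assert np.allclose(p.sd, 1.0)

    def test_training_set_becomes_zero_mean_unit_variance(self, rng):
        X = rng.uniform(-50, 50, size=(500, 14)) * rng.uniform(0.1, 10, size=14)
        p = fit_standardizer(X)
        Z = standardize(X, p)
        assert np.all(np.abs(Z.mean(axis=0)) <= 1e-9)
        assert np.all(np.abs(Z.var(axis=0) - 1.0) <= 1e-9)

    def test_constant_feature_flagged_and_zeroed(self, rng):
        X = rng.uniform(0, 1, size=(100, 14))
        X[:, 3] = 5.0
        p = fit_standardizer(X)
        assert p.degenerate[3] and not p.degenerate[0]
        Z = standardize(X, p)
        assert np.all(Z[:, 3] == 0.0)

    def test_transform_matches_hand_computation(self, rng):
        Xtrain = rng.uniform(0, 10, size=(200, 14))
        p = fit_standardizer(Xtrain)
        Xnew = rng.uniform(0, 10, size=(10, 14))
        Z = standardize(Xnew, p)
        for i in range(10):
            for j in range(14):
                assert Z[i, j] == pytest.approx(
                    (Xnew[i, j] - Xtrain[:, j].mean()) / Xtrain[:, j].std(), rel=1e-12
                )

    def test_roundtrip_bijection(self, rng):
        X = rng.uniform(0, 10, size=(50, 14))
        p = fit_standardizer(X)
        assert np.allclose(unstandardize(standardize(X, p), p), X, atol=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_standardizer(np.zeros((1, 14)))
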