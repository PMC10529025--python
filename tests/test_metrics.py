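"""Metric suite against independent direct-formula oracles."""

import numpy as np
import pytest

import despeckle as dsp
from despeckle.metrics import dei, fom_from_edge_maps, ssim_map

from _oracles import fr_oracle, uqi_oracle


class TestFRSuite:
    def test_identity_pair_identities(self, phantom):
        report = dsp.fr_suite(phantom, phantom, 1.0)
        assert report["MSE"] == 0.0 and report["PSNR"] == np.inf
        assert report["AD"] == report["MD"] == report["NAE"] == report["LMSE"] == 0.0
        assert report["NK"] == report["SC"] == 1.0
        assert report["CoC"] == pytest.approx(1.0, abs=1e-12)
        assert report["MSSIM"] == pytest.approx(1.0, abs=1e-12)
        assert report["UQI"] == pytest.approx(1.0, abs=1e-9)
        assert report["QILV"] == pytest.approx(1.0, abs=1e-9)
        assert report["FOM"] == 1.0
        assert report["SRS"] == pytest.approx(100.0, abs=1e-9)

    def test_toy_pair_matches_direct_formula_oracle(self):
        ref = np.array(
            [[1.0, 2.0, 3.0, 4.0],
             [2.0, 3.0, 4.0, 5.0],
             [5.0, 4.0, 3.0, 2.0],
             [1.0, 1.0, 2.0, 2.0]]
        )
        test = np.array(
            [[1.5, 2.0, 2.5, 4.0],
             [2.0, 3.5, 4.0, 4.5],
             [5.5, 4.0, 2.5, 2.0],
             [1.0, 1.5, 2.0, 2.5]]
        )
        report = dsp.fr_suite(test, ref, dynamic_range=8.0)
        oracle = fr_oracle(test, ref, 8.0)
        for name, expected in oracle.items():
            assert report[name] == pytest.approx(expected, abs=1e-9), name

    def test_constant_shift_examples(self, rng):
        ref = rng.uniform(size=(16, 16))
        test = ref + 0.25
        report = dsp.fr_suite(test, ref)
        assert report["AD"] == pytest.approx(-0.25)
        assert report["MD"] == pytest.approx(0.25)

    def test_eight_bit_unit_difference_psnr(self):
        ref = np.full((16, 16), 100.0)
        test = ref + 1.0
        mse, rmse, psnr = dsp.mse_rmse_psnr(test, ref, dynamic_range=255.0)
        assert mse == 1.0 and rmse == 1.0
        assert psnr == pytest.approx(20.0 * np.log10(255.0))
        assert psnr == pytest.approx(48.1308, abs=1e-4)

    def test_psnr_rmse_mutual_consistency(self, rng):
        for _ in range(10):
            a = rng.uniform(size=(16, 16))
            b = rng.uniform(size=(16, 16))
            mse, rmse, psnr = dsp.mse_rmse_psnr(a, b, 1.0)
            assert abs(rmse**2 - mse) < 1e-12
            assert abs(psnr - 10.0 * np.log10(1.0 / mse)) < 1e-9

    def test_uqi_matches_sliding_window_oracle(self, rng):
        ref = rng.uniform(0.2, 1.0, (16, 16))
        test = np.clip(ref + 0.1 * rng.normal(size=(16, 16)), 0, 1.2)
        report = dsp.fr_suite(test, ref)
        assert report["UQI"] == pytest.approx(uqi_oracle(test, ref), abs=1e-9)

    def test_constant_images_report_nan_sentinels(self):
        a = np.full((16, 16), 0.5)
        report = dsp.fr_suite(a, a)
        assert np.isnan(report["CoC"])
        assert np.isnan(report["LMSE"])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dsp.mse_rmse_psnr(np.ones((8, 8)), np.ones((8, 9)))

    def test_symmetry_and_argument_order(self, rng):
        a = rng.uniform(size=(32, 32))
        b = np.clip(a + 0.2 * rng.normal(size=(32, 32)), 0, 1.5)
        ra, rb = dsp.fr_suite(b, a), dsp.fr_suite(a, b)
        # symmetric metrics survive the swap; reference-first ones do not
        assert ra["CoC"] == pytest.approx(rb["CoC"], abs=1e-12)
        assert ra["MSSIM"] == pytest.approx(rb["MSSIM"], abs=1e-9)
        assert ra["NK"] != pytest.approx(rb["NK"], abs=1e-6)
        assert ra["SC"] == pytest.approx(1.0 / rb["SC"], abs=1e-9)

    def test_shift_invariant_family(self, rng):
        a = rng.uniform(size=(16, 16))
        b = np.clip(a + 0.1 * rng.normal(size=(16, 16)), 0, 1.2)
        base = dsp.fr_suite(b, a)
        shifted = dsp.fr_suite(b + 0.3, a + 0.3)
        for name in ("MSE", "RMSE", "PSNR", "AD", "MD", "CoC", "LMSE"):
            assert shifted[name] == pytest.approx(base[name], abs=1e-9), name


class TestMSSIM:
    def test_matches_literal_windowed_formula(self, rng):
        """Interior of the SSIM map vs a literal Gaussian-weighted
        sliding-window evaluation of the SSIM formula."""
        ref = rng.uniform(0.1, 0.9, (16, 16))
        test = np.clip(ref + 0.1 * rng.normal(size=(16, 16)), 0, 1)
        L, sigma, half = 1.0, 1.5, 5
        c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
        yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
        kernel = np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))
        kernel /= kernel.sum()
        smap = ssim_map(test, ref, L)
        for r in range(half, 16 - half):
            for c in range(half, 16 - half):
                x = test[r - half : r + half + 1, c - half : c + half + 1]
                y = ref[r - half : r + half + 1, c - half : c + half + 1]
                ux, uy = np.sum(kernel * x), np.sum(kernel * y)
                vx = np.sum(kernel * x * x) - ux**2
                vy = np.sum(kernel * y * y) - uy**2
                cov = np.sum(kernel * x * y) - ux * uy
                expected = ((2 * ux * uy + c1) * (2 * cov + c2)) / (
                    (ux**2 + uy**2 + c1) * (vx + vy + c2)
                )
                assert smap[r, c] == pytest.approx(expected, abs=1e-9)

    def test_inverted_image_scores_below_one(self, phantom):
        assert dsp.mssim(1.0 - phantom, phantom) < 1.0

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            dsp.mssim(np.ones((8, 8)), np.ones((8, 8)))


class TestPrattFOM:
    def test_identical_edge_maps_score_one(self):
        edges = np.zeros((32, 32), dtype=bool)
        edges[10, 5:25] = True
        assert fom_from_edge_maps(edges, edges) == 1.0

    def test_empty_detection_scores_zero(self):
        ideal = np.zeros((32, 32), dtype=bool)
        ideal[10, 10] = True
        assert fom_from_edge_maps(np.zeros((32, 32), dtype=bool), ideal) == 0.0

    def test_single_displaced_detection(self):
        # one ideal pixel, one detection at Euclidean distance 3:
        # 1 / (1 + 9/9) = 0.5
        ideal = np.zeros((32, 32), dtype=bool)
        detected = np.zeros((32, 32), dtype=bool)
        ideal[10, 10] = True
        detected[10, 13] = True
        assert fom_from_edge_maps(detected, ideal) == pytest.approx(0.5)

    def test_edgeless_reference_rejected(self):
        with pytest.raises(ValueError, match="no edge pixels"):
            dsp.pratt_fom(np.zeros((32, 32)), np.zeros((32, 32)))


class TestNRSuite:
    def test_identity_filter_degenerate_values(self, noisy):
        report = dsp.nr_suite(noisy, noisy)
        assert report["ENL"] == np.inf or report["ENL"] > 0  # ratio is constant 1
        assert report["gamma"] == 0.0
        assert report["tau_ENL"] == 0.0
        assert report["tau_theta"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_image_dei_is_one(self):
        assert dei(np.full((32, 32), 0.7)) == pytest.approx(1.0)

    def test_smoothing_lowers_dei(self, noisy):
        from scipy.ndimage import uniform_filter

        assert dei(uniform_filter(noisy, 5)) < dei(noisy)

    def test_enl_matches_moment_oracle(self, rng):
        ideal = np.full((64, 64), 0.8)
        variance = 0.01
        observed = ideal + rng.normal(0, np.sqrt(variance), ideal.shape)
        mask = np.ones_like(ideal, dtype=bool)
        report = dsp.nr_suite(observed, observed, homogeneous_mask=mask)
        expected = observed.mean() ** 2 / observed.var()
        assert report["ENL"] == pytest.approx(expected, rel=1e-12)
        # ENL ~ mean^2 / (relative variance): close to 0.8^2 / 0.01 = 64
        assert report["ENL"] == pytest.approx(
            ideal[0, 0] ** 2 / variance, rel=0.1
        )


class TestSRS:
    def test_identity_is_maximal(self, phantom, noisy):
        identity = dsp.srs(phantom, phantom)
        assert identity == pytest.approx(100.0, abs=1e-9)
        assert dsp.srs(np.clip(noisy, 0, 1), phantom) < identity

    def test_two_stage_composition(self, phantom, noisy):
        test = np.clip(noisy, 0, 1)
        stage1 = float(np.mean(ssim_map(test, phantom)))
        stage2 = dsp.pratt_fom(test, phantom)
        assert dsp.srs(test, phantom) == pytest.approx(100.0 * stage1 * stage2, abs=1e-12)


def test_quality_degrades_monotonically_with_noise(phantom128):
    scores = []
    for level in (0.05, 0.1, 0.2):
        noisy = dsp.add_speckle(phantom128, dsp.SpeckleParams(variance=level, seed=13))
        test = np.clip(noisy, 0, 1)
        _, _, psnr = dsp.mse_rmse_psnr(test, phantom128)
        scores.append((psnr, dsp.mssim(test, phantom128)))
    assert scores[0][0] > scores[1][0] > scores[2][0]
    assert scores[0][1] > scores[1][1] > scores[2][1]
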