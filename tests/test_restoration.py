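"""Fuzzy non-local restoration: memberships, LLMMSE, defuzzification,
and the vectorized image path against a brute-force per-pixel oracle."""

import numpy as np
import pytest

import despeckle as dsp
from despeckle.metrics import mse_rmse_psnr, pratt_fom


class TestTrapezoid:
    Z = dsp.MembershipParams(0.0, 1.0, 2.0, 4.0)

    @pytest.mark.parametrize(
        "a,expected",
        [
            (-1.0, 0.0),
            (0.0, 0.0),  # a <= Z1
            (0.5, 0.5),  # rising ramp midpoint
            (1.0, 1.0),
            (1.7, 1.0),  # plateau
            (2.0, 1.0),
            (3.0, 0.5),  # falling ramp: (4-3)/(4-2)
            (4.0, 0.0),
            (9.0, 0.0),
        ],
    )
    def test_values(self, a, expected):
        assert dsp.trapezoidal_membership(a, self.Z) == pytest.approx(expected)

    def test_degenerate_corners_act_as_steps(self):
        step = dsp.MembershipParams(1.0, 1.0, 2.0, 2.0)
        assert dsp.trapezoidal_membership(0.99, step) == 0.0
        assert dsp.trapezoidal_membership(1.0, step) == 1.0
        assert dsp.trapezoidal_membership(2.0, step) == 1.0
        assert dsp.trapezoidal_membership(2.01, step) == 0.0

    def test_corner_ordering_enforced(self):
        with pytest.raises(ValueError):
            dsp.MembershipParams(2.0, 1.0, 3.0, 4.0)


class TestWindowSimilarity:
    def test_self_similarity(self, rng):
        w = rng.uniform(0.5, 1.0, (5, 5))
        spec = dsp.WindowSpec(noise_variance=0.01)
        rec = dsp.window_similarity(w, w, spec)
        assert rec.mean_ratio == 1.0
        assert rec.variance_ratio == 1.0
        assert rec.distance_tji == 0.0
        assert rec.weight == 1.0

    def test_doubled_window_has_mean_ratio_two(self, rng):
        w = rng.uniform(0.5, 1.0, (5, 5))
        rec = dsp.window_similarity(w, 2.0 * w, dsp.WindowSpec(noise_variance=0.01))
        assert rec.mean_ratio == pytest.approx(2.0)

    def test_gaussian_factor_at_distance_tau(self):
        # constant shift c on a flat-plateau pair: t = c; with tau = c the
        # raw Gaussian factor is exp(-1/2)
        base = np.full((5, 5), 1.0)
        shifted = base + 0.1
        spec = dsp.WindowSpec(noise_variance=0.1**2)
        rec = dsp.window_similarity(base, shifted, spec)
        assert rec.distance_tji == pytest.approx(0.1)
        assert rec.membership == 1.0  # ratios 1.1 and 1 sit on the plateaus
        assert rec.weight == pytest.approx(np.exp(-0.5))

    def test_low_membership_records_are_rejected(self):
        base = np.full((5, 5), 1.0)
        alien = np.full((5, 5), 10.0)  # mean ratio 10, far outside Z4
        rec = dsp.window_similarity(base, alien, dsp.WindowSpec(noise_variance=1.0))
        assert rec.membership == 0.0
        assert rec.weight == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dsp.window_similarity(np.ones((5, 5)), np.ones((3, 3)), dsp.WindowSpec())


class TestLLMMSE:
    def test_worked_gain_example(self):
        # window mean 10, variance 8, center 14, noise 2 -> 10 + 0.75*4 = 13
        window = np.array([8.0, 14.0, 8.0])
        assert dsp.llmmse_estimate(window, 2.0) == pytest.approx(13.0)

    def test_no_noise_passes_center_through(self, rng):
        w = rng.normal(size=(5, 5))
        assert dsp.llmmse_estimate(w, 0.0) == pytest.approx(w[2, 2])

    def test_full_noise_collapses_to_mean(self, rng):
        w = rng.normal(size=(5, 5))
        assert dsp.llmmse_estimate(w, 10.0 * w.var()) == pytest.approx(w.mean())

    def test_flat_window_returns_mean(self):
        assert dsp.llmmse_estimate(np.full((3, 3), 4.2), 1.0) == pytest.approx(4.2)


class TestDefuzzify:
    def make(self, value, weight):
        return dsp.SimilarityRecord(
            center=(0, 0), distance_tji=0.0, mean_ratio=1.0,
            variance_ratio=1.0, membership=1.0, weight=weight, center_value=value,
        )

    def test_singleton(self):
        assert dsp.defuzzify_pixel([self.make(3.3, 1.0)]) == 3.3

    def test_equal_weights_average(self):
        recs = [self.make(2.0, 0.5), self.make(4.0, 0.5)]
        assert dsp.defuzzify_pixel(recs) == pytest.approx(3.0)

    def test_weighted_mean(self):
        recs = [self.make(0.0, 0.25), self.make(10.0, 0.75)]
        assert dsp.defuzzify_pixel(recs) == pytest.approx(7.5)

    def test_zero_weights_fall_back(self):
        recs = [self.make(5.0, 0.0)]
        assert dsp.defuzzify_pixel(recs, fallback=1.25) == 1.25
        with pytest.raises(ValueError):
            dsp.defuzzify_pixel(recs)


class TestRestoreImage:
    def test_constant_image_passes_through(self):
        img = np.full((32, 32), 0.6)
        out = dsp.restore_image(img, dsp.WindowSpec(noise_variance=0.05))
        assert np.max(np.abs(out - img)) < 1e-10

    def test_zero_noise_variance_is_exact_identity(self, rng):
        img = rng.uniform(size=(32, 32))
        out = dsp.restore_image(img, dsp.WindowSpec(noise_variance=0.0))
        assert np.array_equal(out, img)

    def test_matches_brute_force_per_pixel_oracle(self, rng):
        """The vectorized path must agree with a literal reimplementation
        from the scalar operations (similarity -> LLMMSE -> defuzzify)."""
        img = rng.uniform(0.2, 1.0, (18, 18))
        lr, sr, tau2 = 1, 3, 0.02
        spec = dsp.WindowSpec(local_radius=lr, search_radius=sr, noise_variance=tau2)
        cfg = dsp.MembershipConfig()
        out = dsp.restore_image(img, spec, cfg)

        pad = sr + lr
        padded = np.pad(img, pad, mode="symmetric")
        expected = np.empty_like(img)
        for r in range(img.shape[0]):
            for c in range(img.shape[1]):
                pr, pc = r + pad, c + pad
                Oj = padded[pr - lr : pr + lr + 1, pc - lr : pc + lr + 1]
                records = []
                for dy in range(-sr, sr + 1):
                    for dx in range(-sr, sr + 1):
                        qr, qc = pr + dy, pc + dx
                        Oi = padded[qr - lr : qr + lr + 1, qc - lr : qc + lr + 1]
                        rec = dsp.window_similarity(
                            Oj, Oi, spec, cfg.z_mean, cfg.z_var, cfg.floor
                        )
                        rec.center_value = dsp.llmmse_estimate(Oi, tau2)
                        records.append(rec)
                expected[r, c] = dsp.defuzzify_pixel(records)
        assert np.allclose(out, expected, atol=1e-10)

    def test_output_confined_to_input_range(self, phantom128):
        noisy = dsp.add_speckle(phantom128, dsp.SpeckleParams(variance=0.1, seed=3))
        out = dsp.restore_image(noisy, dsp.WindowSpec(noise_variance=0.02))
        assert out.min() >= noisy.min() - 1e-12
        assert out.max() <= noisy.max() + 1e-12

    def test_restoration_reduces_mse_against_clean(self, phantom, noisy):
        tau2 = dsp.estimate_speckle_level(noisy) * noisy[noisy > 0.05].mean()
        restored = dsp.restore_image(np.clip(noisy, 0, None), dsp.WindowSpec(noise_variance=tau2))
        mse_noisy = mse_rmse_psnr(np.clip(noisy, 0, 1), phantom)[0]
        mse_restored = mse_rmse_psnr(np.clip(restored, 0, 1), phantom)[0]
        assert mse_restored < mse_noisy

    def test_restoration_retains_edges(self, phantom, noisy):
        tau2 = dsp.estimate_speckle_level(noisy) * noisy[noisy > 0.05].mean()
        restored = dsp.restore_image(np.clip(noisy, 0, None), dsp.WindowSpec(noise_variance=tau2))
        fom_noisy = pratt_fom(np.clip(noisy, 0, 1), phantom)
        fom_restored = pratt_fom(np.clip(restored, 0, 1), phantom)
        assert fom_restored >= fom_noisy

    def test_invalid_window_spec(self):
        with pytest.raises(ValueError):
            dsp.WindowSpec(local_radius=0)
        with pytest.raises(ValueError):
            dsp.WindowSpec(local_radius=3, search_radius=2)
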