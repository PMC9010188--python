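import numpy as np
import pytest
from scipy import ndimage, stats

from eegaffect.core import CANONICAL_BANDS, ClassProfile
from eegaffect import features, synthio
from eegaffect.features import (DETensor, LDSConfig, VARIANCE_FLOOR,
                                differential_entropy, extract_de_tensor,
                                lds_smooth, minmax_standardize, smooth_tensor,
                                tensor_to_plane, to_feature_image)

from conftest import make_recording


class TestDifferentialEntropy:
    def test_zero_point_of_closed_form(self):
        # var([-1, 1]) == 1 (ddof=0); scale so var == 1/(2*pi*e)
        window = np.array([-1.0, 1.0]) / np.sqrt(2 * np.pi * np.e)
        assert differential_entropy(window) == pytest.approx(0.0, abs=1e-12)

    def test_unit_variance_closed_form(self):
        assert differential_entropy([-1.0, 1.0]) == pytest.approx(
            0.5 * np.log(2 * np.pi * np.e), abs=1e-12)
        assert 0.5 * np.log(2 * np.pi * np.e) == pytest.approx(1.4189, abs=5e-4)

    def test_agrees_with_nonparametric_estimator(self):
        rng = np.random.default_rng(0)
        sample = rng.normal(0, 2.0, size=100_000)
        oracle = stats.differential_entropy(sample)  # Vasicek estimator
        assert differential_entropy(sample) == pytest.approx(oracle, abs=0.02)

    def test_constant_window_hits_floor(self):
        floor = 0.5 * np.log(2 * np.pi * np.e * VARIANCE_FLOOR)
        assert differential_entropy(np.full(100, 7.0)) == pytest.approx(floor)

    def test_monotone_in_variance(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=500)
        values = [differential_entropy(base * s) for s in (0.5, 1, 2, 4, 8)]
        assert np.all(np.diff(values) > 0)

    def test_location_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        assert differential_entropy(x + 100.0) == pytest.approx(
            differential_entropy(x), abs=1e-9)

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError, match=">= 2 samples"):
            differential_entropy([1.0])


class TestExtractDETensor:
    def test_conformant_shape(self):
        rec = synthio.generate_recording(synthio.default_profile(0), 9, 200, seed=0)
        # 9 s at 1 s windows -> 62 x 9 x 5 (conformant 180 covered in acceptance)
        tensor = extract_de_tensor(rec, window_length=1.0)
        assert tensor.shape == (62, 9, 5)
        assert np.all(np.isfinite(tensor.values))

    def test_rejects_nonmultiple_duration(self):
        rec = make_recording(duration=9.5, sample_rate=200)
        with pytest.raises(ValueError, match="segment"):
            extract_de_tensor(rec, window_length=1.0)

    def test_gamma_boost_shifts_de_by_half_log_ratio(self):
        neutral = synthio.default_profile(0)
        boosted = ClassProfile(label=0, band_variance=tuple(
            v * (10.0 if b.name == "gamma" else 1.0)
            for b, v in zip(CANONICAL_BANDS, neutral.band_variance)))
        rec = synthio.generate_recording(boosted, 60, 200, seed=21)
        tensor = extract_de_tensor(rec)
        # oracle: closed form on the measured band variances
        from scipy import signal as sg

        def realized_var(band):
            sos = features.band_sos(band.low, band.high, 200)
            return sg.sosfiltfilt(sos, rec.data, axis=1).var()

        ratio = realized_var(CANONICAL_BANDS[4]) / realized_var(CANONICAL_BANDS[0])
        gap = tensor.values[:, :, 4].mean() - tensor.values[:, :, 0].mean()
        # mean log window-variance sits slightly below log total variance for
        # the narrow low-frequency band (few effective DOF per 1 s window),
        # so the closed-form oracle holds only to ~0.15 nats
        assert gap == pytest.approx(0.5 * np.log(ratio), abs=0.2)

    def test_constant_channel_maps_to_floor(self):
        rec = make_recording(n_channels=3, duration=4, sample_rate=200)
        rec.data[1, :] = 5.0
        tensor = extract_de_tensor(rec)
        floor = 0.5 * np.log(2 * np.pi * np.e * VARIANCE_FLOOR)
        # filtering a constant yields (numerically) zero-variance windows
        assert np.all(tensor.values[1] <= floor + 1e-6)


class TestLDSSmooth:
    def test_constant_series_is_fixed_point(self):
        series = np.full(50, 3.7)
        np.testing.assert_array_equal(lds_smooth(series), series)

    def test_alternating_noise_collapses_to_constant(self):
        eps = 0.1
        series = 5.0 + eps * (-1.0) ** np.arange(100)
        smoothed = lds_smooth(series)
        assert np.all(np.abs(smoothed - 5.0) <= eps)
        # oracle: a 20-sample moving average also pins the constant
        oracle = lds_smooth(series, LDSConfig(method="moving_average"))
        assert np.all(np.abs(oracle - 5.0) <= eps)

    def test_length_one_unchanged(self):
        np.testing.assert_array_equal(lds_smooth(np.array([2.5])), [2.5])

    def test_output_length_preserved(self):
        rng = np.random.default_rng(0)
        series = rng.normal(size=77)
        assert lds_smooth(series).shape == (77,)

    def test_first_difference_variance_does_not_increase(self):
        rng = np.random.default_rng(3)
        series = np.cumsum(rng.normal(size=200)) + rng.normal(size=200)
        for config in (LDSConfig(), LDSConfig(method="moving_average")):
            smoothed = lds_smooth(series, config)
            assert np.var(np.diff(smoothed)) <= np.var(np.diff(series))

    def test_mean_preserved_for_stationary_input(self):
        rng = np.random.default_rng(4)
        series = 10.0 + rng.normal(size=150)
        smoothed = lds_smooth(series)
        assert smoothed.mean() == pytest.approx(series.mean(), rel=0.01)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="non-finite"):
            lds_smooth(np.array([1.0, np.nan, 2.0]))

    def test_smooth_tensor_matches_per_series(self, conformant_tensor):
        smoothed = smooth_tensor(conformant_tensor)
        assert smoothed.shape == conformant_tensor.shape
        one = lds_smooth(conformant_tensor.values[5, :, 2])
        np.testing.assert_allclose(smoothed.values[5, :, 2], one)


class TestMinmaxStandardize:
    def test_basic_example(self):
        np.testing.assert_allclose(minmax_standardize([2, 4, 6]), [0, 0.5, 1])

    def test_idempotent_on_attained_extrema(self):
        seq = np.array([0.0, 0.25, 1.0, 0.5])
        np.testing.assert_allclose(minmax_standardize(seq), seq)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        np.testing.assert_allclose(minmax_standardize(3.2 * x + 7),
                                   minmax_standardize(x), atol=1e-12)

    def test_constant_maps_to_half_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = minmax_standardize(np.full(5, 9.0))
        np.testing.assert_array_equal(out, 0.5)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            minmax_standardize([])


class TestFeatureImage:
    def test_shape_and_range(self, conformant_tensor):
        image = to_feature_image(conformant_tensor)
        assert image.values.shape == (224, 224)
        assert image.values.min() >= 0 and image.values.max() <= 1
        assert image.scale_min < image.scale_max

    def test_constant_tensor_gives_half_image(self):
        tensor = DETensor(values=np.full((62, 180, 5), 2.0), window_length=1.0)
        image = to_feature_image(tensor)
        np.testing.assert_array_equal(image.values, 0.5)

    def test_rejects_nonconformant_shape(self):
        tensor = DETensor(values=np.zeros((62, 20, 5)), window_length=1.0)
        with pytest.raises(ValueError, match="62 x 180 x 5"):
            to_feature_image(tensor)

    def test_deterministic(self, conformant_tensor):
        a = to_feature_image(conformant_tensor)
        b = to_feature_image(conformant_tensor)
        np.testing.assert_array_equal(a.values, b.values)

    def test_layout_plane_shape_and_indexing(self, conformant_tensor):
        plane = tensor_to_plane(conformant_tensor)
        assert plane.shape == (310, 180)
        # row b*62 + c holds channel c of band b
        np.testing.assert_array_equal(plane[3 * 62 + 17],
                                      conformant_tensor.values[17, :, 3])

    def test_band_locality_of_layout(self, conformant_tensor, rng):
        """Perturbing one band changes only that band's mapped rows."""
        other = DETensor(values=conformant_tensor.values.copy(), window_length=1.0)
        other.values[:, :, 2] += rng.normal(size=(62, 180))
        p1, p2 = tensor_to_plane(conformant_tensor), tensor_to_plane(other)
        changed = np.where(np.any(p1 != p2, axis=1))[0]
        assert changed.min() >= 2 * 62 and changed.max() < 3 * 62
        # after bilinear resampling the change stays inside the mapped strip
        z1 = ndimage.zoom(p1, (224 / 310, 224 / 180), order=1, mode="nearest",
                          grid_mode=True)
        z2 = ndimage.zoom(p2, (224 / 310, 224 / 180), order=1, mode="nearest",
                          grid_mode=True)
        changed_rows = np.where(np.any(z1 != z2, axis=1))[0]
        lo = int(np.floor(2 * 62 * 224 / 310)) - 1
        hi = int(np.ceil(3 * 62 * 224 / 310)) + 1
        assert changed_rows.min() >= lo and changed_rows.max() <= hi


def test_full_chain_deterministic_and_serializable(tmp_path):
    rec = synthio.generate_recording(synthio.default_profile(1), 30, 200, seed=8)
    tensor = smooth_tensor(extract_de_tensor(rec))
    from eegaffect import io

    io.save_tensor(tensor, tmp_path / "t.h5")
    reloaded = io.load_tensor(tmp_path / "t.h5")
    np.testing.assert_array_equal(reloaded.values, tensor.values)
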