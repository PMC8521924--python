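"""Feature bank: closed forms, brute-force oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegclean import features as F
from eegclean.features import FEATURE_FAMILIES, FEATURE_NAMES, FeatureConfig
from eegclean.io_epochs import EpochSet

FS = 200.0


def sine(freq, n=1000, fs=FS, amp=1.0, phase=0.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


class TestEntropies:
    def test_constant_signal_zero_bits(self):
        assert F.shannon_entropy(np.full(100, 3.7)) == 0.0

    def test_square_wave_one_bit(self):
        x = np.tile([0.0, 1.0], 50)
        assert F.shannon_entropy(x, n_bins=2) == pytest.approx(1.0)

    def test_uniform_noise_log2_bins(self):
        x = np.random.default_rng(0).uniform(0, 1, 10**6)
        assert F.shannon_entropy(x, 64) == pytest.approx(6.0, abs=0.02)

    def test_brute_force_oracle_on_toy_signals(self):
        # direct probability enumeration on 8-sample signals
        for x in ([0, 0, 1, 1, 2, 2, 3, 3], [0, 0, 0, 0, 1, 1, 3, 3], [1, 2, 1, 2, 1, 2, 1, 2]):
            x = np.asarray(x, dtype=float)
            n_bins = 4
            lo, hi = x.min(), x.max()
            edges = np.linspace(lo, hi, n_bins + 1)
            counts = np.zeros(n_bins)
            for v in x:  # manual binning, right edge inclusive in last bin
                b = min(int((v - lo) / (hi - lo) * n_bins), n_bins - 1)
                counts[b] += 1
            p = counts[counts > 0] / len(x)
            expected = -np.sum(p * np.log2(p))
            assert F.shannon_entropy(x, n_bins) == pytest.approx(expected)

    def test_tsallis_two_equal_bins_q2(self):
        x = np.tile([0.0, 1.0], 50)
        s = F.tsallis_entropies(x, q_orders=[2.0], n_bins=2)
        assert s[0] == pytest.approx(0.5)  # 1 - 2*0.25

    def test_tsallis_constant_zero(self):
        s = F.tsallis_entropies(np.full(50, 2.0), q_orders=[1.5, 2.0, 5.0])
        np.testing.assert_allclose(s, 0.0)

    def test_tsallis_q_near_one_matches_shannon_nats(self):
        x = np.random.default_rng(1).normal(size=4000)
        s = F.tsallis_entropies(x, q_orders=[1.0001])[0]
        shannon_nats = F.shannon_entropy(x) * np.log(2)
        assert s == pytest.approx(shannon_nats, abs=1e-3)


class TestSubbandIQ:
    def test_constant_all_zero(self):
        np.testing.assert_array_equal(F.subband_information_quantity(np.full(400, 1.0), FS), 0)

    def test_alpha_sine_concentrates_alpha_band(self):
        iq = F.subband_information_quantity(sine(10, n=1000), FS)
        assert iq[2] > iq[4]  # alpha subband entropy > gamma subband entropy

    def test_white_noise_subbands_comparable(self):
        x = np.random.default_rng(0).standard_normal(4000)
        iq = F.subband_information_quantity(x, FS)
        assert iq.max() / iq.min() < 1.2


class TestCepstrum:
    def test_white_noise_c1_near_zero(self):
        x = np.random.default_rng(0).standard_normal(2**14)
        c1, _ = F.cepstrum_coefficients(x)
        assert abs(c1) < 0.05

    def test_amplitude_scaling_moves_only_c0(self):
        x = np.random.default_rng(1).standard_normal(2048)
        np.testing.assert_allclose(
            F.cepstrum_coefficients(x), F.cepstrum_coefficients(2 * x), atol=1e-9
        )

    def test_echo_appears_at_lag(self):
        rng = np.random.default_rng(2)
        n, k = 2**14, 50
        base = rng.standard_normal(n + k)
        x = base[k:] + 0.5 * base[:-k]
        mag = np.abs(np.fft.rfft(x))
        c = np.fft.irfft(np.log(mag + 1e-12), n=n)
        body = np.abs(c[1 : n // 2])
        assert abs(c[k]) > 10 * np.median(body)
        assert np.argmax(body) == k - 1


class TestHjorth:
    def test_constant_zero(self):
        assert F.hjorth_params(np.full(100, 5.0)) == (0.0, 0.0)

    def test_sine_mobility_closed_form(self):
        mob, _ = F.hjorth_params(sine(10, n=2000))
        assert mob == pytest.approx(2 * np.sin(np.pi * 10 / FS), abs=1e-3)

    def test_sine_complexity_near_one(self):
        _, comp = F.hjorth_params(sine(10, n=2000))
        assert comp == pytest.approx(1.0, abs=1e-2)


class TestNonlinear:
    def test_sine_lyapunov_nonchaotic(self):
        lyap, _, _ = F.nonlinear_features(sine(10, n=1000), FS)
        assert lyap <= 0.01

    def test_white_noise_higuchi_two(self):
        x = np.random.default_rng(0).standard_normal(1000)
        _, fd, _ = F.nonlinear_features(x, FS)
        assert fd == pytest.approx(2.0, abs=0.1)

    def test_ramp_higuchi_one(self):
        _, fd, _ = F.nonlinear_features(np.linspace(0, 1, 1000), FS)
        assert fd == pytest.approx(1.0, abs=0.05)

    def test_short_series_sentinel(self):
        lyap, _, _ = F.nonlinear_features(np.random.default_rng(0).normal(size=30), FS)
        assert lyap == 0.0


class TestAR:
    @pytest.mark.parametrize(
        "a1,a2",
        [(0.5, 0.0), (0.0, 0.0), (1.2, -0.4)],
        ids=["ar1_half", "white", "ar2"],
    )
    def test_generating_process_recovery(self, a1, a2):
        rng = np.random.default_rng(42)
        n = 10**5
        e = rng.standard_normal(n)
        x = np.zeros(n)
        for i in range(2, n):
            x[i] = a1 * x[i - 1] + a2 * x[i - 2] + e[i]
        got = F.arma_coefficients(x)
        assert got[0] == pytest.approx(a1, abs=0.03)
        assert got[1] == pytest.approx(a2, abs=0.03)


class TestSpectral:
    def test_pure_alpha_sine(self):
        out = F.spectral_features(sine(10, n=2000), FS)
        assert out["median_frequency"] == pytest.approx(10, abs=0.5)
        for band in ("delta", "theta", "beta", "gamma"):
            assert out["power_alpha"] > 10 * out[f"power_{band}"]
        assert out["diffuse_slowing"] == 0.0

    def test_slow_sine_flags_diffuse_slowing(self):
        assert F.spectral_features(sine(5, n=2000), FS)["diffuse_slowing"] == 1.0

    def test_sine_std_closed_form(self):
        out = F.spectral_features(sine(10, n=2000, amp=7.0), FS)
        assert out["signal_std"] == pytest.approx(7.0 / np.sqrt(2), rel=0.01)


class TestBurstSuppression:
    def test_constant_low_voltage(self):
        out = F.burst_suppression_features(np.full(1000, 3.0), FS)
        assert out["lv_fraction_5uv"] == 1.0
        assert out["lv_fraction_20uv"] == 1.0
        assert out["n_bursts"] == 0

    def two_burst_signal(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.5, 2000)  # near-zero background
        for start in (300, 1200):
            x[start : start + 100] += 60 * np.sin(2 * np.pi * 10 * np.arange(100) / FS)
        return x

    def test_two_bursts_detected(self):
        out = F.burst_suppression_features(self.two_burst_signal(), FS)
        assert out["n_bursts"] == 2
        assert out["burst_len_mean"] == pytest.approx(0.5, abs=0.05)

    def test_regularity_oracle_and_ordering(self):
        # explicit-loop oracle for the sorted-squared-amplitude formula
        def reg_oracle(x):
            u = sorted((v * v for v in x), reverse=True)
            n = len(u)
            num = sum((i + 1) ** 2 * ui for i, ui in enumerate(u))
            return (3.0 * num / (n * n * sum(u))) ** 0.5

        rng = np.random.default_rng(1)
        x = rng.normal(size=256)
        assert F.regularity(x) == pytest.approx(reg_oracle(x), abs=1e-12)
        stationary = sine(10, n=2000)
        assert F.regularity(stationary) > F.regularity(self.two_burst_signal())

    def test_all_zero_signal(self):
        out = F.burst_suppression_features(np.zeros(1000), FS)
        assert out["regularity"] == 1.0
        assert out["n_bursts"] == 0
        assert out["lv_fraction_5uv"] == 1.0


class TestSpikes:
    def test_injected_spike_counted(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1.0, 1000)
        x[500:510] += 8.0  # 50 ms at 200 Hz, far beyond 3 sigma
        out = F.spike_features(x, FS)
        assert out["n_spikes"] >= 1

    def test_long_excursion_not_a_spike(self):
        x = sine(10, n=1000, amp=1.0)  # bounded, never beyond 3 sigma
        x2 = x.copy()
        x2[400:420] = 0.0
        x2[420:440] += 30.0  # 100 ms plateau: too long
        out = F.spike_features(x2, FS)
        long_runs = out["n_spikes"]
        assert long_runs == 0

    def test_no_excursions(self):
        out = F.spike_features(sine(10, n=1000), FS)
        assert (out["n_spikes"], out["n_sharp_spikes"], out["delta_burst_after_spike"]) == (0, 0, 0)


class TestConnectivity:
    def test_identical_channels(self):
        x = np.random.default_rng(0).standard_normal(400)
        out = F.connectivity_features(np.stack([x, x]), FS)
        assert out["coherence_delta"] == pytest.approx(1.0, abs=1e-9)
        assert out["phase_lag_index"] == pytest.approx(0.0, abs=1e-9)
        assert out["xcorr_magnitude"] == pytest.approx(1.0, abs=1e-6)
        assert out["xcorr_lag"] == 0.0

    def test_delayed_copy_lag(self):
        x = sine(10, n=400)
        y = np.roll(x, 5)
        out = F.connectivity_features(np.stack([x, y]), FS)
        assert out["xcorr_lag"] == pytest.approx(25.0)  # 5 samples at 200 Hz

    def test_quadrature_pli_is_one(self):
        t = np.arange(400) / FS
        out = F.connectivity_features(
            np.stack([np.sin(2 * np.pi * 10 * t), np.cos(2 * np.pi * 10 * t)]), FS
        )
        assert out["phase_lag_index"] == pytest.approx(1.0, abs=0.02)

    def test_granger_directionality(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(500)
        y = np.zeros(500)
        for i in range(1, 500):
            y[i] = 0.9 * x[i - 1] + 0.1 * rng.standard_normal()
        assert F._granger_f(x, y) > F._granger_f(y, x)

    def test_granger_matches_statsmodels(self):
        import warnings

        from statsmodels.tsa.stattools import grangercausalitytests

        rng = np.random.default_rng(3)
        x = rng.standard_normal(500)
        y = np.zeros(500)
        for i in range(1, 500):
            y[i] = 0.7 * x[i - 1] + 0.3 * rng.standard_normal()
        ours = F._granger_f(x, y, max_order=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = grangercausalitytests(np.column_stack([y, x]), maxlag=1, verbose=False)
        theirs = res[1][0]["ssr_ftest"][0]
        assert ours == pytest.approx(theirs, rel=0.02)

    def test_independent_channels_low_mi(self):
        rng = np.random.default_rng(0)
        out = F.mutual_information(rng.standard_normal(4000), rng.standard_normal(4000))
        assert out < 0.05

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="2 channels"):
            F.connectivity_features(np.zeros((1, 100)), FS)


class TestExtraction:
    def test_registry_counts(self):
        assert len(FEATURE_NAMES) == 58
        fam = {f: sum(1 for v in FEATURE_FAMILIES.values() if v == f) for f in set(FEATURE_FAMILIES.values())}
        assert fam == {"complexity": 25, "continuity": 27, "connectivity": 6}

    def test_identical_epochs_identical_vectors(self):
        rng = np.random.default_rng(0)
        ep = rng.normal(0, 10, (3, 400))
        es = EpochSet(np.stack([ep, ep]), FS)
        fm = F.extract_features(es)
        np.testing.assert_array_equal(fm.values[0], fm.values[1])

    def test_parallel_determinism(self, small_set):
        es = small_set["es"].select(range(8))
        serial = F.extract_features(es, FeatureConfig(n_jobs=1))
        parallel = F.extract_features(es, FeatureConfig(n_jobs=2))
        np.testing.assert_array_equal(serial.values, parallel.values)

    def test_all_finite_on_degenerate_epochs(self):
        data = np.zeros((3, 2, 400))
        data[1] = 5.0  # constant
        data[2, 0] = sine(10, n=400)
        fm = F.extract_features(EpochSet(data, FS))
        assert np.all(np.isfinite(fm.values))
        assert fm.values.shape == (3, 58)

    def test_amplitude_scale_covariance(self):
        rng = np.random.default_rng(7)
        ep = rng.normal(0, 10, (3, 400)) + sine(10, n=400)
        es1 = EpochSet(ep[None], FS)
        es2 = EpochSet(2 * ep[None], FS)
        f1 = F.extract_features(es1).to_dataframe().iloc[0]
        f2 = F.extract_features(es2).to_dataframe().iloc[0]
        assert f2["signal_std"] == pytest.approx(2 * f1["signal_std"], rel=1e-6)
        for band in ("delta", "alpha", "gamma"):
            assert f2[f"power_{band}"] == pytest.approx(4 * f1[f"power_{band}"], rel=1e-6)
        for inv in ("hjorth_mobility", "phase_lag_index", "coherence_delta", "regularity", "diffuse_slowing"):
            assert f2[inv] == pytest.approx(f1[inv], rel=1e-6, abs=1e-9)

    def test_csv_round_trip(self, tmp_path):
        fm = F.extract_features(EpochSet(np.random.default_rng(0).normal(size=(2, 2, 400)), FS))
        fm.to_csv(tmp_path / "f.csv")
        back = F.FeatureMatrix.from_csv(tmp_path / "f.csv")
        np.testing.assert_allclose(back.values, fm.values, rtol=1e-12)
        assert back.names == fm.names


class TestStandardize:
    def test_zero_mean_unit_std(self):
        fm = F.FeatureMatrix(np.random.default_rng(0).normal(size=(50, 58)))
        z = F.standardize(fm)
        np.testing.assert_allclose(z.values.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(z.values.std(axis=0), 1, atol=1e-9)

    def test_constant_column_maps_to_zero(self):
        vals = np.random.default_rng(0).normal(size=(20, 58))
        vals[:, 7] = 3.14
        z = F.standardize(F.FeatureMatrix(vals))
        np.testing.assert_array_equal(z.values[:, 7], 0.0)
        assert np.all(np.isfinite(z.values))

    def test_inverse_round_trip(self):
        vals = np.random.default_rng(1).normal(size=(20, 58))
        z = F.standardize(F.FeatureMatrix(vals))
        back = F.destandardize(z)
        np.testing.assert_allclose(back.values, vals, atol=1e-9)


class TestRangeInvariants:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_entropy_and_range_properties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, rng.uniform(0.5, 50), size=400)
        assert F.shannon_entropy(x) >= 0
        assert np.all(F.tsallis_entropies(x) >= 0)
        assert 0 < F.regularity(x) <= 1.0
        bs = F.burst_suppression_features(x, FS)
        for t in (5, 10, 20):
            assert 0 <= bs[f"lv_fraction_{t}uv"] <= 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_pair_measures_bounded(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(2, 300))
        out = F.connectivity_features(data, FS)
        assert 0 <= out["coherence_delta"] <= 1 + 1e-9
        assert 0 <= out["phase_lag_index"] <= 1 + 1e-9
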