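"""HRV feature extraction against hand-derived values and brute-force oracles."""

import math

import numpy as np
import pytest

from hrvgap import (
    BeatSeries,
    GapAwareView,
    Periodogram,
    RRSeries,
    SpectralBands,
    SynthParams,
    band_powers,
    compute_all,
    default_grid,
    derive_params,
    hr_mean,
    lomb_psd,
    no_interpolation_view,
    apply_mask,
    simulate_mask,
    pnn50,
    poincare,
    rmssd,
    sdnn,
    synth_beats,
)

WORKED = RRSeries(np.array([1.0, 0.8, 1.0, 0.8]))


# ---------------------------------------------------------------------------
# brute-force oracles: plain Python loops, independent of the implementation


def _oracle_hr_mean(d):
    return sum(60.0 / x for x in d) / len(d)


def _oracle_rmssd(d):
    diffs = [d[i + 1] - d[i] for i in range(len(d) - 1)]
    return math.sqrt(sum(x * x for x in diffs) / len(diffs))


def _oracle_sdnn(d):
    m = sum(d) / len(d)
    return math.sqrt(sum((x - m) ** 2 for x in d) / (len(d) - 1))


def _oracle_pnn50(d):
    diffs = [d[i + 1] - d[i] for i in range(len(d) - 1)]
    return sum(1 for x in diffs if abs(x) > 0.050) / len(d)


def _oracle_poincare(d):
    """Rotate each (d_n, d_{n+1}) pair by 45 degrees; coordinate sample SDs."""
    u = [(d[i + 1] - d[i]) / math.sqrt(2) for i in range(len(d) - 1)]
    v = [(d[i + 1] + d[i]) / math.sqrt(2) for i in range(len(d) - 1)]

    def _sd(xs):
        m = sum(xs) / len(xs)
        return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))

    return _sd(u), _sd(v)


class TestWorkedValues:
    def test_hr_mean(self):
        assert hr_mean(WORKED) == pytest.approx(67.5)

    def test_rmssd(self):
        assert rmssd(WORKED) == pytest.approx(0.2)

    def test_sdnn(self):
        assert sdnn(WORKED) == pytest.approx(math.sqrt(0.04 / 3), abs=1e-12)
        assert sdnn(WORKED) == pytest.approx(0.11547, abs=5e-6)

    def test_pnn50_counts_over_intervals_not_pairs(self):
        # 3 exceedances over 4 RR-intervals
        assert pnn50(WORKED) == pytest.approx(0.75)

    def test_constant_rr_features_vanish(self):
        const = RRSeries(np.full(50, 0.8))
        assert hr_mean(const) == pytest.approx(75.0)
        assert rmssd(const) == 0.0
        assert sdnn(const) == pytest.approx(0.0, abs=1e-12)
        assert pnn50(const) == 0.0
        sd1, sd2 = poincare(const)
        assert sd1 == pytest.approx(0.0, abs=1e-12)
        assert sd2 == pytest.approx(0.0, abs=1e-12)

    def test_pnn50_threshold_is_strict(self):
        d = RRSeries(np.array([0.800, 0.850, 0.800, 0.850]))  # diffs exactly 50 ms
        assert pnn50(d) == 0.0
        d2 = RRSeries(np.array([0.800, 0.851, 0.800]))
        assert pnn50(d2) == pytest.approx(2 / 3)


class TestBruteForceOracles:
    """Vectorised features match loop implementations on 200 random inputs."""

    @pytest.mark.parametrize("feature,oracle", [
        (hr_mean, _oracle_hr_mean),
        (rmssd, _oracle_rmssd),
        (sdnn, _oracle_sdnn),
        (pnn50, _oracle_pnn50),
    ])
    def test_time_domain(self, feature, oracle):
        rng = np.random.default_rng(101)
        for _ in range(200):
            n = rng.integers(5, 60)
            d = rng.uniform(0.4, 1.4, n)
            got = feature(RRSeries(d))
            assert got == pytest.approx(oracle(list(d)), rel=1e-12)

    def test_poincare_rotation_oracle(self):
        rng = np.random.default_rng(202)
        for _ in range(200):
            n = rng.integers(5, 100)
            d = rng.uniform(0.4, 1.4, n)
            sd1, sd2 = poincare(RRSeries(d))
            o1, o2 = _oracle_poincare(list(d))
            assert sd1 == pytest.approx(o1, rel=1e-12)
            assert sd2 == pytest.approx(o2, rel=1e-12)

    def test_poincare_alternating_closed_form(self):
        a, b = 0.8, 1.0
        n = 201  # durations a,b,a,b,... -> 200 lag-1 pairs
        d = np.tile([a, b], n)[:n]
        sd1, sd2 = poincare(RRSeries(d))
        diffs = np.abs(np.diff(d)) / math.sqrt(2)
        # all rotated x-coordinates are +/-|a-b|/sqrt(2); sample-sd factor applies
        m = len(diffs)
        expected_sd1 = (b - a) / math.sqrt(2) * math.sqrt(m / (m - 1))
        assert sd1 == pytest.approx(expected_sd1, rel=1e-12)
        assert sd2 == pytest.approx(0.0, abs=1e-12)

    def test_sd1_sd2_variance_identity(self):
        """sd1^2 + sd2^2 equals the sum of the lag-1 coordinate variances
        (exact algebra of the 45-degree rotation)."""
        rng = np.random.default_rng(303)
        for _ in range(50):
            d = rng.uniform(0.4, 1.4, rng.integers(5, 80))
            sd1, sd2 = poincare(RRSeries(d))
            v = np.var(d[:-1], ddof=1) + np.var(d[1:], ddof=1)
            assert sd1**2 + sd2**2 == pytest.approx(v, rel=1e-10)


class TestGapAwareStatistics:
    def test_gap_pairs_excluded_from_hr_mean(self):
        # beats 0.8s apart with beat index 3 missing
        ts = np.array([0.8, 1.6, 2.4, 4.0, 4.8])
        view = GapAwareView(ts, np.array([True, True, False, True]))
        expected = np.mean([60 / 0.8, 60 / 0.8, 60 / 0.8])
        assert hr_mean(view) == pytest.approx(expected)

    def test_difference_terms_need_both_durations_flagged(self):
        ts = np.array([1.0, 1.8, 2.6, 4.2, 5.0, 5.9])
        flags = np.array([True, True, False, True, True])
        view = GapAwareView(ts, flags)
        d = np.diff(ts)
        valid_diffs = [d[1] - d[0], d[4] - d[3]]
        expected = math.sqrt(np.mean(np.square(valid_diffs)))
        assert rmssd(view) == pytest.approx(expected, rel=1e-12)

    def test_gap_aware_matches_bruteforce_over_simulated_mask(self, noisy_window):
        mask = simulate_mask(derive_params(0.3, 10), noisy_window.n_beats, seed=17)
        view = no_interpolation_view(apply_mask(noisy_window, mask))
        d = view.durations
        ok = view.consecutive
        brute_d = [d[i] for i in range(len(d)) if ok[i]]
        assert sdnn(view) == pytest.approx(_oracle_sdnn(brute_d), rel=1e-12)
        assert hr_mean(view) == pytest.approx(_oracle_hr_mean(brute_d), rel=1e-12)

    def test_all_masked_window_yields_all_nan(self):
        view = GapAwareView(np.array([1.0]), np.array([], dtype=bool))
        fs = compute_all(view)
        assert all(math.isnan(v) for v in fs.as_dict().values())


class TestSpectral:
    def test_lf_tone_recovered_at_grid_resolution(self):
        beats = synth_beats(SynthParams(300.0, lf_amp=3.0, hf_amp=0.0,
                                        noise_sd=0.0, seed=1))
        psd = lomb_psd(beats)
        peak = psd.frequencies[np.argmax(psd.power)]
        assert abs(peak - 0.1) <= 0.002

    def test_hf_tone_lands_in_hf_band(self):
        beats = synth_beats(SynthParams(300.0, lf_amp=0.0, hf_amp=2.0,
                                        noise_sd=0.0, seed=1))
        bp = band_powers(lomb_psd(beats))
        assert bp["hf"] > bp["lf"] and bp["hf"] > bp["vlf"]

    def test_constant_rr_spectrum_is_flat_zero(self, constant_rr):
        psd = lomb_psd(constant_rr)
        assert np.all(psd.power < 1e-20)

    def test_tone_survives_30pct_burst_gaps_without_imputation(self):
        """Lomb-Scargle handles the uneven sampling of a gapped series."""
        beats = synth_beats(SynthParams(300.0, lf_amp=3.0, hf_amp=0.0,
                                        noise_sd=0.0, seed=2))
        mask = simulate_mask(derive_params(0.3, 10), beats.n_beats, seed=6)
        view = no_interpolation_view(apply_mask(beats, mask))
        psd = lomb_psd(view)
        peak = psd.frequencies[np.argmax(psd.power)]
        assert abs(peak - 0.1) <= 0.002

    def test_band_partition_sums_to_total(self, noisy_window):
        bp = band_powers(lomb_psd(noisy_window))
        assert bp["vlf"] + bp["lf"] + bp["hf"] == pytest.approx(
            bp["total_power"], rel=1e-12)

    def test_single_mass_band_membership(self):
        psd = Periodogram(np.array([0.1]), np.array([2.0]))
        bp = band_powers(psd)
        assert bp["lf"] == bp["total_power"] == 2.0
        assert bp["vlf"] == 0.0 and bp["hf"] == 0.0
        assert math.isnan(bp["lf_hf"])

    def test_default_grid_bounds_and_step(self):
        g = default_grid()
        assert g[0] == pytest.approx(0.002)
        assert g[-1] == pytest.approx(0.400)
        assert np.allclose(np.diff(g), 0.002)

    def test_lomb_matches_least_squares_oracle(self, noisy_window):
        """lomb_psd equals an explicit Lomb least-squares sinusoid fit at the
        duration midpoint times (independent oracle for the spectral path)."""
        ts = noisy_window.timestamps
        t = (ts[:-1] + ts[1:]) / 2.0
        y = noisy_window.durations - noisy_window.durations.mean()
        for f in (0.05, 0.13, 0.31):
            w = 2 * np.pi * f
            tau = (np.arctan2(np.sum(np.sin(2 * w * t)), np.sum(np.cos(2 * w * t)))
                   / (2 * w))
            c = np.cos(w * (t - tau))
            s = np.sin(w * (t - tau))
            oracle = 0.5 * ((y @ c) ** 2 / (c @ c) + (y @ s) ** 2 / (s @ s))
            got = lomb_psd(noisy_window, grid=np.array([f])).power[0]
            assert got == pytest.approx(oracle * 2.0 / len(y), rel=1e-9)


class TestComputeAll:
    def test_gap_free_synthetic_window_all_finite(self, noisy_window):
        fs = compute_all(noisy_window)
        assert fs.all_defined

    def test_offset_invariance(self, noisy_window):
        """All features depend on durations and relative times only."""
        fs0 = compute_all(noisy_window)
        fs1 = compute_all(noisy_window.shifted(1234.5))
        for k, v in fs0.as_dict().items():
            assert v == pytest.approx(fs1.as_dict()[k], rel=1e-9), k

    def test_rr_input_uses_cumsum_timestamps(self, noisy_window):
        fs_beats = compute_all(noisy_window)
        fs_rr = compute_all(RRSeries(noisy_window.durations))
        for k in ("sdnn", "rmssd", "lf", "hf", "total_power"):
            assert fs_beats.as_dict()[k] == pytest.approx(fs_rr.as_dict()[k], rel=1e-9)

    def test_nonmonotone_series_marked_invalid_not_clamped(self):
        ts = np.array([0.8, 1.6, 1.5, 2.4, 3.2, 4.0])
        bad = BeatSeries(ts, validate=False)
        fs = compute_all(bad)
        assert all(math.isnan(v) for v in fs.as_dict().values())

    def test_undefined_features_are_nan_never_zero(self):
        two = BeatSeries(np.array([0.8, 1.6]))
        fs = compute_all(two)
        assert fs.hr_mean == pytest.approx(75.0)
        assert math.isnan(fs.rmssd) and math.isnan(fs.sd1)
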