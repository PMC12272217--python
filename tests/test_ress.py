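"""RESS: narrowband filtering, GED fitting, SNR spectra, normalisation."""

import warnings

import numpy as np
import pytest

import periflick as pf
from periflick.containers import Epochs
from periflick.ress import (
    apply_filter,
    compute_covariances,
    fit_ress,
    fit_ress_from_epochs,
    gaussian_bandpass,
    normalize_attention,
    snr_spectrum,
    time_resolved_snr,
)

SFREQ = 500.0


def sinusoid(freq, n, sfreq=SFREQ, amp=1.0, phase=0.0):
    t = np.arange(n) / sfreq
    return amp * np.sin(2 * np.pi * freq * t + phase)


def make_epochs(data, sfreq=SFREQ, sides=None):
    n_trials, n_ch, _ = data.shape
    import pandas as pd

    meta = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "condition": "control",
            "side": sides if sides is not None else ["left"] * n_trials,
        }
    )
    return Epochs(
        data=data,
        sfreq=sfreq,
        ch_names=[f"ch{i}" for i in range(n_ch)],
        metadata=meta,
    )


class TestGaussianBandpass:
    def test_center_frequency_gain_unity(self):
        x = sinusoid(13.0, int(20 * SFREQ))
        y = gaussian_bandpass(x, 13.0, 1.0, SFREQ)
        assert y.std() / x.std() == pytest.approx(1.0, abs=0.01)

    def test_half_amplitude_at_half_fwhm(self):
        x = sinusoid(13.5, int(40 * SFREQ))  # f + fwhm/2
        y = gaussian_bandpass(x, 13.0, 1.0, SFREQ)
        assert y.std() / x.std() == pytest.approx(0.5, abs=0.02)

    def test_white_noise_band_concentration(self, rng):
        x = rng.standard_normal(int(60 * SFREQ))
        y = gaussian_bandpass(x, 13.0, 1.0, SFREQ)
        spec = np.abs(np.fft.rfft(y)) ** 2
        freqs = np.fft.rfftfreq(len(y), 1 / SFREQ)
        inside = spec[np.abs(freqs - 13.0) <= 2.0].sum()
        assert inside / spec.sum() > 0.95

    def test_zero_phase(self):
        x = sinusoid(13.0, int(20 * SFREQ))
        y = gaussian_bandpass(x, 13.0, 2.0, SFREQ)
        mid = slice(2000, -2000)
        r = np.corrcoef(x[mid], y[mid])[0, 1]
        assert r > 0.9999

    def test_short_series_warns(self):
        with pytest.warns(RuntimeWarning, match="short"):
            gaussian_bandpass(np.ones(int(0.5 * SFREQ)), 13.0, 1.0, SFREQ)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError):
            gaussian_bandpass(np.ones(1000), 249.9, 1.0, SFREQ)


class TestComputeCovariances:
    def test_identical_trials_average_to_single_covariance(self, rng):
        trial = rng.standard_normal((4, int(9 * SFREQ)))
        data = np.stack([trial, trial])
        ep = make_epochs(data)
        S2, R2 = compute_covariances(ep, 13.0)
        S1, R1 = compute_covariances(make_epochs(trial[np.newaxis]), 13.0)
        assert np.allclose(S2, S1)
        assert np.allclose(R2, R1)

    def test_single_channel_target_dominates_S(self, rng):
        n = int(9 * SFREQ)
        data = 0.1 * rng.standard_normal((3, 5, n))
        data[:, 2] += sinusoid(13.0, n, amp=5.0)
        S, _ = compute_covariances(make_epochs(data), 13.0)
        assert np.argmax(np.diag(S)) == 2

    def test_target_free_data_gives_S_close_to_R(self, rng):
        data = rng.standard_normal((6, 4, int(9 * SFREQ)))
        S, R = compute_covariances(make_epochs(data), 13.0)
        dist = np.linalg.norm(S - R) / np.linalg.norm(R)
        assert dist < 0.35  # white noise: equal expected power in all bands


class TestFitRESS:
    def test_identity_pair_degenerate(self):
        filt = fit_ress(np.eye(4), np.eye(4))
        assert filt.degenerate
        assert np.allclose(filt.eigenvalues, 1.0, atol=0.02)

    def test_diagonal_closed_form(self):
        filt = fit_ress(np.diag([4.0, 1.0]), np.eye(2), shrinkage=0.0)
        assert filt.eigenvalues[0] == pytest.approx(4.0)
        assert np.abs(filt.weights) == pytest.approx([1.0, 0.0], abs=1e-12)
        assert not filt.degenerate

    def test_asymmetric_matrices_rejected(self):
        M = np.array([[1.0, 0.5], [0.0, 1.0]])
        with pytest.raises(ValueError):
            fit_ress(M, np.eye(2))

    def test_eigenvalues_sorted_descending(self, rng):
        A = rng.standard_normal((6, 6))
        S = A @ A.T
        B = rng.standard_normal((6, 6))
        R = B @ B.T + 6 * np.eye(6)
        filt = fit_ress(S, R)
        assert np.all(np.diff(filt.eigenvalues) <= 1e-12)

    def test_ged_optimality_beats_every_channel(self, rng):
        # GED maximises the Rayleigh quotient, so the component SNR at f
        # must reach at least the best single channel's SNR (brute force)
        n = int(9 * SFREQ)
        n_better = 0
        for rep in range(20):
            mixing = rng.standard_normal(6)
            source = sinusoid(13.0, n, amp=1.0, phase=rng.uniform(0, 2 * np.pi))
            data = 1.0 * rng.standard_normal((8, 6, n))
            data += np.einsum("c,t->ct", mixing, source)[np.newaxis]
            ep = make_epochs(data)
            filt = fit_ress_from_epochs(ep, 13.0, sign_channel_name="ch0")
            comp = apply_filter(ep, filt)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                comp_snr = snr_spectrum(comp, SFREQ).at(13.0)
                chan_snrs = [
                    snr_spectrum(data[:, c, :], SFREQ).at(13.0) for c in range(6)
                ]
            if comp_snr >= max(chan_snrs) * 0.999:
                n_better += 1
        assert n_better == 20

    def test_top_eigenvalue_above_one_with_target_power(self, rng):
        n = int(9 * SFREQ)
        data = rng.standard_normal((6, 4, n))
        data[:, 1] += sinusoid(13.0, n, amp=2.0)
        ep = make_epochs(data)
        filt = fit_ress_from_epochs(ep, 13.0, sign_channel_name="ch0")
        assert filt.eigenvalues[0] > 1.0

    def test_serialization_roundtrip(self, rng):
        A = rng.standard_normal((4, 4))
        filt = fit_ress(A @ A.T, np.eye(4), target_freq=13.0)
        d = filt.to_dict()
        assert d["target_freq"] == 13.0
        assert len(d["weights"]) == 4
        import json

        json.dumps(d)  # must be JSON-serialisable


class TestApplyFilter:
    def test_basis_vector_returns_channel(self, rng):
        data = rng.standard_normal((3, 4, 100))
        ep = make_epochs(data)
        filt = fit_ress(np.eye(4), np.eye(4))
        filt.weights = np.eye(4)[2]
        assert np.allclose(apply_filter(ep, filt), data[:, 2, :])

    def test_linearity(self, rng):
        data = rng.standard_normal((2, 4, 50))
        filt = fit_ress(np.eye(4), np.eye(4))
        filt.weights = rng.standard_normal(4)
        assert np.allclose(apply_filter(data * 2, filt), 2 * apply_filter(data, filt))

    def test_channel_mismatch_rejected(self, rng):
        filt = fit_ress(np.eye(3), np.eye(3))
        with pytest.raises(ValueError):
            apply_filter(rng.standard_normal((2, 5, 50)), filt)


class TestSNRSpectrum:
    def test_white_noise_snr_near_one(self, rng):
        x = rng.standard_normal((40, int(9 * SFREQ)))
        spec = snr_spectrum(x, SFREQ)
        sel = (spec.freqs >= 5) & (spec.freqs <= 30)
        assert 0.8 <= spec.snr[sel].mean() <= 1.25

    def test_snr_scales_with_squared_amplitude(self, rng):
        n = int(9 * SFREQ)
        noise = rng.standard_normal((30, n))
        snrs = []
        for amp in (0.5, 1.0):
            x = noise + sinusoid(13.0, n, amp=amp)
            snrs.append(snr_spectrum(x, SFREQ).at(13.0))
        assert snrs[1] / snrs[0] == pytest.approx(4.0, rel=0.25)

    def test_off_target_tone_gives_unit_snr(self, rng):
        n = int(9 * SFREQ)
        x = sinusoid(13.0, n) + 0.1 * rng.standard_normal((30, n))
        # evaluated where the noise neighbourhood excludes the tone itself
        assert snr_spectrum(x, SFREQ).at(20.0) == pytest.approx(1.0, abs=0.5)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal((5, int(9 * SFREQ))) + sinusoid(13.0, int(9 * SFREQ))
        a = snr_spectrum(x, SFREQ)
        b = snr_spectrum(x * 37.5, SFREQ)
        assert np.allclose(a.snr, b.snr, equal_nan=True)

    def test_invalid_neighborhood(self):
        with pytest.raises(ValueError):
            snr_spectrum(np.ones(5000), SFREQ, skip=2.0, span=1.0)


class TestTimeResolvedSNR:
    def test_stationary_tone_flat_trace(self, rng):
        n = int(9 * SFREQ)
        x = sinusoid(13.0, n, amp=2.0) + rng.standard_normal((10, n))
        tc = time_resolved_snr(x, 13.0, SFREQ)
        assert tc.values.std() / tc.values.mean() < 0.2

    def test_noise_only_near_unity(self, rng):
        tc = time_resolved_snr(
            rng.standard_normal((20, int(9 * SFREQ))), 13.0, SFREQ
        )
        assert tc.values.mean() == pytest.approx(1.0, abs=0.3)

    def test_onset_ramp_crossing_within_one_second(self, small_epochs, small_filters):
        # ground-truth envelope: attended source ramps up 0.5 s after cue
        # onset (3 s); the trace must cross half its plateau within 1 s
        left = small_epochs.select(
            (small_epochs.metadata["side"] == "left").to_numpy()
        )
        filt = small_filters[("control", 13.0)]
        comp = apply_filter(left, filt)
        tc = time_resolved_snr(comp, 13.0, SFREQ, window=2.0, step=0.1)
        plateau = tc.values[(tc.times > 4.5) & (tc.times < 6.0)].mean()
        baseline = tc.values[tc.times < 2.5].mean()
        half = baseline + 0.5 * (plateau - baseline)
        crossing = tc.times[
            (tc.times > 2.5) & (tc.values > half)
        ][0]
        assert 2.5 < crossing < 4.0  # window centre; cue at 3 s

    def test_window_longer_than_epoch_rejected(self, rng):
        with pytest.raises(ValueError):
            time_resolved_snr(rng.standard_normal(100), 13.0, SFREQ, window=2.0)


class TestNormalizeAttention:
    def test_self_subtraction_zeroes_signal(self, small_epochs, small_filters):
        filt = small_filters[("control", 13.0)]
        comp = apply_filter(small_epochs, filt)
        diff = comp - comp
        assert np.all(diff == 0)

    def test_fixation_phase_symmetric_near_zero(self, small_epochs, small_filters):
        # during fixation both tags run at the same amplitude, so the
        # target-minus-nontarget SNR difference should vanish on average
        left = small_epochs.select(
            (small_epochs.metadata["side"] == "left").to_numpy()
        )
        tc = normalize_attention(
            left,
            small_filters[("control", 13.0)],
            small_filters[("control", 15.0)],
            mode="snr",
        )
        fix = tc.values[tc.times < 2.0]
        assert abs(fix.mean()) < 2.0  # SNR units; fixation symmetry

    def test_attended_positive_during_cue(self, small_epochs, small_filters):
        left = small_epochs.select(
            (small_epochs.metadata["side"] == "left").to_numpy()
        )
        tc = normalize_attention(
            left,
            small_filters[("control", 13.0)],
            small_filters[("control", 15.0)],
            mode="snr",
        )
        cue = tc.values[(tc.times > 4.0) & (tc.times < 6.0)].mean()
        fix = tc.values[tc.times < 2.0].mean()
        assert cue > fix
        assert tc.normalized

    def test_signal_mode_positive_during_cue(self, small_epochs, small_filters):
        left = small_epochs.select(
            (small_epochs.metadata["side"] == "left").to_numpy()
        )
        tc = normalize_attention(
            left,
            small_filters[("control", 13.0)],
            small_filters[("control", 15.0)],
            mode="signal",
        )
        cue = tc.values[(tc.times > 4.0) & (tc.times < 6.0)].mean()
        fix = tc.values[tc.times < 2.0].mean()
        assert cue > fix

    def test_unknown_mode_rejected(self, small_epochs, small_filters):
        with pytest.raises(ValueError):
            normalize_attention(
                small_epochs,
                small_filters[("control", 13.0)],
                small_filters[("control", 15.0)],
                mode="power",
            )
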