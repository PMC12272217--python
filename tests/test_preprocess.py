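"""Preprocessing chain: FIR filter, bad channels, interpolation, epoching."""

import numpy as np
import pandas as pd
import pytest

import periflick as pf
from periflick.containers import Recording
from periflick.preprocess import (
    ARTIFACT_CLASSES,
    bandpass_filter,
    design_bandpass,
    detect_bad_channels,
    epoch,
    prune_components,
    rereference_average,
    spherical_interpolate,
)
from periflick.synth import default_montage_positions

SFREQ = 500.0


def noise_recording(rng, n_ch=8, n_samples=20_000, positions=False):
    names = ["Fp1", "Fz", "Cz", "C3", "C4", "O1", "Oz", "O2"][:n_ch]
    rec = Recording(
        data=rng.standard_normal((n_ch, n_samples)),
        sfreq=SFREQ,
        ch_names=names,
        positions=default_montage_positions(names) if positions else {},
    )
    return rec


class TestBandpassFilter:
    def test_passband_sinusoid_preserved(self, rng):
        t = np.arange(30_000) / SFREQ
        rec = noise_recording(rng, n_samples=30_000)
        rec.data[:] = np.sin(2 * np.pi * 20.0 * t)
        out = bandpass_filter(rec)
        mid = slice(5000, 25_000)
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_dc_strongly_attenuated(self, rng):
        rec = noise_recording(rng)
        rec.data += 50.0
        out = bandpass_filter(rec)
        # DC lies in the stopband: offset reduced by > 40 dB
        assert abs(out.data[:, 3000:-3000].mean()) < 50.0 * 1e-2

    def test_minus_6db_points_at_cutoffs(self):
        # frequency response of the designed taps at the stated cutoffs
        h = design_bandpass(SFREQ)
        freqs = np.fft.rfftfreq(2**18, d=1.0 / SFREQ)
        H = np.abs(np.fft.rfft(h, n=2**18))
        for fc in (0.5, 40.5):
            gain_db = 20 * np.log10(H[np.argmin(np.abs(freqs - fc))])
            assert gain_db == pytest.approx(-6.02, abs=0.5)

    def test_zero_phase(self, rng):
        # a symmetric filter applied with delay compensation must not shift
        # the peak of a band-limited pulse
        rec = noise_recording(rng, n_samples=30_000)
        t = np.arange(30_000) / SFREQ
        rec.data[:] = np.sin(2 * np.pi * 10 * t) * np.exp(-((t - 30) ** 2))
        out = bandpass_filter(rec)
        assert abs(np.argmax(out.data[0]) - np.argmax(rec.data[0])) <= 1

    def test_too_short_recording_rejected(self, rng):
        rec = noise_recording(rng, n_samples=1000)
        with pytest.raises(ValueError):
            bandpass_filter(rec)


class TestDetectBadChannels:
    def test_statistically_identical_channels_pass(self, rng):
        rec = noise_recording(rng)
        rec.data = np.tile(rec.data[0], (rec.n_channels, 1))
        assert detect_bad_channels(rec) == []

    def test_broadband_noisy_channel_flagged(self, rng):
        rec = noise_recording(rng)
        rec.data[3] *= 20.0
        assert detect_bad_channels(rec) == [rec.ch_names[3]]

    def test_flat_channel_flagged(self, rng):
        rec = noise_recording(rng)
        rec.data[5] = 1e-8 * rng.standard_normal(rec.n_samples)
        assert detect_bad_channels(rec) == [rec.ch_names[5]]

    def test_needs_four_channels(self, rng):
        rec = noise_recording(rng)
        rec.data = rec.data[:3]
        rec.ch_names = rec.ch_names[:3]
        with pytest.raises(ValueError):
            detect_bad_channels(rec)


class TestSphericalInterpolate:
    def test_no_bads_is_identity(self, rng):
        rec = noise_recording(rng, positions=True)
        out = spherical_interpolate(rec, [])
        assert np.array_equal(out.data, rec.data)

    def test_constant_scalp_pattern_reproduced(self, rng):
        # spherical splines reproduce a spatially constant field exactly
        names = list(pf.SimConfig().ch_names)
        ts = rng.standard_normal(5000)
        rec = Recording(
            data=np.tile(ts, (len(names), 1)),
            sfreq=SFREQ,
            ch_names=names,
            positions=default_montage_positions(names),
        )
        out = spherical_interpolate(rec, ["Oz"])
        oz = names.index("Oz")
        err = np.abs(out.data[oz] - ts).max() / np.abs(ts).max()
        assert err < 0.01
        assert out.n_interpolated == 1

    def test_smooth_topography_leave_one_out(self, rng):
        # leave-out oracle: drop Oz from a smooth dipolar field and check
        # the spline estimate correlates with the held-out truth
        names = list(pf.SimConfig().ch_names)
        pos = default_montage_positions(names)
        direction = np.array([0.0, -1.0, 0.5])
        gains = np.array([pos[c] @ direction for c in names])
        gains /= np.abs(gains).max()
        ts = rng.standard_normal(5000)
        rec = Recording(
            data=np.outer(gains, ts),
            sfreq=SFREQ,
            ch_names=names,
            positions=pos,
        )
        true_oz = rec.data[names.index("Oz")].copy()
        out = spherical_interpolate(rec, ["Oz"])
        r = np.corrcoef(out.data[names.index("Oz")], true_oz)[0, 1]
        assert r > 0.9
        # good channels untouched
        good = [i for i, c in enumerate(names) if c != "Oz"]
        assert np.array_equal(out.data[good], rec.data[good])

    def test_too_few_good_channels(self, rng):
        rec = noise_recording(rng, positions=True)
        with pytest.raises(ValueError):
            spherical_interpolate(rec, rec.ch_names[:5])


class TestAverageReference:
    def test_two_channel_arithmetic(self):
        rec = Recording(
            data=np.array([[1.0], [3.0]]), sfreq=SFREQ, ch_names=["a", "b"]
        )
        out = rereference_average(rec)
        assert out.data[:, 0].tolist() == [-1.0, 1.0]

    def test_idempotent(self, rng):
        rec = noise_recording(rng)
        once = rereference_average(rec)
        twice = rereference_average(once)
        assert np.allclose(once.data, twice.data)

    def test_column_sums_zero_and_rank_ledger(self, rng):
        rec = noise_recording(rng)
        out = rereference_average(rec)
        assert np.abs(out.data.sum(axis=0)).max() < 1e-9
        assert out.reference == "average"
        assert out.effective_rank == rec.n_channels - 1


class TestPruneComponents:
    def make_orthogonal_case(self, rng, n=8, n_samples=10_000):
        from scipy.stats import ortho_group

        Q = ortho_group.rvs(n, random_state=int(rng.integers(2**31)))
        sources = rng.standard_normal((n, n_samples))
        rec = noise_recording(rng, n_ch=n, n_samples=n_samples)
        rec.data = Q @ sources
        return rec, Q.T, sources  # unmixing = Q^T for orthogonal mixing

    def scores(self, n, overrides=None):
        df = pd.DataFrame(0.05, index=range(n), columns=list(ARTIFACT_CLASSES))
        df["brain"] = 1.0 - df.sum(axis=1)
        for (row, col), val in (overrides or {}).items():
            df.loc[row, "brain"] += df.loc[row, col] - val
            df.loc[row, col] = val
        return df

    def test_all_below_threshold_roundtrip(self, rng):
        rec, unmix, _ = self.make_orthogonal_case(rng)
        out, removed = prune_components(rec, unmix, self.scores(8))
        assert removed == []
        assert np.allclose(out.data, rec.data, atol=1e-10)

    def test_flagged_component_projection_removed(self, rng):
        rec, unmix, sources = self.make_orthogonal_case(rng)
        out, removed = prune_components(
            rec, unmix, self.scores(8, {(2, "ocular"): 0.9})
        )
        assert removed == [2]
        # residual variance equals the variance of the remaining components
        assert np.sum(out.data**2) == pytest.approx(
            np.sum(sources[[i for i in range(8) if i != 2]] ** 2), rel=1e-9
        )
        # the removed component no longer projects into the data
        assert np.abs(unmix[2] @ out.data).max() < 1e-9

    def test_exact_boundary_score_retained(self, rng):
        rec, unmix, _ = self.make_orthogonal_case(rng)
        out, removed = prune_components(
            rec, unmix, self.scores(8, {(1, "muscular"): 0.70})
        )
        assert removed == []

    def test_all_flagged_refused(self, rng):
        rec, unmix, _ = self.make_orthogonal_case(rng)
        bad = self.scores(8, {(i, "line"): 0.95 for i in range(8)})
        with pytest.raises(ValueError):
            prune_components(rec, unmix, bad)


class TestEpoch:
    def test_all_trials_epoched(self, small_session, small_config):
        rec, _ = small_session
        ep = epoch(rec)
        assert ep.n_trials == small_config.n_trials
        assert ep.n_times == int(9 * rec.sfreq)
        assert list(ep.metadata.columns) == ["trial", "condition", "side"]

    def test_overrunning_trial_dropped(self, small_session):
        rec, _ = small_session
        clipped = rec.copy()
        last_fix = rec.events[rec.events.phase == "fixation"]["sample"].max()
        clipped.data = clipped.data[:, : last_fix + int(rec.sfreq)]  # 1 s left
        clipped.events = clipped.events[
            clipped.events["sample"] < clipped.data.shape[1]
        ]
        with pytest.warns(RuntimeWarning, match="dropped 1"):
            ep = epoch(clipped)
        assert ep.n_trials == rec.events.phase.eq("fixation").sum() - 1

    def test_no_events_rejected(self, rng):
        rec = noise_recording(rng)
        with pytest.raises(ValueError):
            epoch(rec)


class TestPreprocessChain:
    def test_full_chain_report(self, small_session, small_config):
        rec, _ = small_session
        epochs, report = pf.preprocess(rec)
        assert report["n_trials"] == small_config.n_trials
        assert report["bad_channels"] == []
        # rank ledger: 32 channels - 0 interpolated - 1 (average reference)
        assert report["effective_rank"] == rec.n_channels - 1
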