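"""Rhythmic entrainment source separation (RESS).

A RESS spatial filter maximises the signal-to-noise ratio at a stimulation
frequency by solving the generalized eigenvalue problem ``S w = lambda R w``
between the channel covariance of narrowband-filtered data at the target
frequency (S) and the average covariance at neighbouring frequencies (R).
The top eigenvector acts as a spatial filter whose backprojection yields a
single component time series per trial.

Because the filter is fitted to maximise target-frequency power, raw
component SNR overestimates the stimulus response; the attention analysis
therefore subtracts the *nontarget* component (the filter centred on the
other tag frequency) from the target component before quantifying SNR
(:func:`normalize_attention`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .containers import Epochs

__all__ = [
    "RESSFilter",
    "SNRSpectrum",
    "SNRTimeCourse",
    "gaussian_bandpass",
    "compute_covariances",
    "fit_ress",
    "fit_ress_from_epochs",
    "apply_filter",
    "snr_spectrum",
    "time_resolved_snr",
    "normalize_attention",
]


@dataclass
class RESSFilter:
    """Fitted RESS spatial filter for one target frequency.

    ``weights`` is the unit-norm top generalized eigenvector; ``eigenvalues``
    the full descending spectrum; ``topography = S @ weights`` the forward
    projection of the component.  ``degenerate`` is set when the eigenvalue
    spectrum is (numerically) flat and the component therefore arbitrary.
    """

    target_freq: float
    weights: np.ndarray
    eigenvalues: np.ndarray
    topography: np.ndarray
    S: np.ndarray = field(repr=False)
    R: np.ndarray = field(repr=False)
    fwhm: float = 1.0
    neighbor_distance: float = 1.0
    neighbor_fwhm: float = 1.0
    shrinkage: float = 0.01
    fit_window: tuple[float, float] = (3.0, 9.0)
    degenerate: bool = False

    def to_dict(self) -> dict:
        """JSON-serialisable representation (weights, eigenvalues, parameters)."""
        return {
            "target_freq": self.target_freq,
            "weights": self.weights.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "topography": self.topography.tolist(),
            "fwhm": self.fwhm,
            "neighbor_distance": self.neighbor_distance,
            "neighbor_fwhm": self.neighbor_fwhm,
            "shrinkage": self.shrinkage,
            "fit_window": list(self.fit_window),
            "degenerate": self.degenerate,
        }


@dataclass
class SNRSpectrum:
    """Spectral SNR: power at each bin over mean power of its neighbours."""

    freqs: np.ndarray
    snr: np.ndarray
    skip: float
    span: float

    def at(self, freq: float) -> float:
        """SNR at the bin nearest to ``freq``."""
        return float(self.snr[np.argmin(np.abs(self.freqs - freq))])


@dataclass
class SNRTimeCourse:
    """Sliding-window SNR at one frequency, per trial and trial-averaged."""

    times: np.ndarray
    values: np.ndarray  # trial-mean trace
    per_trial: np.ndarray = field(repr=False)  # (n_trials, n_times)
    freq: float = 0.0
    normalized: bool = False


def gaussian_bandpass(
    x: np.ndarray, f: float, fwhm: float, sfreq: float
) -> np.ndarray:
    """Zero-phase narrowband filter: Gaussian amplitude response around ``f``.

    The FFT of the signal (last axis) is multiplied by a Gaussian centred
    at ``f`` whose amplitude response has full width ``fwhm`` at half
    maximum, then inverted; being a real symmetric spectral weighting, the
    operation is zero-phase by construction.
    """
    x = np.asarray(x, dtype=float)
    if f + fwhm >= sfreq / 2:
        raise ValueError("f + fwhm must lie below Nyquist")
    n = x.shape[-1]
    # below ~2/fwhm seconds the band is not spectrally resolvable
    if n < 2.0 / max(fwhm, 1e-12) * sfreq:
        warnings.warn(
            f"series of {n / sfreq:.2f} s is short for fwhm={fwhm} Hz "
            "(spectral resolution insufficient)",
            RuntimeWarning,
            stacklevel=2,
        )
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    sd = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    gauss = np.exp(-((freqs - f) ** 2) / (2 * sd**2))
    return np.fft.irfft(np.fft.rfft(x, axis=-1) * gauss, n=n, axis=-1)


def _trial_covariance(x: np.ndarray) -> np.ndarray:
    """Channel covariance of one (channels x time) block, time-demeaned."""
    xc = x - x.mean(axis=1, keepdims=True)
    return xc @ xc.T / (x.shape[1] - 1)


def compute_covariances(
    epochs: Epochs,
    f: float,
    fwhm: float = 1.0,
    neighbor_distance: float = 1.0,
    neighbor_fwhm: float = 1.0,
    window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Target-band and neighbour-band covariance matrices.

    ``S`` averages, over trials, the channel covariance of data narrowband
    filtered at ``f``; ``R`` averages the covariances at the two flanking
    frequencies ``f - d`` and ``f + d``.  The default window covers the cue
    and target phases (0 to 6 s after cue onset).
    """
    if window is None:
        cue = epochs.phase_onsets.get("cue", 3.0)
        window = (cue, cue + 6.0)
    sl = epochs.time_slice(*window)
    if sl.stop - sl.start < 2:
        raise ValueError("fit window outside epochs")

    n_ch = len(epochs.ch_names)
    S = np.zeros((n_ch, n_ch))
    R = np.zeros((n_ch, n_ch))
    freqs_R = (f - neighbor_distance, f + neighbor_distance)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for trial in epochs.data:
            S += _trial_covariance(gaussian_bandpass(trial, f, fwhm, epochs.sfreq)[:, sl])
            for fr in freqs_R:
                R += 0.5 * _trial_covariance(
                    gaussian_bandpass(trial, fr, neighbor_fwhm, epochs.sfreq)[:, sl]
                )
    S /= epochs.n_trials
    R /= epochs.n_trials
    S = 0.5 * (S + S.T)
    R = 0.5 * (R + R.T)
    return S, R


def fit_ress(
    S: np.ndarray,
    R: np.ndarray,
    shrinkage: float = 0.01,
    target_freq: float = 0.0,
    sign_channel: int | None = None,
    **meta,
) -> RESSFilter:
    """Generalized eigendecomposition of the covariance pair.

    Solves ``S w = lambda R_sh w`` with the neighbour covariance shrunk
    toward a scaled identity, ``R_sh = (1 - g) R + g mean(eig(R)) I``,
    which keeps the problem well posed on rank-deficient (average-
    referenced, interpolated) data.  The eigenvector with the largest
    eigenvalue becomes the spatial filter; its sign is fixed so the
    component topography ``S w`` is positive at ``sign_channel`` (the
    posterior midline channel in the session pipeline).
    """
    S = np.asarray(S, dtype=float)
    R = np.asarray(R, dtype=float)
    if S.shape != R.shape or S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S and R must be square matrices of equal size")
    if not (np.allclose(S, S.T, atol=1e-8) and np.allclose(R, R.T, atol=1e-8)):
        raise ValueError("S and R must be symmetric")

    mean_eig = np.trace(R) / R.shape[0]
    R_sh = (1.0 - shrinkage) * R + shrinkage * mean_eig * np.eye(R.shape[0])
    try:
        evals, evecs = linalg.eigh(S, R_sh)
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            f"generalized eigendecomposition failed (R singular after "
            f"shrinkage={shrinkage}): {err}"
        ) from err
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    w = evecs[:, 0]
    w = w / np.linalg.norm(w)
    topo = S @ w
    ref = sign_channel if sign_channel is not None else int(np.argmax(np.abs(topo)))
    if topo[ref] < 0:
        w, topo = -w, -topo

    spread = evals[0] - evals[-1]
    degenerate = bool(spread <= 1e-10 * max(abs(evals[0]), 1.0))
    return RESSFilter(
        target_freq=target_freq,
        weights=w,
        eigenvalues=evals,
        topography=topo,
        S=S,
        R=R,
        shrinkage=shrinkage,
        degenerate=degenerate,
        **meta,
    )


def fit_ress_from_epochs(
    epochs: Epochs,
    f: float,
    fwhm: float = 1.0,
    neighbor_distance: float = 1.0,
    neighbor_fwhm: float = 1.0,
    shrinkage: float = 0.01,
    window: tuple[float, float] | None = None,
    sign_channel_name: str = "Oz",
) -> RESSFilter:
    """Covariance computation plus GED in one call, on a set of epochs."""
    S, R = compute_covariances(epochs, f, fwhm, neighbor_distance, neighbor_fwhm, window)
    sign_idx = (
        epochs.ch_names.index(sign_channel_name)
        if sign_channel_name in epochs.ch_names
        else None
    )
    if window is None:
        cue = epochs.phase_onsets.get("cue", 3.0)
        window = (cue, cue + 6.0)
    return fit_ress(
        S,
        R,
        shrinkage=shrinkage,
        target_freq=f,
        sign_channel=sign_idx,
        fwhm=fwhm,
        neighbor_distance=neighbor_distance,
        neighbor_fwhm=neighbor_fwhm,
        fit_window=tuple(window),
    )


def apply_filter(epochs: Epochs | np.ndarray, filt: RESSFilter) -> np.ndarray:
    """Backproject the filter: component(t) = w^T data(t), per trial.

    Accepts an :class:`Epochs` or a raw (trials x channels x time) /
    (channels x time) array; returns (trials x time) or (time,).
    """
    data = epochs.data if isinstance(epochs, Epochs) else np.asarray(epochs)
    if data.shape[-2] != filt.weights.size:
        raise ValueError(
            f"channel count {data.shape[-2]} does not match filter "
            f"({filt.weights.size} weights)"
        )
    return np.einsum("c,...ct->...t", filt.weights, data)


def snr_spectrum(
    x: np.ndarray, sfreq: float, skip: float = 0.5, span: float = 2.0
) -> SNRSpectrum:
    """Neighbour-bin SNR spectrum of a component time series.

    Power at each FFT bin is divided by the mean power over flanking bins
    at distances in (skip, span] on both sides, so featureless noise has
    SNR ~ 1 and a sinusoid stands out as a sharp peak at its frequency.
    Multi-trial input (trials x time) is averaged at the power-spectrum
    level before the ratio.
    """
    if span <= skip:
        raise ValueError("span must exceed skip")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[-1]
    if n < 2 * sfreq:
        warnings.warn(
            "series shorter than 2 s; SNR spectrum poorly resolved",
            RuntimeWarning,
            stacklevel=2,
        )
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    power = (np.abs(np.fft.rfft(x, axis=-1)) ** 2).mean(axis=0)

    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    k_skip = int(np.floor(skip / df))
    k_span = int(np.floor(span / df))
    offsets = np.concatenate(
        [np.arange(-k_span, -k_skip), np.arange(k_skip + 1, k_span + 1)]
    )
    snr = np.full_like(power, np.nan)
    idx = np.arange(len(power))
    neigh = idx[:, None] + offsets[None, :]
    valid = (neigh >= 0) & (neigh < len(power))
    neigh_clipped = np.clip(neigh, 0, len(power) - 1)
    noise_sum = np.where(valid, power[neigh_clipped], 0.0).sum(axis=1)
    noise_cnt = valid.sum(axis=1)
    ok = noise_cnt > 0
    noise = np.where(ok, noise_sum / np.maximum(noise_cnt, 1), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr[ok] = power[ok] / noise[ok]
    return SNRSpectrum(freqs=freqs, snr=snr, skip=skip, span=span)


def time_resolved_snr(
    component: np.ndarray,
    f: float,
    sfreq: float,
    window: float = 2.0,
    step: float = 0.1,
    tmin: float = 0.0,
    skip: float = 0.5,
    span: float = 2.0,
) -> SNRTimeCourse:
    """Sliding-window SNR at frequency ``f`` for component time series.

    Each window of ``window`` seconds (stepped by ``step``) yields one SNR
    value per trial via :func:`snr_spectrum`; time stamps mark window
    centres relative to ``tmin`` (trial onset).
    """
    comp = np.atleast_2d(np.asarray(component, dtype=float))
    n_win = int(round(window * sfreq))
    n_step = max(1, int(round(step * sfreq)))
    if n_win > comp.shape[-1]:
        raise ValueError("window longer than the epoch")
    starts = np.arange(0, comp.shape[-1] - n_win + 1, n_step)
    per_trial = np.empty((comp.shape[0], len(starts)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j, s0 in enumerate(starts):
            seg = comp[:, s0 : s0 + n_win]
            freqs = np.fft.rfftfreq(n_win, d=1.0 / sfreq)
            power = np.abs(np.fft.rfft(seg, axis=-1)) ** 2
            fi = int(np.argmin(np.abs(freqs - f)))
            df = freqs[1] - freqs[0]
            k_skip = int(np.floor(skip / df))
            k_span = int(np.floor(span / df))
            offs = np.concatenate(
                [np.arange(-k_span, -k_skip), np.arange(k_skip + 1, k_span + 1)]
            )
            neigh = fi + offs
            neigh = neigh[(neigh >= 0) & (neigh < len(freqs))]
            noise = power[:, neigh].mean(axis=1)
            per_trial[:, j] = power[:, fi] / noise
    times = tmin + (starts + n_win / 2) / sfreq
    return SNRTimeCourse(
        times=times,
        values=per_trial.mean(axis=0),
        per_trial=per_trial,
        freq=f,
        normalized=False,
    )


def normalize_attention(
    epochs: Epochs,
    filt_target: RESSFilter,
    filt_nontarget: RESSFilter,
    mode: str = "signal",
    window: float = 2.0,
    step: float = 0.1,
) -> SNRTimeCourse:
    """Attention-normalised SNR time course (target minus nontarget).

    The RESS filter overfits power at its own frequency, so the component
    of the *nontarget* tag frequency is used as a within-trial control:

    - ``mode='signal'`` (default): the nontarget component time series is
      subtracted from the target component per trial, and the SNR of the
      difference is computed at the target frequency.
    - ``mode='snr'``: SNR traces are computed separately for the target
      component (at the target frequency) and the nontarget component (at
      the nontarget frequency) and subtracted, so the trace reads directly
      as an attended-minus-unattended SNR difference.
    """
    if mode not in ("signal", "snr"):
        raise ValueError(f"unknown mode {mode!r} (use 'signal' or 'snr')")
    comp_t = apply_filter(epochs, filt_target)
    comp_n = apply_filter(epochs, filt_nontarget)
    if mode == "signal":
        tc = time_resolved_snr(
            comp_t - comp_n, filt_target.target_freq, epochs.sfreq, window, step,
            tmin=epochs.tmin,
        )
    else:
        tc_t = time_resolved_snr(
            comp_t, filt_target.target_freq, epochs.sfreq, window, step,
            tmin=epochs.tmin,
        )
        tc_n = time_resolved_snr(
            comp_n, filt_nontarget.target_freq, epochs.sfreq, window, step,
            tmin=epochs.tmin,
        )
        per_trial = tc_t.per_trial - tc_n.per_trial
        tc = SNRTimeCourse(
            times=tc_t.times,
            values=per_trial.mean(axis=0),
            per_trial=per_trial,
            freq=filt_target.target_freq,
        )
    tc.normalized = True
    return tc
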