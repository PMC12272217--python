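"""Continuous-data conditioning and epoching.

The pipeline order is fixed: band-pass filter -> bad-channel detection ->
spherical interpolation -> average reference -> (optional independent-
component pruning) -> epoching.  Each step updates the rank ledger carried
by the :class:`~periflick.containers.Recording` so downstream
eigendecompositions can be adjusted for rank deficiency.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal

from .containers import Epochs, Recording

__all__ = [
    "design_bandpass",
    "bandpass_filter",
    "detect_bad_channels",
    "spherical_interpolate",
    "rereference_average",
    "prune_components",
    "epoch",
    "preprocess",
    "ARTIFACT_CLASSES",
]

#: Independent-component classes treated as artifactual; a component is
#: discarded when its confidence score for any of these exceeds 0.70.
ARTIFACT_CLASSES = ("ocular", "muscular", "heart", "line", "electrode", "other")

DEFAULT_NUMTAPS = 1651  # symmetric FIR at 500 Hz; integer group delay
DEFAULT_CUTOFFS = (0.5, 40.5)  # -6 dB (half-amplitude) points, Hz


def design_bandpass(
    sfreq: float,
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
    numtaps: int | None = None,
) -> np.ndarray:
    """Design the linear-phase band-pass FIR (Hamming-windowed sinc).

    The windowed-sinc design places the -6 dB (half-amplitude) points at
    the cutoff frequencies, giving a 1-40 Hz passband for the default
    0.5/40.5 Hz cutoffs.  The default length of 1651 taps is defined at
    500 Hz and rescaled proportionally (kept odd) for other rates so the
    transition bands stay fixed in Hz.
    """
    if numtaps is None:
        numtaps = int(round(DEFAULT_NUMTAPS * sfreq / 500.0))
        numtaps += 1 - numtaps % 2  # odd length -> integer group delay
    return signal.firwin(
        numtaps, cutoffs, pass_zero=False, window="hamming", fs=sfreq
    )


def bandpass_filter(
    rec: Recording,
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
    numtaps: int | None = None,
) -> Recording:
    """Zero-phase band-pass filter of the continuous recording.

    The symmetric FIR is applied once per channel by convolution centred on
    each sample (group delay compensated), so the net phase response is
    zero; edges are reflection-padded by half the filter length.
    """
    h = design_bandpass(rec.sfreq, cutoffs, numtaps)
    if rec.n_samples <= len(h):
        raise ValueError(
            f"recording ({rec.n_samples} samples) shorter than filter ({len(h)} taps)"
        )
    half = len(h) // 2
    out = rec.copy()
    padded = np.pad(rec.data, ((0, 0), (half, half)), mode="reflect")
    filtered = signal.oaconvolve(padded, h[np.newaxis, :], mode="valid", axes=1)
    out.data = filtered[:, : rec.n_samples]
    return out


def _channel_log_power(
    data: np.ndarray, sfreq: float, band: tuple[float, float] = (1.0, 40.0)
) -> np.ndarray:
    """Mean log10 Welch PSD per channel over the given band (2 s segments)."""
    nperseg = min(int(2 * sfreq), data.shape[1])
    freqs, psd = signal.welch(data, fs=sfreq, nperseg=nperseg, axis=1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    with np.errstate(divide="ignore"):
        logp = np.log10(np.maximum(psd[:, sel], np.finfo(float).tiny))
    return logp.mean(axis=1)


def detect_bad_channels(
    rec: Recording, n_sd: float = 3.0, band: tuple[float, float] = (1.0, 40.0)
) -> list[str]:
    """Channels whose average spectral power deviates from the rest.

    A channel is flagged when its mean log-power (Welch PSD over ``band``)
    lies more than ``n_sd`` robust standard deviations (1.4826 x MAD) from
    the median across channels.  Both unusually noisy and unusually flat
    (e.g. disconnected) channels are caught.
    """
    if rec.n_channels < 4:
        raise ValueError("bad-channel detection needs at least 4 channels")
    power = _channel_log_power(rec.data, rec.sfreq, band)
    med = np.median(power)
    robust_sd = 1.4826 * np.median(np.abs(power - med))
    if robust_sd == 0:
        return []
    flagged = np.abs(power - med) > n_sd * robust_sd
    return [rec.ch_names[i] for i in np.flatnonzero(flagged)]


def spherical_interpolate(rec: Recording, bad: list[str]) -> Recording:
    """Replace bad channels by spherical-spline estimates from the others.

    Delegates the spline computation to MNE's EEG implementation on the
    recording's own electrode positions; good channels are untouched and
    the interpolation count is added to the rank ledger.
    """
    unknown = [b for b in bad if b not in rec.ch_names]
    if unknown:
        raise ValueError(f"bad channels not in recording: {unknown}")
    if not bad:
        return rec.copy()
    n_good = rec.n_channels - len(bad)
    if n_good < 4:
        raise ValueError("spherical interpolation needs at least 4 good channels")
    if not rec.positions:
        raise ValueError("channel positions required for spherical interpolation")

    import mne

    mne.set_log_level("ERROR")
    info = mne.create_info(rec.ch_names, rec.sfreq, ch_types="eeg")
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose="ERROR")  # uV -> V
    montage = mne.channels.make_dig_montage(
        ch_pos={c: rec.positions[c] for c in rec.ch_names}, coord_frame="head"
    )
    raw.set_montage(montage)
    raw.info["bads"] = list(bad)
    raw.interpolate_bads(reset_bads=True, mode="accurate")

    out = rec.copy()
    bad_idx = [rec.ch_names.index(b) for b in bad]
    out.data[bad_idx] = raw.get_data()[bad_idx] * 1e6  # good channels untouched
    out.n_interpolated = rec.n_interpolated + len(bad)
    return out


def rereference_average(rec: Recording) -> Recording:
    """Re-reference to the average of all channels.

    Subtracts the instantaneous channel mean; afterwards the per-sample
    channel mean is identically zero and the data rank drops by one
    (recorded in the rank ledger through ``reference='average'``).
    Idempotent.
    """
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    out = rec.copy()
    out.data = rec.data - rec.data.mean(axis=0, keepdims=True)
    out.reference = "average"
    return out


def prune_components(
    rec: Recording,
    unmixing: np.ndarray,
    class_scores: pd.DataFrame,
    threshold: float = 0.70,
) -> tuple[Recording, list[int]]:
    """Remove independent components classified as artifactual.

    Components whose confidence score is strictly above ``threshold`` for
    any artifact class (ocular, muscular, heart, line, electrode, other)
    are dropped and the data reconstructed from the remainder.  The
    component classifier itself is external: this function owns only the
    pruning rule, taking an unmixing matrix (components x channels, e.g.
    from an infomax ICA restricted to the effective data rank) and a table
    of per-component class scores.

    Returns the cleaned recording and the indices of removed components.
    """
    unmixing = np.asarray(unmixing, dtype=float)
    n_comp = unmixing.shape[0]
    if unmixing.shape[1] != rec.n_channels:
        raise ValueError("unmixing columns must match channel count")
    if len(class_scores) != n_comp:
        raise ValueError("class_scores rows must match component count")
    artifact_cols = [c for c in class_scores.columns if c in ARTIFACT_CLASSES]
    if not artifact_cols:
        raise ValueError(f"class_scores must contain columns from {ARTIFACT_CLASSES}")
    row_sums = class_scores.sum(axis=1).to_numpy()
    if np.any(row_sums > 1.0 + 1e-6):
        raise ValueError("class score rows must sum to at most 1")

    flagged = (class_scores[artifact_cols].to_numpy() > threshold).any(axis=1)
    removed = list(np.flatnonzero(flagged))
    if len(removed) == n_comp:
        raise ValueError("all components classified artifactual; refusing to prune")
    keep = np.flatnonzero(~flagged)

    sources = unmixing @ rec.data
    mixing = np.linalg.pinv(unmixing)
    out = rec.copy()
    out.data = mixing[:, keep] @ sources[keep]
    return out, removed


def epoch(rec: Recording, duration: float = 9.0) -> Epochs:
    """Cut one epoch per trial, time-locked to fixation onset (t = 0).

    Every fixation event must be followed by cue and target events for the
    same trial inside the window; trials overrunning the recording end are
    dropped with a warning.
    """
    n_win = int(round(duration * rec.sfreq))
    if not len(rec.events):
        raise ValueError("recording has no events")
    fix = rec.events[rec.events["phase"] == "fixation"]
    rows, arrays = [], []
    n_dropped = 0
    for _, ev in fix.iterrows():
        start = int(ev["sample"])
        if start + n_win > rec.n_samples:
            n_dropped += 1
            continue
        same_trial = rec.events[rec.events["trial"] == ev["trial"]]
        if not {"cue", "target"} <= set(same_trial["phase"]):
            n_dropped += 1
            continue
        arrays.append(rec.data[:, start : start + n_win])
        rows.append(
            {"trial": ev["trial"], "condition": ev["condition"], "side": ev["side"]}
        )
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} incomplete trial(s) at epoching",
            RuntimeWarning,
            stacklevel=2,
        )
    if not arrays:
        raise ValueError("no complete trials to epoch")
    return Epochs(
        data=np.stack(arrays),
        sfreq=rec.sfreq,
        ch_names=list(rec.ch_names),
        metadata=pd.DataFrame(rows).reset_index(drop=True),
    )


def preprocess(
    rec: Recording,
    epoch_duration: float = 9.0,
    ica_pruner=None,
) -> tuple[Epochs, dict]:
    """Run the full conditioning chain in its fixed order.

    ``ica_pruner``, when given, is a callable ``Recording -> (Recording,
    removed_indices)`` slotted between average referencing and epoching
    (e.g. an external ICA + component classifier wrapped around
    :func:`prune_components`); synthetic sessions contain no ocular or
    muscular artifacts, so the default skips it.

    Returns the epochs and a report dict (bad channels, counts, rank).
    """
    filtered = bandpass_filter(rec)
    bad = detect_bad_channels(filtered)
    interp = spherical_interpolate(filtered, bad)
    reref = rereference_average(interp)
    removed: list[int] = []
    if ica_pruner is not None:
        reref, removed = ica_pruner(reref)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        epochs = epoch(reref, epoch_duration)
    report = {
        "bad_channels": bad,
        "n_interpolated": reref.n_interpolated,
        "n_components_removed": len(removed),
        "effective_rank": reref.effective_rank,
        "n_trials": epochs.n_trials,
    }
    return epochs, report
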