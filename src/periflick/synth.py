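"""Synthetic EEG sessions for the frequency-tagged spatial-attention task.

Generates 32-channel, 500 Hz recordings of the three-phase trial paradigm
(3 s fixation / 3 s cue / 3 s target) with steady-state responses at the
two tag frequencies (13 Hz left, 15 Hz right), 1/f background noise, and
occipital alpha that is suppressed when gaze leaves the central fixation
cross.  Every session comes with ground truth (per-trial attended side,
condition, injected source amplitudes, and mixing topographies) so each
downstream stage can be tested against known quantities.

The statistical structure mirrors the task design: 30 trials per
modulation-depth condition (control / periliminal / subliminal, 90 trials
total), both flickers driven at a baseline amplitude during fixation
(central gaze), and the attended-side source raised by ``attention_ratio``
with a 0.5 s linear onset ramp once the cue appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Recording

__all__ = [
    "Condition",
    "SimConfig",
    "GroundTruth",
    "make_pink_noise",
    "make_ssvep_source",
    "contrast_response",
    "occipital_topography",
    "default_montage_positions",
    "simulate_session",
]

#: 32-channel 10-20 layout with a parieto-occipital row, matching a typical
#: 32-electrode research cap.
CHANNELS_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "PO4", "PO8",
    "O1", "Oz", "O2",
]


def default_montage_positions(ch_names: list[str] | None = None) -> dict[str, np.ndarray]:
    """3-D scalp positions (metres) from the standard 10-20 montage."""
    import mne

    mne.set_log_level("ERROR")
    montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    names = ch_names if ch_names is not None else CHANNELS_32
    missing = [c for c in names if c not in pos]
    if missing:
        raise ValueError(f"channels missing from standard montage: {missing}")
    return {c: np.asarray(pos[c], dtype=float) for c in names}


@dataclass(frozen=True)
class Condition:
    """One modulation-depth condition of the task.

    ``response_gain`` is the effective SSVEP response gain of the condition
    (multiplies ``ssvep_gain``).  When None it is derived from the
    modulation depth through :func:`contrast_response`.  The defaults carry
    an explicit calibration: near-threshold contrasts drive the visual
    response far more weakly than a compressive power law of physical
    contrast alone would predict, and the subliminal condition (one
    staircase step below threshold) sits well below the periliminal one.
    """

    name: str
    modulation_depth: float
    response_gain: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must lie in [0, 1]")


def _default_conditions() -> tuple[Condition, ...]:
    return (
        Condition("control", 0.70, response_gain=1.0),
        Condition("periliminal", 0.02, response_gain=0.45),
        Condition("subliminal", 0.0198, response_gain=0.12),
    )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated session.

    Amplitudes are in microvolts at the topography maximum.  The attended
    source runs at ``attention_ratio`` times the unattended baseline during
    the cue and target phases, reached through a linear ramp of
    ``onset_ramp`` seconds after cue onset.
    """

    n_channels: int = 32
    ch_names: tuple[str, ...] = tuple(CHANNELS_32)
    sfreq: float = 500.0
    n_trials_per_condition: int = 30
    conditions: tuple[Condition, ...] = field(default_factory=_default_conditions)
    phase_durations: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tag_freqs: tuple[float, float] = (13.0, 15.0)  # (left, right)
    ssvep_gain: float = 1.2  # uV per unit effective contrast, unattended baseline
    attention_ratio: float = 2.0
    onset_ramp: float = 0.5  # s, latency+rise of the attention effect
    harmonic_weights: tuple[float, float] = (1.0, 0.3)  # at f and 2f
    noise_exponent: float = 1.0
    noise_rms: float = 10.0  # uV per channel, broadband 1/f background
    alpha_band: tuple[float, float] = (8.0, 12.0)
    alpha_amplitude: float = 4.0  # uV RMS at topography maximum
    alpha_suppression: float = 0.7  # multiplier during cue/target (gaze shift)
    topo_sigma: float = 0.045  # m, Gaussian width of source topographies
    inter_trial_gap: float = 1.0  # s of signal-free background between trials
    contrast_gamma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ch_names) != self.n_channels:
            raise ValueError("ch_names length must equal n_channels")
        if any(d <= 0 for d in self.phase_durations):
            raise ValueError("phase durations must be positive")
        f_l, f_r = self.tag_freqs
        if f_l == f_r:
            raise ValueError("tag frequencies must be distinct")
        if max(f_l, f_r) >= self.sfreq / 2:
            raise ValueError("tag frequencies must lie below Nyquist")
        if not self.attention_ratio > 0:
            raise ValueError("attention_ratio must be positive")
        if self.noise_exponent < 0:
            raise ValueError("noise_exponent must be non-negative")

    @property
    def trial_duration(self) -> float:
        return float(sum(self.phase_durations))

    @property
    def n_trials(self) -> int:
        return self.n_trials_per_condition * len(self.conditions)


@dataclass
class GroundTruth:
    """What was actually injected into a simulated session.

    ``trials`` has one row per trial: condition, attended side, and the true
    per-phase source amplitudes (microvolts) for the left (13 Hz) and right
    (15 Hz) tag sources.  ``topographies`` maps side -> channel weight
    vector (unit maximum) through which that source was mixed.
    """

    trials: pd.DataFrame
    topographies: dict[str, np.ndarray]
    config: SimConfig


def make_pink_noise(
    n_samples: int,
    exponent: float,
    sfreq: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Zero-mean noise whose power spectrum follows ``f**(-exponent)``.

    Shapes the spectrum of Gaussian white noise by ``f**(-exponent/2)`` in
    the frequency domain (DC removed) and normalises to unit RMS.
    ``exponent=0`` returns white noise; ``exponent=1`` the 1/f background
    typical of resting EEG.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if exponent < 0:
        raise ValueError("exponent must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n_samples)
    x -= x.mean()
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def make_ssvep_source(
    freq: float,
    envelope: np.ndarray,
    harmonic_weights: tuple[float, ...] = (1.0, 0.3),
    sfreq: float = 500.0,
    phase: float = 0.0,
) -> np.ndarray:
    """Steady-state response at ``freq``: sinusoids at f and 2f under an envelope.

    The response is modelled at the fundamental and first harmonic only
    (the frequencies the analysis characterises), with relative amplitudes
    ``harmonic_weights``; a full square-wave response is deliberately not
    synthesised.  The envelope (values in [0, 1]) carries onset dynamics.
    """
    envelope = np.asarray(envelope, dtype=float)
    for k, w in enumerate(harmonic_weights, start=1):
        if w > 0 and k * freq >= sfreq / 2:
            raise ValueError(
                f"harmonic {k}f = {k * freq} Hz exceeds Nyquist ({sfreq / 2} Hz)"
            )
    t = np.arange(envelope.size) / sfreq
    x = np.zeros_like(envelope)
    for k, w in enumerate(harmonic_weights, start=1):
        if w != 0:
            x += w * np.sin(2 * np.pi * k * freq * t + phase)
    return x * envelope


def contrast_response(modulation_depth: float, gamma: float = 0.5) -> float:
    """Effective response gain of a flicker of given modulation depth.

    A compressive power law ``depth**gamma`` (monotone, 0 at zero depth,
    1 at full depth for gamma=1); the exponent is configurable because no
    canonical contrast-response function exists for near-threshold
    square-wave flickers.
    """
    if not 0.0 <= modulation_depth <= 1.0:
        raise ValueError("modulation_depth must lie in [0, 1]")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return float(modulation_depth**gamma)


def occipital_topography(
    positions: dict[str, np.ndarray],
    ch_names: list[str],
    lateral_shift: float = 0.0,
    sigma: float = 0.045,
) -> np.ndarray:
    """Gaussian channel weights centred on the parieto-occipital scalp.

    The centre sits at Oz shifted laterally by ``lateral_shift`` metres
    (positive = right), so the two tag sources project dominantly to
    O1/Oz/O2 and the PO row.  Weights are normalised to unit maximum.
    """
    if "Oz" not in positions:
        raise ValueError("topography anchor Oz missing from positions")
    center = positions["Oz"].copy()
    center[0] += lateral_shift
    w = np.array(
        [np.exp(-np.sum((positions[c] - center) ** 2) / (2 * sigma**2)) for c in ch_names]
    )
    return w / w.max()


def _alpha_background(
    n_samples: int, sfreq: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS narrowband noise in the alpha band (smooth band edges)."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    lo, hi = band
    center = 0.5 * (lo + hi)
    sd = (hi - lo) / 4.0
    mask = np.exp(-((freqs - center) ** 2) / (2 * sd**2))
    x = np.fft.irfft(spec * mask, n=n_samples)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _attention_envelope(
    n_fix: int, n_cue: int, n_target: int, ramp_samples: int, low: float, high: float
) -> np.ndarray:
    """Source amplitude envelope over one trial: low during fixation, ramping
    to high after cue onset, sustained through the target phase."""
    env = np.empty(n_fix + n_cue + n_target)
    env[:n_fix] = low
    ramp_samples = min(max(ramp_samples, 1), n_cue)
    ramp = np.linspace(low, high, ramp_samples, endpoint=True)
    env[n_fix : n_fix + ramp_samples] = ramp
    env[n_fix + ramp_samples :] = high
    return env


def simulate_session(config: SimConfig) -> tuple[Recording, GroundTruth]:
    """Simulate one full session of the spatial-attention task.

    Returns a continuous :class:`Recording` (channels x samples, microvolts)
    with fixation/cue/target event markers for every trial, and the
    :class:`GroundTruth` of injected amplitudes and topographies.

    Trials are organised in condition blocks of ``n_trials_per_condition``
    trials with balanced, randomly ordered left/right cues, separated by
    ``inter_trial_gap`` seconds of background-only signal.
    """
    rng = np.random.default_rng(config.seed)
    sfreq = config.sfreq
    ch_names = list(config.ch_names)
    positions = default_montage_positions(ch_names)

    n_fix, n_cue, n_target = (int(round(d * sfreq)) for d in config.phase_durations)
    n_trial = n_fix + n_cue + n_target
    n_gap = int(round(config.inter_trial_gap * sfreq))
    n_trials = config.n_trials
    n_total = n_trials * n_trial + (n_trials + 1) * n_gap

    topo_left = occipital_topography(positions, ch_names, -0.025, config.topo_sigma)
    topo_right = occipital_topography(positions, ch_names, +0.025, config.topo_sigma)
    topo_alpha = occipital_topography(positions, ch_names, 0.0, config.topo_sigma * 1.5)

    # background: independent 1/f noise per channel + occipital alpha
    data = np.empty((len(ch_names), n_total))
    for c in range(len(ch_names)):
        data[c] = config.noise_rms * make_pink_noise(
            n_total, config.noise_exponent, sfreq, rng
        )
    alpha = _alpha_background(n_total, sfreq, config.alpha_band, rng)
    alpha_env = np.ones(n_total)  # filled with suppression below, per trial

    # trial schedule: one block per condition, balanced sides within block
    side_codes = []
    for _ in config.conditions:
        half = config.n_trials_per_condition // 2
        sides = ["left"] * half + ["right"] * (config.n_trials_per_condition - half)
        side_codes.extend(rng.permutation(sides))

    ramp_samples = int(round(config.onset_ramp * sfreq))
    f_left, f_right = config.tag_freqs
    events: list[dict] = []
    truth_rows: list[dict] = []

    cursor = n_gap
    trial_idx = 0
    for cond in config.conditions:
        gain = (
            cond.response_gain
            if cond.response_gain is not None
            else contrast_response(cond.modulation_depth, config.contrast_gamma)
        )
        base_amp = config.ssvep_gain * gain
        attended_amp = config.attention_ratio * base_amp
        for _ in range(config.n_trials_per_condition):
            side = side_codes[trial_idx]
            env_att = _attention_envelope(
                n_fix, n_cue, n_target, ramp_samples, base_amp, attended_amp
            )
            env_unatt = np.full(n_trial, base_amp)
            env_left, env_right = (
                (env_att, env_unatt) if side == "left" else (env_unatt, env_att)
            )
            # make_ssvep_source is linear in its envelope, so the amplitude
            # envelopes (in microvolts) are passed directly
            src_left = make_ssvep_source(
                f_left, env_left, config.harmonic_weights, sfreq
            )
            src_right = make_ssvep_source(
                f_right, env_right, config.harmonic_weights, sfreq
            )

            sl = slice(cursor, cursor + n_trial)
            data[:, sl] += np.outer(topo_left, src_left)
            data[:, sl] += np.outer(topo_right, src_right)
            # gaze leaves the fixation cross at cue onset -> alpha suppression
            alpha_env[cursor + n_fix : cursor + n_trial] = config.alpha_suppression

            for phase, offset in (
                ("fixation", 0),
                ("cue", n_fix),
                ("target", n_fix + n_cue),
            ):
                events.append(
                    {
                        "sample": cursor + offset,
                        "phase": phase,
                        "side": side,
                        "condition": cond.name,
                        "trial": trial_idx,
                    }
                )
            amp_l = {"fixation": base_amp, "cue": attended_amp, "target": attended_amp}
            amp_u = {"fixation": base_amp, "cue": base_amp, "target": base_amp}
            att_l = amp_l if side == "left" else amp_u
            att_r = amp_l if side == "right" else amp_u
            truth_rows.append(
                {
                    "trial": trial_idx,
                    "condition": cond.name,
                    "side": side,
                    "attended_freq": f_left if side == "left" else f_right,
                    "amp_fix_left": att_l["fixation"],
                    "amp_cue_left": att_l["cue"],
                    "amp_target_left": att_l["target"],
                    "amp_fix_right": att_r["fixation"],
                    "amp_cue_right": att_r["cue"],
                    "amp_target_right": att_r["target"],
                }
            )
            cursor += n_trial + n_gap
            trial_idx += 1

    data += np.outer(topo_alpha, config.alpha_amplitude * alpha * alpha_env)

    rec = Recording(
        data=data,
        sfreq=sfreq,
        ch_names=ch_names,
        positions=positions,
        events=pd.DataFrame(events),
        reference="FCz",
    )
    truth = GroundTruth(
        trials=pd.DataFrame(truth_rows),
        topographies={"left": topo_left, "right": topo_right},
        config=config,
    )
    return rec, truth
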