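"""Flicker stimulus modelling.

A repetitive visual stimulus ("flicker") alternates between an OFF state at
the background gray level and an ON state whose gray level is set by the
amplitude modulation depth: the fraction of the background-to-white range
that the ON state spans.  The flicker waveform is an ideal 50%-duty square
wave rendered on a fixed-refresh frame grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FlickerSpec",
    "depth_to_gray",
    "frame_sequence",
    "ideal_waveform_spectrum",
    "frame_table",
]


@dataclass(frozen=True)
class FlickerSpec:
    """Specification of a square-wave luminance flicker.

    Parameters
    ----------
    freq : float
        Flicker frequency in Hz.  Must lie below half the refresh rate.
    modulation_depth : float
        Amplitude modulation depth ``m`` in [0, 1]: the ON/OFF contrast as a
        fraction of the maximal (background-to-white) gray range.
    background_gray : int
        OFF-state gray level (8-bit), also the screen background.
    max_gray : int
        Brightest gray level reachable at full modulation depth.
    size_px : tuple of int
        (width, height) of the flickering panel in pixels.  Metadata only.
    refresh_rate : float
        Monitor refresh rate in Hz, defining the frame grid.
    """

    freq: float
    modulation_depth: float
    background_gray: int = 130
    max_gray: int = 255
    size_px: tuple[int, int] = (640, 1080)
    refresh_rate: float = 120.0
    # measured background luminance, cd/m^2; carried as metadata only
    background_luminance: float | None = field(default=124.0, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError(
                f"modulation_depth must lie in [0, 1], got {self.modulation_depth}"
            )
        if self.background_gray > self.max_gray:
            raise ValueError("background_gray must not exceed max_gray")
        if not self.freq > 0:
            raise ValueError("freq must be positive")
        if self.freq >= self.refresh_rate / 2:
            raise ValueError(
                f"freq={self.freq} Hz is not representable on a "
                f"{self.refresh_rate} Hz frame grid (needs freq < refresh/2)"
            )


def depth_to_gray(spec: FlickerSpec) -> int:
    """ON-state gray level for a flicker of given modulation depth.

    The ON level is ``g0 + (max_gray - g0) * m`` truncated to an integer
    gray value; the OFF state is always the background ``g0``.  At 70% depth
    on a 130 background this gives 130 + (255 - 130) * 0.7 = 217.
    """
    g0 = spec.background_gray
    return int(math.floor(g0 + (spec.max_gray - g0) * spec.modulation_depth))


def frame_sequence(spec: FlickerSpec, duration: float) -> np.ndarray:
    """Per-frame ON/OFF states of the flicker over ``duration`` seconds.

    The ideal 50%-duty square wave at ``spec.freq`` is sampled at each frame
    midpoint ``(k + 0.5) / refresh_rate``; the frame is ON when the waveform
    is in its first half-cycle.  For frequencies that divide the refresh
    rate (15 Hz on 120 Hz) this yields exact integer blocks (4 ON, 4 OFF);
    for incommensurate frequencies (13 Hz on 120 Hz) the block lengths
    alternate so the long-run ON fraction still converges to 0.5.

    Returns
    -------
    ndarray of bool, shape (n_frames,)
        ``True`` for ON frames.  ``n_frames = ceil(duration * refresh)``,
        at least 1.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    n_frames = max(1, math.ceil(duration * spec.refresh_rate))
    k = np.arange(n_frames)
    phase = spec.freq * (k + 0.5) / spec.refresh_rate
    return (phase % 1.0) < 0.5


def ideal_waveform_spectrum(spec: FlickerSpec, n_harmonics: int = 10) -> pd.DataFrame:
    """Fourier line spectrum of the ideal square-wave flicker.

    A 50%-duty square wave contains only odd harmonics with amplitudes
    proportional to 1/n; even harmonics vanish.  Amplitudes are normalised
    so the fundamental is 1.

    Returns a DataFrame with columns ``harmonic``, ``freq_hz``, ``amplitude``.
    """
    n = np.arange(1, n_harmonics + 1)
    amp = np.where(n % 2 == 1, 1.0 / n, 0.0)
    return pd.DataFrame(
        {"harmonic": n, "freq_hz": n * spec.freq, "amplitude": amp}
    )


def frame_table(spec: FlickerSpec, duration: float) -> pd.DataFrame:
    """Frame-by-frame schedule as a table suitable for CSV export.

    Columns: ``frame_index``, ``time_s`` (frame onset), ``state`` (1=ON),
    ``gray_level`` (the displayed gray value for that frame).
    """
    states = frame_sequence(spec, duration)
    on_gray = depth_to_gray(spec)
    idx = np.arange(len(states))
    return pd.DataFrame(
        {
            "frame_index": idx,
            "time_s": idx / spec.refresh_rate,
            "state": states.astype(int),
            "gray_level": np.where(states, on_gray, spec.background_gray),
        }
    )
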