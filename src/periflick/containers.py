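"""In-memory containers shared across the pipeline.

``Recording`` holds continuous multichannel EEG with event markers;
``Epochs`` holds the trial x channel x time array cut around fixation
onsets.  Both are light dataclasses over numpy arrays and pandas tables:
they carry exactly the state the analysis needs (sampling rate, channel
positions for spherical interpolation, a rank ledger for downstream
eigendecompositions) and convert to/from MNE objects at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["Recording", "Epochs", "EVENT_PHASES"]

EVENT_PHASES = ("fixation", "cue", "target")


@dataclass
class Recording:
    """Continuous multichannel EEG (microvolts) with event markers.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    sfreq : float
        Sampling rate in Hz.
    ch_names : list of str
        Unique channel labels (10-20 montage names).
    positions : dict
        Channel label -> 3-D scalp position in metres (head frame);
        required for spherical-spline interpolation.
    events : pandas.DataFrame
        Columns ``sample`` (int), ``phase`` (fixation/cue/target),
        ``side`` (left/right), ``condition`` (str), ``trial`` (int),
        sorted by sample.
    reference : str
        Current reference ('FCz', 'average', ...).
    n_interpolated : int
        Number of channels replaced by interpolation (rank bookkeeping).
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    reference: str = "FCz"
    n_interpolated: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("data rows must match ch_names")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")
        if len(self.events) and not self.events["sample"].is_monotonic_increasing:
            self.events = self.events.sort_values("sample", ignore_index=True)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def effective_rank(self) -> int:
        """Channel count minus interpolated channels minus 1 if average-referenced."""
        return self.n_channels - self.n_interpolated - (
            1 if self.reference == "average" else 0
        )

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            ch_names=list(self.ch_names),
            positions={k: np.array(v) for k, v in self.positions.items()},
            events=self.events.copy(),
        )


@dataclass
class Epochs:
    """Trial x channel x time array with per-trial metadata.

    The epoch window is [0, 9] s with fixation onset at time 0; phase
    boundaries (cue onset at 3 s, target onset at 6 s) are carried in
    ``phase_onsets``.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    metadata: pd.DataFrame
    tmin: float = 0.0
    phase_onsets: dict[str, float] = field(
        default_factory=lambda: {"fixation": 0.0, "cue": 3.0, "target": 6.0}
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x time)")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata rows must match trial count")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("data channel axis must match ch_names")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_times) / self.sfreq

    def time_slice(self, tmin: float, tmax: float) -> slice:
        """Sample slice for the half-open window [tmin, tmax) in seconds."""
        i0 = int(round((tmin - self.tmin) * self.sfreq))
        i1 = int(round((tmax - self.tmin) * self.sfreq))
        return slice(max(i0, 0), min(i1, self.n_times))

    def select(self, mask: np.ndarray) -> "Epochs":
        """Sub-select trials by boolean mask or index array."""
        return Epochs(
            data=self.data[mask],
            sfreq=self.sfreq,
            ch_names=list(self.ch_names),
            metadata=self.metadata.iloc[np.atleast_1d(mask)].reset_index(drop=True)
            if np.asarray(mask).dtype != bool
            else self.metadata[mask].reset_index(drop=True),
            tmin=self.tmin,
            phase_onsets=dict(self.phase_onsets),
        )
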