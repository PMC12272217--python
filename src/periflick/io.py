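"""File I/O: BrainVision and EDF recordings, TSV/JSON result tables.

Recordings are written in the BrainVision triple (.vhdr/.vmrk/.eeg,
32-bit IEEE float, multiplexed, microvolts) with events stored as stimulus
markers; reading goes through MNE's BrainVision and EDF readers, with
event markers converted back to the package's event table.  Epochs are
persisted as a numpy array plus a TSV metadata sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Epochs, Recording

__all__ = [
    "write_brainvision",
    "read_brainvision",
    "read_edf",
    "save_epochs",
    "load_epochs",
    "write_ground_truth",
    "save_filters",
]

_MARKER_FIELDS = ("phase", "side", "condition", "trial")


def _encode_marker(ev: pd.Series) -> str:
    return ":".join(str(ev.get(f, "")) for f in _MARKER_FIELDS)


def _decode_marker(desc: str) -> dict:
    parts = desc.split(":")
    out = dict(zip(_MARKER_FIELDS, parts + [""] * (len(_MARKER_FIELDS) - len(parts))))
    try:
        out["trial"] = int(out["trial"])
    except (ValueError, TypeError):
        out["trial"] = -1
    return out


def write_brainvision(rec: Recording, basename: str | Path) -> Path:
    """Write a recording as a BrainVision .vhdr/.vmrk/.eeg triple.

    Data are stored as multiplexed IEEE 32-bit floats in microvolts
    (resolution 1); events become ``Stimulus`` markers whose description
    encodes phase, side, condition and trial index.  Returns the header
    path.
    """
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name.removesuffix(".vhdr")
    vhdr, vmrk, eeg = (base.parent / f"{stem}{ext}" for ext in (".vhdr", ".vmrk", ".eeg"))

    sampling_interval_us = 1e6 / rec.sfreq
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={sampling_interval_us:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(rec.ch_names, start=1):
        lines.append(f"Ch{i}={ch},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, (_, ev) in enumerate(rec.events.iterrows(), start=2):
        # BrainVision marker positions are 1-based sample indices
        mlines.append(
            f"Mk{k}=Stimulus,{_encode_marker(ev)},{int(ev['sample']) + 1},1,0"
        )
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    rec.data.astype("<f4").T.tofile(eeg)  # multiplexed: sample-major
    return vhdr


def read_brainvision(path: str | Path, positions: dict | None = None) -> Recording:
    """Read a BrainVision triple into a :class:`Recording` (microvolts).

    ``positions`` may supply channel coordinates; otherwise standard 10-20
    montage positions are attached for channels with known labels.
    """
    import mne

    mne.set_log_level("ERROR")
    vhdr = Path(path)
    if not vhdr.exists():
        raise FileNotFoundError(f"header file not found: {vhdr}")
    for tag, ext in (("marker", ".vmrk"), ("data", ".eeg")):
        sibling = vhdr.with_suffix(ext)
        if not sibling.exists():
            raise FileNotFoundError(f"BrainVision {tag} file missing: {sibling}")
    raw = mne.io.read_raw_brainvision(vhdr, preload=True, verbose="ERROR")
    return _raw_to_recording(raw, positions)


def read_edf(path: str | Path, positions: dict | None = None) -> Recording:
    """Read an EDF recording with an annotation/event channel."""
    import mne

    mne.set_log_level("ERROR")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"EDF file not found: {p}")
    raw = mne.io.read_raw_edf(p, preload=True, verbose="ERROR")
    return _raw_to_recording(raw, positions)


def _raw_to_recording(raw, positions: dict | None) -> Recording:
    ch_names = list(raw.ch_names)
    data = raw.get_data() * 1e6  # V -> uV
    rows = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        desc = desc.split("/", 1)[-1]  # strip MNE's "Stimulus/" prefix
        if desc in ("New Segment", ""):
            continue
        rows.append(
            {"sample": int(round(onset * raw.info["sfreq"])), **_decode_marker(desc)}
        )
    events = pd.DataFrame(rows)
    if positions is None:
        from .synth import default_montage_positions

        try:
            positions = default_montage_positions(ch_names)
        except ValueError:
            positions = {}
    return Recording(
        data=data,
        sfreq=float(raw.info["sfreq"]),
        ch_names=ch_names,
        positions=positions,
        events=events,
    )


def save_epochs(epochs: Epochs, basename: str | Path) -> Path:
    """Persist epochs as ``<base>_data.npy`` + ``<base>_metadata.tsv``."""
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    np.save(f"{base}_data.npy", epochs.data)
    meta = epochs.metadata.copy()
    meta.to_csv(f"{base}_metadata.tsv", sep="\t", index=False)
    sidecar = {
        "sfreq": epochs.sfreq,
        "ch_names": epochs.ch_names,
        "tmin": epochs.tmin,
        "phase_onsets": epochs.phase_onsets,
    }
    Path(f"{base}_info.json").write_text(json.dumps(sidecar, indent=1))
    return Path(f"{base}_data.npy")


def load_epochs(basename: str | Path) -> Epochs:
    base = Path(basename)
    data = np.load(f"{base}_data.npy")
    meta = pd.read_csv(f"{base}_metadata.tsv", sep="\t")
    info = json.loads(Path(f"{base}_info.json").read_text())
    return Epochs(
        data=data,
        sfreq=info["sfreq"],
        ch_names=info["ch_names"],
        metadata=meta,
        tmin=info["tmin"],
        phase_onsets=info["phase_onsets"],
    )


def write_ground_truth(truth, path: str | Path) -> Path:
    """Ground-truth trial table (condition, side, amplitudes) to TSV."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    truth.trials.to_csv(p, sep="\t", index=False)
    return p


def save_filters(filters: dict, path: str | Path) -> Path:
    """Serialize fitted RESS filters to JSON (weights, eigenvalues, params)."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    payload = {str(k): f.to_dict() for k, f in filters.items()}
    p.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return p
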