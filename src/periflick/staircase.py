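"""Two-phase staircase protocol for the flicker visibility threshold.

The perceptual visibility threshold of a flicker is measured with a
descending/ascending staircase on the amplitude modulation depth.  Each
block presents four stimuli in random order: the two task flickers (13 and
15 Hz) at the current depth and two static (non-flickering) stimuli; the
observer presses a key whenever they see a flicker.  An *error* is a miss
on a flicker trial or a response on a static trial.

The descending phase starts at 5% of the maximal modulation depth and
steps down by 0.1 percentage points of the maximal depth per block, until
more than two errors occur within a block.  The ascending phase then steps
up by 0.02 percentage points per block until both flicker trials in a
block are detected.  The final ascending depth is the *periliminal* depth;
the *subliminal* depth sits one ascending step (0.0002) below it.

Simulated observers respond through a logistic psychometric function with
lapse and guess rates, so threshold-recovery properties of the protocol
can be checked against known ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Observer",
    "StaircaseResult",
    "ProtocolFailureWarning",
    "DESCENDING_STEP",
    "ASCENDING_STEP",
    "run_block",
    "run_staircase",
]

DESCENDING_STEP = 0.001  # -0.1% of maximal depth per descending block
ASCENDING_STEP = 0.0002  # +0.02% of maximal depth per ascending block


class ProtocolFailureWarning(RuntimeWarning):
    """The descending staircase reached zero depth without triggering its
    stop rule; the ascending phase was started from zero as a fallback."""


@dataclass(frozen=True)
class Observer:
    """Simulated participant for the visibility-threshold protocol.

    Detection of a flicker at modulation depth ``d`` follows a logistic
    psychometric function

        P(detect) = guess + (1 - guess - lapse) / (1 + exp(-slope (d - t)))

    where ``t`` is the true threshold.  On static stimuli the observer
    false-alarms with probability ``guess_rate``.
    """

    true_threshold: float
    slope: float = 2000.0
    lapse_rate: float = 0.02
    guess_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.lapse_rate <= 1 or not 0 <= self.guess_rate <= 1:
            raise ValueError("lapse_rate and guess_rate must lie in [0, 1]")
        if not self.slope > 0:
            raise ValueError("slope must be positive")

    def p_detect(self, depth: float) -> float:
        """Probability of reporting a flicker at the given depth."""
        core = 1.0 / (1.0 + np.exp(-self.slope * (depth - self.true_threshold)))
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * core


@dataclass
class StaircaseResult:
    periliminal: float
    subliminal: float
    trace: pd.DataFrame = field(repr=False)
    n_descending_blocks: int = 0
    n_ascending_blocks: int = 0


def run_block(
    depth: float, observer: Observer, rng: np.random.Generator
) -> list[dict]:
    """Present one four-trial block (two flickers + two statics) at ``depth``.

    Returns a list of four trial records with keys ``stimulus_type``
    ('flicker_13', 'flicker_15', 'static'), ``response`` (bool, key press)
    and ``error`` (bool).  Trial order within the block is randomised.
    """
    if not 0.0 <= depth <= 1.0:
        raise ValueError(f"depth must lie in [0, 1], got {depth}")
    stimuli = ["flicker_13", "flicker_15", "static", "static"]
    order = rng.permutation(4)
    trials = []
    for i in order:
        stim = stimuli[i]
        if stim == "static":
            resp = bool(rng.random() < observer.guess_rate)
            err = resp  # false alarm
        else:
            resp = bool(rng.random() < observer.p_detect(depth))
            err = not resp  # miss
        trials.append({"stimulus_type": stim, "response": resp, "error": err})
    return trials


def run_staircase(
    observer: Observer,
    start_depth: float = 0.05,
    max_errors: int = 2,
) -> StaircaseResult:
    """Run the full descending/ascending protocol on a simulated observer.

    Parameters
    ----------
    observer : Observer
        The simulated participant (carries its own seed).
    start_depth : float
        Initial modulation depth of the descending phase (default 5% of
        the maximal depth).
    max_errors : int
        Descending blocks stop once a block contains *more than* this many
        errors (default 2, i.e. >2 errors in a four-trial block).

    Returns
    -------
    StaircaseResult
        Periliminal depth (final ascending depth), subliminal depth (one
        ascending step below, clamped at 0 with a warning), and the full
        per-trial trace.

    Warns
    -----
    ProtocolFailureWarning
        If the descending phase reaches zero depth without ever meeting
        the stop rule (possible for observers whose error rate below
        threshold rarely exceeds two per block); the ascending phase then
        starts from zero depth, which still converges on the threshold.
    """
    if not 0.0 < start_depth <= 1.0:
        raise ValueError("start_depth must lie in (0, 1]")
    rng = np.random.default_rng(observer.seed)
    rows: list[dict] = []
    block_idx = 0

    def record(depth: float, phase: str, trials: list[dict]) -> int:
        nonlocal block_idx
        for t in trials:
            rows.append({"block": block_idx, "phase": phase, "depth": depth, **t})
        block_idx += 1
        return sum(t["error"] for t in trials)

    # descending phase
    depth = start_depth
    n_desc = 0
    while True:
        errors = record(depth, "descending", run_block(depth, observer, rng))
        n_desc += 1
        if errors > max_errors:
            break
        next_depth = depth - DESCENDING_STEP
        if next_depth < 0:
            warnings.warn(
                "descending staircase reached zero depth without exceeding "
                f"{max_errors} errors in any block; ascending from zero",
                ProtocolFailureWarning,
                stacklevel=2,
            )
            depth = -ASCENDING_STEP  # first ascending block lands at 0 + step
            break
        depth = round(next_depth, 10)

    # ascending phase: climb until both flicker trials in a block are hits
    n_asc = 0
    while True:
        depth = round(min(depth + ASCENDING_STEP, 1.0), 10)
        trials = run_block(depth, observer, rng)
        record(depth, "ascending", trials)
        n_asc += 1
        flicker_hits = [
            t["response"] for t in trials if t["stimulus_type"].startswith("flicker")
        ]
        if all(flicker_hits):
            break

    periliminal = depth
    subliminal = periliminal - ASCENDING_STEP
    if subliminal < 0:
        warnings.warn("subliminal depth clamped at 0", RuntimeWarning, stacklevel=2)
        subliminal = 0.0
    return StaircaseResult(
        periliminal=periliminal,
        subliminal=round(subliminal, 10),
        trace=pd.DataFrame(rows),
        n_descending_blocks=n_desc,
        n_ascending_blocks=n_asc,
    )
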