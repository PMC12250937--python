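"""Hard-threshold negative-peak spike detection with per-channel refractory.

A spike is declared at sample t when, over the three most recent filtered
samples, the middle one (t-1) is (i) the lowest of the three and (ii)
strictly below a fixed negative threshold. After a detection a per-channel
refractory counter suppresses further detections for a configured number of
acquisition loops (1.5 ms by default), so multi-peaked waveforms are counted
once. The event timestamp is the index of the peak sample (t-1).

Tie handling (the comparison rule is otherwise underdetermined for flat
troughs): ``y1 < y_t`` strict against the newest sample and ``y1 <= y2``
non-strict against the oldest, so a flat-bottomed trough fires once, at its
last minimum sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .units import uv_to_counts


@dataclass(frozen=True)
class DetectorConfig:
    """Threshold / refractory configuration for one detector instance."""

    threshold_uV: float
    refractory_ms: float
    fs_hz: int

    def __post_init__(self):
        if self.threshold_uV >= 0:
            raise ValueError("threshold must be negative (uV)")
        if self.refractory_ms <= 0:
            raise ValueError("refractory must be > 0 ms")
        if self.refractory_samples < 1:
            raise ValueError("refractory shorter than one sample period")

    @property
    def threshold_counts(self) -> int:
        """Threshold on the integer count scale (filter has unity passband
        gain, so filtered counts and raw counts share the scale)."""
        return uv_to_counts(self.threshold_uV)

    @property
    def refractory_samples(self) -> int:
        return int(round(self.refractory_ms * self.fs_hz / 1000.0))


@dataclass
class DetectorState:
    """Per-channel detector memory: the two previous filtered samples plus
    the refractory acquisition-loop counter."""

    y1: int = 0
    y2: int = 0
    refractory_counter: int = 0
    samples_seen: int = 0


@dataclass(frozen=True)
class SpikeEvent:
    headstage: int
    channel: int
    sample_index: int
    threshold_uV: float


def detect_step(state: DetectorState, y_t: int, cfg: DetectorConfig):
    """One detector step; returns ``(new_state, spike)``.

    While the refractory counter is active the comparison is not evaluated
    at all and the counter is decremented once per call (one acquisition
    loop). The peak that started the refractory period is itself reported.
    """
    y_t = int(y_t)
    spike = False
    refrc = state.refractory_counter
    if refrc > 0:
        refrc -= 1
    elif (state.samples_seen >= 2 and state.y1 < y_t
          and state.y1 <= state.y2 and state.y1 < cfg.threshold_counts):
        spike = True
        refrc = cfg.refractory_samples
    return DetectorState(y1=y_t, y2=state.y1, refractory_counter=refrc,
                         samples_seen=state.samples_seen + 1), spike


def detect_offline(filtered, cfg: DetectorConfig,
                   state: DetectorState | None = None) -> np.ndarray:
    """Batch detection over a stored filtered trace.

    Definitionally the left-fold of :func:`detect_step` from a fresh state;
    this is the offline arm of the streaming-vs-offline comparison. Returns
    the peak sample indices of all events (int64, sorted).
    """
    y = np.ascontiguousarray(filtered, dtype=np.int64)
    if state is None:
        state = DetectorState()
    cap = y.shape[0] // (cfg.refractory_samples + 1) + 2
    out = np.empty(cap, dtype=np.int64)
    nev, y1, y2, refrc, seen = _kernels.detect_batch(
        y, cfg.threshold_counts, cfg.refractory_samples,
        state.y1, state.y2, state.refractory_counter, state.samples_seen,
        out)
    state.y1, state.y2 = int(y1), int(y2)
    state.refractory_counter, state.samples_seen = int(refrc), int(seen)
    return out[:nev].copy()


def events_to_frame(events, fs_hz: int) -> pd.DataFrame:
    """Tabulate spike events (`headstage,channel,sample_index,time_s,
    threshold_uV`)."""
    rows = [(e.headstage, e.channel, e.sample_index,
             e.sample_index / fs_hz, e.threshold_uV) for e in events]
    return pd.DataFrame(rows, columns=["headstage", "channel",
                                       "sample_index", "time_s",
                                       "threshold_uV"])


def events_to_csv(events, fs_hz: int, path_or_buf) -> None:
    events_to_frame(events, fs_hz).to_csv(path_or_buf, index=False)
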