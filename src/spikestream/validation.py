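"""Streaming-vs-offline comparison protocol and its accuracy/error metrics.

The validation question is not whether the detector finds "true" spikes but
whether the streaming (real-time) implementation behaves exactly like the
offline batch implementation of the same algorithm: per channel, the
percentage error is ``delta = (v_o - v_e) / v_e * 100`` (observed = streaming
count, expected = offline count) and the percentage accuracy is
``E_acc = 100 - delta``. The protocol generates a cohort of synthetic
"animals", runs both arms at a triple of nested thresholds, and aggregates
the per-channel metrics as the unweighted mean over all
(animal, channel, threshold) cells, alongside an exact spike-index match
check per channel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codec import StreamHeader, encode_stream
from .detector import DetectorConfig, detect_offline
from .engine import EngineConfig, process_stream
from .filters import design_quantized, filter_batch
from .synthetic import (ChannelSpec, RecordingSpec, generate_recording,
                        make_template, recording_to_matrix)

log = logging.getLogger(__name__)

#: Threshold triples used per animal, in microvolts (nested, most permissive
#: first). Either triple can be selected per animal in the full protocol.
THRESHOLD_TRIPLES = ((-50.0, -70.0, -90.0), (-70.0, -90.0, -110.0))


class UndefinedComparisonError(ValueError):
    """Raised when ``v_e == 0`` but ``v_o > 0`` (percentage error has no
    finite value; the protocol flags and excludes such cells)."""


def percentage_error(v_o: int, v_e: int) -> float:
    """Signed percentage error ``(v_o - v_e) / v_e * 100``.

    Over-detection by the streaming arm is positive. ``(0, 0)`` is defined
    as 0 (a silent channel processed identically is a perfect match).
    """
    if v_e == 0:
        if v_o == 0:
            return 0.0
        raise UndefinedComparisonError(
            f"observed {v_o} spikes where the offline reference found none")
    return (v_o - v_e) / v_e * 100.0


def accuracy(v_o: int, v_e: int) -> float:
    """Percentage accuracy ``E_acc = 100 - delta``."""
    return 100.0 - percentage_error(v_o, v_e)


def compare_spike_trains(observed, expected):
    """Exact element-wise comparison of two sorted index sequences.

    Returns ``(identical, mismatch)``; ``mismatch`` reports the first
    divergence as ``(position, observed_value, expected_value)`` with None
    for a missing element.
    """
    obs = np.asarray(observed, dtype=np.int64)
    exp = np.asarray(expected, dtype=np.int64)
    n = min(obs.size, exp.size)
    neq = np.nonzero(obs[:n] != exp[:n])[0]
    if neq.size:
        i = int(neq[0])
        return False, (i, int(obs[i]), int(exp[i]))
    if obs.size != exp.size:
        i = n
        return False, (i,
                       int(obs[i]) if obs.size > n else None,
                       int(exp[i]) if exp.size > n else None)
    return True, None


@dataclass(frozen=True)
class ChannelComparison:
    v_o: int
    v_e: int
    delta_pct: float
    e_acc_pct: float
    indices_identical: bool


@dataclass
class ValidationReport:
    table: pd.DataFrame
    mean_e_acc_pct: float
    mean_delta_pct: float
    n_cells: int
    n_excluded: int
    all_indices_identical: bool
    first_mismatch: tuple | None = None

    def to_csv(self, path_or_buf) -> None:
        self.table.to_csv(path_or_buf, index=False)

    def summary(self) -> dict:
        return {
            "mean_e_acc_pct": self.mean_e_acc_pct,
            "mean_delta_pct": self.mean_delta_pct,
            "n_cells": self.n_cells,
            "n_excluded": self.n_excluded,
            "all_indices_identical": self.all_indices_identical,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def make_animal_spec(master_seed: int, animal: int, *, fs_hz: int = 20000,
                     duration_s: float = 60.0, n_headstages: int = 2,
                     n_channels_per_hs: int = 16) -> RecordingSpec:
    """Randomized but reproducible per-animal recording spec.

    Channel parameters emulate the spread of a cortical multi-electrode
    recording: firing rates U(2, 10) Hz, background noise sigma
    U(10, 20) uV, spike peak U(-300, -50) uV, drift up to 300 uV below 3 Hz.
    """
    rng = np.random.default_rng([master_seed, animal])
    specs = {}
    for hs in range(n_headstages):
        for ch in range(n_channels_per_hs):
            tpl = make_template(
                "biphasic",
                duration_ms=float(rng.uniform(0.8, 2.0)),
                peak_amplitude_uV=float(rng.uniform(-300.0, -50.0)),
                fs_hz=fs_hz)
            specs[(hs, ch)] = ChannelSpec(
                firing_rate_hz=float(rng.uniform(2.0, 10.0)),
                template=tpl,
                noise_sigma_uV=float(rng.uniform(10.0, 20.0)),
                drift_amplitude_uV=float(rng.uniform(0.0, 300.0)),
                drift_freq_hz=float(rng.uniform(0.5, 3.0)),
            )
    seed = int(rng.integers(2**31))
    return RecordingSpec(fs_hz=fs_hz, duration_s=duration_s,
                         n_headstages=n_headstages,
                         n_channels_per_hs=n_channels_per_hs,
                         channel_specs=specs, seed=seed)


_AREA_NAMES = ("RFA", "S1")


def _area(headstage: int) -> str:
    return (_AREA_NAMES[headstage] if headstage < len(_AREA_NAMES)
            else f"area{headstage}")


def run_protocol(n_animals: int = 6, *, n_headstages: int = 2,
                 n_channels_per_hs: int = 16,
                 thresholds_uV=THRESHOLD_TRIPLES[0],
                 duration_s: float = 60.0, fs_hz: int = 20000,
                 refractory_ms: float = 1.5, fc_hz: float = 300.0,
                 master_seed: int = 42,
                 streaming_threshold_offset_counts: int = 0
                 ) -> ValidationReport:
    """Full streaming-vs-offline comparison over a synthetic cohort.

    For each animal a recording is generated, serialized to the raw frame
    stream, and processed by the streaming engine at each threshold; the
    offline arm filters each channel in batch and applies the same detector.
    Per-channel counts and exact event indices are compared.

    ``streaming_threshold_offset_counts`` is a self-test hook: it offsets
    the streaming arm's threshold by the given number of counts so harness
    tests can verify that a deliberately perturbed implementation is caught.
    """
    if any(t >= 0 for t in thresholds_uV):
        raise ValueError("thresholds must be negative (uV)")
    q = design_quantized(fs_hz, fc_hz)
    rows = []
    excluded = 0
    first_mismatch = None
    for animal in range(n_animals):
        spec = make_animal_spec(master_seed, animal, fs_hz=fs_hz,
                                duration_s=duration_s,
                                n_headstages=n_headstages,
                                n_channels_per_hs=n_channels_per_hs)
        traces, _ = generate_recording(spec)
        mat = recording_to_matrix(traces, spec)
        header = StreamHeader(fs_hz=fs_hz, n_headstages=n_headstages,
                              n_channels_per_hs=n_channels_per_hs)
        raw_stream = encode_stream(mat, header)
        # offline arm: batch-filter each channel once, detect per threshold
        filtered = {}
        for hs in range(n_headstages):
            for ch in range(n_channels_per_hs):
                slot = ch * n_headstages + hs
                filtered[(hs, ch)] = filter_batch(mat[:, slot], q)
        for thr in thresholds_uV:
            det = DetectorConfig(threshold_uV=thr,
                                 refractory_ms=refractory_ms, fs_hz=fs_hz)
            if streaming_threshold_offset_counts:
                stream_det = _OffsetDetectorConfig(det,
                    streaming_threshold_offset_counts)
            else:
                stream_det = det
            cfg = EngineConfig(fs_hz=fs_hz, detector=stream_det, filter=q)
            result = process_stream(raw_stream, cfg)
            for hs in range(n_headstages):
                for ch in range(n_channels_per_hs):
                    obs = result.events_for_channel(hs, ch)
                    exp = detect_offline(filtered[(hs, ch)], det)
                    identical, mism = compare_spike_trains(obs, exp)
                    if not identical and first_mismatch is None:
                        first_mismatch = (animal, thr, hs, ch, mism)
                    v_o, v_e = int(obs.size), int(exp.size)
                    try:
                        delta = percentage_error(v_o, v_e)
                        eacc = accuracy(v_o, v_e)
                        flag = False
                    except UndefinedComparisonError:
                        delta = np.nan
                        eacc = np.nan
                        flag = True
                        excluded += 1
                        log.warning(
                            "animal %d thr %.0f uV (hs %d, ch %d): %d "
                            "streaming spikes but empty offline reference; "
                            "cell excluded from means", animal, thr, hs, ch,
                            v_o)
                    rows.append({
                        "animal": animal, "area": _area(hs),
                        "threshold_uV": thr, "headstage": hs, "channel": ch,
                        "v_o": v_o, "v_e": v_e, "delta_pct": delta,
                        "e_acc_pct": eacc,
                        "indices_identical": identical,
                        "excluded": flag,
                    })
    table = pd.DataFrame(rows)
    valid = table[~table["excluded"]]
    return ValidationReport(
        table=table,
        mean_e_acc_pct=float(valid["e_acc_pct"].mean()),
        mean_delta_pct=float(valid["delta_pct"].mean()),
        n_cells=len(table),
        n_excluded=excluded,
        all_indices_identical=bool(table["indices_identical"].all()),
        first_mismatch=first_mismatch,
    )


class _OffsetDetectorConfig(DetectorConfig):
    """Self-test hook: a detector whose integer threshold is deliberately
    offset by a fixed number of counts (used to prove the protocol catches
    a divergent streaming arm)."""

    def __new__(cls, base: DetectorConfig, offset_counts: int):
        self = object.__new__(cls)
        object.__setattr__(self, "threshold_uV", base.threshold_uV)
        object.__setattr__(self, "refractory_ms", base.refractory_ms)
        object.__setattr__(self, "fs_hz", base.fs_hz)
        object.__setattr__(self, "_offset", offset_counts)
        return self

    def __init__(self, *args, **kwargs):  # state set in __new__
        pass

    @property
    def threshold_counts(self) -> int:
        return DetectorConfig.threshold_counts.fget(self) + self._offset
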