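"""Synthetic multi-channel extracellular recordings with known ground truth.

Emulates what a chronically implanted multi-electrode probe sees during
spontaneous cortical activity: negative-going action potentials (tens to a
few hundred microvolts at the peak) from units firing at a few Hz, riding on
white Gaussian background noise plus a slow sinusoidal electrode drift.
Traces are synthesized in microvolts and quantized to the 16-bit ADC count
scale of the acquisition front end (0.195 uV per count), so every downstream
stage of the streaming pipeline can be exercised without any real data.

Reproducibility contract: each channel draws from its own random substream
keyed by ``(seed, headstage, channel)`` (numpy ``SeedSequence`` entropy
list), spike train first, then noise. Adding channels to a spec therefore
never perturbs the traces of existing ones.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .units import quantize_trace

log = logging.getLogger(__name__)

SUPPORTED_FS_HZ = (20000, 25000, 30000)

#: Generator dead time default, seconds. Deliberately above the detector's
#: 1.5 ms refractory so ground-truth spikes can never overlap within one
#: detector refractory window.
DEFAULT_DEAD_TIME_S = 0.002

#: Minimum allowed generator dead time, seconds.
MIN_DEAD_TIME_S = 0.002

TEMPLATE_KINDS = ("biphasic", "triangular")

GroundTruth = dict  # {(headstage, channel): np.ndarray of peak sample indices}


@dataclass(frozen=True)
class SpikeTemplate:
    """A single action-potential waveform in microvolts.

    The global minimum of ``samples`` equals ``peak_amplitude_uV`` exactly and
    is the alignment point used for ground-truth timestamps.
    """

    samples: np.ndarray
    duration_ms: float
    peak_amplitude_uV: float
    kind: str = "biphasic"

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", s)
        if s.size < 3:
            raise ValueError("template must have at least 3 samples")
        if self.peak_amplitude_uV >= 0:
            raise ValueError("peak amplitude must be negative (uV)")
        if abs(s[0]) > 1.0 or abs(s[-1]) > 1.0:
            raise ValueError("template must start and end within 1 uV of zero")

    @property
    def peak_index(self) -> int:
        """Index of the (unique) global minimum sample."""
        return int(np.argmin(self.samples))

    def __len__(self) -> int:
        return self.samples.size


def make_template(kind: str, duration_ms: float, peak_amplitude_uV: float,
                  fs_hz: int) -> SpikeTemplate:
    """Build a deterministic spike waveform.

    ``biphasic`` is a smooth asymmetric trough (60% of the duration) followed
    by a positive rebound at 25% of the trough depth; ``triangular`` is a
    linear dip with the minimum at the template midpoint. Both start and end
    at zero and have a single global minimum equal to ``peak_amplitude_uV``.
    """
    if peak_amplitude_uV >= 0:
        raise ValueError("peak amplitude must be negative (uV)")
    if not 0.5 <= duration_ms <= 3.0:
        raise ValueError("template duration must be in [0.5, 3] ms")
    n = int(round(duration_ms * fs_hz / 1000.0))
    if n < 3:
        raise ValueError("template too short for this sampling rate")
    if kind == "biphasic":
        t = np.linspace(0.0, 1.0, n)
        w = np.zeros(n)
        trough = t <= 0.6
        u = t[trough] / 0.6
        # asymmetric cubic bump u^2(1-u), max 4/27 at u=2/3
        w[trough] = -(u * u * (1.0 - u)) / (4.0 / 27.0)
        v = (t[~trough] - 0.6) / 0.4
        w[~trough] = 0.25 * np.sin(np.pi * v)
    elif kind == "triangular":
        mid = (n - 1) // 2
        w = np.concatenate([np.linspace(0.0, -1.0, mid + 1),
                            np.linspace(-1.0, 0.0, n - mid)[1:]])
    else:
        raise ValueError(f"unknown template kind: {kind!r}")
    w = w * (peak_amplitude_uV / w.min())
    # enforce a unique global minimum if the sampling grid produced a tie
    mins = np.flatnonzero(w == w.min())
    if mins.size > 1:
        w[mins[1:]] *= 1.0 - 1e-9
    return SpikeTemplate(samples=w, duration_ms=duration_ms,
                         peak_amplitude_uV=peak_amplitude_uV, kind=kind)


@dataclass(frozen=True)
class ChannelSpec:
    """Per-channel generation parameters (all amplitudes in microvolts)."""

    firing_rate_hz: float = 0.0
    template: SpikeTemplate | None = None
    noise_sigma_uV: float = 0.0
    drift_amplitude_uV: float = 0.0
    drift_freq_hz: float = 1.0
    dead_time_s: float = DEFAULT_DEAD_TIME_S

    def __post_init__(self):
        if self.firing_rate_hz < 0:
            raise ValueError("firing rate must be >= 0")
        if self.noise_sigma_uV < 0 or self.drift_amplitude_uV < 0:
            raise ValueError("noise/drift amplitudes must be >= 0")
        if self.drift_amplitude_uV > 0 and not 0 < self.drift_freq_hz < 300:
            raise ValueError("drift frequency must lie below the 300 Hz "
                             "highpass cutoff")
        if self.firing_rate_hz > 0 and self.template is None:
            raise ValueError("a template is required when the firing rate "
                             "is positive")


@dataclass(frozen=True)
class RecordingSpec:
    """Full description of one synthetic multi-channel recording."""

    fs_hz: int
    duration_s: float
    n_headstages: int
    n_channels_per_hs: int
    channel_specs: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.fs_hz not in SUPPORTED_FS_HZ:
            raise ValueError(f"fs_hz must be one of {SUPPORTED_FS_HZ}")
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")
        if not 1 <= self.n_headstages <= 8:
            raise ValueError("n_headstages must be in [1, 8]")
        if not 1 <= self.n_channels_per_hs <= 16:
            raise ValueError("n_channels_per_hs must be in [1, 16]")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        for hs, ch in self.channel_specs:
            if not (0 <= hs < self.n_headstages
                    and 0 <= ch < self.n_channels_per_hs):
                raise ValueError(f"channel key {(hs, ch)} outside grid")

    @property
    def n_channels(self) -> int:
        return self.n_headstages * self.n_channels_per_hs

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs_hz))


def generate_spike_train(rate_hz: float, duration_s: float, dead_time_s: float,
                         fs_hz: int, rng: np.random.Generator) -> np.ndarray:
    """Poisson spike times with an absolute dead time, as sample indices.

    A renewal process with inter-event gaps ``dead_time + Exp(1/rate)``; the
    expected count is approximately ``rate * T / (1 + rate * dead_time)``.
    All returned inter-spike intervals are >= ``ceil(dead_time * fs)``
    samples.
    """
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    if dead_time_s < MIN_DEAD_TIME_S - 1e-12:
        raise ValueError("generator dead time must be >= 2 ms")
    n_samples = int(round(duration_s * fs_hz))
    if rate_hz == 0:
        return np.empty(0, dtype=np.int64)
    times = []
    t = rng.exponential(1.0 / rate_hz)
    while t < duration_s:
        times.append(t)
        t += dead_time_s + rng.exponential(1.0 / rate_hz)
    gap_min = int(np.ceil(dead_time_s * fs_hz - 1e-9))
    out = []
    last = -gap_min
    for idx in np.rint(np.asarray(times) * fs_hz).astype(np.int64):
        if idx < n_samples and idx - last >= gap_min:
            out.append(idx)
            last = idx
    return np.asarray(out, dtype=np.int64)


_SILENT = ChannelSpec()


def generate_recording(spec: RecordingSpec):
    """Synthesize all channels of a recording.

    Returns ``(traces, ground_truth)`` where ``traces`` maps
    ``(headstage, channel)`` to a float64 microvolt array of
    ``spec.n_samples`` samples, and ``ground_truth`` maps the same keys to
    sorted arrays of template-peak sample indices. A template overlapping the
    trace end is truncated at the boundary (its ground-truth index is kept).
    """
    n = spec.n_samples
    traces: dict = {}
    gt: GroundTruth = {}
    t_axis = None
    for hs in range(spec.n_headstages):
        for ch in range(spec.n_channels_per_hs):
            cs = spec.channel_specs.get((hs, ch), _SILENT)
            rng = np.random.default_rng([spec.seed, hs, ch])
            if cs.firing_rate_hz > 0:
                idx = generate_spike_train(cs.firing_rate_hz, spec.duration_s,
                                           cs.dead_time_s, spec.fs_hz, rng)
            else:
                idx = np.empty(0, dtype=np.int64)
            if cs.noise_sigma_uV > 0:
                trace = rng.normal(0.0, cs.noise_sigma_uV, n)
            else:
                trace = np.zeros(n)
            if cs.drift_amplitude_uV > 0:
                if t_axis is None:
                    t_axis = np.arange(n) / spec.fs_hz
                trace += cs.drift_amplitude_uV * np.sin(
                    2.0 * np.pi * cs.drift_freq_hz * t_axis)
            if idx.size:
                tpl = cs.template.samples
                pk = cs.template.peak_index
                for i in idx:
                    start = int(i) - pk
                    a, b = max(start, 0), min(start + tpl.size, n)
                    trace[a:b] += tpl[a - start:b - start]
            traces[(hs, ch)] = trace
            gt[(hs, ch)] = idx
    return traces, gt


def to_adc_counts(trace_uv) -> np.ndarray:
    """Quantize a microvolt trace to int16 ADC counts (0.195 uV/count).

    Values beyond the 16-bit rails saturate silently; the saturation count is
    logged at INFO level.
    """
    counts, _ = quantize_trace(trace_uv)
    return counts


def recording_to_matrix(traces, spec: RecordingSpec) -> np.ndarray:
    """Quantize all channels and arrange them in stream slot order.

    Returns an int16 array of shape ``(n_samples, n_channels)`` with column
    ``ch * n_headstages + hs`` holding channel ``(hs, ch)`` — the serial
    order of the frame format (channel outer, headstage inner).
    """
    mat = np.zeros((spec.n_samples, spec.n_channels), dtype=np.int16)
    for (hs, ch), trace in traces.items():
        mat[:, ch * spec.n_headstages + hs] = to_adc_counts(trace)
    return mat


# ---------------------------------------------------------------------------
# serialization

def recording_spec_to_yaml(spec: RecordingSpec) -> str:
    channels = []
    for (hs, ch), cs in sorted(spec.channel_specs.items()):
        entry = {
            "headstage": hs, "channel": ch,
            "firing_rate_hz": float(cs.firing_rate_hz),
            "noise_sigma_uV": float(cs.noise_sigma_uV),
            "drift_amplitude_uV": float(cs.drift_amplitude_uV),
            "drift_freq_hz": float(cs.drift_freq_hz),
            "dead_time_s": float(cs.dead_time_s),
        }
        if cs.template is not None:
            entry["template"] = {
                "kind": cs.template.kind,
                "duration_ms": float(cs.template.duration_ms),
                "peak_amplitude_uV": float(cs.template.peak_amplitude_uV),
            }
        channels.append(entry)
    doc = {
        "fs_hz": spec.fs_hz,
        "duration_s": float(spec.duration_s),
        "n_headstages": spec.n_headstages,
        "n_channels_per_hs": spec.n_channels_per_hs,
        "seed": spec.seed,
        "channels": channels,
    }
    return yaml.safe_dump(doc, sort_keys=False)


_TOP_KEYS = {"fs_hz", "duration_s", "n_headstages", "n_channels_per_hs",
             "seed", "channels"}
_CH_KEYS = {"headstage", "channel", "firing_rate_hz", "noise_sigma_uV",
            "drift_amplitude_uV", "drift_freq_hz", "dead_time_s", "template"}
_TPL_KEYS = {"kind", "duration_ms", "peak_amplitude_uV"}


def recording_spec_from_yaml(text: str) -> RecordingSpec:
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError("recording config must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    fs_hz = int(doc["fs_hz"])
    channel_specs = {}
    for entry in doc.get("channels", []) or []:
        bad = set(entry) - _CH_KEYS
        if bad:
            raise ValueError(f"unknown channel keys: {sorted(bad)}")
        key = (int(entry["headstage"]), int(entry["channel"]))
        tpl = None
        if "template" in entry and entry["template"] is not None:
            tdoc = entry["template"]
            bad = set(tdoc) - _TPL_KEYS
            if bad:
                raise ValueError(f"unknown template keys: {sorted(bad)}")
            tpl = make_template(tdoc["kind"], float(tdoc["duration_ms"]),
                                float(tdoc["peak_amplitude_uV"]), fs_hz)
        channel_specs[key] = ChannelSpec(
            firing_rate_hz=float(entry.get("firing_rate_hz", 0.0)),
            template=tpl,
            noise_sigma_uV=float(entry.get("noise_sigma_uV", 0.0)),
            drift_amplitude_uV=float(entry.get("drift_amplitude_uV", 0.0)),
            drift_freq_hz=float(entry.get("drift_freq_hz", 1.0)),
            dead_time_s=float(entry.get("dead_time_s", DEFAULT_DEAD_TIME_S)),
        )
    return RecordingSpec(
        fs_hz=fs_hz,
        duration_s=float(doc["duration_s"]),
        n_headstages=int(doc["n_headstages"]),
        n_channels_per_hs=int(doc["n_channels_per_hs"]),
        channel_specs=channel_specs,
        seed=int(doc["seed"]),
    )


def ground_truth_to_csv(gt: GroundTruth, path_or_buf) -> None:
    rows = [(hs, ch, int(i))
            for (hs, ch) in sorted(gt) for i in gt[(hs, ch)]]
    df = pd.DataFrame(rows, columns=["headstage", "channel", "sample_index"])
    df.to_csv(path_or_buf, index=False)


def ground_truth_from_csv(path_or_buf) -> GroundTruth:
    df = pd.read_csv(path_or_buf)
    gt: GroundTruth = {}
    for (hs, ch), grp in df.groupby(["headstage", "channel"]):
        gt[(int(hs), int(ch))] = np.sort(
            grp["sample_index"].to_numpy(dtype=np.int64))
    return gt
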