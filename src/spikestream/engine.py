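"""Real-time datapath emulation: decode -> filter -> detect -> encode.

One shared filter/detector datapath visits the channels of every frame in
serialization order, fetching and writing per-channel state from a 128-slot
state store (the software image of the hardware's dual-port RAMs). The
engine consumes a raw `.nsf` stream and produces the filtered+flags stream
— the raw samples are replaced by filtered ones, mirroring the hardware
trade-off — plus the list of spike events.

The module also carries the timing model of the emulated hardware: the
supported (sampling rate, clock) pairs all give 2800 clock cycles per
sampling period, and worst-case detection latency is the time to acquire the
two samples the 2nd-order filter needs plus the serial pipeline's
processing time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .codec import (PAYLOAD_FILTERED, PAYLOAD_RAW, HEADER_NBYTES,
                    StreamDecoder, StreamHeader, encode_frames,
                    slot_to_channel)
from .detector import DetectorConfig, DetectorState, SpikeEvent
from .filters import FilterState, QuantizedBiquad, design_quantized

log = logging.getLogger(__name__)

#: Supported sampling-rate / clock pairings of the emulated controller.
CLOCK_FOR_FS = {30000: 84_000_000, 25000: 70_000_000, 20000: 56_000_000}

#: Per-channel depth of the serial processing pipeline, in clock cycles.
DEFAULT_PIPELINE_CYCLES = 20

MAX_CHANNELS = 128
_STORE_HS = 8
_STORE_CH = 16

#: Frames per kernel block (bounds peak memory, does not affect results).
_CHUNK_FRAMES = 200_000


@dataclass(frozen=True)
class EngineConfig:
    fs_hz: int
    detector: DetectorConfig
    filter: QuantizedBiquad
    clock_hz: int | None = None
    pipeline_cycles_per_channel: int = DEFAULT_PIPELINE_CYCLES

    def __post_init__(self):
        if self.fs_hz not in CLOCK_FOR_FS:
            raise ValueError(f"unsupported sampling rate {self.fs_hz}")
        if self.clock_hz is None:
            object.__setattr__(self, "clock_hz", CLOCK_FOR_FS[self.fs_hz])
        elif self.clock_hz != CLOCK_FOR_FS[self.fs_hz]:
            raise ValueError(
                f"(fs, clock) = ({self.fs_hz}, {self.clock_hz}) is not a "
                f"supported pairing {CLOCK_FOR_FS}")
        if self.detector.fs_hz != self.fs_hz or self.filter.fs_hz != self.fs_hz:
            raise ValueError("detector/filter sampling rate mismatch")
        if self.pipeline_cycles_per_channel < 0:
            raise ValueError("pipeline depth must be >= 0")

    @classmethod
    def from_params(cls, fs_hz: int, threshold_uV: float = -50.0,
                    refractory_ms: float = 1.5, fc_hz: float = 300.0,
                    pipeline_cycles_per_channel: int = DEFAULT_PIPELINE_CYCLES
                    ) -> "EngineConfig":
        return cls(fs_hz=fs_hz,
                   detector=DetectorConfig(threshold_uV=threshold_uV,
                                           refractory_ms=refractory_ms,
                                           fs_hz=fs_hz),
                   filter=design_quantized(fs_hz, fc_hz),
                   pipeline_cycles_per_channel=pipeline_cycles_per_channel)


@dataclass(frozen=True)
class LatencyReport:
    """Worst-case spike-detection latency decomposition."""

    samples_needed: int
    acquisition_time_s: float
    processing_time_s: float
    total_s: float

    @property
    def total_us(self) -> float:
        return self.total_s * 1e6


@dataclass(frozen=True)
class CycleBudget:
    cycles_available_per_frame: int
    cycles_per_channel: float
    feasible: bool


def latency_model(config: EngineConfig,
                  samples_needed: int = 2) -> LatencyReport:
    """Latency = acquisition of the samples the filter needs + serial
    processing time of one channel slot at the paired clock."""
    acq = samples_needed / config.fs_hz
    proc = config.pipeline_cycles_per_channel / config.clock_hz
    return LatencyReport(samples_needed=samples_needed,
                         acquisition_time_s=acq, processing_time_s=proc,
                         total_s=acq + proc)


def cycle_budget(config: EngineConfig, n_channels: int) -> CycleBudget:
    """Clock cycles available per sampling period versus the serial load."""
    if not 1 <= n_channels <= MAX_CHANNELS:
        raise ValueError(f"channel count must be in [1, {MAX_CHANNELS}]")
    avail = config.clock_hz // config.fs_hz
    used = n_channels * config.pipeline_cycles_per_channel
    return CycleBudget(cycles_available_per_frame=avail,
                       cycles_per_channel=avail / n_channels,
                       feasible=used <= avail)


def max_feasible_channels(config: EngineConfig) -> int:
    """Largest addressable channel count the per-frame budget sustains."""
    avail = config.clock_hz // config.fs_hz
    if config.pipeline_cycles_per_channel == 0:
        return MAX_CHANNELS
    return min(MAX_CHANNELS, avail // config.pipeline_cycles_per_channel)


class StateStore:
    """Per-channel filter and detector state for all 128 addressable
    channels (16 channels x 8 headstages), materialized regardless of how
    many channels are actually driven."""

    def __init__(self):
        n = _STORE_HS * _STORE_CH
        self.w1 = np.zeros(n, dtype=np.int64)
        self.w2 = np.zeros(n, dtype=np.int64)
        self.y1 = np.zeros(n, dtype=np.int64)
        self.y2 = np.zeros(n, dtype=np.int64)
        self.refrc = np.zeros(n, dtype=np.int64)
        self.seen = np.zeros(n, dtype=np.int64)

    @staticmethod
    def address(headstage: int, channel: int) -> int:
        if not (0 <= headstage < _STORE_HS and 0 <= channel < _STORE_CH):
            raise ValueError("state store address out of range")
        return channel * _STORE_HS + headstage

    def filter_state(self, headstage: int, channel: int) -> FilterState:
        k = self.address(headstage, channel)
        return FilterState(w1=int(self.w1[k]), w2=int(self.w2[k]))

    def detector_state(self, headstage: int, channel: int) -> DetectorState:
        k = self.address(headstage, channel)
        return DetectorState(y1=int(self.y1[k]), y2=int(self.y2[k]),
                             refractory_counter=int(self.refrc[k]),
                             samples_seen=int(self.seen[k]))


class StreamingEngine:
    """Incremental stream processor.

    Feed raw `.nsf` bytes in chunks of any size; each call returns the
    encoded output bytes produced so far (header once, then filtered+flags
    frames). Per-channel state is carried across calls, so splitting a
    stream into chunks yields bit-identical results to one-shot processing.
    """

    def __init__(self, config: EngineConfig):
        self.config = config
        self.store = StateStore()
        self.header: StreamHeader | None = None
        self.out_header: StreamHeader | None = None
        self._hdr_buf = bytearray()
        self._decoder: StreamDecoder | None = None
        self._slot_map: np.ndarray | None = None
        self._seq = 0
        self._ev_frames: list[np.ndarray] = []
        self._ev_slots: list[np.ndarray] = []
        self.n_state_saturations = 0
        self.n_output_saturations = 0

    def process(self, data) -> bytes:
        out = bytearray()
        data = bytes(data)
        if self.header is None:
            self._hdr_buf.extend(data)
            if len(self._hdr_buf) < HEADER_NBYTES:
                return b""
            self.header = StreamHeader.unpack(bytes(self._hdr_buf))
            if self.header.payload_kind != PAYLOAD_RAW:
                raise ValueError("engine input must be a raw stream "
                                 "(payload_kind 0)")
            if self.header.fs_hz != self.config.fs_hz:
                raise ValueError(
                    f"stream sampled at {self.header.fs_hz} Hz but engine "
                    f"configured for {self.config.fs_hz} Hz")
            if (self.header.n_headstages > _STORE_HS
                    or self.header.n_channels_per_hs > _STORE_CH):
                raise ValueError("stream layout exceeds the 128-channel "
                                 "state store")
            n_hs = self.header.n_headstages
            slots = np.arange(self.header.n_channels, dtype=np.int64)
            self._slot_map = (slots // n_hs) * _STORE_HS + (slots % n_hs)
            self._decoder = StreamDecoder(self.header)
            self.out_header = StreamHeader(
                fs_hz=self.header.fs_hz, n_headstages=n_hs,
                n_channels_per_hs=self.header.n_channels_per_hs,
                payload_kind=PAYLOAD_FILTERED)
            out += self.out_header.pack()
            data = bytes(self._hdr_buf[HEADER_NBYTES:])
            self._hdr_buf.clear()
        frames = self._decoder.feed(data)
        if frames:
            fidx = np.array([f.frame_index for f in frames], dtype=np.uint32)
            samples = np.stack([f.samples for f in frames]).astype(np.int64)
            for lo in range(0, len(frames), _CHUNK_FRAMES):
                hi = min(lo + _CHUNK_FRAMES, len(frames))
                out += self._run_block(fidx[lo:hi], samples[lo:hi])
        return bytes(out)

    def _run_block(self, fidx: np.ndarray, x: np.ndarray) -> bytes:
        n_frames, n_slots = x.shape
        cfg, q = self.config.detector, self.config.filter
        filtered = np.empty((n_frames, n_slots), dtype=np.int16)
        spikes = np.zeros((n_frames, n_slots), dtype=np.uint8)
        cap = n_slots * (n_frames // (cfg.refractory_samples + 1) + 2)
        ev_frame = np.empty(cap, dtype=np.int64)
        ev_slot = np.empty(cap, dtype=np.int64)
        st = self.store
        nev, sat_state, sat_out = _kernels.process_frames(
            x, self._slot_map, q.qb0, q.qb1, q.qb2, q.qa1, q.qa2,
            cfg.threshold_counts, cfg.refractory_samples,
            st.w1, st.w2, st.y1, st.y2, st.refrc, st.seen,
            self._seq, filtered, spikes, ev_frame, ev_slot)
        self._seq += n_frames
        self.n_state_saturations += int(sat_state)
        self.n_output_saturations += int(sat_out)
        if nev:
            self._ev_frames.append(ev_frame[:nev].copy())
            self._ev_slots.append(ev_slot[:nev].copy())
        return encode_frames(fidx, filtered, spikes.astype(bool))

    def finish(self) -> None:
        if self._decoder is not None:
            self._decoder.finish()

    # -- results ----------------------------------------------------------

    @property
    def frames_processed(self) -> int:
        return self._seq

    @property
    def event_arrays(self):
        """Events as ``(sample_index, slot)`` int64 arrays (stream order)."""
        if self._ev_frames:
            return (np.concatenate(self._ev_frames),
                    np.concatenate(self._ev_slots))
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))

    def spike_events(self) -> list[SpikeEvent]:
        frames, slots = self.event_arrays
        n_hs = self.header.n_headstages if self.header else 1
        thr = self.config.detector.threshold_uV
        out = []
        for f, s in zip(frames, slots):
            hs, ch = slot_to_channel(int(s), n_hs)
            out.append(SpikeEvent(headstage=hs, channel=ch,
                                  sample_index=int(f), threshold_uV=thr))
        return out

    def events_for_channel(self, headstage: int, channel: int) -> np.ndarray:
        frames, slots = self.event_arrays
        slot = channel * self.header.n_headstages + headstage
        return frames[slots == slot]

    def report(self) -> dict:
        dec = self._decoder.state if self._decoder else None
        lat = latency_model(self.config)
        n_ch = self.header.n_channels if self.header else 0
        budget = cycle_budget(self.config, n_ch) if n_ch else None
        frames, slots = self.event_arrays
        per_channel = {}
        if self.header:
            for slot in range(self.header.n_channels):
                hs, ch = slot_to_channel(slot, self.header.n_headstages)
                per_channel[f"hs{hs}_ch{ch}"] = int((slots == slot).sum())
        return {
            "frames_processed": self.frames_processed,
            "n_events": int(frames.size),
            "events_per_channel": per_channel,
            "resync_events": dec.resync_events if dec else 0,
            "bytes_skipped": dec.bytes_skipped if dec else 0,
            "bytes_dropped_trailing": (dec.bytes_dropped_trailing
                                       if dec else 0),
            "filter_state_saturations": self.n_state_saturations,
            "output_saturations": self.n_output_saturations,
            "latency": {
                "samples_needed": lat.samples_needed,
                "acquisition_time_us": lat.acquisition_time_s * 1e6,
                "processing_time_us": lat.processing_time_s * 1e6,
                "total_us": lat.total_us,
            },
            "cycle_budget": ({
                "cycles_available_per_frame":
                    budget.cycles_available_per_frame,
                "cycles_per_channel": budget.cycles_per_channel,
                "feasible": budget.feasible,
            } if budget else None),
        }


@dataclass
class StreamResult:
    output_bytes: bytes
    events: list
    event_frames: np.ndarray
    event_slots: np.ndarray
    report: dict
    header: StreamHeader

    def events_for_channel(self, headstage: int, channel: int) -> np.ndarray:
        slot = channel * self.header.n_headstages + headstage
        return self.event_frames[self.event_slots == slot]


def process_stream(data: bytes, config: EngineConfig) -> StreamResult:
    """One-shot convenience wrapper around :class:`StreamingEngine`."""
    eng = StreamingEngine(config)
    out = eng.process(data)
    eng.finish()
    frames, slots = eng.event_arrays
    return StreamResult(output_bytes=out, events=eng.spike_events(),
                        event_frames=frames, event_slots=slots,
                        report=eng.report(), header=eng.header)
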