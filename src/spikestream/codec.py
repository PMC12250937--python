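"""Bit-exact encoder and Moore-machine decoder for the framed `.nsf` stream.

The acquisition controller multiplexes all channels serially: every sampling
period it emits one *frame* — a fixed 64-bit synchronization word, a frame
counter, then one signed 16-bit sample per channel in channel-major order
(channel outer, headstage inner), optionally followed by a spike-flag
bitmap. A 16-byte file header carries the layout. Everything is
little-endian; the byte-level layout is documented in ``docs/format.md``.

Two decoders are provided and kept equivalent by tests:

* :func:`fsm_step` — the reference Moore state machine, consuming one 16-bit
  word per step (the synchronization word is consumed as four words), whose
  left-fold over a well-formed stream defines the decode semantics;
* :class:`StreamDecoder` — an incremental, byte-oriented decoder with a
  vectorized fast path and byte-by-byte resynchronization after corruption.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

#: 64-bit frame synchronization word (the "magic number" starting each
#: acquisition loop). An arbitrary fixed constant with low self-similarity.
SYNC_WORD = 0x5AFEC0DE5A17E5D1
SYNC_BYTES = SYNC_WORD.to_bytes(8, "little")
#: The sync word as the four little-endian 16-bit words a serial decoder sees.
SYNC_WORDS = tuple((SYNC_WORD >> (16 * i)) & 0xFFFF for i in range(4))

MAGIC = b"NSF1"
_HEADER = struct.Struct("<4sHIBBB3s")
HEADER_NBYTES = _HEADER.size  # 16

PAYLOAD_RAW = 0
PAYLOAD_FILTERED = 1

SEEK_SYNC = "SEEK_SYNC"
IN_FRAME = "IN_FRAME"


@dataclass(frozen=True)
class StreamHeader:
    """16-byte `.nsf` container header."""

    fs_hz: int
    n_headstages: int
    n_channels_per_hs: int
    payload_kind: int = PAYLOAD_RAW
    version: int = 1

    def __post_init__(self):
        if self.payload_kind not in (PAYLOAD_RAW, PAYLOAD_FILTERED):
            raise ValueError("payload_kind must be 0 (raw) or 1 "
                             "(filtered+flags)")
        if not 1 <= self.n_headstages <= 255 or not 1 <= self.n_channels_per_hs <= 255:
            raise ValueError("channel layout fields must fit in one byte")

    @property
    def n_channels(self) -> int:
        return self.n_headstages * self.n_channels_per_hs

    @property
    def flag_nbytes(self) -> int:
        if self.payload_kind != PAYLOAD_FILTERED:
            return 0
        return (self.n_channels + 7) // 8

    @property
    def frame_nbytes(self) -> int:
        return 8 + 4 + 2 * self.n_channels + self.flag_nbytes

    def pack(self) -> bytes:
        return _HEADER.pack(MAGIC, self.version, self.fs_hz,
                            self.n_headstages, self.n_channels_per_hs,
                            self.payload_kind, b"\x00\x00\x00")

    @classmethod
    def unpack(cls, data: bytes) -> "StreamHeader":
        if len(data) < HEADER_NBYTES:
            raise ValueError("header truncated")
        magic, version, fs, n_hs, n_ch, kind, _ = _HEADER.unpack(
            data[:HEADER_NBYTES])
        if magic != MAGIC:
            raise ValueError(f"bad magic tag {magic!r}, expected {MAGIC!r}")
        return cls(fs_hz=fs, n_headstages=n_hs, n_channels_per_hs=n_ch,
                   payload_kind=kind, version=version)


def channel_slot(headstage: int, channel: int, n_headstages: int) -> int:
    """Serial slot of a channel within a frame (channel outer, hs inner)."""
    return channel * n_headstages + headstage


def slot_to_channel(slot: int, n_headstages: int):
    """Inverse of :func:`channel_slot`: slot -> (headstage, channel)."""
    return slot % n_headstages, slot // n_headstages


# ---------------------------------------------------------------------------
# encoding

def encode_frames(frame_indices, samples: np.ndarray, flags=None) -> bytes:
    """Serialize frames (no header).

    ``samples`` is int16 of shape ``(n_frames, n_channels)`` in slot order;
    ``flags``, if given, is a boolean array of the same shape and selects the
    filtered+flags payload layout.
    """
    samples = np.ascontiguousarray(samples, dtype="<i2")
    n_frames, n_ch = samples.shape
    fb = 0 if flags is None else (n_ch + 7) // 8
    flen = 8 + 4 + 2 * n_ch + fb
    buf = np.empty((n_frames, flen), dtype=np.uint8)
    buf[:, :8] = np.frombuffer(SYNC_BYTES, dtype=np.uint8)
    buf[:, 8:12] = (np.ascontiguousarray(frame_indices, dtype="<u4")
                    .reshape(n_frames, 1).view(np.uint8))
    buf[:, 12:12 + 2 * n_ch] = samples.view(np.uint8)
    if flags is not None:
        packed = np.packbits(np.asarray(flags, dtype=np.uint8), axis=1,
                             bitorder="little")
        buf[:, 12 + 2 * n_ch:] = packed
    return buf.tobytes()


def encode_stream(samples, header: StreamHeader, flags=None) -> bytes:
    """Serialize a whole recording as header + one frame per sample period.

    ``samples`` may be an int16 array ``(n_frames, n_channels)`` in slot
    order, or a mapping ``(headstage, channel) -> 1-D array`` (all channels
    equal length). Frame indices run 0..n_frames-1.
    """
    if isinstance(samples, dict):
        lengths = {len(v) for v in samples.values()}
        if len(lengths) > 1:
            raise ValueError("ragged channel lengths")
        n_frames = lengths.pop() if lengths else 0
        mat = np.zeros((n_frames, header.n_channels), dtype=np.int16)
        for (hs, ch), v in samples.items():
            mat[:, channel_slot(hs, ch, header.n_headstages)] = v
        samples = mat
    samples = np.asarray(samples, dtype=np.int16)
    if samples.ndim != 2 or samples.shape[1] != header.n_channels:
        raise ValueError("sample matrix shape does not match header layout")
    if header.payload_kind == PAYLOAD_FILTERED and flags is None:
        flags = np.zeros(samples.shape, dtype=bool)
    if header.payload_kind == PAYLOAD_RAW:
        flags = None
    return header.pack() + encode_frames(
        np.arange(samples.shape[0], dtype=np.uint32), samples, flags)


# ---------------------------------------------------------------------------
# decoding

@dataclass
class DecoderState:
    """Observable state of the stream decoder (Moore machine).

    ``word_position`` counts 16-bit words within the current frame: 0-3 sync,
    4-5 frame index, then one word per channel slot (plus flag words for
    payload kind 1). Outputs are a function of the post-transition state
    only.
    """

    n_headstages: int
    n_channels_per_hs: int
    payload_kind: int = PAYLOAD_RAW
    phase: str = SEEK_SYNC
    word_position: int = 0
    current_channel: int = 0
    current_headstage: int = 0
    frames_decoded: int = 0
    resync_events: int = 0
    bytes_skipped: int = 0
    bytes_dropped_trailing: int = 0
    # internal registers (part of the state so outputs stay Moore)
    frame_index: int = 0
    _frame_index_lo: int = 0
    _at_boundary: bool = False
    _last_word: int = 0

    @property
    def n_channels(self) -> int:
        return self.n_headstages * self.n_channels_per_hs

    @classmethod
    def initial(cls, header: StreamHeader) -> "DecoderState":
        if header.payload_kind == PAYLOAD_FILTERED and header.flag_nbytes % 2:
            raise ValueError(
                "the word-level FSM requires an even spike-flag bitmap; "
                "use decode_stream/StreamDecoder for this layout")
        return cls(n_headstages=header.n_headstages,
                   n_channels_per_hs=header.n_channels_per_hs,
                   payload_kind=header.payload_kind)


def fsm_step(state: DecoderState, word: int):
    """Advance the decoder by one 16-bit word.

    Pure transition function: returns ``(new_state, emitted)`` where
    ``emitted`` is ``(frame_index, headstage, channel, sample)`` when the new
    state has just consumed a sample word, else ``None``. The left-fold of
    this function over a well-formed word stream reproduces
    :func:`decode_stream`.
    """
    word &= 0xFFFF
    s = replace(state, _last_word=word)
    emitted = None
    n_slots = s.n_channels
    flag_words = 0
    if s.payload_kind == PAYLOAD_FILTERED:
        flag_words = ((n_slots + 7) // 8) // 2
    if s.phase == SEEK_SYNC:
        if word == SYNC_WORDS[s.word_position]:
            s.word_position += 1
            if s.word_position == 4:
                s.phase = IN_FRAME
                s._at_boundary = False
        else:
            if s._at_boundary:
                s.resync_events += 1
                s._at_boundary = False
            s.bytes_skipped += 2
            s.word_position = 1 if word == SYNC_WORDS[0] else 0
    else:  # IN_FRAME
        if s.word_position == 4:
            s._frame_index_lo = word
            s.word_position = 5
        elif s.word_position == 5:
            s.frame_index = s._frame_index_lo | (word << 16)
            s.word_position = 6
            s.current_channel = 0
            s.current_headstage = 0
        else:
            slot = s.word_position - 6
            if slot < n_slots:
                s.current_headstage, s.current_channel = slot_to_channel(
                    slot, s.n_headstages)
                sample = word - 0x10000 if word >= 0x8000 else word
                emitted = (s.frame_index, s.current_headstage,
                           s.current_channel, sample)
            s.word_position += 1
            if s.word_position == 6 + n_slots + flag_words:
                s.frames_decoded += 1
                s.phase = SEEK_SYNC
                s.word_position = 0
                s._at_boundary = True
    return s, emitted


@dataclass
class DecodedFrame:
    frame_index: int
    samples: np.ndarray          # int16, one per slot
    flags: np.ndarray | None = None  # bool, one per slot (payload kind 1)


class StreamDecoder:
    """Incremental byte-stream decoder with resynchronization.

    Feed arbitrary byte chunks; complete frames come back as
    :class:`DecodedFrame`. On a sync-word mismatch at an expected frame
    boundary the decoder scans byte-by-byte for the next sync word; each
    contiguous corrupted region counts as one resynchronization event and no
    sample from it is ever emitted. A partial trailing frame is dropped (and
    counted) by :meth:`finish`.
    """

    def __init__(self, header: StreamHeader):
        self.header = header
        self._buf = bytearray()
        self._frame_len = header.frame_nbytes
        self._n_slots = header.n_channels
        self._sync_arr = np.frombuffer(SYNC_BYTES, dtype=np.uint8)
        self._episode_counted = False
        self._last_frame_index = -1
        self._warned_duplicate = False
        self.frames_decoded = 0
        self.resync_events = 0
        self.bytes_skipped = 0
        self.bytes_dropped_trailing = 0
        self.bytes_fed = 0
        self.finished = False

    @property
    def phase(self) -> str:
        if self._buf and self._buf[:min(len(self._buf), 8)] == \
                SYNC_BYTES[:min(len(self._buf), 8)]:
            return IN_FRAME
        return SEEK_SYNC

    @property
    def state(self) -> DecoderState:
        """Snapshot of the decoder progress in DecoderState form."""
        return DecoderState(
            n_headstages=self.header.n_headstages,
            n_channels_per_hs=self.header.n_channels_per_hs,
            payload_kind=self.header.payload_kind,
            phase=self.phase,
            frames_decoded=self.frames_decoded,
            resync_events=self.resync_events,
            bytes_skipped=self.bytes_skipped,
            bytes_dropped_trailing=self.bytes_dropped_trailing,
        )

    def feed(self, data) -> list[DecodedFrame]:
        if self.finished:
            raise RuntimeError("decoder already finished")
        self._buf.extend(data)
        self.bytes_fed += len(data)
        out: list[DecodedFrame] = []
        buf = self._buf
        pos = 0
        flen = self._frame_len
        ns = self._n_slots
        fb = self.header.flag_nbytes
        while True:
            n = len(buf)
            # align to a sync word, skipping corrupted bytes
            i = buf.find(SYNC_BYTES, pos)
            if i == -1:
                keep = max(n - 7, pos)  # retain a possible sync prefix
                if keep > pos:
                    self.bytes_skipped += keep - pos
                    if not self._episode_counted:
                        self.resync_events += 1
                        self._episode_counted = True
                pos = keep
                break
            if i > pos:
                self.bytes_skipped += i - pos
                if not self._episode_counted:
                    self.resync_events += 1
                pos = i
            self._episode_counted = False
            avail = (n - pos) // flen
            if avail == 0:
                break
            arr = np.frombuffer(buf, dtype=np.uint8, count=avail * flen,
                                offset=pos).reshape(avail, flen)
            ok = (arr[:, :8] == self._sync_arr).all(axis=1)
            k = avail if bool(ok.all()) else int(np.argmin(ok))
            if k > 0:
                block = arr[:k]
                fidx = block[:, 8:12].copy().view("<u4").ravel()
                smp = (block[:, 12:12 + 2 * ns].copy().view("<i2")
                       .reshape(k, ns))
                if fb:
                    packed = block[:, 12 + 2 * ns:].copy()
                    flags = np.unpackbits(packed, axis=1,
                                          bitorder="little")[:, :ns]
                for j in range(k):
                    fi = int(fidx[j])
                    if fi <= self._last_frame_index and \
                            not self._warned_duplicate:
                        log.warning("non-increasing frame_index %d after %d "
                                    "(passed through)", fi,
                                    self._last_frame_index)
                        self._warned_duplicate = True
                    self._last_frame_index = max(self._last_frame_index, fi)
                    out.append(DecodedFrame(
                        frame_index=fi,
                        samples=smp[j],
                        flags=flags[j].astype(bool) if fb else None))
                self.frames_decoded += k
                pos += k * flen
            if k < avail:
                # mismatch at an expected frame boundary -> resynchronize;
                # the byte scan resumes right at the bad boundary
                self.resync_events += 1
                self._episode_counted = True
            # either way, keep scanning from the current position
        # views of the old buffer may still be alive; rebind instead of
        # resizing in place
        self._buf = bytearray(memoryview(buf)[pos:]) if pos else buf
        return out

    def finish(self) -> None:
        """Mark end of stream; any buffered partial frame is dropped."""
        if not self.finished:
            self.bytes_dropped_trailing = len(self._buf)
            if self.bytes_dropped_trailing:
                log.info("dropped %d trailing bytes (partial frame)",
                         self.bytes_dropped_trailing)
            self.finished = True


def decode_stream(payload: bytes, header: StreamHeader):
    """Decode a frame payload (header already parsed and stripped).

    Returns ``(samples, state)`` where ``samples`` is a list of
    ``(frame_index, headstage, channel, sample)`` tuples in serialization
    order and ``state`` summarizes frames decoded, resynchronization events
    and dropped bytes.
    """
    dec = StreamDecoder(header)
    frames = dec.feed(payload)
    dec.finish()
    n_hs = header.n_headstages
    out = []
    for fr in frames:
        fi = fr.frame_index
        for slot, sample in enumerate(fr.samples):
            hs, ch = slot_to_channel(slot, n_hs)
            out.append((fi, hs, ch, int(sample)))
    return out, dec.state
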