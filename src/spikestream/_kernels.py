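"""Numba kernels for the integer filter/detector datapath.

These loops are bitwise-identical folds of the pure-Python reference steps
(`filters.biquad_step`, `detector.detect_step`); the test suite asserts the
equivalence. All arithmetic is int64 with explicit saturation, matching the
documented fixed-point conventions.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Saturation bound of the Direct-Form-II state accumulator (48-bit
#: datapath). Chosen so every intermediate product stays within int64 even
#: with both states pinned at the rails.
STATE_CAP = 1 << 45

_I16_MAX = 32767
_I16_MIN = -32768


@njit(cache=True)
def biquad_batch(x, qb0, qb1, qb2, qa1, qa2, w1, w2):
    """Filter one channel; returns (y, w1, w2, n_state_saturations)."""
    n = x.shape[0]
    y = np.empty(n, np.int64)
    n_sat = 0
    for i in range(n):
        acc = (qa1 * w1 + qa2 * w2) >> 16
        w = (x[i] << 16) - acc
        if w > STATE_CAP:
            w = STATE_CAP
            n_sat += 1
        elif w < -STATE_CAP:
            w = -STATE_CAP
            n_sat += 1
        y[i] = (qb0 * w + qb1 * w1 + qb2 * w2 + (1 << 31)) >> 32
        w2 = w1
        w1 = w
    return y, w1, w2, n_sat


@njit(cache=True)
def detect_batch(y, thr, refr_n, y1, y2, refrc, seen, out_idx):
    """Run the detector over one channel's filtered counts.

    Events are written into ``out_idx`` (caller-sized); returns
    ``(n_events, y1, y2, refrc, seen)`` so state can be carried across
    chunks. Event index = position of the peak sample (t-1).
    """
    n = y.shape[0]
    nev = 0
    for i in range(n):
        v = y[i]
        if refrc > 0:
            refrc -= 1
        elif seen >= 2 and y1 < v and y1 <= y2 and y1 < thr:
            refrc = refr_n
            out_idx[nev] = i - 1
            nev += 1
        y2 = y1
        y1 = v
        seen += 1
    return nev, y1, y2, refrc, seen


@njit(cache=True)
def process_frames(x, slot_map, qb0, qb1, qb2, qa1, qa2, thr, refr_n,
                   w1, w2, y1, y2, refrc, seen, start_seq,
                   filtered, spikes, ev_frame, ev_slot):
    """Serial decode->filter->detect pass over a block of frames.

    ``x`` is int64 ``(n_frames, n_slots)`` in serialization order;
    ``slot_map[s]`` is the state-store address of slot ``s``. One shared
    datapath visits the channels of each frame in order, fetching and
    writing per-channel state, exactly as the hardware's dual-port RAMs do.
    Outputs: ``filtered`` int16 (saturated), ``spikes`` uint8 flags, event
    arrays; returns ``(n_events, n_state_sat, n_output_sat)``.
    """
    n_frames, n_slots = x.shape
    nev = 0
    sat_state = 0
    sat_out = 0
    for i in range(n_frames):
        for s in range(n_slots):
            k = slot_map[s]
            acc = (qa1 * w1[k] + qa2 * w2[k]) >> 16
            w = (x[i, s] << 16) - acc
            if w > STATE_CAP:
                w = STATE_CAP
                sat_state += 1
            elif w < -STATE_CAP:
                w = -STATE_CAP
                sat_state += 1
            v = (qb0 * w + qb1 * w1[k] + qb2 * w2[k] + (1 << 31)) >> 32
            w2[k] = w1[k]
            w1[k] = w
            if refrc[k] > 0:
                refrc[k] -= 1
            elif seen[k] >= 2 and y1[k] < v and y1[k] <= y2[k] and y1[k] < thr:
                refrc[k] = refr_n
                ev_frame[nev] = start_seq + i - 1
                ev_slot[nev] = s
                nev += 1
                spikes[i, s] = 1
            y2[k] = y1[k]
            y1[k] = v
            seen[k] += 1
            if v > _I16_MAX:
                filtered[i, s] = _I16_MAX
                sat_out += 1
            elif v < _I16_MIN:
                filtered[i, s] = _I16_MIN
                sat_out += 1
            else:
                filtered[i, s] = v
    return nev, sat_state, sat_out
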