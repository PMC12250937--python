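"""Second-order Butterworth highpass in deterministic fixed-point arithmetic.

The streaming datapath filters every channel with the same 2nd-order
highpass Butterworth section (cutoff 300 Hz by default), realized in
Direct-Form-II so that exactly two delay states per channel have to live in
the per-channel state store. Coefficients are designed with the bilinear
transform (prewarped), quantized to signed Q2.16, and executed with integer
arithmetic only, so results are bit-reproducible across platforms.

Arithmetic conventions (frozen; see docs/methods.md):

* coefficients: signed Q2.16 (18-bit), ``q = round(c * 2**16)`` half-up,
  with the quantized feedforward taps re-balanced so ``qb0+qb1+qb2 == 0``
  exactly — the highpass keeps an exact DC zero in fixed point;
* states: Direct-Form-II delays held at input-times-2^16 scale in a wide
  (48-bit datapath) saturating accumulator, ``|w| <= 2**45``;
* feedback rescale: arithmetic (floor) right shift by 16;
* output rescale: right shift by 32 with round-to-nearest (half toward
  +infinity).

Floating point exists in this module only for response analysis; the
production path is all-integer.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np

from . import _kernels

log = logging.getLogger(__name__)

Q_SHIFT = 16
Q_ONE = 1 << Q_SHIFT
#: Saturation bound of the Direct-Form-II state accumulator.
STATE_CAP = _kernels.STATE_CAP


@dataclass(frozen=True)
class BiquadCoeffs:
    """Real-valued biquad coefficients, a0 normalized to 1."""

    b0: float
    b1: float
    b2: float
    a1: float
    a2: float
    fs_hz: int
    fc_hz: float


@dataclass(frozen=True)
class QuantizedBiquad:
    """Q2.16 fixed-point biquad, ``qb0 + qb1 + qb2 == 0`` by construction."""

    qb0: int
    qb1: int
    qb2: int
    qa1: int
    qa2: int
    fs_hz: int
    fc_hz: float
    shift: int = Q_SHIFT


@dataclass
class FilterState:
    """The two Direct-Form-II delay states of one channel (wide counts)."""

    w1: int = 0
    w2: int = 0


def design_highpass_butterworth(fs_hz: int, fc_hz: float) -> BiquadCoeffs:
    """Closed-form bilinear-transform design with cutoff prewarping.

    With ``K = tan(pi * fc / fs)`` and ``norm = 1 + sqrt(2) K + K**2``::

        b0 = 1/norm   b1 = -2/norm   b2 = 1/norm
        a1 = 2 (K**2 - 1) / norm
        a2 = (1 - sqrt(2) K + K**2) / norm

    The magnitude response is exactly 1/sqrt(2) at ``fc`` and exactly 0 at
    DC (``b0 + b1 + b2 == 0``).
    """
    if not 0 < fc_hz < fs_hz / 2:
        raise ValueError("cutoff must lie strictly below the Nyquist "
                         "frequency")
    k = math.tan(math.pi * fc_hz / fs_hz)
    norm = 1.0 + math.sqrt(2.0) * k + k * k
    return BiquadCoeffs(
        b0=1.0 / norm,
        b1=-2.0 / norm,
        b2=1.0 / norm,
        a1=2.0 * (k * k - 1.0) / norm,
        a2=(1.0 - math.sqrt(2.0) * k + k * k) / norm,
        fs_hz=fs_hz,
        fc_hz=fc_hz,
    )


def _q16(value: float) -> int:
    # round-to-nearest, half toward +infinity
    return int(math.floor(value * Q_ONE + 0.5))


def quantize(coeffs: BiquadCoeffs) -> QuantizedBiquad:
    """Quantize to signed Q2.16, preserving the exact DC zero.

    ``qb1`` is forced to ``-(qb0 + qb2)`` after rounding, so the sum of the
    feedforward taps is exactly zero and a constant input decays to exactly
    zero output — no slow drift under DC offset.
    """
    for name in ("b0", "b1", "b2", "a1", "a2"):
        if abs(getattr(coeffs, name)) >= 2.0:
            raise OverflowError(f"|{name}| >= 2 cannot be represented "
                                "in Q2.16")
    qb0 = _q16(coeffs.b0)
    qb2 = _q16(coeffs.b2)
    q = QuantizedBiquad(
        qb0=qb0,
        qb1=-(qb0 + qb2),
        qb2=qb2,
        qa1=_q16(coeffs.a1),
        qa2=_q16(coeffs.a2),
        fs_hz=coeffs.fs_hz,
        fc_hz=coeffs.fc_hz,
    )
    limit = 1 << 17
    for name in ("qb0", "qb1", "qb2", "qa1", "qa2"):
        if not -limit <= getattr(q, name) < limit:
            raise OverflowError(f"{name} exceeds the signed 18-bit range")
    return q


def design_quantized(fs_hz: int, fc_hz: float = 300.0) -> QuantizedBiquad:
    """Convenience: design and quantize in one step."""
    return quantize(design_highpass_butterworth(fs_hz, fc_hz))


def biquad_step(state: FilterState, x: int, q: QuantizedBiquad):
    """One integer Direct-Form-II step; returns ``(new_state, y)``.

    This is the reference automaton: :func:`filter_batch` and the streaming
    engine are bitwise-identical left-folds of it.
    """
    acc = (q.qa1 * state.w1 + q.qa2 * state.w2) >> Q_SHIFT
    w = (int(x) << Q_SHIFT) - acc
    if w > STATE_CAP:
        w = STATE_CAP
        log.debug("filter state saturated (+)")
    elif w < -STATE_CAP:
        w = -STATE_CAP
        log.debug("filter state saturated (-)")
    y = (q.qb0 * w + q.qb1 * state.w1 + q.qb2 * state.w2 + (1 << 31)) >> 32
    return FilterState(w1=w, w2=state.w1), y


def filter_batch(trace, q: QuantizedBiquad,
                 state: FilterState | None = None) -> np.ndarray:
    """Filter a whole trace from zero (or given) state.

    Bitwise identical to folding :func:`biquad_step` over the trace, and to
    the streaming engine's per-channel output. Returns full-precision
    filtered counts (int64, not clipped to 16 bits).
    """
    x = np.ascontiguousarray(trace, dtype=np.int64)
    if state is None:
        state = FilterState()
    y, w1, w2, n_sat = _kernels.biquad_batch(
        x, q.qb0, q.qb1, q.qb2, q.qa1, q.qa2, state.w1, state.w2)
    state.w1, state.w2 = int(w1), int(w2)
    if n_sat:
        log.info("filter state saturated on %d samples", n_sat)
    return y


# ---------------------------------------------------------------------------
# response analysis (inspection/test support; not the production path)

def dequantized(q: QuantizedBiquad) -> BiquadCoeffs:
    """The real coefficients actually realized by the fixed-point filter."""
    return BiquadCoeffs(
        b0=q.qb0 / Q_ONE, b1=q.qb1 / Q_ONE, b2=q.qb2 / Q_ONE,
        a1=q.qa1 / Q_ONE, a2=q.qa2 / Q_ONE,
        fs_hz=q.fs_hz, fc_hz=q.fc_hz)


def magnitude_response(coeffs, freqs_hz) -> np.ndarray:
    """|H(e^{j 2 pi f / fs})| for BiquadCoeffs or QuantizedBiquad."""
    if isinstance(coeffs, QuantizedBiquad):
        coeffs = dequantized(coeffs)
    f = np.asarray(freqs_hz, dtype=np.float64)
    z = np.exp(-2j * np.pi * f / coeffs.fs_hz)
    num = coeffs.b0 + coeffs.b1 * z + coeffs.b2 * z * z
    den = 1.0 + coeffs.a1 * z + coeffs.a2 * z * z
    return np.abs(num / den)


def measure_cutoff_hz(q: QuantizedBiquad, lo_hz: float = 1.0,
                      hi_hz: float | None = None,
                      tol_hz: float = 1e-6) -> float:
    """-3 dB frequency of the realized filter, located by bisection.

    The magnitude response of a highpass is monotone through the transition
    band, so the 1/sqrt(2) crossing is bracketed between ``lo_hz`` and
    ``hi_hz`` (default: just below Nyquist).
    """
    target = 1.0 / math.sqrt(2.0)
    if hi_hz is None:
        hi_hz = q.fs_hz / 2.0 - 1.0
    flo, fhi = lo_hz, hi_hz
    if not (magnitude_response(q, flo) < target < magnitude_response(q, fhi)):
        raise ValueError("-3 dB crossing not bracketed")
    while fhi - flo > tol_hz:
        mid = 0.5 * (flo + fhi)
        if magnitude_response(q, mid) < target:
            flo = mid
        else:
            fhi = mid
    return 0.5 * (flo + fhi)


def coefficients_to_json(coeffs: BiquadCoeffs, q: QuantizedBiquad) -> str:
    """Export designed and quantized coefficients for inspection."""
    return json.dumps({
        "fs_hz": coeffs.fs_hz, "fc_hz": coeffs.fc_hz,
        "b0": coeffs.b0, "b1": coeffs.b1, "b2": coeffs.b2,
        "a1": coeffs.a1, "a2": coeffs.a2,
        "qb0": q.qb0, "qb1": q.qb1, "qb2": q.qb2,
        "qa1": q.qa1, "qa2": q.qa2, "shift": q.shift,
    }, indent=2)
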