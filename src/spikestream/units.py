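"""Amplitude conversions between microvolts and 16-bit ADC counts.

The acquisition front end digitizes extracellular voltage at 16 bits with a
least-significant-bit scale of 0.195 uV per count (the LSB of the commercial
amplifier family the datapath targets). All integer processing in this
package happens on the count scale; thresholds configured in microvolts are
converted once, up front.
"""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger(__name__)

#: LSB scale of the acquisition chain, microvolts per ADC count.
ADC_UV_PER_COUNT = 0.195

ADC_MIN = -32768
ADC_MAX = 32767


def uv_to_counts(value_uv: float, scale: float = ADC_UV_PER_COUNT) -> int:
    """Convert a scalar microvolt value to the nearest integer ADC count."""
    return int(np.rint(value_uv / scale))


def counts_to_uv(counts, scale: float = ADC_UV_PER_COUNT) -> np.ndarray:
    """Convert ADC counts back to microvolts (within +-scale/2 of the input)."""
    return np.asarray(counts, dtype=np.float64) * scale


def quantize_trace(trace_uv, scale: float = ADC_UV_PER_COUNT):
    """Round a microvolt trace to int16 counts, saturating at the ADC rails.

    Returns ``(counts, n_saturated)``; saturation is silent but counted.
    """
    counts = np.rint(np.asarray(trace_uv, dtype=np.float64) / scale)
    n_sat = int(np.count_nonzero((counts < ADC_MIN) | (counts > ADC_MAX)))
    if n_sat:
        log.info("ADC quantization saturated %d samples", n_sat)
    return np.clip(counts, ADC_MIN, ADC_MAX).astype(np.int16), n_sat
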