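"""Streaming engine: fold equivalence, channel isolation, timing model."""

import numpy as np
import pytest

import spikestream as ss
from conftest import make_noise_stream


def _offline(mat, slot, cfg):
    y = ss.filter_batch(mat[:, slot], cfg.filter)
    return y, ss.detect_offline(y, cfg.detector)


def test_single_channel_stream_equals_batch(q20):
    """Events and filtered samples of a 1-channel stream are bitwise equal
    to filter_batch + detect_offline on that channel."""
    data, mat, header = make_noise_stream(1, 1, 20000, seed=4,
                                          sigma_counts=300)
    cfg = ss.EngineConfig.from_params(20000, threshold_uV=-50.0)
    res = ss.process_stream(data, cfg)
    y, events = _offline(mat, 0, cfg)
    np.testing.assert_array_equal(res.events_for_channel(0, 0), events)
    out_payload = res.output_bytes[16:]
    out_header = ss.StreamHeader.unpack(res.output_bytes)
    tuples, _ = ss.decode_stream(out_payload, out_header)
    streamed = np.array([t[3] for t in tuples], dtype=np.int64)
    np.testing.assert_array_equal(streamed,
                                  np.clip(y, -32768, 32767))


def test_multichannel_equivalence_every_channel(q20):
    """Per-channel equivalence on an 8-channel stream (2 hs x 4 ch)."""
    data, mat, header = make_noise_stream(2, 4, 10000, seed=6,
                                          sigma_counts=200)
    cfg = ss.EngineConfig.from_params(20000, threshold_uV=-40.0)
    res = ss.process_stream(data, cfg)
    for hs in range(2):
        for ch in range(4):
            slot = ss.channel_slot(hs, ch, 2)
            _, events = _offline(mat, slot, cfg)
            np.testing.assert_array_equal(res.events_for_channel(hs, ch),
                                          events)


def test_interleaving_invariance():
    """A channel's output does not depend on what the other 127 channels
    carry (per-channel state isolation in the shared datapath)."""
    rng = np.random.default_rng(12)
    trace = np.rint(rng.normal(0, 250, 5000)).astype(np.int16)
    cfg = ss.EngineConfig.from_params(20000, threshold_uV=-40.0)
    # alone
    h1 = ss.StreamHeader(fs_hz=20000, n_headstages=1, n_channels_per_hs=1)
    alone = ss.process_stream(ss.encode_stream(trace[:, None], h1), cfg)
    # embedded among full-scale garbage on all other channels
    h128 = ss.StreamHeader(fs_hz=20000, n_headstages=8,
                           n_channels_per_hs=16)
    mat = rng.integers(-32768, 32768, (5000, 128)).astype(np.int16)
    slot = ss.channel_slot(3, 7, 8)
    mat[:, slot] = trace
    crowd = ss.process_stream(ss.encode_stream(mat, h128), cfg)
    np.testing.assert_array_equal(alone.events_for_channel(0, 0),
                                  crowd.events_for_channel(3, 7))


def test_128_channel_single_spike_isolation(q20):
    """A spike only on (hs 7, ch 15) of a fully loaded 128-channel stream
    produces exactly one event, on that channel."""
    fs = 20000
    tpl = ss.make_template("biphasic", 1.2, -200.0, fs)
    mat = np.zeros((4000, 128), dtype=np.int16)
    slot = ss.channel_slot(7, 15, 8)
    s = ss.to_adc_counts(tpl.samples)
    mat[2000:2000 + len(s), slot] = s
    header = ss.StreamHeader(fs_hz=fs, n_headstages=8, n_channels_per_hs=16)
    cfg = ss.EngineConfig.from_params(fs, threshold_uV=-50.0)
    res = ss.process_stream(ss.encode_stream(mat, header), cfg)
    assert res.event_frames.size == 1
    assert res.events_for_channel(7, 15).size == 1
    assert res.report["events_per_channel"]["hs7_ch15"] == 1


def test_chunked_processing_equals_one_shot():
    """Processing a stream in arbitrary byte chunks with carried state gives
    bit-identical output and events (restart equivalence)."""
    data, _, _ = make_noise_stream(2, 4, 3000, seed=7, sigma_counts=250)
    cfg = ss.EngineConfig.from_params(20000, threshold_uV=-40.0)
    one = ss.process_stream(data, cfg)
    eng = ss.StreamingEngine(cfg)
    out = b""
    cuts = [0, 5, 16, 17, 1000, len(data) // 2, len(data)]
    for a, b in zip(cuts, cuts[1:]):
        out += eng.process(data[a:b])
    eng.finish()
    assert out == one.output_bytes
    np.testing.assert_array_equal(eng.event_arrays[0], one.event_frames)
    np.testing.assert_array_equal(eng.event_arrays[1], one.event_slots)


def test_frame_conservation():
    """The output stream carries exactly as many frames as decodable input
    frames, with the input frame indices preserved."""
    data, _, header = make_noise_stream(1, 3, 500, seed=8)
    cfg = ss.EngineConfig.from_params(20000)
    res = ss.process_stream(data, cfg)
    out_header = ss.StreamHeader.unpack(res.output_bytes)
    assert out_header.payload_kind == 1
    assert len(res.output_bytes) == 16 + 500 * out_header.frame_nbytes
    tuples, state = ss.decode_stream(res.output_bytes[16:], out_header)
    assert state.frames_decoded == 500


def test_spike_flags_match_events():
    """Set bits in the output flag bitmap correspond one-to-one to events
    (flag raised in the frame where the detection step ran, i.e. one frame
    after the peak sample)."""
    data, mat, header = make_noise_stream(2, 2, 4000, seed=13,
                                          sigma_counts=250)
    cfg = ss.EngineConfig.from_params(20000, threshold_uV=-40.0)
    res = ss.process_stream(data, cfg)
    out_header = ss.StreamHeader.unpack(res.output_bytes)
    dec = ss.StreamDecoder(out_header)
    frames = dec.feed(res.output_bytes[16:])
    flagged = [(i, slot) for i, fr in enumerate(frames)
               for slot in np.flatnonzero(fr.flags)]
    expected = sorted((int(f) + 1, int(s))
                      for f, s in zip(res.event_frames, res.event_slots))
    assert sorted(flagged) == expected
    assert len(flagged) > 0


def test_engine_rejects_bad_streams_and_configs(det20, q20):
    cfg = ss.EngineConfig.from_params(20000)
    # filtered input refused
    h1 = ss.StreamHeader(fs_hz=20000, n_headstages=1, n_channels_per_hs=1,
                         payload_kind=1)
    stream1 = ss.encode_stream(np.zeros((2, 1), np.int16), h1)
    with pytest.raises(ValueError, match="raw stream"):
        ss.process_stream(stream1, cfg)
    # sampling-rate mismatch refused
    h2 = ss.StreamHeader(fs_hz=30000, n_headstages=1, n_channels_per_hs=1)
    stream2 = ss.encode_stream(np.zeros((2, 1), np.int16), h2)
    with pytest.raises(ValueError, match="configured"):
        ss.process_stream(stream2, cfg)
    # unsupported (fs, clock) pairing refused
    with pytest.raises(ValueError, match="pairing"):
        ss.EngineConfig(fs_hz=20000, detector=det20, filter=q20,
                        clock_hz=84_000_000)
    with pytest.raises(ValueError, match="unsupported"):
        ss.EngineConfig.from_params(44100)


@pytest.mark.parametrize("fs,clock,expect_us", [
    (20000, 56_000_000, 100.35714285714286),
    (25000, 70_000_000, 80.28571428571429),
    (30000, 84_000_000, 66.9047619047619),
])
def test_latency_model(fs, clock, expect_us):
    cfg = ss.EngineConfig.from_params(fs)
    assert cfg.clock_hz == clock
    rep = ss.latency_model(cfg)
    assert rep.samples_needed == 2
    assert rep.total_us == pytest.approx(expect_us, rel=1e-12)
    assert rep.total_s == pytest.approx(rep.acquisition_time_s
                                        + rep.processing_time_s)


def test_latency_degenerate_pipeline():
    cfg = ss.EngineConfig.from_params(20000, pipeline_cycles_per_channel=0)
    assert ss.latency_model(cfg).total_s == 2 / 20000


def test_latency_bound_at_20khz():
    """Worst-case latency at 20 kHz / 56 MHz stays within 100.37 us."""
    cfg = ss.EngineConfig.from_params(20000)
    assert ss.latency_model(cfg).total_us <= 100.37


@pytest.mark.parametrize("fs", (20000, 25000, 30000))
def test_cycle_budget_is_2800_for_all_pairings(fs):
    cfg = ss.EngineConfig.from_params(fs)
    budget = ss.cycle_budget(cfg, 128)
    assert budget.cycles_available_per_frame == 2800
    assert budget.feasible  # 128 x 20 = 2560 <= 2800


def test_cycle_budget_boundaries():
    cfg = ss.EngineConfig.from_params(20000, pipeline_cycles_per_channel=22)
    assert not ss.cycle_budget(cfg, 128).feasible  # 128 x 22 = 2816 > 2800
    assert ss.cycle_budget(cfg, 127).feasible      # 127 x 22 = 2794
    with pytest.raises(ValueError):
        ss.cycle_budget(cfg, 129)
    assert ss.max_feasible_channels(ss.EngineConfig.from_params(20000)) == 128


def test_state_store_covers_all_128_addressable_channels():
    store = ss.StateStore()
    assert store.w1.size == 128
    st = store.filter_state(7, 15)
    assert (st.w1, st.w2) == (0, 0)
    det = store.detector_state(0, 0)
    assert det.samples_seen == 0
    with pytest.raises(ValueError):
        store.address(8, 0)
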