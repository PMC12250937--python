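"""Synthetic recording generator: templates, trains, traces, quantization."""

import io

import numpy as np
import pytest

import spikestream as ss
from spikestream.synthetic import (ground_truth_from_csv, ground_truth_to_csv,
                                   recording_spec_from_yaml,
                                   recording_spec_to_yaml)


@pytest.mark.parametrize("kind,duration_ms,peak,fs,n_expected", [
    ("biphasic", 1.0, -100.0, 20000, 20),
    ("triangular", 1.0, -50.0, 20000, 20),
    ("biphasic", 1.0, -100.0, 30000, 30),
    ("biphasic", 0.5, -60.0, 20000, 10),
    ("triangular", 2.0, -250.0, 25000, 50),
])
def test_template_shape_contract(kind, duration_ms, peak, fs, n_expected):
    tpl = ss.make_template(kind, duration_ms, peak, fs)
    assert len(tpl) == n_expected
    assert tpl.samples.min() == peak
    # unique global minimum at a deterministic position
    assert np.count_nonzero(tpl.samples == tpl.samples.min()) == 1
    assert abs(tpl.samples[0]) <= 1.0 and abs(tpl.samples[-1]) <= 1.0
    if kind == "triangular":
        assert tpl.peak_index == (n_expected - 1) // 2
    # deterministic for fixed arguments
    again = ss.make_template(kind, duration_ms, peak, fs)
    np.testing.assert_array_equal(tpl.samples, again.samples)


def test_template_rejects_bad_parameters():
    with pytest.raises(ValueError):
        ss.make_template("biphasic", 1.0, 100.0, 20000)
    with pytest.raises(ValueError):
        ss.make_template("biphasic", 0.2, -100.0, 20000)
    with pytest.raises(ValueError):
        ss.make_template("sinusoidal", 1.0, -100.0, 20000)


def test_spike_train_edges():
    rng = np.random.default_rng(0)
    assert ss.generate_spike_train(0.0, 10.0, 0.002, 20000, rng).size == 0
    with pytest.raises(ValueError):
        ss.generate_spike_train(-1.0, 10.0, 0.002, 20000, rng)
    with pytest.raises(ValueError):
        ss.generate_spike_train(5.0, 10.0, 0.001, 20000, rng)


def test_spike_train_dead_time_statistics():
    """Mean count over 200 seeds matches the dead-time-corrected Poisson
    expectation rate*T/(1 + rate*dead_time) within 3 standard errors."""
    rate, T, dead, fs = 5.0, 60.0, 0.002, 20000
    counts = []
    for seed in range(200):
        rng = np.random.default_rng(seed)
        idx = ss.generate_spike_train(rate, T, dead, fs, rng)
        assert np.all(np.diff(idx) >= int(np.ceil(dead * fs)))
        counts.append(idx.size)
    counts = np.asarray(counts, dtype=float)
    expected = rate * T / (1.0 + rate * dead)
    se = counts.std(ddof=1) / np.sqrt(len(counts))
    assert abs(counts.mean() - expected) < 3 * se + 1.0


def _uniform_spec(duration_s=1.0, seed=3, rate=5.0, sigma=0.0, drift=0.0,
                  peak=-150.0, n_hs=1, n_ch=1, fs=20000):
    tpl = ss.make_template("biphasic", 1.2, peak, fs)
    cs = ss.ChannelSpec(firing_rate_hz=rate, template=tpl,
                        noise_sigma_uV=sigma, drift_amplitude_uV=drift,
                        drift_freq_hz=2.0)
    return ss.RecordingSpec(
        fs_hz=fs, duration_s=duration_s, n_headstages=n_hs,
        n_channels_per_hs=n_ch, seed=seed,
        channel_specs={(h, c): cs for h in range(n_hs) for c in range(n_ch)})


def test_recording_silent_channels_are_zero():
    spec = ss.RecordingSpec(fs_hz=20000, duration_s=0.1, n_headstages=1,
                            n_channels_per_hs=2, seed=0, channel_specs={})
    traces, gt = ss.generate_recording(spec)
    for v in traces.values():
        assert not v.any()
    assert all(g.size == 0 for g in gt.values())


def test_recording_noiseless_minimum_is_template_peak():
    spec = _uniform_spec(rate=5.0, sigma=0.0)
    traces, gt = ss.generate_recording(spec)
    tr = traces[(0, 0)]
    assert gt[(0, 0)].size > 0
    assert tr.min() == pytest.approx(-150.0)
    # peak-aligned: the trace attains the template peak at each truth index
    for i in gt[(0, 0)]:
        assert tr[i] == pytest.approx(-150.0)


def test_recording_determinism_and_channel_isolation():
    spec = _uniform_spec(sigma=12.0, n_hs=2, n_ch=3)
    t1, g1 = ss.generate_recording(spec)
    t2, g2 = ss.generate_recording(spec)
    for k in t1:
        np.testing.assert_array_equal(t1[k], t2[k])
        np.testing.assert_array_equal(g1[k], g2[k])
    # adding channels must not perturb existing ones (per-channel substreams)
    wide = _uniform_spec(sigma=12.0, n_hs=2, n_ch=16)
    t3, g3 = ss.generate_recording(wide)
    for k in t1:
        np.testing.assert_array_equal(t1[k], t3[k])


def test_ground_truth_respects_generator_dead_time():
    spec = _uniform_spec(duration_s=5.0, rate=20.0)
    _, gt = ss.generate_recording(spec)
    isi = np.diff(gt[(0, 0)])
    assert np.all(isi >= 0.002 * 20000)


def test_template_truncated_at_trace_end():
    """A truth spike whose template spills past the end is truncated."""
    fs = 20000
    tpl = ss.make_template("biphasic", 1.2, -150.0, fs)
    # short recording at a high rate makes a boundary spike likely
    for seed in range(30):
        spec = _uniform_spec(duration_s=0.05, seed=seed, rate=40.0)
        traces, gt = ss.generate_recording(spec)
        assert traces[(0, 0)].size == spec.n_samples
        assert np.all(gt[(0, 0)] < spec.n_samples)


@pytest.mark.parametrize("uv,count", [
    (0.0, 0),
    (-97.5, -500),     # -97.5 / 0.195 is exactly -500
    (0.195, 1),
    (-10000.0, -32768),  # saturates: -10000/0.195 ~ -51282
    (10000.0, 32767),
])
def test_adc_count_scale(uv, count):
    assert ss.to_adc_counts(np.array([uv]))[0] == count


def test_adc_inverse_scaling_error_bound():
    rng = np.random.default_rng(1)
    uv = rng.uniform(-500, 500, 1000)
    back = ss.counts_to_uv(ss.to_adc_counts(uv))
    assert np.max(np.abs(back - uv)) <= 0.0975 + 1e-12


def test_drift_alone_is_rejected_by_the_highpass(q20):
    """Electrode drift up to 500 uV below 5 Hz never crosses -50 uV after
    the 300 Hz highpass."""
    fs = 20000
    t = np.arange(fs * 5) / fs
    for amp, f in [(500.0, 5.0), (500.0, 1.0), (200.0, 4.0)]:
        counts = ss.to_adc_counts(amp * np.sin(2 * np.pi * f * t))
        y = ss.filter_batch(counts, q20)
        assert ss.counts_to_uv(y).min() > -50.0


def test_noiseless_spike_detected_at_truth_index(q20):
    """A lone noiseless template, filtered then thresholded at 60% of its
    peak, yields exactly one event within the filter's group delay (<=2
    samples) of the ground-truth index. Uses a 1 ms template: the 300 Hz
    highpass passes ~62% of the raw peak for troughs that fast, so the 60%
    threshold sits below the filtered peak."""
    fs = 20000
    for peak in (-80.0, -150.0, -250.0):
        tpl = ss.make_template("biphasic", 1.0, peak, fs)
        trace = np.zeros(2000)
        k = 1000
        trace[k - tpl.peak_index:k - tpl.peak_index + len(tpl)] += tpl.samples
        cfg = ss.DetectorConfig(threshold_uV=0.6 * peak, refractory_ms=1.5,
                                fs_hz=fs)
        events = ss.detect_offline(ss.filter_batch(ss.to_adc_counts(trace),
                                                   q20), cfg)
        assert events.size == 1
        assert abs(int(events[0]) - k) <= 2


def test_recording_spec_yaml_roundtrip():
    spec = _uniform_spec(sigma=12.0, drift=100.0, n_hs=2, n_ch=2)
    text = recording_spec_to_yaml(spec)
    back = recording_spec_from_yaml(text)
    assert back.fs_hz == spec.fs_hz
    assert back.seed == spec.seed
    assert back.channel_specs.keys() == spec.channel_specs.keys()
    t1, _ = ss.generate_recording(spec)
    t2, _ = ss.generate_recording(back)
    for k in t1:
        np.testing.assert_array_equal(t1[k], t2[k])


def test_recording_spec_yaml_rejects_unknown_keys():
    spec = _uniform_spec()
    text = recording_spec_to_yaml(spec) + "\nbogus_key: 1\n"
    with pytest.raises(ValueError, match="unknown config keys"):
        recording_spec_from_yaml(text)


def test_ground_truth_csv_roundtrip():
    _, gt = ss.generate_recording(_uniform_spec(duration_s=2.0, n_hs=2,
                                                n_ch=2))
    buf = io.StringIO()
    ground_truth_to_csv(gt, buf)
    buf.seek(0)
    assert buf.getvalue().splitlines()[0] == "headstage,channel,sample_index"
    back = ground_truth_from_csv(buf)
    for k, v in gt.items():
        if v.size:
            np.testing.assert_array_equal(back[k], v)
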