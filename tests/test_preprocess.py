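"""Reader and preprocessing-chain tests: blink boundaries, interpolation,
zero-phase filtering, decimation, run classification and measures."""

import numpy as np
import pytest

from bipr.io import read_samples
from bipr.preprocess import (
    bandpass_filter,
    classify_run,
    compute_run_measures,
    detect_zero_spans,
    downsample_100hz,
    interpolate_gaps,
    preprocess_trace,
    upsample_to_1khz,
)
from bipr.simulate import SimRunConfig, generate_pupil_run, write_asc
from bipr.trace import BlinkEvent, ClosureEvent, PupilTrace

from conftest import insert_zero_span, make_trace


class TestReadSamples:
    def test_delimited_zero_mapping(self, tmp_path):
        p = tmp_path / "run.csv"
        p.write_text("t_ms,pupil\n0,800\n1,0\n2,0\n3,810\n")
        tr = read_samples(p, dialect="delimited")
        assert tr.n == 4
        assert np.count_nonzero(tr.pupil == 0) == 2

    def test_eblink_labels_ignored(self, tmp_path):
        # recorder labels a 10 ms gap as EBLINK; blink re-detection must
        # classify it as a sub-40 ms short gap instead
        lines = []
        for t in range(100):
            v = 0.0 if 50 <= t < 60 else 700.0
            lines.append(f"{t}\t640.0\t512.0\t{v}")
        lines.insert(50, "EBLINK R 50 60 10")
        p = tmp_path / "run.asc"
        p.write_text("\n".join(lines) + "\n")
        tr = read_samples(p, dialect="asc_like")
        assert tr.n == 100
        blinks, closures, short = detect_zero_spans(tr)
        assert blinks == [] and closures == []
        assert len(short) == 1

    def test_nonuniform_timestamps_error(self, tmp_path):
        p = tmp_path / "run.asc"
        p.write_text("\n".join(f"{2 * t}\t.\t.\t700.0" for t in range(50)) + "\n")
        with pytest.raises(ValueError, match="non-uniform"):
            read_samples(p, dialect="asc_like", sampling_rate=1000)

    def test_blank_and_nonnumeric_pupil_is_missing(self, tmp_path):
        p = tmp_path / "run.asc"
        p.write_text("0\t.\t.\t.\n1\t.\t.\t700.0\n2\t.\t.\t700.0\n")
        tr = read_samples(p)
        assert tr.pupil[0] == 0.0 and tr.pupil[1] == 700.0

    def test_rate_inferred_from_spacing(self, tmp_path):
        p = tmp_path / "run.asc"
        p.write_text("\n".join(f"{2 * t}\t.\t.\t700.0" for t in range(50)) + "\n")
        assert read_samples(p).sampling_rate == 500.0


class TestUpsample:
    def test_constant_trace(self):
        tr = make_trace(np.full(500, 700.0), fs=500)
        up = upsample_to_1khz(tr)
        assert up.n == 1000
        assert np.all(up.pupil == 700.0)

    def test_zero_span_length_preserved(self):
        tr = insert_zero_span(make_trace(np.full(500, 700.0), fs=500), 200, 40)
        up = upsample_to_1khz(tr)
        zeros = np.flatnonzero(up.pupil == 0)
        assert zeros.size == 40
        assert up.t_ms[zeros[0]] == 200.0  # onset unchanged

    def test_linear_ramp_midpoints(self):
        x = np.linspace(100, 200, 500)
        up = upsample_to_1khz(make_trace(x, fs=500))
        expected = np.interp(up.t_ms, np.arange(500) * 2.0, x)
        assert np.allclose(up.pupil[:-1], expected[:-1], atol=1e-9)

    def test_1khz_passthrough_and_bad_rate(self):
        tr = make_trace(np.full(100, 1.0), fs=1000)
        assert upsample_to_1khz(tr) is tr
        with pytest.raises(ValueError):
            upsample_to_1khz(make_trace(np.full(100, 1.0), fs=250))


class TestZeroSpanBoundaries:
    @pytest.mark.parametrize(
        "dur_ms,n_blinks,n_closures,n_short",
        [(39, 0, 0, 1), (40, 1, 0, 0), (400, 1, 0, 0), (401, 0, 1, 0)],
    )
    def test_duration_partition(self, constant_trace, dur_ms, n_blinks, n_closures, n_short):
        tr = insert_zero_span(constant_trace, 5000, dur_ms)
        blinks, closures, short = detect_zero_spans(tr)
        assert (len(blinks), len(closures), len(short)) == (n_blinks, n_closures, n_short)

    def test_onset_is_first_zero_sample(self, constant_trace):
        tr = insert_zero_span(constant_trace, 5000, 100)
        blinks, _, _ = detect_zero_spans(tr)
        assert blinks[0].onset_ms == 5000.0
        assert blinks[0].duration_ms == 100.0

    def test_event_invariants(self):
        with pytest.raises(ValueError):
            BlinkEvent(onset_ms=0, offset_ms=30)
        with pytest.raises(ValueError):
            ClosureEvent(onset_ms=0, offset_ms=300)


class TestInterpolation:
    def test_constant_trace_reconstructed(self, constant_trace):
        tr = insert_zero_span(constant_trace, 5000, 120)
        blinks, _, short = detect_zero_spans(tr)
        out, stats = interpolate_gaps(tr, blinks, short)
        assert stats.n_interpolated == 1
        assert np.allclose(out.pupil, 800.0, atol=1e-6)
        assert not out.missing.any()

    def test_linear_ramp_reconstructed(self):
        tr = make_trace(np.linspace(100, 200, 10_000))
        tr = insert_zero_span(tr, 5000, 200)
        blinks, _, short = detect_zero_spans(tr)
        out, _ = interpolate_gaps(tr, blinks, short)
        expected = np.linspace(100, 200, 10_000)
        assert np.allclose(out.pupil, expected, atol=1e-6)

    def test_closure_left_missing(self, constant_trace):
        tr = insert_zero_span(constant_trace, 4000, 2000)
        blinks, closures, short = detect_zero_spans(tr)
        out, _ = interpolate_gaps(tr, blinks, short)
        assert len(closures) == 1
        assert out.missing[4000:6000].all()
        # values are bridged for the filter's sake but stay masked
        assert not out.missing[:4000].any() and not out.missing[6000:].any()

    def test_edge_blink_left_missing(self, constant_trace):
        tr = insert_zero_span(constant_trace, 20, 100)
        blinks, _, short = detect_zero_spans(tr)
        out, stats = interpolate_gaps(tr, blinks, short)
        assert stats.n_left_missing == 1
        assert out.missing[20:120].all()


class TestBandpass:
    def test_dc_removed(self):
        tr = make_trace(np.full(100_000, 500.0))
        y = bandpass_filter(tr).pupil
        assert np.max(np.abs(y)) < 1e-3 * 500

    def test_1hz_gain_and_phase(self):
        t = np.arange(120_000) / 1000.0
        tr = make_trace(np.sin(2 * np.pi * 1.0 * t))
        y = bandpass_filter(tr).pupil
        core = slice(30_000, 90_000)
        amp = np.max(np.abs(y[core]))
        assert 0.95 <= amp <= 1.05
        # zero phase: peaks of input and output coincide
        ipk = 30_000 + np.argmax(tr.pupil[core])
        opk = ipk - 20 + np.argmax(y[ipk - 20 : ipk + 20])
        assert abs(int(opk) - int(ipk)) <= 1

    def test_gaussian_pulse_peak_preserved(self):
        t = np.arange(100_000)
        pulse = 10.0 * np.exp(-0.5 * ((t - 50_000) / 300.0) ** 2)
        y = bandpass_filter(make_trace(pulse)).pupil
        assert abs(int(np.argmax(y)) - 50_000) <= 1

    def test_slow_drift_removed(self):
        # sinusoidal drift below the 0.02 Hz edge must not survive
        t = np.arange(200_000) / 1000.0
        x = 800 + 50 * np.sin(2 * np.pi * 0.01 * t)
        y = bandpass_filter(make_trace(x)).pupil
        assert np.abs(y[40_000:160_000]).max() < 0.01 * 50

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            bandpass_filter(make_trace(np.ones(50_000)))


class TestDownsample:
    def test_length_and_pick_rule(self):
        tr = make_trace(np.arange(10_000, dtype=float) + 1.0)
        out = downsample_100hz(tr)
        assert out.n == 1000
        assert np.array_equal(out.pupil, tr.pupil[::10])

    def test_missing_mask_or_rule(self):
        tr = make_trace(np.ones(1000))
        mask = np.zeros(1000, dtype=bool)
        mask[15] = True  # inside block 1
        tr = tr.copy(missing=mask)
        out = downsample_100hz(tr)
        assert out.missing[1] and not out.missing[0] and not out.missing[2]

    def test_rate_check(self):
        with pytest.raises(ValueError):
            downsample_100hz(make_trace(np.ones(100), fs=500))


class TestClassifyRun:
    @pytest.mark.parametrize(
        "loss,state",
        [(0.0, "vigilant"), (0.05, "vigilant"), (0.10, "drowsy"), (0.39, "drowsy"),
         (0.40, "very_drowsy"), (0.75, "very_drowsy"), (0.80, "discarded")],
    )
    def test_bins(self, loss, state):
        n = 10_000
        x = np.full(n, 600.0)
        x[: int(round(loss * n))] = 0.0
        cls = classify_run(make_trace(x))
        assert cls.state == state
        assert cls.loss_fraction == pytest.approx(loss, abs=1e-12)

    def test_scaling_invariance(self):
        x = np.full(1000, 600.0)
        x[:200] = 0.0
        base = classify_run(make_trace(x))
        scaled = classify_run(make_trace(x * 3.7))
        assert scaled == base


class TestRunMeasures:
    def test_rate_no_closures(self):
        tr = make_trace(np.full(60_000, 600.0))
        blinks = [BlinkEvent(onset_ms=1000 + 2000 * i, offset_ms=1100 + 2000 * i) for i in range(12)]
        m = compute_run_measures(tr, blinks, [])
        assert m.blink_rate_per_min == pytest.approx(12.0)
        assert m.mean_blink_duration_ms == pytest.approx(100.0)
        assert m.mean_pupil_size_au == pytest.approx(600.0)

    def test_closures_excluded_from_denominator(self):
        tr = make_trace(np.full(120_000, 600.0))
        blinks = [BlinkEvent(onset_ms=1000 + 3000 * i, offset_ms=1100 + 3000 * i) for i in range(10)]
        closures = [ClosureEvent(onset_ms=60_000, offset_ms=120_000)]
        m = compute_run_measures(tr, blinks, closures)
        assert m.blink_rate_per_min == pytest.approx(10.0)

    def test_no_blinks_flagged(self):
        tr = make_trace(np.full(60_000, 600.0))
        m = compute_run_measures(tr, [], [])
        assert m.blink_rate_per_min == 0.0
        assert np.isnan(m.mean_blink_duration_ms)


class TestEndToEnd:
    def test_groundtruth_events_recovered_exactly(self):
        cfg = SimRunConfig(duration_s=120, noise_sd=0.0, seed=17)
        trace, gt = generate_pupil_run(cfg)
        blinks, closures, _ = detect_zero_spans(trace)
        assert [b.onset_ms for b in blinks] == sorted(gt.blink_onsets_ms)
        durs = {o: d for o, d in zip(gt.blink_onsets_ms, gt.blink_durations_ms)}
        for b in blinks:
            assert b.duration_ms == durs[b.onset_ms]
        assert [c.onset_ms for c in closures] == sorted(gt.closure_onsets_ms)

    def test_preprocessing_deterministic_via_file(self, tmp_path):
        cfg = SimRunConfig(duration_s=120, seed=23)
        trace, gt = generate_pupil_run(cfg)
        p = tmp_path / "run.asc"
        write_asc(trace, p, gt)
        out1 = preprocess_trace(read_samples(p))
        out2 = preprocess_trace(read_samples(p))
        assert np.array_equal(out1[0].pupil, out2[0].pupil)
        assert out1[3] == out2[3]
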