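"""Pupil preprocessing: the six-step chain plus run classification.

The chain mirrors standard resting-state pupillometry practice:

1. read raw samples (see :mod:`bipr.io`);
2. up-sample 500 Hz recordings to 1 kHz;
3. detect blinks as maximal zero-spans of 40-400 ms (inclusive) and
   eyelid closures as spans longer than 400 ms;
4. cubic-spline interpolate blink spans and sub-40 ms glitches;
5. zero-phase FIR band-pass 0.02-4 Hz;
6. decimate to 100 Hz.

Run-level vigilance is classified from the fraction of samples with no
detected pupil, and per-run eye measures (blink rate, blink duration,
mean pupil size) are computed on the raw trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy.fft import irfft, next_fast_len, rfft
from scipy.interpolate import CubicSpline

from .trace import BLINK_MAX_MS, BLINK_MIN_MS, BlinkEvent, ClosureEvent, PupilTrace

__all__ = [
    "upsample_to_1khz",
    "detect_zero_spans",
    "interpolate_gaps",
    "InterpolationStats",
    "bandpass_filter",
    "downsample_100hz",
    "classify_run",
    "RunClassification",
    "compute_run_measures",
    "RunMeasures",
    "preprocess_trace",
]


def upsample_to_1khz(trace: PupilTrace) -> PupilTrace:
    """Up-sample a 500 Hz trace to 1 kHz by midpoint interpolation.

    Missing (zero) spans are never interpolated across: an inserted
    midpoint is zero when its left neighbour is zero, and holds the left
    value when only the right neighbour is zero. This keeps the onset and
    the total length of every zero-span exactly as recorded. A 1 kHz
    input is returned unchanged.
    """
    if trace.sampling_rate == 1000:
        return trace
    if trace.sampling_rate != 500:
        raise ValueError(f"unsupported sampling rate {trace.sampling_rate} Hz")
    x = trace.pupil
    n = x.size
    out = np.empty(2 * n)
    out[0::2] = x
    nxt = np.append(x[1:], x[-1])
    mid = 0.5 * (x + nxt)
    mid = np.where(nxt == 0.0, x, mid)   # do not interpolate into a gap
    mid = np.where(x == 0.0, 0.0, mid)   # gap continues through the midpoint
    out[1::2] = mid
    t = trace.t_ms[0] + np.arange(2 * n) * 1.0
    return PupilTrace(t_ms=t, pupil=out, sampling_rate=1000.0)


def _zero_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of exact zeros as half-open index pairs (i0, i1)."""
    iszero = np.concatenate(([False], x == 0.0, [False]))
    edges = np.flatnonzero(np.diff(iszero.astype(np.int8)))
    return list(zip(edges[0::2], edges[1::2]))


def detect_zero_spans(
    trace: PupilTrace,
) -> tuple[list[BlinkEvent], list[ClosureEvent], list[tuple[float, float]]]:
    """Partition maximal zero-spans into blinks, closures and short gaps.

    Duration boundaries are inclusive at both blink edges: spans of
    40-400 ms are blinks, spans under 40 ms are tracking glitches
    ("short gaps"), spans over 400 ms are eyelid closures. Onset is the
    time of the first zero sample.
    """
    if trace.sampling_rate != 1000:
        raise ValueError("zero-span detection expects a 1 kHz trace")
    step = trace.dt_ms
    blinks: list[BlinkEvent] = []
    closures: list[ClosureEvent] = []
    short: list[tuple[float, float]] = []
    for i0, i1 in _zero_runs(trace.pupil):
        onset = trace.t_ms[i0]
        dur = (i1 - i0) * step
        if dur < BLINK_MIN_MS:
            short.append((onset, onset + dur))
        elif dur <= BLINK_MAX_MS:
            blinks.append(BlinkEvent(onset_ms=onset, offset_ms=onset + dur))
        else:
            closures.append(ClosureEvent(onset_ms=onset, offset_ms=onset + dur))
    return blinks, closures, short


@dataclass
class InterpolationStats:
    """Counters from gap interpolation."""

    n_interpolated: int = 0
    n_left_missing: int = 0   # gaps with insufficient flanking context
    n_clipped: int = 0        # interpolated samples clipped at 0


def interpolate_gaps(
    trace: PupilTrace,
    blinks: list[BlinkEvent],
    short_gaps: list[tuple[float, float]],
    *,
    guard_pre_ms: float = 40.0,
    guard_post_ms: float = 80.0,
    n_context: int = 4,
    context_spacing_ms: float = 10.0,
) -> tuple[PupilTrace, InterpolationStats]:
    """Replace blink spans and short gaps with a cubic-spline fit.

    The replaced region extends a guard margin beyond each gap
    (``guard_pre_ms`` before onset, ``guard_post_ms`` after offset) to
    skip eyelid-edge artifacts; the spline is fit through ``n_context``
    samples on each side taken just outside the guard at
    ``context_spacing_ms`` spacing. Gaps whose context is unavailable
    (trace edge, or neighbouring missing data) are left missing and
    counted. Eyelid closures are never spline-reconstructed: their spans
    stay flagged missing in the output mask for epoch rejection (the
    values are only bridged linearly so the subsequent filter sees no
    artificial cliffs).
    """
    x = trace.pupil.copy()
    missing = trace.pupil == 0.0
    stats = InterpolationStats()
    step = trace.dt_ms
    t0 = trace.t_ms[0]
    sp = max(1, int(round(context_spacing_ms / step)))
    n = x.size

    spans = [(b.onset_ms, b.offset_ms) for b in blinks] + list(short_gaps)
    for onset_ms, offset_ms in spans:
        i_on = int(round((onset_ms - t0) / step))
        i_off = int(round((offset_ms - t0) / step))
        r0 = i_on - int(round(guard_pre_ms / step))
        r1 = i_off + int(round(guard_post_ms / step))
        left = [r0 - 1 - sp * k for k in range(n_context - 1, -1, -1)]
        right = [r1 + sp * k for k in range(n_context)]
        ctx = left + right
        if ctx[0] < 0 or ctx[-1] >= n or any(missing[j] and not (i_on <= j < i_off) for j in ctx):
            stats.n_left_missing += 1
            continue
        if any(x[j] == 0.0 for j in ctx):
            stats.n_left_missing += 1
            continue
        tc = trace.t_ms[ctx]
        vc = x[ctx]
        spline = CubicSpline(tc, vc)
        lo, hi = max(r0, 0), min(r1, n)
        vals = spline(trace.t_ms[lo:hi])
        clipped = vals < 0
        stats.n_clipped += int(clipped.sum())
        vals = np.where(clipped, 0.0, vals)
        x[lo:hi] = vals
        missing[i_on:i_off] = False
        stats.n_interpolated += 1

    # Bridge the values of still-missing spans (closures, failed blinks)
    # linearly so the later band-pass sees no 0-valued cliffs, whose
    # ringing would leak far beyond the masked span. The mask still
    # marks these samples missing; downstream stages never use them.
    if missing.any() and not missing.all():
        valid = np.flatnonzero(~missing)
        gaps = np.flatnonzero(missing)
        x[gaps] = np.interp(gaps, valid, x[valid])
    return trace.copy(pupil=x, missing=missing), stats


def design_bandpass(
    low_hz: float = 0.02, high_hz: float = 4.0, numtaps: int = 30001, fs: float = 1000.0
) -> np.ndarray:
    """Windowed-sinc band-pass built as a difference of two low-passes.

    Subtracting a unity-DC-gain low-pass at the low cutoff from one at the
    high cutoff yields a band-pass with *exactly* zero DC gain, so tonic
    pupil level is fully removed even though the 0.02 Hz edge is extremely
    narrow relative to the sampling rate.
    """
    h_hi = _signal.firwin(numtaps, high_hz, fs=fs, window="hamming")
    h_lo = _signal.firwin(numtaps, low_hz, fs=fs, window="hamming")
    return h_hi - h_lo


def bandpass_filter(
    trace: PupilTrace,
    low_hz: float = 0.02,
    high_hz: float = 4.0,
    numtaps: int = 30001,
) -> PupilTrace:
    """Zero-phase band-pass (0.02-4 Hz) of an interpolated trace.

    The symmetric FIR is applied forward-backward, implemented in the
    frequency domain as multiplication by the squared magnitude response
    with odd-reflection padding — identical to ``filtfilt`` with this
    kernel but fast for very long filters. The missing mask passes
    through untouched.
    """
    n = trace.n
    if n < 3 * numtaps:
        raise ValueError(
            f"trace of {n} samples is shorter than 3x the {numtaps}-tap filter"
        )
    h = design_bandpass(low_hz, high_hz, numtaps, fs=trace.sampling_rate)
    pad = numtaps
    x = trace.pupil
    xp = np.concatenate([2 * x[0] - x[pad:0:-1], x, 2 * x[-1] - x[-2 : -pad - 2 : -1]])
    nfft = next_fast_len(xp.size)
    amp2 = np.abs(rfft(h, nfft)) ** 2  # forward-backward = |H|^2, zero phase
    y = irfft(rfft(xp, nfft) * amp2, nfft)[pad : pad + n]
    return trace.copy(pupil=y, missing=trace.missing_mask().copy())


def downsample_100hz(trace: PupilTrace) -> PupilTrace:
    """Decimate a 1 kHz trace to 100 Hz by keeping every 10th sample.

    Safe only after low-pass filtering at 4 Hz. The missing mask is
    reduced by logical OR over each 10-sample block, so a block with any
    missing source sample yields a missing output sample.
    """
    if trace.sampling_rate != 1000:
        raise ValueError("downsampling expects a 1 kHz trace")
    x = trace.pupil[::10]
    t = trace.t_ms[::10]
    m = trace.missing_mask()
    nblocks = x.size
    padded = np.zeros(nblocks * 10, dtype=bool)
    padded[: m.size] = m
    mask = padded.reshape(nblocks, 10).any(axis=1)
    return PupilTrace(t_ms=t, pupil=x, sampling_rate=100.0, missing=mask)


@dataclass(frozen=True)
class RunClassification:
    """Vigilance state of a run from its fraction of undetected-pupil samples."""

    loss_fraction: float
    state: str


#: loss-fraction bin edges; vigilant is strict (<10%), discarded is strict (>75%)
_STATE_BINS = ((0.10, "vigilant"), (0.40, "drowsy"), (0.75 + 1e-12, "very_drowsy"))


def classify_run(trace: PupilTrace) -> RunClassification:
    """Classify a raw run: <10% loss vigilant, 10-40% drowsy, 40-75% very
    drowsy, >75% discarded. Classification is done on the raw
    (pre-interpolation) trace and depends only on which samples are zero,
    so it is invariant to any positive rescaling of the pupil values."""
    loss = float(np.mean(trace.pupil == 0.0))
    for edge, state in _STATE_BINS:
        if loss < edge:
            return RunClassification(loss_fraction=loss, state=state)
    return RunClassification(loss_fraction=loss, state="discarded")


@dataclass(frozen=True)
class RunMeasures:
    """Per-run eye measures; NaN marks an undefined (flagged) value."""

    blink_rate_per_min: float
    mean_blink_duration_ms: float
    mean_pupil_size_au: float


def compute_run_measures(
    trace: PupilTrace,
    blinks: list[BlinkEvent],
    closures: list[ClosureEvent],
    *,
    blinks_count_as_open: bool = True,
) -> RunMeasures:
    """Blink rate, mean blink duration and mean pupil size for one raw run.

    The blink-rate denominator is eyes-open time: total duration minus
    eyelid-closure time. Blink spans count as open time by default (a
    blink is an open-eye behaviour); set ``blinks_count_as_open=False``
    to exclude them as well. Mean pupil size is computed over raw nonzero
    samples, i.e. the tonic level before any filtering.
    """
    total_s = trace.duration_s
    closed_s = sum(c.duration_ms for c in closures) / 1000.0
    if not blinks_count_as_open:
        closed_s += sum(b.duration_ms for b in blinks) / 1000.0
    open_min = (total_s - closed_s) / 60.0
    if open_min <= 0:
        return RunMeasures(np.nan, np.nan, np.nan)
    rate = len(blinks) / open_min
    mean_dur = float(np.mean([b.duration_ms for b in blinks])) if blinks else np.nan
    nonzero = trace.pupil[trace.pupil > 0]
    mean_pupil = float(nonzero.mean()) if nonzero.size else np.nan
    return RunMeasures(rate, mean_dur, mean_pupil)


def preprocess_trace(
    trace: PupilTrace, *, numtaps: int = 30001
) -> tuple[PupilTrace, list[BlinkEvent], list[ClosureEvent], RunClassification, RunMeasures, InterpolationStats]:
    """Run the full chain on a raw trace.

    Returns the 100 Hz band-passed trace together with the detected
    events, the vigilance classification, the raw-trace run measures and
    the interpolation counters.
    """
    raw1k = upsample_to_1khz(trace)
    cls = classify_run(raw1k)
    blinks, closures, short = detect_zero_spans(raw1k)
    measures = compute_run_measures(raw1k, blinks, closures)
    interp, stats = interpolate_gaps(raw1k, blinks, short)
    filtered = bandpass_filter(interp, numtaps=numtaps)
    out = downsample_100hz(filtered)
    return out, blinks, closures, cls, measures, stats
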