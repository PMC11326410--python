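"""Blink-locked epoch extraction and BIPR peak parameterization.

The blink-induced pupillary response (BIPR) is the average pupil-size
trajectory time-locked to blink onset: a dilation peak (D) around 500 ms
followed by a constriction trough (C) around 1 s. Epochs span -2 s to
+3 s around each blink on the 100 Hz preprocessed trace, are baselined to
the mean of the -200..0 ms window, and are rejected when more than 40% of
the 0-3 s interval is missing. The run's average waveform is parameterized
into six features: D-peak time and amplitude, C-peak time and amplitude,
D-C time difference, and D-C peak drop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trace import BlinkEvent, PupilTrace

__all__ = [
    "EPOCH_GRID_S",
    "BiprEpoch",
    "BiprWaveform",
    "BiprFeatures",
    "EpochRejected",
    "extract_epochs",
    "baseline_epoch",
    "reject_epoch",
    "average_epochs",
    "extract_features",
    "outlier_mask",
    "run_bipr",
]

#: common epoch grid: -2.00 s .. +3.00 s at 100 Hz, 501 samples
EPOCH_GRID_S = np.round(np.arange(-200, 301) * 0.01, 10)
_PRE = 200   # samples before blink onset
_POST = 300  # samples after
_BASELINE = slice(180, 200)       # rel_t in [-0.200, 0) s, 20 samples
_POSTWIN = slice(201, 501)        # rel_t in (0, 3] s, 300 samples


class EpochRejected(ValueError):
    """Raised when an epoch cannot be used (e.g. no baseline samples)."""


@dataclass
class BiprEpoch:
    """One blink-locked pupil segment on the common grid."""

    values: np.ndarray
    missing_mask: np.ndarray
    onset_ms: float = np.nan

    @property
    def rel_t_s(self) -> np.ndarray:
        return EPOCH_GRID_S


@dataclass
class BiprWaveform:
    """Per-run average of the kept epochs; NaN where all epochs miss."""

    mean_values: np.ndarray
    n_epochs_used: int
    n_epochs_rejected: int = 0

    @property
    def rel_t_s(self) -> np.ndarray:
        return EPOCH_GRID_S


@dataclass(frozen=True)
class BiprFeatures:
    """The six BIPR peak parameters of a run-average waveform.

    ``atypical`` flags a waveform whose D amplitude is not positive or
    whose C amplitude is not negative — morphology unlike the canonical
    dilation-then-constriction response.
    """

    d_time_s: float
    d_amp_au: float
    c_time_s: float
    c_amp_au: float
    dc_time_diff_s: float
    dc_peakdrop_au: float
    atypical: bool = False


def extract_epochs(trace: PupilTrace, blinks: list[BlinkEvent]) -> tuple[list[BiprEpoch], int]:
    """Cut one -2..+3 s epoch per blink from the 100 Hz trace.

    Epochs whose window crosses a run edge are dropped and counted
    (second return value). Overlapping epochs from rapid blink trains are
    kept.
    """
    if trace.sampling_rate != 100:
        raise ValueError("epoch extraction expects the 100 Hz preprocessed trace")
    step = trace.dt_ms
    t0 = trace.t_ms[0]
    mask = trace.missing_mask()
    epochs: list[BiprEpoch] = []
    dropped = 0
    for b in blinks:
        idx = int(round((b.onset_ms - t0) / step))
        lo, hi = idx - _PRE, idx + _POST + 1
        if lo < 0 or hi > trace.n:
            dropped += 1
            continue
        epochs.append(
            BiprEpoch(
                values=trace.pupil[lo:hi].copy(),
                missing_mask=mask[lo:hi].copy(),
                onset_ms=b.onset_ms,
            )
        )
    return epochs, dropped


def baseline_epoch(epoch: BiprEpoch) -> BiprEpoch:
    """Subtract the mean of the non-missing samples in [-200, 0) ms.

    Raises :class:`EpochRejected` ("no baseline") when the whole baseline
    window is missing. Baselining is idempotent: the window mean of the
    result is zero.
    """
    vals = epoch.values[_BASELINE]
    ok = ~epoch.missing_mask[_BASELINE]
    if not ok.any():
        raise EpochRejected("no baseline")
    base = float(vals[ok].mean())
    return BiprEpoch(
        values=epoch.values - base,
        missing_mask=epoch.missing_mask.copy(),
        onset_ms=epoch.onset_ms,
    )


def reject_epoch(epoch: BiprEpoch, max_missing_fraction: float = 0.40) -> tuple[bool, str | None]:
    """Keep/drop decision: drop iff the missing fraction over (0, 3] s
    strictly exceeds ``max_missing_fraction``. Returns (keep, reason)."""
    frac = float(epoch.missing_mask[_POSTWIN].mean())
    if frac > max_missing_fraction:
        return False, f"missing fraction {frac:.3f} > {max_missing_fraction}"
    return True, None


def average_epochs(epochs: list[BiprEpoch], n_rejected: int = 0) -> BiprWaveform:
    """Pointwise mean over non-missing values across the kept epochs."""
    if not epochs:
        raise ValueError("cannot average zero epochs")
    vals = np.stack([e.values for e in epochs])
    ok = ~np.stack([e.missing_mask for e in epochs])
    counts = ok.sum(axis=0)
    sums = np.where(ok, vals, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BiprWaveform(mean_values=mean, n_epochs_used=len(epochs), n_epochs_rejected=n_rejected)


def extract_features(
    waveform: BiprWaveform,
    d_window_s: tuple[float, float] = (0.0, 0.9),
    c_search_end_s: float = 2.5,
) -> BiprFeatures:
    """Locate the D and C peaks of a run-average waveform.

    D is the maximum over ``(d_window_s[0], d_window_s[1]]``; C is the
    minimum over ``(d_time, c_search_end_s]``. Ties and edges resolve to
    the earliest time. Raises ``ValueError`` if a search window is
    entirely missing.
    """
    t = EPOCH_GRID_S
    y = waveform.mean_values
    d_lo, d_hi = d_window_s
    din = (t > d_lo) & (t <= d_hi)
    yd = np.where(din, y, np.nan)
    if np.all(np.isnan(yd)):
        raise ValueError("D search window entirely missing")
    di = int(np.nanargmax(yd))
    d_time, d_amp = float(t[di]), float(y[di])
    cin = (t > d_time) & (t <= c_search_end_s)
    yc = np.where(cin, y, np.nan)
    if np.all(np.isnan(yc)):
        raise ValueError("C search window entirely missing")
    ci = int(np.nanargmin(yc))
    c_time, c_amp = float(t[ci]), float(y[ci])
    return BiprFeatures(
        d_time_s=d_time,
        d_amp_au=d_amp,
        c_time_s=c_time,
        c_amp_au=c_amp,
        dc_time_diff_s=c_time - d_time,
        dc_peakdrop_au=d_amp - c_amp,
        atypical=(d_amp <= 0) or (c_amp >= 0),
    )


def outlier_mask(values: np.ndarray, multiplier: float = 2.0) -> np.ndarray:
    """Keep-mask under the 2-IQR fence rule.

    A value is kept iff ``Q1 - multiplier*IQR <= x <= Q3 + multiplier*IQR``
    with quartiles by linear interpolation. Non-finite values are never
    kept. With fewer than 4 finite values no exclusion is applied (all
    finite values kept, with a warning).
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 4:
        warnings.warn("fewer than 4 finite values: outlier exclusion skipped")
        return finite
    q1, q3 = np.percentile(values[finite], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    return finite & (values >= lo) & (values <= hi)


def run_bipr(
    trace_100hz: PupilTrace, blinks: list[BlinkEvent]
) -> tuple[BiprWaveform | None, BiprFeatures | None]:
    """Full per-run BIPR: epochs -> baseline -> rejection -> average -> peaks.

    Returns ``(None, None)`` when no epoch survives; returns the waveform
    with ``None`` features when peak search fails (all-missing windows).
    """
    epochs, _ = extract_epochs(trace_100hz, blinks)
    kept: list[BiprEpoch] = []
    rejected = 0
    for ep in epochs:
        try:
            ep = baseline_epoch(ep)
        except EpochRejected:
            rejected += 1
            continue
        keep, _ = reject_epoch(ep)
        if keep:
            kept.append(ep)
        else:
            rejected += 1
    if not kept:
        return None, None
    wave = average_epochs(kept, n_rejected=rejected)
    try:
        feats = extract_features(wave)
    except ValueError:
        feats = None
    return wave, feats
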