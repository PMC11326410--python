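"""Core containers for pupil time series and detected eye events.

The recording convention throughout the package follows EyeLink output:
pupil size is in arbitrary units (a.u.), and a sample value of exactly
``0.0`` means the pupil was not detected at that time point (blink, eyelid
closure, or tracking loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PupilTrace", "BlinkEvent", "ClosureEvent"]

#: Inclusive blink-duration window in ms: a maximal zero-span of this length
#: is counted as an eye blink. Shorter spans are tracking glitches, longer
#: spans are eyelid closures.
BLINK_MIN_MS = 40.0
BLINK_MAX_MS = 400.0


@dataclass
class PupilTrace:
    """A uniformly sampled pupil-size time series.

    Parameters
    ----------
    t_ms
        Monotone sample times in milliseconds; spacing must equal
        ``1000 / sampling_rate``.
    pupil
        Pupil size in arbitrary units, ``>= 0``; exactly ``0.0`` encodes a
        missing (undetected) pupil in raw traces.
    sampling_rate
        Samples per second.
    missing
        Explicit missingness mask. On raw traces this is simply
        ``pupil == 0``; after interpolation the mask carries forward the
        spans that could not be reconstructed (eyelid closures, edge
        blinks) even though the stored values may be non-zero.
    """

    t_ms: np.ndarray
    pupil: np.ndarray
    sampling_rate: float
    missing: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        if self.t_ms.shape != self.pupil.shape:
            raise ValueError("t_ms and pupil must have equal length")
        if self.t_ms.size < 2:
            raise ValueError("trace needs at least 2 samples")
        step = 1000.0 / self.sampling_rate
        dt = np.diff(self.t_ms)
        if not np.allclose(dt, step, atol=step * 0.51):
            bad = int(np.argmax(np.abs(dt - step) > step * 0.51))
            raise ValueError(
                f"non-uniform timestamps at sample {bad}: step {dt[bad]} ms, "
                f"expected {step} ms at {self.sampling_rate} Hz"
            )
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.pupil.shape:
                raise ValueError("missing mask length mismatch")

    @property
    def n(self) -> int:
        return self.pupil.size

    @property
    def duration_s(self) -> float:
        return self.n / self.sampling_rate

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    def missing_mask(self) -> np.ndarray:
        """The effective missing mask (``pupil == 0`` if none was set)."""
        if self.missing is not None:
            return self.missing
        return self.pupil == 0.0

    def copy(self, **changes) -> "PupilTrace":
        out = replace(self, **changes)
        if "pupil" not in changes:
            out.pupil = self.pupil.copy()
        if "t_ms" not in changes:
            out.t_ms = self.t_ms.copy()
        if "missing" not in changes and self.missing is not None:
            out.missing = self.missing.copy()
        return out


@dataclass(frozen=True)
class BlinkEvent:
    """A pupil-loss interval of 40–400 ms (inclusive), counted as a blink.

    ``onset_ms`` is the time of the first zero-valued sample; ``offset_ms``
    is the time at which the pupil signal resumes, so
    ``duration_ms = offset_ms - onset_ms`` equals the number of zero
    samples times the sample step.
    """

    onset_ms: float
    offset_ms: float

    def __post_init__(self) -> None:
        d = self.duration_ms
        if not (BLINK_MIN_MS <= d <= BLINK_MAX_MS):
            raise ValueError(f"blink duration {d} ms outside [40, 400]")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass(frozen=True)
class ClosureEvent:
    """A pupil-loss interval longer than 400 ms: an eyelid closure.

    Closures are excluded from the eyes-open time used as the blink-rate
    denominator and are never spline-interpolated.
    """

    onset_ms: float
    offset_ms: float

    def __post_init__(self) -> None:
        if self.duration_ms <= BLINK_MAX_MS:
            raise ValueError(f"closure duration {self.duration_ms} ms must exceed 400")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms
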