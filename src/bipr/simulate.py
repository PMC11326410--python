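"""Synthetic pupil recordings, twin phenotypes and multi-run measure tables.

Every downstream stage of the pipeline is testable against these generators
because they carry explicit ground truth: blink/closure event times for the
pupil traces, population variance fractions for the twin phenotypes, and
variance components for the subject x run tables.

The pupil generator emulates the phenomenology of EyeLink resting-state
recordings: a tonic pupil level in arbitrary units, band-limited noise, an
optional slow sinusoidal drift, Poisson-placed blinks (40-400 ms of signal
loss) and longer eyelid closures, and an additive blink-induced pupillary
response (BIPR) kernel locked to each blink onset — a positive dilation
lobe near 500 ms followed by a negative constriction lobe near 1 s, each
modelled as a Gaussian bump. Signal loss is imposed *after* kernel
injection, so the first ~100 ms of the response is occluded by the blink
itself, as in real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .trace import PupilTrace

__all__ = [
    "SimRunConfig",
    "GroundTruth",
    "TwinSimSpec",
    "MultiRunSimSpec",
    "generate_pupil_run",
    "generate_twin_dataset",
    "generate_multirun_measures",
    "kernel_waveform",
    "kernel_peaks",
    "write_asc",
    "write_ground_truth",
]


@dataclass
class SimRunConfig:
    """Parameters of one simulated resting-state pupil run.

    Defaults describe a vigilant 300 s run at 1 kHz: a spontaneous blink
    rate of 15/min, blink durations of 100-300 ms, occasional eyelid
    closures, and a BIPR kernel with a dilation peak of +30 a.u. at 500 ms
    and a constriction trough of -20 a.u. at 1 s after blink onset.
    Amplitudes are in EyeLink arbitrary units and are free parameters.
    """

    sampling_rate: float = 1000.0
    duration_s: float = 300.0
    baseline_pupil: float = 800.0
    blink_rate_per_min: float = 15.0
    blink_dur_ms_range: tuple[float, float] = (100.0, 300.0)
    closure_rate_per_min: float = 0.5
    closure_dur_ms_range: tuple[float, float] = (500.0, 2000.0)
    d_latency_s: float = 0.5
    d_amp: float = 30.0
    d_width_s: float = 0.15
    c_latency_s: float = 1.0
    c_amp: float = -20.0
    c_width_s: float = 0.25
    noise_sd: float = 5.0
    slow_drift_amp: float = 0.0
    slow_drift_hz: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate not in (500.0, 1000.0, 500, 1000):
            raise ValueError("sampling_rate must be 500 or 1000 Hz")
        if self.baseline_pupil <= 0:
            raise ValueError("baseline_pupil must be positive")
        lo, hi = self.blink_dur_ms_range
        if not (40.0 <= lo <= hi <= 400.0):
            raise ValueError("blink durations must lie in [40, 400] ms")
        clo, chi = self.closure_dur_ms_range
        if not (400.0 < clo <= chi):
            raise ValueError("closure durations must exceed 400 ms")
        if self.blink_rate_per_min < 0 or self.closure_rate_per_min < 0:
            raise ValueError("event rates must be nonnegative")
        if self.d_amp < 0:
            raise ValueError("dilation amplitude d_amp must be >= 0")
        if self.c_amp > 0:
            raise ValueError("constriction amplitude c_amp must be <= 0")
        if self.c_latency_s <= self.d_latency_s:
            raise ValueError("c_latency_s must exceed d_latency_s")
        if self.slow_drift_hz >= 0.02:
            raise ValueError("slow drift must stay below the 0.02 Hz high-pass edge")


@dataclass
class GroundTruth:
    """Realized event times (sample-quantized) and the kernel parameters."""

    blink_onsets_ms: list[float] = field(default_factory=list)
    blink_durations_ms: list[float] = field(default_factory=list)
    closure_onsets_ms: list[float] = field(default_factory=list)
    closure_durations_ms: list[float] = field(default_factory=list)
    d_latency_s: float = 0.5
    d_amp: float = 0.0
    d_width_s: float = 0.15
    c_latency_s: float = 1.0
    c_amp: float = 0.0
    c_width_s: float = 0.25


def _place_events(
    rng: np.random.Generator,
    durations_ms: np.ndarray,
    duration_s: float,
    min_gap_ms: float = 1000.0,
) -> list[tuple[float, float]]:
    """Place events of given durations uniformly with a minimum gap.

    Samples the exact distribution of a homogeneous Poisson process
    conditioned on the event count and on pairwise separation of at
    least ``min_gap_ms``: event order is shuffled, the total slack
    (run length minus durations and guards) is split by uniform order
    statistics, and onsets are the cumulative sums. The guard keeps
    post-blink epochs analyzable. Raises when the event demand exceeds
    the run length.
    """
    n = durations_ms.size
    if n == 0:
        return []
    total_ms = duration_s * 1000.0
    order = rng.permutation(n)
    durs = np.asarray(durations_ms, dtype=float)[order]
    slack = total_ms - durs.sum() - min_gap_ms * (n - 1)
    if slack <= 0:
        raise RuntimeError(
            f"{n} events demand {durs.sum() / 1000:.1f} s plus "
            f"{min_gap_ms * (n - 1) / 1000:.1f} s of guards in a "
            f"{duration_s:.0f} s run; event density too high for "
            "non-overlapping placement"
        )
    u = np.sort(rng.uniform(0.0, slack, size=n))
    offsets = np.concatenate(([0.0], np.cumsum(durs[:-1] + min_gap_ms)))
    onsets = u + offsets
    out: list[tuple[float, float]] = [(0.0, 0.0)] * n
    for k, idx in enumerate(order):  # undo the shuffle: results follow input order
        out[idx] = (float(onsets[k]), float(onsets[k] + durs[k]))
    return out


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """White Gaussian noise low-passed at 4 Hz, rescaled to sample SD ``sd``.

    The 4 Hz limit keeps the noise inside the pipeline's 0.02-4 Hz
    pass-band so it survives filtering (unlike broadband sensor noise).
    """
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    b, a = _signal.butter(4, 4.0, btype="low", fs=fs)
    shaped = _signal.filtfilt(b, a, white)
    s = shaped.std()
    if s == 0:
        return np.zeros(n)
    return shaped * (sd / s)


def generate_pupil_run(cfg: SimRunConfig) -> tuple[PupilTrace, GroundTruth]:
    """Simulate one pupil run and return the trace with its ground truth.

    The trace has ``duration_s * sampling_rate`` samples. Blink and closure
    spans are exactly 0.0; each blink onset adds the two-lobe BIPR kernel
    starting at that onset (before the zero-span is imposed). Identical
    configs reproduce identical traces bit-for-bit.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = float(cfg.sampling_rate)
    step_ms = 1000.0 / fs
    n = int(round(cfg.duration_s * fs))
    t_ms = np.arange(n) * step_ms

    n_blinks = rng.poisson(cfg.blink_rate_per_min * cfg.duration_s / 60.0)
    n_closures = rng.poisson(cfg.closure_rate_per_min * cfg.duration_s / 60.0)
    blink_durs = rng.uniform(*cfg.blink_dur_ms_range, size=n_blinks)
    closure_durs = rng.uniform(*cfg.closure_dur_ms_range, size=n_closures)
    # quantize durations to whole samples so detected events can match exactly
    blink_durs = np.round(blink_durs / step_ms) * step_ms
    closure_durs = np.round(closure_durs / step_ms) * step_ms

    both = _place_events(
        rng, np.concatenate([blink_durs, closure_durs]), cfg.duration_s
    )
    blinks = both[:n_blinks]
    closures = both[n_blinks:]
    # quantize onsets to the sample grid
    blinks = [(round(s / step_ms) * step_ms, round(s / step_ms) * step_ms + (e - s)) for s, e in blinks]
    closures = [(round(s / step_ms) * step_ms, round(s / step_ms) * step_ms + (e - s)) for s, e in closures]
    blinks.sort()
    closures.sort()

    pupil = np.full(n, cfg.baseline_pupil)
    if cfg.slow_drift_amp:
        phase = rng.uniform(0, 2 * np.pi)
        pupil = pupil + cfg.slow_drift_amp * np.sin(
            2 * np.pi * cfg.slow_drift_hz * t_ms / 1000.0 + phase
        )
    pupil = pupil + _band_limited_noise(rng, n, fs, cfg.noise_sd)

    # additive BIPR kernel at every blink onset, support to 5 SD past C lobe
    support_s = cfg.c_latency_s + 5.0 * cfg.c_width_s
    k = int(round(support_s * fs))
    tk = np.arange(k) / fs
    kernel = cfg.d_amp * np.exp(-0.5 * ((tk - cfg.d_latency_s) / cfg.d_width_s) ** 2) + (
        cfg.c_amp * np.exp(-0.5 * ((tk - cfg.c_latency_s) / cfg.c_width_s) ** 2)
    )
    for onset_ms, _ in blinks:
        i0 = int(round(onset_ms / step_ms))
        i1 = min(i0 + k, n)
        pupil[i0:i1] += kernel[: i1 - i0]

    # impose signal loss last so blinks occlude the kernel's first stretch
    for onset_ms, end_ms in blinks + closures:
        i0 = int(round(onset_ms / step_ms))
        i1 = int(round(end_ms / step_ms))
        pupil[i0:i1] = 0.0

    gt = GroundTruth(
        blink_onsets_ms=[s for s, _ in blinks],
        blink_durations_ms=[e - s for s, e in blinks],
        closure_onsets_ms=[s for s, _ in closures],
        closure_durations_ms=[e - s for s, e in closures],
        d_latency_s=cfg.d_latency_s,
        d_amp=cfg.d_amp,
        d_width_s=cfg.d_width_s,
        c_latency_s=cfg.c_latency_s,
        c_amp=cfg.c_amp,
        c_width_s=cfg.c_width_s,
    )
    return PupilTrace(t_ms=t_ms, pupil=pupil, sampling_rate=fs), gt


def kernel_waveform(gt: GroundTruth | SimRunConfig, fs: float = 100.0, t_end_s: float = 3.0):
    """The injected BIPR kernel sampled on a post-blink grid.

    Returns ``(t_s, values)``. Note the two lobes overlap: the summed
    kernel's maximum sits slightly *before* the D-lobe center (the C
    lobe's rising flank pulls it earlier) and its minimum slightly after
    the C-lobe center, so peak-recovery checks must compare against this
    waveform's extrema, not the lobe centers.
    """
    t = np.arange(0.0, t_end_s + 0.5 / fs, 1.0 / fs)
    y = gt.d_amp * np.exp(-0.5 * ((t - gt.d_latency_s) / gt.d_width_s) ** 2) + gt.c_amp * np.exp(
        -0.5 * ((t - gt.c_latency_s) / gt.c_width_s) ** 2
    )
    return t, y


def kernel_peaks(cfg: SimRunConfig | GroundTruth, fs: float = 100.0) -> tuple[float, float, float, float]:
    """Ground-truth (d_time, d_amp, c_time, c_amp) of the summed kernel.

    Uses the same search rule as feature extraction: D is the maximum
    over (0, 0.9] s, C the minimum after D up to 2.5 s.
    """
    t, y = kernel_waveform(cfg, fs=fs)
    din = (t > 0) & (t <= 0.9)
    di = int(np.argmax(np.where(din, y, -np.inf)))
    cin = (t > t[di]) & (t <= 2.5)
    ci = int(np.argmin(np.where(cin, y, np.inf)))
    return float(t[di]), float(y[di]), float(t[ci]), float(y[ci])


# ---------------------------------------------------------------------------
# twin phenotypes


@dataclass
class TwinSimSpec:
    """Generative spec for twin-pair phenotypes under a variance-component model.

    ``fractions`` are the standardized components ``(a2, c2_or_d2, e2)``;
    the middle entry is the shared-environment fraction c2 for the ACE
    branch (families ACE/AE/CE/E) and the dominance fraction d2 for ADE.
    Components absent from the family must be zero.
    """

    family: str
    fractions: tuple[float, float, float]
    n_mz: int
    n_dz: int
    mean: float = 0.0
    total_variance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        fam = self.family.upper()
        if fam not in {"ACE", "ADE", "AE", "CE", "E"}:
            raise ValueError(f"unknown family {self.family!r}")
        self.family = fam
        a2, m2, e2 = self.fractions
        if min(a2, m2, e2) < 0 or abs(a2 + m2 + e2 - 1.0) > 1e-12:
            raise ValueError("fractions must be nonnegative and sum to 1")
        if fam in {"AE", "E"} and m2 != 0:
            raise ValueError(f"{fam} model admits no c2/d2 component")
        if fam in {"CE", "E"} and a2 != 0:
            raise ValueError(f"{fam} model admits no a2 component")
        if self.n_mz < 0 or self.n_dz < 0:
            raise ValueError("pair counts must be nonnegative")
        if self.total_variance <= 0:
            raise ValueError("total_variance must be positive")


def _pair_draws(rng, n, r):
    """n pairs of standard normals with correlation r."""
    shared = rng.standard_normal(n)
    z1 = np.sqrt(r) * shared + np.sqrt(1 - r) * rng.standard_normal(n)
    z2 = np.sqrt(r) * shared + np.sqrt(1 - r) * rng.standard_normal(n)
    return z1, z2


def generate_twin_dataset(spec: TwinSimSpec) -> pd.DataFrame:
    """Simulate twin pairs and return a table (pair_id, zygosity, y1, y2).

    Additive-genetic deviates are identical within MZ pairs and correlate
    0.5 within DZ pairs; dominance deviates correlate 1.0 (MZ) and 0.25
    (DZ); shared environment is common to both twins of every pair; unique
    environment is independent. The population intra-pair covariance is
    therefore ``a2 + c2 (+ d2)`` for MZ and ``a2/2 + c2 (+ d2/4)`` for DZ,
    scaled by ``total_variance``.
    """
    rng = np.random.default_rng(spec.seed)
    a2, m2, e2 = spec.fractions
    is_ade = spec.family == "ADE"
    c2, d2 = (0.0, m2) if is_ade else (m2, 0.0)
    sd = np.sqrt(spec.total_variance)

    rows = []
    for zyg, npairs, r_a, r_d in (("MZ", spec.n_mz, 1.0, 1.0), ("DZ", spec.n_dz, 0.5, 0.25)):
        A1, A2 = _pair_draws(rng, npairs, r_a)
        D1, D2 = _pair_draws(rng, npairs, r_d)
        C = rng.standard_normal(npairs)
        E1 = rng.standard_normal(npairs)
        E2 = rng.standard_normal(npairs)
        y1 = spec.mean + sd * (np.sqrt(a2) * A1 + np.sqrt(c2) * C + np.sqrt(d2) * D1 + np.sqrt(e2) * E1)
        y2 = spec.mean + sd * (np.sqrt(a2) * A2 + np.sqrt(c2) * C + np.sqrt(d2) * D2 + np.sqrt(e2) * E2)
        for i in range(npairs):
            rows.append((f"{zyg}{i:05d}", zyg, y1[i], y2[i]))
    return pd.DataFrame(rows, columns=["pair_id", "zygosity", "y1", "y2"])


# ---------------------------------------------------------------------------
# multi-run subject x run tables


@dataclass
class MultiRunSimSpec:
    """Two-way random-effects generative spec: y_sr = mean + u_s + v_r + e_sr.

    ``var_subject``, ``var_run`` and ``var_error`` are the variances of the
    subject effect, the run (session) effect and the residual. The implied
    population ICC(2,k) is
    ``var_subject / (var_subject + (var_run + var_error) / k)``.
    """

    n_subjects: int
    k_runs: int
    var_subject: float
    var_run: float
    var_error: float
    mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.var_subject, self.var_run, self.var_error) < 0:
            raise ValueError("variance components must be nonnegative")
        if self.n_subjects < 1 or self.k_runs < 1:
            raise ValueError("need at least one subject and one run")

    @property
    def population_icc2k(self) -> float:
        denom = self.var_subject + (self.var_run + self.var_error) / self.k_runs
        if denom == 0:
            return float("nan")
        return self.var_subject / denom


def generate_multirun_measures(spec: MultiRunSimSpec) -> pd.DataFrame:
    """Simulate a long table (subject, run, value) under the two-way model."""
    rng = np.random.default_rng(spec.seed)
    u = rng.normal(0, np.sqrt(spec.var_subject), spec.n_subjects)
    v = rng.normal(0, np.sqrt(spec.var_run), spec.k_runs)
    e = rng.normal(0, np.sqrt(spec.var_error), (spec.n_subjects, spec.k_runs))
    y = spec.mean + u[:, None] + v[None, :] + e
    subj = np.repeat(np.arange(spec.n_subjects), spec.k_runs)
    run = np.tile(np.arange(spec.k_runs), spec.n_subjects)
    return pd.DataFrame({"subject": subj, "run": run, "value": y.ravel()})


# ---------------------------------------------------------------------------
# writers


def write_asc(trace: PupilTrace, path, ground_truth: GroundTruth | None = None) -> None:
    """Write a trace in the ASC-like sample format the reader accepts.

    Lines are ``<t>\\t<x>\\t<y>\\t<pupil>`` with constant gaze placeholders.
    If ground truth is given, recorder-style SBLINK/EBLINK annotations are
    interleaved — downstream analysis must re-detect blinks from the zero
    spans and ignore these labels.
    """
    events = []
    if ground_truth is not None:
        for onset, dur in zip(ground_truth.blink_onsets_ms, ground_truth.blink_durations_ms):
            events.append((onset, f"SBLINK R {onset:.0f}"))
            events.append((onset + dur, f"EBLINK R {onset:.0f} {onset + dur:.0f} {dur:.0f}"))
    events.sort()
    ei = 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"MSG\t0 RECCFG CR {trace.sampling_rate:.0f} 2 1 R\n")
        for t, p in zip(trace.t_ms, trace.pupil):
            while ei < len(events) and events[ei][0] <= t:
                fh.write(events[ei][1] + "\n")
                ei += 1
            if p == 0.0:
                fh.write(f"{t:.1f}\t.\t.\t0.0\n")
            else:
                fh.write(f"{t:.1f}\t640.0\t512.0\t{p:.4f}\n")


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Write the event ground truth as a delimited sidecar table."""
    rows = [
        ("blink", o, d) for o, d in zip(gt.blink_onsets_ms, gt.blink_durations_ms)
    ] + [
        ("closure", o, d) for o, d in zip(gt.closure_onsets_ms, gt.closure_durations_ms)
    ]
    pd.DataFrame(rows, columns=["kind", "onset_ms", "duration_ms"]).to_csv(path, index=False)
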