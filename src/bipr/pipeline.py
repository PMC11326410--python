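"""End-to-end orchestration: simulate -> preprocess -> BIPR -> reports.

The pipeline is pure dataflow between serialized delimited artifacts:
each stage reads its inputs, writes its outputs under the configured
directory, and never mutates another stage's files. A manifest records
the configuration hash and the run ids that produced every report row,
and a fixed master seed makes the whole artifact set byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import epochs as ep
from . import preprocess as pp
from .io import read_samples
from .measures import MEASURES, merge_drowsy
from .reliability import icc_report, within_subject_reliability
from .simulate import (
    SimRunConfig,
    TwinSimSpec,
    generate_pupil_run,
    generate_twin_dataset,
    write_asc,
    write_ground_truth,
)
from .state import BONFERRONI_ALPHA, paired_state_table, state_anova
from .twin import intrapair_correlations, profile_ci, select_model

__all__ = ["PipelineConfig", "run_pipeline", "apply_outlier_exclusion", "preprocess_file", "cohort_measure_table"]


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults are the analysis' stated values."""

    out_dir: str = "pipeline_out"
    seed: int = 0

    # cohort simulation
    n_subjects: int = 20
    runs_per_subject: int = 3
    run_duration_s: float = 300.0
    sampling_rate: float = 1000.0
    drowsy_run_fraction: float = 0.3
    noise_sd: float = 5.0

    # preprocessing thresholds
    blink_min_ms: float = 40.0
    blink_max_ms: float = 400.0
    state_edges: tuple[float, float, float] = (0.10, 0.40, 0.75)
    filter_low_hz: float = 0.02
    filter_high_hz: float = 4.0
    filter_numtaps: int = 30001

    # epoching
    epoch_pre_s: float = 2.0
    epoch_post_s: float = 3.0
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    max_missing_fraction: float = 0.40
    d_window_s: tuple[float, float] = (0.0, 0.9)
    c_search_end_s: float = 2.5

    # outlier exclusion
    outlier_multiplier: float = 2.0
    outlier_scope: str = "per_state"  # or "pooled" / "none"

    # analysis toggles
    run_reliability: bool = True
    run_anova: bool = True
    run_heritability: bool = True

    # twin simulation for the heritability stage: measure -> (family, fractions)
    twin_n_mz: int = 44
    twin_n_dz: int = 36
    twin_specs: dict = field(
        default_factory=lambda: {
            "blink_rate": ("AE", (0.49, 0.0, 0.51)),
            "pupil_size": ("AE", (0.62, 0.0, 0.38)),
        }
    )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        for key in ("state_edges", "baseline_ms", "d_window_s"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "twin_specs" in raw:
            raw["twin_specs"] = {
                k: (v[0], tuple(v[1])) for k, v in raw["twin_specs"].items()
            }
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def apply_outlier_exclusion(
    table: pd.DataFrame,
    measures: list[str] | None = None,
    multiplier: float = 2.0,
    scope: str = "per_state",
) -> pd.DataFrame:
    """Mask outliers (2-IQR fence) to NaN, per measure within each state.

    ``scope`` is ``per_state`` (fences computed within each vigilance
    state, the default), ``pooled`` (across states), or ``none``.
    """
    if scope == "none":
        return table.copy()
    measures = measures or MEASURES
    out = table.copy()
    groups = [out] if scope == "pooled" else [g for _, g in out.groupby("state")]
    for grp in groups:
        for m in measures:
            if m not in grp.columns:
                continue
            keep = ep.outlier_mask(grp[m].to_numpy(dtype=float), multiplier=multiplier)
            bad = grp.index[~keep & np.isfinite(grp[m].to_numpy(dtype=float))]
            out.loc[bad, m] = np.nan
    return out


def preprocess_file(path, dialect: str = "asc_like", numtaps: int = 30001):
    """Read one raw run file and push it through the full preprocessing chain."""
    raw = read_samples(path, dialect=dialect)
    return pp.preprocess_trace(raw, numtaps=numtaps)


def _subject_params(rng: np.random.Generator) -> dict:
    """Stable per-subject physiology: tonic level, blink habits, BIPR shape."""
    mean_dur = float(np.clip(rng.normal(200.0, 30.0), 90.0, 330.0))
    return {
        "baseline_pupil": float(np.clip(rng.normal(800.0, 80.0), 300.0, None)),
        # upper clip keeps total event demand placeable with the 1 s
        # inter-event guard on a 300 s run
        "blink_rate_per_min": float(np.clip(rng.normal(15.0, 4.0), 3.0, 22.0)),
        "blink_dur_ms_range": (mean_dur - 50.0, mean_dur + 50.0),
        "d_latency_s": float(np.clip(rng.normal(0.5, 0.05), 0.3, 0.7)),
        "d_amp": float(np.clip(rng.normal(30.0, 5.0), 5.0, None)),
        "c_latency_s": float(np.clip(rng.normal(1.0, 0.08), 0.75, 1.4)),
        "c_amp": float(-np.clip(rng.normal(20.0, 4.0), 3.0, None)),
    }


def simulate_cohort(cfg: PipelineConfig, raw_dir: Path) -> pd.DataFrame:
    """Write ASC files + ground-truth sidecars for a simulated cohort.

    Each subject has stable blink/BIPR parameters across runs; a
    configured fraction of runs gets a high eyelid-closure rate, which
    pushes them into the drowsy classification bins.
    """
    raw_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(cfg.seed)
    index_rows = []
    for s in range(cfg.n_subjects):
        sp = _subject_params(master)
        for r in range(cfg.runs_per_subject):
            drowsy = master.uniform() < cfg.drowsy_run_fraction
            run_cfg = SimRunConfig(
                sampling_rate=cfg.sampling_rate,
                duration_s=cfg.run_duration_s,
                noise_sd=cfg.noise_sd,
                closure_rate_per_min=5.0 if drowsy else 0.3,
                closure_dur_ms_range=(1000.0, 3000.0) if drowsy else (500.0, 2000.0),
                seed=int(master.integers(2**31)),
                **sp,
            )
            trace, gt = generate_pupil_run(run_cfg)
            stem = f"sub{s:03d}_run{r}"
            write_asc(trace, raw_dir / f"{stem}.asc", gt)
            write_ground_truth(gt, raw_dir / f"{stem}_truth.csv")
            index_rows.append(
                (f"sub{s:03d}", f"run{r}", f"{stem}.asc",
                 sp["d_latency_s"], sp["d_amp"], sp["c_latency_s"], sp["c_amp"])
            )
    index = pd.DataFrame(
        index_rows,
        columns=["subject", "run", "file", "d_latency_s", "d_amp", "c_latency_s", "c_amp"],
    )
    index.to_csv(raw_dir / "index.csv", index=False)
    return index


def cohort_measure_table(cfg: PipelineConfig, raw_dir: Path, waveform_path: Path | None = None) -> pd.DataFrame:
    """Preprocess every indexed run and assemble the long measure table."""
    index = pd.read_csv(raw_dir / "index.csv")
    rows = []
    waves = []
    for rec in index.itertuples():
        out, blinks, closures, cls, meas, _ = preprocess_file(
            raw_dir / rec.file, numtaps=cfg.filter_numtaps
        )
        row = {
            "subject": rec.subject,
            "run": rec.run,
            "state": merge_drowsy(cls.state),
            "loss_fraction": cls.loss_fraction,
            "blink_rate": meas.blink_rate_per_min,
            "blink_duration": meas.mean_blink_duration_ms,
            "pupil_size": meas.mean_pupil_size_au,
        }
        wave, feats = ep.run_bipr(out, blinks)
        if feats is not None:
            row.update(
                d_time=feats.d_time_s,
                d_amp=feats.d_amp_au,
                c_time=feats.c_time_s,
                c_amp=feats.c_amp_au,
                dc_time_diff=feats.dc_time_diff_s,
                dc_peakdrop=feats.dc_peakdrop_au,
            )
        else:
            row.update({m: np.nan for m in MEASURES[3:]})
        if wave is not None:
            wdf = pd.DataFrame(
                {
                    "subject": rec.subject,
                    "run": rec.run,
                    "rel_t_s": wave.rel_t_s,
                    "mean": wave.mean_values,
                    "n_used": wave.n_epochs_used,
                }
            )
            waves.append(wdf)
        rows.append(row)
    table = pd.DataFrame(rows)
    if waveform_path is not None and waves:
        pd.concat(waves, ignore_index=True).to_csv(waveform_path, index=False)
    return table


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run every enabled stage; returns a name -> path map of artifacts."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []
    artifacts: dict[str, Path] = {}

    raw_dir = out / "raw"
    index = simulate_cohort(cfg, raw_dir)
    log_lines.append(f"simulated {len(index)} runs for {cfg.n_subjects} subjects")

    waveform_path = out / "waveforms.csv"
    table = cohort_measure_table(cfg, raw_dir, waveform_path)
    table = table[table["state"] != "discarded"].reset_index(drop=True)
    table = apply_outlier_exclusion(
        table, multiplier=cfg.outlier_multiplier, scope=cfg.outlier_scope
    )
    measures_path = out / "measures.csv"
    table.to_csv(measures_path, index=False)
    artifacts["measures"] = measures_path
    artifacts["waveforms"] = waveform_path
    log_lines.append(f"measure table: {len(table)} runs after discarding")

    if cfg.run_reliability:
        rel = icc_report(table)
        within = []
        for state in table["state"].unique():
            w = within_subject_reliability(table, state)
            within.append((state, w.mean, w.median, w.sd, w.n_subjects, w.n_skipped))
        rel_path = out / "reliability.csv"
        rel.to_csv(rel_path, index=False)
        pd.DataFrame(
            within, columns=["state", "mean_r", "median_r", "sd_r", "n_subjects", "n_skipped"]
        ).to_csv(out / "within_subject.csv", index=False)
        artifacts["reliability"] = rel_path
        artifacts["within_subject"] = out / "within_subject.csv"
        log_lines.append(f"reliability: {len(rel)} measure x state cells")

    if cfg.run_anova:
        paired = paired_state_table(table)
        res = state_anova(paired, alpha=BONFERRONI_ALPHA)
        anova_path = out / "anova.csv"
        pd.DataFrame([dataclasses.asdict(r) for r in res]).to_csv(anova_path, index=False)
        artifacts["anova"] = anova_path
        log_lines.append(f"anova: {len(res)} measures compared")

    if cfg.run_heritability:
        her_rows = []
        rng = np.random.default_rng(cfg.seed + 1)
        for measure, (family, fractions) in cfg.twin_specs.items():
            spec = TwinSimSpec(
                family=family,
                fractions=tuple(fractions),
                n_mz=cfg.twin_n_mz,
                n_dz=cfg.twin_n_dz,
                seed=int(rng.integers(2**31)),
            )
            twins = generate_twin_dataset(spec)
            corrs = intrapair_correlations(twins)
            best, _ = select_model(twins)
            cis = {}
            for comp in ("a2", "c2", "d2", "e2"):
                if best.components[comp] > 0 or comp == "e2":
                    try:
                        lo, hi, _ = profile_ci(twins, best, comp)
                    except ValueError:
                        continue
                    cis[comp] = (lo, hi)
            her_rows.append(
                {
                    "measure": measure,
                    "r_mz": corrs.r_mz,
                    "r_dz": corrs.r_dz,
                    "best_model": best.model,
                    "a2": best.a2,
                    "c2": best.c2,
                    "d2": best.d2,
                    "e2": best.e2,
                    **{
                        f"{c}_ci": f"{lo:.3f}-{hi:.3f}" for c, (lo, hi) in cis.items()
                    },
                }
            )
        her_path = out / "heritability.csv"
        pd.DataFrame(her_rows).to_csv(her_path, index=False)
        artifacts["heritability"] = her_path
        log_lines.append(f"heritability: {len(her_rows)} phenotypes modelled")

    manifest = {
        "config_hash": cfg.config_hash(),
        "config": dataclasses.asdict(cfg),
        "runs": index.to_dict(orient="records"),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    artifacts["manifest"] = out / "manifest.json"
    with open(out / "pipeline.log", "w", encoding="utf-8") as fh:
        fh.write("\n".join(log_lines) + "\n")
    artifacts["log"] = out / "pipeline.log"
    return artifacts
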