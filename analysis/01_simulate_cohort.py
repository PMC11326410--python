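"""Simulate the resting-state eye-tracking cohort.

Writes ASC-like raw sample files plus ground-truth sidecars for a cohort
of subjects with stable per-subject physiology (tonic pupil, blink habits,
BIPR kernel shape) and a mix of vigilant and drowsy runs.
"""

import argparse
from pathlib import Path

from bipr.pipeline import PipelineConfig, simulate_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-subjects", type=int, default=20)
    ap.add_argument("--runs-per-subject", type=int, default=3)
    ap.add_argument("--duration-s", type=float, default=300.0)
    args = ap.parse_args()

    cfg = PipelineConfig(
        out_dir=str(args.out),
        seed=args.seed,
        n_subjects=args.n_subjects,
        runs_per_subject=args.runs_per_subject,
        run_duration_s=args.duration_s,
    )
    index = simulate_cohort(cfg, args.out / "raw")
    cfg.to_yaml(args.out / "config.yaml")
    print(f"wrote {len(index)} runs for {args.n_subjects} subjects under {args.out}/raw")


if __name__ == "__main__":
    main()
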