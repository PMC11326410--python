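"""Preprocess every raw run and assemble the measure table.

Each run goes through the six-step chain (up-sample, blink detection,
spline interpolation, 0.02-4 Hz zero-phase band-pass, 100 Hz decimation),
is classified by vigilance, and contributes one row of the nine eye
measures (blink rate/duration, pupil size, six BIPR peak parameters).
Discarded runs (>75% pupil loss) are dropped; outliers beyond two IQR of
the quartiles are masked per measure within each state.
"""

import argparse
from pathlib import Path

import pandas as pd

from bipr.pipeline import PipelineConfig, apply_outlier_exclusion, cohort_measure_table


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    cfg = PipelineConfig.from_yaml(args.cohort / "config.yaml")
    table = cohort_measure_table(cfg, args.cohort / "raw", args.cohort / "waveforms.csv")
    n_total = len(table)
    table = table[table["state"] != "discarded"].reset_index(drop=True)
    table = apply_outlier_exclusion(table, multiplier=cfg.outlier_multiplier,
                                    scope=cfg.outlier_scope)
    out = args.cohort / "measures.csv"
    table.to_csv(out, index=False)
    counts = table["state"].value_counts().to_dict()
    print(f"{n_total} runs preprocessed, {len(table)} kept: {counts}")
    print(f"measure table -> {out}")
    with pd.option_context("display.width", 120):
        print(table.groupby("state")[["blink_rate", "pupil_size", "d_time", "c_time"]].mean().round(3))


if __name__ == "__main__":
    main()
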