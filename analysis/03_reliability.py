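"""Test-retest reliability of the nine eye measures.

ICC(2,k) (two-way random effects, average agreement) per measure and
vigilance state, plus the within-subject correlation of normalized
measure vectors between runs of the same state.
"""

import argparse
from pathlib import Path

import pandas as pd

from bipr.reliability import icc_report, within_subject_reliability


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    table = pd.read_csv(args.cohort / "measures.csv")
    rel = icc_report(table)
    rel.to_csv(args.cohort / "reliability.csv", index=False)
    print("ICC(2,k) per measure and state:")
    print(rel.pivot(index="measure", columns="state", values="icc").round(3))

    rows = []
    for state in sorted(table["state"].unique()):
        w = within_subject_reliability(table, state)
        rows.append((state, w.mean, w.median, w.sd, w.n_subjects))
        print(
            f"within-subject ({state}): mean r={w.mean:.3f} median={w.median:.3f} "
            f"sd={w.sd:.3f} over {w.n_subjects} subjects"
        )
    pd.DataFrame(rows, columns=["state", "mean_r", "median_r", "sd_r", "n_subjects"]).to_csv(
        args.cohort / "within_subject.csv", index=False
    )


if __name__ == "__main__":
    main()
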