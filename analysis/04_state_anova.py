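"""Vigilant vs all-drowsy comparison of the nine measures.

One-way ANOVA per measure on subjects contributing both states, with
Bonferroni correction at alpha = 0.05/9.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from bipr.state import paired_state_table, state_anova


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    table = pd.read_csv(args.cohort / "measures.csv")
    paired = paired_state_table(table)
    n_sub = paired["subject_id"].nunique()
    res = state_anova(paired)
    df = pd.DataFrame([dataclasses.asdict(r) for r in res])
    df.to_csv(args.cohort / "anova.csv", index=False)
    print(f"{n_sub} subjects contribute both states")
    print(df.round(4).to_string(index=False))
    n_sig = int(df["significant_after_correction"].sum())
    print(f"{n_sig}/{len(df)} measures significant after Bonferroni correction")


if __name__ == "__main__":
    main()
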