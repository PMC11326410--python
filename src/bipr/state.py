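"""Vigilant vs all-drowsy comparison of the nine eye measures.

A one-way ANOVA compares the two vigilance states per measure, using
only subjects that contribute both states (a paired dataset), with a
Bonferroni-adjusted alpha of 0.05/9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .measures import MEASURES

__all__ = ["AnovaResult", "state_anova", "paired_state_table", "BONFERRONI_ALPHA"]

BONFERRONI_ALPHA = 0.05 / 9


@dataclass(frozen=True)
class AnovaResult:
    measure: str
    f_stat: float
    df_between: int
    df_within: int
    p: float
    significant_after_correction: bool


def paired_state_table(table: pd.DataFrame, measures: list[str] | None = None) -> pd.DataFrame:
    """Per-subject state means, restricted to subjects with both states.

    Input is the long measure table (subject, run, state, measures);
    output has one row per subject x measure with columns
    ``value_vigilant`` and ``value_all_drowsy``.
    """
    measures = measures or MEASURES
    agg = table.groupby(["subject", "state"])[measures].mean().reset_index()
    rows = []
    for m in measures:
        wide = agg.pivot(index="subject", columns="state", values=m)
        if not {"vigilant", "all_drowsy"}.issubset(wide.columns):
            continue
        both = wide[["vigilant", "all_drowsy"]].dropna()
        for subject, r in both.iterrows():
            rows.append((subject, m, r["vigilant"], r["all_drowsy"]))
    return pd.DataFrame(rows, columns=["subject_id", "measure_name", "value_vigilant", "value_all_drowsy"])


def state_anova(
    paired: pd.DataFrame, alpha: float = BONFERRONI_ALPHA, repeated: bool = False
) -> list[AnovaResult]:
    """One-way ANOVA per measure between the two state groups.

    ``repeated=True`` switches to a repeated-measures variant (one-way on
    the paired differences, equivalent to a paired t-test) for
    sensitivity; the default is the plain two-group ANOVA on dual-state
    subjects. Measures with fewer than 3 paired subjects are skipped.
    """
    results: list[AnovaResult] = []
    for m, grp in paired.groupby("measure_name"):
        a = grp["value_vigilant"].to_numpy(dtype=float)
        b = grp["value_all_drowsy"].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        n = a.size
        if n < 3:
            continue
        if repeated:
            t, p = stats.ttest_rel(a, b)
            f = float(t * t)
            dfb, dfw = 1, n - 1
        else:
            f, p = stats.f_oneway(a, b)
            f = float(f)
            dfb, dfw = 1, 2 * n - 2
        f = max(f, 0.0) if np.isfinite(f) else 0.0
        if not np.isfinite(p):  # zero between-group variance: p degenerates
            p = float(stats.f.sf(f, dfb, dfw)) if f > 0 else 1.0
        results.append(
            AnovaResult(
                measure=m,
                f_stat=f,
                df_between=dfb,
                df_within=dfw,
                p=float(p),
                significant_after_correction=bool(p < alpha),
            )
        )
    return results
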