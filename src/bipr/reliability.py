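"""Test-retest reliability: ICC(2,k) and within-subject run correlations.

ICC(2,k) is the intraclass correlation of a two-way random-effects model
(subjects and runs both random) for the average of k measurements, with
absolute agreement:

    ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

where MSR, MSC and MSE are the between-subject, between-run and residual
mean squares of the two-way ANOVA, and n is the number of subjects.

Within-subject reliability correlates, per subject, the z-scored vectors
of the nine measures between runs of the same vigilance state.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .measures import MEASURES

__all__ = ["ICCResult", "icc2k", "WithinSubjectResult", "within_subject_reliability", "icc_report"]


@dataclass(frozen=True)
class ICCResult:
    icc: float
    msr: float
    msc: float
    mse: float
    n_subjects: int
    k_runs: float


def _icc_from_ms(msr: float, msc: float, mse: float, n: int) -> float:
    denom = msr + (msc - mse) / n
    if denom == 0:
        return float("nan")
    return (msr - mse) / denom


def icc2k(values: np.ndarray) -> ICCResult:
    """ICC(2,k) of a subject x run matrix.

    NaN cells mark runs a subject did not contribute. Balanced matrices
    use the exact two-way ANOVA decomposition. Unbalanced matrices use
    unweighted subject and run means, with k taken as the harmonic mean
    of per-subject run counts (subjects with fewer than 2 runs are
    dropped) — an approximation documented as such.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D subject x run matrix")
    have = ~np.isnan(x)
    x = x[have.sum(axis=1) >= 2]
    have = ~np.isnan(x)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 runs")

    if have.all():
        m = x.mean()
        ri = x.mean(axis=1)
        cj = x.mean(axis=0)
        msr = k * np.sum((ri - m) ** 2) / (n - 1)
        msc = n * np.sum((cj - m) ** 2) / (k - 1)
        sse = np.sum((x - ri[:, None] - cj[None, :] + m) ** 2)
        mse = sse / ((n - 1) * (k - 1))
        k_eff: float = float(k)
    else:
        counts = have.sum(axis=1)
        k_eff = len(counts) / np.sum(1.0 / counts)
        ri = np.nanmean(x, axis=1)
        cj = np.nanmean(x, axis=0)
        m = ri.mean()
        msr = k_eff * np.sum((ri - m) ** 2) / (n - 1)
        kc = int(have.any(axis=0).sum())
        msc = n * np.nansum((cj - np.nanmean(cj)) ** 2) / max(kc - 1, 1)
        resid = x - ri[:, None] - cj[None, :] + m
        dfe = int(have.sum()) - n - kc + 1
        mse = np.nansum(resid[have] ** 2) / max(dfe, 1)
        # unbalanced cells: use the variance-component form with negative
        # mean-square differences truncated at zero, which keeps the
        # estimate inside [0, 1] even at very small n
        vs = max((msr - mse) / k_eff, 0.0)
        vr = max((msc - mse) / n, 0.0)
        denom = vs + (vr + mse) / k_eff
        icc = vs / denom if denom > 0 else float("nan")
        return ICCResult(icc, msr, msc, mse, n, k_eff)
    if msr == 0 and msc == 0 and mse == 0:
        return ICCResult(float("nan"), msr, msc, mse, n, k_eff)
    return ICCResult(_icc_from_ms(msr, msc, mse, n), msr, msc, mse, n, k_eff)


@dataclass(frozen=True)
class WithinSubjectResult:
    mean: float
    median: float
    sd: float
    n_subjects: int
    n_skipped: int


def within_subject_reliability(
    table: pd.DataFrame, state: str, measures: list[str] | None = None
) -> WithinSubjectResult:
    """Per-subject correlation of normalized measure vectors between runs.

    Each measure is centered and scaled over *all* runs of the state
    (pooled z-scoring), then for every subject with >= 2 runs the Pearson
    correlation between run vectors is computed for each run pair and
    averaged. Subjects whose correlation is undefined (constant vector,
    or < 2 shared finite measures) are skipped and counted.
    """
    measures = measures or MEASURES
    sub = table[table["state"] == state]
    z = sub.copy()
    for m in measures:
        col = sub[m].astype(float)
        sd = col.std(ddof=1)
        z[m] = (col - col.mean()) / sd if sd > 0 else np.nan

    per_subject: list[float] = []
    skipped = 0
    for _, grp in z.groupby("subject"):
        if len(grp) < 2:
            continue
        vecs = grp[measures].to_numpy(dtype=float)
        rs = []
        for i, j in combinations(range(len(vecs)), 2):
            a, b = vecs[i], vecs[j]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 2 or a[ok].std() == 0 or b[ok].std() == 0:
                continue
            rs.append(np.corrcoef(a[ok], b[ok])[0, 1])
        if rs:
            per_subject.append(float(np.mean(rs)))
        else:
            skipped += 1
    if not per_subject:
        return WithinSubjectResult(np.nan, np.nan, np.nan, 0, skipped)
    arr = np.asarray(per_subject)
    return WithinSubjectResult(
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else np.nan,
        n_subjects=arr.size,
        n_skipped=skipped,
    )


def icc_report(table: pd.DataFrame, measures: list[str] | None = None) -> pd.DataFrame:
    """ICC(2,k) per measure and state from a long measure table.

    Returns a tidy frame (measure, state, icc, n_subjects, k_runs)
    mirroring the usual reliability-table layout.
    """
    measures = measures or MEASURES
    rows = []
    for state, grp in table.groupby("state"):
        wide_base = grp.pivot_table(index="subject", columns="run", values=measures, aggfunc="first")
        for m in measures:
            wide = wide_base[m]
            try:
                res = icc2k(wide.to_numpy(dtype=float))
            except ValueError:
                continue
            rows.append((m, state, res.icc, res.n_subjects, res.k_runs))
    return pd.DataFrame(rows, columns=["measure", "state", "icc", "n_subjects", "k_runs"])
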