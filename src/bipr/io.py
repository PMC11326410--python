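"""Readers for raw pupil sample streams.

Two dialects are supported:

* ``asc_like`` — the tab-separated sample format of EyeLink ASC exports:
  ``<t>\\t<x>\\t<y>\\t<pupil>`` with optional trailing fields. Lines whose
  first token is alphabetic (``MSG``, ``SBLINK``, ``EBLINK``, ``ESACC``,
  ...) are recorder events and are skipped; in particular the recorder's
  own EBLINK labels are ignored, because blinks are re-detected from the
  zero spans of the pupil channel.
* ``delimited`` — a plain two-column CSV with header ``t_ms,pupil``.

In both dialects a blank or non-numeric pupil field maps to 0.0
(pupil not detected).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trace import PupilTrace

__all__ = ["read_samples"]


def read_samples(path, dialect: str = "asc_like", sampling_rate: float | None = None) -> PupilTrace:
    """Read a raw sample stream into a :class:`PupilTrace`.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"asc_like"`` or ``"delimited"`` (see module docstring).
    sampling_rate
        Declared rate in Hz. If omitted, inferred from the median
        timestamp step. Timestamps deviating from uniform spacing by more
        than half a sample raise an error.
    """
    if dialect == "delimited":
        df = pd.read_csv(path)
        if not {"t_ms", "pupil"}.issubset(df.columns):
            raise ValueError(f"{path}: delimited dialect needs header 't_ms,pupil'")
        t = df["t_ms"].to_numpy(dtype=float)
        p = pd.to_numeric(df["pupil"], errors="coerce").fillna(0.0).to_numpy(dtype=float)
    elif dialect == "asc_like":
        from io import StringIO

        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.readlines()
        # event lines (MSG / SBLINK / EBLINK / ESACC / ...) start alphabetic
        keep = [(i, ln) for i, ln in enumerate(lines) if ln[:1].isdigit() or ln[:1] == "-"]
        if not keep:
            raise ValueError(f"{path}: no sample lines found")
        linenos = np.array([i for i, _ in keep]) + 1
        body = "".join(ln for _, ln in keep)
        df = pd.read_csv(StringIO(body), sep="\t", header=None, engine="c", na_values=["."])
        if df.shape[1] < 4:  # fall back for space-separated exports
            df = pd.read_csv(StringIO(body), sep=r"\s+", header=None, na_values=["."])
        if df.shape[1] < 4:
            raise ValueError(f"{path}:{linenos[0]}: expected >= 4 fields")
        df = df.apply(pd.to_numeric, errors="coerce")
        t = df[0].to_numpy(dtype=float)
        if np.isnan(t).any():
            raise ValueError(
                f"{path}:{linenos[int(np.argmax(np.isnan(t)))]}: unparseable timestamp"
            )
        # col 3 is NaN for a '.' pupil marker (legal) or a short line (error)
        for row in np.flatnonzero(df[3].isna().to_numpy()):
            if len(keep[row][1].split()) < 4:
                raise ValueError(f"{path}:{linenos[row]}: expected >= 4 fields")
        p = df[3].fillna(0.0).to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 sample lines, got {t.size}")
    if sampling_rate is None:
        sampling_rate = 1000.0 / float(np.median(np.diff(t)))
        sampling_rate = 500.0 if abs(sampling_rate - 500.0) < 1 else round(sampling_rate)
    # negative pupil sizes are recorder glitches -> missing
    p = np.where(p > 0, p, 0.0)
    return PupilTrace(t_ms=t, pupil=p, sampling_rate=float(sampling_rate))
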