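"""Per-sequence quality metrics.

Three measures used to screen barcode sequences:

* the barcode quality index ``B_q``: the fraction of positions whose base
  call reaches the acceptable quality threshold *q* (Phred QV), weighted by
  how far the position's contig coverage *c* saturates the expected coverage
  *x* — ``B_q = (1/L) * sum_i 1[QV_i >= q] * min(c_i, x) / x``;
* linguistic complexity (LC): vocabulary richness, the product over pattern
  sizes k of (distinct k-mers observed / maximum possible distinct k-mers)
  within a sliding window, averaged over windows;
* homopolymer runs at or above a length threshold (runs of eight or more
  identical bases are associated with PCR slippage artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .records import BarcodeLibrary, BarcodeEvalError


class QCError(BarcodeEvalError):
    pass


@dataclass
class QCResult:
    specimen_id: str
    marker: str
    length: int
    b_index: float | None
    lc: float
    homopolymers: list[tuple[str, int, int]]


def quality_index(
    qualities: Sequence[int],
    coverage: Sequence[int],
    q: int = 30,
    x: int = 2,
) -> float:
    """Barcode quality index B_q in [0, 1].

    Monotone non-decreasing in every quality value and coverage count, and
    invariant under duplication of the sequence (it is a per-position mean).
    """
    qv = np.asarray(qualities, dtype=float)
    cov = np.asarray(coverage, dtype=float)
    if qv.size == 0 or cov.size == 0:
        raise QCError("empty quality or coverage input")
    if qv.shape != cov.shape:
        raise QCError("qualities and coverage lengths differ")
    if (qv < 0).any():
        raise QCError("negative quality value")
    weights = np.minimum(cov, x) / x
    return float(np.mean((qv >= q) * weights))


def _window_lc(window: str, kmin: int, kmax: int) -> float:
    lc = 1.0
    w = len(window)
    for k in range(kmin, kmax + 1):
        distinct = len({window[i : i + k] for i in range(w - k + 1)})
        possible = min(4**k, w - k + 1)
        lc *= distinct / possible
    return lc


def linguistic_complexity(
    sequence: str,
    window: int = 100,
    step: int = 1,
    kmin: int = 3,
    kmax: int = 6,
    aggregate: str = "mean",
) -> float:
    """Linguistic complexity of a sequence, in (0, 1].

    Per window w: ``LC_w = prod_k U_k / min(4^k, |w| - k + 1)`` where U_k is
    the number of distinct k-mers in the window.  Windows slide by ``step``;
    a sequence shorter than the window is scored as a single window.  The
    per-window values are combined by arithmetic mean (or minimum when
    ``aggregate='min'``).  Ambiguity codes count as distinct symbols.
    """
    L = len(sequence)
    if L < kmax:
        raise QCError(f"sequence shorter than the maximum pattern size ({kmax})")
    if aggregate not in ("mean", "min"):
        raise QCError(f"unknown aggregate mode {aggregate!r}")
    if L <= window:
        values = [_window_lc(sequence, kmin, kmax)]
    else:
        values = [
            _window_lc(sequence[s : s + window], kmin, kmax)
            for s in range(0, L - window + 1, step)
        ]
    return float(np.mean(values) if aggregate == "mean" else np.min(values))


def find_homopolymers(
    sequence: str, min_length: int = 8
) -> list[tuple[str, int, int]]:
    """Maximal runs of one symbol at or above ``min_length``.

    Returns (base, run length, 1-based start), sorted by start.  A run is
    reported once at its full length.
    """
    runs = []
    i = 0
    L = len(sequence)
    while i < L:
        j = i
        while j < L and sequence[j] == sequence[i]:
            j += 1
        if j - i >= min_length:
            runs.append((sequence[i], j - i, i + 1))
        i = j
    return runs


def qc_table(
    lib: BarcodeLibrary,
    q: int = 30,
    x: int = 2,
    window: int = 100,
    step: int = 1,
    kmin: int = 3,
    kmax: int = 6,
    min_homopolymer: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One QC row per record plus a per-marker summary (median and IQR).

    ``b_index`` is left missing (NaN) for records without quality values;
    LC and homopolymer counts need only the sequence.
    """
    rows = []
    for rec in lib.records:
        b = (
            quality_index(rec.qualities, rec.coverage, q=q, x=x)
            if rec.qualities is not None and rec.coverage is not None
            else np.nan
        )
        homos = find_homopolymers(rec.sequence, min_length=min_homopolymer)
        rows.append(
            {
                "specimen_id": rec.specimen_id,
                "species": rec.species,
                "marker": rec.marker,
                "length": len(rec.sequence),
                "b_index": b,
                "lc": linguistic_complexity(
                    rec.sequence, window=window, step=step, kmin=kmin, kmax=kmax
                ),
                "n_homopolymers": len(homos),
                "homopolymers": ";".join(f"{b_}{l}@{s}" for b_, l, s in homos),
            }
        )
    cols = [
        "specimen_id",
        "species",
        "marker",
        "length",
        "b_index",
        "lc",
        "n_homopolymers",
        "homopolymers",
    ]
    table = pd.DataFrame(rows, columns=cols)
    if table.empty:
        return table, pd.DataFrame(
            columns=["marker", "metric", "median", "q1", "q3", "min", "max"]
        )
    summaries = []
    for marker, grp in table.groupby("marker", sort=False):
        for metric in ("b_index", "lc"):
            vals = grp[metric].dropna()
            if vals.empty:
                continue
            summaries.append(
                {
                    "marker": marker,
                    "metric": metric,
                    "median": vals.median(),
                    "q1": vals.quantile(0.25),
                    "q3": vals.quantile(0.75),
                    "min": vals.min(),
                    "max": vals.max(),
                }
            )
    return table, pd.DataFrame(summaries)
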