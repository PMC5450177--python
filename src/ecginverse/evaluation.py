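"""Detection scoring: event matching and Se / DER / Acc metrics.

Sensitivity, detection error rate and accuracy are defined as

    Se  = 100 * TP / (TP + FN)
    DER = 100 * (FP + FN) / TP
    Acc = 100 * TP / (TP + FP + FN)

Note DER uses TP (not total beats) in the denominator, so it can exceed
100 for very poor detectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = ["DetectionReport", "match_events", "metrics", "summarize_table"]


def _round2(x: float) -> float:
    """Round half away from zero to 2 decimals (printed-table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DetectionReport:
    tp: int
    fn: int
    fp: int
    se: float
    der: float | None
    acc: float


def match_events(detected, truth, tol_s: float = 0.075):
    """Greedy one-to-one nearest matching within ``±tol_s``.

    Returns ``(tp, fn, fp)``; unmatched truth events count as FN,
    unmatched detections as FP.  Symmetric: swapping the two lists swaps
    FN and FP.
    """
    if tol_s <= 0:
        raise ValueError("tol_s must be positive")
    det = np.asarray(detected, dtype=float)
    tru = np.asarray(truth, dtype=float)
    pairs = []
    for i, d in enumerate(det):
        dt = np.abs(tru - d)
        for j in np.flatnonzero(dt <= tol_s):
            pairs.append((abs(d - tru[j]), i, int(j)))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _dist, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        tp += 1
    return tp, len(tru) - tp, len(det) - tp


def metrics(tp: int, fn: int, fp: int) -> DetectionReport:
    """Se / DER / Acc percentages, reported to two decimals."""
    if tp + fn <= 0:
        raise ValueError("tp + fn must be positive (no truth events)")
    se = _round2(100.0 * tp / (tp + fn))
    acc = _round2(100.0 * tp / (tp + fp + fn))
    if tp > 0:
        der = _round2(100.0 * (fp + fn) / tp)
    else:
        warnings.warn("no true positives: DER is undefined", stacklevel=2)
        der = None
    return DetectionReport(tp=tp, fn=fn, fp=fp, se=se, der=der, acc=acc)


def summarize_table(rows: pd.DataFrame) -> dict:
    """Column sums of FN/FP counts across records.

    ``rows`` must carry fn/fp columns (e.g. fn_r, fp_r, fn_t, fp_t);
    every fn*/fp* column is summed and an overall total per wave is
    reported as ``total_<suffix>`` for matching fn/fp pairs.
    """
    if rows.empty:
        raise ValueError("rows must be non-empty")
    out: dict[str, int] = {}
    for col in rows.columns:
        if col.startswith(("fn", "fp")):
            out[f"sum_{col}"] = int(rows[col].sum())
    for col in rows.columns:
        if col.startswith("fn"):
            suffix = col[2:]
            fp_col = "fp" + suffix
            if fp_col in rows.columns:
                out[f"total{suffix or ''}"] = (
                    out[f"sum_{col}"] + out[f"sum_{fp_col}"]
                )
    return out
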