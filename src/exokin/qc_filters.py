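"""Exclusion rules for analytical error, with an auditable ledger.

Two well-level rules: strictly negative reduced values are analytical
error and removed; within each cell of up to four analytical replicates,
Tukey-fence outliers (1.5 x IQR beyond the quartiles, quartiles by linear
interpolation) are flagged and at most one — the flagged value farthest
from the median — is removed. Every removal is logged with its reason so
the run can report "excluded X of N (y%)".
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REASONS = ("negative_value", "iqr_outlier", "concentration_drop",
           "nonsignificant_model", "mmrt_invalid")


@dataclass
class ExclusionLedger:
    """Counts of excluded data-points by reason, plus the inspected total."""
    counts: Counter = field(default_factory=Counter)
    inspected: int = 0
    rows: list = field(default_factory=list)  # (reason, reference) provenance

    def inspect(self, n: int) -> None:
        self.inspected += int(n)

    def exclude(self, reason: str, n: int = 1, ref=None) -> None:
        if reason not in REASONS:
            raise ValueError(f"unknown exclusion reason: {reason}")
        self.counts[reason] += int(n)
        if ref is not None:
            self.rows.append((reason, ref))

    @property
    def total_excluded(self) -> int:
        return sum(self.counts.values())

    def merge(self, other: "ExclusionLedger") -> None:
        self.counts.update(other.counts)
        self.inspected += other.inspected
        self.rows.extend(other.rows)


def drop_negative(values, ledger: ExclusionLedger | None = None,
                  inspect: bool = True):
    """Remove strictly negative values (analytical error); zeros retained."""
    arr = np.asarray(values, dtype=float)
    keep = ~(arr < 0)
    if ledger is not None:
        if inspect:
            ledger.inspect(arr.size)
        n_bad = int((~keep).sum())
        if n_bad:
            ledger.exclude("negative_value", n_bad)
    return arr[keep]


def iqr_fences(values, k: float = 1.5) -> tuple[float, float]:
    """Tukey fences [Q1 - k*IQR, Q3 + k*IQR], linear-interpolation quartiles."""
    arr = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(arr, [25.0, 75.0])  # linear interpolation default
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def iqr_replicate_filter(reps, ledger: ExclusionLedger | None = None,
                         k: float = 1.5, ref=None):
    """Remove at most one fence-crossing value from a replicate cell.

    When several replicates cross the fences, the one farthest from the
    median is removed; ties break toward the larger absolute value, then
    the first index. Fewer than two values pass through untouched.
    """
    arr = np.asarray(reps, dtype=float)
    if arr.size < 2:
        if arr.size:
            log.warning("iqr_replicate_filter: <2 values, passthrough")
        return arr
    lo, hi = iqr_fences(arr, k=k)
    flagged = np.flatnonzero((arr < lo) | (arr > hi))
    if flagged.size == 0:
        return arr
    med = np.median(arr)
    dist = np.abs(arr[flagged] - med)
    # farthest from median; ties -> larger |value|, then first index
    order = sorted(range(flagged.size),
                   key=lambda i: (-dist[i], -abs(arr[flagged[i]]), i))
    drop = flagged[order[0]]
    if ledger is not None:
        ledger.exclude("iqr_outlier", 1, ref=ref)
    return np.delete(arr, drop)


def filter_replicate_cells(rates: pd.DataFrame, ledger: ExclusionLedger,
                           value_col: str = "rate_nmol_g_h") -> pd.DataFrame:
    """Apply both well-level rules per enzyme x depth x core x temperature x
    substrate x timepoint cell; returns surviving rows."""
    keys = ["enzyme", "depth_cm", "core", "temperature_C",
            "substrate_uM", "timepoint_h"]
    kept = []
    for key, cell in rates.groupby(keys, sort=False):
        vals = cell[value_col].to_numpy(dtype=float)
        ledger.inspect(vals.size)
        neg = vals < 0
        if neg.any():
            ledger.exclude("negative_value", int(neg.sum()), ref=key)
        cell = cell[~neg]
        vals = vals[~neg]
        if vals.size >= 2:
            lo, hi = iqr_fences(vals)
            flagged = np.flatnonzero((vals < lo) | (vals > hi))
            if flagged.size:
                med = np.median(vals)
                dist = np.abs(vals[flagged] - med)
                order = sorted(range(flagged.size),
                               key=lambda i: (-dist[i],
                                              -abs(vals[flagged[i]]), i))
                drop_pos = flagged[order[0]]
                ledger.exclude("iqr_outlier", 1, ref=key)
                cell = cell.drop(cell.index[drop_pos])
        kept.append(cell)
    return pd.concat(kept, ignore_index=True)


def exclusion_summary(ledger: ExclusionLedger) -> pd.DataFrame:
    """Tabulate exclusions by reason with fractions of inspected points."""
    n = ledger.inspected
    rows = [{"reason": r, "count": int(ledger.counts.get(r, 0)),
             "fraction": (ledger.counts.get(r, 0) / n) if n else 0.0}
            for r in REASONS]
    rows.append({"reason": "total", "count": ledger.total_excluded,
                 "fraction": (ledger.total_excluded / n) if n else 0.0})
    df = pd.DataFrame(rows)
    pct = 100.0 * (ledger.total_excluded / n) if n else 0.0
    log.info("excluded %d out of %d data-points (%.1f%%)",
             ledger.total_excluded, n, pct)
    return df
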