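"""Aggregate classified reads into per-variant percent-cleaved time courses.

The tidy table convention used throughout the package is one row per
(variant, replicate, timepoint) with columns ``variant``, ``replicate``,
``time_min``, ``n_cleaved``, ``n_full``, ``pct_cleaved``, ``suppressed``.
Cells with fewer than ``min_total`` reads are suppressed — flagged and
excluded from fitting — so low-coverage cells are never mistaken for true
0% cleavage.
"""
from __future__ import annotations

from typing import Iterable

import pandas as pd

COUNT_COLUMNS = ["variant", "replicate", "time_min", "n_cleaved", "n_full"]
DEFAULT_MIN_TOTAL = 50


def count_reads(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-read records (columns ``variant``, ``status``,
    ``replicate``, ``time_min``; discarded rows allowed and ignored) into
    per-cell cleaved/full counts. Cells with no reads produce no row."""
    kept = records[records["status"].isin(["cleaved", "full_length"])]
    if kept.empty:
        return pd.DataFrame(columns=COUNT_COLUMNS)
    wide = (
        kept.groupby(["variant", "replicate", "time_min", "status"], observed=True)
        .size()
        .unstack("status", fill_value=0)
    )
    for col in ("cleaved", "full_length"):
        if col not in wide:
            wide[col] = 0
    out = wide.reset_index().rename(
        columns={"cleaved": "n_cleaved", "full_length": "n_full"}
    )
    return out[COUNT_COLUMNS].sort_values(COUNT_COLUMNS[:3]).reset_index(drop=True)


def aggregate_counts(
    sample_counts: Iterable[tuple[str, float, pd.DataFrame]]
) -> pd.DataFrame:
    """Combine per-sample (replicate, time, variant-by-status count tables
    as produced by read processing) into the tidy count table."""
    rows = []
    for replicate, time_min, counts in sample_counts:
        if counts.empty:
            continue
        wide = counts.pivot_table(
            index="variant", columns="status", values="n", fill_value=0, aggfunc="sum"
        )
        for col in ("cleaved", "full_length"):
            if col not in wide:
                wide[col] = 0
        for variant, row in wide.iterrows():
            rows.append(
                {
                    "variant": variant,
                    "replicate": replicate,
                    "time_min": float(time_min),
                    "n_cleaved": int(row["cleaved"]),
                    "n_full": int(row["full_length"]),
                }
            )
    out = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return out.sort_values(COUNT_COLUMNS[:3]).reset_index(drop=True)


def percent_cleaved_table(
    counts: pd.DataFrame, min_total: int = DEFAULT_MIN_TOTAL
) -> pd.DataFrame:
    """Add ``pct_cleaved`` = 100 * cleaved / total and a ``suppressed`` flag
    for cells whose total coverage falls below ``min_total``."""
    out = counts.copy()
    total = out["n_cleaved"] + out["n_full"]
    out["pct_cleaved"] = (100.0 * out["n_cleaved"] / total.where(total > 0)).fillna(0.0)
    out["suppressed"] = total < max(min_total, 1)
    return out


def time_course(pct_table: pd.DataFrame, variant: str, replicate: str) -> pd.DataFrame:
    """Unsuppressed points for one (variant, replicate), sorted by time.
    Columns: ``time_min``, ``pct_cleaved``, ``n_total``."""
    sel = pct_table[
        (pct_table["variant"] == variant)
        & (pct_table["replicate"] == replicate)
        & (~pct_table["suppressed"])
    ].copy()
    sel["n_total"] = sel["n_cleaved"] + sel["n_full"]
    sel = sel.sort_values("time_min").reset_index(drop=True)
    return sel[["time_min", "pct_cleaved", "n_total"]]
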