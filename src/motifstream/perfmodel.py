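"""Amdahl's-law performance modelling for the parallelizable scan core.

The maximum overall speedup achievable by parallelizing a portion of a
program that takes fraction f of total runtime is 1/(1-f).  The fraction f
is supplied by the user (e.g. measured with gprof); the module performs no
self-profiling, keeping it deterministic and hardware-independent.
Displayed values are rounded to 2 decimal places (round-half-even); exact
values are retained internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd


@dataclass
class ProfileRecord:
    """One profiled dataset: total time, scan-core fraction, optional speedup."""

    label: str
    total_time: float
    fraction_in_core: float
    achieved_speedup: float | None = None

    def __post_init__(self) -> None:
        if self.total_time <= 0:
            raise ValueError("total_time must be positive")
        if not (0.0 <= self.fraction_in_core < 1.0):
            raise ValueError("fraction_in_core must lie in [0, 1)")
        if self.achieved_speedup is not None and self.achieved_speedup <= 0:
            raise ValueError("achieved_speedup must be positive")


def amdahl_limit(f: float) -> float:
    """Theoretical speedup bound 1/(1-f) for parallelized fraction f."""
    if not (0.0 <= f < 1.0):
        raise ValueError("f must lie in [0, 1)")
    return 1.0 / (1.0 - f)


def speedup(t_original: float, t_new: float) -> float:
    """Overall speedup: original runtime over accelerated runtime."""
    if t_original <= 0 or t_new <= 0:
        raise ValueError("times must be positive")
    return t_original / t_new


def profile_report(records: list[ProfileRecord]) -> pd.DataFrame:
    """Tabulate theoretical limits against achieved speedups.

    Columns: label, fraction_in_core, theoretical_limit, achieved_speedup,
    achieved_over_limit.  An achieved speedup exceeding its theoretical
    limit triggers a warning (measurement noise), never a failure.
    """
    rows = []
    for r in records:
        limit = amdahl_limit(r.fraction_in_core)
        ratio = (r.achieved_speedup / limit
                 if r.achieved_speedup is not None else None)
        if r.achieved_speedup is not None and r.achieved_speedup > limit:
            warnings.warn(
                f"{r.label}: achieved speedup {r.achieved_speedup:.2f} "
                f"exceeds Amdahl limit {limit:.2f}", RuntimeWarning,
                stacklevel=2)
        rows.append((r.label, r.fraction_in_core, limit,
                     r.achieved_speedup, ratio))
    return pd.DataFrame(rows, columns=[
        "label", "fraction_in_core", "theoretical_limit",
        "achieved_speedup", "achieved_over_limit"])


def read_profile_tsv(path: str | Path) -> list[ProfileRecord]:
    """Read records from a TSV: label, total_time, fraction_in_core
    [, new_time]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"label", "total_time", "fraction_in_core"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        achieved = None
        if "new_time" in df.columns and pd.notna(getattr(row, "new_time")):
            achieved = speedup(row.total_time, getattr(row, "new_time"))
        records.append(ProfileRecord(
            label=str(row.label), total_time=float(row.total_time),
            fraction_in_core=float(row.fraction_in_core),
            achieved_speedup=achieved))
    return records


def write_report_tsv(report: pd.DataFrame, path: str | Path,
                     header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        report.round(2).to_csv(fh, sep="\t", index=False)
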