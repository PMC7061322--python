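"""File formats: wide latency CSV, per-participant metrics CSV, JSON report.

The latency table is wide (one row per participant, one ``trial_NN`` column
per trial) since the trial count is fixed by the task.  The metrics table
carries tract microstructure (fornix/ILF FA and MD), hippocampal and total
intracranial volumes and gender; hemispheric ILF columns, when present, are
averaged into the bilateral measure.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .learning import LatencySeries

__all__ = [
    "read_latency_table",
    "write_latency_table",
    "read_metrics_table",
    "proportional_volume",
    "write_report",
    "read_report",
    "ParseError",
]

logger = logging.getLogger("navlearn")

DEFAULT_GENDER_MAP = {"F": 0, "M": 1}

REQUIRED_METRIC_COLUMNS = (
    "participant_id",
    "fornix_fa",
    "fornix_md",
    "hippocampal_volume",
    "etiv",
    "gender",
)


class ParseError(ValueError):
    """Malformed input table; the message names the offending row/column."""


def read_latency_table(path, t_max: float = 60.0) -> list[LatencySeries]:
    """Read a wide latency CSV into per-participant series.

    The header must be ``participant_id, trial_01..trial_NN`` (consecutive,
    zero-padded); every cell must be numeric, positive and at most
    ``t_max``.  Rows with missing or out-of-range cells are rejected with
    the row and column named.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "participant_id":
        raise ParseError(
            f"{path}: first column must be 'participant_id', got {df.columns[0]!r}"
        )
    trial_cols = list(df.columns[1:])
    expected = [f"trial_{i:02d}" for i in range(1, len(trial_cols) + 1)]
    if trial_cols != expected:
        raise ParseError(
            f"{path}: trial columns must be {expected[0]}..{expected[-1]}, "
            f"got {trial_cols}"
        )
    if len(trial_cols) < 4:
        raise ParseError(f"{path}: need at least 4 trial columns")
    series = []
    for i, row in df.iterrows():
        pid = str(row["participant_id"])
        for col in trial_cols:
            val = pd.to_numeric(row[col], errors="coerce")
            if pd.isna(val):
                raise ParseError(f"{path}: row {i + 2} column {col}: missing or non-numeric")
            if val <= 0 or val > t_max:
                raise ParseError(
                    f"{path}: row {i + 2} column {col}: latency {val} outside (0, {t_max}]"
                )
        series.append(
            LatencySeries(pid, row[trial_cols].to_numpy(dtype=float), t_max)
        )
    return series


def write_latency_table(series: list[LatencySeries] | pd.DataFrame, path) -> None:
    """Write a wide latency CSV (inverse of :func:`read_latency_table`)."""
    if isinstance(series, pd.DataFrame):
        df = series
    else:
        df = pd.DataFrame(
            np.array([s.latencies for s in series]),
            columns=[f"trial_{i + 1:02d}" for i in range(series[0].n_trials)],
        )
        df.insert(0, "participant_id", [s.participant_id for s in series])
    df.to_csv(path, index=False, float_format="%.12g")


def read_metrics_table(
    path, gender_map: dict | None = None
) -> pd.DataFrame:
    """Read and validate the per-participant metrics CSV.

    Accepts either bilateral ``ilf_fa``/``ilf_md`` columns or hemispheric
    ``ilf_fa_left``/``ilf_fa_right`` (and md) pairs, which are averaged into
    the bilateral measure.  FA must lie in (0, 1); MD and volumes must be
    positive (MD in 1e-3 mm^2/s).  Gender strings are mapped through
    ``gender_map`` (default {"F": 0, "M": 1}).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for metric in ("ilf_fa", "ilf_md"):
        if metric not in df.columns:
            lr = [f"{metric}_left", f"{metric}_right"]
            if not all(c in df.columns for c in lr):
                raise ParseError(
                    f"{path}: need either {metric!r} or both of {lr}"
                )
            df[metric] = df[lr].mean(axis=1)
    gender_map = DEFAULT_GENDER_MAP if gender_map is None else gender_map
    if df["gender"].dtype == object:
        unknown = set(df["gender"].astype(str)) - set(gender_map)
        if unknown:
            raise ParseError(f"{path}: unmapped gender codes {sorted(unknown)}")
        df["gender"] = df["gender"].astype(str).map(gender_map)
    if not df["gender"].isin([0, 1]).all():
        raise ParseError(f"{path}: gender must code to 0/1")
    for col in ("fornix_fa", "ilf_fa"):
        bad = df.index[(df[col] <= 0) | (df[col] >= 1)]
        if len(bad):
            raise ParseError(
                f"{path}: row {bad[0] + 2} column {col}: FA outside (0, 1)"
            )
    for col in ("fornix_md", "ilf_md", "hippocampal_volume", "etiv"):
        bad = df.index[df[col] <= 0]
        if len(bad):
            raise ParseError(
                f"{path}: row {bad[0] + 2} column {col}: must be positive"
            )
    df["participant_id"] = df["participant_id"].astype(str)
    keep = list(REQUIRED_METRIC_COLUMNS) + ["ilf_fa", "ilf_md"]
    return df[[c for c in dict.fromkeys(keep)]]


def proportional_volume(volume: float, etiv: float):
    """Hippocampal volume as a proportion of total intracranial volume.

    Accepts scalars or arrays; both inputs must be positive.  Ratios at or
    above 1 are anatomically implausible and trigger a logged warning.
    """
    volume = np.asarray(volume, dtype=float)
    etiv = np.asarray(etiv, dtype=float)
    if np.any(volume <= 0) or np.any(etiv <= 0):
        raise ValueError("volume and eTIV must be positive")
    ratio = volume / etiv
    if np.any(ratio >= 1):
        logger.warning("proportional volume >= 1: implausible anatomy")
    return float(ratio) if ratio.ndim == 0 else ratio


REPORT_REQUIRED_KEYS = (
    "schema_version",
    "settings",
    "exclusions",
    "learning",
    "correlations",
    "comparisons",
    "partial_correlations",
    "alpha",
)


def write_report(report: dict, path) -> None:
    """Serialise an analysis report to JSON (sorted keys, deterministic).

    The report must contain every pipeline stage; a report missing a stage
    (for example the exclusion table) fails schema validation.
    """
    missing = [k for k in REPORT_REQUIRED_KEYS if k not in report]
    if missing:
        raise ValueError(f"report is missing required sections {missing}")
    path = Path(path)
    path.write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
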