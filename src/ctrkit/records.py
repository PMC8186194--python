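"""Measurement records shared by the phantom simulators, extractor, and workflows."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

METHODS = ("reference", "manual", "ai_only", "ai_assisted")

#: Column order of the canonical measurement table.
MEASUREMENT_COLUMNS = ["case_id", "method", "observer", "replicate", "ctr", "failed"]


@dataclass(frozen=True)
class MeasurementRecord:
    """One CTR observation: a value, or a flagged failure with no value."""

    case_id: str
    method: str
    observer_id: str
    replicate: int
    ctr: Optional[float]
    failed: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        if self.failed and self.ctr is not None:
            raise ValueError("failed record must not carry a CTR value")
        if not self.failed:
            if self.ctr is None or not math.isfinite(self.ctr):
                raise ValueError("non-failed record requires a finite CTR value")
            if not 0.0 < self.ctr <= 1.5:
                raise ValueError(f"CTR value {self.ctr} outside plausible range (0, 1.5]")


def records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    """Convert records to the canonical measurement table (ctr is NaN when failed)."""
    rows = [
        {
            "case_id": r.case_id,
            "method": r.method,
            "observer": r.observer_id,
            "replicate": r.replicate,
            "ctr": float("nan") if r.failed else r.ctr,
            "failed": int(r.failed),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    key = df[["case_id", "method", "observer", "replicate"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate measurement key {dup}")
    return df


def frame_to_records(df: pd.DataFrame) -> list[MeasurementRecord]:
    """Inverse of :func:`records_to_frame`."""
    out = []
    for row in df.itertuples(index=False):
        failed = bool(row.failed)
        out.append(
            MeasurementRecord(
                case_id=str(row.case_id),
                method=str(row.method),
                observer_id=str(row.observer),
                replicate=int(row.replicate),
                ctr=None if failed else float(row.ctr),
                failed=failed,
            )
        )
    return out


def write_measurements(df: pd.DataFrame, path) -> None:
    """Write the measurement table as CSV with empty ctr cells for failures."""
    df.to_csv(path, index=False, float_format="%.10g")


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"case_id": str, "method": str, "observer": str})
    df["replicate"] = df["replicate"].astype(int)
    df["failed"] = df["failed"].astype(int)
    return df[MEASUREMENT_COLUMNS]
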