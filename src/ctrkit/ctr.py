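"""CTR extraction from heart and lung masks via horizontal extreme points.

Diameters use the inclusive pixel-span convention (rightmost - leftmost + 1)
applied identically to both masks.  A measurement fails — rather than
erroring — when a mask is empty, the heart diameter is below the minimum
plausible size (default 3 mm), or the heart span exceeds the thoracic span
by more than a small tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ctrkit.records import MeasurementRecord

FAILURE_REASONS = (
    "none",
    "empty_heart",
    "empty_lung",
    "heart_too_small",
    "lung_too_small",
    "heart_exceeds_thorax",
)

#: Pixels of heart overhang past the thoracic span tolerated before failure.
HEART_OVERHANG_TOL_PX = 2


@dataclass(frozen=True)
class CTRResult:
    heart_diameter: Optional[float]  # mm
    thoracic_diameter: Optional[float]  # mm
    ctr: Optional[float]
    failed: bool
    failure_reason: str = "none"

    def __post_init__(self) -> None:
        if self.failure_reason not in FAILURE_REASONS:
            raise ValueError(f"unknown failure reason {self.failure_reason!r}")
        if self.failed and self.ctr is not None:
            raise ValueError("failed result must not carry a CTR")
        if not self.failed and (self.ctr is None or self.ctr <= 0):
            raise ValueError("successful result requires ctr > 0")


def _column_span(mask: np.ndarray) -> Optional[tuple[int, int]]:
    cols = np.flatnonzero(mask.any(axis=0))
    if cols.size == 0:
        return None
    return int(cols[0]), int(cols[-1])


def compute_ctr(
    heart_mask: np.ndarray,
    lung_mask: np.ndarray,
    pixel_spacing: float,
    min_heart_mm: float = 3.0,
    min_lung_mm: float = 30.0,
) -> CTRResult:
    """Extract CTR from a heart/lung mask pair.

    Shape mismatch or non-positive spacing is an input error (raised);
    implausible anatomy is a measurement failure (flagged in the result).
    """
    heart_mask = np.asarray(heart_mask, dtype=bool)
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if heart_mask.shape != lung_mask.shape:
        raise ValueError(f"mask shapes differ: {heart_mask.shape} vs {lung_mask.shape}")
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be > 0")

    def _failed(reason: str) -> CTRResult:
        return CTRResult(None, None, None, failed=True, failure_reason=reason)

    heart_span = _column_span(heart_mask)
    if heart_span is None:
        return _failed("empty_heart")
    lung_span = _column_span(lung_mask)
    if lung_span is None:
        return _failed("empty_lung")

    heart_px = heart_span[1] - heart_span[0] + 1
    lung_px = lung_span[1] - lung_span[0] + 1
    heart_mm = heart_px * pixel_spacing
    lung_mm = lung_px * pixel_spacing
    if heart_mm < min_heart_mm:
        return _failed("heart_too_small")
    if lung_mm < min_lung_mm:
        return _failed("lung_too_small")
    if heart_px > lung_px + HEART_OVERHANG_TOL_PX:
        return _failed("heart_exceeds_thorax")

    ctr = min(heart_px / lung_px, 1.0)
    return CTRResult(heart_mm, lung_mm, float(ctr), failed=False)


def measure_case(case, min_heart_mm: float = 3.0) -> CTRResult:
    """Extract CTR from a phantom case's ground-truth masks."""
    return compute_ctr(case.heart_mask, case.lung_mask, case.pixel_spacing, min_heart_mm)


def measure_population(
    mask_pairs,
    manifest: pd.DataFrame,
    *,
    method: str = "reference",
    min_heart_mm: float = 3.0,
) -> tuple[list[MeasurementRecord], dict[str, int]]:
    """Measure every case in a manifest.

    ``mask_pairs`` maps case_id -> (heart_mask, lung_mask).  Returns one
    record per case (failures propagated as failed records) together with
    failure counts per group.
    """
    records: list[MeasurementRecord] = []
    failures: dict[str, int] = {}
    for row in manifest.itertuples(index=False):
        case_id = str(row.case_id)
        if case_id not in mask_pairs:
            raise IOError(f"missing masks for case {case_id}")
        heart_mask, lung_mask = mask_pairs[case_id]
        result = compute_ctr(
            heart_mask, lung_mask, float(row.pixel_spacing_mm), min_heart_mm
        )
        records.append(
            MeasurementRecord(
                case_id=case_id,
                method=method,
                observer_id="extractor",
                replicate=1,
                ctr=result.ctr,
                failed=result.failed,
            )
        )
        if result.failed:
            failures[row.group] = failures.get(row.group, 0) + 1
    return records, failures
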