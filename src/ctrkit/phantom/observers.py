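"""Simulated measurement processes: human observers and the AI-only reader.

All noise is multiplicative (relative) on the true CTR, since measurement
variation is naturally expressed as a percentage of the mean.  The AI error
is a two-component normal mixture (a tight core plus occasional large
misses) with group-dependent hard-failure probabilities; the default
failure rates concentrate failures in the normal group (290/4,933 normal vs
9/2,517 cardiomegaly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ctrkit.records import MeasurementRecord

#: Default AI failure rates from the clinical outcome counts.
DEFAULT_FAIL_PROB_NORMAL = 290 / 4933
DEFAULT_FAIL_PROB_CARDIOMEGALY = 9 / 2517


@dataclass(frozen=True)
class ObserverModel:
    """A human observer with a relative bias and relative measurement SD."""

    observer_id: str
    relative_bias: float = 0.0
    relative_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be >= 0")


@dataclass(frozen=True)
class AIErrorModel:
    """AI-only error: normal mixture plus per-group segmentation-failure events."""

    core_sd: float = 0.004
    outlier_sd: float = 0.18
    outlier_prob: float = 0.095
    fail_prob_normal: float = DEFAULT_FAIL_PROB_NORMAL
    fail_prob_cardiomegaly: float = DEFAULT_FAIL_PROB_CARDIOMEGALY
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.outlier_prob, self.fail_prob_normal, self.fail_prob_cardiomegaly):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.core_sd < 0 or self.outlier_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.core_sd > self.outlier_sd:
            raise ValueError("core_sd must not exceed outlier_sd")

    def fail_prob(self, group: str) -> float:
        return self.fail_prob_normal if group == "normal" else self.fail_prob_cardiomegaly

    def effective_sd(self) -> float:
        """SD of the relative-error mixture (no failures)."""
        var = (1 - self.outlier_prob) * self.core_sd**2 + self.outlier_prob * self.outlier_sd**2
        return float(np.sqrt(var))


def _truths(cases: Iterable) -> tuple[list[str], np.ndarray, list[str]]:
    ids, ctrs, groups = [], [], []
    for c in cases:
        ids.append(c.case_id)
        ctrs.append(c.true_ctr)
        groups.append(c.group)
    return ids, np.asarray(ctrs, dtype=float), groups


def simulate_manual(
    cases: Sequence,
    observer: ObserverModel,
    *,
    replicate: int = 1,
    method: str = "manual",
    session: int = 0,
) -> list[MeasurementRecord]:
    """Simulate one manual reading session over all cases.

    measured = true_ctr * (1 + bias + eps), eps ~ Normal(0, relative_sd^2).
    ``replicate`` and ``session`` key independent noise streams so repeated
    sessions by the same observer are independent yet reproducible.
    """
    ids, ctrs, _ = _truths(cases)
    rng = np.random.default_rng([observer.seed, session, replicate, 0x5EED])
    eps = rng.normal(0.0, observer.relative_sd, size=len(ids)) if observer.relative_sd else 0.0
    values = ctrs * (1.0 + observer.relative_bias + eps)
    return [
        MeasurementRecord(
            case_id=cid,
            method=method,
            observer_id=observer.observer_id,
            replicate=replicate,
            ctr=float(v),
        )
        for cid, v in zip(ids, values)
    ]


def simulate_ai_only(cases: Sequence, model: AIErrorModel) -> list[MeasurementRecord]:
    """Simulate the AI-only reader: mixture noise, or a hard failure per case."""
    ids, ctrs, groups = _truths(cases)
    rng = np.random.default_rng([model.seed, 0xA1])
    n = len(ids)
    fail_p = np.array([model.fail_prob(g) for g in groups])
    fails = rng.random(n) < fail_p
    is_outlier = rng.random(n) < model.outlier_prob
    sds = np.where(is_outlier, model.outlier_sd, model.core_sd)
    eps = rng.normal(0.0, 1.0, size=n) * sds
    values = np.clip(ctrs * (1.0 + eps), 1e-6, 1.5)
    records = []
    for cid, v, failed in zip(ids, values, fails):
        records.append(
            MeasurementRecord(
                case_id=cid,
                method="ai_only",
                observer_id="ai",
                replicate=1,
                ctr=None if failed else float(v),
                failed=bool(failed),
            )
        )
    return records
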