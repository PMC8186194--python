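"""Population sampling: per-group true-CTR distributions and case generation.

Default group parameters: normal CTR 0.454 +/- 0.043 and cardiomegaly
0.569 +/- 0.047 (cardiomegaly is conventionally defined by CTR > 0.5,
hence the optional lower truncation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from ctrkit.phantom.geometry import InvalidGeometryError, PhantomCase, PhantomGeometry, render_phantom

_MAX_REJECTION_TRIES = 1000

NORMAL_CTR_MEAN = 0.454
NORMAL_CTR_SD = 0.043
CARDIOMEGALY_CTR_MEAN = 0.569
CARDIOMEGALY_CTR_SD = 0.047


class SamplingFailureError(RuntimeError):
    """Rejection sampling could not produce a CTR inside the valid range."""


@dataclass(frozen=True)
class CaseTruth:
    """Lightweight case descriptor: enough to simulate measurements without pixels."""

    case_id: str
    group: str
    true_ctr: float


@dataclass(frozen=True)
class PopulationSpec:
    """Two-group CTR population with optional lower truncation for cardiomegaly."""

    n_normal: int = 0
    n_cardiomegaly: int = 0
    ctr_mean_normal: float = NORMAL_CTR_MEAN
    ctr_sd_normal: float = NORMAL_CTR_SD
    ctr_mean_cardiomegaly: float = CARDIOMEGALY_CTR_MEAN
    ctr_sd_cardiomegaly: float = CARDIOMEGALY_CTR_SD
    truncate_cardiomegaly_at: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_cardiomegaly < 0:
            raise ValueError("counts must be >= 0")
        for sd in (self.ctr_sd_normal, self.ctr_sd_cardiomegaly):
            if sd <= 0:
                raise ValueError("SDs must be > 0")
        for mean in (self.ctr_mean_normal, self.ctr_mean_cardiomegaly):
            if not 0.0 < mean < 1.0:
                raise ValueError("means must be in (0, 1)")


def _sample_truncated_normal(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    lower: float,
    upper: float,
) -> np.ndarray:
    """Rejection sampling from Normal(mean, sd) restricted to (lower, upper)."""
    out = np.empty(n)
    filled = 0
    for _ in range(_MAX_REJECTION_TRIES):
        if filled == n:
            break
        draw = rng.normal(mean, sd, size=max(n - filled, 16))
        keep = draw[(draw > lower) & (draw < upper)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    if filled < n:
        raise SamplingFailureError(
            f"could not sample {n} CTR values in ({lower}, {upper}) "
            f"from Normal({mean}, {sd}) after {_MAX_REJECTION_TRIES} rounds"
        )
    return out


def sample_truths(spec: PopulationSpec, max_ctr: float = 0.95) -> list[CaseTruth]:
    """Sample per-case true CTRs (no rendering).

    Deterministic under ``spec.seed``.  Cardiomegaly values can additionally
    be truncated from below at ``spec.truncate_cardiomegaly_at``.
    """
    rng = np.random.default_rng(spec.seed)
    normal = _sample_truncated_normal(
        rng, spec.n_normal, spec.ctr_mean_normal, spec.ctr_sd_normal, 0.05, max_ctr
    )
    lower_c = max(0.05, spec.truncate_cardiomegaly_at or 0.05)
    cardio = _sample_truncated_normal(
        rng,
        spec.n_cardiomegaly,
        spec.ctr_mean_cardiomegaly,
        spec.ctr_sd_cardiomegaly,
        lower_c,
        max_ctr,
    )
    truths = [
        CaseTruth(case_id=f"N{i:05d}", group="normal", true_ctr=float(v))
        for i, v in enumerate(normal)
    ]
    truths += [
        CaseTruth(case_id=f"C{i:05d}", group="cardiomegaly", true_ctr=float(v))
        for i, v in enumerate(cardio)
    ]
    return truths


def generate_population(
    spec: PopulationSpec,
    geometry: PhantomGeometry | None = None,
) -> list[PhantomCase]:
    """Render one :class:`PhantomCase` per sampled true CTR.

    Per-group sample moments of ``true_ctr`` converge to the spec values as
    n grows; identical specs give identical populations.
    """
    geometry = geometry or PhantomGeometry()
    truths = sample_truths(spec, max_ctr=geometry.max_ctr)
    seed_seq = np.random.SeedSequence(spec.seed)
    case_seeds = seed_seq.generate_state(max(len(truths), 1)) if truths else []
    cases = []
    for truth, case_seed in zip(truths, case_seeds):
        cases.append(
            render_phantom(
                truth.true_ctr,
                geometry,
                int(case_seed),
                case_id=truth.case_id,
                group=truth.group,
            )
        )
    return cases


def iter_population(
    spec: PopulationSpec, geometry: PhantomGeometry | None = None
) -> Iterator[PhantomCase]:
    """Streaming variant of :func:`generate_population` (same cases, same order)."""
    geometry = geometry or PhantomGeometry()
    truths = sample_truths(spec, max_ctr=geometry.max_ctr)
    case_seeds = np.random.SeedSequence(spec.seed).generate_state(max(len(truths), 1))
    for truth, case_seed in zip(truths, case_seeds):
        yield render_phantom(
            truth.true_ctr,
            geometry,
            int(case_seed),
            case_id=truth.case_id,
            group=truth.group,
        )
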