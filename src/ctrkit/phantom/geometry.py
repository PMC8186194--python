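"""Phantom geometry and rendering.

A phantom is a minimal frontal-chest composition of ellipses on a square
grid: a thoracic outline, two lateral lung fields whose union's horizontal
extent defines the thoracic span, and a central heart ellipse whose
horizontal span is set directly from the designed CTR.  The construction
makes extreme-point CTR exact up to rasterization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np


class InvalidGeometryError(ValueError):
    """The requested phantom cannot be constructed (e.g. heart cannot fit)."""


@dataclass(frozen=True)
class PhantomGeometry:
    """Rendering configuration for synthetic phantoms.

    ``thorax_span_frac_range`` is the range (as a fraction of image width)
    from which the thoracic horizontal span of each case is drawn, so cases
    vary in size like real patients do.
    """

    image_size: int = 256
    pixel_spacing_mm: float = 0.7
    thorax_span_frac_range: tuple[float, float] = (0.70, 0.85)
    lung_halfwidth_frac: float = 0.19  # of thoracic span, per lung field
    lung_height_frac: float = 0.62  # of image height
    heart_height_frac: float = 0.30
    heart_center_shift_frac: float = 0.04  # leftward shift of heart, of span
    # grayscale levels
    background_level: float = 0.70
    body_level: float = 0.55
    lung_level: float = 0.22
    heart_level: float = 0.82
    noise_sd: float = 0.02
    max_ctr: float = 0.95

    def __post_init__(self) -> None:
        lo, hi = self.thorax_span_frac_range
        if not (0 < lo <= hi < 1):
            raise InvalidGeometryError("thorax_span_frac_range must satisfy 0 < lo <= hi < 1")
        if self.image_size < 16:
            raise InvalidGeometryError("image_size too small")
        if self.pixel_spacing_mm <= 0:
            raise InvalidGeometryError("pixel_spacing_mm must be positive")
        if not 0 < self.max_ctr < 1:
            raise InvalidGeometryError("max_ctr must be in (0, 1)")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomGeometry":
        data = json.loads(text)
        if "thorax_span_frac_range" in data:
            data["thorax_span_frac_range"] = tuple(data["thorax_span_frac_range"])
        return cls(**data)


@dataclass
class PhantomCase:
    """One synthetic case: image, ground-truth masks, and the designed CTR."""

    case_id: str
    image: np.ndarray  # float in [0, 1], shape (H, W)
    lung_mask: np.ndarray  # bool, shape (H, W)
    heart_mask: np.ndarray  # bool, shape (H, W)
    pixel_spacing: float  # mm per pixel, isotropic
    true_ctr: float
    group: str  # "normal" | "cardiomegaly"
    thorax_span_px: float = field(default=0.0)

    def class_map(self) -> np.ndarray:
        """Per-pixel labels: 0 background, 1 lung, 2 heart (heart overrides lung)."""
        labels = np.zeros(self.image.shape, dtype=np.int64)
        labels[self.lung_mask] = 1
        labels[self.heart_mask] = 2
        return labels


def _ellipse_mask(shape: tuple[int, int], cx: float, cy: float, a: float, b: float) -> np.ndarray:
    h, w = shape
    y, x = np.ogrid[:h, :w]
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0


def render_phantom(
    true_ctr: float,
    geometry: PhantomGeometry,
    seed: int,
    *,
    case_id: str = "case",
    group: str = "normal",
    thorax_span_px: Optional[float] = None,
) -> PhantomCase:
    """Render one phantom with the given designed CTR.

    Raises :class:`InvalidGeometryError` when the heart cannot be placed
    strictly inside the thoracic span (``true_ctr`` outside (0, max_ctr]).
    """
    if not 0.0 < true_ctr < 1.0:
        raise InvalidGeometryError(f"true_ctr {true_ctr} outside (0, 1)")
    if true_ctr > geometry.max_ctr:
        raise InvalidGeometryError(
            f"true_ctr {true_ctr:.3f} exceeds geometry max_ctr {geometry.max_ctr}"
        )

    rng = np.random.default_rng(seed)
    n = geometry.image_size
    shape = (n, n)
    cx = (n - 1) / 2.0
    lo, hi = geometry.thorax_span_frac_range
    if thorax_span_px is None:
        thorax_span_px = float(rng.uniform(lo, hi) * n)
    span = float(thorax_span_px)
    if span >= n:
        raise InvalidGeometryError("thoracic span does not fit in the image")

    # Thoracic outline: slightly wider than the lung span, for the body shade.
    thorax = _ellipse_mask(shape, cx, 0.52 * n, 0.5 * span * 1.06, 0.46 * n)

    # Lung fields: outer edges exactly at cx +/- span/2.
    a_l = geometry.lung_halfwidth_frac * span
    cy_l = 0.48 * n
    b_l = geometry.lung_height_frac * n / 2.0
    left = _ellipse_mask(shape, cx - span / 2.0 + a_l, cy_l, a_l, b_l)
    right = _ellipse_mask(shape, cx + span / 2.0 - a_l, cy_l, a_l, b_l)
    lung_mask = left | right

    # Heart: horizontal span = true_ctr * thoracic span, shifted left but
    # kept strictly inside the lung union's horizontal extent.
    a_h = true_ctr * span / 2.0
    max_shift = (span / 2.0 - a_h) * 0.9
    shift = -min(geometry.heart_center_shift_frac * span, max_shift)
    b_h = geometry.heart_height_frac * n / 2.0
    heart_mask = _ellipse_mask(shape, cx + shift, 0.58 * n, a_h, b_h)

    if not heart_mask.any() or not lung_mask.any():
        raise InvalidGeometryError("degenerate geometry: empty heart or lung raster")

    image = np.full(shape, geometry.background_level, dtype=np.float64)
    image[thorax] = geometry.body_level
    image[lung_mask] = geometry.lung_level
    image[heart_mask] = geometry.heart_level
    if geometry.noise_sd > 0:
        image = image + rng.normal(0.0, geometry.noise_sd, shape)
    image = np.clip(image, 0.0, 1.0)

    return PhantomCase(
        case_id=case_id,
        image=image,
        lung_mask=lung_mask,
        heart_mask=heart_mask,
        pixel_spacing=geometry.pixel_spacing_mm,
        true_ctr=float(true_ctr),
        group=group,
        thorax_span_px=span,
    )
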