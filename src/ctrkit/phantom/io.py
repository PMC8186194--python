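"""On-disk layout for phantom populations: PNG images/masks plus a manifest CSV."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from PIL import Image

from ctrkit.phantom.geometry import PhantomCase

MANIFEST_COLUMNS = [
    "case_id",
    "group",
    "true_ctr",
    "pixel_spacing_mm",
    "image_path",
    "lung_mask_path",
    "heart_mask_path",
]


def _save_gray(path: Path, array: np.ndarray) -> None:
    Image.fromarray((np.clip(array, 0, 1) * 255).round().astype(np.uint8)).save(path)


def _save_mask(path: Path, mask: np.ndarray) -> None:
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8)).save(path)


def load_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path)) > 127


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.float64) / 255.0


def write_population(cases: Iterable[PhantomCase], outdir) -> Path:
    """Write one PNG triple per case and a manifest CSV; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        image_path = outdir / f"{case.case_id}_image.png"
        lung_path = outdir / f"{case.case_id}_lung.png"
        heart_path = outdir / f"{case.case_id}_heart.png"
        _save_gray(image_path, case.image)
        _save_mask(lung_path, case.lung_mask)
        _save_mask(heart_path, case.heart_mask)
        rows.append(
            {
                "case_id": case.case_id,
                "group": case.group,
                "true_ctr": case.true_ctr,
                "pixel_spacing_mm": case.pixel_spacing,
                "image_path": image_path.name,
                "lung_mask_path": lung_path.name,
                "heart_mask_path": heart_path.name,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        manifest, index=False, float_format="%.10g"
    )
    return manifest


def read_manifest(manifest_path) -> pd.DataFrame:
    """Read a manifest CSV; relative paths are resolved against its directory."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype={"case_id": str, "group": str})
    base = manifest_path.parent
    for col in ("image_path", "lung_mask_path", "heart_mask_path"):
        df[col] = [str(base / p) if not Path(p).is_absolute() else p for p in df[col]]
    return df
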