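"""Readers and writers for the package's on-disk artifacts.

Patch datasets use the class-folder layout (``root/<CODE>/<uuid>.png``),
regions are PNG pairs (image + single-channel label mask), cohorts and
activation tables are UTF-8 CSV with '.' decimals, and score models /
stain profiles are JSON.
"""

from __future__ import annotations

import logging
import uuid
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .cohort import ACTIVATION_COLUMNS
from .textures import TextureParams, generate_patch, generate_region
from .tissue import CLASS_CODES

logger = logging.getLogger(__name__)

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}

REQUIRED_CLINICAL_COLUMNS = ("patient_id", "stage", "sex", "age",
                             "time_OS", "event_OS")
_OPTIONAL_CLINICAL_COLUMNS = ("time_DSS", "event_DSS", "time_RFS", "event_RFS",
                              "caf_score", "path_stroma_pct", "tumor_purity")


# ---------------------------------------------------------------------------
# patch datasets


def write_patch_dataset(root: str | Path, n_per_class: int,
                        params: TextureParams | None = None) -> dict[str, int]:
    """Synthesize a class-folder patch dataset of PNGs.

    File names are deterministic UUIDs drawn from the generator seed.
    Returns the per-class file count.
    """
    params = params or TextureParams()
    root = Path(root)
    rng = np.random.default_rng((params.seed & 0x7FFFFFFF) ^ 0x5EED)
    counts = {}
    for code in CLASS_CODES:
        d = root / code
        d.mkdir(parents=True, exist_ok=True)
        for i in range(n_per_class):
            patch = generate_patch(code, params, index=i)
            name = uuid.UUID(bytes=rng.bytes(16), version=4)
            Image.fromarray(patch).save(d / f"{name}.png")
        counts[code] = n_per_class
    return counts


def read_patch_dataset(root: str | Path):
    """Read a class-folder patch dataset.

    Returns (patches, labels, counts): a list of (H, W, 3) uint8 arrays,
    integer class indices, and a per-class count report.  Unknown class
    directories are an error; non-image files are skipped with a
    warning; empty class directories get a warning and count 0.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    patches, labels = [], []
    counts = {c: 0 for c in CLASS_CODES}
    for d in sorted(p for p in root.iterdir() if p.is_dir()):
        if d.name not in CLASS_CODES:
            raise ValueError(
                f"unknown class directory {d.name!r}; valid codes are "
                f"{list(CLASS_CODES)}"
            )
        ci = CLASS_CODES.index(d.name)
        files = sorted(d.iterdir())
        for f in files:
            if f.suffix.lower() not in _IMAGE_SUFFIXES:
                logger.warning("skipping non-image file %s", f)
                continue
            patches.append(np.asarray(Image.open(f).convert("RGB")))
            labels.append(ci)
            counts[d.name] += 1
        if counts[d.name] == 0:
            logger.warning("class directory %s is empty", d)
    return patches, np.asarray(labels, dtype=int), counts


# ---------------------------------------------------------------------------
# regions


def write_region(path_image: str | Path, path_mask: str | Path,
                 composition: dict, params: TextureParams | None = None,
                 index: int = 0, size: int = 1500) -> None:
    """Synthesize a region and write image + class-index mask PNGs."""
    image, mask = generate_region(composition, params, index=index, size=size)
    Image.fromarray(image).save(path_image)
    Image.fromarray(mask, mode="L").save(path_mask)


def read_region(path_image: str | Path):
    return np.asarray(Image.open(path_image).convert("RGB"))


def read_mask(path_mask: str | Path):
    return np.asarray(Image.open(path_mask).convert("L"))


# ---------------------------------------------------------------------------
# clinical tables


def read_clinical_table(path: str | Path) -> tuple[pd.DataFrame, int]:
    """Read and validate a clinical CSV.

    Requires patient_id, stage, sex, age, time_OS, event_OS.  Rows with
    missing required endpoint fields are dropped and counted — never
    imputed.  Optional endpoint/comparator columns are kept when
    present.  Returns (table, n_dropped).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing required column(s): {missing}")

    before = len(df)
    df = df.dropna(subset=["patient_id", "stage", "sex", "age",
                           "time_OS", "event_OS"])
    n_dropped = before - len(df)
    if n_dropped:
        logger.info("dropped %d rows with missing required fields", n_dropped)

    df = df.astype({"stage": int, "sex": int, "age": float,
                    "time_OS": float, "event_OS": int})
    if not df["stage"].isin([1, 2, 3, 4]).all():
        bad = sorted(set(df["stage"]) - {1, 2, 3, 4})
        raise ValueError(f"stage out of range: {bad} (must be 1-4)")
    if not df["sex"].isin([0, 1]).all():
        raise ValueError("sex must be coded 0 (female) / 1 (male)")
    if (df["time_OS"] <= 0).any():
        raise ValueError("survival times must be > 0")

    keep = [c for c in df.columns
            if c in REQUIRED_CLINICAL_COLUMNS + _OPTIONAL_CLINICAL_COLUMNS
            or c in ACTIVATION_COLUMNS]
    return df[keep].reset_index(drop=True), n_dropped


def write_activation_table(path: str | Path, rows: pd.DataFrame) -> None:
    """Write a per-region or pooled per-patient activation CSV."""
    rows.to_csv(path, index=False, float_format="%.10g")


def read_activation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ACTIVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"activation table missing column(s): {missing}")
    return df
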