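"""Image-set loading, blank-frame cleaning and feature-table I/O.

The pipeline moves labeled 2-D grayscale MRI slices (one folder per class,
or NIfTI volumes sliced along the last axis) into model-ready tensors, and
passes feature matrices between stages as CSV tables with a ``label`` column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}
NIFTI_EXTENSIONS = (".nii", ".nii.gz")

#: per-channel mean/std used by ImageNet-pretrained backbones
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


class DataError(ValueError):
    """Raised for malformed inputs (missing roots, bad tables, degenerate images)."""


@dataclass
class LabeledImage:
    """A single grayscale (H×W) or RGB (H×W×3) slice with its class label."""

    pixels: np.ndarray
    label: str
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim not in (2, 3):
            raise DataError(f"image {self.source_id!r}: expected 2-D or 3-D pixels, "
                            f"got ndim={self.pixels.ndim}")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise DataError(f"image {self.source_id!r}: 3-D pixels must have 3 channels")
        if min(self.pixels.shape[:2]) < 1:
            raise DataError(f"image {self.source_id!r}: zero-area image")
        if not np.all(np.isfinite(self.pixels)):
            raise DataError(f"image {self.source_id!r}: non-finite intensities")


@dataclass
class LabeledImageSet:
    images: list[LabeledImage] = field(default_factory=list)
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for im in self.images:
            if im.label not in self.classes:
                raise DataError(f"label {im.label!r} of {im.source_id!r} "
                                f"not in class list {self.classes}")

    def __len__(self) -> int:
        return len(self.images)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for im in self.images:
            counts[im.label] += 1
        return counts


@dataclass
class FeatureMatrix:
    """N×d feature matrix with per-row labels; the currency between stages."""

    X: np.ndarray
    y: np.ndarray
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y)
        self.feature_ids = list(self.feature_ids)
        if self.X.ndim != 2:
            raise DataError("X must be 2-D")
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise DataError("feature matrix contains NaN/Inf")
        if self.X.shape[0] != self.y.shape[0]:
            raise DataError(f"row/label mismatch: {self.X.shape[0]} rows, "
                            f"{self.y.shape[0]} labels")
        if self.X.shape[1] != len(self.feature_ids):
            raise DataError(f"{self.X.shape[1]} columns but "
                            f"{len(self.feature_ids)} feature_ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise DataError("feature_ids are not unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> list:
        return sorted(set(self.y.tolist()))


# ---------------------------------------------------------------------------
# image loading
# ---------------------------------------------------------------------------

def _load_one_image(path: Path, label: str) -> LabeledImage:
    with Image.open(path) as img:
        if img.mode in ("L", "I", "I;16", "F"):
            arr = np.asarray(img.convert("F"), dtype=float)
        elif img.mode in ("RGB", "RGBA", "P"):
            arr = np.asarray(img.convert("RGB"), dtype=float)
        else:
            arr = np.asarray(img.convert("F"), dtype=float)
    return LabeledImage(pixels=arr, label=label, source_id=str(path))


def _nifti_slices(path: Path, label: str) -> list[LabeledImage]:
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
    if vol.ndim == 2:
        vol = vol[:, :, None]
    if vol.ndim != 3:
        raise DataError(f"{path}: expected a 2-D or 3-D NIfTI volume, got ndim={vol.ndim}")
    out = []
    for k in range(vol.shape[-1]):  # axial slices along the last axis, 0-based index
        out.append(LabeledImage(pixels=vol[:, :, k], label=label,
                                source_id=f"{path}#slice{k}"))
    return out


def load_image_dataset(root: str | Path,
                       layout: str = "per-class-folders",
                       classes: Sequence[str] | None = None) -> LabeledImageSet:
    """Load a labeled image set from ``root``.

    ``layout='per-class-folders'`` expects one subfolder per class holding
    PNG/JPEG files; ``layout='nifti-volumes'`` expects per-class subfolders of
    ``.nii``/``.nii.gz`` volumes, each expanded into axial slices.  Ordering is
    deterministic (lexicographic by path).  Unreadable files are logged and
    skipped; their count is reported in the log.
    """
    root = Path(root)
    if not root.is_dir():
        raise DataError(f"dataset root {root} does not exist")
    if layout not in ("per-class-folders", "nifti-volumes"):
        raise DataError(f"unrecognized layout {layout!r}")

    if classes is None:
        classes = sorted(p.name for p in root.iterdir() if p.is_dir())
    classes = list(classes)

    images: list[LabeledImage] = []
    skipped = 0
    for cls in classes:
        cls_dir = root / cls
        if not cls_dir.is_dir():
            logger.warning("class folder %s missing; class kept with 0 images", cls_dir)
            continue
        for path in sorted(cls_dir.rglob("*")):
            if not path.is_file():
                continue
            name = path.name.lower()
            try:
                if layout == "per-class-folders":
                    if path.suffix.lower() in IMAGE_EXTENSIONS:
                        images.append(_load_one_image(path, cls))
                else:
                    if name.endswith(NIFTI_EXTENSIONS):
                        images.extend(_nifti_slices(path, cls))
            except (OSError, DataError) as exc:
                skipped += 1
                logger.warning("skipping unreadable file %s: %s", path, exc)

    result = LabeledImageSet(images=images, classes=classes)
    logger.info("loaded %d images (%d skipped) from %s: %s",
                len(result), skipped, root, result.class_counts())
    return result


def filter_blank_images(image_set: LabeledImageSet,
                        max_intensity_threshold: float = 0.0
                        ) -> tuple[LabeledImageSet, int]:
    """Drop frames whose maximum intensity is ≤ threshold (blank slices).

    The default threshold 0 removes strictly all-zero frames — the "totally
    black" slices that carry no anatomy.  Survivor ordering is preserved and
    the removed count is returned.  Idempotent.
    """
    if max_intensity_threshold < 0:
        raise DataError("threshold must be >= 0")
    kept = [im for im in image_set.images
            if float(np.max(im.pixels)) > max_intensity_threshold]
    removed = len(image_set) - len(kept)
    if removed:
        logger.info("removed %d blank image(s) at threshold %g",
                    removed, max_intensity_threshold)
    return LabeledImageSet(images=kept, classes=list(image_set.classes)), removed


def to_model_input(image: LabeledImage,
                   target_size: tuple[int, int] = (224, 224),
                   normalization: str = "unit") -> np.ndarray:
    """Convert a slice to a ``target_size×3`` float array for the backbone.

    Grayscale inputs are replicated across three channels *before*
    normalization; resizing is deterministic bilinear.  Schemes:

    - ``unit``: divide by 255 (scale-to-[0,1])
    - ``imagenet``: scale to [0,1] then subtract/divide the ImageNet
      per-channel mean/std
    - ``none``: raw intensities
    """
    arr = image.pixels
    if arr.size == 0 or min(arr.shape[:2]) < 1:
        raise DataError(f"image {image.source_id!r}: degenerate 0-area image")
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)

    h, w = target_size
    if arr.shape[:2] != (h, w):
        chans = [
            np.asarray(Image.fromarray(arr[:, :, c].astype(np.float32), mode="F")
                       .resize((w, h), Image.BILINEAR))
            for c in range(3)
        ]
        arr = np.stack(chans, axis=2).astype(float)

    if normalization == "unit":
        arr = arr / 255.0
    elif normalization == "imagenet":
        arr = (arr / 255.0 - IMAGENET_MEAN) / IMAGENET_STD
    elif normalization != "none":
        raise DataError(f"unknown normalization scheme {normalization!r}")
    return arr


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

LABEL_COLUMN = "label"


def write_feature_table(fm: FeatureMatrix, path: str | Path) -> Path:
    """Write a FeatureMatrix as CSV (or Parquet for ``.parquet`` paths).

    The header carries the feature ids; labels live in a ``label`` column.
    """
    path = Path(path)
    df = pd.DataFrame(fm.X, columns=fm.feature_ids)
    df.insert(0, LABEL_COLUMN, fm.y)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    if not path.exists():
        raise DataError(f"feature table {path} does not exist")
    try:
        if path.suffix == ".parquet":
            df = pd.read_parquet(path)
        else:
            df = pd.read_csv(path)
    except Exception as exc:  # ragged rows, encoding failures, ...
        raise DataError(f"cannot parse feature table {path}: {exc}") from exc

    if LABEL_COLUMN not in df.columns:
        raise DataError(f"{path}: missing required {LABEL_COLUMN!r} column")
    y = df[LABEL_COLUMN].to_numpy()
    feats = df.drop(columns=[LABEL_COLUMN])
    for col in feats.columns:
        numeric = pd.to_numeric(feats[col], errors="coerce")
        bad = numeric.isna() & feats[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(f"{path}: non-numeric feature cell in column {col!r}, "
                            f"row {row}")
        feats[col] = numeric
    if feats.isna().to_numpy().any():
        idx = int(np.flatnonzero(feats.isna().any(axis=1).to_numpy())[0])
        raise DataError(f"{path}: missing feature value in row {idx}")
    X = feats.to_numpy(dtype=float)
    if X.shape[0] == 0:
        X = X.reshape(0, len(feats.columns))
    return FeatureMatrix(X=X, y=y, feature_ids=[str(c) for c in feats.columns])
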