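"""Synthetic fixtures with planted structure.

Two generators make every pipeline stage testable without external data:

- :func:`make_feature_fixture` emulates the statistical situation wrapper
  feature selection faces after deep-feature extraction — a few columns that
  separate the classes, correlated redundant copies of them, and pure noise.
- :func:`make_image_fixture` emulates a slice dataset: per-class geometric
  blobs on a dark background, with a planted fraction of all-black frames to
  exercise the blank-image filter.

Both are pure functions of their spec (seed included) and return exact
ground truth so recovery tests never have to re-infer structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import FeatureMatrix, LabeledImage, LabeledImageSet


@dataclass
class SyntheticFeatureSpec:
    """Planted-structure feature matrix parameters.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 4 balanced classes of 50 samples, 60 columns of which 8 are
    class-informative Gaussians (class means ``class_sep`` apart in the
    informative subspace), 8 are noisy linear copies of informative columns,
    and the rest are standard-normal noise.
    """

    n_per_class: int = 50
    n_classes: int = 4
    d: int = 60
    n_informative: int = 8
    n_redundant: int = 8
    class_sep: float = 4.0
    noise_sd: float = 1.0
    redundant_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_informative + self.n_redundant > self.d:
            raise ValueError("n_informative + n_redundant must be <= d")
        if self.class_sep < 0 or self.noise_sd <= 0:
            raise ValueError("class_sep must be >= 0 and noise_sd > 0")


@dataclass
class SyntheticImageSpec:
    n_per_class: int = 10
    n_classes: int = 4
    height: int = 240
    width: int = 240
    blank_fraction: float = 0.0
    noise_sd: float = 8.0
    shape_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.blank_fraction < 1:
            raise ValueError("blank_fraction must be in [0, 1)")
        if self.n_classes < 1 or self.n_per_class < 1:
            raise ValueError("need at least one class and one image per class")


def make_feature_fixture(spec: SyntheticFeatureSpec
                         ) -> tuple[FeatureMatrix, dict[str, list[int]]]:
    """Generate the planted-structure feature matrix and its ground truth.

    Informative columns hold class-conditional Gaussians: each class gets a
    mean vector drawn on the unit sphere of the informative subspace and
    scaled to ``class_sep``, with isotropic ``noise_sd`` noise around it.
    Redundant columns are linear copies of cyclically-chosen informative
    columns plus ``redundant_noise_sd`` noise.  Remaining columns are pure
    standard-normal noise.  Returns the matrix plus the exact
    informative/redundant/noise column index sets.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_class * spec.n_classes
    informative = list(range(spec.n_informative))
    redundant = list(range(spec.n_informative,
                           spec.n_informative + spec.n_redundant))
    noise = list(range(spec.n_informative + spec.n_redundant, spec.d))

    y = np.repeat([f"class{c}" for c in range(spec.n_classes)], spec.n_per_class)

    X = np.empty((n, spec.d))
    if spec.n_informative:
        means = rng.standard_normal((spec.n_classes, spec.n_informative))
        norms = np.linalg.norm(means, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        means = means / norms * spec.class_sep
        per_class = np.repeat(means, spec.n_per_class, axis=0)
        X[:, informative] = per_class + spec.noise_sd * rng.standard_normal(
            (n, spec.n_informative))
    for j, col in enumerate(redundant):
        src = informative[j % spec.n_informative]
        X[:, col] = X[:, src] + spec.redundant_noise_sd * rng.standard_normal(n)
    if noise:
        X[:, noise] = rng.standard_normal((n, len(noise)))

    # shuffle rows so folds/holdouts are not trivially ordered by class
    order = rng.permutation(n)
    fm = FeatureMatrix(X=X[order], y=y[order],
                       feature_ids=[f"f{j}" for j in range(spec.d)])
    truth = {"informative": informative, "redundant": redundant, "noise": noise}
    return fm, truth


def _blob(h: int, w: int, cy: float, cx: float, ry: float, rx: float,
          intensity: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    return mask * intensity


def make_image_fixture(spec: SyntheticImageSpec
                       ) -> tuple[LabeledImageSet, list[str]]:
    """Generate per-class elliptical blobs on dark background, plus blanks.

    Class ``c`` gets an ellipse whose radius and eccentricity depend on ``c``
    (so a classifier can tell classes apart), jittered in position, with
    additive half-normal noise.  ``blank_fraction`` of all frames (rounded
    down, spread round-robin over classes) are emitted all-zero; their
    source ids are returned as ground truth for the blank filter.
    """
    rng = np.random.default_rng(spec.seed)
    classes = [f"class{c}" for c in range(spec.n_classes)]
    n_total = spec.n_per_class * spec.n_classes
    n_blank = int(spec.blank_fraction * n_total)

    # round-robin blank assignment: image k of class c is blank when its
    # global rank (c + k * n_classes) falls below n_blank
    images: list[LabeledImage] = []
    blank_ids: list[str] = []
    h, w = spec.height, spec.width
    for k in range(spec.n_per_class):
        for c, cls in enumerate(classes):
            source_id = f"synthetic/{cls}/img{k:04d}"
            if c + k * spec.n_classes < n_blank:
                pixels = np.zeros((h, w))
                blank_ids.append(source_id)
            else:
                base_r = 0.12 + 0.06 * c
                ecc = 1.0 + 0.35 * c
                cy = h / 2 + rng.uniform(-h * 0.08, h * 0.08)
                cx = w / 2 + rng.uniform(-w * 0.08, w * 0.08)
                pixels = _blob(h, w, cy, cx, base_r * h, base_r * w * ecc,
                               intensity=150.0 + 20.0 * c)
                pixels += np.abs(rng.standard_normal((h, w))) * spec.noise_sd
                pixels = np.clip(pixels, 0, 255)
            images.append(LabeledImage(pixels=pixels, label=cls,
                                       source_id=source_id))
    return LabeledImageSet(images=images, classes=classes), blank_ids
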