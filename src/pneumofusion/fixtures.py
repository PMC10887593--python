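"""Synthetic two-class chest-X-ray-like image fixtures and dataset I/O.

The generator emulates the directory layout of the public pediatric
chest-X-ray pneumonia collection: ``<root>/<split>/<class>/*.png`` with the
two diagnostic classes ``normal`` and ``pneumonia``.  A "normal" image is a
mid-gray field with two dark elliptical lung fields plus Gaussian noise; a
"pneumonia" image additionally carries blurred bright "opacity" blobs
planted inside the lung fields.  The construction guarantees the two classes
are separable by simple intensity statistics, which the training smoke
tests rely on, while remaining far from anatomically realistic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

CLASSES = ("normal", "pneumonia")
SPLITS = ("train", "val", "test")

# Class proportions of the source dataset: train 3875 pneumonia / 1341 normal,
# test 390/234, val 8/8.  Used to build down-scaled imbalanced fixtures.
SOURCE_SPLIT_COUNTS = {
    "train": {"pneumonia": 3875, "normal": 1341},
    "test": {"pneumonia": 390, "normal": 234},
    "val": {"pneumonia": 8, "normal": 8},
}


class DatasetStructureError(ValueError):
    """Raised when an on-disk dataset does not have the two-class layout."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic image generator.

    n_per_class: images per class in each generated split.
    image_size: side of the square image in pixels.
    opacity_count_range: inclusive (lo, hi) number of bright blobs planted
        in a pneumonia-class image.
    blob_sigma: Gaussian blur width (pixels) applied to the planted blobs.
    noise_sd: additive Gaussian pixel noise, 8-bit intensity units.
    seed: master RNG seed; identical config + seed gives bit-identical files.
    """

    n_per_class: int = 25
    image_size: int = 224
    opacity_count_range: tuple[int, int] = (2, 5)
    blob_sigma: float = 4.0
    noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 0:
            raise ValueError("n_per_class must be >= 0")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        lo, hi = self.opacity_count_range
        if not (0 < lo <= hi):
            raise ValueError("opacity_count_range must satisfy 0 < lo <= hi")
        if self.blob_sigma < 0 or self.noise_sd < 0:
            raise ValueError("blob_sigma and noise_sd must be >= 0")


@dataclass
class DatasetManifest:
    """File paths + labels for one split directory."""

    records: list[tuple[Path, str]] = field(default_factory=list)
    split: str = "train"
    skipped: list[Path] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, label in self.records:
            counts[label] = counts.get(label, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.records)

    def paths(self) -> list[Path]:
        return [p for p, _ in self.records]

    def labels(self) -> list[str]:
        return [lab for _, lab in self.records]

    def subset(self, indices) -> "DatasetManifest":
        return DatasetManifest(records=[self.records[i] for i in indices],
                               split=self.split)

    def to_csv(self, path: Path | str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "label", "split"])
            for p, lab in self.records:
                writer.writerow([str(p), lab, self.split])


# ----------------------------------------------------------------------
def _lung_mask(size: int) -> np.ndarray:
    """Boolean mask of two elliptical 'lung fields'."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64) / size
    left = ((xx - 0.32) / 0.16) ** 2 + ((yy - 0.52) / 0.30) ** 2 <= 1.0
    right = ((xx - 0.68) / 0.16) ** 2 + ((yy - 0.52) / 0.30) ** 2 <= 1.0
    return left | right


def render_sample(cfg: SyntheticConfig, label: str,
                  rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Render one uint8 grayscale image plus its planted-opacity mask.

    The mask is boolean, True where the blurred blob signal contributes
    more than 20 intensity units (all False for the "normal" class); it is
    what interpretability checks compare heatmap mass against.
    """
    size = cfg.image_size
    mask = _lung_mask(size)
    img = np.full((size, size), 150.0)
    img[mask] = 55.0
    blobs = np.zeros_like(img)
    if label == "pneumonia":
        lo, hi = cfg.opacity_count_range
        n_blobs = int(rng.integers(lo, hi + 1))
        inside_y, inside_x = np.nonzero(mask)
        for _ in range(n_blobs):
            k = int(rng.integers(0, inside_y.size))
            cy, cx = inside_y[k], inside_x[k]
            radius = float(rng.uniform(0.03, 0.08)) * size
            yy, xx = np.mgrid[0:size, 0:size]
            blobs += 140.0 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                                    / (2 * radius ** 2))
        if cfg.blob_sigma > 0:
            blobs = gaussian_filter(blobs, cfg.blob_sigma)
        blobs = blobs * mask
        img = img + blobs
    img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
    return (np.clip(np.round(img), 0, 255).astype(np.uint8),
            blobs > 20.0)


def render_image(cfg: SyntheticConfig, label: str,
                 rng: np.random.Generator) -> np.ndarray:
    """Render one uint8 grayscale image for the given class."""
    return render_sample(cfg, label, rng)[0]


def generate_synthetic_dataset(cfg: SyntheticConfig, out_dir: Path | str,
                               splits: tuple[str, ...] = SPLITS,
                               class_counts: dict[str, dict[str, int]] | None
                               = None) -> dict[str, DatasetManifest]:
    """Write a synthetic dataset under ``out_dir/<split>/<class>/``.

    By default every split gets ``cfg.n_per_class`` images per class;
    ``class_counts`` (split -> label -> count) overrides that, e.g. via
    :func:`scaled_source_counts` to mirror the source dataset's imbalance.
    Returns one manifest per split, records in sorted-path order.
    """
    out_dir = Path(out_dir)
    master = np.random.default_rng(cfg.seed)
    # one independent child seed per (split, class), drawn deterministically
    manifests: dict[str, DatasetManifest] = {}
    for split in splits:
        manifest = DatasetManifest(split=split)
        for label in CLASSES:
            n = cfg.n_per_class
            if class_counts is not None:
                n = class_counts.get(split, {}).get(label, 0)
            class_dir = out_dir / split / label
            class_dir.mkdir(parents=True, exist_ok=True)
            child = np.random.default_rng(master.integers(0, 2 ** 31))
            for i in range(n):
                img = render_image(cfg, label, child)
                path = class_dir / f"{label}_{i:04d}.png"
                Image.fromarray(img, mode="L").save(path)
                manifest.records.append((path, label))
        manifest.records.sort(key=lambda rec: rec[0])
        manifests[split] = manifest
    return manifests


def scaled_source_counts(scale: float) -> dict[str, dict[str, int]]:
    """Source-dataset class counts scaled down by ``scale`` (ceil, >=1)."""
    return {
        split: {label: max(1, int(np.ceil(count * scale)))
                for label, count in counts.items()}
        for split, counts in SOURCE_SPLIT_COUNTS.items()
    }


# ----------------------------------------------------------------------
def load_image_directory(root: Path | str,
                         split: str | None = None) -> DatasetManifest:
    """Build a manifest from one split directory with two class subdirs.

    Labels are taken from the subdirectory names; records come back in
    deterministic sorted-path order.  Files that cannot be decoded as images
    are collected in ``manifest.skipped`` rather than silently dropped.
    """
    root = Path(root)
    if not root.is_dir():
        raise DatasetStructureError(f"{root} is not a directory")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if len(class_dirs) != 2:
        raise DatasetStructureError(
            f"{root} must contain exactly 2 class subdirectories, "
            f"found {len(class_dirs)}")
    manifest = DatasetManifest(split=split or root.name)
    for class_dir in class_dirs:
        label = class_dir.name
        for path in sorted(class_dir.iterdir()):
            if not path.is_file():
                continue
            try:
                with Image.open(path) as im:
                    im.verify()
            except Exception:
                manifest.skipped.append(path)
                continue
            manifest.records.append((path, label))
    manifest.records.sort(key=lambda rec: rec[0])
    return manifest


def load_manifest_images(manifest: DatasetManifest) -> list[np.ndarray]:
    """Decode every manifest record to a grayscale uint8 array."""
    images = []
    for path, _ in manifest.records:
        with Image.open(path) as im:
            images.append(np.asarray(im.convert("L")))
    return images
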