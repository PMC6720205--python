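"""Image containers, I/O and preprocessing.

Storage domain is 8-bit grayscale ([0, 255]); the network domain is
[-1, 1] (paired with a tanh generator output).  Conventions: row-major
pixel grids, origin at the top-left, rotations counter-clockwise.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

__all__ = [
    "GrayImage",
    "LabeledImageSet",
    "load_images",
    "save_images",
    "augment_rotations",
    "resize_to_network",
    "normalize",
    "denormalize",
    "LUMA_WEIGHTS",
    "STORAGE_RANGE",
    "NETWORK_RANGE",
]

STORAGE_RANGE = (0.0, 255.0)
NETWORK_RANGE = (-1.0, 1.0)

#: ITU-R BT.601 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


@dataclass
class GrayImage:
    """A 2-D intensity grid with a declared value range."""

    pixels: np.ndarray
    value_range: tuple[float, float] = STORAGE_RANGE

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError(f"expected a non-empty 2-D grid, got shape {self.pixels.shape}")
        lo, hi = self.value_range
        if self.pixels.size and (self.pixels.min() < lo or self.pixels.max() > hi):
            raise ValueError(
                f"pixel values [{self.pixels.min()}, {self.pixels.max()}] "
                f"outside declared range [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class LabeledImageSet:
    """A list of same-sized grayscale images with one class label each.

    Labels are cell counts (1, 2 or 4); ``provenance`` records whether the
    set is phantom, real or generated.
    """

    images: list[np.ndarray] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)
    provenance: str = "real"
    masks: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("one label per image required")
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError(f"all images must share dimensions, got {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.images)

    def stack(self) -> np.ndarray:
        """All images as an (N, H, W) array."""
        return np.stack(self.images) if self.images else np.empty((0, 0, 0))

    def subset(self, label: int) -> "LabeledImageSet":
        idx = [i for i, lab in enumerate(self.labels) if lab == label]
        return LabeledImageSet(
            images=[self.images[i] for i in idx],
            labels=[label] * len(idx),
            provenance=self.provenance,
            masks=[self.masks[i] for i in idx] if self.masks is not None else None,
        )


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3) array to single-channel luma, rounded to uint8."""
    w = np.asarray(LUMA_WEIGHTS, dtype=np.float64)
    gray = rgb[..., :3].astype(np.float64) @ w
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def load_images(
    directory: str | Path,
    expected_size: int | None = None,
    manifest: str | Path | None = None,
) -> LabeledImageSet:
    """Load a directory of grayscale PNG/TIFF images.

    An optional manifest CSV with columns ``filename,label`` supplies class
    labels; files without a manifest entry get label 0 (unknown).  RGB inputs
    are converted to luma; a size mismatch against ``expected_size`` raises
    with the offending filename.
    """
    directory = Path(directory)
    labels_by_name: dict[str, int] = {}
    if manifest is not None:
        with open(manifest, newline="") as fh:
            for row in csv.DictReader(fh):
                labels_by_name[row["filename"]] = int(row["label"])

    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    if not files:
        warnings.warn(f"no images found in {directory}", stacklevel=2)
        return LabeledImageSet()

    images, labels = [], []
    for path in files:
        try:
            arr = np.asarray(Image.open(path))
        except Exception as exc:  # unreadable file: report which one
            raise OSError(f"could not read image {path.name}: {exc}") from exc
        if arr.ndim == 3:
            arr = rgb_to_gray(arr)
        arr = arr.astype(np.uint8)
        if expected_size is not None and arr.shape != (expected_size, expected_size):
            raise ValueError(
                f"{path.name}: expected {expected_size}x{expected_size}, got {arr.shape}"
            )
        images.append(arr)
        labels.append(labels_by_name.get(path.name, 0))
    return LabeledImageSet(images=images, labels=labels)


def save_images(
    imgset: LabeledImageSet,
    directory: str | Path,
    prefix: str = "img",
    manifest_name: str = "manifest.csv",
    seeds: Sequence[int] | None = None,
) -> Path:
    """Write a set as PNGs plus a ``filename,label[,seed]`` manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, lab) in enumerate(zip(imgset.images, imgset.labels)):
        name = f"{prefix}_{i:05d}.png"
        Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").save(directory / name)
        rows.append((name, lab, seeds[i] if seeds is not None else ""))
        if imgset.masks is not None:
            mask_name = f"{prefix}_{i:05d}_mask.png"
            Image.fromarray(
                (np.asarray(imgset.masks[i]) > 0).astype(np.uint8) * 255, mode="L"
            ).save(directory / mask_name)
    manifest = directory / manifest_name
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "seed"])
        writer.writerows(rows)
    return manifest


def augment_rotations(imgset: LabeledImageSet) -> LabeledImageSet:
    """Four-fold rotation augmentation (0, 90, 180, 270 degrees).

    Grid rotations of square images are exact pixel permutations, so the
    augmentation is lossless and conserves every per-image intensity
    multiset.  Output size is 4x the input; labels are preserved.
    """
    images, labels = [], []
    for img, lab in zip(imgset.images, imgset.labels):
        if img.shape[0] != img.shape[1]:
            raise ValueError(f"rotation augmentation needs square images, got {img.shape}")
        for k in range(4):
            images.append(np.rot90(img, k=k).copy())
            labels.append(lab)
    return LabeledImageSet(images=images, labels=labels, provenance=imgset.provenance)


def resize_to_network(img: np.ndarray, side: int = 200) -> np.ndarray:
    """Downscale a square image to ``side`` x ``side``.

    When the input side is an integer multiple of ``side`` the resize is an
    exact block mean (e.g. 600 -> 200 averages 3x3 blocks); other ratios fall
    back to bilinear interpolation.  Upscaling is rejected.
    """
    img = np.asarray(img)
    h, w = img.shape
    if h != w:
        raise ValueError(f"square input required, got {img.shape}")
    if side > h:
        raise ValueError(f"upscaling {h} -> {side} not supported")
    if side == h:
        return img.copy()
    out_dtype = img.dtype
    if h % side == 0:
        f = h // side
        out = img.astype(np.float64).reshape(side, f, side, f).mean(axis=(1, 3))
    else:
        from skimage.transform import resize as _sk_resize

        out = _sk_resize(img.astype(np.float64), (side, side), order=1, anti_aliasing=True)
    if np.issubdtype(out_dtype, np.integer):
        info = np.iinfo(out_dtype)
        return np.clip(np.round(out), info.min, info.max).astype(out_dtype)
    return out.astype(out_dtype)


def normalize(img: np.ndarray, src: tuple[float, float] = STORAGE_RANGE,
              dst: tuple[float, float] = NETWORK_RANGE) -> np.ndarray:
    """Affine map from the storage range to the network range (float64)."""
    (a, b), (c, d) = src, dst
    return (np.asarray(img, dtype=np.float64) - a) * ((d - c) / (b - a)) + c


def denormalize(img: np.ndarray, src: tuple[float, float] = NETWORK_RANGE,
                dst: tuple[float, float] = STORAGE_RANGE) -> np.ndarray:
    """Inverse of :func:`normalize`; clips and rounds back to uint8 storage."""
    out = normalize(img, src=src, dst=dst)
    return np.clip(np.round(out), dst[0], dst[1]).astype(np.uint8)
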