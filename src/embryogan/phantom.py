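"""Seeded phantom generator for early-embryo microscopy frames.

Real time-lapse incubator images of cleavage-stage embryos are nearly
uniform gray: a bright-rimmed circular culture-well region, one to four
translucent cells with darker membranes, a mild illumination gradient,
and sensor noise (Gaussian plus occasional salt-and-pepper pixels).  The
phantom reproduces that first- and second-order statistical structure
with parametric discs; it makes no attempt at physically based optics.
Every image is a pure function of its configuration, so identical
(config, seed) pairs give bit-identical frames, and the analytic
geometry (disc centres, radii, painted intensity levels) is emitted
alongside each image as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .imageset import LabeledImageSet

__all__ = ["PhantomConfig", "PhantomSample", "generate_phantom", "generate_phantom_truth",
           "generate_dataset", "CELL_CLASSES"]

#: Cleavage stages modeled: one-, two- and four-cell embryos.
CELL_CLASSES = (1, 2, 4)


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one phantom frame.

    All radius parameters are fractions: ``well_radius_frac`` of the image
    half-width, ``cell_radius_range`` of the well radius.  Intensities are
    8-bit units.  ``illumination_gradient`` is the peak-to-peak additive
    ramp as a fraction of full scale (uneven lamp field); set it to 0
    together with the noise terms for a piecewise-constant frame.
    """

    image_size: int = 600
    cell_count: int = 1
    well_radius_frac: float = 0.88
    cell_radius_range: tuple[float, float] = (0.18, 0.30)
    rim_contrast: float = 45.0
    noise_sigma: float = 6.0
    salt_pepper_frac: float = 0.002
    seed: int = 0
    illumination_gradient: float = 0.04
    allow_overlap: bool = True
    # painted intensity levels (8-bit), chosen for a mid-gray frame
    outside_level: float = 96.0
    background_level: float = 136.0
    ring_level: float = 205.0
    cell_delta: float = -18.0  # translucent interior relative to background

    def __post_init__(self) -> None:
        if self.cell_count not in CELL_CLASSES:
            raise ValueError(f"cell_count must be one of {CELL_CLASSES}, got {self.cell_count}")
        lo, hi = self.cell_radius_range
        for name, frac in [("well_radius_frac", self.well_radius_frac),
                           ("cell_radius_range min", lo), ("cell_radius_range max", hi),
                           ("salt_pepper_frac", self.salt_pepper_frac)]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {frac}")
        if lo > hi:
            raise ValueError("cell_radius_range must be (min, max)")
        if self.image_size < 8:
            raise ValueError("image_size too small")


@dataclass
class PhantomSample:
    """A phantom frame plus its generative ground truth."""

    image: np.ndarray                      # uint8 (H, W)
    mask: np.ndarray                       # uint8 labels 0=background, 1..k per cell
    cell_centers: list[tuple[float, float]]
    cell_radii: list[float]
    well_center: tuple[float, float]
    well_radius: float
    ring_halfwidth: float
    rim_width: float
    levels: dict = field(default_factory=dict)  # painted intensity per region


def _disc(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float, r: float) -> np.ndarray:
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def generate_phantom_truth(config: PhantomConfig) -> PhantomSample:
    """Generate one phantom frame with its ground-truth geometry."""
    rng = np.random.default_rng(config.seed)
    n = config.image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)

    half = n / 2.0
    well_r = config.well_radius_frac * half
    # small jitter of the well centre, as in hand-positioned dishes
    wc_y = half + rng.uniform(-0.02, 0.02) * n
    wc_x = half + rng.uniform(-0.02, 0.02) * n
    ring_hw = max(2.0, 0.008 * n)
    rim_w = max(2.0, 0.006 * n)

    # sample cell geometry (order fixed for determinism)
    r_lo, r_hi = (f * well_r for f in config.cell_radius_range)
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(config.cell_count):
        r = rng.uniform(r_lo, r_hi)
        for _attempt in range(500):
            # uniform over the placement disc that keeps the cell inside the well
            rho = (well_r - ring_hw - rim_w - r) * np.sqrt(rng.uniform())
            phi = rng.uniform(0, 2 * np.pi)
            cy, cx = wc_y + rho * np.sin(phi), wc_x + rho * np.cos(phi)
            if config.allow_overlap or all(
                (cy - oy) ** 2 + (cx - ox) ** 2 > (r + orad) ** 2
                for (oy, ox), orad in zip(centers, radii)
            ):
                break
        centers.append((cy, cx))
        radii.append(r)

    levels = {
        "outside": config.outside_level,
        "background": config.background_level,
        "ring": config.ring_level,
        "cell_interior": config.background_level + config.cell_delta,
        "cell_rim": config.background_level + config.cell_delta - config.rim_contrast,
    }

    img = np.full((n, n), levels["outside"], dtype=np.float64)
    d2_well = (yy - wc_y) ** 2 + (xx - wc_x) ** 2
    img[d2_well <= (well_r + ring_hw) ** 2] = levels["background"]
    ring = (d2_well >= (well_r - ring_hw) ** 2) & (d2_well <= (well_r + ring_hw) ** 2)
    img[ring] = levels["ring"]

    mask = np.zeros((n, n), dtype=np.uint8)
    for k, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        body = _disc(yy, xx, cy, cx, r)
        interior = _disc(yy, xx, cy, cx, r - rim_w)
        img[body] = levels["cell_rim"]
        img[interior] = levels["cell_interior"]
        mask[body] = k

    if config.illumination_gradient:
        tilt = rng.uniform(0, 2 * np.pi)
        ramp = ((xx - half) * np.cos(tilt) + (yy - half) * np.sin(tilt)) / n
        img += config.illumination_gradient * 255.0 * ramp

    if config.noise_sigma > 0:
        img += rng.normal(0.0, config.noise_sigma, size=img.shape)
    if config.salt_pepper_frac > 0:
        n_bad = int(round(config.salt_pepper_frac * img.size))
        if n_bad:
            flat_idx = rng.choice(img.size, size=n_bad, replace=False)
            vals = np.where(rng.uniform(size=n_bad) < 0.5, 0.0, 255.0)
            img.flat[flat_idx] = vals

    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return PhantomSample(
        image=image, mask=mask, cell_centers=centers, cell_radii=radii,
        well_center=(wc_y, wc_x), well_radius=well_r,
        ring_halfwidth=ring_hw, rim_width=rim_w, levels=levels,
    )


def generate_phantom(config: PhantomConfig) -> np.ndarray:
    """Generate one phantom frame (uint8 grid); see :func:`generate_phantom_truth`."""
    return generate_phantom_truth(config).image


def _derived_seed(base_seed: int, label: int, index: int) -> int:
    """Per-image seed split from (base_seed, class, index); independently reproducible."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(label, index))
    return int(ss.generate_state(1)[0])


def generate_dataset(
    counts: Sequence[int],
    base_seed: int = 0,
    config: PhantomConfig | None = None,
) -> LabeledImageSet:
    """Generate a labeled phantom set, ``counts`` per class in order (1, 2, 4).

    Each image is generated from a seed derived from (base_seed, class,
    index), so any subset of the dataset is reproducible on its own.
    """
    if len(counts) != len(CELL_CLASSES):
        raise ValueError(f"counts must give one entry per class {CELL_CLASSES}")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    template = config or PhantomConfig()

    images, labels, masks = [], [], []
    for label, count in zip(CELL_CLASSES, counts):
        for i in range(count):
            cfg = replace(template, cell_count=label, seed=_derived_seed(base_seed, label, i))
            sample = generate_phantom_truth(cfg)
            images.append(sample.image)
            masks.append(sample.mask)
            labels.append(label)
    return LabeledImageSet(images=images, labels=labels, provenance="phantom", masks=masks)
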