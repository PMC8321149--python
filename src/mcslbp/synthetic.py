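"""Synthetic bark-like color textures with channel-confined class structure.

Each class is an oriented binary grating (orientation, period and duty cycle
are the class identity) injected into a configurable subset of the R, G, B
channels; the remaining channels carry i.i.d. uniform noise.  Gratings mimic
the oriented micro-texture of tree bark and wood at desk scale while keeping
the LBP structure analytically predictable: the class signal lives only in
the signal channels, the phase of the grating is randomized per image (LBP
histograms are translation invariant, so phase does not leak class
information), and additive clamped Gaussian noise controls the difficulty.

Defaults emulate a small NewBarkTex-style set: 64 x 64 images, four classes
at orientations k*180/4 degrees, five images per class per subset, signal in
the R channel only, noise sigma = 8.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .color_spaces import ColorImage

SUBSETS = ("train", "validation", "test")

#: Binary grating levels (dark, bright).
_GRATING_LEVELS = (64.0, 192.0)


@dataclass(frozen=True)
class ClassPattern:
    """Oriented binary grating defining one texture class."""

    orientation_deg: float
    period: float = 6.0
    duty: float = 0.5

    def __post_init__(self) -> None:
        if self.period <= 1.0:
            raise ValueError("period must exceed one pixel")
        if not 0.0 < self.duty < 1.0:
            raise ValueError("duty cycle must lie in (0, 1)")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a generated dataset."""

    n_classes: int = 4
    images_per_class_per_subset: int = 5
    size: int = 64
    signal_channels: tuple[str, ...] = ("R",)
    noise_sigma: float = 8.0
    seed: int = 0
    patterns: tuple[ClassPattern, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.size < 16:
            raise ValueError("image size must be >= 16")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if not self.signal_channels:
            raise ValueError("at least one signal channel is required")
        for c in self.signal_channels:
            if c not in ("R", "G", "B"):
                raise ValueError(f"unknown channel {c!r}")
        if not self.patterns:
            object.__setattr__(
                self,
                "patterns",
                tuple(
                    ClassPattern(orientation_deg=180.0 * k / self.n_classes)
                    for k in range(self.n_classes)
                ),
            )
        if len(self.patterns) != self.n_classes:
            raise ValueError("one pattern per class required")


def make_texture(
    pattern: ClassPattern,
    size: int = 64,
    signal_channels: tuple[str, ...] = ("R",),
    noise_sigma: float = 8.0,
    seed: int | np.random.SeedSequence = 0,
) -> ColorImage:
    """Generate one RGB texture image of the given class pattern.

    Signal channels carry the oriented binary grating (random phase) plus
    clamped Gaussian noise; the other channels are i.i.d. uniform noise.
    """
    if not signal_channels:
        raise ValueError("at least one signal channel is required")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    theta = np.radians(pattern.orientation_deg)
    phase_offset = rng.uniform(0.0, 1.0)
    phase = (xx * np.cos(theta) + yy * np.sin(theta)) / pattern.period + phase_offset
    grating = np.where(np.mod(phase, 1.0) < pattern.duty, *_GRATING_LEVELS)
    channel_index = {"R": 0, "G": 1, "B": 2}
    pixels = np.empty((size, size, 3), dtype=np.float64)
    for name, k in channel_index.items():
        if name in signal_channels:
            noisy = grating + rng.normal(0.0, noise_sigma, grating.shape)
            pixels[:, :, k] = noisy
        else:
            pixels[:, :, k] = rng.uniform(0.0, 255.999, grating.shape)
    pixels = np.clip(np.floor(pixels + 0.5), 0, 255)
    return ColorImage(pixels.astype(np.uint8), "RGB")


def _image_seed(master: int, class_idx: int, subset: str, img_idx: int):
    return np.random.SeedSequence(
        entropy=(int(master), class_idx, SUBSETS.index(subset), img_idx)
    )


def generate_arrays(
    config: SyntheticConfig,
    subsets: tuple[str, ...] = SUBSETS,
) -> tuple[list[ColorImage], np.ndarray, np.ndarray, list[str]]:
    """Generate a dataset in memory.

    Returns (images, labels, subsets, sample_ids); labels are "class<k>".
    Per-image seeds derive deterministically from the master seed, so any
    subset can be regenerated independently and byte-identically.
    """
    images: list[ColorImage] = []
    labels: list[str] = []
    subset_tags: list[str] = []
    ids: list[str] = []
    for subset in subsets:
        if subset not in SUBSETS:
            raise ValueError(f"unknown subset {subset!r}")
        for k in range(config.n_classes):
            for i in range(config.images_per_class_per_subset):
                img = make_texture(
                    config.patterns[k],
                    size=config.size,
                    signal_channels=config.signal_channels,
                    noise_sigma=config.noise_sigma,
                    seed=_image_seed(config.seed, k, subset, i),
                )
                images.append(img)
                labels.append(f"class{k}")
                subset_tags.append(subset)
                ids.append(f"{subset}_c{k}_{i:03d}")
    return images, np.asarray(labels), np.asarray(subset_tags), ids


def make_dataset(config: SyntheticConfig, out_dir: str | Path) -> Path:
    """Write a dataset of PNG images plus a manifest CSV; returns its path.

    The manifest has columns sample_id, path, label, subset and is balanced:
    every (class, subset) cell holds ``images_per_class_per_subset`` rows.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    images, labels, subset_tags, ids = generate_arrays(config)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "path", "label", "subset"])
        for img, label, subset, sid in zip(images, labels, subset_tags, ids):
            rel = f"images/{sid}.png"
            Image.fromarray(img.pixels, mode="RGB").save(out_dir / rel)
            writer.writerow([sid, rel, label, subset])
    return manifest_path
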