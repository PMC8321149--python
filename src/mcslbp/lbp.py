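"""LBP code images, EOCLBP histograms and multi-space candidate features.

The basic LBP operator thresholds the P neighbor levels of each pixel against
the center level and sums the resulting bits with weights 2^p.  The extended
opponent-color variant (EOCLBP) applies this operator to every ordered pair of
color components (Ck, Ck'): the center level is read from Ck and the P
neighbor levels from Ck', giving nine Q-bin histograms per color space (three
within-component, six between-component).  Computed over NS color spaces the
candidate descriptor holds delta_max * NS = 9 * NS histograms, i.e.
Q * 9 * NS scalar bin features (20,736 with the nine default spaces at P=8).

Conventions: P=8 neighbors at radius R=1 on the square grid, no interpolation;
neighbor p=0 is East and the order proceeds counter-clockwise
(E, NE, N, NW, W, SW, S, SE); a neighbor equal to the center sets its bit
(s(0)=1); the R-pixel image border is excluded rather than padded; histograms
are unit-normalized so differently sized images remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .color_spaces import COLOR_SPACES, ColorImage, ColorSpaceSet, convert

#: Fixed EOCLBP pair order: within-component first, then between-component.
PAIR_ORDER: tuple[tuple[int, int], ...] = (
    (0, 0), (1, 1), (2, 2),
    (0, 1), (1, 0),
    (0, 2), (2, 0),
    (1, 2), (2, 1),
)

#: Histograms per color space (delta_max).
DELTA_MAX = len(PAIR_ORDER)

#: (row, column) offsets for p = 0..7: East, then counter-clockwise.
_NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1),
)


@dataclass(frozen=True)
class LBPParams:
    """LBP neighborhood: P neighbors at radius R; Q = 2^P histogram bins."""

    P: int = 8
    R: int = 1

    def __post_init__(self) -> None:
        if self.P < 1:
            raise ValueError("P must be >= 1")
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.P != 8:
            raise ValueError("only the basic P=8 square neighborhood is supported")

    @property
    def Q(self) -> int:
        return 2 ** self.P

    def offsets(self) -> tuple[tuple[int, int], ...]:
        return tuple((dy * self.R, dx * self.R) for dy, dx in _NEIGHBOR_OFFSETS)


def lbp_code(center: int, neighbors: np.ndarray, P: int = 8) -> int:
    """Code a single pixel: sum of 2^p over neighbors n_p >= center."""
    neighbors = np.asarray(neighbors)
    if neighbors.shape != (P,):
        raise ValueError(f"expected {P} neighbors, got shape {neighbors.shape}")
    bits = neighbors.astype(np.int64) >= int(center)
    return int(np.sum(bits * (1 << np.arange(P, dtype=np.int64))))


def lbp_code_image(
    center_plane: np.ndarray,
    neighbor_plane: np.ndarray,
    params: LBPParams = LBPParams(),
) -> np.ndarray:
    """LBP code image over the interior of a pair of component planes.

    The center level is read from ``center_plane`` and the P neighbor levels
    from ``neighbor_plane`` (the two coincide for within-component LBP).  The
    output covers the (H-2R) x (W-2R) interior; no padding is fabricated.
    """
    c = np.asarray(center_plane)
    n = np.asarray(neighbor_plane)
    if c.shape != n.shape:
        raise ValueError(f"plane shapes differ: {c.shape} vs {n.shape}")
    R = params.R
    H, W = c.shape
    if H < 2 * R + 1 or W < 2 * R + 1:
        raise ValueError(f"plane {c.shape} too small for radius {R}")
    center = c[R:H - R, R:W - R].astype(np.int16)
    codes = np.zeros(center.shape, dtype=np.uint16 if params.P > 8 else np.uint8)
    for p, (dy, dx) in enumerate(params.offsets()):
        shifted = n[R + dy:H - R + dy, R + dx:W - R + dx].astype(np.int16)
        codes |= ((shifted >= center).astype(codes.dtype) << p)
    return codes


def normalize_histogram(counts: np.ndarray) -> np.ndarray:
    """Divide a count histogram by its total so it sums to one."""
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero histogram")
    return counts / total


def eoclbp(image: ColorImage, params: LBPParams = LBPParams()) -> np.ndarray:
    """The nine EOCLBP histograms of one image, as a (9, Q) array.

    Rows follow the fixed pair order (C1,C1),(C2,C2),(C3,C3),(C1,C2),(C2,C1),
    (C1,C3),(C3,C1),(C2,C3),(C3,C2); each row is unit-normalized.
    """
    Q = params.Q
    out = np.empty((DELTA_MAX, Q), dtype=np.float64)
    for d, (k, kp) in enumerate(PAIR_ORDER):
        codes = lbp_code_image(image.component(k), image.component(kp), params)
        counts = np.bincount(codes.ravel(), minlength=Q)
        out[d] = normalize_histogram(counts)
    return out


@dataclass(frozen=True)
class BinProvenance:
    """Identity of one candidate bin feature: color space, pair, bin index."""

    space: str
    pair: tuple[int, int]
    bin: int


def feature_provenance(
    spaces: ColorSpaceSet = ColorSpaceSet(),
    params: LBPParams = LBPParams(),
) -> list[BinProvenance]:
    """Per-column provenance in (space-major, pair-minor, bin-minor) order."""
    return [
        BinProvenance(space, pair, b)
        for space in spaces.spaces
        for pair in PAIR_ORDER
        for b in range(params.Q)
    ]


def multispace_features(
    image: ColorImage,
    spaces: ColorSpaceSet = ColorSpaceSet(),
    params: LBPParams = LBPParams(),
) -> np.ndarray:
    """Full multi-space EOCLBP descriptor of one RGB image, as a flat row.

    The image is converted to each space of ``spaces`` in order; the nine
    EOCLBP histograms of each space are concatenated (space-major, pair-minor,
    bin-minor), giving Q * delta_max * NS features.
    """
    if image.space != "RGB":
        raise ValueError("multispace_features expects an RGB-coded image")
    blocks = [eoclbp(convert(image, s), params).ravel() for s in spaces.spaces]
    return np.concatenate(blocks)


@dataclass
class FeatureMatrix:
    """N samples x D candidate bin features with per-column provenance."""

    values: np.ndarray
    labels: np.ndarray
    provenance: list[BinProvenance]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("one label per sample required")
        if len(self.provenance) != self.values.shape[1]:
            raise ValueError("one provenance record per column required")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.values.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        idx = np.flatnonzero(np.asarray(mask))
        return FeatureMatrix(
            self.values[idx],
            self.labels[idx],
            self.provenance,
            [self.sample_ids[i] for i in idx],
        )


def extract_features(
    images: list[ColorImage],
    labels,
    spaces: ColorSpaceSet = ColorSpaceSet(),
    params: LBPParams = LBPParams(),
    sample_ids: list[str] | None = None,
) -> FeatureMatrix:
    """Extract the candidate FeatureMatrix from a list of RGB images."""
    if not images:
        raise ValueError("no images to extract from")
    rows = np.stack([multispace_features(im, spaces, params) for im in images])
    return FeatureMatrix(rows, np.asarray(labels), feature_provenance(spaces, params),
                         sample_ids or [])
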