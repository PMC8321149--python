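"""Color space coding of 8-bit RGB textures.

Nine color spaces are supported, spanning the four classical families used in
color texture analysis: primary (RGB, normalized rgb), luminance-chrominance
(YCbCr, (wb,rg,by)), independent-component (Ohta's I1I2I3) and perceptual
(HSV, HSI, HLS, improved HLS).  Every derived component is re-quantized to
integer levels 0..255 so that the LBP operator applies uniformly to any
component of any space.

Conventions fixed here (the literature leaves them open):

* rounding is half-away-from-zero followed by clamping to [0, 255];
* hue, natively in degrees [0, 360), is mapped linearly by H*255/360 and then
  treated as an ordinary scalar level (its circularity is ignored downstream);
* undefined hue (achromatic pixel) and undefined saturation are set to 0;
* signed chrominance components are quantized from symmetric ranges, e.g.
  (R-G)/2 over [-127.5, 127.5], so that zero chrominance maps to level 128;
* a black pixel has chromaticity r = g = b = 1/3, i.e. level 85.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The nine supported color spaces, in canonical order.
COLOR_SPACES: tuple[str, ...] = (
    "RGB",
    "rgb",
    "YCbCr",
    "wb_rg_by",
    "I1I2I3",
    "HSV",
    "HSI",
    "HLS",
    "IHLS",
)


class ColorSpaceError(ValueError):
    """Raised for an unknown color-space identifier."""


@dataclass
class ColorImage:
    """An H x W x 3 image with integer levels in [0, 255] and a space tag."""

    pixels: np.ndarray
    space: str = "RGB"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected an HxWx3 array, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 3 or self.pixels.shape[1] < 3:
            raise ValueError("image must be at least 3x3 (LBP needs an interior)")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel levels must lie in [0, 255]")
        if self.space not in COLOR_SPACES:
            raise ColorSpaceError(f"unknown color space {self.space!r}")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def component(self, k: int) -> np.ndarray:
        """Return component plane C(k+1), k in {0, 1, 2}."""
        return self.pixels[:, :, k]


@dataclass(frozen=True)
class ColorSpaceSet:
    """Ordered, duplicate-free collection of color-space identifiers."""

    spaces: tuple[str, ...] = field(default=COLOR_SPACES)

    def __post_init__(self) -> None:
        for s in self.spaces:
            if s not in COLOR_SPACES:
                raise ColorSpaceError(f"unknown color space {s!r}")
        if len(set(self.spaces)) != len(self.spaces):
            raise ValueError("duplicate color space identifiers")
        if not self.spaces:
            raise ValueError("color space set must be non-empty")

    @property
    def NS(self) -> int:
        return len(self.spaces)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def quantize_channel(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Affine map of a real-valued plane onto integer levels 0..255.

    x maps to round(255 * (x - lo) / (hi - lo)), rounded half-away-from-zero
    and clamped to [0, 255].  Monotone non-decreasing in x.
    """
    if not hi > lo:
        raise ValueError(f"require hi > lo, got lo={lo}, hi={hi}")
    values = np.asarray(values, dtype=np.float64)
    scaled = 255.0 * (values - lo) / (hi - lo)
    return np.clip(_round_half_away(scaled), 0, 255).astype(np.uint8)


def _hsv_hue_degrees(R: np.ndarray, G: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Hexcone hue in degrees [0, 360); achromatic pixels get hue 0."""
    mx = np.maximum(np.maximum(R, G), B)
    mn = np.minimum(np.minimum(R, G), B)
    d = mx - mn
    safe = np.where(d > 0, d, 1.0)
    h = np.zeros_like(R)
    h = np.where((mx == R) & (d > 0), np.mod((G - B) / safe, 6.0), h)
    h = np.where((mx == G) & (d > 0) & (mx != R), (B - R) / safe + 2.0, h)
    h = np.where((mx == B) & (d > 0) & (mx != R) & (mx != G), (R - G) / safe + 4.0, h)
    return 60.0 * h


def _quantize_hue(h_deg: np.ndarray) -> np.ndarray:
    return quantize_channel(h_deg, 0.0, 360.0)


def _to_rgb_chromaticity(R, G, B):
    total = R + G + B
    safe = np.where(total > 0, total, 1.0)
    r = np.where(total > 0, R / safe, 1.0 / 3.0)
    g = np.where(total > 0, G / safe, 1.0 / 3.0)
    b = np.where(total > 0, B / safe, 1.0 / 3.0)
    return [quantize_channel(c, 0.0, 1.0) for c in (r, g, b)]


def _to_ycbcr(R, G, B):
    # Full-range BT.601.
    Y = 0.299 * R + 0.587 * G + 0.114 * B
    Cb = 128.0 - 0.168736 * R - 0.331264 * G + 0.5 * B
    Cr = 128.0 + 0.5 * R - 0.418688 * G - 0.081312 * B
    return [quantize_channel(c, 0.0, 255.0) for c in (Y, Cb, Cr)]


def _to_wb_rg_by(R, G, B):
    wb = (R + G + B) / 3.0
    rg = (R - G) / 2.0
    by = (2.0 * B - R - G) / 4.0
    return [
        quantize_channel(wb, 0.0, 255.0),
        quantize_channel(rg, -127.5, 127.5),
        quantize_channel(by, -127.5, 127.5),
    ]


def _to_i1i2i3(R, G, B):
    i1 = (R + G + B) / 3.0
    i2 = (R - B) / 2.0
    i3 = (2.0 * G - R - B) / 4.0
    return [
        quantize_channel(i1, 0.0, 255.0),
        quantize_channel(i2, -127.5, 127.5),
        quantize_channel(i3, -127.5, 127.5),
    ]


def _to_hsv(R, G, B):
    mx = np.maximum(np.maximum(R, G), B)
    mn = np.minimum(np.minimum(R, G), B)
    d = mx - mn
    s = np.where(mx > 0, d / np.where(mx > 0, mx, 1.0), 0.0)
    return [
        _quantize_hue(_hsv_hue_degrees(R, G, B)),
        quantize_channel(s, 0.0, 1.0),
        quantize_channel(mx, 0.0, 255.0),
    ]


def _to_hls(R, G, B):
    mx = np.maximum(np.maximum(R, G), B)
    mn = np.minimum(np.minimum(R, G), B)
    d = mx - mn
    L = (mx + mn) / 2.0
    denom = np.where(L <= 127.5, mx + mn, 510.0 - mx - mn)
    s = np.where(d > 0, d / np.where(denom > 0, denom, 1.0), 0.0)
    return [
        _quantize_hue(_hsv_hue_degrees(R, G, B)),
        quantize_channel(L, 0.0, 255.0),
        quantize_channel(s, 0.0, 1.0),
    ]


def _to_hsi(R, G, B):
    I = (R + G + B) / 3.0
    mn = np.minimum(np.minimum(R, G), B)
    s = np.where(I > 0, 1.0 - mn / np.where(I > 0, I, 1.0), 0.0)
    # arccos hue; undefined (R=G=B) -> 0
    num = 0.5 * ((R - G) + (R - B))
    den = np.sqrt((R - G) ** 2 + (R - B) * (G - B))
    defined = den > 0
    theta = np.degrees(np.arccos(np.clip(num / np.where(defined, den, 1.0), -1.0, 1.0)))
    h = np.where(defined, np.where(B <= G, theta, 360.0 - theta), 0.0)
    return [
        _quantize_hue(np.mod(h, 360.0)),
        quantize_channel(s, 0.0, 1.0),
        quantize_channel(I, 0.0, 255.0),
    ]


def _to_ihls(R, G, B):
    # Hanbury's improved HLS: HSV hue, Rec.709 luminance, saturation max-min.
    mx = np.maximum(np.maximum(R, G), B)
    mn = np.minimum(np.minimum(R, G), B)
    Y = 0.2126 * R + 0.7152 * G + 0.0722 * B
    return [
        _quantize_hue(_hsv_hue_degrees(R, G, B)),
        quantize_channel(Y, 0.0, 255.0),
        quantize_channel(mx - mn, 0.0, 255.0),
    ]


_CONVERTERS = {
    "rgb": _to_rgb_chromaticity,
    "YCbCr": _to_ycbcr,
    "wb_rg_by": _to_wb_rg_by,
    "I1I2I3": _to_i1i2i3,
    "HSV": _to_hsv,
    "HSI": _to_hsi,
    "HLS": _to_hls,
    "IHLS": _to_ihls,
}


def convert(image: ColorImage, target: str) -> ColorImage:
    """Convert an RGB-coded image to ``target``, re-quantized to 0..255.

    Converting to RGB returns an identical copy.  The input must be tagged
    RGB; chained conversions through intermediate spaces are not defined.
    """
    if image.space != "RGB":
        raise ValueError(f"convert expects an RGB input, got {image.space!r}")
    if target == "RGB":
        return ColorImage(image.pixels.copy(), "RGB")
    try:
        converter = _CONVERTERS[target]
    except KeyError:
        raise ColorSpaceError(f"unknown color space {target!r}") from None
    R, G, B = (image.pixels[:, :, k].astype(np.float64) for k in range(3))
    planes = converter(R, G, B)
    return ColorImage(np.stack(planes, axis=-1), target)
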