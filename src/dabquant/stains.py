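"""Beer–Lambert colour deconvolution for H-DAB brightfield images.

A brightfield pixel records transmitted light ``I`` against an incident
(white) reference ``I0``; the optical density ``OD = -log10(I / I0)`` is
additive across chromogens, so an RGB pixel is a non-negative linear
combination of per-stain unit vectors in OD space.  This module converts
8-bit RGB images to raw per-channel OD, unmixes raw OD into stain channels
(hematoxylin, DAB, residual) by solving the 3x3 linear system, and provides
the inverse composition used by the synthetic image generator.

Conventions: base-10 optical density; intensities are floored at
``i_floor`` (default 1 count) before the logarithm so saturated black
pixels map to a finite ``od_cap = log10(I0 / i_floor)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RGBImage",
    "StainMatrix",
    "ODImage",
    "HDAB_DEFAULT",
    "rgb_to_od",
    "deconvolve",
    "compose",
]

#: Default intensity floor (counts) guarding the logarithm.
I_FLOOR = 1.0

RAW_CHANNELS = ("red_od", "green_od", "blue_od")
STAIN_CHANNELS = ("hematoxylin", "dab", "residual")


class StainConfigError(ValueError):
    """Raised for unusable stain matrices or white references."""


@dataclass
class RGBImage:
    """An 8-bit RGB brightfield image with physical pixel size.

    Parameters
    ----------
    pixels : (H, W, 3) uint8 array
    white_reference : 3 intensities of unstained background (default 255).
    pixel_size_um : physical edge length of one pixel in micrometres.
    """

    pixels: np.ndarray
    white_reference: np.ndarray = field(
        default_factory=lambda: np.array([255.0, 255.0, 255.0])
    )
    pixel_size_um: float = 0.25

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.white_reference = np.asarray(self.white_reference, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel intensities must lie in [0, 255]")
        if self.white_reference.shape != (3,):
            raise ValueError("white_reference must have 3 components")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class StainMatrix:
    """Three unit stain vectors in OD space, rows = stains.

    The default is the classical Ruifrok–Johnson H-DAB basis with the
    residual taken as the normalised cross product of the H and DAB
    vectors.  The vectors actually used by any given scanner/staining
    batch differ; they are configurable (YAML, see :mod:`dabquant.io`).
    """

    vectors: np.ndarray
    names: tuple[str, str, str] = STAIN_CHANNELS

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != (3, 3):
            raise StainConfigError("stain matrix must be 3x3 (rows = stains)")
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise StainConfigError("stain vectors must be unit length")
        if np.linalg.matrix_rank(self.vectors) < 3:
            raise StainConfigError("stain matrix is singular")

    @classmethod
    def from_unnormalized(cls, h, dab, residual=None) -> "StainMatrix":
        h = np.asarray(h, dtype=float)
        dab = np.asarray(dab, dtype=float)
        h = h / np.linalg.norm(h)
        dab = dab / np.linalg.norm(dab)
        if residual is None:
            residual = np.cross(h, dab)
        residual = np.asarray(residual, dtype=float)
        residual = residual / np.linalg.norm(residual)
        return cls(np.stack([h, dab, residual]))

    @property
    def inverse(self) -> np.ndarray:
        # unmixing matrix: raw-od row vector @ inverse -> stain amounts
        return np.linalg.inv(self.vectors)


#: Ruifrok–Johnson H-DAB stain basis (hematoxylin, DAB, residual).
HDAB_DEFAULT = StainMatrix.from_unnormalized(
    h=[0.65, 0.70, 0.29], dab=[0.27, 0.57, 0.78]
)


@dataclass
class ODImage:
    """Per-pixel optical densities, either raw RGB-OD or unmixed stain-OD."""

    channels: np.ndarray  # (H, W, C) float
    channel_names: tuple[str, ...]
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 3:
            raise ValueError("channels must be (H, W, C)")
        if self.channels.shape[2] != len(self.channel_names):
            raise ValueError("channel_names must match channel count")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[:2]

    def channel(self, name: str) -> np.ndarray:
        """Return one 2-D channel by name."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None
        return self.channels[..., idx]

    @property
    def is_stain(self) -> bool:
        return self.channel_names == STAIN_CHANNELS


def rgb_to_od(image: RGBImage, i_floor: float = I_FLOOR) -> ODImage:
    """Convert an RGB image to raw per-channel optical density.

    ``OD_c = -log10(max(I_c, i_floor) / I0_c)``.  With the default floor of
    one count the OD is capped at ``log10(I0)`` (~2.407 for I0 = 255).
    """
    if np.any(image.white_reference <= 0):
        raise StainConfigError("white_reference must be strictly positive")
    intensities = np.maximum(image.pixels.astype(float), i_floor)
    od = -np.log10(intensities / image.white_reference)
    od = np.maximum(od, 0.0)
    return ODImage(od, RAW_CHANNELS, image.pixel_size_um)


def deconvolve(od: ODImage, stains: StainMatrix = HDAB_DEFAULT) -> ODImage:
    """Unmix raw RGB-OD into stain-OD channels.

    Solves ``raw_od = stain_amounts @ M`` per pixel (M rows are the unit
    stain vectors); negative solutions are non-physical and clamped to 0.
    """
    if od.channel_names != RAW_CHANNELS:
        raise ValueError("deconvolve expects raw RGB-OD channels")
    flat = od.channels.reshape(-1, 3)
    amounts = flat @ stains.inverse
    amounts = np.maximum(amounts, 0.0)
    return ODImage(
        amounts.reshape(od.channels.shape), stains.names, od.pixel_size_um
    )


def compose(
    stain_od: ODImage,
    stains: StainMatrix = HDAB_DEFAULT,
    white_reference=(255.0, 255.0, 255.0),
    pixel_size_um: float | None = None,
) -> RGBImage:
    """Render stain-OD channels to an 8-bit RGB image (forward model).

    ``raw_od = stain_amounts @ M``; ``I = round(I0 * 10**(-raw_od))``
    clamped to [0, 255].  Inverse of :func:`deconvolve` up to 8-bit
    quantization.
    """
    if np.any(stain_od.channels < 0):
        raise ValueError("stain OD must be non-negative")
    white = np.asarray(white_reference, dtype=float)
    raw = stain_od.channels.reshape(-1, 3) @ stains.vectors
    intensities = white * np.exp(-math.log(10.0) * raw)
    # round-half-up; intensities are non-negative by construction
    pixels = (np.minimum(intensities, 255.0) + 0.5).astype(np.uint8)
    return RGBImage(
        pixels.reshape(stain_od.channels.shape),
        white_reference=white,
        pixel_size_um=pixel_size_um or stain_od.pixel_size_um,
    )
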