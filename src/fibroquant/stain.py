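"""Optical-density conversion and Sirius Red stain separation.

Brightfield intensities are converted to optical density (OD) under the
Beer-Lambert model, ``od_c = -log10(I_c / I0_c)``, and each pixel's OD
vector is decomposed onto a two-stain basis: the Sirius Red (SR) collagen
vector and a residual vector absorbing background tint.  The SR protocol
used for microtissue sections carries no hematoxylin counterstain, so a
two-stain model (collagen + residual) is sufficient; no third channel is
fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RGBImage",
    "StainProfile",
    "ODImage",
    "DEFAULT_SR_RGB",
    "default_stain_profile",
    "rgb_to_od",
    "separate_collagen",
]

#: RGB color of fully stained collagen used by the synthetic renderer over a
#: white background; its normalized OD defines the default SR stain vector.
DEFAULT_SR_RGB = (200, 60, 60)

# Intensity floor before the log: avoids infinite OD at zero pixels.
_INTENSITY_FLOOR = 1.0


@dataclass
class RGBImage:
    """An 8-bit RGB brightfield image with spatial calibration.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3)
        Integer intensities in [0, 255].
    pixel_size_um : float
        Side length of one pixel in micrometers (e.g. 0.221 for 40x scans).
    """

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) pixels, got {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("stain vector must be nonzero")
    return v / n


@dataclass
class StainProfile:
    """Two-stain OD basis: SR collagen vector plus a residual vector."""

    sr_vector: np.ndarray
    residual_vector: np.ndarray
    background_intensity: np.ndarray = field(
        default_factory=lambda: np.array([255.0, 255.0, 255.0])
    )

    def __post_init__(self) -> None:
        self.sr_vector = _unit(self.sr_vector)
        self.residual_vector = _unit(self.residual_vector)
        self.background_intensity = np.asarray(self.background_intensity, dtype=float)
        if np.any(self.background_intensity <= 0) or np.any(
            self.background_intensity > 255
        ):
            raise ValueError("background_intensity must lie in (0, 255] per channel")
        cross = np.linalg.norm(np.cross(self.sr_vector, self.residual_vector))
        if cross < 1e-8:
            raise ValueError("stain vectors are collinear; profile is degenerate")

    @property
    def basis(self) -> np.ndarray:
        """3x2 matrix whose columns are the stain vectors."""
        return np.stack([self.sr_vector, self.residual_vector], axis=1)


@dataclass
class ODImage:
    """Optical-density transform of an RGB image plus the unmixed SR channel."""

    od: np.ndarray  # (H, W, 3), dimensionless, >= 0
    pixel_size_um: float
    saturated_mask: np.ndarray  # (H, W) bool
    collagen: np.ndarray | None = None  # (H, W), filled by separate_collagen


def od_from_rgb_color(rgb, background=(255.0, 255.0, 255.0)) -> np.ndarray:
    """Optical density of a single RGB color against a background intensity."""
    rgb = np.maximum(np.asarray(rgb, dtype=float), _INTENSITY_FLOOR)
    return -np.log10(rgb / np.asarray(background, dtype=float))


def default_stain_profile(background=(255.0, 255.0, 255.0)) -> StainProfile:
    """SR vector from the synthetic render color; neutral-gray residual.

    The residual axis is the achromatic direction (equal absorbance in all
    channels); it soaks up background tint and faint nonspecific absorbance.
    """
    sr = od_from_rgb_color(DEFAULT_SR_RGB)
    residual = np.array([1.0, 1.0, 1.0])
    return StainProfile(
        sr_vector=sr, residual_vector=residual, background_intensity=background
    )


def estimate_background(image: RGBImage, percentile: float = 99.0) -> np.ndarray:
    """Per-channel background intensity I0 as a high percentile of the image."""
    flat = image.pixels.reshape(-1, 3).astype(float)
    bg = np.percentile(flat, percentile, axis=0)
    return np.maximum(bg, _INTENSITY_FLOOR)


def rgb_to_od(image: RGBImage, profile: StainProfile) -> ODImage:
    """Convert RGB intensities to per-channel optical density.

    ``od_c = -log10(max(I_c, 1) / I0_c)`` clipped below at 0.  Pixels with
    any channel at or below the intensity floor are flagged saturated: their
    OD is a lower bound, not a measurement.
    """
    pixels = np.asarray(image.pixels, dtype=float)
    i0 = profile.background_intensity
    if i0.shape != (3,):
        raise ValueError("background_intensity must have 3 channels")
    od = -np.log10(np.maximum(pixels, _INTENSITY_FLOOR) / i0)
    od = np.clip(od, 0.0, None)
    saturated = np.any(pixels <= _INTENSITY_FLOOR, axis=2)
    return ODImage(od=od, pixel_size_um=image.pixel_size_um, saturated_mask=saturated)


def separate_collagen(od_image: ODImage, profile: StainProfile) -> ODImage:
    """Unmix the SR collagen channel by per-pixel least squares.

    Each OD vector is decomposed onto {sr_vector, residual_vector}; the
    collagen channel is the SR coefficient with negative values clipped to
    zero (concentrations cannot be negative).  The input ODImage is returned
    with its ``collagen`` field filled.
    """
    basis = profile.basis  # 3x2
    pinv = np.linalg.pinv(basis)  # 2x3
    h, w = od_image.od.shape[:2]
    coeffs = od_image.od.reshape(-1, 3) @ pinv.T  # (N, 2)
    collagen = np.clip(coeffs[:, 0], 0.0, None).reshape(h, w)
    od_image.collagen = collagen
    return od_image


def invert_image(image: RGBImage) -> RGBImage:
    """Intensity inversion (255 - I), as applied to polarized-light captures."""
    return RGBImage(pixels=255 - image.pixels.astype(np.uint8), pixel_size_um=image.pixel_size_um)
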