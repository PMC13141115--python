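"""Illumination-field correction and z-projection.

Fluorescence tiles are corrected by dividing by a normalized shading
(flat-field) reference; brightfield snapshots are flattened by dividing by
a heavy Gaussian blur of themselves (the FIJI-style "Gaussian background
correction using division"); chip z-stacks are collapsed to one plane by a
plain or contrast-weighted mean along z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from mifprep.model import ImagePlane, ValidationError, ZStack

__all__ = [
    "ShadingField",
    "build_shading_field",
    "correct_shading",
    "brightfield_flatten",
    "project_weighted",
]

EPS_WEIGHT = 1e-6


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def _to_uint16(x: np.ndarray) -> np.ndarray:
    return np.clip(_round_half_up(x), 0, 65535).astype(np.uint16)


@dataclass(frozen=True)
class ShadingField:
    """A multiplicative illumination field, mean-normalized to 1.

    Dividing a tile by the field removes vignetting and other smooth
    illumination inhomogeneity while preserving the mean intensity scale.
    """

    field: np.ndarray
    source: str = "reference_image"

    def __post_init__(self) -> None:
        f = np.asarray(self.field, dtype=np.float64)
        if f.ndim != 2 or f.size == 0:
            raise ValidationError("shading field must be a nonempty 2-D raster")
        if np.any(f <= 0) or not np.all(np.isfinite(f)):
            raise ValidationError("shading field values must be finite and > 0")
        f = f / f.mean()
        object.__setattr__(self, "field", f)
        if self.source not in ("reference_image", "uniform"):
            raise ValidationError(f"unknown shading source {self.source!r}")

    @classmethod
    def uniform(cls, shape: tuple[int, int]) -> "ShadingField":
        return cls(np.ones(shape), source="uniform")

    @property
    def shape(self) -> tuple[int, int]:
        return self.field.shape


def build_shading_field(
    reference: ImagePlane, floor_quantile: float = 0.01
) -> ShadingField:
    """Turn a shading-reference image into a correction field.

    The reference is floored at its ``floor_quantile`` intensity (so dark
    or dead pixels never cause division blow-ups) and normalized to unit
    mean.
    """
    if not 0 < floor_quantile < 0.5:
        raise ValidationError("floor_quantile must lie in (0, 0.5)")
    ref = reference.astype_float()
    if ref.max() == 0:
        raise ValidationError("shading reference is identically zero")
    q = np.quantile(ref, floor_quantile)
    if q <= 0:
        positive = ref[ref > 0]
        q = positive.min()
    floored = np.maximum(ref, q)
    return ShadingField(floored / floored.mean(), source="reference_image")


def correct_shading(tile: ImagePlane, field: ShadingField) -> ImagePlane:
    """Divide a tile by the shading field (flat-field correction)."""
    if tile.shape != field.shape:
        raise ValidationError(
            f"tile shape {tile.shape} does not match field shape {field.shape}"
        )
    out = tile.astype_float() / field.field
    return tile.with_pixels(_to_uint16(out))


def brightfield_flatten(image: ImagePlane, sigma_px: float = 50.0) -> ImagePlane:
    """Flatten a brightfield image by Gaussian division.

    ``output = image / G_sigma(image) * mean(image)`` with reflective
    boundaries; sigma must be well above the cellular texture scale so that
    the blur captures only the illumination profile.
    """
    if sigma_px < 1:
        raise ValidationError("sigma_px must be >= 1")
    img = image.astype_float()
    mean = img.mean()
    if mean == 0:
        raise ValidationError("cannot flatten an all-zero image")
    blur = ndi.gaussian_filter(img, sigma=sigma_px, mode="reflect")
    blur = np.maximum(blur, np.finfo(np.float64).tiny)
    return image.with_pixels(_to_uint16(img / blur * mean))


def project_weighted(stack: ZStack, mode: str = "weighted_contrast") -> ImagePlane:
    """Collapse a z-stack to a single plane.

    ``mode="mean"`` is the per-pixel arithmetic mean over z.
    ``mode="weighted_contrast"`` weights each slice per pixel by
    ``EPS + local variance`` in a 3x3 window, so in-focus structure
    dominates the projection — the use case is cells adhering to a chip
    membrane at varying focal depth.
    """
    if mode not in ("mean", "weighted_contrast"):
        raise ValidationError(f"unknown projection mode {mode!r}")
    data = np.stack([s.astype_float() for s in stack.slices])
    if mode == "mean":
        proj = data.mean(axis=0)
    else:
        weights = np.empty_like(data)
        for z in range(data.shape[0]):
            m = ndi.uniform_filter(data[z], size=3, mode="reflect")
            m2 = ndi.uniform_filter(data[z] ** 2, size=3, mode="reflect")
            weights[z] = EPS_WEIGHT + np.maximum(m2 - m**2, 0.0)
        weights /= weights.sum(axis=0, keepdims=True)
        proj = (weights * data).sum(axis=0)
    return ImagePlane(_to_uint16(proj), pixel_size=stack.slices[0].pixel_size)
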