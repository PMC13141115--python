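"""Diffuse-background and autofluorescence removal.

The rolling-ball background is the upper envelope of a ball of radius
``radius_px`` rolled beneath the intensity surface — equivalently the
grayscale opening of the plane with the spherical cap as a non-flat
structuring element.  Subtracting it removes haze that varies on scales
larger than the ball while leaving objects smaller than the ball intact.
For large radii the classical shrink/roll/expand strategy keeps the cost
bounded; the exact (non-downscaled) mode is always available.

Autofluorescence is handled the way sequential-mIF practitioners do at the
bench: the specimen's endogenous fluorescence is acquired as a channel of
its own and subtracted (optionally auto-scaled) from affected marker
channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

from mifprep.model import ImagePlane, ValidationError

__all__ = [
    "BallElement",
    "rolling_ball_background",
    "subtract_background",
    "subtract_autofluorescence",
]

DOWNSCALE_THRESHOLD = 16


@dataclass(frozen=True)
class BallElement:
    """Spherical-cap structuring element of a rolling ball.

    ``profile[y, x] = sqrt(r^2 - y^2 - x^2)`` over the disk ``y^2 + x^2 <=
    r^2``; ``footprint`` marks the disk.
    """

    radius_px: int
    profile: np.ndarray
    footprint: np.ndarray

    @classmethod
    def build(cls, radius_px: int) -> "BallElement":
        if radius_px < 1:
            raise ValidationError("ball radius must be >= 1 px")
        r = int(radius_px)
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        d2 = yy**2 + xx**2
        footprint = d2 <= r * r
        profile = np.where(footprint, np.sqrt(np.maximum(r * r - d2, 0.0)), 0.0)
        return cls(radius_px=r, profile=profile, footprint=footprint)


def _opening(arr: np.ndarray, ball: BallElement) -> np.ndarray:
    eroded = ndi.grey_erosion(
        arr, footprint=ball.footprint, structure=ball.profile, mode="nearest"
    )
    return ndi.grey_dilation(
        eroded, footprint=ball.footprint, structure=ball.profile, mode="nearest"
    )


def rolling_ball_background(
    plane: ImagePlane, radius_px: int, exact: bool = False
) -> ImagePlane:
    """Estimate the rolling-ball background of a plane.

    ``exact=True`` performs the opening at full resolution.  Otherwise,
    for ``radius_px > 16`` the plane is downscaled by ``ceil(radius/16)``,
    rolled at the reduced radius and upsampled back — the classical
    large-radius strategy.  The background never exceeds the plane.
    """
    if radius_px < 1:
        raise ValidationError("radius_px must be >= 1")
    arr = plane.astype_float()
    factor = int(np.ceil(radius_px / DOWNSCALE_THRESHOLD))
    if exact or factor <= 1:
        bg = _opening(arr, BallElement.build(radius_px))
    else:
        small_shape = (
            max(1, int(np.ceil(arr.shape[0] / factor))),
            max(1, int(np.ceil(arr.shape[1] / factor))),
        )
        small = resize(arr, small_shape, order=1, anti_aliasing=True, mode="edge")
        small_bg = _opening(small, BallElement.build(max(1, round(radius_px / factor))))
        bg = resize(small_bg, arr.shape, order=1, mode="edge")
        bg = np.minimum(bg, arr)  # envelope property must survive resampling
    return plane.with_pixels(np.clip(np.floor(bg + 0.5), 0, 65535).astype(np.uint16))


def subtract_background(
    plane: ImagePlane, radius_px: int = 50, exact: bool = False
) -> ImagePlane:
    """Subtract the rolling-ball background, flooring at zero."""
    bg = rolling_ball_background(plane, radius_px, exact=exact)
    out = plane.pixels.astype(np.int32) - bg.pixels.astype(np.int32)
    return plane.with_pixels(np.clip(out, 0, 65535).astype(np.uint16))


def estimate_af_scale(marker: np.ndarray, af: np.ndarray) -> float:
    """Least-squares slope of marker on autofluorescence over signal-poor
    pixels (below the marker's median), clipped to [0, 3]."""
    sel = marker < np.percentile(marker, 50)
    a, m = af[sel], marker[sel]
    denom = float(np.dot(a, a))
    if denom == 0:
        return 0.0
    return float(np.clip(np.dot(a, m) / denom, 0.0, 3.0))


def subtract_autofluorescence(
    marker: ImagePlane, af: ImagePlane, scale: float | str = "auto"
) -> tuple[ImagePlane, float]:
    """Subtract a scaled autofluorescence channel from a marker channel.

    ``scale="auto"`` estimates the scale from signal-poor pixels so that
    genuine marker signal does not bias it.  Returns the corrected plane
    and the scale actually used.
    """
    if marker.shape != af.shape:
        raise ValidationError(
            f"marker shape {marker.shape} does not match AF shape {af.shape}"
        )
    m = marker.astype_float()
    a = af.astype_float()
    if scale == "auto":
        s = estimate_af_scale(m, a)
    else:
        s = float(scale)
        if s < 0:
            raise ValidationError("AF scale must be nonnegative")
    out = np.clip(np.floor(m - s * a + 0.5), 0, 65535).astype(np.uint16)
    return marker.with_pixels(out), s
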