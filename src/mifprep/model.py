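"""Core in-memory types of the pipeline.

Conventions used everywhere in the package:

* rasters are 2-D ``numpy`` arrays of unsigned 16-bit intensities,
  coordinates are (row, col), 0-based, origin top-left, y grows downward;
* intensities live in [0, 65535]; every operation clips before casting;
* cycles are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

ROLES = ("nuclear", "marker", "autofluorescence", "brightfield")

__all__ = [
    "ImagePlane",
    "ZStack",
    "ChannelRecord",
    "TileGrid",
    "HyperStack",
    "ValidationError",
    "as_plane",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass(frozen=True)
class ImagePlane:
    """A single 2-D unsigned-16-bit intensity raster.

    Parameters
    ----------
    pixels
        2-D ``uint16`` array (anything castable without loss is accepted).
    pixel_size
        Micrometres per pixel, optional, must be positive when given.
    """

    pixels: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError(
                f"ImagePlane requires a nonempty 2-D raster, got shape {px.shape}"
            )
        if px.dtype != np.uint16:
            if np.issubdtype(px.dtype, np.floating):
                if np.any(~np.isfinite(px)):
                    raise ValidationError("ImagePlane pixels must be finite")
            arr = np.asarray(px)
            if arr.min() < 0 or arr.max() > 65535:
                raise ValidationError("ImagePlane intensities must lie in [0, 65535]")
            px = arr.astype(np.uint16)
        object.__setattr__(self, "pixels", px)
        if self.pixel_size is not None and not self.pixel_size > 0:
            raise ValidationError("pixel_size must be > 0")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)

    def with_pixels(self, pixels: np.ndarray) -> "ImagePlane":
        return replace(self, pixels=pixels)

    def __eq__(self, other: object) -> bool:  # pixel-wise equality
        if not isinstance(other, ImagePlane):
            return NotImplemented
        return (
            self.pixels.shape == other.pixels.shape
            and bool(np.array_equal(self.pixels, other.pixels))
            and self.pixel_size == other.pixel_size
        )


def as_plane(obj: "ImagePlane | np.ndarray", pixel_size: float | None = None) -> ImagePlane:
    """Coerce a raw array into an :class:`ImagePlane` (arrays are clipped/rounded)."""
    if isinstance(obj, ImagePlane):
        return obj
    arr = np.asarray(obj, dtype=np.float64)
    arr = np.clip(np.floor(arr + 0.5), 0, 65535).astype(np.uint16)
    return ImagePlane(arr, pixel_size=pixel_size)


@dataclass(frozen=True)
class ZStack:
    """An ordered stack of same-shaped planes along the optical axis."""

    slices: tuple[ImagePlane, ...]
    z_spacing: float | None = None

    def __post_init__(self) -> None:
        slices = tuple(self.slices)
        if len(slices) < 1:
            raise ValidationError("ZStack needs at least one slice")
        shape = slices[0].shape
        for k, s in enumerate(slices):
            if s.shape != shape:
                raise ValidationError(
                    f"slice {k} shape {s.shape} differs from {shape}"
                )
        object.__setattr__(self, "slices", slices)

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape


@dataclass(frozen=True)
class ChannelRecord:
    """Bookkeeping for one acquired channel of one cycle.

    ``role`` distinguishes the per-cycle nuclear (DAPI) reference from
    marker, autofluorescence and brightfield channels; every cycle of a
    manifest must carry exactly one nuclear record.
    """

    cycle: int
    channel_name: str
    marker: str
    fluorophore: str
    exposure_ms: float
    role: str

    def __post_init__(self) -> None:
        if int(self.cycle) < 1:
            raise ValidationError(f"cycle must be >= 1, got {self.cycle}")
        object.__setattr__(self, "cycle", int(self.cycle))
        if not float(self.exposure_ms) > 0:
            raise ValidationError(
                f"exposure_ms must be > 0, got {self.exposure_ms}"
            )
        object.__setattr__(self, "exposure_ms", float(self.exposure_ms))
        if self.role not in ROLES:
            raise ValidationError(
                f"role {self.role!r} not in {sorted(ROLES)}"
            )


def validate_manifest(records: Sequence[ChannelRecord]) -> list[ChannelRecord]:
    """Check manifest-level invariants (uniqueness, one nuclear per cycle)."""
    records = list(records)
    seen: set[tuple[int, str]] = set()
    for rec in records:
        key = (rec.cycle, rec.channel_name)
        if key in seen:
            raise ValidationError(
                f"duplicate (cycle, channel_name) = {key} in manifest"
            )
        seen.add(key)
    cycles = sorted({r.cycle for r in records})
    for cyc in cycles:
        n_nuc = sum(1 for r in records if r.cycle == cyc and r.role == "nuclear")
        if n_nuc == 0:
            raise ValidationError(f"cycle {cyc}: no nuclear channel")
        if n_nuc > 1:
            raise ValidationError(f"cycle {cyc}: {n_nuc} nuclear channels (need exactly 1)")
    return records


@dataclass(frozen=True)
class TileGrid:
    """Geometry of a rectangular tile scan.

    ``overlap_fraction`` is the fraction of each tile shared with its
    neighbour; acquisition order is row-major or snake-by-row (odd rows
    acquired right-to-left).
    """

    rows: int
    cols: int
    tile_shape: tuple[int, int]
    overlap_fraction: float = 0.1
    acquisition_order: str = "row_major"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValidationError("grid needs rows >= 1 and cols >= 1")
        if not (0 <= self.overlap_fraction < 0.5):
            raise ValidationError(
                f"overlap_fraction must lie in [0, 0.5), got {self.overlap_fraction}"
            )
        if self.acquisition_order not in ("row_major", "snake_by_row"):
            raise ValidationError(
                f"unknown acquisition_order {self.acquisition_order!r}"
            )
        h, w = self.tile_shape
        if h < 1 or w < 1:
            raise ValidationError("tile_shape must be positive")
        object.__setattr__(self, "tile_shape", (int(h), int(w)))

    @property
    def n_tiles(self) -> int:
        return self.rows * self.cols

    def step(self) -> tuple[int, int]:
        """Nominal origin-to-origin spacing (row, col) in pixels."""
        h, w = self.tile_shape
        return (
            int(round(h * (1.0 - self.overlap_fraction))),
            int(round(w * (1.0 - self.overlap_fraction))),
        )

    def mosaic_shape(self) -> tuple[int, int]:
        """Nominal extent of the stitched canvas."""
        sh, sw = self.step()
        h, w = self.tile_shape
        return ((self.rows - 1) * sh + h, (self.cols - 1) * sw + w)

    def acquisition_to_grid(self, index: int) -> tuple[int, int]:
        """Map acquisition index (0-based) to its grid cell (row, col)."""
        if not 0 <= index < self.n_tiles:
            raise ValidationError(f"tile index {index} out of range")
        r, c = divmod(index, self.cols)
        if self.acquisition_order == "snake_by_row" and r % 2 == 1:
            c = self.cols - 1 - c
        return (r, c)


@dataclass
class HyperStack:
    """The registered, ordered collection of planes across cycles and channels.

    ``planes[i]`` is described by ``records[i]``; planes are cycle-major
    (all channels of cycle 1, then cycle 2, ...).
    """

    planes: list[ImagePlane]
    records: list[ChannelRecord]
    registered: bool = False
    pixel_size: float | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.planes) != len(self.records):
            raise ValidationError(
                f"{len(self.planes)} planes but {len(self.records)} records"
            )
        if self.planes:
            shape = self.planes[0].shape
            for plane, rec in zip(self.planes, self.records):
                if plane.shape != shape:
                    raise ValidationError(
                        f"cycle {rec.cycle} / {rec.channel_name}: "
                        f"shape {plane.shape} ≠ {shape}"
                    )
            cycles = [r.cycle for r in self.records]
            if any(b < a for a, b in zip(cycles, cycles[1:])):
                raise ValidationError("cycles must appear in nondecreasing order")

    def __len__(self) -> int:
        return len(self.planes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes[0].shape

    @property
    def cycles(self) -> list[int]:
        return sorted({r.cycle for r in self.records})

    def planes_of_cycle(self, cycle: int) -> list[tuple[int, ChannelRecord, ImagePlane]]:
        """(index, record, plane) triples of one cycle, in stack order."""
        return [
            (i, rec, plane)
            for i, (rec, plane) in enumerate(zip(self.records, self.planes))
            if rec.cycle == cycle
        ]

    def nuclear_plane(self, cycle: int) -> ImagePlane:
        for _, rec, plane in self.planes_of_cycle(cycle):
            if rec.role == "nuclear":
                return plane
        raise ValidationError(f"cycle {cycle}: no nuclear plane in stack")

    def find(self, cycle: int, marker: str) -> ImagePlane:
        for _, rec, plane in self.planes_of_cycle(cycle):
            if rec.marker == marker:
                return plane
        raise KeyError(f"no plane for cycle {cycle}, marker {marker!r}")


def iter_cycles(records: Iterable[ChannelRecord]) -> list[int]:
    return sorted({r.cycle for r in records})
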