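"""Reading and writing the pipeline's on-disk formats.

Single planes and stacks travel as grayscale TIFF (uncompressed or
losslessly compressed); the channel manifest is a six-column CSV; a
hyperstack is a multi-page TIFF plus a JSON sidecar carrying the manifest
and registration state.  8-bit input is promoted to 16-bit by the exact
factor 257 (so 255 maps to 65535).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from mifprep.model import (
    ChannelRecord,
    HyperStack,
    ImagePlane,
    ValidationError,
    ZStack,
    validate_manifest,
)

__all__ = [
    "read_plane",
    "write_plane",
    "read_zstack",
    "read_manifest",
    "write_manifest",
    "assemble_hyperstack",
    "write_hyperstack",
    "read_hyperstack",
    "FormatError",
]

MANIFEST_COLUMNS = ["cycle", "channel_name", "marker", "fluorophore", "exposure_ms", "role"]


class FormatError(ValueError):
    """Raised for files whose layout the pipeline does not accept."""


def _promote(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise FormatError(f"{path}: RGB(A) image with samples={arr.shape[-1]}; expected grayscale")
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D plane, got ndim={arr.ndim}")
    if arr.dtype == np.uint8:
        return arr.astype(np.uint16) * np.uint16(257)
    if arr.dtype == np.uint16:
        return arr
    if np.issubdtype(arr.dtype, np.integer):
        if arr.min() < 0 or arr.max() > 65535:
            raise FormatError(f"{path}: integer intensities out of [0, 65535]")
        return arr.astype(np.uint16)
    raise FormatError(f"{path}: unsupported dtype {arr.dtype}")


def read_plane(path: str | Path, pixel_size: float | None = None) -> ImagePlane:
    """Read one grayscale TIFF plane; 8-bit content is promoted by x257."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    with tifffile.TiffFile(path) as tif:
        n_pages = len(tif.pages)
        if n_pages != 1:
            raise FormatError(f"{path}: expected a single plane, found pages={n_pages}")
        arr = tif.pages[0].asarray()
    return ImagePlane(_promote(arr, path), pixel_size=pixel_size)


def write_plane(plane: ImagePlane, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, plane.pixels, photometric="minisblack")


def read_zstack(path: str | Path, z_spacing: float | None = None) -> ZStack:
    """Read a multi-page TIFF as a z-stack of planes."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    with tifffile.TiffFile(path) as tif:
        planes = [ImagePlane(_promote(p.asarray(), path)) for p in tif.pages]
    return ZStack(tuple(planes), z_spacing=z_spacing)


def write_zstack(stack: ZStack, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, np.stack([s.pixels for s in stack.slices]), photometric="minisblack"
    )


def read_manifest(path: str | Path) -> list[ChannelRecord]:
    """Read and validate the channel manifest CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such manifest: {path}")
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing manifest columns {missing}")
    records = [
        ChannelRecord(
            cycle=int(row.cycle),
            channel_name=str(row.channel_name),
            marker=str(row.marker),
            fluorophore=str(row.fluorophore),
            exposure_ms=float(row.exposure_ms),
            role=str(row.role),
        )
        for row in df.itertuples(index=False)
    ]
    return validate_manifest(records)


def write_manifest(records: Sequence[ChannelRecord], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([vars(r) for r in records], columns=MANIFEST_COLUMNS).to_csv(
        path, index=False
    )


def assemble_hyperstack(
    per_cycle_stacks: Sequence[tuple[int, Sequence[ImagePlane]]],
    manifest: Sequence[ChannelRecord],
) -> HyperStack:
    """Concatenate per-cycle channel stacks into one unregistered hyperstack.

    Planes of each cycle must be supplied in that cycle's manifest row
    order; the result is cycle-major.
    """
    manifest = validate_manifest(manifest)
    by_cycle: dict[int, list[ChannelRecord]] = {}
    for rec in manifest:
        by_cycle.setdefault(rec.cycle, []).append(rec)

    supplied = {cyc: list(planes) for cyc, planes in per_cycle_stacks}
    if set(supplied) != set(by_cycle):
        raise ValidationError(
            f"cycles supplied {sorted(supplied)} do not match manifest cycles {sorted(by_cycle)}"
        )

    planes: list[ImagePlane] = []
    records: list[ChannelRecord] = []
    ref_shape: tuple[int, int] | None = None
    for cyc in sorted(by_cycle):
        recs = by_cycle[cyc]
        if len(supplied[cyc]) != len(recs):
            raise ValidationError(
                f"cycle {cyc}: {len(supplied[cyc])} planes for {len(recs)} manifest records"
            )
        for rec, plane in zip(recs, supplied[cyc]):
            if ref_shape is None:
                ref_shape = plane.shape
            if plane.shape != ref_shape:
                raise ValidationError(
                    f"cycle {cyc} / {rec.channel_name}: shape {plane.shape} ≠ {ref_shape}"
                )
            planes.append(plane)
            records.append(rec)
    return HyperStack(planes=planes, records=records, registered=False)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_hyperstack(stack: HyperStack, path: str | Path) -> None:
    """Write a hyperstack as multi-page TIFF + JSON sidecar manifest.

    Pages are cycle-major and named ``c{cycle}_{marker}``; read-back with
    :func:`read_hyperstack` reproduces pixels bit-exactly and manifest
    fields field-exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.stack([p.pixels for p in stack.planes])
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "registered": stack.registered,
        "pixel_size": stack.pixel_size,
        "pages": [
            {"name": f"c{rec.cycle}_{rec.marker}", **vars(rec)}
            for rec in stack.records
        ],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_hyperstack(path: str | Path) -> HyperStack:
    path = Path(path)
    sidecar = json.loads(_sidecar_path(path).read_text())
    with tifffile.TiffFile(path) as tif:
        arrs = [p.asarray() for p in tif.pages]
    records = [
        ChannelRecord(
            cycle=pg["cycle"],
            channel_name=pg["channel_name"],
            marker=pg["marker"],
            fluorophore=pg["fluorophore"],
            exposure_ms=pg["exposure_ms"],
            role=pg["role"],
        )
        for pg in sidecar["pages"]
    ]
    planes = [ImagePlane(_promote(a, path)) for a in arrs]
    return HyperStack(
        planes=planes,
        records=records,
        registered=bool(sidecar["registered"]),
        pixel_size=sidecar.get("pixel_size"),
    )
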