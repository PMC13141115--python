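"""Seeded, ground-truthed synthetic multi-cycle mIF acquisitions.

The generator emulates what a cyclic-immunofluorescence scanner delivers:
per-cycle, per-channel grids of 16-bit tiles with

* nuclei (soft-edged discs) whose centroids, radii and class memberships
  are the ground truth;
* membrane or nuclear-factor marker channels rendered only over member
  cells;
* a multiplicative vignette (shading field) per channel, with a matching
  shading-reference image;
* per-tile stage jitter, per-cycle whole-sample drift, per-cycle signal
  retention (stripping losses), broad background haze, autofluorescent
  debris, and — for the chip preset — a lattice of small round membrane
  pores;
* Poisson shot noise plus Gaussian read noise.

Everything derives deterministically from one master seed, so every
pipeline stage can be checked against the generating parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mifprep import io as mio
from mifprep.model import ChannelRecord, ImagePlane, TileGrid, ValidationError, ZStack

__all__ = [
    "SceneTruth",
    "make_scene",
    "render_clean_plane",
    "render_cycle",
    "render_zstack",
    "write_fixture",
]

# study-condition defaults
NUCLEAR_AMPLITUDE = 3000.0
MARKER_AMPLITUDE = 2500.0
DEBRIS_AMPLITUDE = 2000.0
HAZE_AMPLITUDE = 400.0
HAZE_SCALE = 150.0
READ_NOISE_SD = 2.0
VIGNETTE_STRENGTH = 0.5
RETENTION_PER_CYCLE = 0.95
JITTER_MAX_PX = 5
DRIFT_MAX_PX = 8
MEMBRANE_MARGIN = 2.5
PAD = JITTER_MAX_PX + 3

FLUOROPHORES = ("A488", "A555", "A647", "A750")


@dataclass
class SceneTruth:
    """Complete generating parameters of one synthetic acquisition."""

    seed: int
    image_shape: tuple[int, int]
    centroids: np.ndarray  # (n, 2) float, reference-frame (row, col)
    radii: np.ndarray  # (n,)
    class_names: list[str]
    membership: np.ndarray  # (n,) int index into class_names
    grid: TileGrid
    manifest: list[ChannelRecord]
    marker_class: dict[str, str]  # marker -> class it labels
    marker_style: dict[str, str]  # marker -> "membrane" | "nuclear_factor"
    drifts: dict[int, tuple[float, float]]  # cycle -> (dy, dx)
    jitter: dict[tuple[int, int], tuple[int, int]]  # (cycle, tile) -> (dy, dx)
    retention: dict[int, float]  # cycle -> multiplicative factor
    vignette: dict[str, float]  # channel_name -> vignette strength
    haze_amplitude: float = HAZE_AMPLITUDE
    haze_scale: float = HAZE_SCALE
    read_noise_sd: float = READ_NOISE_SD
    debris: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    pores: tuple[int, float] | None = None  # (spacing_px, radius_px)
    membrane_style: str = "disk"  # "disk" (full footprint) or "ring"

    @property
    def n_cells(self) -> int:
        return len(self.radii)

    @property
    def cycles(self) -> list[int]:
        return sorted({r.cycle for r in self.manifest})

    def class_of(self, i: int) -> str:
        return self.class_names[self.membership[i]]

    def cells_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(1, self.n_cells + 1),
                "row": self.centroids[:, 0],
                "col": self.centroids[:, 1],
                "radius": self.radii,
                "cell_class": [self.class_of(i) for i in range(self.n_cells)],
            }
        )


def _default_manifest(
    class_names: Sequence[str], n_cycles: int
) -> tuple[list[ChannelRecord], dict[str, str], dict[str, str]]:
    """Cycle plan: membrane markers one class per cycle, then nuclear-factor
    markers, then an autofluorescence cycle, then DAPI-only cycles."""
    records: list[ChannelRecord] = []
    marker_class: dict[str, str] = {}
    marker_style: dict[str, str] = {}
    extra_plan: list[tuple[str, str, str]] = []  # (marker, class, style)
    for cls in class_names:
        extra_plan.append((f"mem{cls}", cls, "membrane"))
    for cls in class_names:
        extra_plan.append((f"nf{cls}", cls, "nuclear_factor"))

    for cyc in range(1, n_cycles + 1):
        records.append(
            ChannelRecord(
                cycle=cyc, channel_name="DAPI", marker="DAPI",
                fluorophore="DAPI", exposure_ms=20.0, role="nuclear",
            )
        )
        k = cyc - 1
        if k < len(extra_plan):
            marker, cls, style = extra_plan[k]
            records.append(
                ChannelRecord(
                    cycle=cyc, channel_name=FLUOROPHORES[k % len(FLUOROPHORES)],
                    marker=marker, fluorophore=FLUOROPHORES[k % len(FLUOROPHORES)],
                    exposure_ms=100.0, role="marker",
                )
            )
            marker_class[marker] = cls
            marker_style[marker] = style
        elif k == len(extra_plan):
            records.append(
                ChannelRecord(
                    cycle=cyc, channel_name="AF", marker="AF",
                    fluorophore="A555", exposure_ms=100.0, role="autofluorescence",
                )
            )
    return records, marker_class, marker_style


def make_scene(
    n_cells: int = 400,
    classes: Mapping[str, float] | None = None,
    image_shape: tuple[int, int] | None = None,
    seed: int = 0,
    grid: TileGrid | None = None,
    n_cycles: int = 6,
    radius_mean: float = 5.5,
    radius_sd: float = 0.8,
    n_debris: int = 8,
    pores: tuple[int, float] | None = None,
    membrane_style: str = "disk",
    drift_max_px: float = DRIFT_MAX_PX,
    jitter_max_px: int = JITTER_MAX_PX,
) -> SceneTruth:
    """Draw a ground-truth scene: cell geometry, memberships, acquisition
    parameters.

    Nuclei are placed by rejection sampling with no overlap; memberships
    are multinomial with the declared class proportions.  Raises when the
    requested nuclei would demand more than 60% of the frame.
    """
    classes = dict(classes or {"A": 0.5, "B": 0.5})
    if abs(sum(classes.values()) - 1.0) > 1e-9:
        raise ValidationError("class proportions must sum to 1")
    if grid is None:
        grid = TileGrid(rows=2, cols=2, tile_shape=(288, 288), overlap_fraction=0.125)
    if image_shape is None:
        image_shape = grid.mosaic_shape()

    area = image_shape[0] * image_shape[1]
    if n_cells * np.pi * (radius_mean + 2 * radius_sd) ** 2 > 0.6 * area:
        raise ValidationError(
            f"{n_cells} nuclei of radius ~{radius_mean} exceed 60% of the frame"
        )

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    margin = radius_mean + 4 * radius_sd + drift_max_px + 4
    centroids = np.zeros((n_cells, 2))
    radii = np.zeros(n_cells)
    placed = 0
    attempts = 0
    while placed < n_cells:
        attempts += 1
        if attempts > 200 * max(n_cells, 1):
            raise ValidationError("rejection sampling failed: packing infeasible")
        r = float(np.clip(rng.normal(radius_mean, radius_sd), 2.5, None))
        pos = rng.uniform(margin, np.array(image_shape) - margin)
        if placed:
            d = np.hypot(*(centroids[:placed] - pos).T)
            if np.any(d < radii[:placed] + r + 3.0):
                continue
        centroids[placed] = pos
        radii[placed] = r
        placed += 1

    class_names = list(classes)
    membership = rng.choice(
        len(class_names), size=n_cells, p=[classes[c] for c in class_names]
    )

    manifest, marker_class, marker_style = _default_manifest(class_names, n_cycles)

    cycles = sorted({r.cycle for r in manifest})
    drifts: dict[int, tuple[float, float]] = {}
    jitter: dict[tuple[int, int], tuple[int, int]] = {}
    for cyc in cycles:
        if cyc == cycles[0]:
            drifts[cyc] = (0.0, 0.0)
        else:
            drifts[cyc] = tuple(rng.uniform(-drift_max_px, drift_max_px, size=2))
        for t in range(grid.n_tiles):
            jitter[(cyc, t)] = tuple(
                rng.integers(-jitter_max_px, jitter_max_px + 1, size=2).tolist()
            )
    retention = {cyc: RETENTION_PER_CYCLE ** (cyc - 1) for cyc in cycles}

    channel_names = sorted({r.channel_name for r in manifest})
    vignette = {
        ch: VIGNETTE_STRENGTH * (0.8 + 0.4 * rng.random()) for ch in channel_names
    }

    debris = np.column_stack(
        [
            rng.uniform(margin, image_shape[0] - margin, n_debris),
            rng.uniform(margin, image_shape[1] - margin, n_debris),
            rng.uniform(4.0, 9.0, n_debris),
        ]
    ) if n_debris else np.zeros((0, 3))

    return SceneTruth(
        seed=int(seed),
        image_shape=tuple(image_shape),
        centroids=centroids,
        radii=radii,
        class_names=class_names,
        membership=membership,
        grid=grid,
        manifest=manifest,
        marker_class=marker_class,
        marker_style=marker_style,
        drifts=drifts,
        jitter=jitter,
        retention=retention,
        vignette=vignette,
        debris=debris,
        pores=pores,
        membrane_style=membrane_style,
    )


def _paint_blobs(
    canvas: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    amplitude: float,
    drift: tuple[float, float],
    sharpness: float = 4.0,
    inner_radii: np.ndarray | None = None,
) -> None:
    """Add soft-edged discs ``amplitude * exp(-(d/r)^sharpness)`` in place.

    ``inner_radii`` carves out the centre (membrane-ring rendering).
    """
    h, w = canvas.shape
    for k in range(len(radii)):
        cy, cx = centers[k, 0] + drift[0], centers[k, 1] + drift[1]
        r = radii[k]
        ext = int(np.ceil(3 * r))
        r0, r1 = max(int(cy) - ext, 0), min(int(cy) + ext + 1, h)
        c0, c1 = max(int(cx) - ext, 0), min(int(cx) + ext + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d = np.hypot(yy - cy, xx - cx)
        blob = amplitude * np.exp(-((d / r) ** sharpness))
        if inner_radii is not None:
            blob *= 1.0 - np.exp(-((d / inner_radii[k]) ** sharpness))
        canvas[r0:r1, c0:c1] += blob


def _haze(truth: SceneTruth) -> np.ndarray:
    h, w = truth.image_shape
    cy, cx = 0.6 * h, 0.45 * w
    yy, xx = np.mgrid[0:h, 0:w]
    return truth.haze_amplitude * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * truth.haze_scale**2)
    )


def _pore_lattice(truth: SceneTruth, drift: tuple[float, float]) -> np.ndarray:
    """Small perfectly round objects on a regular lattice (chip membrane)."""
    spacing, radius = truth.pores  # type: ignore[misc]
    h, w = truth.image_shape
    centers = []
    for r in np.arange(spacing / 2, h, spacing):
        for c in np.arange(spacing / 2, w, spacing):
            centers.append((r, c))
    canvas = np.zeros((h, w))
    centers_arr = np.array(centers)
    _paint_blobs(
        canvas, centers_arr, np.full(len(centers_arr), radius), 300.0, drift, sharpness=6.0
    )
    return canvas


def render_clean_plane(truth: SceneTruth, cycle: int, record: ChannelRecord) -> np.ndarray:
    """Noise-free, shading-free full-frame render of one channel (float)."""
    canvas = np.zeros(truth.image_shape, dtype=np.float64)
    drift = truth.drifts[cycle]
    scale = truth.retention[cycle]

    if record.role == "nuclear":
        _paint_blobs(canvas, truth.centroids, truth.radii, NUCLEAR_AMPLITUDE, drift)
    elif record.role == "marker":
        cls = truth.marker_class[record.marker]
        members = np.array(
            [truth.class_of(i) == cls for i in range(truth.n_cells)], dtype=bool
        )
        if members.any():
            centers = truth.centroids[members]
            radii = truth.radii[members]
            if truth.marker_style[record.marker] == "membrane":
                outer = radii + MEMBRANE_MARGIN
                inner = radii * 0.6 if truth.membrane_style == "ring" else None
                _paint_blobs(
                    canvas, centers, outer, MARKER_AMPLITUDE, drift, inner_radii=inner
                )
            else:  # nuclear-factor marker: over the nucleus itself
                _paint_blobs(canvas, centers, radii, MARKER_AMPLITUDE, drift)
    elif record.role == "autofluorescence":
        if len(truth.debris):
            _paint_blobs(
                canvas, truth.debris[:, :2], truth.debris[:, 2], DEBRIS_AMPLITUDE, drift,
            )
    elif record.role == "brightfield":
        canvas += 20000.0
        _paint_blobs(canvas, truth.centroids, truth.radii + 2, -4000.0, drift)

    canvas *= scale
    if record.role in ("nuclear", "marker") and truth.haze_amplitude > 0:
        canvas += _haze(truth)
    if truth.pores is not None:
        canvas += _pore_lattice(truth, drift)
    return canvas


def shading_field_array(truth: SceneTruth, channel_name: str) -> np.ndarray:
    """The channel's multiplicative vignette over the tile footprint
    (max 1 at centre, unnormalized)."""
    h, w = truth.grid.tile_shape
    yy, xx = np.mgrid[0:h, 0:w]
    rho2 = (((yy - (h - 1) / 2) / ((h - 1) / 2)) ** 2 + ((xx - (w - 1) / 2) / ((w - 1) / 2)) ** 2) / 2.0
    return 1.0 - truth.vignette[channel_name] * rho2


def shading_reference(truth: SceneTruth, channel_name: str, level: float = 20000.0) -> ImagePlane:
    """A clean shading-reference image: uniform scene under the vignette."""
    arr = shading_field_array(truth, channel_name) * level
    return ImagePlane(np.clip(np.floor(arr + 0.5), 0, 65535).astype(np.uint16))


def _cut_tiles(
    truth: SceneTruth, frame: np.ndarray, cycle: int
) -> list[np.ndarray]:
    """Cut the full frame into jittered tiles, acquisition order."""
    grid = truth.grid
    padded = np.pad(frame, PAD, mode="constant")
    h, w = grid.tile_shape
    step_r, step_c = grid.step()
    tiles = []
    for t in range(grid.n_tiles):
        r, c = grid.acquisition_to_grid(t)
        jy, jx = truth.jitter[(cycle, t)]
        r0 = r * step_r + jy + PAD
        c0 = c * step_c + jx + PAD
        tiles.append(padded[r0 : r0 + h, c0 : c0 + w].copy())
    return tiles


def render_cycle(
    truth: SceneTruth,
    cycle: int,
    channels: Sequence[ChannelRecord] | None = None,
    noise: bool = True,
    apply_shading: bool = True,
) -> tuple[dict[str, list[ImagePlane]], list[ChannelRecord]]:
    """Render one acquisition cycle as per-channel jittered tile lists.

    Tiles carry the channel's vignette and, when ``noise`` is on, Poisson
    shot noise plus Gaussian read noise seeded per
    (master seed, cycle, channel, tile).
    """
    records = [r for r in truth.manifest if r.cycle == cycle] if channels is None else list(channels)
    out: dict[str, list[ImagePlane]] = {}
    for ci, rec in enumerate(records):
        frame = render_clean_plane(truth, cycle, rec)
        tiles = _cut_tiles(truth, frame, cycle)
        field = shading_field_array(truth, rec.channel_name) if apply_shading else 1.0
        planes = []
        for ti, tile in enumerate(tiles):
            arr = tile * field
            if noise:
                rng = np.random.default_rng(
                    np.random.SeedSequence([truth.seed, cycle, ci, ti, 1])
                )
                arr = rng.poisson(np.clip(arr, 0, None)).astype(np.float64)
                arr += rng.normal(0.0, truth.read_noise_sd, size=arr.shape)
            planes.append(
                ImagePlane(np.clip(np.floor(arr + 0.5), 0, 65535).astype(np.uint16))
            )
        out[rec.channel_name] = planes
    return out, records


def render_zstack(
    truth: SceneTruth,
    cycle: int,
    record: ChannelRecord,
    n_slices: int = 3,
    defocus_sigma: float = 2.5,
) -> ZStack:
    """A chip-style z-stack: the in-focus render plus defocused copies."""
    from scipy.ndimage import gaussian_filter

    frame = render_clean_plane(truth, cycle, record)
    slices = []
    centre = (n_slices - 1) / 2
    for z in range(n_slices):
        sigma = defocus_sigma * abs(z - centre)
        arr = gaussian_filter(frame, sigma) if sigma > 0 else frame
        slices.append(ImagePlane(np.clip(np.floor(arr + 0.5), 0, 65535).astype(np.uint16)))
    return ZStack(tuple(slices))


def evaluate_identity_recovery(
    truth: SceneTruth,
    cells: pd.DataFrame,
    reference_cycle: int | None = None,
    match_radius_px: float = 5.0,
) -> float:
    """Fraction of ground-truth cells assigned their true class.

    The pipeline's output frame is anchored at the reference cycle's
    top-left tile, whose stage jitter offsets the whole mosaic relative to
    the scene coordinates; the known jitter is removed before matching
    each truth centroid to the nearest segmented cell (within
    ``match_radius_px``).  Unmatched or misassigned cells count as wrong.
    """
    from scipy.spatial import cKDTree

    if truth.n_cells == 0:
        return float("nan")
    ref_cycle = truth.cycles[0] if reference_cycle is None else reference_cycle
    anchor_tile = next(
        t for t in range(truth.grid.n_tiles) if truth.grid.acquisition_to_grid(t) == (0, 0)
    )
    j0 = np.array(truth.jitter[(ref_cycle, anchor_tile)], dtype=float)
    drift0 = np.array(truth.drifts[ref_cycle], dtype=float)
    expected_pos = truth.centroids + drift0 - j0

    pts = cells[["centroid_row", "centroid_col"]].to_numpy()
    if len(pts) == 0:
        return 0.0
    d, idx = cKDTree(pts).query(expected_pos)
    pred = cells["assigned_identity"].to_numpy()[idx]
    expected_id = np.array([f"mem{truth.class_of(i)}" for i in range(truth.n_cells)])
    return float(((d <= match_radius_px) & (pred == expected_id)).mean())


def write_fixture(
    truth: SceneTruth, directory: str | Path, noise: bool = True
) -> Path:
    """Write a complete on-disk acquisition the pipeline can consume.

    Layout: ``manifest.csv``, ``truth.json``, ``truth_cells.csv``,
    ``shading/<channel>.tif`` references, and
    ``tiles/c{cycle}_{channel}_t{k}.tif`` per tile.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mio.write_manifest(truth.manifest, directory / "manifest.csv")
    truth.cells_table().to_csv(directory / "truth_cells.csv", index=False)

    meta = {
        "seed": truth.seed,
        "image_shape": list(truth.image_shape),
        "grid": {
            "rows": truth.grid.rows,
            "cols": truth.grid.cols,
            "tile_shape": list(truth.grid.tile_shape),
            "overlap_fraction": truth.grid.overlap_fraction,
            "acquisition_order": truth.grid.acquisition_order,
        },
        "drifts": {str(c): list(d) for c, d in truth.drifts.items()},
        "jitter": {f"{c}:{t}": list(j) for (c, t), j in truth.jitter.items()},
        "retention": {str(c): v for c, v in truth.retention.items()},
        "class_names": truth.class_names,
        "marker_class": truth.marker_class,
        "membrane_style": truth.membrane_style,
        "pores": list(truth.pores) if truth.pores else None,
    }
    (directory / "truth.json").write_text(json.dumps(meta, indent=1))

    shading_dir = directory / "shading"
    for ch in sorted({r.channel_name for r in truth.manifest}):
        mio.write_plane(shading_reference(truth, ch), shading_dir / f"{ch}.tif")

    tiles_dir = directory / "tiles"
    for cyc in truth.cycles:
        rendered, records = render_cycle(truth, cyc, noise=noise)
        for rec in records:
            for t, plane in enumerate(rendered[rec.channel_name]):
                mio.write_plane(
                    plane, tiles_dir / f"c{cyc}_{rec.channel_name}_t{t:02d}.tif"
                )
    return directory
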