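"""Tile-grid stitching: nominal placement, pairwise refinement, blending.

Tiles are first placed on the nominal grid implied by the tile shape and
overlap fraction.  For every adjacent pair the residual translation is
estimated by phase correlation restricted to the nominal overlap strip;
global placements are then solved by anchoring the top-left tile and
accumulating pairwise shifts along a maximum-correlation spanning tree.
Pairs whose aligned-strip correlation falls below ``min_correlation``
fall back to the nominal offset and are flagged in the QC report.
Blending is linear feathering: each pixel of a tile is weighted by its
distance to the tile's nearest edge, weights normalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.registration import phase_cross_correlation

from mifprep.model import ImagePlane, TileGrid, ValidationError
from mifprep.registration import estimate_shift

__all__ = [
    "TilePlacement",
    "nominal_positions",
    "refine_offsets",
    "blend_mosaic",
    "stitch",
]

MIN_STRIP_PX = 8


@dataclass
class TilePlacement:
    """Placement of one tile: grid cell, nominal and refined origins."""

    tile_index: int  # acquisition index into the tile list
    grid_cell: tuple[int, int]
    nominal_origin: tuple[float, float]
    refined_origin: tuple[float, float]
    pair_scores: list[tuple[int, float]] = field(default_factory=list)
    fallback_pairs: list[int] = field(default_factory=list)


def nominal_positions(grid: TileGrid) -> list[TilePlacement]:
    """Integer nominal origins on the regular grid, row-major by grid cell.

    ``tile_index`` records which acquired tile lands in each cell (snake
    acquisition is remapped to row-major cells).
    """
    step_r, step_c = grid.step()
    cell_to_acq = {grid.acquisition_to_grid(i): i for i in range(grid.n_tiles)}
    placements = []
    for r in range(grid.rows):
        for c in range(grid.cols):
            origin = (float(r * step_r), float(c * step_c))
            placements.append(
                TilePlacement(
                    tile_index=cell_to_acq[(r, c)],
                    grid_cell=(r, c),
                    nominal_origin=origin,
                    refined_origin=origin,
                )
            )
    return placements


STRIP_MARGIN = 8


def _strip_pair(
    a: np.ndarray, b: np.ndarray, axis: int, ov: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Overlap strips of tile ``a`` (trailing edge) and tile ``b`` (leading).

    Strips are widened by a stage-jitter margin so the shared content
    survives a few pixels of misplacement; the returned margin enters the
    residual arithmetic.
    """
    m = min(STRIP_MARGIN, a.shape[axis] - ov)
    width = ov + m
    if axis == 0:
        return a[-width:, :], b[:width, :], m
    return a[:, -width:], b[:, :width], m


def _shared_crop(
    sa: np.ndarray, sb: np.ndarray, d: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Crops of the two strips that cover exactly the same scene region,
    given ``sb[p] == sa[p + d]`` for integer ``d``."""
    lo = np.maximum(0, -d)
    hi = np.minimum(sa.shape, np.array(sa.shape) - d)
    if np.any(hi - lo < MIN_STRIP_PX):
        return sa[:0, :0], sb[:0, :0]
    win_b = (slice(lo[0], hi[0]), slice(lo[1], hi[1]))
    win_a = (slice(lo[0] + d[0], hi[0] + d[0]), slice(lo[1] + d[1], hi[1] + d[1]))
    return sa[win_a], sb[win_b]


def _pair_shift(
    a: np.ndarray, b: np.ndarray, axis: int, ov: int, upsample: int
) -> tuple[np.ndarray, float]:
    """Residual (dy, dx) of tile b relative to its nominal position, plus score.

    Two passes: an integer shift from plain cross-correlation of the
    widened strips (robust to the strips' non-shared content), then
    subpixel refinement by phase correlation on the exactly-shared crop,
    which also yields an honest correlation score.
    """
    sa, sb, m = _strip_pair(a, b, axis, ov)
    if sa.std() == 0 or sb.std() == 0:
        return np.zeros(2), 0.0

    def _masked_cc(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        # masked (non-circular) cross-correlation: returns integer d such
        # that y[p] == x[p + d] over the shared content
        ones = np.ones(x.shape, dtype=bool)
        d, _, _ = phase_cross_correlation(x, y, reference_mask=ones, moving_mask=ones)
        return np.round(d).astype(int)

    d0 = _masked_cc(sa, sb)
    # iterate on the exactly-shared crop until the integer part settles
    crop_a = crop_b = None
    for _ in range(3):
        crop_a, crop_b = _shared_crop(sa, sb, d0)
        if crop_a.size == 0 or crop_a.std() == 0 or crop_b.std() == 0:
            return np.zeros(2), 0.0
        step = _masked_cc(crop_a, crop_b)
        if not step.any():
            break
        d0 = d0 + step
    fine = estimate_shift(crop_a, crop_b, upsample=upsample)
    total = d0 - np.array([fine.dy, fine.dx])
    residual = total.astype(float)
    residual[axis] -= m
    # guard against wrap-around interpretations larger than the strip itself
    limit = np.array(sa.shape) / 2.0
    if abs(residual[0]) > limit[0] or abs(residual[1]) > limit[1]:
        return np.zeros(2), 0.0
    return residual, max(fine.peak_correlation, 0.0)


def refine_offsets(
    tiles: list[ImagePlane],
    grid: TileGrid,
    min_correlation: float = 0.3,
    upsample: int = 10,
) -> list[TilePlacement]:
    """Refine tile placements by phase correlation on overlap strips."""
    if len(tiles) != grid.n_tiles:
        raise ValidationError(
            f"{len(tiles)} tiles supplied for a {grid.rows}x{grid.cols} grid"
        )
    h, w = grid.tile_shape
    step_r, step_c = grid.step()
    ov_r, ov_c = h - step_r, w - step_c
    if grid.rows > 1 and ov_r < MIN_STRIP_PX:
        raise ValidationError(
            f"vertical overlap strip of {ov_r} px is below the {MIN_STRIP_PX} px minimum"
        )
    if grid.cols > 1 and ov_c < MIN_STRIP_PX:
        raise ValidationError(
            f"horizontal overlap strip of {ov_c} px is below the {MIN_STRIP_PX} px minimum"
        )

    placements = nominal_positions(grid)
    by_cell = {p.grid_cell: p for p in placements}
    arrays = {p.grid_cell: tiles[p.tile_index].astype_float() for p in placements}

    # pairwise residual shifts between adjacent grid cells
    edges: list[tuple[tuple[int, int], tuple[int, int], np.ndarray, float]] = []
    for r in range(grid.rows):
        for c in range(grid.cols):
            for dr, dc, axis, ov in ((1, 0, 0, ov_r), (0, 1, 1, ov_c)):
                nb = (r + dr, c + dc)
                if nb[0] >= grid.rows or nb[1] >= grid.cols:
                    continue
                residual, score = _pair_shift(
                    arrays[(r, c)], arrays[nb], axis, ov, upsample
                )
                nominal_rel = np.array([dr * step_r, dc * step_c], dtype=float)
                a, b = by_cell[(r, c)], by_cell[nb]
                a.pair_scores.append((b.tile_index, score))
                b.pair_scores.append((a.tile_index, score))
                if score < min_correlation:
                    residual = np.zeros(2)
                    a.fallback_pairs.append(b.tile_index)
                    b.fallback_pairs.append(a.tile_index)
                edges.append(((r, c), nb, nominal_rel + residual, score))

    # maximum-correlation spanning tree, anchored at cell (0, 0)
    adjacency: dict[tuple[int, int], list[tuple[float, tuple[int, int], np.ndarray]]] = {
        p.grid_cell: [] for p in placements
    }
    for u, v, rel, score in edges:
        adjacency[u].append((score, v, rel))
        adjacency[v].append((score, u, -rel))

    origin: dict[tuple[int, int], np.ndarray] = {(0, 0): np.zeros(2)}
    frontier = list(adjacency[(0, 0)])
    frontier_from = [(0, 0)] * len(frontier)
    while len(origin) < len(placements) and frontier:
        best = int(np.argmax([s for s, v, _ in frontier]))
        score, v, rel = frontier.pop(best)
        u = frontier_from.pop(best)
        if v in origin:
            continue
        origin[v] = origin[u] + rel
        for item in adjacency[v]:
            if item[1] not in origin:
                frontier.append(item)
                frontier_from.append(v)

    for p in placements:
        p.refined_origin = tuple(origin[p.grid_cell])
    return placements


def blend_mosaic(
    tiles: list[ImagePlane],
    placements: list[TilePlacement],
    canvas_shape: tuple[int, int] | None = None,
) -> ImagePlane:
    """Blend placed tiles into one mosaic with linear edge feathering.

    Regions covered by a single tile reproduce that tile bit-exactly (for
    integer placements); overlaps are weighted by each pixel's distance to
    its tile's nearest edge.  ``canvas_shape`` fixes the output extent
    (origins are then interpreted on that canvas); otherwise the canvas is
    the bounding box of all placed tiles.
    """
    origins = np.array([p.refined_origin for p in placements], dtype=float)
    if not np.all(np.isfinite(origins)):
        raise ValidationError("non-finite tile placement")
    shapes = np.array([tiles[p.tile_index].shape for p in placements])

    if canvas_shape is None:
        base = origins.min(axis=0)
        origins = origins - base
        extent = (origins + shapes).max(axis=0)
        canvas_shape = (int(np.ceil(extent[0])), int(np.ceil(extent[1])))

    acc = np.zeros(canvas_shape, dtype=np.float64)
    wacc = np.zeros(canvas_shape, dtype=np.float64)
    cover = np.zeros(canvas_shape, dtype=np.int32)

    prepared = []
    for p, origin in zip(placements, origins):
        arr = tiles[p.tile_index].astype_float()
        h, w = arr.shape
        # tiles are pasted on the pixel grid at the rounded origin; the
        # real-valued refinement is kept in the placement metadata
        oi = np.floor(origin + 0.5).astype(int)
        wy = np.minimum(np.arange(1, h + 1), np.arange(h, 0, -1)).astype(float)
        wx = np.minimum(np.arange(1, w + 1), np.arange(w, 0, -1)).astype(float)
        weight = np.outer(wy, wx)
        r0, c0 = oi
        rs, re = max(r0, 0), min(r0 + h, canvas_shape[0])
        cs, ce = max(c0, 0), min(c0 + w, canvas_shape[1])
        if rs >= re or cs >= ce:
            continue
        tr, tc = rs - r0, cs - c0
        sub = (slice(rs, re), slice(cs, ce))
        tsub = (slice(tr, tr + (re - rs)), slice(tc, tc + (ce - cs)))
        acc[sub] += weight[tsub] * arr[tsub]
        wacc[sub] += weight[tsub]
        cover[sub] += 1
        prepared.append((p, sub, tsub))

    out = np.zeros(canvas_shape, dtype=np.float64)
    covered = wacc > 0
    out[covered] = acc[covered] / wacc[covered]

    # single-coverage regions: copy source values verbatim (bit exactness)
    for p, sub, tsub in prepared:
        raw = tiles[p.tile_index].pixels[tsub].astype(np.float64)
        single = cover[sub] == 1
        out[sub][single] = raw[single]

    return ImagePlane(np.clip(np.floor(out + 0.5), 0, 65535).astype(np.uint16))


def stitch(
    tiles: list[ImagePlane],
    grid: TileGrid,
    min_correlation: float = 0.3,
    placements: list[TilePlacement] | None = None,
    canvas_shape: tuple[int, int] | None = None,
) -> tuple[ImagePlane, list[TilePlacement]]:
    """Refine placements (unless given) and blend in one call."""
    if placements is None:
        placements = refine_offsets(tiles, grid, min_correlation=min_correlation)
    return blend_mosaic(tiles, placements, canvas_shape=canvas_shape), placements
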