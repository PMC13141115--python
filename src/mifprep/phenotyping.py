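"""Nucleus segmentation and imaging cytometry.

Cell identity in tissue mIF cannot be read from marker intensity alone:
membrane markers of adjacent cell types overlap, so a naive per-pixel
call produces spurious "biphenotypic" cells.  The rule implemented here
segments nuclei on the DAPI channel first and assigns a cell to a marker
class only when at least a threshold fraction (default 60%) of its
nuclear pixels falls inside that marker's binarized mask; conflicting
qualifying markers resolve by the largest fraction, with near-ties
reported rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import relabel_sequential, watershed

from mifprep.model import HyperStack, ImagePlane, ValidationError

__all__ = [
    "LabelMap",
    "CellRecord",
    "CellTable",
    "segment_nuclei",
    "import_labelmap",
    "export_labelmap",
    "marker_mask",
    "overlap_fractions",
    "assign_identity",
    "quantify",
]

TIE_MARGIN = 0.01
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class LabelMap:
    """Integer raster of segmented nuclei: 0 = background, 1..N = cells."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or not np.issubdtype(lab.dtype, np.integer):
            raise ValidationError("label map must be a 2-D integer raster")
        if lab.min() < 0:
            raise ValidationError("labels must be nonnegative")
        object.__setattr__(self, "labels", lab.astype(np.int32))

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class CellRecord:
    cell_id: int
    centroid: tuple[float, float]
    area_px: int
    overlap_fraction: dict[str, float] = field(default_factory=dict)
    mean_intensity: dict[str, float] = field(default_factory=dict)
    valid: dict[str, bool] = field(default_factory=dict)
    assigned_identity: str = UNASSIGNED
    tie_flag: bool = False


@dataclass
class CellTable:
    """Per-cell quantification with provenance."""

    cells: list[CellRecord]
    markers: list[str]
    sample_id: str = ""
    config_hash: str = ""

    def __len__(self) -> int:
        return len(self.cells)

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, list] = {
            "cell_id": [c.cell_id for c in self.cells],
            "centroid_row": [c.centroid[0] for c in self.cells],
            "centroid_col": [c.centroid[1] for c in self.cells],
            "area_px": [c.area_px for c in self.cells],
        }
        for m in self.markers:
            cols[f"frac_{m}"] = [c.overlap_fraction.get(m, 0.0) for c in self.cells]
            cols[f"mean_{m}"] = [c.mean_intensity.get(m, 0.0) for c in self.cells]
            cols[f"valid_{m}"] = [c.valid.get(m, True) for c in self.cells]
        cols["assigned_identity"] = [c.assigned_identity for c in self.cells]
        cols["tie_flag"] = [c.tie_flag for c in self.cells]
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_dataframe().to_csv(path, index=False)


def segment_nuclei(
    nuclear: ImagePlane,
    smooth_sigma: float = 1.5,
    min_area: int = 30,
    max_area: int = 2000,
) -> LabelMap:
    """Segment nuclei from the DAPI channel.

    Gaussian smoothing, Otsu global threshold, hole filling, then a
    watershed on the negated distance transform (seeded at regional maxima
    with minimum separation ``ceil(sqrt(min_area))``) splits touching
    nuclei.  Components outside [min_area, max_area] px² are discarded and
    labels are made contiguous.
    """
    img = nuclear.astype_float()
    if img.std() == 0:
        raise ValidationError("cannot segment a constant nuclear plane")
    smoothed = gaussian(img, sigma=smooth_sigma, preserve_range=True)
    mask = smoothed >= threshold_otsu(smoothed)
    mask = ndi.binary_fill_holes(mask)

    distance = ndi.distance_transform_edt(mask)
    min_sep = int(np.ceil(np.sqrt(min_area)))
    seeds_rc = peak_local_max(
        distance, min_distance=min_sep, labels=mask, exclude_border=False
    )
    seed_map = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(seeds_rc, start=1):
        seed_map[r, c] = i
    if seed_map.max() == 0:
        labels = ndi.label(mask)[0]
    else:
        labels = watershed(-distance, markers=seed_map, mask=mask)

    areas = np.bincount(labels.ravel())
    bad = np.flatnonzero((areas < min_area) | (areas > max_area))
    keep = labels.copy()
    keep[np.isin(labels, bad[bad > 0])] = 0
    relabelled, _, _ = relabel_sequential(keep)
    return LabelMap(relabelled.astype(np.int32))


def export_labelmap(labels: LabelMap, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if labels.n_cells > 65535:
        raise ValidationError("more than 65535 cells cannot round-trip as 16-bit TIFF")
    tifffile.imwrite(path, labels.labels.astype(np.uint16), photometric="minisblack")


def import_labelmap(path: str | Path, expected_shape: tuple[int, int]) -> LabelMap:
    """Import an externally segmented label map (e.g. a deep-learning
    segmenter's output) as 16-bit integer TIFF; labels are made contiguous."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such label map: {path}")
    arr = tifffile.imread(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValidationError(f"{path}: label map must be integer-valued, got {arr.dtype}")
    if arr.ndim != 2 or tuple(arr.shape) != tuple(expected_shape):
        raise ValidationError(
            f"{path}: label map shape {arr.shape} does not match expected {tuple(expected_shape)}"
        )
    relabelled, _, _ = relabel_sequential(arr.astype(np.int64))
    return LabelMap(relabelled.astype(np.int32))


def marker_mask(
    plane: ImagePlane, method: str = "otsu", fixed_threshold: float | None = None
) -> np.ndarray:
    """Binarize a marker channel; threshold by Otsu or a fixed value."""
    img = plane.astype_float()
    if method == "otsu":
        if img.std() == 0:
            raise ValidationError("Otsu threshold undefined on a constant plane")
        thr = threshold_otsu(img)
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValidationError("fixed method requires fixed_threshold")
        thr = float(fixed_threshold)
    else:
        raise ValidationError(f"unknown mask method {method!r}")
    return img >= thr


def overlap_fractions(labels: LabelMap, mask: np.ndarray) -> np.ndarray:
    """Fraction of each cell's pixels inside the mask; index i-1 = cell i."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != labels.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match labels shape {labels.shape}"
        )
    n = labels.n_cells
    if n == 0:
        return np.zeros(0)
    areas = np.bincount(labels.labels.ravel(), minlength=n + 1)[1:]
    inside = np.bincount(
        labels.labels.ravel(), weights=mask.ravel().astype(float), minlength=n + 1
    )[1:]
    return inside / np.maximum(areas, 1)


def assign_identity(
    fractions: Mapping[str, float],
    threshold: float = 0.60,
    exclusive: bool = True,
) -> tuple[str, bool]:
    """Assign a cell identity from per-marker nuclear-overlap fractions.

    A marker qualifies when its fraction is at least ``threshold``.  With
    no qualifier the cell is unassigned; with several and
    ``exclusive=True`` the largest fraction wins unless the top two are
    within 0.01 of each other, which is flagged as a tie (and left
    unassigned).  ``exclusive=False`` reports all qualifiers joined by
    '+'.
    """
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must lie in (0, 1]")
    qualifying = sorted(
        ((m, f) for m, f in fractions.items() if f >= threshold),
        key=lambda kv: (-kv[1], kv[0]),
    )
    if not qualifying:
        return UNASSIGNED, False
    if len(qualifying) == 1:
        return qualifying[0][0], False
    if not exclusive:
        return "+".join(sorted(m for m, _ in qualifying)), False
    (top_m, top_f), (_, second_f) = qualifying[0], qualifying[1]
    if top_f - second_f < TIE_MARGIN:
        return UNASSIGNED, True
    return top_m, False


def quantify(
    stack: HyperStack,
    labels: LabelMap,
    masks: Mapping[str, np.ndarray],
    threshold: float = 0.60,
    exclusive: bool = True,
    identity_markers: Sequence[str] | None = None,
    sample_id: str = "",
    config_hash: str = "",
) -> CellTable:
    """Build the per-cell table: geometry, overlaps, intensities, identity.

    ``masks`` maps marker name to its binary raster; ``identity_markers``
    restricts which markers compete for identity (all masked markers by
    default).  Mean intensities are recorded for every marker; a validity
    flag marks intensities of markers incompatible with the assigned
    identity (recorded, not deleted).
    """
    if not stack.registered:
        raise ValidationError("quantify requires a registered stack")
    if labels.shape != stack.shape:
        raise ValidationError(
            f"label shape {labels.shape} does not match stack shape {stack.shape}"
        )
    markers = list(masks)
    id_markers = list(identity_markers) if identity_markers is not None else markers

    fracs = {m: overlap_fractions(labels, masks[m]) for m in markers}

    # mean marker intensity per cell, over the latest plane carrying the marker
    marker_planes: dict[str, np.ndarray] = {}
    for rec, plane in zip(stack.records, stack.planes):
        if rec.marker in markers:
            marker_planes[rec.marker] = plane.astype_float()
    means: dict[str, np.ndarray] = {}
    n = labels.n_cells
    areas = np.bincount(labels.labels.ravel(), minlength=n + 1)[1:]
    for m in markers:
        if m in marker_planes:
            sums = np.bincount(
                labels.labels.ravel(), weights=marker_planes[m].ravel(), minlength=n + 1
            )[1:]
            means[m] = sums / np.maximum(areas, 1)
        else:
            means[m] = np.zeros(n)

    props = regionprops(labels.labels)
    cells: list[CellRecord] = []
    for prop in props:
        i = prop.label
        cell_fracs = {m: float(fracs[m][i - 1]) for m in markers}
        identity, tie = assign_identity(
            {m: cell_fracs[m] for m in id_markers}, threshold=threshold, exclusive=exclusive
        )
        valid = {
            m: (identity == UNASSIGNED) or (m == identity) or (m not in id_markers)
            for m in markers
        }
        cells.append(
            CellRecord(
                cell_id=int(i),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area_px=int(prop.area),
                overlap_fraction=cell_fracs,
                mean_intensity={m: float(means[m][i - 1]) for m in markers},
                valid=valid,
                assigned_identity=identity,
                tie_flag=tie,
            )
        )
    return CellTable(cells=cells, markers=markers, sample_id=sample_id, config_hash=config_hash)
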