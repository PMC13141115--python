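"""End-to-end orchestration: config validation, stage ordering, provenance.

The default stage order mirrors how cyclic-mIF acquisitions are prepared
in practice: (chip only) z-projection → shading-correct tiles → stitch
per channel → rolling-ball background subtraction → per-cycle stacks →
hyperstack → registration on the nuclear reference → optional
autofluorescence subtraction → retention QC → phenotyping.  Every stage
writes its artifacts under one run directory together with a JSON
provenance record (resolved config, input hashes, package version,
per-stage wall time).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from mifprep import __version__
from mifprep import io as mio
from mifprep.background import subtract_autofluorescence, subtract_background
from mifprep.field_correction import (
    brightfield_flatten,
    build_shading_field,
    correct_shading,
    project_weighted,
)
from mifprep.model import HyperStack, ImagePlane, TileGrid, ValidationError
from mifprep.phenotyping import export_labelmap, marker_mask, quantify, segment_nuclei
from mifprep.registration import dapi_retention_qc, register_cycles
from mifprep.stitching import blend_mosaic, refine_offsets

__all__ = ["RunConfig", "validate_config", "run_pipeline", "ConfigError"]

log = logging.getLogger("mifprep")


class ConfigError(ValueError):
    """Raised with every configuration violation listed at once."""


_DEFAULTS: dict[str, Any] = {
    "shading": {"enabled": True, "floor_quantile": 0.01, "dir": None},
    "stitching": {"min_correlation": 0.3, "upsample": 10},
    "background": {"radius_px": 50, "exact": False, "af_scale": "auto", "af_channels": []},
    "registration": {"reference_cycle": None, "upsample": 10, "max_shift_frac": 0.1},
    "projection": {"enabled": False, "mode": "weighted_contrast"},
    "brightfield": {"sigma_px": 50},
    "phenotyping": {
        "enabled": True,
        "threshold": 0.6,
        "exclusive": True,
        "smooth_sigma": 1.5,
        "min_area": 30,
        "max_area": 2000,
        "identity_markers": None,
        "mask_method": "otsu",
        "dice_threshold": 0.7,
    },
    "seed": 0,
    "log_level": "INFO",
}


@dataclass
class RunConfig:
    input_dir: Path
    output_dir: Path
    manifest: Path
    grid: TileGrid
    params: dict[str, Any] = field(default_factory=dict)

    def stage(self, name: str) -> dict[str, Any]:
        return self.params[name]


def _merge_defaults(user: dict, defaults: dict) -> dict:
    out = {}
    for key, val in defaults.items():
        if isinstance(val, dict):
            out[key] = _merge_defaults(user.get(key, {}) or {}, val)
        else:
            out[key] = user.get(key, val)
    return out


def validate_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run config, fill defaults, list every violation."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return resolve_config(raw, base=path.parent)


def resolve_config(raw: dict[str, Any], base: Path | None = None) -> RunConfig:
    errors: list[str] = []
    base = base or Path.cwd()

    def _path(key: str, default: Path | None = None, must_exist: bool = True) -> Path | None:
        val = raw.get(key)
        if val is None:
            if default is None:
                errors.append(f"missing required field: {key}")
                return None
            val = default
        p = Path(val)
        if not p.is_absolute():
            p = base / p
        if must_exist and not p.exists():
            errors.append(f"{key}: path does not exist: {p}")
        return p

    input_dir = _path("input_dir")
    manifest = _path(
        "manifest", default=(input_dir / "manifest.csv") if input_dir else None
    )
    output_dir = _path("output_dir", must_exist=False)

    grid_raw = raw.get("grid") or {}
    grid = None
    missing_grid = [
        k for k in ("rows", "cols", "tile_height", "tile_width") if k not in grid_raw
    ]
    errors.extend(f"missing required field: grid.{k}" for k in missing_grid)
    if not missing_grid:
        ov = grid_raw.get("overlap_fraction", 0.1)
        if not (0 <= float(ov) < 0.5):
            errors.append(f"grid.overlap_fraction {ov} outside [0, 0.5)")
        else:
            try:
                grid = TileGrid(
                    rows=int(grid_raw["rows"]),
                    cols=int(grid_raw["cols"]),
                    tile_shape=(int(grid_raw["tile_height"]), int(grid_raw["tile_width"])),
                    overlap_fraction=float(ov),
                    acquisition_order=grid_raw.get("acquisition_order", "row_major"),
                )
            except (ValidationError, KeyError, ValueError) as exc:
                errors.append(f"grid: {exc}")

    params = _merge_defaults(raw, _DEFAULTS)
    if not 0 < float(params["shading"]["floor_quantile"]) < 0.5:
        errors.append("shading.floor_quantile outside (0, 0.5)")
    if int(params["background"]["radius_px"]) < 1:
        errors.append("background.radius_px must be >= 1")
    if not 0 < float(params["phenotyping"]["threshold"]) <= 1:
        errors.append("phenotyping.threshold outside (0, 1]")
    if params["projection"]["mode"] not in ("mean", "weighted_contrast"):
        errors.append("projection.mode must be mean or weighted_contrast")

    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    assert input_dir and output_dir and manifest and grid
    return RunConfig(
        input_dir=input_dir, output_dir=output_dir, manifest=manifest,
        grid=grid, params=params,
    )


def _hash_inputs(cfg: RunConfig) -> str:
    h = hashlib.sha256()
    for f in sorted(cfg.input_dir.rglob("*")):
        if f.is_file():
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()[:16]


def _read_channel_tiles(cfg: RunConfig, cycle: int, channel: str) -> list[ImagePlane]:
    tiles_dir = cfg.input_dir / "tiles"
    paths = sorted(tiles_dir.glob(f"c{cycle}_{channel}_t*.tif"))
    if len(paths) != cfg.grid.n_tiles:
        raise ValidationError(
            f"cycle {cycle} / {channel}: found {len(paths)} tiles, grid expects {cfg.grid.n_tiles}"
        )
    proj = cfg.stage("projection")
    planes = []
    for p in paths:
        if proj["enabled"]:
            planes.append(project_weighted(mio.read_zstack(p), mode=proj["mode"]))
        else:
            planes.append(mio.read_plane(p))
    return planes


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Run every stage on one acquisition; returns artifact paths + QC."""
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    artifacts: dict[str, Any] = {}

    def _timed(name: str):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                log.info("stage %s: start", name)

            def __exit__(self_, *exc):
                timings[name] = round(time.perf_counter() - self_.t0, 3)
                log.info("stage %s: %.2fs", name, timings[name])

        return _T()

    manifest = mio.read_manifest(cfg.manifest)
    cycles = sorted({r.cycle for r in manifest})
    shading_cfg = cfg.stage("shading")
    shading_dir = Path(shading_cfg["dir"]) if shading_cfg["dir"] else cfg.input_dir / "shading"
    canvas = cfg.grid.mosaic_shape()

    stitch_qc: dict[str, Any] = {}
    per_cycle: list[tuple[int, list[ImagePlane]]] = []
    with _timed("preprocess_stitch_subtract"):
        for cyc in cycles:
            recs = [r for r in manifest if r.cycle == cyc]
            corrected: dict[str, list[ImagePlane]] = {}
            for rec in recs:
                tiles = _read_channel_tiles(cfg, cyc, rec.channel_name)
                ref_path = shading_dir / f"{rec.channel_name}.tif"
                if shading_cfg["enabled"] and ref_path.exists():
                    fld = build_shading_field(
                        mio.read_plane(ref_path), floor_quantile=shading_cfg["floor_quantile"]
                    )
                    tiles = [correct_shading(t, fld) for t in tiles]
                corrected[rec.channel_name] = tiles

            nuclear = next(r for r in recs if r.role == "nuclear")
            placements = refine_offsets(
                corrected[nuclear.channel_name],
                cfg.grid,
                min_correlation=cfg.stage("stitching")["min_correlation"],
            )
            stitch_qc[str(cyc)] = {
                "pairs": [
                    {"tile": p.tile_index, "scores": p.pair_scores, "fallback": p.fallback_pairs}
                    for p in placements
                ],
                "refined_origins": [list(p.refined_origin) for p in placements],
            }

            bg = cfg.stage("background")
            mosaics: list[ImagePlane] = []
            for rec in recs:
                mosaic = blend_mosaic(corrected[rec.channel_name], placements, canvas_shape=canvas)
                if rec.role == "brightfield":
                    mosaic = brightfield_flatten(mosaic, sigma_px=cfg.stage("brightfield")["sigma_px"])
                else:
                    mosaic = subtract_background(
                        mosaic, radius_px=int(bg["radius_px"]), exact=bool(bg["exact"])
                    )
                mosaics.append(mosaic)
            per_cycle.append((cyc, mosaics))

    with _timed("assemble_register"):
        stack = mio.assemble_hyperstack(per_cycle, manifest)
        reg = cfg.stage("registration")
        stack, shifts = register_cycles(
            stack,
            reference_cycle=reg["reference_cycle"],
            upsample=int(reg["upsample"]),
            max_shift_frac=float(reg["max_shift_frac"]),
        )
        artifacts["shifts"] = [
            {"cycle": s.cycle, "dy": s.dy, "dx": s.dx,
             "peak_correlation": s.peak_correlation, "flagged": s.flagged}
            for s in shifts
        ]

    bg = cfg.stage("background")
    af_scales: dict[str, float] = {}
    if bg["af_channels"]:
        with _timed("af_subtraction"):
            af_planes = [
                (i, rec) for i, rec in enumerate(stack.records)
                if rec.role == "autofluorescence"
            ]
            if not af_planes:
                raise ValidationError("af_channels configured but no autofluorescence plane")
            af = stack.planes[af_planes[-1][0]]
            for i, rec in enumerate(stack.records):
                if rec.marker in bg["af_channels"]:
                    corrected_plane, s = subtract_autofluorescence(
                        stack.planes[i], af, scale=bg["af_scale"]
                    )
                    stack.planes[i] = corrected_plane
                    af_scales[f"c{rec.cycle}_{rec.marker}"] = s
    artifacts["af_scales"] = af_scales

    with _timed("qc"):
        report = dapi_retention_qc(stack, threshold_dice=cfg.stage("phenotyping")["dice_threshold"])
        artifacts["retention"] = report.as_dicts()

    hs_path = out / "hyperstack.tif"
    mio.write_hyperstack(stack, hs_path)
    artifacts["hyperstack"] = str(hs_path)
    (out / "stitch_qc.json").write_text(json.dumps(stitch_qc, indent=1))
    (out / "qc.json").write_text(
        json.dumps({"retention": artifacts["retention"], "shifts": artifacts["shifts"]}, indent=1)
    )

    ph = cfg.stage("phenotyping")
    if ph["enabled"]:
        with _timed("phenotyping"):
            ref_cycle = cycles[0] if cfg.stage("registration")["reference_cycle"] is None else cfg.stage("registration")["reference_cycle"]
            labels = segment_nuclei(
                stack.nuclear_plane(ref_cycle),
                smooth_sigma=float(ph["smooth_sigma"]),
                min_area=int(ph["min_area"]),
                max_area=int(ph["max_area"]),
            )
            masks = {
                rec.marker: marker_mask(stack.planes[i], method=ph["mask_method"])
                for i, rec in enumerate(stack.records)
                if rec.role == "marker"
            }
            table = quantify(
                stack, labels, masks,
                threshold=float(ph["threshold"]),
                exclusive=bool(ph["exclusive"]),
                identity_markers=ph["identity_markers"],
                sample_id=cfg.input_dir.name,
                config_hash=hashlib.sha256(
                    json.dumps(cfg.params, sort_keys=True, default=str).encode()
                ).hexdigest()[:12],
            )
            table.to_csv(out / "cell_table.csv")
            export_labelmap(labels, out / "nuclei_labels.tif")
            artifacts["cell_table"] = str(out / "cell_table.csv")
            artifacts["n_cells"] = len(table)

    provenance = {
        "version": __version__,
        "config": json.loads(json.dumps(cfg.params, default=str)),
        "grid": {
            "rows": cfg.grid.rows, "cols": cfg.grid.cols,
            "tile_shape": list(cfg.grid.tile_shape),
            "overlap_fraction": cfg.grid.overlap_fraction,
            "acquisition_order": cfg.grid.acquisition_order,
        },
        "input_hash": _hash_inputs(cfg),
        "timings_s": timings,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    artifacts["provenance"] = str(out / "provenance.json")
    return artifacts
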