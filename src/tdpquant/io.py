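"""Scene I/O, Z-projection, configuration, and pipeline orchestration.

Scenes travel as two-page 16-bit TIFFs (page order: endogenous, exogenous)
with a JSON sidecar holding the pixel calibration and saturation value.
Z-stacks are reduced by per-pixel maximum projection before any
quantification, matching the projected 2-D fields all statistics are
defined on.
"""

from __future__ import annotations

import json
import logging
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__, densitometry, frap, quantify
from .segment import (
    ClassifierParams,
    ImageScene,
    SegmentationResult,
    assemblies_to_frame,
    build_cell_records,
    cells_to_frame,
    detect_assemblies,
    segment_cells,
    segment_nuclei,
)
from .synthetic import SceneConfig, render_scene

logger = logging.getLogger("tdpquant")


def max_project(stack: np.ndarray, axis: int = 0) -> np.ndarray:
    """Per-pixel maximum projection along the Z axis."""
    return np.asarray(stack).max(axis=axis)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_scene(scene: ImageScene, path) -> Path:
    """Write a scene as a two-page uint16 TIFF plus a JSON sidecar."""
    path = Path(path)
    data = np.stack(
        [
            np.clip(np.round(scene.endogenous), 0, scene.bit_saturation),
            np.clip(np.round(scene.exogenous), 0, scene.bit_saturation),
        ]
    ).astype(np.uint16)
    tifffile.imwrite(path, data)
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "pixel_size_um": scene.pixel_size_um,
                "bit_saturation": scene.bit_saturation,
                "channel_order": ["endogenous", "exogenous"],
            },
            indent=2,
        )
    )
    return path


def read_scene(
    path,
    pixel_size_um: float | None = None,
    bit_saturation: float | None = None,
) -> ImageScene:
    """Read a 1–2 channel TIFF (optionally a Z-stack) into a scene.

    Accepted layouts: (2, H, W) channel-first, (Z, 2, H, W) Z-stacks
    (max-projected), or (H, W) single-channel (used for both channels).
    Calibration comes from the JSON sidecar unless given explicitly.
    """
    path = Path(path)
    img = tifffile.imread(path)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    pixel_size_um = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    bit_saturation = (
        bit_saturation if bit_saturation is not None else meta.get("bit_saturation")
    )
    if pixel_size_um is None:
        raise ValueError(f"missing pixel calibration for {path}; provide a sidecar or flag")
    if bit_saturation is None:
        bit_saturation = float(np.iinfo(img.dtype).max) if img.dtype.kind == "u" else 65535.0

    if img.ndim == 4:  # (Z, C, H, W)
        img = max_project(img, axis=0)
    if img.ndim == 3 and img.shape[-1] in (3, 4) and img.shape[0] not in (1, 2):
        raise ValueError("RGB(A) image without a channel map is not supported")
    if img.ndim == 3:
        if img.shape[0] == 2:
            endo, exo = img[0], img[1]
        elif img.shape[0] == 1:
            endo = exo = img[0]
        else:  # treat leading axis as Z for a single-channel stack
            endo = exo = max_project(img, axis=0)
    elif img.ndim == 2:
        endo = exo = img
    else:
        raise ValueError(f"unsupported TIFF layout with shape {img.shape}")
    return ImageScene(
        endogenous=endo.astype(float),
        exogenous=exo.astype(float),
        pixel_size_um=float(pixel_size_um),
        bit_saturation=float(bit_saturation),
    )


def write_ground_truth(gt, prefix) -> None:
    prefix = Path(prefix)
    gt.cells.to_csv(prefix.with_name(prefix.name + "_cells.csv"), index=False)
    gt.assemblies.to_csv(prefix.with_name(prefix.name + "_assemblies.csv"), index=False)


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Run-level configuration (YAML-serializable, CLI-overridable)."""

    seed: int = 0
    output_dir: str = "tdpquant_out"
    pixel_size_um: float = 0.19
    bit_saturation: float = 65535.0
    classifier: dict = field(default_factory=dict)
    simulate: dict | None = None
    scenes: list[dict] | None = None  # [{path, condition, control: bool}]
    frap_traces: str | None = None
    densitometry_table: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def process_scene(scene: ImageScene, params: ClassifierParams | None = None):
    """Segment one scene end to end.

    Returns ``(seg, cells, assemblies, qc)``.
    """
    nuclei = segment_nuclei(scene)
    cells_lab = segment_cells(scene, nuclei)
    seg = SegmentationResult(nucleus_labels=nuclei, cell_labels=cells_lab)
    assemblies, qc = detect_assemblies(scene, seg, params, return_qc=True)
    cells = build_cell_records(scene, seg, assemblies)
    return seg, cells, assemblies, qc


def _gather_scenes(cfg: RunConfig):
    """Yield (name, condition, is_control, scene) from simulation or files."""
    out = []
    if cfg.simulate:
        sim = dict(cfg.simulate)
        n_images = int(sim.pop("n_images", 2))
        control_variant = sim.pop("control_variant", "GFP_only")
        conditions = sim.pop("conditions", ["WT"])
        shape = tuple(sim.pop("image_shape_px", (512, 512)))
        base = dict(
            image_shape_px=shape,
            pixel_size_um=cfg.pixel_size_um,
            bit_saturation=cfg.bit_saturation,
            **sim,
        )
        idx = 0
        for variant, is_ctrl in [(control_variant, True)] + [(v, False) for v in conditions]:
            for j in range(n_images):
                scfg = SceneConfig(variant=variant, seed=cfg.seed * 100003 + idx, **base)
                scene, _ = render_scene(scfg)
                out.append((f"{variant}_{j}", variant, is_ctrl, scene))
                idx += 1
    for entry in cfg.scenes or []:
        name = Path(entry["path"]).stem
        out.append(
            (
                name,
                entry.get("condition", name),
                bool(entry.get("control", False)),
                entry["path"],
            )
        )
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute simulate (optional) → segment → quantify (+ FRAP, densitometry).

    Per-scene failures are isolated: one unreadable scene is reported in the
    run report without aborting the batch.  Outputs tidy CSVs plus a JSON
    report under ``cfg.output_dir``; deterministic given the seed.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = ClassifierParams(**cfg.classifier)

    processed = []  # (name, condition, is_control, cells, assemblies, qc)
    failures = []
    for name, condition, is_ctrl, src in _gather_scenes(cfg):
        try:
            scene = src if isinstance(src, ImageScene) else read_scene(
                src, pixel_size_um=cfg.pixel_size_um
            )
            _, cells, assemblies, qc = process_scene(scene, params)
            processed.append((name, condition, is_ctrl, cells, assemblies, qc))
        except Exception as exc:  # scene-level isolation
            logger.warning("scene %s failed: %s", name, exc)
            failures.append({"scene": name, "error": str(exc), "trace": traceback.format_exc()})
    control_cells = [c for _, _, is_ctrl, cells, _, _ in processed if is_ctrl for c in cells]
    ref = quantify.build_control_reference(control_cells) if len(control_cells) >= 4 else None

    cell_frames, asm_frames, quant_frames, summaries = [], [], [], []
    for name, condition, is_ctrl, cells, assemblies, qc in processed:
        if ref is not None:
            quantify.apply_transfection_gate(cells, ref)
            quantify.flag_sequestering(assemblies, ref)
            quants = [quantify.partition_endogenous(c, assemblies, ref) for c in cells]
            qf = quantify.cellquants_to_frame(quants)
            qf.insert(0, "scene", name)
            qf.insert(1, "condition", condition)
            qf.insert(2, "control", is_ctrl)
            quant_frames.append(qf)
        summary = quantify.summarize_image(cells, assemblies)
        summaries.append(
            {
                "scene": name,
                "condition": condition,
                "control": is_ctrl,
                "n_cells": summary.n_cells,
                "n_transfected": summary.n_transfected,
                "pct_cells_with_puncta": summary.pct_cells_with_puncta,
                "puncta_per_cell": summary.puncta_per_cell,
                "pct_transfected_with_inclusions": summary.pct_transfected_with_inclusions,
                "inclusions_per_transfected_cell": summary.inclusions_per_transfected_cell,
                **{f"qc_{k}": v for k, v in qc.items()},
            }
        )
        cf = cells_to_frame(cells)
        cf.insert(0, "scene", name)
        cf.insert(1, "condition", condition)
        cell_frames.append(cf)
        af = assemblies_to_frame(assemblies)
        af.insert(0, "scene", name)
        af.insert(1, "condition", condition)
        asm_frames.append(af)

    if cell_frames:
        pd.concat([f for f in cell_frames if len(f)] or cell_frames).to_csv(
            outdir / "cells.csv", index=False
        )
        pd.concat([f for f in asm_frames if len(f)] or asm_frames).to_csv(
            outdir / "assemblies.csv", index=False
        )
    pd.DataFrame(summaries).to_csv(outdir / "image_summaries.csv", index=False)

    regressions = []
    if quant_frames:
        quant = pd.concat(quant_frames)
        quant.to_csv(outdir / "cell_quant.csv", index=False)
        # control batches yield the reference, not regressions
        for condition, grp in quant[~quant.control].groupby("condition"):
            sel = grp[grp.exogenous_level > (ref.transfected_gfp_threshold if ref else 0)]
            if len(sel) >= 3 and np.ptp(sel.exogenous_level.to_numpy()) > 0:
                for response, col in (
                    ("diffuse", "diffuse_signal"),
                    ("sequestered", "sequestered_signal"),
                ):
                    r = quantify.regress_concentration(
                        sel.exogenous_level, sel[col], response
                    )
                    regressions.append(
                        {
                            "condition": condition,
                            "response": response,
                            "slope": r.slope,
                            "intercept": r.intercept,
                            "r_squared": r.r_squared,
                            "n": r.n,
                        }
                    )
    if regressions:
        pd.DataFrame(regressions).to_csv(outdir / "regressions.csv", index=False)

    frap_out = None
    if cfg.frap_traces:
        metrics = frap.analyze_traces_frame(pd.read_csv(cfg.frap_traces))
        metrics.to_csv(outdir / "frap_metrics.csv", index=False)
        frap_out = len(metrics)
    dens_out = None
    if cfg.densitometry_table:
        lanes = densitometry.lanes_from_frame(pd.read_csv(cfg.densitometry_table))
        densitometry.ratios_frame(lanes).to_csv(outdir / "editing_ratios.csv", index=False)
        dens_out = len(lanes)

    report = {
        "version": __version__,
        "config": asdict(cfg),
        "n_scenes": len(processed),
        "n_failed_scenes": len(failures),
        "failures": failures,
        "control_reference": asdict(ref) if ref else None,
        "regressions": regressions,
        "n_frap_traces": frap_out,
        "n_densitometry_lanes": dens_out,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
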