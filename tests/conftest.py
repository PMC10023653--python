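"""Shared fixtures: synthetic scenes and hand-built classifier objects."""

from __future__ import annotations

import math

import numpy as np
import pytest

from tdpquant.io import process_scene
from tdpquant.segment import ClassifierParams, ImageScene, SegmentationResult
from tdpquant.synthetic import SceneConfig, render_scene

SAT = 65535.0
PX = 0.19


def paint_disk(img, center, diameter_um, value, px=PX, core_frac=None, core_value=None):
    """Paint a disk (or a ring when core_frac is given) of known diameter."""
    r = 0.5 * diameter_um / px
    cy, cx = center
    yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    img[d2 <= r * r] = value
    if core_frac is not None:
        img[d2 <= (core_frac * r) ** 2] = core_value


def object_scene(objects, shape=(200, 200), nucleus=None, px=PX):
    """Scene with hand-placed exogenous objects on a blank background.

    ``objects``: list of dicts with center, diameter_um, value and optional
    core_frac/core_value.  ``nucleus``: optional (center, radius_um) painted
    as the single nucleus label.
    """
    exo = np.zeros(shape)
    endo = np.zeros(shape)
    for ob in objects:
        paint_disk(
            exo, ob["center"], ob["diameter_um"], ob["value"], px=px,
            core_frac=ob.get("core_frac"), core_value=ob.get("core_value"),
        )
    nuc = np.zeros(shape, np.int32)
    cell = np.zeros(shape, np.int32)
    if nucleus is not None:
        (cy, cx), r_um = nucleus
        r = r_um / px
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        nuc[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = 1
        cell[:] = 1
    scene = ImageScene(endogenous=endo, exogenous=exo, pixel_size_um=px, bit_saturation=SAT)
    return scene, SegmentationResult(nucleus_labels=nuc, cell_labels=cell)


def classify_oracle(mask_area_px, max_frac, core_rim_ratio, px=PX, params=None):
    """Independent restatement of the decision table on measured properties."""
    p = params or ClassifierParams()
    eq_diam = 2.0 * math.sqrt(mask_area_px * px * px / math.pi)
    if eq_diam >= p.inclusion_min_diameter_um and max_frac >= p.inclusion_intensity_frac:
        return "inclusion"
    if p.puncta_min_diameter_um <= eq_diam < p.puncta_max_diameter_um:
        return "anisosome" if core_rim_ratio <= p.shell_core_rim_ratio_max else "punctum"
    return None


def match_to_detected(gt, assemblies, shape):
    """Match ground-truth assemblies to detections by centre containment."""
    amap = np.zeros(shape, np.int32)
    for r in assemblies:
        amap[r.rows, r.cols] = r.id
    byid = {r.id: r for r in assemblies}
    out = []
    for _, a in gt.assemblies.iterrows():
        did = int(amap[int(round(a.row)), int(round(a.col))])
        out.append((a, byid.get(did)))
    return out


NUCLEAR_ORACLE = dict(
    variant="2KQ",
    assembly_rates={"anisosome": 3.0, "punctum": 1.5, "inclusion": 0.3},
    sequestration_coefficient=6.0,
    noise_sd=0.0,
    overlap_policy="drop",
)
CYTO_ORACLE = dict(
    variant="dNLS_2KQ",
    assembly_rates={"punctum": 2.0},
    sequestration_coefficient=4.0,
    noise_sd=0.0,
    overlap_policy="drop",
)


@pytest.fixture(scope="session")
def nuclear_oracle_scene():
    """One noiseless nuclear-variant scene plus its processed results."""
    cfg = SceneConfig(n_cells=12, image_shape_px=(640, 640), seed=7, **NUCLEAR_ORACLE)
    scene, gt = render_scene(cfg)
    seg, cells, assemblies, qc = process_scene(scene)
    return cfg, scene, gt, seg, cells, assemblies


@pytest.fixture(scope="session")
def control_scene():
    """GFP-only control scene (no assemblies, no sequestration)."""
    cfg = SceneConfig(
        variant="GFP_only", n_cells=14, image_shape_px=(640, 640), noise_sd=150.0, seed=21
    )
    scene, gt = render_scene(cfg)
    seg, cells, assemblies, qc = process_scene(scene)
    return cfg, scene, gt, seg, cells, assemblies
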