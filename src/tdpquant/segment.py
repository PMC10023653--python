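"""Nucleus/cell segmentation and assembly detection/classification.

Scenes carry two channels: the endogenous (CRISPR-tagged, e.g. mCherry)
channel, which is diffuse and nuclear in every cell, and the exogenous
(over-expressed GFP-variant) channel, which is bright only in transfected
cells and concentrated inside self-assembled structures.

Assemblies detected in the exogenous channel are classified by a fixed
decision table expressed in physical units:

* candidate objects are connected components of pixels at or above 25% of
  the bit saturation value;
* an object is an **inclusion** when its area-equivalent diameter is at
  least 4 µm and its maximum intensity reaches 60% of saturation;
* otherwise, objects of 0.5–4 µm equivalent diameter are **anisosomes**
  (shell-like, dark core) when the mean intensity of the core zone (within
  40% of the equivalent radius of the hole-filled object) is at most half
  the rim mean, and **puncta** (radially homogeneous droplets) otherwise;
* everything else is discarded and tallied in a QC report.

An object is *nuclear* when at least half of its (hole-filled) pixels fall
inside the parent nucleus, *cytoplasmic* otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_li, threshold_otsu
from skimage.measure import profile_line, regionprops
from skimage.segmentation import expand_labels, watershed

CORE_RADIUS_FRAC = 0.4  # core zone = pixels within this fraction of the equivalent radius


@dataclass
class ImageScene:
    """Two-channel scene with pixel calibration; the unit of segmentation."""

    endogenous: np.ndarray
    exogenous: np.ndarray
    pixel_size_um: float = 0.19
    bit_saturation: float = 65535.0

    def __post_init__(self) -> None:
        self.endogenous = np.asarray(self.endogenous, dtype=float)
        self.exogenous = np.asarray(self.exogenous, dtype=float)
        if self.endogenous.shape != self.exogenous.shape:
            raise ValueError("channels must have the same shape")
        if self.endogenous.ndim != 2:
            raise ValueError("channels must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.bit_saturation <= 0:
            raise ValueError("bit_saturation must be positive")


@dataclass
class ClassifierParams:
    """Decision-table thresholds, in fractions of saturation and µm."""

    inclusion_intensity_frac: float = 0.60
    puncta_intensity_frac: float = 0.25
    inclusion_min_diameter_um: float = 4.0
    puncta_min_diameter_um: float = 0.5
    puncta_max_diameter_um: float = 4.0
    shell_core_rim_ratio_max: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.puncta_intensity_frac < self.inclusion_intensity_frac <= 1):
            raise ValueError("need 0 < puncta frac < inclusion frac <= 1")
        if not (0 < self.puncta_min_diameter_um < self.puncta_max_diameter_um):
            raise ValueError("puncta diameter bounds out of order")


@dataclass
class SegmentationResult:
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray


@dataclass
class AssemblyRecord:
    """One detected object, with per-channel intensity bookkeeping.

    Sums are split by compartment so that downstream pool partitioning can
    hold the conservation identity exactly (masks are disjoint pixel sets).
    """

    id: int
    cell_id: int
    cls: str  # inclusion | anisosome | punctum
    compartment: str  # nuclear | cytoplasmic
    rows: np.ndarray
    cols: np.ndarray
    area_um2: float
    equivalent_diameter_um: float
    mean_exogenous: float
    max_exogenous: float
    mean_endogenous: float
    core_rim_ratio: float
    on_border: bool
    endogenous_sum_nuclear: float
    endogenous_sum_cytoplasmic: float
    n_px_nuclear: int
    n_px_cytoplasmic: int
    sequestering: bool | None = None


@dataclass
class CellRecord:
    """One segmented cell with partitioned nuclear endogenous pools."""

    id: int
    nucleus_area_px: int
    cell_area_px: int
    nuclear_endogenous_total_mean: float
    nuclear_endogenous_diffuse_mean: float
    nuclear_total_sum: float
    nuclear_diffuse_sum: float
    diffuse_area_px: int
    exogenous_level: float
    assembly_ids: list[int] = field(default_factory=list)
    transfected: bool | None = None


_THRESHOLDS = {"li": threshold_li, "otsu": threshold_otsu}


def segment_nuclei(
    scene: ImageScene,
    min_diameter_um: float = 5.0,
    method: str = "li",
) -> np.ndarray:
    """Label nuclei from the endogenous channel.

    Global automatic threshold, hole filling (nucleolar voids and
    assembly-core voids belong to the nucleus), removal of objects below the
    minimum nucleus diameter, then distance-transform watershed to split
    touching nuclei.
    """
    img = scene.endogenous
    if img.max() <= 0:
        return np.zeros(img.shape, dtype=np.int32)
    thresh = _THRESHOLDS[method](img)
    fg = ndimage.binary_fill_holes(img > thresh)
    min_r_px = 0.5 * min_diameter_um / scene.pixel_size_um
    min_area_px = math.pi * min_r_px**2
    lab, _ = ndimage.label(fg)
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_area_px
    keep[0] = False
    fg = keep[lab]
    if not fg.any():
        return np.zeros(img.shape, dtype=np.int32)

    dist = ndimage.distance_transform_edt(fg)
    # seeds: maxima of the smoothed distance map, at least a nucleus radius apart
    smooth = ndimage.gaussian_filter(dist, sigma=min_r_px / 2)
    footprint = np.ones((int(2 * min_r_px) | 1,) * 2, dtype=bool)
    maxima = (smooth == ndimage.maximum_filter(smooth, footprint=footprint)) & fg
    markers, n = ndimage.label(maxima)
    if n == 0:
        markers, _ = ndimage.label(fg)
    # collapse marker plateaus to single labels per connected plateau (already labeled)
    labels = watershed(-dist, markers=markers, mask=fg)
    # merge over-segmented fragments below the minimum nucleus area into neighbours
    sizes = np.bincount(labels.ravel())
    small = np.nonzero(sizes < min_area_px)[0]
    small = small[small != 0]
    for s in small:
        grown = expand_labels(np.where(labels == s, 0, labels), distance=2)
        region = labels == s
        neigh = grown[region]
        neigh = neigh[neigh > 0]
        labels[region] = np.bincount(neigh).argmax() if neigh.size else 0
    return _relabel_sequential(labels)


def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1)
    return lut[labels]


def segment_cells(
    scene: ImageScene,
    nuclei: np.ndarray,
    max_expand_um: float = 8.0,
    method: str = "li",
) -> np.ndarray:
    """Grow each nucleus into a cell region by bounded expansion.

    Expansion is limited to ``max_expand_um`` beyond the nucleus and to
    foreground of the summed two-channel image, so untransfected cells with
    dark cytoplasm stay close to their nuclei.  Every nucleus pixel belongs
    to its own cell by construction.
    """
    if nuclei.max() == 0:
        return np.zeros_like(nuclei)
    total = scene.endogenous + scene.exogenous
    thresh = _THRESHOLDS[method](total) if total.max() > 0 else np.inf
    fg = ndimage.binary_fill_holes(total > thresh)
    expanded = expand_labels(nuclei, distance=max_expand_um / scene.pixel_size_um)
    cells = np.where(fg | (nuclei > 0), expanded, 0)
    # keep each cell connected to its nucleus
    return np.where(cells > 0, cells, 0).astype(np.int32)


def detect_assemblies(
    scene: ImageScene,
    seg: SegmentationResult,
    params: ClassifierParams | None = None,
    return_qc: bool = False,
):
    """Detect and classify exogenous-channel assemblies.

    Returns the list of :class:`AssemblyRecord`; with ``return_qc=True``
    also returns a dict counting discarded candidates (too small, or large
    objects that fail the inclusion intensity criterion).
    """
    params = params or ClassifierParams()
    px = scene.pixel_size_um
    sat = scene.bit_saturation
    exo = scene.exogenous
    endo = scene.endogenous
    candidate = exo >= params.puncta_intensity_frac * sat
    lab, n = ndimage.label(candidate)
    qc = {"too_small": 0, "unclassified_large": 0, "n_candidates": int(n)}
    records: list[AssemblyRecord] = []
    next_id = 1
    h, w = exo.shape
    for sl, obj_idx in zip(ndimage.find_objects(lab), range(1, n + 1)):
        raw = lab[sl] == obj_idx
        filled = ndimage.binary_fill_holes(raw)
        rows, cols = np.nonzero(filled)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        area_px = rows.size
        area_um2 = area_px * px * px
        eq_diam_um = 2.0 * math.sqrt(area_um2 / math.pi)
        vals = exo[rows, cols]
        max_int = float(vals.max())
        core_rim = math.nan
        if eq_diam_um >= params.inclusion_min_diameter_um and max_int >= params.inclusion_intensity_frac * sat:
            cls = "inclusion"
        elif params.puncta_min_diameter_um <= eq_diam_um < params.puncta_max_diameter_um:
            core_rim = _core_rim_ratio(exo, rows, cols, px, eq_diam_um)
            cls = "anisosome" if core_rim <= params.shell_core_rim_ratio_max else "punctum"
        else:
            if eq_diam_um < params.puncta_min_diameter_um:
                qc["too_small"] += 1
            else:
                qc["unclassified_large"] += 1
            continue

        cell_id = _parent_cell(seg.cell_labels, rows, cols)
        in_nucleus = seg.nucleus_labels[rows, cols] == cell_id if cell_id else np.zeros(area_px, bool)
        nuclear_frac = in_nucleus.mean() if area_px else 0.0
        compartment = "nuclear" if nuclear_frac >= 0.5 else "cytoplasmic"
        endo_vals = endo[rows, cols]
        on_border = bool(
            (rows.min() == 0) or (cols.min() == 0) or (rows.max() == h - 1) or (cols.max() == w - 1)
        )
        records.append(
            AssemblyRecord(
                id=next_id,
                cell_id=int(cell_id),
                cls=cls,
                compartment=compartment,
                rows=rows,
                cols=cols,
                area_um2=area_um2,
                equivalent_diameter_um=eq_diam_um,
                mean_exogenous=float(vals.mean()),
                max_exogenous=max_int,
                mean_endogenous=float(endo_vals.mean()),
                core_rim_ratio=core_rim,
                on_border=on_border,
                endogenous_sum_nuclear=float(endo_vals[in_nucleus].sum()),
                endogenous_sum_cytoplasmic=float(endo_vals[~in_nucleus].sum()),
                n_px_nuclear=int(in_nucleus.sum()),
                n_px_cytoplasmic=int((~in_nucleus).sum()),
            )
        )
        next_id += 1
    if return_qc:
        return records, qc
    return records


def _core_rim_ratio(
    exo: np.ndarray, rows: np.ndarray, cols: np.ndarray, px: float, eq_diam_um: float
) -> float:
    """Mean intensity of the core zone over the rim zone of a filled object."""
    cy, cx = rows.mean(), cols.mean()
    r_core_px = CORE_RADIUS_FRAC * (0.5 * eq_diam_um / px)
    d2 = (rows - cy) ** 2 + (cols - cx) ** 2
    core = d2 <= r_core_px**2
    if not core.any() or core.all():
        return 1.0  # degenerate: no resolvable core/rim split
    vals = exo[rows, cols]
    rim_mean = vals[~core].mean()
    if rim_mean <= 0:
        return 1.0
    return float(vals[core].mean() / rim_mean)


def _parent_cell(cell_labels: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> int:
    cy, cx = int(round(rows.mean())), int(round(cols.mean()))
    cid = int(cell_labels[cy, cx])
    if cid:
        return cid
    under = cell_labels[rows, cols]
    under = under[under > 0]
    return int(np.bincount(under).argmax()) if under.size else 0


def build_cell_records(
    scene: ImageScene,
    seg: SegmentationResult,
    assemblies: list[AssemblyRecord],
) -> list[CellRecord]:
    """Per-cell nuclear pools: total, and diffuse (nucleus minus assemblies).

    Because detected assemblies are disjoint connected components, the
    diffuse and sequestered nuclear sums partition the nuclear total exactly.
    """
    endo = scene.endogenous
    exo = scene.exogenous
    by_cell: dict[int, list[AssemblyRecord]] = {}
    for rec in assemblies:
        by_cell.setdefault(rec.cell_id, []).append(rec)
    out: list[CellRecord] = []
    for cid in range(1, int(seg.nucleus_labels.max()) + 1):
        nuc = seg.nucleus_labels == cid
        nuc_area = int(nuc.sum())
        if nuc_area == 0:
            continue
        cell = seg.cell_labels == cid
        total_sum = float(endo[nuc].sum())
        recs = by_cell.get(cid, [])
        seq_nuc_sum = sum(r.endogenous_sum_nuclear for r in recs)
        seq_nuc_px = sum(r.n_px_nuclear for r in recs)
        diffuse_sum = total_sum - seq_nuc_sum
        diffuse_px = nuc_area - seq_nuc_px
        out.append(
            CellRecord(
                id=cid,
                nucleus_area_px=nuc_area,
                cell_area_px=int(cell.sum()),
                nuclear_endogenous_total_mean=total_sum / nuc_area,
                nuclear_endogenous_diffuse_mean=diffuse_sum / diffuse_px if diffuse_px else math.nan,
                nuclear_total_sum=total_sum,
                nuclear_diffuse_sum=diffuse_sum,
                diffuse_area_px=diffuse_px,
                exogenous_level=float(exo[cell].mean()) if cell.any() else math.nan,
                assembly_ids=[r.id for r in recs],
            )
        )
    return out


def line_profile(
    scene: ImageScene,
    start: tuple[float, float],
    end: tuple[float, float],
    control_means: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Sampled intensities of both channels along a segment.

    ``start``/``end`` are (row, col) pixel coordinates.  When
    ``control_means`` = (endogenous, exogenous) is supplied, each channel is
    normalized to the corresponding mean level of GFP-transfected control
    cells, matching the relative-intensity convention of per-cell profile
    panels.
    """
    h, w = scene.endogenous.shape
    for p in (start, end):
        if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
            raise ValueError("profile endpoints must lie inside the image")
    if start == end:
        raise ValueError("degenerate zero-length segment")
    endo = profile_line(scene.endogenous, start, end, mode="reflect")
    exo = profile_line(scene.exogenous, start, end, mode="reflect")
    dist_um = np.linspace(0, math.hypot(end[0] - start[0], end[1] - start[1]), endo.size)
    dist_um = dist_um * scene.pixel_size_um
    if control_means is not None:
        endo = endo / control_means[0]
        exo = exo / control_means[1]
    return pd.DataFrame({"distance_um": dist_um, "endogenous": endo, "exogenous": exo})


def assemblies_to_frame(assemblies: list[AssemblyRecord]) -> pd.DataFrame:
    cols = [
        "id", "cell_id", "cls", "compartment", "area_um2", "equivalent_diameter_um",
        "mean_exogenous", "max_exogenous", "mean_endogenous", "core_rim_ratio",
        "on_border", "endogenous_sum_nuclear", "endogenous_sum_cytoplasmic",
        "n_px_nuclear", "n_px_cytoplasmic", "sequestering",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in assemblies], columns=cols)


def frame_to_assemblies(df: pd.DataFrame) -> list[AssemblyRecord]:
    """Rebuild assembly records from a CSV frame (pixel masks not restored)."""
    out = []
    for _, r in df.iterrows():
        out.append(
            AssemblyRecord(
                id=int(r.id), cell_id=int(r.cell_id), cls=r.cls, compartment=r.compartment,
                rows=np.empty(0, int), cols=np.empty(0, int),
                area_um2=float(r.area_um2),
                equivalent_diameter_um=float(r.equivalent_diameter_um),
                mean_exogenous=float(r.mean_exogenous), max_exogenous=float(r.max_exogenous),
                mean_endogenous=float(r.mean_endogenous),
                core_rim_ratio=float(r.core_rim_ratio), on_border=bool(r.on_border),
                endogenous_sum_nuclear=float(r.endogenous_sum_nuclear),
                endogenous_sum_cytoplasmic=float(r.endogenous_sum_cytoplasmic),
                n_px_nuclear=int(r.n_px_nuclear), n_px_cytoplasmic=int(r.n_px_cytoplasmic),
            )
        )
    return out


def frame_to_cells(df: pd.DataFrame) -> list[CellRecord]:
    """Rebuild cell records from a CSV frame (pixel masks not restored)."""
    out = []
    for _, r in df.iterrows():
        out.append(
            CellRecord(
                id=int(r.id), nucleus_area_px=int(r.nucleus_area_px),
                cell_area_px=int(r.cell_area_px),
                nuclear_endogenous_total_mean=float(r.nuclear_endogenous_total_mean),
                nuclear_endogenous_diffuse_mean=float(r.nuclear_endogenous_diffuse_mean),
                nuclear_total_sum=float(r.nuclear_total_sum),
                nuclear_diffuse_sum=float(r.nuclear_diffuse_sum),
                diffuse_area_px=int(r.diffuse_area_px),
                exogenous_level=float(r.exogenous_level),
            )
        )
    return out


def cells_to_frame(cells: list[CellRecord]) -> pd.DataFrame:
    cols = [
        "id", "nucleus_area_px", "cell_area_px", "nuclear_endogenous_total_mean",
        "nuclear_endogenous_diffuse_mean", "nuclear_total_sum", "nuclear_diffuse_sum",
        "diffuse_area_px", "exogenous_level", "transfected",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in cells], columns=cols)
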