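"""Per-cell and per-image sequestration statistics.

The central readout is the depletion of the *diffuse* nuclear endogenous
TDP-43 pool (nucleus excluding assembly pixels) as exogenous variant
expression rises, and its exact complement: the endogenous signal
*sequestered* into nuclear or cytoplasmic assemblies.  All pools are pixel
sums over disjoint masks, so

    diffuse + nuclear-sequestered = nuclear total

holds exactly for every cell.  Fold changes are normalized to the mean
nuclear endogenous intensity of GFP-only control cells; an assembly is
*sequestering* when its mean endogenous intensity strictly exceeds the
lower-quartile diffuse nuclear intensity of those control cells.
Concentration dependence is assessed by ordinary least squares of a per-cell
response (diffuse or sequestered signal) against the cell's exogenous level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .segment import AssemblyRecord, CellRecord


@dataclass
class ControlReference:
    """Intensity references derived from GFP-only control cells."""

    control_diffuse_Q1: float
    control_mean_endogenous: float
    control_mean_exogenous: float
    transfected_gfp_threshold: float


@dataclass
class CellQuant:
    cell_id: int
    fold_total_nuclear: float
    fold_diffuse_nuclear: float
    diffuse_signal: float
    sequestered_signal: float  # nuclear + cytoplasmic assembly pixels
    sequestered_nuclear_signal: float
    sequestered_cytoplasmic_signal: float
    proportion_sequestered: float
    exogenous_level: float


@dataclass
class ImageSummary:
    n_cells: int
    n_transfected: int
    pct_cells_with_puncta: float
    puncta_per_cell: float
    pct_transfected_with_inclusions: float
    inclusions_per_transfected_cell: float
    mean_area_um2_by_class: dict
    pct_sequestering_by_class_compartment: dict


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared out of [0, 1]")


def build_control_reference(
    control_cells: list[CellRecord], quantile_method: str = "linear"
) -> ControlReference:
    """Quartile, mean and gating references from GFP-only control cells.

    The lower quartile of per-cell diffuse nuclear means uses
    linear-interpolation between order statistics (configurable through
    ``quantile_method``, passed to :func:`numpy.quantile`).

    Control scenes mix GFP-positive and GFP-negative cells, so the
    transfection gate is the 99th percentile of exogenous intensity within
    the GFP-*negative* subpopulation (below an Otsu split of the control
    exogenous levels); when the split is degenerate the 99th percentile of
    all control cells is used.  The control exogenous mean, used to
    normalize intensity profiles, is taken over the GFP-positive
    subpopulation when one exists.
    """
    if len(control_cells) < 4:
        raise ValueError("need at least 4 control cells")
    diffuse = np.array([c.nuclear_endogenous_diffuse_mean for c in control_cells])
    total = np.array([c.nuclear_endogenous_total_mean for c in control_cells])
    exo = np.array([c.exogenous_level for c in control_cells])
    gate_pop = exo
    pos_pop = exo
    if np.ptp(exo) > 0:
        from skimage.filters import threshold_otsu

        split = threshold_otsu(exo)
        low, high = exo[exo <= split], exo[exo > split]
        if low.size >= 2 and high.size >= 1:
            gate_pop, pos_pop = low, high
    return ControlReference(
        control_diffuse_Q1=float(np.quantile(diffuse, 0.25, method=quantile_method)),
        control_mean_endogenous=float(total.mean()),
        control_mean_exogenous=float(pos_pop.mean()),
        transfected_gfp_threshold=float(np.quantile(gate_pop, 0.99, method=quantile_method)),
    )


def flag_sequestering(
    assemblies: list[AssemblyRecord], ref: ControlReference
) -> list[AssemblyRecord]:
    """Mark assemblies whose mean endogenous intensity strictly exceeds Q1."""
    for rec in assemblies:
        rec.sequestering = bool(rec.mean_endogenous > ref.control_diffuse_Q1)
    return assemblies


def apply_transfection_gate(
    cells: list[CellRecord], ref: ControlReference
) -> list[CellRecord]:
    """Set the transfected flag: exogenous level above the control gate."""
    for c in cells:
        c.transfected = bool(c.exogenous_level > ref.transfected_gfp_threshold)
    return cells


def partition_endogenous(
    cell: CellRecord,
    assemblies: list[AssemblyRecord],
    ref: ControlReference | None = None,
) -> CellQuant:
    """Split a cell's endogenous signal into diffuse and sequestered pools.

    Nuclear conservation (diffuse + nuclear sequestered = nuclear total) is
    exact by mask disjointness; cytoplasmic assembly signal is reported
    separately and enters the whole-cell sequestered proportion.
    """
    if cell.nucleus_area_px <= 0:
        raise ValueError(f"cell {cell.id} has no nucleus mask")
    own = [a for a in assemblies if a.cell_id == cell.id]
    seq_nuc = float(sum(a.endogenous_sum_nuclear for a in own))
    seq_cyt = float(sum(a.endogenous_sum_cytoplasmic for a in own))
    diffuse = cell.nuclear_total_sum - seq_nuc
    pool = diffuse + seq_nuc + seq_cyt
    prop = (seq_nuc + seq_cyt) / pool if pool > 0 else 0.0
    if ref is not None and ref.control_mean_endogenous > 0:
        fold_total = cell.nuclear_endogenous_total_mean / ref.control_mean_endogenous
        fold_diffuse = cell.nuclear_endogenous_diffuse_mean / ref.control_mean_endogenous
    else:
        fold_total = math.nan
        fold_diffuse = math.nan
    return CellQuant(
        cell_id=cell.id,
        fold_total_nuclear=fold_total,
        fold_diffuse_nuclear=fold_diffuse,
        diffuse_signal=diffuse,
        sequestered_signal=seq_nuc + seq_cyt,
        sequestered_nuclear_signal=seq_nuc,
        sequestered_cytoplasmic_signal=seq_cyt,
        proportion_sequestered=prop,
        exogenous_level=cell.exogenous_level,
    )


_PUNCTA_LIKE = ("punctum", "anisosome")


def summarize_image(
    cells: list[CellRecord], assemblies: list[AssemblyRecord]
) -> ImageSummary:
    """Per-image assembly frequency and size statistics.

    Puncta/anisosome frequencies are per cell; inclusion frequencies are per
    *transfected* cell and reported as NaN when the image has no transfected
    cells (undefined denominator, not zero).  Border-straddling objects are
    excluded from size statistics.
    """
    n_cells = len(cells)
    if n_cells == 0:
        return ImageSummary(0, 0, math.nan, math.nan, math.nan, math.nan, {}, {})
    transfected = [c for c in cells if c.transfected]
    by_cell: dict[int, list[AssemblyRecord]] = {}
    for a in assemblies:
        by_cell.setdefault(a.cell_id, []).append(a)

    def _count(cell: CellRecord, classes) -> int:
        return sum(1 for a in by_cell.get(cell.id, []) if a.cls in classes)

    puncta_counts = [_count(c, _PUNCTA_LIKE) for c in cells]
    pct_with_puncta = 100.0 * np.mean([n > 0 for n in puncta_counts])
    puncta_per_cell = float(np.mean(puncta_counts))
    if transfected:
        incl_counts = [_count(c, ("inclusion",)) for c in transfected]
        pct_transf_incl = 100.0 * np.mean([n > 0 for n in incl_counts])
        incl_per_transf = float(np.mean(incl_counts))
    else:
        pct_transf_incl = math.nan
        incl_per_transf = math.nan

    areas: dict[str, float] = {}
    for cls in ("inclusion", "anisosome", "punctum"):
        vals = [a.area_um2 for a in assemblies if a.cls == cls and not a.on_border]
        areas[cls] = float(np.mean(vals)) if vals else math.nan
    seq_pct: dict[tuple[str, str], float] = {}
    for cls in ("inclusion", "anisosome", "punctum"):
        for comp in ("nuclear", "cytoplasmic"):
            flags = [
                a.sequestering
                for a in assemblies
                if a.cls == cls and a.compartment == comp and a.sequestering is not None
            ]
            seq_pct[(cls, comp)] = 100.0 * float(np.mean(flags)) if flags else math.nan
    return ImageSummary(
        n_cells=n_cells,
        n_transfected=len(transfected),
        pct_cells_with_puncta=float(pct_with_puncta),
        puncta_per_cell=puncta_per_cell,
        pct_transfected_with_inclusions=pct_transf_incl,
        inclusions_per_transfected_cell=incl_per_transf,
        mean_area_um2_by_class=areas,
        pct_sequestering_by_class_compartment=seq_pct,
    )


def regress_concentration(
    exogenous_levels, responses, response: str = "diffuse"
) -> RegressionResult:
    """OLS fit of a per-cell response against exogenous expression level."""
    x = np.asarray(exogenous_levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size:
        raise ValueError("predictor and response lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 cells for a regression")
    if np.ptp(x) == 0:
        raise ValueError("degenerate zero-variance predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    rsq = float(model.rsquared)
    if not math.isfinite(rsq):  # constant response: no variance to explain
        rsq = 0.0
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=min(max(rsq, 0.0), 1.0),
        n=int(x.size),
    )


def cellquants_to_frame(quants: list[CellQuant]) -> pd.DataFrame:
    cols = [
        "cell_id", "fold_total_nuclear", "fold_diffuse_nuclear", "diffuse_signal",
        "sequestered_signal", "sequestered_nuclear_signal",
        "sequestered_cytoplasmic_signal", "proportion_sequestered", "exogenous_level",
    ]
    return pd.DataFrame([{c: getattr(q, c) for c in cols} for q in quants], columns=cols)
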