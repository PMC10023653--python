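"""Ground-truthed synthetic microscopy scenes and FRAP traces.

The generator emulates two-channel (endogenous-mCherry, exogenous-GFP)
single-plane confocal fields of HEK-like cells:

* every cell carries diffuse nuclear endogenous signal with 1–3 dark
  nucleolar voids;
* a configurable fraction of cells is transfected with an exogenous
  TDP-43-GFP variant whose per-cell level is lognormal (cell-to-cell
  variability in over-expression);
* transfected cells form assemblies — droplet-like *puncta* (0.5–2.5 µm
  homogeneous disks), shell-like *anisosomes* (1–4 µm rings with a dark
  core) and saturated amorphous *inclusions* (> 4 µm) — at per-class
  Poisson counts;
* the endogenous channel is enriched inside assemblies by a partition
  coefficient that scales with the cell's exogenous expression level
  (mass-action-like recruitment, the source of concentration-dependent
  sequestration), while the per-cell total endogenous pool is conserved
  exactly, so sequestration of the diffuse nuclear pool is a ground truth
  rather than a fitted quantity;
* Gaussian read noise is added last; ground truth is emitted before noise.

Nuclear variants (WT, 4FL, 2KQ) express and assemble in the nucleus; ∆NLS
variants in the cytoplasm; anisosomes are nuclear structures.  The scene is
a 2-D field; projected 3-D assemblies may overlap, so crowded regimes (for
example the ~20 anisosomes per cell formed by nuclear 4FL/2KQ) render with
overlapping rings, with pixel ownership resolved first-placed-wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frap import FrapTrace
from .segment import ImageScene

VARIANTS = ("GFP_only", "WT", "4FL", "2KQ", "dNLS", "dNLS_4FL", "dNLS_2KQ")
CYTOPLASMIC_VARIANTS = frozenset({"dNLS", "dNLS_4FL", "dNLS_2KQ"})

# true diameter ranges (µm) per assembly class
CLASS_DIAMETER_UM = {
    "punctum": (0.5, 2.5),
    "anisosome": (1.0, 4.0),
    "inclusion": (4.6, 7.0),
}
ANISOSOME_CORE_FRAC = 0.5  # inner/outer radius of the shell
ANISOSOME_CORE_LEVEL = 0.15  # core intensity relative to rim (<= 0.3 by construction)

DEFAULT_ASSEMBLY_RATES = {
    "GFP_only": {},
    "WT": {"punctum": 1.5, "inclusion": 0.3},
    "4FL": {"anisosome": 20.0, "inclusion": 0.3},
    "2KQ": {"anisosome": 20.0, "inclusion": 0.3},
    "dNLS": {"punctum": 2.0, "inclusion": 0.5},
    "dNLS_4FL": {"punctum": 3.0, "inclusion": 0.8},
    "dNLS_2KQ": {"punctum": 3.0, "inclusion": 0.8},
}
DEFAULT_SEQUESTRATION = {
    "GFP_only": 0.0,
    "WT": 3.0,
    "4FL": 6.0,
    "2KQ": 6.0,
    "dNLS": 2.0,
    "dNLS_4FL": 4.0,
    "dNLS_2KQ": 4.0,
}


@dataclass
class SceneConfig:
    """Study conditions for one rendered scene."""

    image_shape_px: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.19
    bit_saturation: float = 65535.0
    n_cells: int = 30
    transfection_fraction: float = 0.7
    exo_expression_log_mean: float = math.log(0.05 * 65535.0)
    exo_expression_log_sd: float = 0.5
    variant: str = "WT"
    assembly_rates: dict[str, float] | None = None
    sequestration_coefficient: float | None = None
    endo_level_log_mean: float = math.log(0.12 * 65535.0)
    endo_level_log_sd: float = 0.08
    nucleus_semi_major_um: tuple[float, float] = (5.0, 6.5)
    nucleus_aspect: tuple[float, float] = (0.75, 0.95)
    cyto_scale: float = 1.6
    noise_sd: float = 300.0
    overlap_policy: str = "overlap"  # "overlap": accept crowding (projected 3-D); "drop": omit unplaceable draws
    seed: int = 0

    def __post_init__(self) -> None:
        if self.overlap_policy not in ("overlap", "drop"):
            raise ValueError("overlap_policy must be 'overlap' or 'drop'")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.assembly_rates is None:
            self.assembly_rates = dict(DEFAULT_ASSEMBLY_RATES[self.variant])
        if self.sequestration_coefficient is None:
            self.sequestration_coefficient = DEFAULT_SEQUESTRATION[self.variant]
        if any(r < 0 for r in self.assembly_rates.values()):
            raise ValueError("assembly rates must be nonnegative")
        if not 0 <= self.transfection_fraction <= 1:
            raise ValueError("transfection_fraction must be in [0, 1]")
        if self.pixel_size_um <= 0 or self.bit_saturation <= 0:
            raise ValueError("pixel_size_um and bit_saturation must be positive")
        if self.n_cells < 0 or self.noise_sd < 0:
            raise ValueError("n_cells and noise_sd must be nonnegative")
        if self.sequestration_coefficient < 0:
            raise ValueError("sequestration_coefficient must be nonnegative")
        unknown = set(self.assembly_rates) - set(CLASS_DIAMETER_UM)
        if unknown:
            raise ValueError(f"unknown assembly classes: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Generator-emitted truth: per-cell/assembly tables plus label images."""

    cells: pd.DataFrame
    assemblies: pd.DataFrame
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    assembly_filled: np.ndarray
    assembly_shell: np.ndarray
    assembly_core: np.ndarray
    noiseless_endogenous: np.ndarray
    noiseless_exogenous: np.ndarray


@dataclass
class FrapSimConfig:
    """Generating model for a single-exponential FRAP recovery.

    The recovery kernel is 2^(-t / half_time_s), so ``half_time_s`` is the
    literal half-time; a shared factor exp(-reference_decay_rate * t)
    multiplies ROI and reference, emulating acquisition photobleaching that
    double normalization cancels exactly.
    """

    pre_bleach_frames: int = 3
    frame_interval_s: float = 1.0
    total_time_s: float = 120.0
    post_bleach_floor: float = 0.53  # I0
    plateau: float = 0.74
    half_time_s: float = 8.7
    reference_decay_rate: float = 0.002
    background_level: float = 0.05
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pre_bleach_frames < 1 or self.frame_interval_s <= 0 or self.total_time_s <= 0:
            raise ValueError("invalid frame/time configuration")
        if not 0 <= self.post_bleach_floor < 1:
            raise ValueError("post_bleach_floor must be in [0, 1)")
        if not self.post_bleach_floor <= self.plateau <= 1:
            raise ValueError("plateau must lie in [post_bleach_floor, 1]")
        if self.half_time_s <= 0:
            raise ValueError("half_time_s must be positive")
        if self.reference_decay_rate < 0 or self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("rates/levels must be nonnegative")


# ---------------------------------------------------------------------------
# geometry helpers


def _ellipse_pixels(shape, center, a_px, b_px, angle):
    """Pixel (rows, cols) inside a rotated ellipse, clipped to the image."""
    cy, cx = center
    r = max(a_px, b_px)
    r0 = max(int(math.floor(cy - r)) - 1, 0)
    r1 = min(int(math.ceil(cy + r)) + 2, shape[0])
    c0 = max(int(math.floor(cx - r)) - 1, 0)
    c1 = min(int(math.ceil(cx + r)) + 2, shape[1])
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, int), np.empty(0, int)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - cy
    dx = xx - cx
    ca, sa = math.cos(angle), math.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    return yy[inside] + 0, xx[inside] + 0


def _in_ellipse(p, center, a_px, b_px, angle) -> bool:
    dy, dx = p[0] - center[0], p[1] - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    if a_px <= 0 or b_px <= 0:
        return False
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


def _blob_pixels(shape, center, r0_px, eps, phases):
    """Amorphous blob: disk with low-order radial harmonic perturbation."""
    cy, cx = center
    rmax = r0_px * (1 + eps.sum())
    r0i = max(int(math.floor(cy - rmax)) - 1, 0)
    r1i = min(int(math.ceil(cy + rmax)) + 2, shape[0])
    c0i = max(int(math.floor(cx - rmax)) - 1, 0)
    c1i = min(int(math.ceil(cx + rmax)) + 2, shape[1])
    yy, xx = np.mgrid[r0i:r1i, c0i:c1i]
    dy = yy - cy
    dx = xx - cx
    theta = np.arctan2(dy, dx)
    rad = r0_px * (
        1.0
        + sum(e * np.cos((m + 2) * theta + ph) for m, (e, ph) in enumerate(zip(eps, phases)))
    )
    inside = dy**2 + dx**2 <= rad**2
    return yy[inside], xx[inside]


# ---------------------------------------------------------------------------
# scene rendering


def render_scene(cfg: SceneConfig) -> tuple[ImageScene, GroundTruth]:
    """Render a two-channel scene and its ground truth.

    Raises ``ValueError`` when the requested cells cannot be placed without
    nucleus/cell overlap within a bounded number of attempts.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_shape_px
    px = cfg.pixel_size_um
    sat = cfg.bit_saturation
    k_seq = cfg.sequestration_coefficient
    exp_level = math.exp(cfg.exo_expression_log_mean + 0.5 * cfg.exo_expression_log_sd**2)

    endo = np.zeros((h, w))
    exo = np.zeros((h, w))
    nucleus_labels = np.zeros((h, w), np.int32)
    cell_labels = np.zeros((h, w), np.int32)
    nucleoli = np.zeros((h, w), bool)
    asm_filled = np.zeros((h, w), np.int32)
    asm_shell = np.zeros((h, w), np.int32)
    asm_core = np.zeros((h, w), np.int32)

    # --- cell placement (nuclei must not overlap; bounded attempts) ---------
    placed = []  # (center, a_px, b_px, angle, R_px)
    for i in range(cfg.n_cells):
        ok = False
        for _ in range(500):
            a_um = rng.uniform(*cfg.nucleus_semi_major_um)
            b_um = a_um * rng.uniform(*cfg.nucleus_aspect)
            angle = rng.uniform(0, math.pi)
            a_px, b_px = a_um / px, b_um / px
            r_cell = cfg.cyto_scale * a_px
            if 2 * r_cell >= min(h, w):
                continue
            cy = rng.uniform(r_cell, h - 1 - r_cell)
            cx = rng.uniform(r_cell, w - 1 - r_cell)
            if all(
                math.hypot(cy - p[0][0], cx - p[0][1]) > r_cell + p[4] for p in placed
            ):
                placed.append(((cy, cx), a_px, b_px, angle, r_cell))
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not place {cfg.n_cells} non-overlapping cells in a "
                f"{h}x{w} image after bounded attempts"
            )

    cell_rows = []
    asm_rows = []
    asm_meta = []  # (id, cell_id, cls, compartment, amp, core_level, nominal_d_um)
    next_asm = 1

    for cid, (center, a_px, b_px, angle) in enumerate(
        ((p[0], p[1], p[2], p[3]) for p in placed), start=1
    ):
        cy, cx = center
        ca_px, cb_px = cfg.cyto_scale * a_px, cfg.cyto_scale * b_px
        rr, cc = _ellipse_pixels((h, w), center, ca_px, cb_px, angle)
        cell_labels[rr, cc] = cid
        rr, cc = _ellipse_pixels((h, w), center, a_px, b_px, angle)
        nucleus_labels[rr, cc] = cid

        # nucleolar voids
        for _ in range(int(rng.integers(1, 4))):
            t = rng.uniform(0, 2 * math.pi)
            u = math.sqrt(rng.uniform())
            off_u = 0.55 * a_px * u * math.cos(t)
            off_v = 0.55 * b_px * u * math.sin(t)
            caa, saa = math.cos(angle), math.sin(angle)
            ncy = cy + off_u * saa + off_v * caa
            ncx = cx + off_u * caa - off_v * saa
            na = rng.uniform(0.6, 1.2) / px
            nb = na * rng.uniform(0.7, 1.0)
            nr, nc = _ellipse_pixels((h, w), (ncy, ncx), na, nb, rng.uniform(0, math.pi))
            keep = nucleus_labels[nr, nc] == cid
            nucleoli[nr[keep], nc[keep]] = True

        transfected = bool(rng.random() < cfg.transfection_fraction)
        level = (
            float(rng.lognormal(cfg.exo_expression_log_mean, cfg.exo_expression_log_sd))
            if transfected
            else 0.0
        )
        base_endo = float(rng.lognormal(cfg.endo_level_log_mean, cfg.endo_level_log_sd))

        # --- assemblies -----------------------------------------------------
        local = []  # (center, r_px) for overlap checks
        if transfected and cfg.variant != "GFP_only":
            draws: list[tuple[str, float]] = []
            for cls in ("inclusion", "anisosome", "punctum"):
                rate = cfg.assembly_rates.get(cls, 0.0)
                if rate <= 0:
                    continue
                count = int(rng.poisson(rate))
                draws.extend((cls, float(rng.uniform(*CLASS_DIAMETER_UM[cls]))) for _ in range(count))
            # place largest assemblies first: greatly improves packing success
            draws.sort(key=lambda cd: (-cd[1], cd[0]))
            for cls, d_um in draws:
                    r_px = 0.5 * d_um / px
                    # inclusions are perturbed blobs; reserve their maximal extent
                    r_eff = 1.25 * r_px if cls == "inclusion" else r_px
                    compartment = (
                        "cytoplasmic"
                        if (cfg.variant in CYTOPLASMIC_VARIANTS and cls != "anisosome")
                        else "nuclear"
                    )
                    pos = _place_assembly(
                        rng, compartment, center, (a_px, b_px), (ca_px, cb_px), angle, r_eff, local,
                        allow_overlap=cfg.overlap_policy == "overlap",
                    )
                    if pos is None:
                        continue  # drop policy: unplaceable draw omitted from scene and truth
                    local.append((pos, r_eff))
                    if cls == "anisosome":
                        rim = rng.uniform(0.32, 0.55) * sat
                        amp, core_level = rim, ANISOSOME_CORE_LEVEL * rim
                    elif cls == "punctum":
                        amp, core_level = rng.uniform(0.32, 0.55) * sat, math.nan
                    else:
                        amp, core_level = rng.uniform(0.75, 0.95) * sat, math.nan

                    fr, fc = _render_assembly_mask(
                        rng, (h, w), cls, pos, r_px, px
                    )
                    full_d_um = 2.0 * math.sqrt(fr.size * px * px / math.pi)
                    unclaimed = asm_filled[fr, fc] == 0
                    fr, fc = fr[unclaimed], fc[unclaimed]
                    if fr.size:  # occluded draws keep a truth row but paint nothing
                        asm_filled[fr, fc] = next_asm
                        if cls == "anisosome":
                            d2 = (fr - pos[0]) ** 2 + (fc - pos[1]) ** 2
                            core_sel = d2 <= (ANISOSOME_CORE_FRAC * r_px) ** 2
                            asm_core[fr[core_sel], fc[core_sel]] = next_asm
                            asm_shell[fr[~core_sel], fc[~core_sel]] = next_asm
                        else:
                            asm_shell[fr, fc] = next_asm
                    asm_meta.append(
                        {
                            "assembly_id": next_asm,
                            "cell_id": cid,
                            "true_class": cls,
                            "compartment": compartment,
                            "row": pos[0],
                            "col": pos[1],
                            "diameter_um": full_d_um if cls == "inclusion" else d_um,
                            "rendered_diameter_um": 2.0 * math.sqrt(fr.size * px * px / math.pi),
                            "amplitude": amp,
                            "core_rim_ratio_true": (
                                ANISOSOME_CORE_LEVEL if cls == "anisosome" else math.nan
                            ),
                        }
                    )
                    next_asm += 1

        cell_rows.append(
            {
                "cell_id": cid,
                "row": cy,
                "col": cx,
                "semi_major_um": a_px * px,
                "semi_minor_um": b_px * px,
                "angle_rad": angle,
                "transfected": transfected,
                "exo_level": level,
                "base_endo_level": base_endo,
            }
        )

    cells_df = pd.DataFrame(
        cell_rows,
        columns=[
            "cell_id", "row", "col", "semi_major_um", "semi_minor_um", "angle_rad",
            "transfected", "exo_level", "base_endo_level",
        ],
    )
    asm_df = pd.DataFrame(
        asm_meta,
        columns=[
            "assembly_id", "cell_id", "true_class", "compartment", "row", "col",
            "diameter_um", "rendered_diameter_um", "amplitude", "core_rim_ratio_true",
        ],
    )

    # --- intensity painting (per cell, conservation by construction) --------
    diffuse_conc = np.zeros(len(cells_df))
    for i, cell in cells_df.iterrows():
        cid = int(cell.cell_id)
        ids = asm_df.loc[asm_df.cell_id == cid, "assembly_id"].to_numpy()
        # partition coefficient scales with expression: mass-action recruitment
        k_cell = k_seq * cell.exo_level / exp_level if cell.transfected else 0.0
        bbox = _cell_bbox(cell, cfg, (h, w))
        nl = nucleus_labels[bbox]
        cl = cell_labels[bbox]
        fil = asm_filled[bbox]
        shl = asm_shell[bbox]
        cor = asm_core[bbox]
        vo = nucleoli[bbox]
        n_mask = nl == cid
        own_fil = np.isin(fil, ids) if ids.size else np.zeros_like(n_mask)
        own_shl = np.isin(shl, ids) if ids.size else np.zeros_like(n_mask)
        own_cor = np.isin(cor, ids) if ids.size else np.zeros_like(n_mask)
        a_d = int((n_mask & ~vo & ~own_fil).sum())
        a_shell = int(own_shl.sum())
        endow = cell.base_endo_level * float((n_mask & ~vo).sum())
        denom = a_d + k_cell * a_shell
        conc = endow / denom if denom > 0 else 0.0
        diffuse_conc[i] = conc
        view = endo[bbox]
        view[n_mask & ~vo & ~own_fil] = conc
        view[own_shl] = k_cell * conc
        view[own_cor] = 0.0
        if cell.transfected:
            c_mask = cl == cid
            if cfg.variant == "GFP_only":
                diff_region = c_mask
            elif cfg.variant in CYTOPLASMIC_VARIANTS:
                diff_region = c_mask & ~n_mask
            else:
                diff_region = n_mask & ~vo
            xview = exo[bbox]
            xview[diff_region & ~own_fil] = cell.exo_level
            for aid in ids:
                meta = asm_df.loc[asm_df.assembly_id == aid].iloc[0]
                sel_s = shl == aid
                xview[sel_s] = meta.amplitude
                sel_c = cor == aid
                if sel_c.any():
                    xview[sel_c] = ANISOSOME_CORE_LEVEL * meta.amplitude

    # quantize to whole grey levels; ground truth integrates the quantized image
    endo_q = np.round(np.clip(endo, 0, sat))
    exo_q = np.round(np.clip(exo, 0, sat))

    totals = _integrate_truth(
        cells_df, asm_df, endo_q, nucleus_labels, asm_filled, asm_shell, diffuse_conc
    )
    cells_df = pd.concat([cells_df, totals], axis=1)
    if len(asm_df):
        seq = ndimage_sum_by_label(endo_q, asm_filled, asm_df["assembly_id"].to_numpy())
        asm_df["sequestered_endogenous"] = seq
        counts = np.bincount(
            asm_filled.ravel(), minlength=int(asm_df["assembly_id"].max()) + 1
        )
        asm_df["n_px"] = counts[asm_df["assembly_id"].to_numpy()]
    else:
        asm_df["sequestered_endogenous"] = pd.Series(dtype=float)
        asm_df["n_px"] = pd.Series(dtype=int)

    if cfg.noise_sd > 0:
        endo_out = np.clip(endo_q + rng.normal(0, cfg.noise_sd, endo_q.shape), 0, sat)
        exo_out = np.clip(exo_q + rng.normal(0, cfg.noise_sd, exo_q.shape), 0, sat)
    else:
        endo_out, exo_out = endo_q.copy(), exo_q.copy()

    scene = ImageScene(
        endogenous=endo_out, exogenous=exo_out, pixel_size_um=px, bit_saturation=sat
    )
    gt = GroundTruth(
        cells=cells_df,
        assemblies=asm_df,
        nucleus_labels=nucleus_labels,
        cell_labels=cell_labels,
        assembly_filled=asm_filled,
        assembly_shell=asm_shell,
        assembly_core=asm_core,
        noiseless_endogenous=endo_q,
        noiseless_exogenous=exo_q,
    )
    return scene, gt


def _cell_bbox(cell, cfg: SceneConfig, shape):
    r = cfg.cyto_scale * cell.semi_major_um / cfg.pixel_size_um + 2
    r0 = max(int(cell.row - r), 0)
    r1 = min(int(cell.row + r) + 1, shape[0])
    c0 = max(int(cell.col - r), 0)
    c1 = min(int(cell.col + r) + 1, shape[1])
    return np.s_[r0:r1, c0:c1]


def _place_assembly(rng, compartment, center, nuc_ab, cell_ab, angle, r_px, local, allow_overlap=True):
    """Sample an assembly centre; avoid overlap for a bounded number of tries.

    Returns ``None`` when placement fails and overlap is not allowed.
    """
    cy, cx = center
    a, b = nuc_ab
    ca, cb = cell_ab
    for attempt in range(150):
        if compartment == "nuclear":
            aa, bb = max(a - r_px, 0.5), max(b - r_px, 0.5)
            t = rng.uniform(0, 2 * math.pi)
            u = math.sqrt(rng.uniform())
            off_u = aa * u * math.cos(t)
            off_v = bb * u * math.sin(t)
            caa, saa = math.cos(angle), math.sin(angle)
            pos = (cy + off_u * saa + off_v * caa, cx + off_u * caa - off_v * saa)
        else:
            t = rng.uniform(0, 2 * math.pi)
            u = math.sqrt(rng.uniform())
            aa, bb = max(ca - r_px, 1.0), max(cb - r_px, 1.0)
            off_u = aa * u * math.cos(t)
            off_v = bb * u * math.sin(t)
            caa, saa = math.cos(angle), math.sin(angle)
            pos = (cy + off_u * saa + off_v * caa, cx + off_u * caa - off_v * saa)
            # large objects (inclusions) cannot clear the nucleus by a full
            # radius inside the annulus; in projection they press against it,
            # so the exclusion margin is capped at a fraction of the annulus
            margin = min(r_px, 0.4 * (ca - a))
            if _in_ellipse(pos, center, a + margin, b + margin, angle):
                continue  # would intrude too far into the nucleus
        if all(math.hypot(pos[0] - p[0], pos[1] - p[1]) > r_px + rp + 2.0 for p, rp in local):
            return pos
    # bounded attempts exhausted: accept overlap (projected 3-D field) or drop
    return pos if allow_overlap else None


def _render_assembly_mask(rng, shape, cls, pos, r_px, px):
    if cls == "inclusion":
        for _ in range(6):
            eps = rng.uniform(0, 0.12, size=3) / np.arange(1, 4)
            phases = rng.uniform(0, 2 * math.pi, size=3)
            fr, fc = _blob_pixels(shape, pos, r_px, eps, phases)
            d_um = 2.0 * math.sqrt(fr.size * px * px / math.pi)
            if d_um > 4.05:
                return fr, fc
        return fr, fc
    return _ellipse_pixels(shape, pos, r_px, r_px, 0.0)


def ndimage_sum_by_label(values: np.ndarray, labels: np.ndarray, index: np.ndarray) -> np.ndarray:
    from scipy import ndimage as ndi

    if index.size == 0:
        return np.empty(0)
    return np.asarray(ndi.sum_labels(values, labels, index), dtype=float)


def _integrate_truth(cells_df, asm_df, endo_q, nucleus_labels, asm_filled, asm_shell, diffuse_conc):
    rows = []
    for i, cell in cells_df.iterrows():
        cid = int(cell.cell_id)
        ids = asm_df.loc[asm_df.cell_id == cid, "assembly_id"].to_numpy()
        n_mask = nucleus_labels == cid
        own_fil = np.isin(asm_filled, ids) if ids.size else np.zeros_like(n_mask)
        diffuse = float(endo_q[n_mask & ~own_fil].sum())
        seq_nuc = float(endo_q[n_mask & own_fil].sum())
        seq_cyt = float(endo_q[~n_mask & own_fil].sum())
        pool = diffuse + seq_nuc + seq_cyt
        rows.append(
            {
                "diffuse_conc": diffuse_conc[i],
                "total_endogenous": pool,
                "diffuse_endogenous": diffuse,
                "sequestered_nuclear": seq_nuc,
                "sequestered_cytoplasmic": seq_cyt,
                "proportion_sequestered": (seq_nuc + seq_cyt) / pool if pool > 0 else 0.0,
                "n_assemblies": int(ids.size),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "diffuse_conc", "total_endogenous", "diffuse_endogenous",
            "sequestered_nuclear", "sequestered_cytoplasmic",
            "proportion_sequestered", "n_assemblies",
        ],
    )


# ---------------------------------------------------------------------------
# FRAP trace simulation


def render_frap_trace(cfg: FrapSimConfig) -> FrapTrace:
    """Simulate ROI / reference / background series for one bleach event.

    ROI follows ``bg + s(t) * [I0 + (plateau - I0) * (1 - 2^(-t/t_half))]``
    for t >= 0 and ``bg + s(t)`` pre-bleach, where
    ``s(t) = exp(-reference_decay_rate * t)`` also multiplies the reference,
    so double normalization recovers the decay-free recovery curve exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.frame_interval_s
    pre_t = np.arange(-cfg.pre_bleach_frames, 0) * dt
    post_t = np.arange(0.0, cfg.total_time_s + 0.5 * dt, dt)
    t = np.concatenate([pre_t, post_t])
    s = np.exp(-cfg.reference_decay_rate * t)
    recovery = cfg.post_bleach_floor + (cfg.plateau - cfg.post_bleach_floor) * (
        1.0 - np.exp2(-post_t / cfg.half_time_s)
    )
    roi = cfg.background_level + s * np.concatenate([np.ones(pre_t.size), recovery])
    reference = cfg.background_level + s
    background = np.full(t.size, cfg.background_level)
    if cfg.noise_sd > 0:
        roi = roi + rng.normal(0, cfg.noise_sd, t.size)
        reference = reference + rng.normal(0, cfg.noise_sd, t.size)
        background = background + rng.normal(0, cfg.noise_sd, t.size)
    return FrapTrace(
        time_s=t, roi=roi, reference=reference, background=background,
        n_pre=cfg.pre_bleach_frames,
    )
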