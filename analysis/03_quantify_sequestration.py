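"""Quantify sequestration and depletion of diffuse nuclear endogenous TDP-43.

Builds the control reference from GFP-only scenes, flags sequestering
assemblies, partitions each cell's endogenous pools, summarizes per image,
and fits the concentration-dependence regressions per condition.
Re-runs segmentation in memory (records carry the pixel sums the pools
need), guided by the manifest from 01.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tdpquant import quantify
from tdpquant.io import process_scene, read_scene

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    manifest = pd.read_csv(RESULTS / "scene_manifest.csv")
    processed = []
    for _, entry in manifest.iterrows():
        scene = read_scene(entry.path)
        _, cells, assemblies, _ = process_scene(scene)
        processed.append((entry, cells, assemblies))

    control_cells = [c for e, cells, _ in processed if e.control for c in cells]
    ref = quantify.build_control_reference(control_cells)
    print(f"control reference: Q1={ref.control_diffuse_Q1:.1f}, "
          f"mean endo={ref.control_mean_endogenous:.1f}, "
          f"GFP gate={ref.transfected_gfp_threshold:.1f}")

    quant_rows, summary_rows = [], []
    for entry, cells, assemblies in processed:
        quantify.apply_transfection_gate(cells, ref)
        quantify.flag_sequestering(assemblies, ref)
        for c in cells:
            q = quantify.partition_endogenous(c, assemblies, ref)
            quant_rows.append({
                "scene": entry.scene, "condition": entry.condition,
                "control": entry.control, "transfected": c.transfected,
                **{k: getattr(q, k) for k in (
                    "cell_id", "fold_total_nuclear", "fold_diffuse_nuclear",
                    "diffuse_signal", "sequestered_signal",
                    "proportion_sequestered", "exogenous_level")},
            })
        s = quantify.summarize_image(cells, assemblies)
        summary_rows.append({
            "scene": entry.scene, "condition": entry.condition,
            "n_cells": s.n_cells, "n_transfected": s.n_transfected,
            "pct_cells_with_puncta": s.pct_cells_with_puncta,
            "puncta_per_cell": s.puncta_per_cell,
            "pct_transfected_with_inclusions": s.pct_transfected_with_inclusions,
            "inclusions_per_transfected_cell": s.inclusions_per_transfected_cell,
        })
    quant = pd.DataFrame(quant_rows)
    quant.to_csv(RESULTS / "cell_quant.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(RESULTS / "image_summaries.csv", index=False)

    print("\nMean fold-change of diffuse nuclear endogenous signal (transfected cells):")
    sel = quant[quant.transfected & ~quant.control]
    print(sel.groupby("condition").fold_diffuse_nuclear.mean().round(3).to_string())
    print("\nMean proportion of endogenous signal sequestered:")
    print(sel.groupby("condition").proportion_sequestered.mean().round(3).to_string())

    reg_rows = []
    for cond, grp in sel.groupby("condition"):
        if len(grp) < 3 or np.ptp(grp.exogenous_level.to_numpy()) == 0:
            continue
        for response, col in (("diffuse", "diffuse_signal"), ("sequestered", "sequestered_signal")):
            r = quantify.regress_concentration(grp.exogenous_level, grp[col])
            reg_rows.append({"condition": cond, "response": response,
                             "slope": r.slope, "intercept": r.intercept,
                             "r_squared": r.r_squared, "n": r.n})
    reg = pd.DataFrame(reg_rows)
    reg.to_csv(RESULTS / "regressions.csv", index=False)
    print("\nConcentration-dependence OLS slopes (per-cell response vs GFP level):")
    print(reg.to_string(index=False))

    truth = pd.read_csv(ROOT / "scratch" / "truth_cells.csv")
    gt_prop = (
        truth[truth.transfected & (truth.condition != "GFP_only")]
        .groupby("condition").proportion_sequestered.mean().round(3)
    )
    print("\nGround-truth mean proportion sequestered, for comparison:")
    print(gt_prop.to_string())
    print("\nIn the crowded 2KQ anisosome regime (~20 rings per nucleus) touching "
          "rings merge in projection into components the decision table discards, "
          "so measured sequestration underestimates the truth there; resolvable "
          "regimes recover the truth to within 2% (see tests).")


if __name__ == "__main__":
    main()
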