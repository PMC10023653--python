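"""Segment every simulated scene and classify its assemblies.

Reads the TIFF scenes from scratch/scenes/ via the manifest, runs
nucleus/cell segmentation and the inclusion/anisosome/punctum decision
table, and writes per-cell and per-assembly tables to results/.
"""

from pathlib import Path

import pandas as pd

from tdpquant.io import process_scene, read_scene
from tdpquant.segment import assemblies_to_frame, cells_to_frame

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    manifest = pd.read_csv(RESULTS / "scene_manifest.csv")
    cell_rows, asm_rows, qc_rows = [], [], []
    for _, entry in manifest.iterrows():
        scene = read_scene(entry.path)
        _, cells, assemblies, qc = process_scene(scene)
        cf = cells_to_frame(cells)
        cf.insert(0, "scene", entry.scene)
        cf.insert(1, "condition", entry.condition)
        af = assemblies_to_frame(assemblies)
        af.insert(0, "scene", entry.scene)
        af.insert(1, "condition", entry.condition)
        cell_rows.append(cf)
        asm_rows.append(af)
        qc_rows.append({"scene": entry.scene, **qc})
        print(f"{entry.scene}: {len(cells)} cells, {len(assemblies)} assemblies, qc={qc}")
    pd.concat(cell_rows).to_csv(RESULTS / "cells.csv", index=False)
    pd.concat(asm_rows).to_csv(RESULTS / "assemblies.csv", index=False)
    pd.DataFrame(qc_rows).to_csv(RESULTS / "segmentation_qc.csv", index=False)
    asm = pd.concat(asm_rows)
    print("\nDetected assemblies per condition/class:")
    print(asm.groupby(["condition", "cls"]).size().to_string())
    print("\nNote: the crowded 2KQ anisosome regime (~20 per cell) undercounts in "
          "projection because touching rings merge; see docs/methods.md.")


if __name__ == "__main__":
    main()
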