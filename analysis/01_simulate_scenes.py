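"""Render the study's imaging conditions as ground-truthed synthetic scenes.

Conditions: GFP-only controls, nuclear WT (puncta), nuclear 2KQ
(anisosome-rich, ~20 per transfected cell), and cytoplasmic ΔNLS/2KQ
(puncta + inclusions).  Scenes (two-page TIFF + JSON sidecar) and the bulky
ground-truth tables go to scratch/; the manifest and summaries to results/.
"""

from pathlib import Path

import pandas as pd

from tdpquant.io import write_scene
from tdpquant.synthetic import SceneConfig, render_scene

ROOT = Path(__file__).resolve().parents[1]
SCENE_DIR = ROOT / "scratch" / "scenes"
RESULTS = ROOT / "results"

N_IMAGES = 4
N_CELLS = 20
SHAPE = (896, 896)
SEED = 20230317

CONDITIONS = ["GFP_only", "WT", "2KQ", "dNLS_2KQ"]


def main() -> None:
    SCENE_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cell_rows, asm_rows, manifest = [], [], []
    idx = 0
    for variant in CONDITIONS:
        for j in range(N_IMAGES):
            cfg = SceneConfig(
                variant=variant, n_cells=N_CELLS, image_shape_px=SHAPE, seed=SEED + idx
            )
            scene, gt = render_scene(cfg)
            name = f"{variant}_{j:02d}"
            write_scene(scene, SCENE_DIR / f"{name}.tif")
            for df, rows in ((gt.cells, cell_rows), (gt.assemblies, asm_rows)):
                out = df.copy()
                out.insert(0, "scene", name)
                out.insert(1, "condition", variant)
                rows.append(out)
            manifest.append(
                {"scene": name, "condition": variant,
                 "control": variant == "GFP_only", "path": str(SCENE_DIR / f"{name}.tif")}
            )
            idx += 1
            print(f"{name}: {len(gt.cells)} cells, {len(gt.assemblies)} assemblies")
    asm_rows = [f for f in asm_rows if len(f)]  # control scenes have no assemblies
    pd.concat(cell_rows).to_csv(SCENE_DIR.parent / "truth_cells.csv", index=False)
    pd.concat(asm_rows).to_csv(SCENE_DIR.parent / "truth_assemblies.csv", index=False)
    pd.DataFrame(manifest).to_csv(RESULTS / "scene_manifest.csv", index=False)
    truth = pd.concat(asm_rows)
    per_cond = truth.groupby(["condition", "true_class"]).size()
    print("\nGround-truth assemblies per condition/class:")
    print(per_cond.to_string())


if __name__ == "__main__":
    main()
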