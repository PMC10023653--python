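# tdpquant

Quantitative single-cell analysis of TDP-43 self-assembly and sequestration
in two-channel fluorescence microscopy, with FRAP mobility metrics and
immunoblot densitometry — exercised end to end on synthetic, ground-truthed
data.

## The problem

TDP-43 is a nuclear RNA-binding protein whose nuclear depletion and
aggregation are hallmarks of ALS and FTD. In cells carrying an
endogenously tagged TDP-43 (e.g. TDP-43–mCherry) and over-expressing a
GFP-tagged variant (wild-type, RNA-binding-ablated 4FL,
acetylation-mimicking 2KQ, or their cytoplasmic ∆NLS forms), the variant
self-assembles into three kinds of condensates:

* **puncta** — droplet-like, radially homogeneous, 0.5–2.5 µm;
* **anisosomes** — shell-like rings with a TDP-43-void core, ~1–4 µm;
* **inclusions** — large (> 4 µm), amorphous, fluorescence-saturated.

These assemblies recruit ("sequester") endogenous TDP-43 out of its diffuse
nuclear pool. The central readouts are: how much endogenous signal each
cell retains diffusely vs sequestered (an exact pixel-sum partition of the
nucleus), how that partition depends on the variant's expression level
(OLS of per-cell response vs GFP level), and whether the sequestered
protein remains mobile (FRAP).

## What the package computes

| Module | Computation |
| --- | --- |
| `tdpquant.synthetic` | Ground-truthed two-channel scenes (diffuse nuclei with nucleolar voids, lognormal per-cell expression, partition-coefficient-driven sequestration with exact signal conservation) and single-exponential FRAP traces with shared acquisition-bleaching decay |
| `tdpquant.segment` | Nucleus/cell segmentation (automatic threshold + hole filling + watershed) and the assembly decision table: detection at ≥ 25% of saturation; inclusion if ≥ 4 µm and max ≥ 60% of saturation; anisosome vs punctum by core/rim intensity ratio (≤ 0.5); per-channel line profiles |
| `tdpquant.quantify` | Control references (lower-quartile diffuse intensity, GFP gate), sequestering flags, diffuse/sequestered pool partition (`diffuse + nuclear sequestered = nuclear total`, exact), per-image summaries, concentration-dependence regressions |
| `tdpquant.frap` | EasyFRAP-style double normalization (background + unbleached reference), single-exponential recovery fit, mobile fraction, AUC over the 120-s window, maximal recovery, half-time by interpolation and ln2/k |
| `tdpquant.densitometry` | Total-protein-normalized CRISPR editing ratios from immunoblot band tables |
| `tdpquant.io` / `tdpquant.cli` | TIFF + sidecar I/O, Z-stack maximum projection, YAML-configured pipeline, `tdpquant` CLI (`simulate`, `segment`, `frap`, `editing-ratio`, `run`) |

Key definitions, in the field's notation:

* mobile fraction: `m.f. = 100 · (I_max − I0) / (1 − I0)` on the
  double-normalized scale (pre-bleach ≡ 1);
* double normalization:
  `I_dn(t) = [mean_pre(ref−bg)/(ref(t)−bg(t))] · [(roi(t)−bg(t))/mean_pre(roi−bg)]`;
* editing ratio: `Σ tagged / (Σ tagged + Σ untagged)` after dividing each
  band by the lane's total-protein signal;
* an assembly *sequesters* endogenous TDP-43 when its mean endogenous
  intensity strictly exceeds the lower quartile of diffuse nuclear
  intensity in GFP-only control cells.

## Worked example

```python
from tdpquant.synthetic import SceneConfig, render_scene
from tdpquant.io import process_scene
from tdpquant import quantify

cfg = SceneConfig(
    variant="2KQ", n_cells=12, image_shape_px=(640, 640),
    assembly_rates={"anisosome": 3, "punctum": 1.5, "inclusion": 0.3},
    sequestration_coefficient=6.0, noise_sd=0.0,
    overlap_policy="drop", seed=3,
)
scene, truth = render_scene(cfg)
seg, cells, assemblies, qc = process_scene(scene)
for cell in cells[:3]:
    q = quantify.partition_endogenous(cell, assemblies)
    print(f"cell {cell.id}: {q.proportion_sequestered:.3f} sequestered")
```

prints

```
cell 1: 0.000 sequestered
cell 2: 0.809 sequestered
cell 3: 0.000 sequestered
```

i.e. cells 1 and 3 are untransfected (their endogenous TDP-43 is entirely
diffuse), while the brightly expressing cell 2 has 80.9% of its endogenous
signal recruited into a detected 2KQ-variant assembly — the
concentration dependence the regressions quantify. Because the generator
conserves each cell's total signal exactly, these measured proportions
match the scene's ground truth to within 2% on noiseless scenes.

The numbered drivers under `analysis/` run the full study on synthetic
batches (`01_simulate_scenes.py` → `05_editing_ratios.py`) and write tidy
tables under `results/`; bulky scene TIFFs and raw traces go to `scratch/`.

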