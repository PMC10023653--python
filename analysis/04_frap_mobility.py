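"""FRAP mobility of endogenous TDP-43 across assembly contexts.

Simulates seeded recovery traces for four contexts with generating
parameters in the regimes the mobility comparisons distinguish — diffuse
nuclear protein, anisosome-confined protein (slower recovery, still
mobile), and nuclear/cytoplasmic inclusion-trapped protein (near-immobile)
— then runs double normalization and metric extraction on every trace.
"""

from pathlib import Path

import pandas as pd

from tdpquant import frap
from tdpquant.synthetic import FrapSimConfig, render_frap_trace

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

# generating parameters per context: (I0, plateau, half-time s)
CONTEXTS = {
    "diffuse_nuclear": (0.53, 0.74, 8.7),
    "anisosome": (0.40, 0.72, 19.5),
    "nuclear_inclusion": (0.10, 0.15, 26.0),
    "cytoplasmic_inclusion": (0.08, 0.13, 17.0),
}
N_TRACES = 15
SEED = 404


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    trace_frames = []
    for ci, (context, (i0, plateau, t_half)) in enumerate(CONTEXTS.items()):
        for j in range(N_TRACES):
            cfg = FrapSimConfig(
                post_bleach_floor=i0, plateau=plateau, half_time_s=t_half,
                reference_decay_rate=0.002, background_level=0.05,
                noise_sd=0.02, seed=SEED + 100 * ci + j,
            )
            trace = render_frap_trace(cfg)
            df = trace.to_dataframe()
            df.insert(0, "trace_id", f"{context}_{j:02d}")
            trace_frames.append(df)
            m = frap.analyze_trace(trace)
            rows.append({
                "context": context, "trace": j,
                "mobile_fraction_pct": m.mobile_fraction_pct, "auc": m.auc,
                "max_recovery": m.max_recovery, "t_half_s": m.t_half_s,
                "t_half_fit_s": m.t_half_fit_s, "fit_ok": m.fit.fit_ok,
            })
    (ROOT / "scratch").mkdir(exist_ok=True)
    pd.concat(trace_frames).to_csv(ROOT / "scratch" / "frap_traces.csv", index=False)
    metrics = pd.DataFrame(rows)
    metrics.to_csv(RESULTS / "frap_metrics.csv", index=False)
    agg = metrics.groupby("context")[
        ["mobile_fraction_pct", "auc", "max_recovery", "t_half_fit_s"]
    ].median().round(2)
    agg.to_csv(RESULTS / "frap_summary.csv")
    print("Median FRAP metrics per context:")
    print(agg.to_string())
    print("\nInclusion-confined protein is near-immobile (m.f. < 15%); "
          "anisosome-confined protein stays mobile but recovers ~2x slower "
          "than the diffuse pool.")


if __name__ == "__main__":
    main()
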