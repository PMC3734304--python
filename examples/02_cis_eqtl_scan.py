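"""Run the dual-test cis-eQTL scan on a simulated cohort.

Normalizes counts (median-of-ratios), selects variants within the cis
window, and tests each with (a) linear regression on additive dosage and
(b) the directional probabilistic-index trend test with Monte-Carlo
permutation p-values, then BH-adjusts each method's p-values. The top rows
of each table should show the planted variant (var0100) with the smallest p.
"""

import pandas as pd

from cistrend import PlantedEffect, SimConfig
from cistrend.pipeline import run_eqtl, run_simulate

cfg = SimConfig(planted_effects=[PlantedEffect(100, 1.0)], seed=42)
paths = run_simulate(cfg, "cohort_demo")
out = run_eqtl(
    genotypes=paths["genotypes"],
    counts=paths["counts"],
    gene=cfg.target_gene,
    anchor_chrom=cfg.chrom,
    anchor_pos=cfg.anchor_pos,
    outdir="eqtl_demo",
    window_bp=1_000_000,
    permutations=1000,
    seed=7,
    truth=paths["truth"],
)

for method in ("linear", "directional"):
    df = pd.read_csv(out[method], sep="\t")
    print(f"\n== {method}: top 5 of {len(df)} variants by p ==")
    cols = ["snp", "position", "statistic", "direction", "p", "p_adjusted",
            "planted"]
    print(df.sort_values("p").head(5)[cols].to_string(index=False))
print("\n'planted' marks the variant the simulation made causal; a small")
print("adjusted p at that row means the scan recovered it above the noise.")
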