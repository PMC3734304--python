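"""Generate a synthetic eQTL cohort and look at what was planted.

Builds the default study-shaped cohort — 84 cases + 15 controls, 468
Hardy-Weinberg variants within +/- 1 Mb of the anchor, negative-binomial
read counts — with one planted cis effect (beta = 1.0 on the log-mean per
alt allele) and the default 0.7 case shift on the target gene, then writes
all four files (VCF, counts, sample sheet, truth table) to ./cohort_demo.
"""

from cistrend import PlantedEffect, SimConfig
from cistrend.pipeline import run_simulate

cfg = SimConfig(planted_effects=[PlantedEffect(100, 1.0)], seed=42)
paths = run_simulate(cfg, "cohort_demo")

print("Cohort written:")
for name, path in paths.items():
    print(f"  {name:10s} {path}")
print(f"\n{cfg.n_cases} cases + {cfg.n_controls} controls, "
      f"{cfg.n_variants} variants, {cfg.n_genes} genes.")
print("The truth table records the planted (variant, gene, beta) triples and")
print("the case effect, so downstream hits can be checked against it.")
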