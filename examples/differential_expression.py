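"""Z-ratio differential expression on a planted synthetic experiment.

Simulates a 4-group (sham, PHEN, mTBI, mTBI_PHEN) x n=5 array experiment
with 100 planted probes, runs the Z-score -> Z-ratio -> five-criterion
chain for the three treatment-vs-sham comparisons, and prints per-comparison
discovery counts plus the strongest hits.
"""

from zratio import pipeline
from zratio.simulate import (
    SimulationConfig,
    design_from_config,
    recovery_effect_layout,
    simulate_expression,
)

effects, _ = recovery_effect_layout()  # 100 probes, |fold| = 2, 4 Venn patterns
cfg = SimulationConfig(n_probes=5000, noise_sd=0.05, effects=effects, seed=1)
matrix, truth = simulate_expression(cfg)
design = design_from_config(cfg)

tables = pipeline.run_comparisons(
    matrix, design, [("mTBI", "sham"), ("mTBI_PHEN", "sham"), ("PHEN", "sham")]
)

for label, table in tables.items():
    n_up = int((table["direction"] == "up").sum())
    n_down = int((table["direction"] == "down").sum())
    print(f"{label}: {n_up} up, {n_down} down significant probes")

top = (
    tables["mTBI_vs_sham"]
    .query("significant")
    .reindex(columns=["z_ratio", "fold_change", "p_z", "q", "p_anova"])
    .sort_values("z_ratio", ascending=False)
    .head(3)
)
print("\nstrongest up-regulated probes in mTBI vs sham:")
print(top.to_string(float_format="%.3g"))
print(
    "\nEach row is one probe: its Z-ratio (group-mean Z difference in units"
    "\nof the comparison-wide sd), signed fold change on raw intensities,"
    "\nz-test p, BH q and across-group ANOVA p. Planted probes carry"
    "\n|fold| = 2, so recovered Z-ratios sit far above the 1.5 cutoff."
)
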