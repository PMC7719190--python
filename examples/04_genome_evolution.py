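"""Evolve a genomic content network and sweep the HGT rate.

A scaled-down run of the genome-evolution model (selection proportional to
genome size^h; gene loss/gain/HGT) shows nestedness building up when the HGT
rate is high, and the HGT sweep shows the phase-transition-like dependence of
final NODF on the HGT rate.  The full-scale published setting (500x200,
5e5 steps) is what scripts/acceptance.py runs.
"""

from gcnfr import EvolutionParams, evolve_gcn, hgt_sweep

params = EvolutionParams(
    h=2.0, q_gl=0.2, q_gg=0.005, q_hgt=0.795,
    n_species=100, n_genes_init=60, p_connect=0.8, n_steps=30_000,
    seed=1, n_checkpoints=3,
)
result = evolve_gcn(params)
print("NODF trajectory (step, NODF):")
for step, value in result.nodf_trajectory:
    print(f"  {step:>7d}  {value:.4f}")
print("event counts:", result.event_counts)

base = EvolutionParams(
    h=2.0, q_gl=0.2, q_gg=0.005, q_hgt=0.795,
    n_species=100, n_genes_init=60, p_connect=0.8, n_steps=30_000,
)
table = hgt_sweep([0.0, 2.0], [0.1, 0.4, 0.795], q_gg=0.005, base=base,
                  seeds=[1, 2])
summary = table.groupby(["h", "q_hgt"])["nodf"].mean().round(4)
print("\nmean final NODF by (h, q_hgt):")
print(summary.to_string())

print(
    "\nWith selection (h=2) and high HGT the network becomes strongly nested;"
    "\nwith low HGT, or without selection, nestedness stays near the random"
    "\nbaseline."
)
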