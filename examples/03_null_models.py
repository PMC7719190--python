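"""Disentangle what drives redundancy: network structure vs composition.

Compares the real per-sample nFR against null models that randomize either
the genomic content network (4 schemes, increasingly constrained) or the
sample compositions (3 schemes), with paired Wilcoxon tests and BH-FDR
correction.  On a nested GCN, destroying the network structure should lower
nFR; permuting abundances within a sample's own members should not.
"""

from gcnfr import NullSpec, SynthSpec, null_comparison, synth_gcn, synth_profiles

# housekeeping core + private specialist genes: redundancy comes from the
# universal columns, which complete randomization destroys but
# degree-preserving rearrangement cannot
g = synth_gcn(
    SynthSpec("housekeeping_specialist", 25, 100, n_housekeeping=25, seed=1)
)
profiles = synth_profiles(40, g, richness=10, concentration=1.0, seed=2)

specs = [
    NullSpec("gcn", 1, n_replicates=20, seed=11),
    NullSpec("gcn", 2, n_replicates=20, seed=12),
    NullSpec("gcn", 4, n_replicates=20, seed=13),
    NullSpec("composition", 1, n_replicates=20, seed=14),
    NullSpec("composition", 2, n_replicates=20, seed=15),
]
table = null_comparison(profiles, g, specs)
print(table.round(4).to_string(index=False))

print(
    "\n'real>null' with small FDR-corrected p: the randomization destroyed"
    "\nstructure that the real configuration relies on for its redundancy."
    "\nPermuting abundances among a sample's own members (Null-composition-2)"
    "\nchanges nFR far less: membership matters more than abundances."
)
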