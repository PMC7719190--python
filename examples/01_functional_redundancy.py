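"""Quantify within-sample functional redundancy on synthetic communities.

Builds three archetypal genomic content networks — fully specialized
(disjoint genomes), fully redundant (one shared genome), and an intermediate
housekeeping + specialist structure — then decomposes the diversity of the
same set of samples under each: TD (Gini-Simpson), FD (Rao's Q), and
FR = TD - FD.  nFR = FR/TD is 0 when every taxon is functionally unique and
1 when all taxa are interchangeable.
"""

from gcnfr import SynthSpec, batch_diversity, synth_gcn, synth_profiles

for kind, kwargs in [
    ("disjoint_genomes", {}),
    ("housekeeping_specialist", {"n_housekeeping": 30}),
    ("identical_genomes", {}),
]:
    g = synth_gcn(SynthSpec(kind, n_species=20, n_genes=80, seed=1, **kwargs))
    profiles = synth_profiles(6, g, richness=8, concentration=1.0, seed=2)
    result = batch_diversity(profiles, g, method="weighted_jaccard")
    print(f"\n=== {kind} ===")
    print(result.round(4).to_string(index=False))
    print(f"mean nFR = {result['nFR'].mean():.4f}")

print(
    "\nDisjoint genomes force nFR = 0 (all taxonomic diversity is functional"
    "\ndiversity); a shared genome forces nFR = 1; a housekeeping core with"
    "\nprivate specialist genes sits in between."
)
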