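"""Measure GCN nestedness and test it against the degree-matched ensemble.

NODF (on the 0-1 scale) is high when small genomes carry subsets of the genes
of large genomes.  The bipartite configuration model (BiCM) is the
maximum-entropy ensemble matching the observed degree sequences on average;
an observed NODF far above the ensemble mean means the nested structure is
not explained by the degree sequences alone.
"""

from gcnfr import (
    EvolutionParams,
    SynthSpec,
    bicm_nodf_test,
    evolve_gcn,
    nodf,
    synth_gcn,
)

staircase = synth_gcn(SynthSpec("nested", 10, 10, fill=0.5))
print(f"perfect staircase NODF = {nodf(staircase.binary):.3f} (maximal)")

random_gcn = synth_gcn(SynthSpec("random", 30, 60, fill=0.3, seed=4))
res = bicm_nodf_test(random_gcn.binary, n_samples=500, seed=0)
print(
    f"random GCN:  NODF = {res.nodf:.3f}, ensemble {res.ensemble_mean:.3f} "
    f"+/- {res.ensemble_std:.3f}, z = {res.z_score:.2f}, p = {res.p_value:.3f}"
)

evolved = evolve_gcn(
    EvolutionParams(
        h=2.0, q_gl=0.2, q_gg=0.005, q_hgt=0.795,
        n_species=30, n_genes_init=25, p_connect=0.5, n_steps=8000, seed=3,
    )
).final_gcn
res = bicm_nodf_test(evolved.binary, n_samples=500, seed=0)
print(
    f"evolved GCN: NODF = {res.nodf:.3f}, ensemble {res.ensemble_mean:.3f} "
    f"+/- {res.ensemble_std:.3f}, z = {res.z_score:.2f}, p = {res.p_value:.3f}"
)

print(
    "\nThe z score measures nestedness in excess of what the degree sequences"
    "\nalone produce: the GCN evolved with selection and high HGT scores above"
    "\nits ensemble, while the Bernoulli-random GCN does not."
)
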