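# Methods

## The redundancy decomposition

For a sample with taxonomic profile `p` over the `N` species of a genomic
content network (GCN) `G` (`N × M`, non-negative integer copy numbers), we
take taxonomic diversity to be the Gini-Simpson index `TD = 1 − Σ p_i²` and
functional diversity to be Rao's quadratic entropy
`FD = Σ_{i≠j} d_ij p_i p_j`, with `d_ij` the pairwise functional distance
between genomes.  Functional redundancy is their difference,
`FR = Σ_{i≠j} (1 − d_ij) p_i p_j`, the expected functional similarity of two
randomly drawn members of distinct draws; the decomposition `FR + FD = TD`
is an algebraic identity and is enforced in tests to 1e-12.  `nFR = FR/TD`
is undefined for single-taxon samples and reported as NaN (never 0);
downstream statistics drop NaN rows.

Distances: weighted Jaccard `1 − Σ min(G_i, G_j)/Σ max(G_i, G_j)` (default),
uncentered cosine ("correlation"), and Sørensen
`1 − 2Σ min/(Σ G_i + Σ G_j)`.  All are 0 iff the two copy-number rows are
identical and 1 iff their supports are disjoint (cosine: 0/1 at the same
extremes, identity only in direction).  The cosine distance is undefined for
an all-zero genome; empty genomes are rejected at load (and, in randomized
null GCNs where they can legitimately arise, handled by the convention
empty-vs-empty = 0, empty-vs-nonempty = 1 for the min/max family).
Zero-abundance species are excluded before the pair sums — algebraically
equivalent and much cheaper for sparse samples over a large pool.

Profiles are aligned to the GCN by species label.  Species in a profile that
are missing from the GCN raise by default; `on_unmatched="drop"` restricts
to the pool, renormalizes, and logs the retained abundance fraction (the
choice matters when profiling against a body-site-specific pool).

## Nestedness and the maximum-entropy test

NODF of the binary support, on the 0–1 scale: for each unordered row pair
with untied degrees, the shared-neighbor count divided by the smaller
degree; likewise for column pairs; summed and divided by
`N(N−1)/2 + M(M−1)/2`.  Tied-degree pairs contribute zero by definition.
The implementation is vectorized via `B Bᵀ` / `Bᵀ B` and is tested against a
literal double-loop oracle on random matrices.

Significance against the bipartite configuration model (BiCM): link
probabilities `p_ia = x_i y_a/(1 + x_i y_a)` with multipliers fitted by a
damped fixed-point iteration (damping 0.5, tolerance 1e-10, max 1e5
iterations) so that expected degrees match observed ones.  Saturated or
empty rows/columns make the finite-multiplier problem unsolvable, so they
are peeled off iteratively and their links fixed at probability 1 or 0; the
fit runs on the remainder.  A consequence worth knowing: a *perfectly*
nested (prefix) matrix is uniquely determined by its degree sequences, so
peeling consumes the whole matrix and the ensemble is degenerate
(`ensemble_std = 0`, flagged, no z test).  Ensemble moments of NODF are
estimated by Monte-Carlo sampling from the fitted probabilities (default
1000 draws) rather than by analytic linearization — unbiased for the
ratio-form NODF statistic and easy to verify; the one-sample z test is
reported two-sided by default with the one-sided upper-tail p alongside.

## Null models

GCN family: (1) complete randomization reassigns the edges, with their
copy-number multiset, to uniformly random distinct cells; (2) each species
keeps its copy-number multiset but resamples which genes carry it; (3) the
mirror on the gene side; (4) curveball trades on the binary support —
5 × (edge count) trades per replicate — preserving both unweighted degree
sequences exactly, with each species' copy numbers reassigned to its new
edge slots (species weighted degrees exact, gene weighted degrees only
approximate; exact joint preservation is over-constrained for integer
weights).  If no trade changes the matrix (no checkerboard submatrix — true
of any perfectly nested support), the input is returned with a warning.
Schemes 1–3 can produce empty rows/columns; such outputs are valid null
GCNs and bypass the non-emptiness check.

Composition family: (1) each sample's non-zero abundance multiset moves to a
uniformly drawn species subset of equal richness; (2) abundances permuted
within the sample's own support; (3) each species' non-zero abundances
permuted across the samples containing it; rows renormalized.

Comparison pipeline: per-sample nFR under the null is averaged over
replicates (default 100), paired with the real nFR, tested with the
two-sided Wilcoxon signed-rank (exact distribution for ≤ 25 pairs, normal
approximation beyond), and corrected across all schemes in a run with
Benjamini–Hochberg.  All-zero differences short-circuit to p = 1 with a
degeneracy flag.

## Genome-evolution model

State: per-species gene *sets* (binary genomes; the model's events concern
gene presence, not dosage).  Initial condition: bipartite Erdős–Rényi,
defaults 500 species × 200 genes at connection probability 0.8; an initially
empty genome (essentially impossible at these defaults) receives one random
gene.  Per step: species `i` chosen with probability ∝ `k_i^h` (`k_i` =
genome size, `h ≥ 0` the selection pressure, `h = 0` neutral, `0^0 := 1`),
then exactly one event with probabilities `(q_gl, q_gg, q_hgt)` summing
to 1:

* **loss** — remove a uniformly chosen gene; skipped on single-gene genomes
  so no genome ever empties;
* **gain** — add a brand-new, globally unique gene node;
* **HGT** — uniform random donor among the other species; the transferred
  gene is drawn uniformly among the donor's genes *not already carried by
  the recipient*, and the event is skipped only when the donor's genome is
  a subset of the recipient's.

The HGT convention deserves its own note, because the alternative — draw
uniformly over the whole donor genome and treat a duplicate as a skipped
no-op — looks equally natural.  It is not neutral: duplicate draws hit large
recipients far more often, which self-limits the growth of gene-rich
genomes, keeps genome sizes narrow, and caps the final nestedness near
NODF ≈ 0.19 under the headline parameters.  Drawing among novel genes
(default) lets selection amplify genome-size differences and produces the
strongly nested, fat-gene-tailed networks the model is meant to generate
(final NODF ≈ 0.65–0.71 across seeds at the headline setting).  The
alternative remains available via `hgt_novel_only=False`.

Event counts (executed + skipped per type) always sum to the step count.
Zero-carrier genes are pruned from the final network; species labels are
positional, gene labels follow creation order.  NODF is recorded at step 0,
at optional evenly spaced checkpoints, and at the end; tracking can be
disabled for very large gene universes (`track_nodf=False`), since the
column-pair computation is quadratic in the number of genes.

The HGT sweep holds `q_gg` fixed (default 0.005) and lets
`q_gl = 1 − q_gg − q_hgt` absorb the remainder, skipping infeasible grid
points.  The KL diagnostic normalizes each network's gene degrees by that
network's maximum, histograms both on `n_bins` equal bins over [0, 1] with
an additive pseudocount (default 1) to keep the divergence finite, and
returns `D_KL(reference ‖ simulated)`.

## FMT engraftment regression

`f_ds = |post ∩ (donor − pre)| / |post|`: the fraction of the post-FMT
community's strains that came specifically from the donor.  The denominator
choice (all post-FMT strains) is an assumption; an abundance-weighted
variant is available via `weighted=True` when post-FMT abundances are
supplied.  The regression is plain OLS of `f_ds` on the chosen pre-FMT
metric (TD, FD or FR, computed from the pre-FMT profile and the GCN) and
days post-FMT, one model per metric, with the overall F test.  Repeated
measures per recipient enter as independent rows — a documented limitation,
not a mixed model.

## Synthetic data

GCN archetypes: `disjoint_genomes` and `identical_genomes` reproduce the
analytic extremes exactly (FR ≡ 0 and FD ≡ 0 respectively);
`housekeeping_specialist` is a universal core plus one-owner private genes;
`nested` is a strict staircase whose largest genome carries every gene
(NODF = 1 when both degree sequences are strictly decreasing, which requires
a square matrix); `random` is Bernoulli(fill) with empty rows/columns
repaired by a single random edge; `modular` is block-diagonal Bernoulli.
Copy numbers default to 1; a geometric option exercises the weighted code
paths.  Profiles: uniform species subsets of fixed richness with symmetric
Dirichlet abundances (concentration 1 by default — realistically uneven;
large values approach uniform).

The FMT generator constructs cohorts whose realized data satisfy
`f_ds = β₀ + β_FR·FR_pre + β₂·t_post + ε` *exactly*: `f_ds` is quantized to
`k/n_post` (default denominator 100) by the strain-set construction, and the
recipient's pre-FMT FR is then re-solved so the linear relation holds at the
realized value — the pre-FMT profile mixes the two functionally closest
species of the supplied pool at the solved ratio (two-species profiles keep
the FR equation invertible in closed form).  With `noise_sd = 0` an OLS fit
recovers the coefficients to numerical precision, which is the basis of the
regression-recovery tests.  Defaults: β₀ = 0.8, β₂ = 0.001/day, sampling
days {2, 14, 42, 84}, FR range spanning ~[0.04, 0.41] on a shared-genome
pool.  A paper-consistent barrier effect is `fr_effect ≤ 0`.

## What the synthetic conditions do and do not show

The generators emulate the *statistical structure* each method consumes —
nested/random/modular bipartite supports, sparse uneven abundance vectors,
linear engraftment effects — not real metagenomes: no sequencing noise, no
compositional correlation between samples, no phylogenetic signal in gene
content, and species pools orders of magnitude smaller than a real reference
(hundreds, not tens of thousands of gene families).  Passing tests therefore
validate the estimators and the model mechanics, not field performance on
shotgun data.  Problem sizes in the test suite and acceptance script (GCNs
up to 500 × ~2500 after evolution, cohorts of 25–40 samples, ensembles of
hundreds of draws) were chosen to exercise every code path at full published
scale for the simulator and at reduced scale elsewhere.

## Numerical choices

BiCM: damping 0.5, tolerance 1e-10 on the max absolute degree residual,
max 1e5 iterations, convergence failure raises with the residual.  Distance
matrices are symmetrized, clipped to [0, 1], zero-diagonal-enforced after
floating-point pdist.  Histogram bins are half-open with the last bin closed
at 1.  Wilcoxon switches from exact to normal approximation above 25 pairs.
Nested orderings break degree ties by label for determinism.  All
randomness flows through `numpy.random.default_rng` seeds; identical seeds
give bit-identical results, including the simulator (verified in tests).
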