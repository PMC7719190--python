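"""Genome-evolution simulator: selection, gene gain/loss and HGT.

The model evolves a bipartite species-gene network from a random initial
condition.  At each time step one species ``i`` is chosen with probability
proportional to ``k_i ** h``, where ``k_i`` is its current genome size
(number of distinct genes) and ``h >= 0`` is the selection pressure (``h = 0``
is the neutral model: larger genomes are not favored).  The chosen genome then
undergoes exactly one of three events, drawn with rates that sum to one:

* gene loss (``q_gl``)  — a uniformly chosen gene is removed;
* gene gain (``q_gg``)  — a brand-new gene node is added;
* HGT (``q_hgt``)       — a uniformly chosen donor species transfers one of
  its genes into genome ``i``.  By default the transferred gene is drawn
  uniformly among the donor's genes that the recipient does not already carry
  (a transfer of an already-present gene would not change a presence/absence
  genome); the event is skipped only when the donor's genome is a subset of
  the recipient's.  With ``hgt_novel_only=False`` the gene is drawn uniformly
  over the whole donor genome and a duplicate draw is a skipped no-op, which
  strongly damps the growth of large genomes and with it the nestedness the
  model builds up.

Genomes are presence/absence sets (no copy numbers).  Losing the last gene of
a single-gene genome is skipped so no genome ever becomes empty.  Genes left
with no carrier are pruned from the final network.

High HGT rates homogenize gene content and, above a threshold, produce the
nested incidence structure and fat-tailed gene degree distribution seen in
real genomic content networks; the HGT sweep and the Kullback-Leibler
diagnostic on normalized gene-degree distributions quantify both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gcn import GCN
from .nestedness import nodf

logger = logging.getLogger(__name__)

_BLOCK = 1 << 16  # pre-drawn uniform block size


@dataclass
class EvolutionParams:
    """Simulator configuration.

    Defaults are the published headline setting apart from the rates, which
    must be given: a 500 x 200 random bipartite initial network with
    connection probability 0.8, evolved for 5e5 steps.
    """

    h: float
    q_gl: float
    q_gg: float
    q_hgt: float
    n_species: int = 500
    n_genes_init: int = 200
    p_connect: float = 0.8
    n_steps: int = 500_000
    seed: int = 0
    hgt_novel_only: bool = True
    n_checkpoints: int = 0  # intermediate NODF samples along the trajectory
    track_nodf: bool = True  # disable to skip NODF evaluation (huge networks)

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("selection pressure h must be >= 0")
        if min(self.q_gl, self.q_gg, self.q_hgt) < 0:
            raise ValueError("event rates must be non-negative")
        if abs(self.q_gl + self.q_gg + self.q_hgt - 1.0) > 1e-12:
            raise ValueError("q_gl + q_gg + q_hgt must equal 1")
        if not (0.0 <= self.p_connect <= 1.0):
            raise ValueError("p_connect must lie in [0, 1]")
        if self.n_species < 2 or self.n_genes_init < 1 or self.n_steps < 0:
            raise ValueError("invalid simulation dimensions")


@dataclass
class EvolutionResult:
    final_gcn: GCN
    nodf_trajectory: list[tuple[int, float]]
    event_counts: dict[str, int]
    params: EvolutionParams = field(repr=False)

    @property
    def final_nodf(self) -> float:
        if not self.nodf_trajectory:
            raise ValueError("NODF tracking was disabled for this run")
        return self.nodf_trajectory[-1][1]


class _Uniforms:
    """Blocked stream of uniforms from one Generator (fast scalar draws)."""

    __slots__ = ("rng", "buf", "pos")

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.buf = rng.random(_BLOCK)
        self.pos = 0

    def next(self) -> float:
        if self.pos == _BLOCK:
            self.buf = self.rng.random(_BLOCK)
            self.pos = 0
        v = self.buf[self.pos]
        self.pos += 1
        return v


def _state_to_gcn(genomes: list[list[int]]) -> GCN:
    """Assemble the binary GCN of the current state, pruning carrier-less
    genes and relabeling columns in first-appearance order of gene id."""
    all_genes = sorted({g for genome in genomes for g in genome})
    col = {g: a for a, g in enumerate(all_genes)}
    mat = np.zeros((len(genomes), len(all_genes)), dtype=np.int64)
    for i, genome in enumerate(genomes):
        mat[i, [col[g] for g in genome]] = 1
    species = [f"S{i:04d}" for i in range(len(genomes))]
    genes = [f"G{g:06d}" for g in all_genes]
    return GCN(species, genes, mat)


def evolve_gcn(params: EvolutionParams) -> EvolutionResult:
    """Run the genome-evolution model and return the final (binary) GCN.

    The trajectory records NODF at step 0, at ``n_checkpoints`` evenly spaced
    intermediate steps, and at the final step.  Event counts tally executed
    and skipped events per type; their sum equals ``n_steps``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_species

    # initial random bipartite graph; empty initial genomes get one random
    # gene so every species is a valid genome from the start
    adj = rng.random((n, params.n_genes_init)) < params.p_connect
    for i in np.flatnonzero(~adj.any(axis=1)):
        adj[i, rng.integers(params.n_genes_init)] = True

    genomes: list[list[int]] = [list(np.flatnonzero(adj[i])) for i in range(n)]
    pos: list[dict[int, int]] = [
        {g: idx for idx, g in enumerate(genome)} for genome in genomes
    ]
    k = np.array([len(genome) for genome in genomes], dtype=np.float64)
    h = params.h
    # 0^0 := 1 so empty genomes (never arising under the loss guard) would
    # still be selectable in the neutral model
    w = np.where(k > 0, k**h, 1.0) if h > 0 else np.ones(n)
    next_gene = params.n_genes_init

    u = _Uniforms(rng)
    thr_loss = params.q_gl
    thr_gain = params.q_gl + params.q_gg
    counts = {
        "loss_executed": 0,
        "loss_skipped": 0,
        "gain_executed": 0,
        "hgt_executed": 0,
        "hgt_skipped": 0,
    }
    novel_only = params.hgt_novel_only

    checkpoints = set()
    if params.n_checkpoints > 0 and params.n_steps > 0 and params.track_nodf:
        checkpoints = {
            int(round(s))
            for s in np.linspace(0, params.n_steps, params.n_checkpoints + 2)[1:-1]
        }
    trajectory: list[tuple[int, float]] = []
    if params.track_nodf:
        trajectory.append((0, nodf(_state_to_gcn(genomes).binary)))

    for step in range(params.n_steps):
        if h == 0.0:
            i = int(u.next() * n)
        else:
            c = np.cumsum(w)
            i = int(np.searchsorted(c, u.next() * c[-1], side="right"))
            if i >= n:  # numerical edge at the top of the cumulative sum
                i = n - 1
        ev = u.next()
        if ev < thr_loss:
            ki = len(genomes[i])
            if ki <= 1:
                counts["loss_skipped"] += 1
            else:
                idx = int(u.next() * ki)
                gene = genomes[i][idx]
                last = genomes[i][-1]
                genomes[i][idx] = last
                pos[i][last] = idx
                genomes[i].pop()
                del pos[i][gene]
                k[i] -= 1.0
                if h > 0:
                    w[i] = k[i] ** h
                counts["loss_executed"] += 1
        elif ev < thr_gain:
            gene = next_gene
            next_gene += 1
            pos[i][gene] = len(genomes[i])
            genomes[i].append(gene)
            k[i] += 1.0
            if h > 0:
                w[i] = k[i] ** h
            counts["gain_executed"] += 1
        else:
            j = int(u.next() * (n - 1))
            if j >= i:
                j += 1
            donor = genomes[j]
            mine = pos[i]
            if novel_only:
                candidates = [gg for gg in donor if gg not in mine]
                gene = (
                    candidates[int(u.next() * len(candidates))]
                    if candidates
                    else None
                )
            else:
                gene = donor[int(u.next() * len(donor))]
                if gene in mine:
                    gene = None
            if gene is None:
                counts["hgt_skipped"] += 1
            else:
                mine[gene] = len(genomes[i])
                genomes[i].append(gene)
                k[i] += 1.0
                if h > 0:
                    w[i] = k[i] ** h
                counts["hgt_executed"] += 1
        if (step + 1) in checkpoints:
            trajectory.append((step + 1, nodf(_state_to_gcn(genomes).binary)))

    final = _state_to_gcn(genomes)
    if params.track_nodf and params.n_steps > 0:
        trajectory.append((params.n_steps, nodf(final.binary)))
    assert sum(counts.values()) == params.n_steps
    return EvolutionResult(final, trajectory, counts, params)


def kl_gene_degree(
    g_ref: GCN,
    g_sim: GCN,
    n_bins: int = 20,
    pseudocount: float = 1.0,
) -> float:
    """KL divergence D(reference || simulated) of normalized gene degrees.

    Each network's gene (unweighted) degrees are divided by that network's
    maximum gene degree, histogrammed on ``n_bins`` equal bins over [0, 1]
    with an additive pseudocount per bin, and compared as discrete
    distributions.  Always >= 0; 0 for identical networks.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    def _dist(g: GCN) -> np.ndarray:
        deg = g.binary.sum(axis=0).astype(float)
        norm = deg / deg.max()
        counts, _ = np.histogram(norm, bins=n_bins, range=(0.0, 1.0))
        counts = counts + pseudocount
        return counts / counts.sum()

    p = _dist(g_ref)
    q = _dist(g_sim)
    return float(np.sum(p * np.log(p / q)))


def hgt_sweep(
    h_values,
    q_hgt_grid,
    q_gg: float,
    base: EvolutionParams,
    seeds,
    g_ref: GCN | None = None,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Final NODF (and optional KL diagnostic) over an HGT-rate grid.

    ``q_gg`` is held fixed and ``q_gl = 1 - q_gg - q_hgt`` absorbs the
    remainder; infeasible grid points (negative loss rate) are skipped with a
    warning.  Returns one row per (h, q_hgt, seed).
    """
    rows = []
    for h in h_values:
        for q_hgt in q_hgt_grid:
            q_gl = 1.0 - q_gg - q_hgt
            if q_gl < -1e-12:
                logger.warning("skipping infeasible grid point q_hgt=%g (q_gl<0)", q_hgt)
                continue
            q_gl = max(q_gl, 0.0)
            for seed in seeds:
                params = EvolutionParams(
                    h=h,
                    q_gl=q_gl,
                    q_gg=q_gg,
                    q_hgt=q_hgt,
                    n_species=base.n_species,
                    n_genes_init=base.n_genes_init,
                    p_connect=base.p_connect,
                    n_steps=base.n_steps,
                    seed=seed,
                    hgt_novel_only=base.hgt_novel_only,
                )
                result = evolve_gcn(params)
                row = {
                    "h": h,
                    "q_hgt": q_hgt,
                    "q_gl": q_gl,
                    "q_gg": q_gg,
                    "seed": seed,
                    "nodf": result.final_nodf,
                }
                if g_ref is not None:
                    row["kl_gene_degree"] = kl_gene_degree(
                        g_ref, result.final_gcn, n_bins=n_bins
                    )
                rows.append(row)
    return pd.DataFrame(rows)
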