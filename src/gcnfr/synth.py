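"""Synthetic GCNs, abundance profiles and FMT cohorts.

These generators provide seed-deterministic inputs with known structure for
every stage of the pipeline:

* GCN archetypes — the two analytic extremes (``disjoint_genomes``: every
  taxon fully specialized, all pairwise distances 1, FR identically 0;
  ``identical_genomes``: one shared genome, all distances 0, FR = TD), the
  intermediate ``housekeeping_specialist`` structure (a core of universal
  genes plus per-species private genes), perfectly ``nested`` staircases,
  Bernoulli ``random`` supports, and block-``modular`` supports.
* Sparse Dirichlet abundance profiles: per sample a uniform species subset of
  fixed richness with symmetric-Dirichlet abundances.
* FMT cohorts with a controlled linear engraftment model: the realized
  fraction of donor-specific strains satisfies
  ``f_ds = beta0 + fr_effect * FR_pre + beta2 * t_post + noise`` exactly
  (strain sets are constructed to realize the target fraction, and the
  recipient's two-species pre-FMT profile is solved to realize the target FR),
  so regression recovery can be validated against known coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fmt import FMTRecord
from .gcn import GCN, TaxonomicProfile, functional_distance_matrix

GCN_KINDS = (
    "nested",
    "random",
    "modular",
    "housekeeping_specialist",
    "identical_genomes",
    "disjoint_genomes",
)


@dataclass
class SynthSpec:
    kind: str
    n_species: int
    n_genes: int
    fill: float = 0.5
    n_housekeeping: int = 0
    n_modules: int = 4
    copy_numbers: str = "ones"  # or "geometric"
    geometric_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in GCN_KINDS:
            raise ValueError(f"unknown GCN kind {self.kind!r}")
        if self.n_species < 1 or self.n_genes < 1:
            raise ValueError("dimensions must be positive")
        if not (0.0 < self.fill <= 1.0):
            raise ValueError("fill must lie in (0, 1]")
        if self.copy_numbers not in ("ones", "geometric"):
            raise ValueError("copy_numbers must be 'ones' or 'geometric'")


def _staircase_degrees(n: int, m: int, fill: float) -> np.ndarray:
    """Strictly decreasing row degrees in [1, m] with mean ~ fill * m.

    The largest genome always carries every gene so no gene column is empty.
    """
    if n > m:
        raise ValueError("nested staircase needs n_species <= n_genes")
    hi = int(round(2 * fill * m)) - 1
    hi = min(m, max(hi, n))
    deg = np.round(np.linspace(hi, 1, n)).astype(int)
    deg[0] = m
    # enforce strict decrease top-down (stays >= 1 because n <= m)
    for i in range(1, n):
        deg[i] = min(deg[i], deg[i - 1] - 1)
    return deg


def synth_gcn(spec: SynthSpec) -> GCN:
    """Generate a GCN of the requested archetype (see module docstring)."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_species, spec.n_genes
    b = np.zeros((n, m), dtype=np.int64)

    if spec.kind == "nested":
        for i, deg in enumerate(_staircase_degrees(n, m, spec.fill)):
            b[i, :deg] = 1
    elif spec.kind == "random":
        b = (rng.random((n, m)) < spec.fill).astype(np.int64)
        for i in np.flatnonzero(b.sum(axis=1) == 0):
            b[i, rng.integers(m)] = 1
        for a in np.flatnonzero(b.sum(axis=0) == 0):
            b[rng.integers(n), a] = 1
    elif spec.kind == "modular":
        sp_mod = np.sort(rng.integers(0, spec.n_modules, size=n))
        ge_mod = np.sort(rng.integers(0, spec.n_modules, size=m))
        same = sp_mod[:, None] == ge_mod[None, :]
        b = (same & (rng.random((n, m)) < spec.fill)).astype(np.int64)
        for i in np.flatnonzero(b.sum(axis=1) == 0):
            cand = np.flatnonzero(ge_mod == sp_mod[i])
            b[i, cand[rng.integers(len(cand))] if len(cand) else rng.integers(m)] = 1
        for a in np.flatnonzero(b.sum(axis=0) == 0):
            cand = np.flatnonzero(sp_mod == ge_mod[a])
            b[cand[rng.integers(len(cand))] if len(cand) else rng.integers(n), a] = 1
    elif spec.kind == "housekeeping_specialist":
        n_hk = spec.n_housekeeping
        if not (0 < n_hk < m):
            raise ValueError("housekeeping_specialist needs 0 < n_housekeeping < n_genes")
        if m - n_hk < n:
            raise ValueError("need at least one private gene per species")
        b[:, :n_hk] = 1
        private = np.arange(n_hk, m)
        owner = np.repeat(np.arange(n), int(np.ceil(len(private) / n)))[: len(private)]
        b[owner, private] = 1
    elif spec.kind == "identical_genomes":
        b[:, :] = 1
    else:  # disjoint_genomes
        if m < n:
            raise ValueError("disjoint_genomes needs n_genes >= n_species")
        bounds = np.linspace(0, m, n + 1).astype(int)
        for i in range(n):
            b[i, bounds[i]: bounds[i + 1]] = 1

    if spec.copy_numbers == "geometric":
        cn = rng.geometric(spec.geometric_p, size=b.shape)
        b = b * cn

    species = [f"sp{i:03d}" for i in range(n)]
    genes = [f"g{a:04d}" for a in range(m)]
    return GCN(species, genes, b)


def synth_profiles(
    n_samples: int,
    g: GCN,
    richness: int,
    concentration: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sparse Dirichlet abundance profiles over the GCN's species pool.

    Each sample occupies a uniformly chosen subset of ``richness`` species
    with symmetric-Dirichlet(``concentration``) relative abundances; rows sum
    to one.
    """
    if richness < 1 or richness > g.n_species:
        raise ValueError(
            f"richness must lie in [1, {g.n_species}], got {richness}"
        )
    rng = np.random.default_rng(seed)
    x = np.zeros((n_samples, g.n_species))
    for s in range(n_samples):
        members = rng.choice(g.n_species, size=richness, replace=False)
        x[s, members] = rng.dirichlet(np.full(richness, concentration))
    index = [f"sample{s:03d}" for s in range(n_samples)]
    return pd.DataFrame(x, index=index, columns=g.species)


def _min_distance_pair(d: np.ndarray) -> tuple[int, int, float]:
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    flat = np.argmin(d[iu])
    return int(iu[0][flat]), int(iu[1][flat]), float(d[iu][flat])


def synth_fmt_dataset(
    n_recipients: int,
    fr_effect: float,
    noise_sd: float,
    g: GCN,
    seed: int = 0,
    beta0: float = 0.8,
    beta2: float = 0.001,
    t_grid: tuple[int, ...] = (2, 14, 42, 84),
    n_post: int = 100,
    method: str = "weighted_jaccard",
) -> tuple[list[FMTRecord], dict[str, float]]:
    """FMT cohort with a known linear engraftment model.

    Each recipient's pre-FMT profile is supported on the two closest species
    of ``g`` (pairwise distance ``d``), whose mixing weight is solved so that
    the profile's FR hits an exact target; the post-FMT strain set realizes
    ``f_ds = k / n_post`` exactly.  Targets are chosen so the realized data
    satisfy ``f_ds = beta0 + fr_effect * FR_pre + beta2 * t_post + eps`` with
    ``eps ~ N(0, noise_sd)`` (``eps = 0`` gives exact OLS recovery of the
    coefficients).  Returns the records and the ground-truth coefficients.

    A paper-consistent engraftment barrier corresponds to ``fr_effect <= 0``.
    """
    rng = np.random.default_rng(seed)
    d = functional_distance_matrix(g, method).values
    i0, j0, dmin = _min_distance_pair(d)
    fr_max_feasible = (1.0 - dmin) / 2.0
    if fr_max_feasible <= 0:
        raise ValueError(
            "species pool has no functionally similar pair; FR cannot vary"
        )
    fr_hi = 0.9 * fr_max_feasible
    fr_lo = 0.1 * fr_hi

    records: list[FMTRecord] = []
    for r in range(n_recipients):
        t_post = int(rng.choice(t_grid))
        fr_raw = rng.uniform(fr_lo, fr_hi)
        eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        fr_target = fr_raw
        for _ in range(3):  # quantize f_ds to k/n_post, re-solve FR to match
            f_target = beta0 + fr_effect * fr_target + beta2 * t_post + eps
            k = int(round(min(max(f_target, 0.0), 1.0) * n_post))
            if fr_effect != 0.0:
                fr_new = (k / n_post - eps - beta0 - beta2 * t_post) / fr_effect
                fr_new = min(max(fr_new, 1e-6), fr_max_feasible - 1e-9)
                if fr_new == fr_target:
                    break
                fr_target = fr_new
            else:
                break
        # two-species profile with FR = 2 (1 - d) p (1 - p) = fr_target
        s = fr_target / (2.0 * (1.0 - dmin))
        p_major = 0.5 * (1.0 + math.sqrt(max(0.0, 1.0 - 4.0 * s)))
        abund = np.zeros(g.n_species)
        abund[i0] = p_major
        abund[j0] = 1.0 - p_major
        profile = TaxonomicProfile(f"R{r:02d}_pre", abund)

        donor = {f"R{r:02d}:donor{x:03d}" for x in range(n_post)}
        resident = {f"R{r:02d}:res{x:03d}" for x in range(n_post)}
        donor_sorted = sorted(donor)
        resident_sorted = sorted(resident)
        post = set(donor_sorted[:k]) | set(resident_sorted[: n_post - k])
        records.append(
            FMTRecord(
                recipient_id=f"R{r:02d}",
                donor_strains=donor,
                pre_strains=resident,
                post_strains=post,
                t_post=t_post,
                pre_profile=profile,
            )
        )
    truth = {"beta0": beta0, "fr_effect": fr_effect, "beta2": beta2}
    return records, truth
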