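"""Randomization null models for GCNs and for sample compositions.

Two families of null models disentangle what drives a sample's normalized
functional redundancy (nFR): the structure of the genomic content network, or
the microbial composition of the sample.

GCN randomizations (composition fixed):
  1. complete randomization — edges (with their copy numbers) reassigned to
     uniformly random distinct species-gene cells;
  2. species-degree preserving — each species keeps its genes' copy numbers
     but the gene identities are resampled uniformly without replacement;
  3. gene-degree preserving — the mirror of 2 on the gene side;
  4. species- and gene-degree preserving — curveball trades on the binary
     support (both unweighted degree sequences preserved exactly), each
     species' copy-number multiset traveling with its edge slots.

Composition randomizations (GCN fixed):
  1. random assemblage — each sample's non-zero abundance multiset reassigned
     to a uniformly drawn species subset of equal richness from the pool;
  2. per-sample abundance permutation among the sample's own species;
  3. per-species abundance permutation across the samples containing it.

The comparison pipeline recomputes nFR per sample under each null (averaged
over replicates), pairs it with the real nFR, applies the two-sided Wilcoxon
signed-rank test, and corrects across the schemes tested in one run with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import batch_diversity
from .gcn import GCN, align_profiles

logger = logging.getLogger(__name__)

GCN_SCHEMES = (1, 2, 3, 4)
COMPOSITION_SCHEMES = (1, 2, 3)


@dataclass
class NullSpec:
    """One null model: family ('gcn' or 'composition'), scheme number,
    replicate count, and seed."""

    family: str
    scheme: int
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("gcn", "composition"):
            raise ValueError(f"unknown family {self.family!r}")
        valid = GCN_SCHEMES if self.family == "gcn" else COMPOSITION_SCHEMES
        if self.scheme not in valid:
            raise ValueError(f"scheme {self.scheme} invalid for family {self.family!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def name(self) -> str:
        label = "Null-GCN" if self.family == "gcn" else "Null-composition"
        return f"{label}-{self.scheme}"


def _curveball(rows: list[dict], n_cols: int, n_trades: int, rng: np.random.Generator) -> bool:
    """In-place curveball trades on row gene->copy-number dicts.

    Each trade picks two rows, pools their exclusive genes, and deals the pool
    back at the original exclusive-set sizes.  Copy numbers stay attached to
    the row that holds the slot: the multiset of copy numbers of each row is
    unchanged (genes swapped out hand their copy numbers to genes swapped in).
    Returns True if any trade changed the matrix.
    """
    n_rows = len(rows)
    changed = False
    pairs = rng.integers(0, n_rows, size=(n_trades, 2))
    for i, j in pairs:
        if i == j:
            continue
        ri, rj = rows[i], rows[j]
        only_i = [g for g in ri if g not in rj]
        only_j = [g for g in rj if g not in ri]
        if not only_i or not only_j:
            continue
        pool = only_i + only_j
        perm = rng.permutation(len(pool))
        new_i = [pool[k] for k in perm[: len(only_i)]]
        new_j = [pool[k] for k in perm[len(only_i):]]
        if set(new_i) != set(only_i):
            changed = True
            cn_i = [ri.pop(g) for g in only_i]
            cn_j = [rj.pop(g) for g in only_j]
            for g, c in zip(new_i, cn_i):
                ri[g] = c
            for g, c in zip(new_j, cn_j):
                rj[g] = c
    return changed


def randomize_gcn(g: GCN, scheme: int, seed: int | np.random.Generator = 0) -> GCN:
    """Randomize a GCN under one of the four schemes (see module docstring).

    Outputs keep the original labels.  Complete randomization can leave some
    species or genes with empty rows/columns; such outputs are valid null GCNs
    and are returned with ``require_nonempty=False``.
    """
    if scheme not in GCN_SCHEMES:
        raise ValueError(f"unknown GCN scheme {scheme}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, m = g.n_species, g.n_genes
    mat = g.matrix

    if scheme == 1:
        edges = np.flatnonzero(mat.ravel())
        weights = mat.ravel()[edges]
        cells = rng.choice(n * m, size=len(edges), replace=False)
        new = np.zeros(n * m, dtype=np.int64)
        new[cells] = rng.permutation(weights)
        return GCN(g.species, g.genes, new.reshape(n, m), require_nonempty=False)

    if scheme == 2:
        new = np.zeros_like(mat)
        for i in range(n):
            cols = np.flatnonzero(mat[i])
            new_cols = rng.choice(m, size=len(cols), replace=False)
            new[i, new_cols] = rng.permutation(mat[i, cols])
        return GCN(g.species, g.genes, new, require_nonempty=False)

    if scheme == 3:
        new = np.zeros_like(mat)
        for a in range(m):
            rows = np.flatnonzero(mat[:, a])
            new_rows = rng.choice(n, size=len(rows), replace=False)
            new[new_rows, a] = rng.permutation(mat[rows, a])
        return GCN(g.species, g.genes, new, require_nonempty=False)

    # scheme 4: curveball on the support, copy numbers travel with the row
    rows = [
        {int(a): int(mat[i, a]) for a in np.flatnonzero(mat[i])} for i in range(n)
    ]
    n_edges = int((mat > 0).sum())
    changed = _curveball(rows, m, n_trades=5 * n_edges, rng=rng)
    if not changed:
        logger.warning(
            "curveball randomization left the GCN unchanged "
            "(no swappable checkerboard submatrix)"
        )
    new = np.zeros_like(mat)
    for i, row in enumerate(rows):
        for a, c in row.items():
            new[i, a] = c
    return GCN(g.species, g.genes, new, require_nonempty=False)


def randomize_compositions(
    profiles: pd.DataFrame,
    g: GCN,
    scheme: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Randomize a samples x species abundance table under one of the three
    composition schemes (see module docstring).  Rows are renormalized."""
    if scheme not in COMPOSITION_SCHEMES:
        raise ValueError(f"unknown composition scheme {scheme}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aligned = align_profiles(profiles, g)
    x = aligned.to_numpy(copy=True)
    n_samples, n_species = x.shape

    if scheme == 1:
        new = np.zeros_like(x)
        for s in range(n_samples):
            nz = np.flatnonzero(x[s])
            if len(nz) > n_species:
                raise ValueError("sample richness exceeds species pool")
            target = rng.choice(n_species, size=len(nz), replace=False)
            new[s, target] = rng.permutation(x[s, nz])
        x = new
    elif scheme == 2:
        for s in range(n_samples):
            nz = np.flatnonzero(x[s])
            x[s, nz] = x[s, nz][rng.permutation(len(nz))]
    else:  # scheme 3
        for i in range(n_species):
            nz = np.flatnonzero(x[:, i])
            x[nz, i] = x[nz, i][rng.permutation(len(nz))]

    totals = x.sum(axis=1, keepdims=True)
    x = x / totals
    return pd.DataFrame(x, index=aligned.index, columns=aligned.columns)


def _null_nfr(
    profiles: pd.DataFrame,
    g: GCN,
    spec: NullSpec,
    method: str,
) -> pd.DataFrame:
    """Per-sample nFR under the null, averaged over replicates."""
    rng = np.random.default_rng(spec.seed)
    acc = None
    for _ in range(spec.n_replicates):
        if spec.family == "gcn":
            g_null = randomize_gcn(g, spec.scheme, rng)
            res = batch_diversity(profiles, g_null, method=method)
        else:
            p_null = randomize_compositions(profiles, g, spec.scheme, rng)
            res = batch_diversity(p_null, g, method=method)
        vals = res.set_index("sample_id")["nFR"]
        acc = vals if acc is None else acc + vals
    return (acc / spec.n_replicates).to_frame("null_nFR")


def null_comparison(
    profiles: pd.DataFrame,
    g: GCN,
    specs: NullSpec | list[NullSpec],
    method: str = "weighted_jaccard",
) -> pd.DataFrame:
    """Real-vs-null nFR comparison for one or more null models.

    For each null model, the per-sample nFR is recomputed under every
    replicate and averaged; real and null nFR are then compared with the
    two-sided Wilcoxon signed-rank test (exact distribution for <= 25 pairs).
    p values are Benjamini-Hochberg corrected across all schemes in the run.
    Returns one row per scheme with the median nFRs, test statistic, raw and
    FDR-corrected p, and effect direction.
    """
    if isinstance(specs, NullSpec):
        specs = [specs]
    real = batch_diversity(profiles, g, method=method).set_index("sample_id")["nFR"]
    if real.notna().sum() < 6:
        raise ValueError("need >= 6 samples with defined nFR for a paired test")
    rows = []
    for spec in specs:
        null = _null_nfr(profiles, g, spec, method)["null_nFR"]
        paired = pd.concat([real, null], axis=1, keys=["real", "null"]).dropna()
        diff = paired["real"] - paired["null"]
        degenerate = bool((diff == 0).all())
        if degenerate:
            stat, p = 0.0, 1.0
        else:
            mode = "exact" if len(diff) <= 25 else "approx"
            stat, p = stats.wilcoxon(
                paired["real"], paired["null"], alternative="two-sided", method=mode
            )
        direction = "real>null" if diff.median() > 0 else (
            "real<null" if diff.median() < 0 else "none"
        )
        rows.append(
            {
                "scheme": spec.name,
                "n_samples": len(paired),
                "n_replicates": spec.n_replicates,
                "median_real_nFR": float(paired["real"].median()),
                "median_null_nFR": float(paired["null"].median()),
                "wilcoxon_statistic": float(stat),
                "p_value": float(p),
                "direction": direction,
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(rows)
    out["p_value_fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (FDR control)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
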