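"""Genomic content networks (GCNs) and functional distances.

A genomic content network is a weighted bipartite graph linking the taxa of a
species pool to the genes carried in their genomes.  It is represented here by
its ``N x M`` incidence matrix ``G`` of non-negative integer gene copy numbers:
``G[i, a]`` is the copy number of gene ``a`` in the genome of species ``i``.

The GCN maps any taxonomic profile ``p`` (relative species abundances) onto a
functional profile ``f`` (relative gene abundances) via ``f = c * p @ G`` with
the normalization constant ``c = 1 / sum(p @ G)``, and it fixes the pairwise
functional distances ``d_ij`` between species, which downstream modules use to
decompose taxonomic diversity into functional diversity and functional
redundancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

#: Supported functional distance measures between genomes (copy-number rows).
DISTANCE_METHODS = ("weighted_jaccard", "correlation", "sorensen")


class GCNFormatError(ValueError):
    """Raised when an incidence matrix violates the GCN format contract."""


class AlignmentError(ValueError):
    """Raised when a profile cannot be aligned to a GCN's species pool."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dup = next(l for l in labels if l in seen or seen.add(l))  # type: ignore[func-returns-value]
        raise GCNFormatError(f"duplicate {what} label: {dup!r}")


@dataclass
class GCN:
    """Species x gene incidence matrix with non-negative integer copy numbers.

    Parameters
    ----------
    species : sequence of str
        Row labels (taxa), unique.
    genes : sequence of str
        Column labels (genes / gene families), unique.
    matrix : ndarray of int, shape (N, M)
        ``matrix[i, a]`` = copy number of gene ``a`` in genome ``i``.
    require_nonempty : bool
        If True (default), all-zero rows or columns are rejected.  Randomized
        (null-model) GCNs may legitimately contain empty genomes and are
        constructed with ``require_nonempty=False``.
    """

    species: list[str]
    genes: list[str]
    matrix: np.ndarray
    require_nonempty: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.species = [str(s) for s in self.species]
        self.genes = [str(g) for g in self.genes]
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape != (len(self.species), len(self.genes)):
            raise GCNFormatError(
                f"matrix shape {m.shape} does not match "
                f"{len(self.species)} species x {len(self.genes)} genes"
            )
        if m.size == 0:
            raise GCNFormatError("empty GCN")
        if not np.issubdtype(m.dtype, np.integer):
            if not np.allclose(m, np.round(m)):
                raise GCNFormatError("copy numbers must be integers")
            m = np.round(m).astype(np.int64)
        if (m < 0).any():
            raise GCNFormatError("copy numbers must be non-negative")
        _check_unique(self.species, "species")
        _check_unique(self.genes, "gene")
        if self.require_nonempty:
            if (m.sum(axis=1) == 0).any():
                bad = self.species[int(np.argmax(m.sum(axis=1) == 0))]
                raise GCNFormatError(f"species {bad!r} has an empty genome")
            if (m.sum(axis=0) == 0).any():
                bad = self.genes[int(np.argmax(m.sum(axis=0) == 0))]
                raise GCNFormatError(f"gene {bad!r} occurs in no genome")
        self.matrix = np.ascontiguousarray(m, dtype=np.int64)

    # -- basic views -------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def binary(self) -> np.ndarray:
        """Binary support ``B`` of the incidence matrix (presence/absence)."""
        return (self.matrix > 0).astype(np.int8)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.species, columns=self.genes)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame, prune_empty: bool = False) -> "GCN":
        """Build a GCN from a labeled DataFrame, optionally pruning empties."""
        m = df.to_numpy()
        if prune_empty:
            row_ok = (np.asarray(m) > 0).any(axis=1)
            col_ok = (np.asarray(m) > 0).any(axis=0)
            n_drop = int((~row_ok).sum() + (~col_ok).sum())
            if n_drop:
                logger.warning(
                    "pruned %d empty row(s)/column(s) from GCN", n_drop
                )
                df = df.loc[row_ok, col_ok]
        return cls(list(df.index), list(df.columns), df.to_numpy())

    @classmethod
    def read_tsv(cls, path: str | Path, prune_empty: bool = False) -> "GCN":
        """Read a GCN from a TSV file (first row gene labels, first column
        species labels, integer body)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        try:
            return cls.from_frame(df, prune_empty=prune_empty)
        except GCNFormatError as exc:
            raise GCNFormatError(f"{path}: {exc}") from exc

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="species")


# Loader alias matching the operational vocabulary used elsewhere.
def load_gcn(path: str | Path, prune_empty: bool = False) -> GCN:
    """Load and validate a GCN from a TSV file."""
    return GCN.read_tsv(path, prune_empty=prune_empty)


@dataclass
class TaxonomicProfile:
    """Relative species abundances of one sample, aligned to a GCN's species
    order.  Renormalized to sum to one on construction."""

    sample_id: str
    abundances: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=float)
        if a.ndim != 1:
            raise ValueError("abundances must be a 1-D vector")
        if (a < 0).any():
            raise ValueError("abundances must be non-negative")
        total = a.sum()
        if total <= 0:
            raise ValueError(f"sample {self.sample_id!r}: zero total abundance")
        if abs(total - 1.0) > 1e-9:
            logger.debug("renormalizing profile %s (sum=%g)", self.sample_id, total)
        self.abundances = a / total

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.abundances > 0)


@dataclass
class FunctionalProfile:
    """Relative gene abundances of one sample, aligned to a GCN's gene order."""

    sample_id: str
    abundances: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=float)
        if (a < 0).any():
            raise ValueError("abundances must be non-negative")
        total = a.sum()
        if total <= 0:
            raise ValueError(f"sample {self.sample_id!r}: zero total abundance")
        self.abundances = a / total


@dataclass
class DistanceMatrix:
    """Symmetric pairwise functional distances in [0, 1] with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    method: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")
        v = np.clip(v, 0.0, 1.0)
        np.fill_diagonal(v, 0.0)
        self.values = (v + v.T) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="species")


def functional_profile(p: TaxonomicProfile, g: GCN) -> FunctionalProfile:
    """Map a taxonomic profile onto the gene (functional) profile f = c p G.

    ``c`` normalizes the gene abundances to sum to one; it is undefined (and an
    error) when the profile's support carries no genes at all.
    """
    if len(p.abundances) != g.n_species:
        raise AlignmentError(
            f"profile length {len(p.abundances)} != {g.n_species} species"
        )
    raw = p.abundances @ g.matrix
    total = raw.sum()
    if total <= 0:
        raise ValueError(
            f"sample {p.sample_id!r}: abundance restricted to empty genomes; "
            "normalization constant undefined"
        )
    return FunctionalProfile(p.sample_id, raw / total)


def _jaccard_sorensen(m: np.ndarray, method: str) -> np.ndarray:
    """Weighted Jaccard / Sørensen distances via L1 identities.

    For non-negative x, y:  sum(min) = (sx + sy - ||x-y||_1)/2 and
    sum(max) = (sx + sy + ||x-y||_1)/2.
    """
    x = m.astype(float)
    row_sums = x.sum(axis=1)
    l1 = squareform(pdist(x, metric="cityblock"))
    ssum = row_sums[:, None] + row_sums[None, :]
    if method == "weighted_jaccard":
        max_sum = (ssum + l1) / 2.0
        min_sum = (ssum - l1) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - np.where(max_sum > 0, min_sum / np.where(max_sum > 0, max_sum, 1.0), 1.0)
        # two empty genomes: identical, distance 0
        empty = row_sums == 0
        d[np.ix_(empty, empty)] = 0.0
    else:  # sorensen
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(ssum > 0, l1 / np.where(ssum > 0, ssum, 1.0), 0.0)
    return d


def functional_distance_matrix(g: GCN, method: str = "weighted_jaccard") -> DistanceMatrix:
    """Pairwise functional distances between genomes (copy-number rows).

    ``weighted_jaccard``: ``1 - sum_a min(G_ia, G_ja) / sum_a max(G_ia, G_ja)``;
    ``correlation``: one minus the uncentered cosine similarity of the rows;
    ``sorensen``: ``1 - 2 sum_a min(G_ia, G_ja) / (sum_a G_ia + sum_a G_ja)``.

    All three are 0 for identical genomes and 1 for disjoint gene supports.
    """
    if method not in DISTANCE_METHODS:
        raise ValueError(f"unknown distance method {method!r}; choose from {DISTANCE_METHODS}")
    m = g.matrix.astype(float)
    if method == "correlation":
        if (m.sum(axis=1) == 0).any():
            raise ValueError("correlation distance undefined for empty genomes")
        d = squareform(pdist(m, metric="cosine"))
    else:
        d = _jaccard_sorensen(m, method)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(g.species), d, method)


@dataclass
class DegreeProfiles:
    """Unweighted (distinct-gene) and weighted (copy-number-sum) degrees."""

    species_unweighted: pd.Series
    gene_unweighted: pd.Series
    species_weighted: pd.Series
    gene_weighted: pd.Series


def degree_profiles(g: GCN) -> DegreeProfiles:
    """Degree sequences of both sides of the bipartite GCN.

    The unweighted degree of a species is the number of distinct genes in its
    genome; the unweighted degree of a gene is the number of genomes carrying
    it.  The weighted degrees are the corresponding copy-number sums.
    """
    b = g.binary
    return DegreeProfiles(
        species_unweighted=pd.Series(b.sum(axis=1), index=g.species, name="k_species"),
        gene_unweighted=pd.Series(b.sum(axis=0), index=g.genes, name="k_gene"),
        species_weighted=pd.Series(g.matrix.sum(axis=1), index=g.species, name="w_species"),
        gene_weighted=pd.Series(g.matrix.sum(axis=0), index=g.genes, name="w_gene"),
    )


def distance_histogram(d: DistanceMatrix, bin_width: float = 0.02) -> pd.DataFrame:
    """Histogram of off-diagonal pairwise distances over [0, 1].

    Bins are half-open ``[lo, hi)`` of width ``bin_width`` (the last bin is
    closed at 1).  Counts each unordered species pair once; the total count is
    always ``N (N - 1) / 2``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(round(1.0 / bin_width, 9)))
    edges = np.arange(n_bins + 1) * bin_width
    edges[-1] = max(edges[-1], 1.0)
    iu = np.triu_indices(len(d.labels), k=1)
    vals = d.values[iu]
    counts, _ = np.histogram(vals, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


# -- profile tables --------------------------------------------------------

def read_profiles(path: str | Path) -> pd.DataFrame:
    """Read a samples x species relative-abundance table (TSV, labeled)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.to_csv(path, sep="\t", index_label="sample_id")


def align_profiles(
    profiles: pd.DataFrame,
    g: GCN,
    on_unmatched: str = "raise",
) -> pd.DataFrame:
    """Align a samples x species table to a GCN's species order.

    Species present in the GCN but absent from the table are filled with zero
    abundance.  Species present in the table but absent from the GCN either
    raise (default, preventing silent redundancy bias) or are dropped with the
    per-sample retained abundance fraction logged (``on_unmatched='drop'``),
    after which rows are renormalized.
    """
    if on_unmatched not in ("raise", "drop"):
        raise ValueError("on_unmatched must be 'raise' or 'drop'")
    extra = [c for c in profiles.columns if c not in set(g.species)]
    if extra:
        carried = profiles[extra].to_numpy().sum(axis=1)
        if (carried > 0).any():
            if on_unmatched == "raise":
                raise AlignmentError(
                    f"{len(extra)} profiled species absent from GCN "
                    f"(e.g. {extra[:3]}); pass on_unmatched='drop' to restrict"
                )
            retained = 1.0 - carried / profiles.to_numpy().sum(axis=1)
            logger.warning(
                "dropping %d species absent from GCN; mean retained abundance %.3f",
                len(extra),
                float(np.mean(retained)),
            )
    aligned = profiles.reindex(columns=g.species, fill_value=0.0).astype(float)
    totals = aligned.to_numpy().sum(axis=1)
    if (totals <= 0).any():
        bad = aligned.index[int(np.argmax(totals <= 0))]
        raise AlignmentError(f"sample {bad!r} has no abundance on GCN species")
    return aligned.div(totals, axis=0)


def profiles_to_records(profiles: pd.DataFrame) -> Iterable[TaxonomicProfile]:
    for sample_id, row in profiles.iterrows():
        yield TaxonomicProfile(str(sample_id), row.to_numpy(dtype=float))
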