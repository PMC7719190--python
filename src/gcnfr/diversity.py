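"""Within-sample diversity decomposition: TD, FD, FR and normalized FR.

Taxonomic diversity (TD) is the Gini-Simpson index, the probability that two
randomly drawn members (with replacement) belong to different taxa.  Functional
diversity (FD) is Rao's quadratic entropy, the expected functional distance of
such a pair.  Functional redundancy is the part of taxonomic diversity not
explained by functional diversity,

    FR = TD - FD = sum_{i != j} (1 - d_ij) p_i p_j,

the expected functional *similarity* of two randomly drawn distinct-taxon
members.  The normalized redundancy nFR = FR / TD removes the dependence on
the sample's own taxonomic diversity (undefined for single-taxon samples).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gcn import (
    GCN,
    AlignmentError,
    DistanceMatrix,
    TaxonomicProfile,
    align_profiles,
    functional_distance_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class DiversityResult:
    sample_id: str
    td: float
    fd: float
    fr: float
    nfr: float  # NaN when TD == 0 (single-taxon sample)


def _as_vector(p: TaxonomicProfile | np.ndarray) -> np.ndarray:
    if isinstance(p, TaxonomicProfile):
        return p.abundances
    a = np.asarray(p, dtype=float)
    return a / a.sum()


def _as_distance(d: DistanceMatrix | np.ndarray) -> np.ndarray:
    return d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)


def gini_simpson(p: TaxonomicProfile | np.ndarray) -> float:
    """Gini-Simpson index ``1 - sum_i p_i^2`` (in ``[0, 1 - 1/N]``)."""
    a = _as_vector(p)
    return float(1.0 - a @ a)


def _check_aligned(a: np.ndarray, d: np.ndarray) -> None:
    if d.shape != (len(a), len(a)):
        raise AlignmentError(
            f"profile length {len(a)} does not match distance matrix {d.shape}"
        )


def rao_q(p: TaxonomicProfile | np.ndarray, d: DistanceMatrix | np.ndarray) -> float:
    """Rao's quadratic entropy ``sum_{i != j} d_ij p_i p_j``."""
    a = _as_vector(p)
    dv = _as_distance(d)
    _check_aligned(a, dv)
    s = np.flatnonzero(a > 0)  # restricting to the support is exact (p_i = 0 terms vanish)
    a_s = a[s]
    return float(a_s @ dv[np.ix_(s, s)] @ a_s)


def functional_redundancy(
    p: TaxonomicProfile | np.ndarray,
    d: DistanceMatrix | np.ndarray,
    sample_id: str | None = None,
) -> DiversityResult:
    """Decompose a sample's diversity into TD, FD, FR and nFR.

    FR is evaluated directly as the expected pairwise functional similarity
    ``sum_{i != j} (1 - d_ij) p_i p_j``; TD and FD come from the Gini-Simpson
    index and Rao's Q, so ``FR = TD - FD`` holds as an algebraic identity.
    """
    a = _as_vector(p)
    dv = _as_distance(d)
    _check_aligned(a, dv)
    if sample_id is None:
        sample_id = p.sample_id if isinstance(p, TaxonomicProfile) else ""
    s = np.flatnonzero(a > 0)
    a_s = a[s]
    d_s = dv[np.ix_(s, s)]
    td = float(1.0 - a_s @ a_s)
    fd = float(a_s @ d_s @ a_s)
    sim = (1.0 - d_s)
    np.fill_diagonal(sim, 0.0)
    fr = float(a_s @ sim @ a_s)
    nfr = fr / td if td > 0 else math.nan
    return DiversityResult(sample_id, td=td, fd=fd, fr=fr, nfr=nfr)


def batch_diversity(
    profiles: pd.DataFrame,
    g: GCN,
    method: str = "weighted_jaccard",
    on_unmatched: str = "raise",
) -> pd.DataFrame:
    """Diversity decomposition for every sample of a profile table.

    The distance matrix is computed once from the GCN and reused.  Per-sample
    failures are logged and reported as NaN rows so one degenerate sample does
    not abort a cohort run.
    """
    cols = ["sample_id", "TD", "FD", "FR", "nFR", "distance_method"]
    if len(profiles) == 0:
        return pd.DataFrame(columns=cols)
    aligned = align_profiles(profiles, g, on_unmatched=on_unmatched)
    d = functional_distance_matrix(g, method)
    rows = []
    for sample_id, row in aligned.iterrows():
        try:
            r = functional_redundancy(row.to_numpy(), d.values, sample_id=str(sample_id))
            rows.append((r.sample_id, r.td, r.fd, r.fr, r.nfr, method))
        except Exception as exc:  # pragma: no cover - defensive path
            logger.warning("sample %s failed: %s", sample_id, exc)
            rows.append((str(sample_id), math.nan, math.nan, math.nan, math.nan, method))
    return pd.DataFrame(rows, columns=cols)
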