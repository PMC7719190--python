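"""Donor-strain engraftment after fecal microbiota transplantation (FMT).

For each recipient, the engraftment outcome is summarized by the fraction of
donor-specific strains, ``f_ds``: among the strains observed post-FMT, the
fraction that are present in the donor but absent from the recipient's
pre-FMT community.  The hypothesis under test is that high functional
redundancy (FR) of the pre-FMT microbiota raises a barrier to engraftment —
newly arriving strains are functionally redundant with residents and lose the
competition — so ``f_ds`` should associate negatively with pre-FMT FR.

The test is an ordinary multiple linear regression of ``f_ds`` on the chosen
pre-FMT diversity metric (TD, FD or FR, computed from the recipient's pre-FMT
taxonomic profile and a GCN) and the number of days post-FMT, with the overall
F test for significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .diversity import functional_redundancy
from .gcn import GCN, TaxonomicProfile, functional_distance_matrix

METRICS = ("TD", "FD", "FR")


@dataclass
class FMTRecord:
    """Strain-level observations for one recipient at one post-FMT time point."""

    recipient_id: str
    donor_strains: set[str]
    pre_strains: set[str]
    post_strains: set[str]
    t_post: int  # days post-FMT
    pre_profile: TaxonomicProfile | None = None
    post_abundances: dict[str, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.donor_strains:
            raise ValueError("donor strain set must be non-empty")
        if self.t_post <= 0:
            raise ValueError("t_post must be a positive number of days")


def donor_specific_fraction(rec: FMTRecord, weighted: bool = False) -> float:
    """Fraction of the post-FMT community made of donor-specific strains.

    ``f_ds = |post & (donor - pre)| / |post|``.  With ``weighted=True`` the
    strains are weighted by their post-FMT relative abundances instead of
    counted (requires ``post_abundances``).  Returns NaN for an empty post
    set (undefined).
    """
    if not rec.post_strains:
        return math.nan
    donor_specific = rec.donor_strains - rec.pre_strains
    if weighted:
        if rec.post_abundances is None:
            raise ValueError("weighted f_ds requires post_abundances")
        total = sum(rec.post_abundances.get(s, 0.0) for s in rec.post_strains)
        if total <= 0:
            return math.nan
        hit = sum(
            rec.post_abundances.get(s, 0.0)
            for s in rec.post_strains & donor_specific
        )
        return hit / total
    return len(rec.post_strains & donor_specific) / len(rec.post_strains)


@dataclass
class RegressionReport:
    """OLS fit of f_ds on a pre-FMT diversity metric and days post-FMT."""

    metric: str
    params: pd.Series  # const, metric_pre, t_post
    bse: pd.Series
    f_statistic: float
    f_pvalue: float
    r_squared: float
    n_obs: int
    design: pd.DataFrame = field(repr=False)
    response: pd.Series = field(repr=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "stderr": self.bse})


def _metric_value(metric: str, p: TaxonomicProfile, d: np.ndarray) -> float:
    res = functional_redundancy(p, d)
    return {"TD": res.td, "FD": res.fd, "FR": res.fr}[metric]


def engraftment_regression(
    records: list[FMTRecord],
    metric: str,
    g: GCN,
    method: str = "weighted_jaccard",
    weighted_fds: bool = False,
) -> RegressionReport:
    """Regress f_ds on the pre-FMT diversity metric and days post-FMT.

    Repeated measures of a recipient enter as independent rows.  Records with
    an undefined f_ds (empty post set) are dropped.  Raises on fewer than 4
    usable records or on a rank-deficient design (a constant predictor).
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    d = functional_distance_matrix(g, method).values
    rows = []
    for rec in records:
        fds = donor_specific_fraction(rec, weighted=weighted_fds)
        if math.isnan(fds):
            continue
        if rec.pre_profile is None:
            raise ValueError(f"record {rec.recipient_id!r} lacks a pre-FMT profile")
        rows.append(
            {
                "recipient_id": rec.recipient_id,
                "f_ds": fds,
                "metric_pre": _metric_value(metric, rec.pre_profile, d),
                "t_post": float(rec.t_post),
            }
        )
    df = pd.DataFrame(rows)
    if len(df) < 4:
        raise ValueError(f"need >= 4 records with defined f_ds, got {len(df)}")
    x = sm.add_constant(df[["metric_pre", "t_post"]], has_constant="add")
    for col in ("metric_pre", "t_post"):
        if df[col].nunique() < 2:
            raise ValueError(f"rank-deficient design: predictor {col!r} is constant")
    fit = sm.OLS(df["f_ds"], x).fit()
    return RegressionReport(
        metric=metric,
        params=fit.params,
        bse=fit.bse,
        f_statistic=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        r_squared=float(fit.rsquared),
        n_obs=int(fit.nobs),
        design=x,
        response=df["f_ds"],
    )
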