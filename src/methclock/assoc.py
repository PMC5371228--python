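"""Age-association testing and methylome entropy.

Each site's methylation fraction is regressed on the configured covariates
plus a continuous age term; significance of age is assessed with a
drop-one F-test (full model vs the model without the age column), with
Benjamini-Hochberg control of the false-discovery rate across sites.
Replication re-tests the primary hits in independent cohorts, applying BH
within the candidate subset.

Per-sample methylome disorder over a set of N sites is summarized as

    entropy = (1 / (N * log(1/2))) * sum_i [ MF_i*log(MF_i) + (1-MF_i)*log(1-MF_i) ]

which is 1 when every fraction is 0.5 and 0 when every fraction is 0 or 1
(terms at exactly 0 or 1 contribute zero).  The normalizer cancels the
logarithm base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import days_to_months
from .design import build_design


@dataclass
class AssociationTable:
    """Per-site drop-one F-test results with BH q-values."""

    table: pd.DataFrame  # rss_full, rss_reduced, F, p, q, age_coef
    fdr_level: float

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["q"] <= self.fdr_level]


def _rss_via_projection(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares per response column, via a thin QR."""
    Q, _ = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)
    return np.einsum("ij,ij->j", resid, resid)


def test_age_association(
    fractions: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: Sequence[str] = ("treatment", "sex"),
    fdr_level: float = 0.01,
    age_transform: Callable | None = None,
) -> AssociationTable:
    """Drop-one F-test of age for every site, vectorized across sites.

    ``covariates`` are the non-age terms of the full model (categoricals
    one-hot encoded against a reference level); age always enters as the
    last, continuous term.  By default age is used untransformed (days);
    pass ``numpy.log2`` via ``age_transform`` for the clock's scale — the
    F-test is invariant to monotone-linear reparameterizations but the
    reported coefficient is not.
    """
    meta = meta.loc[fractions.index]
    full = build_design(meta, [*covariates, "age"], age_transform=age_transform)
    reduced = full.drop(columns=["age"])
    n, p_full = full.shape
    if n <= p_full:
        raise ValueError(f"too few samples (n={n}) for {p_full} model columns")
    Y = fractions.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("fractions contain missing values; impute first")
    Xf = full.to_numpy(dtype=float)
    Xr = reduced.to_numpy(dtype=float)
    rss_f = _rss_via_projection(Xf, Y)
    rss_r = _rss_via_projection(Xr, Y)
    df_resid = n - p_full
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (rss_r - rss_f) / (rss_f / df_resid)
    F = np.clip(F, 0.0, None)
    p = stats.f.sf(F, 1, df_resid)
    coef, *_ = np.linalg.lstsq(Xf, Y, rcond=None)
    age_coef = coef[list(full.columns).index("age")]
    q = bh_fdr(pd.Series(p, index=fractions.columns))
    table = pd.DataFrame(
        {
            "rss_full": rss_f,
            "rss_reduced": rss_r,
            "F": F,
            "p": p,
            "q": q.to_numpy(),
            "age_coef": age_coef,
        },
        index=fractions.columns,
    )
    return AssociationTable(table=table, fdr_level=fdr_level)


def bh_fdr(pvalues: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement.

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending order statistics,
    capped at 1.
    """
    p = pd.Series(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p.to_numpy(), kind="mergesort")
    ranked = p.to_numpy()[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return pd.Series(q, index=p.index)


def replicate_associations(
    primary: AssociationTable,
    replication_fractions: pd.DataFrame,
    replication_meta: pd.DataFrame,
    covariates: Sequence[str] = ("treatment", "sex"),
    fdr_level: float = 0.01,
    age_transform: Callable | None = None,
) -> pd.Index:
    """Retain primary hits that stay significant in a replication cohort.

    Testing is restricted to the primary-significant sites present in the
    replication data and BH is applied within that subset; the result is
    the intersection of significance.
    """
    candidates = [s for s in primary.significant if s in replication_fractions.columns]
    if not candidates:
        raise ValueError("no primary candidate sites present in replication data")
    rep = test_age_association(
        replication_fractions[candidates],
        replication_meta,
        covariates=covariates,
        fdr_level=fdr_level,
        age_transform=age_transform,
    )
    return rep.significant


@dataclass
class EntropySeries:
    """Per-sample entropy with its correlation against age in months."""

    per_sample: pd.DataFrame  # entropy, age_months
    pearson_r: float
    pearson_p: float
    n_sites: int


def entropy_values(fractions: pd.DataFrame) -> pd.Series:
    """Per-sample methylome entropy over the given sites, in [0, 1]."""
    if fractions.shape[1] == 0:
        raise ValueError("entropy requires at least one site")
    mf = fractions.to_numpy(dtype=float)
    if np.isnan(mf).any():
        raise ValueError("fractions contain missing values; impute first")
    if ((mf < 0) | (mf > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = mf * np.log(mf) + (1.0 - mf) * np.log(1.0 - mf)
    term = np.where((mf <= 0.0) | (mf >= 1.0), 0.0, term)  # boundary sites contribute 0
    n_sites = mf.shape[1]
    vals = term.sum(axis=1) / (n_sites * np.log(0.5))
    return pd.Series(vals, index=fractions.index, name="entropy")


def entropy(fractions: pd.DataFrame, meta: pd.DataFrame) -> EntropySeries:
    """Entropy per sample plus its Pearson correlation with age (months)."""
    vals = entropy_values(fractions)
    age_months = pd.Series(
        days_to_months(meta.loc[fractions.index, "age_days"]), index=fractions.index
    )
    if len(vals) >= 3 and vals.std() > 0 and age_months.std() > 0:
        r, p = stats.pearsonr(vals, age_months)
    else:
        r, p = float("nan"), float("nan")
    per_sample = pd.DataFrame({"entropy": vals, "age_months": age_months})
    return EntropySeries(per_sample=per_sample, pearson_r=float(r), pearson_p=float(p),
                         n_sites=fractions.shape[1])
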