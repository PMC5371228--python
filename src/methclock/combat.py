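"""Empirical-Bayes location/scale batch correction (ComBat algorithm).

Each site is standardized by a covariate-adjusted least-squares fit with a
pooled variance; per-batch location (gamma) and scale (delta) effects are
estimated on the standardized data and shrunk toward a prior across sites
by empirical Bayes.  Two prior modes are provided:

* ``parametric`` — normal prior on locations, inverse-gamma on scales,
  posterior by the usual fixed-point iteration;
* ``nonparametric`` (default) — the posterior expectation of each site's
  (gamma, delta) under the empirical prior formed by all *other* sites'
  estimates, weighted by the likelihood of the site's standardized data.
  The integration sums over the empirical prior exactly, so the fit is
  deterministic.

Covariate signal (age on the log2(days) scale, sex, treatment) is part of
the standardization fit and is restored after adjustment, so the clock's
age signal survives correction.  Adjusted values are not clamped to
[0, 1]; clamping is left to reporting code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import age_log2, build_design


@dataclass
class BatchModel:
    """Fitted standardization plus per-batch EB adjustment parameters."""

    batches: list[str]
    covariate_columns: list[str]
    covariates: list[str]
    grand_mean: np.ndarray  # (G,)
    beta_cov: np.ndarray  # (p_cov, G)
    var_pooled: np.ndarray  # (G,)
    gamma_star: pd.DataFrame  # batches x sites
    delta_star: pd.DataFrame  # batches x sites, > 0
    site_ids: list[str]
    mode: str

    def __post_init__(self) -> None:
        if (self.delta_star.to_numpy() <= 0).any():
            raise ValueError("delta_star must be positive")
        if len(self.batches) < 2:
            raise ValueError("batch correction needs >= 2 batches")


def _designs(meta: pd.DataFrame, covariates: Sequence[str], batch_col: str):
    batches = sorted(meta[batch_col].astype(str).unique())
    B = pd.DataFrame(
        {b: (meta[batch_col].astype(str) == b).astype(float) for b in batches},
        index=meta.index,
    )
    C = build_design(meta, covariates, intercept=False, age_transform=age_log2)
    X = pd.concat([B, C], axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            "covariates are confounded with batch (design rank "
            f"{rank} < {X.shape[1]}); check columns {list(X.columns)}"
        )
    return batches, B, C, X


def fit_batch_model(
    fractions: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "treatment"),
    batch_col: str = "study",
    mode: str = "nonparametric",
) -> BatchModel:
    """Fit the EB batch model on a complete samples x sites fraction table."""
    if mode not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown mode {mode!r}")
    meta = meta.loc[fractions.index]
    counts = meta[batch_col].astype(str).value_counts()
    singletons = counts.index[counts < 2].tolist()
    if singletons:
        raise ValueError(f"singleton batches cannot be corrected: {singletons}")
    batches, B, C, X = _designs(meta, covariates, batch_col)

    Y = fractions.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("fractions contain missing values; impute first")
    n, G = Y.shape
    nb = len(batches)
    Xm = X.to_numpy()
    beta, *_ = np.linalg.lstsq(Xm, Y, rcond=None)  # (nb + p_cov, G)
    batch_means, beta_cov = beta[:nb], beta[nb:]
    weights = B.to_numpy().sum(axis=0) / n
    grand_mean = weights @ batch_means  # (G,)
    resid = Y - Xm @ beta
    var_pooled = np.einsum("ij,ij->j", resid, resid) / n
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = grand_mean[None, :] + C.to_numpy() @ beta_cov
    Z = (Y - stand_mean) / np.sqrt(var_pooled)[None, :]

    batch_idx = [np.flatnonzero(B[b].to_numpy() > 0) for b in batches]
    gamma_hat = np.vstack([Z[idx].mean(axis=0) for idx in batch_idx])
    # population (1/n_i) variance around the batch mean: a fit on data with
    # no batch effect then adjusts to the identity exactly
    delta_hat = np.vstack([Z[idx].var(axis=0, ddof=0) for idx in batch_idx])
    delta_hat = np.maximum(delta_hat, 1e-12)

    if mode == "parametric":
        gamma_star, delta_star = _parametric_posterior(Z, batch_idx, gamma_hat, delta_hat)
    else:
        gamma_star, delta_star = _nonparametric_posterior(Z, batch_idx, gamma_hat, delta_hat)

    sites = list(fractions.columns)
    return BatchModel(
        batches=batches,
        covariate_columns=list(C.columns),
        covariates=list(covariates),
        grand_mean=grand_mean,
        beta_cov=beta_cov,
        var_pooled=var_pooled,
        gamma_star=pd.DataFrame(gamma_star, index=batches, columns=sites),
        delta_star=pd.DataFrame(np.maximum(delta_star, 1e-12), index=batches, columns=sites),
        site_ids=sites,
        mode=mode,
    )


def _parametric_posterior(Z, batch_idx, gamma_hat, delta_hat, tol=1e-6, max_iter=500):
    nb, G = gamma_hat.shape
    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i, idx in enumerate(batch_idx):
        n_i = len(idx)
        g_hat, d_hat = gamma_hat[i], delta_hat[i]
        g_bar, t2 = g_hat.mean(), max(g_hat.var(ddof=1), 1e-12)
        m, s2 = d_hat.mean(), max(d_hat.var(ddof=1), 1e-12)
        a_prior = (2 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        g_new, d_new = g_hat.copy(), d_hat.copy()
        sdat = Z[idx]  # (n_i, G)
        for _ in range(max_iter):
            g_old, d_old = g_new.copy(), d_new.copy()
            g_new = (t2 * n_i * g_hat + d_new * g_bar) / (t2 * n_i + d_new)
            ssq = ((sdat - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (0.5 * ssq + b_prior) / (n_i / 2.0 + a_prior - 1.0)
            change = max(
                np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
                np.abs(d_new - d_old).max() / np.abs(d_old).max(),
            )
            if change < tol:
                break
        gamma_star[i], delta_star[i] = g_new, d_new
    return gamma_star, delta_star


def _nonparametric_posterior(Z, batch_idx, gamma_hat, delta_hat):
    """Posterior expectation under the empirical prior of the other sites.

    For site g in batch i the weight of prior atom j (j != g) is the
    normal likelihood of site g's standardized observations under
    N(gamma_hat[j], delta_hat[j]); the posterior is the weighted mean of
    the (gamma_hat, delta_hat) atoms.
    """
    nb, G = gamma_hat.shape
    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i, idx in enumerate(batch_idx):
        sdat = Z[idx]  # (n_i, G)
        n_i = len(idx)
        sum_z = sdat.sum(axis=0)  # (G,)
        sum_z2 = (sdat**2).sum(axis=0)
        g, d = gamma_hat[i], delta_hat[i]  # (G,) prior atoms
        # log-likelihood matrix: rows = data site, cols = prior atom
        quad = (
            sum_z2[:, None] - 2.0 * np.outer(sum_z, g) + n_i * (g**2)[None, :]
        )
        loglik = -0.5 * quad / d[None, :] - 0.5 * n_i * np.log(2 * np.pi * d)[None, :]
        np.fill_diagonal(loglik, -np.inf)  # leave-one-out empirical prior
        loglik -= loglik.max(axis=1, keepdims=True)
        w = np.exp(loglik)
        w_sum = w.sum(axis=1)
        gamma_star[i] = (w @ g) / w_sum
        delta_star[i] = (w @ d) / w_sum
    return gamma_star, delta_star


def apply_batch_model(
    fractions: pd.DataFrame,
    model: BatchModel,
    meta: pd.DataFrame,
    batch_col: str = "study",
) -> pd.DataFrame:
    """Adjust a fraction table with a fitted model (sites must match)."""
    if list(fractions.columns) != model.site_ids:
        raise ValueError("matrix sites do not match the fitted batch model")
    meta = meta.loc[fractions.index]
    labels = meta[batch_col].astype(str)
    unseen = sorted(set(labels) - set(model.batches))
    if unseen:
        raise ValueError(f"unseen batch labels: {unseen}")
    C = build_design(meta, model.covariates, intercept=False, age_transform=age_log2)
    if list(C.columns) != model.covariate_columns:
        raise ValueError(
            f"covariate encoding mismatch: fit used {model.covariate_columns}, "
            f"apply produced {list(C.columns)}"
        )
    Y = fractions.to_numpy(dtype=float)
    stand_mean = model.grand_mean[None, :] + C.to_numpy() @ model.beta_cov
    Z = (Y - stand_mean) / np.sqrt(model.var_pooled)[None, :]
    gamma = model.gamma_star.loc[labels].to_numpy()
    delta = model.delta_star.loc[labels].to_numpy()
    adjusted = (Z - gamma) / np.sqrt(delta) * np.sqrt(model.var_pooled)[None, :] + stand_mean
    return pd.DataFrame(adjusted, index=fractions.index, columns=fractions.columns)


def combat(
    fractions: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "treatment"),
    batch_col: str = "study",
    mode: str = "nonparametric",
) -> tuple[pd.DataFrame, BatchModel]:
    """Fit and apply in one step (the joint-fit default of the pipeline)."""
    model = fit_batch_model(fractions, meta, covariates, batch_col, mode)
    return apply_batch_model(fractions, model, meta, batch_col), model


def _pc_batch_r2(fractions: pd.DataFrame, labels: pd.Series, n_pcs: int = 2) -> list[float]:
    Y = fractions.to_numpy(dtype=float)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Yc, full_matrices=False)
    out = []
    for k in range(min(n_pcs, len(S))):
        pc = U[:, k] * S[k]
        groups = [pc[(labels == b).to_numpy()] for b in labels.unique()]
        grand = pc.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_total = ((pc - grand) ** 2).sum()
        out.append(float(ss_between / ss_total) if ss_total > 0 else 0.0)
    return out


def check_batch_removal(
    before: pd.DataFrame,
    after: pd.DataFrame,
    meta: pd.DataFrame,
    batch_col: str = "study",
) -> pd.DataFrame:
    """Variance of the top principal components explained by batch.

    Reports the R-squared of each of the first two PC scores on the batch
    factor, for the matrix before and after adjustment.
    """
    labels = meta.loc[before.index, batch_col].astype(str)
    if labels.nunique() < 2:
        raise ValueError("need >= 2 batches for a batch-removal diagnostic")
    r2_before = _pc_batch_r2(before, labels)
    r2_after = _pc_batch_r2(after, meta.loc[after.index, batch_col].astype(str))
    rows = []
    for k in range(len(r2_before)):
        rows.append({"component": f"PC{k + 1}", "r2_before": r2_before[k],
                     "r2_after": r2_after[k] if k < len(r2_after) else float("nan")})
    return pd.DataFrame(rows).set_index("component")
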