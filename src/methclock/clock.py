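"""The elastic-net epigenetic clock: training, prediction, controls.

The clock is a penalized linear regression of log2(age in days) on
batch-corrected methylation fractions:

    minimize (1/2n) * ||y - b - Xw||^2 + lambda * (rho*||w||_1 + (1-rho)/2*||w||_2^2)

Hyperparameters (lambda, rho) are chosen by k-fold cross-validation (4
folds by default), scoring each candidate by the mean held-out Pearson
correlation between predicted and chronological log-age; the winner is
refit on the full training set.  Weights are in log2(days) per unit
methylation fraction; predicted age in days is 2**(b + Xw).

A covariate-shuffle permutation control re-runs batch correction and
training on metadata shuffled within study and checks that the model
learned from the real data attains the smallest wild-type residual.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, Lasso, Ridge

from .combat import combat
from .core import days_to_months

DEFAULT_L1_RATIOS = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, defined as 0 when either input is (numerically) constant."""
    if np.ptp(a) < 1e-12 or np.ptp(b) < 1e-12:
        return 0.0
    r = stats.pearsonr(a, b)[0]
    return float(r) if np.isfinite(r) else 0.0


@dataclass
class ClockModel:
    """Selected sites, weights (log2-days per fraction unit) and intercept."""

    weights: pd.Series  # nonzero site weights
    intercept: float
    alpha: float  # overall penalty strength lambda
    l1_ratio: float  # L1/L2 mixing rho
    training_samples: list[str]
    site_universe: list[str]  # feature columns seen at training time

    @property
    def sites(self) -> list[str]:
        return list(self.weights.index)

    def to_frame(self) -> pd.DataFrame:
        """Model table: one row per site (chrom, start, stop, weight) + intercept."""
        from .core import parse_site_id

        rows = []
        for sid, w in self.weights.items():
            chrom, pos = parse_site_id(sid)
            rows.append({"chrom": chrom, "start": pos, "stop": pos + 1, "weight": w})
        rows.append({"chrom": "intercept", "start": -1, "stop": -1, "weight": self.intercept})
        return pd.DataFrame(rows)


@dataclass
class CVReport:
    """Per-fold held-out Pearson r for the selected hyperparameters."""

    fold_r: list[float]
    mean_r: float
    grid_scores: pd.DataFrame  # alpha, l1_ratio, mean_r


@dataclass
class PredictionResult:
    """Per-sample epigenetic vs chronological age."""

    table: pd.DataFrame  # epigenetic_age_days/_months, age_days/_months, residual_months

    @property
    def residuals_months(self) -> pd.Series:
        return self.table["residual_months"]

    @property
    def mean_abs_error_months(self) -> float:
        return float(self.table["residual_months"].abs().mean())


def _fit_enet(X: np.ndarray, y: np.ndarray, alpha: float, l1_ratio: float) -> ElasticNet:
    if alpha == 0.0:
        # unpenalized limit: coordinate descent is unreliable at alpha=0
        model = Ridge(alpha=0.0, solver="svd")
    elif l1_ratio == 1.0:
        model = Lasso(alpha=alpha, max_iter=10000, tol=1e-4)
    elif l1_ratio == 0.0:
        model = Ridge(alpha=alpha * len(y))
    else:
        model = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=10000, tol=1e-4)
    model.fit(X, y)
    return model


def _alpha_grid(X: np.ndarray, y: np.ndarray, l1_ratio: float, n_alphas: int,
                eps: float = 1e-3) -> np.ndarray:
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    alpha_max = np.abs(Xc.T @ yc).max() / (n * max(l1_ratio, 0.1))
    alpha_max = max(alpha_max, 1e-8)
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max * eps), n_alphas)


def make_folds(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Shuffle once by seed, then split into contiguous blocks."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(order, folds)]


def train_clock(
    fractions: pd.DataFrame,
    meta: pd.DataFrame,
    folds: int = 4,
    l1_ratios: Sequence[float] = DEFAULT_L1_RATIOS,
    n_alphas: int = 50,
    seed: int = 0,
    criterion: str = "pearson",
) -> tuple[ClockModel, CVReport]:
    """Cross-validated elastic-net fit of log2(age_days) on fractions."""
    if criterion not in ("pearson", "mse"):
        raise ValueError(f"unknown criterion {criterion!r}")
    meta = meta.loc[fractions.index]
    y = np.log2(meta["age_days"].to_numpy(dtype=float))
    X = fractions.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("fractions contain missing values; impute first")
    n = len(y)
    if n < 2 * folds:
        raise ValueError(f"need >= {2 * folds} samples for {folds}-fold CV")
    if len(l1_ratios) == 0:
        raise ValueError("empty hyperparameter grid")
    fold_idx = make_folds(n, folds, seed)
    for k, te in enumerate(fold_idx):
        if np.ptp(y[np.setdiff1d(np.arange(n), te)]) == 0:
            raise ValueError(f"fold {k}: constant age in training portion")

    grid_rows = []
    best = None  # (score, alpha, l1_ratio)
    for rho in l1_ratios:
        alphas = _alpha_grid(X, y, rho, n_alphas)
        # held-out predictions for the whole path, per fold
        preds = np.empty((len(alphas), n))
        for te in fold_idx:
            tr = np.setdiff1d(np.arange(n), te)
            model = ElasticNet(
                alpha=alphas[0], l1_ratio=max(rho, 1e-3), max_iter=10000,
                tol=1e-4, warm_start=True,
            )
            for ai, alpha in enumerate(alphas):
                model.set_params(alpha=alpha)
                model.fit(X[tr], y[tr])
                preds[ai, te] = model.predict(X[te])
        for ai, alpha in enumerate(alphas):
            rs = []
            for te in fold_idx:
                rs.append(_safe_pearson(preds[ai, te], y[te]))
            if criterion == "pearson":
                score = float(np.mean(rs))
            else:
                score = -float(np.mean((preds[ai] - y) ** 2))
            grid_rows.append({"alpha": alpha, "l1_ratio": rho, "mean_r": float(np.mean(rs)),
                              "score": score})
            if best is None or score > best[0]:
                best = (score, alpha, rho)

    _, alpha, rho = best
    final = _fit_enet(X, y, alpha, rho)
    weights = pd.Series(final.coef_, index=fractions.columns)
    weights = weights[weights != 0.0]
    model = ClockModel(
        weights=weights,
        intercept=float(final.intercept_),
        alpha=float(alpha),
        l1_ratio=float(rho),
        training_samples=list(fractions.index),
        site_universe=list(fractions.columns),
    )
    # per-fold r of the selected hyperparameters
    fold_r = []
    for te in fold_idx:
        tr = np.setdiff1d(np.arange(n), te)
        m = _fit_enet(X[tr], y[tr], alpha, rho)
        fold_r.append(_safe_pearson(m.predict(X[te]), y[te]))
    report = CVReport(
        fold_r=fold_r,
        mean_r=float(np.mean(fold_r)),
        grid_scores=pd.DataFrame(grid_rows),
    )
    return model, report


def predict_age(model: ClockModel, fractions: pd.DataFrame, meta: pd.DataFrame) -> PredictionResult:
    """Predict epigenetic age; residual = epigenetic - chronological (months)."""
    missing = [s for s in model.sites if s not in fractions.columns]
    if missing:
        raise ValueError(f"matrix lacks model sites: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    X = fractions[model.sites].to_numpy(dtype=float)
    log_age = model.intercept + X @ model.weights.to_numpy()
    epi_days = np.power(2.0, log_age)
    meta = meta.loc[fractions.index]
    age_days = meta["age_days"].to_numpy(dtype=float)
    table = pd.DataFrame(
        {
            "epigenetic_age_days": epi_days,
            "epigenetic_age_months": days_to_months(epi_days),
            "age_days": age_days,
            "age_months": days_to_months(age_days),
        },
        index=fractions.index,
    )
    table["residual_months"] = table["epigenetic_age_months"] - table["age_months"]
    return PredictionResult(table=table)


def classify_direction(fractions: pd.DataFrame, meta: pd.DataFrame,
                       sites: Sequence[str] | None = None) -> pd.Series:
    """Per-site gain/loss of methylation with age.

    Sign of the Pearson correlation between the site's fraction and
    log2(age) over the given samples; exact zero correlation is reported
    as ``"flat"``.
    """
    if sites is not None:
        fractions = fractions[list(sites)]
    log_age = np.log2(meta.loc[fractions.index, "age_days"].to_numpy(dtype=float))
    X = fractions.to_numpy(dtype=float)
    xc = X - X.mean(axis=0)
    ac = log_age - log_age.mean()
    cov = ac @ xc
    labels = np.where(cov > 0, "gain", np.where(cov < 0, "loss", "flat"))
    return pd.Series(labels, index=fractions.columns, name="direction")


CLOCK_REGIONS = ("enhancer", "promoter", "exon", "intron", "intergenic")


def resolve_region_precedence(
    annotation: pd.DataFrame, regions: Sequence[str] = CLOCK_REGIONS
) -> pd.Series:
    """Single region label per site, prioritizing enhancer then promoter.

    Remaining overlaps resolve in the listed order; unannotated sites get
    ``"intergenic"``.
    """
    out = pd.Series("intergenic", index=annotation.index)
    for region in reversed([r for r in regions if r in annotation.columns]):
        out[annotation[region].astype(bool)] = region
    return out


def clock_site_enrichment(
    model_sites: Sequence[str],
    candidate_sites: Sequence[str],
    annotation: pd.DataFrame,
    regions: Sequence[str] = CLOCK_REGIONS,
) -> pd.DataFrame:
    """Fisher 2x2 enrichment of clock sites per region, with precedence."""
    from .xspecies import fisher_enrichment

    candidates = pd.Index(candidate_sites)
    unknown = [s for s in model_sites if s not in set(candidates)]
    if unknown:
        raise ValueError("model sites must be a subset of candidate sites")
    label = resolve_region_precedence(annotation.loc[candidates], regions)
    selected = candidates.isin(set(model_sites))
    rows = []
    for region in regions:
        in_region = (label == region).to_numpy()
        a = int((selected & in_region).sum())
        b = int((selected & ~in_region).sum())
        c = int((~selected & in_region).sum())
        d = int((~selected & ~in_region).sum())
        odds, p = fisher_enrichment([a, b, c, d])
        rows.append({"region": region, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds, "p": p})
    return pd.DataFrame(rows).set_index("region")


@dataclass
class PermutationControl:
    """Real vs covariate-shuffled pipeline residuals."""

    real_mean_abs_residual: float
    permuted_mean_abs_residuals: list[float]

    @property
    def rank(self) -> int:
        """1-based rank of the real model (1 = smallest residual of all)."""
        return 1 + sum(p < self.real_mean_abs_residual for p in self.permuted_mean_abs_residuals)


def permutation_control(
    fractions: pd.DataFrame,
    meta: pd.DataFrame,
    train_samples: Sequence[str],
    eval_samples: Sequence[str],
    n_permutations: int = 120,
    seed: int = 0,
    covariates: Sequence[str] = ("age", "sex", "treatment"),
    batch_col: str = "study",
    combat_mode: str = "parametric",
    **train_kwargs,
) -> PermutationControl:
    """Covariate-shuffle control of the full normalize-and-train pipeline.

    For each permutation the covariate rows of the metadata are shuffled
    within study, batch correction is refit, the clock retrained, and the
    mean |epigenetic - chronological| residual of the evaluation samples
    (scored against their true ages) recorded.  The real model should
    minimize the residual when a genuine age signal is present.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)

    def run(meta_run: pd.DataFrame) -> float:
        adjusted, _ = combat(fractions, meta_run, covariates=covariates,
                             batch_col=batch_col, mode=combat_mode)
        model, _ = train_clock(adjusted.loc[list(train_samples)],
                               meta_run, seed=seed, **train_kwargs)
        pred = predict_age(model, adjusted.loc[list(eval_samples)], meta)
        return pred.mean_abs_error_months

    real = run(meta)
    shuffle_cols = [c for c in ("age_days", "sex", "treatment") if c in meta.columns]
    permuted = []
    for _ in range(n_permutations):
        meta_p = meta.copy()
        for batch in meta[batch_col].unique():
            idx = meta.index[meta[batch_col] == batch]
            perm = rng.permutation(len(idx))
            meta_p.loc[idx, shuffle_cols] = meta.loc[idx, shuffle_cols].iloc[perm].to_numpy()
        permuted.append(run(meta_p))
    return PermutationControl(real_mean_abs_residual=real,
                              permuted_mean_abs_residuals=permuted)
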