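"""Scoring lifespan-extending treatments against the clock.

Treated animals are compared with age-matched, same-background controls:
the reduction in epigenetic age (months), a two-sample t-test per group,
and a one-way ANOVA across the old-age groups.  A PCA of the clock's
sites summarizes the age/treatment structure along PC1 (oriented to
increase with age), and hierarchical clustering with average linkage and
Euclidean distance reproduces the heatmap view of the most variable clock
sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .clock import PredictionResult


@dataclass
class TreatmentComparison:
    """Per-group reductions vs matched controls plus the pooled ANOVA."""

    per_group: pd.DataFrame  # treatment, age_group, n_treated, n_control, reduction_months, t, p
    anova_F: float
    anova_p: float


def compare_treatments(
    predictions: PredictionResult,
    meta: pd.DataFrame,
    age_groups: dict[str, Sequence[str]] | None = None,
    anova_group: str | None = None,
    equal_var: bool = True,
) -> TreatmentComparison:
    """Compare treated groups with their age-matched, same-strain controls.

    ``age_groups`` maps a group label (e.g. ``"22m"``) to the sample ids in
    that chronological-age group; by default samples are grouped by their
    rounded age in months.  Within each (group, strain), every treatment
    other than ``"none"`` is tested against the untreated controls:
    reduction = mean(control epigenetic age) - mean(treated), Student's
    t-test (Welch via ``equal_var=False``).  The ANOVA pools all
    treatments of ``anova_group`` (default: the oldest group) on
    epigenetic age.
    """
    table = predictions.table
    meta = meta.loc[table.index]
    if age_groups is None:
        months = table["age_months"].round().astype(int)
        age_groups = {f"{m}m": list(table.index[months == m]) for m in sorted(months.unique())}

    rows = []
    for group, ids in age_groups.items():
        ids = [s for s in ids if s in table.index]
        sub_meta = meta.loc[ids]
        for strain in sub_meta["strain"].unique():
            strain_ids = sub_meta.index[sub_meta["strain"] == strain]
            control_ids = [s for s in strain_ids if sub_meta.loc[s, "treatment"] == "none"]
            for treatment in sub_meta.loc[strain_ids, "treatment"].unique():
                if treatment == "none":
                    continue
                treated_ids = [s for s in strain_ids if sub_meta.loc[s, "treatment"] == treatment]
                if len(treated_ids) < 2:
                    continue
                if len(control_ids) < 2:
                    raise ValueError(
                        f"treated group ({group}, {strain}, {treatment}) has no matched controls"
                    )
                treated = table.loc[treated_ids, "epigenetic_age_months"]
                control = table.loc[control_ids, "epigenetic_age_months"]
                t, p = stats.ttest_ind(control, treated, equal_var=equal_var)
                rows.append(
                    {
                        "age_group": group,
                        "strain": strain,
                        "treatment": treatment,
                        "n_treated": len(treated_ids),
                        "n_control": len(control_ids),
                        "reduction_months": float(control.mean() - treated.mean()),
                        "t": float(t),
                        "p": float(p),
                    }
                )
    per_group = pd.DataFrame(rows)

    if anova_group is None and age_groups:
        anova_group = list(age_groups)[-1]
    anova_F = anova_p = float("nan")
    if anova_group in age_groups:
        ids = [s for s in age_groups[anova_group] if s in table.index]
        groups = [
            table.loc[[s for s in ids if meta.loc[s, "treatment"] == tr], "epigenetic_age_months"]
            for tr in meta.loc[ids, "treatment"].unique()
        ]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) >= 2:
            anova_F, anova_p = (float(v) for v in stats.f_oneway(*groups))
    return TreatmentComparison(per_group=per_group, anova_F=anova_F, anova_p=anova_p)


@dataclass
class PCAResult:
    """Centered PCA of clock sites with a PC1 ~ age + treatment regression."""

    scores: pd.DataFrame  # samples x PCs
    loadings: pd.DataFrame  # sites x PCs
    variance_explained: np.ndarray
    pc1_regressions: pd.DataFrame  # per strain: term, coef, p


def pca_clock_sites(
    fractions: pd.DataFrame,
    meta: pd.DataFrame,
    n_components: int = 2,
) -> PCAResult:
    """Centered (unscaled) PCA by SVD; PC1 oriented to rise with age.

    Also regresses PC1 on age + treatment (categorical) within each
    strain, reporting coefficients and p-values.
    """
    if fractions.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    meta = meta.loc[fractions.index]
    X = fractions.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(S))
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    # fix the sign convention: PC1 increases with age
    age = meta["age_days"].to_numpy(dtype=float)
    if np.corrcoef(scores[:, 0], age)[0, 1] < 0:
        scores[:, 0] *= -1.0
        loadings[:, 0] *= -1.0
    var = S**2 / max(len(X) - 1, 1)
    var_explained = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)

    import statsmodels.formula.api as smf

    reg_rows = []
    df = pd.DataFrame({"pc1": scores[:, 0],
                       "age": np.log2(age),
                       "treatment": meta["treatment"].astype(str),
                       "strain": meta["strain"].astype(str)},
                      index=fractions.index)
    for strain, sub in df.groupby("strain"):
        terms = "age + treatment" if sub["treatment"].nunique() > 1 else "age"
        if sub["age"].nunique() < 2 and "+" not in terms:
            continue
        try:
            fit = smf.ols(f"pc1 ~ {terms}", data=sub).fit()
        except Exception:
            continue
        for term in fit.params.index:
            if term == "Intercept":
                continue
            reg_rows.append({"strain": strain, "term": term,
                             "coef": float(fit.params[term]),
                             "p": float(fit.pvalues[term])})
    cols = ["PC" + str(i + 1) for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=fractions.index, columns=cols),
        loadings=pd.DataFrame(loadings, index=fractions.columns, columns=cols),
        variance_explained=var_explained,
        pc1_regressions=pd.DataFrame(reg_rows),
    )


@dataclass
class ClusterResult:
    """Average-linkage dendrogram over samples with the scaled site matrix."""

    linkage: np.ndarray
    leaf_order: list[str]
    scaled: pd.DataFrame  # samples x sites after per-site scaling
    sites: list[str]


def top_variable_sites(fractions: pd.DataFrame, k: int,
                       samples: Sequence[str] | None = None) -> list[str]:
    """The k sites of largest variance (n-1 denominator) over the given samples."""
    sub = fractions.loc[list(samples)] if samples is not None else fractions
    var = sub.var(axis=0, ddof=1)
    return list(var.sort_values(ascending=False, kind="mergesort").index[:k])


def cluster_heatmap(
    fractions: pd.DataFrame,
    sites: Sequence[str] | None = None,
    k: int | None = 20,
    variance_samples: Sequence[str] | None = None,
    scale: str = "minmax",
) -> ClusterResult:
    """Hierarchical clustering of samples over (top-variable) clock sites.

    Sites are rescaled per site — min-max to [0, 1] by default (the
    convention of the heatmap plotting tools), z-score optionally — then
    samples are clustered on Euclidean distances with average linkage.
    Zero-range sites are dropped with a warning.  Leaf order is the
    deterministic scipy ordering (ties broken by original index).
    """
    import warnings

    if sites is None:
        if k is None or k > fractions.shape[1]:
            raise ValueError("k must be <= number of sites")
        sites = top_variable_sites(fractions, k, variance_samples)
    sub = fractions[list(sites)]
    if scale == "minmax":
        rng_ = sub.max(axis=0) - sub.min(axis=0)
        dead = list(rng_.index[rng_ == 0])
        if dead:
            warnings.warn(f"{len(dead)} zero-range sites dropped before scaling")
            sub = sub.drop(columns=dead)
            rng_ = rng_.drop(index=dead)
        scaled = (sub - sub.min(axis=0)) / rng_
    elif scale == "zscore":
        sd = sub.std(axis=0, ddof=1)
        dead = list(sd.index[sd == 0])
        if dead:
            warnings.warn(f"{len(dead)} zero-variance sites dropped before scaling")
            sub = sub.drop(columns=dead)
            sd = sd.drop(index=dead)
        scaled = (sub - sub.mean(axis=0)) / sd
    else:
        raise ValueError(f"unknown scale {scale!r}")
    dist = pdist(scaled.to_numpy(dtype=float), metric="euclidean")
    Z = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(Z)
    return ClusterResult(
        linkage=Z,
        leaf_order=[scaled.index[i] for i in order],
        scaled=scaled,
        sites=list(scaled.columns),
    )


def plot_heatmap(result: ClusterResult, path: str) -> None:
    """Render the clustered heatmap to a file (thin matplotlib wrapper)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = result.scaled.loc[result.leaf_order]
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(data.to_numpy().T, aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(result.sites)))
    ax.set_yticklabels(result.sites, fontsize=6)
    ax.set_xticks(range(len(result.leaf_order)))
    ax.set_xticklabels(result.leaf_order, rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="scaled methylation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
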