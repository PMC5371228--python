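"""Design-matrix construction shared by the regression and batch steps.

Categorical covariates are one-hot encoded against a reference level (the
lexically first level); age enters as a continuous term, by default on the
log2(days) scale the clock operates on.  The same builder serves the
per-site age-association models and the covariate part of the batch
corrector, so both stages agree on the encoding.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd


def age_log2(age_days: pd.Series) -> pd.Series:
    return np.log2(age_days.astype(float))


def build_design(
    meta: pd.DataFrame,
    covariates: Sequence[str],
    intercept: bool = True,
    age_transform: Callable[[pd.Series], pd.Series] | None = age_log2,
) -> pd.DataFrame:
    """Encode the listed covariates into a numeric design matrix.

    ``"age"`` (or ``"age_days"``) is treated as continuous and passed
    through ``age_transform``; any other numeric column is used as is;
    object/categorical columns are one-hot encoded dropping the reference
    level.  Raises if the resulting matrix is rank deficient, naming the
    collinear columns.
    """
    cols: dict[str, np.ndarray] = {}
    if intercept:
        cols["intercept"] = np.ones(len(meta))
    for cov in covariates:
        if cov in ("age", "age_days"):
            age = meta["age_days"]
            vals = age_transform(age) if age_transform is not None else age.astype(float)
            cols["age"] = np.asarray(vals, dtype=float)
            continue
        if cov not in meta.columns:
            raise KeyError(f"covariate {cov!r} not in metadata")
        series = meta[cov]
        if pd.api.types.is_numeric_dtype(series):
            cols[cov] = series.to_numpy(dtype=float)
        else:
            levels = sorted(series.astype(str).unique())
            for level in levels[1:]:  # first level is the reference
                cols[f"{cov}[{level}]"] = (series.astype(str) == level).to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=meta.index)
    _check_full_rank(design)
    return design


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns involved in the collinearity via QR pivoting
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        dropped = [design.columns[i] for i in piv[rank:]]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {dropped}"
        )


def ols_fit(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients for possibly many responses at once.

    ``X`` is (n, p), ``Y`` is (n, k); returns (p, k).
    """
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return coef
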