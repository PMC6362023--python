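"""Sample filtering, gene filtering and covariate adjustment of expression.

The adjustment regresses each gene's expression on RNA integrity (RIN),
ethnicity and sex, and keeps residual + fitted intercept as the adjusted
value, so adjusted values stay on the original expression scale with the
covariate structure removed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

log = logging.getLogger(__name__)

__all__ = ["filter_samples", "filter_genes", "adjust_expression", "CovariateAdjuster"]

DEFAULT_COVARIATES = ("RIN", "ethnicity", "sex")
_CATEGORICAL = {"ethnicity", "sex"}


def filter_samples(
    expr: pd.DataFrame, samples: pd.DataFrame, rin_min: float = 7.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop low-RNA-integrity samples (RIN < ``rin_min``); column order kept."""
    missing = set(expr.columns) - set(samples["sample_id"])
    if missing:
        raise ValueError(f"expression columns without metadata: {sorted(missing)[:5]}")
    rin = samples.set_index("sample_id")["RIN"]
    keep_ids = {sid for sid in expr.columns if rin[sid] >= rin_min}
    if not keep_ids:
        raise ValueError(f"RIN filter (RIN >= {rin_min}) removed every sample")
    kept_cols = [c for c in expr.columns if c in keep_ids]
    kept_samples = samples[samples["sample_id"].isin(keep_ids)].reset_index(drop=True)
    return expr[kept_cols], kept_samples


def filter_genes(expr: pd.DataFrame, genes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Remove genes unexpressed in every sample or absent from the annotation;
    collapse duplicate gene ids.

    Duplicates keep the row with the highest mean expression (ties: first
    after a stable sort on gene id), so the result does not depend on input
    row order for distinct-mean duplicates.
    """
    out = expr
    if genes is not None:
        known = set(genes["gene_id"])
        out = out.loc[[g in known for g in out.index]]
    nonzero = (out.to_numpy() != 0).any(axis=1)
    out = out.loc[nonzero]
    if out.index.has_duplicates:
        means = out.mean(axis=1).to_numpy()
        tmp = out.assign(_mean=means)
        tmp = tmp.sort_index(kind="stable")
        tmp = tmp.sort_values("_mean", ascending=False, kind="stable")
        tmp = tmp[~tmp.index.duplicated(keep="first")].drop(columns="_mean")
        out = tmp.sort_index(kind="stable")
        log.info("collapsed duplicate gene ids; %d genes remain", len(out))
    return out


def _design_matrix(samples: pd.DataFrame, covariates: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Intercept + numeric covariates + treatment-coded dummies (most frequent
    level as reference). Collinear columns are dropped with a warning."""
    cols: list[np.ndarray] = [np.ones(len(samples))]
    names = ["intercept"]
    for cov in covariates:
        if cov not in samples.columns:
            raise ValueError(f"covariate {cov!r} missing from sample table")
        if cov in _CATEGORICAL or samples[cov].dtype == object:
            counts = samples[cov].value_counts()
            ref = counts.index[0]
            for level in sorted(l for l in counts.index if l != ref):
                cols.append((samples[cov] == level).to_numpy(dtype=float))
                names.append(f"{cov}[{level}]")
        else:
            cols.append(samples[cov].to_numpy(dtype=float))
            names.append(cov)
    X = np.column_stack(cols)
    # mean-centre covariate columns: the intercept then absorbs covariate
    # location, so adjusted values are invariant to shifting a covariate or
    # to the dummy reference choice, and the intercept is the gene mean
    X[:, 1:] -= X[:, 1:].mean(axis=0)
    # greedy rank check, dropping collinear columns left to right
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) == len(trial):
            keep.append(j)
        else:
            log.warning("dropping collinear design column %r", names[j])
    return X[:, keep], [names[j] for j in keep]


class CovariateAdjuster(BaseEstimator, TransformerMixin):
    """Per-gene OLS removal of technical/demographic covariates.

    Fits, for every gene, expression ~ intercept + RIN + ethnicity + sex and
    replaces values with residual + fitted intercept. sklearn-style
    transformer over a genes × samples DataFrame; the sample metadata is
    supplied to :meth:`fit` and must cover every expression column.

    Attributes
    ----------
    coef_ : ndarray of shape (n_genes, n_design_columns)
    design_columns_ : list of str
    """

    def __init__(self, covariates: tuple[str, ...] = DEFAULT_COVARIATES):
        self.covariates = covariates

    def fit(self, X: pd.DataFrame, y=None, *, samples: pd.DataFrame):
        if X.shape[1] < 2:
            raise ValueError("need at least two samples to adjust expression")
        meta = samples.set_index("sample_id").loc[list(X.columns)].reset_index()
        D, names = _design_matrix(meta, tuple(self.covariates))
        coef, *_ = np.linalg.lstsq(D, X.to_numpy().T, rcond=None)
        self.design_ = D
        self.design_columns_ = names
        self.coef_ = coef.T
        self.gene_index_ = X.index
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "coef_"):
            raise ValueError("CovariateAdjuster is not fitted")
        fitted = self.coef_ @ self.design_.T
        resid = X.to_numpy() - fitted
        adjusted = resid + self.coef_[:, [0]]  # residual + per-gene intercept
        return pd.DataFrame(adjusted, index=X.index, columns=X.columns)


def adjust_expression(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Residual-plus-intercept covariate adjustment (see CovariateAdjuster)."""
    adj = CovariateAdjuster(covariates=covariates)
    return adj.fit(expr, samples=samples).transform(expr)
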