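"""Gene-property regression: association Z against expression scores.

The core model regresses the gene-level association Z-score on a continuous
gene-level property (here, the stage-wise relative expression score) with
technical covariates for gene size and SNP density:

    Z ~ intercept + score + size + density + log(size) + log(density) [+ conditioned scores]

The t-test on the score coefficient is two-tailed; per analysis tier the
p-value is Bonferroni-adjusted for the number of (stage × group) tests in
that tier. Conditional analyses add the conditioned stage's scores as
covariates and are reported at uncorrected p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

log = logging.getLogger(__name__)

__all__ = [
    "PropertyResult",
    "GenePropertyRegression",
    "property_regression",
    "tier_analysis",
    "conditional_pair",
    "DEFAULT_PROPERTY_COVARIATES",
]

DEFAULT_PROPERTY_COVARIATES = ("size", "density", "log_size", "log_density")
MIN_GENES = 10


@dataclass
class PropertyResult:
    stage: str
    group: str
    beta: float
    se: float
    t: float
    p: float
    n_genes: int
    m: int | None = None
    p_adj: float | None = None
    conditioned_on: tuple[str, ...] = ()
    dropped_collinear: tuple[str, ...] = ()

    @property
    def signed_log10p(self) -> float:
        return float(-np.log10(max(self.p, 1e-300)) * np.sign(self.beta))

    def adjust(self, m: int) -> "PropertyResult":
        self.m = m
        self.p_adj = min(1.0, self.p * m)
        return self

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "group": self.group,
            "beta": self.beta,
            "se": self.se,
            "t": self.t,
            "p": self.p,
            "p_adj": self.p_adj,
            "m": self.m,
            "n_genes": self.n_genes,
            "conditioned_on": ";".join(self.conditioned_on),
            "signed_log10p": self.signed_log10p,
        }


def _drop_collinear(X: pd.DataFrame, protect: int = 2) -> tuple[pd.DataFrame, list[str]]:
    """Greedy left-to-right rank filter. The first ``protect`` columns
    (intercept and the property itself) are never dropped."""
    arr = X.to_numpy().copy()
    # scale-invariant rank test: normalise columns before checking
    norms = np.linalg.norm(arr, axis=0)
    arr = arr / np.where(norms > 0, norms, 1.0)
    keep = list(range(min(protect, arr.shape[1])))
    dropped: list[str] = []
    for j in range(len(keep), arr.shape[1]):
        trial = keep + [j]
        if norms[j] > 0 and np.linalg.matrix_rank(arr[:, trial], tol=1e-7) == len(trial):
            keep.append(j)
        else:
            dropped.append(X.columns[j])
    if dropped:
        log.warning("dropping collinear covariates: %s", dropped)
    return X.iloc[:, keep], dropped


class GenePropertyRegression(BaseEstimator):
    """sklearn-style estimator for the property regression.

    ``fit(X, y)`` expects ``X`` as a DataFrame whose first column is the
    gene property and remaining columns are covariates (conditioned scores
    included); ``y`` is the vector of gene association Z-scores. Rows with
    missing values are dropped. Fitted attributes: ``beta_``, ``se_``,
    ``t_``, ``p_`` for the property coefficient, ``n_``, ``dropped_``.
    """

    def __init__(self, min_genes: int = MIN_GENES):
        self.min_genes = min_genes

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        mask = np.isfinite(X.to_numpy()).all(axis=1) & np.isfinite(y)
        n_dropped = int((~mask).sum())
        if n_dropped:
            log.info("dropping %d genes with incomplete data", n_dropped)
        X, y = X.loc[mask], y[mask]
        if len(X) < self.min_genes:
            raise ValueError(f"need at least {self.min_genes} genes with complete data, got {len(X)}")
        prop = X.columns[0]
        if np.ptp(X[prop].to_numpy()) < 1e-12:
            raise ValueError(f"degenerate property: {prop!r} is constant")
        design = sm.add_constant(X, has_constant="add")
        design, dropped = _drop_collinear(design)
        fit = sm.OLS(y, design).fit()
        self.result_ = fit
        self.beta_ = float(fit.params[prop])
        self.se_ = float(fit.bse[prop])
        self.t_ = float(fit.tvalues[prop])
        self.p_ = float(fit.pvalues[prop])
        self.n_ = int(len(X))
        self.dropped_ = tuple(dropped)
        return self


def _join(
    assoc: pd.DataFrame,
    scores: pd.Series,
    conditional: dict[str, pd.Series],
    covariates: tuple[str, ...],
) -> tuple[pd.DataFrame, np.ndarray]:
    tab = assoc.set_index("gene_id")
    df = pd.DataFrame({"score": scores})
    for name, s in conditional.items():
        df[f"cond_{name}"] = s
    df = df.join(tab[list(covariates) + ["z"]], how="inner")
    y = df.pop("z").to_numpy()
    # order: score first (protected), then conditionals, then covariates
    cols = ["score"] + [c for c in df.columns if c.startswith("cond_")] + list(covariates)
    return df[cols], y


def property_regression(
    assoc: pd.DataFrame,
    scores: pd.Series,
    conditional: dict[str, pd.Series] | None = None,
    covariates: tuple[str, ...] = DEFAULT_PROPERTY_COVARIATES,
    stage: str = "",
    group: str = "",
) -> PropertyResult:
    """Regress gene Z on one (stage, group) score vector with covariates.

    ``scores``/conditional score vectors are indexed by gene id; the gene
    universe is the intersection with the association table, with
    incomplete rows dropped.
    """
    conditional = conditional or {}
    X, y = _join(assoc, scores, conditional, covariates)
    est = GenePropertyRegression().fit(X, y)
    return PropertyResult(
        stage=stage,
        group=group,
        beta=est.beta_,
        se=est.se_,
        t=est.t_,
        p=est.p_,
        n_genes=est.n_,
        conditioned_on=tuple(conditional.keys()),
        dropped_collinear=est.dropped_,
    )


def tier_analysis(
    assoc: pd.DataFrame,
    scores_long: pd.DataFrame,
    plan: list[dict],
    covariates: tuple[str, ...] = DEFAULT_PROPERTY_COVARIATES,
) -> pd.DataFrame:
    """One property regression per (stage, group) in the tier plan.

    ``scores_long`` holds stacked score tables for every group in the plan.
    Output rows are ordered by tier, then group, then stage, and carry the
    tier-appropriate Bonferroni m plus figure-ready signed -log10(p).
    """
    rows = []
    for entry in plan:
        group = entry["group"]
        sub = scores_long[scores_long["group"] == group.label]
        for stage in sub["stage"].unique():
            s = sub[sub["stage"] == stage].set_index("gene_id")["score"]
            res = property_regression(
                assoc, s, covariates=covariates, stage=stage, group=group.label
            ).adjust(entry["m"])
            d = res.to_dict()
            d["tier"] = entry["tier"]
            rows.append(d)
    out = pd.DataFrame(rows)
    front = ["tier", "group", "stage", "beta", "se", "t", "p", "p_adj", "m", "n_genes"]
    return out[front + [c for c in out.columns if c not in front]]


def conditional_pair(
    assoc: pd.DataFrame,
    scores_a: pd.Series,
    scores_b: pd.Series,
    labels: tuple[str, str] = ("A", "B"),
    group: str = "",
    covariates: tuple[str, ...] = DEFAULT_PROPERTY_COVARIATES,
) -> tuple[PropertyResult, PropertyResult]:
    """Reciprocal conditional analyses: A conditioned on B, and B on A.

    Reported at uncorrected p, matching how conditional results are read.
    """
    la, lb = labels
    res_a = property_regression(
        assoc, scores_a, {lb: scores_b}, covariates=covariates, stage=la, group=group
    )
    res_b = property_regression(
        assoc, scores_b, {la: scores_a}, covariates=covariates, stage=lb, group=group
    )
    return res_a, res_b
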