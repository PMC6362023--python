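"""Stage-wise relative expression scores.

For one gene, one ordered stage and one group of brain regions, fit

    expression = intercept + region dummies + 1{sample is from the stage}

by OLS over the group's samples and define

    score = R^2 * sgn(stage coefficient)

so a gene relatively over-expressed at the stage scores towards +1, one
relatively under-expressed scores towards -1, and a flat gene scores 0.
Degenerate cases: a gene with zero variance within the group scores 0 at
every stage; a stage with no samples in the group (or one comprising the
whole group, where the indicator is confounded with the intercept) yields a
missing value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .config import WHOLE_BRAIN

__all__ = [
    "RegionGroup",
    "compute_expression_score",
    "score_table",
    "score_matrix",
    "tier_plan",
    "ExpressionScorer",
]

_EPS_VAR = 1e-12


@dataclass(frozen=True)
class RegionGroup:
    label: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"region group {self.label!r} has no members")


def _stage_design(samples: pd.DataFrame, stage: str) -> tuple[np.ndarray, bool]:
    """Design [intercept | region dummies | stage indicator]; returns the
    matrix and whether the stage indicator is estimable (not constant)."""
    regions = sorted(samples["region"].unique())
    n = len(samples)
    cols = [np.ones(n)]
    for reg in regions[1:]:  # first region is the reference level
        cols.append((samples["region"] == reg).to_numpy(dtype=float))
    ind = (samples["stage"] == stage).to_numpy(dtype=float)
    estimable = 0.0 < ind.mean() < 1.0
    cols.append(ind)
    return np.column_stack(cols), estimable


def compute_expression_score(
    values: np.ndarray | pd.Series,
    samples: pd.DataFrame,
    stage: str,
) -> tuple[float, float, int]:
    """(score, R², sign) for one gene's values over one region group's samples."""
    y = np.asarray(values, dtype=float)
    if y.shape[0] != len(samples):
        raise ValueError("values and sample table lengths differ")
    if len(samples) < 2:
        raise ValueError("need at least two samples to score a stage")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst < _EPS_VAR:
        return 0.0, 0.0, 0
    X, estimable = _stage_design(samples, stage)
    if not estimable:
        return float("nan"), float("nan"), 0
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    r2 = max(0.0, 1.0 - float(resid @ resid) / sst)
    coef = beta[-1]
    sign = int(np.sign(coef)) if abs(coef) > 1e-12 else 0
    return r2 * sign, r2, sign


def score_table(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    group: RegionGroup,
    stages: Sequence[str],
) -> pd.DataFrame:
    """Long table of scores: one row per (gene, stage) within a region group.

    Columns: gene_id, stage, group, score, r2, sign. Missing stages (absent
    from the group's samples) propagate as NaN.
    """
    members = set(group.members)
    mask = samples["region"].isin(members).to_numpy()
    if not mask.any():
        raise ValueError(f"no samples for region group {group.label!r}")
    sub = samples.loc[mask].reset_index(drop=True)
    cols = [c for c in expr.columns if c in set(sub["sample_id"])]
    sub = sub.set_index("sample_id").loc[cols].reset_index()
    Y = expr[cols].to_numpy()  # genes x samples
    n_g = Y.shape[0]
    sst = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    flat = sst < _EPS_VAR
    sst_safe = np.where(flat, 1.0, sst)

    frames = []
    for stage in stages:
        X, estimable = _stage_design(sub, stage)
        if not estimable:
            score = np.full(n_g, np.nan)
            r2 = np.full(n_g, np.nan)
            sign = np.zeros(n_g, dtype=int)
        else:
            beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
            resid = Y.T - X @ beta
            r2 = 1.0 - (resid**2).sum(axis=0) / sst_safe
            r2 = np.clip(r2, 0.0, 1.0)
            coef = beta[-1]
            sign = np.where(np.abs(coef) > 1e-12, np.sign(coef), 0.0)
            score = r2 * sign
            score[flat] = 0.0
            r2[flat] = 0.0
            sign = sign.astype(int)
            sign[flat] = 0
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": expr.index,
                    "stage": stage,
                    "group": group.label,
                    "score": score,
                    "r2": r2,
                    "sign": sign,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def score_matrix(scores_long: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long score table to genes × stages (one region group)."""
    groups = scores_long["group"].unique()
    if len(groups) != 1:
        raise ValueError("score_matrix expects a single region group")
    return scores_long.pivot(index="gene_id", columns="stage", values="score")


def tier_plan(
    region_groups: dict[str, tuple[str, ...]],
    stages: Sequence[str],
) -> list[dict]:
    """Hierarchical analysis plan.

    Tier 1 pools every region (whole brain; Bonferroni m = #stages). Tier 2
    analyses each region group separately (m = #stages × #groups).
    """
    all_members = tuple(r for members in region_groups.values() for r in members)
    plan = [
        {
            "tier": 1,
            "group": RegionGroup(WHOLE_BRAIN, all_members),
            "m": len(stages),
        }
    ]
    m2 = len(stages) * len(region_groups)
    for label, members in region_groups.items():
        plan.append({"tier": 2, "group": RegionGroup(label, tuple(members)), "m": m2})
    return plan


class ExpressionScorer(BaseEstimator):
    """sklearn-style wrapper computing stage scores for one region group.

    Parameters
    ----------
    group : RegionGroup
    stages : sequence of ordered stage labels

    After ``fit(expr, samples=...)`` exposes ``scores_`` (long table) and
    ``matrix_`` (genes × stages).
    """

    def __init__(self, group: RegionGroup = None, stages: Sequence[str] = ()):
        self.group = group
        self.stages = stages

    def fit(self, X: pd.DataFrame, y=None, *, samples: pd.DataFrame):
        self.scores_ = score_table(X, samples, self.group, list(self.stages))
        self.matrix_ = score_matrix(self.scores_)
        return self

    def fit_transform(self, X: pd.DataFrame, y=None, *, samples: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X, samples=samples).matrix_
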