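"""Decile-based competitive enrichment and GO/MP pathway refinement.

Genes are ranked by relative expression at a stage of interest and split
into ten equal bins; each decile is tested for association enrichment with
a two-tailed competitive regression (membership indicator plus gene
size/density covariates). Significant same-direction deciles are merged and
scanned for GO/MP term over-representation by Fisher's exact test against
the expressed-gene background, Bonferroni-corrected per source. Surviving
terms go through a step-wise refinement (smallest term's genes removed
first; weaker terms failing an uncorrected re-test are dropped), and
refined terms get a one-tailed conditional gene-set association test
against the rest of the significant deciles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

log = logging.getLogger(__name__)

__all__ = [
    "TermCollection",
    "EnrichmentResult",
    "CompetitiveGeneSetTest",
    "decile_bins",
    "competitive_decile_test",
    "decile_scan",
    "merge_significant_deciles",
    "fisher_term_scan",
    "refine_terms",
    "conditional_term_association",
    "DEFAULT_EVIDENCE_EXCLUDE",
]

DEFAULT_EVIDENCE_EXCLUDE = ("IEA", "NAS", "RCA")
DEFAULT_SET_COVARIATES = ("size", "density", "log_size", "log_density")
N_DECILES = 10


@dataclass(frozen=True)
class TermCollection:
    """GO/MP-style gene-set collection.

    ``frame`` has one row per annotation: term_id, source, name, gene_id,
    evidence. GO and MP sources are analysed separately downstream.
    """

    frame: pd.DataFrame

    def filter_evidence(self, exclude: tuple[str, ...] = DEFAULT_EVIDENCE_EXCLUDE) -> "TermCollection":
        keep = ~self.frame["evidence"].isin(exclude)
        return TermCollection(self.frame.loc[keep].reset_index(drop=True))

    def to_dict(self, source: str | None = None) -> dict[str, set[str]]:
        f = self.frame if source is None else self.frame[self.frame["source"] == source]
        return {t: set(d["gene_id"]) for t, d in f.groupby("term_id")}

    def sources(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["source"].unique()))

    def names(self) -> dict[str, str]:
        return dict(zip(self.frame["term_id"], self.frame["name"]))


@dataclass
class EnrichmentResult:
    unit: str
    test: str  # competitive | fisher | conditional
    effect: float  # regression beta or Fisher odds ratio
    p: float
    p_adj: float | None = None
    direction: int = 0
    n_set: int = 0
    extra: dict | None = None

    @property
    def signed_log10p(self) -> float:
        return float(-np.log10(max(self.p, 1e-300)) * (self.direction or 1))


# ------------------------------------------------------------------ deciles


def decile_bins(scores: pd.Series, n_bins: int = N_DECILES) -> pd.Series:
    """Assign genes to expression deciles, 1 = lowest.

    Rank ascending by score with ties broken by gene id, then split by
    largest-remainder allocation: the first ``n %% n_bins`` bins get the
    extra gene, so bin sizes differ by at most one and the assignment is a
    pure function of the sorted (score, gene id) sequence.
    """
    s = scores.dropna()
    n = len(s)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} scored genes, got {n}")
    order = sorted(s.index, key=lambda g: (s[g], g))
    base, extra = divmod(n, n_bins)
    sizes = [base + (1 if i < extra else 0) for i in range(n_bins)]
    out = {}
    pos = 0
    for b, size in enumerate(sizes, start=1):
        for g in order[pos : pos + size]:
            out[g] = b
        pos += size
    return pd.Series(out, name="decile").sort_index()


class CompetitiveGeneSetTest(BaseEstimator):
    """Competitive gene-set association: Z ~ membership + covariates.

    ``fit(X, y, gene_set=...)`` takes X as a DataFrame of per-gene
    covariates indexed by gene id and y as the matching Z vector. The test
    asks whether genes in the set are more (or less) associated than the
    genes outside it; fitted attributes ``beta_``, ``se_``, ``t_``, ``p_``
    (two-tailed), ``p_one_tailed_`` in the configured direction.
    """

    def __init__(self, alternative: str = "two-sided", extra_indicators: tuple[str, ...] = ()):
        self.alternative = alternative
        self.extra_indicators = extra_indicators

    def fit(self, X: pd.DataFrame, y, *, gene_set, extra_sets: dict[str, set] | None = None):
        genes = X.index
        member = np.asarray([g in gene_set for g in genes], dtype=float)
        if member.sum() == 0:
            raise ValueError("gene set does not intersect the universe")
        if member.sum() == len(genes):
            raise ValueError("gene set equals the whole universe; competitive test undefined")
        design = pd.DataFrame({"const": 1.0, "in_set": member}, index=genes)
        for name, s in (extra_sets or {}).items():
            design[name] = np.asarray([g in s for g in genes], dtype=float)
        design = pd.concat([design, X], axis=1)
        arr = design.to_numpy().copy()
        norms = np.linalg.norm(arr, axis=0)
        arr = arr / np.where(norms > 0, norms, 1.0)
        keep = [0, 1]
        for j in range(2, arr.shape[1]):
            trial = keep + [j]
            if norms[j] > 0 and np.linalg.matrix_rank(arr[:, trial], tol=1e-7) == len(trial):
                keep.append(j)
            else:
                log.warning("dropping collinear column %r", design.columns[j])
        fit = sm.OLS(np.asarray(y, dtype=float), design.iloc[:, keep]).fit()
        self.result_ = fit
        self.beta_ = float(fit.params["in_set"])
        self.se_ = float(fit.bse["in_set"])
        self.t_ = float(fit.tvalues["in_set"])
        self.p_ = float(fit.pvalues["in_set"])
        df = fit.df_resid
        if self.alternative == "greater":
            self.p_one_tailed_ = float(stats.t.sf(self.t_, df))
        elif self.alternative == "less":
            self.p_one_tailed_ = float(stats.t.cdf(self.t_, df))
        else:
            self.p_one_tailed_ = None
        self.n_set_ = int(member.sum())
        return self


def _covariate_frame(assoc: pd.DataFrame, covariates: tuple[str, ...]) -> tuple[pd.DataFrame, np.ndarray]:
    tab = assoc.set_index("gene_id")
    X = tab[list(covariates)]
    mask = np.isfinite(X.to_numpy()).all(axis=1) & np.isfinite(tab["z"].to_numpy())
    return X.loc[mask], tab.loc[mask, "z"].to_numpy()


def competitive_decile_test(
    assoc: pd.DataFrame,
    decile_genes: set[str],
    covariates: tuple[str, ...] = DEFAULT_SET_COVARIATES,
    unit: str = "decile",
    n_tests: int = N_DECILES,
) -> EnrichmentResult:
    """Two-tailed competitive test of one decile against the rest, with
    Bonferroni adjustment for the ten decile tests."""
    X, y = _covariate_frame(assoc, covariates)
    est = CompetitiveGeneSetTest().fit(X, y, gene_set=decile_genes)
    return EnrichmentResult(
        unit=unit,
        test="competitive",
        effect=est.beta_,
        p=est.p_,
        p_adj=min(1.0, est.p_ * n_tests),
        direction=int(np.sign(est.beta_)),
        n_set=est.n_set_,
    )


def decile_scan(
    assoc: pd.DataFrame,
    deciles: pd.Series,
    covariates: tuple[str, ...] = DEFAULT_SET_COVARIATES,
) -> list[EnrichmentResult]:
    universe = set(assoc["gene_id"]) & set(deciles.index)
    out = []
    for b in range(1, int(deciles.max()) + 1):
        members = set(deciles.index[deciles == b]) & universe
        out.append(
            competitive_decile_test(assoc, members, covariates, unit=f"decile_{b}")
        )
    return out


def merge_significant_deciles(
    results: list[EnrichmentResult],
    deciles: pd.Series,
    alpha: float = 0.05,
) -> set[str]:
    """Union of genes in Bonferroni-significant deciles sharing the
    direction of the most significant one. Empty when nothing passes."""
    sig = [r for r in results if r.p_adj is not None and r.p_adj < alpha]
    if not sig:
        log.info("no decile passes adjusted significance; downstream steps skipped")
        return set()
    lead = min(sig, key=lambda r: r.p_adj)
    merged: set[str] = set()
    for r in sig:
        if r.direction == lead.direction:
            b = int(r.unit.rsplit("_", 1)[1])
            merged |= set(deciles.index[deciles == b])
    return merged


# -------------------------------------------------------------------- fisher


def _fisher(a: int, b: int, c: int, d: int, alternative: str) -> tuple[float, float]:
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(odds), float(p)


def fisher_term_scan(
    set_genes: set[str],
    terms: TermCollection,
    background: set[str],
    alternative: str = "greater",
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-term Fisher's exact test of the merged decile set against the
    expressed-gene background; Bonferroni correction over the testable terms
    of each source separately."""
    if not set_genes <= background:
        raise ValueError("set genes must be a subset of the background universe")
    out: list[EnrichmentResult] = []
    for source in terms.sources():
        tdict = terms.to_dict(source)
        testable = {}
        for tid, members in sorted(tdict.items()):
            overlap_bg = members & background
            if not overlap_bg:
                log.info("term %s has no background overlap; skipped", tid)
                continue
            testable[tid] = overlap_bg
        m = len(testable)
        for tid, members in testable.items():
            a = len(members & set_genes)
            b = len(set_genes) - a
            c = len(members) - a
            d = len(background) - len(set_genes) - c
            odds, p = _fisher(a, b, c, d, alternative)
            out.append(
                EnrichmentResult(
                    unit=tid,
                    test="fisher",
                    effect=odds,
                    p=p,
                    p_adj=min(1.0, p * m),
                    direction=1 if a / max(len(set_genes), 1) >= len(members) / len(background) else -1,
                    n_set=a,
                    extra={"source": source, "m": m, "table": (a, b, c, d)},
                )
            )
    return out


def refine_terms(
    significant: list[EnrichmentResult],
    terms: TermCollection,
    set_genes: set[str],
    background: set[str],
    alpha_retest: float = 0.05,
    alternative: str = "greater",
) -> tuple[list[EnrichmentResult], list[dict]]:
    """Step-wise refinement of Bonferroni-significant terms.

    Terms are processed smallest membership first (ties by term id). At each
    step the current term's genes are removed — cumulatively — from the
    universe, and every remaining term with weaker original enrichment
    (larger original p) is re-tested on the reduced universe by Fisher's
    exact test; those with uncorrected re-test p > ``alpha_retest`` are
    dropped. Returns survivors (with a ``retest_p`` entry) and an audit log.
    """
    if not significant:
        return [], []
    tdict = terms.to_dict()
    order = sorted(
        significant, key=lambda r: (len(tdict[r.unit] & background), r.unit)
    )
    alive = {r.unit: r for r in order}
    orig_p = {r.unit: r.p for r in order}
    processed: list[str] = []
    audit: list[dict] = []
    step = 0
    for r in order:
        if r.unit not in alive:
            continue
        step += 1
        processed.append(r.unit)
        for other in list(alive.values()):
            # "weaker" = larger original p, ties broken by term id
            if (orig_p[other.unit], other.unit) <= (orig_p[r.unit], r.unit):
                continue
            # genes removed so far come from *other* terms: shared genes go
            # too, but a term's own earlier removal never blanks itself
            removed = set().union(
                *(tdict[t] & background for t in processed if t != other.unit)
            )
            bg = background - removed
            sg = set_genes - removed
            members = tdict[other.unit] & bg
            a = len(members & sg)
            b = len(sg) - a
            c = len(members) - a
            d = len(bg) - len(sg) - c
            _, p_re = _fisher(a, b, c, d, alternative)
            dropped = p_re > alpha_retest
            audit.append(
                {
                    "step": step,
                    "removed_term": r.unit,
                    "retested_term": other.unit,
                    "retest_p": p_re,
                    "dropped": dropped,
                }
            )
            if dropped:
                del alive[other.unit]
    survivors = []
    for r in order:
        if r.unit in alive:
            retests = [e["retest_p"] for e in audit if e["retested_term"] == r.unit]
            r.extra = {**(r.extra or {}), "retest_p": retests[-1] if retests else None}
            survivors.append(r)
    return survivors, audit


# --------------------------------------------------------------- conditional


def conditional_term_association(
    assoc: pd.DataFrame,
    term_and_decile_genes: set[str],
    decile_genes: set[str],
    covariates: tuple[str, ...] = DEFAULT_SET_COVARIATES,
    direction: str = "greater",
) -> EnrichmentResult | None:
    """One-tailed gene-set association of (term ∩ significant deciles),
    conditioning on decile membership.

    Z ~ intercept + 1{term ∩ deciles} + 1{deciles} + covariates; one-tailed
    t-test on the first indicator in ``direction`` ("greater" for
    enrichment-type stages, "less" to probe depletion-type stages for genes
    of *lower* association).
    """
    if not term_and_decile_genes:
        log.info("term has no overlap with the significant deciles; skipped")
        return None
    if not term_and_decile_genes <= decile_genes:
        raise ValueError("term∩decile genes must be a subset of the decile genes")
    X, y = _covariate_frame(assoc, covariates)
    est = CompetitiveGeneSetTest(alternative=direction).fit(
        X, y, gene_set=term_and_decile_genes, extra_sets={"in_deciles": decile_genes}
    )
    return EnrichmentResult(
        unit="term|deciles",
        test="conditional",
        effect=est.beta_,
        p=est.p_one_tailed_,
        direction=1 if direction == "greater" else -1,
        n_set=est.n_set_,
    )
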