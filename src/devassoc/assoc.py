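"""Gene-level association from GWAS summary statistics.

SNP p-values are combined per gene with the SNP-wise mean statistic

    T = sum_i Q_i,   Q_i = upper-tail chi^2_1 quantile of p_i,

whose null, for SNP z-scores correlated by the LD matrix R, is the quadratic
form z' z with z ~ N(0, R), i.e. a weighted sum of independent chi^2_1
variables with weights the eigenvalues of R. Three nulls are provided:

``exact``  Imhof numerical inversion of the characteristic function over the
           eigenvalues (default; accurate over the full p range).
``brown``  Satterthwaite/Brown two-moment scaled chi-square
           (c = Var/2E, f = 2E^2/Var with E = k, Var = 2 sum R_ij^2).
``mc``     Monte-Carlo draws from the multivariate-normal null (the oracle
           mode used in tests).

Gene Z is the probit transform Z = Phi^{-1}(1 - p), so stronger association
means larger Z.
"""

from __future__ import annotations

import logging
import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, stats

log = logging.getLogger(__name__)

__all__ = [
    "filter_snps",
    "map_snps_to_genes",
    "snpwise_mean_pvalue",
    "gene_z",
    "gene_covariates",
    "gene_association_table",
    "DEFAULT_XMHC",
    "UPSTREAM",
    "DOWNSTREAM",
]

UPSTREAM = 35_000
DOWNSTREAM = 10_000

#: default extended-MHC exclusion interval (chromosome, 1-based inclusive bp)
DEFAULT_XMHC = ("6", 25_000_000, 34_000_000)
DEFAULT_EXCLUDED_CHROMS = ("X",)

_P_FLOOR = 1e-300


# ---------------------------------------------------------------- filtering


def filter_snps(
    snps: pd.DataFrame,
    maf_min: float | None = 0.01,
    info_min: float | None = 0.6,
    exclude_regions: tuple[tuple[str, int, int], ...] = (DEFAULT_XMHC,),
    exclude_chroms: tuple[str, ...] = DEFAULT_EXCLUDED_CHROMS,
) -> pd.DataFrame:
    """Apply MAF/INFO quality filters and genomic exclusions (xMHC-style
    intervals, whole chromosomes). Passing ``None`` for a threshold skips
    that filter (for summary statistics lacking the column)."""
    keep = np.ones(len(snps), dtype=bool)
    if maf_min is not None and "MAF" in snps.columns:
        keep &= snps["MAF"].to_numpy() >= maf_min
    if info_min is not None and "INFO" in snps.columns:
        keep &= snps["INFO"].to_numpy() >= info_min
    chroms = snps["CHR"].astype(str).to_numpy()
    pos = snps["BP"].to_numpy()
    for c in exclude_chroms:
        keep &= chroms != str(c)
    for c, lo, hi in exclude_regions:
        keep &= ~((chroms == str(c)) & (pos >= lo) & (pos <= hi))
    out = snps.loc[keep].reset_index(drop=True)
    if out.empty:
        log.warning("SNP filtering removed every SNP")
    return out


def map_snps_to_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    up: int = UPSTREAM,
    down: int = DOWNSTREAM,
) -> dict[str, list[str]]:
    """Strand-aware window assignment of SNPs to protein-coding genes.

    A + strand gene [s, e] captures positions in [s - up, e + down]; a -
    strand gene captures [s - down, e + up]. A SNP may map to several genes.
    """
    coding = genes[genes["biotype"] == "protein_coding"]
    bad = set(coding["strand"].unique()) - {"+", "-"}
    if bad:
        raise ValueError(f"unknown strand symbol(s): {sorted(bad)}")
    mapping: dict[str, list[str]] = {}
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): d.sort_values("BP") for c, d in snps.groupby(snps["CHR"].astype(str))
    }
    for g in coding.itertuples(index=False):
        chrom_snps = by_chrom.get(str(g.chrom))
        if chrom_snps is None:
            mapping[g.gene_id] = []
            continue
        if g.strand == "+":
            lo, hi = g.start - up, g.end + down
        else:
            lo, hi = g.start - down, g.end + up
        pos = chrom_snps["BP"].to_numpy()
        i, j = np.searchsorted(pos, lo, "left"), np.searchsorted(pos, hi, "right")
        mapping[g.gene_id] = chrom_snps["SNP"].to_numpy()[i:j].tolist()
    return mapping


# ------------------------------------------------------------- null models


def _validate_R(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("LD matrix must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("LD matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValueError("LD matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(R)
    if lam[0] < -1e-8:
        raise ValueError("LD matrix is not positive semi-definite")
    return R


def _imhof_sf(x: float, lam: np.ndarray) -> float:
    """Survival function of sum(lam_i * chi^2_1) at x by Imhof inversion."""
    lam = lam[lam > 1e-12]
    k = lam.size
    if k == 0 or x <= 0:
        return 1.0
    if np.allclose(lam, lam[0]):
        return float(stats.chi2.sf(x / lam[0], k))

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * x * u
        rho = np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2)))
        return np.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(integrand, 0.0, np.inf, limit=1000, epsabs=1e-12, epsrel=1e-10)
    sf = 0.5 + val / np.pi
    if sf <= 0.0:  # quadrature cancellation in an extreme tail
        return _brown_sf(x, float(lam.sum()), 2.0 * float((lam**2).sum()))
    return float(min(1.0, sf))


def _brown_sf(T: float, mean: float, var: float) -> float:
    c = var / (2.0 * mean)
    f = 2.0 * mean**2 / var
    return float(stats.chi2.sf(T / c, f))


class _ExactNull:
    """Exact null for one eigenvalue multiset via Ruben's representation.

    With beta = min eigenvalue, the quadratic form is a nonnegative mixture
    of scaled central chi-squares, Q ~ beta * chi^2_{k + 2J} with mixing
    weights a_j from Ruben's recursion. All terms are positive, so the
    survival function is accurate at any tail depth (unlike oscillatory
    inversion) and evaluation vectorises over T.
    """

    _MAX_TERMS = 50_000

    def __init__(self, lam: tuple[float, ...]):
        self.lam = np.asarray(lam, dtype=float)
        lam = self.lam
        beta = float(lam.min())
        b = 1.0 - beta / lam
        b_max = float(b.max())
        a = np.zeros(self._MAX_TERMS + 1)
        c = np.zeros(self._MAX_TERMS + 1)
        a[0] = float(np.prod(np.sqrt(beta / lam)))
        powers = b.copy()
        m = 0
        while m < self._MAX_TERMS:
            m += 1
            c[m] = powers.sum()
            powers *= b
            a[m] = 0.5 / m * float(np.dot(c[1 : m + 1][::-1], a[:m]))
            # geometric bound on the unaccumulated mixture mass
            if b_max < 1.0 and a[m] * b_max / (1.0 - b_max) < 1e-16 and m > 5:
                break
        self.beta = beta
        self.a = a[: m + 1]
        self.dfs = lam.size + 2.0 * np.arange(self.a.size)

    def sf(self, T) -> np.ndarray:
        T = np.atleast_1d(np.asarray(T, dtype=float))
        out = stats.chi2.sf(T[:, None] / self.beta, self.dfs[None, :]) @ self.a
        out[T <= 0] = 1.0
        return np.clip(out, _P_FLOOR, 1.0)


@lru_cache(maxsize=256)
def _cached_null(lam_key: tuple[float, ...]) -> _ExactNull:
    return _ExactNull(lam_key)


def _eig_key(R: np.ndarray) -> tuple[float, ...]:
    lam = np.linalg.eigvalsh(R)
    lam = lam[lam > 1e-10]
    return tuple(np.round(lam, 8))


def snpwise_mean_pvalue(
    snp_ps,
    R: np.ndarray,
    method: str = "exact",
    draws: int = 100_000,
    rng: np.random.Generator | None = None,
    p_floor: float = _P_FLOOR,
) -> float:
    """Combine SNP p-values into a gene-wide p-value under the LD-aware null.

    Parameters
    ----------
    snp_ps : sequence of per-SNP two-sided p-values in (0, 1]
    R : SNP correlation (LD) matrix, symmetric PSD with unit diagonal
    method : "exact" (Imhof, default), "brown" (two-moment), or "mc"
    draws : Monte-Carlo sample size for ``method="mc"``
    """
    p = np.asarray(snp_ps, dtype=float)
    if p.size == 0:
        raise ValueError("no SNP p-values supplied")
    if np.any(p <= 0):
        log.warning("clamping %d nonpositive p-values to %.0e", int((p <= 0).sum()), p_floor)
        p = np.maximum(p, p_floor)
    if np.any(p > 1):
        raise ValueError("SNP p-values must be in (0, 1]")
    R = _validate_R(R)
    if R.shape[0] != p.size:
        raise ValueError("LD matrix size does not match number of SNPs")
    T = float(stats.chi2.isf(p, 1).sum())
    k = p.size
    if method == "exact":
        if k == 1:
            return float(stats.chi2.sf(T, 1))
        return float(_cached_null(_eig_key(R)).sf(T)[0])
    if method == "brown":
        var = 2.0 * float((R**2).sum())
        return max(_brown_sf(T, float(k), var), p_floor)
    if method == "mc":
        rng = rng if rng is not None else np.random.default_rng(0)
        lam, V = np.linalg.eigh(R)
        lam = np.clip(lam, 0.0, None)
        A = V * np.sqrt(lam)
        z = rng.standard_normal((draws, k)) @ A.T
        Tnull = (z**2).sum(axis=1)
        return float((np.count_nonzero(Tnull >= T) + 1) / (draws + 1))
    raise ValueError(f"unknown null method {method!r}")


def gene_z(p) -> np.ndarray | float:
    """Probit transform Z = Phi^{-1}(1 - p); larger association, larger Z."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr <= 0) | (arr >= 1)):
        raise ValueError("gene p-values must lie strictly inside (0, 1)")
    out = stats.norm.isf(arr)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


# ------------------------------------------------------------- covariates


def _window_span(g, up: int, down: int) -> tuple[int, int]:
    if g.strand == "+":
        return g.start - up, g.end + down
    return g.start - down, g.end + up


def gene_covariates(
    mapping: dict[str, list[str]],
    genes: pd.DataFrame,
    up: int = UPSTREAM,
    down: int = DOWNSTREAM,
) -> pd.DataFrame:
    """Per-gene size and SNP-density covariates (raw and natural-log).

    Size is the window-extended span in bp (1-based inclusive), density the
    mapped SNP count over that span.
    """
    gids = list(mapping.keys())
    gtab = genes.set_index("gene_id").loc[gids]
    if (gtab["end"] < gtab["start"]).any():
        bad = gtab.index[gtab["end"] < gtab["start"]][0]
        raise ValueError(f"gene {bad} has nonpositive length")
    # strand-aware window span; inclusive 1-based length
    size = (gtab["end"] - gtab["start"] + 1 + up + down).to_numpy()
    k = np.array([len(mapping[g]) for g in gids])
    out = pd.DataFrame(
        {"gene_id": gids, "n_snps": k, "size": size, "density": k / size}
    )
    out["log_size"] = np.log(out["size"])
    with np.errstate(divide="ignore"):
        out["log_density"] = np.where(out["n_snps"] > 0, np.log(out["density"]), np.nan)
    return out


# ------------------------------------------------------- assembled per gene


def _assemble_R(snp_ids: list[str], ld_entry) -> np.ndarray:
    """LD matrix for the mapped SNP list from a per-gene (ids, R) entry;
    SNPs without LD information are treated as uncorrelated."""
    k = len(snp_ids)
    R = np.eye(k)
    if ld_entry is None:
        return R
    ids, Rsrc = ld_entry
    if list(ids) == list(snp_ids):
        return np.asarray(Rsrc, dtype=float)
    idx = {s: i for i, s in enumerate(ids)}
    present = [(j, idx[s]) for j, s in enumerate(snp_ids) if s in idx]
    for a, (ja, ia) in enumerate(present):
        for jb, ib in present[a + 1 :]:
            R[ja, jb] = R[jb, ja] = Rsrc[ia, ib]
    return R


def gene_association_table(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    ld: dict[str, tuple[list[str], np.ndarray]] | None,
    up: int = UPSTREAM,
    down: int = DOWNSTREAM,
    method: str = "exact",
    mc_draws: int = 100_000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Full gene analysis: map filtered SNPs, combine p-values under the
    LD-aware null, transform to Z, attach covariates.

    Genes with no mapped SNPs are dropped (a gene p-value needs k >= 1).
    """
    mapping = map_snps_to_genes(snps, genes, up=up, down=down)
    mapping = {g: ids for g, ids in mapping.items() if ids}
    covs = gene_covariates(mapping, genes, up=up, down=down)

    # vectorised: one chi2 quantile pass over all SNPs, then batch the
    # survival-function evaluation by LD eigen-structure
    snp_index = {s: i for i, s in enumerate(snps["SNP"])}
    q_all = stats.chi2.isf(np.maximum(snps["P"].to_numpy(), 1e-300), 1)
    gene_list = list(mapping.keys())
    T = np.empty(len(gene_list))
    keys: list[tuple[float, ...]] = []
    for i, gid in enumerate(gene_list):
        snp_ids = mapping[gid]
        idx = [snp_index[s] for s in snp_ids]
        T[i] = q_all[idx].sum()
        R = _assemble_R(snp_ids, None if ld is None else ld.get(gid))
        keys.append(_eig_key(R) if method != "brown" else (float((R**2).sum()), len(snp_ids)))
    pvals = np.empty(len(gene_list))
    if method == "exact":
        by_key: dict[tuple, list[int]] = {}
        for i, key in enumerate(keys):
            by_key.setdefault(key, []).append(i)
        for key, idxs in by_key.items():
            pvals[idxs] = _cached_null(key).sf(T[idxs])
    elif method == "brown":
        for i, (ssq, k) in enumerate(keys):
            pvals[i] = max(_brown_sf(T[i], float(k), 2.0 * ssq), _P_FLOOR)
    elif method == "mc":
        rng = rng if rng is not None else np.random.default_rng(0)
        for i, key in enumerate(keys):
            lam = np.asarray(key)
            draws_z = rng.standard_normal((mc_draws, lam.size)) * np.sqrt(lam)
            Tnull = (draws_z**2).sum(axis=1)
            pvals[i] = (np.count_nonzero(Tnull >= T[i]) + 1) / (mc_draws + 1)
    else:
        raise ValueError(f"unknown null method {method!r}")
    out = covs.set_index("gene_id").loc[gene_list].reset_index()
    out["p"] = np.clip(pvals, 1e-300, 1 - 1e-16)
    out["z"] = gene_z(out["p"].to_numpy())
    return out
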