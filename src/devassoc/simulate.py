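"""Synthetic study generator: expression, GWAS summary statistics, gene sets.

Emulates the statistical structure of a developmental brain-expression ×
psychiatric-GWAS study: a multi-region, multi-stage expression matrix with
technical covariates; per-SNP association p-values with block LD whose
gene-level noncentrality can be tied to planted stage-specific expression
biases; gene annotations including deliberately-filterable content (an
xMHC-like long-range-LD zone, an X-like chromosome, non-coding genes,
low-MAF/low-INFO SNPs, all-zero genes); and GO/MP-style term collections
with evidence codes.

Planting model
--------------
Each :class:`~devassoc.config.PlantedEffect` draws (or shares) a latent
vector ``v`` over genes. Expression at the planted (stage, group) is shifted
by ``amplitude * sign(rho) * v`` and the planted gene-level association Z is
``z_scale * (sum_l c_l v_l + sqrt(max(0, 1 - sum c_l^2)) * eps)`` where
``c_l`` sums ``|rho|`` over effects sharing latent ``l``. Positive rho makes
relatively *high* expression at the stage co-occur with stronger
association; negative rho plants the depletion pattern.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig, WHOLE_BRAIN, all_regions

__all__ = [
    "gene_ids",
    "simulate_sample_metadata",
    "simulate_expression",
    "simulate_gene_table",
    "simulate_gwas_summary",
    "simulate_annotation_sets",
    "planted_latents",
    "planted_gene_z",
]

# rng stream ids, one per generator component
_STREAM_META = 1
_STREAM_EXPR = 2
_STREAM_LATENT = 3
_STREAM_GENES = 4
_STREAM_GWAS = 5
_STREAM_TERMS = 6

# canonical SNP-to-gene window (bp), shared with the mapping step
UPSTREAM = 35_000
DOWNSTREAM = 10_000

_XMHC_CHROM = "6"
_XMHC_START = 25_000_000
_XMHC_END = 34_000_000


def gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def simulate_sample_metadata(config: SimulationConfig) -> pd.DataFrame:
    """One row per (subject, region); each subject belongs to one stage."""
    config.validate()
    rng = config.rng(_STREAM_META)
    cov = config.covariates
    regions = all_regions(config.region_groups)
    rows = []
    for si, stage in enumerate(config.stages):
        for k in range(config.subjects_per_stage):
            subject = f"S{si:02d}{chr(ord('a') + k)}"
            ethnicity = cov.ethnicities[rng.integers(len(cov.ethnicities))]
            sex = cov.sexes[rng.integers(len(cov.sexes))]
            for region in regions:
                rin = rng.uniform(*cov.rin_range)
                rows.append(
                    {
                        "sample_id": f"{subject}_{region}",
                        "subject_id": subject,
                        "age": float(si),
                        "stage": stage,
                        "region": region,
                        "RIN": round(rin, 3),
                        "ethnicity": ethnicity,
                        "sex": sex,
                    }
                )
    return pd.DataFrame(rows)


def planted_latents(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Per-latent standard-normal loadings over genes, shared across effects
    that declare the same latent key. Deterministic given the seed."""
    rng = config.rng(_STREAM_LATENT)
    latents: dict[str, np.ndarray] = {}
    for eff in config.planted_effects:
        key = eff.latent_key
        if key in latents:
            continue
        if eff.loadings is not None:
            latents[key] = np.asarray(eff.loadings, dtype=float)
        else:
            latents[key] = rng.standard_normal(config.n_genes)
    return latents


def planted_gene_z(config: SimulationConfig) -> np.ndarray:
    """Planted per-gene association *strength* (zero when nothing planted).

    The gene-level statistic combines squared SNP z-scores, so association
    carries no sign: the strength must be a nonnegative monotone function of
    the latent driving expression. With raw = sum_l c_l v_l + noise (unit
    variance; c_l sums |rho| over effects sharing latent l), the planted
    strength is ``z_scale * Phi(raw)`` — bounded, increasing, and linear
    through the bulk of the latent distribution.
    """
    if not config.planted_effects:
        return np.zeros(config.n_genes)
    from scipy import stats

    latents = planted_latents(config)
    coef: dict[str, float] = {}
    for eff in config.planted_effects:
        coef[eff.latent_key] = coef.get(eff.latent_key, 0.0) + abs(eff.rho)
    w = np.zeros(config.n_genes)
    for key, c in coef.items():
        w += c * latents[key]
    var_w = sum(c * c for c in coef.values())
    rng = config.rng(_STREAM_LATENT + 100)
    if var_w <= 1.0:
        raw = w + np.sqrt(1.0 - var_w) * rng.standard_normal(config.n_genes)
    else:
        raw = w / np.sqrt(var_w)
    return config.planted_z_scale * stats.norm.cdf(raw)


def _zero_gene_mask(config: SimulationConfig) -> np.ndarray:
    rng = config.rng(_STREAM_EXPR + 100)
    return rng.random(config.n_genes) < config.zero_gene_fraction


def simulate_expression(samples: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Genes × samples RPKM-like matrix.

    expression = gene baseline + region effect + stage effect + covariate
    effects + planted stage shifts + Gaussian noise, floored at zero. A
    random ``zero_gene_fraction`` of genes is zero everywhere (exercises the
    unexpressed-gene filter).
    """
    config.validate()
    if samples.empty:
        raise ConfigError("sample table is empty")
    rng = config.rng(_STREAM_EXPR)
    n_g = config.n_genes
    ids = gene_ids(n_g)
    n_s = len(samples)
    regions = list(all_regions(config.region_groups))
    stages = list(config.stages)
    cov = config.covariates

    baseline = rng.uniform(*config.baseline_range, size=n_g)
    region_eff = rng.normal(0.0, config.region_effect_sd, size=(n_g, len(regions)))
    stage_eff = rng.normal(0.0, config.stage_effect_sd, size=(n_g, len(stages)))
    rin_coef = rng.normal(0.0, cov.rin_effect, size=n_g)
    eth_eff = rng.normal(0.0, cov.ethnicity_effect_sd, size=(n_g, len(cov.ethnicities)))
    sex_coef = rng.normal(0.0, cov.sex_effect_sd, size=n_g)

    r_idx = samples["region"].map({r: i for i, r in enumerate(regions)}).to_numpy()
    s_idx = samples["stage"].map({s: i for i, s in enumerate(stages)}).to_numpy()
    e_idx = samples["ethnicity"].map({e: i for i, e in enumerate(cov.ethnicities)}).to_numpy()
    is_m = (samples["sex"] == cov.sexes[-1]).to_numpy(dtype=float)
    rin_c = samples["RIN"].to_numpy(dtype=float) - float(np.mean(cov.rin_range))

    x = (
        baseline[:, None]
        + region_eff[:, r_idx]
        + stage_eff[:, s_idx]
        + rin_coef[:, None] * rin_c[None, :]
        + eth_eff[:, e_idx]
        + sex_coef[:, None] * is_m[None, :]
    )

    if config.planted_effects:
        latents = planted_latents(config)
        for eff in config.planted_effects:
            members = set(config.group_regions(eff.region_group))
            in_target = (
                (samples["stage"] == eff.stage).to_numpy()
                & samples["region"].isin(members).to_numpy()
            )
            shift = config.planted_amplitude * np.sign(eff.rho) * latents[eff.latent_key]
            x[:, in_target] += shift[:, None]

    x += rng.normal(0.0, config.noise_sd, size=(n_g, n_s))
    np.maximum(x, 0.0, out=x)
    x[_zero_gene_mask(config), :] = 0.0
    return pd.DataFrame(x, index=pd.Index(ids, name="gene_id"), columns=samples["sample_id"].to_numpy())


def simulate_gene_table(config: SimulationConfig) -> pd.DataFrame:
    """Gene annotations: id, chromosome, 1-based inclusive start/end, strand,
    biotype. Reserves slices of genes on an X-like chromosome, inside an
    xMHC-like zone on chromosome 6, and as non-coding biotypes."""
    config.validate()
    rng = config.rng(_STREAM_GENES)
    n = config.n_genes
    ids = gene_ids(n)
    perm = rng.permutation(n)
    n_x = int(round(config.x_gene_fraction * n))
    n_mhc = int(round(config.xmhc_gene_fraction * n))
    n_nc = int(round(config.noncoding_fraction * n))
    x_set = set(perm[:n_x])
    mhc_set = set(perm[n_x : n_x + n_mhc])
    nc_set = set(perm[n_x + n_mhc : n_x + n_mhc + n_nc])

    lengths = rng.integers(*config.gene_length_range, size=n, endpoint=True)
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    chrom = np.empty(n, dtype=object)
    start = np.zeros(n, dtype=np.int64)
    autosomes = [str(c) for c in range(1, config.n_chromosomes + 1)]
    cursor = {c: 1_000_000 for c in autosomes + ["X"]}
    mhc_cursor = _XMHC_START + 500_000
    auto_i = 0
    for i in range(n):
        if i in mhc_set:
            chrom[i] = _XMHC_CHROM
            length = min(int(lengths[i]), 60_000)
            lengths[i] = length
            start[i] = mhc_cursor
            mhc_cursor += length + int(rng.integers(20_000, 60_000))
            if mhc_cursor > _XMHC_END - 100_000:
                mhc_cursor = _XMHC_START + 500_000 + int(rng.integers(0, 50_000))
            continue
        if i in x_set:
            c = "X"
        else:
            c = autosomes[auto_i % len(autosomes)]
            auto_i += 1
        chrom[i] = c
        start[i] = cursor[c]
        cursor[c] += int(lengths[i]) + int(rng.integers(*config.gene_gap_range, endpoint=True))
        if c == _XMHC_CHROM and _XMHC_START - 200_000 < cursor[c] < _XMHC_END + 200_000:
            cursor[c] = _XMHC_END + 500_000  # keep ordinary chr6 genes out of the zone
    end = start + lengths - 1
    biotype = np.where([i in nc_set for i in range(n)], "lincRNA", "protein_coding")
    return pd.DataFrame(
        {
            "gene_id": ids,
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand": strands,
            "biotype": biotype,
        }
    )


def _cs_blocks(k: int, block: int) -> list[int]:
    sizes = [block] * (k // block)
    if k % block:
        sizes.append(k % block)
    return sizes


def compound_symmetry(k: int, r: float) -> np.ndarray:
    R = np.full((k, k), r, dtype=float)
    np.fill_diagonal(R, 1.0)
    return R


def block_ld_matrix(k: int, block: int, r: float) -> np.ndarray:
    """Block-diagonal compound-symmetry LD: correlation ``r`` within blocks
    of size ``block``, zero across blocks."""
    R = np.eye(k)
    pos = 0
    for b in _cs_blocks(k, block):
        R[pos : pos + b, pos : pos + b] = compound_symmetry(b, r)
        pos += b
    return R


def simulate_gwas_summary(
    genes: pd.DataFrame,
    planted_gene_z: np.ndarray | pd.Series,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, tuple[list[str], np.ndarray]]]:
    """Per-SNP summary statistics plus per-gene LD matrices.

    Each gene gets ``snps_per_gene`` SNPs uniformly inside its strand-aware
    35 kb / 10 kb window (occasionally one just outside it), MAF/INFO mostly
    above the standard filters with deliberate low-quality exceptions, and
    z-scores drawn from a block compound-symmetry multivariate normal whose
    mean is ``planted_z / sqrt(k)`` on every in-window SNP. Two-sided normal
    p-values.
    """
    config.validate()
    if not 0.0 <= config.ld_r < 1.0:
        raise ConfigError("simulator LD requires 0 <= ld_r < 1 (compound symmetry)")
    z_planted = np.asarray(planted_gene_z, dtype=float)
    if z_planted.shape[0] != len(genes):
        raise ConfigError("planted_gene_z length must match gene table")
    if not np.all(np.isfinite(z_planted)):
        raise ConfigError("planted_gene_z must be finite")
    rng = config.rng(_STREAM_GWAS)
    r = config.ld_r
    lo, hi = config.snps_per_gene

    records: list[tuple] = []
    ld: dict[str, tuple[list[str], np.ndarray]] = {}
    snp_counter = 0
    for gi, g in enumerate(genes.itertuples(index=False)):
        k = int(rng.integers(lo, hi + 1))
        if g.strand == "+":
            w_lo, w_hi = g.start - UPSTREAM, g.end + DOWNSTREAM
        else:
            w_lo, w_hi = g.start - DOWNSTREAM, g.end + UPSTREAM
        pos = np.sort(rng.integers(max(1, w_lo), w_hi + 1, size=k))
        mean = np.full(k, z_planted[gi] / np.sqrt(k))
        # block compound-symmetry draw
        z = np.empty(k)
        p0 = 0
        for b in _cs_blocks(k, config.ld_block_size):
            shared = rng.standard_normal()
            z[p0 : p0 + b] = np.sqrt(r) * shared + np.sqrt(1 - r) * rng.standard_normal(b)
            p0 += b
        z += mean
        ids = [f"rs{snp_counter + j + 1}" for j in range(k)]
        snp_counter += k
        maf = rng.uniform(0.01, 0.5, size=k)
        low_m = rng.random(k) < config.low_maf_fraction
        maf[low_m] = rng.uniform(0.001, 0.0099, size=low_m.sum())
        info = rng.uniform(0.6, 1.0, size=k)
        low_i = rng.random(k) < config.low_info_fraction
        info[low_i] = rng.uniform(0.2, 0.59, size=low_i.sum())
        for j in range(k):
            records.append((ids[j], g.chrom, int(pos[j]), z[j], maf[j], info[j]))
        ld[g.gene_id] = (ids, block_ld_matrix(k, config.ld_block_size, r))
        if rng.random() < config.outside_snp_fraction:
            snp_counter += 1
            out_pos = max(1, w_lo - 5_000)
            records.append(
                (
                    f"rs{snp_counter}",
                    g.chrom,
                    int(out_pos),
                    rng.standard_normal(),
                    rng.uniform(0.01, 0.5),
                    rng.uniform(0.6, 1.0),
                )
            )
    snps = pd.DataFrame(records, columns=["SNP", "CHR", "BP", "z", "MAF", "INFO"])
    from scipy import stats

    snps["P"] = 2.0 * stats.norm.sf(np.abs(snps["z"].to_numpy()))
    snps["P"] = snps["P"].clip(lower=1e-300)
    return snps[["SNP", "CHR", "BP", "P", "MAF", "INFO"]], ld


def simulate_annotation_sets(
    genes: pd.DataFrame,
    config: SimulationConfig,
    *,
    term_sizes: list[int] | None = None,
    n_terms: int = 40,
    overlap: float = 0.0,
    sources: tuple[str, ...] = ("GO", "MP"),
    evidence_codes: tuple[str, ...] = ("EXP", "IDA", "IMP", "IEA", "NAS", "RCA"),
    evidence_probs: tuple[float, ...] = (0.3, 0.25, 0.25, 0.1, 0.05, 0.05),
):
    """GO/MP-style term collection over the gene table, with per-annotation
    evidence codes and controllable pairwise overlap between consecutive
    terms (``overlap=1.0`` makes adjacent same-size terms identical)."""
    from .pathways import TermCollection

    if genes.empty:
        raise ConfigError("gene table is empty")
    rng = config.rng(_STREAM_TERMS)
    universe = genes["gene_id"].to_numpy()
    if term_sizes is None:
        # log-uniform sizes between 10 and 200 (or the universe, if smaller)
        upper = max(11, min(200, len(universe)))
        term_sizes = [
            int(np.exp(rng.uniform(np.log(10), np.log(upper)))) for _ in range(n_terms)
        ]
    rows = []
    prev: np.ndarray | None = None
    for ti, size in enumerate(term_sizes):
        if size > len(universe):
            raise ConfigError(f"term size {size} exceeds number of genes {len(universe)}")
        n_shared = int(round(overlap * size)) if prev is not None else 0
        n_shared = min(n_shared, len(prev) if prev is not None else 0, size)
        members = []
        if n_shared:
            members.extend(prev[:n_shared])
        pool = np.setdiff1d(universe, np.asarray(members, dtype=object), assume_unique=False)
        extra = rng.choice(pool, size=size - n_shared, replace=False)
        members.extend(extra)
        members = np.asarray(members, dtype=object)
        prev = members
        source = sources[ti % len(sources)]
        term_id = f"{source}:{ti + 1:07d}"
        ev = rng.choice(evidence_codes, size=size, p=evidence_probs)
        for gid, code in zip(members, ev):
            rows.append((term_id, source, f"synthetic term {ti + 1}", gid, code))
    frame = pd.DataFrame(rows, columns=["term_id", "source", "name", "gene_id", "evidence"])
    return TermCollection(frame)
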