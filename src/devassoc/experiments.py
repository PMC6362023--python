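"""In-memory replicate drivers for calibration and power experiments.

These run the analysis chain (simulate → filter → adjust → score →
gene association → property regression) without file I/O, for Monte-Carlo
studies of type-I error, planted-effect recovery and conditional-analysis
behaviour. Used by the test suite and the acceptance script.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import adjust as adj
from . import assoc as ga
from . import gene_property as gp
from . import scores as sc
from . import simulate as sim
from .config import SimulationConfig, WHOLE_BRAIN
from .scores import RegionGroup

__all__ = ["simulate_inputs", "replicate_property_scan", "replicate_conditional"]


def simulate_inputs(config: SimulationConfig):
    """One synthetic study: adjusted expression, metadata, gene association."""
    samples = sim.simulate_sample_metadata(config)
    expr = sim.simulate_expression(samples, config)
    genes = sim.simulate_gene_table(config)
    z = sim.planted_gene_z(config)
    snps, ld = sim.simulate_gwas_summary(genes, z, config)

    expr, samples = adj.filter_samples(expr, samples)
    expr = adj.filter_genes(expr, genes)
    expr = adj.adjust_expression(expr, samples)
    snps = ga.filter_snps(snps)
    assoc = ga.gene_association_table(snps, genes[genes["gene_id"].isin(expr.index)], ld)
    return expr, samples, genes, assoc


def _group(config: SimulationConfig, label: str) -> RegionGroup:
    return RegionGroup(label, config.group_regions(label))


def replicate_property_scan(
    config: SimulationConfig,
    group: str = WHOLE_BRAIN,
    m: int | None = None,
) -> pd.DataFrame:
    """Property regression at every stage for one region group.

    Returns one row per stage with beta, p, p_adj (Bonferroni over the
    supplied ``m``, default the number of stages) and signed -log10(p).
    """
    expr, samples, genes, assoc = simulate_inputs(config)
    scores_long = sc.score_table(expr, samples, _group(config, group), list(config.stages))
    m = m if m is not None else len(config.stages)
    rows = []
    for stage in config.stages:
        s = scores_long[scores_long["stage"] == stage].set_index("gene_id")["score"]
        if s.notna().sum() == 0 or s.dropna().nunique() <= 1:
            # stage absent from the filtered samples, or its scores are
            # degenerate (e.g. the stage confounded with an adjustment
            # covariate in a very small sample)
            continue
        res = gp.property_regression(assoc, s, stage=stage, group=group).adjust(m)
        rows.append(res.to_dict())
    return pd.DataFrame(rows)


def replicate_conditional(
    config: SimulationConfig,
    stage_a: str,
    stage_b: str,
    group: str = WHOLE_BRAIN,
) -> dict:
    """Marginal and reciprocal conditional slopes for two stages."""
    expr, samples, genes, assoc = simulate_inputs(config)
    # each stage's score only involves its own indicator, so scoring can be
    # restricted to the two stages of interest
    scores_long = sc.score_table(expr, samples, _group(config, group), [stage_a, stage_b])

    def stage_scores(stage):
        return scores_long[scores_long["stage"] == stage].set_index("gene_id")["score"]

    sa, sb = stage_scores(stage_a), stage_scores(stage_b)
    marg_a = gp.property_regression(assoc, sa, stage=stage_a, group=group)
    marg_b = gp.property_regression(assoc, sb, stage=stage_b, group=group)
    cond_a, cond_b = gp.conditional_pair(assoc, sa, sb, labels=(stage_a, stage_b), group=group)
    return {
        "marginal_a": marg_a,
        "marginal_b": marg_b,
        "conditional_a": cond_a,
        "conditional_b": cond_b,
    }


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return dataclasses.replace(config, seed=int(seed) % (2**31 - 1))


def refinement_replicate(config: SimulationConfig, aux_seed: int = 0) -> dict | None:
    """One end-to-end decile/pathway replicate with a causal and a decoy term.

    Plants association tied to expression at the configured stage, runs the
    decile scan, merges significant deciles, then builds a term collection
    containing (a) a causal term: the 40 merged-decile genes with the
    largest planted association strength, (b) a decoy whose overlap with the
    merged deciles is entirely the causal term's genes plus outside-decile
    padding, and (c) random terms. Runs the Fisher scan, step-wise
    refinement and the conditional term test. Returns None when no decile
    reaches adjusted significance.
    """
    from . import pathways as pw

    stage = config.planted_effects[0].stage
    expr, samples, genes, assoc = simulate_inputs(config)
    group = _group(config, WHOLE_BRAIN)
    st = sc.score_table(expr, samples, group, [stage])
    s = st.set_index("gene_id")["score"]
    s = s[s.index.isin(assoc["gene_id"])]
    deciles = pw.decile_bins(s)
    scan = pw.decile_scan(assoc, deciles)
    merged = pw.merge_significant_deciles(scan, deciles)
    if not merged:
        return None
    strength = pd.Series(sim.planted_gene_z(config), index=sim.gene_ids(config.n_genes))
    causal = set(sorted(merged, key=lambda g: -strength.get(g, -np.inf))[:40])
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7, aux_seed)))
    outside = sorted(set(deciles.index) - merged)
    decoy = causal | set(rng.choice(outside, 45, replace=False))
    rows = [("GO:causal", "GO", "causal", g, "EXP") for g in sorted(causal)]
    rows += [("GO:decoy", "GO", "decoy", g, "EXP") for g in sorted(decoy)]
    for t in range(20):
        members = rng.choice(sorted(deciles.index), rng.integers(20, 120), replace=False)
        rows += [(f"GO:r{t:03d}", "GO", f"random {t}", g, "EXP") for g in members]
    terms = pw.TermCollection(
        pd.DataFrame(rows, columns=["term_id", "source", "name", "gene_id", "evidence"])
    )
    background = set(deciles.index)
    hits = pw.fisher_term_scan(merged, terms, background)
    sig = [r for r in hits if r.p_adj is not None and r.p_adj < 0.05]
    refined, audit = pw.refine_terms(sig, terms, merged, background)
    refined_ids = {r.unit for r in refined}
    sig_ids = {r.unit for r in sig}
    cond = pw.conditional_term_association(assoc, causal & merged, merged)
    return {
        "merged_size": len(merged),
        "causal_significant": "GO:causal" in sig_ids,
        "causal_refined": "GO:causal" in refined_ids,
        "decoy_significant": "GO:decoy" in sig_ids,
        "decoy_dropped": "GO:decoy" in sig_ids and "GO:decoy" not in refined_ids,
        "conditional_p": None if cond is None else cond.p,
        "audit_len": len(audit),
    }
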