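"""End-to-end orchestration: simulate/load → filter → adjust → score →
gene association → property regressions → decile/pathway analyses.

Every run writes intermediate artifacts and a manifest (config echo, seed,
row counts at each filter step) so any stage can be re-run from its inputs.
Outputs are deterministic given the config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import adjust as adj
from . import assoc as ga
from . import gene_property as gp
from . import io as dio
from . import pathways as pw
from . import scores as sc
from . import simulate as sim
from .config import DEFAULT_REGION_GROUPS, DEFAULT_STAGES, SimulationConfig, WHOLE_BRAIN

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and analysis plan for one pipeline run."""

    # either a simulation config, or paths to the five inputs
    simulate: SimulationConfig | None = None
    expr_path: str | None = None
    samples_path: str | None = None
    sumstats_path: str | None = None
    gene_loc_path: str | None = None
    ld_dir: str | None = None
    gmt_paths: tuple[str, ...] = ()
    # vocabulary (taken from `simulate` when simulating)
    stages: tuple[str, ...] = DEFAULT_STAGES
    region_groups: dict = field(default_factory=lambda: dict(DEFAULT_REGION_GROUPS))
    # thresholds
    rin_min: float = 7.0
    maf_min: float = 0.01
    info_min: float = 0.6
    window: tuple[int, int] = (ga.UPSTREAM, ga.DOWNSTREAM)
    exclude_regions: tuple = (ga.DEFAULT_XMHC,)
    exclude_chroms: tuple = ("X",)
    alpha: float = 0.05
    alpha_retest: float = 0.05
    fisher_alternative: str = "greater"
    evidence_exclude: tuple[str, ...] = pw.DEFAULT_EVIDENCE_EXCLUDE
    null_method: str = "exact"
    mc_draws: int = 100_000
    # pathway stage selection: explicit list of {stage, group, direction},
    # or automatic from tier-2 significant results
    pathway_stages: tuple = ()
    pathway_auto: bool = True
    make_plots: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            simcfg = raw.pop("simulate")
            if isinstance(simcfg, dict):
                if "planted_effects" in simcfg:
                    from .config import PlantedEffect

                    simcfg["planted_effects"] = tuple(
                        PlantedEffect(**e) for e in simcfg["planted_effects"]
                    )
                raw["simulate"] = SimulationConfig(**simcfg)
        for key in ("stages", "gmt_paths", "exclude_chroms", "evidence_exclude"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=str))


def _load_inputs(cfg: PipelineConfig, outdir: Path, manifest: dict):
    if cfg.simulate is not None:
        simcfg = dataclasses.replace(cfg.simulate, seed=cfg.seed)
        samples = sim.simulate_sample_metadata(simcfg)
        expr = sim.simulate_expression(samples, simcfg)
        genes = sim.simulate_gene_table(simcfg)
        z = sim.planted_gene_z(simcfg)
        snps, ld = sim.simulate_gwas_summary(genes, z, simcfg)
        terms = sim.simulate_annotation_sets(genes, simcfg)
        inputs = outdir / "inputs"
        inputs.mkdir(parents=True, exist_ok=True)
        dio.write_expression(expr, inputs / "expression.tsv")
        dio.write_samples(samples, inputs / "samples.tsv")
        dio.write_sumstats(snps, inputs / "sumstats.txt")
        dio.write_gene_loc(genes, inputs / "genes.loc")
        dio.write_gmt(terms, inputs / "terms.gmt")
        stages = tuple(simcfg.stages)
        groups = dict(simcfg.region_groups)
        manifest["simulated"] = True
    else:
        for name in ("expr_path", "samples_path", "sumstats_path", "gene_loc_path"):
            if getattr(cfg, name) is None:
                raise ValueError(f"pipeline stage 'load': missing input {name}")
        expr = dio.read_expression(cfg.expr_path)
        samples = dio.read_samples(cfg.samples_path)
        snps = dio.read_sumstats(cfg.sumstats_path)
        genes = dio.read_gene_loc(cfg.gene_loc_path)
        ld = dio.read_ld_dir(cfg.ld_dir) if cfg.ld_dir else None
        terms = None
        if cfg.gmt_paths:
            frames = [dio.read_gmt(p).frame for p in cfg.gmt_paths]
            terms = pw.TermCollection(pd.concat(frames, ignore_index=True))
        stages = tuple(cfg.stages)
        groups = dict(cfg.region_groups)
        manifest["simulated"] = False
    return expr, samples, snps, genes, ld, terms, stages, groups


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run the full analysis; returns the manifest dict."""
    t0 = time.monotonic()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "counts": {}}
    counts = manifest["counts"]

    stage_name = "load"
    try:
        expr, samples, snps, genes, ld, terms, stages, groups = _load_inputs(
            cfg, outdir, manifest
        )
        counts["samples_raw"] = int(len(samples))
        counts["genes_raw"] = int(len(expr))
        counts["snps_raw"] = int(len(snps))

        stage_name = "filter_samples"
        expr, samples = adj.filter_samples(expr, samples, rin_min=cfg.rin_min)
        counts["samples_rin"] = int(len(samples))

        stage_name = "filter_genes"
        expr = adj.filter_genes(expr, genes)
        counts["genes_filtered"] = int(len(expr))

        stage_name = "adjust_expression"
        expr = adj.adjust_expression(expr, samples)
        dio.write_expression(expr, outdir / "expression_adjusted.tsv")

        stage_name = "score"
        plan = sc.tier_plan(groups, stages)
        scores_long = pd.concat(
            [sc.score_table(expr, samples, e["group"], stages) for e in plan],
            ignore_index=True,
        )
        scores_long.to_csv(outdir / "expression_scores.tsv", sep="\t", index=False)

        stage_name = "gene_association"
        snps = ga.filter_snps(
            snps,
            maf_min=cfg.maf_min,
            info_min=cfg.info_min,
            exclude_regions=tuple(cfg.exclude_regions),
            exclude_chroms=tuple(cfg.exclude_chroms),
        )
        counts["snps_filtered"] = int(len(snps))
        if cfg.null_method == "mc" and ld is None and cfg.simulate is None:
            raise ValueError("Monte-Carlo null requires LD input; pass --ld or use --null exact")
        assoc = ga.gene_association_table(
            snps,
            genes[genes["gene_id"].isin(expr.index)],
            ld,
            up=cfg.window[0],
            down=cfg.window[1],
            method=cfg.null_method,
            mc_draws=cfg.mc_draws,
            rng=np.random.default_rng(np.random.SeedSequence((cfg.seed, 97))),
        )
        counts["genes_associated"] = int(len(assoc))
        assoc.to_csv(outdir / "gene_association.tsv", sep="\t", index=False)

        stage_name = "gene_property"
        results = gp.tier_analysis(assoc, scores_long, plan)
        results.to_csv(outdir / "property_results.tsv", sep="\t", index=False)
        if cfg.make_plots:
            from .plotting import plot_signed_bars

            for entry in plan:
                sub = results[results["group"] == entry["group"].label]
                plot_signed_bars(
                    sub,
                    outdir / f"property_{entry['group'].label.replace(' ', '_')}.png",
                    m=entry["m"],
                    alpha=cfg.alpha,
                    title=entry["group"].label,
                )

        stage_name = "pathways"
        targets = [dict(t) for t in cfg.pathway_stages]
        if not targets and cfg.pathway_auto:
            sig = results[(results["tier"] == 2) & (results["p_adj"] < cfg.alpha)]
            targets = [
                {
                    "stage": r.stage,
                    "group": r.group,
                    "direction": "greater" if r.beta > 0 else "less",
                }
                for r in sig.itertuples()
            ]
        pathway_summaries = []
        if targets and terms is not None:
            terms_f = terms.filter_evidence(tuple(cfg.evidence_exclude))
            for tgt in targets:
                summary = _run_pathway_block(
                    cfg, outdir, assoc, scores_long, terms_f, tgt
                )
                pathway_summaries.append(summary)
        manifest["pathway_targets"] = pathway_summaries

        manifest["config"] = cfg.to_jsonable()
        manifest["runtime_s"] = None  # kept out of the manifest for byte-stable reruns
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        log.info("pipeline finished in %.1fs", time.monotonic() - t0)
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") from exc


def _run_pathway_block(cfg, outdir, assoc, scores_long, terms, tgt) -> dict:
    stage, group = tgt["stage"], tgt["group"]
    direction = tgt.get("direction", "greater")
    tag = f"{group}_{stage}".replace(" ", "_")
    s = scores_long[
        (scores_long["group"] == group) & (scores_long["stage"] == stage)
    ].set_index("gene_id")["score"]
    s = s[s.index.isin(assoc["gene_id"])]
    deciles = pw.decile_bins(s)
    scan = pw.decile_scan(assoc, deciles)
    pd.DataFrame(
        [
            {
                "decile": r.unit,
                "beta": r.effect,
                "p": r.p,
                "p_adj": r.p_adj,
                "direction": r.direction,
                "signed_log10p": r.signed_log10p,
            }
            for r in scan
        ]
    ).to_csv(outdir / f"decile_scan_{tag}.tsv", sep="\t", index=False)
    merged = pw.merge_significant_deciles(scan, deciles, alpha=cfg.alpha)
    summary = {"stage": stage, "group": group, "n_merged": len(merged)}
    if not merged:
        return summary
    background = set(deciles.index)
    hits = pw.fisher_term_scan(
        merged, terms, background, alternative=cfg.fisher_alternative
    )
    pd.DataFrame(
        [
            {
                "term": r.unit,
                "source": (r.extra or {}).get("source"),
                "odds_ratio": r.effect,
                "p": r.p,
                "p_adj": r.p_adj,
                "n_overlap": r.n_set,
            }
            for r in hits
        ]
    ).to_csv(outdir / f"term_scan_{tag}.tsv", sep="\t", index=False)
    sig_terms = [r for r in hits if r.p_adj is not None and r.p_adj < cfg.alpha]
    refined, audit = pw.refine_terms(
        sig_terms, terms, merged, background,
        alpha_retest=cfg.alpha_retest, alternative=cfg.fisher_alternative,
    )
    pd.DataFrame(audit).to_csv(
        outdir / f"refinement_audit_{tag}.tsv", sep="\t", index=False
    )
    tdict = terms.to_dict()
    cond_rows = []
    for r in refined:
        overlap = tdict[r.unit] & merged
        res = pw.conditional_term_association(
            assoc, overlap, merged, direction=direction
        )
        if res is not None:
            cond_rows.append(
                {"term": r.unit, "beta": res.effect, "p_one_tailed": res.p, "n_overlap": res.n_set}
            )
    pd.DataFrame(cond_rows).to_csv(
        outdir / f"conditional_terms_{tag}.tsv", sep="\t", index=False
    )
    summary.update(n_significant_terms=len(sig_terms), n_refined=len(refined))
    return summary
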