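"""End-to-end orchestration: quantify -> DE -> networks -> differential
co-expression -> selection scan -> prune -> enrichment, from one config."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpr, de, diffcoex, enrich, io, popgen, quant

log = logging.getLogger("silknet")

DEFAULT_PARAMS = {
    "quant": {"fpkm_floor": 1.0, "max_low_samples": 10},
    "de": {"fixed_dispersion": 0.1, "dispersion": None},
    "network": {
        "beta": 16,
        "cut_height": 0.995,
        "min_module_size": 30,
        "r2_target": 0.85,
        "log_transform": True,
    },
    "diffcoex": {"fc_threshold": 1.5, "weight_floor": 0.05},
    "popgen": {
        "window_size": 50_000,
        "step": 25_000,
        "estimator": "weir_cockerham",
        "pi_stat": "ratio",
        "lower_q": 0.05,
        "upper_q": 0.95,
    },
    "enrich": {"sig_cut": 0.05, "min_term_size": 2},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def merge_params(cfg: dict) -> dict:
    params = {k: dict(v) for k, v in DEFAULT_PARAMS.items()}
    for stage, overrides in (cfg.get("params") or {}).items():
        if stage not in params:
            raise ValueError(f"unknown parameter group {stage!r}")
        params[stage].update(overrides or {})
    return params


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def quantify(counts, design, gene_lengths, params) -> dict:
    """TMM -> FPKM -> collapse -> low-expression filter -> non-varying filter."""
    norm = quant.compute_tmm_factors(counts)
    fpkm = quant.compute_fpkm(counts, gene_lengths, norm)
    kept, removed_low = quant.filter_low_expression(
        fpkm, params["fpkm_floor"], params["max_low_samples"]
    )
    collapsed = quant.collapse_replicates(kept, design)
    expr, removed_flat = quant.remove_nonvarying(collapsed)
    log.info(
        "quantify: %d genes in, %d after FPKM filter, %d after variance filter",
        counts.shape[0], kept.shape[0], expr.shape[0],
    )
    return {
        "norm": norm,
        "fpkm": fpkm,
        "expr": expr,
        "removed_low": removed_low,
        "removed_nonvarying": removed_flat,
        "bands": quant.classify_expression_levels(fpkm),
    }


def condition_expression(expr: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Columns of the collapsed matrix belonging to one condition."""
    cols = [c for c in expr.columns if c.startswith(f"{condition}_")]
    if len(cols) < 3:
        raise ValueError(f"fewer than 3 stage columns for condition {condition!r}")
    return expr[cols]


def build_network(expr_cond: pd.DataFrame, params) -> dict:
    """Similarity -> soft-threshold adjacency -> TOM for one condition.

    Correlations are computed on log2(FPKM + 1) by default; raw-scale Pearson
    is dominated by the highest-expression column.
    """
    if params.get("log_transform", True):
        expr_cond = np.log2(expr_cond + 1.0)
    expr_cond, _ = quant.remove_nonvarying(expr_cond)
    sim = coexpr.pearson_similarity(expr_cond)
    beta = params["beta"]
    report = None
    if beta in (None, "auto"):
        beta, report = coexpr.pick_soft_threshold(sim, r2_target=params["r2_target"])
    adj = coexpr.soft_adjacency(sim, beta)
    tom = coexpr.tom_similarity(adj)
    return {"sim": sim, "beta": beta, "adj": adj, "tom": tom, "report": report}


def run_pipeline(cfg: dict, outdir: str | Path, seed: int | None = None) -> dict:
    """Run all stages and write every output table plus a summary JSON.

    ``seed`` only affects optional synthetic input generation performed by the
    CLI; the analysis itself is deterministic.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = merge_params(cfg)
    inputs = cfg["inputs"]
    for stage, ps in params.items():
        log.info("params[%s] = %s", stage, ps)

    counts = io.read_counts(inputs["counts"])
    design = io.read_sample_sheet(inputs["samples"])
    models = io.read_gene_models(inputs["gene_models"])
    annotation = io.read_annotation(inputs["annotation"]) if inputs.get("annotation") else {}
    seeds_cfg = inputs.get("seed_genes", [])
    seed_genes = (
        io.read_gene_list(seeds_cfg) if isinstance(seeds_cfg, str) else list(seeds_cfg)
    )

    # --- quantification ---
    q = quantify(counts, design, models["length"], params["quant"])
    q["norm"].to_csv(outdir / "norm_factors.tsv", sep="\t", index_label="sample")
    q["fpkm"].to_csv(outdir / "fpkm_per_sample.tsv", sep="\t", index_label="gene")
    q["expr"].to_csv(outdir / "expression.tsv", sep="\t", index_label="gene")
    pd.DataFrame(
        {"gene": q["removed_low"] + q["removed_nonvarying"],
         "reason": ["low_expression"] * len(q["removed_low"])
         + ["non_varying"] * len(q["removed_nonvarying"])}
    ).to_csv(outdir / "removed_genes.tsv", sep="\t", index=False)

    # --- differential expression ---
    de_res = de.run_de(
        counts, design, q["norm"],
        dispersion=params["de"]["dispersion"],
        fixed_dispersion=params["de"]["fixed_dispersion"],
    )
    de_res.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    deg_counts = de.deg_summary(de_res)
    deg_genes = set(de_res.loc[de_res["is_deg"], "gene"])

    # --- co-expression networks ---
    nets = {c: build_network(condition_expression(q["expr"], c), params["network"])
            for c in ("domestic", "wild")}
    common = nets["domestic"]["tom"].index.intersection(nets["wild"]["tom"].index)
    tom_d = nets["domestic"]["tom"].loc[common, common]
    tom_w = nets["wild"]["tom"].loc[common, common]
    modules = {
        c: coexpr.detect_modules(
            nets[c]["tom"], params["network"]["cut_height"],
            params["network"]["min_module_size"],
        )
        for c in ("domestic", "wild")
    }
    consensus = coexpr.consensus_modules(
        tom_d, tom_w, params["network"]["cut_height"],
        params["network"]["min_module_size"],
    )
    for name, labels in {**modules, "consensus": consensus}.items():
        labels.rename("module").to_csv(
            outdir / f"modules_{name}.tsv", sep="\t", index_label="gene"
        )

    # --- differential co-expression around seed genes ---
    present_seeds = [s for s in seed_genes if s in consensus.index]
    summary_networks = {}
    if present_seeds:
        seed_modules = {
            m for m in consensus.reindex(present_seeds) if m != coexpr.UNASSIGNED
        }
        universe = sorted(
            set(present_seeds)
            | {g for g in consensus.index[consensus.isin(seed_modules)] if g in deg_genes}
        )
        edges = diffcoex.differential_edges(
            tom_d, tom_w, universe, params["diffcoex"]["fc_threshold"]
        )
        edges.to_csv(outdir / "differential_edges.tsv", sep="\t", index=False)
        networks = diffcoex.build_seed_networks(
            present_seeds, consensus, deg_genes, edges,
            params["diffcoex"]["weight_floor"],
        )
        for cond, net in networks.items():
            net.edges.to_csv(outdir / f"network_{cond}_edges.tsv", sep="\t", index=False)
        degree_table = diffcoex.seed_degree_table(networks)
        degree_table.to_csv(outdir / "seed_degrees.tsv", sep="\t", index_label="gene")
        summary_networks = {
            "n_differential_edges": int(len(edges)),
            "network_sizes": {c: int(len(n.edges)) for c, n in networks.items()},
            "seed_degrees": {
                c: {g: int(v) for g, v in n.seed_degrees().items()}
                for c, n in networks.items()
            },
        }
    else:
        networks = {}
        log.warning("no seed genes present after filtering; skipping diffcoex stage")

    # --- selection scan ---
    summary_popgen = {}
    selected_genes: set[str] = set()
    if inputs.get("vcf"):
        popmap = io.read_population_map(inputs["popmap"])
        panel_d, panel_w, vcf_report = popgen.read_vcf_panels(inputs["vcf"], popmap)
        stats = popgen.window_stats(
            panel_d, panel_w, params["popgen"]["window_size"],
            params["popgen"]["step"], params["popgen"]["estimator"],
        )
        with open(outdir / "window_stats.tsv", "w") as fh:
            fh.write("# coordinates: 0-based half-open\n")
            stats.to_csv(fh, sep="\t", index=False)
        regions, thresholds = popgen.call_selection_regions(
            stats, params["popgen"]["pi_stat"],
            params["popgen"]["lower_q"], params["popgen"]["upper_q"],
        )
        regions.to_csv(outdir / "selection_regions.bed", sep="\t", index=False, header=False)
        selected_genes = popgen.overlap_genes(regions, models)
        pd.Series(sorted(selected_genes), name="gene").to_csv(
            outdir / "selected_genes.tsv", sep="\t", index=False
        )
        summary_popgen = {
            "vcf": vcf_report,
            "n_windows": int(len(stats)),
            "n_regions": int(len(regions)),
            "n_selected_genes": len(selected_genes),
            "thresholds": thresholds,
        }
        if networks:
            pruned = {
                c: diffcoex.prune_by_selection(n, selected_genes)
                for c, n in networks.items()
            }
            for cond, net in pruned.items():
                net.edges.to_csv(
                    outdir / f"network_{cond}_pruned_edges.tsv", sep="\t", index=False
                )
            summary_networks["seed_degrees_pruned"] = {
                c: {g: int(v) for g, v in n.seed_degrees().items()}
                for c, n in pruned.items()
            }

    # --- enrichment ---
    summary_enrich = {}
    if annotation:
        universe_genes = [g for g in q["expr"].index if annotation.get(g)]
        stages = list(dict.fromkeys(design["stage"]))
        up_by_stage, down_by_stage = {}, {}
        for st in stages:
            sub = de_res[(de_res["stage"] == st) & de_res["is_deg"]]
            for direction, store in (("up", up_by_stage), ("down", down_by_stage)):
                study = [
                    g for g in sub.loc[sub["direction"] == direction, "gene"]
                    if g in universe_genes
                ]
                res = enrich.hypergeom_enrich(
                    study, universe_genes, annotation,
                    params["enrich"]["min_term_size"],
                )
                store[st] = res
                res.to_csv(
                    outdir / f"enrichment_{direction}_{st}.tsv", sep="\t", index=False
                )
        shift = enrich.functional_shift(
            up_by_stage, down_by_stage, stages, params["enrich"]["sig_cut"]
        )
        shift.to_csv(outdir / "functional_shift.tsv", sep="\t", index=False)
        summary_enrich = {
            "n_universe": len(universe_genes),
            "n_shift_terms": int(len(shift)),
        }

    from . import __version__

    summary = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "n_genes_input": int(counts.shape[0]),
        "n_samples": int(counts.shape[1]),
        "n_genes_filtered": int(q["expr"].shape[0]),
        "degs_per_stage": deg_counts,
        "beta": {c: int(nets[c]["beta"]) for c in nets},
        "n_modules": {
            c: int((m[m != coexpr.UNASSIGNED]).nunique()) for c, m in modules.items()
        },
        "n_consensus_modules": int(
            consensus[consensus != coexpr.UNASSIGNED].nunique()
        ),
        "diffcoex": summary_networks,
        "popgen": summary_popgen,
        "enrichment": summary_enrich,
    }
    io.write_json(summary, outdir / "summary.json")
    return summary
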