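"""End-to-end orchestration of the diallel methylation analysis.

Stages: RPM profiling -> per-combination DMS calling (parents, reciprocal
hybrids, hybrid vs each parent, hybrid vs MPV) -> parental categories and
inheritance patterns -> reciprocal sets (HDS/PDS/Ins/PSD) and reciprocal
non-additive merging -> gene assignment, DMG collapse, GO enrichment.
Everything is deterministic given the inputs; ``run_all`` additionally
handles simulation from a config file and writes all result tables with a
manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, genes as genes_mod, io, patterns, profiling, reciprocal
from .types import CrossDesign, SiteCountTable, Thresholds


@dataclass
class PipelineResult:
    """All intermediate and final products of one pipeline run."""

    profile: profiling.MethylationProfile
    comparisons: dict[tuple[str, str], pd.DataFrame]
    categories: dict[str, pd.Series]  # per combination
    pattern_calls: dict[str, pd.DataFrame]  # per hybrid
    reciprocal_sets: dict[str, reciprocal.ReciprocalSets]
    merged_nonadditive: dict[str, pd.DataFrame]
    dmgs: pd.DataFrame
    enrichment: pd.DataFrame
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_analysis(
    table: SiteCountTable,
    design: CrossDesign,
    gene_features=None,
    te_features=None,
    go_map: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    dispersion: float = differential.DEFAULT_DISPERSION,
    thresholds: Thresholds = Thresholds(),
    psd_rule: str = "strict",
    background_mode: str = "assayed",
    bh_correct: bool = False,
) -> PipelineResult:
    """Run every analysis stage on an in-memory dataset.

    ``bh_correct`` applies Benjamini–Hochberg adjustment within every
    comparison before the significance call (off by default: the study rule
    is raw p < 0.05).
    """
    design.validate_against(table)
    gene_features = gene_features or []
    te_features = te_features or []

    profile = profiling.compute_rpm(table)
    if gene_features or te_features:
        profiling.assign_elements(profile, gene_features, te_features, flank=thresholds.flank)

    def compare(a: str, b: str) -> pd.DataFrame:
        return differential.compare_samples(
            table, a, b, dispersion=dispersion, thresholds=thresholds,
            bh_correct=bh_correct,
        )

    comparisons: dict[tuple[str, str], pd.DataFrame] = {}
    categories: dict[str, pd.Series] = {}
    pattern_calls: dict[str, pd.DataFrame] = {}
    rec_sets: dict[str, reciprocal.ReciprocalSets] = {}
    merged: dict[str, pd.DataFrame] = {}

    for combo, fab, fba in design.combinations:
        pa, _ = design.hybrid_parents(fab)  # maternal parent of F_ab = parent A
        pb, _ = design.hybrid_parents(fba)
        comparisons[(pa, pb)] = compare(pa, pb)
        comparisons[(fab, fba)] = compare(fab, fba)
        categories[combo] = patterns.classify_parental_category(
            comparisons[(pa, pb)], table.column(pa), table.column(pb)
        )
        for hyb in (fab, fba):
            for par in (pa, pb):
                if (par, hyb) not in comparisons:
                    comparisons[(par, hyb)] = compare(par, hyb)
            key = (f"MPV({pa},{pb})", hyb)
            comparisons[key] = differential.compare_to_mpv(
                table, hyb, pa, pb, dispersion=dispersion, thresholds=thresholds,
                bh_correct=bh_correct,
            )
            pattern_calls[hyb] = patterns.classify_patterns(
                table.sites,
                hyb,
                categories[combo],
                comparisons[key],
                comparisons[(pa, hyb)],
                comparisons[(pb, hyb)],
            )
        rec_sets[combo] = reciprocal.build_reciprocal_sets(
            combo,
            table.sites,
            comparisons[(fab, fba)],
            comparisons[(pa, pb)],
            comparisons[(pa, fab)]["significant"].to_numpy(),
            comparisons[(pb, fab)]["significant"].to_numpy(),
            comparisons[(pb, fba)]["significant"].to_numpy(),
            comparisons[(pa, fba)]["significant"].to_numpy(),
            psd_rule=psd_rule,
        )
        merged[combo] = reciprocal.merge_reciprocal_nonadditive(
            combo, pattern_calls[fab], pattern_calls[fba]
        )

    all_merged = (
        pd.concat(merged.values(), ignore_index=True)
        if merged
        else pd.DataFrame(columns=["chrom", "pos", "context", "combination", "pair_label"])
    )
    if gene_features and len(all_merged):
        pairs = genes_mod.assign_sites_to_genes(all_merged, gene_features, thresholds.flank)
        dmgs = genes_mod.collapse_dmgs(pairs)
    else:
        dmgs = genes_mod.collapse_dmgs(pd.DataFrame(columns=list(all_merged.columns) + ["gene_id"]))
    if annotation is not None and len(dmgs):
        dmgs = genes_mod.join_annotations(dmgs, annotation)

    enrich_frames = []
    if go_map is not None and gene_features and len(dmgs):
        for (combo, context), grp in dmgs.groupby(["combination", "context"], observed=True):
            if background_mode == "assayed":
                background = genes_mod.assayed_background(
                    table.sites, gene_features, context, thresholds.flank
                )
            else:
                background = {g.gene_id for g in gene_features}
            res = genes_mod.fisher_enrichment(
                set(grp["gene_id"]), go_map, background,
                min_term_genes=thresholds.min_term_genes,
            )
            res.insert(0, "combination", combo)
            res.insert(1, "context", context)
            enrich_frames.append(res)
    enrich_frames = [f for f in enrich_frames if len(f)]
    enrichment = (
        pd.concat(enrich_frames, ignore_index=True)
        if enrich_frames
        else pd.DataFrame(
            columns=["combination", "context", "go_id", "go_name", "k", "K", "m", "M", "p_value"]
        )
    )

    result = PipelineResult(
        profile=profile,
        comparisons=comparisons,
        categories=categories,
        pattern_calls=pattern_calls,
        reciprocal_sets=rec_sets,
        merged_nonadditive=merged,
        dmgs=dmgs,
        enrichment=enrichment,
    )
    result.tables = _collect_tables(result, table, design, thresholds)
    return result


def _collect_tables(
    result: PipelineResult,
    table: SiteCountTable,
    design: CrossDesign,
    thresholds: Thresholds,
) -> dict[str, pd.DataFrame]:
    tables: dict[str, pd.DataFrame] = {}
    profile = result.profile
    if profile.memberships is not None:
        summaries = profiling.summarize_regions(profile)
        tables.update(summaries)
        hyper_frames = []
        for context in table.sites["context"].unique():
            h = profiling.detect_hyper_sites(profile, context, thresholds)
            hyper_frames.append(h)
        tables["hyper_sites"] = pd.concat(hyper_frames, ignore_index=True)
    dms_frames = [df for df in result.comparisons.values()]
    tables["dms_all_comparisons"] = pd.concat(dms_frames, ignore_index=True)
    tables["pattern_calls"] = pd.concat(result.pattern_calls.values(), ignore_index=True)
    primary = profile.primary_element
    summ = patterns.tabulate_patterns(tables["pattern_calls"], None)
    tables.update(summ)
    rec_summaries, rec_frames = [], []
    for combo, sets in result.reciprocal_sets.items():
        rec_frames.append(sets.frame())
        s = reciprocal.summarize_reciprocal(sets, result.merged_nonadditive[combo], primary)
        rec_summaries.append(s["reciprocal_summary"])
    tables["reciprocal_sets"] = pd.concat(rec_frames, ignore_index=True)
    tables["reciprocal_summary"] = (
        pd.concat(rec_summaries, ignore_index=True) if rec_summaries else pd.DataFrame()
    )
    tables["reciprocal_nonadditive"] = (
        pd.concat(result.merged_nonadditive.values(), ignore_index=True)
        if result.merged_nonadditive
        else pd.DataFrame()
    )
    tables["dmgs"] = result.dmgs
    tables["enrichment"] = result.enrichment
    return tables


def run_all(config: dict, out_dir: str | Path) -> pd.DataFrame:
    """Config-driven end-to-end run; returns the written manifest.

    The config dict mirrors the YAML the CLI accepts: an optional
    ``simulate`` block (seed + generator overrides) or explicit input paths
    (``counts``, ``design``, ``genes``, ``tes``, ``go_map``, ``annotation``),
    plus ``dispersion``, ``thresholds``, ``psd_rule``, ``background``.
    """
    from .simulate import SimulationConfig, simulate_dataset
    from .types import default_diallel_design

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    thresholds = Thresholds(**config.get("thresholds", {}))
    dispersion = config.get("dispersion", differential.DEFAULT_DISPERSION)

    if "simulate" in config:
        sim_cfg = SimulationConfig(**config["simulate"])
        data = simulate_dataset(sim_cfg)
        table, design = data["table"], data["design"]
        gene_features, te_features = data["genes"], data["tes"]
        go_map, truth = data["go_map"], data["truth"]
        annotation = None
    else:
        table = io.read_site_counts(config["counts"])
        design = (
            io.read_design(config["design"]) if "design" in config else default_diallel_design()
        )
        gene_features = io.read_gene_annotation(config["genes"]) if "genes" in config else []
        te_features = io.read_te_annotation(config["tes"]) if "tes" in config else []
        go_map = io.read_go_map(config["go_map"]) if "go_map" in config else None
        annotation = (
            io.read_annotation_table(config["annotation"]) if "annotation" in config else None
        )
        truth = None

    result = run_analysis(
        table,
        design,
        gene_features,
        te_features,
        go_map,
        annotation,
        dispersion=dispersion,
        thresholds=thresholds,
        psd_rule=config.get("psd_rule", "strict"),
        background_mode=config.get("background", "assayed"),
    )
    tables = dict(result.tables)
    tables["site_counts"] = table.to_frame()
    if truth is not None:
        tables["truth"] = truth
    return io.write_results(tables, out_dir)
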