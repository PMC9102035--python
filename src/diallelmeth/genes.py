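"""Gene assignment, non-additively methylated genes (DMGs), GO enrichment.

Reciprocal non-additive DMSs are assigned to every gene whose body or 2 kb
flank contains them; a gene with one or more assigned sites is a single DMG
per (combination, context) whether or not the site labels agree (conflicts
are flagged, never dropped).  GO over-representation uses the one-sided
Fisher exact (hypergeometric upper tail) test; terms with fewer than 5 DMGs
annotated are dropped before reporting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .types import GeneFeature


def _window_trees(genes: list[GeneFeature], flank: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        lo = max(1, g.start - flank)
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, g.end + flank + 1, g.gene_id)
    return trees


def assign_sites_to_genes(
    sites: pd.DataFrame, genes: list[GeneFeature], flank: int = 2000
) -> pd.DataFrame:
    """(gene_id, site) pairs for sites within a gene's body or ±``flank`` bp.

    A site inside several genes' windows yields one pair per gene.  Extra
    columns of ``sites`` (labels etc.) are carried through.
    """
    trees = _window_trees(genes, flank)
    rows = []
    chroms = sites["chrom"].to_numpy()
    poss = sites["pos"].to_numpy()
    for i in range(len(sites)):
        tree = trees.get(chroms[i])
        if tree is None:
            continue
        for hit in sorted(tree[int(poss[i])], key=lambda iv: iv.data):
            row = sites.iloc[i].to_dict()
            row["gene_id"] = hit.data
            rows.append(row)
    cols = list(sites.columns) + ["gene_id"]
    return pd.DataFrame(rows, columns=cols)


def collapse_dmgs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Collapse (gene, site) pairs into one DMG per (gene, combination,
    context); ``label_conflict`` is set when the supporting pair labels
    disagree."""
    if not len(pairs):
        return pd.DataFrame(
            columns=["gene_id", "combination", "context", "n_sites", "labels", "label_conflict"]
        )
    grouped = pairs.groupby(["gene_id", "combination", "context"], observed=True)
    out = grouped.agg(
        n_sites=("pair_label", "size"),
        labels=("pair_label", lambda s: ",".join(sorted(set(s)))),
        label_conflict=("pair_label", lambda s: s.nunique() > 1),
    ).reset_index()
    return out.sort_values(["combination", "context", "gene_id"]).reset_index(drop=True)


def assayed_background(
    all_sites: pd.DataFrame,
    genes: list[GeneFeature],
    context: str | None = None,
    flank: int = 2000,
) -> set[str]:
    """Genes whose ±flank window contains at least one assayed site (of the
    given context when specified) — the default enrichment background."""
    sub = all_sites if context is None else all_sites[all_sites["context"] == context]
    trees = _window_trees(genes, flank)
    hit: set[str] = set()
    for chrom, grp in sub.groupby("chrom", observed=True):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for pos in grp["pos"].to_numpy():
            for iv in tree[int(pos)]:
                hit.add(iv.data)
    return hit


def fisher_enrichment(
    dmg_list: set[str] | list[str],
    go_map: pd.DataFrame,
    background: set[str] | list[str],
    min_term_genes: int = 5,
    min_on: str = "study",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """One-sided over-representation of GO terms among DMGs.

    For a term annotated to ``m`` of ``M`` background genes, with ``k`` of
    the ``K`` DMGs annotated, the p-value is the hypergeometric upper tail
    P(X >= k).  Terms failing the minimum-annotated-genes filter (``k`` with
    ``min_on='study'``, the default literal reading; ``m`` with
    ``min_on='background'``) are dropped.  Rows sorted by p then term id.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background gene set")
    dmgs = set(dmg_list)
    universe = background | dmgs  # background is expected to cover the DMG list
    K = len(dmgs)
    M = len(universe)
    go = go_map[go_map["gene_id"].isin(universe)]
    rows = []
    for (go_id, go_name), grp in go.groupby(["go_id", "go_name"], observed=True):
        term_genes = set(grp["gene_id"])
        m = len(term_genes)
        k = len(term_genes & dmgs)
        if min_on == "study" and k < min_term_genes:
            continue
        if min_on == "background" and m < min_term_genes:
            continue
        p = float(hypergeom.sf(k - 1, M, m, K))
        rows.append(
            {"go_id": go_id, "go_name": go_name, "k": k, "K": K, "m": m, "M": M, "p_value": p}
        )
    out = pd.DataFrame(rows, columns=["go_id", "go_name", "k", "K", "m", "M", "p_value"])
    if bh_correct and len(out):
        from scipy.stats import false_discovery_control

        out["p_adjusted"] = false_discovery_control(out["p_value"], method="bh")
    return out.sort_values(["p_value", "go_id"]).reset_index(drop=True)


def join_annotations(dmgs: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Left-join a gene -> class/note table onto the DMG table; genes absent
    from the table keep an empty class."""
    ann = annotation.drop_duplicates("gene_id")
    extra = [c for c in ann.columns if c != "gene_id"]
    out = dmgs.merge(ann, on="gene_id", how="left")
    for c in extra:
        out[c] = out[c].fillna("")
    return out
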