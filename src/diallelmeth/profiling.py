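"""Site-level methylation profiling.

Methylation level of a restriction site is its reads-per-million (RPM):
count / library size * 1e6.  Element-level methylation is the sum of the RPM
of the member sites.  Sites are assigned to genomic elements (gene body,
2 kb flanks, TE, intergenic; exon/intron when exon models are available) with
multi-membership allowed, plus a single ``primary_element`` per site for
distribution summaries, chosen by the fixed gene-centric priority
gene_body > upstream2k > downstream2k > TE > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .types import (
    ELEMENT_PRIORITY,
    GeneFeature,
    SiteCountTable,
    TeFeature,
    Thresholds,
)


@dataclass
class MethylationProfile:
    """RPM matrix plus per-site element annotation."""

    table: SiteCountTable
    rpm: np.ndarray  # sites x samples
    memberships: pd.DataFrame | None = None  # boolean columns per element label
    primary_element: pd.Series | None = None

    def rpm_frame(self) -> pd.DataFrame:
        out = self.table.sites.copy()
        for j, s in enumerate(self.table.samples):
            out[s] = self.rpm[:, j]
        return out


def compute_rpm(
    table: SiteCountTable, library_sizes: np.ndarray | None = None
) -> MethylationProfile:
    """RPM[i, s] = counts[i, s] / library_size[s] * 1e6.

    ``library_sizes`` overrides the table's (e.g. per-context sums); the
    default joint column sums make every sample's RPM total exactly 1e6.
    """
    sizes = table.library_sizes if library_sizes is None else np.asarray(library_sizes)
    if (sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    rpm = table.counts / sizes[np.newaxis, :] * 1e6
    return MethylationProfile(table=table, rpm=rpm)


def _interval_trees(features, start_attr="start", end_attr="end"):
    trees: dict[str, IntervalTree] = {}
    for f in features:
        # IntervalTree is half-open; +1 on the inclusive end
        trees.setdefault(f.chrom, IntervalTree()).addi(
            getattr(f, start_attr), getattr(f, end_attr) + 1, f
        )
    return trees


def _flank_windows(gene: GeneFeature, flank: int) -> dict[str, tuple[int, int]]:
    """Strand-aware upstream/downstream windows, excluding the gene body."""
    before = (max(1, gene.start - flank), gene.start - 1)
    after = (gene.end + 1, gene.end + flank)
    if gene.strand == "+":
        return {"upstream2k": before, "downstream2k": after}
    return {"upstream2k": after, "downstream2k": before}


def assign_elements(
    profile: MethylationProfile,
    genes: list[GeneFeature],
    tes: list[TeFeature],
    exons: list[tuple[str, int, int]] | None = None,
    flank: int = 2000,
) -> MethylationProfile:
    """Annotate every site with element memberships and a primary label.

    Memberships are per-feature: a site in one gene's body and another gene's
    flank carries both labels.  Exon/intron sub-labels are filled only when
    ``exons`` is given; intron = in a gene body but in no exon.
    """
    sites = profile.table.sites
    gene_trees = _interval_trees(genes)
    te_trees = _interval_trees(tes)
    flank_trees: dict[str, dict[str, IntervalTree]] = {"upstream2k": {}, "downstream2k": {}}
    for g in genes:
        for label, (lo, hi) in _flank_windows(g, flank).items():
            if lo <= hi:
                flank_trees[label].setdefault(g.chrom, IntervalTree()).addi(lo, hi + 1, g)
    exon_trees: dict[str, IntervalTree] = {}
    if exons:
        for chrom, start, end in exons:
            exon_trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)

    labels = ["gene_body", "exon", "intron", "upstream2k", "downstream2k", "TE", "intergenic"]
    member = {lab: np.zeros(len(sites), dtype=bool) for lab in labels}
    chroms = sites["chrom"].to_numpy()
    poss = sites["pos"].to_numpy()
    for i in range(len(sites)):
        chrom, pos = chroms[i], int(poss[i])
        in_gene = chrom in gene_trees and bool(gene_trees[chrom][pos])
        member["gene_body"][i] = in_gene
        if in_gene and exon_trees:
            in_exon = chrom in exon_trees and bool(exon_trees[chrom][pos])
            member["exon"][i] = in_exon
            member["intron"][i] = not in_exon
        for lab in ("upstream2k", "downstream2k"):
            tree = flank_trees[lab].get(chrom)
            member[lab][i] = tree is not None and bool(tree[pos])
        member["TE"][i] = chrom in te_trees and bool(te_trees[chrom][pos])
    none_of = ~(
        member["gene_body"] | member["upstream2k"] | member["downstream2k"] | member["TE"]
    )
    member["intergenic"] = none_of

    primary = np.full(len(sites), "intergenic", dtype=object)
    for lab in reversed(ELEMENT_PRIORITY):
        primary[member[lab]] = lab
    profile.memberships = pd.DataFrame(member, index=sites.index)
    profile.primary_element = pd.Series(primary, index=sites.index, name="primary_element")
    return profile


def detect_hyper_sites(
    profile: MethylationProfile,
    context: str,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Flag sites whose RPM is at least ``hyper_multiple`` (default 5) times
    the mean RPM over all sites of the same context, per sample.

    Returns a boolean frame (context sites x samples); the boundary value is
    included ("at least").
    """
    mask = profile.table.context_mask(context)
    if not mask.any():
        raise ValueError(f"no sites with context {context}")
    sub = profile.rpm[mask]
    threshold = thresholds.hyper_multiple * sub.mean(axis=0)
    flags = sub >= threshold[np.newaxis, :]
    out = profile.table.sites.loc[mask, ["chrom", "pos", "context"]].reset_index(drop=True)
    for j, s in enumerate(profile.table.samples):
        out[s] = flags[:, j]
    return out


def paired_t_test(x, y) -> tuple[float, float]:
    """Classical paired t-test on two matched value vectors.

    Returns (t, two-sided p).  Degenerate inputs follow fixed conventions:
    all-identical pairs give (0, 1); a constant nonzero difference gives
    (signed inf, 0) — a sure difference with no within-pair variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired_t_test needs two equal-length vectors, n >= 2")
    d = x - y
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return 0.0, 1.0
        return float(np.sign(d[0]) * np.inf), 0.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def summarize_regions(profile: MethylationProfile) -> dict[str, pd.DataFrame]:
    """Per (sample, context, element) mean and summed site RPM, the global
    per-sample means, and the distribution of sites over primary elements.

    The element summed level is the sum of member-site RPM; distribution
    ratios use the single primary label and sum to 1 within each context.
    """
    if profile.memberships is None:
        raise ValueError("assign_elements must run before summarize_regions")
    sites = profile.table.sites
    samples = profile.table.samples
    rows = []
    for context in sites["context"].unique():
        cmask = profile.table.context_mask(context)
        for element in profile.memberships.columns:
            emask = cmask & profile.memberships[element].to_numpy()
            if not emask.any():
                continue
            sub = profile.rpm[emask]
            for j, s in enumerate(samples):
                rows.append(
                    {
                        "sample": s,
                        "context": context,
                        "element": element,
                        "n_sites": int(emask.sum()),
                        "mean_rpm": sub[:, j].mean(),
                        "summed_rpm": sub[:, j].sum(),
                    }
                )
    region = pd.DataFrame(rows)
    glob = []
    for context in sites["context"].unique():
        cmask = profile.table.context_mask(context)
        for j, s in enumerate(samples):
            glob.append(
                {
                    "sample": s,
                    "context": context,
                    "mean_rpm": profile.rpm[cmask, j].mean(),
                }
            )
    dist = (
        pd.DataFrame(
            {
                "context": sites["context"],
                "primary_element": profile.primary_element,
            }
        )
        .groupby(["context", "primary_element"], observed=True)
        .size()
        .rename("n_sites")
        .reset_index()
    )
    dist["ratio"] = dist["n_sites"] / dist.groupby("context")["n_sites"].transform("sum")
    return {
        "region_summary": region,
        "global_summary": pd.DataFrame(glob),
        "element_distribution": dist,
    }
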