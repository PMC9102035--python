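"""Parental-category stratification and non-additive inheritance patterns.

Each site is first stratified by the parents' methylation relationship:
``A_gt_B`` / ``B_gt_A`` (the parents are a significant DMS pair in the stated
direction), ``equal_zero`` (no methylation detected in either parent — both
raw counts zero), or ``equal_pos`` otherwise.

A hybrid's inheritance at a site is Additive when the hybrid is not a DMS
against the mid-parent value.  Non-additive sites fall in six patterns:

* parents unequal — ``HP`` / ``LP``: hybrid similar to the high / low parent
  (not a DMS against that parent); ``GT_HP`` / ``LT_LP``: hybrid
  significantly beyond the high / low parent.
* parents equal — ``Above`` / ``Below``: hybrid above / below the common
  parental level (direction of the vs-MPV fold change; at equal parents the
  MPV is the parental level, so no further test is needed).

"Similar to a parent" is operationalised as "not a significant DMS vs that
parent" under the same test and thresholds — the only internally consistent
reading, since no numeric similarity band exists.  A hybrid significantly
different from both parents yet strictly between them is outside the six
patterns; it is assigned the nearer parent's label (smaller |log2fc|; tie ->
LP) and flagged ``between_parents`` so it can be excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def classify_parental_category(
    dms_parents: pd.DataFrame,
    counts_a: np.ndarray,
    counts_b: np.ndarray,
) -> pd.Series:
    """Per-site parental category from the parent-vs-parent DMS table.

    ``dms_parents`` must come from comparing parent A (sample_a) with parent B
    (sample_b), so log2fc < 0 means A is the higher parent.
    """
    counts_a = np.asarray(counts_a)
    counts_b = np.asarray(counts_b)
    sig = dms_parents["significant"].to_numpy()
    lfc = dms_parents["log2fc"].to_numpy()
    cat = np.full(len(dms_parents), "equal_pos", dtype=object)
    cat[(counts_a == 0) & (counts_b == 0)] = "equal_zero"
    cat[sig & (lfc < 0)] = "A_gt_B"
    cat[sig & (lfc > 0)] = "B_gt_A"
    return pd.Series(cat, index=dms_parents.index, name="parental_category")


def classify_patterns(
    sites: pd.DataFrame,
    hybrid: str,
    category: pd.Series,
    dms_vs_mpv: pd.DataFrame,
    dms_vs_parent_a: pd.DataFrame,
    dms_vs_parent_b: pd.DataFrame,
) -> pd.DataFrame:
    """Pattern calls for one hybrid over all sites.

    The three DMS tables must share the site universe; the vs-parent tables
    are the hybrid against parent A and parent B (hybrid as sample_b, so
    log2fc > 0 means the hybrid is above that parent).  Returns one row per
    site with ``label``, ``direction_vs_mpv`` and the ``between_parents``
    flag.
    """
    n = len(sites)
    for df, name in (
        (dms_vs_mpv, "vs_mpv"),
        (dms_vs_parent_a, "vs_parent_a"),
        (dms_vs_parent_b, "vs_parent_b"),
    ):
        if len(df) != n:
            raise ValueError(f"site universes differ: {name} has {len(df)} rows, sites {n}")

    cat = category.to_numpy()
    mpv_sig = dms_vs_mpv["significant"].to_numpy()
    mpv_lfc = dms_vs_mpv["log2fc"].to_numpy()
    a_sig = dms_vs_parent_a["significant"].to_numpy()
    a_lfc = dms_vs_parent_a["log2fc"].to_numpy()
    b_sig = dms_vs_parent_b["significant"].to_numpy()
    b_lfc = dms_vs_parent_b["log2fc"].to_numpy()

    # orient per site to high/low parent from the parental category
    a_high = cat == "A_gt_B"
    b_high = cat == "B_gt_A"
    unequal = a_high | b_high
    hi_sig = np.where(a_high, a_sig, b_sig)
    hi_lfc = np.where(a_high, a_lfc, b_lfc)
    lo_sig = np.where(a_high, b_sig, a_sig)
    lo_lfc = np.where(a_high, b_lfc, a_lfc)

    label = np.full(n, "Additive", dtype=object)
    between = np.zeros(n, dtype=bool)

    nonadd = mpv_sig
    equal = nonadd & ~unequal
    label[equal & (mpv_lfc > 0)] = "Above"
    label[equal & (mpv_lfc <= 0)] = "Below"

    une = nonadd & unequal
    gt_hp = une & hi_sig & (hi_lfc > 0)
    lt_lp = une & lo_sig & (lo_lfc < 0)
    rest = une & ~gt_hp & ~lt_lp
    near_hp = np.abs(hi_lfc) < np.abs(lo_lfc)  # tie -> LP
    ns_both = rest & ~hi_sig & ~lo_sig
    hp_only = rest & ~hi_sig & lo_sig
    lp_only = rest & hi_sig & ~lo_sig
    sig_both = rest & hi_sig & lo_sig  # between the parents, unlike both
    label[gt_hp] = "GT_HP"
    label[lt_lp] = "LT_LP"
    label[hp_only] = "HP"
    label[lp_only] = "LP"
    label[ns_both & near_hp] = "HP"
    label[ns_both & ~near_hp] = "LP"
    label[sig_both & near_hp] = "HP"
    label[sig_both & ~near_hp] = "LP"
    between[sig_both] = True

    direction = np.where(mpv_sig & (mpv_lfc > 0), "hyper",
                         np.where(mpv_sig, "hypo", "none"))
    out = sites[["chrom", "pos", "context"]].copy()
    out["hybrid"] = hybrid
    out["parental_category"] = cat
    out["label"] = label
    out["direction_vs_mpv"] = direction
    out["between_parents"] = between
    out["log2fc_vs_mpv"] = mpv_lfc
    out["p_vs_mpv"] = dms_vs_mpv["p_value"].to_numpy()
    return out


def tabulate_patterns(
    calls: pd.DataFrame, primary_element: pd.Series | None = None
) -> dict[str, pd.DataFrame]:
    """Summaries of non-additive pattern calls.

    Returns counts and proportions per (hybrid, context, label), the split by
    parental category, the hyper/hypo split vs MPV, and — when a primary
    element annotation is supplied (aligned with the call rows of one hybrid)
    — the genomic-element distribution of non-additive DMSs.
    """
    nonadd = calls[calls["label"] != "Additive"]
    by_label = (
        nonadd.groupby(["hybrid", "context", "label"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    if len(by_label):
        by_label["proportion"] = by_label["n"] / by_label.groupby(
            ["hybrid", "context"], observed=True
        )["n"].transform("sum")
    else:
        by_label["proportion"] = pd.Series(dtype=float)
    by_category = (
        nonadd.groupby(["hybrid", "context", "parental_category"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    by_direction = (
        nonadd.groupby(["hybrid", "context", "direction_vs_mpv"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    out = {
        "pattern_counts": by_label,
        "pattern_by_category": by_category,
        "pattern_by_direction": by_direction,
    }
    if primary_element is not None:
        ann = calls.copy()
        ann["primary_element"] = primary_element.to_numpy()
        out["pattern_by_element"] = (
            ann[ann["label"] != "Additive"]
            .groupby(["hybrid", "context", "primary_element"], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )
    return out
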