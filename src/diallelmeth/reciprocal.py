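"""Reciprocal-hybrid layer: parent-of-origin inheritance of methylation.

For a combination (F_ab, F_ba) of reciprocal crosses of parents A and B:

* **HDS** — sites significantly different between the two reciprocal hybrids;
* **PDS** — sites significantly different between the two parents;
* **Ins** — the intersection HDS ∩ PDS;
* **PSD** — parental-selective-difference sites: Ins sites where each hybrid
  inherited its own maternal (or each its own paternal) parent's methylation
  status.  "Inherited parent X's status" is operationalised as *not* a DMS
  against X *and* a DMS against the other parent, under one threshold set.
  Ins sites where both hybrids match one fixed parent are flagged
  ``uniparental`` (they fail the simultaneous-own-parent rule).

Non-additive pattern calls of the two reciprocal hybrids are merged into
reciprocal non-additive DMSs when both labels fall in one similarity class:
{HP, GT_HP}, {LP, LT_LP}, {Above}, {Below}.  A mixed class reports the
non-extreme member (HP or LP) as the pair label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import CrossDesign

SIMILARITY_CLASSES = {
    "HP": "HP",
    "GT_HP": "HP",
    "LP": "LP",
    "LT_LP": "LP",
    "Above": "Above",
    "Below": "Below",
}


@dataclass
class ReciprocalSets:
    """Per-combination site sets as a boolean frame (one row per site)."""

    combination: str
    sites: pd.DataFrame  # chrom, pos, context
    hds: np.ndarray
    pds: np.ndarray
    ins: np.ndarray
    psd_mode: np.ndarray  # 'none' | 'maternal' | 'paternal' | 'uniparental' | 'other'

    def frame(self) -> pd.DataFrame:
        out = self.sites[["chrom", "pos", "context"]].copy()
        out["combination"] = self.combination
        out["hds"] = self.hds
        out["pds"] = self.pds
        out["ins"] = self.ins
        out["psd_mode"] = self.psd_mode
        return out


def _match(sig_vs: np.ndarray) -> np.ndarray:
    """A hybrid 'matches' a parent when it is not a DMS against it."""
    return ~sig_vs


def build_reciprocal_sets(
    combination: str,
    sites: pd.DataFrame,
    dms_hybrids: pd.DataFrame,
    dms_parents: pd.DataFrame,
    sig_fab_vs_mat: np.ndarray,
    sig_fab_vs_pat: np.ndarray,
    sig_fba_vs_mat: np.ndarray,
    sig_fba_vs_pat: np.ndarray,
    psd_rule: str = "strict",
) -> ReciprocalSets:
    """HDS/PDS/Ins/PSD for one reciprocal combination.

    ``sig_fab_vs_mat`` etc. are per-site significance vectors of each hybrid
    against its own maternal / paternal parent (F_ab's maternal parent is A,
    F_ba's is B).  ``psd_rule='strict'`` requires each hybrid to be
    non-different from the designated parent AND different from the other;
    ``'nearest'`` only requires it to be non-different from the designated
    parent.
    """
    n = len(sites)
    for arr in (sig_fab_vs_mat, sig_fab_vs_pat, sig_fba_vs_mat, sig_fba_vs_pat):
        if len(arr) != n:
            raise ValueError("per-parent significance vectors must match the site universe")
    hds = dms_hybrids["significant"].to_numpy()
    pds = dms_parents["significant"].to_numpy()
    ins = hds & pds

    fab_m = _match(sig_fab_vs_mat)
    fab_p = _match(sig_fab_vs_pat)
    fba_m = _match(sig_fba_vs_mat)
    fba_p = _match(sig_fba_vs_pat)
    if psd_rule == "strict":
        maternal = fab_m & sig_fab_vs_pat & fba_m & sig_fba_vs_pat
        paternal = fab_p & sig_fab_vs_mat & fba_p & sig_fba_vs_mat
        # both hybrids stuck to one fixed parent (A for both, or B for both)
        uni_a = fab_m & sig_fab_vs_pat & fba_p & sig_fba_vs_mat
        uni_b = fab_p & sig_fab_vs_mat & fba_m & sig_fba_vs_pat
    elif psd_rule == "nearest":
        maternal = fab_m & fba_m & ~(fab_p & fba_p)
        paternal = fab_p & fba_p & ~(fab_m & fba_m)
        uni_a = fab_m & fba_p & ~maternal & ~paternal
        uni_b = fab_p & fba_m & ~maternal & ~paternal
    else:
        raise ValueError(f"unknown psd_rule {psd_rule!r}")

    mode = np.full(n, "none", dtype=object)
    mode[ins & (uni_a | uni_b)] = "uniparental"
    mode[ins & maternal] = "maternal"
    mode[ins & paternal] = "paternal"
    mode[ins & (mode == "none")] = "other"
    mode[~ins] = "none"
    return ReciprocalSets(combination, sites, hds, pds, ins, mode)


def merge_reciprocal_nonadditive(
    combination: str,
    calls_fab: pd.DataFrame,
    calls_fba: pd.DataFrame,
) -> pd.DataFrame:
    """Merge the two reciprocal hybrids' pattern calls at each site.

    Emits a row only where both hybrids carry a non-additive label from the
    same similarity class; ``pair_label`` is the class representative (HP for
    any {HP, GT_HP} mix, LP for {LP, LT_LP}, the shared label otherwise).
    """
    if len(calls_fab) != len(calls_fba):
        raise ValueError("reciprocal call tables must share the site universe")
    la = calls_fab["label"].to_numpy()
    lb = calls_fba["label"].to_numpy()
    cls_a = np.array([SIMILARITY_CLASSES.get(x, "") for x in la], dtype=object)
    cls_b = np.array([SIMILARITY_CLASSES.get(x, "") for x in lb], dtype=object)
    keep = (cls_a != "") & (cls_a == cls_b)
    pair = np.where(la == lb, la, cls_a)  # identical labels kept; mix -> class rep
    out = calls_fab.loc[keep, ["chrom", "pos", "context", "parental_category"]].copy()
    out["combination"] = combination
    out["label_a"] = la[keep]
    out["label_b"] = lb[keep]
    out["pair_label"] = pair[keep]
    out["parental_region"] = np.where(
        out["parental_category"].isin(["A_gt_B", "B_gt_A"]), "unequal", "equal"
    )
    return out.reset_index(drop=True)


def summarize_reciprocal(
    sets: ReciprocalSets,
    merged: pd.DataFrame,
    primary_element: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-combination, per-context summary of the reciprocal layer.

    Ratios with an empty denominator are reported as NaN (undefined), never 0.
    """
    frame = sets.frame()
    rows = []
    for context, sub in frame.groupby("context", observed=True):
        n_hds = int(sub["hds"].sum())
        n_pds = int(sub["pds"].sum())
        n_ins = int(sub["ins"].sum())
        n_mat = int((sub["psd_mode"] == "maternal").sum())
        n_pat = int((sub["psd_mode"] == "paternal").sum())
        n_uni = int((sub["psd_mode"] == "uniparental").sum())
        n_psd = n_mat + n_pat
        rows.append(
            {
                "combination": sets.combination,
                "context": context,
                "n_hds": n_hds,
                "n_pds": n_pds,
                "n_ins": n_ins,
                "n_psd": n_psd,
                "n_psd_maternal": n_mat,
                "n_psd_paternal": n_pat,
                "n_uniparental": n_uni,
                "ins_over_hds": n_ins / n_hds if n_hds else np.nan,
                "ins_over_pds": n_ins / n_pds if n_pds else np.nan,
                "psd_over_ins": n_psd / n_ins if n_ins else np.nan,
                "psd_over_hds": n_psd / n_hds if n_hds else np.nan,
            }
        )
    pair_counts = (
        merged.groupby(["combination", "context", "pair_label"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    if len(pair_counts):
        pair_counts["proportion"] = pair_counts["n"] / pair_counts.groupby(
            ["combination", "context"], observed=True
        )["n"].transform("sum")
    region_split = (
        merged.groupby(["combination", "context", "parental_region"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    out = {
        "reciprocal_summary": pd.DataFrame(rows),
        "pair_label_counts": pair_counts,
        "parental_region_split": region_split,
    }
    if primary_element is not None and len(merged):
        key = primary_element.copy()
        key.index = pd.MultiIndex.from_frame(
            sets.sites[["chrom", "pos", "context"]]
        )
        midx = pd.MultiIndex.from_frame(merged[["chrom", "pos", "context"]])
        ann = merged.copy()
        ann["primary_element"] = key.loc[midx].to_numpy()
        out["element_distribution"] = (
            ann.groupby(["combination", "context", "primary_element"], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )
    return out


def reciprocal_swap_check(sets_fwd: ReciprocalSets, sets_swapped: ReciprocalSets) -> bool:
    """True when swapping the two hybrids' roles swaps maternal<->paternal."""
    swap = {"maternal": "paternal", "paternal": "maternal"}
    expected = np.array(
        [swap.get(m, m) for m in sets_fwd.psd_mode], dtype=object
    )
    return bool(np.array_equal(expected, sets_swapped.psd_mode))
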