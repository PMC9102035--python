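"""Scoring of pipeline output against the simulator's spike-in truth.

All metrics are computed over (hybrid, site) pairs: a pair is truth
non-additive when the truth table's infinite-data label for that hybrid is
not Additive, and called non-additive when the classifier labelled it so.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pipeline import PipelineResult
from .types import CrossDesign


def truth_pairs(truth: pd.DataFrame, design: CrossDesign) -> pd.DataFrame:
    """Long form of the truth table: one row per (site, hybrid) with the true
    label, restricted to the combination each spike targets."""
    combo_hyb = {name: (a, b) for name, a, b in design.combinations}
    rows = []
    for row in truth.itertuples(index=False):
        if not row.combination or pd.isna(row.combination):
            continue
        fab, fba = combo_hyb[row.combination]
        rows.append(
            {
                "site_index": row.site_index,
                "combination": row.combination,
                "hybrid": fab,
                "true_label": row.pattern_a,
                "psd_mode": row.psd_mode,
            }
        )
        rows.append(
            {
                "site_index": row.site_index,
                "combination": row.combination,
                "hybrid": fba,
                "true_label": row.pattern_b,
                "psd_mode": row.psd_mode,
            }
        )
    return pd.DataFrame(rows)


def evaluate_patterns(result: PipelineResult, truth: pd.DataFrame, design: CrossDesign) -> dict:
    """Sensitivity/FDR of the non-additive DMS call and six-way label accuracy.

    Sensitivity: truth non-additive pairs called non-additive.  FDR: called
    non-additive pairs whose truth is additive (unspiked sites are additive
    by construction).  Label accuracy: exact six-way agreement among true
    positives.
    """
    pairs = truth_pairs(truth, design)
    truth_nonadd = pairs[pairs["true_label"] != "Additive"]
    truth_lookup = {
        (r.hybrid, r.site_index): r.true_label for r in pairs.itertuples(index=False)
    }

    tp = fn = 0
    correct = 0
    for r in truth_nonadd.itertuples(index=False):
        called = result.pattern_calls[r.hybrid]["label"].iat[r.site_index]
        if called != "Additive":
            tp += 1
            if called == r.true_label:
                correct += 1
        else:
            fn += 1

    n_called = fp = 0
    for hyb, calls in result.pattern_calls.items():
        called_idx = np.nonzero((calls["label"] != "Additive").to_numpy())[0]
        n_called += len(called_idx)
        for i in called_idx:
            if truth_lookup.get((hyb, int(i)), "Additive") == "Additive":
                fp += 1
    return {
        "n_truth_nonadditive": len(truth_nonadd),
        "n_called_nonadditive": n_called,
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "fdr": fp / n_called if n_called else np.nan,
        "label_accuracy": correct / tp if tp else np.nan,
    }


def evaluate_psd(result: PipelineResult, truth: pd.DataFrame) -> dict:
    """PSD recall among spiked Ins sites and maternal/paternal attribution
    accuracy among called PSD sites that carry a truth mode."""
    spiked = truth[truth["psd_mode"].isin(["maternal", "paternal"])]
    truth_mode = {
        (r.combination, r.site_index): r.psd_mode for r in spiked.itertuples(index=False)
    }
    in_ins = called_psd_on_spiked = correct = 0
    n_called_psd = false_psd = 0
    mat_in_ins = mat_called = 0
    for combo, sets in result.reciprocal_sets.items():
        mode = sets.psd_mode
        for (c2, i), tmode in truth_mode.items():
            if c2 != combo:
                continue
            if sets.ins[i]:
                in_ins += 1
                if tmode == "maternal":
                    mat_in_ins += 1
                    if mode[i] == "maternal":
                        mat_called += 1
                if mode[i] in ("maternal", "paternal"):
                    called_psd_on_spiked += 1
                    if mode[i] == tmode:
                        correct += 1
        called_idx = np.nonzero(np.isin(mode, ["maternal", "paternal"]))[0]
        n_called_psd += len(called_idx)
        for i in called_idx:
            if (combo, int(i)) not in truth_mode:
                false_psd += 1
    return {
        "n_spiked_psd_in_ins": in_ins,
        "n_called_psd": n_called_psd,
        "n_false_psd": false_psd,
        "psd_recall_in_ins": called_psd_on_spiked / in_ins if in_ins else np.nan,
        "maternal_recall_in_ins": mat_called / mat_in_ins if mat_in_ins else np.nan,
        "attribution_accuracy": correct / called_psd_on_spiked
        if called_psd_on_spiked
        else np.nan,
    }


def evaluate_parent_dms(result: PipelineResult, truth: pd.DataFrame, design: CrossDesign) -> dict:
    """Recall of the spiked parental divergence (per targeted combination)."""
    parent_of = {}
    for combo, fab, _ in design.combinations:
        pa, _m = design.hybrid_parents(fab)
        parent_of[combo] = combo
    spiked = truth[truth["parental_category"].isin(["A_gt_B", "B_gt_A"])]
    tp = n = 0
    for r in spiked.itertuples(index=False):
        combo = r.combination
        fab = next(a for name, a, b in design.combinations if name == combo)
        fba = next(b for name, a, b in design.combinations if name == combo)
        pa, _ = design.hybrid_parents(fab)
        pb, _ = design.hybrid_parents(fba)
        dms = result.comparisons[(pa, pb)]
        n += 1
        if dms["significant"].iat[r.site_index]:
            lfc = dms["log2fc"].iat[r.site_index]
            called = "A_gt_B" if lfc < 0 else "B_gt_A"
            if called == r.parental_category:
                tp += 1
    return {"n_spiked_parent_dms": n, "parent_dms_recall": tp / n if n else np.nan}
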