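import numpy as np
import pandas as pd
import pytest

from diallelmeth import patterns
from diallelmeth.types import PATTERN_LABELS


def dms_frame(sig, lfc):
    n = len(sig)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n + 1),
            "context": "CCGG",
            "log2fc": lfc,
            "p_value": np.where(sig, 0.001, 0.5),
            "significant": sig,
        }
    )


def sites_frame(n):
    return pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, n + 1), "context": "CCGG"})


class TestParentalCategory:
    def test_four_categories(self):
        dms = dms_frame(
            sig=[True, True, False, False],
            lfc=[-2.0, 2.0, 0.3, 0.0],
        )
        cat = patterns.classify_parental_category(
            dms, np.array([40, 5, 12, 0]), np.array([10, 20, 10, 0])
        )
        assert list(cat) == ["A_gt_B", "B_gt_A", "equal_pos", "equal_zero"]

    def test_swap_parents_mirrors_direction(self):
        dms_ab = dms_frame([True], [-2.0])
        dms_ba = dms_frame([True], [2.0])
        a, b = np.array([40]), np.array([10])
        assert patterns.classify_parental_category(dms_ab, a, b)[0] == "A_gt_B"
        assert patterns.classify_parental_category(dms_ba, b, a)[0] == "B_gt_A"


class TestPatternRules:
    """Constructed comparisons exercising each decision branch.

    Sites: parents A=400, B=100 rpm except where noted; hybrid as stated.
    """

    def build(self, category, mpv, vs_a, vs_b):
        cat = pd.Series([category])
        calls = patterns.classify_patterns(
            sites_frame(1), "F12", cat,
            dms_frame([mpv[0]], [mpv[1]]),
            dms_frame([vs_a[0]], [vs_a[1]]),
            dms_frame([vs_b[0]], [vs_b[1]]),
        )
        return calls.iloc[0]

    def test_additive_when_not_significant_vs_mpv(self):
        assert self.build("A_gt_B", (False, 0.5), (False, 0), (False, 0))["label"] == "Additive"

    def test_below_on_equal_parents(self):
        row = self.build("equal_pos", (True, -3.3), (True, -3.3), (True, -3.3))
        assert row["label"] == "Below" and row["direction_vs_mpv"] == "hypo"

    def test_above_on_parentally_unmethylated_site(self):
        row = self.build("equal_zero", (True, 4.0), (True, 4.0), (True, 4.0))
        assert row["label"] == "Above" and row["direction_vs_mpv"] == "hyper"

    def test_hp_similar_to_high_parent(self):
        # hybrid 400 = high parent A; significant vs MPV 250, ns vs A, sig vs B
        row = self.build("A_gt_B", (True, 1.1), (False, 0.0), (True, 2.0))
        assert row["label"] == "HP" and not row["between_parents"]

    def test_lp_similar_to_low_parent(self):
        row = self.build("A_gt_B", (True, -1.2), (True, -2.0), (False, 0.0))
        assert row["label"] == "LP"

    def test_gt_hp_beyond_high_parent(self):
        row = self.build("A_gt_B", (True, 2.7), (True, 2.0), (True, 4.0))
        assert row["label"] == "GT_HP"

    def test_lt_lp_beyond_low_parent(self):
        row = self.build("A_gt_B", (True, -4.2), (True, -5.0), (True, -3.0))
        assert row["label"] == "LT_LP"

    def test_between_parents_flagged_and_assigned_nearer(self):
        # significantly different from both but strictly between: nearer = A
        row = self.build("A_gt_B", (True, 1.05), (True, -1.1), (True, 1.5))
        assert row["label"] == "HP" and row["between_parents"]

    def test_labels_exhaustive_and_exclusive(self, small_result):
        for hyb, calls in small_result.pattern_calls.items():
            assert calls["label"].isin(PATTERN_LABELS).all()
            assert len(calls) == len(small_result.profile.table.sites)


class TestRelabelInvariance:
    def test_parent_swap_leaves_pattern_labels_invariant(self):
        """Swapping which parent is 'A' flips the category but not the six
        inheritance labels."""
        sig = [True]
        cat_fwd = pd.Series(["A_gt_B"])
        cat_rev = pd.Series(["B_gt_A"])
        mpv = dms_frame(sig, [2.7])
        vs_hi = dms_frame(sig, [2.0])
        vs_lo = dms_frame(sig, [4.0])
        fwd = patterns.classify_patterns(sites_frame(1), "H", cat_fwd, mpv, vs_hi, vs_lo)
        rev = patterns.classify_patterns(sites_frame(1), "H", cat_rev, mpv, vs_lo, vs_hi)
        assert fwd["label"].iloc[0] == rev["label"].iloc[0] == "GT_HP"


class TestTabulate:
    def test_proportions_sum_to_one_per_hybrid_context(self, small_result):
        counts = patterns.tabulate_patterns(
            pd.concat(small_result.pattern_calls.values(), ignore_index=True)
        )["pattern_counts"]
        sums = counts.groupby(["hybrid", "context"])["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_all_additive_gives_empty_table(self):
        calls = pd.DataFrame(
            {
                "chrom": "chr1", "pos": [1, 2], "context": "CCGG",
                "hybrid": "F12", "parental_category": "equal_pos",
                "label": "Additive", "direction_vs_mpv": "none",
            }
        )
        assert len(patterns.tabulate_patterns(calls)["pattern_counts"]) == 0

    def test_simple_proportions(self):
        calls = pd.DataFrame(
            {
                "chrom": "chr1", "pos": [1, 2, 3, 4], "context": "CCGG",
                "hybrid": "F12", "parental_category": "equal_pos",
                "label": ["Below", "Below", "Below", "Above"],
                "direction_vs_mpv": ["hypo", "hypo", "hypo", "hyper"],
            }
        )
        counts = patterns.tabulate_patterns(calls)["pattern_counts"]
        assert dict(zip(counts["label"], counts["proportion"])) == {
            "Above": 0.25, "Below": 0.75,
        }
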