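import numpy as np
import pandas as pd
import pytest

from diallelmeth import reciprocal


def sites_frame(n):
    return pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, n + 1), "context": "CCGG"})


def sig_frame(sig):
    return pd.DataFrame({"significant": np.asarray(sig, dtype=bool)})


def build(hds, pds, fab_mat, fab_pat, fba_mat, fba_pat, rule="strict"):
    n = len(hds)
    return reciprocal.build_reciprocal_sets(
        "F1221", sites_frame(n), sig_frame(hds), sig_frame(pds),
        np.asarray(fab_mat, dtype=bool), np.asarray(fab_pat, dtype=bool),
        np.asarray(fba_mat, dtype=bool), np.asarray(fba_pat, dtype=bool),
        psd_rule=rule,
    )


class TestPsdCalling:
    def test_maternal_psd(self):
        # F12 ~ P1 (ns vs maternal, sig vs paternal); F21 ~ P2 likewise
        sets = build([1], [1], [0], [1], [0], [1])
        assert sets.psd_mode[0] == "maternal"

    def test_paternal_psd(self):
        sets = build([1], [1], [1], [0], [1], [0])
        assert sets.psd_mode[0] == "paternal"

    def test_uniparental_both_match_same_fixed_parent(self):
        # F12 ~ P1 (its maternal) and F21 ~ P1 (its paternal): Ins but not PSD
        sets = build([1], [1], [0], [1], [1], [0])
        assert sets.psd_mode[0] == "uniparental"
        sets2 = build([1], [1], [1], [0], [0], [1])  # both match P2
        assert sets2.psd_mode[0] == "uniparental"

    def test_all_four_match_configurations_enumerated(self):
        """Of the 4 clean one-parent-per-hybrid configurations, exactly the
        two own-parent-symmetric ones qualify as PSD."""
        modes = set()
        for fab_to_p1 in (True, False):
            for fba_to_p1 in (True, False):
                sets = build(
                    [1], [1],
                    [0 if fab_to_p1 else 1], [1 if fab_to_p1 else 0],
                    [1 if fba_to_p1 else 0], [0 if fba_to_p1 else 1],
                )
                modes.add((fab_to_p1, fba_to_p1, sets.psd_mode[0]))
        assert modes == {
            (True, False, "maternal"),
            (False, True, "paternal"),
            (True, True, "uniparental"),
            (False, False, "uniparental"),
        }

    def test_hds_without_pds_excluded_from_ins(self):
        sets = build([1], [0], [0], [1], [0], [1])
        assert not sets.ins[0] and sets.psd_mode[0] == "none"

    def test_set_algebra_invariants_on_simulated_data(self, small_result):
        for sets in small_result.reciprocal_sets.values():
            psd = np.isin(sets.psd_mode, ["maternal", "paternal"])
            assert np.all(psd <= sets.ins)
            assert np.all(sets.ins <= (sets.hds & sets.pds))

    def test_swapping_hybrids_swaps_maternal_paternal(self):
        fab_mat, fab_pat = [0, 1], [1, 0]
        fba_mat, fba_pat = [0, 1], [1, 0]
        fwd = build([1, 1], [1, 1], fab_mat, fab_pat, fba_mat, fba_pat)
        assert list(fwd.psd_mode) == ["maternal", "paternal"]
        # relabelling the two hybrid columns: the sample now called F_ab
        # carries F_ba's data, and parent A is that sample's *paternal*
        # parent — the per-parent vectors permute accordingly
        swapped = build([1, 1], [1, 1], fba_pat, fba_mat, fab_pat, fab_mat)
        assert reciprocal.reciprocal_swap_check(fwd, swapped)


class TestMerge:
    def make_calls(self, labels):
        n = len(labels)
        return pd.DataFrame(
            {
                "chrom": "chr1", "pos": np.arange(1, n + 1), "context": "CCGG",
                "parental_category": "A_gt_B", "label": labels,
            }
        )

    @pytest.mark.parametrize(
        "la,lb,expected",
        [
            ("HP", "GT_HP", "HP"),       # similar trends -> conservative member
            ("Below", "Below", "Below"),  # identical
            ("GT_HP", "GT_HP", "GT_HP"),
            ("LT_LP", "LP", "LP"),
        ],
    )
    def test_emitted_pairs(self, la, lb, expected):
        merged = reciprocal.merge_reciprocal_nonadditive(
            "F1221", self.make_calls([la]), self.make_calls([lb])
        )
        assert len(merged) == 1 and merged["pair_label"].iloc[0] == expected

    @pytest.mark.parametrize(
        "la,lb",
        [("Above", "Below"), ("HP", "LP"), ("Additive", "Below"), ("GT_HP", "LT_LP")],
    )
    def test_discordant_pairs_not_emitted(self, la, lb):
        merged = reciprocal.merge_reciprocal_nonadditive(
            "F1221", self.make_calls([la]), self.make_calls([lb])
        )
        assert len(merged) == 0


class TestSummaries:
    def test_psd_partition_of_ins(self, small_result):
        for combo, sets in small_result.reciprocal_sets.items():
            f = sets.frame()
            ins = f[f["ins"]]
            assert (ins["psd_mode"] != "none").all()
            assert (f.loc[~f["ins"], "psd_mode"] == "none").all()

    def test_empty_hds_gives_nan_ratios_not_zero(self):
        sets = build([0], [0], [0], [0], [0], [0])
        summary = reciprocal.summarize_reciprocal(sets, pd.DataFrame(
            columns=["combination", "context", "pair_label", "parental_region"]
        ))["reciprocal_summary"]
        assert np.isnan(summary["psd_over_hds"].iloc[0])
        assert np.isnan(summary["psd_over_ins"].iloc[0])

    def test_ratios_within_unit_interval(self, small_result):
        summ = small_result.tables["reciprocal_summary"]
        for col in ("ins_over_hds", "psd_over_ins", "psd_over_hds"):
            vals = summ[col].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()
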