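import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diallelmeth import profiling
from diallelmeth.types import GeneFeature, SiteCountTable, TeFeature


def make_table(positions, counts, context="CCGG", chrom="chr1", samples=None):
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "context": context}
    )
    counts = np.asarray(counts)
    if counts.ndim == 1:
        counts = counts[:, None]
    samples = samples or [f"s{i+1}" for i in range(counts.shape[1])]
    return SiteCountTable(sites, counts, samples)


class TestRpm:
    def test_rpm_formula(self):
        t = make_table([1, 2, 3], [2, 3, 5])
        prof = profiling.compute_rpm(t)
        np.testing.assert_allclose(prof.rpm[:, 0], [200000, 300000, 500000])

    def test_scale_invariance(self):
        t1 = make_table([1, 2], [3, 7])
        t2 = make_table([1, 2], [6, 14])
        np.testing.assert_allclose(
            profiling.compute_rpm(t1).rpm, profiling.compute_rpm(t2).rpm
        )

    def test_per_sample_total_is_1e6_with_column_sum_libraries(self, small_dataset):
        prof = profiling.compute_rpm(small_dataset["table"])
        np.testing.assert_allclose(prof.rpm.sum(axis=0), 1e6, rtol=1e-6)


class TestElements:
    GENE = GeneFeature("gA", "chr1", 5000, 8000, "+")
    TE = TeFeature("chr1", 3400, 3600, "te1")

    def assign(self, positions, genes=None, tes=None):
        t = make_table(positions, np.ones(len(positions), dtype=int))
        prof = profiling.compute_rpm(t)
        profiling.assign_elements(
            prof, genes if genes is not None else [self.GENE],
            tes if tes is not None else []
        )
        return prof

    def test_upstream_window_on_plus_strand(self):
        prof = self.assign([3500])
        assert prof.primary_element.iloc[0] == "upstream2k"

    def test_window_boundary_excluded(self):
        prof = self.assign([2999])
        assert prof.primary_element.iloc[0] == "intergenic"

    def test_strand_flips_flanks(self):
        minus = GeneFeature("gB", "chr1", 5000, 8000, "-")
        prof = self.assign([3500, 9000], genes=[minus])
        assert list(prof.primary_element) == ["downstream2k", "upstream2k"]

    def test_priority_gene_body_over_te(self):
        # brute-force check: the site is inside both features
        te = TeFeature("chr1", 6000, 7000, "te2")
        prof = self.assign([6500], tes=[te])
        assert prof.memberships.loc[0, "gene_body"] and prof.memberships.loc[0, "TE"]
        assert prof.primary_element.iloc[0] == "gene_body"

    def test_every_site_gets_exactly_one_primary_label(self, small_result):
        prof = small_result.profile
        assert prof.primary_element.notna().all()
        dist = small_result.tables["element_distribution"]
        sums = dist.groupby("context")["ratio"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_exon_intron_split_when_exons_given(self):
        t = make_table([5500, 6500], [1, 1])
        prof = profiling.compute_rpm(t)
        profiling.assign_elements(prof, [self.GENE], [], exons=[("chr1", 5000, 6000)])
        assert list(prof.memberships["exon"]) == [True, False]
        assert list(prof.memberships["intron"]) == [False, True]


class TestHyperSites:
    def test_boundary_equality_included(self):
        t = make_table([1, 2, 3, 4, 5], [0, 0, 0, 0, 100])
        prof = profiling.compute_rpm(t)
        flags = profiling.detect_hyper_sites(prof, "CCGG")
        assert list(flags["s1"]) == [False, False, False, False, True]

    def test_constant_vector_has_no_hyper_sites(self):
        t = make_table([1, 2, 3], [7, 7, 7])
        prof = profiling.compute_rpm(t)
        assert not profiling.detect_hyper_sites(prof, "CCGG")["s1"].any()

    def test_direct_arithmetic_example(self):
        t = make_table([1, 2, 3, 4, 5], [10, 10, 10, 10, 160])
        prof = profiling.compute_rpm(t)
        # mean 38, threshold 190: the 160-count site (rpm 8e5 < 9.5e5) stays
        assert not profiling.detect_hyper_sites(prof, "CCGG")["s1"].any()

    def test_unknown_context_rejected(self):
        t = make_table([1], [1])
        with pytest.raises(ValueError):
            profiling.detect_hyper_sites(profiling.compute_rpm(t), "CCWGG")


class TestPairedT:
    def test_symmetric_differences_give_t_zero(self):
        t, p = profiling.paired_t_test([1, 0, 1], [0, 1, 1])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_constant_nonzero_difference_is_degenerate(self):
        t, p = profiling.paired_t_test([3, 4, 5, 6], [1, 2, 3, 4])
        assert math.isinf(t) and t > 0 and p == 0.0

    def test_identical_pairs(self):
        assert profiling.paired_t_test([2, 5, 9], [2, 5, 9]) == (0.0, 1.0)

    def test_closed_form_example(self):
        # diffs (1,2,3): t = mean/(sd/sqrt(n)) = 2*sqrt(3)
        t, p = profiling.paired_t_test([2, 4, 6], [1, 2, 3])
        assert t == pytest.approx(2 * math.sqrt(3), abs=1e-9)
        assert p == pytest.approx(0.0742, abs=2e-4)

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        t, p = profiling.paired_t_test(x, y)
        d = x - y
        t_ref = d.mean() / (d.std(ddof=1) / math.sqrt(n))
        from scipy.stats import t as tdist

        p_ref = 2 * tdist.sf(abs(t_ref), n - 1)
        assert t == pytest.approx(t_ref, abs=1e-9)
        assert p == pytest.approx(p_ref, abs=1e-9)


class TestRegionSummary:
    def test_summed_level_is_sum_of_member_site_rpm(self):
        t = make_table([5500, 6500], [1, 3])
        prof = profiling.compute_rpm(t)
        profiling.assign_elements(prof, [TestElements.GENE], [])
        region = profiling.summarize_regions(prof)["region_summary"]
        gb = region[region["element"] == "gene_body"].iloc[0]
        assert gb["summed_rpm"] == pytest.approx(1e6)
        assert gb["mean_rpm"] == pytest.approx(5e5)

    def test_all_intergenic_distribution(self):
        t = make_table([10, 20], [1, 1])
        prof = profiling.compute_rpm(t)
        profiling.assign_elements(prof, [], [])
        dist = profiling.summarize_regions(prof)["element_distribution"]
        assert dist["ratio"].tolist() == [1.0]
        assert dist["primary_element"].tolist() == ["intergenic"]
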