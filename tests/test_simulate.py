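import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diallelmeth.simulate import (
    SimulationConfig,
    infinite_data_label,
    simulate_counts,
    simulate_dataset,
    simulate_genome,
)


class TestGenome:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=3, n_chrom=2, chrom_len=300_000, n_genes=40,
                               n_te=30, n_sites_per_context=300, library_size_mean=50_000)
        g1, t1, s1 = simulate_genome(cfg)
        g2, t2, s2 = simulate_genome(cfg)
        assert g1 == g2 and t1 == t2
        pd.testing.assert_frame_equal(s1, s2)

    def test_site_counts_per_context_exact(self):
        cfg = SimulationConfig(seed=3, n_chrom=2, chrom_len=300_000, n_genes=40,
                               n_te=30, n_sites_per_context=250, library_size_mean=50_000)
        _, _, sites = simulate_genome(cfg)
        assert sites["context"].value_counts().to_dict() == {"CCGG": 250, "CCWGG": 250}

    def test_genes_do_not_overlap(self):
        cfg = SimulationConfig(seed=5, n_chrom=2, chrom_len=400_000, n_genes=60,
                               n_te=10, n_sites_per_context=100, library_size_mean=50_000)
        genes, _, _ = simulate_genome(cfg)
        for chrom in {g.chrom for g in genes}:
            spans = sorted((g.start, g.end) for g in genes if g.chrom == chrom)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2

    def test_no_genes_means_no_genic_sites(self):
        cfg = SimulationConfig(seed=5, n_chrom=1, chrom_len=200_000, n_genes=0,
                               n_te=20, n_sites_per_context=100, library_size_mean=50_000,
                               site_element_weights={"te": 0.5, "intergenic": 0.5})
        genes, tes, sites = simulate_genome(cfg)
        assert genes == [] and len(tes) == 20 and len(sites) == 200

    def test_too_small_genome_raises(self):
        cfg = SimulationConfig(seed=5, n_chrom=1, chrom_len=5_000, n_genes=10,
                               n_te=0, n_sites_per_context=10, library_size_mean=1000)
        with pytest.raises(ValueError, match="too small"):
            simulate_genome(cfg)


class TestCounts:
    def test_byte_reproducible_given_seed(self, small_dataset):
        d2 = simulate_dataset(SimulationConfig(
            seed=7, n_chrom=4, chrom_len=500_000, n_genes=150, n_te=120,
            n_sites_per_context=1500, library_size_mean=150_000,
        ))
        np.testing.assert_array_equal(small_dataset["table"].counts, d2["table"].counts)
        pd.testing.assert_frame_equal(small_dataset["truth"], d2["truth"])

    def test_no_spikes_means_empty_truth(self):
        cfg = SimulationConfig(seed=2, n_chrom=2, chrom_len=300_000, n_genes=30,
                               n_te=20, n_sites_per_context=300, library_size_mean=50_000,
                               frac_parent_dms=0.0, frac_nonadditive=0.0,
                               frac_zero_sites=0.0)
        _, _, sites = simulate_genome(cfg)
        _, truth = simulate_counts(cfg, sites)
        assert len(truth) == 0

    def test_nb_moments_match_at_null_sites(self):
        """Unspiked-site counts follow NB(mu, phi): pooled z-scores of the
        per-site variance estimate stay within Monte-Carlo error."""
        cfg = SimulationConfig(seed=11, n_chrom=2, chrom_len=2_000_000, n_genes=10,
                               n_te=10, n_sites_per_context=10_000,
                               library_size_mean=2_000_000, dispersion=0.1,
                               baseline_logmean_sd=0.0, frac_parent_dms=0.0,
                               frac_nonadditive=0.0, frac_zero_sites=0.0,
                               library_jitter=0.0)
        _, _, sites = simulate_genome(cfg)
        table, _ = simulate_counts(cfg, sites)
        counts = table.counts.astype(float)
        mu = counts.mean()
        # chi-square goodness of fit of binned counts against NB pmf
        r = 1 / cfg.dispersion
        p = r / (r + mu)
        edges = np.quantile(stats.nbinom(r, p).rvs(20000, random_state=0), np.linspace(0, 1, 11))
        edges = np.unique(edges)
        obs, _ = np.histogram(counts.ravel(), bins=np.r_[-0.5, edges[1:-1] + 0.5, np.inf])
        cdf = stats.nbinom(r, p).cdf(np.r_[edges[1:-1], np.inf])
        expected = np.diff(np.r_[0, cdf]) * counts.size
        chi2 = ((obs - expected) ** 2 / expected).sum()
        # generous bound: the fitted-moment chi-square should not explode
        assert chi2 / len(obs) < 10

    def test_psd_maternal_truth_means_follow_each_maternal_parent(self, small_dataset):
        truth = small_dataset["truth"]
        mat = truth[(truth["psd_mode"] == "maternal") & (truth["combination"] == "F1221")]
        assert len(mat) > 0
        np.testing.assert_allclose(mat["mu_F12"], mat["mu_P1"])
        np.testing.assert_allclose(mat["mu_F21"], mat["mu_P2"])

    def test_truth_labels_consistent_with_infinite_data_classifier(self, small_dataset):
        """Every recorded pattern equals what the decision rules produce from
        the true means with noise-free significance."""
        truth = small_dataset["truth"]
        design = small_dataset["design"]
        combo = {name: (a, b) for name, a, b in design.combinations}
        checked = 0
        for r in truth.itertuples(index=False):
            if not r.combination:
                continue
            fab, fba = combo[r.combination]
            pa, _ = design.hybrid_parents(fab)
            pb, _ = design.hybrid_parents(fba)
            mu = {s: getattr(r, f"mu_{s}") for s in (pa, pb, fab, fba)}
            hi, lo = max(mu[pa], mu[pb]), min(mu[pa], mu[pb])
            assert infinite_data_label(mu[fab], hi, lo, r.parental_category) == r.pattern_a
            assert infinite_data_label(mu[fba], hi, lo, r.parental_category) == r.pattern_b
            checked += 1
        assert checked > 100

    def test_below_truth_means_sit_below_both_parents(self, small_dataset):
        truth = small_dataset["truth"]
        below = truth[(truth["pattern_a"] == "Below") & (truth["combination"] == "F1221")]
        assert len(below) > 0
        for col in ("mu_F12", "mu_F21"):
            assert (below[col] < below[["mu_P1", "mu_P2"]].min(axis=1)).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="pattern_mix"):
            SimulationConfig(pattern_mix={"HP": 1.0, "bogus": 0.0})
        with pytest.raises(ValueError, match="budget"):
            SimulationConfig(frac_parent_dms=0.5, frac_nonadditive=0.4,
                             frac_zero_sites=0.2)
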