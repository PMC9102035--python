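"""Synthetic diallel-cross MethylRAD data with spike-in truth.

The generator emulates the 3-parent full-diallel design the analysis assumes:
3 parents and 6 reciprocal hybrids, two restriction contexts (CCGG/CCWGG),
negative-binomial site counts (variance mu + phi*mu^2; phi = 0 is Poisson)
over a log-normal spread of per-site baseline abundances, with a small
uniform library-size jitter so RPM normalisation is exercised nontrivially.

Spike-in structure, all recorded in a truth table:

* **structural zeros** — sites unmethylated in every sample (the
  "P1 = P2 = 0" parental category);
* **parental divergence** — for one chosen parent pair the high parent's mean
  is the low parent's times ``2**effect_log2fc``; hybrids stay at their own
  mid-parent value (additive);
* **PSD spikes** — a fraction of the parent-divergent sites where both
  reciprocal hybrids' means equal their own maternal (or both their own
  paternal) parent's mean;
* **non-additive spikes** — hybrid means of one combination set per pattern:
  ``Above``/``Below`` = MPV x 2**(+/-effect) at parent-equal sites;
  ``GT_HP`` = high parent x 2**effect, ``LT_LP`` = low parent / 2**effect,
  ``LP`` = low parent, ``HP`` = high parent x 2**0.5 at sites given their own
  parental divergence.  (``HP`` sits slightly above the high parent: a hybrid
  exactly at the high parent is never more than 2-fold away from MPV, so it
  could never clear the |log2FC| > 1 non-additive call and the intended label
  would not be recoverable even from infinite data; the 2**0.5 offset keeps
  the site a vs-MPV DMS while remaining below the DMS threshold against the
  high parent.  ``LP`` needs no offset: log2(MPV/LP) = log2((2**e + 1)/2) > 1
  for e >= 2.)

Truth-table labels are, by construction, exactly what the pattern classifier
would return from the true means under infinite data (see
:func:`infinite_data_label`), which is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import (
    CrossDesign,
    GeneFeature,
    SiteCountTable,
    TeFeature,
    default_diallel_design,
)

NONADDITIVE_PATTERNS = ("HP", "LP", "GT_HP", "LT_LP", "Above", "Below")
UNEQUAL_PATTERNS = ("HP", "LP", "GT_HP", "LT_LP")
HP_OFFSET_LOG2 = 0.5  # HP spike sits 2**0.5 above the high parent; see module docstring


@dataclass
class SimulationConfig:
    """Knobs of the synthetic diallel dataset (defaults are the study
    conditions used throughout the package's own benchmarks)."""

    seed: int = 0
    n_chrom: int = 10
    chrom_len: int = 2_000_000
    n_genes: int = 2000
    n_te: int = 1500
    n_sites_per_context: int = 20_000
    library_size_mean: int = 2_000_000
    dispersion: float = 0.01
    baseline_logmean_sd: float = 0.6
    frac_parent_dms: float = 0.05
    frac_nonadditive: float = 0.05
    frac_zero_sites: float = 0.05
    pattern_mix: dict[str, float] = field(
        default_factory=lambda: {p: 1 / 6 for p in NONADDITIVE_PATTERNS}
    )
    frac_psd_maternal: float = 0.3
    frac_psd_paternal: float = 0.1
    effect_log2fc: float = 3.0
    library_jitter: float = 0.1
    gene_len_range: tuple[int, int] = (1000, 5000)
    te_len_range: tuple[int, int] = (200, 2000)
    site_element_weights: dict[str, float] = field(
        default_factory=lambda: {"gene_body": 0.3, "flank": 0.2, "te": 0.25, "intergenic": 0.25}
    )
    n_go_terms: int = 40
    go_genes_per_term: int = 50

    def __post_init__(self) -> None:
        fracs = [
            self.frac_parent_dms,
            self.frac_nonadditive,
            self.frac_zero_sites,
            self.frac_psd_maternal,
            self.frac_psd_paternal,
        ]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("all spike fractions must lie in [0, 1]")
        if self.frac_parent_dms + self.frac_nonadditive + self.frac_zero_sites > 1:
            raise ValueError("spike fractions exceed the site budget")
        if self.frac_psd_maternal + self.frac_psd_paternal > 1:
            raise ValueError("PSD fractions of parent-divergent sites exceed 1")
        if abs(sum(self.pattern_mix.values()) - 1.0) > 1e-9:
            raise ValueError("pattern_mix must sum to 1")
        if set(self.pattern_mix) - set(NONADDITIVE_PATTERNS):
            raise ValueError(f"pattern_mix keys must be among {NONADDITIVE_PATTERNS}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def simulate_genome(
    config: SimulationConfig,
) -> tuple[list[GeneFeature], list[TeFeature], pd.DataFrame]:
    """Place non-overlapping genes, TEs in the remaining space, and
    restriction sites over the elements with configurable shares.

    Returns (genes, TEs, site frame with chrom/pos/context columns).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1:02d}" for i in range(config.n_chrom)]

    # genes: split across chromosomes, placed by stick-breaking of the slack
    genes: list[GeneFeature] = []
    per_chrom = np.full(config.n_chrom, config.n_genes // config.n_chrom)
    per_chrom[: config.n_genes % config.n_chrom] += 1
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        lengths = rng.integers(*config.gene_len_range, size=k, endpoint=True)
        slack = config.chrom_len - int(lengths.sum())
        if slack < k:
            raise ValueError(
                f"genome too small: {k} genes of total length {lengths.sum()} "
                f"do not fit in {chrom} ({config.chrom_len} bp)"
            )
        gaps = rng.dirichlet(np.ones(k + 1)) * slack
        start = 1
        for i in range(k):
            start += int(gaps[i])
            end = start + int(lengths[i]) - 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneFeature(f"gene{len(genes) + 1:05d}", chrom, start, end, strand))
            start = end + 1

    # TEs: uniform within inter-gene free space of a random chromosome
    free: dict[str, list[tuple[int, int]]] = {}
    for chrom in chroms:
        spans = sorted((g.start, g.end) for g in genes if g.chrom == chrom)
        gaps_c, cursor = [], 1
        for s, e in spans:
            if s > cursor:
                gaps_c.append((cursor, s - 1))
            cursor = e + 1
        if cursor <= config.chrom_len:
            gaps_c.append((cursor, config.chrom_len))
        free[chrom] = gaps_c
    tes: list[TeFeature] = []
    attempts = 0
    while len(tes) < config.n_te:
        attempts += 1
        if attempts > 50 * config.n_te:
            raise ValueError("genome too small to host the requested TEs")
        chrom = chroms[int(rng.integers(len(chroms)))]
        gaps_c = free[chrom]
        if not gaps_c:
            continue
        lo, hi = gaps_c[int(rng.integers(len(gaps_c)))]
        length = int(rng.integers(*config.te_len_range, endpoint=True))
        if hi - lo + 1 < length:
            continue
        start = int(rng.integers(lo, hi - length + 2))
        tes.append(TeFeature(chrom, start, start + length - 1, f"te{len(tes) + 1:05d}"))

    # sites: element class by weight, then uniform within a random feature
    weights = config.site_element_weights
    classes = list(weights)
    probs = np.array([weights[c] for c in classes], dtype=float)
    probs /= probs.sum()
    taken: set[tuple[str, int, str]] = set()
    rows: list[tuple[str, int, str]] = []
    for context in ("CCGG", "CCWGG"):
        placed = 0
        guard = 0
        while placed < config.n_sites_per_context:
            guard += 1
            if guard > 100 * config.n_sites_per_context:
                raise ValueError("genome too small to host the requested sites")
            cls = classes[int(rng.choice(len(classes), p=probs))]
            if cls == "gene_body" and genes:
                g = genes[int(rng.integers(len(genes)))]
                chrom, pos = g.chrom, int(rng.integers(g.start, g.end + 1))
            elif cls == "flank" and genes:
                g = genes[int(rng.integers(len(genes)))]
                off = int(rng.integers(1, 2001))
                pos = g.start - off if rng.random() < 0.5 else g.end + off
                chrom = g.chrom
                if pos < 1:
                    continue
            elif cls == "te" and tes:
                t = tes[int(rng.integers(len(tes)))]
                chrom, pos = t.chrom, int(rng.integers(t.start, t.end + 1))
            else:
                chrom = chroms[int(rng.integers(len(chroms)))]
                pos = int(rng.integers(1, config.chrom_len + 1))
            key = (chrom, pos, context)
            if key in taken:
                continue
            taken.add(key)
            rows.append(key)
            placed += 1
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "context"])
    sites = sites.sort_values(["context", "chrom", "pos"]).reset_index(drop=True)
    return genes, tes, sites


def _spike_assignments(config: SimulationConfig, n_sites: int, rng: np.random.Generator):
    """Disjoint site index sets for every spike type, plus per-spike metadata."""
    idx = rng.permutation(n_sites)
    n_zero = int(round(config.frac_zero_sites * n_sites))
    n_pd = int(round(config.frac_parent_dms * n_sites))
    n_na = int(round(config.frac_nonadditive * n_sites))
    zero = idx[:n_zero]
    pd_idx = idx[n_zero : n_zero + n_pd]
    na_idx = idx[n_zero + n_pd : n_zero + n_pd + n_na]

    n_mat = int(round(config.frac_psd_maternal * n_pd))
    n_pat = int(round(config.frac_psd_paternal * n_pd))
    psd_mat = pd_idx[:n_mat]
    psd_pat = pd_idx[n_mat : n_mat + n_pat]

    patterns = list(config.pattern_mix)
    p = np.array([config.pattern_mix[k] for k in patterns])
    na_patterns = rng.choice(patterns, size=n_na, p=p)
    return zero, pd_idx, psd_mat, psd_pat, na_idx, na_patterns


def simulate_counts(
    config: SimulationConfig,
    sites: pd.DataFrame,
    design: CrossDesign | None = None,
) -> tuple[SiteCountTable, pd.DataFrame]:
    """Draw the 9-sample count matrix and the spike-in truth table.

    The truth table has one row per structurally special site: its parental
    category for the affected combination, the pattern both reciprocal
    hybrids should classify as (derived from the true means via
    :func:`infinite_data_label`), the PSD mode, and the true (pre-jitter)
    mean of every sample on the expected-count scale.
    """
    design = design or default_diallel_design()
    if len(design.parents) != 3 or len(design.hybrids) != 6 or len(design.combinations) != 3:
        raise ValueError("simulate_counts expects a 3-parent diallel (3 x 6 x 3 design)")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(sites)
    samples = design.all_samples()
    eff = 2.0 ** config.effect_log2fc

    # baseline relative abundance, scaled so expected column sums hit the
    # target library size
    w = rng.lognormal(mean=0.0, sigma=config.baseline_logmean_sd, size=n)
    zero, pd_idx, psd_mat, psd_pat, na_idx, na_patterns = _spike_assignments(config, n, rng)
    w[zero] = 0.0

    combos = design.combinations
    combo_of_pd = rng.integers(len(combos), size=len(pd_idx))
    high_is_a = rng.random(len(pd_idx)) < 0.5
    combo_of_na = rng.integers(len(combos), size=len(na_idx))
    na_high_is_a = rng.random(len(na_idx)) < 0.5

    mu = np.tile(w[:, None], (1, len(samples)))
    explicit = np.zeros_like(mu, dtype=bool)  # cells set by a spike, not baseline
    col = {s: samples.index(s) for s in samples}
    combo_parents = {}
    for name, fab, fba in combos:
        mat_a, pat_a = design.hybrid_parents(fab)
        combo_parents[name] = (mat_a, pat_a, fab, fba)

    # (site_index, combination, category, psd_mode); labels derived afterwards
    truth_meta: list[tuple[int, str, str, str]] = []
    for i in zero:
        truth_meta.append((int(i), "", "equal_zero", "none"))

    # parental divergence (incl. PSD carve-outs)
    psd_mode_of = {int(i): "maternal" for i in psd_mat}
    psd_mode_of.update({int(i): "paternal" for i in psd_pat})
    for j, i in enumerate(pd_idx):
        name = combos[combo_of_pd[j]][0]
        pa, pb, fab, fba = combo_parents[name]
        hi, lo = (pa, pb) if high_is_a[j] else (pb, pa)
        mu[i, col[hi]] = w[i] * eff
        explicit[i, col[hi]] = True
        mode = psd_mode_of.get(int(i), "none")
        if mode == "maternal":  # each hybrid matches its own maternal parent
            mu[i, col[fab]] = mu[i, col[pa]]
            mu[i, col[fba]] = mu[i, col[pb]]
        elif mode == "paternal":
            mu[i, col[fab]] = mu[i, col[pb]]
            mu[i, col[fba]] = mu[i, col[pa]]
        else:
            mpv = 0.5 * (mu[i, col[pa]] + mu[i, col[pb]])
            mu[i, col[fab]] = mpv
            mu[i, col[fba]] = mpv
        explicit[i, col[fab]] = explicit[i, col[fba]] = True
        truth_meta.append((int(i), name, "A_gt_B" if high_is_a[j] else "B_gt_A", mode))

    # non-additive spikes (both reciprocal hybrids share the pattern level)
    for j, i in enumerate(na_idx):
        pattern = str(na_patterns[j])
        name = combos[combo_of_na[j]][0]
        pa, pb, fab, fba = combo_parents[name]
        if pattern in UNEQUAL_PATTERNS:
            hi, lo = (pa, pb) if na_high_is_a[j] else (pb, pa)
            mu[i, col[hi]] = w[i] * eff
            explicit[i, col[hi]] = True
            level = {
                "HP": mu[i, col[hi]] * 2.0 ** HP_OFFSET_LOG2,
                "LP": mu[i, col[lo]],
                "GT_HP": mu[i, col[hi]] * eff,
                "LT_LP": mu[i, col[lo]] / eff,
            }[pattern]
            category = "A_gt_B" if na_high_is_a[j] else "B_gt_A"
        else:
            level = w[i] * eff if pattern == "Above" else w[i] / eff
            category = "equal_pos"
        mu[i, col[fab]] = level
        mu[i, col[fba]] = level
        explicit[i, col[fab]] = explicit[i, col[fba]] = True
        truth_meta.append((int(i), name, category, "none"))

    # hybrids of *other* combinations sharing a moved parent stay additive:
    # reset every non-explicit hybrid cell at a spiked site to its own MPV
    spiked = np.unique(np.concatenate([pd_idx, na_idx]).astype(int)) if len(pd_idx) + len(na_idx) else np.array([], dtype=int)
    for hyb, mcode, pcode in design.hybrids:
        m_s, p_s = design.parents[mcode], design.parents[pcode]
        c = col[hyb]
        for i in spiked:
            if not explicit[i, c]:
                mu[i, c] = 0.5 * (mu[i, col[m_s]] + mu[i, col[p_s]])

    # expected-count scale (pre-jitter) for the truth table
    scale = config.library_size_mean / max(w.sum(), 1.0)
    true_means = mu * scale

    # library-size jitter and NB sampling
    jitter = rng.uniform(1 - config.library_jitter, 1 + config.library_jitter, len(samples))
    counts = _nb_sample(rng, true_means * jitter[None, :], config.dispersion)
    table = SiteCountTable(sites, counts, samples)

    truth_rows = []
    for i, combo, category, mode in truth_meta:
        row = {
            "site_index": i,
            "chrom": sites.iloc[i]["chrom"],
            "pos": int(sites.iloc[i]["pos"]),
            "context": sites.iloc[i]["context"],
            "combination": combo,
            "parental_category": category,
            "psd_mode": mode,
        }
        if combo:
            pa, pb, fab, fba = combo_parents[combo]
            hi_mu = max(mu[i, col[pa]], mu[i, col[pb]])
            lo_mu = min(mu[i, col[pa]], mu[i, col[pb]])
            row["pattern_a"] = infinite_data_label(mu[i, col[fab]], hi_mu, lo_mu, category)
            row["pattern_b"] = infinite_data_label(mu[i, col[fba]], hi_mu, lo_mu, category)
        else:
            row["pattern_a"] = row["pattern_b"] = "Additive"
        for s in samples:
            row[f"mu_{s}"] = true_means[i, col[s]]
        truth_rows.append(row)
    columns = [
        "site_index", "chrom", "pos", "context", "combination",
        "parental_category", "pattern_a", "pattern_b", "psd_mode",
    ] + [f"mu_{s}" for s in samples]
    truth = pd.DataFrame(truth_rows, columns=columns)
    return table, truth


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mu, phi) with variance mu + phi*mu^2; phi = 0 is Poisson."""
    if dispersion == 0.0:
        return rng.poisson(mean).astype(np.int64)
    r = 1.0 / dispersion
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    lam = rng.gamma(shape=r, scale=mean[pos] / r)
    out[pos] = rng.poisson(lam)
    return out


def simulate_go_map(
    config: SimulationConfig, genes: list[GeneFeature]
) -> pd.DataFrame:
    """Random gene -> GO-term mapping over the simulated gene universe."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    gene_ids = [g.gene_id for g in genes]
    rows = []
    for t in range(config.n_go_terms):
        term = f"GO:{7000000 + t:07d}"
        name = f"synthetic biological process {t + 1}"
        k = min(config.go_genes_per_term, len(gene_ids))
        for gid in rng.choice(gene_ids, size=k, replace=False):
            rows.append({"gene_id": gid, "go_id": term, "go_name": name})
    return pd.DataFrame(rows).drop_duplicates(["gene_id", "go_id"]).reset_index(drop=True)


def simulate_dataset(config: SimulationConfig, design: CrossDesign | None = None):
    """One-call convenience: genome + counts + truth + GO map + design."""
    design = design or default_diallel_design()
    genes, tes, sites = simulate_genome(config)
    table, truth = simulate_counts(config, sites, design)
    go_map = simulate_go_map(config, genes)
    return {
        "genes": genes,
        "tes": tes,
        "table": table,
        "truth": truth,
        "go_map": go_map,
        "design": design,
    }


def infinite_data_label(
    mu_hybrid: float, mu_high: float, mu_low: float, category: str,
    log2fc_threshold: float = 1.0,
) -> str:
    """Pattern label implied by true means under infinite data.

    With unbounded counts any nonzero difference is significant in p, so the
    DMS call reduces to the fold-change threshold; this mirrors the
    classifier's decision rules on noise-free input and is the consistency
    oracle for the truth table.
    """
    def lfc(x, y):
        return np.log2((x + 1e-300) / (y + 1e-300)) if (x > 0 or y > 0) else 0.0

    def sig(x, y):
        return abs(lfc(x, y)) > log2fc_threshold and x != y

    mpv = 0.5 * (mu_high + mu_low)
    if not sig(mu_hybrid, mpv):
        return "Additive"
    if category in ("equal_pos", "equal_zero"):
        return "Above" if mu_hybrid > mpv else "Below"
    if sig(mu_hybrid, mu_high) and mu_hybrid > mu_high:
        return "GT_HP"
    if sig(mu_hybrid, mu_low) and mu_hybrid < mu_low:
        return "LT_LP"
    if not sig(mu_hybrid, mu_high) and not sig(mu_hybrid, mu_low):
        return "HP" if abs(lfc(mu_hybrid, mu_high)) < abs(lfc(mu_hybrid, mu_low)) else "LP"
    if not sig(mu_hybrid, mu_high):
        return "HP"
    if not sig(mu_hybrid, mu_low):
        return "LP"
    return "HP" if abs(lfc(mu_hybrid, mu_high)) < abs(lfc(mu_hybrid, mu_low)) else "LP"
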