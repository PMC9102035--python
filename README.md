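# diallelmeth

Analysis pipeline for DNA methylation inheritance in a plant **diallel
cross** assayed by methylation-dependent restriction-site sequencing
(MethylRAD-style counts at CCGG/CCWGG sites, W = A or T).  Given per-site
read counts for three parents and their six reciprocal F1 hybrids, the
package answers, for every site and hybrid:

* Is the site differentially methylated between any two samples, or
  between a hybrid and its **mid-parent value** (MPV), the additive
  expectation?
* If a hybrid departs from MPV, *how*: at the high or low parent's level
  (HP/LP), beyond either parent (>HP/<LP), or above/below two equal
  parents (Above/Below) — the six non-additive inheritance patterns?
* Do the two reciprocal hybrids of a cross inherit each their **own
  maternal (or paternal) parent's** methylation status at sites where the
  parents differ (parental-selective-difference sites, PSD) — the
  signature of parent-of-origin and cytoplasmic effects?
* Which genes carry reciprocal non-additive sites (DMGs), and are any GO
  terms over-represented among them?

It is aimed at epigenomics researchers studying heterosis who have
site-level count tables, gene models (GFF3) and TE intervals (BED), and at
method developers: a fully ground-truthed synthetic diallel generator
makes every stage testable without sequencing data.

## Model

Counts at a site are modelled NB(μ, φ) with variance μ + φμ² (φ = 0 is
Poisson; default φ = 0.01 since unreplicated designs cannot estimate it).
Methylation level is RPM = count/library × 10⁶.  Two columns are compared
with the exact test for unreplicated NB counts: libraries are equalised to
their geometric mean and the split of the total n is negative
hypergeometric,

    P(a | n) = C(a+r−1, a) C(n−a+r−1, n−a) / C(n+2r−1, n),  r = 1/φ,

Binomial(n, ½) at φ = 0; the two-sided p sums all outcomes no more
probable than the observed one.  A **DMS** requires |log₂FC| > 1 and
p < 0.05.  MPV is tested as integer pseudo-counts at a 10⁶ reference.
Full details, including the PSD rule and the simulator's spike
construction, are in [docs/methods.md](docs/methods.md).

## Worked example

```python
from diallelmeth.simulate import SimulationConfig, simulate_dataset
from diallelmeth.pipeline import run_analysis

data = simulate_dataset(SimulationConfig(seed=1, n_chrom=2,
    chrom_len=400_000, n_genes=80, n_te=60,
    n_sites_per_context=500, library_size_mean=80_000))
result = run_analysis(data["table"], data["design"],
                      data["genes"], data["tes"], data["go_map"])
print(result.tables["reciprocal_summary"][
    ["combination", "context", "n_hds", "n_pds", "n_ins",
     "n_psd_maternal", "n_psd_paternal"]].to_string(index=False))
```

prints

```
combination context  n_hds  n_pds  n_ins  n_psd_maternal  n_psd_paternal
      F1221    CCGG      2     31      1               1               0
      F1221   CCWGG      6     35      2               2               0
      F1331    CCGG      8     34      6               3               2
      F1331   CCWGG      5     34      4               3               1
      F2332    CCGG      5     27      4               3               1
      F2332   CCWGG      7     26      6               3               2
```

Reading the F1331/CCGG row: 8 CCGG sites differ between the reciprocal
hybrids F13 and F31 (HDS), 34 differ between parents P1 and P3 (PDS), 6
are in both (Ins), and of those, 3 show both hybrids matching their own
maternal parent and 2 their own paternal parent — the maternal-biased
inheritance the generator spiked (30% vs 10% of parent-divergent sites;
at this toy size each cell holds only a handful of sites, the full-size
run below gives ~100 maternal vs ~35 paternal per cell).  `result.pattern_calls`, `result.dmgs` and `result.enrichment`
hold the per-hybrid pattern labels, the non-additively methylated genes
and the GO tests.

The same analysis as a narrative over a full-size dataset (40,000 sites,
library mean 2×10⁶) lives in `analysis/01_simulate.py` …
`analysis/05_genes_enrichment.py`, each writing its tables under
`results/`; a CLI (`diallelmeth simulate|profile|dms|classify|reciprocal|
genes|run-all`) exposes every stage on files.

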