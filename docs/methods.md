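# Methods

## Scope and data model

`diallelmeth` analyses DNA methylation in a plant diallel cross assayed by
methylation-dependent restriction-site sequencing (MethylRAD-style data).
The unit of observation is a restriction site in one of two cytosine
contexts, CCGG or CCWGG (W = A or T); the measurement is the read count at
that site in each of nine samples: three parents (P1, P2, P3) and the six
reciprocal F1 hybrids (F12, F21, F13, F31, F23, F32, where Fab has parent a
as the maternal line).  Sites are unstranded and identified by
(chromosome, 1-based position, context).  All interval arithmetic is
1-based inclusive internally; BED input is converted at the boundary.

## Methylation levels and genomic elements

The methylation level of a site in a sample is its reads-per-million,
RPM = count / library size × 10⁶, with the library size defaulting to the
sample's column sum over all sites of both contexts (a per-context
denominator is available, `per_context_library_sizes`; the choice of
denominator is exposed rather than fixed because either convention is
defensible for a two-enzyme assay).  The level of a genomic element is the
sum of the RPM of its member sites.

Sites are annotated against gene models and transposable-element intervals
with multi-membership: gene body (pos ∈ [start, end]), strand-aware 2 kb
upstream/downstream flanks (excluding the body; a flank overlapping a
neighbouring gene still counts as this gene's flank), TE, and intergenic
(none of the above).  Exon/intron sub-labels are filled only when exon
records are available.  For distribution summaries each site additionally
gets one `primary_element` by the fixed gene-centric priority
gene_body > upstream2k > downstream2k > TE > intergenic, so distribution
ratios partition to 1 and either genic roll-up can be recomputed from the
output.

A site is hyper-methylated in a sample if its RPM is **at least** five
times the mean RPM over all sites of the same context in that sample; the
boundary is included.  Sample-level comparisons of mean levels use the
classical paired t-test (t from the differences, p from t with n−1 df);
two degenerate cases have fixed conventions — all pairs identical gives
(0, 1), a constant nonzero difference gives (±inf, 0).

## The exact test for unreplicated counts

Differential methylation between two single count columns is tested with
the classic exact negative-binomial test (the construction behind edgeR's
`exactTest`, re-implemented here).  Counts are modelled NB(μ, φ) with
variance μ + φμ²; φ = 0 is Poisson.  The two libraries are equalised by
proportional scaling to their geometric-mean depth with rounding; for two
equal-mean NB observations the split of the total n is then negative
hypergeometric,

    P(a | n) = C(a+r−1, a) · C(n−a+r−1, n−a) / C(n+2r−1, n),   r = 1/φ,

degenerating to Binomial(n, ½) at φ = 0.  The two-sided p-value sums the
probabilities of all outcomes no more probable than the observed one
(outcomes within a 10⁻⁸ relative band count as ties; a doubled-one-tail
variant is available).  The implementation groups sites by conditional
total so each pmf vector is built once, and computes the NB log-pmf from
running sums of log(r+i) rather than differences of log-gamma values,
which cancel catastrophically at small dispersions (r ≳ 10¹⁵ falls back
to the binomial limit, whose correction is O(n²/r)); p-values agree with Bioconductor
edgeR's `exactTest(rejection.region="smallp")` to 12 significant digits on
spot checks frozen into the test suite, and with a brute-force integer
binomial oracle to < 10⁻⁹ at φ = 0.

Without replicates φ cannot be estimated from the data, so it is a fixed,
explicit parameter, default **φ = 0.01** (biological CV 0.1, a conventional
value for genetically identical material).  The fold change is
log2 of the library-equalised abundances with a 0.5 pseudocount, so two
all-zero columns give exactly 0.  A site is a **DMS** when |log2FC| > 1
and p < 0.05 (both thresholds configurable; Benjamini–Hochberg adjustment
of p within a comparison is available and off by default).

## Mid-parent value

The additive expectation for a hybrid is the mid-parent value,
MPV = (RPM_P1 + RPM_P2)/2, re-expressed as integer pseudo-counts at a
reference depth of 10⁶ so the exact test applies unchanged.  Two
alternative constructions were evaluated and rejected: expressing MPV at a
library-matched reference, and representing MPV as the parents' count sum
with summed library.  Both raise the null false-positive rate of the
hybrid-vs-MPV call (0.012 and 0.014 vs 0.006 on matched-dispersion null
simulations) because proportional library scaling distorts the count
variance when it scales counts up; the 10⁶ reference is the conservative
choice.

## Parental categories and inheritance patterns

Per parent pair, each site falls in one of four categories: P1 > P2 or
P2 > P1 (the parents are a DMS pair, direction from the fold change),
P1 = P2 = 0 (both raw counts zero), or P1 = P2 > 0 (the rest).

A hybrid's inheritance at a site is **Additive** when it is not a DMS
against the MPV.  Otherwise:

* parents unequal — **>HP** if a DMS above the high parent, **<LP** if a
  DMS below the low parent, **HP**/**LP** if not a DMS against the
  high/low parent ("similar to" a parent is operationalised as "not a DMS
  against it" under the same thresholds — the only internally consistent
  reading when no numeric similarity band is given).  A hybrid that is a
  DMS against both parents yet lies strictly between them is outside the
  six patterns; it gets the nearer parent's label (smaller |log2FC|, tie →
  LP) and a `between_parents` flag so it can be excluded.
* parents equal — **Above**/**Below** by the sign of the vs-MPV fold
  change; no further test is needed because at equal parents the MPV *is*
  the common parental level.  Parentally unmethylated sites with a
  methylated hybrid are Above.

The seven labels are exhaustive and mutually exclusive per (site, hybrid),
asserted programmatically.

## Reciprocal hybrids: PSD and reciprocal non-additive DMSs

Per combination (Fab, Fba): **HDS** = sites where the two reciprocal
hybrids differ (DMS), **PDS** = sites where the two parents differ,
**Ins** = HDS ∩ PDS.  A **PSD** (parental selective difference) site is an
Ins site where each hybrid inherited its own maternal — or each its own
paternal — parent's methylation status, with "inherited X's status" read
strictly: not a DMS against X *and* a DMS against the other parent
(`psd_rule="strict"`; a `"nearest"` relaxation drops the second clause).
Ins sites where both hybrids match one fixed parent are kept with a
`uniparental` flag, and the remainder as `other`, so all reported ratios
(Ins/HDS, PSD/Ins, PSD/HDS, maternal vs paternal) are recomputable from
the output tables; empty denominators yield NaN, never 0.

Pattern calls of the two reciprocal hybrids merge into a **reciprocal
non-additive DMS** when both labels fall in one similarity class —
{HP, >HP}, {LP, <LP}, {Above}, {Below} — with the non-extreme member as
the pair label for mixed classes.  Above and Below match only themselves;
the classes generalise the single worked example of a parent-level match
paired with its exceedance.

## Genes and enrichment

Reciprocal non-additive DMSs are assigned to every gene whose body ± 2 kb
contains them (a site in several windows yields one pair per gene).  A
gene with ≥ 1 assigned site is one DMG per (combination, context)
regardless of how many sites support it or whether their labels agree;
conflicts are flagged.  GO over-representation uses the one-sided Fisher
exact test (hypergeometric upper tail via `scipy.stats.hypergeom.sf`)
against a background of genes whose window contains ≥ 1 assayed site of
the relevant context (`background="assayed"`; `"all"` selectable — the
assayed restriction is the unbiased choice for a reduced-representation
assay).  Terms with fewer than 5 study-list genes are dropped (`min_on=
"study"`, the literal reading; a background-side filter is selectable).
No multiple-testing correction is applied by default; BH is available.

## The simulator

The generator emulates the 3-parent diallel, not real soybean data: a
multi-chromosome genome with non-overlapping uniformly placed genes, TEs
in the remaining space, and sites placed over element classes with
configurable shares; per-site baseline abundances are log-normal
(σ = 0.6), counts are NB with shared dispersion, and library sizes get a
±10% uniform jitter so RPM normalisation is exercised nontrivially.
Defaults are the package's benchmark study conditions: 20,000 sites per
context, library mean 2×10⁶, φ = 0.01, 5% parental-divergence spikes, 5%
non-additive spikes with a uniform pattern mix, 5% structural parental
zeros, maternal/paternal PSD carve-outs of 30%/10% of the
parent-divergent sites, effect size 2³.

Spike construction: a parental-divergence spike raises one randomly chosen
parent of one randomly chosen combination to 2³× the baseline; hybrids not
explicitly spiked sit at the MPV of their own parents (also across
combinations sharing a moved parent).  PSD spikes set both reciprocal
hybrids to their designated parent's mean.  Non-additive spikes set both
hybrids of one combination to the pattern level: Above/Below = MPV × 2^±e
at parent-equal sites; >HP = high parent × 2^e, <LP = low parent / 2^e,
LP = low parent at sites given their own divergence.  **HP is spiked at
high parent × 2^0.5, not at the high parent itself**: a hybrid exactly at
the high parent is never more than 2-fold from MPV, so it could never
clear the |log2FC| > 1 non-additive call — the intended label would be
unrecoverable even from infinite data.  The 2^0.5 offset keeps the site a
vs-MPV DMS while staying below the DMS threshold against the high parent.
Truth-table labels are derived from the true means with the classifier's
own decision rules under noise-free significance (`infinite_data_label`),
and the test suite asserts that consistency; this also means PSD spikes
carry their honest per-hybrid labels (the low-parent-matching hybrid of a
maternal PSD site is truly LP, the high-parent-matching one truly
Additive).

What the simulator does **not** model: enzyme-site sequence composition,
digestion or alignment artefacts, chromosome-scale methylation gradients,
correlated neighbouring sites, context-specific dispersion, batch effects.
Passing benchmarks therefore demonstrates correctness of the inference
machinery under the stated noise model, not performance on real tissue.

## Benchmarks and problem sizes

The acceptance surface (tests/test_acceptance.py, scripts/acceptance.py)
computes, at the generator defaults with a caller-supplied seed:

* exact-test agreement with integer binomial enumeration over all 496
  count pairs with total ≤ 30 (observed ≤ 2×10⁻¹⁵);
* Fisher agreement with integer hypergeometric summation, exhaustive over
  all ~3.2×10⁵ tables with background ≤ 50 plus 2000 random tables with
  background ≤ 200 (observed ≤ 4×10⁻¹⁶) — the exhaustive bound is capped
  at 50 because an exact integer oracle over every table up to 200 is
  ~7×10⁷ cases;
* Type-I control on a spike-free simulation at φ = 0.05 (fraction of
  p < 0.05 ≤ 0.05 + 3 binomial SEs; observed ≈ 0.045);
* spike recovery at the defaults, analysed with BH adjustment on (the
  FDR-controlled operating point): sensitivity ≈ 0.92 at FDR ≈ 0.01,
  six-way label accuracy ≈ 0.99, PSD attribution accuracy 1.00.  With raw
  p (the classical reporting rule, the pipeline default) sensitivity rises
  to ≈ 0.95 but FDR reaches ≈ 0.25 at the 5% spike density — raw p < 0.05
  on ~38,000 null sites per hybrid yields ~250 conjunction false positives
  against ~750 true spikes, which is the known cost of unadjusted
  per-site testing, not a defect of the test (its null p-values are
  uniform-conservative, see the Type-I check);
* set-algebra invariants (PSD ⊆ Ins ⊆ HDS ∩ PDS) and the seven-label
  partition, asserted on every simulated dataset;
* RPM totals of 10⁶ per sample to 10⁻⁶ relative; hyper-site boundary
  equality;
* bitwise determinism of two identically configured end-to-end runs
  (SHA-256 of every written table).

## Known limitations

* Dispersion is a single shared constant; no trended or tagwise
  estimation (impossible without replicates, and deliberately explicit).
* Library equalisation uses proportional scaling with rounding rather
  than quantile-to-quantile NB adjustment; at very unequal depths the
  test drifts conservative (scaling down) or liberal (scaling up), which
  is why MPV uses the conservative 10⁶ reference.
* The between-parents-unlike-both case is flagged, not resolved — no
  principled six-way assignment exists for it.
* GO enrichment does not propagate the GO graph; terms are treated as
  flat annotations.
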