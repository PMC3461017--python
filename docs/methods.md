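# Methods

This note records the models implemented in `sweepscan`, the choices made
where the underlying procedures admit more than one reading, and what the
synthetic cohorts do and do not establish about behaviour on real data.

## Fst scan

**Estimator.** Per-SNP two-population coancestry (Reynolds-type) Fst, as a
method-of-moments ratio. With sample frequencies `p̃ᵢ` from `nᵢ` diploids
and unbiased gene diversities `ĥᵢ = 2nᵢ/(2nᵢ−1) · 2p̃ᵢ(1−p̃ᵢ)`:

    numerator   a = (p̃₁−p̃₂)² − ĥ₁/(4n₁) − ĥ₂/(4n₂)
    denominator a + (ĥ₁+ĥ₂)/2

The numerator is an unbiased estimate of `θ·h_a` (θ the coancestry
divergence, `h_a` the ancestral gene diversity) and the denominator of
`h_a`, so the ratio targets θ, which under pure drift for t generations in
populations of size N equals `1 − (1−1/2N)^t ≈ 1 − exp(−t/2N)`. The drift
recovery test exercises exactly this identity. Fixed opposite alleles give
exactly 1; the estimate is clamped to [0, 1] for reporting, but the
unclamped value drives the empirical-null ranking so that ties at 0 do not
distort it. Missing genotypes are dropped per SNP per population.

Loci are combined genome-wide as the ratio of summed numerators to summed
denominators (`multi_locus_fst`), the consistent multi-locus form of the
estimator; averaging per-SNP ratios is biased downward by denominator noise
(about −20% at θ = 0.2 under the drift simulations). Scan output remains
per-SNP, as region detection requires.

**Exact test.** The permutation test on the 2×2 allele-count table is
realized analytically: the two-sided Fisher/hypergeometric sum of all
tables (fixed margins) no more probable than the observed one. This is the
all-permutations limit of permuting allele labels across populations — a
sampled permutation scheme cannot resolve p-values of order 1e-18 that a
genome-wide Bonferroni threshold requires. A 10⁵-draw Monte-Carlo
permutation oracle cross-checks the implementation in the tests.

**Filters.** MAF > 5% in *either* population (strict inequality); exact
Hardy–Weinberg test p > 0.05 — applied within each population separately,
with both required to pass, the conservative reading of an unqualified
"in HWE" filter. The Bonferroni m is the post-filter SNP count, recorded in
the run manifest.

**Empirical null.** Intergenic = at least 50 kb (inclusive boundary) from
every annotated gene. `p_E` is the fraction of intergenic SNPs with
strictly greater (unclamped) Fst; intergenic SNPs are excluded from
candidacy since they constitute the null.

## Haplotype statistics

**EHH.** At a core SNP, carriers of an allele class are partitioned by
their full sequence between the core and each successive site; EHH is the
within-class pair fraction Σ C(kⱼ,2)/C(n,2), computed independently
leftward and rightward. Genetic positions come from linear interpolation of
the recombination map, extrapolating beyond the terminal anchors at the
terminal rate (flagged in logs).

**iHH/iHS.** Trapezoid integral of EHH over cM, truncated at the first
EHH < 0.05 crossing with the crossing point linearly interpolated. Cores
whose EHH has not decayed below the cutoff at a chromosome end are dropped
from iHS rather than integrated to the edge — integrating to the edge
biases the integral downward asymmetrically. iHS requires derived-allele
orientation and DAF within [0.10, 0.90]; raw scores are standardized in 20
equal-width DAF bins (bins with fewer than two scores leave their records
flagged unstandardized).

**XP-EHH.** Site-level (pooled) EHH: all haplotypes participate and pairs
must also match at the core itself, so the profile starts at the core-site
homozygosity. A per-allele mode is available. Both populations are
integrated over the same interval per side, delimited by the 0.05 crossing
of the pooled two-population profile; where that profile has not crossed at
a chromosome end, both integrals truncate there and the record is flagged
`edge`. Scores are standardized genome-wide and given two-tailed Gaussian
p-values. Positive values mean longer-range haplotypes in the test cohort.

The genome-wide significance threshold is the normal quantile solving
`2(1−Φ(z)) = α/m` with m the scored-SNP count. At the historical scan size
m = 1,373,755 this quantile is ≈ 5.51; published scans of that size have
used a lower operational cutoff (≈ 4.8) whose derivation is not
reconstructible from (m, α) alone, so the threshold is a configuration
knob and the manifest records both m and the computed quantile.

**Scan engine.** Whole-panel scans use a pair-based formulation: the number
of carrier pairs identical from the core out to site s equals the number of
pairs whose first mismatch lies beyond s, so one forward and one backward
first-mismatch recurrence over cores yields every profile in O(pairs) per
core. The per-core partition-refinement walk is kept as the reference
implementation; tests assert exact agreement between the two and against an
all-pairs brute force.

## Regions

Genotype R² is the squared Pearson correlation of 0/1/2 dosage vectors over
pairwise-complete individuals (≥3 required), computed in the test cohort
only. Clusters are connected components (networkx) of the R² ≥ 0.25 graph
over candidate SNPs, per chromosome; singletons are retained. A cluster is
attributed to the test population iff its maximum member XP-EHH strictly
exceeds 3. iHS windows slide one SNP at a time; non-overlap is enforced at
selection by greedy descending-score choice with ties to the smaller start
index, and the top-0.02% count is taken over all scored windows
genome-wide, rounded up (a `nonoverlapping` denominator mode is provided,
as the alternative reading). Concordant regions are maximal segments
covered by regions of ≥2 metrics (any shared basepair; no reciprocal
overlap requirement), found by an endpoint sweep and verified against a
per-basepair counting oracle.

## Resequencing readout

Allele frequency from diploid genotype counts, `p = (2n_BB + n_AB)/2n`,
with a ±1-standard-error binomial interval over the 2n chromosomes for the
68% level (z = 1 by convention; other levels use the normal quantile). A
10,000-draw simulation in the tests confirms 60–75% finite-sample coverage
at n = 6 diploids.

## Synthetic cohorts

Two generators, each minimal for the statistic it calibrates:

* **Independent-sites drift** (Fst null/alternative): ancestral frequencies
  uniform on [0.05, 0.95]; binomial Wright–Fisher resampling for t
  generations in each population; cohorts drawn under Hardy–Weinberg, and
  haplotype panels drawn per-haplotype so that collapsing pairs reproduces
  the genotype matrix exactly. Default cohort sizes 156/110 diploids mirror
  a HapMap-scale two-cohort design.

* **Linked-sites forward simulation** (iHS/XP-EHH): N diploids per
  population, Poisson crossovers placed on the cM map each meiosis,
  additive selection s at a focal site starting from one copy in the test
  population, rejection-conditioned on reaching a target frequency band;
  the reference population shares the founder haplotypes and drifts
  neutrally for the same number of generations, so the derived allele is
  private to the test cohort. With s = 0 the focal allele instead starts at
  a standing frequency drawn inside the band and drifts for a fixed 100
  generations — a frequency-matched neutral control. Mutations are placed
  once on the founders (infinite-sites); no recurrent mutation.

**Problem sizes.** Defaults are N = 1000 diploids, 1200 SNPs on 25 Mb at
1 cM/Mb. N must be large relative to the samples: at small N, recent
coalescence leaves sampled haplotype pairs identical over long ranges,
which both inflates ancestral-allele iHH (diluting iHS) and leaves EHH
plateaus near the truncation cutoff. N = 1000 with ≤80-diploid samples
keeps that background small while remaining desk-scale; the map is long
enough that sweep-borne haplotypes decay below the cutoff inside the
chromosome. The end-to-end concordance study uses a larger frame —
N = 2000, 2500 SNPs on 50 Mb, a sweep conditioned to 0.75–0.85 frequency,
and genes tiling the swept interval (`genes_over_sweep_bp`) — because
cross-metric concordance targets sweeps near fixation at genic loci: the
intergenic-null design cannot, by construction, flag a sweep in a gene
desert, and genome-wide Bonferroni thresholds are only meaningful when the
sweep occupies a small fraction of the scanned SNPs.

**What passing does not show.** The generators have constant population
size, no admixture or bottlenecks, uniform recombination unless a map is
supplied, site-independent founder variation, and complete phased data.
Power measured here therefore calibrates the machinery, not human
demography: real-data thresholds still require genome-scale SNP counts, and
phasing error, allele-orientation error and annotation incompleteness are
outside what these tests can certify.

## Numerical and degenerate-input conventions

Coordinates are 1-based inclusive internally; BED converts on read. Sites
monomorphic and identical in both populations yield an undefined (NaN) Fst
record. Zero-variance dosage vectors have undefined R² and never form
edges. EHH walks stop early once EHH reaches 0 (it cannot recover) and
whole-scan results are identical to the per-core definition. Empirical
p-values against an empty intergenic set raise an error rather than
returning a default. All simulators are deterministic given (seed, config),
and pipeline reruns with identical config are byte-identical.

A note on iHS window localization: at 50-SNP window granularity the
top-ranked window reliably falls inside the hitchhiking footprint (within
~1 cM of the favored site) but need not straddle the favored SNP itself —
the MAF bound removes near-fixed hitchhikers at the sweep center, and a
single-origin sweep's footprint is asymmetric, so the peak density of
|iHS| > 2 SNPs often sits on one shoulder. The localization test judges the
window against the footprint for this reason; region-level outputs (LD
clusters over window candidates) recover the favored site itself, as the
end-to-end check shows.
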