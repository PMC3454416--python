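# Methods

## Coordinate model

All coordinates are 0-based, half-open (BED convention). An array CpG probe
is represented by a single genomic point — the first base pair of its probe
sequence — i.e. the 1-bp interval `[pos, pos + 1)`. Gene regions are
extended by a flank (default 2,000 bp) on both sides, clamped to the
chromosome, and merged into a disjoint, non-adjacent union before any
coverage or overlap computation, so overlapping extended regions never
double-count base pairs. Strand is ignored throughout. Probes on
chromosomes absent from the genome definition raise an error rather than
being dropped silently, because silent loss would corrupt the proportion
denominators below.

## Enrichment ratio

For a probe subset of size `n` with `k` points inside a merged track of
`C` covered base pairs on a `G`-bp genome,

    enrichment = (k / n) / ((C − k) / (G − n)).

Each probe occupies exactly 1 bp, so the `k` in-track probe base pairs are
removed from the non-probe covered count and all `n` probe base pairs from
the non-probe total. Degenerate cases: `k = 0` returns 0; a track composed
entirely of probe base pairs (`C = k`) returns +inf. The denominator is the
*whole genome*; because promoter-biased 27k-style arrays sample CpG-dense
regions rather than the genome uniformly, this choice inflates enrichment
relative to an array-background-restricted null. That caveat applies
equally to all subsets compared within a run, and the case-control test
below is immune to it because both groups share the array background.

## Track-randomization Monte Carlo test

Null model: probe coordinates are preserved exactly; the track is redrawn
by, per chromosome, independently permuting the multiset of segment lengths
and the multiset of internal gaps (the distances *between* consecutive
segments), laying them out alternately, and placing the whole arrangement
at a leading offset drawn uniformly from the remaining slack. Only
between-segment distances are constrained — the flanks to the chromosome
ends are free, since they are not distances between regions. Segments never
move across chromosomes, keeping per-chromosome composition fixed. Whether
length/gap *pairings* should be preserved jointly rather than permuted
independently is a genuinely open design point; independent permutation is
this package's documented choice.

The test statistic is the point-overlap count (equal to base-pair overlap
for 1-bp probes), not the enrichment ratio. With `n_mc` null draws
(default 50,000) the empirical P-value is one-sided (greater) with the
add-one convention

    P = (1 + #{null ≥ observed}) / (1 + n_mc),

which is never 0 and has floor 1/50,001 ≈ 0.00002 at the default
resolution. Ties count as extreme. Depletion is deliberately not tested
(no two-sided or lesser alternative): the scientific question is
enrichment, and depleted subsets simply report large P.

Determinism: all randomness flows through a `numpy` `Generator` seeded
explicitly; identical inputs and seed give bit-identical results. In the
pipeline, each report row derives its own seed from the run seed and the
row label via a short hash, so adding or removing a subset does not shift
the seeds of the others.

## Case-control label-permutation test

For two disjoint probe subsets (e.g. hyper- vs hypo-methylated sites of one
age group), the fold difference is the ratio of in-track proportions
(case / control), with sentinels +inf when only the control proportion is 0
and NaN when both are. Significance: case/control labels are permuted
uniformly over the pooled points preserving group sizes (simple label
shuffle without replacement — the standard exchangeability null); the
statistic is the case in-track count, equivalent to the case proportion at
fixed group size; the P-value is one-sided greater with the same add-one
convention. An exhaustive enumerator over all label assignments serves as
the oracle for small pooled sets in the tests.

## Probe partitioning

The significance cutoff is Bonferroni, `alpha / n_probes`, computed from
the probe count observed in the input file (at 27,578 probes and
alpha = 0.05 this is 1.81304e-06). Significance is strict (`p < cutoff`).
A site is *unique* to a group when significant there and not significant
(`p ≥ cutoff`) in both other groups; `≥` keeps the two regimes exhaustive
at the boundary. Hyper/hypo assignment uses strict slope inequalities; a
slope of exactly 0 lands in neither set and is counted and logged. Top-k
selection orders by P ascending with deterministic tie-breaks: |slope|
descending, then probe ID ascending.

## Synthetic studies

The generator emulates the inputs of a promoter-array methylation-aging
study: equal-length chromosomes; `n_genes` non-overlapping gene regions
with log-normal lengths placed uniformly per chromosome; and a probe table
in which each configured significant probe is significant in exactly its
focal age group (signal P ~ U(0, cutoff), elsewhere U(cutoff, 1)), with
|slope| log-normal around 0.005 per year and the sign set by direction.

The planted signal is defined through the placement probability
`q = min(1, ρ·c)`: a hyper-methylated significant probe falls uniformly
inside the merged extended track with probability `q` and uniformly outside
otherwise, where `c = C/G` is the track's coverage fraction. Then
`E[k/n] = ρ·c` and the measured enrichment ratio is `ρ` up to an O(c)
finite-genome correction, giving a closed-form link between the generator
knob and the estimand, so parameter-recovery tests are exact rather than
eyeballed. Hypo-significant and non-significant probes are uniform over the
genome; positions are deduplicated.

Default scale mirrors the study conditions: 27,578 probes; 1,792 gene
regions; ±2,000 bp flank; per-group (hyper, hypo) significant counts
fetal (20, 83), child (287, 154), adult (1,867, 440); planted ρ = 3; a
22-chromosome, 3.08-Gbp genome with log-normal gene lengths
(median 20 kb, σ = 0.6), chosen so the extended merged track covers a
small percent-scale fraction of the genome, as a bivalent gene track does.
When a smaller array is requested without explicit counts, the per-group
counts are scaled proportionally. What the generator does *not* emulate:
array probe chemistry, beta-value distributions, CpG-island clustering of
probes (probes are uniform, not promoter-biased), correlated methylation of
neighboring CpGs, or the age-regression fitting itself — slopes and
P-values are drawn, not fitted. Passing tests therefore demonstrate the
correctness and calibration of the interval arithmetic and resampling
machinery under a known ground truth, not robustness to the spatial probe
bias of real arrays.

## Problem sizes in the test suite

Property and calibration tests run at reduced scale as the package's own
choice of economical-but-sufficient designs: oracle comparisons on 1,000
random instances of ≤100 points × ≤50 intervals; permutation-vs-enumeration
at pooled size 12 with 20,000 Monte Carlo permutations (3-standard-error
band); null calibration over 200 replicate studies at 500 resamples each,
judged against the exact binomial 99% interval around the nominal 5% level;
parameter recovery of ρ = 3 at coverage c ≈ 0.05 averaged over 50
replicates (10% band); randomization uniformity over 1,000 draws
(chi-squared goodness of fit, 10 bins, α = 0.001). The acceptance script
runs the enrichment test at the full 50,000-sample resolution on a compact
study with a strongly planted signal.

## Known limitations

- Whole-genome denominator (see above): absolute enrichment values against
  a promoter-biased array are inflated relative to an array-background
  null; comparisons between subsets within a run are unaffected.
- The randomization null conditions on the observed per-chromosome
  length/gap multisets; tracks whose segments nearly fill a chromosome
  leave little slack and the null collapses toward the observed layout
  (an infeasible layout raises an error).
- Fold differences are ratios of small-count proportions for small subsets
  and are reported without confidence intervals; the permutation P is the
  inferential quantity.
- No liftover: all inputs must share one assembly. No FDR across report
  rows; rows are separate hypotheses reported as-is.
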