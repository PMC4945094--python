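# Methods

`xover` implements the statistical machinery for mapping meiotic crossovers
(COs) at three scales — a multi-megabase selected region, a single ~10 kb
amplicon, and genome-wide interval sets — together with a synthetic-data
generator that provides ground truth for every estimator.  This note records
the models, their assumptions, the parameter choices, and what passing the
synthetic tests does and does not establish.

## Double-selection mapping (`xover.mapping`)

**Model.** A trans-hemizygous F1 carries two selectable insertions on
opposite homologs, flanking the region of interest.  In a backcross, a
gamete transmits both insertions only if an odd number of COs occurred
between them.  For a region of genetic length `c` centimorgans with
`c << 50`, the recombinant gamete fraction is `c/100` and double crossovers
are negligible, so a recombinant gamete is double resistant with probability
1/2 and

    cM = 100 * 2 * (N_dr / N_total),

with a binomial standard error of `200 * sqrt(p(1-p)/N_total)` on the
double-resistant proportion `p`.  The estimator is undefined at `N_total = 0`
and the interpretation breaks as `c` approaches 50 (a half-Morgan region);
both are rejected explicitly.

**Interval maps.** Each genotyped double-resistant individual shows one
Col-homozygous block and one heterozygous block; the CO is placed between
the closest informative markers flanking the single C↔H transition.  Rows
with no transition (non-recombinant within the markers) or with two or more
transitions (double CO or genotyping error) are excluded and tallied in a QC
table rather than silently dropped — the design genotypes exactly one
interval per recombinant.  Missing calls widen an assignment; a widened
assignment is distributed over the elementary intervals it spans
proportionally to physical length (an explicit `wide="error"` mode refuses
them instead).  The full-screen genetic distance is then allocated over
intervals proportionally to the genotyped subset's counts, which is the only
allocation under which per-interval centimorgans sum to the screen total
when only a subset of recombinants is genotyped.

**Hotspot/coldspot tests.**  The global 2×n test compares observed interval
counts with expectations proportional to physical interval length (Pearson
chi-square, default d.f. = n_intervals − 1; the alternative bookkeeping that
counts flank intervals is available through the `df` argument, since either
convention appears in practice).  Per-interval 2×2 tests compare
`(N_i, N − N_i)` with `(E_i, N − E_i)` on 1 d.f. without continuity
correction — the expected row is model-derived, not a second sample —
followed by Benjamini–Hochberg adjustment across intervals.  The
`direction` column ("higher"/"lower") classifies two-sided rejections.

## Pollen typing (`xover.pollen`)

**Titration.**  Limiting-dilution PCR with molecules Poisson-distributed
over reactions: a reaction receiving volume `v` is negative with probability
`exp(-λv)`, so a single dilution gives `λ = -ln(1 - k/n)/v`, with a
Clopper–Pearson interval transformed through the same map.  A dilution
series is pooled by maximizing the product-binomial likelihood in `λ`
(bisection on the score; profile-likelihood 95% CI at the χ²₁ cutoff).
An all-positive plate has no finite estimate and raises an error advising
further dilution.  The amplicon genetic distance is
`cM = 100 * c_co / (c_co + c_par)`: the crossover assay amplifies one of the
two reciprocal CO classes and the parental assay one of the two parental
classes, so the factors of two cancel.

**Read classification.**  Reads are placed by exact full-length matching
against the two parental haplotype sequences, both strands (seed-free
two-haplotype search; the amplicon is small enough that direct substring
search is exact and fast).  A read matching both haplotypes covers no SNP
and is `ambiguous`; matching one haplotype at more than one position is also
`ambiguous` (non-unique); matching neither — e.g. any sequencing error under
exact matching — is `unmapped`.  These are statuses, never exceptions.  The
template holds both haplotypes in one indel-free coordinate system; a
length mismatch at load time is an error, since the assay's primers flank
indel polymorphisms and the coordinate system assumes they are normalized
out.

**Filter cascade.**  Classified pairs pass sequential filters named after
the attrition table they produce: Mapped (both ends placed), Unique
(neither end ambiguous), Matched (one Col and one Ler end), Orientate (the
Ler end at the lower coordinate; `orientation="col-left"` flips the
polarity for amplicons read in the opposite genomic orientation — the
correct polarity depends on which strand the amplicon was amplified from,
so it is a flag, not a guess), and Strand (opposite strands).  Dropped
records keep a `dropped_at:<filter>` status; the cascade is idempotent on
retained records and drops+retained always equals input.

**Fractional interval assignment.**  A retained pair constrains its CO to
an uncertainty gap of `d` bp; each bp receives `1/d`, so a SNP-delimited
sub-interval of width `w` inside the gap accrues `w/d`.  Two gap
definitions are provided: `inner-gap` (the unsequenced interior between the
two reads; reproduces the canonical 200 bp → 0.005/bp example) and the
default `snp-bounded` (shrunk to the span between the last Ler-supporting
SNP and the first Col-supporting SNP, the tightest region the data
support).  Overlapping reads (`d ≤ 0`) are excluded as `dropped_at:gap`.
Accumulated weights are normalized by the number of pairs used, so the
profile sums to one; normalization by all mapped pairs instead of retained
pairs would only rescale the profile uniformly.

**Resolution caveat.**  The 1/d scheme distributes weight across the gap
proportionally to sub-interval width.  A true hotspot much narrower than
the typical gap therefore leaks weight into wider neighbouring intervals,
and crossovers inside a SNP desert wider than a sequencing fragment are
undetectable (no flanking read can reach a SNP).  Both are properties of
the assay, not of this implementation; the recovery tests place hotspots in
SNP intervals of width comparable to the fragment inner gap (~250 bp)
because that is the scale at which the assay is informative.

**Sanger molecules.**  A single CO molecule reads as one haplotype for a
prefix of SNPs and the other for the suffix; the CO interval lies between
the last SNP of one and the first of the other.  Molecules with more than
one switch are excluded as complex and reported.  Interval rates are
`amplicon_cM × (count_i/n) / (width_i/10⁶)`.

## Overlap nulls (`xover.overlap`)

Gene clustering alone changes how many genes are expected to overlap a CO
interval set, so observed overlaps are judged against a clustering-matched
null: `n` blocks of length `b` are dropped uniformly on the genome and each
background gene whose start falls in a block is kept with probability `p`.
Blocks may overlap (independent uniform placement; forbidding overlap
changes expectations negligibly at realistic parameters).  The `(n, b, p)`
triple is fitted by grid search minimizing the sum of two-sample
Kolmogorov–Smirnov sup-distances between sample and target on (i) distances
between consecutive gene starts and (ii) gene widths, averaged over a
configurable number of draws per grid point (default 10).  The KS statistic
is computed exactly on the empirical CDFs; no asymptotic p-value is needed
for an argmin objective.  Identifiability requires a background
substantially denser than the block length — with mean gene spacing near
`b` the (b, p) pair trades off along a ridge.

The observed target-set overlap is placed on the resampled null with the
`(r+1)/(n+1)` quantile convention (no zero p-values); the two-sided p
doubles the smaller tail.  Overlap itself is "≥ 1 shared bp" in half-open
BED coordinates, computed by merge-and-search and verified against an
O(n²) oracle in the tests.

The block-bootstrap Z test resamples the *interval* set instead: intervals
are grouped into genome blocks of `block_len` by start coordinate and each
block receives an independent circular shift per replicate, preserving
within-block clustering; the statistic (overlapped bp by default, interval
count optionally — both are provided since either is a reasonable choice)
is standardized by the null mean and SD, with a one-tailed normal p on |Z|.
A statistic invariant under shifting (e.g. features covering the whole
genome) has SD 0 and is rejected explicitly.

## Motif scanning (`xover.motif`)

The default matrix is the degenerate PWM of a CTT-repeat 16-mer consensus
(weight 1 on the consensus base), under which the normalized score
`(S − S_min)/(S_max − S_min)` is exactly the fraction of matching
positions, making "≥ 80% identity" a 0.8 score threshold; a count-matrix
constructor with optional pseudocount covers weighted motifs.  Windows are
scanned on both strands with minus-strand hits reported at their mirrored
forward offset; overlapping hits are all reported, which matters for repeat
motifs.  Promoter windows default to TSS ± window/2, with a
`tss-downstream` anchor as the alternative reading of "windows around the
TSS" — the two conventions genuinely differ and neither is claimed
canonical.  Genes are split into high/low recombination classes by the rate
of the map interval containing their TSS (default threshold 4.82 cM/Mb, a
male Col×Ler genome-average rate); the motif-presence × class 2×2 table
uses the Yates-corrected chi-square by default — the corrected statistic is
the one consistent with the association p-value this analysis is known for,
while the uncorrected Pearson value (≈6.89 vs ≈5.76 corrected on the same
table) is exposed via `correction=False`.

## Fluorescent pollen (`xover.ftl`)

Pollen from an FTL/++ hemizygote falls into four fluorescence classes;
yellow-alone (Y) and red-alone (R) grains are recombinant, both-colors (RY)
and colorless parental.  Genetic distance is `cM = 100·Y/(Y+RY)` with the
binomial SE of the proportion.  Genotype effects are tested with a binomial
GLM (logit link) on recombinant successes out of trials, genotype and
replicate entering as fixed-effect indicators (treatment coding against a
reference genotype); Wald z/p per genotype.  The GLM's recombinant
definition defaults to Y out of Y+RY, matching the cM formula's
denominator; the alternative (Y+R out of total) is a flag.  IRLS runs to a
deviance tolerance of 1e-10 (≤ 50 iterations) via statsmodels.  A genotype
with zero or all recombinants separates the likelihood: its coefficient is
reported as ±∞ and its p-value falls back to Fisher's exact test of pooled
counts against the reference.

## LD-map post-processing (`xover.ldmap`)

Population-scaled maps (ρ = 4Nₑr per SNP interval) are masked by setting
intervals with ρ > 100 or SNP spacing > 50 kb to zero (per-interval
application of the thresholds — the map's native resolution; the filter is
idempotent and refuses an already-rescaled map).  Rescaling aggregates ρ
onto experimental-map intervals by length-weighted mean and fits
experimental cM/Mb on aggregated ρ by OLS with intercept (an
intercept-free option is provided; "regression onto" does not pin the
form), then applies the fitted line to the whole map, clamping negative
predictions to zero and counting them.  Constant ρ carries no scale
information and maps to the experimental mean with slope zero.

## Synthetic data (`xover.simulate`)

The generator reproduces the statistical structure each estimator assumes,
with all randomness drawn from one explicitly passed seed/Generator (fixed
seed ⇒ bit-identical output).

* **Backcross screens**: piecewise-constant rate map (total ≤ 50 cM
  enforced); each gamete recombinant with probability total_cm/100, at most
  one CO per gamete — adequate for the ≤ ~23 cM regions this design
  targets, and consistent with one transition per genotyped recombinant;
  CO positions ∝ rate × interval length; double-resistant recovery with
  probability 1/2.  Defaults mirror a cluster screen: 9,016 progeny, 94
  markers, ~22.8 cM over 3.87 Mb, a 30× hotspot interval, 700–725
  genotyped recombinants.
* **Read-pair libraries**: every molecule is a Ler|Col chimera at its CO
  (the configuration the crossover allele-specific PCR amplifies);
  fragment lengths Normal(350, 35) truncated to [2×read_len, amplicon],
  75 bp reads from the fragment ends on opposite strands, uniform
  substitution errors only (no indels — sufficient to exercise an
  exact-match classifier; error rate capped below 5%).
* **Amplicon templates**: ~9.4 kb, 40 SNPs on a jittered regular grid
  (±40% of the mean spacing, ≥ 20 bp apart), GC 0.36 — emulating the
  fairly even Col/Ler polymorphism density of a pollen-typing amplicon
  without deserts wider than a fragment.
* **Clustered genes**: uniform cluster anchors, exponential within-cluster
  start spacing (default scale 4 kb), lognormal widths (median 3 kb),
  overlaps resolved by shifting, plus an unclustered background set.
* **Pollen counts**: multinomial over the four classes at
  (r/2, r/2, (1−r)/2, (1−r)/2) for recombinant fraction r.
* **Titrations**: reaction positive with probability 1 − exp(−λv).

**What the synthetic tests show.**  Passing them demonstrates estimator
correctness and calibration under the generating assumptions: single COs
per gamete, error-free genotyping unless injected, substitution-only
sequencing noise, independence across gametes/molecules/grains, and
homogeneous amplification.  Real data add genotyping error correlated
along chromosomes, PCR chimeras and amplification bias, segmental
duplications breaking unique exact matching, and FTL silencing — none of
which the generator emulates, so agreement on synthetic data bounds only
the statistical, not the experimental, error.

## Problem sizes in the test suite

The suite exercises recovery at the scale of the original screens where
that is cheap (9,016 progeny; 700–725 genotyped recombinants; 94 markers;
10⁴ read pairs; 30,000 grains × 19 genotypes × 3 replicates) and uses
100–500 replicates for coverage/calibration checks, with 100–200
resampling replicates inside each overlap null.  These sizes keep the full
suite around two minutes while leaving the binomial/multinomial noise terms
small relative to every tested tolerance.
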