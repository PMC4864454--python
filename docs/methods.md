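# Methods

`a3gscan` screens multi-species alignments for clusters of germline
substitutions bearing the mutational signature of APOBEC3G (A3G), a
primate cytidine deaminase that converts C→U on single-stranded DNA with
a preference for CC/CCC contexts.  This note describes the models and
procedures the package implements, the choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show
about real data.

## Mutation calling

Lineage-specific substitutions are called from a four-taxon alignment
`((target, sister), outgroup1, outgroup2)` by outgroup-confirmed
parsimony: the ancestral state of the target/sister ancestor is the
sister allele whenever it equals at least one non-missing outgroup
allele, and a mutation is called wherever the target allele differs from
that state.  Columns are discarded when the target or sister allele is
missing (any non-ACGT symbol; soft-masked bases are uppercased, not
dropped), when both outgroups are missing, or when any exclusion mask
(repeats, segmental duplications) covers them.  The count of surviving
columns is the *callable length*, the denominator of the per-bp mutation
probability π used by the cluster score.

Two deliberate simplifications are inherited from the parsimony design:
sites where the target matches an outgroup but not the sister are still
called (possible homoplasy; rare at the per-branch rates the screen
assumes, and bounded by the tests at ≤2% false calls at rate 1e-3), and
no attempt is made to model back-mutation.

Sequence context for motif evaluation is read from the target sequence
with the inferred ancestral allele substituted at *every* called site,
so each mutation's context describes the pre-mutation haplotype even
when neighbouring sites were also hit.  A `context_mode="reference"`
flag substitutes only at the focal site for sensitivity analysis.

For the three-descendant scenario (modern plus two archaic lineages),
per-lineage allele tracks assign each mutation to `common` (derived in
all tracked lineages), a single lineage (derived in exactly one), or
`unassigned` (strict subsets or missing data; excluded from
branch-specific sets).

## Clustering and the cluster score

Clusters are maximal chains of ≥2 mutations in which consecutive
positions differ by ≤50 bp (100/300/1000 bp supported).  On sorted
unique positions, consecutive-gap chaining is equivalent to connected
components of the all-pairs within-window graph; the test suite checks
this equivalence against a quadratic union-find oracle.  Clusters
containing a consecutive pair ≤10 bp apart are removed entirely as
potential complex mutations (a single replication/repair tract), and
clusters mixing ancestral bases are typed `N` and excluded from
coordinated-cluster statistics; both are written to side files rather
than silently dropped.

The cluster score is the probability of observing k−1 further mutations
within x−1 bp of the first, with x the cluster span and π the
genome-wide per-bp mutation probability:

    p(k, x; π) = Σ_{j=0}^{x−k} C(k−2+j, j) (1−π)^j π^{k−1}

i.e. the lower CDF at x−k failures of a negative binomial with k−1
successes and success probability π, equivalently P(Binomial(x−1, π) ≥
k−1).  The binomial coefficient is the standard negative-binomial form
that makes the verbal definition exact; tests pin the implementation to
a term-by-term summation (1e-12), the k=2 geometric closed form
1−(1−π)^{x−1}, and Monte-Carlo window frequencies (1e7 replicates, 4σ).
π is computed per lineage from its own mutation count over the callable
length.

Expected counts under the independence null use the printed identities
`Σ N_i p^i` (all mutations of a cluster sharing one ancestral state,
with p the prevalence of that state) and `Σ N_i (1−(1−p)^i)` (at least
one motif mutation, the closed form of the binomial sum), with
cluster-wise binomial variances for the calibration bands.

## Motif enrichment

The signal for a motif is the fraction of clustered mutations sitting at
the motif's mutated position, pooling C-coordinated clusters (plus
strand) with G-coordinated clusters (matched through the motif's reverse
complement).  Built-in motifs follow the deaminase signature literature,
with the mutated position at the 3′-most C except TC (its only C) and
TCW (middle C): A3G CC/CCC, A3B TC/TCW, A3F TTC, AID WRC, and the mouse
A3 TYC negative control; all are configurable as `PATTERN:INDEX:LABEL`.

Enrichment E = signal/background is computed against four backgrounds:

* **genomic** — motif occurrences on both strands over C+G counts
  (both-strand counting keeps the background consistent with the pooled
  C/G signal);
* **random mutations** — each mutation is relocated uniformly to a
  callable position carrying the same ancestral base, the randomised set
  is re-clustered with identical parameters (including any p-value
  threshold), and the pooled motif fraction is taken over replicates
  (default 100).  Base-matched placement is the default because signal
  and background are defined per ancestral base; an unconstrained mode
  is available;
* **random clusters** — every coordinated cluster is relocated to a
  uniform random locus preserving span, internal offsets and mutation
  types; relocated positions that carry the cluster's ancestral base
  enter the denominator and motif matches the numerator;
* **local context** — motif over ancestral-base occurrences inside the
  union of 10-kb windows centred on cluster midpoints, clipped at
  chromosome ends.

One-tailed exact (hypergeometric) tests compare mutation counts in/out
of the motif against background counts, with Bonferroni correction
across the motif panel of one invocation; the regional analyses use
two-tailed tests with Bonferroni or Benjamini–Hochberg.  A zero
background is reported as an infinite-E flag rather than an exception.
Zero cells are handled by the exact computation; no continuity
corrections.

The 48-triplet scan evaluates every trinucleotide with a C at each of
its three positions (16 patterns per mutated position) as an independent
motif against the genomic background, flagging CpG-containing triplets
(`CG` anywhere in the pattern).  A property worth knowing when reading
scan output on strongly clustered signals: a mutation whose context is
CCN necessarily matches several registers at once (CCC at index 2 and
CCN at index 1), so sister registers of a genuinely active motif can
reach significance alongside it.  On weak, real-data-scale signals this
leakage stays below the significance threshold; on dense synthetic
signals it does not.  The scan reports all 48 rows so the reader can see
the register structure rather than a single winner.

CpG controls separate enzymatic CCC enrichment from spontaneous
deamination of methylated CpG: (a) a CpG-filtered mutation set (mutated
C immediately 5′ of G on its strand) against a CpG-masked genomic
background; (b) exclusion of CCCG contexts from signal and background;
(c) an additivity decomposition of per-site mutation rates over
CCC-only, CpG-only, CCC∩CpG and neither strata (a CCCG mutation belongs
to the intersection stratum).

## Regional analyses

The putative enzyme-induced set is the union of mutations in C/G
coordinated clusters containing at least one CCC (or GGG
reverse-complement) mutation; the control set is all other mutations.
Per-region fold change is `(a3g_in/a3g_total)/(control_in/control_total)`
with membership decided by the single-base position in half-open
intervals; clusters are assigned per mutation, not per cluster.
Expression deciles are length-weighted base deciles over interval
levels; the Pearson correlation of fold change against mean decile level
is reported over the first nine deciles, with the top decile reported
separately (highly transcribed regions are expected to be unusually
constrained).  The branch comparison tests, per region family, the 2×2
table of in-region A3G vs control counts between two branches
(two-tailed exact test, FDR-adjusted).

At desk-scale mutation densities (π ≈ 1e-3–2e-3), pair clusters are
individually nonsignificant (p(k=2, x≤51) ≥ 0.04), so thresholding at
p < 0.01 before defining the enzyme set would silently move roughly half
of the genuine events — and their expression gradient — into the control
set and compress every regional contrast.  The regional analyses
therefore accept the unthresholded coordinated-cluster set by default in
the synthetic scenarios, where chance clusters contribute under 1% of
it; at genome scale, where chance clusters dominate, the p < 0.01
definition is the appropriate one and is what the pipeline's default
configuration applies.

## Error estimation

Standard errors come from a block bootstrap: the callable genome is
tiled with contiguous ~90-kb blocks (the last block of a chromosome may
be short), blocks are resampled with replacement, pooled, and the
statistic recomputed; the SD across replicates is the SE, with 2.5/97.5
percentile intervals alongside.  The production default is 10,000
replicates; the test suite uses 200–2,000 except for the calibration
check, which runs the full 10,000.  By default backgrounds are held
fixed across replicates (recomputing them per replicate is available but
costly); SEs therefore reflect sampling variation of the signal, not of
the background, which is estimated from far more observations.

## Synthetic data generator

The generator emulates the inputs of the screen on a single short
chromosome:

* **Ancestral sequence** — i.i.d. bases at a target GC fraction
  (default 0.41).  CpG dinucleotide frequency is rescaled by a
  multiplier using composition-preserving transpositions (a distant G is
  moved next to a C, or the G of a CG is moved away), converging by
  recount; multipliers of roughly 0.1–2.5 are supported before the
  transposition pools exhaust, which covers the biologically relevant
  depleted range.
* **Branch substitutions** — independent per-site Bernoulli draws on
  each branch of the fixed tree shape, derived alleles uniform over the
  three alternatives; rates above 0.1/bp are rejected because the
  parsimony caller assumes low homoplasy.  CpG sites mutate at
  `multiplier ×` the branch rate, 90% transitions.
* **Planted events** — event counts are Poisson(rate × length); each
  event draws a size from a truncated geometric on 2..5 (the in-vivo
  distribution of mutations per deamination event is unknown; this is a
  modelling choice, configurable), a strand (reverse with probability
  0.5, reflecting a strand-symmetric free enzyme), and a chain of
  same-strand cytosines spaced 11–50 bp apart so that planted clusters
  exercise the intended acceptance path of the ≤10 bp complex-mutation
  exclusion (a separate configuration deliberately violates it).  Each
  mutation slot's motif class — the 3′ C of a CCC context with
  probability `motif_fidelity`, otherwise a CC that is not CCC — is
  committed *before* positions are searched; re-anchoring on placement
  failure then cannot bias realised motif fractions (per-attempt
  redrawing would skew them toward the denser CC class, measurably:
  ~0.6 realised at nominal 0.8).  Rare class sequences that defeat
  rejection sampling (long all-CCC chains) are placed by a deterministic
  backward viability sweep over the motif pools, which finds a
  class-consistent chain whenever one exists and otherwise raises an
  error reporting the achievable event count.  Derived alleles are C→T
  with probability 0.7, remainder split C→G/C→A, matching the
  transition-heavy signature of the enzyme.
* **Expression-weighted planting** — `by_level:<track>` weights event
  anchors by the covering interval's level, emulating preferential
  activity on transcribed (single-stranded) DNA.
* **Lineage assignment** — whole events (they occur in one generation on
  one branch) and individual background mutations are assigned to
  `common` or one of three descendant lineages with configurable
  proportions, and allele tracks are emitted accordingly.

Defaults define the baseline study conditions used throughout the tests:
2 Mb, background 1e-3/bp on the target branch, ~300 events
(rate 1.5e-4/bp) at fidelity 0.8.

What the generator does **not** emulate: indels and alignment gaps,
recombination, selection, rate heterogeneity along the chromosome,
demographic history, or archaic sequencing error.  Consequently, green
tests demonstrate the correctness and calibration of the statistical
machinery under its own assumptions — not robustness to alignment
artefacts or non-equilibrium base composition, which real analyses must
address through the mask inputs.

## Numerical choices and degenerate inputs

Coordinates are 0-based half-open everywhere internally; BED is native
and any 1-based conversion happens at I/O boundaries only.  Cluster
p-values use `scipy.stats.nbinom.cdf` (no manual summation in the
production path).  Overlapping annotation intervals are merged with
length-weighted levels; merging adjacent intervals never changes any
count.  Empty mutation sets, zero-variance enrichment series, and
all-A/T genomes raise typed errors (`UndefinedStatisticError`) rather
than returning NaN; an all-constant bootstrap statistic returns SE
exactly 0.  Randomised backgrounds may occasionally produce replicates
with no coordinated clusters; such replicates are skipped and the
pooled counts reflect the rest.

## Known limitations

Long sparse clusters broken by interleaved mutations are not detected
(a conservative choice shared with the chaining definition).  The
random-mutation background samples positions with replacement within a
replicate; duplicate positions (rare at realistic densities) are
dropped.  The registered-triplet scan's sister-register leakage under
dense clustered signal is discussed above.  CpG enrichment multipliers
beyond ~2.5 exhaust the transposition pools and raise an error rather
than silently under-delivering.
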