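# Methods

## Scope and objects

The package works with four kinds of objects: unphased multi-locus genotypes
(per-locus unordered allele pairs over an ordered locus set, by default HLA
A/B/C/DRB1), population haplotype-frequency tables f_k(h), match
stringencies (a considered locus subset plus an allele-mismatch budget:
8/8 = four loci / 0 mismatches, 7/8 = four loci / 1, 6/6 and 5/6 the
analogues after one locus is dropped), and registries (populations with
registered donor counts and availability rates). Allele codes are opaque
strings: no HLA nomenclature parsing, truncation or G/P-group logic is
attempted, and genotypes with missing typings are rejected rather than
imputed.

## EM haplotype-frequency estimation

A genotype heterozygous at H loci decomposes into 2^(H-1) unordered phase
pairs. The E-step assigns each observed genotype to its decompositions with
weights (2 − δ(h1,h2)) f(h1) f(h2), normalized per genotype; the M-step sets
f(h) to the expected gamete count divided by 2n. Identical genotypes are
aggregated with multiplicities before iteration, so cost scales with the
number of distinct genotypes, not the sample size.

Numerical choices (the source analysis specifies none, so these are package
decisions):

- convergence when |Δ log-likelihood| < 1e-8, capped at 1000 iterations;
- support restricted to haplotypes compatible with at least one observation
  (every genotype therefore has positive probability at any interior point,
  so the E-step can never divide by zero);
- default initialization is uniform over the support; `init="random"` draws
  a flat-Dirichlet start from `random_state`. The uniform start can be a
  stationary point of a likelihood ridge — a dataset of only double
  heterozygotes leaves the four compatible haplotypes at 0.25 forever —
  which is the correct fixed point of the likelihood but not a unique
  maximizer; random restarts are how such multimodality is exposed. Ties are
  not broken automatically: the result reports the attained likelihood, the
  init used and the seed.
- frequencies below 1e-12 are pruned and the table renormalized (far below
  any frequency that could matter at registry scale);
- the observed-data log-likelihood is asserted non-decreasing at every
  iteration; a decrease beyond round-off raises immediately.

The estimator is exposed in scikit-learn form (`HaplotypeFrequencyEM` with
`fit`, `score`, `get_params`/`set_params`, fitted attributes `table_`,
`log_likelihood_`, `n_iter_`, `converged_`); the rest of the pipeline
(frequency algebra, registry model, generator) is functional because nothing
in it is fit/predict-shaped.

The test oracle for EM optimality uses the fact that every phase
decomposition of a genotype carries the same per-locus alleles, so any EM
fixed point has haplotype margins equal to the sample allele frequencies;
on 2-locus/2-allele data the MLE therefore lies on a one-parameter family
that can be scanned on a fine grid (step 1e-5, giving a likelihood gap
well below the 1e-6 comparison tolerance).

## Frequency algebra

Dropping a locus from consideration is marginalization: reduced-haplotype
frequencies are sums over the dropped locus's alleles, preserving total
mass exactly. HWE genotype probabilities and per-donor match probabilities
q_k(g) are computed from an exhaustively enumerated genotype-probability
map (one O(H²) pass over unordered haplotype pairs; distinct phase pairs
that collapse to the same unphased genotype are accumulated). Mismatch-
tolerant q scans this map rather than generating mismatch neighborhoods —
simpler and exact at the supports this package targets. Exact enumeration
is capped at 2×10⁶ haplotype pairs (a few seconds of scan time); larger
supports must use the registry model's Monte Carlo mode. Per-locus mismatch
is 2 minus the multiset intersection of the two allele pairs (homozygotes
count their allele twice), summed over considered loci with a total budget;
for a budget of 1 this coincides with "a single allele mismatch at any
considered locus".

## Registry match likelihood

Effective donor counts N_k = donors × availability are kept real-valued and
used directly as exponents: the at-least-one-match probability for patient
genotype g is 1 − Π_k (1 − q_k(g))^{N_k}, evaluated as
exp(N_k·log1p(−q_k)) for stability with tiny q and large N (q = 1
short-circuits the factor to zero). Donors of every population count toward
every patient's search. The patient genotype is drawn from the patient
population's own HWE distribution; exact mode takes the expectation over
the enumerated patient genotype map, Monte Carlo mode averages over sampled
patient genotypes (default 100,000, seed mandatory) and reports the
standard error of the mean. Sampled genotypes are deduplicated before the
q computation, so the Monte Carlo cost is bounded by the distinct-genotype
count.

The locus-drop report tabulates, per patient population, the full-locus
baseline likelihoods (8/8, 7/8), each dropped locus's 6/6 and 5/6
likelihoods, and the absolute gains (6/6 over 8/8, 5/6 over 7/8) — the
"open bar" increments of a stacked presentation. Implied orderings
(8/8 ≤ 7/8 ≤ 5/6, 8/8 ≤ 6/6 ≤ 5/6, monotonicity in every N_k) hold by
construction and are enforced in the test suite.

## Synthetic data

The generator emulates the structure the analysis assumes about a real
registry without simulating genetics it never models: linkage
disequilibrium is induced by drawing each population's support as a sparse
subset of the allele-combination space (frequencies live at the haplotype
level, never as allele-frequency products); a configurable fraction of each
support comes from a shared pool, the rest is population-private;
frequencies are symmetric Dirichlet draws with concentration 0.5 by default
(skewed spectra, as real HLA tables show). One master seed is split via
`numpy.random.SeedSequence` into named substreams (stream 0 for support
sampling, stream 1+i for population i's frequencies), so runs are
bit-reproducible across platforms.

What the generator does **not** emulate: realistic HLA allele spectra or
nomenclature, typing ambiguity, admixture, recombination, or the
within-population relatedness of real registries. Passing tests therefore
demonstrate correctness of the estimation and matching machinery under the
model's own assumptions, not calibration against any real registry; the
actual registry haplotype frequencies and availability rates needed for
real-world numbers are proprietary and are deliberately out of scope.

### The packaged minority scenario

Two populations over 4 loci with 6 alleles each: a majority population
(20 haplotypes, 90% shared with the common pool, 4000 registered donors at
0.6 availability → N = 2400) and a minority population (36 haplotypes —
individually rarer — only 10% shared, 500 donors at 0.4 availability →
N = 200). Sizes were chosen once so the likelihoods sit in an informative
regime (minority baseline around 0.6–0.75, majority near but not at 1.0,
across seeds) rather than saturating at 1; with these counts the scenario
reproduces the qualitative pattern of interest at every seed tested: the
minority baseline full-match likelihood is strictly below the majority's,
and dropping any single locus strictly increases every population's
likelihood. The `paper-replica` command runs simulation → EM → report on
this scenario and exits with status 3 naming the violated inequality if the
pattern ever fails.

## Problem sizes

Defaults used by the replica workflow and the acceptance script: 1500 donor
genotypes sampled per population for the EM step, exact-mode likelihoods
(patient maps of at most 666 genotypes), 20,000 Monte Carlo samples for the
exact-vs-MC consistency check and 10,000 replicates for the registry
simulation oracle on a 40-donor registry. These sizes keep every
stochastic check's standard error small relative to the effects measured
while completing in seconds.

## Known limitations

- Typing ambiguity (serologic vs allele-level) is not modeled; the EM
  assumes fully resolved allele-level typings.
- The mismatch budget is totaled across loci rather than capped per locus;
  the two definitions coincide for the budget-1 criteria used here.
- No standard errors on estimated haplotype frequencies; uncertainty in the
  registry likelihood induced by EM error is assessed empirically (the
  end-to-end recovery test bounds it at 0.02 absolute for the standard
  scenario) rather than analytically.
- Patient populations are treated as unadmixed members of one registry
  population.
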