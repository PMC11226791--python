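# Methods

## The mating model

We track a large (effectively infinite) population of hermaphroditic plants
with perfect flowers. Two biallelic loci (A/a, B/b) at recombination
distance `r` define four haplotypes: neutral AB, killer Ab, sensitive aB and
suicide ab. During male gametogenesis, pollen carrying allele `a` dies with
probability `k` whenever the parent plant carries at least one `b` allele
(sporophytic toxin, gametophytic rescue). Female gametes are untouched.
Ordered by phase, there are ten diploid genotypes; the two double
heterozygotes AB|ab and Ab|aB are distinct states because they produce
different recombinant pollen.

One generation proceeds as:

1. **Gamete matrices.** For genotype h1|h2, mass (1−r)/2 goes on each
   parental haplotype and r/2 on each recombinant; the female matrix Gf is
   exactly this, the male matrix Gm additionally multiplies every
   a-carrying entry by (1−k) in b-carrying genotypes. Rows of Gf sum to 1;
   male row sums below 1 measure pollen lost to killing.
2. **Pollen pool.** Cross-pollination draws from a common pool with
   haplotype frequencies f ∝ Gmᵀθ. The pool size M_pool is a constant of
   the model — killing only reshuffles pool composition, never the amount a
   flower receives from outside.
3. **Fertility.** A flower of genotype i has pollen
   N_i = M_pool + M_self·rowsum(Gm_i) available and fertility
   φ_i = min(1, N_i·R/(M_pool+M_self)). R ≥ 1 is the pollen redundancy
   level; at R = 1 any pollen loss costs fertility one-for-one, at R = 10 a
   flower tolerates a 90% loss.
4. **Offspring.** The female gamete (row of Gf) meets a pollen haplotype
   drawn from the mixture of self pollen (mass M_self·Gm_i) and pool pollen
   (mass M_pool·f), normalized by N_i. Next-generation frequencies are the
   fertility-weighted offspring masses θ′_j ∝ Σ_i θ_i φ_i p_ij,
   renormalized. Renormalization is required because the masses sum to the
   population mean fertility (< 1 whenever killing bites); frequencies must
   remain a probability vector.

Only the ratio of M_self to M_pool matters, and it equals the selfing rate
s = M_self/(M_self+M_pool); we fix M_self + M_pool = 1.

### Parameters

| name | meaning | range | default |
| --- | --- | --- | --- |
| r | recombination rate between toxin and antidote loci | [0, 0.5] | — |
| s | selfing rate (probability a flower receives own pollen) | [0, 1] | — |
| k | killing efficiency of a-pollen in b-carriers | [0, 1] | 1 |
| R | pollen redundancy (delivered / needed) | ≥ 1 | 10 |

`k = 1` throughout the reference experiments; the parameter is exposed but
its exploration is out of scope. `s` may be exactly 0 or 1; near-zero
selfing in reference runs uses the literal value 1e−5 rather than a special
case.

### Stop rules and equilibrium classes

Long-run iteration stops when the killer or sensitive haplotype crosses a
loss threshold, or after `max_generations` (default 10,000). Two threshold
conventions exist in the literature this model follows, and both are
implemented: an absolute cutoff (frequency < 0.001, the default) and a
relative one (< 1% of the haplotype's own initial frequency). They agree on
every reference scenario; the relative rule is the default for the
mutation-origin scenario, where the killer *starts* at 0.001.

Terminal states are classified by which haplotypes exceed a presence
threshold (10⁻³): fixation of killer, sensitive or neutral, or coexistence
of neutral+sensitive or neutral+killer. Killer and sensitive cannot coexist
at equilibrium — every Ab×aB fusion costs the `a` allele more than the `A`
allele — so any other presence set is reported as `unresolved`. Two
boundary effects deserve note. At s = 1 exactly, killer and sensitive pure
lines never exchange gametes, so an initial mixture of homozygotes is
stationary and both persist trivially; the non-coexistence argument
presumes some outcrossing. And a few extreme parameter combinations (r near
0.5 with s near 1) decline so slowly that the 10,000-generation cap fires
mid-transient; given a longer horizon these converge to a non-coexisting
state, which the test suite verifies explicitly at a 50,000-generation cap.

### Neutral limits

With k = 0 the model is selectively neutral: per-locus allele frequencies
are exactly invariant for every r, s, R, and haplotype frequencies are
invariant under full linkage (r = 0). With r > 0, recombination moves
haplotype frequencies toward linkage equilibrium even without killing —
phase imbalance between AB|ab and Ab|aB double heterozygotes converts into
haplotype change — so haplotype-level invariance is deliberately *not*
asserted away from r = 0.

## Numerical experiments

Invasion runs start from killer homozygotes at frequency f0 against
sensitive homozygotes at 1−f0. The fate is `eliminated` if the terminal
killer frequency is below 10⁻³, otherwise `increased`/`decreased` against
f0. Threshold searches bisect on r ∈ [0, 0.5] or s ∈ [0, 1] to tolerance
10⁻³, judging spread from the terminal state of a full run; brackets are
verified at both ends, and if the fate is not monotone across the bracket
(it is not at the degenerate s = 1 endpoint) a 0.005-step grid scan
locates the boundary before a local bisection refines it. The minimum
invasion frequency instead uses a 100-generation horizon (frequency after
100 generations above the start), bisected to 10⁻⁴; both horizons are
configurable.

The mutation-origin scenario introduces killer homozygotes at a small
frequency (default 10⁻³) into a neutral+sensitive stand as a one-shot
conversion of neutral mass; recurrent mutation is out of scope. At full
linkage the killer can only cannibalize sensitive mass, so its maximum
frequency is capped by the initial sensitive frequency.

## Introgression statistics

f4(A,B;C,D) is the mean over sites of (p_A−p_B)(p_C−p_D) on derived-allele
frequencies; sites with missing values are excluded. For a genomic region,
the introgression indicator is the maximum of |f4| over every four-taxon
subset arranged so the species tree restricted to it has unrooted topology
[(A,B),(C,D)] — under that arrangement f4 has expectation 0 without gene
flow, in either sign's direction, which is why the absolute value is used.
Subsets whose restriction is a star are skipped with a warning.
Tree-inconsistent arrangements (nonzero expectation under the tree) are not
enumerated. Outlier ranks against a user-supplied or simulated null sample
use the add-one empirical rule p = (1+#{null ≥ obs})/(1+n), and ranks from
several loci combine via Fisher's method (X² = −2Σ ln p, χ² with 2m df).

## Synthetic data

**Wright–Fisher oracle.** Each of N diploid offspring draws a maternal
flower with probability ∝ (empirical genotype frequency × fertility) — soft
selection — then a genotype from that flower's offspring distribution;
equivalently a multinomial draw from the deterministic update of the
empirical frequencies. Its replicate mean converges to the recursion as N
grows; the suite checks agreement within three Monte-Carlo standard errors
at N = 10,000 over 200 replicates at generations 1, 10 and 50. This
construction is one reasonable finite-population counterpart, used as a
convergence oracle, not as a claim about any particular species' demography.

**Species alleles.** Each site draws a root frequency uniform on
[0.1, 0.9] and accumulates independent zero-mean Gaussian increments with
variance `intensity × branch length` down the tree, truncated to [0, 1];
truncation slightly biases extreme sites, so the default intensity (0.02
per unit branch) is kept small enough that E[f4] = 0 holds within
Monte-Carlo error, which the tests verify rather than assume. An
introgression event replaces the recipient's frequency by the donor's at a
seeded uniform choice of sites. This is the simplest generator with the f4
null property the statistic assumes — deliberately not a coalescent; it has
no linkage, no mutation model and no sampling noise, so passing tests show
correctness of the statistics, not realism of rice data.

**Fixtures.** `write_fixtures` emits a ladder species tree of seven
populations (mirroring the shape of an AA-genome *Oryza* phylogeny), a
frequency table snapped to multiples of 1/n_haplotypes, per-population
FASTA alignments that reparse to the table exactly (derived base T against
an `ancestral` all-A reference row), a null-value file, and a SHA-256
manifest; everything is bit-identical for a given seed.

## Problem sizes and determinism

The reference grids are 20×20 in (r, s) at R ∈ {1, 1.5, 10} and f0 ∈
{0.001, 0.1, 0.5}; bisections take ~10–20 deterministic runs; Monte-Carlo
checks use 200 replicates (null distributions, oracle comparisons) or 50
(detection), and the Fisher calibration uses 10,000 draws. All stochastic
components take explicit integer seeds; the deterministic recursion is
bit-reproducible (same input, same output). Probabilities are clipped to
[0, 1] at tolerance 10⁻¹²; genotype vectors renormalize each generation in
double precision.

## Known limitations

- No evolution of r, s or R (no modifier loci), no female-gamete killers,
  no diploid viability selection, no more than two loci.
- The species-allele generator is not a coalescent: no ILS-induced
  correlation structure, no finite-sample allele-frequency noise.
- Threshold searches assume fate is monotone in the search variable except
  at documented degenerate endpoints; wildly non-monotone regimes would
  fall back to the grid scan.
- The empirical rice-genome computation (alignment, tree building, real
  null regions) is out of scope; the f4 machinery accepts user tables for
  such data but ships only synthetic inputs.
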