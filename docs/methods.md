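# Methods

## The model

`invfate` simulates an isolated, random-mating population of `N` diploid
individuals under a discrete-generation Wright–Fisher model with soft
selection: each generation exactly `N` offspring are produced, each from two
parents drawn independently with probability proportional to fitness
(selfing permitted), so only relative fitness matters and carrying capacity
is always reached.

**Genome.** Three chromosomes (default 1 Mb each) assort independently.
Allelic state is simulated only in coding sequence — alternating segments of
50 kb coding / 100 kb non-coding starting at bp 0 of each chromosome, 300 kb
coding per chromosome, with leftover non-coding sequence at the chromosome
end. Non-coding sequence contributes recombination distance only. All
coordinates are 0-based, half-open.

**Mutation.** New mutations arrive at rate `mu` (default 8.4e-9 per coding
bp per generation), Poisson per gamete, uniform over coding positions. Every
mutation is deleterious and fully recessive; the magnitude of its selection
coefficient is drawn from a gamma distribution with shape 0.5 and mean 0.005
(the classic `beta = 100` parameterized as a rate). About 5% of draws fall
below the drift barrier `1/(2N)` at N = 25,000 (gamma CDF = 0.0504) — these
are the *effectively neutral* mutations; no separate neutral class is
simulated. Fitness is multiplicative over loci homozygous for a mutation,
with factors `max(0, 1+s)` (the clamp makes gamma-tail draws with |s| >= 1
act as recessive lethals). Heterozygous mutations contribute nothing.

**Inversion.** After burn-in, a single haplotype copy is flagged as the
inverted arrangement `I`; all others are standard `S`. The inversion spans
30% of chromosome 1 (10% of the genome) by default, centered — the source
model says only "between two given loci", so the centered placement is this
package's convention, recorded in run metadata. Its only direct fitness
effect is a heterokaryotype advantage: IS individuals are multiplied by
`1 + s_het` (default 0.003, i.e. `2 N s_het = 150`). Breakpoint effects are
not modeled. The inverted region is *not* coordinate-reversed: the inversion
is a recombination-modifying flag on a collinear coordinate system, which is
sufficient because position order inside the span affects neither fitness
nor gene flux in this model.

**Recombination.** Initiations occur at rate `r = (rho + gamma)/2` per bp
per meiosis (the halving folds female-limited recombination into both
sexes), uniform along the genome and identical for all karyotypes. Each
initiation is a crossover with probability `rho/(rho+gamma)`, otherwise a
gene-conversion tract of Poisson(`lambda` = 500 bp) length. Tract direction
is not specified by the source model; tracts here extend rightward from the
initiation point, truncated at the chromosome end, and copy from the
homologous chromatid. In heterokaryotype (IS) parents, crossover breakpoints
falling inside the inversion span are deleted — modeling the loss of
single-crossover products as suppression rather than gamete death; under
soft selection the two are equivalent for genotype frequencies, and deletion
preserves fecundity. All within-span breakpoints are deleted wholesale, so
no double-crossover gene flux exists; gene conversion is never suppressed
and is therefore the only gene flux between arrangements. Gametes inherit
the arrangement flag of whichever parental haplotype contributes the span
(well-defined, since no crossover falls inside it in IS parents).

**Soft-selection pruning.** Mutations reaching all 2N haplotypes multiply
every individual's fitness by the same constant, so they are removed from
all haplotypes and appended to a substitution log (position, effect, origin
and fixation generation, region class). A seeded run is trajectory-identical
with and without pruning; the suite asserts this.

## Rescaling

Simulating N = 25,000 with a 3 Mb genome is wasteful when the dynamics are
controlled by the products `2 N mu L`, `2 N s`, `2 N r L` and `lambda / L`.
`rescale(params, Q)` divides the population size and all lengths by `Q`,
multiplies `mu`, `rho`, `gamma` by `Q^2` and the selection scale (`mean_s`,
`s_het`) by `Q`, leaving those four products exactly invariant (asserted to
machine precision). The published scale is `Q = 10` (N = 2,500, 100 kb
chromosomes, `s_het` = 0.03); generation counts compress by `Q` in real
terms but are configured per profile, not rescaled automatically.

## Profiles and problem sizes

- `unscaled` — the raw parameter table (reference only).
- `published` — Q = 10, burn-in 500,000 generations, horizon 500,000: the
  cluster-scale configuration that produces the published headline numbers
  (thousands of arrangement-private fixed differences, 46%/5% neutral
  fractions). This package encodes it but its test suite never runs it.
- `published-small-n` — same with N = 500 (N = 5,000 unscaled), the
  balanced-lethal-prone regime.
- `desk` — Q = 50 (N = 500, 20 kb chromosomes, `s_het` = 0.15), burn-in
  4,000 generations (8N), horizon 10,000. One desk generation corresponds to
  five published-scale generations, so a 10,000-generation desk run covers the
  first fifth of the published horizon — enough for the qualitative
  contrasts (arrangement asymmetry, GC suppression of accumulation, F_ST
  structure), which are established well within that window.
- `desk-small-n` — Q = 50 with N = 100 (N = 5,000 unscaled at the extra
  rescale), burn-in 2,000 generations, horizon 10,000: the workstation
  analogue of the small-population runs, where both arrangements degrade and
  balanced lethal systems form.

Test-suite cohorts use these profiles with a horizon of 5,000 generations
for the paired GC comparison (the contrasts are already decisive there) and
10,000 for the small-N cohort. Aggressive rescaling has a known cost: at
Q = 50 the mean |s| is 0.25, so the gamma tail produces many outright
recessive lethals and per-haplotype load is far more granular than at the
published scale. The qualitative mechanisms (arrangement privacy of
mutations, ratchet asymmetry, associative overdominance) are preserved —
that is what the desk cohorts assert — but desk-scale *counts* of fixed
differences or neutral fractions are not comparable to cluster-scale output,
which is why the published quantitative values are tied to the cluster-scale
profiles.

## Execution paths

The per-meiosis operations (`draw_meiosis_events`,
`suppress_heterokaryotype_crossovers`, `make_gamete`, `next_generation`) are
implemented twice on one model definition:

- a readable object-level path (`reproduction.py`) over `Haplotype` /
  `Individual` / `Population`, used directly by the unit and property tests
  and suitable for populations of tens of individuals;
- a numba kernel (`_kernel.py`, wrapped by `engine.Engine`) that stores
  haplotypes as position-sorted arrays of mutation-table slots and advances
  whole generations in compiled code. The experiment layer runs on the
  engine.

Both paths are validated against the same external oracles: Poisson
initiation rates and the crossover/GC split, the two-locus gamete table
(`c = (1 - exp(-2 rho d))/2`), fitness-proportional parent sampling, the
neutral stationarity expectations E[S] (Watterson) and E[pi] = 4 N mu L, and
the engine's object-model round trip must reproduce loads and fitnesses
exactly.

## Randomness and determinism

Every run draws from a single seeded stream (NumPy `Generator` for the
object path and recorder; the kernel's seeded MT19937 for the engine). Sub-
seeds for replicates and sweep grid points derive from the master seed via
`SeedSequence(master, spawn_key=(grid point, replicate))`, so parallel and
serial execution give identical per-run output, and re-running a replicate
from a shared burn-in reseeds the kernel so results are independent of
execution order. Identical config + seed reproduces results bit-for-bit;
the suite asserts this.

## Statistics and classifiers

**F_ST.** Per segregating site, Hudson's two-population estimator on sample
allele frequencies: `F_ST = 1 - Hw/Hb`, `Hw` the mean within-arrangement
heterozygosity `2pq`, `Hb = p1 q2 + p2 q1`; no small-sample correction;
pooled-monomorphic sites skipped. The estimator choice is recorded in run
metadata.

**Arrangement fixation.** A mutation is "fixed in an arrangement" when it is
carried by every copy of that arrangement in the full population (snapshot-
based estimates from 100-haplotype samples are also available). Fixation
curves accumulate counts per kb of the relevant extent by origin generation.

**Minority/majority.** Resolved per run as the arrangement with the lower
mean frequency over the final ten recorded intervals, not instantaneous
frequency.

**Inviability.** A homokaryotype is inviable when its mean relative fitness
(versus the contemporaneous population mean, averaged over the last ten
recorded intervals) is strictly below 0.001. When a homokaryotype class is
absent or rare, *virtual* homokaryotypes — random same-arrangement haplotype
pairings scored by the same fitness function without `s_het` — stand in,
flagged as such. A balanced lethal system is both homokaryotypes inviable
while the polymorphism persists; its predicted equilibrium inversion
frequency is 0.5, against `s_het/(1 + 2 s_het)` when only the minority
homokaryotype is lethal (both anchored by the deterministic genotype
recursion in the tests).

**Haplotype structuring.** The source model never states a scoring rule, so
the classifier here is this package's operationalization, fully
parameterized: structuring is called for an arrangement iff (a) the
(possibly virtual) homokaryotype relative-fitness sample is bimodal — a
near-zero mode (< 0.001) and a viable mode each holding >= 10% of the
sample, separated by an empty gap of one order of magnitude — AND (b)
average-linkage clustering of the within-span haplotype sample by Hamming
distance yields >= 2 clusters with mean between-cluster distance >= 2x the
mean within-cluster distance; the reported cluster count is the
ratio-maximizing cut. Fewer than 20 sampled haplotypes returns
"undetermined", never "absent". Detection is invariant to row/column
permutation.

**Fate classification.** From the recorded series: lost / fixed at the
absorption generation, else polymorphic; the short-term flag tests
segregation at 10,000 generations after introduction (clipped to the
horizon for shorter runs).

## Single-locus control

The overdominant reference model is a biallelic Wright–Fisher locus with
genotype fitnesses 1 : 1+s_het : 1, one initial allele copy, deterministic
selection applied to expected frequency followed by binomial resampling of
2N copies, run to absorption or a 10,000-generation horizon (the source
reports identical short- and long-term fates for this model, so one horizon
suffices). At the rescaled parameters (N = 2,500, s_het = 0.03) the
establishment probability is ~0.057, matching the Galton–Watson survival
probability for Poisson(1.03) offspring; losses conclude within a couple of
hundred generations and fixation never occurs. `scripts/acceptance.py`
recomputes these two quantities with 10,000 replicates (five times the
published count, for a tighter estimate; the replicate count is Monte-Carlo
precision, not a model condition).

## Degenerate inputs and numerical choices

- Fitness factors clamp at zero; an all-zero-fitness population raises a
  distinct extinction error rather than being conflated with inversion loss.
- The deterministic equilibrium recursion iterates to |dp| < 1e-13, giving
  closed-form agreement to ~1e-10.
- Mutation positions are integers; two mutations may occupy one position
  (they remain distinct alleles — infinite-sites in effect, since the
  per-position mutation rate is tiny at every supported scale).
- Engine buffers grow by doubling when a generation would overflow them; the
  generation is then re-run, which consumes additional RNG draws but remains
  deterministic for a given configuration and seed.
- `is_effectively_neutral` uses the strict inequality |s| < 1/(2N) with the
  *total* population size, never an arrangement count.

## Known limitations

- No beneficial mutations, no incomplete dominance, no epistasis, no back
  mutation, no double crossovers within the span, no separate sexes, no
  migration or demographic change. These mirror the source model's scope.
- Crossover interference is absent (Poisson initiations).
- The desk profiles trade DFE realism for speed as described above; claims
  about absolute fixed-difference counts or neutral fractions require the
  cluster-scale profiles.
- The structuring classifier's thresholds are conventions; alternative
  parameterizations are exposed as keyword arguments rather than tested
  alternatives.
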