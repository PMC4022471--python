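# Methods

## Meiosis model

One meiosis is represented by four haploid products arranged as two MI poles
(products 0,1 and 2,3); the post-meiotic mitosis duplicates each product,
giving eight nuclei. A heterozygous locus always segregates 2:2 among the
four products, encoded as a parental-origin vector with six possible values:
two pole-pure vectors (FDS) and four pole-mixed ones (SDS).

**Phenomenological mode (default).** Each locus draws its pattern type —
SDS with its own probability `s`, FDS otherwise — independently of its
neighbours; `s` is the primary observable of tetrad analysis and is what
strains in the library carry. The *phase* of the vector (which pole or
chromatid gets which parent) is coupled along a chromosome: given the
previous locus's vector, a candidate vector with `d` products of flipped
parental origin is weighted by `r^d (1−r)^(4−d)` within its pattern type,
where `r ∈ [0, 0.5]` is the pairwise recombination fraction (default 0.5;
loci on different chromosomes are always at 0.5). This is per-product
recombination with probability `r`, conditioned on the independently drawn
pattern type. The conditioning is what keeps the model consistent: naive
independent per-product flips would break the 2:2 dosage invariant. At the
default `r = 0.5` the weights are flat and loci are exactly independent,
which reproduces the observed 50:50 segregation of the second killer locus
among survivors of the two-killer cross. The exact enumerator and the Monte
Carlo sampler share this one transition kernel and differ only in summing
versus sampling, so enumeration is a true oracle for the simulator. For
`r < 0.5` the marginal per-product recombination fraction between
*pattern-discordant* neighbours deviates from `r` (the conditioning
redistributes mass); none of the encoded crosses uses `r < 0.5`.

**Mechanistic mode.** Crossovers on a chromosome arm (centromere at 0) are
a Poisson process with bivalent intensity `2x` for map length `x` Morgans;
each crossover picks one chromatid per homolog uniformly (no chromatid or
crossover interference) and exchanges distal segments. SDS frequencies and
recombination fractions then emerge, with the classical ceiling of 2/3 and
closed form `s(x) = (2/3)(1 − e^(−3x))`, which the test suite verifies by
simulation at `x ∈ {0.05, 0.5, 2}`.

**Packaging.** Binucleate tetrads give each spore the two distinct products
of one MI pole (so FDS ⇒ homokaryotic spores, SDS ⇒ four heterokaryotic
spores); uninucleate octads give every nucleus its own spore, making
heterokaryotic rescue impossible — a heterozygous killer then always leaves
exactly four viable and four dead spores, independent of `s`. Within-pole
chromatid assignment at SDS is uniform and independent across loci; the
true multilocus joint pattern for two simultaneously-SDS loci is not
constrained by single-locus observations, and this choice is documented so
results are reproducible. Ascus spore order carries no meaning in any
output; classes are unordered, as rosettes are scored.

## Killing rule

The zygote context resolves, once per cross: the set of alleles present,
the active distorters among them, and each allele's *effective* responder
coverage (empty if the allele requires a trans-activator that is absent
from the zygote). A spore survives iff every active distorter is covered by
the union of its nuclei's effective responders. Consequences, all exercised
by tests: homozygous killers are silent; one resistant nucleus rescues a
binucleate spore; a killer covered by another segregating element is fully
masked; killers with no effective responder anywhere produce 100% empty
asci. Killing is spore-autonomous with an optional per-distorter
`killing_efficiency` (default 1.0, matching the observed all-or-none death);
values below 1 are the only way odd spore counts can arise in tetrads,
because the two spores of one pole are genetically identical twins.

## Strain library choices

* Transgene backgrounds follow each strain's construction history: the
  pigment-locus *Spok1* and GFP-tagged insertions sit in an *S*-type
  background carrying wild-type *Spok2*; the *Spok2*, *Spok2^AA* and
  *Spok^N* insertions sit in the *Spok2*-deletion background. The
  N-terminally tagged *mCherry-Spok2* strain is also modelled in the
  deletion background — a wild-type *Spok2* background would trans-activate
  its responder and contradict its barren cross against the deletion strain.
* Trans-activated killers (*mCherry-Spok2*, *Spok2^AA*, *Spok^N*) cover the
  *Spok2*-product killers and themselves, with wild-type *Spok2* products
  as activators. For *Spok^N* the coverage of wild-type *Spok2* is forced
  by its fully 4-spored cross against the allelic *Spok2* insertion.
* The resistant non-killer isolate A406 is modelled with two responder-only
  alleles, one allelic to each killer locus: under spore-autonomous killing
  a resistance that suppresses killing to 0% in crosses against *both*
  killers must be allelic to both. Where that resistance actually resides
  is not known.
* C-terminally tagged responder-only alleles are encoded with the coverage
  their non-killing crosses demonstrate. Their reported fully-4-spored
  crosses against killer strains cannot arise from any spore-autonomous
  responder and are outside this model (see limitations).
* A further killer present in two isolates ("Spok3"-type) is left as a
  commented-out stub: its interaction with the *Spok1* strain is
  uncharacterised.

## Inference

`estimate_sds` uses the binomial MLE (4-spored fraction for a killer locus)
with Clopper–Pearson intervals — exact intervals because real ascus and
progeny counts in this system are small (tens, not thousands). The
cross-aware wrapper refuses loci whose killing signal is masked or absent,
rather than returning a silently wrong estimate. The centromere distance
`100·s/2` cM is standard tetrad mapping. `transmission_scan` applies exact
two-sided binomial tests against 0.5 per marker with Benjamini–Hochberg
adjustment at α = 0.05 (the original scan was read by eye; the correction
is this package's addition) and flags the longest contiguous run of
significant markers. `goodness_of_fit` pools classes with expectation
below 5 for the chi-square path and switches to an exact multinomial test
(point-probability ordering) for totals of 40 or fewer.

## Introgression

Backcrossing keeps, each generation, one surviving ascospore that carries
the driver and comes from an FDS ascus (SDS survivors are heterokaryotic
and are not selected). The driver chromosome is simulated mechanistically;
gametes are drawn until the driver shows FDS, a random driver-carrying
chromatid is kept, and its donor intervals are intersected with the
lineage's. Generation 0 (the F1) has donor fraction exactly 0.5; unselected
genome decays as `(1/2)^(g+1)`, reported in closed form and verifiable with
`simulate_neutral_chromosome`. Driver-linked segment lengths are reported
in map units; converting to physical units needs a user-supplied kb/cM
scale, and any single real strain is one realisation of this distribution.
One selected survivor per generation is assumed (screening depth per
generation is not documented for the real program).

## Problem sizes and numerical choices

Simulated checks use 10,000 asci per cross (binomial SE ≤ 0.5 percentage
points for the percentages involved), 200 replicates for CI-coverage
calibration (via the documented fast path that draws multinomial counts
from the exact distribution — statistically identical to counting simulated
asci), 100 replicates of 50-progeny datasets for scan localisation, and
3-SE tolerances wherever Monte Carlo output is compared to an exact value.
All randomness flows through a single seeded NumPy generator per run;
identical seeds give byte-identical outputs. Exact enumeration is limited
to three heterozygous loci (the sample space grows as 6 per locus) and to
deterministic killing.

## What the synthetic data do and do not cover

The generator reproduces the *genetics* of the system: segregation
geometry, linkage, killing epistasis, dominant pigment marking, and
survivor sampling for marker scans (one homokaryotic-at-driver spore per
ascus, which fixes the driver column for the donor allele exactly as
survivor scoring does). It does not model: ascus-to-ascus variation in
penetrance, the rare 3- or 5-spored asci of real rosettes, sterility and
fertility differences between crosses (sterile pairings are registered as
untestable), nuclear migration cytology, or any molecular mechanism of the
toxin. Passing tests therefore validate the genetic rule system and the
estimators, not cell biology.
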