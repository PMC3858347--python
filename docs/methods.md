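# Methods

This note documents the model implemented by `drivesim`: its assumptions,
parameters, numerical choices, and the limits of what its synthetic
inputs and tests can show.

## Genetic systems

Both drive systems are encoded as allele copy counts at autosomal
biallelic loci; there are no parent-of-origin effects other than the
maternal Medea toxin, which depends only on the mother's own genotype, so
ordered haplotypes are unnecessary.

* **Medea** (one locus, alleles *M*/*m*): embryos of a mother carrying at
  least one *M* die unless they themselves carry an *M*, with probability
  `medea_lethality` (default 1.0 — complete maternal-effect lethality has
  been demonstrated empirically; the parameter is exposed because
  intermediate toxin efficiencies are biologically plausible).  Per-copy
  embryonic cost `c_M` gives genotype viabilities 1, (1−c_M), (1−c_M)²;
  a dominant female-specific fecundity cost `c_F` (default 0.1) scales a
  carrier mother's mean batch size.
* **Killer-Rescue** (two unlinked loci, *K*/*k* and *R*/*r*): any embryo
  with ≥1 *K* and no *R* dies; kill and rescue are dominant and complete.
  Per-copy embryonic costs `c_K`, `c_R`; overall viability multiplies
  across loci.  No fecundity cost.

Drive lethality and embryonic costs are applied together at egg hatch, as
a single binomial thinning with probability (lethality survival ×
embryonic multiplier); the order inside the product is immaterial, but it
is fixed so random-number streams are reproducible.  The fecundity cost
deterministically scales the Poisson mean of each batch (per-batch and
lifetime application are equivalent in expectation; we apply it per
batch).

## Spatial population engine

Houses form a rectangular row-major grid; neighbourhoods are von Neumann
(2–4 orthogonal neighbours; the grid edge is absorbing in the sense that
no houses exist beyond it).  One day applies, in fixed order: immature
development/survival, pupal emergence, scheduled releases, adult
survival, mating, dispersal, oviposition.  The ordering is a model choice
(releases precede mating so released adults can mate the same day).

**Development.**  Stage durations `d_egg=3`, `d_larva=8`, `d_pupa=2` days
at the optimal temperature; the development rate scales by a factor
rising linearly from 0 at `t_min=14` °C to 1 at `t_opt=26` °C, constant
to `t_max=40` °C, zero outside.  This deliberately simple pluggable
maturation model preserves the qualitative mechanism (warmer is faster,
within a viable band) without an enzyme-kinetics calibration.

**Larval competition.**  Each larva demands `larval_demand=0.12` mass
units/day (times the temperature factor) from its container's food pool;
when the pool cannot cover total demand, all larvae in the container get
the same fractional ration.  Growth adds ration × `growth_efficiency` to
per-capita mass; daily larval survival scales from its nominal value at
full ration down to `starvation_factor=0.5` of it at zero ration.
Natural containers replenish at their per-container daily rate, capped at
`food_cap_days=5` days of supply so food does not accumulate without
bound in empty containers.  Pupae carry their final larval mass, which
becomes adult body size — so crowded containers produce small adults that
are correspondingly weak mate competitors.

**Adults.**  Constant daily survival 0.89 (a free calibration knob; the
resulting ~9-day mean adult lifespan is in the plausible range for the
species).  Unmated females mate on the first day they share a house with
a male, choosing among the house's males with probability proportional to
body size, and store that mate's genotype for all future ovipositions
(strict monogamy).  Every adult disperses with daily probability 0.30 to
a uniformly drawn compass direction; a draw pointing off-grid means no
movement that day ("blocked draws stay" — the simplest rule consistent
with an edge without neighbours; a redraw-among-valid-directions variant
is available as `edge_rule="redraw"`).  Mated females lay with daily
probability 1/3 (a stand-in for the gonotrophic cycle) a Poisson batch
with mean `base_batch=60` × fecundity multiplier, into a container chosen
uniformly among the accepting containers of their current house.  Egg sex
is independent male/female with probability 1/2.

These demographic defaults were chosen once so that the synthetic study
area equilibrates at roughly 9 adults per house with strongly
density-regulated immatures; they are model constants, not field
estimates.

## Releases

Adult releases add homozygous construct adults (1 day old, mean wildtype
size, unmated; released females virgin) to every house, or to the release
site set.  Egg releases create one dedicated container per site and event
holding equal male and female egg cohorts, pre-loaded with exactly the
cohort's full larval demand (`count × larval_demand × d_larva`) and never
replenished, closed to wild oviposition, and removed as soon as all
occupants have died or emerged — releases therefore never create breeding
sites.  "10% of houses" is realised as every tenth house in row-major
order (61 of 612; deterministic), with uniform random site selection as
an option.  Weekly cadence starts at day 365 after a one-year burn-in.
Egg releases are converted to adult-equivalents by Monte-Carlo simulation
of a standalone release container; at low density this converges to the
product of daily stage survivals (0.99³ × 0.99⁸ × 0.99² ≈ 0.88).

## Outcome census

Allele frequencies are censused over all living individuals (immatures
included) by default, with an adults-only switch, since the convention is
not dictated by the model.  Boundary terminal frequencies of exactly 0.2
or 0.8 are assigned to the partial-spread class (the defining
inequalities are strict, leaving the boundary unassigned; the choice is
configurable).  Terminal evaluation is 3 × 365 days after the first
release, with 1- and 2-year checkpoints recorded.

## Deterministic oracles

The panmictic recursions use non-overlapping generations.  Medea tracks
genotype frequencies and contracts the full mating table each generation,
because the toxin depends on the mother's genotype rather than her
transmitted gamete; the fecundity cost enters as a weight on a mother's
chance of being the dam of a random offspring — the deterministic
analogue of batch-size scaling.  KR tracks the four gamete frequencies,
carrying linkage disequilibrium exactly; within an individual the
unlinked loci segregate independently.  The release-threshold solver
bisects on the initial Hardy-Weinberg frequency; "spreads" means escaping
above the unstable internal equilibrium created by the embryonic cost.
Two structural facts matter when interpreting it: a cost-free element
spreads from any positive frequency (threshold 0), and a per-copy
embryonic cost protects rare wild-type alleles inside heterozygotes, so
the high stable state sits slightly below allele fixation — from a 5%
release the cost-free element passes 0.99 only at generation 124, with
the last percent taking a quarter of that time.

Agreement between the recursions and the stochastic engine is checked in
a generation-synchronised single-house harness that reuses the engine's
own mating and inheritance machinery but replaces demography with fixed
population-size resampling of each offspring pool (N = 10,000); observed
mean absolute allele-frequency deviation over 20 generations is ~0.01,
consistent with pure drift and no detectable bias.

## Synthetic environment

The temperature series is a sinusoid (mean 26 °C, amplitude 1.5 °C,
period 365 d) plus Gaussian daily noise (SD 1 °C) — a tropical series
with a mild seasonal cycle.  Containers per house follow a zero-inflated
negative binomial (20% structural zeros, NB mean 2, shape 2), and each
container's daily food rate is lognormal (median 2, log-SD 0.6).  These
shapes reproduce two robust features of entomological container surveys —
overdispersion and many container-free houses — but the parameters are
stand-ins, not estimates for any real city; the generators are labelled
synthetic throughout.  Each of the 153 synthetic surveyed profiles is
instantiated exactly 4 times at permuted grid positions (612 houses),
mirroring the survey-replication construction of the original study area.
Rainfall-driven container filling and any weather variable other than
temperature are out of scope.

Consequently, passing tests demonstrate the *mechanisms* — drive
genetics, density regulation, spatial spread, release logistics — under
realistic heterogeneity, not quantitative predictions for a particular
city.  Desk-scale house populations (~9 adults) are smaller than
field-calibrated ones, so absolute release thresholds (e.g. how many
males per house guarantee full spread) are smaller here than a field
model would give; the qualitative orderings between strategies are the
meaningful outputs.

## Problem sizes used in tests and the acceptance script

Scaled-down sweeps run on the `mid` fixture (20 × 20 houses = a 100-house
synthetic survey × 4) with 8 replicates per arm in the test suite and 5
in the acceptance script, paired replicate seeds across arms (common
random numbers), full burn-in and 3-year horizon.  Oracle–simulator
agreement uses N = 10,000 with 20 generations × 20 replicates; panmictic
Hardy-Weinberg checks use N = 5,000.  Replicate streams derive from
(base seed, scenario index, replicate index) via seed sequences, so every
output is exactly reproducible from the configuration.

## Known limitations

- No dengue transmission, biting, or human hosts; efficacy is measured
  purely as transgene frequency.
- No gonotrophic-cycle bookkeeping, senescence, or sex-specific
  dispersal/survival; released and resident adults perform identically
  apart from genotype effects.
- The maturation and food models are deliberately simplified stand-ins
  for a calibrated enzyme-kinetics/larval-biomass model; absolute rates
  should not be interpreted quantitatively.
- Single connected grid only; no immigration from outside the simulated
  area, so "lost" is absorbing.
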