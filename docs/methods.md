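# Methods

`mscmig` implements Bayesian inference under the multispecies coalescent
with migration for multi-locus sequence data, together with the simulation,
validation and data-preparation machinery needed to exercise it end to end
on synthetic data.

## Model

A demographic model is a rooted population tree. Each branch (population)
`b` carries a mutation-scaled size `theta_b = 4 N_b mu`; each internal node
a mutation-scaled divergence time `tau = T mu / g` (expected substitutions
per site); and gene flow is modelled by directed **migration bands**
between populations whose existence intervals overlap, with scaled rate
`M = m / mu` (`m` = per-generation migration probability). The per-band
**total migration rate** `m_tot = M * tau_m` (with `tau_m` the band's time
span) is the mutation-rate-free measure of cumulative gene flow used for
significance calls.

Latent per-locus genealogies follow the structured coalescent: within
population `b` each unordered lineage pair coalesces at rate `2/theta_b`;
backward in time a lineage residing in a band's target population jumps to
the source population at rate `M`; at each divergence time the child
populations' lineages merge into the parent. Loci are unlinked and assumed
recombination-free internally; sequences evolve by JC69. Intra-locus
recombination is deliberately not simulated even where a per-generation
recombination rate is known for the system (0.92e-8/bp for the dog genome):
for 1 kb loci the per-locus rate is negligible relative to coalescent
times, and the inference model itself assumes recombination-free loci. The
constant is kept here for documentation only.

Two mutation-rate/generation-time combinations are bundled for unit
conversion: combination (i) `mu = 4e-9 /bp/generation`, `g = 4.5 y`
(supported by recent pedigree-based canid estimates; used for all preset
scaled values) and combination (ii) `mu = 1e-8`, `g = 3 y` (traditional in
dog-domestication work). Under these, years convert between combinations
by the exact factor 3.75 and individuals by 2.5.

## Likelihood

`inference.jc69_log_likelihood` is Felsenstein pruning with uniform root
frequencies. Alignment cells are IUPAC bitmasks, so the tip partial vector
is read directly off the cell: `N` contributes 1 for every state, an
ambiguity code 1 for each compatible state (this is how heterozygote codes
on read are handled — the two phases are summed per site independently);
the synthetic path only produces `A,C,G,T`. Columns are compressed to
unique site patterns before pruning.

`inference.coalescent_migration_log_density` evaluates the structured
coalescent density of a genealogy with its migration path: `2/theta` per
coalescence, `M` per migration event, times
`exp(-[sum_b C(k_b,2) 2/theta_b + sum_bands k_target M] dt)` over the
piecewise-constant intervals. Inconsistent states (an event outside its
band's window, residence mismatches, an event on an `M = 0` band) yield
`-inf` rather than an exception, so proposals can be scored uniformly.
The genealogy is considered complete at its grand MRCA; no factor is
accumulated above the root.

## Sampler

`inference.run_mcmc` is a single-chain Metropolis–Hastings sampler over
`(theta, tau, M, genealogies)`, with independent Gamma priors per
parameter class. One iteration sweeps:

1. **Node-time slides** for every internal node of every locus: reflected
   uniform proposal inside the interval bounded by child/parent nodes and
   adjacent migration events; the coalescence population is re-derived at
   the proposed time and the move rejected if the two child lineages
   reside in different populations there.
2. **Prune-and-regraft with migration-path resampling**, one lineage per
   locus per iteration: the lineage is detached, its parent node spliced
   out, and a new path simulated backward under the conditional structured
   coalescent given the remaining ("resident") lineages — migrating at the
   band rates and coalescing with each same-population resident at rate
   `2/theta`. The Hastings ratio uses the exact path densities of the new
   and the old path under the same residents; because the path proposal is
   the exact conditional law, the coalescent-density and proposal terms
   cancel analytically and the move reduces to a likelihood ratio on
   zero-information data — a property the test suite exploits as a strong
   internal consistency check. This move also changes the number of
   migration events, with the path density supplying the dimension
   matching; a separate event birth/death pair is therefore not needed.
   The lineage above the resident root (the "trunk") is treated as
   migration-free during resimulation; proposals that would strand stored
   trunk events above a new root are rejected, keeping the kernel exactly
   reversible.
3. **Migration-event time slides**: uniform redraw within the window
   bounded by neighbouring events/nodes, the band's active window and the
   residence interval of the band's target population.
4. **Multiplicative random walks** on each `theta` and each `M`, using
   sufficient statistics (coalescence counts and pair-time integrals per
   population; event counts and exposure integrals per band) accumulated
   once per iteration, so each update is O(1). Proposals that underflow to
   zero are rejected so the chains stay in the support.
5. **`tau` updates with rubber-band rescaling**: event times inside the
   two child populations are rescaled linearly onto the new interval, and
   times inside the updated (ancestral) population are rescaled against
   its fixed upper boundary (shifted, for the root population); the
   Jacobian enters the acceptance ratio. A rescaling that breaks event
   ordering on some lineage (possible when migration interleaves affected
   and unaffected populations) makes that state invalid and the proposal
   is rejected.

Proposal windows are fixed during sampling (no adaptation after burn-in,
preserving detailed balance); an optional burn-in-only auto-tune
(acceptance target 20–50%, frozen at the end of burn-in) is on by default
and can be disabled (`McmcSettings(tune=False)`), which — together with
absolute window sizes — keeps the kernel homogeneous when chains are
resumed across calls (`resume_from`), as the Geweke-style test requires.

Initialisation draws `theta`/`tau` from their priors subject to the tree
ordering and simulates initial genealogies under that model, which
guarantees a finite starting density; `M` starts at its prior mean, since
a draw from the very diffuse default migration prior (shape 0.002)
underflows to zero with high probability.

**Priors.** Defaults are Gamma(1, 10 000) on every `theta` and `tau`, and
Gamma(0.002, 0.00001) on every `M` — the documented conventions of the
original sampler family this package reimplements (the exact values used
in the source analysis are in an unavailable supplement). All are
configuration, not constants. The spike-plus-heavy-tail shape of the `M`
prior is integral to the band-significance rule: with no migration signal
the posterior of `m_tot` collapses onto 0, which is what lets the "HPDI
excludes 0" clause discriminate. Note that for parameter-recovery studies
the `theta`/`tau` prior mean should be matched to the order of magnitude
of the system under study (the recovery study below uses Gamma(1, 1000)
for its 1e-3-scale toy parameters); with the 1e-4-scale default, truths an
order of magnitude above the prior mean are visibly shrunk at desk-scale
locus counts — ordinary Bayesian behaviour, not a sampler defect.

The hot loop is compiled with numba (`mscmig._engine`); the pure-Python
density and likelihood functions are the reference implementation, and the
test suite asserts the engine's cached values agree with them to float
precision on states visited by real chains.

## Posterior summaries and the band rule

`posterior.hpdi` computes the discrete shortest-window HPDI (no kernel
smoothing): the shortest contiguous window of the sorted samples holding
`ceil(level*n)` of them, ties resolved toward the smallest lower bound.
`posterior.band_significant` applies the two-clause rule: significant if
the 95% HPDI of `m_tot` excludes 0 (lower bound > 1e-12; samples are
non-negative) **or** `P(m_tot > 0.03) > 0.5`. The threshold clause is read
as a posterior probability; the posterior-mean reading is available via
`use_mean=True`. `posterior.select_bands` screens candidate bands in
groups on a locus subset (default 5 000) and returns the union of
significant bands for a final run. `posterior.summarize` reports every
parameter as posterior mean and 95% HPDI in scaled units and converted
under both rate combinations (HPDIs are computed on scaled values; under
the linear conversions the choice is immaterial up to printed rounding).

## Local-ancestry masking

`ancestry_mask` reimplements the dog-ancestry robustness step as a
penalized-switch dynamic program. Sites are filtered by Hudson's FST
estimator (chosen because the source names no estimator; Weir–Cockerham is
available as an option) at a 0.5 cutoff. Per-site emission cost is the
negative log-probability of the target's allele dosage under the labelled
source's allele frequency (Hardy–Weinberg for diploid targets; frequencies
clamped to [1e-3, 1-1e-3] so fixed panels stay finite); each label switch
costs a fixed penalty (50 by default, playing the same role as the
original tool's switch-penalty parameter — the robustness conclusion, not
numeric identity with the unpublished emission model, is the target).
Segment boundaries fall at midpoints between differing-label neighbours.
Loci are retained only if fully contained in a single kept-label segment
(0-based half-open containment).

## Synthetic data

`synthetic_data` generates every input. Scenario presets mirror the
original validation design: `control` is the full nine-taxon canid model
with the published point estimates converted under combination (i);
`reduced_split` multiplies the Portuguese/Spanish divergence by 0.1;
`panmixia` merges the two Iberian populations into one leaf of size
`theta_ancIB`. Defaults are 15 000 loci of 1 kb with one haploid sequence
per sampled population, matching the study design. Values the source does
not print are documented placeholders (flagged in the preset's metadata):
dog-clade split at 90% of the wolf/dog split; Spanish and Croatian sizes
at three times the Italian; Chinese wolf 20 000; basenji/dingo 5 000;
jackal 50 000; jackal divergence 400 kya; root size 100 000. The
dog-to-Spanish-wolf band is proxied through the basenji leaf because the
nine-taxon tree has no boxer reference leaf and the ancestral-dog branch
does not coexist with the Spanish wolf. One reported split-time figure
differs between sections of the source (ca 6 vs 6.2 kya); the preset uses
6.2 kya.

The toy scenarios are the default test surface: `toy2` (two populations,
`theta` 0.001/0.001/0.002, `tau` 0.001) and `toy3` (three populations,
`theta_A = theta_B = 8e-4`, `theta_C = 1e-3`, `theta_AB = 1.2e-3`,
`theta_root = 1.5e-3`, `tau_AB = 8e-4`, `tau_root = 2e-3`), both sampled
with two haploid sequences per population — emulating one diploid genome
each, and necessary for present-day sizes to be identifiable at all.

`generate_admixture_fixture` builds ancestry panels with complementary
frequency pairs chosen so the large-sample Hudson FST equals the requested
value, and draws the target's dosages from the true segment's source.

What the generator does **not** emulate: sequencing error and
genotype-calling noise (the real pipeline consumes final genotype calls),
alignment/mappability artefacts, linked selection, and intra-locus
recombination. Passing tests therefore demonstrate correctness of the
inference machinery under its own model assumptions, not robustness to
real-data artefacts.

## Validation studies and problem sizes

All study sizes are the package's own desk-scale choices, documented here:

* **Prior recovery**: two populations + one band, three all-N loci,
  120 000 iterations; posterior of every `theta`/`tau` vs its Gamma prior
  by KS test.
* **Geweke-style joint check**: successive-conditional simulator (MCMC
  transitions alternated with data re-simulation from the current
  genealogies), 800 cycles, fixed windows, no tuning; first-moment
  z-scores within 3 Monte Carlo s.e.
* **Parameter recovery**: `toy3`, 100 loci x 1 kb, 20 replicates, 10 000
  iterations (3 000 burn-in), prior Gamma(1, 1000); 95% HPDI coverage at
  least 16/20 per parameter and posterior means within 25% of truth on
  average.
* **Split-time validation**: the Iberian three-population sub-model
  (Portuguese, Spanish, Italian) with all `theta`/`tau` multiplied by 10 —
  a uniform rescaling that is information-equivalent to 10x longer loci
  (the likelihood depends only on parameter-length products) while
  preserving every relative quantity, in particular the split-time ratio
  under test; 400 loci, 7 000 iterations per run. The reduced-split
  posterior mean must fall below 25% of the control's; the panmixia
  posterior concentrates below the control. The full nine-population,
  15 000-locus replication is not desk-scale and is intentionally out of
  the default suite.

## Known limitations

* Single chain, no Metropolis coupling, no marginal-likelihood machinery.
* Fixed event capacity per lineage (24); proposals exceeding it are
  rejected (irrelevant at desk-scale migration intensities).
* `tau` mixing relies on the burn-in auto-tune when the initial prior
  draw is far from the posterior scale; very short runs without tuning
  can under-explore deep divergence times.
* Populations are panmictic with constant size per branch; no admixture
  (reticulation) nodes — gene flow only via migration bands.
* At most ~20 sampled genomes is the intended scale; the per-iteration
  cost is linear in loci and roughly linear in lineages.
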