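# mscmig

Bayesian demographic inference under the **multispecies coalescent with
migration**, for multi-locus genome data — with the full synthetic-data,
validation and post-processing tool chain needed to exercise it without any
external data.

The package grew out of the demographic analysis of Southern European grey
wolf genomes: a rooted population tree (wolves, dogs, golden-jackal
outgroup) in which each branch has a scaled effective size
`theta = 4*Ne*mu`, each split a scaled divergence time `tau = T*mu/g`, and
post-divergence gene flow runs through directed *migration bands* with
scaled rate `M = m/mu`. From thousands of short, unlinked, neutrally
evolving loci, a Metropolis–Hastings sampler jointly infers the population
sizes, split times, migration rates and per-locus genealogies (topology,
node times and migration paths), under Gamma priors and a JC69 sequence
likelihood. Because `theta`, `tau` and `M` are mutation-scaled, results are
reported under two alternative (mutation rate, generation time)
combinations — (i) 4e-9/bp/generation with 4.5 y, (ii) 1e-8 with 3 y — and
the per-band *total migration rate* `m_tot = M * tau_m` is scale-free.

Who this is for: population geneticists who want a desk-scale,
fully-testable implementation of coalescent-with-migration inference — to
study its behaviour (parameter recovery, split-time resolution, gene-flow
detection rules), to generate matched synthetic datasets, or to run the
same two-step band-selection and local-ancestry-masking procedures used in
wolf/dog demographic studies.

What is in the box:

| module | contents |
| --- | --- |
| `mscmig.demography` | model types, validity rules, all unit conversions, the published canid model preset, config-file I/O |
| `mscmig.coalsim` | backward-in-time structured-coalescent simulator with migration bands |
| `mscmig.seqevolve` | JC69 sequence evolution, quality/CpG masking rules, multi-locus + FASTA I/O |
| `mscmig.inference` | pruning likelihood, genealogy density, the MCMC sampler (numba-compiled core), ESS diagnostics |
| `mscmig.posterior` | HPDI, the two-clause band-significance rule, two-step band selection, dual-scale summary tables |
| `mscmig.ancestry_mask` | Hudson FST site filtering, penalized-switch local-ancestry DP, locus masking |
| `mscmig.synthetic_data` | scenario presets (control / reduced split / panmixia / toys), dataset + fixture generators |
| `mscmig.cli` | `mscmig` command: simulate, infer, select-bands, summarize, mask-ancestry, recovery-test |

## Worked example

Simulate 100 loci under the two-population toy model
(`theta_A = theta_B = 0.001`, `theta_root = 0.002`, `tau_root = 0.001`,
two haploid samples per population), re-infer the parameters, and compare
the posterior with the generating truth:

```bash
mscmig recovery-test --scenario toy2 --n-loci 100 --iterations 8000 \
    --seed 7 --out runs/toy2
```

```text
 parameter  truth  post_mean  hpdi_lo  hpdi_hi  covered
   theta_A  0.001   0.000887 0.000613 0.001122     True
   theta_B  0.001   0.000884 0.000641 0.001153     True
theta_root  0.002   0.001953 0.001460 0.002582     True
  tau_root  0.001   0.000972 0.000762 0.001255     True
4/4 true values inside the 95% HPDI
```

Each row is one model parameter: the generating truth, the posterior mean,
and the 95% highest-posterior-density interval; `covered` says whether the
truth lies inside the interval. Here all four parameters are recovered
with posterior means within a few percent of the truth.

The same run via the library, with dual-scale reporting:

```python
from mscmig import make_scenario, generate_dataset, run_mcmc, summarize
from mscmig.inference import McmcSettings

sc = make_scenario("toy2", n_loci=100, locus_length=1000, seed=7)
loci, truth = generate_dataset(sc)
trace = run_mcmc(loci, sc.model,
                 settings=McmcSettings(iterations=8000, burn_in=2000,
                                       sample_every=10, seed=8))
print(summarize(trace).to_string(index=False))
```

`summarize` reports every `theta` as individuals and every `tau` as years
under both rate combinations; for instance a posterior mean
`tau = 3.2e-5` prints as 36.0 kya under combination (i) and 9.6 kya under
combination (ii) — the two differ by the exact factor 3.75 (2.5 for
population sizes).

The published canid model is available as a preset:

```python
from mscmig import wolf_dog_preset
from mscmig.demography import COMBO_I, tau_to_years

model = wolf_dog_preset()
print(round(tau_to_years(model.tree.tau["ancDW"], COMBO_I)))   # 36000
print([b.name for b in model.bands])
# ['basenji->israeli', 'dingo->chinese', 'basenji->spanish']
```

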