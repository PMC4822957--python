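# paleocontam

Joint Bayesian estimation of present-day human contamination, sequencing
error and demographic history for an ancient hominin nuclear genome.

When an ancient genome (say, a Neanderthal) is sequenced, some fragments
come from present-day humans who handled the material. `paleocontam`
models, at every biallelic polarized site, the counts of ancestral (`a`)
and derived (`d`) fragments as a binomial mixture: a fragment is a
contaminant with probability *r*<sub>C</sub> (derived with probability
given by the contaminant-panel frequency *w*), otherwise endogenous with
the unknown diploid genotype *i* ∈ {0, 1, 2} integrated out; per-fragment
errors flip alleles at rate *ε*. The genotype prior
P[*i* | *y*, τ<sub>C</sub>, τ<sub>A</sub>] comes from Wright–Fisher
diffusion theory: neutral variation in the common ancestor of the ancient
population and a present-day "anchor" population (observed frequency *y*)
drifts independently for τ<sub>C</sub> (anchor side) and τ<sub>A</sub>
(ancient side) drift units (time / 2N). A three-population extension adds
two anchor panels with fixed post-split drifts τ<sub>Y</sub>, τ<sub>Z</sub>
and an admixture pulse of proportion α from the archaic population into
anchor Y at time β, solved numerically on a frequency grid. All
parameters are sampled with a Metropolis–Hastings sampler under uniform
priors; candidate contaminant panels can be ranked by log-posterior mode.

## Worked example

Simulate a 30X ancient genome with 25% contamination and refit it:

```bash
paleocontam simulate --r-c 0.25 --eps 0.001 --tau-c 0.5 --tau-a 0.5 \
    --coverage 30 --n-sites 80000 --seed 1 --out-prefix sim
paleocontam fit2p sim.sites.tsv --n-steps 30000 --burn-in 21000 --thin 10 \
    --n-chains 5 --seed 7 --out-prefix fit
python -c "import json; s=json.load(open('fit.summary.json')); \
    print({k: round(v,4) for k,v in s['modes'].items()})"
```

prints (seed-exact):

```
{'r_c': 0.2508, 'eps': 0.001, 'tau_C': 0.5004, 'tau_A': 0.4986}
```

i.e. the contamination rate is recovered to within 0.0008, the error rate
to the precision shown, and both drift times to within 0.3% of the values
used to generate the data. Five independent chains are run and the one
with the highest posterior is kept: the posterior surface has a mirror
basin near eps ~ 1 that traps some random starts (see
`docs/methods.md`). `fit.trace.tsv` holds the retained posterior samples
(step, log-posterior, parameters); `fit.summary.json` holds posterior
modes, 95% quantiles, the acceptance rate and a boundary-sticking
convergence flag. In library code the same run is
`paleocontam.fit_two_pop(data, cfg=ChainConfig(...))`.

Converting a drift time to calendar years, with an effective size and
generation time:

```python
>>> from paleocontam import drift_to_years
>>> drift_to_years(0.42, 21818, 29)   # modern-human drift vs Neanderthals
531486
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs, from scratch, the neutral coalescent replicate design behind the
simulation studies — 20,000 independent loci (θ = 1) with a 100-haploid
anchor panel, a 100-haploid contaminant panel from the same population
and a diploid archaic sample under a two-population split, each replicate
conditioned on holding at least one SNP segregating in both panels — and
writes the total usable-SNP count as JSON (a couple of minutes with
msprime).

## Layout

- `paleocontam.model` — closed-form genotype priors, read mixtures, and
  the vectorized genome log-likelihood (single, two-error, ts/tv and
  ancestral-state-misidentification error variants).
- `paleocontam.threepop` — spectral solver for the three-population joint
  SFS with an admixture pulse.
- `paleocontam.mcmc` — Metropolis–Hastings sampler, posterior summaries,
  multi-chain management, contaminant-panel ranking.
- `paleocontam.simulate` — synthetic-data generator and independent
  Monte-Carlo oracles (forward Wright–Fisher, msprime coalescent).
- `paleocontam.io` / `paleocontam.cli` — site-table and panel TSV I/O,
  pileup converter, command-line interface.

See `docs/methods.md` for the model, its assumptions and the numerical
choices.
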