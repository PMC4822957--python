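# Methods

## Data model

The data are per-site fragment counts from an ancient DNA library at
biallelic sites with known ancestral/derived polarization: `a` ancestral
and `d` derived fragments at site *j*, plus the derived-allele frequency
`w` in a candidate contaminant panel and the frequency `y` (or count out
of a panel of `n_Y` haploids) in an anchor population related to the
ancient sample. Only sites segregating in the contaminant panel and with
0 < y < 1 are used; triallelic sites must be removed upstream (the pileup
converter refuses them) and CpG sites can be filtered (recommended for
empirical data, since their elevated mutation rate otherwise mimics
contamination heterogeneity across GC strata).

Given the true (unknown) genotype *i* of the ancient individual, the
derived count is binomial with parameter

    q_i = r_c [w(1-eps) + (1-w) eps] + (1-r_c) [ (i/2)(1-eps) + (1-i/2) eps ]

(the heterozygote endogenous term collapses to (1-r_c)/2 for any eps).
The genome log-likelihood is the sum over sites of the log of the
genotype-marginalized binomial, with the genotype prior P[i | anchor data,
demography] supplied by one of the two demographic models below. The
likelihood never involves the population mutation rate; theta appears
only in the simulator.

### Error-model variants

* **single** — one genome-wide per-fragment error rate.
* **ts/tv** — separate rates at transition and transversion sites
  (deamination inflates transition errors in ancient DNA); every site
  carries an `is_transition` flag.
* **two-error** — rates eps1/eps2 with a fraction phi of the data under
  eps1. Since the count representation does not retain fragment identity,
  the mixture is applied independently at each site; for i.i.d. fragments
  this is marginally equivalent to a fragment-level assignment.
* **single + ASM** — with probability `r_asm` a site is mispolarized; the
  flipped component swaps a and d, complements w and y, and recomputes
  the genotype prior at 1-y. ASM is only offered with the single-error
  variant; combining it with the other variants multiplies mixture
  components without evidence the original tool supports it.

## Two-population genotype prior

The prior P[i | y, tau_C, tau_A] is the exact diffusion solution for
neutral variation: standing variation in the common ancestor (density
proportional to 1/x) plus new mutations on the anchor branch, drifting
independently down the anchor branch (tau_C) and the ancient branch
(tau_A), conditioned on the anchor frequency y. In the tau -> 0 limit it
is Hardy-Weinberg at y; as tau_C grows the prior shrinks the implied
ancestral frequency as E[x0 | y] = y e^{-tau_C}. The closed form treats
the anchor panel frequency as the population frequency (the panel is
assumed large); with small panels (e.g. 20 haploids) the extra sampling
noise acts like extra drift and biases the drift estimates slightly
upward. This is documented behaviour, not corrected.

A forward binomial Wright-Fisher simulator (`wf_forward_oracle`)
validates the closed form by importance sampling: standing variants start
from the stationary segregating profile (P[k] ~ 1/k), branch mutations
enter at single-copy frequency at the stationary influx rate, and paths
are weighted by landing in a small window around y. The branch-mutation
component is oversampled 10x because such paths are individually cheap
but rare in the window.

## Three-population model and numerical SFS

Demography: ancestral population -> archaic branch (drift tau_A) and
modern branch (drift tau_C); modern splits into anchors Y and Z with
*fixed* post-split drifts tau_Y, tau_Z (estimated upstream without the
archaic genome); an instantaneous pulse at time beta before present
replaces a fraction alpha of Y with the archaic population. The pulse
must sit on the Y branch (beta <= tau_Y) and before archaic sampling
(beta <= tau_A); the donor is the archaic population beta before its
sampling time.

The joint SFS over (archaic genotype, Y count, Z count) is computed on a
frequency grid:

* **Grid.** Smoothstep-transformed (crowded near 0 and 1), default 61
  points per axis. The crowding resolves the boundary layer of the 1/x
  profile where mutation influx enters; on a uniform grid the
  conditionals at single-copy count cells converge only O(dx).
* **Drift propagator.** The diffusion generator is discretized as the
  unique birth-death chain matching the diffusion's first two moments at
  every grid point, with absorbing boundaries. Propagators, their time
  integrals and the stationary profile all come from one eigendecomposition
  of the symmetrized generator, so the solution is exact in time (no time
  stepping) and a full SFS evaluates in ~1.5 ms — fast enough to sit
  inside the MCMC loop, recomputed once per proposed demography and
  reused across all sites. Heterozygosity decays exactly as e^{-tau}
  under the discrete propagator (quadratics are in the scheme's kernel),
  which the tests assert at 1e-10.
* **Mutation model.** The root population carries the discrete
  mutation-drift stationary profile (the grid analogue of theta/x) and
  every branch receives the constant low-frequency influx theta/2 per
  unit drift time that maintains it. These two pieces together are the
  exact discrete analogue of the continuum standing-variation model that
  underlies the two-population closed form, and the alpha = 0,
  tau_Y = tau_Z = 0 limit of the solver reproduces that closed form to
  < 0.01 per entry. Influx per unit drift time is branch-independent,
  which corresponds to all populations sharing the ancestral effective
  size; branch-specific sizes are not modelled (the model is
  parameterized by drift times only, as in the two-population case).
  Mutations private to Z or to the post-pulse archaic branch can never
  satisfy the 0 < y < 1 usability filter and are omitted, so cells with
  Y count 0 or n_Y are not meaningful.
* **Pulse.** The post-pulse Y frequency (1-alpha) x_Y + alpha x_A is
  deposited back onto the grid by linear interpolation, then drifts beta
  and is binomially projected onto panel counts.

An independent msprime coalescent oracle (infinite-sites mutations on all
branches) reproduces the solver's conditional genotype probabilities cell
by cell at a demography realizable with equal population sizes
(tau_A = tau_C + tau_Y). Demographies violating that constraint (e.g. a
Neanderthal-like tau_A = 2.5) are perfectly valid model inputs but
correspond, in a real genealogy, to a smaller archaic population whose
branch influx the equal-size convention overstates; the conditional
probabilities at Z-monomorphic cells then depend on that convention.

## MCMC

Uniform priors on every parameter, user-modifiable bounds; defaults
r_c, eps, alpha in [0, 1], drifts in [0, 5], beta per user interval. Each
step proposes all parameters jointly from independent normals with s.d. =
prior range / c (default c = 1,000); a proposal outside any bound has
zero prior density and is rejected before the likelihood is touched —
with uniform priors inside the support the acceptance probability is
min(1, exp(delta log-likelihood)). Defaults: 100,000 steps, 40,000
burn-in, thinning 100; a long-regime preset (1,000,000 steps, 940,000
burn-in) exists for low-coverage genomes, where running ~10 chains and
keeping the one with the highest log posterior is the recommended
protocol.

Summaries: per-parameter histogram mode with Freedman-Diaconis bins (ties
broken toward the bin with more neighbour mass, then the lower value),
2.5%/97.5% quantiles, max log posterior over retained samples, acceptance
rate, and a convergence flag that trips when any mode sits within 1% of a
prior bound (the boundary-sticking failure mode seen on low-coverage
data). No Gelman-Rubin statistic is computed.

The posterior surface is multimodal: a mirror basin near eps ~ 1 (flipped
read polarity) and, in the three-population model, a basin near alpha ~ 1
(anchor Y replaced by the archaic side, with the drift roles swapped)
attract a substantial fraction of random starts. Both sit far below the
true mode in log likelihood (hundreds to thousands of units on realistic
data sizes), so the multi-chain best-of protocol resolves them; single
chains from random starts should not be trusted without it.

Contaminant-panel ranking refits the model once per candidate panel with
the same anchor, settings and seed and sorts by the maximum log-posterior
over retained samples. This is an explicit heuristic — MCMC samples carry
no marginal likelihood, so it is not Bayesian model selection.

## Synthetic data

The default generator is coalescent-free and model-congruent: anchor
counts from the neutral conditioned SFS (P[k] ~ 1/k), genotypes from the
model's own conditional law (closed form or SFS grid), coverage ~
Poisson(lambda) (sites with zero coverage are dropped and counted), and
reads from the contamination/error binomials with the contaminant panel
equal to the anchor panel unless stated. Green recovery tests therefore
establish correctness of the inference machinery, not realism of the
model; the independent-physics oracles (forward Wright-Fisher, msprime
genealogies, the five-population tree generator for panel-ranking
experiments) cover the latter at desk scale. Features of real data that
the generator does not emulate: linkage between sites, reference bias,
fragment-length and position-dependent damage structure, and
base-quality variation.

Two stressors are modelled at count level:

* **Deamination** adds an extra transition-site error of
  (0.08 + 0.34)/50 + 0.01 ~ 0.018 to endogenous fragments only —
  terminal C->T rates of ~8% (5') and ~34% (3') plus ~1% residual,
  averaged over a typical ~50 bp ancient fragment. Position-within-
  fragment structure is not represented (counts carry no positions); the
  ts/tv fit still sees the inflated transition error.
* **Single-contaminant mode** draws a per-site pair of panel chromosomes
  and samples all contaminant fragments from it, overdispersing the
  contaminant reads relative to panel-frequency sampling.

The replicate-count bookkeeping (`count_usable_snps`) follows the
original simulation design: independent coalescent loci with theta = 1, a
100-haploid anchor panel and a 100-haploid contaminant panel drawn from
the same modern population, usable = segregating in both panels,
replicates conditioned (by redrawing) on at least one usable SNP. This
yields ~4.5 usable SNPs per replicate (~90,000 over 20,000 replicates);
the expectation is demography-independent because the panel-side
genealogy of a constant-size population does not feel the archaic split.

## Scaled test protocol

The acceptance tests run chains of 25,000-30,000 steps with ~70% burn-in
and 5-6 seeds (best chain kept) instead of the production 100,000-step
defaults, and the three-population recovery uses 20,000 sites and
proposal constant c = 300 for faster traversal of the [0, 5] drift box.
These are runtime scalings of the stated protocols, not changes to the
model or tolerances. The long burn-in fraction matters at desk scale:
with a 40% burn-in the retained window still contains the transient of
chains that start far away, and the histogram mode can land on the
transient rather than the stationary mass.

## Known limitations

* Drift times near the 5-unit prior ceiling stick at the boundary on weak
  data (flagged, not fixed), matching the production tool's behaviour on
  low-coverage genomes.
* The anchor-frequency plug-in ignores panel sampling noise in the
  two-population model; small panels bias drifts upward.
* The three-population solver's equal-size influx convention (above).
* The admixture time beta is weakly identified; it is sampled, and with
  an ancient-pulse prior its posterior is close to its prior.
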