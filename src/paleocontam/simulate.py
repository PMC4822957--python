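"""Synthetic data generation and independent Monte-Carlo oracles.

Two kinds of generator live here and are deliberately kept apart:

* a coalescent-free generator (:func:`simulate_dataset`) that draws panel
  frequencies from the neutral conditioned sample SFS (P[k] proportional
  to 1/k), genotypes from the model's own conditional law, coverage from a
  Poisson and reads from the binomial contamination/error mixture — used
  for model-congruent parameter-recovery experiments;
* coalescent- and forward-simulation oracles (:func:`wf_forward_oracle`,
  :func:`simulate_tree_panels`, :func:`coalescent_threepop_conditional`,
  :func:`count_usable_snps`) that implement independent population-genetic
  physics (binomial Wright-Fisher reproduction, msprime genealogies) and
  are used to validate the analytic and numeric genotype probabilities and
  to reproduce the replicate-count bookkeeping of the original simulation
  design.

The population-scaled mutation rate theta exists only in this module; no
likelihood computation depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .model import (SiteData, TwoPopDemography, SingleError, TwoError,
                    TsTvError, AsmError, ErrorModel, genotype_probs_two_pop)
from .threepop import ThreePopDemography, expected_joint_sfs

__all__ = [
    "SyntheticScenario",
    "sample_panel_frequency",
    "simulate_dataset",
    "wf_forward_oracle",
    "simulate_tree_panels",
    "coalescent_threepop_conditional",
    "count_usable_snps",
]

# Count-level stand-in for post-mortem deamination: terminal C->T rates of
# ~8% (5') and ~34% (3') plus ~1% residual, averaged over a typical ~50 bp
# ancient fragment, add roughly (0.08 + 0.34)/50 + 0.01 of extra error at
# transition sites of endogenous fragments.
DEAMINATION_EXTRA_TS_ERROR = (0.08 + 0.34) / 50.0 + 0.01
TRANSITION_FRACTION = 2.0 / 3.0  # share of transition SNPs genome-wide


@dataclass
class SyntheticScenario:
    """Full generative configuration for one synthetic dataset."""

    demography: Union[TwoPopDemography, ThreePopDemography]
    r_c: float = 0.0
    error: ErrorModel = SingleError(0.001)
    coverage: float = 30.0
    panel_size: int = 100          # anchor panel haploid size (n_y for three-pop)
    n_z: int = 20                  # Z panel haploid size (three-pop only)
    same_panel: bool = True        # contaminant panel == anchor panel
    n_sites: int = 80_000          # target number of usable SNPs
    single_contaminant: bool = False
    deamination: bool = False
    deamination_extra: float = DEAMINATION_EXTRA_TS_ERROR
    ts_fraction: float = TRANSITION_FRACTION
    seed: Optional[int] = None
    theta: float = 1.0             # simulator-only; never enters a likelihood
    grid_points: Optional[int] = None

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("mean coverage must be > 0")
        if self.panel_size < 2 or self.n_z < 2:
            raise ValueError("panel sizes must be >= 2")
        for nm in ("r_c", "deamination_extra", "ts_fraction"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must be in [0, 1]")


def sample_panel_frequency(n: int, rng: np.random.Generator,
                           size: Optional[int] = None) -> np.ndarray:
    """Derived count k in {1..n-1} with P[k] proportional to 1/k — the
    neutral sample SFS conditioned on segregating in a panel of ``n``
    haploids, which is what independent coalescent replicates realize."""
    if n < 2:
        raise ValueError("panel size must be >= 2")
    k = np.arange(1, n)
    p = (1.0 / k) / np.sum(1.0 / k)
    return rng.choice(k, size=size, p=p)


def _per_site_eps(error: ErrorModel, is_ts: np.ndarray, deam_extra: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-site error rate of the *endogenous* fragments under the truth
    error model, with the deamination surcharge already applied where
    requested (deam_extra = 0 disables it)."""
    n = len(is_ts)
    if isinstance(error, SingleError):
        eps = np.full(n, error.eps)
    elif isinstance(error, TsTvError):
        eps = np.where(is_ts, error.eps_ts, error.eps_tv)
    elif isinstance(error, TwoError):
        eps = np.where(rng.uniform(size=n) < error.phi, error.eps1, error.eps2)
    elif isinstance(error, AsmError):
        eps = np.full(n, error.eps)
    else:
        raise TypeError(f"unknown error model {error!r}")
    return np.clip(eps + deam_extra * is_ts, 0.0, 1.0)


def simulate_dataset(sc: SyntheticScenario) -> Tuple[SiteData, dict]:
    """Generate usable sites plus a truth record for recovery tests.

    Per site: draw the anchor frequency (conditioned neutral SFS for the
    two-population model; the solver's joint SFS for the three-population
    model), the true ancient genotype from the model's conditional law,
    coverage ~ Poisson(lambda) (zero-coverage sites are dropped and
    counted), contaminant fragment counts ~ Binomial(coverage, r_c), and
    allele counts from the error-aware binomials.  The deamination toggle
    inflates the transition-site error of endogenous fragments only; it
    never touches the error model used for fitting.
    """
    rng = np.random.default_rng(sc.seed)
    n = sc.n_sites
    dem = sc.demography
    three_pop = isinstance(dem, ThreePopDemography)

    if three_pop:
        grid = expected_joint_sfs(dem, sc.panel_size, sc.n_z,
                                  **({"grid_points": sc.grid_points} if sc.grid_points else {}))
        mass = grid.sfs.copy()
        mass[:, 0, :] = 0.0
        mass[:, sc.panel_size, :] = 0.0     # condition on Y segregating
        flat = mass.reshape(-1)
        cell = rng.choice(flat.size, size=n, p=flat / flat.sum())
        geno, rem = np.divmod(cell, (sc.panel_size + 1) * (sc.n_z + 1))
        y_cnt, z_cnt = np.divmod(rem, sc.n_z + 1)
        y = y_cnt / sc.panel_size
    else:
        y_cnt = sample_panel_frequency(sc.panel_size, rng, size=n)
        y = y_cnt / sc.panel_size
        z_cnt = None
        gp = genotype_probs_two_pop(y, dem)
        u = rng.uniform(size=n)
        cum = np.cumsum(gp, axis=1)
        geno = (u[:, None] > cum).sum(axis=1)

    if not sc.same_panel:
        raise NotImplementedError(
            "independent contaminant panels come from simulate_tree_panels")
    w = y.copy()

    is_ts = rng.uniform(size=n) < sc.ts_fraction
    eps_endo = _per_site_eps(sc.error, is_ts,
                             sc.deamination_extra if sc.deamination else 0.0, rng)
    # contaminant fragments: sequencing error only, no deamination
    eps_cont = _per_site_eps(sc.error, is_ts, 0.0, rng)

    cov = rng.poisson(sc.coverage, size=n)
    n_cont = rng.binomial(cov, sc.r_c)
    n_endo = cov - n_cont

    if sc.single_contaminant:
        # one diploid contaminant: fix a per-site pair of panel chromosomes
        g_cont = rng.binomial(2, w)
        w_eff = g_cont / 2.0
    else:
        w_eff = w
    p_cont = w_eff * (1.0 - eps_cont) + (1.0 - w_eff) * eps_cont
    p_endo = (geno / 2.0) * (1.0 - eps_endo) + (1.0 - geno / 2.0) * eps_endo
    d = rng.binomial(n_endo, p_endo) + rng.binomial(n_cont, p_cont)
    a = cov - d

    if isinstance(sc.error, AsmError) and sc.error.r_asm > 0:
        flip = rng.uniform(size=n) < sc.error.r_asm
        a[flip], d[flip] = d[flip].copy(), a[flip].copy()
        w[flip] = 1.0 - w[flip]
        y[flip] = 1.0 - y[flip]
        y_cnt = np.where(flip, sc.panel_size - y_cnt, y_cnt)

    keep = cov > 0
    data = SiteData(
        a=a[keep], d=d[keep], w=w[keep], y=y[keep],
        is_transition=is_ts[keep],
        y_count=y_cnt[keep] if three_pop else None,
        z_count=z_cnt[keep] if three_pop else None,
        n_y=sc.panel_size if three_pop else None,
        n_z=sc.n_z if three_pop else None,
    )
    truth = {
        "r_c": sc.r_c, "error": sc.error, "demography": dem,
        "coverage": sc.coverage, "n_sites_drawn": n,
        "n_zero_coverage": int((~keep).sum()), "seed": sc.seed,
        "genotype_counts": np.bincount(geno[keep], minlength=3).tolist(),
    }
    return data, truth


# ---------------------------------------------------------------------------
# forward Wright-Fisher oracle
# ---------------------------------------------------------------------------

def wf_forward_oracle(y: float, dem: TwoPopDemography, n_pop: int = 1_000,
                      reps: int = 100_000, bin_halfwidth: float = 0.01,
                      seed: Optional[int] = None
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo estimate of P[i | y, tau_C, tau_A] from forward binomial
    Wright-Fisher reproduction in a population of ``n_pop`` diploids.

    The conditional law of the ancestral state given an anchor frequency
    in [y - h, y + h] is realized by importance weighting forward paths:
    standing variants start from the stationary segregating profile
    (P[k] ~ 1/k, weight a_{2N-1} in total) and new mutations enter on the
    anchor branch at single-copy frequency at the stationary influx rate
    (total weight N tau_C, contributing genotype 0 with certainty).
    Returns (probabilities, Monte-Carlo standard errors); fails if no path
    lands in the anchor-frequency bin.
    """
    if n_pop < 100:
        raise ValueError("n_pop must be >= 100")
    if reps < 1_000:
        raise ValueError("reps must be >= 1000")
    if not 0.0 < y < 1.0:
        raise ValueError("y must be strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    two_n = 2 * n_pop
    gens_c = int(round(dem.tau_C * two_n))
    gens_a = int(round(dem.tau_A * two_n))

    n_standing = reps
    # branch-mutation paths are far cheaper (most die within a few
    # generations) but rarer in the anchor bin, so oversample them
    n_branch = 10 * reps
    # standing component: k0 ~ 1/k; total expected segregating sites a_{2N-1}
    kvals = np.arange(1, two_n)
    pk = (1.0 / kvals) / np.sum(1.0 / kvals)
    a_harm = np.sum(1.0 / kvals)
    k0 = rng.choice(kvals, size=n_standing, p=pk)
    anchor = k0.copy()
    for _ in range(gens_c):
        seg = (anchor > 0) & (anchor < two_n)
        if seg.any():
            anchor[seg] = rng.binomial(two_n, anchor[seg] / two_n)
    w_st = np.full(n_standing, a_harm / n_standing)

    # branch-mutation component: enter at count 1 at uniform times; total
    # expected number over the branch is N per drift unit (theta = 1)
    if gens_c > 0:
        enter_gen = rng.integers(0, gens_c, size=n_branch)
        br = np.ones(n_branch, dtype=np.int64)
        for g in range(gens_c):
            active = np.flatnonzero((enter_gen <= g) & (br > 0) & (br < two_n))
            if active.size:
                br[active] = rng.binomial(two_n, br[active] / two_n)
        w_br = np.full(n_branch, (n_pop * dem.tau_C) / n_branch)
    else:
        br = np.zeros(0, dtype=np.int64)
        w_br = np.zeros(0)

    lo_bin = (y - bin_halfwidth) * two_n
    hi_bin = (y + bin_halfwidth) * two_n
    hit_st = (anchor >= lo_bin) & (anchor <= hi_bin)
    hit_br = (br >= lo_bin) & (br <= hi_bin)
    n_hits = int(hit_st.sum() + hit_br.sum())
    if n_hits == 0:
        raise RuntimeError(
            "no forward path landed in the anchor-frequency bin; "
            "increase reps or bin_halfwidth")

    # archaic side: standing paths restart from k0 and drift tau_A; branch
    # paths are absent from the archaic population (frequency 0)
    arch = k0[hit_st].copy()
    for _ in range(gens_a):
        seg = (arch > 0) & (arch < two_n)
        if seg.any():
            arch[seg] = rng.binomial(two_n, arch[seg] / two_n)
    xa = arch / two_n
    g_st = np.stack([(1 - xa) ** 2, 2 * xa * (1 - xa), xa ** 2], axis=1)
    g_br = np.tile([1.0, 0.0, 0.0], (int(hit_br.sum()), 1))
    g = np.concatenate([g_st, g_br], axis=0)
    wts = np.concatenate([w_st[hit_st], w_br[hit_br]])

    wsum = wts.sum()
    probs = (wts[:, None] * g).sum(axis=0) / wsum
    resid = g - probs[None, :]
    se = np.sqrt(np.sum((wts[:, None] * resid) ** 2, axis=0)) / wsum
    return probs, se


# ---------------------------------------------------------------------------
# msprime-backed oracles
# ---------------------------------------------------------------------------

def _tree_demography(drifts: Dict[str, float], alpha: float, n_e: int):
    """Five-population demography for panel-misspecification experiments:
    ((A,B),(C,D)) modern clade with an ancient outgroup O, optional pulse
    from O into the A/B ancestor.  Drift times tau convert to generations
    as tau * 2 Ne at constant Ne."""
    import msprime
    t_ab = drifts["terminal"] * 2 * n_e
    t_abcd = t_ab + drifts["internal"] * 2 * n_e
    t_root = t_abcd + drifts["modern_stem"] * 2 * n_e
    t_pulse = 0.5 * (t_ab + t_abcd)
    dem = msprime.Demography()
    for name in ("A", "B", "C", "D", "O"):
        dem.add_population(name=name, initial_size=n_e)
    for name in ("AB", "CD", "ABCD", "ROOT"):
        dem.add_population(name=name, initial_size=n_e)
    dem.add_population_split(time=t_ab, derived=["A", "B"], ancestral="AB")
    dem.add_population_split(time=t_ab, derived=["C", "D"], ancestral="CD")
    if alpha > 0:
        dem.add_mass_migration(time=t_pulse, source="AB", dest="O", proportion=alpha)
    dem.add_population_split(time=t_abcd, derived=["AB", "CD"], ancestral="ABCD")
    dem.add_population_split(time=t_root, derived=["ABCD", "O"], ancestral="ROOT")
    dem.sort_events()
    return dem, t_root


def simulate_tree_panels(panel_size: int = 100, alpha: float = 0.0,
                         drifts: Optional[Dict[str, float]] = None,
                         sequence_length: float = 8e6, n_e: int = 10_000,
                         seed: Optional[int] = None) -> Dict[str, np.ndarray]:
    """Coalescent-sampled joint panel frequencies for four present-day
    populations (A, B, C, D) plus archaic genotypes from an outgroup O,
    with optional gene flow O -> ancestor of A/B at rate ``alpha``.

    Returns a dict with derived counts per panel, the archaic genotype per
    site, and the panel size; sites are restricted to those segregating in
    every panel so all four candidate contaminant vectors cover the same
    loci.
    """
    import msprime
    drifts = drifts or {"terminal": 0.1, "internal": 0.1, "modern_stem": 0.2}
    dem, _ = _tree_demography(drifts, alpha, n_e)
    samples = {p: panel_size // 2 for p in ("A", "B", "C", "D")}
    samples["O"] = 1
    ts = msprime.sim_ancestry(samples=samples, demography=dem,
                              sequence_length=sequence_length,
                              recombination_rate=1e-8, random_seed=_msp_seed(seed, 0))
    ts = msprime.sim_mutations(ts, rate=1.25e-8, random_seed=_msp_seed(seed, 1))
    pops = {p: ts.samples(population=i) for i, p in
            enumerate(("A", "B", "C", "D", "O"))}
    geno = np.minimum(ts.genotype_matrix(), 1)  # (sites, samples)
    counts = {p: geno[:, nodes].sum(axis=1) for p, nodes in pops.items()}
    seg = np.ones(len(geno), dtype=bool)
    for p in ("A", "B", "C", "D"):
        seg &= (counts[p] > 0) & (counts[p] < panel_size)
    out = {p: counts[p][seg] for p in ("A", "B", "C", "D")}
    out["archaic_genotype"] = counts["O"][seg]
    out["panel_size"] = panel_size
    return out


def _msp_seed(seed: Optional[int], offset: int) -> Optional[int]:
    if seed is None:
        return None
    return int((seed * 7919 + offset) % (2**31 - 1)) + 1


def coalescent_threepop_conditional(dem: ThreePopDemography, n_y: int, n_z: int,
                                    reps: int = 200_000, n_e: int = 10_000,
                                    theta: float = 1.0,
                                    seed: Optional[int] = None):
    """Monte-Carlo estimate of P[i | y_count, z_count] from independent
    coalescent replicates with mutations, as an oracle for the numerical
    SFS solver.  Returns (counts[i, y, z], conditional, se) where cells
    with few hits carry large standard errors."""
    import msprime
    t_pulse = dem.beta * 2 * n_e
    t_yz = dem.tau_Y * 2 * n_e
    t_root = t_yz + dem.tau_C * 2 * n_e
    # archaic Ne chosen so the archaic branch accrues tau_A of drift over
    # the same wall-clock span t_root
    ne_arch = max(t_root / (2.0 * dem.tau_A), 1.0) if dem.tau_A > 0 else n_e
    # the Z branch spans [0, t_yz]: choose its size to accrue tau_Z of drift
    ne_z = max(t_yz / (2.0 * dem.tau_Z), 1.0) if dem.tau_Z > 0 else n_e

    d = msprime.Demography()
    d.add_population(name="Y", initial_size=n_e)
    d.add_population(name="Z", initial_size=ne_z if dem.tau_Z > 0 else n_e)
    d.add_population(name="ARCH", initial_size=ne_arch)
    d.add_population(name="M", initial_size=n_e)
    d.add_population(name="ROOT", initial_size=n_e)
    if dem.tau_Z == 0:
        # zero drift on Z: effectively infinite size; msprime needs finite,
        # so use a huge population
        d.populations[1].initial_size = 1e12
    if dem.alpha > 0:
        d.add_mass_migration(time=t_pulse, source="Y", dest="ARCH", proportion=dem.alpha)
    d.add_population_split(time=t_yz, derived=["Y", "Z"], ancestral="M")
    d.add_population_split(time=t_root, derived=["M", "ARCH"], ancestral="ROOT")
    d.sort_events()
    mu = theta / (4.0 * n_e)
    counts = np.zeros((3, n_y + 1, n_z + 1))
    anc = msprime.sim_ancestry(
        samples={"Y": n_y // 2, "Z": n_z // 2, "ARCH": 1}, demography=d,
        sequence_length=1, num_replicates=reps, random_seed=_msp_seed(seed, 0))
    rng = np.random.default_rng(_msp_seed(seed, 1))
    for ts in anc:
        # infinite-sites mutations: every mutation is its own biallelic site
        ts = msprime.sim_mutations(ts, rate=mu, discrete_genome=False,
                                   model=msprime.BinaryMutationModel(),
                                   random_seed=int(rng.integers(1, 2**31 - 1)))
        if ts.num_sites == 0:
            continue
        y_nodes = ts.samples(population=0)
        z_nodes = ts.samples(population=1)
        a_nodes = ts.samples(population=2)
        g = np.minimum(ts.genotype_matrix(), 1)
        yc = g[:, y_nodes].sum(axis=1)
        zc = g[:, z_nodes].sum(axis=1)
        ac = g[:, a_nodes].sum(axis=1)
        np.add.at(counts, (ac, yc, zc), 1.0)
    tot = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(tot > 0, counts / tot, np.nan)
        se = np.sqrt(np.clip(cond * (1 - cond), 0, None) / np.maximum(tot, 1))
    return counts, cond, se


def count_usable_snps(n_replicates: int = 20_000, panel_size: int = 100,
                      dem: Optional[TwoPopDemography] = None,
                      n_e: int = 10_000, theta: float = 1.0,
                      seed: Optional[int] = None) -> int:
    """Total usable SNPs from independent neutral coalescent replicates.

    Each replicate (theta = 1 per locus) samples an anchor panel and a
    contaminant panel of ``panel_size`` haploids from the same modern
    population plus a diploid archaic individual under a two-population
    split; a SNP is usable when it segregates in both panels (the anchor
    filter 0 < y < 1 and the contaminant filter 0 < w < 1).  Replicates
    are conditioned on containing at least one usable SNP, by redrawing.
    """
    import msprime
    dem = dem or TwoPopDemography(tau_C=0.2, tau_A=0.2)
    t_split = dem.tau_C * 2 * n_e
    ne_arch = max(t_split / (2.0 * dem.tau_A), 1.0) if dem.tau_A > 0 else n_e
    d = msprime.Demography()
    d.add_population(name="MOD", initial_size=n_e)
    d.add_population(name="ARCH", initial_size=ne_arch)
    d.add_population(name="ROOT", initial_size=n_e)
    d.add_population_split(time=t_split, derived=["MOD", "ARCH"], ancestral="ROOT")
    mu = theta / (4.0 * n_e)
    n_half = panel_size // 2
    rng = np.random.default_rng(_msp_seed(seed, 1))
    total = 0
    done = 0
    while done < n_replicates:
        batch = min(n_replicates - done, 2_000)
        anc = msprime.sim_ancestry(
            samples={"MOD": 2 * n_half, "ARCH": 1}, demography=d,
            sequence_length=1, num_replicates=batch,
            random_seed=int(rng.integers(1, 2**31 - 1)))
        for ts in anc:
            ts = msprime.sim_mutations(ts, rate=mu, discrete_genome=False,
                                       model=msprime.BinaryMutationModel(),
                                       random_seed=int(rng.integers(1, 2**31 - 1)))
            usable = 0
            if ts.num_sites:
                g = np.minimum(ts.genotype_matrix(), 1)
                mod = ts.samples(population=0)
                anchor = g[:, mod[:panel_size]].sum(axis=1)
                contam = g[:, mod[panel_size:]].sum(axis=1)
                ok = ((anchor > 0) & (anchor < panel_size)
                      & (contam > 0) & (contam < panel_size))
                usable = int(ok.sum())
            if usable >= 1:          # condition: redraw zero-SNP replicates
                total += usable
                done += 1
                if done == n_replicates:
                    break
    return total
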