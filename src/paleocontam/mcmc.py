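"""Metropolis-Hastings sampler and posterior summaries.

All parameters carry independent uniform priors with user-modifiable
bounds.  Each step proposes every parameter jointly from independent
normals centred at the current state, with standard deviation equal to the
prior range divided by a tunable constant (default 1,000).  A proposal
with any coordinate outside its prior bounds has zero prior density and is
rejected before the likelihood is evaluated; inside the support the
uniform prior cancels and the acceptance probability is the bare
likelihood ratio min(1, exp(loglik_new - loglik_old)).

Summaries follow the reporting conventions of the inference tool this
package reimplements: per-parameter posterior modes (histogram mode with
Freedman-Diaconis bins), 2.5%/97.5% quantiles, the maximum log-posterior
over retained samples, the acceptance rate, and a boundary-sticking
convergence flag (mode within 1% of the prior range of either bound).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PriorSpec",
    "ChainConfig",
    "PosteriorSummary",
    "ChainResult",
    "mh_accept_prob",
    "run_chain",
    "posterior_mode",
    "best_of_chains",
    "rank_panels",
    "fit_two_pop",
    "fit_three_pop",
]

DEFAULT_DRIFT_BOUNDS = (0.0, 5.0)


@dataclass
class PriorSpec:
    """Ordered per-parameter uniform prior bounds."""

    bounds: Dict[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"prior for {name} needs lower < upper, got ({lo}, {hi})")

    @property
    def names(self) -> List[str]:
        return list(self.bounds)

    @property
    def lo(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds.values()])

    @property
    def hi(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds.values()])

    def replace(self, **kw: Tuple[float, float]) -> "PriorSpec":
        b = dict(self.bounds)
        for k, v in kw.items():
            if k not in b:
                raise KeyError(f"unknown parameter {k}")
            b[k] = v
        return PriorSpec(b)

    @classmethod
    def two_pop(cls, error: str = "single") -> "PriorSpec":
        b: Dict[str, Tuple[float, float]] = {"r_c": (0.0, 1.0)}
        b.update(_error_bounds(error))
        b["tau_C"] = DEFAULT_DRIFT_BOUNDS
        b["tau_A"] = DEFAULT_DRIFT_BOUNDS
        return cls(b)

    @classmethod
    def three_pop(cls, beta_bounds: Tuple[float, float] = (0.0, 0.1)) -> "PriorSpec":
        b: Dict[str, Tuple[float, float]] = {"r_c": (0.0, 1.0), "eps": (0.0, 1.0)}
        b["tau_C"] = DEFAULT_DRIFT_BOUNDS
        b["tau_A"] = DEFAULT_DRIFT_BOUNDS
        b["alpha"] = (0.0, 1.0)
        b["beta"] = beta_bounds
        return cls(b)


def _error_bounds(error: str) -> Dict[str, Tuple[float, float]]:
    if error == "single":
        return {"eps": (0.0, 1.0)}
    if error == "two_error":
        return {"eps1": (0.0, 1.0), "eps2": (0.0, 1.0), "phi": (0.0, 1.0)}
    if error == "ts_tv":
        return {"eps_ts": (0.0, 1.0), "eps_tv": (0.0, 1.0)}
    if error == "asm":
        return {"eps": (0.0, 1.0), "r_asm": (0.0, 1.0)}
    raise ValueError(f"unknown error model name {error!r}")


@dataclass
class ChainConfig:
    """MCMC run settings.  ``proposal_c`` is the constant dividing each
    prior range to give the per-parameter proposal standard deviation."""

    n_steps: int = 100_000
    burn_in: int = 40_000
    thin: int = 100
    proposal_c: float = 1_000.0
    n_chains: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_steps > 0 and not self.burn_in < self.n_steps:
            raise ValueError("burn_in must be smaller than n_steps")
        if self.thin < 1 or self.proposal_c <= 0 or self.n_chains < 1:
            raise ValueError("need thin >= 1, proposal_c > 0, n_chains >= 1")

    @classmethod
    def long_regime(cls, **kw) -> "ChainConfig":
        """Preset for low-coverage genomes: 1,000,000 steps with a 940,000
        burn-in, sampling every 100 steps (typically with 10 chains)."""
        kw.setdefault("n_steps", 1_000_000)
        kw.setdefault("burn_in", 940_000)
        kw.setdefault("thin", 100)
        return cls(**kw)


@dataclass
class PosteriorSummary:
    modes: Dict[str, float]
    q025: Dict[str, float]
    q975: Dict[str, float]
    log_post_mode: float
    acceptance_rate: float
    converged: bool
    n_retained: int
    seed: Optional[int] = None
    config: Optional[dict] = None

    def to_json(self, **kw) -> str:
        return json.dumps(self.__dict__, indent=2, default=float, **kw)


@dataclass
class ChainResult:
    trace: pd.DataFrame          # columns: step, log_post, <parameters...>
    summary: Optional[PosteriorSummary]
    priors: PriorSpec
    config: ChainConfig

    @property
    def param_names(self) -> List[str]:
        return [c for c in self.trace.columns if c not in ("step", "log_post")]


def mh_accept_prob(loglik_new: float, loglik_old: float) -> float:
    """min(1, exp(loglik_new - loglik_old)); NaN input is a hard failure."""
    if math.isnan(loglik_new) or math.isnan(loglik_old):
        raise ValueError("NaN log-likelihood in acceptance ratio")
    return min(1.0, math.exp(min(loglik_new - loglik_old, 0.0)))


def posterior_mode(samples: Sequence[float]) -> float:
    """Histogram mode with Freedman-Diaconis bin width.

    Ties between equal-count bins are broken toward the bin with higher
    neighbour mass, then toward the lower value.  Requires >= 50 samples.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 50:
        raise ValueError(f"posterior_mode needs >= 50 samples, got {x.size}")
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    width = 2.0 * iqr / x.size ** (1.0 / 3.0)
    if width <= 0 or x.max() == x.min():
        return float(np.median(x))
    nbins = max(1, int(np.ceil((x.max() - x.min()) / width)))
    counts, edges = np.histogram(x, bins=nbins)
    best = np.flatnonzero(counts == counts.max())
    if best.size > 1:
        padded = np.concatenate([[0], counts, [0]])
        neigh = padded[best] + padded[best + 2]  # left + right neighbour
        best = best[neigh == neigh.max()]
    b = int(best[0])
    return float(0.5 * (edges[b] + edges[b + 1]))


def summarize(trace: pd.DataFrame, priors: PriorSpec,
              acceptance_rate: float, cfg: Optional[ChainConfig] = None
              ) -> PosteriorSummary:
    names = [c for c in trace.columns if c not in ("step", "log_post")]
    modes, lo_q, hi_q = {}, {}, {}
    converged = True
    for name in names:
        s = trace[name].to_numpy()
        if len(s) == 1:
            m = float(s[0])
        else:
            m = posterior_mode(s)
        modes[name] = m
        lo_q[name] = float(np.quantile(s, 0.025))
        hi_q[name] = float(np.quantile(s, 0.975))
        lo, hi = priors.bounds[name]
        margin = 0.01 * (hi - lo)
        if m <= lo + margin or m >= hi - margin:
            converged = False
    return PosteriorSummary(
        modes=modes, q025=lo_q, q975=hi_q,
        log_post_mode=float(trace["log_post"].max()),
        acceptance_rate=acceptance_rate, converged=converged,
        n_retained=len(trace), seed=cfg.seed if cfg else None,
        config={k: getattr(cfg, k) for k in ("n_steps", "burn_in", "thin", "proposal_c")} if cfg else None,
    )


def run_chain(loglik_fn: Callable[[np.ndarray], float], priors: PriorSpec,
              cfg: ChainConfig) -> ChainResult:
    """Single Metropolis-Hastings chain.

    The initial state is uniform-random from the priors under ``cfg.seed``;
    retained samples are the post-burn-in states at every ``thin``-th step.
    Identical seeds give bit-identical traces.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = priors.lo, priors.hi
    sd = (hi - lo) / cfg.proposal_c
    x = rng.uniform(lo, hi)
    ll = float(loglik_fn(x))
    if math.isnan(ll):
        raise ValueError("NaN log-likelihood at the initial state")
    names = priors.names
    rows = []
    n_acc = 0
    if cfg.n_steps == 0:
        rows.append((0, ll, *x))
    for step in range(1, cfg.n_steps + 1):
        prop = x + rng.normal(0.0, 1.0, size=len(x)) * sd
        # out-of-prior proposals have acceptance 0: draw nothing further
        if np.all(prop >= lo) and np.all(prop <= hi):
            llp = float(loglik_fn(prop))
            if math.isnan(llp):
                raise ValueError(f"NaN log-likelihood at step {step}")
            if llp >= ll or rng.uniform() < math.exp(llp - ll):
                x, ll = prop, llp
                n_acc += 1
        if step > cfg.burn_in and (step - cfg.burn_in) % cfg.thin == 0:
            rows.append((step, ll, *x))
    trace = pd.DataFrame(rows, columns=["step", "log_post", *names])
    acc = n_acc / cfg.n_steps if cfg.n_steps else 0.0
    summary = None
    if len(trace) >= 50 or len(trace) == 1:
        summary = summarize(trace, priors, acc, cfg)
        if cfg.n_steps > 0 and n_acc == 0:
            summary.converged = False
    return ChainResult(trace=trace, summary=summary, priors=priors, config=cfg)


def run_chains(loglik_fn, priors, cfg: ChainConfig) -> List[ChainResult]:
    """Run ``cfg.n_chains`` independent chains with per-chain seeds derived
    from ``cfg.seed`` (seed + chain index, kept below 2**31)."""
    results = []
    for i in range(cfg.n_chains):
        seed = None if cfg.seed is None else int((cfg.seed + i) % 2**31)
        sub = ChainConfig(n_steps=cfg.n_steps, burn_in=cfg.burn_in, thin=cfg.thin,
                          proposal_c=cfg.proposal_c, n_chains=1, seed=seed)
        results.append(run_chain(loglik_fn, priors, sub))
    return results


def best_of_chains(results: Sequence[ChainResult]) -> ChainResult:
    """The chain whose retained samples attain the maximum log-posterior;
    its summary gains the list of all chains' log-posterior modes."""
    if not results:
        raise ValueError("need at least one chain")
    scores = [float(r.trace["log_post"].max()) for r in results]
    best = results[int(np.argmax(scores))]
    if best.summary is not None:
        best.summary.config = dict(best.summary.config or {})
        best.summary.config["all_chain_log_post_modes"] = scores
    return best


# ---------------------------------------------------------------------------
# model-specific front ends
# ---------------------------------------------------------------------------

def _two_pop_loglik_fn(data, error: str):
    from .model import (TwoPopLikelihood, TwoPopDemography, SingleError,
                        TwoError, TsTvError, AsmError)
    kinds = {"single": SingleError, "two_error": TwoError,
             "ts_tv": TsTvError, "asm": AsmError}
    kind = kinds[error]
    ev = TwoPopLikelihood(data, kind)

    def fn(theta: np.ndarray) -> float:
        if error == "single":
            err = SingleError(theta[1])
            k = 2
        elif error == "two_error":
            err = TwoError(theta[1], theta[2], theta[3])
            k = 4
        elif error == "ts_tv":
            err = TsTvError(theta[1], theta[2])
            k = 3
        else:
            err = AsmError(theta[1], theta[2])
            k = 3
        dem = TwoPopDemography(tau_C=theta[k], tau_A=theta[k + 1])
        return ev.loglik(theta[0], err, dem)

    return fn


def fit_two_pop(data, error: str = "single", priors: Optional[PriorSpec] = None,
                cfg: Optional[ChainConfig] = None) -> ChainResult:
    """Fit the two-population model; returns the best chain when
    ``cfg.n_chains > 1``."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    priors = priors or PriorSpec.two_pop(error)
    cfg = cfg or ChainConfig()
    fn = _two_pop_loglik_fn(data, error)
    if cfg.n_chains == 1:
        return run_chain(fn, priors, cfg)
    return best_of_chains(run_chains(fn, priors, cfg))


def fit_three_pop(data, tau_Y: float, tau_Z: float,
                  priors: Optional[PriorSpec] = None,
                  cfg: Optional[ChainConfig] = None,
                  grid_points: Optional[int] = None) -> ChainResult:
    """Fit the three-population admixture model with fixed post-split
    anchor drifts ``tau_Y``/``tau_Z`` (estimated separately upstream)."""
    from .threepop import ThreePopLikelihood, DEFAULT_GRID
    if len(data) == 0:
        raise ValueError("empty dataset")
    priors = priors or PriorSpec.three_pop(beta_bounds=(0.0, min(0.1, tau_Y) or 0.1))
    cfg = cfg or ChainConfig()
    ev = ThreePopLikelihood(data, grid_points=grid_points or DEFAULT_GRID,
                            tau_Y=tau_Y, tau_Z=tau_Z)

    def fn(theta: np.ndarray) -> float:
        return ev.loglik(r_c=theta[0], eps=theta[1], tau_C=theta[2],
                         tau_A=theta[3], alpha=theta[4], beta=theta[5])

    if cfg.n_chains == 1:
        return run_chain(fn, priors, cfg)
    return best_of_chains(run_chains(fn, priors, cfg))


def rank_panels(data, panels: Dict[str, np.ndarray], error: str = "single",
                priors: Optional[PriorSpec] = None,
                cfg: Optional[ChainConfig] = None) -> List[Tuple[str, float]]:
    """Refit the two-population model once per candidate contaminant panel
    and order panels by descending log-posterior mode.

    This is a heuristic for suggesting the contaminant population, not
    Bayesian model selection (MCMC samples carry no marginal likelihood).
    All fits share the anchor, the chain settings and the seed, so the
    comparison differs only in the contaminant frequencies.  Every panel
    must cover exactly the data's sites.
    """
    from .model import SiteData
    if len(panels) < 2:
        raise ValueError("need at least two candidate panels")
    for name, w in panels.items():
        if len(w) != len(data):
            raise ValueError(f"panel {name!r} covers {len(w)} sites, data has {len(data)}")
    out = []
    for name, w in panels.items():
        d = SiteData(a=data.a, d=data.d, w=np.asarray(w, float), y=data.y,
                     is_transition=data.is_transition, is_cpg=data.is_cpg)
        res = fit_two_pop(d, error=error, priors=priors, cfg=cfg)
        out.append((name, float(res.trace["log_post"].max())))
    out.sort(key=lambda t: -t[1])
    return out
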