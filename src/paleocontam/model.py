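"""Probabilistic model for contamination/error/drift inference from aDNA counts.

The data at one biallelic, polarized site are the numbers of ancient-library
fragments carrying the ancestral (``a``) and derived (``d``) allele, together
with the derived-allele frequency ``w`` in a candidate contaminant panel and
the frequency ``y`` in an "anchor" population related to the ancient sample.
Fragments are modelled as a binomial mixture: with probability ``r_c`` a
fragment comes from the contaminant population (derived with probability
``w`` before error), otherwise from the ancient individual whose unknown
genotype ``i`` in {0, 1, 2} is integrated out under a neutral two-population
drift prior parameterized by the drift times ``tau_C`` (anchor side) and
``tau_A`` (ancient side), both in units of generations / (2N).

All likelihood computations are in log space; binomial coefficients use
log-gamma, so high-coverage sites (a + d >> 50) are safe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.special import gammaln

from . import _fastlik

__all__ = [
    "SiteObservation",
    "SiteData",
    "TwoPopDemography",
    "SingleError",
    "TwoError",
    "TsTvError",
    "AsmError",
    "ErrorModel",
    "genotype_probs_two_pop",
    "mixture_probs",
    "site_log_likelihood",
    "dataset_log_likelihood",
    "drift_to_years",
    "TwoPopLikelihood",
]

_LOG_TINY = 1e-300


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoPopDemography:
    """Drift times (time in generations scaled by 2N) on the two branches.

    ``tau_C`` separates the anchor population from the common ancestor,
    ``tau_A`` separates the ancient sample's population from it.
    """

    tau_C: float
    tau_A: float

    def __post_init__(self) -> None:
        import math
        for name in ("tau_C", "tau_A"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class SingleError:
    """One genome-wide per-fragment error rate."""

    eps: float

    def __post_init__(self) -> None:
        _check_prob("eps", self.eps)


@dataclass(frozen=True)
class TwoError:
    """Two genome-wide error rates; a fraction ``phi`` of the data is under
    ``eps1``, the rest under ``eps2``.  Fragment identity is not retained in
    the count representation, so the mixture is applied independently at
    every site (marginally equivalent for i.i.d. fragments)."""

    eps1: float
    eps2: float
    phi: float

    def __post_init__(self) -> None:
        _check_prob("eps1", self.eps1)
        _check_prob("eps2", self.eps2)
        _check_prob("phi", self.phi)


@dataclass(frozen=True)
class TsTvError:
    """Separate error rates for transition and transversion sites; every
    site must carry an ``is_transition`` flag."""

    eps_ts: float
    eps_tv: float

    def __post_init__(self) -> None:
        _check_prob("eps_ts", self.eps_ts)
        _check_prob("eps_tv", self.eps_tv)


@dataclass(frozen=True)
class AsmError:
    """Single error rate plus an ancestral-state-misidentification rate.

    With probability ``r_asm`` the site is mispolarized: the likelihood term
    is evaluated with ancestral/derived swapped (a <-> d) and all frequencies
    complemented (w -> 1-w, y -> 1-y, genotype prior recomputed at 1-y).
    """

    eps: float
    r_asm: float

    def __post_init__(self) -> None:
        _check_prob("eps", self.eps)
        _check_prob("r_asm", self.r_asm)


ErrorModel = Union[SingleError, TwoError, TsTvError, AsmError]


def _check_prob(name: str, v: float) -> None:
    if not 0.0 <= v <= 1.0:  # NaN fails both comparisons
        raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SiteObservation:
    """One genome site: fragment counts, panel frequencies and flags."""

    a: int
    d: int
    w: float
    y: float
    z: Optional[float] = None
    is_transition: bool = False
    is_cpg: bool = False
    region_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.a < 0 or self.d < 0:
            raise ValueError("fragment counts must be non-negative")
        _check_prob("w", self.w)
        _check_prob("y", self.y)

    @property
    def usable(self) -> bool:
        return 0.0 < self.w < 1.0 and 0.0 < self.y < 1.0


@dataclass
class SiteData:
    """Column-oriented container for a collection of usable sites.

    ``y_count``/``z_count`` (with panel haploid sizes ``n_y``/``n_z``) are
    present for three-population data, where the anchor panels enter the
    likelihood as integer sample counts.
    """

    a: np.ndarray
    d: np.ndarray
    w: np.ndarray
    y: np.ndarray
    is_transition: np.ndarray = field(default=None)  # type: ignore[assignment]
    is_cpg: np.ndarray = field(default=None)  # type: ignore[assignment]
    y_count: Optional[np.ndarray] = None
    z_count: Optional[np.ndarray] = None
    n_y: Optional[int] = None
    n_z: Optional[int] = None
    chrom: Optional[np.ndarray] = None
    pos: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int64)
        self.d = np.asarray(self.d, dtype=np.int64)
        self.w = np.asarray(self.w, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.a)
        for name in ("d", "w", "y"):
            if len(getattr(self, name)) != n:
                raise ValueError("all site columns must have equal length")
        if self.is_transition is None:
            self.is_transition = np.zeros(n, dtype=bool)
        else:
            self.is_transition = np.asarray(self.is_transition, dtype=bool)
        if self.is_cpg is None:
            self.is_cpg = np.zeros(n, dtype=bool)
        else:
            self.is_cpg = np.asarray(self.is_cpg, dtype=bool)
        if np.any(self.a < 0) or np.any(self.d < 0):
            raise ValueError("fragment counts must be non-negative")

    def __len__(self) -> int:
        return len(self.a)

    @classmethod
    def from_sites(cls, sites) -> "SiteData":
        sites = list(sites)
        return cls(
            a=[s.a for s in sites],
            d=[s.d for s in sites],
            w=[s.w for s in sites],
            y=[s.y for s in sites],
            is_transition=[s.is_transition for s in sites],
            is_cpg=[s.is_cpg for s in sites],
        )

    def subset(self, mask: np.ndarray) -> "SiteData":
        kw = {}
        for name in ("y_count", "z_count", "chrom", "pos"):
            v = getattr(self, name)
            kw[name] = v[mask] if v is not None else None
        return SiteData(
            a=self.a[mask], d=self.d[mask], w=self.w[mask], y=self.y[mask],
            is_transition=self.is_transition[mask], is_cpg=self.is_cpg[mask],
            n_y=self.n_y, n_z=self.n_z, **kw,
        )


# ---------------------------------------------------------------------------
# closed-form pieces
# ---------------------------------------------------------------------------

def genotype_probs_two_pop(y, dem: TwoPopDemography) -> np.ndarray:
    """Prior probability of ancient genotype i in {0,1,2} given the anchor
    population derived frequency ``y`` under the two-population drift model.

    The formulas are the exact diffusion solution for neutral standing
    variation at the ancestral split drifting independently down both
    branches; in the tau -> 0 limit they collapse to Hardy-Weinberg
    proportions at ``y``.  Returns an array with shape ``y.shape + (3,)``.
    Tiny negative round-off (> -1e-12) is clamped to 0 and the triple
    renormalized.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ValueError("anchor frequency y must lie strictly inside (0, 1)")
    e_c = np.exp(-dem.tau_C)
    e_ac = np.exp(-dem.tau_A - dem.tau_C)
    e_a3c = np.exp(-dem.tau_A - 3.0 * dem.tau_C)
    p0 = 1.0 - y * e_c - 0.5 * y * e_ac + y * (y - 0.5) * e_a3c
    p1 = y * e_ac + y * (1.0 - 2.0 * y) * e_a3c
    p2 = y * e_c - 0.5 * y * e_ac + y * (y - 0.5) * e_a3c
    p = np.stack([p0, p1, p2], axis=-1)
    if np.any(p < -1e-9):  # genuine negativity would be a bug, not round-off
        raise FloatingPointError("genotype probability below round-off tolerance")
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=-1, keepdims=True)
    return p


def mixture_probs(r_c: float, eps: float, w) -> np.ndarray:
    """Probability q_i that a sampled fragment shows the derived allele,
    given true ancient genotype i, contamination rate ``r_c``, per-fragment
    error ``eps`` and contaminant-panel derived frequency ``w``.

    A contaminant fragment is derived with probability w(1-eps) + (1-w)eps;
    an endogenous fragment carries a derived allele with probability i/2
    before error.  The heterozygote endogenous term simplifies to
    (1 - r_c)/2 regardless of eps.  Shape: ``w.shape + (3,)``.
    """
    _check_prob("r_c", r_c)
    _check_prob("eps", eps)
    w = np.asarray(w, dtype=float)
    if np.any(w < 0.0) or np.any(w > 1.0):
        raise ValueError("w must be in [0, 1]")
    m = w * (1.0 - eps) + (1.0 - w) * eps
    q0 = r_c * m + (1.0 - r_c) * eps
    q1 = r_c * m + (1.0 - r_c) * 0.5
    q2 = r_c * m + (1.0 - r_c) * (1.0 - eps)
    return np.stack([q0, q1, q2], axis=-1)


def drift_to_years(tau: float, ne: float, gen_years: float) -> int:
    """Convert a drift time to calendar years: tau * 2 * Ne * generation
    time, rounded to the nearest year (t / (2 Ne) ~ tau)."""
    if tau < 0 or ne < 0 or gen_years < 0:
        raise ValueError("all inputs must be >= 0")
    return int(round(tau * 2.0 * ne * gen_years))


# ---------------------------------------------------------------------------
# site / dataset likelihood
# ---------------------------------------------------------------------------

def _log_binom_pmf_terms(a: int, d: int, q: np.ndarray) -> np.ndarray:
    """log[ C(a+d, d) q^d (1-q)^a ] for each q (the coefficient included)."""
    n = a + d
    lc = gammaln(n + 1) - gammaln(d + 1) - gammaln(a + 1)
    lq = np.log(np.clip(q, _LOG_TINY, 1.0))
    l1q = np.log(np.clip(1.0 - q, _LOG_TINY, 1.0))
    return lc + d * lq + a * l1q


def _logsumexp(v: np.ndarray) -> float:
    m = np.max(v)
    if not np.isfinite(m):
        return -np.inf
    return float(m + np.log(np.sum(np.exp(v - m))))


def site_log_likelihood(obs: SiteObservation, r_c: float, err: ErrorModel,
                        gp: np.ndarray, dem: Optional[TwoPopDemography] = None
                        ) -> float:
    """Log-probability of one site's counts, marginalized over the ancient
    genotype with prior ``gp`` (which must sum to 1).

    Error-variant semantics: ``SingleError`` uses one eps everywhere;
    ``TsTvError`` picks eps_ts or eps_tv from ``obs.is_transition``;
    ``TwoError`` mixes the two single-error likelihoods with weight phi
    before the log; ``AsmError`` mixes the normal term with a fully
    polarization-flipped term (counts swapped, frequencies complemented,
    genotype prior recomputed at 1-y, which requires ``dem``).
    """
    gp = np.asarray(gp, dtype=float)
    if abs(gp.sum() - 1.0) > 1e-6:
        raise ValueError("genotype prior gp must be normalized")
    if obs.a + obs.d == 0:
        return 0.0
    lgp = np.log(np.clip(gp, _LOG_TINY, 1.0))

    def single_terms(eps: float, a: int, d: int, w: float, lg: np.ndarray) -> np.ndarray:
        q = mixture_probs(r_c, eps, w)
        return _log_binom_pmf_terms(a, d, q) + lg

    if isinstance(err, SingleError):
        return _logsumexp(single_terms(err.eps, obs.a, obs.d, obs.w, lgp))
    if isinstance(err, TsTvError):
        eps = err.eps_ts if obs.is_transition else err.eps_tv
        return _logsumexp(single_terms(eps, obs.a, obs.d, obs.w, lgp))
    if isinstance(err, TwoError):
        t1 = single_terms(err.eps1, obs.a, obs.d, obs.w, lgp) + np.log(max(err.phi, _LOG_TINY))
        t2 = single_terms(err.eps2, obs.a, obs.d, obs.w, lgp) + np.log(max(1.0 - err.phi, _LOG_TINY))
        return _logsumexp(np.concatenate([t1, t2]))
    if isinstance(err, AsmError):
        if dem is None:
            raise ValueError("AsmError needs the demography to recompute the prior at 1-y")
        lgp_flip = np.log(np.clip(genotype_probs_two_pop(1.0 - obs.y, dem), _LOG_TINY, 1.0))
        t1 = single_terms(err.eps, obs.a, obs.d, obs.w, lgp) + np.log(max(1.0 - err.r_asm, _LOG_TINY))
        t2 = single_terms(err.eps, obs.d, obs.a, 1.0 - obs.w, lgp_flip) + np.log(max(err.r_asm, _LOG_TINY))
        return _logsumexp(np.concatenate([t1, t2]))
    raise TypeError(f"unknown error model {err!r}")


class TwoPopLikelihood:
    """Vectorized genome log-likelihood under the two-population model.

    Factorizes the dataset over unique contaminant (``w``) and anchor
    (``y``) frequencies so each evaluation computes the small q- and
    genotype-probability tables once and sums per-site terms in a compiled
    kernel; this is what makes 10^5-10^6-site MCMC runs practical.
    """

    def __init__(self, data: SiteData, error_kind: type = SingleError):
        if len(data) == 0:
            warnings.warn("empty dataset: log-likelihood is identically 0")
        self.error_kind = error_kind
        self.uw, iw = np.unique(data.w, return_inverse=True)
        self.uy, iy = np.unique(data.y, return_inverse=True)
        if np.any(self.uw <= 0.0) or np.any(self.uw >= 1.0):
            raise ValueError("usable sites require 0 < w < 1")
        if np.any(self.uy <= 0.0) or np.any(self.uy >= 1.0):
            raise ValueError("usable sites require 0 < y < 1")
        self.n_sites = len(data)
        # aggregate sites sharing (a, d, w, y, transition flag); the weight
        # vector carries multiplicities, which cuts the per-step kernel cost
        # several-fold at high coverage and by orders of magnitude at low
        it = data.is_transition.astype(np.int64)
        if error_kind is not TsTvError:
            it = np.zeros_like(it)   # flag is inert: fold flagged tuples together
        if len(data):
            amax = int(max(data.a.max(), data.d.max())) + 1
            key = ((data.a.astype(np.int64) * amax + data.d) * 2 + it)
            key = (key * len(self.uw) + iw) * len(self.uy) + iy
            ukey, first, wt = np.unique(key, return_index=True, return_counts=True)
        else:
            first = np.zeros(0, dtype=np.int64)
            wt = np.zeros(0)
        self.a = data.a[first].astype(np.float64)
        self.d = data.d[first].astype(np.float64)
        self.iw = iw[first].astype(np.int64)
        self.iy = iy[first].astype(np.int64)
        self.it = it[first]
        self.wt = wt.astype(np.float64)
        n = self.a + self.d
        self.lc = gammaln(n + 1) - gammaln(self.d + 1) - gammaln(self.a + 1)

    # -- small per-evaluation tables (lean: inputs pre-validated) -------
    @staticmethod
    def _log_q_tables(r_c: float, eps: float, w: np.ndarray):
        m = r_c * (w * (1.0 - 2.0 * eps) + eps)
        one_m = 1.0 - r_c
        q = np.empty((len(w), 3))
        q[:, 0] = m + one_m * eps
        q[:, 1] = m + one_m * 0.5
        q[:, 2] = m + one_m * (1.0 - eps)
        lq = np.log(np.clip(q, _LOG_TINY, 1.0))
        l1q = np.log(np.clip(1.0 - q, _LOG_TINY, 1.0))
        return lq, l1q

    def _log_p_table(self, dem: TwoPopDemography, y: np.ndarray) -> np.ndarray:
        e_c = np.exp(-dem.tau_C)
        e_ac = np.exp(-dem.tau_A - dem.tau_C)
        e_a3c = np.exp(-dem.tau_A - 3.0 * dem.tau_C)
        p = np.empty((len(y), 3))
        half = 0.5 * y * e_ac
        tail = y * (y - 0.5) * e_a3c
        p[:, 0] = 1.0 - y * e_c - half + tail
        p[:, 1] = y * e_ac + y * (1.0 - 2.0 * y) * e_a3c
        p[:, 2] = y * e_c - half + tail
        np.clip(p, _LOG_TINY, 1.0, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return np.log(p)

    def loglik(self, r_c: float, err: ErrorModel, dem: TwoPopDemography) -> float:
        if len(self.a) == 0:
            return 0.0
        lp = self._log_p_table(dem, self.uy)
        if isinstance(err, SingleError):
            lq, l1q = self._log_q_tables(r_c, err.eps, self.uw)
            return _fastlik.ll_single(self.a, self.d, self.wt, self.iw, self.iy,
                                      lq, l1q, lp, self.lc)
        if isinstance(err, TsTvError):
            lq_tv, l1q_tv = self._log_q_tables(r_c, err.eps_tv, self.uw)
            lq_ts, l1q_ts = self._log_q_tables(r_c, err.eps_ts, self.uw)
            return _fastlik.ll_tstv(self.a, self.d, self.wt, self.iw, self.iy, self.it,
                                    lq_tv, l1q_tv, lq_ts, l1q_ts, lp, self.lc)
        if isinstance(err, TwoError):
            lq1, l1q1 = self._log_q_tables(r_c, err.eps1, self.uw)
            lq2, l1q2 = self._log_q_tables(r_c, err.eps2, self.uw)
            lphi = np.log(max(err.phi, _LOG_TINY))
            l1phi = np.log(max(1.0 - err.phi, _LOG_TINY))
            return _fastlik.ll_two_error(self.a, self.d, self.wt, self.iw, self.iy,
                                         lq1, l1q1, lq2, l1q2, lphi, l1phi,
                                         lp, self.lc)
        if isinstance(err, AsmError):
            lq, l1q = self._log_q_tables(r_c, err.eps, self.uw)
            lqf, l1qf = self._log_q_tables(r_c, err.eps, 1.0 - self.uw)
            lpf = self._log_p_table(dem, 1.0 - self.uy)
            lr = np.log(max(err.r_asm, _LOG_TINY))
            l1r = np.log(max(1.0 - err.r_asm, _LOG_TINY))
            return _fastlik.ll_asm(self.a, self.d, self.wt, self.iw, self.iy,
                                   lq, l1q, lqf, l1qf, lp, lpf, lr, l1r, self.lc)
        raise TypeError(f"unknown error model {err!r}")


def dataset_log_likelihood(data, r_c: float, err: ErrorModel,
                           dem: TwoPopDemography) -> float:
    """Sum of site log-likelihoods over a dataset (site-order invariant).

    ``data`` may be a :class:`SiteData` or an iterable of
    :class:`SiteObservation`; sites with a + d = 0 contribute 0.
    """
    if not isinstance(data, SiteData):
        data = SiteData.from_sites(data)
    if len(data) == 0:
        warnings.warn("empty dataset: log-likelihood is 0")
        return 0.0
    return TwoPopLikelihood(data, type(err)).loglik(r_c, err, dem)
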