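"""Numerical joint site-frequency spectrum for the three-population model.

Demography: an ancestral population at neutral mutation-drift equilibrium
splits into an archaic branch (drift ``tau_A``) and a modern branch (drift
``tau_C``); the modern branch splits into two anchor populations Y and Z
with fixed post-split drifts ``tau_Y`` and ``tau_Z``; at time ``beta``
before present an instantaneous admixture pulse replaces a fraction
``alpha`` of Y with the archaic population:  x_Y <- (1-alpha) x_Y + alpha x_A.

The Wright-Fisher diffusion is solved on a regular frequency grid by exact
matrix exponentiation of the birth-death (tridiagonal) discretization of
the pure-drift generator, with absorbing boundaries.  Neutral variation
enters in two exactly equivalent ways that together reproduce the
continuum model (and hence the two-population closed form in the alpha=0
limit): the root population carries the discrete mutation-drift stationary
profile (the grid analogue of the theta/x density), and every branch
receives the constant low-frequency mutation influx theta/2 per unit drift
time that maintains that profile.  Omitting the branch influx would drain
the boundary layer of the 1/x profile and bias conditional probabilities
at low sample counts.  The overall theta scaling is arbitrary (conditional
genotype probabilities are scale-free) and fixed to 1.

All propagators, time-integrated propagators and the stationary profile
come from one cached eigendecomposition of the symmetrized generator, so a
full joint SFS evaluates in milliseconds and can sit inside an MCMC loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import binom

__all__ = [
    "ThreePopDemography",
    "SfsGrid",
    "drift_kernel",
    "expected_joint_sfs",
    "genotype_probs_three_pop",
    "ThreePopLikelihood",
]

DEFAULT_GRID = 61  # grid points per frequency axis (>= 60 rule of thumb)


@dataclass(frozen=True)
class ThreePopDemography:
    """Drift times, admixture proportion ``alpha`` and pulse time ``beta``
    (all drifts in diffusion units, time / 2N).  The pulse occurs on the Y
    branch after the Y/Z split, so ``beta <= tau_Y`` is required; the donor
    is the archaic population ``beta`` before its sampling time."""

    tau_C: float
    tau_A: float
    tau_Y: float
    tau_Z: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("tau_C", "tau_A", "tau_Y", "tau_Z", "beta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta > self.tau_Y + 1e-12:
            raise ValueError("beta must not exceed tau_Y (pulse is on the Y branch)")


@dataclass
class SfsGrid:
    """Expected joint SFS over (archaic genotype i, Y derived count, Z
    derived count), shape (3, n_y + 1, n_z + 1), plus its provenance."""

    sfs: np.ndarray
    n_y: int
    n_z: int
    dem: ThreePopDemography
    grid_points: int

    def conditional(self) -> np.ndarray:
        """P[i | y_count, z_count]: normalize over i.  Zero-mass cells get NaN."""
        tot = self.sfs.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0.0, self.sfs / tot, np.nan)


def _grid(grid_points: int) -> np.ndarray:
    """Frequency grid crowded near 0 and 1 (smoothstep-transformed), so
    the low-frequency boundary layer of the 1/x profile — where mutation
    influx enters — is resolved far better than a uniform grid allows."""
    u = np.linspace(0.0, 1.0, grid_points)
    return u * u * (3.0 - 2.0 * u)


@lru_cache(maxsize=8)
def _drift_eigensystem(grid_points: int):
    """Eigendecomposition of the interior pure-drift generator.

    The generator is a birth-death chain on the (nonuniform) grid with the
    unique up/down rates matching the diffusion's first two moments at
    every interior point:

        r+_j = V_j / (h_j (h_{j-1} + h_j)),   r-_j = V_j / (h_{j-1} (h_{j-1} + h_j))

    with V(x) = x(1-x) and h the local spacings.  Quadratics are in the
    scheme's kernel, so heterozygosity decays exactly as e^{-tau}.  Every
    birth-death chain is reversible, so the generator symmetrizes with the
    geometric-mean trick: B[j, j+1] = sqrt(r+_j r-_{j+1}).

    Returns (x, r_minus, r_plus, s, lam, u) with s the symmetrizing scale
    (sqrt of the stationary weights) and (lam, u) the eigensystem of B.
    """
    x = _grid(grid_points)
    h = np.diff(x)
    v = x[1:-1] * (1.0 - x[1:-1])
    h_lo = h[:-1]
    h_hi = h[1:]
    r_plus = v / (h_hi * (h_lo + h_hi))
    r_minus = v / (h_lo * (h_lo + h_hi))
    n = grid_points - 2
    off = np.sqrt(r_plus[:-1] * r_minus[1:])
    b = np.zeros((n, n))
    idx = np.arange(n)
    b[idx, idx] = -(r_plus + r_minus)
    b[idx[:-1], idx[:-1] + 1] = off
    b[idx[:-1] + 1, idx[:-1]] = off
    # detailed balance: pi_{j+1}/pi_j = r+_j / r-_{j+1}; s = sqrt(pi)
    log_s = 0.5 * np.concatenate([[0.0], np.cumsum(np.log(r_plus[:-1] / r_minus[1:]))])
    s = np.exp(log_s - log_s.max() / 2.0)
    lam, u = np.linalg.eigh(b)
    return x, r_minus, r_plus, s, lam, u


def _interior_to_full(mat_int, flux0, flux1, grid_points, diag_boundary):
    """Assemble a full (G, G) matrix from an interior block and the two
    absorbed-mass columns; ``diag_boundary`` fills the boundary diagonal."""
    g = grid_points
    k = np.zeros((g, g))
    k[0, 0] = diag_boundary
    k[-1, -1] = diag_boundary
    k[1:-1, 1:-1] = mat_int
    k[1:-1, 0] = flux0
    k[1:-1, -1] = flux1
    return k


@lru_cache(maxsize=64)
def drift_kernel(tau: float, grid_points: int = DEFAULT_GRID) -> np.ndarray:
    """Transition matrix K[from, to] of pure Wright-Fisher drift run for
    ``tau`` drift units on the frequency grid, boundaries absorbing.

    Exact matrix exponential of the discretized generator via its
    symmetrized eigendecomposition; rows sum to 1, fixation/loss mass is
    routed to the boundary states from the time-integrated flux through
    the first and last interior states.  Cached (treat the result as
    read-only): inside MCMC the kernels of fixed drift times are reused
    across all proposals.
    """
    if tau < 0 or not np.isfinite(tau):
        raise ValueError("tau must be finite and >= 0")
    g = grid_points
    x, r_minus, r_plus, s, lam, u = _drift_eigensystem(g)
    if tau == 0.0:
        return np.eye(g)
    # Q = S^-1 B S with S = diag(s), so exp(tau Q)[j,k] = core_jk s_k / s_j
    core = (u * np.exp(tau * lam)) @ u.T
    kint = core * (s[None, :] / s[:, None])
    # absorbed mass: edge rate * int_0^tau P_{j,edge}(t) dt
    icore = (u * ((np.exp(tau * lam) - 1.0) / lam)) @ u.T
    iint = icore * (s[None, :] / s[:, None])
    k = _interior_to_full(kint, iint[:, 0] * r_minus[0], iint[:, -1] * r_plus[-1], g, 1.0)
    np.clip(k, 0.0, None, out=k)
    k /= k.sum(axis=1, keepdims=True)
    return k


def drift_kernel_integral(tau: float, grid_points: int = DEFAULT_GRID) -> np.ndarray:
    """Time-integrated propagator  int_0^tau K_u du  (exact).

    Row j gives the expected occupation, over a drift episode of length
    ``tau``, of each state for a trajectory started at state j; used to
    accumulate the contribution of mutations arising at a uniform rate
    along a branch.
    """
    if tau < 0 or not np.isfinite(tau):
        raise ValueError("tau must be finite and >= 0")
    g = grid_points
    if tau == 0.0:
        return np.zeros((g, g))
    x, r_minus, r_plus, s, lam, u = _drift_eigensystem(g)
    e = np.exp(tau * lam)
    icore = (u * ((e - 1.0) / lam)) @ u.T
    iint = icore * (s[None, :] / s[:, None])
    # int_0^tau of the absorbed mass: edge rate * ((e^{lam tau}-1)/lam^2 - tau/lam)
    dcore = (u * ((e - 1.0) / lam ** 2 - tau / lam)) @ u.T
    dint = dcore * (s[None, :] / s[:, None])
    ik = _interior_to_full(iint, dint[:, 0] * r_minus[0], dint[:, -1] * r_plus[-1], g, tau)
    np.clip(ik, 0.0, None, out=ik)
    return ik


@lru_cache(maxsize=8)
def _standing_profile(grid_points: int) -> np.ndarray:
    """Stationary mass-per-cell profile of mutation-drift balance, theta=1.

    Solves  f Q = -sigma e_1  with the influx sigma = 1/(2 x_1) that makes
    the continuum solution equal theta/x; this is the exact discrete
    analogue (boundary layer included) of the standing-variation density.
    """
    g = grid_points
    x, r_minus, r_plus, s, lam, u = _drift_eigensystem(g)
    sigma = 1.0 / (2.0 * x[1])
    # f = sigma * e_1 (-Q_int)^{-1};  (-Q)^{-1}[j,k] = core_jk s_k / s_j
    core = (u * (-1.0 / lam)) @ u.T
    row = sigma * core[0, :] * s / s[0]
    f = np.zeros(g)
    f[1:-1] = row
    return f


def _influx_vector(tau: float, grid_points: int) -> np.ndarray:
    """Frequency distribution (mass per cell) at the end of a branch of
    length ``tau`` contributed by mutations arising along that branch at
    the stationary influx rate; equals sigma * int_0^tau K_u[1, :] du.
    Only the single-copy row of the integrated propagator is needed, so
    this is O(G^2)."""
    g = grid_points
    if tau == 0.0:
        return np.zeros(g)
    x, r_minus, r_plus, s, lam, u = _drift_eigensystem(g)
    sigma = 1.0 / (2.0 * x[1])
    e = np.exp(tau * lam)
    row = np.zeros(g)
    coef = u[0] * ((e - 1.0) / lam)
    row[1:-1] = (coef @ u.T) * s / s[0]
    dcoef = u[0] * ((e - 1.0) / lam ** 2 - tau / lam)
    drow = (dcoef @ u.T) * s / s[0]
    row[0] = drow[0] * r_minus[0]
    row[-1] = drow[-1] * r_plus[-1]
    np.clip(row, 0.0, None, out=row)
    return sigma * row


@lru_cache(maxsize=32)
def _binom_projection(n: int, grid_points: int) -> np.ndarray:
    """P[count | population frequency x_j] for a sample of ``n`` haploids."""
    x = _grid(grid_points)
    counts = np.arange(n + 1)
    return binom.pmf(counts[None, :], n, x[:, None])


def expected_joint_sfs(dem: ThreePopDemography, n_y: int, n_z: int,
                       grid_points: int = DEFAULT_GRID) -> SfsGrid:
    """Expected (unnormalized, theta = 1) joint SFS for a sample of 2
    archaic chromosomes, ``n_y`` Y haploids and ``n_z`` Z haploids.

    Sums the mutation-origin contributions that can yield a Y-segregating
    site: root standing variation (shared by all branches), influx on the
    modern stem, on the Y branch before and after the pulse, and on the
    archaic branch before the pulse (whose variants reach Y only through
    admixture).  Mutations private to Z or to the post-pulse archaic
    branch cannot segregate in Y and are omitted; cells with Y count 0 or
    n_y are therefore not meaningful and are excluded downstream.
    """
    if n_y < 2 or n_z < 2:
        raise ValueError("panel sizes must be >= 2")
    if dem.beta > dem.tau_A:
        raise ValueError("beta must not exceed tau_A (donor predates archaic sampling)")
    g = grid_points
    x = _grid(g)

    k_a1 = drift_kernel(dem.tau_A - dem.beta, g)   # root -> archaic at pulse time
    k_b = drift_kernel(dem.beta, g)                # pulse time -> present
    k_c = drift_kernel(dem.tau_C, g)               # root -> Y/Z split
    k_y1 = drift_kernel(dem.tau_Y - dem.beta, g)   # split -> Y at pulse time
    k_z = drift_kernel(dem.tau_Z, g)               # split -> Z at present

    b_arch = k_b @ _binom_projection(2, g)         # (g, 3)
    b_y = k_b @ _binom_projection(n_y, g)          # (g, n_y + 1)
    b_z = k_z @ _binom_projection(n_z, g)          # (g, n_z + 1)

    f0 = _standing_profile(g)

    # joint mass over (archaic state d at pulse time, modern state m at the
    # Y/Z split): root standing variation drifts down both branches; stem
    # influx enters with the archaic fixed at 0 (state index 0)
    e2 = k_a1.T @ (f0[:, None] * k_c)
    e2[0, :] += _influx_vector(dem.tau_C, g)

    # D[d, p, z] = sum_m E2[d, m] K_Y1[m, p] B_z[m, z]  (as one matmul)
    f_t = (k_y1[:, :, None] * b_z[:, None, :]).reshape(g, -1)
    d_t = (e2 @ f_t).reshape(g, g, n_z + 1)

    # pulse: post-pulse Y frequency v = (1-alpha) x_p + alpha x_d, then
    # drift beta and binomial-project -> interpolate rows of b_y at v
    vfreq = (1.0 - dem.alpha) * x[None, :] + dem.alpha * x[:, None]  # (d, p)
    i0 = np.clip(np.searchsorted(x, vfreq) - 1, 0, g - 2)
    frac = (vfreq - x[i0]) / (x[i0 + 1] - x[i0])
    w_t = (1.0 - frac)[:, :, None] * b_y[i0] + frac[:, :, None] * b_y[i0 + 1]

    # sum over the pre-pulse Y state with a batched matmul, then over the
    # archaic state:  M[d, y, z] = W[d]^T D[d];  SFS[i] = sum_d Ba[d, i] M[d]
    m_t = np.matmul(w_t.transpose(0, 2, 1), d_t)
    sfs = np.tensordot(b_arch.T, m_t, axes=1)

    # influx on the Y branch before the pulse: archaic and Z fixed at 0,
    # the pulse dilutes the variant by (1 - alpha)
    y_pre = _influx_vector(dem.tau_Y - dem.beta, g)
    sfs[0, :, 0] += y_pre @ w_t[0]
    # influx on the Y branch after the pulse: no further pulse or drift
    # beyond what the integrated propagator already contains
    y_post = _influx_vector(dem.beta, g)
    sfs[0, :, 0] += y_post @ _binom_projection(n_y, g)
    # influx on the archaic branch before the pulse: reaches Y (as alpha*x)
    # through admixture, and the archaic sample through beta more drift
    a_pre = _influx_vector(dem.tau_A - dem.beta, g)
    sfs[:, :, 0] += (b_arch * a_pre[:, None]).T @ w_t[:, 0, :]

    np.clip(sfs, 0.0, None, out=sfs)
    if not np.all(np.isfinite(sfs)):
        raise FloatingPointError(
            "non-finite mass in the joint SFS; solver did not converge "
            f"(dem={dem}, grid_points={grid_points})")
    return SfsGrid(sfs=sfs, n_y=n_y, n_z=n_z, dem=dem, grid_points=g)


def genotype_probs_three_pop(y_count: int, z_count: int, sfs: SfsGrid) -> np.ndarray:
    """P[i | y_count, z_count] from a precomputed joint SFS grid."""
    if not (0 <= y_count <= sfs.n_y and 0 <= z_count <= sfs.n_z):
        raise ValueError("counts outside panel sizes")
    col = sfs.sfs[:, y_count, z_count]
    tot = col.sum()
    if tot <= 0.0:
        raise ValueError(f"zero-mass cell (y={y_count}, z={z_count}); site must be skipped")
    return col / tot


class ThreePopLikelihood:
    """Genome log-likelihood with two anchor panels entering as counts.

    The SFS grid is computed once per proposed demography and reused across
    all sites: the per-site loop runs only over (y_count, z_count, a, d)
    through the same compiled kernel as the two-population model, with the
    genotype-prior table indexed by occupied (y, z) cells.
    """

    def __init__(self, data, grid_points: int = DEFAULT_GRID,
                 tau_Y: float = 0.0, tau_Z: float = 0.0):
        from scipy.special import gammaln
        from . import _fastlik
        self._fastlik = _fastlik
        if data.y_count is None or data.z_count is None or data.n_y is None or data.n_z is None:
            raise ValueError("three-population data needs y_count/z_count and panel sizes")
        self.n_y = int(data.n_y)
        self.n_z = int(data.n_z)
        self.tau_Y = float(tau_Y)
        self.tau_Z = float(tau_Z)
        self.grid_points = grid_points
        self.uw, iw = np.unique(data.w, return_inverse=True)
        cells = data.y_count.astype(np.int64) * (self.n_z + 1) + data.z_count.astype(np.int64)
        self.ucells, icell = np.unique(cells, return_inverse=True)
        self.cell_y = self.ucells // (self.n_z + 1)
        self.cell_z = self.ucells % (self.n_z + 1)
        if np.any(self.cell_y <= 0) or np.any(self.cell_y >= self.n_y):
            raise ValueError("usable sites require the Y panel to be segregating")
        # aggregate identical (a, d, w, cell) tuples; weights carry counts
        amax = int(max(data.a.max(), data.d.max())) + 1
        key = (data.a.astype(np.int64) * amax + data.d) * len(self.uw) + iw
        key = key * len(self.ucells) + icell
        ukey, first, wt = np.unique(key, return_index=True, return_counts=True)
        self.a = data.a[first].astype(np.float64)
        self.d = data.d[first].astype(np.float64)
        self.iw = iw[first].astype(np.int64)
        self.icell = icell[first].astype(np.int64)
        self.wt = wt.astype(np.float64)
        n = self.a + self.d
        self.lc = gammaln(n + 1) - gammaln(self.d + 1) - gammaln(self.a + 1)
        self._skipped_cells = 0
        self._cache_key = None
        self._cache_lp = None

    def _log_p_table(self, tau_C, tau_A, alpha, beta) -> np.ndarray:
        key = (tau_C, tau_A, alpha, beta)
        if key == self._cache_key:
            return self._cache_lp
        dem = ThreePopDemography(tau_C=tau_C, tau_A=tau_A, tau_Y=self.tau_Y,
                                 tau_Z=self.tau_Z, alpha=alpha, beta=beta)
        grid = expected_joint_sfs(dem, self.n_y, self.n_z, self.grid_points)
        cols = grid.sfs[:, self.cell_y, self.cell_z].T  # (ncells, 3)
        tot = cols.sum(axis=1, keepdims=True)
        bad = (tot[:, 0] <= 0.0)
        if np.any(bad):
            self._skipped_cells = int(bad.sum())
            warnings.warn(f"{self._skipped_cells} zero-mass (y,z) cells; "
                          "their sites contribute 0 to the likelihood")
            cols[bad] = 1.0
            tot[bad] = 3.0
        lp = np.log(np.clip(cols / tot, 1e-300, 1.0))
        self._cache_key = key
        self._cache_lp = lp
        return lp

    def loglik(self, r_c, eps, tau_C, tau_A, alpha, beta) -> float:
        from .model import mixture_probs
        if beta > tau_A or beta > self.tau_Y + 1e-12:
            return -np.inf   # pulse older than a branch it must sit on
        lp = self._log_p_table(tau_C, tau_A, alpha, beta)
        q = mixture_probs(r_c, eps, self.uw)
        lq = np.log(np.clip(q, 1e-300, 1.0))
        l1q = np.log(np.clip(1.0 - q, 1e-300, 1.0))
        return self._fastlik.ll_single(self.a, self.d, self.wt, self.iw, self.icell,
                                       lq, l1q, lp, self.lc)
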