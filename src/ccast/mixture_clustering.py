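"""Candidate subpopulation discovery: nonparametric EM mixtures and HCLUST.

The primary clusterer is an EM-like estimator for a nonparametric
multivariate finite mixture: conditional on its component, a cell's marker
coordinates are independent, each with a completely unspecified univariate
density.  The fit alternates

* an M-step updating the mixing proportions ``lambda_j`` as posterior
  column means,
* a KDE-step re-estimating each per-component per-marker density as a
  posterior-weighted Gaussian kernel density estimate with a single pooled
  Silverman-type bandwidth, and
* an E-step recomputing posterior responsibilities from the product of the
  per-marker densities,

initialized from a hard k-means partition so the whole procedure is
deterministic given the seed.  Agglomerative hierarchical clustering is
provided as a drop-in alternative hard clusterer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .io_cyto import ExpressionTable

__all__ = [
    "WeightedKDE",
    "MixtureFit",
    "kmeans_init",
    "bandwidth_rule",
    "npem_estep",
    "npem_mstep",
    "npem_kde_step",
    "npem_fit",
    "hclust_labels",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)
#: multiplicative floor applied to densities inside the E-step product
DENSITY_FLOOR = 1e-300


@dataclass(frozen=True)
class WeightedKDE:
    """Weighted Gaussian kernel density ``f(u) = sum_i w_i K((u-x_i)/h) / (h sum_i w_i)``."""

    points: np.ndarray
    weights: np.ndarray
    bandwidth: float

    def __call__(self, u):
        u = np.asarray(u, dtype=float)
        z = (u[..., None] - self.points) / self.bandwidth
        kern = np.exp(-0.5 * z * z) / _SQRT_2PI
        return kern @ self.weights / (self.weights.sum() * self.bandwidth)


@dataclass
class MixtureFit:
    """Result of :func:`npem_fit`.

    ``densities[j][k]`` is the weighted KDE of marker ``k`` under component
    ``j`` (``None`` for components frozen out by the mass floor).  Hard
    labels are the per-row posterior argmax.
    """

    m: int
    mixing_proportions: np.ndarray
    posteriors: np.ndarray
    densities: list
    bandwidth: float
    n_iter: int
    converged: bool
    objective_trace: np.ndarray

    @property
    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.posteriors, axis=1)


def kmeans_init(table: ExpressionTable, m: int, seed: int) -> np.ndarray:
    """Hard 0/1 posterior matrix from a single fixed-seed k-means run."""
    n = table.n_cells
    if m > n:
        raise ValueError(f"m={m} components exceed n={n} cells")
    if m < 1:
        raise ValueError("m must be >= 1")
    if m == 1:
        return np.ones((n, 1))
    km = KMeans(n_clusters=m, n_init=1, random_state=seed)
    labels = km.fit_predict(table.values)
    post = np.zeros((n, m))
    post[np.arange(n), labels] = 1.0
    return post


def bandwidth_rule(table: ExpressionTable) -> float:
    """Silverman-type bandwidth on the pooled vector of all n*r values.

    ``h = 0.9 * min(sigma, IQR/1.34) * N**(-1/5)`` with ``N = n*r``; sigma
    is the sample standard deviation (ddof=1) and IQR the interquartile
    range of the pooled values.  One bandwidth is shared by every
    component/marker density.
    """
    pooled = table.values.ravel()
    sigma = pooled.std(ddof=1) if pooled.size > 1 else 0.0
    q25, q75 = np.percentile(pooled, [25.0, 75.0])
    spread = min(sigma, (q75 - q25) / 1.34)
    if not spread > 0:
        raise ValueError("degenerate data for bandwidth (zero pooled spread)")
    return 0.9 * spread * pooled.size ** (-0.2)


def npem_mstep(posteriors: np.ndarray) -> np.ndarray:
    """Mixing proportions as posterior column means."""
    posteriors = np.asarray(posteriors, dtype=float)
    if posteriors.size == 0:
        raise ValueError("empty posterior matrix")
    return posteriors.mean(axis=0)


def npem_kde_step(table: ExpressionTable, posteriors: np.ndarray, h: float) -> list:
    """Per-component per-marker weighted KDEs with shared bandwidth ``h``.

    Components whose total posterior mass falls below one cell (mixing
    proportion below 1/n) cannot support a density estimate and are frozen
    out: their entry is ``None`` and a warning is emitted.
    """
    if not h > 0:
        raise ValueError("bandwidth must be positive")
    posteriors = np.asarray(posteriors, dtype=float)
    n, m = posteriors.shape
    mass = posteriors.sum(axis=0)
    densities = []
    for j in range(m):
        if mass[j] < 1.0:
            warnings.warn(
                f"component {j} has mixing proportion below 1/n and is frozen out",
                RuntimeWarning,
                stacklevel=2,
            )
            densities.append(None)
            continue
        densities.append(
            [
                WeightedKDE(table.values[:, k].copy(), posteriors[:, j].copy(), h)
                for k in range(table.n_markers)
            ]
        )
    return densities


def npem_estep(
    table: ExpressionTable, mixing: np.ndarray, densities: list
) -> np.ndarray:
    """Posterior responsibilities ``p_ij ∝ lambda_j * prod_k f_jk(x_ik)``.

    Computed in log space with a floor of ``DENSITY_FLOOR`` on each density
    factor so that a cell far in the tails of every component still gets a
    well-defined (near-uniform among surviving components) posterior.
    """
    mixing = np.asarray(mixing, dtype=float)
    n, m = table.n_cells, len(mixing)
    log_floor = np.log(DENSITY_FLOOR)
    logpost = np.full((n, m), -np.inf)
    for j in range(m):
        if densities[j] is None or mixing[j] <= 0:
            continue
        acc = np.full(n, np.log(mixing[j]))
        for k in range(table.n_markers):
            f = densities[j][k](table.values[:, k])
            acc += np.maximum(np.log(np.maximum(f, DENSITY_FLOOR)), log_floor)
        logpost[:, j] = acc
    norm = logsumexp(logpost, axis=1)
    bad = ~np.isfinite(norm)
    if np.any(bad):
        raise FloatingPointError(
            f"zero mixture density at cell(s) {np.flatnonzero(bad).tolist()}"
        )
    return np.exp(logpost - norm[:, None])


def _log_density_matrix(
    kernels: list[np.ndarray], posteriors: np.ndarray, active: np.ndarray
) -> np.ndarray:
    """Sum over markers of log f_jk(x_ik) for all cells i and components j.

    ``kernels[k]`` is the precomputed n x n matrix ``K((x_ik - x_i'k)/h)/h``;
    the weighted KDE at the data points is then a single matrix product with
    the posterior columns.
    """
    n, m = posteriors.shape
    mass = posteriors.sum(axis=0)
    out = np.zeros((n, m))
    for K in kernels:
        f = K @ posteriors  # (n, m); unnormalized
        with np.errstate(divide="ignore", invalid="ignore"):
            f = f / mass
        f[:, ~active] = 0.0
        out += np.log(np.maximum(f, DENSITY_FLOOR))
    return out


def npem_fit(
    table: ExpressionTable,
    m: int,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int = 0,
) -> MixtureFit:
    """Fit the nonparametric mixture by iterating M -> KDE -> E from k-means.

    Convergence is declared when both the mixing proportions and the
    posterior matrix change by less than ``tol`` in max-absolute norm; the
    per-iteration change norm is recorded in ``objective_trace``.  On
    non-convergence a warning is emitted and the fit is returned with
    ``converged=False``.  Deterministic given ``seed``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    n = table.n_cells
    post = kmeans_init(table, m, seed)
    h = bandwidth_rule(table)

    # Kernel matrices are fixed across iterations (data and h do not move).
    x = table.values
    kernels = [
        np.exp(-0.5 * ((x[:, None, k] - x[None, :, k]) / h) ** 2) / (_SQRT_2PI * h)
        for k in range(table.n_markers)
    ]

    mixing = npem_mstep(post)
    active = np.ones(m, dtype=bool)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mixing = npem_mstep(post)
        newly_frozen = active & (mixing < 1.0 / n)
        if np.any(newly_frozen):
            warnings.warn(
                f"component(s) {np.flatnonzero(newly_frozen).tolist()} fell below "
                "mass 1/n and were frozen out",
                RuntimeWarning,
                stacklevel=2,
            )
            active &= ~newly_frozen
        logf = _log_density_matrix(kernels, post, active)
        with np.errstate(divide="ignore"):
            logpost = np.where(active & (mixing > 0), np.log(np.where(mixing > 0, mixing, 1.0)), -np.inf) + logf
        norm = logsumexp(logpost, axis=1)
        bad = ~np.isfinite(norm)
        if np.any(bad):
            raise FloatingPointError(
                f"zero mixture density at cell(s) {np.flatnonzero(bad).tolist()}"
            )
        new_post = np.exp(logpost - norm[:, None])
        delta = max(
            float(np.abs(new_post - post).max()),
            float(np.abs(npem_mstep(new_post) - mixing).max()),
        )
        trace.append(delta)
        post = new_post
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"npEM did not converge in {max_iter} iterations (last delta {trace[-1]:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    mixing = npem_mstep(post)  # final M-step so lambda matches the posteriors
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        densities = npem_kde_step(table, post, h)
    return MixtureFit(
        m=m,
        mixing_proportions=mixing,
        posteriors=post,
        densities=densities,
        bandwidth=h,
        n_iter=n_iter,
        converged=converged,
        objective_trace=np.asarray(trace),
    )


def hclust_labels(table: ExpressionTable, m: int, linkage: str = "ward") -> np.ndarray:
    """Hard labels from agglomerative clustering cut at ``m`` clusters.

    Euclidean distances with ward, average or complete linkage; labels are
    0-based and deterministic.
    """
    if linkage not in ("ward", "average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if m > table.n_cells:
        raise ValueError(f"m={m} exceeds n={table.n_cells}")
    if m < 1:
        raise ValueError("m must be >= 1")
    Z = scipy_linkage(table.values, method=linkage)
    return fcluster(Z, t=m, criterion="maxclust") - 1
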