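"""Error norms, KDE smoothing, posterior distances, and the cost model."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "DensityOnGrid",
    "CostReport",
    "l2_error",
    "kde_density",
    "hellinger",
    "kl_divergence",
    "cost_model",
]

#: Floor applied to grid densities before logarithms in the KL divergence,
#: so empty tail cells contribute a large-but-finite penalty instead of inf.
KL_FLOOR = 1e-30


def _trapezoid_weights(n: int, dx: float) -> np.ndarray:
    w = np.full(n, dx)
    w[0] = w[-1] = dx / 2
    return w


def l2_error(rho_a: np.ndarray, rho_b: np.ndarray, dx: float) -> float:
    """L²(dx) distance between two grid fields (trapezoid end-weights).

    Works on 1-D or tensor-grid 2-D fields of identical shape.
    """
    a = np.asarray(rho_a, dtype=float)
    b = np.asarray(rho_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    diff2 = (a - b) ** 2
    for axis in range(a.ndim):
        w = _trapezoid_weights(a.shape[axis], dx)
        shape = [1] * a.ndim
        shape[axis] = -1
        diff2 = diff2 * w.reshape(shape)
    return float(np.sqrt(diff2.sum()))


@dataclass
class DensityOnGrid:
    """Nonnegative density sampled on a tensor grid, normalized over its box."""

    axes: tuple[np.ndarray, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.axes = tuple(np.asarray(a, dtype=float) for a in self.axes)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(a.size for a in self.axes):
            raise ValueError("values shape must match axes")
        if np.any(self.values < 0):
            raise ValueError("density values must be nonnegative")

    @property
    def cell_measure(self) -> float:
        return float(np.prod([a[1] - a[0] for a in self.axes]))

    def integral(self) -> float:
        return float(self.values.sum() * self.cell_measure)

    def normalized(self) -> "DensityOnGrid":
        z = self.integral()
        if z <= 0:
            raise ValueError("cannot normalize an identically-zero density")
        return DensityOnGrid(self.axes, self.values / z)


def kde_density(
    samples: np.ndarray,
    axes: Sequence[np.ndarray],
    bandwidth: Optional[float | str] = None,
) -> DensityOnGrid:
    """Gaussian kernel density estimate of MCMC samples on a tensor grid.

    ``samples`` has shape (n, d); ``axes`` are the grid axes of the
    evaluation box (typically the prior box with ~100 cells per dimension).
    ``bandwidth`` follows ``scipy.stats.gaussian_kde`` (default Silverman's
    rule).  The result is renormalized to integrate to one over the box.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < 2:
        raise ValueError("need at least 2 samples for a KDE")
    if np.any(np.ptp(samples, axis=0) == 0):
        raise ValueError("degenerate samples: zero spread along some component")
    kde = gaussian_kde(samples.T, bw_method="silverman" if bandwidth is None else bandwidth)
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.vstack([m.ravel() for m in mesh])
    vals = kde(pts).reshape(mesh[0].shape)
    vals = np.clip(vals, 0.0, None)
    return DensityOnGrid(tuple(axes), vals).normalized()


def _check_same_grid(p: DensityOnGrid, q: DensityOnGrid) -> None:
    if len(p.axes) != len(q.axes) or any(
        a.shape != b.shape or not np.allclose(a, b) for a, b in zip(p.axes, q.axes)
    ):
        raise ValueError("densities live on different grids")


def hellinger(p: DensityOnGrid, q: DensityOnGrid) -> float:
    """Hellinger distance  sqrt( ½ ∫ (√p − √q)² ), in [0, 1]."""
    _check_same_grid(p, q)
    pn, qn = p.normalized(), q.normalized()
    d2 = 0.5 * np.sum((np.sqrt(pn.values) - np.sqrt(qn.values)) ** 2) * pn.cell_measure
    return float(min(np.sqrt(max(d2, 0.0)), 1.0))


def kl_divergence(p: DensityOnGrid, q: DensityOnGrid) -> float:
    """KL divergence ∫ p log(p/q) on the grid, with a floor under the log."""
    _check_same_grid(p, q)
    pn, qn = p.normalized(), q.normalized()
    pv = np.clip(pn.values, KL_FLOOR, None)
    qv = np.clip(qn.values, KL_FLOOR, None)
    mask = pn.values > 0
    return float(np.sum(pn.values[mask] * np.log(pv[mask] / qv[mask])) * pn.cell_measure)


@dataclass(frozen=True)
class CostReport:
    """Cost of k accepted samples: one-level vs delayed-acceptance sampling.

    ``cost_one = (k / r1) C_R`` and
    ``cost_two = (k / (α β)) C_D + (k / β) C_R``; as the surrogate solve
    cost C_D vanishes the ratio tends to r1/β, the advertised saving.
    """

    r1: float
    beta: float
    alpha: float
    c_de: float
    c_rte: float
    k: int
    cost_one: float
    cost_two: float

    @property
    def ratio(self) -> float:
        return self.cost_two / self.cost_one

    @property
    def limit_ratio(self) -> float:
        """The C_D → 0 limit r1/β."""
        return self.r1 / self.beta


def cost_model(
    r1: float,
    beta: float,
    c_de: float,
    c_rte: float,
    k: int = 1,
    alpha: float = 1.0,
) -> CostReport:
    """Cost comparison of one-level vs DE-assisted sampling for k samples."""
    for name, rate in (("r1", r1), ("beta", beta), ("alpha", alpha)):
        if not 0 < rate <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {rate}")
    if c_rte <= 0 or c_de < 0:
        raise ValueError("solver costs must be positive (C_D may be 0)")
    cost_one = (k / r1) * c_rte
    cost_two = (k / (alpha * beta)) * c_de + (k / beta) * c_rte
    return CostReport(
        r1=r1, beta=beta, alpha=alpha, c_de=c_de, c_rte=c_rte, k=k,
        cost_one=cost_one, cost_two=cost_two,
    )
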