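"""Discrete-ordinates solver for the scaled radiative transfer equation.

The RTE  v·∇f = (σ/ε) L f  is discretized with first-order upwinding on a
tensor grid of spatial nodes and a cell-centered set of directions on the
unit circle, with the collision operator L f = <f>_v − f coupling all
directions at a fixed node.  Two geometries are supported:

* a 1-D slab ("pseudo-2D"): space x ∈ [0, 1], full circle of directions,
  transport term cosθ ∂x only;
* the unit square with transport cosθ ∂x + sinθ ∂y.

Inflow boundary conditions are imposed on the discrete incoming set Γ−:
at a boundary node, every direction whose upwind stencil would leave the
domain carries a prescribed value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .media import Media, evaluate_sigma

__all__ = [
    "PhaseGrid",
    "BoundaryNode",
    "boundary_nodes",
    "InflowData",
    "PhaseSolution",
    "RTESystem",
    "RTEOperator",
    "apply_collision",
    "assemble_rte",
    "solve_rte",
    "density",
    "boundary_current",
    "inflow_mask",
]

#: Normalization constant C_d = 1/d of the velocity second moment
#: <v ⊗ v> = I/d; the direction set lives on the unit circle (d = 2) in
#: both geometries.
C_D = 0.5


@dataclass(frozen=True)
class PhaseGrid:
    """Space × direction grid.

    ``x`` (and ``y`` in 2-D) are node coordinates i·dx on [0, 1]; ``theta``
    are cell-centered directions (m + 1/2)·dv so that cosθ and sinθ never
    vanish, with equal weights summing to one (normalized angular measure).
    """

    x: np.ndarray
    y: Optional[np.ndarray]
    theta: np.ndarray
    weights: np.ndarray
    dx: float

    def __post_init__(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("angular weights must sum to 1 (normalized measure)")
        if np.any(np.isclose(np.cos(self.theta), 0.0)) or np.any(np.isclose(np.sin(self.theta), 0.0)):
            raise ValueError("directions with vanishing cosθ or sinθ break upwinding")

    @classmethod
    def unit_interval(cls, dx: float = 0.05, n_angles: int = 16) -> "PhaseGrid":
        """1-D slab grid on [0, 1] with a full circle of directions."""
        nx = round(1.0 / dx) + 1
        theta = (np.arange(n_angles) + 0.5) * (2.0 * np.pi / n_angles)
        return cls(
            x=np.arange(nx) * dx,
            y=None,
            theta=theta,
            weights=np.full(n_angles, 1.0 / n_angles),
            dx=dx,
        )

    @classmethod
    def unit_square(cls, dx: float = 0.05, n_angles: int = 16) -> "PhaseGrid":
        """Tensor grid on [0, 1]^2 with a full circle of directions."""
        n = round(1.0 / dx) + 1
        theta = (np.arange(n_angles) + 0.5) * (2.0 * np.pi / n_angles)
        return cls(
            x=np.arange(n) * dx,
            y=np.arange(n) * dx,
            theta=theta,
            weights=np.full(n_angles, 1.0 / n_angles),
            dx=dx,
        )

    @property
    def dim(self) -> int:
        return 1 if self.y is None else 2

    @property
    def n_x(self) -> int:
        return self.x.size

    @property
    def n_y(self) -> int:
        return 0 if self.y is None else self.y.size

    @property
    def n_angles(self) -> int:
        return self.theta.size

    @property
    def n_space(self) -> int:
        return self.n_x if self.y is None else self.n_x * self.n_y

    @property
    def n_unknowns(self) -> int:
        return self.n_space * self.n_angles

    def space_points(self) -> np.ndarray:
        """Spatial nodes as an array of shape (n_space,) or (n_space, 2)."""
        if self.y is None:
            return self.x
        X, Y = np.meshgrid(self.x, self.y, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])

    def sigma_on_grid(self, media: Media) -> np.ndarray:
        """sigma sampled at the spatial nodes, flat over n_space."""
        return evaluate_sigma(media, self.space_points())


@dataclass(frozen=True)
class BoundaryNode:
    """One boundary node with its flat spatial index and outward normal."""

    space_index: int
    normal: tuple[float, float]
    coords: tuple[float, ...]


def boundary_nodes(grid: PhaseGrid) -> list[BoundaryNode]:
    """Deterministic enumeration of boundary nodes, each listed once.

    1-D: left node then right node.  2-D: left edge (x=0, all y), right edge
    (x=1, all y), bottom (y=0, interior x), top (y=1, interior x); the four
    corners are assigned to the left/right edges, whose normal they take.
    """
    if grid.y is None:
        n = grid.n_x
        return [
            BoundaryNode(0, (-1.0, 0.0), (grid.x[0],)),
            BoundaryNode(n - 1, (1.0, 0.0), (grid.x[-1],)),
        ]
    nx, ny = grid.n_x, grid.n_y
    out: list[BoundaryNode] = []
    for j in range(ny):
        out.append(BoundaryNode(0 * ny + j, (-1.0, 0.0), (grid.x[0], grid.y[j])))
    for j in range(ny):
        out.append(BoundaryNode((nx - 1) * ny + j, (1.0, 0.0), (grid.x[-1], grid.y[j])))
    for i in range(1, nx - 1):
        out.append(BoundaryNode(i * ny + 0, (0.0, -1.0), (grid.x[i], grid.y[0])))
    for i in range(1, nx - 1):
        out.append(BoundaryNode(i * ny + (ny - 1), (0.0, 1.0), (grid.x[i], grid.y[-1])))
    return out


def inflow_mask(grid: PhaseGrid) -> np.ndarray:
    """Boolean array (n_space, n_angles): True on the discrete incoming set Γ−.

    A (node, direction) pair is incoming when the upwind stencil of any
    transport term would reach outside the domain.
    """
    ct, st = np.cos(grid.theta), np.sin(grid.theta)
    if grid.y is None:
        i = np.arange(grid.n_x)[:, None]
        return ((ct[None, :] > 0) & (i == 0)) | ((ct[None, :] < 0) & (i == grid.n_x - 1))
    nx, ny = grid.n_x, grid.n_y
    I, J = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    I = I.ravel()[:, None]
    J = J.ravel()[:, None]
    return (
        ((ct[None, :] > 0) & (I == 0))
        | ((ct[None, :] < 0) & (I == nx - 1))
        | ((st[None, :] > 0) & (J == 0))
        | ((st[None, :] < 0) & (J == ny - 1))
    )


@dataclass
class InflowData:
    """Prescribed boundary values φ(x_b, v) on the incoming set Γ−.

    Stored as a dense (n_space, n_angles) array whose entries are meaningful
    only where :func:`inflow_mask` is True.
    """

    values: np.ndarray
    grid: PhaseGrid

    def __post_init__(self) -> None:
        expected = (self.grid.n_space, self.grid.n_angles)
        if self.values.shape != expected:
            raise ValueError(f"inflow values must have shape {expected}, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("inflow values must be finite")

    @classmethod
    def constant(cls, grid: PhaseGrid, value: float) -> "InflowData":
        return cls(np.full((grid.n_space, grid.n_angles), float(value)), grid)

    @classmethod
    def isotropic(cls, grid: PhaseGrid, boundary_values: dict[int, float]) -> "InflowData":
        """Direction-independent inflow given as {flat space index: value}."""
        vals = np.zeros((grid.n_space, grid.n_angles))
        for s, v in boundary_values.items():
            vals[s, :] = v
        return cls(vals, grid)


@dataclass
class PhaseSolution:
    """RTE solution f over (space × direction) at Knudsen number epsilon."""

    f: np.ndarray  # (n_x, n_v) or (n_x, n_y, n_v)
    grid: PhaseGrid
    epsilon: float


@dataclass
class RTESystem:
    """Assembled sparse linear system A f = rhs for one medium and inflow."""

    matrix: sp.csc_matrix
    rhs: np.ndarray
    grid: PhaseGrid
    epsilon: float


def apply_collision(f_at_node: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Collision operator L f = <f>_v − f at a single spatial node.

    The weighted average of the output vanishes identically: scattering
    redistributes photons over directions without creating or destroying
    them.
    """
    f = np.asarray(f_at_node, dtype=float)
    w = np.asarray(weights, dtype=float)
    if f.shape != w.shape:
        raise ValueError(f"shape mismatch: f {f.shape} vs weights {w.shape}")
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    return np.sum(w * f) - f


def _assembly_arrays(grid: PhaseGrid, sigma_flat: np.ndarray, epsilon: float):
    """COO arrays of the transport + collision matrix with Γ− identity rows."""
    nv = grid.n_angles
    ct, st = np.cos(grid.theta), np.sin(grid.theta)
    w = grid.weights

    if grid.y is None:
        nx = grid.n_x
        I, M = np.meshgrid(np.arange(nx), np.arange(nv), indexing="ij")
        I, M = I.ravel(), M.ravel()
        row = I * nv + M
        bdry = ((ct[M] > 0) & (I == 0)) | ((ct[M] < 0) & (I == nx - 1))
        neighbors = []  # (col_index, coefficient) per transport term
        ii = ~bdry
        Ii, Mi, ri = I[ii], M[ii], row[ii]
        a = np.abs(ct[Mi]) / grid.dx
        up = np.where(ct[Mi] > 0, Ii - 1, Ii + 1)
        neighbors.append((ri, ri, a))
        neighbors.append((ri, up * nv + Mi, -a))
        node_of = Ii  # flat spatial index of interior unknowns
    else:
        nx, ny = grid.n_x, grid.n_y
        I, J, M = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nv), indexing="ij")
        I, J, M = I.ravel(), J.ravel(), M.ravel()
        row = (I * ny + J) * nv + M
        bdry = (
            ((ct[M] > 0) & (I == 0))
            | ((ct[M] < 0) & (I == nx - 1))
            | ((st[M] > 0) & (J == 0))
            | ((st[M] < 0) & (J == ny - 1))
        )
        ii = ~bdry
        Ii, Ji, Mi, ri = I[ii], J[ii], M[ii], row[ii]
        ax = np.abs(ct[Mi]) / grid.dx
        ay = np.abs(st[Mi]) / grid.dx
        up_i = np.where(ct[Mi] > 0, Ii - 1, Ii + 1)
        up_j = np.where(st[Mi] > 0, Ji - 1, Ji + 1)
        neighbors = [
            (ri, ri, ax),
            (ri, (up_i * ny + Ji) * nv + Mi, -ax),
            (ri, ri, ay),
            (ri, (Ii * ny + up_j) * nv + Mi, -ay),
        ]
        node_of = Ii * ny + Ji

    rows = [row[bdry]]
    cols = [row[bdry]]
    vals = [np.ones(int(bdry.sum()))]
    for r, c, v in neighbors:
        rows.append(r)
        cols.append(c)
        vals.append(v)
    # collision: +(sigma/eps) f − (sigma/eps) Σ_m' w_m' f_m'
    s = sigma_flat[node_of] / epsilon
    rows.append(ri)
    cols.append(ri)
    vals.append(s)
    base_col = node_of * nv
    for mp in range(nv):
        rows.append(ri)
        cols.append(base_col + mp)
        vals.append(-s * w[mp])
    return (
        np.concatenate(rows),
        np.concatenate(cols),
        np.concatenate(vals),
        bdry,
        row,
    )


def assemble_rte(grid: PhaseGrid, media: Media, epsilon: float, inflow: InflowData) -> RTESystem:
    """Assemble the sparse upwind system for  v·∇f − (σ/ε) L f = 0, f|Γ− = φ."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    sigma = grid.sigma_on_grid(media)
    rows, cols, vals, bdry, row = _assembly_arrays(grid, sigma, epsilon)
    n = grid.n_unknowns
    A = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    rhs = np.zeros(n)
    rhs[row[bdry]] = inflow.values.reshape(-1)[row[bdry]]
    return RTESystem(matrix=A, rhs=rhs, grid=grid, epsilon=epsilon)


class SolverError(RuntimeError):
    """Raised when an iterative transport solve fails to converge."""


def solve_rte(system: RTESystem, method: str = "direct", rtol: float = 1e-10) -> PhaseSolution:
    """Solve an assembled RTE system.

    ``method='direct'`` uses a sparse LU factorization; ``method='gmres'``
    uses restarted GMRES with an incomplete-LU preconditioner.  The residual
    is verified against ``rtol * ||rhs||`` in both cases.
    """
    grid = system.grid
    if method == "direct":
        f = spla.splu(system.matrix).solve(system.rhs)
    elif method == "gmres":
        ilu = spla.spilu(system.matrix.tocsc(), drop_tol=1e-5, fill_factor=20)
        prec = spla.LinearOperator(system.matrix.shape, ilu.solve)
        f, info = spla.gmres(
            system.matrix,
            system.rhs,
            M=prec,
            rtol=rtol,
            atol=0.0,
            maxiter=10 * grid.n_unknowns,
        )
        if info != 0:
            raise SolverError(f"GMRES failed to converge (info={info})")
    else:
        raise ValueError(f"unknown method {method!r}")
    resid = np.linalg.norm(system.matrix @ f - system.rhs)
    scale = max(np.linalg.norm(system.rhs), 1.0)
    if resid > 100 * rtol * scale:
        raise SolverError(f"residual {resid:.3e} exceeds tolerance")
    shape = (grid.n_x, grid.n_angles) if grid.y is None else (grid.n_x, grid.n_y, grid.n_angles)
    return PhaseSolution(f=f.reshape(shape), grid=grid, epsilon=system.epsilon)


class RTEOperator:
    """Factorized transport operator for one medium, reusable across sources.

    The matrix depends only on (grid, media, epsilon); each of the K source
    inflows then costs a pair of sparse triangular solves.
    """

    def __init__(self, grid: PhaseGrid, media: Media, epsilon: float):
        if epsilon <= 0:
            raise ValueError(f"epsilon must be positive, got {epsilon}")
        self.grid = grid
        self.epsilon = epsilon
        sigma = grid.sigma_on_grid(media)
        rows, cols, vals, bdry, row = _assembly_arrays(grid, sigma, epsilon)
        n = grid.n_unknowns
        self._bdry_rows = row[bdry]
        self._lu = spla.splu(sp.csc_matrix((vals, (rows, cols)), shape=(n, n)))

    def solve(self, inflow: InflowData) -> PhaseSolution:
        rhs = np.zeros(self.grid.n_unknowns)
        rhs[self._bdry_rows] = inflow.values.reshape(-1)[self._bdry_rows]
        f = self._lu.solve(rhs)
        grid = self.grid
        shape = (grid.n_x, grid.n_angles) if grid.y is None else (grid.n_x, grid.n_y, grid.n_angles)
        return PhaseSolution(f=f.reshape(shape), grid=grid, epsilon=self.epsilon)


def density(sol: PhaseSolution) -> np.ndarray:
    """Velocity-averaged intensity (fluence) ρ(x) = Σ_m w_m f(x, θ_m)."""
    return sol.f @ sol.grid.weights


def boundary_current(sol: PhaseSolution, outgoing_only: bool = False) -> np.ndarray:
    """Boundary measurement h(x_b) = (1/(C_d ε)) Σ_m w_m (v_m · n) f(x_b, θ_m).

    The sum runs over the full direction set (the net current): incoming
    directions carry the prescribed inflow, which the solve stores in f on
    the Γ− rows.  ``outgoing_only=True`` restricts the quadrature to
    v·n > 0; that literal half-range variant retains an O(1/ε) density term
    and does not converge to the diffusion boundary flux.

    Returns one value per node of :func:`boundary_nodes`, in that order.
    """
    grid = sol.grid
    ct, st = np.cos(grid.theta), np.sin(grid.theta)
    f_flat = sol.f.reshape(grid.n_space, grid.n_angles)
    out = np.empty(len(boundary_nodes(grid)))
    for k, bn in enumerate(boundary_nodes(grid)):
        vdotn = ct * bn.normal[0] + st * bn.normal[1]
        fb = f_flat[bn.space_index]
        if outgoing_only:
            sel = vdotn > 0
            out[k] = np.sum(grid.weights[sel] * vdotn[sel] * fb[sel])
        else:
            out[k] = np.sum(grid.weights * vdotn * fb)
    return out / (C_D * sol.epsilon)
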