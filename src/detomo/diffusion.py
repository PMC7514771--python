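"""Limiting diffusion equation  ∇·(1/σ)∇ρ = 0  and its boundary flux.

In the strong-scattering limit the fluence ρ satisfies an elliptic equation
with diffusion coefficient 1/σ and Dirichlet data ξ on the boundary.  The
discretization is the conservation-form finite-difference scheme on the
same tensor grid as the transport solver (equivalent to lowest-order FEM
with mass lumping on this grid), with harmonic averaging of 1/σ across cell
faces so that the flux is continuous through jumps in σ.

The Dirichlet-to-Neumann datum h(x_b) = (1/σ) ∂ρ/∂n is extracted with a
second-order one-sided difference along the inward grid line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .media import Media
from .transport import PhaseGrid, boundary_nodes

__all__ = ["DirichletData", "DESolution", "DEOperator", "solve_de", "dtn_flux"]


@dataclass
class DirichletData:
    """Boundary fluence ξ, one value per node of :func:`boundary_nodes`."""

    values: np.ndarray
    grid: PhaseGrid

    def __post_init__(self) -> None:
        nb = len(boundary_nodes(self.grid))
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (nb,):
            raise ValueError(f"expected {nb} boundary values, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Dirichlet data must be finite")

    @classmethod
    def from_pair(cls, grid: PhaseGrid, left: float, right: float) -> "DirichletData":
        """1-D helper: ξ(0) = left, ξ(1) = right."""
        return cls(np.array([left, right]), grid)

    @classmethod
    def delta(cls, grid: PhaseGrid, boundary_index: int, amplitude: float = 1.0) -> "DirichletData":
        """Kronecker delta at one boundary node (by index in boundary order)."""
        vals = np.zeros(len(boundary_nodes(grid)))
        vals[boundary_index] = amplitude
        return cls(vals, grid)


@dataclass
class DESolution:
    """Fluence ρ per spatial node, shaped (n_x,) or (n_x, n_y)."""

    rho: np.ndarray
    grid: PhaseGrid
    sigma: np.ndarray  # flat over n_space, as sampled for the solve


def _harmonic_face(sa: np.ndarray, sb: np.ndarray) -> np.ndarray:
    """Harmonic mean of 1/σ at two adjacent nodes: 2 / (σ_a + σ_b)."""
    return 2.0 / (sa + sb)


class DEOperator:
    """Factorized diffusion operator for one medium, reusable across sources.

    Dirichlet rows are enforced exactly (identity rows), so a new boundary
    datum only changes the right-hand side.
    """

    def __init__(self, grid: PhaseGrid, media: Media):
        self.grid = grid
        self.sigma = grid.sigma_on_grid(media)
        self._bnodes = boundary_nodes(grid)
        self._bindex = {bn.space_index: k for k, bn in enumerate(self._bnodes)}
        A = self._assemble()
        self._lu = spla.splu(A)

    def _assemble(self) -> sp.csc_matrix:
        grid = self.grid
        s = self.sigma
        dx2 = grid.dx**2
        rows, cols, vals = [], [], []
        if grid.y is None:
            nx = grid.n_x
            for i in range(nx):
                if i in self._bindex:
                    rows.append(i), cols.append(i), vals.append(1.0)
                    continue
                al = _harmonic_face(s[i - 1], s[i]) / dx2
                ar = _harmonic_face(s[i], s[i + 1]) / dx2
                rows += [i, i, i]
                cols += [i - 1, i, i + 1]
                vals += [-al, al + ar, -ar]
        else:
            nx, ny = grid.n_x, grid.n_y
            for i in range(nx):
                for j in range(ny):
                    p = i * ny + j
                    if p in self._bindex:
                        rows.append(p), cols.append(p), vals.append(1.0)
                        continue
                    diag = 0.0
                    for q in (p - ny, p + ny, p - 1, p + 1):
                        a = _harmonic_face(s[p], s[q]) / dx2
                        rows.append(p), cols.append(q), vals.append(-a)
                        diag += a
                    rows.append(p), cols.append(p), vals.append(diag)
        n = grid.n_space
        return sp.csc_matrix((vals, (rows, cols)), shape=(n, n))

    def solve(self, xi: DirichletData) -> DESolution:
        rhs = np.zeros(self.grid.n_space)
        for k, bn in enumerate(self._bnodes):
            rhs[bn.space_index] = xi.values[k]
        rho = self._lu.solve(rhs)
        shape = (self.grid.n_x,) if self.grid.y is None else (self.grid.n_x, self.grid.n_y)
        return DESolution(rho=rho.reshape(shape), grid=self.grid, sigma=self.sigma)


def solve_de(grid: PhaseGrid, media: Media, xi: DirichletData) -> DESolution:
    """Solve the diffusion equation with Dirichlet data ξ on the grid."""
    return DEOperator(grid, media).solve(xi)


def dtn_flux(sol: DESolution, convention: str = "flux") -> np.ndarray:
    """DtN datum per boundary node, in boundary order.

    With the default ``convention='flux'`` this is the outward photon flux
    −(1/σ) ∂ρ/∂n (Fick's law): positive where light leaves the tissue,
    matching the orientation of the transport boundary current so the two
    forward maps converge in the diffusion limit.
    ``convention='gradient'`` returns the bare normal derivative datum
    +(1/σ) ∂ρ/∂n of opposite sign.

    The flux is extracted from the conservation form of the scheme: the
    harmonic-mean face coefficient times the first difference across the
    boundary face.  This is the discrete flux the interior balance actually
    conserves; for piecewise-constant media it is nodally exact (a
    one-sided polynomial stencil is not, because it reaches across σ jumps
    that may sit within two cells of the boundary).  Corner nodes use the
    normal of the edge they are assigned to by :func:`boundary_nodes`.
    """
    if convention not in ("flux", "gradient"):
        raise ValueError(f"convention must be 'flux' or 'gradient', got {convention!r}")
    grid = sol.grid
    dx = grid.dx
    rho_flat = sol.rho.reshape(-1)
    out = np.empty(len(boundary_nodes(grid)))
    if grid.y is None:
        stride_of_normal = {(-1.0, 0.0): 1, (1.0, 0.0): -1}
    else:
        ny = grid.n_y
        stride_of_normal = {
            (-1.0, 0.0): ny,
            (1.0, 0.0): -ny,
            (0.0, -1.0): 1,
            (0.0, 1.0): -1,
        }
    for k, bn in enumerate(boundary_nodes(grid)):
        step = stride_of_normal[bn.normal]  # inward stride in the flat index
        p = bn.space_index
        a_face = _harmonic_face(sol.sigma[p], sol.sigma[p + step])
        # sigma-weighted inward derivative at the boundary face, flipped to
        # the outward normal; a_face plays the role of 1/sigma
        out[k] = -a_face * (rho_flat[p + step] - rho_flat[p]) / dx
    if convention == "flux":
        out = -out
    return out
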