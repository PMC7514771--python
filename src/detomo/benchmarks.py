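"""Canonical benchmark problems: forward-convergence studies and the two
reconstruction examples (single disk; five disks).

These functions pin down the study conditions — grids, sources, priors,
noise level, proposal widths, initialization — so the command line, the
test-suite, and reproduction scripts all run exactly the same problems.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .analysis import l2_error
from .diffusion import DirichletData, solve_de
from .experiments import ExperimentDesign, SyntheticDataset, generate_data
from .inference import (
    ChainRecord,
    GaussianRandomWalk,
    PosteriorEvaluator,
    UniformBoxPrior,
    acceptance_summary,
    mh_sample,
    two_level_sample,
)
from .media import (
    DiskMedia2D,
    example2_truth_vector,
    make_example_media,
    three_bump_medium,
)
from .transport import InflowData, PhaseGrid, assemble_rte, density, solve_rte

__all__ = [
    "EPSILON_LADDER_1D",
    "EPSILON_LADDER_POSTERIOR",
    "example_prior",
    "example_truth",
    "example_proposal",
    "example_initial_state",
    "build_inverse_problem",
    "run_inversion",
    "forward_convergence_1d",
    "forward_convergence_2d",
]

#: Knudsen ladder of the 1-D forward-convergence study.
EPSILON_LADDER_1D = (1.0, 1 / 2, 1 / 4, 1 / 16, 1 / 32, 1 / 64)

#: Knudsen ladder used for posterior comparisons and acceptance-rate trends.
EPSILON_LADDER_POSTERIOR = (1.0, 2**-3, 2**-6)


def example_prior(example_id: int) -> UniformBoxPrior:
    """Uniform prior boxes of the two reconstruction examples.

    Example 1 (parameters (r, h)): r ∈ [0, 0.5], h ∈ [8, 12].  Example 2
    (parameters (h1..h5, r1..r5)): heights in [0, 15], radii in [0, 0.25]
    — wide enough to contain every true inclusion while keeping all disks
    inside the unit square for the fixed centers.
    """
    if example_id == 1:
        return UniformBoxPrior(lower=np.array([0.0, 8.0]), upper=np.array([0.5, 12.0]))
    if example_id == 2:
        return UniformBoxPrior(
            lower=np.zeros(10),
            upper=np.array([15.0] * 5 + [0.25] * 5),
        )
    raise ValueError(f"example_id must be 1 or 2, got {example_id}")


def example_truth(example_id: int) -> np.ndarray:
    """True parameter vectors: (0.4, 10) and the five-disk (h, r) truth."""
    if example_id == 1:
        return np.array([0.4, 10.0])
    if example_id == 2:
        return example2_truth_vector()
    raise ValueError(f"example_id must be 1 or 2, got {example_id}")


def example_proposal(example_id: int, radius_width: float = 0.02, height_width: float = 0.2) -> GaussianRandomWalk:
    """Componentwise random-walk widths: 0.02 for radii, 0.2 for heights
    (roughly 4–5% of the prior ranges)."""
    if example_id == 1:
        return GaussianRandomWalk(np.array([radius_width, height_width]))
    if example_id == 2:
        return GaussianRandomWalk(np.array([height_width] * 5 + [radius_width] * 5))
    raise ValueError(f"example_id must be 1 or 2, got {example_id}")


def example_initial_state(example_id: int, seed: int) -> np.ndarray:
    """Chain initialization.

    Example 1 starts from the prior midpoint.  Example 2 perturbs the truth
    componentwise by the multiplicative rule (0.6 + 0.4·u)·truth with
    u ~ U(0, 1) from the given seed, i.e. an initial guess up to 40% low.
    """
    if example_id == 1:
        return example_prior(1).midpoint()
    if example_id == 2:
        rng = np.random.default_rng(seed)
        truth = example_truth(2)
        return (0.6 + 0.4 * rng.uniform(size=truth.size)) * truth
    raise ValueError(f"example_id must be 1 or 2, got {example_id}")


@dataclass
class InverseProblem:
    """A fully specified Bayesian reconstruction problem."""

    example_id: int
    design: ExperimentDesign
    dataset: SyntheticDataset
    prior: UniformBoxPrior
    surrogate: PosteriorEvaluator  # DE posterior
    target: PosteriorEvaluator  # RTE posterior


def build_inverse_problem(
    example_id: int,
    epsilon: float,
    data_seed: int,
    dx: float = 0.05,
    n_angles: int = 16,
    noise_variance: float = 1e-4,
    data_model: str = "RTE",
) -> InverseProblem:
    """Assemble design, seeded data, and both posterior evaluators.

    The synthetic measurement is produced by the transport forward map at
    the stated Knudsen number (plus N(0, γ²) noise); both posteriors then
    consume that same vector, mirroring a single physical experiment.
    """
    grid = PhaseGrid.unit_square(dx=dx, n_angles=n_angles)
    design = ExperimentDesign.standard(grid, epsilon, noise_variance=noise_variance)
    truth_media = make_example_media(example_id, example_truth(example_id))
    dataset = generate_data(truth_media, design, data_model, data_seed)
    prior = example_prior(example_id)

    def parameterization(theta: np.ndarray) -> DiskMedia2D:
        return make_example_media(example_id, theta)

    common = dict(
        prior=prior,
        data=dataset.measurement.values,
        design=design,
        parameterization=parameterization,
    )
    return InverseProblem(
        example_id=example_id,
        design=design,
        dataset=dataset,
        prior=prior,
        surrogate=PosteriorEvaluator(model="DE", **common),
        target=PosteriorEvaluator(model="RTE", **common),
    )


def run_inversion(
    example_id: int,
    epsilon: float,
    n_steps: int,
    seed: int,
    method: str = "two-level",
    dx: float = 0.05,
    n_angles: int = 16,
    noise_variance: float = 1e-4,
) -> tuple[ChainRecord, dict]:
    """Run a full reconstruction and return (chain, summary).

    ``method`` is ``'two-level'`` (DE-screened transport posterior),
    ``'one-level-rte'``, or ``'one-level-de'``.  Randomness derives from
    the single run seed: the data seed is ``seed`` and the chain (and
    Example-2 initialization) seed is ``seed + 1``.
    """
    problem = build_inverse_problem(
        example_id, epsilon, data_seed=seed, dx=dx, n_angles=n_angles,
        noise_variance=noise_variance,
    )
    chain_seed = seed + 1
    x0 = example_initial_state(example_id, chain_seed)
    proposal = example_proposal(example_id)
    if method == "two-level":
        chain = two_level_sample(
            problem.surrogate, problem.target, proposal, n_steps, chain_seed, x0
        )
    elif method == "one-level-rte":
        chain = mh_sample(problem.target, proposal, n_steps, chain_seed, x0)
    elif method == "one-level-de":
        chain = mh_sample(problem.surrogate, proposal, n_steps, chain_seed, x0)
    else:
        raise ValueError(f"unknown method {method!r}")
    summary = acceptance_summary(chain)
    summary.update(
        example_id=example_id,
        epsilon=epsilon,
        method=method,
        n_sources=problem.design.n_sources,
        n_detectors=problem.design.n_detectors,
        noise_variance=noise_variance,
        run_seed=seed,
    )
    return chain, summary


def forward_convergence_1d(
    epsilons=EPSILON_LADDER_1D,
    dx: float = 0.05,
    n_angles: int = 16,
    inflow_left: float = 1.0,
    inflow_right: float = 0.0,
):
    """1-D slab study: transport density vs diffusion solution per ε.

    The three-bump medium is lit with unit isotropic inflow on the left and
    vacuum on the right; the diffusion reference uses the matching
    Dirichlet data.  Returns (errors, rho_by_eps, rho_de, grid): the L²(dx)
    error ladder, the transport densities, and the diffusion reference.
    """
    grid = PhaseGrid.unit_interval(dx=dx, n_angles=n_angles)
    media = three_bump_medium()
    xi = DirichletData.from_pair(grid, inflow_left, inflow_right)
    rho_de = solve_de(grid, media, xi).rho
    inflow = InflowData.isotropic(
        grid, {0: inflow_left, grid.n_x - 1: inflow_right}
    )
    errors = {}
    rho_by_eps = {}
    for eps in epsilons:
        sol = solve_rte(assemble_rte(grid, media, eps, inflow))
        rho = density(sol)
        rho_by_eps[eps] = rho
        errors[eps] = l2_error(rho, rho_de, dx)
    return errors, rho_by_eps, rho_de, grid


def forward_convergence_2d(
    epsilons=EPSILON_LADDER_POSTERIOR,
    dx: float = 0.05,
    n_angles: int = 16,
    media: Optional[DiskMedia2D] = None,
    source_value: float = 1.0,
):
    """Unit-square study with the single-disk medium lit from the left edge.

    Isotropic unit inflow on the whole left edge (Dirichlet data 1 there
    for the diffusion reference), vacuum elsewhere.  Returns the L²(dx)
    error ladder and the fields, as in :func:`forward_convergence_1d`.
    """
    grid = PhaseGrid.unit_square(dx=dx, n_angles=n_angles)
    if media is None:
        media = make_example_media(1, example_truth(1))
    from .transport import boundary_nodes

    bnodes = boundary_nodes(grid)
    left = {bn.space_index: source_value for bn in bnodes if bn.normal == (-1.0, 0.0)}
    xi_values = np.array(
        [source_value if bn.normal == (-1.0, 0.0) else 0.0 for bn in bnodes]
    )
    rho_de = solve_de(grid, media, DirichletData(xi_values, grid)).rho
    inflow = InflowData.isotropic(grid, left)
    errors = {}
    rho_by_eps = {}
    for eps in epsilons:
        sol = solve_rte(assemble_rte(grid, media, eps, inflow))
        rho = density(sol)
        rho_by_eps[eps] = rho
        errors[eps] = l2_error(rho, rho_de, dx)
    return errors, rho_by_eps, rho_de, grid
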