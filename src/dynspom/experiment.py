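"""Factorial simulation experiment: species x habitat cover x dynamism.

Runs the full (or any reduced) grid of virtual species, habitat-cover
scenarios and patch-turnover levels, with many replicate iterations per
cell, and summarizes equilibrium metapopulation occupancy — the fraction
of occupied patches at the final time step — with 95% confidence
intervals across iterations.

Seeding contract: each (cell, iteration) derives its own
``numpy.random.SeedSequence([base_seed, cell_index, iteration])``, from
which independent landscape and trajectory seeds are spawned. Results are
therefore identical for any worker count and any execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import generate_landscape
from .species import SpeciesParams, build_virtual_species_set
from .spom import simulate_trajectory

__all__ = [
    "ScenarioGrid",
    "ScenarioCell",
    "ScenarioResult",
    "enumerate_scenarios",
    "run_cell",
    "run_experiment",
    "summarize_occupancy",
    "results_to_frame",
]

PAPER_COVERS = (0.05, 0.10, 0.20)
PAPER_DYNAMISMS = (0.0, 0.05, 0.10, 0.20)


@dataclass(frozen=True)
class ScenarioGrid:
    """Definition of a factorial experiment."""

    species: tuple[SpeciesParams, ...] = field(
        default_factory=lambda: tuple(build_virtual_species_set())
    )
    covers: tuple[float, ...] = PAPER_COVERS
    dynamisms: tuple[float, ...] = PAPER_DYNAMISMS
    iterations: int = 500
    steps: int = 100
    init_occupancy: float = 0.5
    base_seed: int = 0
    # landscape generation parameters
    side: float = 3163.0
    mean_area: float = 0.5
    sd_area: float = 0.2
    min_dist: float = 10.0
    initial_age_mode: str = "uniform0_100"
    #: regenerate the landscape for every iteration (CIs then reflect both
    #: landscape and demographic stochasticity); if False, one landscape
    #: per cell is reused across iterations
    fresh_landscape_per_iteration: bool = True
    colonization_rule: str = "product"
    extinction_rule: str = "product"
    ci_method: str = "normal"  #: 'normal' | 'bootstrap'

    @property
    def n_cells(self) -> int:
        return len(self.species) * len(self.covers) * len(self.dynamisms)


@dataclass(frozen=True)
class ScenarioCell:
    index: int
    species: SpeciesParams
    cover: float
    dynamism: float


@dataclass(frozen=True)
class ScenarioResult:
    """Summarized equilibrium occupancy for one grid cell."""

    species_id: int
    preference: str
    cover: float
    dynamism: float
    n_iterations: int
    mean_occupancy: float
    ci_low: float
    ci_high: float
    extinct_fraction: float


def enumerate_scenarios(grid: ScenarioGrid) -> list[ScenarioCell]:
    """Deterministic cell list ordered by (species_id, cover, dynamism)."""
    cells = []
    idx = 0
    for sp in sorted(grid.species, key=lambda s: s.species_id):
        for cover in grid.covers:
            for dyn in grid.dynamisms:
                cells.append(ScenarioCell(idx, sp, cover, dyn))
                idx += 1
    return cells


def _iteration_seeds(base_seed: int, cell_index: int, iteration: int) -> tuple[int, int]:
    """Stable (landscape, trajectory) seed pair for one iteration."""
    ss = np.random.SeedSequence([base_seed, cell_index, iteration])
    land, traj = ss.generate_state(2)
    return int(land % 2**31), int(traj % 2**31)


def summarize_occupancy(
    finals,
    ci_method: str = "normal",
    n_boot: int = 2000,
    boot_seed: int = 0,
) -> tuple[float, float, float, float]:
    """Mean, 95% CI and extinct fraction of final-step occupancies.

    ``normal`` uses mean +/- 1.96 * SE across iterations, clamped to
    [0, 1]; ``bootstrap`` a percentile bootstrap. With a single iteration
    the CI is undefined (NaN) and a warning is issued. Extinct runs
    (occupancy 0) count in the mean and are also reported separately.
    """
    finals = np.asarray(finals, dtype=float)
    if finals.size == 0:
        raise ValueError("no iterations to summarize")
    mean = float(finals.mean())
    extinct = float((finals == 0).mean())
    if finals.size < 2:
        warnings.warn("single iteration: confidence interval undefined")
        return mean, float("nan"), float("nan"), extinct
    if ci_method == "normal":
        se = float(finals.std(ddof=1) / np.sqrt(finals.size))
        lo, hi = mean - 1.96 * se, mean + 1.96 * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(boot_seed)
        idx = rng.integers(0, finals.size, size=(n_boot, finals.size))
        boot_means = finals[idx].mean(axis=1)
        lo, hi = (float(q) for q in np.quantile(boot_means, [0.025, 0.975]))
    else:
        raise ValueError(f"unknown ci_method: {ci_method!r}")
    return mean, max(0.0, float(lo)), min(1.0, float(hi)), extinct


def run_cell(grid: ScenarioGrid, cell: ScenarioCell) -> ScenarioResult:
    """Run all iterations of one cell and summarize them."""
    finals = np.empty(grid.iterations)
    shared_landscape = None
    for it in range(grid.iterations):
        land_seed, traj_seed = _iteration_seeds(grid.base_seed, cell.index, it)
        if grid.fresh_landscape_per_iteration or shared_landscape is None:
            landscape = generate_landscape(
                side=grid.side, cover=cell.cover, mean_area=grid.mean_area,
                sd_area=grid.sd_area, min_dist=grid.min_dist, seed=land_seed,
                initial_age_mode=grid.initial_age_mode,
            )
            if not grid.fresh_landscape_per_iteration:
                shared_landscape = landscape
        else:
            landscape = shared_landscape
        frac = simulate_trajectory(
            landscape, cell.species, cell.dynamism, steps=grid.steps,
            init_occupancy=grid.init_occupancy, seed=traj_seed,
            colonization_rule=grid.colonization_rule,
            extinction_rule=grid.extinction_rule,
        )
        finals[it] = frac[-1]
    mean, lo, hi, extinct = summarize_occupancy(finals, ci_method=grid.ci_method)
    return ScenarioResult(
        species_id=cell.species.species_id, preference=cell.species.preference,
        cover=cell.cover, dynamism=cell.dynamism, n_iterations=grid.iterations,
        mean_occupancy=mean, ci_low=lo, ci_high=hi, extinct_fraction=extinct,
    )


def run_experiment(
    grid: ScenarioGrid,
    parallel_workers: int = 1,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every cell of the grid; returns one tidy row per cell.

    Embarrassingly parallel across cells (seeding is per cell/iteration,
    so the result table is independent of the worker count). Per-cell
    failures are recorded as warnings and the run continues.
    """
    cells = enumerate_scenarios(grid)

    def _safe(cell):
        try:
            return run_cell(grid, cell), None
        except Exception as exc:  # noqa: BLE001 — failures are summarized
            return None, (cell, exc)

    if parallel_workers > 1:
        from joblib import Parallel, delayed

        outcomes = Parallel(n_jobs=parallel_workers)(
            delayed(_safe)(cell) for cell in cells
        )
    else:
        outcomes = []
        iterator = cells
        if progress:
            try:
                from tqdm import tqdm

                iterator = tqdm(cells, desc="scenario cells")
            except ImportError:
                pass
        for cell in iterator:
            outcomes.append(_safe(cell))

    results = [r for r, err in outcomes if r is not None]
    failures = [err for _, err in outcomes if err is not None]
    if failures:
        detail = "; ".join(
            f"cell {c.index} (sp {c.species.species_id}, cover {c.cover}, "
            f"dyn {c.dynamism}): {e}" for c, e in failures
        )
        warnings.warn(f"{len(failures)} scenario cell(s) failed: {detail}")
    return results_to_frame(results)


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": r.species_id, "preference": r.preference,
                "cover": r.cover, "dynamism": r.dynamism,
                "n_iterations": r.n_iterations,
                "mean_occupancy": r.mean_occupancy,
                "ci_low": r.ci_low, "ci_high": r.ci_high,
                "extinct_fraction": r.extinct_fraction,
            }
            for r in results
        ]
    )
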