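"""Stochastic patch occupancy dynamics (Incidence Function Model core).

The occupancy of each patch is a two-state, first-order Markov chain. Per
time step, for every living patch i:

* connectivity  S_i = A_i^c * sum_{j != i} p_j * exp(-alpha * d_ij) * A_j^b
* spatial colonization  C_is = S_i^2 / (S_i^2 + y^2)   (Allee exponent 2)
* spatial extinction    E_is = min(1, e / A_i^x), exactly 1 when
  A_i <= e^(1/x) (the critical-area rule)
* temporal (successional) modifiers C_it, E_it from the patch's age
* combined rates, by default the products
      C_i = C_is * C_it        E_i = E_is * E_it
  i.e. colonization requires both spatial reachability and successional
  suitability, and the successional modifier scales the area-driven
  extinction risk. A probabilistic-OR combination (either process alone
  suffices) is available for both rules; it is not the extinction default
  because the early-successional modifier never drops below 0.5, so
  OR-extinction would forbid early-successional persistence at any age.

Updates are synchronous (all patches in parallel), with no rescue effect:
E_i never depends on connectivity. One uniform deviate is drawn per living
patch, in ascending patch-id order.

A trajectory interleaves landscape dynamics with occupancy dynamics in a
fixed per-step order: patch turnover (occupants of destroyed patches die,
new patches arrive empty at age 0) -> rates on the post-turnover landscape
-> synchronous Bernoulli update -> aging. A newly created patch is thus
colonizable in the very step it appears.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import Landscape, advance_age, apply_turnover, distance_matrix
from .species import SpeciesParams, colonization_modifier, extinction_modifier

__all__ = [
    "OccupancyState",
    "StepRates",
    "connectivity",
    "colonization_spatial",
    "extinction_spatial",
    "combine_rates",
    "step_rates",
    "bernoulli_update",
    "step_occupancy",
    "simulate_trajectory",
]


@dataclass
class OccupancyState:
    """Presence/absence per living patch at one time step.

    ``patch_ids`` must exactly match the living patches (ascending id
    order) of the paired landscape.
    """

    patch_ids: np.ndarray
    occupied: np.ndarray
    time: int = 0

    def __post_init__(self) -> None:
        self.patch_ids = np.asarray(self.patch_ids, dtype=np.int64)
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if self.patch_ids.shape != self.occupied.shape:
            raise ValueError("patch_ids and occupied must have equal length")

    @property
    def fraction_occupied(self) -> float:
        return float(self.occupied.mean()) if self.occupied.size else 0.0


@dataclass
class StepRates:
    """Per-patch rates for one synchronous update."""

    S: np.ndarray  #: connectivity (dimensionless, >= 0)
    C_is: np.ndarray
    E_is: np.ndarray
    C_it: np.ndarray
    E_it: np.ndarray
    C: np.ndarray  #: combined colonization probability
    E: np.ndarray  #: combined extinction probability


def _check_alignment(landscape: Landscape, state: OccupancyState) -> None:
    if not np.array_equal(state.patch_ids, landscape.ids):
        raise ValueError(
            "occupancy state is not aligned with the landscape's living patches"
        )


def connectivity(
    landscape: Landscape,
    state: OccupancyState,
    species: SpeciesParams,
    dist: np.ndarray | None = None,
) -> np.ndarray:
    """Connectivity S_i summed over occupied patches j != i.

    Distances in metres, areas in hectares. ``dist`` may be passed to
    reuse a precomputed centroid distance matrix.
    """
    _check_alignment(landscape, state)
    n = landscape.n_patches
    if n == 0:
        return np.zeros(0)
    if dist is None:
        dist = distance_matrix(landscape)
    kernel = np.exp(-species.alpha * dist)
    np.fill_diagonal(kernel, 0.0)  # j != i
    source = state.occupied * landscape.area**species.b
    return landscape.area**species.c * (kernel @ source)


def colonization_spatial(S, y: float):
    """Allee-type colonization probability C_is = S^2 / (S^2 + y^2)."""
    S = np.asarray(S, dtype=float)
    out = S**2 / (S**2 + y**2)
    return float(out) if out.ndim == 0 else out


def extinction_spatial(area, e: float, x: float):
    """Area-dependent extinction E_is = e / A^x, capped at 1.

    Equals exactly 1 whenever A <= e**(1/x) (patch below critical area).
    """
    area = np.asarray(area, dtype=float)
    out = np.minimum(1.0, e / area**x)
    out = np.where(area <= e ** (1.0 / x), 1.0, out)
    return float(out) if out.ndim == 0 else out


def _check_prob(name: str, p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return p


def combine_rates(
    C_is,
    C_it,
    E_is,
    E_it,
    colonization_rule: str = "product",
    extinction_rule: str = "product",
):
    """Combine spatial and successional rates into per-patch C_i, E_i.

    ``colonization_rule`` and ``extinction_rule`` are each ``"product"``
    (both processes must permit the event) or ``"or"`` (either process
    alone suffices, combined as complementary probabilities,
    ``1 - (1-a)(1-b)``). Both default to product: an unsuitable
    successional stage vetoes colonization outright and scales extinction
    risk, while still guaranteeing metapopulation loss at unsuitable ages
    through the colonization veto. OR-extinction would make every guild
    whose temporal modifier is bounded away from zero (early-successional:
    E_it >= 0.5 at all ages) incapable of persistence.
    """
    C_is = _check_prob("C_is", C_is)
    C_it = _check_prob("C_it", C_it)
    E_is = _check_prob("E_is", E_is)
    E_it = _check_prob("E_it", E_it)

    def _combine(a, b, rule, name):
        if rule == "product":
            return a * b
        if rule == "or":
            return 1.0 - (1.0 - a) * (1.0 - b)
        raise ValueError(f"unknown {name} rule: {rule!r}")

    C = np.clip(_combine(C_is, C_it, colonization_rule, "colonization"), 0.0, 1.0)
    E = np.clip(_combine(E_is, E_it, extinction_rule, "extinction"), 0.0, 1.0)
    if C.ndim == 0:
        return float(C), float(E)
    return C, E


def step_rates(
    landscape: Landscape,
    state: OccupancyState,
    species: SpeciesParams,
    dist: np.ndarray | None = None,
    colonization_rule: str = "product",
    extinction_rule: str = "product",
) -> StepRates:
    """All per-patch rates for one synchronous update of ``state``."""
    S = connectivity(landscape, state, species, dist=dist)
    C_is = colonization_spatial(S, species.y)
    E_is = extinction_spatial(landscape.area, species.e, species.x)
    C_it = colonization_modifier(species.preference, landscape.age)
    E_it = extinction_modifier(species.preference, landscape.age)
    C, E = combine_rates(
        C_is, C_it, E_is, E_it,
        colonization_rule=colonization_rule, extinction_rule=extinction_rule,
    )
    return StepRates(S=S, C_is=C_is, E_is=E_is, C_it=np.asarray(C_it),
                     E_it=np.asarray(E_it), C=np.asarray(C), E=np.asarray(E))


def bernoulli_update(
    occupied: np.ndarray,
    C: np.ndarray,
    E: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Synchronous Bernoulli transition given per-patch rates.

    Empty patches colonize with probability C; occupied patches go extinct
    with probability E. One uniform per patch, in array (patch-id) order.
    """
    u = rng.random(occupied.shape[0])
    return np.where(occupied, u >= E, u < C)


def step_occupancy(
    landscape: Landscape,
    state: OccupancyState,
    species: SpeciesParams,
    rng: np.random.Generator,
    dist: np.ndarray | None = None,
    colonization_rule: str = "product",
    extinction_rule: str = "product",
) -> OccupancyState:
    """One synchronous occupancy transition (no landscape change)."""
    rates = step_rates(
        landscape, state, species, dist=dist,
        colonization_rule=colonization_rule, extinction_rule=extinction_rule,
    )
    occ = bernoulli_update(state.occupied, rates.C, rates.E, rng)
    return OccupancyState(patch_ids=landscape.ids.copy(), occupied=occ,
                          time=state.time + 1)


def initial_state(
    landscape: Landscape, init_occupancy: float, rng: np.random.Generator
) -> OccupancyState:
    """Occupy ``round(init_occupancy * N)`` patches chosen at random."""
    n = landscape.n_patches
    k = int(round(init_occupancy * n))
    occ = np.zeros(n, dtype=bool)
    if k:
        occ[rng.choice(n, size=k, replace=False)] = True
    return OccupancyState(patch_ids=landscape.ids.copy(), occupied=occ, time=0)


def simulate_trajectory(
    landscape: Landscape,
    species: SpeciesParams,
    dynamism: float,
    steps: int = 100,
    init_occupancy: float = 0.5,
    seed: int | np.random.Generator | None = None,
    colonization_rule: str = "product",
    extinction_rule: str = "product",
    return_state: bool = False,
):
    """Simulate one occupancy trajectory on a dynamic landscape.

    Per step, in fixed order: (1) turnover of a ``dynamism`` fraction of
    patches — occupants of destroyed patches die, new patches are empty at
    age 0; (2) rates on the post-turnover landscape; (3) synchronous
    Bernoulli update; (4) aging. All stochastic draws (initial occupancy,
    turnover, placement, occupancy updates) flow from one generator.

    Returns the fraction of occupied living patches as an array of length
    ``steps + 1`` (element 0 is the initial fraction; the last element is
    the equilibrium-occupancy estimate for this run). With
    ``return_state=True``, returns ``(fractions, landscape, state)``.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if not 0 <= init_occupancy <= 1:
        raise ValueError("init_occupancy must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    ls = landscape.copy()
    state = initial_state(ls, init_occupancy, rng)
    frac = np.empty(steps + 1)
    frac[0] = state.fraction_occupied

    static = dynamism == 0
    dist = distance_matrix(ls) if static else None

    for t in range(1, steps + 1):
        if not static:
            ls_new, destroyed, _created = apply_turnover(ls, dynamism, rng)
            keep = ~np.isin(ls.ids, destroyed)
            k_new = ls_new.n_patches - int(keep.sum())
            occ = np.concatenate(
                [state.occupied[keep], np.zeros(k_new, dtype=bool)]
            )
            ls = ls_new
            state = OccupancyState(patch_ids=ls.ids.copy(), occupied=occ,
                                   time=state.time)
            dist = None
        state = step_occupancy(
            ls, state, species, rng, dist=dist,
            colonization_rule=colonization_rule, extinction_rule=extinction_rule,
        )
        ls = advance_age(ls)
        frac[t] = state.fraction_occupied

    if return_state:
        return frac, ls, state
    return frac
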