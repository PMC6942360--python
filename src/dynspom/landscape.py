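"""Random patch-network landscapes with turnover and successional aging.

A landscape is a set of circular habitat patches scattered in a square
arena. Patches have an area (hectares), a position (metres, centroid), and
an age (time steps since creation). Landscape dynamism is modelled as
patch turnover: at each time step a fixed fraction of patches is destroyed
and the same number of new (age-0) patches is created elsewhere, so the
patch count — and, in expectation, the habitat cover — stays constant.

Conventions
-----------
* Patches are circles of radius ``sqrt(area / pi)`` (area converted to m²).
* Distances used by the dispersal kernel are centroid-to-centroid.
* The minimum inter-patch spacing is enforced edge-to-edge, so patches
  never overlap and "inter-patch distance" keeps its physical meaning.
* Coordinates are continuous metres with the origin at an arena corner.
* All randomness flows from a single ``numpy.random.Generator`` in a fixed
  order: for each patch, first its area, then its position attempts; for
  turnover, first the destroyed set, then the replacement patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Patch",
    "Landscape",
    "PlacementError",
    "generate_landscape",
    "distance_matrix",
    "apply_turnover",
    "advance_age",
]

#: resampling floor for truncated-normal patch areas, hectares
AREA_FLOOR_HA = 0.01

#: position attempts per patch before placement is declared infeasible
MAX_ATTEMPTS_PER_PATCH = 5000


class PlacementError(RuntimeError):
    """Rejection sampling could not place the requested patches.

    Raised when the arena is too crowded for the requested patch count,
    spacing and area distribution within the attempt budget.
    """


@dataclass(frozen=True)
class Patch:
    """One circular habitat patch."""

    id: int
    x: float  #: centroid, metres from arena corner
    y: float
    area: float  #: hectares
    age: int  #: time steps since creation

    @property
    def radius(self) -> float:
        """Circle radius in metres implied by the area."""
        return float(np.sqrt(self.area * 1e4 / np.pi))


@dataclass
class Landscape:
    """A set of living patches in a square arena, stored as parallel arrays.

    Arrays are kept sorted by ascending patch id; ids are never reused
    within one trajectory (``next_id`` only grows).
    """

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    area: np.ndarray
    age: np.ndarray
    side: float
    target_cover: float
    mean_area: float
    sd_area: float
    min_dist: float
    rng_seed: int | None = None
    next_id: int = field(default=0)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        self.age = np.asarray(self.age, dtype=np.int64)
        if self.next_id == 0 and self.ids.size:
            self.next_id = int(self.ids.max()) + 1

    @property
    def n_patches(self) -> int:
        return int(self.ids.size)

    @property
    def radius(self) -> np.ndarray:
        """Patch radii in metres."""
        return np.sqrt(self.area * 1e4 / np.pi)

    @property
    def realized_cover(self) -> float:
        """Total patch area divided by arena area (both in hectares)."""
        return float(self.area.sum() / (self.side**2 / 1e4))

    def patches(self) -> list[Patch]:
        return [
            Patch(int(i), float(px), float(py), float(a), int(g))
            for i, px, py, a, g in zip(self.ids, self.x, self.y, self.area, self.age)
        ]

    def copy(self) -> "Landscape":
        return Landscape(
            self.ids.copy(), self.x.copy(), self.y.copy(),
            self.area.copy(), self.age.copy(),
            self.side, self.target_cover, self.mean_area, self.sd_area,
            self.min_dist, self.rng_seed, self.next_id,
        )

    # -- tabular round-trip ------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "x_m": self.x, "y_m": self.y,
             "area_ha": self.area, "age": self.age}
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        side: float,
        target_cover: float = np.nan,
        mean_area: float = np.nan,
        sd_area: float = np.nan,
        min_dist: float = 0.0,
    ) -> "Landscape":
        order = np.argsort(df["id"].to_numpy())
        df = df.iloc[order]
        return cls(
            df["id"].to_numpy(), df["x_m"].to_numpy(), df["y_m"].to_numpy(),
            df["area_ha"].to_numpy(), df["age"].to_numpy(),
            side, target_cover, mean_area, sd_area, min_dist,
        )


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_area(rng: np.random.Generator, mean_area: float, sd_area: float) -> float:
    """Normal(mean, sd) patch area, truncated by resampling at a small floor."""
    for _ in range(10_000):
        a = rng.normal(mean_area, sd_area)
        if a >= AREA_FLOOR_HA:
            return float(a)
    raise PlacementError(
        f"could not draw a patch area >= {AREA_FLOOR_HA} ha from "
        f"normal({mean_area}, {sd_area}) — check the area distribution"
    )


def _place_patches(
    n_new: int,
    side: float,
    mean_area: float,
    sd_area: float,
    min_dist: float,
    rng: np.random.Generator,
    existing_x: np.ndarray,
    existing_y: np.ndarray,
    existing_r: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sequential rejection sampling of ``n_new`` non-overlapping circles.

    Spacing is edge-to-edge: accepted centres satisfy
    ``dist >= r_i + r_j + min_dist`` against every existing patch. Circles
    are kept fully inside the arena.
    """
    xs = list(existing_x)
    ys = list(existing_y)
    rs = list(existing_r)
    new_x = np.empty(n_new)
    new_y = np.empty(n_new)
    new_a = np.empty(n_new)
    for k in range(n_new):
        area = _draw_area(rng, mean_area, sd_area)
        r = float(np.sqrt(area * 1e4 / np.pi))
        if 2 * r >= side:
            raise PlacementError(f"patch radius {r:.1f} m exceeds arena side {side} m")
        placed = False
        occ_x = np.array(xs)
        occ_y = np.array(ys)
        occ_r = np.array(rs)
        for _ in range(MAX_ATTEMPTS_PER_PATCH):
            cx = rng.uniform(r, side - r)
            cy = rng.uniform(r, side - r)
            if occ_x.size:
                d2 = (occ_x - cx) ** 2 + (occ_y - cy) ** 2
                req = occ_r + r + min_dist
                if np.any(d2 < req**2):
                    continue
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"failed to place patch {k + 1}/{n_new} after "
                f"{MAX_ATTEMPTS_PER_PATCH} attempts (side={side} m, "
                f"{len(xs)} patches present, min_dist={min_dist} m): "
                "the parameterization is overcrowded"
            )
        xs.append(cx)
        ys.append(cy)
        rs.append(r)
        new_x[k], new_y[k], new_a[k] = cx, cy, area
    return new_x, new_y, new_a


def patch_count(side: float, cover: float, mean_area: float) -> int:
    """Deterministic patch count: ``round(arena_ha * cover / mean_area)``."""
    return int(round(side**2 / 1e4 * cover / mean_area))


def generate_landscape(
    side: float = 3163.0,
    cover: float = 0.10,
    mean_area: float = 0.5,
    sd_area: float = 0.2,
    min_dist: float = 10.0,
    seed: int | np.random.Generator | None = None,
    initial_age_mode: str = "uniform0_100",
) -> Landscape:
    """Generate a random static patch network.

    Parameters
    ----------
    side
        Arena side length in metres (default ~1000 ha arena).
    cover
        Target habitat cover as a fraction of the arena area; the patch
        count is fixed deterministically at ``round(arena_ha * cover /
        mean_area)`` so realized cover fluctuates slightly around target.
    mean_area, sd_area
        Normal patch-area distribution in hectares, truncated below.
    min_dist
        Minimum edge-to-edge spacing between patches, metres.
    seed
        Integer seed or an existing :class:`numpy.random.Generator`.
    initial_age_mode
        ``"uniform0_100"`` draws each initial age uniformly on the integers
        0..100 so all successional stages are represented at t=0;
        ``"zero"`` starts every patch at age 0.
    """
    if not 0 < cover < 1:
        raise ValueError(f"cover must be in (0, 1), got {cover}")
    if mean_area <= 0:
        raise ValueError(f"mean_area must be positive, got {mean_area}")
    if side <= 0:
        raise ValueError(f"side must be positive, got {side}")
    if initial_age_mode not in ("uniform0_100", "zero"):
        raise ValueError(f"unknown initial_age_mode: {initial_age_mode!r}")

    rng = _as_rng(seed)
    n = patch_count(side, cover, mean_area)
    x, y, area = _place_patches(
        n, side, mean_area, sd_area, min_dist, rng,
        np.empty(0), np.empty(0), np.empty(0),
    )
    if initial_age_mode == "uniform0_100":
        age = rng.integers(0, 101, size=n)
    else:
        age = np.zeros(n, dtype=np.int64)
    return Landscape(
        ids=np.arange(n), x=x, y=y, area=area, age=age,
        side=side, target_cover=cover, mean_area=mean_area,
        sd_area=sd_area, min_dist=min_dist,
        rng_seed=seed if isinstance(seed, int) else None,
        next_id=n,
    )


def distance_matrix(landscape: Landscape) -> np.ndarray:
    """Symmetric matrix of centroid-to-centroid distances, metres."""
    if landscape.n_patches == 0:
        return np.zeros((0, 0))
    pts = np.column_stack([landscape.x, landscape.y])
    if len(pts) == 1:
        return np.zeros((1, 1))
    return squareform(pdist(pts))


def apply_turnover(
    landscape: Landscape,
    fraction: float,
    seed: int | np.random.Generator | None = None,
) -> tuple[Landscape, np.ndarray, np.ndarray]:
    """Destroy and re-create ``round(fraction * N)`` patches (half-up).

    The destroyed set is chosen uniformly at random; replacements are drawn
    from the same area distribution (not copied), placed against the
    survivors and each other under the spacing rule, and start at age 0, so
    the patch count is exactly conserved and cover approximately so.

    Returns the new landscape plus the destroyed and created patch ids.
    Ages are NOT advanced here; see :func:`advance_age`.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = _as_rng(seed)
    n = landscape.n_patches
    k = int(np.floor(fraction * n + 0.5))
    if k == 0:
        return landscape.copy(), np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)

    destroy_pos = rng.choice(n, size=k, replace=False)
    keep = np.ones(n, dtype=bool)
    keep[destroy_pos] = False
    destroyed_ids = landscape.ids[~keep]

    surv_r = landscape.radius[keep]
    new_x, new_y, new_a = _place_patches(
        k, landscape.side, landscape.mean_area, landscape.sd_area,
        landscape.min_dist, rng,
        landscape.x[keep], landscape.y[keep], surv_r,
    )
    created_ids = np.arange(landscape.next_id, landscape.next_id + k, dtype=np.int64)
    out = Landscape(
        ids=np.concatenate([landscape.ids[keep], created_ids]),
        x=np.concatenate([landscape.x[keep], new_x]),
        y=np.concatenate([landscape.y[keep], new_y]),
        area=np.concatenate([landscape.area[keep], new_a]),
        age=np.concatenate([landscape.age[keep], np.zeros(k, dtype=np.int64)]),
        side=landscape.side, target_cover=landscape.target_cover,
        mean_area=landscape.mean_area, sd_area=landscape.sd_area,
        min_dist=landscape.min_dist, rng_seed=landscape.rng_seed,
        next_id=int(landscape.next_id + k),
    )
    return out, np.sort(destroyed_ids), created_ids


def advance_age(landscape: Landscape) -> Landscape:
    """Increment every living patch's age by one time step."""
    out = landscape.copy()
    out.age = out.age + 1
    return out
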