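"""Environments, Poisson place-field maps, and embedded training patterns.

A *place-field map* assigns each of N model place cells a Poisson-distributed
number of field centers scattered uniformly over a 2-D environment.  From the
map we derive, for any location ``x``:

* the **training input** ``b̄(x)`` — for each cell, a sum of Gaussian bumps of
  amplitude ``b_pk`` centered on its field centers;
* the **desired (embedded) activity** ``f̄(x)`` — for each cell, a sum of
  threshold-linear activity bumps of peak ``f_pk``, each vanishing beyond the
  radius ``R = σ·sqrt(2·ln((1+u0)/u0))`` of its field center.

These patterns are what the recurrent weights are trained to hold as stable
fixed points, and the set of cells with ``f̄_i(x) > 0`` (the *embedded active
set*) is the basic object of the stability analysis.

Coordinates are continuous 2-D positions in meters, origin at the lower-left
corner of the environment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Environment",
    "PatternParams",
    "PlaceFieldMap",
    "TrainingGrid",
    "active_bump_radius",
    "calibrate_field_density",
    "sample_place_fields",
    "training_input",
    "desired_activity",
    "embedded_pattern",
    "embedded_active_set",
    "net_activity_constant",
    "default_input_strength",
    "concentric_square_environment",
]


@dataclass(frozen=True)
class PatternParams:
    """Shape parameters of the embedded patterns and training inputs.

    sigma : Gaussian width of a place field, m
    u0    : depolarization shift at which a cell becomes active (sets the
            active-bump radius R = σ·sqrt(2·ln((1+u0)/u0)))
    f_pk  : peak firing rate of an activity bump, Hz
    b_pk  : training-input amplitude (dimensionless); if None it is
            calibrated per network via :func:`default_input_strength`
    """

    sigma: float = 0.10
    u0: float = 0.3
    f_pk: float = 15.0
    b_pk: float | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.u0 <= 0 or self.f_pk <= 0:
            raise ValueError("sigma, u0 and f_pk must be positive")

    @property
    def radius(self) -> float:
        return active_bump_radius(self.sigma, self.u0)


@dataclass(frozen=True)
class Environment:
    """A rectangular 2-D environment, optionally split into learning regions.

    ``region_sequence`` is an ordered list of rectangles ``(x0, y0, x1, y1)``
    that tile the environment without overlap, in the order in which the
    animal learns them (concentric growth for incrementally learned squares).
    An empty sequence means the whole environment is a single region.
    """

    width: float
    height: float
    boundary_margin: float = 0.15
    region_sequence: tuple[tuple[float, float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("environment must have positive width and height")
        if self.boundary_margin < 0:
            raise ValueError("boundary_margin must be nonnegative")
        if self.region_sequence:
            # Regions are stored as nested outer boxes (region k = box k minus
            # the earlier boxes); the last box must cover the environment and
            # every box must lie inside it.
            for x0, y0, x1, y1 in self.region_sequence:
                if not (0 <= x0 < x1 <= self.width and 0 <= y0 < y1 <= self.height):
                    raise ValueError("region box outside environment")
            lx0, ly0, lx1, ly1 = self.region_sequence[-1]
            if not (
                np.isclose(lx1 - lx0, self.width) and np.isclose(ly1 - ly0, self.height)
            ):
                raise ValueError("region sequence must cover the environment")

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def interior(self) -> tuple[float, float, float, float]:
        """Bounding box at least ``boundary_margin`` from every wall."""
        m = self.boundary_margin
        if 2 * m >= min(self.width, self.height):
            raise ValueError("boundary margin leaves no interior")
        return (m, m, self.width - m, self.height - m)

    def contains(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(
            np.all(x[..., 0] >= 0)
            and np.all(x[..., 0] <= self.width)
            and np.all(x[..., 1] >= 0)
            and np.all(x[..., 1] <= self.height)
        )

    def respects_margin(self, x: np.ndarray) -> bool:
        x0, y0, x1, y1 = self.interior
        x = np.asarray(x, dtype=float)
        return bool(
            np.all((x[..., 0] >= x0) & (x[..., 0] <= x1))
            and np.all((x[..., 1] >= y0) & (x[..., 1] <= y1))
        )


def concentric_square_environment(
    side: float, n_regions: int, boundary_margin: float = 0.15
) -> Environment:
    """Square environment split into ``n_regions`` concentric square shells.

    Region 1 is the central square of side ``side/n_regions``; each later
    region is the square ring extending the learned area outward, emulating
    an animal incrementally exploring a growing square environment.
    """
    if n_regions < 1:
        raise ValueError("need at least one region")
    c = side / 2.0
    sides = [side * (k + 1) / n_regions for k in range(n_regions)]
    # Region k is the square shell between box k-1 and box k; stored as the
    # outer box, with membership resolved innermost-first (region_of_points).
    regions = [(c - s / 2, c - s / 2, c + s / 2, c + s / 2) for s in sides]
    return Environment(
        width=side,
        height=side,
        boundary_margin=boundary_margin,
        region_sequence=tuple(regions),
    )


def region_of_points(env: Environment, pts: np.ndarray) -> np.ndarray:
    """Index (0-based) of the first region whose box contains each point.

    With concentric boxes this implements "square shell k": a point belongs
    to the innermost box that contains it.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    out = np.full(len(pts), -1, dtype=int)
    regions = env.region_sequence or ((0.0, 0.0, env.width, env.height),)
    for k, (x0, y0, x1, y1) in enumerate(regions):
        inside = (
            (pts[:, 0] >= x0) & (pts[:, 0] <= x1)
            & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
        )
        out[(out == -1) & inside] = k
    return out


@dataclass(frozen=True)
class TrainingGrid:
    """Uniform grid of training locations, all respecting the boundary margin."""

    locations: np.ndarray  # (L, 2)
    spacing: float

    @classmethod
    def cover(cls, env: Environment, spacing: float = 0.05) -> "TrainingGrid":
        if spacing <= 0:
            raise ValueError("spacing must be positive")
        x0, y0, x1, y1 = env.interior
        xs = np.arange(x0, x1 + 1e-9, spacing)
        ys = np.arange(y0, y1 + 1e-9, spacing)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return cls(np.column_stack([gx.ravel(), gy.ravel()]), spacing)

    def __len__(self) -> int:
        return len(self.locations)

    def restrict_to_region(self, env: Environment, k: int) -> "TrainingGrid":
        """Grid locations belonging to region ``k`` (0-based)."""
        idx = region_of_points(env, self.locations) == k
        return TrainingGrid(self.locations[idx], self.spacing)


@dataclass(frozen=True)
class PlaceFieldMap:
    """Poisson place-field centers for a population of cells.

    Stored flat: ``field_pos[p]`` is the 2-D center of field ``p`` and
    ``field_cell[p]`` the cell it belongs to.  Cells may own zero fields
    (silent cells); they are retained in every vector so that indices are
    stable across operations.
    """

    n_cells: int
    field_pos: np.ndarray  # (F, 2) meters
    field_cell: np.ndarray  # (F,) int
    field_rate_density: float  # λ, fields per m² per cell
    seed: int
    env: Environment

    @property
    def n_fields(self) -> int:
        return len(self.field_cell)

    def fields_per_cell(self) -> np.ndarray:
        return np.bincount(self.field_cell, minlength=self.n_cells)

    def centers(self, i: int) -> np.ndarray:
        return self.field_pos[self.field_cell == i]

    def silent_fraction(self) -> float:
        return float(np.mean(self.fields_per_cell() == 0))


def calibrate_field_density(silent_fraction: float, area: float = 1.0) -> float:
    """Field density λ (fields/m²/cell) from a target silent-cell fraction.

    A cell is silent in an environment of the given area when its Poisson
    field count is zero, so ``exp(-λ·area) = silent_fraction``.
    """
    if not 0.0 < silent_fraction < 1.0:
        raise ValueError("silent_fraction must lie strictly between 0 and 1")
    if area <= 0:
        raise ValueError("area must be positive")
    return -np.log(silent_fraction) / area


def sample_place_fields(
    env: Environment, n_cells: int, lam: float, seed: int
) -> PlaceFieldMap:
    """Draw a place-field map: per-cell counts ``M_i ~ Poisson(λ·area)``,
    centers uniform over the environment.  Deterministic under ``seed``."""
    if lam <= 0:
        raise ValueError("field density λ must be positive")
    if n_cells < 1:
        raise ValueError("need at least one cell")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam * env.area, size=n_cells)
    total = int(counts.sum())
    pos = np.column_stack(
        [
            rng.uniform(0.0, env.width, size=total),
            rng.uniform(0.0, env.height, size=total),
        ]
    )
    cell = np.repeat(np.arange(n_cells), counts)
    return PlaceFieldMap(
        n_cells=n_cells,
        field_pos=pos,
        field_cell=cell,
        field_rate_density=lam,
        seed=seed,
        env=env,
    )


def active_bump_radius(sigma: float, u0: float) -> float:
    """Radius within which a single field contributes positive activity.

    Solves ``(1+u0)·exp(-R²/2σ²) - u0 = 0``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if u0 <= 0:
        raise ValueError("u0 must be positive")
    return sigma * np.sqrt(2.0 * np.log((1.0 + u0) / u0))


def _field_gaussians(pfm: PlaceFieldMap, x: np.ndarray, sigma: float) -> np.ndarray:
    """exp(-|x - c_p|²/2σ²) for every field center ``c_p``."""
    d2 = np.sum((pfm.field_pos - np.asarray(x, dtype=float)) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * sigma**2))


def training_input(
    pfm: PlaceFieldMap, x: np.ndarray, b_pk: float, sigma: float
) -> np.ndarray:
    """Per-cell training input ``b̄_i(x) = b_pk · Σ_m exp(-|x-c_im|²/2σ²)``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    g = _field_gaussians(pfm, x, sigma)
    return b_pk * np.bincount(pfm.field_cell, weights=g, minlength=pfm.n_cells)


def desired_activity(
    pfm: PlaceFieldMap,
    x: np.ndarray,
    sigma: float,
    u0: float,
    f_pk: float,
) -> np.ndarray:
    """Per-cell embedded activity ``f̄_i(x)`` in Hz.

    Each field contributes ``f_pk·[(1+u0)·exp(-d²/2σ²) - u0]₊`` — an activity
    bump of height ``f_pk`` over the field center that falls to zero at the
    radius given by :func:`active_bump_radius`.  Contributions of a cell's
    fields add (threshold per field, not on the summed drive).
    """
    if u0 <= 0:
        raise ValueError("u0 must be positive")
    g = _field_gaussians(pfm, x, sigma)
    per_field = f_pk * np.maximum((1.0 + u0) * g - u0, 0.0)
    return np.bincount(pfm.field_cell, weights=per_field, minlength=pfm.n_cells)


def embedded_pattern(
    pfm: PlaceFieldMap,
    x: np.ndarray,
    sigma: float,
    u0: float,
    f_pk: float,
    f_net: float | None = None,
) -> np.ndarray:
    """Embedded activity pattern at ``x``, optionally normalized so that the
    population activity equals ``f_net`` exactly.

    The attractor construction requires the net embedded activity to be
    independent of location; on a finite Poisson map the raw sum fluctuates
    around its mean, so the pattern embedded (and used in the reduction) is
    the desired activity rescaled to the network constant.  Support and
    shape are unchanged.
    """
    f = desired_activity(pfm, x, sigma, u0, f_pk)
    if f_net is not None:
        total = f.sum()
        if total <= 0.0:
            raise ValueError("no active cell at this location; cannot normalize")
        f *= f_net / total
    return f


def embedded_active_set(
    pfm: PlaceFieldMap, x: np.ndarray, sigma: float, u0: float
) -> np.ndarray:
    """Sorted indices of cells active in the embedded pattern at ``x``:
    cells with at least one field within the active-bump radius of ``x``."""
    f = desired_activity(pfm, x, sigma, u0, f_pk=1.0)
    return np.flatnonzero(f > 0.0)


def net_activity_constant(
    pfm: PlaceFieldMap,
    grid: TrainingGrid,
    sigma: float,
    u0: float,
    f_pk: float,
) -> tuple[float, float]:
    """Mean and coefficient of variation of net embedded activity over a grid.

    The embedded patterns are constructed so the population activity
    ``Σ_i f̄_i(x)`` is (statistically) independent of location; the grid mean
    defines the network constant ``f̄_net`` and the CV quantifies how well a
    finite map honors that homogeneity.
    """
    if len(grid) == 0:
        raise ValueError("training grid is empty")
    totals = np.array(
        [desired_activity(pfm, x, sigma, u0, f_pk).sum() for x in grid.locations]
    )
    mean = float(totals.mean())
    if mean == 0.0:
        warnings.warn("map has no active cell anywhere on the grid", stacklevel=2)
        return 0.0, 0.0
    return mean, float(totals.std() / mean)


def default_input_strength(
    b_pk_hat: float,
    f_net: float,
    f_pk: float,
    n_bar: float,
    sigma: float,
    u0: float,
) -> float:
    """Training-input amplitude ``b̄_pk`` matched to a reduced-input target.

    Summing the training input over an embedded active set and scaling by
    ``f_pk/f̄_net`` should give the reduced training strength ``b̂_pk``.  For a
    bump of radius R the mean Gaussian weight over the active disk is
    ``κ = 2σ²/(R²(1+u0))``, so ``b̄_pk = b̂_pk·f̄_net/(f_pk·N̄·κ)``.
    """
    R = active_bump_radius(sigma, u0)
    kappa = 2.0 * sigma**2 / (R**2 * (1.0 + u0))
    return b_pk_hat * f_net / (f_pk * n_bar * kappa)
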