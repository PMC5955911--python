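"""Recurrent-weight construction: delta-rule embedding and Hebbian sums.

Two ways to build the N×N excitatory weight matrix:

* **Optimal (delta rule).**  Every embedded pattern f̄(x_j) on a training
  grid is driven into being a fixed point of the network under its training
  input b̄(x_j).  At such a fixed point the recurrent drive into an active
  cell must equal ``ū_i + w_I·f̄_I - b̄_i`` (with ``ū_i = f̄_i/f_pk``), and
  the drive into a silent cell must not push it above threshold.  The
  equality part is learned by a normalized least-mean-squares (Kaczmarz)
  sweep over shuffled grid locations; the silent-cell inequality is enforced
  with perceptron-style corrections applied only on violation.  Sub-threshold
  values are otherwise unconstrained, since the fixed point only pins [u]₊.

* **Hebbian (sum of tuning curves).**  ``W_jk = Σ_m Σ_n w_tune(|c_jm - c_kn|)``
  over all field-center pairs of the two cells.  The radial tuning curve is
  itself measured from a delta-rule-trained network in which every cell has
  exactly one field, so the two constructions coincide for single-field maps
  up to the radial-averaging error.  The Hebbian sum is purely additive: in
  incremental learning, weights never decrease.

Incremental learning mimics an animal exploring a growing environment
region by region: the optimal learner re-runs the delta rule on the new
region's grid locations only (earlier regions are not reinforced), while the
Hebbian learner adds the tuning-curve terms of newly visited field pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.spatial.distance import cdist

from .dynamics import NetworkParams
from .environment import (
    Environment,
    PatternParams,
    PlaceFieldMap,
    TrainingGrid,
    desired_activity,
    embedded_pattern,
    net_activity_constant,
    region_of_points,
    training_input,
)

__all__ = [
    "LearningConfig",
    "WeightMatrix",
    "ConvergenceReport",
    "TuningCurve",
    "learn_optimal_weights",
    "compute_tuning_curve",
    "hebbian_weights",
    "incremental_learning",
]


@dataclass(frozen=True)
class LearningConfig:
    """Embedding-solver settings.

    solver          : "lstsq" (default) solves each row's minimum-norm-change
                      interpolation directly (the solution the online rule
                      converges to); "delta" runs the online normalized
                      delta rule
    eta             : online solver only — relative step per location, as a
                      fraction of the normalized (1/‖f̄‖²) Kaczmarz step
    max_epochs      : online solver — sweeps over the shuffled grid;
                      direct solver — inequality-refinement passes
    embed_tolerance : worst-case fixed-point residual (in u units) at which
                      training is declared converged
    shuffle_seed    : seed of the online location-shuffling stream
    """

    solver: str = "lstsq"
    eta: float = 1.0
    max_epochs: int = 200
    embed_tolerance: float = 1e-3
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if self.solver not in ("lstsq", "delta"):
            raise ValueError("solver must be 'lstsq' or 'delta'")
        if not 0.0 < self.eta < 2.0:
            raise ValueError("eta must lie in (0, 2) for a contracting update")
        if self.embed_tolerance <= 0:
            raise ValueError("embed_tolerance must be positive")


@dataclass
class ConvergenceReport:
    converged: bool
    epochs_run: int
    worst_residual: float
    residual_history: list[float] = field(default_factory=list)


@dataclass
class WeightMatrix:
    """Recurrent weights plus provenance.

    Hebbian matrices are exactly symmetric; delta-rule matrices are a small
    perturbation from symmetric (``asymmetry`` reports the relative norm).
    """

    W: np.ndarray
    provenance: str  # "optimal" | "hebbian"
    report: ConvergenceReport | None = None

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def asymmetry(self) -> float:
        denom = np.linalg.norm(self.W)
        if denom == 0.0:
            return 0.0
        return float(np.linalg.norm(self.W - self.W.T) / denom)


def _training_set(
    pfm: PlaceFieldMap,
    grid: TrainingGrid,
    pattern: PatternParams,
    net: NetworkParams,
    b_pk: float,
):
    """Precompute patterns, inputs, targets and active masks for every grid
    location.  Targets are the required recurrent drive (W f̄)_i: an equality
    for active cells, an upper bound for silent ones."""
    L, N = len(grid), pfm.n_cells
    F = np.empty((L, N))
    B = np.empty((L, N))
    for j, x in enumerate(grid.locations):
        # patterns normalized so the net embedded activity is exactly f_net
        # at every location, as the attractor construction requires
        F[j] = embedded_pattern(
            pfm, x, pattern.sigma, pattern.u0, pattern.f_pk, net.f_net
        )
        B[j] = training_input(pfm, x, b_pk, pattern.sigma)
    active = F > 0.0
    f_I = np.full(L, (1.0 - net.theta) * net.f_net)
    U_bar = np.where(active, F / pattern.f_pk, 0.0)
    targets = U_bar + net.w_I * f_I[:, None] - B
    return F, targets, active


def learn_optimal_weights(
    pfm: PlaceFieldMap,
    grid: TrainingGrid,
    pattern: PatternParams,
    net: NetworkParams,
    cfg: LearningConfig | None = None,
    W0: np.ndarray | None = None,
) -> WeightMatrix:
    """Embed every grid pattern as a stable fixed point of the dynamics.

    Each row ``W_i·`` must satisfy an equality ``(W f̄(x_j))_i = target_ij``
    at locations where cell i is active and an inequality (drive at most the
    sub-threshold bound) where it is silent.  The default solver computes,
    per row, the minimum-norm change from ``W0`` meeting the equalities
    (violated inequalities are clamped to the bound and re-solved) — the
    solution the online delta rule converges to.  ``solver="delta"`` runs
    the online rule itself: per location, a normalized LMS step
    ``ΔW_i· = (η/‖f̄‖²)·(target_i - (W f̄)_i)·f̄ᵀ``, with silent-cell rows
    updated only on violation.  Non-convergence is reported, not raised.
    """
    cfg = cfg or LearningConfig()
    b_pk = pattern.b_pk
    if b_pk is None:
        raise ValueError("pattern.b_pk must be set (see default_input_strength)")
    F, targets, active = _training_set(pfm, grid, pattern, net, b_pk)
    L, N = F.shape
    if L == 0:
        raise ValueError("empty training grid")
    if not np.all(active.any(axis=1)):
        raise ValueError("a training location has no active cell; increase λ or N")
    W = np.zeros((N, N)) if W0 is None else np.array(W0, dtype=float, copy=True)
    if cfg.solver == "lstsq":
        return _solve_embedding(W, F, targets, active, cfg)
    return _delta_rule(W, F, targets, active, cfg)


def _solve_embedding(
    W: np.ndarray,
    F: np.ndarray,
    targets: np.ndarray,
    active: np.ndarray,
    cfg: LearningConfig,
) -> WeightMatrix:
    """Row-wise minimum-norm-change interpolation of the embedding constraints.

    Row i's change is ``ΔW_i = Σ_c α_c f̄(x_c)`` over its constraint set, with
    ``G α = residual`` and G the Gram matrix of the constraint patterns;
    violated silent-cell bounds are added to the set (with a small safety
    margin below threshold) over successive passes.
    """
    L, N = F.shape
    G = F @ F.T  # (L, L) pattern Gram matrix, shared by all rows
    margin = cfg.embed_tolerance
    # initial constraint set per row: equality locations; violated bounds are
    # later clamped to (bound - margin) and treated as equalities
    con = [np.flatnonzero(active[:, i]) for i in range(N)]
    T_adj = targets.copy()
    history: list[float] = []
    passes = 0
    for sweep in range(max(cfg.max_epochs, 1)):
        passes = sweep + 1
        err = T_adj - (W @ F.T).T  # (L, N), adjusted target minus drive
        for i in range(N):
            c = con[i]
            if c.size == 0:
                continue
            r = err[c, i]
            if np.max(np.abs(r)) < 1e-12:
                continue
            alpha, *_ = np.linalg.lstsq(G[np.ix_(c, c)], r, rcond=None)
            W[i] += alpha @ F[c]
        # feasibility against the original targets
        err = targets - (W @ F.T).T
        eq_res = np.where(active, err, 0.0)
        viol = (~active) & (err < 0.0)  # drive above the sub-threshold bound
        worst = max(
            float(np.max(np.abs(eq_res))),
            float(np.max(-np.where(viol, err, 0.0))),
        )
        history.append(worst)
        if worst < cfg.embed_tolerance:
            break
        grew = False
        for j, i in zip(*np.nonzero(viol & (err < -0.1 * margin))):
            if j not in con[i]:
                con[i] = np.append(con[i], j)
                T_adj[j, i] = targets[j, i] - margin
                grew = True
        if not grew:
            break  # equality residual floor; more passes cannot help
    converged = bool(history and history[-1] < cfg.embed_tolerance)
    report = ConvergenceReport(converged, passes, history[-1] if history else np.inf, history)
    return WeightMatrix(W, "optimal", report)


def _delta_rule(
    W: np.ndarray,
    F: np.ndarray,
    targets: np.ndarray,
    active: np.ndarray,
    cfg: LearningConfig,
) -> WeightMatrix:
    L, N = F.shape
    # update direction is the pattern's support (columns); the row-wise
    # equality/inequality split comes from `active` (rows)
    act_idx = [np.flatnonzero(F[j] > 0.0) for j in range(L)]
    fa_list = [F[j, idx] for j, idx in enumerate(act_idx)]
    ff = np.array([float(fa @ fa) for fa in fa_list])
    rng = np.random.default_rng(cfg.shuffle_seed)
    history: list[float] = []
    converged = False
    epochs = 0
    silent = ~active
    for epoch in range(cfg.max_epochs):
        epochs = epoch + 1
        worst = 0.0
        for j in rng.permutation(L):
            idx, fa = act_idx[j], fa_list[j]
            drive = W[:, idx] @ fa
            err = targets[j] - drive
            # silent cells: only push the drive back below its bound
            np.minimum(err, 0.0, where=silent[j], out=err)
            w = float(np.max(np.abs(err)))
            if w > worst:
                worst = w
            W[:, idx] += (cfg.eta / ff[j]) * err[:, None] * fa[None, :]
        history.append(worst)
        if worst < cfg.embed_tolerance:
            converged = True
            break
    report = ConvergenceReport(converged, epochs, history[-1], history)
    return WeightMatrix(W, "optimal", report)


@dataclass(frozen=True)
class TuningCurve:
    """Radial weight profile w_tune(d), tabulated and linearly interpolated.

    Zero beyond ``support``.  Approximately Gaussian when measured from a
    trained single-field network.
    """

    distances: np.ndarray  # bin centers, m
    values: np.ndarray
    support: float  # m; w_tune = 0 beyond this

    def __call__(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        out = np.interp(d, self.distances, self.values, right=0.0)
        return np.where(d <= self.support, out, 0.0)

    @property
    def peak(self) -> float:
        return float(np.max(np.abs(self.values)))


def compute_tuning_curve(
    pattern: PatternParams,
    w_I_hat: float = 5.3,
    theta: float = 0.9,
    cfg: LearningConfig | None = None,
    n_cells: int = 700,
    env_side: float = 1.6,
    grid_spacing: float = 0.08,
    seed: int = 1234,
    bin_width: float = 0.01,
    truncate_rel: float = 1e-4,
) -> TuningCurve:
    """Measure w_tune from a delta-rule-trained single-field network.

    Builds a reference environment in which every cell has exactly one field,
    trains the optimal weights, and radially averages W over cell-pair
    distance in ``bin_width`` bins (pairs with both cells well inside the
    boundary, to avoid edge bias).  The tail is truncated where
    ``|w_tune| < truncate_rel × peak``.
    """
    env = Environment(env_side, env_side)
    rng = np.random.default_rng(seed)
    pos = np.column_stack(
        [rng.uniform(0, env_side, n_cells), rng.uniform(0, env_side, n_cells)]
    )
    pfm = PlaceFieldMap(
        n_cells=n_cells,
        field_pos=pos,
        field_cell=np.arange(n_cells),
        field_rate_density=n_cells / env.area,
        seed=seed,
        env=env,
    )
    grid = TrainingGrid.cover(env, grid_spacing)
    f_net, _ = net_activity_constant(pfm, grid, pattern.sigma, pattern.u0, pattern.f_pk)
    n_bar = _mean_active_count(pfm, grid, pattern)
    net = NetworkParams(
        f_pk=pattern.f_pk,
        w_I=w_I_hat / (pattern.f_pk * n_bar),
        theta=theta,
        f_net=f_net,
    )
    if pattern.b_pk is None:
        from .environment import default_input_strength
        from .reduction import balanced_input_strength

        b_hat = balanced_input_strength(1.2, w_I_hat, theta)
        pattern = PatternParams(
            pattern.sigma,
            pattern.u0,
            pattern.f_pk,
            default_input_strength(
                b_hat, f_net, pattern.f_pk, n_bar, pattern.sigma, pattern.u0
            ),
        )
    wm = learn_optimal_weights(pfm, grid, pattern, net, cfg)

    # radial average over interior pairs
    margin = env.boundary_margin + 2.0 * pattern.radius
    interior = np.all((pos >= margin) & (pos <= env_side - margin), axis=1)
    ii = np.flatnonzero(interior)
    d = cdist(pos[ii], pos)
    w = wm.W[np.ix_(ii, np.arange(n_cells))]
    bins = np.arange(0.0, d.max() + bin_width, bin_width)
    which = np.digitize(d.ravel(), bins) - 1
    sums = np.bincount(which, weights=w.ravel(), minlength=len(bins))
    counts = np.bincount(which, minlength=len(bins))
    valid = counts > 0
    centers = (bins + bin_width / 2.0)[valid]
    means = sums[valid] / counts[valid]
    peak = np.max(np.abs(means))
    keep = np.abs(means) >= truncate_rel * peak
    support = float(centers[keep][-1]) if keep.any() else 0.0
    return TuningCurve(centers, np.where(keep, means, 0.0), support)


def _mean_active_count(
    pfm: PlaceFieldMap, grid: TrainingGrid, pattern: PatternParams
) -> float:
    counts = [
        np.count_nonzero(
            desired_activity(pfm, x, pattern.sigma, pattern.u0, 1.0) > 0
        )
        for x in grid.locations[:: max(1, len(grid) // 64)]
    ]
    return float(np.mean(counts))


def hebbian_weights(
    pfm: PlaceFieldMap,
    tuning: TuningCurve,
    chunk: int = 2000,
) -> WeightMatrix:
    """Sum-of-tuning-curves weights over all field-center pairs.

    Exactly symmetric by construction; diagonal entries include the
    cross-field self terms of multi-field cells.
    """
    N = pfm.n_cells
    W = np.zeros((N, N))
    for start in range(0, pfm.n_fields, chunk):
        sl = slice(start, min(start + chunk, pfm.n_fields))
        d = cdist(pfm.field_pos[sl], pfm.field_pos)
        rows, cols = np.nonzero(d <= tuning.support)
        if len(rows) == 0:
            continue
        vals = tuning(d[rows, cols])
        W += coo_matrix(
            (vals, (pfm.field_cell[sl][rows], pfm.field_cell[cols])),
            shape=(N, N),
        ).toarray()
    W = np.maximum(W, 0.0)  # Hebbian weights are nonnegative
    return WeightMatrix((W + W.T) / 2.0, "hebbian")


def incremental_learning(
    pfm: PlaceFieldMap,
    env: Environment,
    pattern: PatternParams,
    net: NetworkParams,
    cfg: LearningConfig | None = None,
    method: str = "optimal",
    tuning: TuningCurve | None = None,
    grid_spacing: float = 0.05,
) -> list[WeightMatrix]:
    """Region-by-region learning over ``env.region_sequence``.

    Optimal: at stage k the delta rule is run on region-k grid locations
    only, starting from the previous matrix (earlier regions are not
    reinforced).  Hebbian: stage k adds the tuning-curve terms of field
    pairs whose later-explored field lies in region k, so entries never
    decrease.  Returns one matrix per stage.
    """
    n_regions = max(len(env.region_sequence), 1)
    full_grid = TrainingGrid.cover(env, grid_spacing)
    out: list[WeightMatrix] = []
    if method == "optimal":
        cfg = cfg or LearningConfig()
        if pattern.b_pk is None:
            raise ValueError("pattern.b_pk must be set")
        W = np.zeros((pfm.n_cells, pfm.n_cells))
        old_grids: list[TrainingGrid] = []
        for k in range(n_regions):
            sub = full_grid.restrict_to_region(env, k)
            if len(sub) == 0:
                raise ValueError(f"region {k} contains no training location")
            # New-region patterns are embedded as equalities.  Previously
            # learned locations are not re-embedded ("not reinforced"), but
            # the new learning must not overdrive them: their targets are
            # kept as one-sided bounds (a cell's drive may not exceed its
            # old embedded value; silent cells stay sub-threshold).
            locs = [g.locations for g in old_grids] + [sub.locations]
            combined = TrainingGrid(np.vstack(locs), grid_spacing)
            F, T, A = _training_set(pfm, combined, pattern, net, pattern.b_pk)
            n_old = len(combined) - len(sub)
            A[:n_old, :] = False
            wm = _solve_embedding(W.copy(), F, T, A, cfg) if cfg.solver == "lstsq" \
                else _delta_rule(W.copy(), F, T, A, cfg)
            W = wm.W
            old_grids.append(sub)
            out.append(WeightMatrix(W.copy(), "optimal", wm.report))
        return out
    if method == "hebbian":
        if tuning is None:
            raise ValueError("hebbian incremental learning needs a tuning curve")
        region = region_of_points(env, pfm.field_pos)
        N = pfm.n_cells
        stages = [np.zeros((N, N)) for _ in range(n_regions)]
        for start in range(0, pfm.n_fields, 2000):
            sl = slice(start, min(start + 2000, pfm.n_fields))
            d = cdist(pfm.field_pos[sl], pfm.field_pos)
            rows, cols = np.nonzero(d <= tuning.support)
            if len(rows) == 0:
                continue
            vals = tuning(d[rows, cols])
            stage = np.maximum(region[sl][rows], region[cols])
            for k in range(n_regions):
                m = stage == k
                if not m.any():
                    continue
                stages[k] += coo_matrix(
                    (vals[m], (pfm.field_cell[sl][rows[m]], pfm.field_cell[cols[m]])),
                    shape=(N, N),
                ).toarray()
        W = np.zeros((N, N))
        for k in range(n_regions):
            Wk = np.maximum(stages[k], 0.0)
            W = W + (Wk + Wk.T) / 2.0
            out.append(WeightMatrix(W.copy(), "hebbian"))
        return out
    raise ValueError(f"unknown method {method!r}")


def single_field_map(
    env: Environment, n_cells: int, seed: int
) -> PlaceFieldMap:
    """Map in which every cell has exactly one uniformly placed field."""
    rng = np.random.default_rng(seed)
    pos = np.column_stack(
        [rng.uniform(0, env.width, n_cells), rng.uniform(0, env.height, n_cells)]
    )
    return PlaceFieldMap(
        n_cells=n_cells,
        field_pos=pos,
        field_cell=np.arange(n_cells),
        field_rate_density=n_cells / env.area,
        seed=seed,
        env=env,
    )
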