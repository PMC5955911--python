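"""Active-set stability index and the a-priori operational-mode test.

For the threshold-linear network, the stability of a fixed point depends only
on which cells are active there — not on the external input or on the
magnitude of the state.  Writing ``S`` for the active excitatory cells and
``S_I`` for the (possibly empty) active inhibitory set, the fixed point is
stable if and only if

    r(S, S_I) = λ_max( f_pk (W - χ_{S_I} w_I 11ᵀ) D(S) ) < 1,

where λ_max is the largest real part over eigenvalues and D(S) zeroes the
columns of inactive cells.  Because zeroed columns contribute only zero
eigenvalues, r is computed on the |S|×|S| submatrix restricted to active
rows/columns.

The *operational-mode test*: with embedded active sets S̄₁, S̄₂ at two
well-separated locations and the inhibitory unit active, the network is in
the combinatorial mode (two co-stable bumps possible) iff
``r(S̄₁ ∪ S̄₂, {inh}) < 1`` and otherwise in the winner-take-all mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import PlaceFieldMap, active_bump_radius, embedded_active_set

__all__ = [
    "StabilityReport",
    "stability_index",
    "classify_mode",
    "local_active_set",
    "mode_vs_area_sweep",
    "MARGINAL_BAND",
]

#: |r - 1| below this is reported as "marginal", never classified
MARGINAL_BAND = 1e-3

#: minimum probe separation (m) for the two-bump mode test
MIN_SEPARATION = 0.5


@dataclass(frozen=True)
class StabilityReport:
    """Outcome of the operational-mode test at two probe locations."""

    r_union: float
    r_bump1: float
    r_bump2: float
    mode: str  # "WTA" | "combinatorial" | "marginal"
    set1: np.ndarray
    set2: np.ndarray

    @property
    def stable_union(self) -> bool:
        return self.r_union < 1.0

    def to_dict(self) -> dict:
        return {
            "r_union": self.r_union,
            "r_bump1": self.r_bump1,
            "r_bump2": self.r_bump2,
            "mode": self.mode,
            "n_set1": int(len(self.set1)),
            "n_set2": int(len(self.set2)),
            "n_overlap": int(len(np.intersect1d(self.set1, self.set2))),
        }


def stability_index(
    W: np.ndarray,
    w_I: float,
    f_pk: float,
    S: np.ndarray,
    inhibitory_active: bool = True,
) -> float:
    """Largest real eigenvalue part of the active-submatrix linearization.

    The fixed point with active excitatory set ``S`` (and the inhibitory unit
    active iff ``inhibitory_active``) is stable iff the returned value is
    below 1.  Independent of the external input and of the state magnitude.
    """
    S = np.asarray(S, dtype=int)
    if S.size == 0:
        return 0.0
    M = W[np.ix_(S, S)].astype(float, copy=True)
    if inhibitory_active:
        M -= w_I
    M *= f_pk
    try:
        eig = np.linalg.eigvals(M)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"eigen-solver failed on |S|={S.size} submatrix "
            f"(‖M‖∞={np.max(np.abs(M)):.3g})"
        ) from exc
    r = float(np.max(eig.real))
    if S.size < W.shape[0]:
        # the equivalent full N x N form carries a zero eigenvalue for every
        # zeroed (inactive) column
        r = max(r, 0.0)
    return r


def classify_mode(
    W: np.ndarray,
    w_I: float,
    f_pk: float,
    pfm: PlaceFieldMap,
    x1: np.ndarray,
    x2: np.ndarray,
    sigma: float,
    u0: float,
) -> StabilityReport:
    """A-priori operational-mode test at two probe locations.

    Evaluates the stability index on S̄₁ ∪ S̄₂ with the inhibitory unit
    active (it is always active at equilibrium for valid parameters), plus
    the single-bump indices r(S̄₁), r(S̄₂) for reference.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.linalg.norm(x1 - x2) < MIN_SEPARATION:
        raise ValueError(
            f"probe locations must be at least {MIN_SEPARATION} m apart"
        )
    for x in (x1, x2):
        if not pfm.env.respects_margin(x):
            raise ValueError("probe location too close to an environment boundary")
    s1 = embedded_active_set(pfm, x1, sigma, u0)
    s2 = embedded_active_set(pfm, x2, sigma, u0)
    union = np.union1d(s1, s2)
    r_union = stability_index(W, w_I, f_pk, union, inhibitory_active=True)
    r1 = stability_index(W, w_I, f_pk, s1, inhibitory_active=True)
    r2 = stability_index(W, w_I, f_pk, s2, inhibitory_active=True)
    if abs(r_union - 1.0) < MARGINAL_BAND:
        mode = "marginal"
    elif r_union < 1.0:
        mode = "combinatorial"
    else:
        mode = "WTA"
    return StabilityReport(r_union, r1, r2, mode, s1, s2)


def local_active_set(
    u: np.ndarray,
    pfm: PlaceFieldMap,
    x_k: np.ndarray,
    delta: float,
    sigma: float | None = None,
    u0: float | None = None,
    other_distance: float | None = None,
) -> np.ndarray:
    """Cells near ``x_k`` that are currently active:
    ``{i : u_i > 0 and min_m |x_k - c_im| < δ}``.

    ``δ`` must exceed the embedded-bump radius (so the whole bump is
    captured) and stay below the distance to the competing location minus
    that radius (so the other bump is excluded); the bounds are checked when
    ``sigma``/``u0``/``other_distance`` are supplied.
    """
    if sigma is not None and u0 is not None:
        R = active_bump_radius(sigma, u0)
        if delta <= R:
            raise ValueError(f"delta must exceed the bump radius R={R:.3f} m")
        if other_distance is not None and delta >= other_distance - R:
            raise ValueError("delta would capture cells of the competing bump")
    u = np.asarray(u, dtype=float)
    d = np.linalg.norm(pfm.field_pos - np.asarray(x_k, dtype=float), axis=1)
    near = np.zeros(pfm.n_cells, dtype=bool)
    near[pfm.field_cell[d < delta]] = True
    return np.flatnonzero(near & (u > 0.0))


def mode_vs_area_sweep(
    weights: list[np.ndarray],
    areas: list[float],
    w_I: float,
    f_pk: float,
    pfm: PlaceFieldMap,
    x1: np.ndarray,
    x2: np.ndarray,
    sigma: float,
    u0: float,
) -> pd.DataFrame:
    """Mode test per learning stage of an incrementally trained network.

    ``weights[k]`` is the weight matrix after learning region ``k`` and
    ``areas[k]`` the cumulative learned area.  Probe locations are fixed
    across stages.  Returns a table (area, r_union, r_bump1, r_bump2, mode).
    """
    if len(weights) != len(areas):
        raise ValueError("need one area per weight matrix")
    rows = []
    for W, area in zip(weights, areas):
        rep = classify_mode(W, w_I, f_pk, pfm, x1, x2, sigma, u0)
        rows.append(
            {
                "area": area,
                "r_union": rep.r_union,
                "r_bump1": rep.r_bump1,
                "r_bump2": rep.r_bump2,
                "mode": rep.mode,
            }
        )
    return pd.DataFrame(rows)
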