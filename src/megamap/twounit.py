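"""Analysis of the reduced 2-unit model.

Two collective threshold-linear units with self-excitation w⁰,
cross-excitation q, and shared thresholded inhibition:

    τ û₁' = -û₁ + w⁰[û₁]₊ + q[û₂]₊ - ŵ_I[[û₁]₊ + [û₂]₊ - θ]₊ + b̂₁ ,
    τ û₂' = -û₂ + q[û₁]₊ + w⁰[û₂]₊ - ŵ_I[[û₁]₊ + [û₂]₊ - θ]₊ + b̂₂ .

All fixed points are enumerated by case analysis over the 2×2×2 sign
configurations (each unit on/off × inhibition on/off): each configuration
yields a linear system whose solution is kept only if sign-consistent, and
its stability follows from the configuration's Jacobian.  Under valid
parameters the both-active fixed point is stable iff w⁰ - q < 1, which is the
winner-take-all / combinatorial dichotomy.

With net input fixed at b̂₁ + b̂₂ = b̂_pk, the qualitative dynamics fall into
four types — unique unit-1 equilibrium (I), unique unit-2 equilibrium (II),
bistable single-unit equilibria / hysteresis (III), unique both-active
equilibrium (IV) — separated by the boundary curves
q = (w⁰-1) + g(±|Δb̂|) with

    g(x) = 2x·(ŵ_I - (w⁰-1)) / (ŵ_I(1+θ) - (w⁰-1) + x).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reduction import ReducedParams, check_constraints
from .stability import stability_index

__all__ = [
    "DynamicsType",
    "FixedPoint",
    "BifurcationDiagram",
    "two_unit_rhs",
    "m_unit_rhs",
    "integrate_two_unit",
    "enumerate_fixed_points",
    "both_active_stable",
    "amplification",
    "g_function",
    "classify_dynamics",
    "detect_hysteresis",
    "bifurcation_diagram",
]

#: sign-consistency tolerance for fixed-point enumeration
SIGN_TOL = 1e-10
#: |q - boundary| below this is "marginal" in classification
BOUNDARY_TOL = 1e-6


class DynamicsType(enum.Enum):
    """Qualitative response to conflicting inputs at fixed net drive."""

    I = "unique unit-1 equilibrium"
    II = "unique unit-2 equilibrium"
    III = "bistable single-unit equilibria (hysteresis)"
    IV = "unique both-active equilibrium"


@dataclass(frozen=True)
class FixedPoint:
    u: tuple[float, float]
    active: tuple[bool, bool]
    inh_active: bool
    stable: bool
    marginal: bool = False

    @property
    def n_active(self) -> int:
        return sum(self.active)


def _reduced_W(rp: ReducedParams) -> np.ndarray:
    return np.array([[rp.w0, rp.q], [rp.q, rp.w0]])


def two_unit_rhs(
    u: np.ndarray, rp: ReducedParams, b: np.ndarray, tau: float = 10.0
) -> np.ndarray:
    """dû/dt (per ms); broadcasts over leading batch dimensions."""
    u = np.asarray(u, dtype=float)
    b = np.broadcast_to(np.asarray(b, dtype=float), u.shape)
    fp = np.maximum(u, 0.0)
    drive = fp @ _reduced_W(rp).T
    inh = np.maximum(fp.sum(axis=-1, keepdims=True) - rp.theta, 0.0)
    return (-u + drive - rp.w_I_hat * inh + b) / tau


def m_unit_rhs(
    u: np.ndarray, rp: ReducedParams, b: np.ndarray, tau: float = 10.0
) -> np.ndarray:
    """M-input generalization: each unit self-excites with w⁰ and receives q
    from every other unit, under the same shared inhibition.  Coincides with
    :func:`two_unit_rhs` at M = 2."""
    u = np.asarray(u, dtype=float)
    if u.shape[-1] < 2:
        raise ValueError("the reduced model needs at least M=2 units")
    b = np.broadcast_to(np.asarray(b, dtype=float), u.shape)
    fp = np.maximum(u, 0.0)
    total = fp.sum(axis=-1, keepdims=True)
    drive = (rp.w0 - rp.q) * fp + rp.q * total
    inh = np.maximum(total - rp.theta, 0.0)
    return (-u + drive - rp.w_I_hat * inh + b) / tau


def integrate_two_unit(
    u0: np.ndarray,
    rp: ReducedParams,
    b: np.ndarray,
    tau: float = 10.0,
    dt: float | None = None,
    T: float = 3000.0,
    tol: float = 1e-9,
    rhs=two_unit_rhs,
) -> tuple[np.ndarray, bool]:
    """Batch explicit-Euler integration to equilibrium.

    ``u0`` may be a single state (2,) or a batch (..., M).  Returns the final
    states and a flag set when every trajectory reached ‖dû/dt‖∞ < tol.
    """
    if dt is None:
        dt = tau / 20.0
    u = np.array(u0, dtype=float, copy=True)
    n_steps = int(round(T / dt))
    converged = False
    for _ in range(n_steps):
        du = rhs(u, rp, b, tau)
        u += dt * du
        if np.max(np.abs(du)) < tol:
            converged = True
            break
    return u, converged


def enumerate_fixed_points(
    rp: ReducedParams,
    b1: float,
    b2: float,
    require_valid: bool = True,
) -> list[FixedPoint]:
    """All sign-consistent fixed points, with stability per configuration.

    Solves the linear system of each of the 8 on/off configurations and keeps
    solutions whose signs match the assumed configuration.  Solutions sitting
    exactly on a threshold boundary (a nominally inactive unit at û = 0, or
    the inhibitory drive exactly at θ) are degenerate and skipped.
    Inhibition-off solutions that survive under valid parameters are
    anomalies; they are returned, not dropped.
    """
    if require_valid and not check_constraints(rp, warn=False).all_pass:
        raise ValueError("reduced parameters violate the model constraints")
    if b1 < 0 or b2 < 0:
        raise ValueError("reduced inputs must be nonnegative")
    W = _reduced_W(rp)
    b = np.array([b1, b2], dtype=float)
    found: list[FixedPoint] = []
    for a1 in (False, True):
        for a2 in (False, True):
            for inh in (False, True):
                act = np.array([a1, a2])
                A = np.flatnonzero(act)
                chi = float(inh)
                if A.size:
                    Msys = np.eye(A.size) - W[np.ix_(A, A)] + chi * rp.w_I_hat
                    rhs_vec = b[A] + chi * rp.w_I_hat * rp.theta
                    try:
                        uA = np.linalg.solve(Msys, rhs_vec)
                    except np.linalg.LinAlgError:
                        continue
                else:
                    uA = np.zeros(0)
                s = float(uA.sum())
                u = np.empty(2)
                u[A] = uA
                inactive = np.flatnonzero(~act)
                u[inactive] = (
                    W[np.ix_(inactive, A)] @ uA
                    - chi * rp.w_I_hat * (s - rp.theta)
                    + b[inactive]
                )
                # sign consistency (strict, with boundary cases degenerate)
                if np.any(np.abs(u[A]) <= SIGN_TOL) or np.any(
                    np.abs(u[inactive]) <= SIGN_TOL
                ):
                    continue
                if np.any(u[A] < 0) or np.any(u[inactive] > 0):
                    continue
                gap = s - rp.theta
                if abs(gap) <= SIGN_TOL:
                    continue
                if inh != (gap > 0):
                    continue
                r = stability_index(W, rp.w_I_hat, 1.0, A, inhibitory_active=inh)
                found.append(
                    FixedPoint(
                        u=(float(u[0]), float(u[1])),
                        active=(a1, a2),
                        inh_active=inh,
                        stable=r < 1.0,
                        marginal=abs(r - 1.0) < 1e-9,
                    )
                )
    return found


def both_active_stable(rp: ReducedParams, marginal_tol: float = 1e-12) -> bool:
    """Stability of the both-active configuration: w⁰ - q < 1.

    Equivalent to both Jacobian eigenvalues (w⁰-q-1)/τ and
    (w⁰+q-2ŵ_I-1)/τ being negative under the parameter constraints.
    Raises for the marginal case w⁰ - q = 1 (to within ``marginal_tol``).
    """
    d = rp.w0 - rp.q
    if abs(d - 1.0) < marginal_tol:
        raise ArithmeticError("marginal: w0 - q = 1 within tolerance")
    return d < 1.0


def both_active_eigenvalues(rp: ReducedParams, tau: float = 10.0) -> tuple[float, float]:
    """Jacobian eigenvalues of the both-active, inhibition-on configuration."""
    return (rp.w0 - rp.q - 1.0) / tau, (rp.w0 + rp.q - 2.0 * rp.w_I_hat - 1.0) / tau


def amplification(rp: ReducedParams, b1: float, b2: float) -> float:
    """State difference at the both-active fixed point:
    û₁ - û₂ = (b̂₁ - b̂₂)/(q - (w⁰ - 1)).  Valid in the combinatorial mode only."""
    denom = rp.q - (rp.w0 - 1.0)
    if denom <= 0:
        raise ValueError(
            "amplification is defined only in the combinatorial mode (q > w0 - 1)"
        )
    return (b1 - b2) / denom


def g_function(x: float, rp: ReducedParams) -> float:
    """Bifurcation function g(x); strictly increasing on [-b̂_pk, b̂_pk], g(0)=0."""
    if abs(x) > rp.b_pk_hat + 1e-12:
        raise ValueError("x outside the admissible input-difference range")
    denom = rp.w_I_hat * (1.0 + rp.theta) - (rp.w0 - 1.0) + x
    if denom <= 0:
        raise ValueError("g-function denominator non-positive: invalid parameters")
    return 2.0 * x * (rp.w_I_hat - (rp.w0 - 1.0)) / denom


def classify_dynamics(
    rp: ReducedParams, db: float, boundary_tol: float = BOUNDARY_TOL
) -> DynamicsType | None:
    """Dynamics type at input difference Δb̂ with net input fixed at b̂_pk.

    Type III (hysteresis) iff q < (w⁰-1) + g(-|Δb̂|); Type IV (two co-stable
    bumps) iff q > (w⁰-1) + g(|Δb̂|); otherwise the stronger input wins
    (I for Δb̂ > 0, II for Δb̂ < 0).  Returns ``None`` within
    ``boundary_tol`` of a boundary ("marginal", never classified).
    """
    if abs(db) > rp.b_pk_hat + 1e-12:
        raise ValueError("Δb̂ outside [-b̂_pk, b̂_pk]")
    lo = (rp.w0 - 1.0) + g_function(-abs(db), rp)
    hi = (rp.w0 - 1.0) + g_function(abs(db), rp)
    if abs(rp.q - lo) < boundary_tol or abs(rp.q - hi) < boundary_tol:
        return None
    if rp.q < lo:
        return DynamicsType.III
    if rp.q > hi:
        return DynamicsType.IV
    return DynamicsType.I if db > 0 else DynamicsType.II


def detect_hysteresis(
    rp: ReducedParams, b1: float, b2: float, tau: float = 10.0
) -> bool:
    """True iff the equilibrium depends on the initial state.

    Integrates from the two desired patterns (1,0) and (0,1) and compares the
    active configurations of the equilibria reached.  Consistency with the
    enumeration (exactly two stable single-unit fixed points) is asserted in
    the test suite rather than here.
    """
    b = np.array([b1, b2])
    u_init = np.array([[1.0, 0.0], [0.0, 1.0]])
    u_fin, ok = integrate_two_unit(u_init, rp, b, tau=tau)
    if not ok:
        raise RuntimeError("two-unit integration did not converge")
    cfg = u_fin > 0.0
    return bool(np.any(cfg[0] != cfg[1]))


@dataclass
class BifurcationDiagram:
    """Grid classification over (Δb̂, q) plus analytic boundary curves."""

    table: pd.DataFrame  # columns: db, q, type, type_sim (may be None)
    boundary_db: np.ndarray
    boundary_lower: np.ndarray  # q = (w0-1) + g(-|db|)
    boundary_upper: np.ndarray  # q = (w0-1) + g(+|db|)
    agreement: float  # simulated vs analytic, off-boundary points


def _simulate_type(
    rp_q: ReducedParams,
    dbs: np.ndarray,
    tau: float = 10.0,
    T: float = 6000.0,
) -> list[DynamicsType]:
    """Protocol for one q-row: start each run from the desired pattern of the
    weaker-input unit; classify by which units are active at the end.

    Near a bifurcation boundary the relaxation is arbitrarily slow, so the
    run is classified from the final state regardless of whether the
    residual tolerance was met; such points sit inside the boundary band
    that the agreement statistic excludes anyway.
    """
    b_pk = rp_q.b_pk_hat
    b = np.column_stack([(b_pk + dbs) / 2.0, (b_pk - dbs) / 2.0])
    init = np.where(dbs[:, None] >= 0, [0.0, 1.0], [1.0, 0.0])
    uf, _ = integrate_two_unit(init, rp_q, b, tau=tau, T=T, tol=1e-9)
    out = []
    for i in range(len(dbs)):
        act = uf[i] > 0.0
        weaker = 1 if dbs[i] >= 0 else 0
        stronger = 1 - weaker
        if act[0] and act[1]:
            out.append(DynamicsType.IV)
        elif act[stronger]:
            out.append(DynamicsType.I if stronger == 0 else DynamicsType.II)
        elif act[weaker]:
            out.append(DynamicsType.III)
        else:
            raise RuntimeError("all-silent equilibrium under valid constraints")
    return out


def bifurcation_diagram(
    rp: ReducedParams,
    q_steps: int = 25,
    db_steps: int = 25,
    simulate: bool = True,
    tau: float = 10.0,
    boundary_tol: float = 1e-3,
) -> BifurcationDiagram:
    """Classify a (Δb̂, q) grid analytically and (optionally) by simulation.

    The q-range is [0, ŵ_I(1-θ)) and Δb̂ spans [-b̂_pk, b̂_pk]; at every grid
    point the parameters are rebalanced so that b̂_pk stays fixed by the
    training constraint.  ``agreement`` is the fraction of points, at least
    ``boundary_tol`` away from a boundary curve in q, where simulation and
    analysis give the same type.
    """
    if q_steps < 2 or db_steps < 2:
        raise ValueError("need at least 2 steps per axis")
    qs = np.linspace(0.0, rp.q_max * (1.0 - 1e-9), q_steps, endpoint=False)
    dbs = np.linspace(-rp.b_pk_hat, rp.b_pk_hat, db_steps)
    rows = []
    sim_all: list[DynamicsType] = []
    for q in qs:
        rp_q = ReducedParams(rp.w0, float(q), rp.w_I_hat, rp.theta, rp.b_pk_hat)
        for db in dbs:
            t = classify_dynamics(rp_q, float(db))
            rows.append({"db": float(db), "q": float(q), "type": t})
        if simulate:
            sim_all.extend(_simulate_type(rp_q, dbs, tau=tau))
    df = pd.DataFrame(rows)
    agreement = float("nan")
    if simulate:
        df["type_sim"] = sim_all
        lo = np.array([(rp.w0 - 1.0) + g_function(-abs(d), rp) for d in df["db"]])
        hi = np.array([(rp.w0 - 1.0) + g_function(abs(d), rp) for d in df["db"]])
        off = (
            (np.abs(df["q"].to_numpy() - lo) > boundary_tol)
            & (np.abs(df["q"].to_numpy() - hi) > boundary_tol)
            & df["type"].notna().to_numpy()
        )
        match = df["type"].to_numpy() == df["type_sim"].to_numpy()
        agreement = float(np.mean(match[off])) if off.any() else float("nan")
    bd_db = np.linspace(-rp.b_pk_hat, rp.b_pk_hat, 201)
    bd_lo = np.array([(rp.w0 - 1.0) + g_function(-abs(d), rp) for d in bd_db])
    bd_hi = np.array([(rp.w0 - 1.0) + g_function(abs(d), rp) for d in bd_db])
    return BifurcationDiagram(df, bd_db, bd_lo, bd_hi, agreement)
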