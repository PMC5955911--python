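"""Firing-rate dynamics of the full place-cell network.

The state ``u ∈ R^N`` (dimensionless depolarization) evolves as

    τ u'(t) = -u(t) + W f(u(t)) - w_I f_I(u(t)) 1 + b,

with threshold-linear activation ``f(u) = f_pk [u]₊`` (Hz) and a single
*instantaneous* global inhibitory unit

    f_I(u) = [1ᵀ f(u) - θ f̄_net]₊ ,

whose activity is recomputed from ``u`` at every evaluation (it carries no
state of its own — the inhibitory time constant is assumed negligible).
Integration is explicit Euler with a fixed step; the piecewise-linear
right-hand side is smooth away from threshold crossings, and step-size
robustness is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkParams",
    "Trajectory",
    "activation",
    "inhibitory_activity",
    "rhs",
    "integrate",
    "find_equilibrium",
    "InstabilityError",
]

#: divergence guard on ‖u‖∞
OVERFLOW_GUARD = 1e6


class InstabilityError(RuntimeError):
    """Raised when the state grows beyond the overflow guard."""


@dataclass(frozen=True)
class NetworkParams:
    """Global parameters of the rate network.

    tau    : membrane time constant, ms
    f_pk   : peak firing rate of an activity bump, Hz
    w_I    : inhibitory weight (dimensionless, ≥ 0)
    theta  : inhibitory threshold as a fraction of f̄_net, in (0, 1)
    f_net  : net embedded activity Σ_i f̄_i(x), Hz (location independent)
    """

    tau: float = 10.0
    f_pk: float = 15.0
    w_I: float = 0.0
    theta: float = 0.9
    f_net: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.f_pk <= 0:
            raise ValueError("tau and f_pk must be positive")
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie in (0, 1)")
        if self.w_I < 0:
            raise ValueError("w_I must be nonnegative")


def activation(u: np.ndarray, f_pk: float) -> np.ndarray:
    """Threshold-linear activity ``f(u) = f_pk·[u]₊`` in Hz."""
    return f_pk * np.maximum(u, 0.0)


def inhibitory_activity(f_vec: np.ndarray, theta: float, f_net: float) -> float:
    """Activity of the global inhibitory unit, ``[Σ_i f_i - θ·f̄_net]₊``."""
    return max(float(np.sum(f_vec)) - theta * f_net, 0.0)


def rhs(
    u: np.ndarray,
    W: np.ndarray,
    params: NetworkParams,
    b: np.ndarray,
) -> np.ndarray:
    """du/dt (per ms) for the rate equation."""
    u = np.asarray(u, dtype=float)
    b = np.asarray(b, dtype=float)
    if W.shape != (u.size, u.size) or b.shape != u.shape:
        raise ValueError(
            f"shape mismatch: u {u.shape}, W {W.shape}, b {b.shape}"
        )
    f = activation(u, params.f_pk)
    f_I = inhibitory_activity(f, params.theta, params.f_net)
    return (-u + W @ f - params.w_I * f_I + b) / params.tau


@dataclass
class Trajectory:
    """Sampled states of an integration run."""

    t: np.ndarray  # (T,) ms
    u: np.ndarray  # (T, N)
    converged: bool  # ‖du/dt‖∞ fell below tol at the final sample
    final_residual: float


def integrate(
    u0: np.ndarray,
    W: np.ndarray,
    params: NetworkParams,
    b: np.ndarray,
    dt: float | None = None,
    T: float = 2000.0,
    tol: float = 1e-6,
    sample_every: int = 1,
) -> Trajectory:
    """Explicit-Euler integration for ``T`` ms with step ``dt`` (default τ/20).

    Stops early once ‖du/dt‖∞ < ``tol`` (per ms).  Raises
    :class:`InstabilityError` if ‖u‖∞ exceeds the overflow guard, which
    happens when the training constraints on the weights are violated.
    """
    if dt is None:
        dt = params.tau / 20.0
    if dt > params.tau / 10.0:
        raise ValueError("dt must be at most tau/10 for a stable explicit step")
    u = np.asarray(u0, dtype=float).copy()
    n_steps = int(round(T / dt))
    ts, us = [0.0], [u.copy()]
    converged = False
    res = np.inf
    for k in range(1, n_steps + 1):
        du = rhs(u, W, params, b)
        u += dt * du
        if np.max(np.abs(u)) > OVERFLOW_GUARD:
            raise InstabilityError(
                f"state diverged at t={k * dt:.1f} ms (‖u‖∞ > {OVERFLOW_GUARD:g}); "
                "check the weight-training constraints"
            )
        if k % sample_every == 0 or k == n_steps:
            ts.append(k * dt)
            us.append(u.copy())
        res = float(np.max(np.abs(du)))
        if res < tol:
            converged = True
            if ts[-1] != k * dt:
                ts.append(k * dt)
                us.append(u.copy())
            break
    return Trajectory(np.array(ts), np.array(us), converged, res)


def find_equilibrium(
    u0: np.ndarray,
    W: np.ndarray,
    params: NetworkParams,
    b: np.ndarray,
    tol: float = 1e-6,
    T_max: float = 2000.0,
    dt: float | None = None,
) -> tuple[np.ndarray, bool]:
    """Integrate until ‖du/dt‖∞ < ``tol`` or ``T_max`` ms.

    Returns the final state and a flag reporting whether the tolerance was
    met (non-convergence is an outcome, not an exception).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    traj = integrate(u0, W, params, b, dt=dt, T=T_max, tol=tol, sample_every=10**9)
    return traj.u[-1], traj.converged
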