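"""Exact linear reduction of the full network to the 2-unit model.

Summing the rate equation over the embedded active sets S̄₁, S̄₂ of two
well-separated locations and scaling by ``f_pk/f̄_net`` collapses the
N-dimensional system onto two collective units with

    û_k = (f_pk/f̄_net) Σ_{i∈S̄_k} u_i ,      b̂_k = (f_pk/f̄_net) Σ_{i∈S̄_k} b_i ,
    w⁰  = (f_pk/f̄_net) Σ_{i,j∈S̄₁} w_ij f̄_j(x₁) ,
    q   = (f_pk/N̄) Σ_{i∈S̄₁, j∈S̄₂} w_ij ,     ŵ_I = f_pk·N̄·w_I ,

with N̄ the mean active-set size.  The reduction neglects (1) cells shared by
both sets, (2) multi-field cells within one set, (3) the directed asymmetry
of q, and (4) changes of bump radius; the first three are accounted for in
the validity report.

A valid parameterization must satisfy:
  1. 0 < θ < 1                      (inhibition on at a pattern, off at rest)
  2. 0 < b̂_pk ≪ 1                  (training input much weaker than the state)
  3. w⁰ > 1                          (single bumps self-sustain without input)
  4. q < ŵ_I(1-θ)                   (training patterns remain fixed points)
and the training-strength balance  1 = w⁰ - ŵ_I(1-θ) + b̂_pk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .environment import PlaceFieldMap, embedded_active_set, embedded_pattern

__all__ = [
    "ReducedParams",
    "ReductionReport",
    "balanced_input_strength",
    "reduce_weights",
    "reduce_inhibition",
    "reduce_input",
    "reduce_state",
    "check_constraints",
    "reduce_megamap",
]


def balanced_input_strength(w0: float, w_I_hat: float, theta: float) -> float:
    """Training strength b̂_pk fixed by the balance 1 = w⁰ - ŵ_I(1-θ) + b̂_pk."""
    return 1.0 - w0 + w_I_hat * (1.0 - theta)


@dataclass(frozen=True)
class ReducedParams:
    """Complete parameterization of the 2-unit model."""

    w0: float
    q: float
    w_I_hat: float
    theta: float
    b_pk_hat: float
    n_bar: float = float("nan")

    @classmethod
    def balanced(
        cls, w0: float, w_I_hat: float, theta: float, q: float, n_bar: float = float("nan")
    ) -> "ReducedParams":
        """Parameters with b̂_pk set by the training-strength balance."""
        return cls(w0, q, w_I_hat, theta, balanced_input_strength(w0, w_I_hat, theta), n_bar)

    @property
    def q_max(self) -> float:
        """Upper limit of admissible cross-excitation, ŵ_I(1-θ)."""
        return self.w_I_hat * (1.0 - self.theta)


@dataclass
class ReductionReport:
    """Per-constraint verdicts plus reduction-validity diagnostics."""

    constraints: dict[str, bool]
    margins: dict[str, float]
    balance_residual: float
    overlap_fraction: float = 0.0
    q_asymmetry: float = 0.0
    valid: bool = True

    @property
    def all_pass(self) -> bool:
        return all(self.constraints.values())


def check_constraints(rp: ReducedParams, warn: bool = True) -> ReductionReport:
    """Evaluate the four parameter constraints and the balance residual."""
    c = {
        "theta_in_(0,1)": 0.0 < rp.theta < 1.0,
        "b_pk_small": 0.0 < rp.b_pk_hat < 1.0,
        "w0_gt_1": rp.w0 > 1.0,
        "q_lt_wIhat(1-theta)": rp.q < rp.q_max,
    }
    m = {
        "theta_in_(0,1)": min(rp.theta, 1.0 - rp.theta),
        "b_pk_small": min(rp.b_pk_hat, 1.0 - rp.b_pk_hat),
        "w0_gt_1": rp.w0 - 1.0,
        "q_lt_wIhat(1-theta)": rp.q_max - rp.q,
    }
    resid = abs(1.0 - (rp.w0 - rp.w_I_hat * (1.0 - rp.theta) + rp.b_pk_hat))
    rep = ReductionReport(c, m, resid)
    if warn and rp.b_pk_hat > 0.2:
        warnings.warn(
            f"b_pk_hat={rp.b_pk_hat:.3g} is large; the training input is "
            "not much weaker than the state",
            stacklevel=2,
        )
    return rep


def _disjoint_sets(
    pfm: PlaceFieldMap, s1: np.ndarray, s2: np.ndarray, x1: np.ndarray, x2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Assign cells in both sets to the nearer location; report the overlap."""
    shared = np.intersect1d(s1, s2)
    if shared.size == 0:
        return s1, s2, 0.0
    d1 = np.empty(shared.size)
    d2 = np.empty(shared.size)
    for a, i in enumerate(shared):
        c = pfm.centers(i)
        d1[a] = np.min(np.linalg.norm(c - x1, axis=1))
        d2[a] = np.min(np.linalg.norm(c - x2, axis=1))
    to1 = shared[d1 <= d2]
    to2 = shared[d1 > d2]
    s1d = np.setdiff1d(s1, to2)
    s2d = np.setdiff1d(s2, to1)
    n_bar = (len(s1) + len(s2)) / 2.0
    return s1d, s2d, float(shared.size / n_bar)


def reduce_weights(
    W: np.ndarray,
    pfm: PlaceFieldMap,
    x1: np.ndarray,
    x2: np.ndarray,
    sigma: float,
    u0: float,
    f_pk: float,
    f_net: float,
) -> tuple[float, float, dict]:
    """Reduced self- and cross-excitation (w⁰, q) at two probe locations.

    w⁰ is the average of the two per-location double sums; q is the
    symmetrized average of the two directed sums, with the directed values
    and the overlap fraction retained in the diagnostics dict.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    s1 = embedded_active_set(pfm, x1, sigma, u0)
    s2 = embedded_active_set(pfm, x2, sigma, u0)
    if s1.size == 0 or s2.size == 0:
        raise ValueError("empty embedded active set at a probe location")
    s1d, s2d, overlap = _disjoint_sets(pfm, s1, s2, x1, x2)
    n_bar = (len(s1d) + len(s2d)) / 2.0

    w0_vals = []
    for s, x in ((s1d, x1), (s2d, x2)):
        # the pattern the network actually embeds: normalized to f_net
        fbar = embedded_pattern(pfm, x, sigma, u0, f_pk, f_net)
        w0_vals.append(
            f_pk / f_net * float(np.sum(W[np.ix_(s, s)] * fbar[s][None, :]))
        )
    q12 = f_pk / n_bar * float(np.sum(W[np.ix_(s1d, s2d)]))  # drive 2 -> 1
    q21 = f_pk / n_bar * float(np.sum(W[np.ix_(s2d, s1d)]))  # drive 1 -> 2
    q = 0.5 * (q12 + q21)
    diag = {
        "w0_per_location": tuple(w0_vals),
        "q_directed": (q12, q21),
        "q_asymmetry": abs(q12 - q21) / abs(q) if q != 0 else 0.0,
        "overlap_fraction": overlap,
        "n_bar": n_bar,
    }
    return float(np.mean(w0_vals)), q, diag


def reduce_inhibition(w_I: float, f_pk: float, n_bar: float) -> float:
    """Reduced inhibitory weight ŵ_I = f_pk·N̄·w_I."""
    return f_pk * n_bar * w_I


def reduce_input(
    b: np.ndarray, s_k: np.ndarray, f_pk: float, f_net: float
) -> float:
    """Reduced input b̂_k = (f_pk/f̄_net)·Σ_{i∈S̄_k} b_i."""
    return f_pk / f_net * float(np.sum(np.asarray(b, dtype=float)[s_k]))


def reduce_state(
    u: np.ndarray, s_k: np.ndarray, f_pk: float, f_net: float
) -> float:
    """Reduced state û_k = (f_pk/f̄_net)·Σ_{i∈S̄_k} u_i.

    For a bump state proportional to the embedded pattern with peak u_pk,
    this evaluates to ≈ u_pk.
    """
    return f_pk / f_net * float(np.sum(np.asarray(u, dtype=float)[s_k]))


def reduce_megamap(
    W: np.ndarray,
    pfm: PlaceFieldMap,
    x1: np.ndarray,
    x2: np.ndarray,
    sigma: float,
    u0: float,
    f_pk: float,
    f_net: float,
    w_I: float,
    theta: float,
) -> tuple[ReducedParams, ReductionReport]:
    """Full reduction at two probes: parameters plus a validity report.

    Validity requires overlap < 5% of N̄ and directed-q asymmetry < 10%;
    beyond those bounds the report downgrades confidence but the parameters
    are still returned.
    """
    w0, q, diag = reduce_weights(W, pfm, x1, x2, sigma, u0, f_pk, f_net)
    n_bar = diag["n_bar"]
    w_I_hat = reduce_inhibition(w_I, f_pk, n_bar)
    rp = ReducedParams.balanced(w0, w_I_hat, theta, q, n_bar)
    rep = check_constraints(rp, warn=False)
    rep.overlap_fraction = diag["overlap_fraction"]
    rep.q_asymmetry = diag["q_asymmetry"]
    rep.valid = (
        rep.all_pass
        and rep.overlap_fraction < 0.05
        and rep.q_asymmetry < 0.10
    )
    return rp, rep
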