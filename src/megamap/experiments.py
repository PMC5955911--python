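"""Conflicting-input experiments on trained networks, and regime fixtures.

The protocols mirror the standard probes of an attractor network's response
to two competing location cues:

* **conflicting input** — a weighted mixture of the two training inputs,
  ``b = (1/b̄_pk)(b¹_pk·b̄(x₁) + b²_pk·b̄(x₂))``, or a random 50/50 split in
  which each cell receives exactly one location's input;
* **activity ratio** — how completely the equilibrium expresses the bump at
  x_k, relative to the equilibrium under that location's isolated input;
* **conflict sweep** — activity ratios across relative input strengths, with
  the 2-unit model's prediction computed side by side;
* **hysteresis probe** — random initial bump mixtures at equal input
  strength; the number of distinct equilibria distinguishes winner-take-all
  (two) from combinatorial (one).

``make_fixture`` builds small deterministic networks verified to sit in a
named regime.  The combinatorial fixture reaches its regime by raising the
place-field density (extra shared fields raise the cross-excitation q, which
is what controls the mode) rather than by growing the environment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import NetworkParams, find_equilibrium
from .environment import (
    Environment,
    PatternParams,
    PlaceFieldMap,
    TrainingGrid,
    default_input_strength,
    desired_activity,
    embedded_active_set,
    net_activity_constant,
    training_input,
)
from .learning import LearningConfig, WeightMatrix, learn_optimal_weights
from .reduction import balanced_input_strength, reduce_megamap, reduce_state
from .stability import StabilityReport, classify_mode
from .twounit import integrate_two_unit

__all__ = [
    "ConflictProtocol",
    "MegamapBundle",
    "FixtureRegimeError",
    "build_conflicting_input",
    "activity_ratio",
    "run_conflict_sweep",
    "run_hysteresis_probe",
    "make_fixture",
    "save_bundle",
    "load_bundle",
]


@dataclass(frozen=True)
class ConflictProtocol:
    """Two probe locations plus the input-mixture rule.

    ``mixture`` is either ``("weighted", b1_pk, b2_pk)`` or
    ``("split_50_50", stream_seed)`` — the random half-and-half assignment
    uses its own seed, separate from the field-map seed.
    """

    x1: tuple[float, float]
    x2: tuple[float, float]
    mixture: tuple

    def __post_init__(self) -> None:
        sep = np.linalg.norm(np.subtract(self.x1, self.x2))
        if sep < 0.5:
            raise ValueError("probe locations must be at least 0.5 m apart")
        kind = self.mixture[0]
        if kind == "weighted":
            if len(self.mixture) != 3 or min(self.mixture[1:]) < 0:
                raise ValueError("weighted mixture needs two nonnegative strengths")
        elif kind != "split_50_50":
            raise ValueError(f"unknown mixture kind {kind!r}")


@dataclass
class MegamapBundle:
    """A trained network with everything needed to probe it."""

    name: str
    pfm: PlaceFieldMap
    pattern: PatternParams  # with b_pk resolved
    net: NetworkParams
    wm: WeightMatrix
    probes: tuple[tuple[float, float], tuple[float, float]]
    report: StabilityReport
    meta: dict = field(default_factory=dict)

    @property
    def env(self) -> Environment:
        return self.pfm.env

    @property
    def expected_mode(self) -> str:
        return self.report.mode


class FixtureRegimeError(RuntimeError):
    """A generated fixture failed its regime verification."""


def build_conflicting_input(
    pfm: PlaceFieldMap,
    protocol: ConflictProtocol,
    b_pk: float,
    sigma: float,
) -> np.ndarray:
    """External input mixing the two locations' training inputs.

    Weighted variant: ``(1/b̄_pk)(b¹_pk·b̄(x₁) + b²_pk·b̄(x₂))``.  Split
    variant: each cell receives exactly one location's full training input,
    chosen 50/50 at random with the protocol's stream seed.
    """
    b1 = training_input(pfm, np.asarray(protocol.x1), b_pk, sigma)
    b2 = training_input(pfm, np.asarray(protocol.x2), b_pk, sigma)
    kind = protocol.mixture[0]
    if kind == "weighted":
        _, s1, s2 = protocol.mixture
        return (s1 * b1 + s2 * b2) / b_pk
    rng = np.random.default_rng(protocol.mixture[1])
    take1 = rng.random(pfm.n_cells) < 0.5
    return np.where(take1, b1, b2)


def activity_ratio(
    u_eq: np.ndarray,
    s_eq: np.ndarray,
    s_k: np.ndarray,
    f_pk: float,
) -> float | None:
    """Bump completeness ``Σ_{i∈S̄_k} f(u_i) / Σ_{i∈S̄_k} f(s_i)``.

    ``s_eq`` is the equilibrium under the isolated input for location k.
    Returns ``None`` (omitted point) when the isolated run produced no bump
    over the set — the ratio is then undefined, not zero.
    """
    denom = float(np.sum(np.maximum(s_eq[s_k], 0.0)))
    if denom <= 0.0:
        return None
    num = float(np.sum(np.maximum(u_eq[s_k], 0.0)))
    return num / denom


def run_conflict_sweep(
    bundle: MegamapBundle,
    n_points: int = 9,
    tol: float = 1e-6,
    T_max: float = 2000.0,
) -> pd.DataFrame:
    """Activity ratios across relative input strengths, with the reduced
    model's prediction side by side.

    Sweeps ``(b¹_pk, b²_pk)`` along ``b¹_pk + b²_pk = b̄_pk``.  Full-model
    runs start from the embedded pattern at x₂ (the weaker-then-stronger
    convention of the conflicting-input protocol); the reduced model is
    integrated from (0, 1) with the reduced inputs of the same mixture.
    """
    pfm, pat, net = bundle.pfm, bundle.pattern, bundle.net
    x1, x2 = map(np.asarray, bundle.probes)
    s1 = embedded_active_set(pfm, x1, pat.sigma, pat.u0)
    s2 = embedded_active_set(pfm, x2, pat.sigma, pat.u0)
    rp, _ = reduce_megamap(
        bundle.wm.W, pfm, x1, x2, pat.sigma, pat.u0,
        pat.f_pk, net.f_net, net.w_I, net.theta,
    )
    u_init = desired_activity(pfm, x2, pat.sigma, pat.u0, pat.f_pk) / pat.f_pk
    fractions = np.linspace(0.0, 1.0, n_points)
    rows = []
    for frac in fractions:
        bp1, bp2 = frac * pat.b_pk, (1.0 - frac) * pat.b_pk
        proto = ConflictProtocol(tuple(x1), tuple(x2), ("weighted", bp1, bp2))
        b = build_conflicting_input(pfm, proto, pat.b_pk, pat.sigma)
        u_eq, ok = find_equilibrium(u_init, bundle.wm.W, net, b, tol=tol, T_max=T_max)
        ratios = []
        for bp, x, s in ((bp1, x1, s1), (bp2, x2, s2)):
            b_iso = (bp / pat.b_pk) * training_input(pfm, x, pat.b_pk, pat.sigma)
            s_init = desired_activity(pfm, x, pat.sigma, pat.u0, pat.f_pk) / pat.f_pk
            s_eq, _ = find_equilibrium(
                s_init, bundle.wm.W, net, b_iso, tol=tol, T_max=T_max
            )
            ratios.append(activity_ratio(u_eq, s_eq, s, pat.f_pk))
        # reduced-model prediction from the same mixture
        b_hat = rp.b_pk_hat * np.array([frac, 1.0 - frac])
        u_hat, _ = integrate_two_unit(np.array([0.0, 1.0]), rp, b_hat, tau=net.tau)
        rows.append(
            {
                "b1_pk": bp1,
                "b2_pk": bp2,
                "act1": ratios[0],
                "act2": ratios[1],
                "u_hat1": max(u_hat[0], 0.0),
                "u_hat2": max(u_hat[1], 0.0),
                "converged": ok,
            }
        )
    return pd.DataFrame(rows)


def run_hysteresis_probe(
    bundle: MegamapBundle,
    n_initial_states: int = 8,
    seed: int = 0,
    cluster_tol: float = 0.1,
) -> pd.DataFrame:
    """Equilibria reached from random initial bump mixtures at equal inputs.

    Initial states are random nonnegative combinations of the two embedded
    patterns; the input is the equal-strength mixture (b̄_pk/2 each).
    Returns one row per run with the reduced coordinates of the equilibrium
    and a cluster label; the number of clusters is the number of distinct
    equilibria (2 in the winner-take-all regime, 1 in the combinatorial).
    """
    pfm, pat, net = bundle.pfm, bundle.pattern, bundle.net
    x1, x2 = map(np.asarray, bundle.probes)
    s1 = embedded_active_set(pfm, x1, pat.sigma, pat.u0)
    s2 = embedded_active_set(pfm, x2, pat.sigma, pat.u0)
    f1 = desired_activity(pfm, x1, pat.sigma, pat.u0, pat.f_pk) / pat.f_pk
    f2 = desired_activity(pfm, x2, pat.sigma, pat.u0, pat.f_pk) / pat.f_pk
    proto = ConflictProtocol(
        tuple(x1), tuple(x2), ("weighted", pat.b_pk / 2.0, pat.b_pk / 2.0)
    )
    b = build_conflicting_input(pfm, proto, pat.b_pk, pat.sigma)
    rng = np.random.default_rng(seed)
    rows = []
    centers: list[np.ndarray] = []
    for _ in range(n_initial_states):
        c1, c2 = rng.uniform(0.0, 1.2, size=2)
        u0 = c1 * f1 + c2 * f2
        u_eq, ok = find_equilibrium(u0, bundle.wm.W, net, b)
        coords = np.array(
            [
                reduce_state(u_eq, s1, pat.f_pk, net.f_net),
                reduce_state(u_eq, s2, pat.f_pk, net.f_net),
            ]
        )
        label = None
        for k, c in enumerate(centers):
            if np.max(np.abs(coords - c)) < cluster_tol:
                label = k
                break
        if label is None:
            label = len(centers)
            centers.append(coords)
        rows.append(
            {
                "c1": c1,
                "c2": c2,
                "u_hat1": coords[0],
                "u_hat2": coords[1],
                "cluster": label,
                "converged": ok,
            }
        )
    return pd.DataFrame(rows)


_FIXTURE_SPECS = {
    # (env side, n_cells, silent fraction in 1 m² [wta] or fields/m² [comb])
    "wta_small": dict(side=2.0, n_cells=2500, lam=0.18),
    "comb_small": dict(side=2.0, n_cells=1000, lam=2.2),
    "single_field": dict(side=1.6, n_cells=700, lam=None),
}


def make_fixture(
    name: str,
    seed: int = 0,
    grid_spacing: float = 0.1,
    w0_nominal: float = 1.2,
    w_I_hat: float = 5.3,
    theta: float = 0.9,
    cfg: LearningConfig | None = None,
    verify: bool = True,
) -> MegamapBundle:
    """Deterministic small trained network in a named regime.

    ``wta_small`` uses a sparse field map (mostly single-field cells: little
    cross-excitation, winner-take-all).  ``comb_small`` uses a dense map
    (several fields per cell: the shared fields raise q into the
    combinatorial regime).  ``single_field`` gives every cell exactly one
    field.  The regime is verified with the operational-mode test; a
    mismatch raises :class:`FixtureRegimeError` rather than shipping a
    mislabeled fixture.
    """
    if name not in _FIXTURE_SPECS:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_SPECS)}")
    recipe = _FIXTURE_SPECS[name]
    side = recipe["side"]
    env = Environment(side, side)
    if name == "single_field":
        from .learning import single_field_map

        pfm = single_field_map(env, recipe["n_cells"], seed)
    else:
        from .environment import sample_place_fields

        pfm = sample_place_fields(env, recipe["n_cells"], recipe["lam"], seed)
    pat0 = PatternParams()
    grid = TrainingGrid.cover(env, grid_spacing)
    f_net, cv = net_activity_constant(pfm, grid, pat0.sigma, pat0.u0, pat0.f_pk)
    x1 = (side / 2.0 - 0.35, side / 2.0)
    x2 = (side / 2.0 + 0.35, side / 2.0)
    s_sizes = [
        len(embedded_active_set(pfm, np.asarray(x), pat0.sigma, pat0.u0))
        for x in (x1, x2)
    ]
    n_bar = float(np.mean(s_sizes))
    if min(s_sizes) < 5:
        raise FixtureRegimeError(
            f"{name}: embedded active sets too small ({s_sizes}); "
            "increase n_cells or field density"
        )
    b_hat_pk = balanced_input_strength(w0_nominal, w_I_hat, theta)
    b_pk = default_input_strength(
        b_hat_pk, f_net, pat0.f_pk, n_bar, pat0.sigma, pat0.u0
    )
    # refine the analytic calibration against this particular map: the
    # reduced training input at the probes should equal b_hat_pk
    from .reduction import reduce_input

    measured = []
    for x in (x1, x2):
        xa = np.asarray(x)
        s_k = embedded_active_set(pfm, xa, pat0.sigma, pat0.u0)
        bvec = training_input(pfm, xa, b_pk, pat0.sigma)
        measured.append(reduce_input(bvec, s_k, pat0.f_pk, f_net))
    b_pk *= b_hat_pk / float(np.mean(measured))
    pattern = PatternParams(pat0.sigma, pat0.u0, pat0.f_pk, b_pk)
    net = NetworkParams(
        f_pk=pattern.f_pk,
        w_I=w_I_hat / (pattern.f_pk * n_bar),
        theta=theta,
        f_net=f_net,
    )
    wm = learn_optimal_weights(pfm, grid, pattern, net, cfg)
    report = classify_mode(
        wm.W, net.w_I, net.f_pk, pfm, np.asarray(x1), np.asarray(x2),
        pattern.sigma, pattern.u0,
    )
    expected = {"wta_small": "WTA", "comb_small": "combinatorial"}.get(name)
    if verify and expected is not None and report.mode != expected:
        raise FixtureRegimeError(
            f"{name}: expected {expected} but mode test gave {report.mode} "
            f"(r_union={report.r_union:.3f}); fixture parameters need re-tuning"
        )
    meta = {
        "seed": seed,
        "grid_spacing": grid_spacing,
        "f_net_cv": cv,
        "n_bar": n_bar,
        "r_union": report.r_union,
        "trained": wm.report.converged if wm.report else None,
    }
    return MegamapBundle(name, pfm, pattern, net, wm, (x1, x2), report, meta)


def save_bundle(bundle: MegamapBundle, path: str | Path) -> None:
    """Serialize a bundle as ``<path>.npz`` (arrays) + ``<path>.json`` (meta)."""
    path = Path(path)
    np.savez(
        path.with_suffix(".npz"),
        W=bundle.wm.W,
        field_pos=bundle.pfm.field_pos,
        field_cell=bundle.pfm.field_cell,
    )
    meta = {
        "version": 1,
        "name": bundle.name,
        "provenance": bundle.wm.provenance,
        "n_cells": bundle.pfm.n_cells,
        "lam": bundle.pfm.field_rate_density,
        "seed": bundle.pfm.seed,
        "env": [bundle.env.width, bundle.env.height, bundle.env.boundary_margin],
        "pattern": [
            bundle.pattern.sigma,
            bundle.pattern.u0,
            bundle.pattern.f_pk,
            bundle.pattern.b_pk,
        ],
        "net": [
            bundle.net.tau,
            bundle.net.f_pk,
            bundle.net.w_I,
            bundle.net.theta,
            bundle.net.f_net,
        ],
        "probes": [list(bundle.probes[0]), list(bundle.probes[1])],
        "report": bundle.report.to_dict(),
        "meta": bundle.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_bundle(path: str | Path) -> MegamapBundle:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arrays = np.load(path.with_suffix(".npz"))
    env = Environment(*meta["env"])
    pfm = PlaceFieldMap(
        n_cells=meta["n_cells"],
        field_pos=arrays["field_pos"],
        field_cell=arrays["field_cell"],
        field_rate_density=meta["lam"],
        seed=meta["seed"],
        env=env,
    )
    pattern = PatternParams(*meta["pattern"])
    net = NetworkParams(*meta["net"])
    wm = WeightMatrix(arrays["W"], meta["provenance"])
    x1, x2 = (tuple(meta["probes"][0]), tuple(meta["probes"][1]))
    report = classify_mode(
        wm.W, net.w_I, net.f_pk, pfm, np.asarray(x1), np.asarray(x2),
        pattern.sigma, pattern.u0,
    )
    return MegamapBundle(
        meta["name"], pfm, pattern, net, wm, (x1, x2), report, meta["meta"]
    )
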