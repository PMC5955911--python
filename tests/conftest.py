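"""Shared fixtures: trained networks are expensive, so they are built once
per session and reused across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from megamap.dynamics import NetworkParams
from megamap.environment import (
    PatternParams,
    TrainingGrid,
    concentric_square_environment,
    default_input_strength,
    embedded_active_set,
    net_activity_constant,
    sample_place_fields,
)
from megamap.experiments import make_fixture
from megamap.learning import (
    LearningConfig,
    compute_tuning_curve,
    incremental_learning,
)
from megamap.reduction import balanced_input_strength

# the canonical reduced parameter set (training-strength balance gives 0.33)
W0_NOMINAL, W_I_HAT, THETA = 1.2, 5.3, 0.9

warnings.filterwarnings(
    "ignore", message="b_pk_hat=.* is large", category=UserWarning
)


@pytest.fixture(scope="session")
def wta_bundle():
    """Sparse-map trained network verified to be in the winner-take-all mode."""
    return make_fixture("wta_small", seed=0)


@pytest.fixture(scope="session")
def comb_bundle():
    """Dense-map trained network verified to be in the combinatorial mode."""
    return make_fixture("comb_small", seed=0)


@pytest.fixture(scope="session")
def tuning_curve():
    return compute_tuning_curve(PatternParams())


@pytest.fixture(scope="session")
def sweep_setup(tuning_curve):
    """Incrementally learned weights (optimal and Hebbian) over a growing
    square environment, with fixed probe locations in the first region."""
    env = concentric_square_environment(3.0, 3)
    pfm = sample_place_fields(env, 2000, 0.6, seed=5)
    grid = TrainingGrid.cover(env, 0.1)
    pat0 = PatternParams()
    f_net, cv = net_activity_constant(pfm, grid, pat0.sigma, pat0.u0, pat0.f_pk)
    x1, x2 = np.array([1.25, 1.45]), np.array([1.75, 1.45])
    s1 = embedded_active_set(pfm, x1, pat0.sigma, pat0.u0)
    s2 = embedded_active_set(pfm, x2, pat0.sigma, pat0.u0)
    n_bar = (len(s1) + len(s2)) / 2.0
    b_pk = default_input_strength(
        balanced_input_strength(W0_NOMINAL, W_I_HAT, THETA),
        f_net, pat0.f_pk, n_bar, pat0.sigma, pat0.u0,
    )
    pattern = PatternParams(b_pk=b_pk)
    net = NetworkParams(
        w_I=W_I_HAT / (pat0.f_pk * n_bar), theta=THETA, f_net=f_net
    )
    seq_opt = incremental_learning(
        pfm, env, pattern, net, LearningConfig(), "optimal", grid_spacing=0.1
    )
    seq_heb = incremental_learning(
        pfm, env, pattern, net, None, "hebbian",
        tuning=tuning_curve, grid_spacing=0.1,
    )
    return {
        "env": env,
        "pfm": pfm,
        "pattern": pattern,
        "net": net,
        "probes": (x1, x2),
        "areas": [1.0, 4.0, 9.0],
        "optimal": seq_opt,
        "hebbian": seq_heb,
    }
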