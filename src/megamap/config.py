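"""YAML configuration for building networks.

Recognized keys (all optional, with package defaults):

.. code-block:: yaml

    environment: {width: 2.0, height: 2.0, margin: 0.15}
    fields:      {lambda: 0.25, silent_fraction: 0.8, seed: 0, n_cells: 1000}
    pattern:     {sigma: 0.10, u0: 0.3, b_pk: null, f_pk: 15.0}
    network:     {theta: 0.9, w_I_hat: 5.3}
    learning:    {eta: 0.5, max_epochs: 200, embed_tolerance: 1.0e-3,
                  grid_spacing: 0.05}

``fields.lambda`` takes precedence over ``fields.silent_fraction`` (the
latter is converted via the Poisson zero-class for a 1 m² environment).
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .environment import (
    Environment,
    PatternParams,
    PlaceFieldMap,
    calibrate_field_density,
    sample_place_fields,
)
from .learning import LearningConfig

__all__ = ["load_config", "environment_from_config", "map_from_config",
           "pattern_from_config", "learning_from_config"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    return cfg


def environment_from_config(cfg: dict) -> Environment:
    e = cfg.get("environment", {})
    return Environment(
        width=float(e.get("width", 2.0)),
        height=float(e.get("height", 2.0)),
        boundary_margin=float(e.get("margin", 0.15)),
    )


def map_from_config(cfg: dict, env: Environment | None = None) -> PlaceFieldMap:
    env = env or environment_from_config(cfg)
    f = cfg.get("fields", {})
    if "lambda" in f:
        lam = float(f["lambda"])
    else:
        lam = calibrate_field_density(float(f.get("silent_fraction", 0.8)), 1.0)
    return sample_place_fields(
        env, int(f.get("n_cells", 1000)), lam, int(f.get("seed", 0))
    )


def pattern_from_config(cfg: dict) -> PatternParams:
    p = cfg.get("pattern", {})
    b_pk = p.get("b_pk")
    return PatternParams(
        sigma=float(p.get("sigma", 0.10)),
        u0=float(p.get("u0", 0.3)),
        f_pk=float(p.get("f_pk", 15.0)),
        b_pk=None if b_pk is None else float(b_pk),
    )


def learning_from_config(cfg: dict) -> LearningConfig:
    l = cfg.get("learning", {})
    return LearningConfig(
        eta=float(l.get("eta", 0.5)),
        max_epochs=int(l.get("max_epochs", 200)),
        embed_tolerance=float(l.get("embed_tolerance", 1e-3)),
        shuffle_seed=int(l.get("shuffle_seed", 0)),
    )
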