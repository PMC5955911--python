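"""Build a Poisson place-field map and inspect the embedded patterns.

Each model place cell owns a Poisson-distributed number of Gaussian place
fields.  At any location x the map defines a training input (sum of Gaussian
bumps) and a desired activity pattern (sum of threshold-linear bumps of peak
f_pk = 15 Hz); the cells active in that pattern form the embedded active set
that the stability analysis operates on.
"""

import numpy as np

from megamap.environment import (
    Environment,
    PatternParams,
    TrainingGrid,
    calibrate_field_density,
    embedded_active_set,
    net_activity_constant,
    sample_place_fields,
)

env = Environment(2.0, 2.0)
lam = calibrate_field_density(silent_fraction=0.8, area=1.0)
print(f"field density calibrated to 80% silent cells per m^2: lambda = {lam:.4f} /m^2")

pfm = sample_place_fields(env, n_cells=2000, lam=lam, seed=0)
counts = pfm.fields_per_cell()
print(f"{pfm.n_cells} cells, {pfm.n_fields} fields in {env.area:.0f} m^2; "
      f"silent fraction {pfm.silent_fraction():.3f} "
      f"(Poisson mean {lam * env.area:.3f} fields/cell)")

pat = PatternParams()
print(f"active-bump radius R = {pat.radius:.3f} m "
      f"(sigma = {pat.sigma} m, u0 = {pat.u0})")

x = np.array([1.0, 1.0])
s = embedded_active_set(pfm, x, pat.sigma, pat.u0)
print(f"embedded active set at {x}: {len(s)} cells "
      "(cells with a field within R of x)")

grid = TrainingGrid.cover(env, 0.1)
f_net, cv = net_activity_constant(pfm, grid, pat.sigma, pat.u0, pat.f_pk)
print(f"net embedded activity over {len(grid)} grid locations: "
      f"{f_net:.1f} Hz, CV {cv:.2f}")
print("The network constant f_net is the grid mean; embedded patterns are "
      "normalized to it, making the attractor homogeneous across locations.")
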