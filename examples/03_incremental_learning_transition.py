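"""Mode transition as an animal incrementally learns a growing environment.

The environment grows in concentric square regions; at each stage only the
novel region's patterns are embedded (old regions are not reinforced).  For
delta-rule (optimal) weights, the cross-excitation q between two fixed probe
bumps grows as cells acquire co-active fields in new regions while the
self-excitation w0 stays pinned, so the union-set stability index r falls
with area — the network crosses from winner-take-all into the combinatorial
mode.  Hebbian weights only ever add excitation, so r rises instead and the
network stays winner-take-all.
"""

import numpy as np

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
from megamap.learning import (
    LearningConfig,
    compute_tuning_curve,
    incremental_learning,
)
from megamap.reduction import balanced_input_strength, reduce_megamap
from megamap.stability import mode_vs_area_sweep

env = concentric_square_environment(3.0, 3)
pfm = sample_place_fields(env, 2000, 0.6, seed=5)
pat0 = PatternParams()
grid = TrainingGrid.cover(env, 0.1)
f_net, _ = net_activity_constant(pfm, grid, pat0.sigma, pat0.u0, pat0.f_pk)
x1, x2 = np.array([1.25, 1.45]), np.array([1.75, 1.45])
n_bar = np.mean([
    len(embedded_active_set(pfm, x, pat0.sigma, pat0.u0)) for x in (x1, x2)
])
pattern = PatternParams(b_pk=default_input_strength(
    balanced_input_strength(1.2, 5.3, 0.9), f_net, pat0.f_pk, n_bar,
    pat0.sigma, pat0.u0,
))
net = NetworkParams(w_I=5.3 / (pat0.f_pk * n_bar), theta=0.9, f_net=f_net)

print("training delta-rule weights region by region (3 stages, 9 m^2) ...")
seq_opt = incremental_learning(
    pfm, env, pattern, net, LearningConfig(), "optimal", grid_spacing=0.1
)
print("building Hebbian weights from the measured tuning curve ...")
tuning = compute_tuning_curve(PatternParams())
seq_heb = incremental_learning(
    pfm, env, pattern, net, None, "hebbian", tuning=tuning, grid_spacing=0.1
)

areas = [1.0, 4.0, 9.0]
for label, seq in (("optimal", seq_opt), ("hebbian", seq_heb)):
    df = mode_vs_area_sweep(
        [w.W for w in seq], areas, net.w_I, pat0.f_pk, pfm, x1, x2,
        pat0.sigma, pat0.u0,
    )
    print(f"\n{label} weights:")
    print(df.to_string(index=False))

rp, _ = reduce_megamap(
    seq_opt[-1].W, pfm, x1, x2, pat0.sigma, pat0.u0, pat0.f_pk, f_net,
    net.w_I, net.theta,
)
print(f"\nreduced weights of the final optimal network: "
      f"w0 = {rp.w0:.3f}, q = {rp.q:.3f}, w0 - q = {rp.w0 - rp.q:.3f}")
print("r < 1 (combinatorial) coincides with w0 - q < 1 in the 2-unit model.")
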