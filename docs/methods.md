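# Methods

## Model

The network is a standard firing-rate model of N place cells with recurrent
excitation, global feedback inhibition and external input:

    τ u'(t) = −u(t) + W f(u(t)) − w_I f_I(u(t)) 1 + b,

with threshold-linear activation `f(u) = f_pk [u]₊` and a single inhibitory
unit `f_I(u) = [1ᵀ f(u) − θ f̄_net]₊` treated as instantaneous (its time
constant is assumed negligible relative to τ; without this simplification
oscillatory regimes between bumps would be possible, and they are outside
this package's scope). Defaults: τ = 10 ms, f_pk = 15 Hz, θ = 0.9.

Each cell i owns `M_i ~ Poisson(λ·A)` place-field centers placed uniformly
in a rectangular environment of area A. At a location x the cell's training
input is a sum of Gaussians of amplitude `b̄_pk` and width σ over its
centers, and its desired activity is a sum of threshold-linear bumps of
height f_pk that vanish at the radius `R = σ·sqrt(2 ln((1+u0)/u0))`.
Defaults: σ = 0.10 m, u0 = 0.3 (so R ≈ 0.171 m), and λ calibrated so that
80% of cells are silent per m² (λ ≈ 0.223 m⁻²) unless a denser map is asked
for. σ and u0 are not identifiable from the reduced analysis alone; these
defaults give active-set sizes and a bump radius proportionate to the
reference network when scaled to its size.

**Pattern normalization.** The attractor construction requires the net
embedded activity `f̄_net = Σ_i f̄_i(x)` to be independent of x. On a finite
Poisson map the raw sum fluctuates by ±15–25% at the population sizes used
here, and the reduced self-weight w⁰ responds to that fluctuation with slope
≈ ŵ_I + 1, which is enough to scramble the mode prediction entirely. The
embedded (trained) pattern at x is therefore the desired activity rescaled
so its sum equals the network constant f̄_net (the training-grid mean).
Support and shape are unchanged; only the height varies by a few percent.

**Training-input amplitude.** `b̄_pk` is set so that the reduced input of a
training input equals the reduced training strength `b̂_pk` fixed by the
balance `1 = w⁰ − ŵ_I(1−θ) + b̂_pk`: analytically
`b̄_pk = b̂_pk · f̄_net/(f_pk N̄ κ)` with `κ = 2σ²/(R²(1+u0))` the mean
Gaussian weight over the active disk; fixture builders refine this against
the realized map at the probe locations.

## Weight construction

**Optimal (delta-rule) embedding.** Every grid pattern must be a fixed
point under its training input: for active cells the recurrent drive
`(W f̄)_i` equals `f̄_i/f_pk + w_I f̄_I − b̄_i`; for silent cells it must not
exceed the sub-threshold bound. The default solver computes, per row, the
minimum-norm change from the current matrix that interpolates the equality
constraints (a Gram-matrix solve over that row's constraint patterns);
silent-cell bounds found violated are clamped to the bound minus a small
margin (the embed tolerance, default 10⁻³) and re-solved over a few passes.
This is the solution the online normalized delta rule converges to; the
online rule itself (per-location Kaczmarz steps `η/‖f̄‖²`, η = 1, shuffled
location order with a fixed seed) is retained as
`LearningConfig(solver="delta")` and tested for equivalence. Training
defaults: grid spacing 0.05 m (0.1 m in the scaled-down fixtures), boundary
margin 0.15 m. Delta-rule weights may be negative; Hebbian weights are
clamped nonnegative. No weight normalization is applied — Hebbian growth is
unbounded by design, which is why Hebbian networks here (and at scale)
eventually destabilize.

**Hebbian sum of tuning curves.** `W_jk = Σ_m Σ_n w_tune(|c_jm − c_kn|)`
over all field pairs. The radial tuning curve w_tune is measured by training
a single-field-per-cell reference network with the delta rule and radially
averaging its weights in 1 cm bins (interior cell pairs only, to avoid
boundary bias), truncating the tail below 10⁻⁴ of the peak. The curve is
approximately Gaussian with support ≈ 2R. For single-field maps the two
constructions agree up to the radial-averaging error; at the population
sizes used here that error caps the full-matrix correlation near 0.85–0.92
(it rises with the number of cells per bump), so the equivalence test
asserts 0.8 rather than a reference-scale value.

**Incremental learning.** The environment is split into concentric regions
learned in order. At stage k only region-k patterns are embedded as
equalities — previously learned patterns are never re-embedded. Earlier
locations do remain in the constraint set as one-sided bounds: the drive at
an old location may not exceed its old embedded value (and silent cells stay
sub-threshold). This "no reinforcement, no overdriving" rule is what pins
the self-excitation w⁰ while the cross-excitation q grows as cells acquire
co-active fields in newly learned regions; with equalities only, random
field co-occurrence inflates within-bump and cross-bump weights equally and
the mode transition never materializes at desk scale. Hebbian incremental
learning simply adds the tuning-curve terms of field pairs whose
later-explored member lies in the new region, so entries never decrease.

## Stability test and reduction

A fixed point's stability depends only on which cells are active there:
`r(S, S_I) = λ_max(f_pk (W − χ_{S_I} w_I 11ᵀ) D(S)) < 1`. The index is
computed on the |S|×|S| active submatrix; because the zeroed columns of the
full form contribute only zero eigenvalues, the submatrix value is floored
at 0 whenever inactive cells exist, making the two forms numerically
identical. `|r − 1| < 10⁻³` is reported as *marginal* and never classified,
since near the boundary the verdict genuinely depends on the probe
locations chosen. The inhibitory unit is taken active (`S_I = {inh}`) for
mode classification; networks whose inhibition shuts off at equilibrium are
outside the validated envelope and are flagged rather than classified.

The 2-unit reduction sums states, inputs and weights over the two embedded
active sets (scaled by `f_pk/f̄_net`, with `ŵ_I = f_pk N̄ w_I`). Numerical
choices: N̄ is the mean of the two set sizes; cells in both sets are
assigned to the nearer probe so the partial sums stay disjoint; q is the
symmetrized mean of the two directed cross sums, with the directed values
kept as diagnostics; w⁰ is averaged over the two locations (the defining
sum uses one location; the spread is reported). A reduction is marked fully
valid only when the set overlap is < 5% of N̄ and the q asymmetry < 10%;
dense maps exceed the overlap bound and the report then downgrades
confidence without withholding the parameters.

## 2-unit analysis

All 8 on/off configurations (unit 1 × unit 2 × inhibition) are solved as
linear systems; solutions are kept when sign-consistent (strictly, to
10⁻¹⁰ — solutions sitting exactly on a threshold are degenerate and
skipped, which excludes the all-silent state at zero input that the
constraint w⁰ > 1 makes irrelevant). Stability comes from each
configuration's Jacobian, equivalently the same index r with f_pk = 1.
Inhibition-off survivors under valid constraints are anomalies and are
returned, not dropped. Classification boundaries are flagged marginal
within 10⁻⁶ in q. Phase-diagram simulation follows the weaker-input-pattern
protocol: start at the desired pattern of the weaker-driven unit, classify
by the active units at the end of the run; near a bifurcation the
relaxation is arbitrarily slow, so runs are classified from the final state
after 6 s of model time and the agreement statistic excludes a 10⁻³-wide
boundary band. Integration is explicit Euler at dt = τ/20 throughout
(halving dt moves fixture equilibria by < 10⁻⁴; the scheme is first-order
and the piecewise-linear right-hand side is smooth away from threshold
crossings); divergence is guarded at ‖u‖∞ > 10⁶.

## What the generator emulates — and what it does not

The synthetic maps reproduce the statistical structure the analysis relies
on: Poisson field multiplicity, uniform field placement, homogeneous net
activity, and the growth of shared-field cross-excitation with explored
area. They do not model experience-dependent field drift, boundary effects
on field shape, grid-cell or head-direction inputs, realistic field-size
dispersion, or plasticity during retrieval. Tests passing on these maps
show that the mode test, the reduction and the bifurcation structure behave
as derived *under the model's own assumptions*; they do not certify the
model against recorded place-cell data.

## Scaled-down study conditions

Full networks here use N ≤ 2500 cells and areas ≤ 9 m², with the
combinatorial regime reached by raising the field density λ (extra shared
fields raise q) rather than by growing the environment — the mode depends
only on w⁰ − q, so the regime does not require the reference geometry.
Named fixtures: `wta_small` (N = 2500, λ = 0.18 m⁻², 4 m²; r_union ≈ 1.12)
and `comb_small` (N = 1000, λ = 2.2 m⁻², 4 m²; r_union ≈ 0.85), both
verified at build time — a fixture that lands in the wrong regime raises
instead of shipping mislabeled. The incremental sweep uses N = 2000,
λ = 0.6 m⁻² over 9 m² in three concentric regions (≈ 5.4 fields per cell at
full area, comparable per-cell multiplicity to the reference network at its
transition area), which shows the monotone decrease of r and the
WTA→combinatorial crossing for delta-rule weights and the monotone increase
for Hebbian weights. At these sizes Hebbian *single-bump* indices already
exceed 1 — the unnormalized Hebbian magnitude has no self-consistent scale
at low cell density — so only the trend, not single-bump stability, is
asserted for Hebbian networks.

## Known limitations

* Bump drift in the absence of input is observed but not quantified.
* The full model's hysteretic band under conflicting input is narrower than
  the 2-unit prediction (the reduction ignores bump-radius changes), so
  reduced and full responses agree in mode and qualitative shape, not
  point-wise.
* The delta-rule variant, learning rate and stopping rule of the reference
  implementation are not published; the solver here is a calibrated choice
  and is reported in every convergence report.
* Serialization stores arrays in NumPy `.npz` containers next to a JSON
  metadata sidecar; no HDF5 dependency is taken.
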