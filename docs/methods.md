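# Methods

This note documents the model and procedures implemented in `swarmlp`, the
defaults and the reasoning behind them, the numerical choices, and what the
synthetic data can and cannot tell you about real cohorts.

## The hybrid optimizer

`optimize(objective, config, algorithm)` searches a box `[lb, ub]^n`.
Positions start i.i.d. uniform in the box with zero velocities; personal
bests start at the initial positions and the global best at the fittest
particle.

Per iteration of the hybrid (`hms_pso`):

1. **PSO phase.** Velocity update with inertia `w_t`, cognitive and social
   terms (`c1 r1 ∘ (p_i − x_i)`, `c2 r2 ∘ (g − x_i)`; `r1`, `r2` fresh
   per-dimension uniforms), clamped to `±v_max`; positions move by the
   velocity and are clamped to the box; current fitness is re-evaluated.
2. **Mental-search phase.** For each particle, `candidates_per_particle`
   Lévy-flight candidates `S = d·α·uσ/|v|^{1/β} ∘ x_i` are drawn (scalars
   `mc ~ N(0,1)`, `d = φ(mc)` the standard-normal density, `β ~ U(β_lo,
   β_hi)`, `σ = sin(πβ/2)`; `u`, `v` per-dimension standard normals), each
   clamped to the box. The personal best is replaced by the current
   position if it is strictly fitter, otherwise by `S` if that is strictly
   fitter (ties keep the incumbent; a non-finite candidate fitness rejects
   the candidate).
3. The global best is refreshed as the fittest personal best, and the
   inertia decays linearly: `w_t = ((t_max − t)/t_max)(w_max − w_min) + w_min`.

Two deliberate non-textbook details are kept because they define this
variant: the multiplicative density factor `d` (a standard Lévy step has no
such factor) and the abbreviated scale `σ = sin(πβ/2)` (the full Mantegna
scale is available via `mantegna_sigma=True` for sensitivity checks).
Because the candidate is *multiplicative* in `x_i`, mental-search steps
shrink near the origin; the PSO phase is what drives fine convergence, and
the mental search supplies occasional large exploratory jumps. A
consequence of the `|v|^{−1/β}` kernel worth stating explicitly: step-size
tails get *heavier* as β falls toward 0.3, and lighter as β approaches
1.99 (σ also shrinks toward 0 there); the property test asserts this
direction.

`pso` is the hybrid without phase 2 — and is implemented as exactly that,
so disabling the mental search is bitwise-identical to PSO under a shared
seed (an asserted invariant). `hms` is a mental-search-only baseline: no
velocity term; each particle greedily moves to its best candidate when that
improves its current fitness. The original mental-search algorithm also
clusters the population (a "cluster size" appears in published parameter
tables); the hybrid's pseudocode has no clustered phase, so `cluster_size`
is accepted in the config but unused.

### Defaults and where they come from

| parameter | default | note |
|---|---|---|
| population | 50 | benchmark protocol |
| iterations | 100 / 500 / 2000 | benchmarks / topology search / dataset training |
| w | (0.729, 0.4) decay | benchmark tables print the constant 0.729 while the pseudocode decays; the decay schedule anchored at 0.729 honors both |
| c1 = c2 | 1.49 | benchmark setting; dataset training uses w = 0.6, c1 = c2 = 1.45 per the dataset parameter table |
| β range | (0.3, 1.99) | mental-search distribution-index range |
| Lévy scale α | 0.01 | as specified |
| v_max | 0.2 (ub − lb) | unspecified upstream; a conventional fraction of the box, overridable |
| candidates/particle | 1 | single mental-search candidate per particle, matching the pseudocode |
| weight bounds | [−10, 10] | the printed "UB 10 / LB 2" cannot be a weight box (it would forbid negative weights); read as a symmetric magnitude bound |

Evaluation accounting: `pop × (1 + iters)` for PSO, `pop × (1 + 2·iters)`
for the hybrid with one candidate per particle (asserted). One root seed
drives each run; studies derive per-run seeds from a root seed via
`SeedSequence`, and every result records its seed.

## Benchmark registry

The 21-function suite (Rosenbrock … Michalewicz) uses the standard
literature definitions; several published formula transcriptions are
corrupted (e.g. Branin missing its `5x₁/π` term, "shifted Schwefel 1.2"
printed as the |x|-sum/product form of Schwefel 2.22), so formulas were
implemented in standard form and validated against the published minima
instead. Entries whose published minimum conflicts with the standard form —
Schwefel ("−418.9829 × 5" for n = 30, standard −418.9829·n), McCormick
(−149.2967921 vs the standard ≈ −1.9133) and Michalewicz (−1.91988 vs the
standard 2-D −1.8013) — carry `verified=False` and are excluded from oracle
assertions. Specific choices: Branin keeps its published [−5, 5]² box
(which contains the minimizer (π, 2.275)); "Dejong" is the sphere (De
Jong's first function, 30-D, [−5.12, 5.12]); Whitley and Zakharov are 30-D,
Schubert/Matyas/Bohachevsky (type 1)/McCormick/Michalewicz 2-D; the
"shifted" Schwefel 1.2 is implemented unshifted (no shift vector is given)
under the id `schwefel_222`, outside the suite. Quartic's additive uniform
noise is drawn once per evaluation from a caller-supplied RNG; with no RNG
the noise term is 0, which is the deterministic mode used in tests and in
the convergence study.

`locate_minimum_oracle` is the independent check on all of this: a dense
axis-aligned grid (default 400 points/axis) followed by repeated 20×
window shrinks around the incumbent, for 1–2-D functions; for higher
dimensions it only screens the canonical candidate points of separable test
functions. It shares no code with the swarm optimizers.

## Network, fitness and gradients

The MLP applies the logistic sigmoid at every neuron, output layer
included (no softmax); the parameter count generalizes `(fan_in + 1) ×
fan_out` summed over layer pairs to any depth, so 4- and 5-hidden-layer
candidates are expressible. The MSE fitness averages squared error over
*every* (sample, output) entry; with one-hot targets this puts the
constant-0.5 predictor at exactly 0.25, a useful no-information reference
across topologies, and RMSE = √MSE. AUC is the Mann–Whitney rank statistic
on the positive-class output (computed via scikit-learn, ties counting one
half); predicted labels are per-row argmax with ties toward the lower
index.

Backpropagation is implemented directly (reverse-mode chain rule with
σ′ = a(1 − a)) and validated against central finite differences at
h = 1e−5. The baseline update rules use the conventional framework
defaults, which is the natural reading of "default learning rates": plain
gradient and SGD 0.1, Adadelta 1.0 (ρ = 0.95, ε = 1e−6), RMSprop 0.001
(ρ = 0.9), Adam 0.001 (β₁ = 0.9, β₂ = 0.999, ε = 1e−8). "Gradient" is
full-batch fixed-step descent; SGD is the same rule over shuffled
mini-batches of 32 (one iteration = one epoch) — whether the original
comparison used mini-batches is unstated, so this is a documented config
choice giving the two rows distinct conventional meanings. Initialization
is uniform(−0.5, 0.5) from the run seed; a non-finite loss marks the run
failed, and study summaries exclude failed runs while reporting their
count.

## Preprocessing

Pipeline order: mean imputation → min-max scaling → one-hot labels →
fitting-side transforms learned on the training partition only. The split
is seeded, disjoint and exhaustive with ⌊0.8 n⌋ training rows (640 → 512 /
128), stratified by default for imbalanced cohorts (largest-remainder
per-class allocation, class ratio preserved within one sample). Whether the
original pipeline fitted the scaler before or after splitting is unstated;
fitting on the training partition only is the leakage-safe order and is
asserted in tests. Constant features scale to 0; held-out values are not
clipped to [0, 1].

## Synthetic cohort

Real sepsis cohorts of this kind are not publicly deposited, so the
generator emulates the *shape* of such a table: 640 patients, exactly 216
positive by construction, 24 numeric features on heterogeneous scales with
sporadic missingness (default rate 0.05 on continuous features only — the
true rate is unknown, so it is an explicit parameter capped at 0.2). The
roster covers the 19 named clinical variables (vitals, blood counts,
inflammatory markers, severity scores, gender, height) padded to 24 inputs
with age and four auxiliary labs (lactate, creatinine, bilirubin, INR),
since the mapping from 19 named variables to 24 network inputs is not
recorded; the padding is a modeling decision, not data provenance. Every
class-conditional distribution is a two-component normal mixture on an
identity or log scale — which uniformly encodes plain normals, log-normals
(CRP, procalcitonin, lactate …) and the bimodal septic temperature
(hypothermic/febrile mixture at 35.5/38.5 °C vs N(36.8, 0.4)) — with
locations chosen for clinical plausibility (septic: tachycardia,
tachypnoea, hypotension, lymphopenia, raised severity scores), declared
once in `DEFAULT_FEATURES` and versioned (`SPEC_VERSION`). Draws are
clipped to declared physiologic ranges.

The effect-size dial interpolates *all* septic-class parameters toward the
non-septic ones (`θ_pos(m) = θ_neg + m (θ_pos − θ_neg)`): multiplier 0
makes the feature distributions label-independent exactly (so a trained
classifier's held-out AUC is ~0.5), multiplier 1 is the declared default,
and larger multipliers approach separable classes. The generator's headline
validity check is that the mean held-out AUC of the hybrid-trained network
is ~0.5 at multiplier 0, > 0.95 at multiplier 5, and monotone across
{0, 1, 5}.

What the generator does **not** emulate: the joint correlation structure of
real vitals and labs (features are drawn independently given the label),
temporal trajectories, informative missingness, label noise, or the
hard class overlap of real sepsis data — the default cohort is much more
separable than a real one (severity scores alone carry strong signal), so
trained-model metrics on it bound pipeline correctness, not clinical
performance.

## Studies and statistics

`run_convergence_study` runs each (function, algorithm) cell for `runs`
seeded repeats; `topology_search` trains candidate hidden-layer layouts
with the hybrid and flags the minimum-MSE row; `run_training_study`
compares the eight optimizers over repeated independent trainings on the
held-out test MSE/RMSE. Run statistics use the population (n) denominator
so that the reported variance is exactly the squared reported standard
deviation, matching how both are printed independently in this literature.
The published benchmark budget ("approximately 5000 evaluations") is read
as population × iterations = 50 × 100 per run; the mental search adds up to
one extra evaluation per particle per iteration on top, accounted
separately.

Desk-scale problem sizes used by the shipped checks (chosen once as this
package's own test scale): the benchmark convergence targets run the full
protocol (population 50, 100 iterations, 30 runs — seconds per function);
cohort-validity trainings use 150 iterations with 30 particles over 10
cohort seeds per effect multiplier; the swarm/MLP fitness-wiring check uses
a 100-sample separable set with 20 particles for 300 iterations; unit-level
study tests use runs of 2–3 with populations around 10.

## Known limitations

- The mental-search candidate is multiplicative in the position, so it
  degenerates at the origin and on near-zero coordinates; this is faithful
  to the variant implemented, not a recommendation.
- The standalone `hms` baseline is a deliberately simple greedy
  mental-search walker, not the full clustered original algorithm.
- 30-D suite functions at the full benchmark budget are expensive in pure
  Python per-evaluation terms; studies accept a `dimension_override` to
  scale them down.
- Gradient baselines implement no learning-rate schedules, early stopping
  or regularization, mirroring the comparison they reproduce.
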