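# Methods

## Problem and pipeline

The package estimates a regression from ten regional mean plantar pressures
during the stance phase of walking (N) to plantar soft-tissue stiffness
(N/m) measured with a handheld damped-oscillation probe, and attributes the
prediction to regions via Mean Impact Value (MIV). The stages are: feature
and target extraction → min-max normalization → 8:2 split → hybrid PSO-GA
search for the network's initial weights and biases → backpropagation
training → error reporting (MBE/RMSE/REP) → MIV contribution rates.

## Measurement conventions

* Regional mean pressure is the arithmetic mean of all provided frames,
  `F_mean = (Σᵢ Fᵢ)/n`. No heel-strike/toe-off windowing is applied; the
  caller supplies the stance window. Pressure-plate exports mix force (N)
  and pressure (N/cm²) conventions; the pipeline is unit-agnostic because
  min-max normalization removes scale — the unit affects labels only.
* Stiffness from an oscillation trace is `S = a_max · m_probe / Δl`.
  The scalar-extraction convention (not fixed by the measurement
  principle itself) is: `a_max` = maximum |acceleration| over the trace;
  `Δl` = peak displacement excursion of the first compression half-cycle
  (from rest to the first oscillation peak). On the generator's
  closed-form underdamped traces this convention recovers the true
  stiffness to O(ζ²) — about 0.4 % at the default damping ratio 0.05,
  inside the 1 % round-trip tolerance the tests assert.

## Network

10–13–1 feedforward net; the hidden size follows the empirical rule
`hidden = input + output + a` with integer `a ∈ [1, 9]`, default a = 2
(a `sqrt` variant, `round(sqrt(input + output)) + a`, is available — the
rule exists in both forms in the literature and the package does not guess
between them beyond the default reproducing 13). Hidden activation tanh,
output linear (logistic hidden available); this is the standard choice for
regression with normalized targets. Training is plain full-batch gradient
descent on the MSE of the normalized data: learning rate 0.01, at most
8000 epochs, early stop at MSE ≤ 1e-6 (the goal applies on the normalized
scale because that is the scale training sees). No momentum, mini-batching,
regularization or validation-based early stopping — deliberately the
minimal optimizer consistent with the stated hyperparameters.

The genome layout is fixed: `[W1 (hidden × input, row-major), b1,
W2 (output × hidden), b2]`, length 157 for 10–13–1, so the metaheuristic
and the network agree bit-exactly.

## Hybrid PSO-GA initializer

Fitness of a genome is the training-set RMSE of its network on the
normalized scale. Core parameters: PSO 30 iterations, 5 particles,
c₁ = c₂ = 4.5; GA 50 generations, population 5, accuracy 1e-6, crossover
rate 0.4. Per iteration the swarm moves
(`v ← w·v + c₁r₁(pbest − x) + c₂r₂(gbest − x)`, `x ← x + v`), a GA runs on
a copy of the current particle positions, and the GA's best individual
replaces the swarm's worst particle with its velocity reset to zero.

Constants the scheme leaves open, and the package's choices (each a config
knob):

* **Inertia weight** — linearly decreasing 0.9 → 0.4. With c₁ = c₂ = 4.5
  (φ = 9, far outside the classical constriction/stability region) an
  uncontrolled swarm diverges; decreasing inertia plus clamping is the
  standard remedy and is required for these coefficients to work at all.
* **Velocity clamp** — |v| ≤ 0.5 × position range; **bounds** — positions
  reflect at ±1, a weight scale suited to data normalized into (0, 1).
* **GA operators** — real-coded genomes, tournament selection (k = 2),
  arithmetic crossover (child = u·p₁ + (1−u)·p₂, u ~ U(0,1)) at rate 0.4,
  per-gene Gaussian mutation (rate 0.1, σ = 0.1 × position range),
  elitism of 1. "Accuracy 1e-6" is read as the GA's early-stop tolerance
  on best-fitness improvement per generation.
* **GA seeding** — from the current swarm positions (the GA refines the
  swarm's region); fresh-random seeding is available. Running the GA once
  per PSO iteration (rather than once total) follows the hybrid's
  description; the one-shot alternative would change only cost, not the
  interfaces.

The global-best trace is non-increasing by construction (bests only ever
improve, and the exchange cannot worsen the swarm because GA elitism keeps
its best at least as good as the best seed). Everything is driven by one
`numpy` Generator, so a seed fixes the best genome, the trace and all
downstream metrics bit-exactly.

## Preprocessing

Min-max normalization `x_std = (x − x_min)/(x_max − x_min)` per feature and
for the target, fitted by default on the **full** dataset before the split
(this mirrors the processing order the pipeline models; it leaks the test
extrema into training, so a strict fit-on-train option exists). Constant
columns raise an error naming the column — the map is undefined there, and
the generator never produces them. The 8:2 split is a seeded uniform row
permutation by default (rows are trials, so a subject's trials can appear
on both sides — flagged as leakage of subject identity); a subject-wise
mode keeps each subject wholly on one side at the cost of only
approximately hitting the 8:2 ratio.

## Error metrics

MBE = mean(y − ŷ) (signed; note that with this orientation a model that
*over*-predicts has negative MBE), RMSE, and REP = |y − ŷ|/y × 100 with
max and mean summaries. REP is taken as a magnitude per sample so the
"maximum"/"average" summaries are non-negative; the signed variant would
make a "maximum" ambiguous. All three are computed on inverse-normalized
predictions so units are N/m and %.

## MIV

Each raw feature column is multiplied by 1.10 and 0.90 (the ±10 %
perturbation acts on the physical pressure scale, then re-normalization
uses the stored parameters), predictions are inverse-normalized, and
`MIV_i = mean(P_i1 − P_i2)` over samples — so MIVs are in N/m and invariant
to constant output shifts. Contribution rates normalize |MIV| to percent.
By default MIV uses all rows (train + test); train-only is available. Ties
in the contribution ranking break by region index (stable). For a linear
model this construction gives MIV_i = 0.2 · coefficient_i · mean(F_i), which
is what makes contribution ranks analytically checkable.

## Synthetic cohort generator

The generator emulates the *statistical* structure of a healthy young-adult
walking study — 30 subjects × 5 trials × both feet = 300 rows; regional
mean pressures with a walking-like profile (defaults, N: hallux 45, toes
12, metatarsals 1–5 = 60/85/90/70/40, midfoot 55, medial heel 95, lateral
heel 80), between-subject variability 10 % and trial-to-trial 5 % of each
regional mean; and a stiffness target

    k_true(F) = 476.99 + Σᵢ signᵢ·magᵢ·(Fᵢ − profileᵢ) + λ·g(F),

with g a heel × central-forefoot interaction (product of relative
deviations of summed heel and summed metatarsal-2–4 load), λ = 0 by
default. Observed stiffness adds Gaussian noise (default SD 5 N/m; either
one draw per trial or the mean of 5 repeat draws, since a protocol may pair
each walking trial with a single probe repeat or with their mean) and is
clipped to the meter's 70–1900 N/m range with a flag, keeping sample counts
exact.

Default effect signs follow the reference directions in
`plantarstiff.regions` (− hallux, toes, metatarsal 1, midfoot; + the other
metatarsals and both heel regions). Default magnitudes are calibrated
analytically in one step: `magᵢ = 3.9 × rateᵢ / profileᵢ`, which (a) makes
linear-model MIV contributions proportional to the reference contribution
rates and (b) puts the cohort stiffness SD near 15 N/m
(Σ(magᵢ·sdᵢ)² + noise² ≈ 15²), with the mean at the intercept 476.99 N/m.
The Monte-Carlo calibration bands asserted in the tests (mean ∈ [470, 485],
SD ∈ [10, 25] N/m over ≥ 1000 draws) follow from this construction.

Raw-signal synthesis exists so the measurement formulas can be exercised
end to end: stance series are positive per-region loading templates
(raised-cosine bumps timed heel → toe) rescaled to match each sample's mean
pressures exactly; oscillation traces are closed-form underdamped
solutions (default probe mass 0.018 kg — a handheld-indenter order of
magnitude; it scales trace synthesis only — damping ratio 0.05, impact
velocity 0.15 m/s, 3200 Hz).

**What passing tests do and do not show.** The generator contains no gait
dynamics, foot anatomy, inter-region correlation structure beyond the
shared subject offset, heteroscedasticity, or model misspecification: its
ground truth is (by default) exactly linear, which real pressure–stiffness
relationships are not. Recovery results on it validate the *machinery* —
that the optimizer, trainer and MIV attribution find structure that is
truly there, with the right signs — not the clinical claim that these
regions drive stiffness in humans.

## Numerical choices and degenerate inputs

Zero-frame series, flat oscillation traces, zero deformation, constant
columns, empty training sets, all-zero MIVs, out-of-range hidden-size
constants and invalid rates all raise `ValueError` early with the offending
quantity named. Positions/velocities are kept finite by clamping and
reflection; REP requires all true values nonzero. Serialized artifacts keep
full float precision; rounding happens only in rendered tables. A single
global seed fans out to per-stage seeds via `SeedSequence.spawn`, so stages
are independently reproducible.

## Problem sizes used in the checked examples

The test suite and the acceptance script run the pipeline at the full study
design (300 samples, 30 PSO iterations, 8000 training epochs) — the whole
fit takes on the order of a second — with 5 independent seeds for the
ground-truth-recovery checks and 100 seeds for optimizer-invariant checks
on a 5-dimensional sphere surrogate; smoke-scale runs (3 subjects, reduced
iterations) are used where only plumbing is under test.

## Known limitations

* The trained network is a point estimate: no uncertainty quantification
  on predictions, metrics or MIVs (point values only, by design).
* MIV's ±10 % multiplicative perturbation conflates effect size with
  feature level: regions with larger mean loads get proportionally larger
  absolute perturbations.
* With 5 particles × 30 iterations in a 157-dimensional space the
  metaheuristic is a coarse initializer, not a global optimizer; quality
  rests on the subsequent gradient descent, which the random-restart
  comparison test quantifies.
* The default trial-random split and full-data normalization reproduce a
  common but leaky protocol; use `mode="subject-wise"` and
  `normalize_on="train"` for honest generalization estimates.
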