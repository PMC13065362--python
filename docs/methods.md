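# Methods

This note records the modelling assumptions, parameter choices, and
numerical decisions behind steerkit, in the spirit of a model-description
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Stimulus space

A stimulus is the vector of signed second-phase current amplitudes (μA)
applied simultaneously to E electrodes; negative amplitudes denote
cathodic-peak, positive anodic-peak pulses. The triphasic pulse shape
(relative amplitudes 2:−3:1, 50 μs per phase) is carried as metadata and
never enters the mathematics — all models operate on the amplitude vector
alone, which is the convention under which thresholds and surfaces are
defined. The standard protocol grid is 20 linearly spaced levels per
electrode on [−1.8, 1.8] μA; for three electrodes that is 8000 stimuli and,
at 20 trials each, 160,000 stimulations. Grids are ordered
lexicographically by electrode index so files and seeded subsampling are
reproducible. A symmetric 20-level grid contains no exact zero level;
single-electrode ("axis") subsets therefore treat the level nearest zero as
"off", breaking the ± tie toward the cathodic level. This is configurable
(`zero_tol`) and matters only for the single-vs-triplet comparison.

## Linear-OR activation model

`p(x) = 1 − Π_i (1 − σ(w_{i0} + w_iᵀx))` with σ the logistic function. The
biophysical reading: each of m discrete sites (sodium-channel band,
locations along the distal axon) sums extracellular drive linearly —
tissue conductivity is linear at stimulation frequencies — and membrane
noise makes firing at a site a sigmoid of that drive; the cell spikes if
any site does. Nonlinear current summation across electrodes emerges
purely from the OR over several reachable sites.

Fitting is penalised maximum likelihood on grouped Bernoulli counts.
Numerical choices:

- Probabilities are evaluated in log space: log(1−σ(z)) = −log(1+eᶻ) and
  log(1−p) = Σ log(1−σᵢ), stable for |z| up to ~10³; logs of p are floored
  at 1e-300.
- Analytic gradient: ∂p/∂z_i = σᵢ(1−p), giving an O(Jm) objective/gradient
  per evaluation (J grid points, m sites).
- Constraints as box bounds for L-BFGS-B: |w_{ik}| ≤ 100 two-sided
  (cathodic/anodic symmetry motivates the lower bound), and the joint
  resting constraint p(0) ≤ 0.01 enforced per site as
  σ(w_{i0}) ≤ 1 − 0.99^(1/m), which implies the joint bound and keeps the
  feasible set a box.
- The likelihood is non-convex, so the optimiser restarts from seeded
  random initialisations (default 20): biases start just inside their cap
  (half the cap odds), weights from N(0, 1). The best objective wins; a
  run that never reports convergence returns the best iterate flagged
  `converged=False`.
- The L2 penalty λ‖W‖² (default λ = 0.5) applies to weights only, not
  biases, and is not scaled by the number of observations; pseudo-R² and
  reported likelihoods are computed without the penalty.
- m is a user-fixed hyperparameter (defaults: 8 for three electrodes, 10
  for four or more); there is no automatic model selection. m = 1 is exact
  logistic regression, which the tests verify against an independent
  penalised-logistic solver.
- The McFadden null model is the intercept-only fit, whose MLE is the
  pooled spike fraction in closed form; a degenerate null (identical
  outcomes fitted perfectly, l₀ = 0) returns pseudo-R² = 0 with a warning.

## Synthetic neurons

The generator produces ground truth with the statistical and geometric
structure the analyses assume, not a biophysical simulation. Each neuron
is a soma plus a two-segment axon polyline that climbs from soma depth
(40 μm below the electrode plane) into the axon layer (12 μm below) and
runs straight; m anatomical sites sit at fixed arc-length spacing (default
20 μm — a free choice, as nothing pins discrete site counts to anatomical
extent). Site weights follow a point-source law: |w| = κ /
(distance^γ · noise_scale) with γ = 1 by default (configurable to 2) and a
1 μm distance floor. The gain κ = 500 μm·logit/μA makes a site 30 μm from
an electrode respond with slope ~17 logit/μA — a 10–90% stochastic
transition of ~0.26 μA around a ~1 μA threshold, i.e. the steep activation
curves of direct single-cell stimulation. Membrane noise is folded into
the sigmoid slope (noise_scale divides the weights); there is no separate
noise term.

Polarity: cathodic sites carry negative weights (driven by cathodic
currents). In the default `dual` mode each anatomical site gains a
mirrored anodic site with negated weights and an independently drawn
threshold, reproducing the paired cathodic/anodic threshold sheets seen
with charge-balanced pulses (not necessarily symmetric about the origin).

Per-site 50% thresholds (drive from the nearest electrode alone) are drawn
from a configurable range, default 0.5–1.5 μA, inside the stimulation
range. Every cell obeys a resting cap p(0) ≤ 0.01, enforced per site. When
a drawn threshold is incompatible with the cap (sigmoid too shallow), the
default resolution pushes the threshold outward, preserving the strict
distance-monotonicity of weight magnitudes; the alternative `rest_logit`
mode instead pins over-excitable sites at the resting ceiling and sharpens
their weights, preserving the drawn thresholds — modelling maximally
excitable cells pressed against the cap.

Randomness: one root seed; every operation derives an independent stream
by hashing (seed, cell_id, operation), so per-cell simulations are
reproducible and order-independent.

What the generator does **not** emulate: ion-channel kinetics, cable
dynamics, spike latency, refractoriness, axon-bundle activation, spike
sorting errors, and electrode-impedance nonuniformity. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative assumptions, not performance on experimental recordings.

## Selectivity

S = p_target · (1 − max non-target p), with the empty non-target maximum
defined as 0 so single-cell populations reduce to S = p. The aggregate
index takes the argmax-probability cell as target (ties to the lowest
index; the value is tie-invariant). Landscapes can be built from empirical
trial fractions or model predictions; provenance is recorded. Logit
transforms clip at ε (default 1/(2T̄) for T̄-trial data, i.e. 0.025 at 20
trials) before mapping to log-odds.

## GP surrogate and level-set sampling

Exact GP regression on (stimulus, logit-selectivity) pairs: RBF kernel
with signal variance, length scale, and white-noise variance fitted by
marginal-likelihood maximisation with seeded restarts (scikit-learn's
GaussianProcessRegressor). The "constant mean" is realised by centring on
the training-target mean, so far from all data the posterior reverts to
that mean with predictive sd √(signal + noise); the predictive convention
includes observation noise. The RBF length scale is bounded below by
0.2 μA (about one level spacing of the standard grid): without the floor,
marginal likelihood happily memorises near-binary logit targets with
sub-resolution length scales, collapsing both generalisation and the
posterior uncertainty the sampler relies on. Constant training targets
short-circuit to a flat posterior with a warning. A guard refuses training
sets beyond 10⁴ points, since exact GP cost grows cubically.

The sampler (β = 2, L = 3, in logit units — L = 3 corresponds to
S ≈ 0.95): per iteration, on unmeasured stimuli, LCB > L moves a stimulus
to the excluded set permanently (its measurements, if any, stay in the
training data); the batch is drawn uniformly among UCB > L. Budget and
batch size are counted in *stimulations*: each selected stimulus is
measured with T Bernoulli trials per cell (default 20), so the default
batch of 1000 stimulations selects 50 stimuli. Measurements are converted
to empirical aggregate selectivity (a per-cell mode would fit each cell's
logit-probability instead; the aggregate is the default because it is the
quantity the search targets). One uniform random warm-up batch precedes
the first GP fit; it depends only on the seed, so runs in different modes
share it. `random` mode replaces the acquisition with uniform sampling;
`hybrid` splits each batch between the two (default 50/50). An empty
eligible set terminates the run early — the expected behaviour on
landscapes with nothing selective to find.

The benchmark scenario (`make_selectivity_scenario`) is a three-cell
population built to contain a genuine high-selectivity region: a sensitive
target under the triplet (thresholds 0.3–0.5 μA) flanked at 70 μm by two
less-sensitive cells (1.4–1.7 μA), all sites at the resting ceiling so
slopes follow from thresholds and the landscape varies over a few grid
steps. On such landscapes, closed-loop sampling concentrates measurements
in and around the selective region; its high-region error is compared
against uniform random sampling at matched budgets in the acceptance
suite. The trade-off is real and expected: by neglecting unselective
regions, level-set sampling is typically *worse* than random sampling on
whole-landscape error — documented here rather than asserted as a test.

## Confidence intervals

Reported intervals use the normal approximation x̄ ± 1.96·s/√n with the
sample (ddof = 1) standard deviation.

## Threshold surfaces

Level sets are extracted by scanning grid edges whose endpoint
probabilities straddle the level (default 0.5) and linearly interpolating
the crossing; empirical surfaces interpolate the trial fractions directly
rather than fitting a model first. Connected components join crossings
within 1.5 grid steps (single-linkage on a radius graph), which separates
cathodic from anodic sheets. The planarity score fits a total-least-squares
plane (SVD) per component and reports the maximum RMS orthogonal residual
normalised by the grid's amplitude span: 0 for planes, rising with
curvature. The score is a diagnostic with a tunable threshold, not a
calibrated classifier of "linear" vs "nonlinear" cells.

## Problem sizes in the test suite

The test and acceptance runs use desk-scale sizes chosen to keep the suite
quick while preserving structure: 9-level grids for fitting unit tests,
the full 20-level grid for parameter recovery, surface taxonomy, and the
sampling benchmark (30 seeds × two modes at 4000-stimulation budgets with
500-stimulation batches, ≈2.5% grid coverage — the sparse-sampling regime
where adaptive acquisition is expected to matter). The paper-scale
settings (batch 1000, larger budgets) remain the library defaults.

## Known limitations

- The linear-OR fit has no noise model beyond Bernoulli counting and can
  overfit aggressively subsampled data; the GP estimates noise explicitly
  but needs enough coverage to do so.
- The generator's weight law and site placement are phenomenological;
  fitted weights should not be mapped back to anatomy.
- The sampler is evaluated offline against a frozen synthetic truth; a
  real closed loop adds spike-sorting and latency constraints not modelled
  here.
- Aggregate-selectivity landscapes inherit the eps-clipping of the logit
  transform; with 20 trials the landscape cannot distinguish selectivities
  above 1 − 1/40 from certainty.
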