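# Methods

`fermaug` studies one question end to end: does augmenting a small set of
fermentation experiments with VAE-generated synthetic time series make an
ethanol soft sensor more accurate and more consistent?  Because the
experimental probe data of the motivating study are not publicly deposited,
the package ships a fermentation simulator whose output has the statistical
structure that the analysis pipeline assumes; every downstream stage
(imputation, generative model, soft sensor, repeated evaluation, statistics)
runs unchanged on real CSV exports with the same schema.

## The simulated process

Each experiment is one cycle of very-high-gravity (VHG) ethanol
fermentation: ~10 h, ~500 samples at roughly 1-min spacing, seven channels —
four online probes (pH, redox potential in mV, capacitance in pF/cm,
temperature in degC) and three concentrations (ethanol, substrate, viable
cells, all g/L).

The kinetic core is the simplest model that produces the qualitative VHG
trajectories: Monod growth with a linear ethanol-inhibition ceiling and a
small maintenance term,

    dX/dt = mu_max * S/(K_s + S) * max(0, 1 - P/P_max) * X
    dS/dt = -(1/Y_xs) dX/dt - m X        (0 once S = 0)
    dP/dt = -Y_ps dS/dt

Defaults (`mu_max` 0.35 1/h, `K_s` 8 g/L, `Y_ps` 0.45, `Y_xs` 0.035,
`P_max` 113 g/L, `m` 0.01 1/h, `S0` 250 g/L, `X0` 8 g/L) are tuned so a
noise-free cycle reaches 108 g/L ethanol around 6.9 h — at which point the
micro-aeration flag switches on for the remaining ~3.5 h — and ends near
111 g/L at 10 h.  Temperature follows the standard VHG cascade: setpoints
34/32/30/28 degC with 2 degC drops when ethanol crosses 40/70/95 g/L.
Integration is fixed-step RK4 (10 substeps per output interval), which
preserves the linear invariant `Y_ps (S0 - S) = P` exactly and keeps the
sampled trajectories monotone; an adaptive solver would buy accuracy the
downstream statistics cannot see.

Probe channels are derived maps: capacitance is affine in viable cells
(0.9 pF/cm per g/L), redox declines affinely with ethanol (1 mV per g/L),
pH drifts 0.15 units below its setpoint over the cycle.  Three stochastic
layers mimic real inter-cycle structure:

* lognormal multipliers (CV 10%) on the kinetic constants per cycle —
  chosen high enough that a leave-one-cycle-out model faces a real
  generalization gap, the situation the augmentation method targets;
* per-cycle sensor-baseline shifts (redox sd 40 mV, capacitance sd
  0.3 pF/cm, pH setpoint sd 0.05) — probes are recalibrated between cycles
  and ORP electrodes in particular drift by tens of mV, which is what makes
  the absolute redox level an unreliable single predictor of ethanol;
* additive Gaussian measurement noise per channel (redox 5 mV,
  capacitance 0.15 pF/cm, ethanol 1.5 g/L, ...).

A default study is 11 cycles with two planted sensor faults: one cycle with
a completely missing redox channel (failed electrode) and one with a
+3.5 pF/cm capacitance bias (uncalibrated probe, roughly a third of the
normal signal span — "consistently far" from the other cycles).  Seeds split
hierarchically (study seed, then one child per cycle), so extending a study
never changes existing cycles.

What the simulator does **not** emulate: aeration and temperature feedback
on the kinetics, cell-treatment carry-over between cycles (cycles are
i.i.d. given their parameter draws), non-Gaussian sensor glitches, and any
calibration against real probe records.  Consequently, a passing pipeline
demonstrates that the method behaves as described **on data with this
structure** — it cannot certify performance on a real reactor.

## Preprocessing

Missing sensor values are KNN-imputed (k = 5, uniform weights) on the pool
of time-point samples across all experiments, using scikit-learn's
nan-aware Euclidean distance over the observed channels; observed entries
are returned bit-identical.  Normalization is per-channel min-max to
[0, 1], which pairs with the generator's bounded (sigmoid) decoder output;
in evaluation runs the normalizer is always fit on the iteration's training
originals only and reused unchanged for synthetic and held-out data.  A
`regrid` operation (linear interpolation onto an even grid) reconciles
experiments recorded with other sampling patterns; the canonical grid is
exactly 500 points over 10 h.

## The generator

The generative model is a convolutional variational autoencoder over whole
experiments shaped (500, 7).  Encoder: five stride-1 'same' convolutions
(kernel length 5; filters 32, 32, 48, 64, 64; ReLU; one dropout layer after
the final convolution), flatten to 32,000, dense 512 and 64 (ReLU), then
linear heads for the mean and log-variance of a 10-dimensional diagonal
Gaussian posterior.  Decoder: the mirror image, ending in a sigmoid.
Training minimizes the negative ELBO — a summed-squared-error
reconstruction term (unit-variance Gaussian likelihood up to constants)
plus the closed-form KL divergence to the standard-normal prior.
Sampling new experiments draws latent vectors, decodes, and
inverse-normalizes; the sampling distribution is discussed below.

The network and its backpropagation are written directly in numpy with an
Adam optimizer; at this scale (a dozen training sequences, ~33 M weights
dominated by the two 32,000 x 512 dense maps) a full framework adds nothing.

Training a 33 M-parameter VAE on eleven sequences for a few hundred
gradient steps is an extreme small-data, short-budget regime, and the
numerical choices below — all config fields or documented constants — are
what make it work.  The failure mode that dominates this regime is
posterior collapse: the KL gradient, renormalized per-coordinate by Adam,
steadily decays the posterior-mean head while the still-underfit decoder
provides no counteracting reconstruction gradient, and the generator ends
up producing forty copies of the mean trajectory.  A collapsed pool is
worse than useless downstream: it biases the soft sensor instead of
diversifying it.

* learning rate 2e-2, small mini-batches (1-2 sequences), linear
  learning-rate warmup over the first 20% of steps and linear decay to
  10% afterwards.  Warmup is essential: without it the very large
  first-epoch reconstruction gradients kill the decoder's ReLU stack for
  some seeds and training plateaus at the variance floor; the decay
  settles the oscillations that otherwise dominate the final epochs;
* the encoder body (convolutions + dense stack) is frozen as a fixed
  random projection (`encoder_lr_scale = 0`): at initialization it
  already separates the eleven experiments well, and any appreciable
  update rate kills its ReLU units within a few epochs because the
  gradients flowing back through the 32,000-dimensional flatten are
  enormous.  The trainable encoder parameters are the two posterior
  heads;
* KL annealing: the KL weight rises linearly from 0 to 1 over the first
  half of training, so the latent code is learned before it is
  regularized; the final objective is the plain ELBO;
* a 10x learning-rate multiplier on the latent bottleneck (the two
  posterior heads and the first decoder layer) — the slowest-learning
  pathway gets the most optimization;
* the log-variance head starts at bias -2 (posterior sd ~0.37), so the
  mean separation between experiments is not swamped by sampling noise
  before the heads have learned anything; the mean head starts random so
  the latent is engaged from the first step (an all-zero head
  initialization is kept as an option for testing);
* the decoder's output layer starts at 10% of its He scale with its bias
  at the logit of the per-channel training mean, so the budget is spent on
  structure rather than on re-learning the mean surface; its sigmoid is
  scaled to span [-0.1, 1.1] because min-max normalized data places every
  channel's extremes exactly at the plain sigmoid's unreachable
  asymptotes (generated output is clipped back to [0, 1]);
* log-variances clipped to [-8, 8] (gradient gated at the clip), keeping
  `exp` finite when mini-batch noise kicks the head around; a loose
  global gradient-norm ceiling (5000) only catches outright explosions;
* the dropout layer after the final encoder convolution defaults to rate
  0: with eleven training sequences, any measurable dropout blurs the
  experiment-identity signal the posterior must extract.

Sampling: by default new experiments are drawn from the *aggregate
posterior* — a uniform mixture over the training experiments' posteriors
q(z|x_i), with a temperature scaling the posterior spread — rather than
from the N(0, I) prior (which remains available).  With few training
sequences and short budgets the aggregate posterior never aligns closely
with the prior, so prior draws intermittently decode to mode-collapsed
mean curves; aggregate-posterior draws depend only on reconstruction
quality and produce the intended pool structure — synthetic curves
covering each original experiment's neighbourhood and the blends between
them.

With these settings a 100-epoch run reaches a reconstruction RMSE of
~0.1 (normalized units) with an actively used latent space (per-sample
KL of tens of nats) and a pool that spans the originals' spread.

Losses are recorded per epoch in the minimized sign convention
(reconstruction + KL = total = negative ELBO).

## The soft sensor

A fixed 4-80-60-1 feedforward network maps one timestep's four probe
values to that timestep's ethanol concentration (normalized space); whole
experiments are stacked row-wise for training.  It is scikit-learn's
`MLPRegressor` (ReLU, Adam, learning rate 1e-3, 200 epochs, plateau-based
early stopping disabled) behind a thin typed surface.  The map is pointwise
in time — no leakage across timesteps — verified by row-permutation
equivariance.

At prediction time, inputs are clamped per feature to the range seen in
training (configurable).  A ReLU network's behaviour outside its training
domain is undefined extrapolation, and deployed soft sensors routinely
clamp inputs to the calibrated sensor range; the clamp makes the response
to an out-of-range probe (exactly the biased-capacitance fault scenario)
deterministic and bounded instead of arbitrary.

## Evaluation protocol and statistics

The unit of splitting is the experiment.  Each iteration holds out one of
the 11 originals uniformly at random, trains on the other 10 plus 0 / 10 /
all of the synthetic pool (regimes `Original`, `Augmented10`,
`Augmented100`), and scores the held-out original in normalized target
space with four metrics: generalized R^2 (can be negative), adjusted R^2
computed with N = number of training *sets* (10/20/110 at full scale) and
p = 4 predictors, MAE and RMSE.  The per-iteration distributions of the
three regimes are compared with Welch's unequal-variance t-test (means) and
the mean-centered Levene test (spreads), two-sided, significance flagged at
p < 0.05, no multiple-testing correction.  One VAE is trained once on all
originals and its pool is reused across iterations; this mirrors the
study design but does leak the held-out experiment's shape into the pool,
so `repeated_evaluation` also accepts a per-split pool for a strict
no-leakage variant.

## Problem sizes

Full scale is 100 iterations, a 100-experiment pool and a 100-epoch
generator.  The bundled acceptance run and the heavyweight tests use a
deliberate desk-scale profile — 20 iterations, a 40-experiment pool,
`Augmented100` replaced by "all of the pool", and a lighter soft-sensor
fit (100 epochs, mini-batch 500) — chosen so the whole study (simulation
through comparison table) completes in roughly a quarter hour on one
core.  The generator keeps its 100 training epochs even at desk scale:
that epoch count is selected from the training-loss curve (losses decline
to roughly that point and then turn irregular), and a generator trained
much shorter sits below the fidelity threshold at which augmentation is
informative at all.  All sizes are ordinary parameters.

## What reproduces at desk scale, and what does not

Augmentation is net-informative only while the spread between experiments
(what a leave-one-experiment-out model must bridge) exceeds the
generator's reconstruction error (the noise a synthetic "ghost" of an
experiment injects).  The motivating study sat deep inside that regime:
its original-only soft sensor was both weak and wildly variable across
splits.  At desk scale this package's generator reaches a reconstruction
RMSE of ~0.1 normalized units — the same order as the simulated study's
generalization gap — so the regimes sit near the boundary: the
spread-reduction effect (the study's headline robustness result)
reproduces cleanly and monotonically across the three regimes, while the
mean-improvement and the anomalous-case rescue, which require the pool to
carry strictly more information than noise, do not reliably emerge.  The
acceptance suite asserts all three directions and reports honestly which
hold.

## Known limitations

* The simulator's realism claims are qualitative (trajectory shapes,
  fault structure, between-cycle variability), not quantitative.
* VAE training promises bit-reproducibility only for a fixed seed within
  one BLAS configuration; across BLAS builds only statistical
  reproducibility is claimed.
* The published study's absolute metric values depend on its unpublished
  experimental data and are not reproducible here; the pipeline reproduces
  the protocol, the derived-column arithmetic and the directional effects.
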