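# Methods

This note documents the models implemented in `shoalhmm`, the
preprocessing conventions, every numerical choice that the science does
not pin down, what the synthetic-data generators do and do not emulate,
and the package's known limitations.

## Observables and preprocessing

Input is a per-trial table of 2D positions (cm) of N ≥ 2 individuals at a
fixed frame rate, with a per-record `tracked` flag. The pipeline:

1. **Complete frames.** Only frames at which *all* N individuals are
   tracked are used, so nearest-neighbour identities and speeds are always
   concurrent and well defined.
2. **Smoothing.** Positions are averaged with a centred 3-frame moving
   window within each run of consecutive tracked frames. The half-window
   edge frames of each run are dropped rather than averaged with a
   shrunken window, so every retained position is a full-window mean;
   runs shorter than the window are discarded.
3. **Speeds.** The instantaneous speed over [t, t+Δ] is the Euclidean
   displacement between consecutive smoothed positions divided by the
   frame interval Δ, and is assigned to time t. This left-aligned
   convention is what makes "the neighbour's concurrent speed" a single
   well-defined number.
4. **Coarse-graining.** Raw speeds are heavily autocorrelated at the frame
   scale; one sample is kept every `step` seconds (default 1.0 s; 0.5 s
   and 2.0 s are supported for robustness analyses), with the phase
   anchored at the first frame of each run. Each run becomes one
   *segment*; any tracking gap ends a segment.
5. **Nearest neighbours.** At each retained sample time the neighbour is
   the other individual at minimal Euclidean distance; ties go to the
   lexicographically smallest id (deterministic and test-friendly).

Shoal-level context is provided by the standard order parameters
polarisation O_p = |Σ u_i|/N and rotation O_r = |Σ u_i × r_i|/N (scalar
cross product of in-plane unit vectors; u_i from the same smoothed
displacements as the speed pipeline). A frame in which any individual has
zero displacement has an undefined heading and is skipped, with the skip
count reported. The bivariate speed/neighbour-speed distribution uses a
fixed 60×60 grid with `v_max` defaulting to the data maximum, and its
permutation control re-pairs speeds and neighbour speeds uniformly at
random; the module stores raw counts, with the log display transform
(zero mapped to zero) as a separate presentation helper.

## The speed models

All emissions are gamma distributions parameterised by mean μ and
standard deviation σ (shape μ²/σ², scale σ²/μ) — supported on speeds ≥ 0
with one parameter each for location and spread.

* **Model 1** (2 parameters): V(t) ~ Γ(μ, σ), i.i.d.
* **Model 2** (6): a 2-state Markov chain with per-state constant-mean
  gamma emissions — movement vs near-stationary phases.
* **Model 3** (11): model 2 plus a third, *social* state emitting
  Γ(max(V_nn(t), mean_floor), σ₃): the emission mean is the nearest
  neighbour's concurrent speed. Concurrent (not lagged) coupling is a
  deliberate simplification, justified by the high autocorrelation of
  speed at the frame scale relative to reaction times; σ₃ is constant
  even though the mean varies, keeping the state parsimonious.

The likelihood is computed with the scaled forward algorithm; each
segment is initialised at the stationary distribution of the transition
matrix and segment contributions multiply. Per-step renormalisation keeps
the recursion stable for series of 10⁵ points and more. Viterbi decoding
is per-segment with the same initialisation.

### Zero speeds and the censoring threshold

Tracked animals frequently register speed exactly 0, where a gamma
density is zero or divergent, and the social emission can have shape ≪ 1
(neighbour nearly stationary), which places substantial probability mass
below any resolvable speed. Observations at or below `V_CLAMP = 1e-3`
cm/s are therefore treated as *censored at zero*: their emission
probability is the gamma mass P(V ≤ V_CLAMP) (via the regularised
incomplete gamma function) instead of a density value. This keeps the
likelihood finite without a zero-inflation component and, unlike
evaluating the density at the clamp point, keeps maximum likelihood
consistent: in recovery experiments the density-at-clamp variant
systematically shrank σ₃ (≈0.5 for a generating value of 1.0) and biased
the social-state transition probabilities by ≈0.05, with a log-likelihood
advantage over the generating parameters, i.e. a genuine bias of that
estimator rather than an optimiser artefact. The social emission mean is
floored at `MEAN_FLOOR = 0.05` cm/s, since a gamma mean of exactly zero
(stationary neighbour) is undefined.

### Fitting

Direct numerical maximum likelihood (not EM): means, SDs and σ₃ are
log-transformed and each transition row uses a multinomial-logit
transform with the diagonal as reference, so every candidate is
automatically positive and row-stochastic. L-BFGS-B runs on the
transformed parameters (bounds ±16 on the transformed scale, `ftol`
1e-8). Multi-start strategy: the first start is deterministic (state
means at the 10th/60th data quantiles, SDs at 0.7× the means,
persistences 0.9), the remaining `n_starts − 1` (default 10 in total)
jitter it; all starts run a short pilot optimisation (60 iterations) and
the best 3 are polished to full tolerance. This makes 10 starts
affordable on 2×10⁵-point datasets (a full fit takes a few minutes on one
CPU) without sacrificing basin coverage. Label switching is resolved
post hoc — non-social states ordered by decreasing mean, the social state
(structurally identified by its emission form) always last. One parameter
set is fitted jointly across all individuals, trials and segments.
Non-convergence of every start is flagged (`converged=False`), not
raised.

## Inference

* **AIC**: −2·loglik + 2k, k ∈ {2, 6, 11}. ΔAIC = AIC(model 2) −
  AIC(model 3); positive favours the social model.
* **Permutation test**: one *global* shuffle of nn_speeds against speeds
  across the whole dataset per replicate (shuffling within trials would
  leave some concurrence intact; the global shuffle destroys all of it,
  which is the quantity under test). Model 3 is refitted to each shuffled
  dataset with the original MLE as warm start plus the same number of
  random restarts as the observed fit, so the null is not
  optimisation-disadvantaged. p = #{permuted ΔAIC ≥ observed}/n_perm,
  ties counted as exceedances (conservative). The default n_perm is 100.
* **Robustness to data loss**: a fraction (default 30%) of pooled sample
  points is deleted uniformly at random; deletions split segments, and
  single-point fragments are retained (they contribute through the
  stationary distribution). Model 3 is refitted per replicate (default
  100) and the parameter table returned.

## Synthetic data

The social model cannot be simulated directly — state-3 emissions
condition on the neighbour's concurrent speed, which would itself need to
be simulated, and the model carries no spatial positions. The generator
therefore uses a **driver–focal** topology: each focal individual gets an
independent "driver" whose 2-state gamma-HMM speed series plays the role
of the nearest-neighbour covariate; the focal's 3-state chain then emits
speeds whose social-state mean is the driver's concurrent (floored)
speed. The coupling is one-directional by construction, which sidesteps
the circularity. Setting the transition probabilities into state 3 to
zero reduces the generator to a plain 2-state simulation (verified by KS
tests). Bernoulli gap injection deletes points independently and rebuilds
segments, exercising the likelihood's restart machinery.

Two study presets ship as YAML files. The `guppy` preset uses state means
2.96/0.20 cm/s, persistences 0.95/0.95/0.56 and a social→moving
probability of 0.44 (social↔stationary set to zero, as the remaining row
mass dictates); the `stickleback` preset uses state means 14.45/5.59
cm/s. Quantities the presets need but no published estimate fixes are set
once to plausible values of the system: σ₁ = 2.0, σ₂ = 0.15, σ₃ = 1.0
cm/s and entry probabilities 0.02/0.01 into the social state for the
guppy conditions (social behaviour rare: the chain's stationary law puts
≈3.6% of time in the social state);
σ₁ = 4.0, σ₂ = 2.0, σ₃ = 2.0 cm/s, persistences 0.9/0.9/0.7 and a
social-heavy transition structure for sticklebacks. Driver chains use the
2-state (guppy 3.05/0.22 cm/s) or the same (stickleback) means with
symmetric persistence. Experiments use 30 trials × 12 (guppy) or 8
(stickleback) individuals × 600 points at 1 s steps — 216,000 and 144,000
observations.

What the generator does **not** emulate: spatial embedding of the speed
series (drivers are not positioned, so the speed generator and the
position generator are separate), reciprocal or group-level coupling,
within-state autocorrelation beyond the Markov chain, measurement noise
on positions, and state-dependent gap structure. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not that real shoals satisfy those assumptions.

A separate correlated-random-walk generator (square arena, reflecting
walls, independent- or shared-heading modes) exercises the trajectory
pipeline and the order parameters.

## Characterisation summaries

From Viterbi decodings the package reports pooled state occupancy,
state-conditional speed samples with empirical CDFs, and — at time points
where every individual of a trial is decoded — the distribution of the
number of simultaneously social individuals. "Number of social nearest
neighbours" of a focal social fish is ambiguous between the out-edge
(its own nearest neighbour) and in-edge (individuals whose nearest
neighbour it is) readings of the neighbour graph; the default counts
social individuals over the union of both, and either single reading is
selectable (`neighbour_def`).

## Numerical conventions and degenerate inputs

* Stationary distributions come from the eigen-decomposition of Tᵀ; a
  chain whose eigenvalue 1 is not simple (reducible into closed classes)
  raises a degeneracy error. Inside the optimiser, where the logit
  transform guarantees strictly positive rows, a direct linear solve is
  used.
* Transition rows sum to 1 within 1e-10 by construction; fitted means and
  SDs are strictly positive (log transform).
* Segment invariants (regular spacing, disjoint cover) are validated on
  every `SpeedSeries` construction, including after gap injection and
  robustness deletion.
* Fewer than 3 lag pairs or zero variance make the lag autocorrelation
  undefined (error, not NaN). Empty histograms are returned as zero
  grids, not errors.
* The forward/Viterbi inner loops are JIT-compiled (numba); the test
  suite checks them against exhaustive path enumeration built only on
  scipy primitives, to 1e-10.

## Limitations

* Only the single nearest neighbour enters the social emission; metric or
  topological multi-neighbour interactions are out of scope.
* Transition probabilities are time-homogeneous; no covariates on the
  chain.
* The model is for analysis, not forward simulation of groups: predicting
  spatial trajectories from a fitted model would require extending it
  with positions and a lagged or reciprocal coupling.
* AIC comparisons between HMMs with different state counts can favour
  larger models for reasons unrelated to the hypothesis of interest; the
  permutation test exists precisely to calibrate the model-2 → model-3
  comparison, and conclusions should rest on it rather than on raw ΔAIC.
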