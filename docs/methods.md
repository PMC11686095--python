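# Methods

## The model

`cerloop` simulates a cortico-cerebellar loop in which a feedforward
cerebellar network learns to steer the dynamics of a weakly plastic cortical
recurrent network. The cortical module is a leaky rate RNN of `n_rnn = 50`
units,

    h_t = α h_{t−1} + W_hh f(h_{t−1}) + W_ih x_t + W_Ch c_t
    z_t = W_rdt f(h_t) + b_rdt,

with f = tanh and leak factor α ∈ [0, 1). α is the discrete remnant of a
continuous membrane equation with time constant τ_M sampled at step Δt,
α = exp(−Δt/τ_M) (`compute_alpha`). The conventional settings — τ_M ≈ 20 ms
at Δt = 50 ms for the motor tasks, τ_M ≈ 90 ms at Δt = 200 ms for the
cognitive tasks — both land near α ≈ 0.1, and α = 0.1 is the configured
default: α, not (τ_M, Δt), is the primary parameter, and the (1 − α)R_m
input scaling of the continuous form is dropped (absorbed into the weight
scale). The small α is deliberate: with fast-leaking units the network
cannot hold information intrinsically, so whatever task memory exists must
come from optimised connectivity or from the loop.

The cerebellar module is a two-layer feedforward expansion,

    c_t = W_PF relu(W_MF f(h_{t−1})),

whose hidden layer models the granule cells (default 1000, a 1:20
divergence from cortex, fixed mossy-fibre weights W_MF) and whose output
layer models Purkinje cells. No bias terms are used in the cerebellar
layers (only the cortical readout has a bias), which makes the zero state
an exact fixed point of the unforced loop. Four loop variants are
implemented: no feedback, readout feedback (the previous readout re-enters
through W_zh), cerebellar feedback, and a cerebellar-readout control where
the model output is produced directly by the cerebellum. For the cognitive
tasks the feedback vector is passed through a softmax before injection to
bound its values. An optional thalamic relay (4 hidden ReLU units fed by a
fixed random projection of cortical and cerebellar activity; both relay
matrices held fixed, since only the input projection is constrained to be a
fixed random map and plasticity is meant to live in the cerebellum and the
cortical input synapses) can replace the direct cerebello-cortical path,
and its output gain can be weakened (0.25) to model thalamic suppression.

Timestep bookkeeping: configs, logs and ablation windows are 1-based
inclusive (a window "8–12" covers five steps); internal arrays are 0-based
with one extra leading row on the state array for h_0 = 0.
`window_to_slice` is the single converter.

## Learning rules

The readout and the parallel fibres learn with local delta rules. The
parallel-fibre rule is behavioural timing-specific: for time window τ the
cerebellar output at t − τ is paired with the target at t,

    ΔW_PF ∝ (∂E/∂c_{t−τ}) g_{t−τ}ᵀ,

so after learning c_t predicts y_{t+τ}. The default single window is τ = 3
steps (≈150 ms at the motor step size, ≈600 ms at the cognitive one); the
temporal-basis configuration runs windows τ ∈ {0..5} simultaneously, each
owning an n_out-sized slice of a concatenated feedback vector. When
feedback is softmax-bounded, the rule is applied to the pre-softmax output
through a cross-entropy loss, which keeps the update local. Each window
normalises its gradient by its own number of valid (t, τ) pairs; pairs
reaching before the first timestep are skipped.

Cortical weights (when plastic) learn without backpropagation through time:
each synapse keeps a leaky eligibility trace ε_t = α ε_{t−1} + a_t of its
presynaptic activity and the gradient is Σ_t L_t ε_t with the instantaneous
learning signal L = W_rdtᵀ (∂E/∂z) ⊙ f′(h) (one-step spatial
backpropagation; routed through the cerebellar network instead for the
cerebellar-readout variant). Because the trace depends only on α and the
presynaptic activity it is stored per presynaptic unit — O(n) memory,
algebraically identical to the per-synapse form. Three regimes gate which
cortical weights learn: fixed RNN (readout only), input plastic (+W_ih,
W_Ch), fully plastic (+W_hh). Gradients are summed over timesteps, averaged
over the batch (the averaging convention of the loss: MSE over steps ×
batch × output dims, cross-entropy over steps × batch), and applied once
per 10-example trial by an ADAM optimizer (η = 0.001; η = 0.0025 for the
cortical weights in the delayed association task, which trains more
stably). A session is 1000 examples = 100 trials. Post-hoc analyses of the
learned dynamics (ablation, selectivity, prediction lead) use the weight
snapshot with the best error on a fixed 100-example held-out validation
set, scored after every session; the switching pipeline uses the live
end-state weights, since retention is defined on the sequential protocol. Cross-entropy targets are
one-hot labels; "belief" is the softmax probability of the correct class
and "selectivity" the pre-softmax logit of the correct class.

Weight initialisation: W_ih, W_hh, W_Ch ~ U(−a, a) with a = 1/√n_rnn;
W_rdt, W_MF, W_PF ~ U(−b, b) with the fan-in bound b = √(6/((1+s²)·fan_in))
= 1/√fan_in at slope s = √5; readout biases U(−1/√n_in, 1/√n_in).

## Tasks

All inputs are synthetic and generated from explicit RNG streams; Gaussian
noise (σ = 0.1) is added to every input timestep including the cue step.

* **Line drawing** (T = 20, MSE): one of six 10-d binary cues at step 1;
  five cues map to straight lines from the origin to endpoints evenly
  spaced on the unit circle (2π/5 apart, drawn as t/19 · y_end), one cue is
  no-go. * **Curl field**: same cues and endpoints, but the path is a
  semi-ellipse (parameter s ∈ [π, 2π]) that deviates laterally by ½ from
  the chord at its midpoint. * **Digit drawing**: same input scheme; six
  fixed 20-point piecewise-linear digit templates (0–5) in [0,1]², shipped
  as a versioned CSV fixture (`data/digit_templates_v1.csv`). The template
  shapes are this package's own arc-length-resampled polylines — any
  smooth, distinct 2-D shape set exercises the temporal-basis mechanism —
  and are frozen for reproducibility.
* **Evidence accumulation** (T = 45 + 5 delay, cross-entropy, softmax
  feedback): per presentation step the 2-d input is zero with probability
  ρ = 0.7, else a one-hot left/right pulse; the 3-way label (left / right /
  equal, ties exact) compares pulse counts and is supervised at the final
  step only. "History-centric" examples are those whose final-third
  evidence (presentation steps 31–45) alone points strictly to the wrong
  answer. A sub-second variant (shorter presentation, ρ = 0.5, no delay,
  α recomputed for Δt = 10 ms) is available through the generator
  parameters. * **Delayed association** (T = 15, cross-entropy, softmax
  feedback): one of two fixed disjoint 5-hot cues at step 1, silence
  after; supervision on the last six steps (10–15 at T = 15). The stated
  "5 timesteps from the end, timestep 10 onwards" is six steps inclusive;
  six are masked.

Context switching uses per-context parallel-fibre masks: each context's
active granule columns are a shared block (fraction = overlap) plus a
disjoint private block; private columns of a new context are freshly
initialised on entry. Ablation presets follow the study protocols:
[1–6, 8–13, 15–20] for the drawing tasks, [1–15, 15–30, 30–45] for
evidence accumulation (boundary steps shared), [1–5, 6–10, 11–15] and the
main window 8–12 for delayed association. Cerebellar ablation sets the
injected cerebellar drive to exactly zero inside the window (the softmax is
bypassed: a silenced cerebellum contributes no current, not a uniform
vector); partial cortical ablation zeroes a random unit subset fixed per
trial.

## Consolidation

After training with cerebellar feedback, unsupervised trials transfer the
loop's drive into the recurrent weights while W_Ch decays geometrically
(ΔW_Ch = −η_Ch W_Ch, default η_Ch = 0.1). The optimal rule sets
ΔW_hh = η_rnn F with F the minimum-norm least-squares solution of
F f(H) = W_Ch C over the trial's concatenated states (ridge optional for
rank-deficient cases); with η_rnn = η_Ch the geometric series
Σ η_rnn(1−η_Ch)^k exactly replaces the decaying drive. The biological rule
is the per-synapse ratio Δw_ij = η_rnn (W_Chʲ c_t)/Σ_k f(h_k,t)
(η_rnn = 3η_Ch = 0.3), a rank-one update whose induced change in recurrent
input is exactly proportional to the cerebellar input at each step. One
application per trial accumulates the rule as the **mean** over timesteps
and batch rather than a raw sum: a T-step sum makes each application T
times the scale the decay schedule can absorb and destabilises the
network, while the mean keeps
each application on the single-step scale, preserves the per-step
proportionality identity, and transfers the drive at the intended
η_rnn/η_Ch rate. Timesteps with near-zero population activity (the rule's
denominator) are skipped under a configurable guard (default |Σf| > 1).
The ratio rule carries a structural caveat: it presumes population activity
with a consistent sign, as rate-based activity would have. With tanh units
the population sum Σ_k f(h_k,t) is near zero-mean and flips sign across
timesteps in many trained networks, and then no single rank-one update
col·Σf(t) can reproduce a constant-sign cerebellar drive at every t — the
rule can destabilise such models regardless of how well they learned the
task. The least-squares rule has no such requirement and consolidates
reliably; it is the rule the shipped consolidation pipeline reports. No optimizer is used
during consolidation and no targets are needed; decay is applied after the
trial's ΔW_hh. The consolidation drive C uses the feedback as it actually
entered the cortex (post-softmax where the task bounds feedback).

## Analysis statistics

* **Selectivity / belief**: per-timestep correct-class logit /
  softmax probability, batch-averaged (optionally per condition).
* **Temporal choice regression**: binary left/right model choices are fit
  as sigmoid(Σ β_i E_i) over the three presentation windows (E_i = #right −
  #left pulses in window i) by minimising the exact negative log-likelihood
  (L-BFGS with analytic gradient); normalized weights β_i/Σβ are reported.
  Near-separable fits (|β| > 10) are retried with a ridge penalty and a
  warning. Tie-class trials are excluded.
* **Activity / covariance change**: per-neuron mean |Δactivity| normalised
  by the baseline-period std (zero-std neurons excluded), and 1 − Pearson
  correlation between the two periods' neuron-covariance matrices
  (∈ [0, 2]); reported changes are baseline-normalised by subtracting the
  within-baseline change.
* **Controllability energy**: input-free noise-driven rollouts of the loop
  (i.i.d. unit-variance Gaussian increments standing in for a Wiener
  process; the noise scale is configurable and reported with results)
  estimate Σ as the time-averaged state covariance over N = 500 samples
  after a 5-step burn-in; the energy vᵀΣv of the normalised cerebellar
  drive direction (probed at step 10) is compared with 100 random unit
  directions, all normalised by the top eigenvalue. For linear dynamics Σ
  solves the discrete Lyapunov equation Σ = AΣAᵀ + Q with A = αI + W_hh,
  which is the test oracle. The rollouts are run input-free, as the
  noise-driven form of the dynamics omits the external input term.
* **SNR decomposition**: population variance splits into a task-agnostic
  part (condition-average of within-condition variance) and a task part
  (total minus task-agnostic); SNR is their ratio. The decoding criterion
  reports the smallest granule count whose decoder error over the last 4
  sessions is below 5% for at least 4 of 5 seeds.
* **Prediction lead**: cue/time-averaged ‖c_t − z_{t+t0}‖ across delays,
  with the self-prediction baseline ‖z_t − z_{t+t0}‖; a cerebellum trained
  with window τ minimises the curve at t0 = τ.
* Cognitive-task error traces are smoothed with a Savitzky–Golay filter
  (window 25, order 3). Summary statistics report mean ± s.e.m. over
  replicate seeds.

## Problem sizes and what the tests show

The shipped pipelines run at reduced scale, chosen as the smallest runs
that express each qualitative effect clearly: line-drawing comparisons use
5 replicates × 40 sessions at the full 50/1000 cortex/granule geometry;
switching uses α = 0.5 (faster curl-field learning) with 20 baseline + 10
curl sessions and zero parallel-fibre overlap (500 private columns per
context); delayed association uses 30 sessions and evidence accumulation a
15-step presentation with 20 sessions; consolidation uses 40 unsupervised
trials. Test evaluation sets are 300–600 examples instead of 1000.

The generators emulate the *statistical structure* of the study conditions
(cue geometry, pulse sparsity, delay structure, noise level), not real
neural or behavioural recordings: passing tests show that the loop
mechanism — cerebellar prediction driving a weakly plastic cortex —
produces the claimed learning, switching, ablation and consolidation
phenomena under these idealised conditions. They do not show that the model
fits any particular animal's recordings, and effects whose magnitude
depends on training duration (e.g. exact error levels) are only meaningful
at the ordinal level here.

## Numerical choices and degenerate inputs

Least squares uses the minimum-norm pseudo-inverse solution; ridge
stabilisation is available but off by default. Cross-entropy probabilities
are clipped at 1e−12 before the log. Softmax subtracts the row maximum.
Ablation windows are validated against the trial length; a cerebellar time
window longer than the trial yields a zero update with a warning. Training
aborts with a diagnostic on non-finite loss. The evidence "equal" class is
exact ties only. RNG streams are spawned via `SeedSequence`; a stored
config plus master seed reproduces any run bit-identically.

## Known limitations

No Dale's law, spiking dynamics, or conduction delays. The comparison
against backpropagation-through-time training is out of scope (BPTT-like
unrolled gradients appear only as test oracles at toy sizes). Demixed PCA
is not implemented; selectivity traces serve as the latent-dynamics
readout. The thalamic relay is forward-only (its weights do not learn).
Consolidation quality depends on how well the model learned the task
beforehand; poorly trained replicates degrade gracefully but do not
consolidate to high accuracy.
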