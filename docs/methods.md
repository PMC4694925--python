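# Methods

`sornlab` simulates a self-organizing recurrent network (SORN) of binary
threshold neurons and reproduces, from seeded simulations alone, the
signature interactions between spontaneous and evoked cortical activity:
quenching of trial-to-trial variability at stimulus onset, spontaneous
activity that outlines and adapts to evoked responses, prior learning, and
decision behaviour reminiscent of sampling-based probabilistic inference.
This note documents the model, the analysis conventions, the numerical
choices, and what the synthetic tasks do and do not show.

## Network model

The network has `n_exc` (default 200) excitatory and `n_inh = 0.2 * n_exc`
inhibitory McCulloch–Pitts units, updated synchronously in discrete time:

    x(t+1) = Θ( W_EE x(t) − W_EI y(t) + W_EU u(t) − T_E(t) )
    y(t+1) = Θ( W_IE x(t+1) − T_I )

Θ is the elementwise Heaviside function; an activation of exactly zero does
not spike (strict inequality — an arbitrary but fixed convention that only
matters on a measure-zero set of configurations). The model is fully
deterministic: all variability comes from the stimulus sequence and the
initial conditions. `W_EE` is sparse (directed connection probability
`p_ee = 0.1`, no autapses); `W_EI` and `W_IE` are dense with rows scaled to
unit sum. Input letters drive pools of `n_input = 10` excitatory units with
constant weight `w_in = 0.5`; inhibitory units receive no direct input.
Excitatory thresholds are evenly spaced in `(0, 0.5)` and inhibitory
thresholds in `(0, t_i_max)`, each assigned to neurons in randomly permuted
order so that threshold rank is uncorrelated with input pools.

`t_i_max` controls the granularity-versus-range trade-off of inhibition:
`0.35` (default) gives fine-grained inhibitory feedback for continuously
stimulated tasks, while `1.0` — used for the trial-structured inference task
— balances excitation and inhibition so that the active inhibitory fraction
tracks the active excitatory fraction even through strong onset transients.

Three plasticity rules act on the excitatory population:

* **STDP** (`eta_stdp = 0.001`): `ΔW_EE = η (x(t+1) x(t)ᵀ − x(t) x(t+1)ᵀ)`
  on existing synapses only, clipped at zero (excitatory weights cannot
  change sign).
* **Synaptic normalization (SN)**: every nonzero weight is relaxed towards
  unit incoming *and* outgoing sums,
  `W_ij ← 0.9 W_ij + 0.1 W_ij / (0.5 Σ_k W_ik + 0.5 Σ_k W_kj)`.
  A doubly-normalized matrix is a fixed point; iterating from random
  weights converges to (approximately) unit row and column sums. Entries
  whose denominator is zero are left unchanged.
* **Intrinsic plasticity (IP)** (`eta_ip = 0.001`): thresholds track
  per-neuron target rates drawn uniformly from `(0.09, 0.11)`,
  `T_E ← T_E + η (x − H)`. Thresholds are unbounded; transient negative
  excursions self-correct.

**Structural plasticity.** Synapses driven to zero by STDP are pruned, and
with probability `structural_rate = 0.1` per plastic step one new random
non-autapse synapse is created with weight `0.001`. This synapse turnover is
what makes the connection fraction converge to a task-dependent equilibrium
instead of being frozen at its initial value; both mechanisms can be
disabled in the config for ablations.

**Within-step order**: state update → STDP → structural change → SN → IP.
The ordering is not uniquely determined by the update equations; this is the
convention of the original SORN model family, and IP uses the state the
update just produced.

**Determinism and reproducibility.** A master seed spawns independent child
streams for topology, thresholds, stimulus order, ambiguous-cue draws and
end-of-phase shuffles, so e.g. the stimulus sequence is reproducible
independently of the network topology. With `noise_sd = 0` whole phase
trajectories are bit-exact across repeats. Optionally, Gaussian noise of
standard deviation `noise_sd` can be added to the excitatory pre-threshold
activation; the number of spikes flipped relative to the noiseless update is
tracked so that noise levels can be expressed as a fraction of disturbed
spikes.

**Implementation.** The phase loop is compiled (numba) over a dense weight
matrix plus an explicit adjacency list, which makes the per-step cost scale
with the ~`p_ee·N²` live synapses; a 120 000-step three-phase experiment at
N=200 runs in about two seconds. The single-step operations (`step`,
`apply_stdp`, `apply_synaptic_normalization`, `apply_ip`) are the readable
reference path, and a test verifies that the compiled loop reproduces their
composed trajectory spike-for-spike.

## Stimulation protocols

Every experiment has three phases, with the excitatory state vector randomly
permuted across neurons at each phase boundary:

1. **self-organization** (50 000 steps): all plasticity on;
2. **training** (20 000 steps): STDP, SN and structural plasticity off, IP
   on; evoked activity is recorded and readouts are trained;
3. **testing** (50 000 steps): IP only; either spontaneous activity (no
   input) or test stimuli.

Presets:

* `random_letters` — ten one-step letters in random alternation, then
  spontaneous activity; used for the basic statistics (ISI/CV, connection
  fraction, lognormal weights, conditional firing probabilities).
* `sequence_recognition` — train on "ABCD" (or, as control, all 24
  permutations) with a fixed 10-step blank, "sleep" (stimulus-free period,
  default 20 000 steps), then probe with "ABCD", "DCBA", "A_CD", "E_CD".
  The *sequence magnitude* is the mean excitatory population rate over the
  four word steps, averaged over presentations. The probe is deliberately
  brief (default 25 presentations per word): IP remains active during
  testing and returns every neuron to its target rate on a timescale of
  ~`1/eta_ip` steps, so any probe long compared to that measures the
  homeostatic equilibrium — identical rates for every stimulus by
  construction — rather than the learned transient response.
* `sequence_priors` — continuous random interleaving of "ABCD" and "EFGH"
  with configurable priors (no blanks); training-phase evoked states and
  testing-phase spontaneous states feed the geometry analyses. Optional
  extra evoked phases (the natural words vs the restructured controls
  "EDCBA"/"HGF", which reuse the same input units) support the KL
  comparison.
* `inference` — trials "AXXX___…"/"BXXX___…" with cue prior `p(A)`,
  disjoint A/B input pools, a shared three-step mask "XXX" and uniform
  10–15-step blanks. During testing, ambiguous cues activate `f_A·10`
  randomly drawn units of the A pool and the complement from the B pool,
  redrawn every trial. Two least-squares readouts (bias term appended) map
  the state at the first blank after the mask to indicators of "A" and "B";
  the network decision is their argmax (exact ties go to "A"). Readout
  training uses equally many A- and B-trial decision states regardless of
  the prior, plus an equal share of letter-evoked states with target zero.

## Analyses

* **ISI/CV**: per-neuron inter-spike intervals (neurons with fewer than 10
  ISIs excluded); an exponential is fitted by maximum likelihood to the
  pooled ISIs above a 2-step cutoff, because the discrete dynamics distort
  only the very small intervals.
* **Fano factor**: causal sliding-window counts (width 5 steps, giving a
  mean of ~0.5 spikes per bin at the 0.1 target rate); mean and variance
  over trials per neuron and offset, restricted to units without direct
  input; the population FF per offset is the variance-on-mean regression
  slope through the origin with weights `1/mean²` (the inverse asymptotic
  variance of the variance estimator), which equals the precision-weighted
  mean of the per-neuron variance/mean ratios.
* **Mean matching**: (neuron, condition) points are histogrammed by mean
  count (bin width 0.2); the greatest common distribution is the bin-wise
  minimum over offsets; points are randomly discarded per offset to match
  it, the FF is recomputed, and the result is averaged over 10 discard
  randomizations. Matching is done per realization (two cue conditions
  each) and summaries are averaged over realizations. The discarded
  fraction is reported; it depends on the size of the onset rate transient
  of the non-input units and is smaller here (~0.5 on average) than the
  roughly two thirds reported for the original analysis.
* **Geometry**: Hamming distance is the metric for all binary-state
  comparisons. PCA components are fitted on the last 2500 training-phase
  evoked states (mean-centered, unscaled). Nonmetric MDS (Kruskal's
  normalized stress-1) embeds the pooled pairwise distances of 150
  spontaneous, 150 time-shuffled spontaneous (each neuron's train permuted
  independently, preserving rates) and 150 evoked states from a random
  5-letter subset. The KL divergence between evoked and spontaneous pattern
  distributions uses a random 16-unit subsample, an add-one prior over the
  2^16 patterns (patterns unseen in both recordings enter through a closed
  form), equal recording lengths, and exclusion of the first 5000 steps of
  each phase.
* **Pattern decoding**: spontaneous states are labelled by the letter of
  the nearest evoked state in a balanced dictionary (blanks removed, every
  letter equally frequent, entries ordered by letter and then recording
  position so that ties resolve to the smallest letter index and earliest
  entry). Word frequencies count the two training words and their
  reversals, normalized over that four-word total.
* **Transition prediction**: the SVD `W_EE = U Σ Vᵀ` is read as a set of
  linear transitions `v_i → u_i σ_i`; each singular vector is matched to
  the letter of the evoked state with the maximal dot product, evaluating
  both sign orientations of the (u_i, v_i) pair jointly and keeping the
  better one (this makes the prediction invariant to the sign ambiguity of
  the SVD); singular values accumulate on letter-transition cells and rows
  are normalized.
* **Predictions from spontaneous activity**: per condition and offset, a
  least-squares map (bias appended, pseudoinverse for wide problems) from
  the state one step before cue onset to the state at onset+Δt, fitted on
  the first half of trials and scored on the second as the mean per-trial
  Pearson correlation, pooled across conditions after averaging. The
  baseline repeats the regression with pre-onset states permuted across
  trials within condition, which keeps the stimulus-average response (bias)
  but destroys trial-specific information. Decision prediction works the
  same way per ambiguity class with the decision as a two-column target;
  its shuffled baseline can exceed 50% whenever the decisions are biased.

## Noisy-channel reference model

Each input unit is a binary channel: a stimulated unit is received as
active with probability `theta1`, an unstimulated one as inactive with
probability `theta0`. A Naive Bayes classifier over the 20 channel outputs
with prior `p(A)` gives the posterior in closed form from the active counts
(n_a, n_b) — computed in log space — and the counts under an ambiguous cue
with fraction `f_A` are exact binomial convolutions, so the decision curve
`p(A | f_A)` is an exact 11×11 expectation (Monte Carlo sampling is kept
only as a test oracle). Fitting to measured decision curves is an
exhaustive grid search over `theta ∈ {0.05, …, 0.95}²` minimizing the
summed mean squared deviation across priors (`NoisyChannelModel(...).fit()`).

Two exact symmetries matter: the curve is invariant under the evidence
bit-flip `(θ1, θ0) → (1−θ1, 1−θ0)` and under the stimulated/unstimulated
role swap `(θ1, θ0) → (θ0, θ1)`, so every grid minimum is a four-fold
class. The fit groups near-exact ties and reports the informative
representative (largest θ1, then largest θ0). The fitted error surface on
simulated decision curves has a shallow ridge of nearly equivalent
(θ1, θ0) pairs; the reported pair should be read with that flatness in
mind, and neighbouring grid cells along the ridge fit almost equally well.

## Problem sizes and what the tests show

The packaged experiments use the standard phase lengths (50 000 / 20 000 /
50 000 steps) at N = 200. The acceptance script fits the channel model to
decision curves averaged over 8 realizations per prior across the nine
priors 0.1–0.9 for each plasticity condition, and uses 3 realizations each
for the PCA and Fano-factor summaries (~5 minutes on one CPU). The test
suite uses 5 realizations × 5 priors for the channel fit, 10 realizations
for the variability-quenching analysis, 20 + 20 for sequence recognition,
6 realizations for the KL comparison and 3 for the prediction suite.

The synthetic tasks are the study conditions themselves — the model *is*
the object of study, and no external data enters. What passing tests show
is therefore internal: that the implemented plasticity rules produce the
claimed emergent phenomena under the stated stimulation statistics. They do
not show anything about real neural tissue beyond the qualitative analogies
the tasks were designed to capture (one-step binary dynamics stand in for
~25 ms spiking windows; letters stand in for oriented gratings or
face/vase stimuli; the linear readout stands in for the experimenter's
decoder, not for a biological decision circuit).

Known limitations, measured honestly on this implementation: the
three-component PCA of two-word evoked activity explains 33–38% of the
variance (sensitive to the inhibitory ceiling; 40–50% is only reached with
coarser inhibition), decoded spontaneous word frequencies overrepresent the
frequent word strongly (~0.98 at a 2/3 prior), mean matching discards
about half of the data points rather than two thirds, and the fitted channel
parameters for the full-plasticity condition land on the flat ridge
between (0.80, 0.50) and (0.90, 0.35) depending on the realization set.
Fano-factor levels sit slightly below 1, as expected for binarized
(Bernoulli-like) counts.
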