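# Methods

`bgexplore` implements a spiking basal-ganglia model of a 5-choice
reversal-learning task, together with the task environment, an
ideal-observer analysis, and the behavioral quantification pipeline used to
compare model and human-style data. This note documents the model, the
choices made where the design was open, the problem sizes used by the test
suite, and the known limitations.

## Circuit model

Seven Izhikevich populations (striatal D1 and D2 projection neurons, GPe,
STN, SNr, superior colliculus principal cells and SC interneurons) are each
divided into five sub-channels, one per saccade target position. Membrane
dynamics follow the quadratic single-compartment form

    C dV/dt = n2 V^2 + n1 V + n0 - U + I,   dU/dt = a (b (V - vr) - U),

with reset `V <- c`, `U <- U + d` at `vpeak`, integrated by forward Euler
at dt = 0.1 ms. Synapses are conductance-based: a presynaptic spike
instantaneously increments the postsynaptic AMPA or GABA conductance by the
synaptic weight; conductances decay with a common 80 ms time constant
(implemented with the exact per-step factor `exp(-dt/tau)`, which is stable
and matches the closed form, rather than a naive Euler decay). The synaptic
current is `I_base - gAMPA (V - 0 mV) - gGABA (V + 90 mV)`.

Neuron parameter sets: striatal projection neurons use the
Humphries-Wood-Gurney medium spiny neuron (C = 50, k = 1, vr = -80,
vt = -25, a = 0.01, b = -20, c = -55, d = 150), which is silent without
strong cortical drive; GPe/SNr use fast tonically active sets and STN a
slow-recovery set in the classic `0.04 V^2 + 5V + 140` form; SC principal
cells use thalamo-cortical parameters (rebound excitability) and SC
interneurons the fast-spiking set. Baseline currents and per-neuron Poisson
background inputs are calibrated so that, without cortical input, striatum
and SC are silent while SNr (~60-70 Hz), GPe (~45 Hz) and STN (~10 Hz) are
tonically active; a calibration test pins this profile.

Connectivity follows the canonical pathways: cortex -> {StrD1, StrD2, STN,
SC} (all-to-all, plastic), StrD1 -> SNr, StrD2 -> GPe, GPe -> SNr, SNr ->
SC and GPe -> STN channel-aligned, STN -> SNr diffuse (surround
suppression), STN -> GPe all-to-all (plastic), plus local inhibition
(diffuse StrD1 collaterals, SC interneuron loop) and SC -> StrD1/StrD2
feedback. Fixed projections are drawn stochastically with per-projection
connection probabilities. GPe -> STN is wired channel-aligned rather than
diffuse: the mechanism requires that inhibiting one GPe sub-channel
disinhibits the *same* STN sub-channel, which is also the activity pattern
the learning rule needs (see below). Synaptic delays are zero (one
integration step). All weights are stated at a reference scale of 100
neurons per channel and multiplied by `100 / n_per_channel` when a smaller
network is built, so total synaptic drive is size-invariant.

A response is read out by one leaky integrator per channel (tau = 100 ms)
that accumulates SC spikes; the first integrator to cross threshold selects
that position. If none crosses within the 1 s stimulus window, the largest
integrator wins provided it exceeds a small floor; otherwise the response
is missing. The floor reconciles the argmax-at-timeout readout with the
task's missing-response reward case.

## Trial structure and dopamine

Each trial simulates a rest phase, the stimulus window (cortex Poisson
drive at 40 Hz until the response), and a post-response window in which the
selected SC sub-channel receives feedback drive (which propagates to the
selected striatal sub-populations), the reward signal is computed, and -
130 ms after stimulus offset - the dopamine traces are set to R and then
decay exponentially (19 ms for STN->GPe; 60 ms for the cortical
projections, a supplementary constant exposed in config). R uses a reward
constant r = 0.25 and a response-specific prediction P_i updated by
+-r/50 and clamped to [-r, 0.8 r]: rewarded response i yields `r - P_i`,
any unrewarded response `-r`, a missing response `-r/2`. A legacy variant
with a single scalar prediction (relaxing toward r when rewarded, reset to
zero otherwise, tau = 60) is available as a config/model variant.
Predictions are never reset between blocks: the model learns continuously.

## Learning rules

**Cortical dopamine-modulated STDP.** Pre/post spike traces feed a
per-synapse eligibility trace (pre-then-post pairings increase it,
post-then-pre decrease it); the weight changes as
`alpha * da_sign * DA(t) * E` plus a small per-presynaptic-spike
normalization decrement, with `da_sign = +1` for cortex->StrD1 and
cortex->STN and `-1` for cortex->StrD2 (dopamine bursts potentiate the
direct and hyperdirect pathway and depress the indirect pathway, and
conversely for dips). The trace constants are supplementary in the source
material and were calibrated here as a package design choice: tau_pre =
80 ms, tau_post = 15 ms, delta_pre = 1, delta_post = 6.667, tau_E = 150 ms.
The near-balance `delta_pre * tau_pre ~ delta_post * tau_post` makes the
eligibility of synapses onto neurons that merely co-fire with cortex
approximately zero (the rate-product terms cancel), so eligibility is
dominated by the post-response feedback window, in which only the selected
channel's striatal neurons fire while the cortical traces decay. This is
what makes credit assignment response-specific: with a shared cortical
input, all striatal channels fire during the stimulus, and without the
balance the eligibility would be nearly uniform across channels (we
verified that a naive parameterization then lets a few unrewarded trials
depress every channel's input below the striatal firing cliff, deadlocking
the model). Learning rates were calibrated so that initial learning
converges after about two to three unrewarded selections, as a calibration
test asserts.

**Cortex->SC STDP.** The same trace machinery applied directly to the
weight, without dopamine; it mimics a cortical activation route to the SC.

**Homeostatic dopamine-gated STN->GPe rule.** Fast spike traces A
(increment 0.001, tau = 50 ms) are compared against their slow running
means (tau = 1e4 ms). A phasic decrease (A/Abar < 0.9) drives LTP, a
phasic increase (A/Abar > 1.1) drives LTD, the postsynaptic deviation
weighted 10-fold; both terms are soft-bounded by the distance to the
weight limits [0, 0.00145 nS] and the net change is gated by the positive
part of the dopamine trace, scaled by 1/tau_w. Weights start uniformly at
0.00063 nS. Slow traces start at zero; a guard treats ratios with an empty
activity history as inside the deadband, so startup transients cause no
plasticity, and the early LTD-bias while the slow traces converge is
shared by all synapses and does not affect the channel pattern. During a
rewarded trial the selected channel's StrD2 feedback inhibits its GPe
sub-channel (phasic decrease -> LTP into the selected GPe column) and
disinhibits its STN sub-channel (phasic increase -> LTD out of the
selected STN row), reproducing the characteristic activity/weight-change
signature. Accumulated over blocks, GPe columns of frequently rewarded
positions end up stronger than never-rewarded ones (the cluster pattern).

The nominal tau_w is 5.06e8 ms; at that speed the cluster pattern needs
the full 60-block experiment to emerge. The reduced `desk` preset uses
tau_w = 2e6 ms so the pattern emerges within a ~15-25-block run, and a
conversion gain maps the nS-scale weights of the rule onto the model's
conductance units.

## Problem sizes and presets

The default configuration is the full-scale network (100 neurons per
sub-channel, 100 cortical neurons, 1.7 s rest). The `desk` preset -- used
by the test suite and the acceptance script -- runs 10 neurons per
sub-channel and 20 cortical neurons with a 250 ms rest phase and the
accelerated tau_w above; weights rescale automatically. The long-horizon
tests further shorten the rest/stimulus windows and run 12-14 blocks with
5 seeds; the initial-learning checks run the first block only for 30
seeds. These sizes were chosen so the full suite completes on a single
CPU in well under half an hour.

## Behavioral analysis pipeline

Only blocks containing at least 7 consecutive rewarded trials are
analyzed. Each block is segmented into perseverative trials (leading
consecutive unrewarded selections of the previously rewarded position),
exploration trials, and the terminal run of consecutive rewarded
selections; the first rewarded selection of that run and sporadic later
selections of the previous position count as exploration. Missing
responses are dropped before segmentation. Immediately repeated identical
unrewarded selections collapse into one. Category selection counts per
exploration phase are weighted by the number of available positions per
category (the previously and newly rewarded positions are not available);
in the never-rewarded design this yields the fixed weights 1/2 (never
category) and 1 (frequent category).

The per-phase unrewarded-exploration-trial series of each agent is fitted
with a single-parameter exponential between fixed endpoints y0 = 1.5 and
y1 (0.5 never / 0.86 rarely, the ideal-observer expectations), with phase
indices normalized by the version's maximum phase count (59 / 69). Negative
time constants are allowed via a symmetric increasing branch so the fit is
not biased toward decay. The half-life ln2/tau is clipped to [-1, 1] and
mapped to a learning rate gamma in [-1, 1] (1 fast decrease, 0 flat, -1
fast increase); tau = 0 maps to gamma = 0. Start/mid/end periods take the
first, centered, and last k exploration phases after excluding post-break
phases (k = 6 for participant-style data, configurable down to 1 per
period for model runs).

## Ideal observer

The observer excludes the previously rewarded position and every response
already found unrewarded; with the exploration bias it exhausts the
frequently rewarded candidates (uniformly, without replacement) before
trying the others. Expectations are computed by exact enumeration of the
decision tree in rational arithmetic and cross-checked by Monte-Carlo
simulation of the same policy. For the rarely-rewarded design the four
previous/new category combinations are weighted by the marginal category
probabilities of the 14-block structure (6/7 frequent, 1/7 rare), treated
as independent across the block pair; this reproduces the printed 0.86
(= 42/49). A toggle conditions the new category on the previous position
being excluded (no block rewards the same position twice in a row), which
gives 0.94 instead and is provided for sensitivity analysis only.

## Synthetic behavioral agents

The analysis pipeline can be exercised without the spiking model by
scripted agents that follow the ideal-observer policy: unbiased, biased
(with a configurable lapse rate), perseverative, and a switching agent
that turns the bias on at a given phase. They emulate the trial-table
schema exactly (perseverative lead-in, exploration, terminal rewarded
run). They do not emulate response latencies, missing responses, or
gradual within-phase learning, so pipeline tests on them validate the
bookkeeping and the fits, not the neural dynamics.

## Known limitations

* The reduced-scale model reproduces the direction and mechanism of the
  published effects, not their printed magnitudes: full-protocol statistics
  (reversal-phase unrewarded selections, mean learning rates, the
  interpolation correlation of 0.33 over 6400 runs) require the full-scale
  network and run lengths.
* At the reduced scale the model does not terminate every block at the
  15-consecutive criterion; unsuccessful blocks occur and are excluded by
  the analysis pipeline exactly as unsuccessful human blocks are. Late in
  long reduced-scale runs the plastic cortical weights drift toward less
  selective configurations, which inflates exploration-trial counts and
  biases the per-agent learning-rate fits downward in both the plastic and
  the ablated model (see the decision record in the test suite's
  acceptance checks).
* Supplementary constants of the source model (per-population noise rates,
  connection probabilities, cortical plasticity constants) are not public;
  the values here are calibrated choices, exposed in `defaults.yaml` so
  they can be corrected if the originals become available.
* The SC is five discrete positions, not a continuous motor map; saccade
  kinematics, eye-tracking timing, and human-protocol execution are out of
  scope (the human block schedule exists only as a schedule generator).
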