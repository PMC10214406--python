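# Default configuration of the spiking basal-ganglia model.
#
# All constants of the membrane and synapse equations are addressable here
# by population / projection name.  Striatal neuron parameters follow the
# Humphries-Wood-Gurney medium spiny neuron; SNr/GPe/STN use tonically
# active parameter sets in the classic quadratic form; SC principal cells
# use thalamo-cortical parameters (rebound after disinhibition) and SC
# interneurons the fast-spiking set.  Projection weights are stated at the
# reference scale of 100 neurons per channel and are rescaled by
# 100 / n_per_channel when a smaller network is built, so total synaptic
# drive is size-invariant.

dt_ms: 0.1

layout:
  n_channels: 5
  n_per_channel: 100
  n_cortex: 100

synapse:
  tau_g_ms: 80.0
  E_AMPA: 0.0
  E_GABA: -90.0

populations:
  StrD1:
    neuron: {C: 50.0, n2: 1.0, n1: 105.0, n0: 2000.0, a: 0.01, b: -20.0, vr: -80.0, vpeak: 40.0, c: -55.0, d: 150.0}
    I_base: 0.0
    noise: {rate_exc: 2000.0, w_exc: 0.018, rate_inh: 2000.0, w_inh: 0.012}
  StrD2:
    neuron: {C: 50.0, n2: 1.0, n1: 105.0, n0: 2000.0, a: 0.01, b: -20.0, vr: -80.0, vpeak: 40.0, c: -55.0, d: 150.0}
    I_base: 0.0
    noise: {rate_exc: 2000.0, w_exc: 0.018, rate_inh: 2000.0, w_inh: 0.012}
  GPe:
    neuron: {C: 1.0, n2: 0.04, n1: 5.0, n0: 140.0, a: 0.1, b: 0.2, vr: 0.0, vpeak: 30.0, c: -65.0, d: 2.0}
    I_base: -3.5
    noise: {rate_exc: 100.0, w_exc: 0.005, rate_inh: 0.0, w_inh: 0.0}
  STN:
    neuron: {C: 1.0, n2: 0.04, n1: 5.0, n0: 140.0, a: 0.005, b: 0.265, vr: 0.0, vpeak: 30.0, c: -65.0, d: 2.0}
    I_base: 2.0
    noise: {rate_exc: 100.0, w_exc: 0.005, rate_inh: 0.0, w_inh: 0.0}
  SNr:
    neuron: {C: 1.0, n2: 0.04, n1: 5.0, n0: 140.0, a: 0.1, b: 0.2, vr: 0.0, vpeak: 30.0, c: -65.0, d: 2.0}
    I_base: 7.0
    noise: {rate_exc: 100.0, w_exc: 0.003, rate_inh: 0.0, w_inh: 0.0}
  SC:
    neuron: {C: 1.0, n2: 0.04, n1: 5.0, n0: 140.0, a: 0.02, b: 0.25, vr: 0.0, vpeak: 30.0, c: -65.0, d: 0.05}
    I_base: -1.0
    noise: {rate_exc: 100.0, w_exc: 0.005, rate_inh: 0.0, w_inh: 0.0}
  SCi:
    neuron: {C: 1.0, n2: 0.04, n1: 5.0, n0: 140.0, a: 0.1, b: 0.2, vr: 0.0, vpeak: 30.0, c: -65.0, d: 2.0}
    I_base: -1.0
    noise: {rate_exc: 100.0, w_exc: 0.005, rate_inh: 0.0, w_inh: 0.0}

# Fixed projections.  pattern: within (channel-aligned) | all (every channel
# pair) | cross (all channel pairs except the own channel).  Weights are
# per-synapse conductance increments at reference scale; p is the
# connection probability.
projections:
  StrD1->SNr: {pattern: within, sign: inh, p: 0.5, weight: 0.0028}
  StrD2->GPe: {pattern: within, sign: inh, p: 0.5, weight: 0.0024}
  GPe->SNr:   {pattern: within, sign: inh, p: 0.5, weight: 0.0005}
  GPe->STN:   {pattern: within, sign: inh, p: 0.5, weight: 0.0004}
  STN->SNr:   {pattern: all,    sign: exc, p: 0.25, weight: 0.00018}
  SNr->SC:    {pattern: within, sign: inh, p: 0.6, weight: 0.004}
  SC->SCi:    {pattern: within, sign: exc, p: 0.6, weight: 0.0002}
  SCi->SC:    {pattern: within, sign: inh, p: 0.6, weight: 0.00075}
  StrD1->StrD1: {pattern: all, sign: inh, p: 0.3, weight: 0.02}
  SC->StrD1:  {pattern: within, sign: exc, p: 0.6, weight: 0.05}
  SC->StrD2:  {pattern: within, sign: exc, p: 0.6, weight: 0.05}

# Cortex drive and the four plastic cortical projections.
cortex:
  rate_hz: 40.0
  projections:
    CTX->StrD1: {rule: da_stdp, da_sign: +1, alpha: 4.0e-4, delta_norm: 0.0,
                 w_init_lo: 0.045, w_init_hi: 0.065, w_max: 0.09}
    CTX->StrD2: {rule: da_stdp, da_sign: -1, alpha: 2.0e-4, delta_norm: 0.0,
                 w_init_lo: 0.030, w_init_hi: 0.040, w_max: 0.06}
    CTX->STN:   {rule: da_stdp, da_sign: +1, alpha: 1.0e-5, delta_norm: 0.0,
                 w_init_lo: 8.0e-5, w_init_hi: 1.2e-4, w_max: 2.0e-4}
    CTX->SC:    {rule: sc_stdp, da_sign: +1, alpha: 1.0e-7, delta_norm: 0.0,
                 w_init_lo: 4.0e-5, w_init_hi: 8.0e-5, w_max: 2.0e-4}
  stdp:
    tau_pre_ms: 80.0
    tau_post_ms: 15.0
    delta_pre: 1.0
    delta_post: 6.667
    tau_E_ms: 150.0

# Homeostatic STN->GPe rule; weights in nS at reference scale.
stn_gpe:
  tau_A_ms: 50.0
  tau_Abar_ms: 1.0e+4
  tau_w_ms: 506.0e+6
  delta_A: 0.001
  epsilon: 10.0
  w_max: 0.00145
  tau_DA_ms: 19.0
  w_init: 0.00063
  weight_gain: 0.45   # conversion of the nS-scale weights to model conductance units

dopamine:
  tau_ctx_ms: 60.0

# Post-selection feedback: SC neurons of the selected channel receive an
# extra Poisson drive, which propagates to StrD1/StrD2 via the SC feedback
# projections.
feedback:
  rate_hz: 600.0
  weight: 0.005
  tail_ms: 170.0   # drive continues this long after reward delivery

integrator:
  increment: 1.0
  tau_ms: 100.0
  threshold: 30.0
  floor: 0.5

timing:
  rest_ms: 1700.0
  max_stimulus_ms: 1000.0
  reward_delay_ms: 130.0
  post_reward_ms: 250.0

reward:
  r: 0.25
  tau_P: 50.0
  tau_P_legacy: 60.0
  mode: specific

# Reduced problem sizes for quick runs: smaller populations (weights are
# rescaled automatically), a shorter rest phase, and a faster STN->GPe
# weight time constant so the cluster pattern emerges within a short run.
presets:
  desk:
    layout: {n_per_channel: 10, n_cortex: 20}
    timing: {rest_ms: 250.0, max_stimulus_ms: 800.0}
    stn_gpe: {tau_w_ms: 2.0e+6}
  full: {}
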