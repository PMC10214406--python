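"""Synaptic learning rules.

Three rules act on different projections:

* **Dopamine-modulated STDP with an eligibility trace** (cortex -> StrD1,
  StrD2, STN).  Pre/post spike traces feed a per-synapse eligibility trace E
  (pre-then-post pairings increase it, post-then-pre decrease it); the
  weight change is ``alpha * E * da_sign * DA`` plus a small normalization
  decrement per presynaptic spike.  ``da_sign = +1`` for the direct and
  hyperdirect pathway (dopamine bursts potentiate), ``-1`` for D2-type
  synapses of the indirect pathway (the contrary effect).

* **Plain STDP** (cortex -> SC), the same trace machinery applied directly
  to the weight without dopamine modulation.

* **Dopamine-gated homeostatic rule** (STN -> GPe).  Fast spike traces A
  are compared with their slow running means Abar; a phasic rate decrease
  (A/Abar < 0.9) drives LTP and a phasic increase (A/Abar > 1.1) drives
  LTD, each soft-bounded by the distance to the weight limits, and the sum
  is gated by the positive part of the dopamine signal - only dopamine
  increases change these weights.

Discrete-time convention (shared with the compiled engine): per step, decay
traces, then apply spike increments, then apply spike-triggered eligibility
or weight events with the updated traces, then integrate the continuous
weight-change terms over dt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DaStdpParameters",
    "StdpTraces",
    "HomeostaticParameters",
    "HomeostaticTraces",
    "update_da_stdp",
    "update_sc_stdp",
    "update_stn_gpe",
]


@dataclass(frozen=True)
class DaStdpParameters:
    tau_pre: float = 15.0
    tau_post: float = 15.0
    delta_pre: float = 1.0
    delta_post: float = 1.0
    tau_E: float = 600.0
    alpha: float = 1.0
    delta_norm: float = 0.0
    da_sign: int = +1
    w_min: float = 0.0
    w_max: float = np.inf

    def __post_init__(self) -> None:
        if min(self.tau_pre, self.tau_post, self.tau_E) <= 0:
            raise ValueError("time constants must be positive")
        if self.alpha < 0 or self.delta_norm < 0:
            raise ValueError("alpha and delta_norm must be non-negative")
        if self.da_sign not in (+1, -1):
            raise ValueError("da_sign must be +1 or -1")


@dataclass
class StdpTraces:
    """Pre/post spike traces and (for the dopamine rule) eligibility."""

    A_pre: np.ndarray
    A_post: np.ndarray
    E: np.ndarray | None = None  # (n_pre, n_post)

    @classmethod
    def zeros(cls, n_pre: int, n_post: int, eligibility: bool = True) -> "StdpTraces":
        return cls(
            A_pre=np.zeros(n_pre),
            A_post=np.zeros(n_post),
            E=np.zeros((n_pre, n_post)) if eligibility else None,
        )


def _advance_traces(
    traces: StdpTraces,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    params: DaStdpParameters,
    dt: float,
    eligibility: bool,
) -> StdpTraces:
    A_pre = traces.A_pre * np.exp(-dt / params.tau_pre)
    A_post = traces.A_post * np.exp(-dt / params.tau_post)
    A_pre = A_pre + params.delta_pre * pre_spikes
    A_post = A_post + params.delta_post * post_spikes
    E = None
    if eligibility:
        E = traces.E * np.exp(-dt / params.tau_E)
        # pre-then-post pairings potentiate, post-then-pre depress
        E = E + np.outer(A_pre, post_spikes) - np.outer(pre_spikes, A_post)
    return StdpTraces(A_pre=A_pre, A_post=A_post, E=E)


def update_da_stdp(
    traces: StdpTraces,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    DA: float,
    w: np.ndarray,
    params: DaStdpParameters,
    dt: float = 0.1,
) -> tuple[StdpTraces, np.ndarray]:
    """One step of the dopamine-modulated rule; returns (traces', new w)."""
    pre = np.asarray(pre_spikes, dtype=float)
    post = np.asarray(post_spikes, dtype=float)
    traces = _advance_traces(traces, pre, post, params, dt, eligibility=True)
    dw = params.alpha * params.da_sign * DA * traces.E * dt
    if params.delta_norm:
        dw = dw - params.delta_norm * pre[:, None]
    w = np.clip(w + dw, params.w_min, params.w_max)
    return traces, w


def update_sc_stdp(
    traces: StdpTraces,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    w: np.ndarray,
    params: DaStdpParameters,
    dt: float = 0.1,
) -> tuple[StdpTraces, np.ndarray]:
    """One step of the plain (non-dopaminergic) STDP rule for cortex -> SC."""
    pre = np.asarray(pre_spikes, dtype=float)
    post = np.asarray(post_spikes, dtype=float)
    traces = _advance_traces(traces, pre, post, params, dt, eligibility=False)
    dw = params.alpha * (np.outer(traces.A_pre, post) - np.outer(pre, traces.A_post))
    if params.delta_norm:
        dw = dw - params.delta_norm * pre[:, None]
    w = np.clip(w + dw, params.w_min, params.w_max)
    return traces, w


# ---------------------------------------------------------------------------
# Homeostatic STN -> GPe rule


@dataclass(frozen=True)
class HomeostaticParameters:
    """Constants of the dopamine-gated homeostatic rule (defaults: full scale)."""

    tau_A: float = 50.0
    tau_Abar: float = 1.0e4
    tau_w: float = 506.0e6
    delta_A: float = 0.001
    epsilon: float = 10.0
    w_max: float = 0.00145
    tau_DA: float = 19.0
    w_init: float = 0.00063
    deadband_lo: float = 0.9
    deadband_hi: float = 1.1

    def __post_init__(self) -> None:
        if not (0 < self.deadband_lo < 1 < self.deadband_hi):
            raise ValueError("deadband must bracket 1")
        if not (0 < self.w_init < self.w_max):
            raise ValueError("w_init must lie strictly inside (0, w_max)")


@dataclass
class HomeostaticTraces:
    A_pre: np.ndarray
    A_post: np.ndarray
    Abar_pre: np.ndarray
    Abar_post: np.ndarray

    @classmethod
    def zeros(cls, n_pre: int, n_post: int) -> "HomeostaticTraces":
        return cls(
            A_pre=np.zeros(n_pre), A_post=np.zeros(n_post),
            Abar_pre=np.zeros(n_pre), Abar_post=np.zeros(n_post),
        )


def _phasic_deviation(
    A: np.ndarray, Abar: np.ndarray, params: HomeostaticParameters
) -> tuple[np.ndarray, np.ndarray]:
    """(decrease, increase) deviations outside the deadband, per neuron.

    Slow traces below the numerical guard mean the neuron has essentially no
    activity history yet; the ratio is then treated as inside the deadband
    so startup transients cause no plasticity.
    """
    ratio = np.ones_like(A)
    valid = Abar > 1e-12
    ratio[valid] = A[valid] / Abar[valid]
    dec = np.maximum(params.deadband_lo - ratio, 0.0)
    inc = np.maximum(ratio - params.deadband_hi, 0.0)
    return dec, inc


def update_stn_gpe(
    traces: HomeostaticTraces,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    DA: float,
    w: np.ndarray,
    params: HomeostaticParameters,
    dt: float = 0.1,
) -> tuple[HomeostaticTraces, np.ndarray]:
    """One step of the homeostatic STN -> GPe rule; returns (traces', new w).

    Weight changes only occur while the dopamine signal is positive; LTP is
    driven by phasic activity decreases and LTD by phasic increases, each
    weighted epsilon-fold for the postsynaptic neuron, and soft-bounded so w
    stays in [0, w_max].
    """
    pre = np.asarray(pre_spikes, dtype=float)
    post = np.asarray(post_spikes, dtype=float)
    decay = np.exp(-dt / params.tau_A)
    A_pre = traces.A_pre * decay + params.delta_A * pre
    A_post = traces.A_post * decay + params.delta_A * post
    Abar_pre = traces.Abar_pre + dt * (A_pre - traces.Abar_pre) / params.tau_Abar
    Abar_post = traces.Abar_post + dt * (A_post - traces.Abar_post) / params.tau_Abar
    new_traces = HomeostaticTraces(A_pre, A_post, Abar_pre, Abar_post)

    da_pos = max(DA, 0.0)
    if da_pos > 0.0:
        dec_pre, inc_pre = _phasic_deviation(A_pre, Abar_pre, params)
        dec_post, inc_post = _phasic_deviation(A_post, Abar_post, params)
        ltp = dec_pre[:, None] + params.epsilon * dec_post[None, :]
        ltd = inc_pre[:, None] + params.epsilon * inc_post[None, :]
        frac = w / params.w_max
        dw = da_pos * ((1.0 - frac) * ltp - frac * ltd) * dt / params.tau_w
        w = np.clip(w + dw, 0.0, params.w_max)
    return new_traces, w
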