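"""Single-compartment Izhikevich neurons with conductance-based synapses.

Membrane dynamics per neuron:

    C dV/dt = n2 V^2 + n1 V + n0 - U + I
      dU/dt = a (b (V - vr) - U)
      if V >= vpeak: V <- c, U <- U + d

with the synaptic current

    I = I_base - gAMPA (V - E_AMPA) - gGABA (V - E_GABA)

Conductances jump by the synaptic weight when a presynaptic spike arrives
and otherwise decay exponentially with a common time constant (80 ms).
Integration is forward Euler at dt = 0.1 ms; the conductance decay uses the
exact per-step factor exp(-dt/tau), which is stable and matches the closed
form.  Background activity is supplied by independent Poisson sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParameters",
    "PopulationState",
    "SynapseConstants",
    "PoissonSource",
    "synaptic_current",
    "step_population",
    "accumulate_and_decay_conductances",
    "poisson_spikes",
]


@dataclass(frozen=True)
class NeuronParameters:
    """Izhikevich parameters for one population.

    The quadratic coefficients (n2, n1, n0) admit both the classic
    ``0.04 V^2 + 5 V + 140`` parameterization (C = 1) and the
    ``k (V - vr)(V - vt)`` form expanded as n2 = k, n1 = -k (vr + vt),
    n0 = k vr vt.
    """

    C: float
    n2: float
    n1: float
    n0: float
    a: float
    b: float
    vr: float
    vpeak: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("capacitance must be positive")
        if self.a <= 0:
            raise ValueError("recovery rate a must be positive")
        if self.vpeak <= self.c:
            raise ValueError("spike cutoff must exceed the reset potential")

    @classmethod
    def from_kform(
        cls, C: float, k: float, vr: float, vt: float, a: float, b: float,
        c: float, d: float, vpeak: float,
    ) -> "NeuronParameters":
        return cls(
            C=C, n2=k, n1=-k * (vr + vt), n0=k * vr * vt,
            a=a, b=b, vr=vr, vpeak=vpeak, c=c, d=d,
        )


@dataclass
class PopulationState:
    """Per-neuron membrane state of one population."""

    V: np.ndarray
    U: np.ndarray
    gAMPA: np.ndarray
    gGABA: np.ndarray
    spiked: np.ndarray  # bool, spikes emitted on the current step

    @classmethod
    def resting(cls, n: int, params: NeuronParameters, v0: float | None = None) -> "PopulationState":
        v = np.full(n, params.vr if v0 is None else v0, dtype=float)
        u = params.b * (v - params.vr)
        return cls(
            V=v, U=u,
            gAMPA=np.zeros(n), gGABA=np.zeros(n),
            spiked=np.zeros(n, dtype=bool),
        )

    @property
    def n(self) -> int:
        return self.V.shape[0]


@dataclass(frozen=True)
class SynapseConstants:
    tau_g: float = 80.0
    E_AMPA: float = 0.0
    E_GABA: float = -90.0
    I_base: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_g <= 0:
            raise ValueError("conductance time constant must be positive")
        if self.E_GABA >= self.E_AMPA:
            raise ValueError("inhibitory reversal must lie below excitatory")


@dataclass(frozen=True)
class PoissonSource:
    """Independent Bernoulli(rate*dt) spike sources, one per target neuron."""

    rate: float  # spikes/s per source
    n_sources: int
    weight: float = 1.0
    sign: str = "excitatory"

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("Poisson rate must be non-negative")
        if self.sign not in ("excitatory", "inhibitory"):
            raise ValueError("sign must be excitatory or inhibitory")


def synaptic_current(state: PopulationState, constants: SynapseConstants) -> np.ndarray:
    """I = I_base - gAMPA (V - E_AMPA) - gGABA (V - E_GABA), per neuron."""
    return (
        constants.I_base
        - state.gAMPA * (state.V - constants.E_AMPA)
        - state.gGABA * (state.V - constants.E_GABA)
    )


def step_population(
    state: PopulationState,
    params: NeuronParameters,
    I: np.ndarray,
    dt: float = 0.1,
) -> PopulationState:
    """One forward-Euler step of the membrane equations plus the reset rule."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    I = np.asarray(I, dtype=float)
    if I.shape != state.V.shape:
        raise ValueError("current vector does not match the population size")
    V, U = state.V, state.U
    dV = (params.n2 * V * V + params.n1 * V + params.n0 - U + I) / params.C
    dU = params.a * (params.b * (V - params.vr) - U)
    Vn = V + dt * dV
    Un = U + dt * dU
    if not (np.all(np.isfinite(Vn)) and np.all(np.isfinite(Un))):
        raise FloatingPointError("membrane integration diverged")
    spiked = Vn >= params.vpeak
    Vn = np.where(spiked, params.c, Vn)
    Un = np.where(spiked, Un + params.d, Un)
    return PopulationState(V=Vn, U=Un, gAMPA=state.gAMPA, gGABA=state.gGABA, spiked=spiked)


def accumulate_and_decay_conductances(
    state: PopulationState,
    exc_input: np.ndarray | float = 0.0,
    inh_input: np.ndarray | float = 0.0,
    dt: float = 0.1,
    constants: SynapseConstants = SynapseConstants(),
) -> PopulationState:
    """Exponentially decay both conductances, then add this step's summed
    presynaptic spike weights (instantaneous conductance increments)."""
    exc = np.asarray(exc_input, dtype=float)
    inh = np.asarray(inh_input, dtype=float)
    if np.any(exc < 0) or np.any(inh < 0):
        raise ValueError("summed spike weights must be non-negative")
    decay = np.exp(-dt / constants.tau_g)
    return PopulationState(
        V=state.V, U=state.U,
        gAMPA=state.gAMPA * decay + exc,
        gGABA=state.gGABA * decay + inh,
        spiked=state.spiked,
    )


def poisson_spikes(
    source: PoissonSource, duration: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli spike indicators, shape (n_steps, n_sources)."""
    p = source.rate * dt / 1000.0
    if p >= 1.0:
        raise ValueError("rate * dt must stay below one spike per step")
    n_steps = int(round(duration / dt))
    return rng.random((n_steps, source.n_sources)) < p
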