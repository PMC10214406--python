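"""Network assembly and simulation windows.

Builds the five-channel basal-ganglia circuit: cortex (Poisson drive),
striatal D1/D2 populations, GPe, STN, SNr, and the superior colliculus with
its inhibitory interneurons, wired along the direct (cortex -> StrD1 ->
SNr), indirect (cortex -> StrD2 -> GPe -> SNr) and hyperdirect (cortex ->
STN -> SNr) pathways, the recurrent STN-GPe loop (STN -> GPe plastic under
the homeostatic dopamine-gated rule), SNr -> SC disinhibition, local
inhibition in StrD1 and SC, and SC -> striatum feedback.  A selected
response is read out by one leaky integrator per channel accumulating SC
spikes.

The per-step dynamics run in the compiled kernel
(:func:`bgexplore.engine.run_window`); this module prepares the flat arrays,
draws all stochastic inputs with a numpy Generator (so runs are reproducible
given config + seed), and exposes the analysis-facing operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import engine
from .task import Outcome

__all__ = [
    "POPULATIONS",
    "ChannelLayout",
    "Projection",
    "IntegratorState",
    "Network",
    "WindowResult",
    "build_network",
    "run_stimulus_window",
    "apply_selection_feedback",
    "mean_channel_weight_matrix",
    "activity_deviation",
    "SpikingAgent",
    "save_weights",
]

POPULATIONS = ("StrD1", "StrD2", "GPe", "STN", "SNr", "SC", "SCi")
PLASTIC_CTX_TARGETS = {"StrD1": "da_stdp", "StrD2": "da_stdp", "STN": "da_stdp", "SC": "sc_stdp"}
REF_N_PER_CHANNEL = 100
REF_N_CORTEX = 100


@dataclass(frozen=True)
class ChannelLayout:
    n_channels: int = 5
    n_per_channel: int = 100
    n_cortex: int = 100

    @property
    def pop_size(self) -> int:
        return self.n_channels * self.n_per_channel

    def pop_slice(self, name: str) -> slice:
        i = POPULATIONS.index(name)
        return slice(i * self.pop_size, (i + 1) * self.pop_size)

    @property
    def n_total(self) -> int:
        return len(POPULATIONS) * self.pop_size

    def channel_of(self, name: str, local_index: int) -> int:
        return local_index // self.n_per_channel


@dataclass
class Projection:
    source: str
    target: str
    pattern: str  # within | all | cross
    sign: str  # exc | inh
    p: float
    weight: float
    plasticity: str = "none"  # none | da_stdp | sc_stdp | stn_gpe


@dataclass
class IntegratorState:
    value: np.ndarray
    increment: float
    tau_ms: float
    threshold: float
    floor: float


@dataclass
class WindowResult:
    selection: int  # channel index, -1 when none crossed
    step: int
    counts: np.ndarray  # (T, n_pops * n_channels) spike counts
    raster: np.ndarray | None = None


class Network:
    """Flat-array state of the built circuit plus its plastic machinery."""

    def __init__(self, config: dict, layout: ChannelLayout, rng: np.random.Generator):
        self.config = config
        self.layout = layout
        self.build_rng = rng
        self.dt = float(config["dt_ms"])
        N = layout.n_total

        syn = config["synapse"]
        self.eA = float(syn["E_AMPA"])
        self.eG = float(syn["E_GABA"])
        self.g_decay = math.exp(-self.dt / float(syn["tau_g_ms"]))

        # per-neuron parameter vectors
        self.V = np.empty(N)
        self.U = np.empty(N)
        self.gA = np.zeros(N)
        self.gG = np.zeros(N)
        names = ("C", "n2", "n1", "n0", "a", "b", "vr", "vpeak", "c", "d")
        self.par = {k: np.empty(N) for k in names}
        self.Ibase = np.empty(N)
        self.p_noise_exc = np.empty(N)
        self.w_noise_exc = np.empty(N)
        self.p_noise_inh = np.empty(N)
        self.w_noise_inh = np.empty(N)
        self.chan_index = np.empty(N, dtype=np.int64)
        for pi, pop in enumerate(POPULATIONS):
            sl = layout.pop_slice(pop)
            spec = config["populations"][pop]
            for k in names:
                self.par[k][sl] = float(spec["neuron"][k])
            self.Ibase[sl] = float(spec["I_base"])
            noise = spec["noise"]
            self.p_noise_exc[sl] = float(noise["rate_exc"]) * self.dt / 1000.0
            self.w_noise_exc[sl] = float(noise["w_exc"])
            self.p_noise_inh[sl] = float(noise["rate_inh"]) * self.dt / 1000.0
            self.w_noise_inh[sl] = float(noise["w_inh"])
            idx = np.arange(layout.pop_size)
            self.chan_index[sl] = pi * layout.n_channels + idx // layout.n_per_channel
        self.invC = 1.0 / self.par["C"]
        self.V[:] = np.where(self.par["vr"] != 0.0, self.par["vr"], -65.0)
        self.U[:] = self.par["b"] * (self.V - self.par["vr"])

        # fixed projections -> dense excitatory / inhibitory matrices
        scale_iz = REF_N_PER_CHANNEL / layout.n_per_channel
        scale_ctx = REF_N_CORTEX / layout.n_cortex
        self.scale_iz = scale_iz
        self.scale_ctx = scale_ctx
        self.Wexc = np.zeros((N, N))
        self.Winh = np.zeros((N, N))
        self.roster: dict[str, Projection] = {}
        for key, pspec in config["projections"].items():
            src, dst = key.split("->")
            proj = Projection(
                source=src, target=dst, pattern=pspec["pattern"],
                sign="exc" if pspec["sign"] == "exc" else "inh",
                p=float(pspec["p"]), weight=float(pspec["weight"]),
            )
            self.roster[key] = proj
            mask = self._pattern_mask(src, dst, proj.pattern, proj.p, rng)
            w = proj.weight * scale_iz
            target = self.Wexc if proj.sign == "exc" else self.Winh
            ssl, dsl = layout.pop_slice(src), layout.pop_slice(dst)
            target[ssl, dsl] += w * mask

        # cortex -> {StrD1, StrD2, STN, SC} plastic projections
        nctx = layout.n_cortex
        self.Wctx = np.zeros((nctx, N))
        self.alpha_col = np.zeros(N)
        self.sign_col = np.ones(N)
        self.use_da_col = np.zeros(N, dtype=np.uint8)
        self.wmin_col = np.zeros(N)
        self.wmax_col = np.full(N, np.inf)
        self.dnorm_col = np.zeros(N)
        stdp = config["cortex"]["stdp"]
        self.d_pre = math.exp(-self.dt / float(stdp["tau_pre_ms"]))
        self.d_post = math.exp(-self.dt / float(stdp["tau_post_ms"]))
        self.d_E = math.exp(-self.dt / float(stdp["tau_E_ms"]))
        self.inc_pre = float(stdp["delta_pre"])
        self.inc_post = float(stdp["delta_post"])
        for key, pspec in config["cortex"]["projections"].items():
            dst = key.split("->")[1]
            sl = layout.pop_slice(dst)
            lo = float(pspec["w_init_lo"]) * scale_ctx
            hi = float(pspec["w_init_hi"]) * scale_ctx
            self.Wctx[:, sl] = rng.uniform(lo, hi, size=(nctx, layout.pop_size))
            self.alpha_col[sl] = float(pspec["alpha"]) * scale_ctx
            self.sign_col[sl] = float(pspec["da_sign"])
            self.use_da_col[sl] = 1 if pspec["rule"] == "da_stdp" else 0
            self.wmin_col[sl] = float(pspec.get("w_min", 0.0)) * scale_ctx
            self.wmax_col[sl] = float(pspec["w_max"]) * scale_ctx
            self.dnorm_col[sl] = float(pspec["delta_norm"]) * scale_ctx
            self.roster[key] = Projection(
                source="CTX", target=dst, pattern="all", sign="exc", p=1.0,
                weight=0.5 * (lo + hi), plasticity=pspec["rule"],
            )
        self.Apre = np.zeros(nctx)
        self.Apost = np.zeros(N)
        self.E = np.zeros((nctx, N))
        self.ctx_rate = float(config["cortex"]["rate_hz"])

        # STN -> GPe homeostatic projection (kept on the nS scale of its rule)
        hom = config["stn_gpe"]
        npop = layout.pop_size
        self.Wsg = np.full((npop, npop), float(hom["w_init"]))
        self.sg_gain = float(hom["weight_gain"]) * scale_iz
        self.hom = hom
        self.hom_decay = math.exp(-self.dt / float(hom["tau_A_ms"]))
        self.hom_dt_tauAbar = self.dt / float(hom["tau_Abar_ms"])
        self.hom_dt_tauw = self.dt / float(hom["tau_w_ms"])
        self.Ah = np.zeros(N)
        self.Abh = np.zeros(N)
        self.roster["STN->GPe"] = Projection(
            source="STN", target="GPe", pattern="all", sign="exc", p=1.0,
            weight=float(hom["w_init"]), plasticity="stn_gpe",
        )

        # dopamine traces: [cortical projections, STN->GPe]
        self.da = np.zeros(2)
        self.da_decay_ctx = math.exp(-self.dt / float(config["dopamine"]["tau_ctx_ms"]))
        self.da_decay_sg = math.exp(-self.dt / float(hom["tau_DA_ms"]))

        intg = config["integrator"]
        self.integrator = IntegratorState(
            value=np.zeros(layout.n_channels),
            increment=float(intg["increment"]),
            tau_ms=float(intg["tau_ms"]),
            threshold=float(intg["threshold"]),
            floor=float(intg["floor"]),
        )
        self.spk_prev = np.zeros(N, dtype=np.uint8)
        self.plastic_ctx = True
        self.plastic_sg = True
        self.feedback_channel: int | None = None

    # -- construction helpers ------------------------------------------------

    def _pattern_mask(
        self, src: str, dst: str, pattern: str, p: float,
        rng: np.random.Generator,
    ) -> np.ndarray:
        lay = self.layout
        npop = lay.pop_size
        ch_src = np.arange(npop) // lay.n_per_channel
        ch_dst = np.arange(npop) // lay.n_per_channel
        if pattern == "within":
            allowed = ch_src[:, None] == ch_dst[None, :]
        elif pattern == "cross":
            allowed = ch_src[:, None] != ch_dst[None, :]
        elif pattern == "all":
            allowed = np.ones((npop, npop), dtype=bool)
        else:
            raise ValueError(f"unknown connectivity pattern {pattern!r}")
        mask = allowed & (rng.random((npop, npop)) < p)
        if src == dst:
            np.fill_diagonal(mask, False)
        return mask

    # -- state snapshot ------------------------------------------------------

    _STATE_ARRAYS = (
        "V", "U", "gA", "gG", "Wctx", "Wsg", "Apre", "Apost", "E",
        "Ah", "Abh", "da", "spk_prev",
    )

    def get_state(self) -> dict[str, np.ndarray]:
        state = {k: getattr(self, k).copy() for k in self._STATE_ARRAYS}
        state["integrator"] = self.integrator.value.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self._STATE_ARRAYS:
            getattr(self, k)[...] = state[k]
        self.integrator.value[...] = state["integrator"]

    # -- simulation ----------------------------------------------------------

    def run_window(
        self,
        duration_ms: float,
        rng: np.random.Generator,
        *,
        ctx_on: bool = False,
        feedback_channel: int | None = None,
        feedback_until_ms: float | None = None,
        stop_at_threshold: bool = False,
        deliver_at_ms: float | None = None,
        R: float = 0.0,
        record_raster: bool = False,
    ) -> WindowResult:
        lay = self.layout
        N = lay.n_total
        T = int(round(duration_ms / self.dt))
        nse = (rng.random((T, N)) < self.p_noise_exc).astype(np.uint8)
        nsi = (rng.random((T, N)) < self.p_noise_inh).astype(np.uint8)
        if ctx_on:
            p_ctx = self.ctx_rate * self.dt / 1000.0
            ctx_sp = (rng.random((T, lay.n_cortex)) < p_ctx).astype(np.uint8)
        else:
            ctx_sp = np.zeros((T, lay.n_cortex), dtype=np.uint8)
        fb = self.config["feedback"]
        if feedback_channel is not None and feedback_channel >= 0:
            sl = lay.pop_slice("SC")
            base = sl.start + feedback_channel * lay.n_per_channel
            fb_idx = np.arange(base, base + lay.n_per_channel, dtype=np.int64)
            p_fb = float(fb["rate_hz"]) * self.dt / 1000.0
            fb_sp = (rng.random((T, fb_idx.size)) < p_fb).astype(np.uint8)
            if feedback_until_ms is not None:
                fb_sp[int(round(feedback_until_ms / self.dt)):, :] = 0
            fb_w = float(fb["weight"])
        else:
            fb_idx = np.zeros(0, dtype=np.int64)
            fb_sp = np.zeros((T, 0), dtype=np.uint8)
            fb_w = 0.0
        da_step = -1 if deliver_at_ms is None else int(round(deliver_at_ms / self.dt))
        counts = np.zeros((T, len(POPULATIONS) * lay.n_channels), dtype=np.int64)
        raster = (
            np.zeros((T, N), dtype=np.uint8) if record_raster else np.zeros((1, 1), dtype=np.uint8)
        )
        stn0 = lay.pop_slice("STN").start
        gpe0 = lay.pop_slice("GPe").start
        sc0 = lay.pop_slice("SC").start
        intg = self.integrator
        par = self.par
        sel, step = engine.run_window(
            T, self.dt,
            self.V, self.U, self.gA, self.gG,
            self.invC, par["n2"], par["n1"], par["n0"], par["a"], par["b"],
            par["vr"], par["vpeak"], par["c"], par["d"], self.Ibase,
            self.eA, self.eG, self.g_decay,
            nse, self.w_noise_exc, nsi, self.w_noise_inh,
            fb_sp, fb_idx, fb_w,
            ctx_sp, self.spk_prev,
            self.Wexc, self.Winh, self.Wctx,
            self.Wsg, self.sg_gain, stn0, gpe0, lay.n_per_channel,
            self.Apre, self.Apost, self.E,
            self.d_pre, self.d_post, self.d_E, self.inc_pre, self.inc_post,
            self.alpha_col, self.sign_col, self.use_da_col, self.wmin_col,
            self.wmax_col, self.dnorm_col,
            np.uint8(self.plastic_ctx),
            self.Ah, self.Abh,
            self.hom_decay, self.hom_dt_tauAbar, float(self.hom["delta_A"]),
            float(self.hom["epsilon"]), float(self.hom["w_max"]),
            0.9, 1.1, self.hom_dt_tauw,
            np.uint8(self.plastic_sg),
            self.da, self.da_decay_ctx, self.da_decay_sg, da_step, R,
            intg.value, math.exp(-self.dt / intg.tau_ms), intg.increment,
            intg.threshold, np.uint8(stop_at_threshold),
            sc0, lay.n_per_channel, lay.n_channels,
            counts, self.chan_index,
            raster, np.uint8(record_raster),
        )
        if stop_at_threshold and sel >= 0:
            counts = counts[: step + 1]
        return WindowResult(
            selection=int(sel), step=int(step), counts=counts,
            raster=raster if record_raster else None,
        )

    def mean_rates(self, counts: np.ndarray) -> dict[str, np.ndarray]:
        """Mean firing rate (Hz) per channel per population over a window."""
        T = counts.shape[0]
        dur_s = T * self.dt / 1000.0
        out = {}
        for pi, pop in enumerate(POPULATIONS):
            cols = slice(pi * self.layout.n_channels, (pi + 1) * self.layout.n_channels)
            out[pop] = counts[:, cols].sum(axis=0) / dur_s / self.layout.n_per_channel
        return out


def build_network(config: dict, rng: np.random.Generator) -> Network:
    """Instantiate the circuit from a configuration dict.

    All stochastic construction (connectivity masks, initial plastic
    cortical weights) is drawn from ``rng``, so identical (config, seed)
    pairs yield identical networks.
    """
    lay_cfg = config["layout"]
    layout = ChannelLayout(
        n_channels=int(lay_cfg["n_channels"]),
        n_per_channel=int(lay_cfg["n_per_channel"]),
        n_cortex=int(lay_cfg["n_cortex"]),
    )
    required = set(config["projections"]) | set(config["cortex"]["projections"])
    missing = {
        "StrD1->SNr", "StrD2->GPe", "GPe->SNr", "GPe->STN", "STN->SNr",
        "SNr->SC", "SC->SCi", "SCi->SC", "StrD1->StrD1", "SC->StrD1",
        "SC->StrD2", "CTX->StrD1", "CTX->StrD2", "CTX->STN", "CTX->SC",
    } - required
    if missing:
        raise ValueError(f"configuration lacks projections: {sorted(missing)}")
    return Network(config, layout, rng)


def run_stimulus_window(
    net: Network, rng: np.random.Generator, *, record_raster: bool = False
) -> tuple[int | None, float, WindowResult]:
    """Stimulus presentation: cortex active until an integrator crosses
    threshold or the maximum presentation time elapses.

    Returns (selected channel | None, latency ms, window result).  Without a
    threshold crossing, the largest integrator wins if it exceeds the
    missing-response floor, otherwise the response is missing.
    """
    net.integrator.value[:] = 0.0
    timing = net.config["timing"]
    res = net.run_window(
        float(timing["max_stimulus_ms"]), rng,
        ctx_on=True, stop_at_threshold=True, record_raster=record_raster,
    )
    if res.selection >= 0:
        return res.selection, (res.step + 1) * net.dt, res
    values = net.integrator.value
    if values.max() >= net.integrator.floor:
        return int(values.argmax()), float(timing["max_stimulus_ms"]), res
    return None, float(timing["max_stimulus_ms"]), res


def apply_selection_feedback(net: Network, selection: int | None) -> Network:
    """Route post-selection feedback drive to the selected channel.

    The drive targets the selected SC sub-population during the outcome
    window and reaches the StrD1/StrD2 sub-populations of the same channel
    through the SC -> striatum feedback projections.  ``None`` is a no-op.
    """
    net.feedback_channel = selection if selection is not None else None
    return net


def mean_channel_weight_matrix(weights: np.ndarray, layout: ChannelLayout) -> np.ndarray:
    """Mean weight from each source channel to each target channel (5x5)."""
    n = layout.n_per_channel
    c = layout.n_channels
    return weights.reshape(c, n, c, n).mean(axis=(1, 3))


def activity_deviation(
    counts: np.ndarray,
    window_start_ms: float,
    *,
    dt_ms: float,
    window_len_ms: float = 300.0,
) -> np.ndarray:
    """Relative rate deviation in a post-dopamine window per sub-population.

    ``(mean rate inside the window - whole-trial mean rate) / whole-trial
    mean rate``; sub-populations silent over the whole trial yield NaN.
    """
    T = counts.shape[0]
    i0 = int(round(window_start_ms / dt_ms))
    i1 = min(T, i0 + int(round(window_len_ms / dt_ms)))
    if i0 >= T:
        raise ValueError("window starts beyond the recorded trial")
    total = counts.mean(axis=0)
    inside = counts[i0:i1].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = (inside - total) / total
    dev[total == 0] = np.nan
    return dev


def save_weights(path, snapshots: dict[str, dict[str, np.ndarray]]) -> None:
    """Write weight snapshots to HDF5, keyed by projection then label."""
    with h5py.File(path, "w") as fh:
        for proj, by_label in snapshots.items():
            grp = fh.create_group(proj.replace("->", "_to_"))
            for label, matrix in by_label.items():
                grp.create_dataset(str(label), data=matrix)


class SpikingAgent:
    """Task-facing wrapper: implements the agent protocol with the network.

    ``select`` simulates the rest phase and the stimulus window;
    ``deliver_outcome`` simulates the post-response period with the
    selection feedback, the reward delay, and the dopamine delivery that
    gates plasticity.
    """

    def __init__(self, net: Network):
        self.net = net
        self.last_selection: int | None = None
        self.last_result: WindowResult | None = None

    def select(self, rng: np.random.Generator) -> tuple[int | None, float]:
        timing = self.net.config["timing"]
        self.net.run_window(float(timing["rest_ms"]), rng)
        channel, latency, res = run_stimulus_window(self.net, rng)
        self.last_selection = channel
        self.last_result = res
        if channel is None:
            return None, latency
        return channel + 1, latency  # channels 0..4 encode positions 1..5

    def deliver_outcome(
        self, outcome: Outcome, R: float, rng: np.random.Generator
    ) -> None:
        timing = self.net.config["timing"]
        delay = float(timing["reward_delay_ms"])
        window = delay + float(timing["post_reward_ms"])
        apply_selection_feedback(self.net, self.last_selection)
        fb_until = delay + float(self.net.config["feedback"]["tail_ms"])
        self.net.run_window(
            window, rng,
            feedback_channel=self.net.feedback_channel,
            feedback_until_ms=min(fb_until, window),
            deliver_at_ms=delay, R=R,
        )
        self.net.feedback_channel = None
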