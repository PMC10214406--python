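"""Behavioral quantification pipeline for reversal-learning trial tables.

Applied identically to simulated and human data.  Per successful block the
trials are segmented into perseverative trials (consecutive unrewarded
selections of the previously rewarded position), exploration trials, and the
terminal run of consecutive rewarded selections; immediately repeated
unrewarded selections are collapsed into one; category selection counts are
weighted by per-category availability; the per-phase unrewarded
exploration-trial series is summarized by an exponential fit whose half-life
maps to a learning rate in [-1, 1].

Pipeline order: successful-block filter -> segmentation -> collapsing ->
counting / weighted frequencies -> fits and period statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import observer
from .task import FREQUENT, OTHER, BlockSchedule

__all__ = [
    "Selection",
    "SegmentedBlock",
    "ExplorationPhase",
    "FitResult",
    "PeriodAssignment",
    "SUCCESS_RUN",
    "segment_block",
    "collapse_repeats",
    "count_unrewarded_exploration_trials",
    "extract_phases",
    "weighted_frequencies",
    "fit_learning_rate",
    "half_life_to_rate",
    "assign_periods",
    "compare_learning_rates",
    "period_frequency_test",
    "generate_synthetic_behavior",
    "unrewarded_series",
]

SUCCESS_RUN = 7  # consecutive rewarded trials that mark a successful block


@dataclass(frozen=True)
class Selection:
    position: int
    rewarded: bool


@dataclass
class SegmentedBlock:
    """One block's trials split into the three behavioral segments."""

    block: int
    rewarded_position: int
    previous_position: int | None
    perseverative: list[Selection]
    exploration: list[Selection]
    terminal: list[Selection]
    success: bool

    @property
    def n_trials(self) -> int:
        return len(self.perseverative) + len(self.exploration) + len(self.terminal)


def _longest_rewarded_run(selections: list[Selection]) -> int:
    best = run = 0
    for s in selections:
        run = run + 1 if s.rewarded else 0
        best = max(best, run)
    return best


def segment_block(
    selections: list[Selection],
    rewarded_position: int,
    previous_position: int | None,
    *,
    success_run: int = SUCCESS_RUN,
) -> SegmentedBlock:
    """Segment one block's ordered selections.

    Perseverative trials are the leading consecutive unrewarded selections
    of the previously rewarded position (none for the first block).  The
    terminal segment is the maximal suffix of consecutive rewarded
    selections minus its first trial, which - like sporadic later selections
    of the previous position - counts as exploration.
    """
    if not selections:
        raise ValueError("empty block")
    success = _longest_rewarded_run(selections) >= success_run

    n_pers = 0
    if previous_position is not None:
        for s in selections:
            if s.position == previous_position and not s.rewarded:
                n_pers += 1
            else:
                break
    # maximal rewarded suffix
    n_term = 0
    for s in reversed(selections[n_pers:]):
        if s.rewarded:
            n_term += 1
        else:
            break
    if n_term > 0:
        n_term -= 1  # first rewarded selection of the run is exploration
    split = len(selections) - n_term
    return SegmentedBlock(
        block=0,
        rewarded_position=rewarded_position,
        previous_position=previous_position,
        perseverative=selections[:n_pers],
        exploration=selections[n_pers:split],
        terminal=selections[split:],
        success=success,
    )


def collapse_repeats(selections: list[Selection]) -> list[Selection]:
    """Merge immediately repeated identical unrewarded selections into one."""
    out: list[Selection] = []
    for s in selections:
        if out and not s.rewarded and not out[-1].rewarded and s.position == out[-1].position:
            continue
        out.append(s)
    return out


@dataclass
class ExplorationPhase:
    """Collapsed exploration segment of one successful block."""

    block: int
    phase_index: int  # 0-based index among exploration phases
    previous_position: int | None
    rewarded_position: int
    selections: list[Selection]
    after_break: bool = False

    @property
    def found(self) -> bool:
        return bool(self.selections) and self.selections[-1].rewarded


def count_unrewarded_exploration_trials(phase: ExplorationPhase) -> int:
    """Exploration selections excluding the final rewarded one."""
    n = len(phase.selections)
    if phase.found:
        n -= 1
    return n


def extract_phases(
    trials: pd.DataFrame,
    schedule: BlockSchedule | None = None,
    *,
    success_run: int = SUCCESS_RUN,
    drop_familiarization: bool = True,
) -> list[ExplorationPhase]:
    """Segment a trial table into per-block collapsed exploration phases.

    ``trials`` uses the standard schema (block, trial, selected, rewarded);
    ``selected == 0`` marks a missing response and is dropped before
    segmentation.  Only successful blocks after the first yield phases; the
    first block is used solely to establish the previous rewarded position.
    Unsuccessful blocks still advance the previous-position bookkeeping.
    """
    fam: set[int] = set()
    breaks: set[int] = set()
    if schedule is not None:
        for b in schedule.blocks:
            if b.familiarization:
                fam.add(b.index)
            if b.after_break:
                breaks.add(b.index)

    phases: list[ExplorationPhase] = []
    prev_rewarded: int | None = None
    phase_index = 0
    first_main = True
    for block_id, grp in trials.groupby("block", sort=True):
        if drop_familiarization and block_id in fam:
            continue
        sel = [
            Selection(int(p), bool(r))
            for p, r in zip(grp["selected"], grp["rewarded"])
            if int(p) != 0
        ]
        if not sel:
            continue
        rewarded_trials = [s.position for s in sel if s.rewarded]
        rewarded_position = rewarded_trials[-1] if rewarded_trials else -1
        seg = segment_block(sel, rewarded_position, prev_rewarded, success_run=success_run)
        if seg.success and not first_main:
            phases.append(
                ExplorationPhase(
                    block=int(block_id),
                    phase_index=phase_index,
                    previous_position=prev_rewarded,
                    rewarded_position=rewarded_position,
                    selections=collapse_repeats(seg.exploration),
                    after_break=block_id in breaks,
                )
            )
        if not first_main:
            phase_index += 1
        if rewarded_position != -1:
            prev_rewarded = rewarded_position
        first_main = False
    return phases


def weighted_frequencies(
    phases: list[ExplorationPhase],
    *,
    frequent: tuple[int, ...] = FREQUENT,
    other: tuple[int, ...] = OTHER,
) -> pd.DataFrame:
    """Availability-weighted selection counts per category per phase.

    For each exploration phase the unrewarded exploration selections are
    split into the frequent and the never/rarely rewarded category and each
    count is divided by the number of positions of that category that were
    actually available for unrewarded exploration (the previously and the
    newly rewarded position are not available).  A weighted count of 1 means
    every available position of that category was selected.  In the
    never-rewarded design this reduces to weight 1/2 for the never category
    and 1 for the frequent one.
    """
    rows = []
    for ph in phases:
        unavailable = {ph.rewarded_position}
        if ph.previous_position is not None:
            unavailable.add(ph.previous_position)
        avail_f = len([p for p in frequent if p not in unavailable])
        avail_o = len([p for p in other if p not in unavailable])
        picks = [
            s.position
            for s in ph.selections
            if not s.rewarded and s.position not in unavailable
        ]
        count_f = sum(1 for p in picks if p in frequent)
        count_o = sum(1 for p in picks if p in other)
        row = {"block": ph.block, "phase": ph.phase_index}
        row["frequent"] = count_f / avail_f if avail_f else np.nan
        row["other"] = count_o / avail_o if avail_o else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=["block", "phase", "frequent", "other"])


# ---------------------------------------------------------------------------
# Exponential learning-rate fit


@dataclass(frozen=True)
class FitResult:
    y0: float
    y1: float
    tau_exp: float
    t_half: float
    gamma: float


def _exp_model(x: np.ndarray, y0: float, y1: float, tau: float) -> np.ndarray:
    """Exponential with a symmetric increasing branch for tau <= 0."""
    x = np.asarray(x, dtype=float)
    if tau > 0:
        return (y0 - y1) * np.exp(-tau * x) + y1
    return -(y0 - y1) * np.exp(tau * x) + 2 * y0 - y1


def half_life_to_rate(t_half: float) -> float:
    """Learning rate in [-1, 1]: -1 fast increase, 0 no change, 1 fast decrease."""
    t_half = min(max(t_half, -1.0), 1.0)
    if t_half < 0:
        return -1.0 - t_half
    return 1.0 - t_half


def fit_learning_rate(
    counts: np.ndarray,
    phase_indices: np.ndarray,
    *,
    version: str = "never",
    y0: float = 1.5,
    y1: float | None = None,
) -> FitResult:
    """Fit the unrewarded-exploration-trial series of one agent.

    Phase indices are normalized by the maximum number of exploration phases
    of the experiment version (never: 59, rarely: 69) so x spans [0, 1]; the
    endpoints y0 = 1.5 and y1 (0.5 never / 0.86 rarely) are the
    ideal-observer expectations without and with the exploration bias.  Only
    the time constant is fitted, by least squares, with negative values
    allowed so increasing series are represented without bias toward decay.
    The half-life ln2/tau is clipped to [-1, 1] and mapped to the learning
    rate; tau = 0 (flat series) maps to rate 0.
    """
    n_max = {"never": 59.0, "rarely": 69.0}.get(version, None)
    if y1 is None:
        y1 = {"never": 0.5, "rarely": 0.86}[version]
    counts = np.asarray(counts, dtype=float)
    x = np.asarray(phase_indices, dtype=float)
    if n_max is not None:
        x = x / n_max
    if counts.size == 0:
        raise ValueError("no exploration phases to fit")

    def residuals(tau: np.ndarray) -> np.ndarray:
        return _exp_model(x, y0, y1, float(tau[0])) - counts

    best = None
    for tau0 in (-20.0, -5.0, -1.0, 1.0, 5.0, 20.0):
        sol = optimize.least_squares(residuals, x0=[tau0], method="lm")
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol
    tau = float(best.x[0])
    if tau == 0.0:
        t_half = 1.0
    else:
        t_half = math.log(2.0) / tau
        t_half = min(max(t_half, -1.0), 1.0)
    return FitResult(y0=y0, y1=y1, tau_exp=tau, t_half=t_half, gamma=half_life_to_rate(t_half))


def unrewarded_series(phases: list[ExplorationPhase]) -> tuple[np.ndarray, np.ndarray]:
    """(phase indices, unrewarded exploration-trial counts) for one agent."""
    idx = np.array([ph.phase_index for ph in phases], dtype=float)
    counts = np.array(
        [count_unrewarded_exploration_trials(ph) for ph in phases], dtype=float
    )
    return idx, counts


# ---------------------------------------------------------------------------
# Periods


@dataclass
class PeriodAssignment:
    start: list[int]  # phase indices
    mid: list[int]
    end: list[int]
    excluded: list[int] = field(default_factory=list)


def assign_periods(
    phases: list[ExplorationPhase],
    *,
    phases_per_period: int = 6,
) -> PeriodAssignment:
    """Assign exploration phases to start / mid / end periods.

    Phases of blocks that follow a break are excluded.  The start period is
    the first ``phases_per_period`` remaining phases, the end period the
    last ones, and the mid period is centered between them.  Model runs have
    no breaks and may use ``phases_per_period = 1``.
    """
    excluded = [ph.phase_index for ph in phases if ph.after_break]
    usable = [ph.phase_index for ph in phases if not ph.after_break]
    k = phases_per_period
    if len(usable) < 3 * k:
        raise ValueError("fewer exploration phases than periods require")
    start = usable[:k]
    end = usable[-k:]
    mid_lo = (len(usable) - k) // 2
    mid = usable[mid_lo : mid_lo + k]
    return PeriodAssignment(start=start, mid=mid, end=end, excluded=excluded)


def compare_learning_rates(
    a: np.ndarray, b: np.ndarray | float
) -> dict[str, float]:
    """t-test between two learning-rate samples (or one sample against a
    constant), with Cohen's d as effect size."""
    a = np.asarray(a, dtype=float)
    if np.isscalar(b) or getattr(b, "ndim", 1) == 0:
        t, p = stats.ttest_1samp(a, float(b))
        d = (a.mean() - float(b)) / a.std(ddof=1)
    else:
        b = np.asarray(b, dtype=float)
        _, p_var = stats.levene(a, b)
        t, p = stats.ttest_ind(a, b, equal_var=p_var >= 0.05)
        pooled = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
        )
        d = (a.mean() - b.mean()) / pooled
    return {"t": float(t), "p": float(p), "cohens_d": float(d)}


def period_frequency_test(
    frequencies: pd.DataFrame, period_phases: list[int]
) -> dict[str, float]:
    """One-way chi-square comparing summed weighted counts of the two
    categories within one period (scaled to pseudo-counts)."""
    sub = frequencies[frequencies["phase"].isin(period_phases)]
    observed = np.array([sub["frequent"].sum(), sub["other"].sum()])
    if observed.sum() == 0:
        return {"chi2": 0.0, "p": 1.0}
    chi2, p = stats.chisquare(observed)
    return {"chi2": float(chi2), "p": float(p)}


# ---------------------------------------------------------------------------
# Synthetic agents (pipeline fixtures and parameter-recovery tests)


def generate_synthetic_behavior(
    policy: str,
    schedule: BlockSchedule,
    rng: np.random.Generator,
    *,
    lapse: float = 0.0,
    bias_onset: int | None = None,
    perseveration: int = 1,
    success_trials: int | None = None,
) -> pd.DataFrame:
    """Trial table for a scripted agent following an ideal-observer policy.

    Policies: ``unbiased`` explores all non-excluded positions uniformly;
    ``biased`` follows the exploration bias (frequent positions first) with
    a ``lapse`` probability of an unbiased pick; ``perseverative`` repeats
    the previously rewarded position ``perseveration`` times before
    exploring unbiased; ``switching`` behaves unbiased before phase
    ``bias_onset`` and biased afterwards.  After finding the rewarded
    position the agent selects it until the block terminates.
    """
    if policy not in ("unbiased", "biased", "perseverative", "switching"):
        raise ValueError(f"unknown policy {policy!r}")
    frequent = set(schedule.frequent)
    records = []
    prev: int | None = None
    phase = 0
    for block in schedule.blocks:
        biased = policy == "biased" or (
            policy == "switching" and bias_onset is not None and phase >= bias_onset
        )
        trial = 1
        n_consec = 0
        target = success_trials or block.consecutive_target
        # perseverative lead-in
        n_pers = perseveration if (policy == "perseverative" and prev is not None) else (
            1 if prev is not None else 0
        )
        for _ in range(n_pers):
            rewarded = prev == block.rewarded
            records.append((block.index, trial, prev, rewarded))
            trial += 1
            if rewarded:
                n_consec += 1
        remaining = [p for p in schedule.frequent + schedule.other if p != prev]
        found = prev == block.rewarded
        while not found and trial <= block.max_trials:
            in_bias = [p for p in remaining if p in frequent]
            if biased and in_bias and rng.random() >= lapse:
                pool = in_bias
            else:
                pool = remaining
            pick = int(pool[rng.integers(len(pool))])
            rewarded = pick == block.rewarded
            records.append((block.index, trial, pick, rewarded))
            trial += 1
            if rewarded:
                found = True
                n_consec = 1
            else:
                remaining.remove(pick)
        while n_consec < target and trial <= block.max_trials:
            records.append((block.index, trial, block.rewarded, True))
            trial += 1
            n_consec += 1
        prev = block.rewarded
        phase += 1
    return pd.DataFrame(records, columns=["block", "trial", "selected", "rewarded"])
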