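"""Reproducible experiment runners.

* :func:`run_simulation` / :func:`run_protocol` - the three task versions
  (never / rarely / all rewarded) with the plastic model or its variants
  (``fixed_stn_gpe`` freezes the STN->GPe projection; ``legacy_prediction``
  uses the scalar reward-prediction signal).
* :func:`train_reversal_state` - trains one block to criterion and switches
  the rewarded position, snapshotting the cortical weights "as after a
  reversal" for the interpolation experiment.
* :func:`run_interpolation` - interpolates the STN->GPe weights from the
  uniform initial matrix toward a trained cluster pattern in 2% steps and
  measures, per level, how often the first explored response is a
  frequently rewarded position.
* :func:`make_report` - summary tables over result bundles.

Every run is fully determined by (config, seed); outputs are plain CSV /
JSON plus HDF5 weight snapshots.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import analysis
from .config import default_config
from .network import (
    SpikingAgent,
    build_network,
    mean_channel_weight_matrix,
    save_weights,
)
from .task import (
    FREQUENT,
    BlockSchedule,
    RewardModel,
    generate_block_schedule,
    run_block,
    trials_to_frame,
)

__all__ = [
    "ExperimentConfig",
    "InterpolationSpec",
    "run_simulation",
    "run_protocol",
    "train_reversal_state",
    "run_interpolation",
    "make_report",
]

VARIANTS = ("plastic", "fixed_stn_gpe", "legacy_prediction")


@dataclass
class ExperimentConfig:
    version: str = "never"
    n_simulations: int = 5
    seeds: list[int] | None = None
    variant: str = "plastic"
    preset: str = "desk"
    n_blocks: int | None = None
    output_dir: str | Path | None = None
    snapshot_every: int = 10  # blocks between STN->GPe weight snapshots
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.seeds is None:
            self.seeds = list(range(self.n_simulations))
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be unique per simulation")


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_simulation(
    seed: int,
    version: str = "never",
    *,
    variant: str = "plastic",
    preset: str = "desk",
    n_blocks: int | None = None,
    overrides: dict | None = None,
    snapshot_every: int = 10,
) -> dict:
    """One full multi-block simulation of one agent.

    Returns a dict with the trial table (``trials``), the schedule, the
    built network (final state), and STN->GPe weight snapshots keyed by
    block index (nS scale).
    """
    cfg = default_config(preset, overrides=overrides or {})
    rng = np.random.default_rng(seed)
    net = build_network(cfg, rng)
    if variant == "fixed_stn_gpe":
        net.plastic_sg = False
    model = RewardModel(
        r=float(cfg["reward"]["r"]),
        tau_P=float(cfg["reward"]["tau_P"]),
        tau_P_legacy=float(cfg["reward"]["tau_P_legacy"]),
        mode="legacy" if variant == "legacy_prediction" else "specific",
    )
    schedule = generate_block_schedule(
        version, n_blocks, np.random.default_rng(seed + 10_000)
    )
    agent = SpikingAgent(net)
    snapshots: dict[int, np.ndarray] = {0: net.Wsg.copy()}
    records = []
    for block in schedule.blocks:
        block_records, model = run_block(agent, block, model, rng)
        records.extend(block_records)
        if snapshot_every and block.index % snapshot_every == 0:
            snapshots[block.index] = net.Wsg.copy()
    snapshots[len(schedule.blocks)] = net.Wsg.copy()
    return {
        "seed": seed,
        "version": version,
        "variant": variant,
        "trials": trials_to_frame(records),
        "schedule": schedule,
        "network": net,
        "snapshots": snapshots,
    }


def run_protocol(config: ExperimentConfig) -> dict:
    """Run every seed of an experiment; optionally persist a result bundle.

    The bundle directory contains one trial table CSV per seed, STN->GPe
    weight snapshots in HDF5, and a manifest with the configuration hash -
    identical (config, seed) pairs give identical outputs.
    """
    cfg = default_config(config.preset, overrides=config.overrides)
    results = []
    for seed in config.seeds:
        results.append(
            run_simulation(
                seed, config.version,
                variant=config.variant, preset=config.preset,
                n_blocks=config.n_blocks, overrides=config.overrides,
                snapshot_every=config.snapshot_every,
            )
        )
    bundle = {
        "config": config,
        "results": results,
        "manifest": {
            "version": config.version,
            "variant": config.variant,
            "preset": config.preset,
            "seeds": list(config.seeds),
            "config_hash": _config_hash(cfg),
        },
    }
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for res in results:
            res["trials"].assign(seed=res["seed"]).to_csv(
                out / f"trials_seed{res['seed']}.csv", index=False
            )
            save_weights(
                out / f"stn_gpe_seed{res['seed']}.h5",
                {"STN->GPe": {str(k): v for k, v in res["snapshots"].items()}},
            )
        with open(out / "manifest.json", "w") as fh:
            json.dump(bundle["manifest"], fh, indent=2)
    return bundle


# ---------------------------------------------------------------------------
# Interpolation experiment


@dataclass
class InterpolationSpec:
    """Levels and repetitions for the cluster-interpolation experiment.

    At full scale 16 levels (0% to 30% in 2% steps) with 400 runs each give
    6400 simulations; reduced runs keep the level grid and shrink the
    repetition count.
    """

    levels: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 0.32, 0.02)
    )
    runs_per_level: int = 400
    preset: str = "desk"
    max_trials: int = 8
    trained_position: int = 3  # frequent position used for pre-training


def train_reversal_state(
    seed: int,
    *,
    preset: str = "desk",
    trained_position: int = 3,
    overrides: dict | None = None,
) -> dict:
    """Cortical weight state "as after a reversal".

    Trains a single block to criterion on one frequent position and
    snapshots the network state; the interpolation runs then switch the
    rewarded position, so the first trials of each run are the reversal.
    Returns the network state dict plus metadata.
    """
    cfg = default_config(preset, overrides=overrides or {})
    rng = np.random.default_rng(seed)
    net = build_network(cfg, rng)
    agent = SpikingAgent(net)
    from .task import Block

    block = Block(1, trained_position, 15, 30)
    model = RewardModel()
    _, model = run_block(agent, block, model, rng)
    state = net.get_state()
    return {
        "state": state,
        "config": cfg,
        "seed": seed,
        "trained_position": trained_position,
    }


def cluster_pattern_from_run(
    seed: int = 0,
    *,
    preset: str = "desk",
    n_blocks: int = 20,
    overrides: dict | None = None,
) -> np.ndarray:
    """Full STN->GPe weight matrix after a never-rewarded training run."""
    res = run_simulation(
        seed, "never", preset=preset, n_blocks=n_blocks,
        overrides=overrides, snapshot_every=0,
    )
    return res["snapshots"][max(res["snapshots"])]


def run_interpolation(
    spec: InterpolationSpec,
    rng: np.random.Generator,
    *,
    cluster: np.ndarray | None = None,
    trained: dict | None = None,
    overrides: dict | None = None,
) -> pd.DataFrame:
    """Simulate single exploration phases under interpolated STN->GPe weights.

    For each level the STN->GPe matrix is set to
    ``w_uniform + level * (w_cluster - w_uniform)`` and one exploration
    phase is simulated from the post-reversal cortical state; the record
    notes whether the first explored response (first selection differing
    from the previously rewarded position) is a frequently rewarded one.
    Returns one row per run (level, first_selection, in_cluster).
    """
    trained = trained or train_reversal_state(
        int(rng.integers(2**31 - 1)), preset=spec.preset,
        trained_position=spec.trained_position, overrides=overrides,
    )
    cfg = trained["config"]
    cluster = (
        cluster
        if cluster is not None
        else cluster_pattern_from_run(
            int(rng.integers(2**31 - 1)), preset=spec.preset, overrides=overrides
        )
    )
    w_uniform = float(cfg["stn_gpe"]["w_init"])
    prev = trained["trained_position"]
    rows = []
    for level in spec.levels:
        for _ in range(spec.runs_per_level):
            run_seed = int(rng.integers(2**31 - 1))
            run_rng = np.random.default_rng(run_seed)
            net = build_network(cfg, np.random.default_rng(trained["seed"]))
            net.set_state(trained["state"])
            net.Wsg[...] = w_uniform + level * (cluster - w_uniform)
            agent = SpikingAgent(net)
            # new rewarded position per the task rule: another frequent one
            candidates = [p for p in FREQUENT if p != prev]
            rewarded = int(candidates[run_rng.integers(len(candidates))])
            from .task import Block

            block = Block(1, rewarded, 15, spec.max_trials)
            model = RewardModel()
            records, model = run_block(agent, block, model, run_rng)
            first = next(
                (r.selected for r in records
                 if r.selected is not None and r.selected != prev),
                None,
            )
            rows.append(
                {
                    "level": float(level),
                    "seed": run_seed,
                    "rewarded": rewarded,
                    "first_selection": first if first is not None else 0,
                    "in_cluster": bool(first in FREQUENT) if first else False,
                }
            )
    return pd.DataFrame(rows)


def interpolation_summary(runs: pd.DataFrame) -> dict:
    """Level-wise in-cluster proportions and the rank correlation between
    interpolation level and the binary first-selection flag."""
    by_level = (
        runs.groupby("level")["in_cluster"].mean().rename("p_in_cluster")
    )
    responded = runs[runs["first_selection"] > 0]
    rho, p = stats.spearmanr(responded["level"], responded["in_cluster"])
    return {
        "proportions": by_level.reset_index(),
        "spearman_r": float(rho),
        "spearman_p": float(p),
        "n": int(len(responded)),
    }


# ---------------------------------------------------------------------------
# Reports


def summarize_run(result: dict) -> dict:
    """Behavioral summary of one simulation (quantities of the result figures)."""
    trials = result["trials"]
    schedule: BlockSchedule = result["schedule"]
    version = result["version"]
    fit_version = "rarely" if version == "rarely" else "never"
    phases = analysis.extract_phases(trials, schedule)
    idx, counts = analysis.unrewarded_series(phases)
    def successful(grp: pd.DataFrame) -> bool:
        rew = grp.loc[grp["selected"] > 0, "rewarded"].to_numpy()
        best = run = 0
        for r in rew:
            run = run + 1 if r else 0
            best = max(best, run)
        return best >= analysis.SUCCESS_RUN

    out = {
        "seed": result["seed"],
        "version": version,
        "variant": result["variant"],
        "n_blocks": len(schedule.blocks),
        "n_success": int(sum(successful(g) for _, g in trials.groupby("block"))),
        "mean_unrewarded_exploration": float(counts.mean()) if counts.size else np.nan,
    }
    # unrewarded selections per reversal phase (perseverative + exploration)
    per_block = []
    for block_id, grp in trials.groupby("block"):
        if block_id == 1:
            continue
        sels = grp[grp["selected"] > 0]
        rew = sels["rewarded"].to_numpy()
        i = len(rew)
        while i > 0 and rew[i - 1]:
            i -= 1
        per_block.append(int((~rew[:i]).sum()))
    out["mean_unrewarded_reversal"] = float(np.mean(per_block)) if per_block else np.nan
    if counts.size >= 3:
        fit = analysis.fit_learning_rate(counts, idx, version=fit_version)
        out["gamma"] = fit.gamma
        out["tau_exp"] = fit.tau_exp
    else:
        out["gamma"] = np.nan
        out["tau_exp"] = np.nan
    W = result["snapshots"][max(result["snapshots"])]
    W0 = result["snapshots"][0]
    M = mean_channel_weight_matrix(W - W0, result["network"].layout)
    freq_cols = [p - 1 for p in schedule.frequent]
    other_cols = [p - 1 for p in schedule.other]
    out["dW_into_frequent"] = float(M[:, freq_cols].mean())
    out["dW_into_other"] = float(M[:, other_cols].mean())
    return out


def make_report(bundles: list[dict]) -> pd.DataFrame:
    """Per-simulation summary rows for one or more result bundles."""
    rows = []
    for bundle in bundles:
        for result in bundle["results"]:
            rows.append(summarize_run(result))
    return pd.DataFrame(rows)
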