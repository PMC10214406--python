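"""Behavioral pipeline on a synthetic agent's trial table.

Generates an agent that switches from unbiased to biased exploration
mid-experiment, then segments blocks, counts unrewarded exploration trials
per phase, and fits the exponential learning rate.
"""
import numpy as np

from bgexplore import analysis, task

sched = task.generate_block_schedule("never", 60, np.random.default_rng(5))
trials = analysis.generate_synthetic_behavior(
    "switching", sched, np.random.default_rng(6), bias_onset=20
)
phases = analysis.extract_phases(trials, sched)
idx, counts = analysis.unrewarded_series(phases)
freq = analysis.weighted_frequencies(phases)
fit = analysis.fit_learning_rate(counts, idx, version="never")

print(f"exploration phases analyzed: {len(phases)}")
print(f"mean unrewarded exploration trials: {counts.mean():.2f}")
print(f"weighted frequency (frequent category, mean): {freq['frequent'].mean():.2f}")
print(f"weighted frequency (never category, mean):    {freq['other'].mean():.2f}")
print(f"fitted tau = {fit.tau_exp:.2f}, half-life = {fit.t_half:.2f}, "
      f"learning rate gamma = {fit.gamma:.2f}")
# gamma > 0 marks a decreasing number of unrewarded exploration trials,
# i.e. the exploration bias being learned during the experiment.
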