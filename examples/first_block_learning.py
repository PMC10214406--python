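"""Initial learning: one first block of the never-rewarded experiment.

Builds the reduced-size spiking network, runs the first block, and prints
the selection sequence: a few unrewarded explorations, then convergence on
the rewarded position until the 15-consecutive criterion.
"""
import numpy as np

from bgexplore import SpikingAgent, build_network, default_config, task

cfg = default_config("desk")
rng = np.random.default_rng(1)
net = build_network(cfg, rng)
agent = SpikingAgent(net)

schedule = task.generate_block_schedule("never", 60, np.random.default_rng(1001))
block = schedule.blocks[0]
records, model = task.run_block(agent, block, task.RewardModel(), rng)

print("rewarded position:", block.rewarded)
print("selections:      ", [r.selected for r in records])
print("rewarded flags:  ", [int(r.rewarded) for r in records])
unrew = sum(1 for r in records if not r.rewarded)
print(f"unrewarded selections before convergence: {unrew}")
# Dopamine dips after unrewarded choices depress the selected channel's
# direct pathway and potentiate its indirect pathway, so the model switches;
# a dopamine burst locks in the rewarded channel.
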