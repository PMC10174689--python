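"""Build a session plan and simulate one agent through it.

The task presents 10 independent blocks of stimulus->key associations (6
blocks with 3 stimuli, 4 with 6), each stimulus 9 times, followed by a
feedback-free test phase.  The agent mixes a one-shot but decaying working
memory with incremental reinforcement learning.
"""

from rlwm import AgentParams, TaskConfig, build_session, simulate_agent

plan = build_session(TaskConfig(), seed=1)
print(f"blocks: {[b.set_size for b in plan.blocks]}")
print(f"learning trials: {sum(len(s) for s in plan.learning_sequence)}, "
      f"test trials: {len(plan.test_sequence)}")

params = AgentParams(
    alpha_pos=0.07,  # learning rate for positive prediction errors
    alpha_neg=0.05,  # ... for negative ones (nu = 0.71: some neglect)
    beta_learn=16.0,  # softmax inverse temperature, learning phase
    beta_test=5.0,  # ... test phase
    epsilon=0.03,  # lapse rate
    phi=0.174,  # WM decay per trial (young-adult group mean)
    omega3=0.8,  # WM reliance at set size 3
    omega6=0.48,  # ... at set size 6
)
records = simulate_agent(plan, params, seed=2, participant="demo", group="young")

learn = records[records.phase == "learn"]
print("\nlearning accuracy by set size "
      "(WM makes the small set size much easier):")
print(learn.groupby("set_size").reward.mean().round(3).to_string())
test = records[records.phase == "test"]
print("\ntest accuracy by set size "
      "(the advantage shrinks once WM cannot contribute):")
print(test.groupby("set_size").reward.mean().round(3).to_string())
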