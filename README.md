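# rlwm — reinforcement-learning / working-memory task modelling

Older adults make worse decisions from experience than young adults, but
standard learning tasks cannot say whether that reflects a failing striatal
reinforcement-learning (RL) system or failing prefrontal working memory (WM):
either system can solve them.  This package implements the full analysis
pipeline for the task design that pulls the two apart — stimulus-response
learning under a *set-size* manipulation (3 vs 6 concurrent associations)
with a delayed, feedback-free test phase — together with the hybrid RL-WM
computational model, its hierarchical Bayesian estimation, and the
downstream analyses linking model parameters to regional neurochemical
measures (MRS glutamate, GABA, NAA) in two-group young/older cohorts.

It is a library for researchers in computational cognitive neuroscience: you
import it from Python (see `examples/`), there is no command-line tool.

## The model

Two modules learn stimulus-action associations in parallel within each block
(both tables initialized at `1/nA`):

* RL values, by an asymmetric delta rule
  `Q(s,a) += alpha± * (r - Q(s,a))`;
* WM weights, by one-shot storage of rewarded outcomes (`W(s,a) <- r`),
  imperfect encoding of unrewarded ones at rate `nu = alpha-/alpha+`, and a
  per-trial decay of every unobserved weight toward baseline,
  `W += phi * (W0 - W)`.

Choices during learning mix the modules' softmax policies with a set-size
dependent WM reliance and a lapse:

    P(a|s) = (1-eps) * [ omega_nS * softmax(beta_L W(s,:))
                       + (1-omega_nS) * softmax(beta_L Q(s,:)) ] + eps/nA

Test-phase choices use only the final Q of the stimulus's source block with
its own inverse temperature `beta_T`.  Parameters are estimated per
participant in a hierarchical Bayesian model (three variants: flat, single
hierarchy, separate hierarchies per age group; `beta_L` is shared within a
group), sampled by an adaptive Metropolis-within-Gibbs sampler over a
numba-compiled likelihood, with WAIC model comparison at the
participant-block level.  Model-independent analyses (trial-level logistic
GLMs, age regressions, train-test comparisons) and the brain-link pipeline
(cross-validated elastic-net feature selection, anatomical-specificity
regressions, bootstrap mediation) complete the pipeline.  A synthetic-cohort
generator reproduces the assumed statistical structure of a two-group study
(including a planted glutamate-decay coupling), so every stage is testable
end to end without any external data.  Details and design decisions:
[docs/methods.md](docs/methods.md).

## Worked example

```python
from rlwm import AgentParams, TaskConfig, build_session, simulate_agent

plan = build_session(TaskConfig(), seed=1)   # 10 blocks, 42 stimuli, 378 learning trials
params = AgentParams(alpha_pos=0.07, alpha_neg=0.05, beta_learn=16.0,
                     beta_test=5.0, epsilon=0.03, phi=0.174,
                     omega3=0.8, omega6=0.48)
records = simulate_agent(plan, params, seed=2, participant="demo", group="young")
print(records[records.phase == "learn"].groupby("set_size").reward.mean())
print(records[records.phase == "test"].groupby("set_size").reward.mean())
```

prints (matching `python examples/01_task_and_simulation.py`):

```
set_size            set_size
3    0.821          3    0.653
6    0.676          6    0.625
```

During learning the agent is far better at set size 3 — working memory can
hold three associations but not six.  At test, with WM unavailable, the
set-size-3 advantage collapses (0.821 -> 0.653) much more than the set-size-6
performance (0.676 -> 0.625): relying on WM during learning left less
RL-encoded knowledge behind.  The other examples fit the hierarchical model
and recover the group decay-rate contrast (`02`), reproduce the trial-level
GLM signature — positive reward-history, negative set-size and delay
coefficients (`03`), and recover a planted glutamate-decay coupling through
the feature-selection, specificity and mediation pipeline (`04`).

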