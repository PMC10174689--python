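"""Hybrid reinforcement-learning / working-memory (RL-WM) generative model.

Two modules learn stimulus->action associations in parallel within each block:

* an RL module tracking values Q via a delta rule with asymmetric learning
  rates (alpha+ for positive, alpha- for negative prediction errors), and
* a WM module storing weights W by one-shot encoding of rewarded outcomes,
  with negative outcomes encoded imperfectly (strength nu = alpha-/alpha+)
  and all unobserved associations decaying toward baseline at rate phi each
  trial.

During learning, choices mix the two modules' softmax policies (shared
inverse temperature beta_L) with a set-size-dependent WM reliance omega, plus
a uniform lapse at rate epsilon.  Test-phase choices are driven by the final
Q-values alone through a separate inverse temperature beta_T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit

from .errors import ConfigError, DataError
from .task import SessionPlan

__all__ = [
    "AgentParams",
    "ModelState",
    "TRIAL_COLUMNS",
    "init_block_state",
    "rl_update",
    "wm_update",
    "wm_decay",
    "learning_policy",
    "test_policy",
    "simulate_agent",
    "session_loglik",
    "PackedSession",
    "pack_session",
]

#: canonical trial-table schema used by every module
TRIAL_COLUMNS = [
    "participant",
    "group",
    "age",
    "phase",
    "block",
    "set_size",
    "trial",
    "stimulus",
    "iteration",
    "action",
    "reward",
    "missed",
]


@dataclass(frozen=True)
class AgentParams:
    """One participant's free parameters.

    alpha_pos, alpha_neg : learning rates for positive/negative prediction
        errors, in (0, 1] and [0, 1] respectively (alpha_pos = 0 would leave
        nu = alpha_neg / alpha_pos undefined and is rejected).
    beta_learn, beta_test : softmax inverse temperatures for the learning and
        test phases (beta_learn is shared across a group when fitted).
    epsilon : uniform lapse probability.
    phi : per-trial WM decay toward baseline.
    omega3, omega6 : WM policy weight in set sizes 3 and 6.
    """

    alpha_pos: float
    alpha_neg: float
    beta_learn: float
    beta_test: float
    epsilon: float
    phi: float
    omega3: float
    omega6: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_pos <= 1.0:
            raise ConfigError(f"alpha_pos must be in (0, 1], got {self.alpha_pos!r}")
        for name in ("alpha_neg", "epsilon", "phi", "omega3", "omega6"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("beta_learn", "beta_test"):
            v = getattr(self, name)
            if v < 0.0:
                raise ConfigError(f"{name} must be >= 0, got {v!r}")

    @property
    def nu(self) -> float:
        """Relative encoding of negative feedback, alpha-/alpha+ (may exceed 1)."""
        return self.alpha_neg / self.alpha_pos

    def omega(self, set_size: int) -> float:
        if set_size == 3:
            return self.omega3
        if set_size == 6:
            return self.omega6
        raise ConfigError(f"no WM reliance weight configured for set_size={set_size}")

    def replace(self, **kwargs) -> "AgentParams":
        return replace(self, **kwargs)

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.alpha_pos,
                self.alpha_neg,
                self.beta_test,
                self.epsilon,
                self.phi,
                self.omega3,
                self.omega6,
            ]
        )


@dataclass
class ModelState:
    """Per-block learner state: Q values and WM weights, both started at 1/nA."""

    Q: np.ndarray  # (set_size, n_actions)
    W: np.ndarray  # (set_size, n_actions)
    set_size: int
    w0: float


def init_block_state(set_size: int, n_actions: int) -> ModelState:
    """Fresh block state with every Q and W entry at the uniform prior 1/nA."""
    if set_size < 1 or n_actions < 1:
        raise ConfigError("set_size and n_actions must be >= 1")
    q0 = 1.0 / n_actions
    return ModelState(
        Q=np.full((set_size, n_actions), q0),
        W=np.full((set_size, n_actions), q0),
        set_size=set_size,
        w0=q0,
    )


def rl_update(
    state: ModelState, s: int, a: int, r: float, alpha_pos: float, alpha_neg: float
) -> ModelState:
    """Delta-rule update of Q(s, a); rate depends on the sign of the error."""
    if not (0.0 <= alpha_pos <= 1.0 and 0.0 <= alpha_neg <= 1.0):
        raise ConfigError("learning rates must be in [0, 1]")
    delta = r - state.Q[s, a]
    rate = alpha_pos if delta > 0 else alpha_neg
    state.Q[s, a] += rate * delta
    return state


def wm_update(state: ModelState, s: int, a: int, r: float, nu: float) -> ModelState:
    """One-shot WM storage: W(s, a) <- r on positive errors; negative errors
    move W toward r at rate nu only."""
    delta = r - state.W[s, a]
    if delta > 0:
        state.W[s, a] = r
    else:
        state.W[s, a] += nu * delta
    return state


def wm_decay(state: ModelState, phi: float, observed: tuple[int, int]) -> ModelState:
    """Pull every WM weight except the observed (s, a) pair toward baseline."""
    if not 0.0 <= phi <= 1.0:
        raise ConfigError("phi must be in [0, 1]")
    s, a = observed
    keep = state.W[s, a]
    state.W += phi * (state.w0 - state.W)
    state.W[s, a] = keep
    return state


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - np.max(x))
    return z / z.sum()


def learning_policy(
    state: ModelState, s: int, params: AgentParams, set_size: int | None = None
) -> np.ndarray:
    """Learning-phase action probabilities: lapse-mixed blend of the WM and RL
    softmax policies, weighted by the set-size-specific WM reliance."""
    ns = state.set_size if set_size is None else set_size
    omega = params.omega(ns)
    n_a = state.Q.shape[1]
    p_rl = _softmax(params.beta_learn * state.Q[s])
    p_wm = _softmax(params.beta_learn * state.W[s])
    p = (1.0 - params.epsilon) * (omega * p_wm + (1.0 - omega) * p_rl)
    return p + params.epsilon / n_a


def test_policy(final_q: np.ndarray, s: int, params: AgentParams) -> np.ndarray:
    """Test-phase action probabilities from the final Q of the source block;
    WM plays no role and Q is no longer updated."""
    q = np.asarray(final_q)
    if q.ndim != 2 or s >= q.shape[0]:
        raise DataError(f"stimulus index {s} not present in the final Q table")
    n_a = q.shape[1]
    p = (1.0 - params.epsilon) * _softmax(params.beta_test * q[s])
    return p + params.epsilon / n_a


# --------------------------------------------------------------------------
# packed sessions and numba kernels (used by simulation and inference)
# --------------------------------------------------------------------------


@dataclass
class PackedSession:
    """One participant's trials in flat arrays, ordered as experienced.

    ``block`` holds 0-based block ordinals, ``stim`` the 0-based within-block
    stimulus index.  ``action`` is 0-based with -1 for missed trials.  Test
    trials carry the ordinal of their source block.
    """

    phase: np.ndarray  # 0 learn, 1 test
    block: np.ndarray
    stim: np.ndarray
    action: np.ndarray
    reward: np.ndarray
    set_sizes: np.ndarray  # per block
    omegas_key: np.ndarray  # per block: 0 -> omega3, 1 -> omega6
    n_actions: int
    participant: object = None
    group: object = None


@njit(cache=True)
def _policy_probs(q_row, w_row, beta_l, omega, eps, n_a, out):
    m = q_row[0]
    for k in range(1, n_a):
        if q_row[k] > m:
            m = q_row[k]
    zs = 0.0
    for k in range(n_a):
        out[k] = math.exp(beta_l * (q_row[k] - m))
        zs += out[k]
    mw = w_row[0]
    for k in range(1, n_a):
        if w_row[k] > mw:
            mw = w_row[k]
    zw = 0.0
    ew = np.empty(n_a)
    for k in range(n_a):
        ew[k] = math.exp(beta_l * (w_row[k] - mw))
        zw += ew[k]
    for k in range(n_a):
        out[k] = (1.0 - eps) * (omega * ew[k] / zw + (1.0 - omega) * out[k] / zs)
        out[k] += eps / n_a


@njit(cache=True)
def _test_probs(q_row, beta_t, eps, n_a, out):
    m = q_row[0]
    for k in range(1, n_a):
        if q_row[k] > m:
            m = q_row[k]
    z = 0.0
    for k in range(n_a):
        out[k] = math.exp(beta_t * (q_row[k] - m))
        z += out[k]
    for k in range(n_a):
        out[k] = (1.0 - eps) * out[k] / z + eps / n_a


@njit(cache=True)
def _session_loglik_core(
    phase,
    block,
    stim,
    action,
    reward,
    set_sizes,
    omega_key,
    n_actions,
    alpha_pos,
    alpha_neg,
    beta_l,
    beta_t,
    eps,
    phi,
    omega3,
    omega6,
):
    n_blocks = set_sizes.shape[0]
    max_ns = 0
    for b in range(n_blocks):
        if set_sizes[b] > max_ns:
            max_ns = set_sizes[b]
    w0 = 1.0 / n_actions
    Q = np.full((n_blocks, max_ns, n_actions), w0)
    W = np.full((n_blocks, max_ns, n_actions), w0)
    nu = alpha_neg / alpha_pos
    pointwise = np.zeros(n_blocks)
    probs = np.empty(n_actions)
    for t in range(phase.shape[0]):
        a = action[t]
        if a < 0:
            continue
        b = block[t]
        s = stim[t]
        if phase[t] == 0:
            omega = omega3 if omega_key[b] == 0 else omega6
            _policy_probs(Q[b, s], W[b, s], beta_l, omega, eps, n_actions, probs)
            pointwise[b] += math.log(probs[a])
            r = reward[t]
            # decay all of this block's unobserved weights toward baseline
            keep = W[b, s, a]
            ns = set_sizes[b]
            for si in range(ns):
                for aj in range(n_actions):
                    W[b, si, aj] += phi * (w0 - W[b, si, aj])
            W[b, s, a] = keep
            # RL delta rule
            d = r - Q[b, s, a]
            if d > 0:
                Q[b, s, a] += alpha_pos * d
            else:
                Q[b, s, a] += alpha_neg * d
            # WM one-shot storage
            dw = r - W[b, s, a]
            if dw > 0:
                W[b, s, a] = r
            else:
                W[b, s, a] += nu * dw
        else:
            _test_probs(Q[b, s], beta_t, eps, n_actions, probs)
            pointwise[b] += math.log(probs[a])
    return pointwise


@njit(cache=True)
def _simulate_core(
    phase,
    block,
    stim,
    correct,
    set_sizes,
    omega_key,
    n_actions,
    alpha_pos,
    alpha_neg,
    beta_l,
    beta_t,
    eps,
    phi,
    omega3,
    omega6,
    miss_rate,
    u_miss,
    u_act,
):
    n_trials = phase.shape[0]
    n_blocks = set_sizes.shape[0]
    max_ns = 0
    for b in range(n_blocks):
        if set_sizes[b] > max_ns:
            max_ns = set_sizes[b]
    w0 = 1.0 / n_actions
    Q = np.full((n_blocks, max_ns, n_actions), w0)
    W = np.full((n_blocks, max_ns, n_actions), w0)
    nu = alpha_neg / alpha_pos
    actions = np.full(n_trials, -1, dtype=np.int64)
    rewards = np.full(n_trials, -1, dtype=np.int64)
    probs = np.empty(n_actions)
    for t in range(n_trials):
        if u_miss[t] < miss_rate:
            continue  # missed: no action, no update
        b = block[t]
        s = stim[t]
        if phase[t] == 0:
            omega = omega3 if omega_key[b] == 0 else omega6
            _policy_probs(Q[b, s], W[b, s], beta_l, omega, eps, n_actions, probs)
        else:
            _test_probs(Q[b, s], beta_t, eps, n_actions, probs)
        acc = 0.0
        a = n_actions - 1
        for k in range(n_actions):
            acc += probs[k]
            if u_act[t] < acc:
                a = k
                break
        actions[t] = a
        # correctness is recorded for both phases; only learning trials
        # deliver it as feedback and update the learner
        rewards[t] = 1 if a == correct[b, s] else 0
        if phase[t] == 0:
            r = float(rewards[t])
            keep = W[b, s, a]
            ns = set_sizes[b]
            for si in range(ns):
                for aj in range(n_actions):
                    W[b, si, aj] += phi * (w0 - W[b, si, aj])
            W[b, s, a] = keep
            d = r - Q[b, s, a]
            if d > 0:
                Q[b, s, a] += alpha_pos * d
            else:
                Q[b, s, a] += alpha_neg * d
            dw = r - W[b, s, a]
            if dw > 0:
                W[b, s, a] = r
            else:
                W[b, s, a] += nu * dw
    return actions, rewards


def _plan_arrays(plan: SessionPlan):
    """Flatten a SessionPlan into kernel-ready arrays (learning then test)."""
    cfg = plan.config
    stim_to_local: dict[int, tuple[int, int]] = {}
    for b_ord, block in enumerate(plan.blocks):
        for k, sid in enumerate(block.stimulus_ids):
            stim_to_local[sid] = (b_ord, k)
    phases, blocks_, stims, correct_sids = [], [], [], []
    for b_ord, seq in enumerate(plan.learning_sequence):
        for sid in seq:
            phases.append(0)
            blocks_.append(b_ord)
            stims.append(stim_to_local[sid][1])
            correct_sids.append(sid)
    for sid, src in plan.test_sequence:
        b_ord, k = stim_to_local[sid]
        phases.append(1)
        blocks_.append(b_ord)
        stims.append(k)
        correct_sids.append(sid)
    set_sizes = np.array([b.set_size for b in plan.blocks], dtype=np.int64)
    omega_key = np.zeros(len(plan.blocks), dtype=np.int64)
    for b_ord, block in enumerate(plan.blocks):
        if block.set_size == cfg.small_set_size:
            omega_key[b_ord] = 0
        elif block.set_size == cfg.large_set_size:
            omega_key[b_ord] = 1
        else:
            raise ConfigError(
                f"no WM reliance weight configured for set_size={block.set_size}"
            )
    correct = np.zeros((len(plan.blocks), int(set_sizes.max())), dtype=np.int64)
    for b_ord, block in enumerate(plan.blocks):
        for k, sid in enumerate(block.stimulus_ids):
            correct[b_ord, k] = block.correct_action[sid] - 1
    return (
        np.array(phases, dtype=np.int64),
        np.array(blocks_, dtype=np.int64),
        np.array(stims, dtype=np.int64),
        correct,
        set_sizes,
        omega_key,
        correct_sids,
    )


def simulate_agent(
    plan: SessionPlan,
    params: AgentParams,
    seed: int,
    participant: str = "sim",
    group: str | float = "",
    age: float = float("nan"),
) -> pd.DataFrame:
    """Simulate one agent through a full session.

    Learning trials sample from the mixture policy and receive deterministic
    reward; test trials sample from the test policy with no feedback and no
    state updates.  Trials are marked missed with the plan's miss_rate and
    contribute no action, reward, or update.  Returns the trial table.
    """
    cfg = plan.config
    phase, block, stim, correct, set_sizes, omega_key, sids = _plan_arrays(plan)
    rng = np.random.default_rng(seed)
    n = phase.shape[0]
    u_miss = rng.random(n)
    u_act = rng.random(n)
    actions, rewards = _simulate_core(
        phase,
        block,
        stim,
        correct,
        set_sizes,
        omega_key,
        cfg.n_actions,
        params.alpha_pos,
        params.alpha_neg,
        params.beta_learn,
        params.beta_test,
        params.epsilon,
        params.phi,
        params.omega3,
        params.omega6,
        cfg.miss_rate,
        u_miss,
        u_act,
    )
    # iteration = ordinal presentation of a stimulus within its phase stream
    iter_count: dict[tuple[int, int], int] = {}
    iters = np.zeros(n, dtype=np.int64)
    trial_in_block = np.zeros(n, dtype=np.int64)
    block_counter: dict[tuple[int, int], int] = {}
    for t in range(n):
        key = (int(phase[t]), sids[t])
        iter_count[key] = iter_count.get(key, 0) + 1
        iters[t] = iter_count[key]
        bkey = (int(phase[t]), int(block[t]))
        block_counter[bkey] = block_counter.get(bkey, 0) + 1
        trial_in_block[t] = block_counter[bkey]
    blk_index = np.array([plan.blocks[b].block_index for b in block])
    missed = actions < 0
    return pd.DataFrame(
        {
            "participant": participant,
            "group": group,
            "age": age,
            "phase": np.where(phase == 0, "learn", "test"),
            "block": blk_index,
            "set_size": set_sizes[block],
            "trial": trial_in_block,
            "stimulus": sids,
            "iteration": iters,
            "action": np.where(missed, np.nan, actions + 1.0),
            # test rows record correctness (no feedback was delivered)
            "reward": np.where(missed, np.nan, rewards.astype(float)),
            "missed": missed,
        }
    )[TRIAL_COLUMNS]


def pack_session(records: pd.DataFrame, n_actions: int = 3) -> PackedSession:
    """Pack one participant's trial table into kernel-ready arrays.

    Records must be ordered as experienced (learning trials of each block in
    order, then test trials).  Blocks are identified by the ``block`` column;
    test trials are assigned to the block in which their stimulus was learned.
    """
    if records["participant"].nunique() != 1:
        raise DataError("pack_session expects exactly one participant")
    learn = records[records["phase"] == "learn"]
    if len(learn) == 0:
        raise DataError("no learning-phase trials present")
    block_ids = list(dict.fromkeys(learn["block"].tolist()))
    block_ord = {b: i for i, b in enumerate(block_ids)}
    stim_local: dict[int, tuple[int, int]] = {}
    set_sizes = np.zeros(len(block_ids), dtype=np.int64)
    for b in block_ids:
        stims = list(dict.fromkeys(learn.loc[learn["block"] == b, "stimulus"]))
        set_sizes[block_ord[b]] = len(stims)
        for k, sid in enumerate(stims):
            stim_local[sid] = (block_ord[b], k)
    ss_vals = sorted(set(int(s) for s in set_sizes))
    omega_key = np.zeros(len(block_ids), dtype=np.int64)
    for i, ns in enumerate(set_sizes):
        if ns == 3:
            omega_key[i] = 0
        elif ns == 6:
            omega_key[i] = 1
        elif len(ss_vals) == 2:
            omega_key[i] = 0 if ns == ss_vals[0] else 1
        else:
            raise ConfigError(f"no WM reliance weight configured for set_size={ns}")

    n = len(records)
    phase = np.where(records["phase"].to_numpy() == "learn", 0, 1).astype(np.int64)
    block = np.empty(n, dtype=np.int64)
    stim = np.empty(n, dtype=np.int64)
    for i, sid in enumerate(records["stimulus"].to_numpy()):
        if sid not in stim_local:
            raise DataError(f"stimulus {sid} was never learned in any block")
        block[i], stim[i] = stim_local[sid]
    act = records["action"].to_numpy(dtype=float)
    missed = records["missed"].to_numpy(dtype=bool)
    action = np.where(missed | ~np.isfinite(act), 0, act).astype(np.int64) - 1
    action[missed | ~np.isfinite(act)] = -1
    rew = records["reward"].to_numpy(dtype=float)
    reward = np.where(np.isfinite(rew), rew, 0.0)
    # within each (participant, block, phase) the trial index must increase
    for (_, _), grp in records.groupby(["phase", "block"], sort=False):
        tr = grp["trial"].to_numpy()
        if np.any(np.diff(tr) <= 0):
            raise DataError("trial_index must be strictly increasing within a block")
    return PackedSession(
        phase=phase,
        block=block,
        stim=stim,
        action=action,
        reward=reward,
        set_sizes=set_sizes,
        omegas_key=omega_key,
        n_actions=n_actions,
        participant=records["participant"].iloc[0],
        group=records["group"].iloc[0] if "group" in records else None,
    )


def _loglik_packed(ps: PackedSession, params: AgentParams) -> np.ndarray:
    return _session_loglik_core(
        ps.phase,
        ps.block,
        ps.stim,
        ps.action,
        ps.reward,
        ps.set_sizes,
        ps.omegas_key,
        ps.n_actions,
        params.alpha_pos,
        params.alpha_neg,
        params.beta_learn,
        params.beta_test,
        params.epsilon,
        params.phi,
        params.omega3,
        params.omega6,
    )


def session_loglik(
    records: pd.DataFrame, params: AgentParams, n_actions: int = 3
) -> tuple[float, dict]:
    """Log-likelihood of one participant's observed choices.

    States are advanced with the observed actions and rewards; missed trials
    contribute nothing and trigger no update.  Returns the total and a dict of
    pointwise log-likelihoods keyed by (participant, block) — the unit used
    for WAIC — with each block's test trials pooled into its unit.
    """
    ps = pack_session(records, n_actions=n_actions)
    pointwise = _loglik_packed(ps, params)
    learn = records[records["phase"] == "learn"]
    block_ids = list(dict.fromkeys(learn["block"].tolist()))
    point = {
        (ps.participant, b): float(pointwise[i]) for i, b in enumerate(block_ids)
    }
    return float(pointwise.sum()), point
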