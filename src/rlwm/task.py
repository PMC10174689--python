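"""Task structure for the set-size-manipulated stimulus-response learning task.

Participants learn deterministic stimulus->action mappings in independent
blocks of set size 3 or 6, each stimulus repeated a fixed number of times with
presentation order constrained so that the delay between successive
presentations of the same stimulus is near-uniform over its designed support.
A surprise test phase re-presents every learned stimulus without feedback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .errors import ConfigError, SequencingError

__all__ = [
    "TaskConfig",
    "Block",
    "SessionPlan",
    "build_session",
    "sequence_block",
    "presentation_delays",
    "delay_support",
]


@dataclass(frozen=True)
class TaskConfig:
    """Session-level task parameters.

    Defaults reproduce the standard design: 10 independent blocks (6 of set
    size 3, 4 of set size 6), 9 presentations per stimulus, 3 response keys.
    """

    n_small_blocks: int = 6
    n_large_blocks: int = 4
    small_set_size: int = 3
    large_set_size: int = 6
    reps_per_stimulus: int = 9
    n_actions: int = 3
    test_reps_per_stimulus: int = 4
    miss_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "n_small_blocks",
            "n_large_blocks",
            "small_set_size",
            "large_set_size",
            "reps_per_stimulus",
            "n_actions",
            "test_reps_per_stimulus",
        ):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ConfigError(f"{name} must be an integer >= 1, got {value!r}")
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ConfigError(f"miss_rate must be in [0, 1], got {self.miss_rate!r}")

    @property
    def n_blocks(self) -> int:
        return self.n_small_blocks + self.n_large_blocks

    @property
    def n_stimuli(self) -> int:
        return (
            self.n_small_blocks * self.small_set_size
            + self.n_large_blocks * self.large_set_size
        )

    @property
    def n_learning_trials(self) -> int:
        return self.n_stimuli * self.reps_per_stimulus


@dataclass(frozen=True)
class Block:
    """One independent learning block with a novel stimulus set."""

    block_index: int  # 1-based position in the session
    set_size: int
    stimulus_ids: tuple[int, ...]
    correct_action: dict[int, int]  # stimulus id -> action in 1..n_actions

    def __post_init__(self) -> None:
        if len(self.stimulus_ids) != self.set_size:
            raise ConfigError(
                f"stimulus_ids must have length set_size={self.set_size}"
            )
        if set(self.correct_action) != set(self.stimulus_ids):
            raise ConfigError("correct_action must cover exactly the block's stimuli")


@dataclass(frozen=True)
class SessionPlan:
    """Full session layout: blocks, learning sequences, and test sequence."""

    config: TaskConfig
    blocks: tuple[Block, ...]
    # per block, the ordered stimulus ids (length set_size * reps_per_stimulus)
    learning_sequence: tuple[tuple[int, ...], ...]
    # ordered (stimulus_id, source_block_index) pairs
    test_sequence: tuple[tuple[int, int], ...]

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "blocks": [
                {
                    "block_index": b.block_index,
                    "set_size": b.set_size,
                    "stimulus_ids": list(b.stimulus_ids),
                    "correct_action": {str(k): v for k, v in b.correct_action.items()},
                }
                for b in self.blocks
            ],
            "learning_sequence": [list(s) for s in self.learning_sequence],
            "test_sequence": [list(p) for p in self.test_sequence],
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "SessionPlan":
        payload = json.loads(text)
        config = TaskConfig(**payload["config"])
        blocks = tuple(
            Block(
                block_index=b["block_index"],
                set_size=b["set_size"],
                stimulus_ids=tuple(b["stimulus_ids"]),
                correct_action={int(k): v for k, v in b["correct_action"].items()},
            )
            for b in payload["blocks"]
        )
        return cls(
            config=config,
            blocks=blocks,
            learning_sequence=tuple(tuple(s) for s in payload["learning_sequence"]),
            test_sequence=tuple(tuple(p) for p in payload["test_sequence"]),
        )


def delay_support(set_size: int) -> np.ndarray:
    """Designed support of between-presentation delays for a block.

    Delays are counted as the number of intervening trials between successive
    presentations of the same stimulus.  With immediate repeats forbidden the
    smallest delay is 1; the sequencer flattens the delay histogram over
    {1, ..., 2*set_size - 4} (set size >= 4; {1, 2, 3} for set size 3 and {1}
    for set size 2), a band around the round-robin spacing set_size - 1 whose
    flat occupancy is achievable under the no-repeat and count constraints.
    """
    if set_size < 2:
        raise SequencingError("delay support undefined for set_size < 2")
    if set_size == 2:
        return np.arange(1, 2)
    top = 3 if set_size == 3 else 2 * set_size - 4
    return np.arange(1, top + 1)


def presentation_delays(sequence) -> np.ndarray:
    """Delay (intervening-trial count) before each presentation.

    Returns a float array aligned with ``sequence``; first presentations of a
    stimulus have no previous occurrence and are flagged as NaN.
    """
    seq = list(sequence)
    if len(seq) == 0:
        raise ConfigError("sequence must be non-empty")
    last_seen: dict = {}
    out = np.full(len(seq), np.nan)
    for i, s in enumerate(seq):
        if s in last_seen:
            out[i] = i - last_seen[s] - 1
        last_seen[s] = i
    return out


@njit(cache=True)
def _hill_climb(seq, set_size, target, max_delay, pairs):
    """Swap-based hill climb flattening the delay histogram.

    ``pairs`` holds the proposal position pairs; swaps creating immediate
    repeats are rejected; equal-score moves are accepted to traverse plateaus.
    Returns the best sequence found and its score.
    """
    n = seq.shape[0]
    last = np.empty(set_size, dtype=np.int64)

    def score(sq):
        for s in range(set_size):
            last[s] = -1
        total = 0
        counts = np.zeros(max_delay + 2, dtype=np.int64)
        for i in range(n):
            s = sq[i]
            if last[s] >= 0:
                d = i - last[s] - 1
                if d > max_delay:
                    counts[max_delay + 1] += 1
                else:
                    counts[d] += 1
            last[s] = i
        for k in range(1, max_delay + 1):
            total += abs(counts[k] - target[k - 1])
        total += 3 * counts[max_delay + 1]
        return total

    best = seq.copy()
    best_score = score(seq)
    for t in range(pairs.shape[0]):
        if best_score == 0:
            break
        i = pairs[t, 0]
        j = pairs[t, 1]
        if seq[i] == seq[j]:
            continue
        tmp = seq[i]
        seq[i] = seq[j]
        seq[j] = tmp
        ok = True
        for pos in (i, j):
            if pos > 0 and seq[pos - 1] == seq[pos]:
                ok = False
            if pos + 1 < n and seq[pos + 1] == seq[pos]:
                ok = False
        if not ok:
            tmp = seq[i]
            seq[i] = seq[j]
            seq[j] = tmp
            continue
        s = score(seq)
        if s <= best_score:
            if s < best_score:
                best = seq.copy()
            best_score = s
        else:
            tmp = seq[i]
            seq[i] = seq[j]
            seq[j] = tmp
    return best, best_score


def _no_repeat_draw(
    set_size: int, reps: int, rng: np.random.Generator
) -> np.ndarray | None:
    """Greedy construction of a sequence with no immediate repeats."""
    remaining = np.full(set_size, reps, dtype=np.int64)
    seq = np.empty(set_size * reps, dtype=np.int64)
    prev = -1
    for i in range(seq.shape[0]):
        avail = [s for s in range(set_size) if s != prev and remaining[s] > 0]
        if not avail:
            return None
        top = max(remaining[s] for s in avail)
        # any stimulus holding more than half the remaining slots must go now
        forced = [s for s in avail if 2 * remaining[s] > remaining.sum() - remaining[s]]
        pool = forced if forced else avail
        weights = np.array([remaining[s] for s in pool], dtype=float)
        choice = pool[rng.choice(len(pool), p=weights / weights.sum())]
        seq[i] = choice
        remaining[choice] -= 1
        prev = choice
    return seq


def sequence_block(
    set_size: int,
    reps: int,
    seed: int | np.random.Generator,
    max_attempts: int = 30000,
) -> list[int]:
    """Pseudo-randomized presentation order for one block.

    Stimuli are locally indexed 0..set_size-1; each occurs exactly ``reps``
    times, never twice in a row, and the histogram of delays between
    successive presentations of the same stimulus is optimized toward a flat
    target over :func:`delay_support` by seeded hill-climbing (random position
    swaps, best sequence kept, ``max_attempts`` proposals).
    """
    if set_size < 2:
        raise SequencingError("set_size must be >= 2 (no-repeat rule infeasible)")
    if reps < 2:
        raise SequencingError("reps must be >= 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    support = delay_support(set_size)
    max_delay = int(support[-1])
    n_obs = set_size * (reps - 1)
    base, rem = divmod(n_obs, len(support))
    target = np.full(len(support), base, dtype=np.int64)
    if rem:
        # spread the remainder over random bins so pooled histograms stay flat
        target[rng.choice(len(support), size=rem, replace=False)] += 1

    n = set_size * reps
    seq = None
    for _ in range(50):
        seq = _no_repeat_draw(set_size, reps, rng)
        if seq is not None:
            break
    if seq is None:
        raise SequencingError(
            f"could not build a no-repeat sequence for set_size={set_size}, reps={reps}"
        )
    pairs = rng.integers(0, n, size=(max_attempts, 2))
    best, _ = _hill_climb(seq, set_size, target, max_delay, pairs)
    return [int(x) for x in best]


def build_session(config: TaskConfig, seed: int) -> SessionPlan:
    """Lay out a full session: block order, stimulus ids, correct mappings,
    learning sequences, and the interleaved test sequence.

    Correct actions are counterbalanced across the session: each action index
    is correct for ``n_stimuli // n_actions`` stimuli (exactly equal when the
    stimulus count is divisible by the number of actions).
    """
    rng = np.random.default_rng(seed)

    set_sizes = [config.small_set_size] * config.n_small_blocks + [
        config.large_set_size
    ] * config.n_large_blocks
    rng.shuffle(set_sizes)

    n_stim = config.n_stimuli
    base, rem = divmod(n_stim, config.n_actions)
    actions = np.repeat(np.arange(1, config.n_actions + 1), base)
    if rem:
        extra = rng.choice(np.arange(1, config.n_actions + 1), size=rem, replace=False)
        actions = np.concatenate([actions, extra])
    actions = rng.permutation(actions)

    blocks: list[Block] = []
    learning: list[tuple[int, ...]] = []
    next_stim = 1
    cursor = 0
    for bi, ns in enumerate(set_sizes, start=1):
        ids = tuple(range(next_stim, next_stim + ns))
        next_stim += ns
        mapping = {
            sid: int(actions[cursor + k]) for k, sid in enumerate(ids)
        }
        cursor += ns
        blocks.append(
            Block(block_index=bi, set_size=ns, stimulus_ids=ids, correct_action=mapping)
        )
        local = sequence_block(ns, config.reps_per_stimulus, rng)
        learning.append(tuple(ids[k] for k in local))

    # test phase: every learned stimulus, test_reps times, one shuffled stream
    pairs = [
        (sid, b.block_index)
        for b in blocks
        for sid in b.stimulus_ids
        for _ in range(config.test_reps_per_stimulus)
    ]
    order = rng.permutation(len(pairs))
    test_seq = [pairs[k] for k in order]
    # repair immediate repeats of the same stimulus where possible
    for i in range(1, len(test_seq)):
        if test_seq[i][0] == test_seq[i - 1][0]:
            for j in range(i + 1, len(test_seq)):
                if (
                    test_seq[j][0] != test_seq[i - 1][0]
                    and (i + 1 >= len(test_seq) or test_seq[j][0] != test_seq[i + 1][0])
                ):
                    test_seq[i], test_seq[j] = test_seq[j], test_seq[i]
                    break

    return SessionPlan(
        config=config,
        blocks=tuple(blocks),
        learning_sequence=tuple(learning),
        test_sequence=tuple(test_seq),
    )
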