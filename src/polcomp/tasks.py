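"""Contextual multi-armed bandit task specifications.

A :class:`Task` is a finite state distribution ``P(s)`` together with a
state-by-action reward matrix ``Q(s, a)``.  Everything downstream — optimal
capacity-limited policies, reward-complexity frontiers, consideration-set
restrictions — is a function of these two objects alone.

The constructors in this module build the standard task families:

* :func:`make_symmetric_task` — each state has a unique optimal action
  (square identity-structured reward matrix).
* :func:`make_random_task` — i.i.d. Uniform(0, 1) rewards; the canonical
  large-action-space test bed (16 states, 32 actions).
* :func:`make_scarce_task` — reward concentrated on a few "rich" action
  columns.
* :func:`make_experiment_task` — the 6-state / 7-action task with a
  state-independent "safety" action yielding a constant +0.2 reward, the
  six unsafe actions yielding +1 (optimal) or -0.18 per state.

All constructors use a flat state distribution.  Indices are 0-based
everywhere, including serialized files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

__all__ = [
    "Task",
    "make_symmetric_task",
    "make_random_task",
    "make_scarce_task",
    "make_experiment_task",
    "perturb_rewards",
    "general_values",
]

_PROB_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class Task:
    """A contextual bandit: state distribution plus reward matrix.

    Parameters
    ----------
    state_probs
        Probability of each state; non-negative, sums to 1 (within 1e-12).
    rewards
        ``(n_states, n_actions)`` matrix of finite rewards ``Q(s, a)``.
    action_labels
        One identifier per action (defaults to ``a0, a1, ...``).
    safety_index
        Optional index of a state-independent action whose reward column is
        constant across states.
    parent_indices
        When this task was produced by restricting another task to a subset
        of actions, the original index of each retained column; ``None`` for
        tasks over their native action space.
    """

    state_probs: np.ndarray
    rewards: np.ndarray
    action_labels: tuple[str, ...] = ()
    safety_index: int | None = None
    parent_indices: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.state_probs, dtype=np.float64).reshape(-1)
        rewards = np.atleast_2d(np.asarray(self.rewards, dtype=np.float64))
        if rewards.ndim != 2 or rewards.shape[0] != probs.shape[0]:
            raise ValueError(
                f"rewards shape {rewards.shape} incompatible with "
                f"{probs.shape[0]} states"
            )
        if probs.size < 1 or rewards.shape[1] < 1:
            raise ValueError("need at least one state and one action")
        if not np.all(np.isfinite(rewards)):
            raise ValueError("rewards must be finite")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > _PROB_TOL:
            raise ValueError("state_probs must be non-negative and sum to 1")
        labels = tuple(self.action_labels) or tuple(
            f"a{j}" for j in range(rewards.shape[1])
        )
        if len(labels) != rewards.shape[1]:
            raise ValueError("action_labels length must equal n_actions")
        if self.safety_index is not None:
            j = int(self.safety_index)
            if not 0 <= j < rewards.shape[1]:
                raise ValueError("safety_index out of range")
            col = rewards[:, j]
            if not np.allclose(col, col[0], rtol=0, atol=1e-12):
                raise ValueError("safety column must be constant across states")
        probs.setflags(write=False)
        rewards.setflags(write=False)
        object.__setattr__(self, "state_probs", probs)
        object.__setattr__(self, "rewards", rewards)
        object.__setattr__(self, "action_labels", labels)
        if self.parent_indices is not None:
            object.__setattr__(
                self, "parent_indices", tuple(int(i) for i in self.parent_indices)
            )

    @property
    def n_states(self) -> int:
        return self.state_probs.shape[0]

    @property
    def n_actions(self) -> int:
        return self.rewards.shape[1]

    @property
    def fingerprint(self) -> str:
        """Stable identifier of (P(s), Q, labels, safety) for cross-checks."""
        h = hashlib.sha1()
        h.update(self.state_probs.tobytes())
        h.update(self.rewards.tobytes())
        h.update("|".join(self.action_labels).encode())
        h.update(str(self.safety_index).encode())
        return h.hexdigest()[:16]

    # ------------------------------------------------------------------ io
    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize to a JSON object; round-trips float64 bit-exactly."""
        obj = {
            "state_probs": self.state_probs.tolist(),
            "rewards": self.rewards.tolist(),
            "action_labels": list(self.action_labels),
            "safety_index": self.safety_index,
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Task":
        """Load from a JSON string or a path to a JSON file."""
        if isinstance(source, Path):
            text = source.read_text()
        else:
            text = str(source)
            if not text.lstrip().startswith("{"):
                text = Path(text).read_text()
        obj = json.loads(text)
        return cls(
            state_probs=np.array(obj["state_probs"], dtype=np.float64),
            rewards=np.array(obj["rewards"], dtype=np.float64),
            action_labels=tuple(obj["action_labels"]),
            safety_index=obj.get("safety_index"),
        )

    def to_csv(self, probs_path: str | Path, matrix_path: str | Path) -> None:
        """Write the state distribution and the labelled reward matrix."""
        np.savetxt(probs_path, self.state_probs[None, :], delimiter=",", fmt="%.17g")
        header = ",".join(self.action_labels)
        np.savetxt(
            matrix_path, self.rewards, delimiter=",", fmt="%.17g",
            header=header, comments="",
        )

    @classmethod
    def from_csv(
        cls,
        probs_path: str | Path,
        matrix_path: str | Path,
        safety_index: int | None = None,
    ) -> "Task":
        probs = np.loadtxt(probs_path, delimiter=",").reshape(-1)
        with open(matrix_path) as fh:
            labels = tuple(fh.readline().strip().split(","))
        rewards = np.atleast_2d(np.loadtxt(matrix_path, delimiter=",", skiprows=1))
        return cls(probs, rewards, labels, safety_index=safety_index)


def _flat(n: int) -> np.ndarray:
    return np.full(n, 1.0 / n)


def make_symmetric_task(
    n_states: int, reward_hi: float = 1.0, reward_lo: float = 0.0
) -> Task:
    """Square task where each state has a unique optimal action.

    ``Q[s, s] = reward_hi`` on the diagonal and ``reward_lo`` elsewhere,
    under a flat state distribution.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if not (np.isfinite(reward_hi) and np.isfinite(reward_lo)):
        raise ValueError("rewards must be finite")
    if not reward_hi > reward_lo:
        raise ValueError("reward_hi must exceed reward_lo")
    q = np.full((n_states, n_states), float(reward_lo))
    np.fill_diagonal(q, float(reward_hi))
    return Task(_flat(n_states), q)


def make_random_task(n_states: int, n_actions: int, rng_seed: int) -> Task:
    """Flat-P(s) task with i.i.d. Uniform(0, 1) reward entries."""
    if n_states < 1 or n_actions < 1:
        raise ValueError("n_states and n_actions must be positive")
    rng = np.random.default_rng(rng_seed)
    q = rng.random((n_states, n_actions))
    return Task(_flat(n_states), q)


def make_scarce_task(
    n_states: int,
    n_actions: int,
    n_rich_actions: int,
    rng_seed: int,
    rich_range: tuple[float, float] = (0.5, 1.0),
    poor_range: tuple[float, float] = (0.0, 0.05),
) -> Task:
    """Task whose reward is concentrated on a few "rich" action columns.

    The first ``n_rich_actions`` columns draw Uniform(*rich_range*) per
    state; the rest draw Uniform(*poor_range*).  This is a synthetic
    stand-in construction — only the qualitative property (reward centred
    on few actions) is pinned down, and the ranges are parameterizable.
    """
    if n_states < 1 or n_actions < 1 or n_rich_actions < 1:
        raise ValueError("counts must be positive")
    if n_rich_actions >= n_actions:
        raise ValueError("n_rich_actions must be < n_actions")
    rng = np.random.default_rng(rng_seed)
    q = rng.uniform(*poor_range, size=(n_states, n_actions))
    q[:, :n_rich_actions] = rng.uniform(*rich_range, size=(n_states, n_rich_actions))
    return Task(_flat(n_states), q)


def make_experiment_task() -> Task:
    """The 6-state / 7-action human-experiment task.

    Six "unsafe" actions are each uniquely optimal for one state (+1 there,
    -0.18 in every other state); the seventh "safety" action yields +0.2
    regardless of state.  The timeout penalty (-1) punishes non-response and
    is not part of Q.  Flat state distribution.
    """
    q = np.full((6, 7), -0.18)
    for s in range(6):
        q[s, s] = 1.0
    q[:, 6] = 0.2
    labels = tuple(f"key{j + 1}" for j in range(6)) + ("safety",)
    return Task(_flat(6), q, labels, safety_index=6)


def perturb_rewards(task: Task, noise_sd: float, rng_seed: int) -> Task:
    """Return a copy of *task* with i.i.d. Gaussian noise added to Q.

    Emulates an agent holding a noisy internal representation of the reward
    structure; the state distribution is untouched.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return task
    rng = np.random.default_rng(rng_seed)
    noisy = task.rewards + rng.normal(0.0, noise_sd, size=task.rewards.shape)
    # the noisy safety column is no longer constant, so the marker is dropped
    return Task(task.state_probs, noisy, task.action_labels, safety_index=None,
                parent_indices=task.parent_indices)


def general_values(task: Task) -> np.ndarray:
    """State-marginalized expected reward of each action.

    ``V(a) = sum_s P(s) Q(s, a)`` — the reward an agent earns by playing
    action ``a`` unconditionally.  The best state-independent policy is a
    point mass on ``argmax_a V(a)``.
    """
    return task.state_probs @ task.rewards
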