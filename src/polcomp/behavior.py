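"""Synthetic choice data and behavioral estimators.

The estimators here are the ones applied to per-block choice data: a
Dirichlet-regularized posterior-mean policy estimate, the mutual
information of that estimate (policy complexity), the number of distinct
actions chosen (with an optional minimum-count threshold against stray key
presses), and the deviation of the empirical (complexity, reward) point
from the full-action-space reward-complexity frontier.

:func:`simulate_agent` generates the synthetic stand-in for human data:
per-trial (state, action, reward) records from a known policy on a known
task, with the state schedule either counterbalanced (each state appears
equally often, shuffled) or i.i.d. from P(s).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .rate_distortion import Frontier, Policy, frontier_reward_at, policy_complexity
from .tasks import Task

__all__ = [
    "ChoiceDataset",
    "BehaviorSummary",
    "simulate_agent",
    "estimate_policy",
    "estimate_complexity",
    "count_actions",
    "summarize",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ChoiceDataset:
    """Per-trial (state, action, reward) records."""

    states: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    n_states: int
    n_actions: int
    task_fingerprint: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.states, dtype=np.intp)
        a = np.asarray(self.actions, dtype=np.intp)
        r = np.asarray(self.rewards, dtype=np.float64)
        if not (s.shape == a.shape == r.shape) or s.ndim != 1:
            raise ValueError("states, actions, rewards must be equal-length 1D")
        if s.size and (s.min() < 0 or s.max() >= self.n_states):
            raise ValueError("state index out of range")
        if a.size and (a.min() < 0 or a.max() >= self.n_actions):
            raise ValueError("action index out of range")
        for arr, name in ((s, "states"), (a, "actions"), (r, "rewards")):
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    @property
    def n_trials(self) -> int:
        return self.states.shape[0]

    def counts(self) -> np.ndarray:
        """State-by-action choice count matrix."""
        c = np.zeros((self.n_states, self.n_actions), dtype=np.int64)
        np.add.at(c, (self.states, self.actions), 1)
        return c

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "state": self.states,
                "action": self.actions,
                "reward": self.rewards,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        n_states: int,
        n_actions: int,
        task_fingerprint: str = "",
    ) -> "ChoiceDataset":
        df = pd.read_csv(path)
        return cls(
            states=df["state"].to_numpy(),
            actions=df["action"].to_numpy(),
            rewards=df["reward"].to_numpy(),
            n_states=n_states,
            n_actions=n_actions,
            task_fingerprint=task_fingerprint,
        )


@dataclasses.dataclass(frozen=True)
class BehaviorSummary:
    """Per-block behavioral summary: the quantities plotted per participant."""

    complexity_bits_est: float
    n_actions_chosen: int
    mean_reward: float
    reward_loss_vs_frontier: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BehaviorSummary":
        if isinstance(source, Path):
            text = source.read_text()
        else:
            text = str(source)
            if not text.lstrip().startswith("{"):
                text = Path(text).read_text()
        return cls(**json.loads(text))


def simulate_agent(
    task: Task,
    policy: Policy,
    n_trials: int,
    rng_seed: int,
    state_schedule: Literal["counterbalanced", "iid"] = "counterbalanced",
) -> ChoiceDataset:
    """Generate per-trial choice data from a known policy.

    ``counterbalanced`` presents each state exactly ``n_trials / n_states``
    times in shuffled order (the empirical state distribution is then
    exactly flat); ``iid`` draws states from ``P(s)``.  Actions are drawn
    from the policy rows; rewards are filled deterministically from Q.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if policy.probs.shape != task.rewards.shape:
        raise ValueError("policy and task dimensions disagree")
    rng = np.random.default_rng(rng_seed)
    if state_schedule == "counterbalanced":
        if n_trials % task.n_states != 0:
            raise ValueError(
                "counterbalanced schedule requires n_trials divisible by n_states"
            )
        states = np.repeat(np.arange(task.n_states), n_trials // task.n_states)
        rng.shuffle(states)
    elif state_schedule == "iid":
        states = rng.choice(task.n_states, size=n_trials, p=task.state_probs)
    else:
        raise ValueError(f"unknown state_schedule: {state_schedule!r}")
    cdf = np.cumsum(policy.probs, axis=1)
    cdf[:, -1] = 1.0
    u = rng.random(n_trials)
    actions = np.argmax(u[:, None] <= cdf[states], axis=1)
    rewards = task.rewards[states, actions]
    return ChoiceDataset(
        states=states,
        actions=actions,
        rewards=rewards,
        n_states=task.n_states,
        n_actions=task.n_actions,
        task_fingerprint=task.fingerprint,
    )


def estimate_policy(
    dataset: ChoiceDataset, alpha: float = 0.01
) -> tuple[Policy, np.ndarray]:
    """Dirichlet posterior-mean policy and empirical state frequencies.

    Per state, a symmetric Dirichlet(alpha) prior over actions is updated
    with the empirical choice counts; the posterior mean is

        pi_hat(a|s) = (count(s, a) + alpha) / (count(s) + n_actions * alpha).

    The small default ``alpha = 0.01`` shrinks just enough that empirical
    reward-complexity points do not land above the reward-complexity
    frontier.  States never visited get the prior mean (uniform) row and a
    logged warning.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if dataset.n_trials == 0:
        raise ValueError("dataset is empty")
    counts = dataset.counts().astype(np.float64)
    row_n = counts.sum(axis=1)
    if np.any(row_n == 0):
        missing = np.flatnonzero(row_n == 0)
        logger.warning(
            "states %s never visited; their rows fall back to the prior mean",
            missing.tolist(),
        )
    probs = (counts + alpha) / (row_n + dataset.n_actions * alpha)[:, None]
    state_freqs = row_n / row_n.sum()
    return Policy(probs), state_freqs


def estimate_complexity(dataset: ChoiceDataset, alpha: float = 0.01) -> float:
    """Policy complexity (bits): MI of the posterior-mean policy under the
    empirical state frequencies."""
    policy, state_freqs = estimate_policy(dataset, alpha)
    return policy_complexity(state_freqs, policy)


def count_actions(dataset: ChoiceDataset, min_count: int = 1) -> int:
    """Number of distinct actions chosen at least ``min_count`` times.

    ``min_count > 1`` guards the consideration-set size estimate against
    occasional unintended key presses.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    totals = np.bincount(dataset.actions, minlength=dataset.n_actions)
    return int(np.count_nonzero(totals >= min_count))


def summarize(
    dataset: ChoiceDataset,
    task: Task,
    full_frontier: Frontier,
    alpha: float = 0.01,
    min_count: int = 1,
) -> BehaviorSummary:
    """Assemble the per-block behavioral summary.

    The frontier deviation is ``mean observed reward`` minus the frontier
    reward at the *estimated* complexity.
    """
    if dataset.task_fingerprint and dataset.task_fingerprint != task.fingerprint:
        raise ValueError("dataset was generated from a different task")
    if full_frontier.task_fingerprint and full_frontier.task_fingerprint != task.fingerprint:
        raise ValueError("frontier was computed for a different task")
    comp = estimate_complexity(dataset, alpha)
    mean_reward = float(dataset.rewards.mean())
    loss = mean_reward - float(frontier_reward_at(full_frontier, comp))
    return BehaviorSummary(
        complexity_bits_est=comp,
        n_actions_chosen=count_actions(dataset, min_count),
        mean_reward=mean_reward,
        reward_loss_vs_frontier=loss,
    )
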