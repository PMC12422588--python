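"""Self-normalized importance sampling (SNIS) estimation of the optimal policy.

Given action samples (alpha_1, ..., alpha_n) drawn *with replacement* from a
proposal distribution P0(a), the optimal full-action-space policy at a given
beta can be estimated by the self-normalized ratio estimator

    pi_hat(a|s)  ∝  sum_j exp(beta Q(s, alpha_j)) * P(alpha_j) / P0(alpha_j)
                            * 1[alpha_j = a],

where P is the optimal marginal action distribution.  Because P is itself
unknown to an agent, it is estimated self-consistently: the current
estimate's marginal ``P_hat(a) = sum_s P(s) pi_hat(a|s)`` replaces it, and
the update is iterated Blahut–Arimoto-style until convergence.  Repeated
draws of the same action contribute through their count (count times the
per-draw weight), so the estimator is informed by sampling frequency —
unlike running Blahut–Arimoto on the set of unique actions, which ignores
it.  The estimator is asymptotically unbiased in n but biased at finite n.

Row normalization is performed in log space (log-sum-exp), so large
negative ``beta * Q`` values cannot underflow the weights.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from .consideration import ActionSample
from .rate_distortion import (
    ConvergenceWarning,
    Frontier,
    Policy,
    ba_fixed_point,
    policy_complexity,
    reward_loss,
    trial_averaged_reward,
)
from .tasks import Task

__all__ = ["SnisEstimate", "snis_policy", "evaluate_snis"]


@dataclasses.dataclass(frozen=True)
class SnisEstimate:
    """SNIS estimate of the optimal policy from one action sample.

    The policy lives on the full action set but carries mass only on the
    sampled actions.
    """

    policy: Policy
    beta: float
    converged: bool
    iterations: int
    sample: ActionSample | None = dataclasses.field(default=None, compare=False)

    def to_files(self, policy_path: str | Path, meta_path: str | Path,
                 action_labels=None) -> None:
        self.policy.to_csv(policy_path, action_labels)
        meta = {
            "beta": self.beta,
            "n": self.sample.size if self.sample is not None else None,
            "proposal": self.sample.proposal.kind if self.sample is not None else None,
            "converged": self.converged,
            "iterations": self.iterations,
        }
        Path(meta_path).write_text(json.dumps(meta, indent=1))


def snis_policy(
    task: Task,
    sample: ActionSample,
    beta: float,
    tol: float = 1e-10,
    max_iter: int = 10000,
    gap_tol: float | None = None,
) -> SnisEstimate:
    """Fixed point of the self-normalized importance-sampling estimator.

    Requires a with-replacement sample whose proposal has positive mass on
    every sampled action.  Initialized uniform over the sampled support
    (the problem restricted to the support is convex, so the converged
    value is init-insensitive).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if not sample.with_replacement:
        raise ValueError("SNIS assumes sampling actions with replacement")
    support = np.array(sorted(sample.unique_actions), dtype=np.intp)
    counts = sample.counts(task.n_actions)[support].astype(np.float64)
    p0 = sample.proposal.probs[support]
    if np.any(p0 <= 0):
        raise ValueError("proposal must have positive mass on every sampled action")
    n_s = task.n_states
    k = support.shape[0]
    # per-(s, a) log weight, constant across iterations:
    #   log count(a) + beta Q(s, a) - log P0(a)
    base = beta * task.rewards[:, support] + (np.log(counts) - np.log(p0))[None, :]
    pi = np.full((n_s, k), 1.0 / k)
    pi, converged, it = ba_fixed_point(
        task.state_probs, base, pi, tol, max_iter, gap_tol
    )
    if not converged:
        warnings.warn(
            f"SNIS fixed point did not converge in {max_iter} iterations "
            f"(beta={beta:g}, n={sample.size})",
            ConvergenceWarning,
        )
    full = np.zeros((n_s, task.n_actions))
    full[:, support] = pi
    return SnisEstimate(
        policy=Policy(full, converged=converged, iterations=it),
        beta=float(beta),
        converged=converged,
        iterations=it,
        sample=sample,
    )


def evaluate_snis(
    task: Task, estimate: SnisEstimate, full_frontier: Frontier
) -> tuple[float, float, float]:
    """Complexity, reward, and frontier loss of an SNIS estimate.

    All three are measured under the *true* task: complexity under P(s),
    reward under the true Q, and the signed loss against the full-task
    frontier at the achieved complexity.
    """
    comp = policy_complexity(task.state_probs, estimate.policy)
    rew = trial_averaged_reward(task, estimate.policy)
    loss = reward_loss(task, estimate.policy, full_frontier)
    return comp, rew, loss
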