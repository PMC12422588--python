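"""Action consideration sets: proposals, sampling, restriction, enumeration.

An agent facing a large action space may optimize its policy over a subset
of actions only.  This module provides the three proposal distributions
through which candidate actions enter the consideration set:

* flat — ``P0(a) = const``;
* general-value-based — ``P0(a) ∝ V(a) = sum_s P(s) Q(s, a)``;
* oracle — the optimal full-task marginal ``P*(a)`` at a given beta
  (a benchmark requiring knowledge of the optimal policy);

together with with/without-replacement sampling, restriction of a task to a
subset of actions, exhaustive subset-frontier enumeration, and the
set-size-specific frontier built as the pointwise max over whether a
designated safety action is retained.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .rate_distortion import (
    Frontier,
    FrontierPoint,
    Policy,
    blahut_arimoto,
    frontier_reward_at,
    trace_frontier,
)
from .tasks import Task, general_values

__all__ = [
    "ProposalDistribution",
    "ActionSample",
    "proposal_distribution",
    "sample_actions",
    "restrict_task",
    "embed_policy",
    "enumerate_subset_frontiers",
    "na_specific_frontier",
    "max_complexity_bound",
]

ProposalKind = Literal["flat", "general_value", "oracle"]
SafetyRule = Literal["include", "exclude", "ignore"]

#: refuse exhaustive enumeration beyond this many subsets
MAX_SUBSETS = 100_000


@dataclasses.dataclass(frozen=True)
class ProposalDistribution:
    """A distribution over actions from which consideration sets are drawn."""

    kind: ProposalKind
    probs: np.ndarray
    beta: float | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=np.float64).reshape(-1)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("proposal probs must be non-negative and sum to 1")
        if self.kind == "flat" and np.any(p <= 0):
            raise ValueError("flat proposal must have full support")
        if self.kind == "oracle" and self.beta is None:
            raise ValueError("oracle proposal requires beta")
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)

    @property
    def n_actions(self) -> int:
        return self.probs.shape[0]


@dataclasses.dataclass(frozen=True)
class ActionSample:
    """An ordered multiset of sampled action indices."""

    draws: tuple[int, ...]
    with_replacement: bool
    proposal: ProposalDistribution

    def __post_init__(self) -> None:
        draws = tuple(int(d) for d in self.draws)
        if not self.with_replacement and len(set(draws)) != len(draws):
            raise ValueError("without-replacement sample contains repeats")
        object.__setattr__(self, "draws", draws)

    @property
    def unique_actions(self) -> frozenset[int]:
        return frozenset(self.draws)

    @property
    def size(self) -> int:
        return len(self.draws)

    def counts(self, n_actions: int) -> np.ndarray:
        return np.bincount(np.array(self.draws), minlength=n_actions)


def proposal_distribution(
    task: Task, kind: ProposalKind, beta: float | None = None
) -> ProposalDistribution:
    """Build one of the three candidate proposal distributions.

    For the general-value proposal, tasks with non-positive general values
    are handled by shifting V by ``-min(V) + 1e-6 * range(V)`` before
    normalizing; this keeps the proposal a valid distribution without
    changing the value ranking (inert for tasks with all-positive V).
    """
    if kind == "flat":
        return ProposalDistribution("flat", np.full(task.n_actions, 1.0 / task.n_actions))
    if kind == "general_value":
        v = general_values(task).astype(np.float64)
        if v.min() <= 0:
            span = v.max() - v.min()
            v = v - v.min() + (1e-6 * span if span > 0 else 1.0)
        return ProposalDistribution("general_value", v / v.sum())
    if kind == "oracle":
        if beta is None:
            raise ValueError("oracle proposal requires beta")
        pol = blahut_arimoto(task, float(beta))
        return ProposalDistribution("oracle", pol.marginal(task.state_probs), beta=float(beta))
    raise ValueError(f"unknown proposal kind: {kind!r}")


def sample_actions(
    proposal: ProposalDistribution,
    size: int,
    with_replacement: bool,
    rng_seed: int,
) -> ActionSample:
    """Draw *size* actions from a proposal distribution.

    With replacement: i.i.d. draws.  Without replacement: sequential
    weighted draws, renormalizing the proposal over the remaining actions
    after each draw.

    Draws are generated by inverting the proposal CDF on uniform variates,
    so two proposals sampled under the same seed consume the same uniforms:
    simulation sweeps exploit this as common random numbers, making
    comparisons across proposals and algorithms paired rather than
    independent.
    """
    if size < 1:
        raise ValueError("size must be positive")
    rng = np.random.default_rng(rng_seed)
    p = proposal.probs
    if with_replacement:
        cdf = np.cumsum(p)
        cdf[-1] = 1.0
        draws = np.searchsorted(cdf, rng.random(size), side="right")
        return ActionSample(tuple(int(d) for d in draws), True, proposal)
    support = int(np.count_nonzero(p))
    if size > support:
        raise ValueError(
            f"cannot draw {size} distinct actions from a proposal with "
            f"support {support}"
        )
    remaining = p.copy()
    draws = []
    for u in rng.random(size):
        cdf = np.cumsum(remaining / remaining.sum())
        cdf[-1] = 1.0
        d = int(np.searchsorted(cdf, u, side="right"))
        draws.append(d)
        remaining[d] = 0.0
    return ActionSample(tuple(draws), False, proposal)


def restrict_task(task: Task, actions: Iterable[int]) -> Task:
    """Remove all but the given actions from a task's reward matrix.

    The returned task keeps the same state distribution, remembers the
    original column indices in ``parent_indices`` (sorted ascending), and
    remaps or clears the safety marker.
    """
    idx = sorted({int(a) for a in actions})
    if not idx:
        raise ValueError("actions must be a non-empty set")
    if idx[0] < 0 or idx[-1] >= task.n_actions:
        raise ValueError("action index out of range")
    safety = None
    if task.safety_index is not None and task.safety_index in idx:
        safety = idx.index(task.safety_index)
    return Task(
        state_probs=task.state_probs,
        rewards=task.rewards[:, idx],
        action_labels=tuple(task.action_labels[j] for j in idx),
        safety_index=safety,
        parent_indices=tuple(idx),
    )


def embed_policy(policy: Policy, parent_indices: Sequence[int], n_actions: int) -> Policy:
    """Lift a restricted-task policy back onto the full action space.

    Mass outside the retained columns is exactly zero.
    """
    idx = list(parent_indices)
    if policy.n_actions != len(idx):
        raise ValueError("policy width must match parent_indices length")
    probs = np.zeros((policy.n_states, n_actions))
    probs[:, idx] = policy.probs
    return Policy(probs, converged=policy.converged, iterations=policy.iterations)


def enumerate_subset_frontiers(
    task: Task,
    set_size: int,
    safety_rule: SafetyRule = "ignore",
    beta_grid: Sequence[float] | np.ndarray | None = None,
) -> dict[tuple[int, ...], Frontier]:
    """Reward-complexity frontier of every consideration set of a given size.

    ``safety_rule`` filters subsets by whether they contain the task's
    safety action ("include" / "exclude"); "ignore" enumerates all subsets.
    Refuses combinatorially infeasible enumerations (> 100000 subsets).
    """
    if not 1 <= set_size <= task.n_actions:
        raise ValueError("set_size must be in [1, n_actions]")
    if safety_rule in ("include", "exclude") and task.safety_index is None:
        raise ValueError(f"safety_rule={safety_rule!r} requires a safety_index")
    from math import comb

    if comb(task.n_actions, set_size) > MAX_SUBSETS:
        raise ValueError(
            f"enumeration of C({task.n_actions}, {set_size}) subsets exceeds "
            f"the {MAX_SUBSETS} guard; use sampling instead"
        )
    out: dict[tuple[int, ...], Frontier] = {}
    for subset in itertools.combinations(range(task.n_actions), set_size):
        if safety_rule == "include" and task.safety_index not in subset:
            continue
        if safety_rule == "exclude" and task.safety_index in subset:
            continue
        out[subset] = trace_frontier(restrict_task(task, subset), beta_grid)
    return out


def export_subset_frontiers(
    frontiers: dict[tuple[int, ...], Frontier],
    out_dir: str | Path,
    set_size: int,
    safety_index: int | None = None,
) -> Path:
    """Write one CSV per subset plus a JSON index; returns the index path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = []
    for subset, frontier in frontiers.items():
        name = "subset_" + "-".join(str(j) for j in subset) + ".csv"
        frontier.to_csv(out / name)
        index.append(
            {
                "subset": list(subset),
                "file": name,
                "set_size": set_size,
                "safety_included": (
                    safety_index in subset if safety_index is not None else None
                ),
            }
        )
    index_path = out / "index.json"
    index_path.write_text(json.dumps(index, indent=1))
    return index_path


def _branch_frontier(
    task: Task,
    set_size: int,
    include_safety: bool,
    beta_grid,
    exploit_symmetry: bool,
) -> Frontier | None:
    """Best frontier among subsets of one safety branch, or None if empty."""
    safety = task.safety_index
    unsafe = [j for j in range(task.n_actions) if j != safety]
    if include_safety:
        k_unsafe = set_size - 1
        if k_unsafe < 0 or k_unsafe > len(unsafe):
            return None
    else:
        if set_size > len(unsafe):
            return None
    if exploit_symmetry:
        if include_safety:
            subset = tuple(sorted([safety] + unsafe[: set_size - 1]))
        else:
            subset = tuple(unsafe[:set_size])
        return trace_frontier(restrict_task(task, subset), beta_grid)
    rule: SafetyRule = "include" if include_safety else "exclude"
    frontiers = enumerate_subset_frontiers(task, set_size, rule, beta_grid)
    if not frontiers:
        return None
    # pointwise-best branch envelope over a shared complexity grid
    all_pts = list(frontiers.values())
    cmax = max(f.complexities.max() for f in all_pts)
    grid = np.linspace(0.0, cmax, 512)
    best = np.max([frontier_reward_at(f, grid) for f in all_pts], axis=0)
    pts = tuple(
        FrontierPoint(beta=float("nan"), complexity_bits=float(c), reward=float(r))
        for c, r in zip(grid, np.maximum.accumulate(best))
    )
    return Frontier(pts, task_fingerprint=all_pts[0].task_fingerprint)


def na_specific_frontier(
    task: Task,
    set_size: int,
    beta_grid: Sequence[float] | np.ndarray | None = None,
    exploit_symmetry: bool = True,
    grid_points: int = 512,
) -> Frontier:
    """Best achievable frontier for a given consideration-set size.

    Takes the pointwise maximum (over a shared complexity grid) of the best
    safety-including and best safety-excluding subset frontiers of that
    size.  When the task's non-safety actions are exchangeable (as in the
    6-state / 7-action experiment task), one representative subset per
    branch suffices (``exploit_symmetry=True``); set it False to force full
    enumeration for asymmetric tasks.
    """
    if task.safety_index is None:
        raise ValueError("na_specific_frontier requires a task with a safety_index")
    if not 1 <= set_size <= task.n_actions:
        raise ValueError("set_size must be in [1, n_actions]")
    branches = [
        f
        for f in (
            _branch_frontier(task, set_size, True, beta_grid, exploit_symmetry),
            _branch_frontier(task, set_size, False, beta_grid, exploit_symmetry),
        )
        if f is not None
    ]
    cmax = max(f.complexities.max() for f in branches)
    grid = np.linspace(0.0, cmax, grid_points)
    best = np.max([frontier_reward_at(f, grid) for f in branches], axis=0)
    best = np.maximum.accumulate(best)  # guard monotonicity against round-off
    pts = tuple(
        FrontierPoint(beta=float("nan"), complexity_bits=float(c), reward=float(r))
        for c, r in zip(grid, best)
    )
    return Frontier(pts, task_fingerprint=task.fingerprint)


def max_complexity_bound(set_size: int, n_states: int) -> float:
    """Mutual-information ceiling (bits) for a consideration set of a size.

    I(S; A) <= min(log2 Na, log2 |S|): bounded by the entropy of either
    variable under a flat state distribution.
    """
    if set_size < 1 or n_states < 1:
        raise ValueError("arguments must be positive")
    return float(min(np.log2(set_size), np.log2(n_states)))
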