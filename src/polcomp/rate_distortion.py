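"""Policy complexity, Blahut–Arimoto optimization, and reward-complexity frontiers.

A capacity-limited agent maximizes trial-averaged reward

    V_pi = sum_s P(s) sum_a pi(a|s) Q(s, a)

subject to a bound on policy complexity, the mutual information

    I_pi(S; A) = sum_s P(s) sum_a pi(a|s) log[ pi(a|s) / P(a) ],

with marginal P(a) = sum_s P(s) pi(a|s).  The Lagrangian form yields the
stationarity condition

    pi*(a|s)  proportional to  exp[ beta Q(s, a) + log P*(a) ],

an alternating fixed point solved by the Blahut–Arimoto (BA) algorithm:
update the policy from the current marginal, recompute the marginal, and
repeat until convergence.  Varying the multiplier beta >= 0 traces the
reward-complexity frontier: the maximal reward achievable at each policy
complexity.  The frontier is concave, and 1/beta (in nats) is its slope at
the corresponding complexity.

All internal computation uses natural logarithms; complexities are reported
in bits.  ``beta`` multiplies Q inside a natural-log exponent, exactly as in
the stationarity condition above.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import rel_entr

from .tasks import Task, general_values

__all__ = [
    "Policy",
    "FrontierPoint",
    "Frontier",
    "ConvergenceWarning",
    "default_beta_grid",
    "policy_complexity",
    "trial_averaged_reward",
    "blahut_arimoto",
    "zero_complexity_endpoint",
    "zero_complexity_policy",
    "trace_frontier",
    "frontier_reward_at",
    "frontier_upper_bound",
    "reward_loss",
]

LN2 = float(np.log(2.0))
#: probabilities below this are treated as exact zeros inside log terms
PROB_FLOOR = 1e-300


class ConvergenceWarning(UserWarning):
    """Fixed-point iteration stopped at max_iter without reaching tol."""


@dataclasses.dataclass(frozen=True)
class Policy:
    """A conditional distribution over actions for each state."""

    probs: np.ndarray
    converged: bool = dataclasses.field(default=True, compare=False)
    iterations: int = dataclasses.field(default=0, compare=False)

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.probs, dtype=np.float64))
        if np.any(p < 0):
            raise ValueError("policy entries must be non-negative")
        if not np.allclose(p.sum(axis=1), 1.0, rtol=0, atol=1e-10):
            raise ValueError("policy rows must sum to 1 (within 1e-10)")
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)

    @property
    def n_states(self) -> int:
        return self.probs.shape[0]

    @property
    def n_actions(self) -> int:
        return self.probs.shape[1]

    def marginal(self, state_probs: np.ndarray) -> np.ndarray:
        """Marginal action distribution P(a) = sum_s P(s) pi(a|s)."""
        return np.asarray(state_probs, dtype=np.float64) @ self.probs

    def to_csv(self, path: str | Path, action_labels: Sequence[str] | None = None) -> None:
        labels = action_labels or [f"a{j}" for j in range(self.n_actions)]
        np.savetxt(path, self.probs, delimiter=",", fmt="%.17g",
                   header=",".join(labels), comments="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Policy":
        return cls(np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1)))


@dataclasses.dataclass(frozen=True)
class FrontierPoint:
    """One (beta, complexity, reward) knot of a reward-complexity curve."""

    beta: float
    complexity_bits: float
    reward: float

    def __post_init__(self) -> None:
        if self.complexity_bits < 0:
            raise ValueError("complexity_bits must be >= 0")


@dataclasses.dataclass(frozen=True)
class Frontier:
    """A reward-complexity curve traced by optimal policies across beta.

    Points are sorted by beta ascending; complexity is non-decreasing in
    beta and reward non-decreasing in complexity (tolerance 1e-9).  Curves
    assembled pointwise (e.g. branch maxima) may carry ``beta = nan`` and
    are ordered by complexity instead.
    """

    points: tuple[FrontierPoint, ...]
    task_fingerprint: str = ""

    def __post_init__(self) -> None:
        pts = tuple(self.points)
        if not pts:
            raise ValueError("frontier must contain at least one point")
        betas = np.array([p.beta for p in pts])
        if not np.any(np.isnan(betas)):
            if np.any(np.diff(betas) < 0):
                raise ValueError("points must be sorted by beta ascending")
            comp = np.array([p.complexity_bits for p in pts])
            if np.any(np.diff(comp) < -1e-9):
                raise ValueError("complexity must be non-decreasing in beta")
        order = np.argsort([p.complexity_bits for p in pts], kind="stable")
        rew = np.array([pts[i].reward for i in order])
        if np.any(np.diff(rew) < -1e-9):
            raise ValueError("reward must be non-decreasing in complexity")
        object.__setattr__(self, "points", pts)

    @property
    def betas(self) -> np.ndarray:
        return np.array([p.beta for p in self.points])

    @property
    def complexities(self) -> np.ndarray:
        return np.array([p.complexity_bits for p in self.points])

    @property
    def rewards(self) -> np.ndarray:
        return np.array([p.reward for p in self.points])

    def to_csv(self, path: str | Path) -> None:
        arr = np.column_stack([self.betas, self.complexities, self.rewards])
        np.savetxt(path, arr, delimiter=",", fmt="%.17g",
                   header="beta,complexity_bits,reward", comments="")

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "task_fingerprint": self.task_fingerprint,
            "points": [dataclasses.asdict(p) for p in self.points],
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Frontier":
        if isinstance(source, Path):
            text = source.read_text()
        else:
            text = str(source)
            if not text.lstrip().startswith("{"):
                text = Path(text).read_text()
        obj = json.loads(text)
        return cls(
            tuple(FrontierPoint(**p) for p in obj["points"]),
            obj.get("task_fingerprint", ""),
        )


def default_beta_grid(
    beta_min: float = 0.05, beta_max: float = 50.0, num: int = 60
) -> np.ndarray:
    """Geometrically spaced beta grid (the analytic beta=0 endpoint is
    prepended separately by :func:`trace_frontier`)."""
    return np.geomspace(beta_min, beta_max, num)


def policy_complexity(state_probs: np.ndarray, policy: Policy) -> float:
    """Mutual information I(S; A) between states and actions, in bits.

    Terms with pi(a|s) = 0 contribute zero; the result is clipped to
    [0, inf) against round-off.
    """
    p_s = np.asarray(state_probs, dtype=np.float64).reshape(-1)
    if p_s.shape[0] != policy.n_states:
        raise ValueError("state_probs length must equal the policy's n_states")
    marg = p_s @ policy.probs
    # rel_entr handles 0 log 0 = 0 and is +inf only if pi > 0 where marg = 0,
    # which cannot happen when p_s > 0 wherever pi's row has mass.
    kl_rows = rel_entr(policy.probs, np.broadcast_to(marg, policy.probs.shape)).sum(axis=1)
    # rows of zero-probability states cannot contribute, even if their KL is inf
    nats = float(p_s[p_s > 0] @ kl_rows[p_s > 0])
    return max(nats / LN2, 0.0)


def trial_averaged_reward(task: Task, policy: Policy) -> float:
    """Expected reward V_pi = sum_s P(s) sum_a pi(a|s) Q(s, a)."""
    if policy.probs.shape != task.rewards.shape:
        raise ValueError("policy and task dimensions disagree")
    return float(task.state_probs @ (policy.probs * task.rewards).sum(axis=1))


def ba_fixed_point(
    state_probs: np.ndarray,
    base_logits: np.ndarray,
    init: np.ndarray,
    tol: float,
    max_iter: int,
    gap_tol: float | None = None,
) -> tuple[np.ndarray, bool, int]:
    """Shared alternating fixed-point core.

    Iterates ``pi(a|s) ∝ exp[base(s, a) + log P(a)]`` with
    ``P(a) = sum_s P(s) pi(a|s)``.  Two stopping rules:

    * max absolute policy change below *tol* (fixed-point convergence);
    * if *gap_tol* is given, a duality-gap certificate: the iteration
      maximizes the concave potential ``G(P) = sum_s P(s)
      logsumexp_a[base(s, a) + log P(a)]`` over the marginal simplex, and
      concavity bounds the remaining improvement by
      ``max_a dG/dP(a) - 1 = max_a sum_s P(s) exp(base - lse) - 1``.
      Stopping at ``gap < gap_tol`` certifies the achieved potential
      (hence the achieved reward-complexity trade-off) within *gap_tol*
      nats even when near-tied actions keep the policy itself drifting
      for tens of thousands of further iterations.
    """
    pi = init
    p_s = state_probs
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        marg = p_s @ pi
        logits = base_logits + np.log(np.maximum(marg, PROB_FLOOR))
        m = logits.max(axis=1, keepdims=True)
        ex = np.exp(logits - m)
        z = ex.sum(axis=1, keepdims=True)
        pi_new = ex / z
        delta = np.abs(pi_new - pi).max()
        pi = pi_new
        if delta < tol:
            converged = True
            break
        if gap_tol is not None:
            lse = m + np.log(z)
            grad = p_s @ np.exp(base_logits - lse)
            if grad.max() - 1.0 < gap_tol:
                converged = True
                break
    return pi, converged, it


def blahut_arimoto(
    task: Task,
    beta: float,
    tol: float = 1e-10,
    max_iter: int = 10000,
    init: Policy | None = None,
    init_seed: int | None = None,
    gap_tol: float | None = None,
) -> Policy:
    """Optimal capacity-limited policy at Lagrange multiplier *beta*.

    Alternates the stationarity update
    ``pi(a|s) ∝ exp[beta Q(s, a) + log P(a)]`` with the marginal
    ``P(a) = sum_s P(s) pi(a|s)`` until the max absolute policy change
    drops below *tol* (or, optionally, until a duality-gap certificate of
    *gap_tol* nats is reached; see :func:`ba_fixed_point`).
    The optimization is convex, so the converged value does not depend on
    the initialization; the default uniform init makes runs reproducible,
    while ``init_seed`` requests a random Dirichlet init.

    Non-convergence within *max_iter* issues a :class:`ConvergenceWarning`
    and returns the last iterate flagged ``converged=False``.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    n_s, n_a = task.rewards.shape
    if init is not None:
        pi = np.array(init.probs, dtype=np.float64)
        if pi.shape != (n_s, n_a):
            raise ValueError("init policy has wrong shape")
    elif init_seed is not None:
        pi = np.random.default_rng(init_seed).dirichlet(np.ones(n_a), size=n_s)
    else:
        pi = np.full((n_s, n_a), 1.0 / n_a)
    pi, converged, it = ba_fixed_point(
        task.state_probs, beta * task.rewards, pi, tol, max_iter, gap_tol
    )
    if not converged:
        warnings.warn(
            f"Blahut-Arimoto did not converge in {max_iter} iterations "
            f"(beta={beta:g})",
            ConvergenceWarning,
        )
    return Policy(pi, converged=converged, iterations=it)


def zero_complexity_endpoint(task: Task) -> FrontierPoint:
    """Analytic frontier endpoint at zero policy complexity.

    The best state-independent policy is a point mass on the action with
    highest general value (ties broken towards the lowest index); BA at
    exactly beta = 0 is degenerate, so the endpoint is computed directly.
    """
    v = general_values(task)
    return FrontierPoint(beta=0.0, complexity_bits=0.0, reward=float(v.max()))


def zero_complexity_policy(task: Task) -> Policy:
    """The point-mass policy realizing :func:`zero_complexity_endpoint`."""
    v = general_values(task)
    best = int(np.argmax(v))  # argmax takes the lowest index on ties
    probs = np.zeros((task.n_states, task.n_actions))
    probs[:, best] = 1.0
    return Policy(probs)


def trace_frontier(
    task: Task,
    beta_grid: Sequence[float] | np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 20000,
    gap_tol: float | None = 1e-10,
) -> Frontier:
    """Trace the reward-complexity frontier over a beta grid.

    Runs Blahut–Arimoto at each beta (ascending) from a fresh uniform init
    and prepends the analytic zero-complexity endpoint.  The policy-change
    tolerance is tighter than the single-call BA default (at small beta the
    iteration contracts slowly and the residual reward deficit must stay
    below the frontier's 1e-9 monotonicity tolerance); the duality-gap stop
    (``gap_tol``, nats) certifies the achieved trade-off once near-tied
    reward entries make further policy drift irrelevant.  Betas that reach
    *max_iter* under both rules are collected into a single aggregated
    :class:`ConvergenceWarning`; their points are still feasible,
    monotonically improved iterates, and the frontier invariants are
    validated on construction.
    """
    grid = np.asarray(
        default_beta_grid() if beta_grid is None else beta_grid, dtype=np.float64
    )
    if grid.size == 0:
        raise ValueError("beta_grid must be non-empty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("beta_grid must be sorted ascending")
    points = [zero_complexity_endpoint(task)]
    capped: list[float] = []
    for beta in grid:
        if beta <= 0:
            continue  # covered by the analytic endpoint
        # the gap bounds the Lagrangian beta*V - I, so the implied reward
        # error is gap/beta: scale the certificate down at small beta to
        # keep reward accuracy uniform across the grid
        scaled_gap = None if gap_tol is None else gap_tol * min(float(beta), 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            pol = blahut_arimoto(
                task, float(beta), tol=tol, max_iter=max_iter, gap_tol=scaled_gap
            )
        if not pol.converged:
            capped.append(float(beta))
        points.append(
            FrontierPoint(
                beta=float(beta),
                complexity_bits=policy_complexity(task.state_probs, pol),
                reward=trial_averaged_reward(task, pol),
            )
        )
    if capped:
        warnings.warn(
            f"{len(capped)} of {grid.size} beta values stopped at max_iter="
            f"{max_iter} (smallest: {capped[0]:g}); their frontier points are "
            "feasible lower bounds",
            ConvergenceWarning,
        )
    return Frontier(tuple(points), task_fingerprint=task.fingerprint)


def frontier_reward_at(frontier: Frontier, complexity_bits: float | np.ndarray) -> float | np.ndarray:
    """Piecewise-linear interpolation of frontier reward at a complexity.

    Below the first knot returns the endpoint reward; beyond the last knot
    clamps to the last reward.
    """
    if not frontier.points:
        raise ValueError("frontier is empty")
    comp = frontier.complexities
    rew = frontier.rewards
    order = np.argsort(comp, kind="stable")
    comp, rew = comp[order], rew[order]
    # collapse (near-)duplicate complexities, keeping the best reward
    keep_c: list[float] = []
    keep_r: list[float] = []
    for c, r in zip(comp, rew):
        if keep_c and c - keep_c[-1] < 1e-12:
            keep_r[-1] = max(keep_r[-1], r)
        else:
            keep_c.append(float(c))
            keep_r.append(float(r))
    out = np.interp(complexity_bits, keep_c, keep_r)
    return float(out) if np.isscalar(complexity_bits) else out


def frontier_upper_bound(
    frontier: Frontier, complexity_bits: float | np.ndarray
) -> float | np.ndarray:
    """Certified upper envelope of a frontier at a given complexity.

    The frontier is concave with slope 1/beta (nats) at the knot traced at
    beta, so every tangent line lies on or above the whole curve; the
    pointwise minimum over knot tangents therefore upper-bounds the reward
    achievable at any complexity.  Use this (rather than the chord
    interpolation of :func:`frontier_reward_at`, which under-estimates
    between knots) when *verifying* that some other curve is dominated by
    this frontier.
    """
    cs = np.atleast_1d(np.asarray(complexity_bits, dtype=np.float64)) * LN2
    betas = frontier.betas
    mask = betas > 0
    if not np.any(mask):
        # single analytic endpoint: flat bound at its reward
        out = np.full_like(cs, frontier.rewards.max())
    else:
        knot_c = frontier.complexities[mask] * LN2
        knot_v = frontier.rewards[mask]
        slopes = 1.0 / betas[mask]
        # tangent value of every knot at every queried complexity
        vals = knot_v[None, :] + (cs[:, None] - knot_c[None, :]) * slopes[None, :]
        out = vals.min(axis=1)
    return float(out[0]) if np.isscalar(complexity_bits) else out


def reward_loss(task: Task, policy: Policy, full_frontier: Frontier) -> float:
    """Signed reward deviation of a policy from the full-task frontier.

    ``V_pi - frontier(I_pi)``; non-positive (up to interpolation error) for
    any realizable policy, since the frontier delimits achievable reward.
    """
    if full_frontier.task_fingerprint and full_frontier.task_fingerprint != task.fingerprint:
        raise ValueError("frontier was computed for a different task")
    comp = policy_complexity(task.state_probs, policy)
    rew = trial_averaged_reward(task, policy)
    return rew - float(frontier_reward_at(full_frontier, comp))
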