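"""Monte-Carlo simulation suites over proposals, algorithms, and set sizes.

Each simulated agent (one "rep") draws a consideration set from a proposal
distribution, derives a policy — Blahut–Arimoto on the retained actions, or
the SNIS estimator on the raw with-replacement sample — and is then scored
on the *true* task: achieved policy complexity, trial-averaged reward, and
signed loss against the full-action-space reward-complexity frontier.  Reps
sharing a beta are aggregated as mean ± SEM of complexity and loss (and
reward), mirroring 2D error-bar summaries.

Three regime "rows" are crossed with each proposal distribution:

* Row 1 — BA on the consideration set, sampling without replacement
  (sizes are consideration-set sizes, Na);
* Row 2 — SNIS, sampling with replacement (sizes are sample sizes, n);
* Row 3 — BA on the unique sampled actions, sampling with replacement.

SNIS is applicable only with replacement; that constraint is enforced at
condition construction.

Randomness is fully determined by (config, master_seed): each rep's seed is
derived from ``SeedSequence((master_seed, crc32(sampling key), rep))``, so
any condition can be re-run independently and reproducibly.  The sampling
key deliberately omits the proposal and algorithm, so conditions differing
only in those are compared on common random numbers.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
import zlib
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .consideration import (
    ProposalDistribution,
    embed_policy,
    proposal_distribution,
    restrict_task,
    sample_actions,
)
from .rate_distortion import (
    ConvergenceWarning,
    Frontier,
    blahut_arimoto,
    frontier_reward_at,
    policy_complexity,
    trial_averaged_reward,
)
from .snis import snis_policy
from .tasks import Task, perturb_rewards

__all__ = [
    "SimCondition",
    "SimResult",
    "run_condition",
    "run_suite",
    "noisy_q_suite",
    "aggregate_results",
]

logger = logging.getLogger(__name__)

Algorithm = Literal["BA", "SNIS"]
Sampling = Literal["with_replacement", "without_replacement"]


@dataclasses.dataclass(frozen=True)
class SimCondition:
    """One cell of the simulation grid.

    ``size`` is the consideration-set size Na for without-replacement
    sampling and the sample size n for with-replacement sampling.
    """

    task_name: str
    proposal_kind: Literal["flat", "general_value", "oracle"]
    algorithm: Algorithm
    sampling: Sampling
    size: int
    beta: float
    n_reps: int
    master_seed: int

    def __post_init__(self) -> None:
        if self.algorithm == "SNIS" and self.sampling != "with_replacement":
            raise ValueError("SNIS is applicable only to sampling with replacement")
        if self.size < 1 or self.n_reps < 1:
            raise ValueError("size and n_reps must be positive")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    def key(self) -> str:
        """Canonical string identifying the condition (seed excluded)."""
        return (
            f"{self.task_name}|{self.proposal_kind}|{self.algorithm}|"
            f"{self.sampling}|{self.size}|{self.beta!r}"
        )

    def sampling_key(self) -> str:
        """Seed-derivation key: proposal and algorithm are deliberately
        excluded, so conditions differing only in those consume the same
        uniform variates (common random numbers).  Combined with
        inverse-CDF sampling this pairs the Monte-Carlo comparisons the
        suite exists to make — proposal against proposal, BA against SNIS
        on the very same with-replacement sample."""
        return f"{self.task_name}|{self.sampling}|{self.size}|{self.beta!r}"


@dataclasses.dataclass(frozen=True)
class SimResult:
    """Per-rep (complexity, reward, loss) triples plus mean/SEM aggregates."""

    condition: SimCondition
    per_rep: np.ndarray  # (n_ok, 3): complexity_bits, reward, loss
    n_failed: int = 0

    @property
    def aggregates(self) -> dict[str, float]:
        cols = {"complexity_bits": 0, "reward": 1, "loss": 2}
        out: dict[str, float] = {}
        n = self.per_rep.shape[0]
        for name, j in cols.items():
            x = self.per_rep[:, j]
            out[f"mean_{name}"] = float(x.mean())
            out[f"sem_{name}"] = float(
                x.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
            )
        return out


def rep_seed(master_seed: int, condition_key: str, rep: int) -> int:
    """Deterministic per-rep seed below 2**31."""
    cond_hash = zlib.crc32(condition_key.encode())
    ss = np.random.SeedSequence((master_seed, cond_hash, rep))
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def run_condition(
    condition: SimCondition,
    task: Task,
    full_frontier: Frontier,
    oracle_proposal: ProposalDistribution | None = None,
) -> SimResult:
    """Run all reps of one condition and aggregate.

    ``oracle_proposal`` lets callers cache the full-task BA marginal per
    beta across conditions; it is computed on demand otherwise.  A failed
    rep is excluded and counted rather than aborting the condition.
    """
    if full_frontier.task_fingerprint and full_frontier.task_fingerprint != task.fingerprint:
        raise ValueError("frontier was computed for a different task")
    if condition.proposal_kind == "oracle":
        proposal = oracle_proposal or proposal_distribution(
            task, "oracle", condition.beta
        )
    else:
        proposal = proposal_distribution(task, condition.proposal_kind)
    with_repl = condition.sampling == "with_replacement"
    rows: list[tuple[float, float, float]] = []
    n_failed = 0
    n_capped = 0
    for rep in range(condition.n_reps):
        seed = rep_seed(condition.master_seed, condition.sampling_key(), rep)
        try:
            sample = sample_actions(proposal, condition.size, with_repl, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                if condition.algorithm == "BA":
                    subset = sorted(sample.unique_actions)
                    sub = restrict_task(task, subset)
                    pol = embed_policy(
                        blahut_arimoto(sub, condition.beta, gap_tol=1e-10),
                        subset,
                        task.n_actions,
                    )
                else:
                    pol = snis_policy(
                        task, sample, condition.beta, gap_tol=1e-10
                    ).policy
            n_capped += not pol.converged
            comp = policy_complexity(task.state_probs, pol)
            rew = trial_averaged_reward(task, pol)
            loss = rew - float(frontier_reward_at(full_frontier, comp))
            rows.append((comp, rew, loss))
        except Exception:  # noqa: BLE001 — a bad rep must not sink the sweep
            n_failed += 1
            logger.exception("rep %d of condition %s failed", rep, condition.key())
    if n_failed:
        logger.warning(
            "condition %s: %d/%d reps failed and were excluded",
            condition.key(), n_failed, condition.n_reps,
        )
    if n_capped:
        logger.info(
            "condition %s: %d/%d reps stopped at max_iter (near-tied rewards"
            " converge slowly; the iterates remain feasible)",
            condition.key(), n_capped, condition.n_reps,
        )
    return SimResult(condition, np.array(rows, dtype=np.float64), n_failed)


def _result_rows(result: SimResult) -> list[dict]:
    c = result.condition
    return [
        {
            "task": c.task_name,
            "proposal": c.proposal_kind,
            "algorithm": c.algorithm,
            "sampling": c.sampling,
            "size": c.size,
            "beta": c.beta,
            "rep": r,
            "complexity_bits": comp,
            "reward": rew,
            "loss": loss,
        }
        for r, (comp, rew, loss) in enumerate(result.per_rep)
    ]


def run_suite(
    task: Task,
    task_name: str,
    beta_grid: Sequence[float],
    proposals: Sequence[str] = ("flat", "general_value", "oracle"),
    na_grid: Sequence[int] = (2, 4, 8, 16, 32),
    n_grid: Sequence[int] = (2, 4, 8, 16, 32),
    n_reps: int = 200,
    master_seed: int = 0,
    full_frontier: Frontier | None = None,
) -> pd.DataFrame:
    """Cartesian sweep over proposals × rows × sizes × beta grid.

    Returns a long-format table with one row per rep; see
    :func:`aggregate_results` for the mean ± SEM summary.
    """
    from .rate_distortion import trace_frontier

    frontier = full_frontier or trace_frontier(task)
    na_grid = [s for s in na_grid if s <= task.n_actions]
    regimes: list[tuple[Algorithm, Sampling, Sequence[int]]] = [
        ("BA", "without_replacement", na_grid),
        ("SNIS", "with_replacement", n_grid),
        ("BA", "with_replacement", n_grid),
    ]
    oracle_cache: dict[float, ProposalDistribution] = {}
    rows: list[dict] = []
    for beta in beta_grid:
        beta = float(beta)
        for proposal in proposals:
            oracle = None
            if proposal == "oracle":
                if beta not in oracle_cache:
                    oracle_cache[beta] = proposal_distribution(task, "oracle", beta)
                oracle = oracle_cache[beta]
            for algorithm, sampling, sizes in regimes:
                for size in sizes:
                    cond = SimCondition(
                        task_name=task_name,
                        proposal_kind=proposal,  # type: ignore[arg-type]
                        algorithm=algorithm,
                        sampling=sampling,
                        size=int(size),
                        beta=beta,
                        n_reps=n_reps,
                        master_seed=master_seed,
                    )
                    rows.extend(_result_rows(run_condition(cond, task, frontier, oracle)))
    return pd.DataFrame(rows)


def aggregate_results(long_df: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM of complexity, reward, and loss per condition cell."""
    group_cols = [
        c
        for c in ("task", "proposal", "algorithm", "sampling", "size",
                  "noise_sd", "safety", "beta")
        if c in long_df.columns
    ]
    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    agg = long_df.groupby(group_cols, as_index=False).agg(
        n_reps=("rep", "count"),
        mean_complexity_bits=("complexity_bits", "mean"),
        sem_complexity_bits=("complexity_bits", _sem),
        mean_reward=("reward", "mean"),
        sem_reward=("reward", _sem),
        mean_loss=("loss", "mean"),
        sem_loss=("loss", _sem),
    )
    return agg


def noisy_q_suite(
    task: Task,
    noise_sds: Sequence[float],
    set_sizes: Sequence[int],
    beta_grid: Sequence[float],
    n_reps: int = 200,
    master_seed: int = 0,
    full_frontier: Frontier | None = None,
) -> pd.DataFrame:
    """Noisy-reward-representation suite on a safety-action task.

    Each rep perturbs Q with Gaussian noise of a given SD, draws a
    consideration set of the given size uniformly among the non-safety
    actions (with the safety action either retained or excluded —
    both variants are produced), runs BA at beta on the *noisy* restricted
    task, and scores the resulting policy on the *true* task against the
    true full frontier.
    """
    from .rate_distortion import trace_frontier

    if task.safety_index is None:
        raise ValueError("noisy_q_suite requires a task with a safety_index")
    frontier = full_frontier or trace_frontier(task)
    unsafe = [j for j in range(task.n_actions) if j != task.safety_index]
    rows: list[dict] = []
    for noise_sd in noise_sds:
        for set_size in set_sizes:
            for safety in ("include", "exclude"):
                n_from_unsafe = set_size - 1 if safety == "include" else set_size
                if n_from_unsafe < 0 or n_from_unsafe > len(unsafe):
                    continue
                for beta in beta_grid:
                    key = f"noisy|{noise_sd!r}|{set_size}|{safety}|{float(beta)!r}"
                    for rep in range(n_reps):
                        rng = np.random.default_rng(
                            rep_seed(master_seed, key, rep)
                        )
                        subset = list(
                            rng.choice(unsafe, size=n_from_unsafe, replace=False)
                        )
                        if safety == "include":
                            subset.append(task.safety_index)
                        subset = sorted(int(j) for j in subset)
                        noisy = perturb_rewards(
                            task, float(noise_sd),
                            int(rng.integers(0, 2**31)),
                        )
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore", ConvergenceWarning)
                            pol = embed_policy(
                                blahut_arimoto(
                                    restrict_task(noisy, subset), float(beta),
                                    gap_tol=1e-10,
                                ),
                                subset,
                                task.n_actions,
                            )
                        comp = policy_complexity(task.state_probs, pol)
                        rew = trial_averaged_reward(task, pol)
                        loss = rew - float(frontier_reward_at(frontier, comp))
                        rows.append(
                            {
                                "task": "noisy",
                                "noise_sd": float(noise_sd),
                                "safety": safety,
                                "size": int(set_size),
                                "beta": float(beta),
                                "rep": rep,
                                "complexity_bits": comp,
                                "reward": rew,
                                "loss": loss,
                            }
                        )
    return pd.DataFrame(rows)
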