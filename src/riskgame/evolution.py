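"""Between-round dynamics: Fermi pairwise imitation, mutation, and the
multi-round simulation driver.

At the end of each round every individual ``i`` draws one model ``j``
uniformly from the rest of the population and copies ``j``'s strategy with
the Fermi probability

    p_ij = 1 / (1 + exp((r_i - r_j) / beta)),

where ``r_i`` is the individual's end-of-round balance and ``beta`` the
learning temperature: small ``beta`` means near-deterministic copying of
the richer partner.  All comparisons use the frozen end-of-round snapshot
and adoptions apply simultaneously (synchronous update).  After learning,
exactly ``round(alpha * N)`` distinct individuals mutate, each to a uniform
strategy other than its current one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.special import expit

from .model_core import (
    THRESHOLD_TOL,
    Params,
    PopulationState,
    RunResult,
    SubgroupAssignment,
    initialize_population,
    partition_into_subgroups,
    play_round,
    strategy_codes,
    validate_params,
)

__all__ = [
    "LearningConfig",
    "fermi_probability",
    "learning_step",
    "mutation_step",
    "run_simulation",
]


@dataclass(frozen=True)
class LearningConfig:
    """Imitation settings.

    ``partner_scope`` selects where model individuals are drawn from:
    ``"population"`` (default) or ``"subgroup"`` (the round's own subgroup;
    requires the assignment to be passed to :func:`learning_step`).
    """

    beta: float = 0.1
    partner_scope: str = "population"
    update_mode: str = "synchronous"

    def __post_init__(self) -> None:
        if not 0 < self.beta <= 1:
            raise ValueError(f"beta must lie in (0, 1], got {self.beta}")
        if self.partner_scope not in ("population", "subgroup"):
            raise ValueError(f"unknown partner_scope {self.partner_scope!r}")
        if self.update_mode != "synchronous":
            raise ValueError("only synchronous updating is implemented")


def fermi_probability(ri, rj, beta: float):
    """Probability that an individual with resources ``ri`` imitates one
    with resources ``rj``: ``1 / (1 + exp((ri - rj) / beta))``.

    Overflow-safe via the logistic sigmoid; saturates to 0/1 for large
    resource gaps.  Accepts scalars or arrays.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    return expit((np.asarray(rj, dtype=np.float64) - ri) / beta)


def _draw_partners(
    n_ind: int,
    cfg: LearningConfig,
    rng: np.random.Generator,
    assignment: SubgroupAssignment | None,
) -> NDArray[np.int64]:
    if cfg.partner_scope == "population":
        j = rng.integers(0, n_ind - 1, size=n_ind)
        j += j >= np.arange(n_ind)  # skip self
        return j
    if assignment is None:
        raise ValueError("subgroup partner_scope requires the round's assignment")
    members = assignment.membership  # (a, n)
    a, n = members.shape
    k = rng.integers(0, n - 1, size=(a, n))
    k += k >= np.arange(n)
    partners = np.take_along_axis(members, k, axis=1)
    j = np.empty(n_ind, dtype=np.int64)
    j[members.reshape(-1)] = partners.reshape(-1)
    return j


def learning_step(
    state: PopulationState,
    cfg: LearningConfig,
    rng: np.random.Generator,
    assignment: SubgroupAssignment | None = None,
) -> PopulationState:
    """Synchronous imitation: each individual draws one partner and adopts
    its pre-learning strategy with the Fermi probability; resources unchanged.
    """
    n_ind = state.strategies.shape[0]
    if n_ind < 2:
        raise ValueError("learning requires at least two individuals")
    j = _draw_partners(n_ind, cfg, rng, assignment)
    p_adopt = fermi_probability(state.resources, state.resources[j], cfg.beta)
    adopt = rng.random(n_ind) < p_adopt
    new = np.where(adopt, state.strategies[j], state.strategies)
    return PopulationState(
        strategies=new.astype(np.int8),
        resources=state.resources,
        round_index=state.round_index,
    )


def _sample_distinct(
    rng: np.random.Generator, n: int, k: int
) -> NDArray[np.int64]:
    """k distinct uniform indices from range(n) via partial Fisher-Yates
    (k scalar integer draws, the call sequence the compiled kernel mirrors)."""
    pool = np.arange(n)
    for i in range(k):
        j = int(rng.integers(i, n))
        pool[i], pool[j] = pool[j], pool[i]
    return pool[:k]


def mutation_step(
    state: PopulationState, p: Params, rng: np.random.Generator
) -> PopulationState:
    """Mutate exactly ``round(alpha * N)`` distinct individuals (round half
    to even), each to a uniform strategy from the allowed set minus its own.
    """
    n_mut = int(np.rint(p.alpha * p.N))
    if n_mut == 0:
        return state
    codes = strategy_codes(p.strategy_set)
    if codes.size < 2:
        raise ValueError("mutation requires at least two allowed strategies")
    idx = _sample_distinct(rng, p.N, n_mut)
    pos = np.searchsorted(codes, state.strategies[idx])
    alt = rng.integers(0, codes.size - 1, size=n_mut)
    alt += alt >= pos  # skip the current strategy
    new = state.strategies.copy()
    new[idx] = codes[alt]
    return PopulationState(
        strategies=new, resources=state.resources, round_index=state.round_index
    )


def run_simulation(
    p: Params,
    seed: int | None = None,
    *,
    learning: LearningConfig | None = None,
    record_resources: bool = False,
    engine: str = "kernel",
) -> RunResult:
    """Run the full multi-round game and record per-round time series.

    Round order: endow + partition + play, then learning, then mutation.
    Fully reproducible from ``(p, seed)``; ``seed`` falls back to
    ``p.seed`` when omitted.

    ``engine="kernel"`` (default) runs the compiled loop, which consumes
    the identical random stream as ``engine="reference"``, the composition
    of the module-level operations; the two produce bit-identical results.
    A non-default ``learning`` configuration forces the reference engine.
    """
    p = validate_params(p)
    if seed is None:
        seed = p.seed
    if seed is None:
        raise ValueError("a seed is required (argument or Params.seed)")
    rng = np.random.default_rng(seed)
    cfg = learning if learning is not None else LearningConfig(beta=p.beta)

    if engine not in ("kernel", "reference"):
        raise ValueError(f"unknown engine {engine!r}")
    if engine == "kernel" and (
        cfg.partner_scope != "population" or cfg.beta != p.beta
    ):
        engine = "reference"

    if engine == "kernel":
        from ._kernel import simulate

        codes = strategy_codes(p.strategy_set)
        strat0 = codes[rng.integers(0, codes.size, size=p.N)].astype(np.int8)
        n_mut = int(np.rint(p.alpha * p.N))
        if n_mut > 0 and codes.size < 2:
            raise ValueError("mutation requires at least two allowed strategies")
        out = simulate(
            rng,
            strat0,
            codes,
            p.rounds,
            p.a,
            p.n,
            float(p.m),
            float(p.u),
            float(p.w1),
            float(p.w),
            float(p.w2),
            float(p.t1),
            float(p.t2),
            float(p.U),
            float(p.beta),
            n_mut,
            THRESHOLD_TOL,
        )
        counts, succ, succ_collab, contrib, c_loss, c_cost, p_loss, p_cost, res = out
        return RunResult(
            params=p,
            seed=int(seed),
            strategy_counts=counts,
            successful_subgroups=succ,
            collaborators_in_successful=succ_collab,
            total_contribution=contrib,
            central_loss=c_loss,
            central_cost=c_cost,
            peer_loss=p_loss,
            peer_cost=p_cost,
            final_resources=res.copy() if record_resources else None,
        )

    state = initialize_population(p, rng)
    t_rounds = p.rounds
    counts = np.empty((t_rounds, 4), dtype=np.int64)
    succ = np.empty(t_rounds, dtype=np.int64)
    succ_collab = np.empty(t_rounds, dtype=np.int64)
    contrib = np.empty(t_rounds)
    c_loss = np.empty(t_rounds)
    c_cost = np.empty(t_rounds)
    p_loss = np.empty(t_rounds)
    p_cost = np.empty(t_rounds)

    for t in range(t_rounds):
        assignment = partition_into_subgroups(p, rng)
        state, ledger = play_round(state, assignment, p)
        counts[t] = np.bincount(state.strategies, minlength=4)
        succ[t] = int(ledger.success.sum())
        succ_collab[t] = int((p.n - ledger.n_D)[ledger.success].sum())
        contrib[t] = ledger.total_contribution.sum()
        c_loss[t] = ledger.central_loss.sum()
        c_cost[t] = ledger.central_cost.sum()
        p_loss[t] = ledger.peer_loss.sum()
        p_cost[t] = ledger.peer_cost.sum()
        state = learning_step(state, cfg, rng, assignment=assignment)
        state = mutation_step(state, p, rng)
        state.round_index = t + 1

    return RunResult(
        params=p,
        seed=int(seed),
        strategy_counts=counts,
        successful_subgroups=succ,
        collaborators_in_successful=succ_collab,
        total_contribution=contrib,
        central_loss=c_loss,
        central_cost=c_cost,
        peer_loss=p_loss,
        peer_cost=p_cost,
        final_resources=state.resources.copy() if record_resources else None,
    )
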