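"""Domain types and single-round mechanics of the risk-resistant threshold game.

The model: a population of ``N = a * n`` individuals is endowed with ``m``
resource units each round and randomly partitioned into ``a`` subgroups of
size ``n``.  Collaborators (strategies C, CP, PP) contribute ``u`` units
toward resisting an external risk; defectors (D) contribute nothing.  Two
sanctioning mechanisms target defectors:

* **central (pool) punishment** — every CP member pays ``w1`` into an
  institution fund; if the subgroup's pooled fund reaches ``w`` the
  institution forms and docks each defector ``t1`` exactly once;
* **peer punishment** — every PP member punishes every defector in the
  subgroup, paying ``w2`` per act and docking that defector ``t2`` per act
  (many-to-many).

Finally the risk resolves: a subgroup whose total contribution reaches the
threshold ``U`` keeps its balances; otherwise every member's balance is set
to zero.

All round mechanics here are deterministic given strategies and a subgroup
assignment; randomness (initialisation, partitioning, learning, mutation)
lives in :mod:`riskgame.evolution`.  Operations accept either a single
subgroup (1-D arrays of length ``n``) or all subgroups stacked as an
``(a, n)`` matrix, which is how :func:`play_round` uses them.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "Strategy",
    "Params",
    "PopulationState",
    "SubgroupAssignment",
    "RoundLedger",
    "RunResult",
    "ParamError",
    "THRESHOLD_TOL",
    "validate_params",
    "strategy_codes",
    "initialize_population",
    "partition_into_subgroups",
    "apply_contributions",
    "apply_central_punishment",
    "apply_peer_punishment",
    "resolve_risk",
    "play_round",
]

#: tolerance for threshold comparisons on real-valued resources; parameters
#: are small rationals (halves), so this only guards against accumulated
#: floating-point error in sums
THRESHOLD_TOL = 1e-9


class Strategy(IntEnum):
    """The four strategies: three collaborator kinds and the defector.

    C   — collaborator, no punishment
    CP  — collaborator supporting central (pool) punishment
    PP  — collaborator enforcing peer punishment
    D   — defector (free-rider), the punishment target
    """

    C = 0
    CP = 1
    PP = 2
    D = 3


ALL_STRATEGIES: tuple[str, ...] = ("C", "CP", "PP", "D")


class ParamError(ValueError):
    """Raised by :func:`validate_params` naming the offending field."""


@dataclass(frozen=True)
class Params:
    """Model constants and run controls.

    Defaults are the baseline simulation setup: 100 individuals in 10
    subgroups of 10, endowment 10, contribution 5, institution support cost
    2 against an establishment threshold of 4, peer-punishment cost 1,
    selection temperature 0.1 and mutation rate 0.05.
    """

    N: int = 100  #: population size (= a * n)
    a: int = 10  #: number of subgroups
    n: int = 10  #: subgroup size
    m: float = 10.0  #: per-round endowment (units)
    u: float = 5.0  #: contribution cost (units)
    w1: float = 2.0  #: per-CP institution support cost (units)
    w: float = 4.0  #: institution establishment threshold (units)
    w2: float = 1.0  #: per-act peer-punishment cost (units)
    t1: float = 5.0  #: central punishment intensity (units per punished D)
    t2: float = 2.5  #: peer punishment intensity (units per punishing PP)
    U: float = 25.0  #: risk-resistance threshold (units)
    beta: float = 0.1  #: learning temperature of the Fermi rule
    alpha: float = 0.05  #: mutation rate (fraction of N mutated per round)
    strategy_set: tuple[str, ...] = ALL_STRATEGIES
    rounds: int = 3000  #: rounds per run
    stable_window: int = 500  #: trailing rounds for stable-state statistics
    replicates: int = 20  #: default replicate count for sweeps
    seed: int | None = None  #: root seed (optional; may be given per run)


def validate_params(p: Params) -> Params:
    """Check every :class:`Params` invariant; return ``p`` unchanged if valid.

    Raises :class:`ParamError` naming the first violated field.
    """
    if p.N != p.a * p.n:
        raise ParamError(f"N: N={p.N} must equal a*n={p.a * p.n}")
    if p.a < 1 or p.n < 1:
        raise ParamError("a/n: subgroup structure must be positive")
    for name in ("m", "u", "w1", "w", "w2", "t1", "t2", "U"):
        if getattr(p, name) < 0:
            raise ParamError(f"{name}: must be >= 0, got {getattr(p, name)}")
    if p.u > p.m:
        raise ParamError(f"u: contribution u={p.u} exceeds endowment m={p.m}")
    if not 0 < p.beta <= 1:
        raise ParamError(f"beta: must lie in (0, 1], got {p.beta}")
    if not 0 <= p.alpha <= 1:
        raise ParamError(f"alpha: must lie in [0, 1], got {p.alpha}")
    if p.w2 > p.t2:
        raise ParamError(f"w2: peer cost w2={p.w2} exceeds intensity t2={p.t2}")
    if p.rounds < 1:
        raise ParamError(f"rounds: must be >= 1, got {p.rounds}")
    if not 0 < p.stable_window <= p.rounds:
        raise ParamError(
            f"stable_window: must lie in [1, rounds], got {p.stable_window}"
        )
    bad = set(p.strategy_set) - set(ALL_STRATEGIES)
    if bad:
        raise ParamError(f"strategy_set: unknown labels {sorted(bad)}")
    if len(set(p.strategy_set)) < 2:
        raise ParamError("strategy_set: at least two distinct strategies required")
    return p


def strategy_codes(strategy_set: tuple[str, ...]) -> NDArray[np.int8]:
    """Canonical (ascending-code) int8 codes for a strategy-label set."""
    return np.array(sorted(Strategy[s] for s in set(strategy_set)), dtype=np.int8)


@dataclass
class PopulationState:
    """Per-individual strategy and resource balance at one point in time."""

    strategies: NDArray[np.int8]  # (N,) codes from Strategy
    resources: NDArray[np.float64]  # (N,) resource balances (units)
    round_index: int = 0


@dataclass(frozen=True)
class SubgroupAssignment:
    """Partition of individuals into ``a`` subgroups of size ``n``.

    ``membership[g]`` holds the individual indices of subgroup ``g``.
    """

    membership: NDArray[np.int64]  # (a, n)


@dataclass
class RoundLedger:
    """Per-subgroup accounting for one round (all arrays have length ``a``)."""

    n_C: NDArray[np.int64]
    n_CP: NDArray[np.int64]
    n_PP: NDArray[np.int64]
    n_D: NDArray[np.int64]
    total_contribution: NDArray[np.float64]
    institution_established: NDArray[np.bool_]
    central_loss: NDArray[np.float64]  # units lost by Ds to central punishment
    central_cost: NDArray[np.float64]  # units paid by CPs (sunk)
    peer_loss: NDArray[np.float64]  # units lost by Ds to peer punishment
    peer_cost: NDArray[np.float64]  # units paid by PPs
    success: NDArray[np.bool_]


@dataclass
class RunResult:
    """Per-round time series for one seeded run (all arrays length ``rounds``)."""

    params: Params
    seed: int
    strategy_counts: NDArray[np.int64]  # (T, 4) counts in C, CP, PP, D order
    successful_subgroups: NDArray[np.int64]  # (T,)
    collaborators_in_successful: NDArray[np.int64]  # (T,)
    total_contribution: NDArray[np.float64]  # (T,) summed over subgroups
    central_loss: NDArray[np.float64]  # (T,) summed over subgroups
    central_cost: NDArray[np.float64]
    peer_loss: NDArray[np.float64]
    peer_cost: NDArray[np.float64]
    final_resources: NDArray[np.float64] | None = None  # (N,) last-round snapshot


def initialize_population(p: Params, rng: np.random.Generator) -> PopulationState:
    """Assign each of the ``N`` individuals a uniform strategy; zero balances."""
    codes = strategy_codes(p.strategy_set)
    if codes.size == 0:
        raise ParamError("strategy_set: empty")
    strategies = codes[rng.integers(0, codes.size, size=p.N)]
    return PopulationState(
        strategies=strategies.astype(np.int8),
        resources=np.zeros(p.N),
        round_index=0,
    )


def partition_into_subgroups(
    p: Params, rng: np.random.Generator
) -> SubgroupAssignment:
    """Uniformly random partition: a permutation chopped into ``a`` blocks of ``n``."""
    perm = rng.permutation(p.N)
    return SubgroupAssignment(membership=perm.reshape(p.a, p.n))


def apply_contributions(
    strategies: NDArray[np.int8], p: Params
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Endow every member ``m`` and collect ``u`` from each collaborator.

    Returns the post-contribution balances and each subgroup's total
    contribution.  ``strategies`` may be ``(n,)`` or ``(a, n)``.
    """
    defects = strategies == Strategy.D
    balances = np.where(defects, p.m, p.m - p.u)
    total = p.u * (strategies.shape[-1] - defects.sum(axis=-1))
    return balances, np.asarray(total, dtype=np.float64)


def apply_central_punishment(
    balances: NDArray[np.float64], strategies: NDArray[np.int8], p: Params
) -> tuple[NDArray[np.float64], NDArray[np.bool_], NDArray[np.float64], NDArray[np.float64]]:
    """Pool-punishment stage: CPs pay ``w1`` (sunk); if the subgroup fund
    ``w1 * n_CP`` reaches ``w`` the institution docks each D ``t1`` once.

    Returns (balances, institution_established, central_loss, central_cost).
    """
    is_cp = strategies == Strategy.CP
    is_d = strategies == Strategy.D
    n_cp = is_cp.sum(axis=-1)
    n_d = is_d.sum(axis=-1)
    inst = np.asarray(p.w1 * n_cp >= p.w - THRESHOLD_TOL)
    fine = (p.t1 * inst)[..., None]  # broadcast over members
    balances = balances - p.w1 * is_cp - fine * is_d
    central_loss = np.asarray(p.t1 * n_d * inst, dtype=np.float64)
    central_cost = np.asarray(p.w1 * n_cp, dtype=np.float64)
    return balances, inst, central_loss, central_cost


def apply_peer_punishment(
    balances: NDArray[np.float64], strategies: NDArray[np.int8], p: Params
) -> tuple[NDArray[np.float64], NDArray[np.float64], NDArray[np.float64]]:
    """Peer-punishment stage: every PP punishes every D in the subgroup.

    Each PP pays ``w2`` per defector; each D loses ``t2`` per punisher.
    Returns (balances, peer_loss, peer_cost).
    """
    is_pp = strategies == Strategy.PP
    is_d = strategies == Strategy.D
    n_pp = is_pp.sum(axis=-1)
    n_d = is_d.sum(axis=-1)
    balances = balances - (p.w2 * n_d)[..., None] * is_pp - (p.t2 * n_pp)[..., None] * is_d
    peer_loss = np.asarray(p.t2 * n_pp * n_d, dtype=np.float64)
    peer_cost = np.asarray(p.w2 * n_pp * n_d, dtype=np.float64)
    return balances, peer_loss, peer_cost


def resolve_risk(
    balances: NDArray[np.float64],
    total_contribution: NDArray[np.float64],
    p: Params,
) -> tuple[NDArray[np.bool_], NDArray[np.float64]]:
    """Threshold resolution: a subgroup succeeds iff its total contribution
    reaches ``U`` (inclusive); every member of a failed subgroup ends at
    exactly 0 — including members whose balance had gone negative.
    """
    success = np.asarray(total_contribution >= p.U - THRESHOLD_TOL)
    balances = np.where(success[..., None], balances, 0.0)
    return success, balances


def play_round(
    state: PopulationState, assignment: SubgroupAssignment, p: Params
) -> tuple[PopulationState, RoundLedger]:
    """One complete round for the whole population.

    Per subgroup: contributions, then central punishment, then peer
    punishment, then risk resolution.  Strategies are untouched; the
    returned state carries the end-of-round balances.
    """
    groups = assignment.membership
    strat = state.strategies[groups]  # (a, n)

    balances, total = apply_contributions(strat, p)
    balances, inst, c_loss, c_cost = apply_central_punishment(balances, strat, p)
    balances, p_loss, p_cost = apply_peer_punishment(balances, strat, p)
    success, balances = resolve_risk(balances, total, p)

    resources = np.empty(p.N)
    resources[groups.reshape(-1)] = balances.reshape(-1)

    n_c = (strat == Strategy.C).sum(axis=-1)
    n_cp = (strat == Strategy.CP).sum(axis=-1)
    n_pp = (strat == Strategy.PP).sum(axis=-1)
    n_d = strat.shape[-1] - n_c - n_cp - n_pp
    ledger = RoundLedger(
        n_C=n_c,
        n_CP=n_cp,
        n_PP=n_pp,
        n_D=n_d,
        total_contribution=total,
        institution_established=inst,
        central_loss=c_loss,
        central_cost=c_cost,
        peer_loss=p_loss,
        peer_cost=p_cost,
        success=success,
    )
    new_state = PopulationState(
        strategies=state.strategies,
        resources=resources,
        round_index=state.round_index,
    )
    return new_state, ledger
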