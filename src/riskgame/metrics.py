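"""Summary statistics over a run: collaboration rate, punishment
enhancement, cost–benefit ratios and resource wastage.

All statistics are window averages over a range of rounds.  The window
argument accepted throughout is one of

* ``"stable"`` — the trailing ``stable_window`` rounds (the evolutionary
  quasi-stationary regime; the default),
* ``"all"`` — every round from the first ("the process"),
* a ``(start, stop)`` tuple or a ``slice`` of round indices.

Cost–benefit ratios pool numerators and denominators across the window
before dividing (a ratio of means), which stays well-defined in rounds
where no defector or no punisher happens to be present; a ratio whose
punisher type or defector count is absent from the whole window is
reported as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import Params, RunResult, Strategy

__all__ = [
    "SummaryStats",
    "collaboration_rate",
    "enhancement",
    "cost_benefit_ratios",
    "cbr_difference",
    "resource_wastage",
    "waste_zone",
    "summarize",
]

#: zone cutpoints for resource wastage k (units of contribution above U)
WASTE_ZONES = (("insufficient", -math.inf), ("none", 0.0), ("slight", 3.0), ("waste", 6.0))


def _window_slice(result: RunResult, window) -> slice:
    t_rounds = result.params.rounds
    if window is None or window == "stable":
        sl = slice(t_rounds - result.params.stable_window, t_rounds)
    elif window == "all":
        sl = slice(0, t_rounds)
    elif isinstance(window, tuple):
        sl = slice(*window)
    elif isinstance(window, slice):
        sl = window
    else:
        raise TypeError(f"unsupported window {window!r}")
    start, stop, step = sl.indices(t_rounds)
    if step != 1 or stop <= start:
        raise ValueError(f"empty or non-contiguous window {window!r}")
    return slice(start, stop)


def collaboration_rate(
    result: RunResult, window="stable", mode: str = "all_members"
) -> float:
    """Fraction of individuals in subgroups that met the risk threshold,
    averaged over the window.

    ``mode="all_members"`` (default) counts every member of a successful
    subgroup, collaborator or defector; ``mode="collaborators_only"``
    counts only the contributing members.
    """
    sl = _window_slice(result, window)
    p = result.params
    if mode == "all_members":
        return float(result.successful_subgroups[sl].mean() / p.a)
    if mode == "collaborators_only":
        return float(result.collaborators_in_successful[sl].mean() / p.N)
    raise ValueError(f"unknown mode {mode!r}")


def enhancement(rate_full: float, rate_reduced: float) -> float:
    """Signed collaboration-rate gain of one punishment type: the rate of
    the full four-strategy run minus a matched run with that punishment's
    strategy removed.  Negative values mean suppression.
    """
    return rate_full - rate_reduced


def cost_benefit_ratios(
    result: RunResult, p: Params | None = None, window="stable"
) -> tuple[float, float]:
    """(central, peer) cost–benefit ratios pooled over the window.

    Each ratio is (resources docked per defector) / (cost paid per punisher
    of that type).  NaN when its punisher type, the defectors, or the cost
    pool are absent from the window.
    """
    sl = _window_slice(result, window)
    n_d = int(result.strategy_counts[sl, Strategy.D].sum())
    n_cp = int(result.strategy_counts[sl, Strategy.CP].sum())
    n_pp = int(result.strategy_counts[sl, Strategy.PP].sum())
    c_loss = float(result.central_loss[sl].sum())
    c_cost = float(result.central_cost[sl].sum())
    p_loss = float(result.peer_loss[sl].sum())
    p_cost = float(result.peer_cost[sl].sum())

    if n_d > 0 and n_cp > 0 and c_cost > 0:
        cbr_central = (c_loss / n_d) / (c_cost / n_cp)
    else:
        cbr_central = math.nan
    if n_d > 0 and n_pp > 0 and p_cost > 0:
        cbr_peer = (p_loss / n_d) / (p_cost / n_pp)
    else:
        cbr_peer = math.nan
    return cbr_central, cbr_peer


def cbr_difference(
    result: RunResult, p: Params | None = None, window="stable"
) -> float:
    """Peer minus central cost–benefit ratio from the same run; NaN when
    either ratio is undefined on the window."""
    cbr_central, cbr_peer = cost_benefit_ratios(result, p, window)
    return cbr_peer - cbr_central


def resource_wastage(
    result: RunResult, p: Params | None = None, window="stable"
) -> float:
    """Mean subgroup contribution over the window minus the threshold U."""
    sl = _window_slice(result, window)
    pars = result.params
    return float((result.total_contribution[sl] / pars.a).mean() - pars.U)


def waste_zone(k: float) -> str:
    """Classify wastage k: ``insufficient`` (k<0), ``none`` (0<=k<3),
    ``slight`` (3<=k<6), ``waste`` (k>=6)."""
    if not math.isfinite(k):
        raise ValueError(f"wastage must be finite, got {k}")
    label = WASTE_ZONES[0][0]
    for name, lower in WASTE_ZONES:
        if k >= lower:
            label = name
    return label


@dataclass(frozen=True)
class SummaryStats:
    """One run's summary on one window; serialises to a flat record."""

    collaboration_rate: float
    strategy_shares: tuple[float, float, float, float]  # C, CP, PP, D
    cbr_central: float
    cbr_peer: float
    cbr_difference: float
    wastage_k: float
    wastage_zone: str

    def to_record(self) -> dict:
        rec = {
            "collaboration_rate": self.collaboration_rate,
            "share_C": self.strategy_shares[0],
            "share_CP": self.strategy_shares[1],
            "share_PP": self.strategy_shares[2],
            "share_D": self.strategy_shares[3],
            "cbr_central": self.cbr_central,
            "cbr_peer": self.cbr_peer,
            "cbr_difference": self.cbr_difference,
            "wastage_k": self.wastage_k,
            "wastage_zone": self.wastage_zone,
        }
        return rec


def summarize(
    result: RunResult, window="stable", collaboration_mode: str = "all_members"
) -> SummaryStats:
    """All summary statistics of one run on one window."""
    sl = _window_slice(result, window)
    p = result.params
    shares = result.strategy_counts[sl].mean(axis=0) / p.N
    cbr_c, cbr_p = cost_benefit_ratios(result, p, window)
    k = resource_wastage(result, p, window)
    return SummaryStats(
        collaboration_rate=collaboration_rate(result, window, collaboration_mode),
        strategy_shares=tuple(float(s) for s in shares),
        cbr_central=cbr_c,
        cbr_peer=cbr_p,
        cbr_difference=cbr_p - cbr_c,
        wastage_k=k,
        wastage_zone=waste_zone(k),
    )
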