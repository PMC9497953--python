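"""Sweep orchestration: parameter grids, matched-seed enhancement
experiments, tabular output and deterministic test fixtures.

Seeding discipline
------------------
``run_sweep`` derives one seed per table row from a stable SHA-256 hash of
(base_seed, t1, t2, U, strategy set, replicate), so rows are unique and the
whole table is reproducible byte-for-byte.  The intensity-sweep and
enhancement experiments instead share one seed per (U, replicate) across
every intensity cell and strategy subset: the full-minus-reduced
subtraction is then a paired comparison, and a reduced run is literally
identical along the axis of the punishment it excludes (an absent strategy
makes that intensity inert).
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evolution import run_simulation
from .metrics import collaboration_rate, cost_benefit_ratios, summarize
from .model_core import (
    Params,
    PopulationState,
    Strategy,
    SubgroupAssignment,
    validate_params,
)

__all__ = [
    "SweepSpec",
    "derive_seed",
    "run_sweep",
    "fig2_experiment",
    "fig3_experiment",
    "write_results",
    "make_fixture",
]

logger = logging.getLogger(__name__)

FULL_SET: tuple[str, ...] = ("C", "CP", "PP", "D")

T1_DEFAULT = tuple(np.arange(2.0, 9.51, 0.5))  # 16 values
T2_DEFAULT = tuple(np.arange(1.0, 6.51, 0.5))  # 12 values
U_DEFAULT = (15.0, 25.0, 35.0)


@dataclass(frozen=True)
class SweepSpec:
    """Grid definition for :func:`run_sweep`."""

    t1_values: tuple[float, ...] = T1_DEFAULT
    t2_values: tuple[float, ...] = T2_DEFAULT
    U_values: tuple[float, ...] = U_DEFAULT
    strategy_sets: tuple[tuple[str, ...], ...] = (FULL_SET,)
    replicates: int = 20
    base_seed: int = 0
    rounds: int | None = None
    stable_window: int | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.t1_values + self.t2_values):
            raise ValueError("punishment intensities must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def derive_seed(base_seed: int, *key) -> int:
    """Stable 31-bit seed from a base seed and an arbitrary hashable key.

    Uses SHA-256 of the repr, so it is reproducible across processes and
    platforms (unlike the built-in ``hash``).
    """
    digest = hashlib.sha256(repr((int(base_seed),) + key).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _seed_key(t1: float, t2: float, U: float, sset: tuple[str, ...], rep: int):
    return (float(t1), float(t2), float(U), tuple(sorted(sset)), int(rep))


def _apply_overrides(p: Params, spec: SweepSpec) -> Params:
    if spec.rounds is not None:
        p = replace(p, rounds=spec.rounds)
    if spec.stable_window is not None:
        p = replace(p, stable_window=spec.stable_window)
    return p


def _run_row(p: Params, seed: int) -> dict:
    result = run_simulation(p, seed)
    stats = summarize(result, "stable")
    cbr_c_proc, cbr_p_proc = cost_benefit_ratios(result, p, "all")
    row = {
        "t1": p.t1,
        "t2": p.t2,
        "U": p.U,
        "strategy_set": ",".join(s for s in FULL_SET if s in p.strategy_set),
        "seed": seed,
        **stats.to_record(),
        "cbr_central_process": cbr_c_proc,
        "cbr_peer_process": cbr_p_proc,
    }
    return row


def run_sweep(spec: SweepSpec, p: Params | None = None) -> pd.DataFrame:
    """Run every (t1, t2, U, strategy set, replicate) combination and
    summarise each run on its stable window; one tidy row per run."""
    if p is None:
        p = Params()
    p = _apply_overrides(validate_params(p), spec)
    rows = []
    grid = itertools.product(
        spec.t1_values, spec.t2_values, spec.U_values, spec.strategy_sets
    )
    for t1, t2, u_risk, sset in grid:
        for rep in range(spec.replicates):
            seed = derive_seed(spec.base_seed, *_seed_key(t1, t2, u_risk, sset, rep))
            pars = replace(p, t1=float(t1), t2=float(t2), U=float(u_risk), strategy_set=tuple(sset))
            try:
                row = _run_row(pars, seed)
            except Exception as err:  # re-raise with the failing cell attached
                raise RuntimeError(
                    f"sweep cell failed: t1={t1} t2={t2} U={u_risk} "
                    f"set={sset} replicate={rep}"
                ) from err
            row["replicate"] = rep
            rows.append(row)
            logger.info(
                "run t1=%s t2=%s U=%s set=%s rep=%d seed=%d rate=%.3f",
                t1, t2, u_risk, ",".join(sset), rep, seed, row["collaboration_rate"],
            )
    return pd.DataFrame(rows)


def fig2_experiment(
    p: Params,
    U: float,
    axis: str,
    replicates: int = 20,
    base_seed: int = 0,
    rounds: int | None = None,
    stable_window: int | None = None,
) -> pd.DataFrame:
    """Collaboration rate along one punishment-intensity axis plus the
    {C,D} baseline, with seeds shared per replicate.

    ``axis="t1"`` sweeps t1 over [2, 9.5] at t2 = 2.5; ``axis="t2"`` sweeps
    t2 over [1, 6.5] at t1 = 5 (the fixed values keep t1 = 2 * t2, i.e.
    t1 : t2 = w1 : w2, so the two punishments are cost-comparable).
    Baseline rows carry an empty t1/t2 and strategy_set "C,D".
    """
    if axis not in ("t1", "t2"):
        raise ValueError(f"axis must be 't1' or 't2', got {axis!r}")
    p = validate_params(p)
    if rounds is not None:
        p = replace(p, rounds=rounds)
    if stable_window is not None:
        p = replace(p, stable_window=stable_window)
    values = T1_DEFAULT if axis == "t1" else T2_DEFAULT
    rows = []
    for rep in range(replicates):
        seed = derive_seed(base_seed, "fig2", float(U), rep)
        for v in values:
            pars = replace(
                p,
                U=float(U),
                t1=float(v) if axis == "t1" else 5.0,
                t2=float(v) if axis == "t2" else 2.5,
                strategy_set=FULL_SET,
            )
            row = _run_row(pars, seed)
            row["replicate"] = rep
            rows.append(row)
        base = replace(p, U=float(U), strategy_set=("C", "D"))
        result = run_simulation(base, seed)
        rows.append(
            {
                "t1": np.nan,
                "t2": np.nan,
                "U": float(U),
                "strategy_set": "C,D",
                "seed": seed,
                "replicate": rep,
                **summarize(result, "stable").to_record(),
                "cbr_central_process": np.nan,
                "cbr_peer_process": np.nan,
            }
        )
    return pd.DataFrame(rows)


def fig3_experiment(
    p: Params | None = None,
    t1_values: tuple[float, ...] = T1_DEFAULT,
    t2_values: tuple[float, ...] = T2_DEFAULT,
    U_values: tuple[float, ...] = U_DEFAULT,
    replicates: int = 20,
    base_seed: int = 0,
    rounds: int | None = None,
    stable_window: int | None = None,
) -> pd.DataFrame:
    """Enhancement surfaces for both punishment types on a (t1, t2, U) grid.

    For every cell and replicate three runs share one seed: the full
    four-strategy set, {C,D,PP} (central punishment removed) and {C,D,CP}
    (peer punishment removed).  Central enhancement = full − {C,D,PP};
    peer enhancement = full − {C,D,CP}.  Because the removed strategy makes
    its intensity inert, each reduced run is computed once per relevant
    intensity and reused along the other axis.
    """
    if p is None:
        p = Params()
    p = validate_params(p)
    if rounds is not None:
        p = replace(p, rounds=rounds)
    if stable_window is not None:
        p = replace(p, stable_window=stable_window)

    rows = []
    for u_risk in U_values:
        for rep in range(replicates):
            seed = derive_seed(base_seed, "fig3", float(u_risk), rep)
            # reduced runs: rate is independent of the excluded intensity
            no_cp = {}
            for t2 in t2_values:
                pars = replace(
                    p, U=float(u_risk), t1=p.t1, t2=float(t2),
                    strategy_set=("C", "PP", "D"),
                )
                no_cp[float(t2)] = collaboration_rate(run_simulation(pars, seed))
            no_pp = {}
            for t1 in t1_values:
                pars = replace(
                    p, U=float(u_risk), t1=float(t1), t2=p.t2,
                    strategy_set=("C", "CP", "D"),
                )
                no_pp[float(t1)] = collaboration_rate(run_simulation(pars, seed))
            for t1 in t1_values:
                for t2 in t2_values:
                    pars = replace(
                        p, U=float(u_risk), t1=float(t1), t2=float(t2),
                        strategy_set=FULL_SET,
                    )
                    rate_full = collaboration_rate(run_simulation(pars, seed))
                    rows.append(
                        {
                            "t1": float(t1),
                            "t2": float(t2),
                            "U": float(u_risk),
                            "replicate": rep,
                            "seed": seed,
                            "rate_full": rate_full,
                            "rate_without_central": no_cp[float(t2)],
                            "rate_without_peer": no_pp[float(t1)],
                            "enh_central": rate_full - no_cp[float(t2)],
                            "enh_peer": rate_full - no_pp[float(t1)],
                        }
                    )
            logger.info("fig3 U=%s replicate %d done", u_risk, rep)
    return pd.DataFrame(rows)


def write_results(
    table: pd.DataFrame,
    path: str | Path,
    fmt: str = "csv",
    metadata: dict | None = None,
) -> Path:
    """Write a sweep table as CSV (default) or JSON-lines plus a JSON
    metadata sidecar ``<stem>.meta.json`` next to it."""
    if table.empty:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        table.to_csv(path, index=False)
    elif fmt in ("jsonl", "json-lines"):
        table.to_json(path, orient="records", lines=True)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    sidecar = path.with_name(path.stem + ".meta.json")
    meta = {"artifact_version": __version__, "rows": int(len(table))}
    if metadata:
        meta.update(_jsonable(metadata))
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def make_fixture(
    composition: list[dict[str, int]] | list[tuple[int, int, int, int]],
    p: Params,
) -> tuple[PopulationState, SubgroupAssignment]:
    """Deterministic population with an exact per-subgroup composition.

    ``composition`` gives, per subgroup, either a ``{"C": 3, ...}`` mapping
    or a ``(n_C, n_CP, n_PP, n_D)`` tuple; members are laid out in
    consecutive index blocks, strategies in C, CP, PP, D order within each
    block.  Resources start at zero.
    """
    p = validate_params(p)
    if len(composition) != p.a:
        raise ValueError(f"expected {p.a} subgroup compositions, got {len(composition)}")
    strategies = np.empty(p.N, dtype=np.int8)
    pos = 0
    for g, comp in enumerate(composition):
        if isinstance(comp, dict):
            counts = [comp.get(s.name, 0) for s in Strategy]
        else:
            counts = list(comp)
        if sum(counts) != p.n:
            raise ValueError(f"subgroup {g}: counts sum to {sum(counts)}, expected {p.n}")
        for strat, count in zip(Strategy, counts):
            strategies[pos : pos + count] = strat
            pos += count
    membership = np.arange(p.N, dtype=np.int64).reshape(p.a, p.n)
    state = PopulationState(
        strategies=strategies, resources=np.zeros(p.N), round_index=0
    )
    return state, SubgroupAssignment(membership=membership)
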