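"""Incremental cost-effectiveness tables, dominance, ranks, price scenarios.

For each (strategy, comparator) pair the table reports incremental cost,
incremental QALY, and their ratio (ICER).  A pair where one arm is both
cheaper and more effective is flagged ``Dominated`` instead of an ICER (the
costlier, less effective arm is the dominated one).  Strategies are ranked
either by net monetary benefit NMB = wtp * QALY - cost at the configured
willingness-to-pay threshold (default) or by ascending mean cost.

The default comparison layout orders strategies by effectiveness and
compares each against every less effective strategy, which is the layout
cost-effectiveness evaluations conventionally print.  An efficiency-frontier
mode (sequential ICERs over non-dominated strategies, with extended
dominance) is available as a separate, clearly labelled output.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig
from .econ import EconomicOutcome, reprice, run_all

DOMINATED = "Dominated"
UNDEFINED = "Undefined"


@dataclass(frozen=True)
class IcerTable:
    """Pairwise incremental table; ``frame`` holds one row per comparison."""

    frame: pd.DataFrame
    wtp: float

    def to_frame(self) -> pd.DataFrame:
        return self.frame

    def row(self, strategy: str, comparator: str | None = None) -> pd.Series:
        f = self.frame
        mask = f["strategy"] == strategy
        if comparator is not None:
            mask &= f["comparator"] == comparator
        hit = f[mask]
        if hit.empty:
            raise KeyError(f"no row for {strategy!r} vs {comparator!r}")
        return hit.iloc[0]

    def rank_of(self, strategy: str) -> int:
        return int(self.row(strategy)["rank"])


def rank_strategies(
    outcomes: list[EconomicOutcome], wtp: float, rank_by: str = "nmb"
) -> dict[str, int]:
    """Rank 1..n: descending net monetary benefit, or ascending mean cost."""
    if rank_by == "nmb":
        score = {o.strategy: -(wtp * o.mean_qaly - o.mean_cost) for o in outcomes}
    elif rank_by == "cost":
        score = {o.strategy: o.mean_cost for o in outcomes}
    else:
        raise ValueError(f"rank_by must be 'nmb' or 'cost', got {rank_by!r}")
    ordered = sorted(score, key=lambda s: (score[s], s))
    return {name: i + 1 for i, name in enumerate(ordered)}


def build_icer_table(
    outcomes: list[EconomicOutcome],
    comparisons: list[tuple[str, str]] | None = None,
    wtp: float = 32517.0,
    rank_by: str = "nmb",
) -> IcerTable:
    """Assemble the incremental cost-effectiveness table.

    ``comparisons`` lists (strategy, comparator) pairs; when omitted,
    strategies are ordered by mean QALY and each is compared against every
    less effective strategy.  The ``icer`` column is numeric where defined
    and NaN otherwise; ``icer_label`` renders the printed cell (the ratio,
    ``Dominated``, or ``Undefined`` when QALYs are tied but costs differ).
    """
    if len(outcomes) < 2:
        raise ValueError("need at least two strategies to compare")
    by_name = {o.strategy: o for o in outcomes}
    if len(by_name) != len(outcomes):
        raise ValueError("duplicate strategy names in outcomes")
    order = sorted(outcomes, key=lambda o: o.mean_qaly)
    if comparisons is None:
        comparisons = [
            (order[i].strategy, order[j].strategy)
            for i in range(len(order))
            for j in range(i)
        ]
    for a, b in comparisons:
        if a not in by_name or b not in by_name:
            raise ValueError(f"comparison ({a!r}, {b!r}) references an unknown strategy")

    ranks = rank_strategies(outcomes, wtp, rank_by)
    listed = {a for a, _ in comparisons}
    rows = []
    for o in order:
        pairs = [(a, b) for a, b in comparisons if a == o.strategy]
        if o.strategy not in listed:
            rows.append(
                {
                    "strategy": o.strategy,
                    "mean_cost": o.mean_cost,
                    "mean_qaly": o.mean_qaly,
                    "comparator": "",
                    "inc_cost": np.nan,
                    "inc_qaly": np.nan,
                    "icer": np.nan,
                    "icer_label": "",
                    "rank": ranks[o.strategy],
                }
            )
        for a, b in pairs:
            comp = by_name[b]
            inc_cost = o.mean_cost - comp.mean_cost
            inc_qaly = o.mean_qaly - comp.mean_qaly
            icer, label = _icer_cell(inc_cost, inc_qaly)
            rows.append(
                {
                    "strategy": o.strategy,
                    "mean_cost": o.mean_cost,
                    "mean_qaly": o.mean_qaly,
                    "comparator": b,
                    "inc_cost": inc_cost,
                    "inc_qaly": inc_qaly,
                    "icer": icer,
                    "icer_label": label,
                    "rank": ranks[o.strategy],
                }
            )
    return IcerTable(frame=pd.DataFrame(rows), wtp=wtp)


def _icer_cell(inc_cost: float, inc_qaly: float) -> tuple[float, str]:
    """Numeric ICER (NaN when dominance/undefined) and its printed label."""
    if inc_qaly == 0 and inc_cost == 0:
        return np.nan, UNDEFINED
    if inc_qaly == 0:
        return np.nan, UNDEFINED
    if (inc_cost >= 0 and inc_qaly < 0) or (inc_cost > 0 and inc_qaly <= 0):
        return np.nan, DOMINATED  # strategy dominated by its comparator
    if inc_cost < 0 and inc_qaly > 0:
        return np.nan, DOMINATED  # comparator dominated by the strategy
    icer = inc_cost / inc_qaly
    return float(icer), f"{icer:.1f}"


def dominates(a: EconomicOutcome, b: EconomicOutcome) -> bool:
    """True when a is at least as cheap and as effective as b, better on one."""
    return (
        a.mean_cost <= b.mean_cost
        and a.mean_qaly >= b.mean_qaly
        and (a.mean_cost < b.mean_cost or a.mean_qaly > b.mean_qaly)
    )


def efficiency_frontier(outcomes: list[EconomicOutcome]) -> pd.DataFrame:
    """Sequential-ICER frontier: sort by QALY, drop dominated and
    extended-dominated strategies, report each frontier step's ICER."""
    order = sorted(outcomes, key=lambda o: (o.mean_qaly, o.mean_cost))
    status = {o.strategy: "frontier" for o in order}
    for o in order:
        if any(dominates(other, o) for other in order if other is not o):
            status[o.strategy] = "dominated"
    frontier = [o for o in order if status[o.strategy] == "frontier"]
    changed = True
    while changed:  # extended dominance: rising ICER along the frontier
        changed = False
        for i in range(1, len(frontier) - 1):
            prev_, cur, nxt = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_in = (cur.mean_cost - prev_.mean_cost) / (cur.mean_qaly - prev_.mean_qaly)
            icer_out = (nxt.mean_cost - cur.mean_cost) / (nxt.mean_qaly - cur.mean_qaly)
            if icer_in > icer_out:
                status[cur.strategy] = "extended-dominated"
                frontier.pop(i)
                changed = True
                break
    rows = []
    prev = None
    for o in order:
        icer = np.nan
        if status[o.strategy] == "frontier":
            if prev is not None:
                icer = (o.mean_cost - prev.mean_cost) / (o.mean_qaly - prev.mean_qaly)
            prev = o
        rows.append(
            {
                "strategy": o.strategy,
                "mean_cost": o.mean_cost,
                "mean_qaly": o.mean_qaly,
                "status": status[o.strategy],
                "frontier_icer": icer,
            }
        )
    return pd.DataFrame(rows)


def price_reduction_grid(
    config: ModelConfig,
    reductions: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8),
    comparisons: list[tuple[str, str]] | None = None,
    rank_by: str = "nmb",
) -> dict[float, IcerTable]:
    """Re-run the economics at reduced drug prices for ALL strategies at once.

    Traces depend only on the curves, so they are computed once and
    re-accumulated per price level; QALY columns are identical across levels
    by construction.
    """
    for r in reductions:
        if not 0 <= r < 1:
            raise ValueError(f"price reductions must lie in [0, 1), got {r}")
    runs = run_all(config)
    out: dict[float, IcerTable] = {}
    for r in reductions:
        outcomes = [
            reprice(trace, config.strategy(name), config, (1.0 - r) * config.strategy(name).price_multiplier)
            for name, (trace, _outcome) in runs.items()
        ]
        out[r] = build_icer_table(
            outcomes, comparisons=comparisons, wtp=config.wtp_threshold, rank_by=rank_by
        )
    return out
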