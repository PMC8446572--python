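"""Discounted lifetime cost and QALY accounting over a cohort trace.

Per cycle k at elapsed time k*delta (delta = 21 days by default), with annual
discount factor d_k = (1 + rate)^(-k * delta_years):

* drug cost accrues on progression-free occupancy (treat-to-progression),
  scaled by the strategy's price multiplier;
* inpatient/follow-up cost accrues on progression-free occupancy;
* progressed-disease treatment and best supportive care accrue on progressed
  occupancy;
* terminal care is a one-off applied to the increment of deaths each cycle;
* severe-adverse-event management is a one-off at cycle 0, SAE rate times the
  management cost (events cluster early in treatment; charging it every cycle
  would let it dominate lifetime costs);
* QALYs accrue as occupancy x state utility x cycle length in years.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import ModelConfig, StrategyProfile
from .errors import ConfigError
from .markov import MarkovTrace, run_trace
from .survival import DAYS_PER_YEAR, apply_hr


def discount_factor(time_years, rate: float):
    """Annual-compounding discount factor (1 + rate)^(-t)."""
    t = np.asarray(time_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    out = (1.0 + rate) ** (-t)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class EconomicOutcome:
    """Discounted lifetime totals for one strategy, with a cost breakdown."""

    strategy: str
    mean_cost: float
    mean_qaly: float
    components: dict[str, float]


def accumulate(
    trace: MarkovTrace, strategy: StrategyProfile, config: ModelConfig
) -> EconomicOutcome:
    """Fold a cohort trace into discounted cost and QALY totals."""
    if abs(trace.cycle_length - config.cycle_length_months) > 1e-9:
        raise ConfigError(
            f"trace cycle length {trace.cycle_length} months does not match "
            f"config cycle length {config.cycle_length_months} months"
        )
    delta_years = config.cycle_length_days / DAYS_PER_YEAR
    k = np.arange(trace.n_cycles)
    d = discount_factor(k * delta_years, config.discount_rate)
    costs = config.costs
    u = config.utilities

    drug = float(np.sum(trace.pfd * d) * strategy.drug_cost_per_cycle * strategy.price_multiplier)
    inpatient = float(np.sum(trace.pfd * d) * costs["inpatient"])
    pd_treatment = float(np.sum(trace.pd * d) * costs["pd_treatment"])
    bsc = float(np.sum(trace.pd * d) * costs["best_supportive_care"])
    ddead = np.diff(trace.dead, prepend=0.0)
    terminal = float(np.sum(ddead * d) * costs["terminal"])
    ae = float(strategy.sae_rate * costs["ae_management"])
    qaly = float(np.sum((trace.pfd * u["pfd"] + trace.pd * u["pd"]) * d) * delta_years)

    components = {
        "drug": drug,
        "inpatient": inpatient,
        "pd_treatment": pd_treatment,
        "bsc": bsc,
        "terminal": terminal,
        "ae": ae,
    }
    return EconomicOutcome(
        strategy=strategy.name,
        mean_cost=float(sum(components.values())),
        mean_qaly=qaly,
        components=components,
    )


def run_strategy(
    config: ModelConfig, name: str, clamp_tol: float | None = None
) -> tuple[MarkovTrace, EconomicOutcome]:
    """Build the strategy's curves (reference curves x its HRs), trace, and totals.

    ``clamp_tol`` overrides the trace's PFS-above-OS abort threshold; PSA
    passes infinity so that extreme joint HR draws are clamped rather than
    aborting the simulation.
    """
    s = config.strategy(name)
    kwargs = {} if clamp_tol is None else {"clamp_tol": clamp_tol}
    trace = run_trace(
        apply_hr(config.os_curve, s.hr_os),
        apply_hr(config.pfs_curve, s.hr_pfs),
        config.cycle_length_months,
        config.termination_death_fraction,
        **kwargs,
    )
    return trace, accumulate(trace, s, config)


def run_all(config: ModelConfig) -> dict[str, tuple[MarkovTrace, EconomicOutcome]]:
    """Trace and outcome for every configured strategy."""
    return {name: run_strategy(config, name) for name in config.strategy_names}


def reprice(
    trace: MarkovTrace,
    strategy: StrategyProfile,
    config: ModelConfig,
    price_multiplier: float,
) -> EconomicOutcome:
    """Re-accumulate an existing trace at a different drug-price multiplier."""
    return accumulate(trace, replace(strategy, price_multiplier=price_multiplier), config)
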