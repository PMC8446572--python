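"""Deterministic and probabilistic sensitivity analysis.

One-way DSA re-runs the full model at each parameter's low and high bound
and reports the ICER swing (tornado rows, widest first).

PSA draws parameter vectors from per-parameter distributions — beta for
probabilities and utilities, lognormal for costs and hazard ratios, fixed
for drug prices, the discount rate, and the Weibull parameters — re-runs the
model per draw, and summarises decision uncertainty as cost-effectiveness
acceptability curves: at each willingness-to-pay value, the fraction of
draws in which each strategy maximises net monetary benefit
NMB = wtp * QALY - cost (ties split uniformly).

Printed (low, high) ranges are treated as 95% intervals, SE = range/3.92;
probability-like parameters without a printed range get a 20% coefficient
of variation.  Hazard ratios are sampled lognormally around their point
estimate with the log-SE implied by their CI.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig, apply_params
from .econ import run_strategy
from .nma import z_quantile

RANGE_TO_SE = 2 * z_quantile(0.95)  # printed range treated as a 95% interval
DEFAULT_CV = 0.20


@dataclass(frozen=True)
class ParamDist:
    """One parameter's sampling rule: ('beta'|'lognormal'|'lognormal_ci'), args."""

    path: str
    kind: str
    args: tuple[float, ...]


@dataclass(frozen=True)
class PsaSpec:
    """Distribution assignment for every sampled parameter plus draw count/seed."""

    params: tuple[ParamDist, ...]
    n_draws: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws <= 0:
            raise ValueError("n_draws must be > 0")
        paths = [p.path for p in self.params]
        if len(set(paths)) != len(paths):
            raise ValueError("each parameter may appear only once in a PsaSpec")


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta(a, b) from a mean in (0,1) and an SE."""
    if not 0 < mean < 1:
        raise ValueError(f"beta mean must be in (0, 1), got {mean}")
    var = se**2
    if var <= 0 or var >= mean * (1 - mean):
        raise ValueError(f"beta variance {var} incompatible with mean {mean}")
    k = mean * (1 - mean) / var - 1.0
    return mean * k, (1 - mean) * k


def lognormal_from_moments(mean: float, se: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal matching a natural-scale mean and SE."""
    if mean <= 0 or se <= 0:
        raise ValueError("lognormal mean and se must be > 0")
    sigma2 = np.log1p((se / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def default_psa_spec(config: ModelConfig, n_draws: int = 10000, seed: int = 0) -> PsaSpec:
    """Distribution assignment following the published parameter table.

    Care costs and hazard ratios: lognormal; utilities and SAE rates: beta;
    drug prices, discount rate, and Weibull parameters: fixed (excluded).
    Parameters with a printed range use SE = range/3.92; SAE rates (no
    printed range) fall back to a 20% coefficient of variation.
    """
    params: list[ParamDist] = []
    for path, (lo, hi) in sorted(config.dsa_ranges.items()):
        se = (hi - lo) / RANGE_TO_SE
        if path.startswith("costs."):
            base = config.costs[path.split(".", 1)[1]]
            params.append(ParamDist(path, "lognormal", lognormal_from_moments(base, se)))
        elif path.startswith("utilities."):
            base = config.utilities[path.split(".", 1)[1]]
            params.append(ParamDist(path, "beta", beta_from_moments(base, se)))
        elif path.endswith((".hr_os", ".hr_pfs")):
            # lognormal around the point estimate with the CI-implied log-SE
            _, name, fld = path.split(".")
            base = getattr(config.strategy(name), fld)
            log_se = (np.log(hi) - np.log(lo)) / RANGE_TO_SE
            params.append(ParamDist(path, "lognormal_ci", (float(np.log(base)), float(log_se))))
        # discount rate and anything else with a range: fixed in PSA
    for s in config.strategies:
        if 0 < s.sae_rate < 1:
            se = DEFAULT_CV * s.sae_rate
            params.append(
                ParamDist(
                    f"strategies.{s.name}.sae_rate", "beta", beta_from_moments(s.sae_rate, se)
                )
            )
    return PsaSpec(params=tuple(params), n_draws=n_draws, seed=seed)


def sample_psa(spec: PsaSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the PSA parameter matrix (n_draws rows, one column per parameter)."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    cols = {}
    for p in spec.params:
        if p.kind == "beta":
            cols[p.path] = rng.beta(*p.args, size=spec.n_draws)
        elif p.kind == "lognormal":
            cols[p.path] = rng.lognormal(p.args[0], p.args[1], size=spec.n_draws)
        elif p.kind == "lognormal_ci":
            cols[p.path] = np.exp(rng.normal(p.args[0], p.args[1], size=spec.n_draws))
        else:
            raise ValueError(f"unknown distribution kind {p.kind!r}")
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class PsaResult:
    """Per-draw discounted (cost, QALY) for each strategy, plus the draws used."""

    strategies: tuple[str, ...]
    costs: np.ndarray  # (n_draws, n_strategies)
    qalys: np.ndarray
    draws: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        data = {}
        for j, s in enumerate(self.strategies):
            data[f"cost_{s}"] = self.costs[:, j]
            data[f"qaly_{s}"] = self.qalys[:, j]
        return pd.DataFrame(data)


def run_psa(config: ModelConfig, spec: PsaSpec | None = None) -> PsaResult:
    """Monte-Carlo PSA: sample parameters, re-run the model per draw."""
    spec = default_psa_spec(config) if spec is None else spec
    draws = sample_psa(spec)
    names = config.strategy_names
    costs = np.empty((spec.n_draws, len(names)))
    qalys = np.empty_like(costs)
    # Independent OS/PFS hazard-ratio draws can cross the curves; clamping
    # (clamp_tol=inf) floors progressed-disease occupancy at zero for such
    # draws instead of aborting the simulation.
    for i in range(spec.n_draws):
        cfg_i = apply_params(config, draws.iloc[i].to_dict())
        for j, name in enumerate(names):
            _, outcome = run_strategy(cfg_i, name, clamp_tol=np.inf)
            costs[i, j] = outcome.mean_cost
            qalys[i, j] = outcome.mean_qaly
    return PsaResult(strategies=tuple(names), costs=costs, qalys=qalys, draws=draws)


@dataclass(frozen=True)
class CeacCurve:
    """Probability each strategy is optimal, per willingness-to-pay value."""

    wtp: np.ndarray
    probabilities: pd.DataFrame  # one column per strategy, rows align with wtp

    def to_frame(self) -> pd.DataFrame:
        out = self.probabilities.copy()
        out.insert(0, "wtp", self.wtp)
        return out


def ceac(
    costs: np.ndarray,
    qalys: np.ndarray,
    wtp_grid,
    strategies: tuple[str, ...] | list[str],
) -> CeacCurve:
    """Acceptability curves from per-draw (cost, QALY) matrices.

    At each wtp value, each draw votes for the strategy with maximal
    NMB = wtp * qaly - cost; exact ties split their vote uniformly.
    """
    costs = np.atleast_2d(np.asarray(costs, dtype=float))
    qalys = np.atleast_2d(np.asarray(qalys, dtype=float))
    wtp = np.atleast_1d(np.asarray(wtp_grid, dtype=float))
    if costs.shape != qalys.shape or costs.shape[1] != len(strategies):
        raise ValueError("costs/qalys must be (n_draws, n_strategies) matching labels")
    if costs.shape[0] == 0 or wtp.size == 0:
        raise ValueError("need at least one draw and one WTP value")
    probs = np.empty((wtp.size, costs.shape[1]))
    for i, lam in enumerate(wtp):
        nmb = lam * qalys - costs
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        share = winners / winners.sum(axis=1, keepdims=True)
        probs[i] = share.mean(axis=0)
    return CeacCurve(wtp=wtp, probabilities=pd.DataFrame(probs, columns=list(strategies)))


def one_way_dsa(
    config: ModelConfig,
    comparison: tuple[str, str] = ("atezolizumab", "nivolumab"),
    parameters: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis (tornado rows).

    Each parameter is set to its low and high bound in turn (all others at
    base), the model re-run for both arms of ``comparison``, and the ICER
    recorded; rows are sorted by |icer_high - icer_low| descending.
    """
    strategy, comparator = comparison
    config.strategy(strategy)
    config.strategy(comparator)
    parameters = dict(config.dsa_ranges) if parameters is None else parameters
    if not parameters:
        raise ValueError("no parameters with ranges to vary")

    def icer_at(cfg: ModelConfig) -> float:
        _, o_s = run_strategy(cfg, strategy)
        _, o_c = run_strategy(cfg, comparator)
        inc_cost = o_s.mean_cost - o_c.mean_cost
        inc_qaly = o_s.mean_qaly - o_c.mean_qaly
        return inc_cost / inc_qaly if inc_qaly != 0 else np.nan

    rows = []
    for path, (lo, hi) in parameters.items():
        icer_lo = icer_at(apply_params(config, {path: lo}))
        icer_hi = icer_at(apply_params(config, {path: hi}))
        rows.append(
            {
                "parameter": path,
                "low": lo,
                "high": hi,
                "icer_low": icer_lo,
                "icer_high": icer_hi,
                "width": abs(icer_hi - icer_lo),
            }
        )
    out = pd.DataFrame(rows).sort_values("width", ascending=False, ignore_index=True)
    return out
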