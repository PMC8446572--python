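"""Synthetic inputs with known ground truth for end-to-end testing.

Generates everything the pipeline consumes without any download: digitized
Kaplan-Meier point clouds from known Weibull curves (with additive
digitization noise and a monotone projection), star-network trial evidence
tables with known true contrasts, and full model configurations — either the
packaged published parameter set or randomized valid configurations.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression

from .config import ModelConfig, StrategyProfile, load_table1, validate_config
from .errors import EvidenceError
from .nma import EffectEstimate
from .survival import KMPoints, WeibullCurve


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a generated evidence base.

    ``true_log_effects`` maps (arm_a, arm_b) ordered pairs per endpoint to
    the true log effect; every arm must connect to ``comparator`` (star
    topology).  ``n_replicates`` lets an edge carry several trials.
    """

    comparator: str = "chemotherapy"
    true_log_effects: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    n_replicates: dict[tuple[str, str], int] = field(default_factory=dict)
    curves: dict[str, WeibullCurve] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for endpoint, edges in self.true_log_effects.items():
            for a, b in edges:
                if self.comparator not in (a, b):
                    raise EvidenceError(
                        f"{endpoint} edge ({a}, {b}) does not touch the common "
                        f"comparator {self.comparator!r} (star topology required)"
                    )


def default_truth(seed: int = 0) -> SyntheticTruth:
    """A four-drug star network with moderately separated true effects."""
    drugs = ["drug_a", "drug_b", "drug_c", "drug_d"]
    rng = np.random.default_rng(seed)
    effects = {
        endpoint: {(d, "chemotherapy"): float(rng.normal(-0.4, 0.25)) for d in drugs}
        for endpoint in ("OS", "PFS")
    }
    return SyntheticTruth(true_log_effects=effects, seed=seed)


def gen_km_points(
    curve: WeibullCurve,
    n_points: int,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
) -> KMPoints:
    """Emulate digitized KM coordinates from a known curve.

    Times sit on a uniform grid over (0, t99] where S(t99) = 0.01; survival
    values get additive gaussian noise, are projected onto a non-increasing
    sequence (L2 isotonic regression), and are clipped into (0, 1].  With
    ``noise_sd = 0`` the exact curve values come back.
    """
    if n_points < 3:
        raise ValueError("need at least 3 points")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t99 = curve.time_at(0.01)
    times = t99 * np.arange(1, n_points + 1) / n_points
    s = curve.survival(times)
    if noise_sd > 0:
        s = s + rng.normal(0.0, noise_sd, size=n_points)
        s = isotonic_regression(s, increasing=False).x  # monotone projection
        s = np.clip(s, 1e-9, 1.0)
    return KMPoints(times=times, survival=s)


def gen_trial_table(
    truth: SyntheticTruth,
    se_range: tuple[float, float] = (0.1, 0.3),
    seed: int | np.random.Generator | None = None,
    sample_noise: bool = True,
) -> list[EffectEstimate]:
    """Simulate a star-network evidence table from known true contrasts.

    Per comparison (and per replicate): se ~ Uniform(se_range) and
    log_effect ~ Normal(true, se); with ``sample_noise=False`` the reported
    effect IS the truth (so the network solution must return it exactly).
    """
    lo, hi = se_range
    if not 0 < lo <= hi:
        raise ValueError("se_range must satisfy 0 < min <= max")
    if seed is None:
        seed = truth.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not truth.true_log_effects:
        raise EvidenceError("truth carries no comparisons")
    out = []
    for endpoint, edges in truth.true_log_effects.items():
        for (a, b), true_effect in edges.items():
            for rep in range(truth.n_replicates.get((a, b), 1)):
                se = float(rng.uniform(lo, hi))
                y = float(rng.normal(true_effect, se)) if sample_noise else true_effect
                out.append(
                    EffectEstimate(f"synthetic-{a}-{rep}", a, b, endpoint, y, se)
                )
    return out


def gen_config(paper_mode: bool = True, seed: int = 0) -> ModelConfig:
    """A full model configuration.

    ``paper_mode=True`` returns the packaged published parameter set
    verbatim.  Otherwise a randomized valid configuration: costs within a
    factor of 3 of the published ones, utilities in (0.2, 0.97) with
    progressed below progression-free, HRs in (0.4, 1.6).
    """
    base = load_table1()
    if paper_mode:
        return base
    rng = np.random.default_rng(seed)

    def jitter(x: float) -> float:
        return float(x * 3.0 ** rng.uniform(-1.0, 1.0))

    u_pfd = float(rng.uniform(0.5, 0.97))
    u_pd = float(rng.uniform(0.2, u_pfd))
    strategies = []
    for s in base.strategies:
        is_ref = s.name == base.reference_strategy
        strategies.append(
            StrategyProfile(
                name=s.name,
                drug_cost_per_cycle=jitter(s.drug_cost_per_cycle),
                sae_rate=float(rng.uniform(0.05, 0.5)),
                hr_os=1.0 if is_ref else float(rng.uniform(0.4, 1.6)),
                hr_pfs=1.0 if is_ref else float(rng.uniform(0.4, 1.6)),
            )
        )
    config = ModelConfig(
        strategies=tuple(strategies),
        reference_strategy=base.reference_strategy,
        os_curve=WeibullCurve(
            scale=jitter(base.os_curve.scale),
            shape=float(rng.uniform(0.5, 1.5)),
            endpoint="OS",
        ),
        pfs_curve=WeibullCurve(
            scale=jitter(base.pfs_curve.scale) + base.os_curve.scale,
            shape=float(rng.uniform(0.5, 1.5)),
            endpoint="PFS",
        ),
        utilities={"pfd": u_pfd, "pd": u_pd},
        costs={k: jitter(v) for k, v in base.costs.items()},
        discount_rate=float(rng.uniform(0.0, 0.08)),
        cycle_length_days=base.cycle_length_days,
        termination_death_fraction=base.termination_death_fraction,
        wtp_threshold=base.wtp_threshold,
        dsa_ranges={},
    )
    return validate_config(config)
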