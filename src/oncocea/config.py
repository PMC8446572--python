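"""Model configuration: schema, validation, YAML/CSV I/O, packaged fixtures.

A :class:`ModelConfig` carries everything the cohort model needs: per-cycle
drug and care costs, severe-adverse-event rates, state utilities, annual
discount rate, willingness-to-pay threshold, the reference strategy's Weibull
OS/PFS parameters, and OS/PFS hazard ratios of every other strategy relative
to the reference.  Costs are unitless money (the source evaluation used 2020
USD at 6.5 CNY/USD); no currency handling happens inside the model.

The packaged fixture ``table1.yaml`` carries the published parameter set for
the four PD-1/PD-L1 strategies (atezolizumab reference); its hazard ratios
are the network-meta-analysis contrasts computed from the packaged
five-trial evidence table.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .survival import DAYS_PER_MONTH, WeibullCurve

COST_KEYS = ("inpatient", "pd_treatment", "best_supportive_care", "terminal", "ae_management")
UTILITY_KEYS = ("pfd", "pd")


@dataclass(frozen=True)
class StrategyProfile:
    """One drug strategy: per-cycle price, SAE rate, and HRs vs the reference."""

    name: str
    drug_cost_per_cycle: float
    sae_rate: float
    hr_os: float = 1.0
    hr_pfs: float = 1.0
    price_multiplier: float = 1.0


@dataclass(frozen=True)
class ModelConfig:
    """Validated parameter set driving the whole pipeline."""

    strategies: tuple[StrategyProfile, ...]
    reference_strategy: str
    os_curve: WeibullCurve
    pfs_curve: WeibullCurve
    utilities: dict[str, float]
    costs: dict[str, float]
    discount_rate: float
    cycle_length_days: float
    termination_death_fraction: float = 0.99
    wtp_threshold: float = 32517.0
    dsa_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def cycle_length_months(self) -> float:
        return self.cycle_length_days / DAYS_PER_MONTH

    @property
    def strategy_names(self) -> list[str]:
        return [s.name for s in self.strategies]

    def strategy(self, name: str) -> StrategyProfile:
        for s in self.strategies:
            if s.name == name:
                return s
        raise ConfigError(f"unknown strategy {name!r}")


def _require_number(value, label: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"field {label!r} must be numeric, got {value!r}")
    v = float(value)
    if not np.isfinite(v):
        raise ConfigError(f"field {label!r} must be finite, got {value!r}")
    return v


def validate_config(config: ModelConfig) -> ModelConfig:
    """Check every schema invariant; raise :class:`ConfigError` naming the violation."""
    c = config
    if not c.strategies:
        raise ConfigError("at least one strategy is required")
    names = c.strategy_names
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate strategy names: {names}")
    if names.count(c.reference_strategy) != 1:
        raise ConfigError(f"unknown reference strategy {c.reference_strategy!r}")
    for key in COST_KEYS:
        if key not in c.costs:
            raise ConfigError(f"missing cost field {key!r}")
        if _require_number(c.costs[key], f"costs.{key}") < 0:
            raise ConfigError(f"cost {key!r} must be >= 0, got {c.costs[key]}")
    for key in UTILITY_KEYS:
        if key not in c.utilities:
            raise ConfigError(f"missing utility field {key!r}")
        u = _require_number(c.utilities[key], f"utilities.{key}")
        if not 0 <= u <= 1:
            raise ConfigError(f"utility {key!r} must be in [0, 1], got {u}")
    if not 0 <= c.discount_rate < 1:
        raise ConfigError(f"discount_rate must be in [0, 1), got {c.discount_rate}")
    if c.cycle_length_days <= 0:
        raise ConfigError(f"cycle_length_days must be > 0, got {c.cycle_length_days}")
    if not 0 < c.termination_death_fraction <= 1:
        raise ConfigError(
            f"termination_death_fraction must be in (0, 1], got {c.termination_death_fraction}"
        )
    if c.wtp_threshold < 0:
        raise ConfigError(f"wtp_threshold must be >= 0, got {c.wtp_threshold}")
    for s in c.strategies:
        if s.drug_cost_per_cycle < 0:
            raise ConfigError(f"strategy {s.name!r}: drug_cost_per_cycle must be >= 0")
        if not 0 <= s.sae_rate <= 1:
            raise ConfigError(f"strategy {s.name!r}: sae_rate must be in [0, 1]")
        if not (np.isfinite(s.hr_os) and s.hr_os > 0):
            raise ConfigError(f"strategy {s.name!r}: hr_os must be finite and > 0")
        if not (np.isfinite(s.hr_pfs) and s.hr_pfs > 0):
            raise ConfigError(f"strategy {s.name!r}: hr_pfs must be finite and > 0")
        if s.price_multiplier < 0:
            raise ConfigError(f"strategy {s.name!r}: price_multiplier must be >= 0")
    ref = c.strategy(c.reference_strategy)
    if ref.hr_os != 1.0 or ref.hr_pfs != 1.0:
        raise ConfigError(
            f"reference strategy {ref.name!r} must have hr_os = hr_pfs = 1.0"
        )
    for key, bounds in c.dsa_ranges.items():
        if len(bounds) != 2 or not bounds[0] < bounds[1]:
            raise ConfigError(f"dsa_ranges[{key!r}] must be (low, high) with low < high")
    return c


def _strategy_from_mapping(m: dict, reference: str) -> StrategyProfile:
    if "name" not in m:
        raise ConfigError("strategy entry missing field 'name'")
    name = str(m["name"])
    for key in ("drug_cost_per_cycle", "sae_rate"):
        if key not in m:
            raise ConfigError(f"strategy {name!r} missing required field {key!r}")
    is_ref = name == reference
    for key in ("hr_os", "hr_pfs"):
        if not is_ref and key not in m:
            raise ConfigError(f"strategy {name!r} missing required field {key!r}")
    return StrategyProfile(
        name=name,
        drug_cost_per_cycle=_require_number(m["drug_cost_per_cycle"], f"{name}.drug_cost_per_cycle"),
        sae_rate=_require_number(m["sae_rate"], f"{name}.sae_rate"),
        hr_os=_require_number(m.get("hr_os", 1.0), f"{name}.hr_os"),
        hr_pfs=_require_number(m.get("hr_pfs", 1.0), f"{name}.hr_pfs"),
        price_multiplier=_require_number(m.get("price_multiplier", 1.0), f"{name}.price_multiplier"),
    )


def config_from_mapping(doc: dict) -> ModelConfig:
    """Build and validate a :class:`ModelConfig` from a parsed YAML mapping."""
    required = (
        "strategies",
        "reference_strategy",
        "os_curve",
        "pfs_curve",
        "utilities",
        "costs",
        "discount_rate",
        "cycle_length_days",
    )
    for key in required:
        if key not in doc:
            raise ConfigError(f"missing field {key!r}")
    reference = str(doc["reference_strategy"])
    strategies = tuple(_strategy_from_mapping(m, reference) for m in doc["strategies"])

    def curve(key: str, endpoint: str) -> WeibullCurve:
        m = doc[key]
        for f in ("scale", "shape"):
            if f not in m:
                raise ConfigError(f"missing field {key}.{f}")
        try:
            return WeibullCurve(
                scale=_require_number(m["scale"], f"{key}.scale"),
                shape=_require_number(m["shape"], f"{key}.shape"),
                endpoint=endpoint,
            )
        except ValueError as exc:
            raise ConfigError(f"{key}: {exc}") from exc

    dsa = {
        str(k): (float(v[0]), float(v[1]))
        for k, v in (doc.get("dsa_ranges") or {}).items()
    }
    config = ModelConfig(
        strategies=strategies,
        reference_strategy=reference,
        os_curve=curve("os_curve", "OS"),
        pfs_curve=curve("pfs_curve", "PFS"),
        utilities={k: _require_number(v, f"utilities.{k}") for k, v in doc["utilities"].items()},
        costs={k: _require_number(v, f"costs.{k}") for k, v in doc["costs"].items()},
        discount_rate=_require_number(doc["discount_rate"], "discount_rate"),
        cycle_length_days=_require_number(doc["cycle_length_days"], "cycle_length_days"),
        termination_death_fraction=_require_number(
            doc.get("termination_death_fraction", 0.99), "termination_death_fraction"
        ),
        wtp_threshold=_require_number(doc.get("wtp_threshold", 32517.0), "wtp_threshold"),
        dsa_ranges=dsa,
    )
    return validate_config(config)


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML model configuration; invalid files are rejected."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"configuration file {path} does not hold a mapping")
    return config_from_mapping(doc)


def config_to_mapping(config: ModelConfig) -> dict:
    return {
        "reference_strategy": config.reference_strategy,
        "strategies": [
            {
                "name": s.name,
                "drug_cost_per_cycle": s.drug_cost_per_cycle,
                "sae_rate": s.sae_rate,
                "hr_os": s.hr_os,
                "hr_pfs": s.hr_pfs,
                "price_multiplier": s.price_multiplier,
            }
            for s in config.strategies
        ],
        "os_curve": {"scale": config.os_curve.scale, "shape": config.os_curve.shape},
        "pfs_curve": {"scale": config.pfs_curve.scale, "shape": config.pfs_curve.shape},
        "utilities": dict(config.utilities),
        "costs": dict(config.costs),
        "discount_rate": config.discount_rate,
        "cycle_length_days": config.cycle_length_days,
        "termination_death_fraction": config.termination_death_fraction,
        "wtp_threshold": config.wtp_threshold,
        "dsa_ranges": {k: [v[0], v[1]] for k, v in config.dsa_ranges.items()},
    }


def write_config(config: ModelConfig, path: str | Path) -> None:
    """Write a config as YAML; ``load_config(write_config(c)) == c`` field-by-field."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_mapping(config), fh, sort_keys=False)


def set_param(config: ModelConfig, path: str, value: float) -> ModelConfig:
    """Return a copy of ``config`` with one dotted-path parameter replaced.

    Supported paths: ``costs.<key>``, ``utilities.<key>``, ``discount_rate``,
    ``wtp_threshold``, ``os_curve.scale`` etc., and
    ``strategies.<name>.<field>``.
    """
    return apply_params(config, {path: value})


def apply_params(config: ModelConfig, params: dict[str, float]) -> ModelConfig:
    """Copy ``config`` with several dotted-path parameters replaced at once."""
    costs = dict(config.costs)
    utilities = dict(config.utilities)
    strategies = {s.name: s for s in config.strategies}
    scalars: dict[str, float] = {}
    curves = {"os_curve": config.os_curve, "pfs_curve": config.pfs_curve}
    for path, value in params.items():
        parts = path.split(".")
        if parts[0] == "costs" and len(parts) == 2 and parts[1] in costs:
            costs[parts[1]] = float(value)
        elif parts[0] == "utilities" and len(parts) == 2 and parts[1] in utilities:
            utilities[parts[1]] = float(value)
        elif path in (
            "discount_rate",
            "wtp_threshold",
            "termination_death_fraction",
            "cycle_length_days",
        ):
            scalars[path] = float(value)
        elif parts[0] in curves and len(parts) == 2 and parts[1] in ("scale", "shape"):
            curves[parts[0]] = replace(curves[parts[0]], **{parts[1]: float(value)})
        elif parts[0] == "strategies" and len(parts) == 3 and parts[1] in strategies:
            s = strategies[parts[1]]
            if not hasattr(s, parts[2]):
                raise ConfigError(f"unknown strategy field {parts[2]!r} in {path!r}")
            strategies[parts[1]] = replace(s, **{parts[2]: float(value)})
        else:
            raise ConfigError(f"unknown parameter path {path!r}")
    new = replace(
        copy.deepcopy(config),
        costs=costs,
        utilities=utilities,
        strategies=tuple(strategies[n] for n in config.strategy_names),
        os_curve=curves["os_curve"],
        pfs_curve=curves["pfs_curve"],
        **scalars,
    )
    return validate_config(new)


def write_results(table, path: str | Path) -> None:
    """Write a tabular result (DataFrame or object with ``to_frame``) as CSV.

    Numeric formatting keeps >= 10 significant digits so a re-read
    round-trips within 1e-6 relative.
    """
    frame = table if isinstance(table, pd.DataFrame) else table.to_frame()
    if frame.empty:
        raise ValueError("refusing to write an empty table")
    frame.to_csv(path, index=False, float_format="%.10g")


def _data_path(name: str) -> Path:
    return Path(resources.files("oncocea").joinpath("data", name))


def table1_path() -> Path:
    """Path to the packaged published parameter-set fixture."""
    return _data_path("table1.yaml")


def load_table1() -> ModelConfig:
    """The packaged published parameter set (atezolizumab reference)."""
    return load_config(table1_path())


def five_trials_path() -> Path:
    """Path to the packaged five-trial high-PD-L1 evidence table."""
    return _data_path("five_trials_high_pdl1.csv")
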