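"""Fixed-effects network meta-analysis on a comparison graph.

Trial-level effect estimates (log hazard ratios or log risk ratios with
standard errors) are combined by weighted least squares on the comparison
graph: with incidence matrix X (one row per estimate, +1/-1 on its two arms)
and weights w = 1/se**2, treatment effects solve the normal equations through
the Moore-Penrose pseudoinverse of the graph Laplacian L = X'WX.  Pairwise
contrasts and their variances come from L+; heterogeneity is summarised by
Cochran's Q over all estimates and I^2 = max(0, (Q - df)/Q).

On a star network (every drug compared only to a common comparator) the WLS
solution coincides with the classical two-step indirect comparison:
pool each edge by inverse variance, subtract pooled edges, add variances.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import EvidenceError

VALID_ENDPOINTS = ("OS", "PFS", "AE", "SAE")


@dataclass(frozen=True)
class EffectEstimate:
    """One comparison's log-scale effect (log HR or log RR) with its SE."""

    trial: str
    arm_a: str
    arm_b: str
    endpoint: str
    log_effect: float
    se: float

    def __post_init__(self) -> None:
        if self.arm_a == self.arm_b:
            raise EvidenceError(f"arms must differ, got {self.arm_a!r} twice")
        if not (np.isfinite(self.se) and self.se > 0):
            raise EvidenceError(f"standard error must be finite and > 0, got {self.se}")
        if not np.isfinite(self.log_effect):
            raise EvidenceError(f"log effect must be finite, got {self.log_effect}")

    @property
    def effect(self) -> float:
        """The ratio-scale effect (HR or RR)."""
        return float(np.exp(self.log_effect))


def z_quantile(level: float) -> float:
    """Two-sided normal quantile for a CI level, e.g. 1.959964 at 0.95."""
    if not 0 < level < 1:
        raise EvidenceError(f"CI level must be in (0, 1), got {level}")
    return float(norm.ppf((1 + level) / 2))


def se_from_ci(point: float, low: float, high: float, level: float = 0.95) -> float:
    """Back-transform a ratio-scale CI to a log-scale standard error.

    se = (ln(high) - ln(low)) / (2 * z), symmetric on the log scale by
    construction.
    """
    if not (low > 0 and high > 0 and point > 0):
        raise EvidenceError("ratio and CI bounds must be positive")
    if not low <= point <= high:
        raise EvidenceError(f"require low <= point <= high, got ({low}, {point}, {high})")
    se = (np.log(high) - np.log(low)) / (2 * z_quantile(level))
    if se <= 0:
        raise EvidenceError("degenerate CI (low == high) gives se = 0")
    return float(se)


def log_rr_from_counts(
    events_a: int,
    n_a: int,
    events_b: int,
    n_b: int,
    *,
    trial: str = "",
    arm_a: str = "a",
    arm_b: str = "b",
    endpoint: str = "SAE",
    continuity_correction: bool = False,
) -> EffectEstimate:
    """Risk ratio of arm_a vs arm_b from 2x2 event counts, on the log scale.

    log RR = ln((events_a/n_a) / (events_b/n_b));
    se = sqrt(1/events_a - 1/n_a + 1/events_b - 1/n_b).

    Zero event counts are rejected unless ``continuity_correction`` is set,
    in which case 0.5 is added to each event cell and 1.0 to each arm size
    (the correction is explicit, never silent).
    """
    for label, e, n in (("a", events_a, n_a), ("b", events_b, n_b)):
        if n <= 0 or e < 0 or e > n:
            raise EvidenceError(f"arm {label}: need 0 <= events <= n with n > 0")
    if events_a == 0 or events_b == 0:
        if not continuity_correction:
            raise EvidenceError(
                "zero events in an arm; pass continuity_correction=True to add 0.5"
            )
        events_a, n_a = events_a + 0.5, n_a + 1.0
        events_b, n_b = events_b + 0.5, n_b + 1.0
    log_effect = np.log((events_a / n_a) / (events_b / n_b))
    se = np.sqrt(1 / events_a - 1 / n_a + 1 / events_b - 1 / n_b)
    return EffectEstimate(trial, arm_a, arm_b, endpoint, float(log_effect), float(se))


def pool_direct(estimates: list[EffectEstimate]) -> EffectEstimate:
    """Fixed-effects (inverse-variance) pooling of one comparison's estimates."""
    if not estimates:
        raise EvidenceError("nothing to pool")
    first = estimates[0]
    for e in estimates[1:]:
        if (e.arm_a, e.arm_b, e.endpoint) != (first.arm_a, first.arm_b, first.endpoint):
            raise EvidenceError(
                "pool_direct requires a single ordered comparison and endpoint; "
                f"got {(first.arm_a, first.arm_b, first.endpoint)} and "
                f"{(e.arm_a, e.arm_b, e.endpoint)}"
            )
    w = np.array([1.0 / e.se**2 for e in estimates])
    y = np.array([e.log_effect for e in estimates])
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    trial = estimates[0].trial if len(estimates) == 1 else "pooled"
    return EffectEstimate(trial, first.arm_a, first.arm_b, first.endpoint, pooled, se)


@dataclass(frozen=True)
class NMAResult:
    """Pairwise league-table solution for one endpoint.

    ``log_effect_matrix[i, j]`` is the pooled log effect of treatment i vs
    treatment j (antisymmetric, zero diagonal); ``se_matrix`` holds the
    contrast standard errors.
    """

    endpoint: str
    treatments: tuple[str, ...]
    log_effect_matrix: np.ndarray
    se_matrix: np.ndarray
    ci_level: float
    Q: float
    df: int
    i_squared: float

    def _idx(self, name: str) -> int:
        try:
            return self.treatments.index(name)
        except ValueError:
            raise KeyError(f"unknown treatment {name!r}") from None

    def log_effect(self, a: str, b: str) -> float:
        return float(self.log_effect_matrix[self._idx(a), self._idx(b)])

    def se(self, a: str, b: str) -> float:
        return float(self.se_matrix[self._idx(a), self._idx(b)])

    def effect(self, a: str, b: str) -> float:
        """Ratio-scale effect (HR/RR) of a vs b."""
        return float(np.exp(self.log_effect(a, b)))

    def ci(self, a: str, b: str) -> tuple[float, float]:
        z = z_quantile(self.ci_level)
        le, se = self.log_effect(a, b), self.se(a, b)
        return float(np.exp(le - z * se)), float(np.exp(le + z * se))

    def league_table(self, digits: int = 2) -> pd.DataFrame:
        """Square table of 'effect (low-high)' strings, row vs column."""
        n = len(self.treatments)
        cells = []
        for i in range(n):
            row = []
            for j in range(n):
                if i == j:
                    row.append(self.treatments[i])
                else:
                    lo, hi = self.ci(self.treatments[i], self.treatments[j])
                    eff = self.effect(self.treatments[i], self.treatments[j])
                    row.append(f"{eff:.{digits}f} ({lo:.{digits}f}-{hi:.{digits}f})")
            cells.append(row)
        return pd.DataFrame(cells, index=self.treatments, columns=self.treatments)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: one row per ordered treatment pair."""
        rows = []
        for a in self.treatments:
            for b in self.treatments:
                if a == b:
                    continue
                lo, hi = self.ci(a, b)
                rows.append(
                    {
                        "endpoint": self.endpoint,
                        "arm_a": a,
                        "arm_b": b,
                        "effect": self.effect(a, b),
                        "ci_low": lo,
                        "ci_high": hi,
                        "log_effect": self.log_effect(a, b),
                        "se": self.se(a, b),
                    }
                )
        return pd.DataFrame(rows)


def _check_connected(treatments: list[str], edges: list[tuple[str, str]]) -> None:
    parent = {t: t for t in treatments}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    roots = {find(t) for t in treatments}
    if len(roots) > 1:
        raise EvidenceError(f"comparison network is disconnected ({len(roots)} components)")


def network_estimates(
    evidence: list[EffectEstimate], endpoint: str, ci_level: float = 0.95
) -> NMAResult:
    """Fixed-effects network solution for one endpoint.

    Weighted least squares via the pseudoinverse of the weighted graph
    Laplacian; Q sums the weighted squared residuals of every estimate
    against its fitted contrast, df = (#estimates - #treatments + 1), and
    I^2 = max(0, (Q - df)/Q).
    """
    est = [e for e in evidence if e.endpoint == endpoint]
    if not est:
        raise EvidenceError(f"no estimates for endpoint {endpoint!r}")
    treatments = sorted({a for e in est for a in (e.arm_a, e.arm_b)})
    _check_connected(treatments, [(e.arm_a, e.arm_b) for e in est])

    # Warn on correlated arms: one trial contributing >1 estimate to the
    # same endpoint (multi-arm trials need a variance decomposition we do
    # not implement; only monotherapy-vs-comparator contrasts are expected).
    trials = [e.trial for e in est if e.trial]
    dupes = {t for t in trials if trials.count(t) > 1}
    if dupes:
        warnings.warn(
            f"trial(s) {sorted(dupes)} contribute multiple {endpoint} estimates; "
            "arm correlations are ignored",
            stacklevel=2,
        )

    idx = {t: i for i, t in enumerate(treatments)}
    n, T = len(est), len(treatments)
    X = np.zeros((n, T))
    y = np.empty(n)
    w = np.empty(n)
    for r, e in enumerate(est):
        X[r, idx[e.arm_a]] = 1.0
        X[r, idx[e.arm_b]] = -1.0
        y[r] = e.log_effect
        w[r] = 1.0 / e.se**2
    L = X.T @ (w[:, None] * X)
    Lp = np.linalg.pinv(L)
    mu = Lp @ X.T @ (w * y)

    log_mat = mu[:, None] - mu[None, :]
    d = np.diag(Lp)
    var = d[:, None] + d[None, :] - 2 * Lp
    se_mat = np.sqrt(np.clip(var, 0.0, None))

    fitted = X @ mu
    Q = float(np.sum(w * (y - fitted) ** 2))
    df = n - (T - 1)
    # I^2 = 0 whenever Q <= df (small epsilon absorbs float noise in a
    # saturated network, where the fit is exact and Q is 0 up to rounding)
    i2 = 0.0 if Q <= df + 1e-12 else (Q - df) / Q
    return NMAResult(
        endpoint=endpoint,
        treatments=tuple(treatments),
        log_effect_matrix=log_mat,
        se_matrix=se_mat,
        ci_level=ci_level,
        Q=Q,
        df=df,
        i_squared=i2,
    )


def read_evidence(path: str | Path, ci_level: float = 0.95) -> list[EffectEstimate]:
    """Read a trial-evidence CSV into effect estimates.

    Columns: trial, arm_a, arm_b, endpoint, then either (effect, ci_low,
    ci_high) for ratio estimates or (events_a, n_a, events_b, n_b) for 2x2
    counts.  Each row must supply exactly one of the two blocks.
    """
    df = pd.read_csv(path)
    required = {"trial", "arm_a", "arm_b", "endpoint"}
    missing = required - set(df.columns)
    if missing:
        raise EvidenceError(f"evidence file missing column(s): {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        endpoint = str(row["endpoint"])
        if endpoint not in VALID_ENDPOINTS:
            raise EvidenceError(f"unknown endpoint {endpoint!r} in trial {row['trial']!r}")
        has_ratio = "effect" in df.columns and pd.notna(row.get("effect"))
        if has_ratio:
            se = se_from_ci(row["effect"], row["ci_low"], row["ci_high"], ci_level)
            out.append(
                EffectEstimate(
                    str(row["trial"]),
                    str(row["arm_a"]),
                    str(row["arm_b"]),
                    endpoint,
                    float(np.log(row["effect"])),
                    se,
                )
            )
        else:
            out.append(
                log_rr_from_counts(
                    int(row["events_a"]),
                    int(row["n_a"]),
                    int(row["events_b"]),
                    int(row["n_b"]),
                    trial=str(row["trial"]),
                    arm_a=str(row["arm_a"]),
                    arm_b=str(row["arm_b"]),
                    endpoint=endpoint,
                )
            )
    return out
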