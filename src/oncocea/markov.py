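"""Three-state cohort trace: progression-free (PFD), progressed (PD), death.

State occupancy follows the partitioned-survival construction: at the start
of cycle k (time k*delta),

    pfd_k  = S_pfs(k*delta)
    dead_k = 1 - S_os(k*delta)
    pd_k   = S_os(k*delta) - S_pfs(k*delta)   (clamped at 0)

which is the unique three-state structure fully determined by the two
published curve parameter pairs.  The implied per-cycle exit probabilities
are emitted alongside for audit.  The whole cohort starts progression-free
and the trace stops at the first cycle where the death fraction reaches the
termination threshold (99% by default), capped at a long fixed horizon.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import StructuralError
from .survival import WeibullCurve

MAX_CYCLES = 2000  # ~115 years of 21-day cycles; guards non-terminating inputs
CLAMP_TOL = 0.05


@dataclass(frozen=True)
class MarkovTrace:
    """Per-cycle state occupancy plus the implied transition probabilities."""

    cycle_length: float  # months
    time: np.ndarray  # months at cycle start
    pfd: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    p_pfs_exit: np.ndarray  # P(leave PFD during cycle k | in PFD at its start)
    p_os_death: np.ndarray  # P(die during cycle k | alive at its start)

    @property
    def n_cycles(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.n_cycles),
                "time_months": self.time,
                "pfd": self.pfd,
                "pd": self.pd,
                "dead": self.dead,
                "p_pfs_exit": self.p_pfs_exit,
                "p_os_death": self.p_os_death,
            }
        )


def _cycle_probs(curve: WeibullCurve, times: np.ndarray, delta: float) -> np.ndarray:
    # 1 - S(t+delta)/S(t), computed in log space to stay stable in the tail
    log_ratio = curve.scale * (times**curve.shape - (times + delta) ** curve.shape)
    return 1.0 - np.exp(log_ratio)


def run_trace(
    os_curve: WeibullCurve,
    pfs_curve: WeibullCurve,
    cycle_length: float,
    stop_fraction: float = 0.99,
    max_cycles: int = MAX_CYCLES,
    clamp_tol: float = CLAMP_TOL,
) -> MarkovTrace:
    """Run the cohort until ``stop_fraction`` of patients have died.

    Parameters are in months.  Raises :class:`StructuralError` when the PFS
    curve exceeds the OS curve by more than ``clamp_tol`` anywhere on the
    horizon (inconsistent inputs); smaller violations are clamped to zero
    progressed-disease occupancy.
    """
    if not 0 < stop_fraction <= 1:
        raise ValueError(f"stop_fraction must be in (0, 1], got {stop_fraction}")
    if cycle_length <= 0:
        raise ValueError(f"cycle_length must be > 0, got {cycle_length}")

    if stop_fraction == 1.0:
        k_stop = max_cycles
    else:
        t_stop = os_curve.time_at(1.0 - stop_fraction)
        k_stop = min(int(np.ceil(t_stop / cycle_length - 1e-12)), max_cycles)
    times = np.arange(k_stop + 1, dtype=float) * cycle_length
    s_os = os_curve.survival(times)
    s_pfs = pfs_curve.survival(times)

    # end at the FIRST cycle where the death fraction crosses the threshold
    dead = 1.0 - s_os
    crossed = np.nonzero(dead >= stop_fraction)[0]
    if crossed.size:
        end = crossed[0]
        times, s_os, s_pfs, dead = (a[: end + 1] for a in (times, s_os, s_pfs, dead))

    raw_pd = s_os - s_pfs
    if raw_pd.min() < -clamp_tol:
        raise StructuralError(
            "PFS survival exceeds OS survival by more than "
            f"{clamp_tol} (max violation {-raw_pd.min():.4f}); curves inconsistent"
        )
    pd_occ = np.maximum(raw_pd, 0.0)
    pfd = np.minimum(s_pfs, s_os)  # keeps pfd + pd + dead == 1 under clamping

    return MarkovTrace(
        cycle_length=float(cycle_length),
        time=times,
        pfd=pfd,
        pd=pd_occ,
        dead=dead,
        p_pfs_exit=_cycle_probs(pfs_curve, times, cycle_length),
        p_os_death=_cycle_probs(os_curve, times, cycle_length),
    )
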