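"""Three-state Markov cohort engine.

States: progression-free (PF), postprogression (PP), dead.  The cohort
starts fully progression-free and is advanced in fixed 21-day cycles.
Per-cycle transition probabilities are derived from the marginal OS and
PFS survival laws:

* death (from either alive state) uses the conditional per-cycle exit
  probability of the OS curve, floored at the age-specific background
  mortality from a life table (``background_mode="floor"``; an additive
  combination is available behind ``background_mode="add"``);
* progression is the PFS conditional exit probability minus the death
  probability, floored at zero, so the trace's alive total reproduces
  the OS curve exactly.

Under the optimistic cure scenario, cycles starting at or after the cure
time use the background mortality alone.  Discounting is annual,
converted to per-cycle factors; half-cycle correction averages the
state occupancy at the two ends of each cycle.  The final cycle is
truncated so accruals cover exactly the requested horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .parametric_survival import ParametricSurvival
from .synthetic_data import LifeTable

__all__ = [
    "DAYS_PER_MONTH",
    "ModelConfig",
    "CohortTrace",
    "cycle_probability",
    "background_mortality",
    "build_trace",
    "life_years",
]

DAYS_PER_MONTH = 365.25 / 12.0


@dataclass(frozen=True)
class ModelConfig:
    """Cycle structure, horizon, discounting and scenario switches.

    ``horizon_years=None`` means lifetime: run until the alive fraction
    falls below 1e-6 or the cohort reaches age 100.
    """

    cycle_days: float = 21.0
    horizon_years: Optional[float] = 3.0
    discount_rate_annual: float = 0.03
    start_age_years: float = 62.0
    max_treatment_cycles: int = 35
    cure_scenario: bool = False
    cure_time_months: float = 30.0
    half_cycle_correction: bool = True
    background_mode: str = "floor"  # "floor" or "add"

    def __post_init__(self) -> None:
        if self.horizon_years is not None and self.horizon_years <= 0:
            raise ValueError("horizon_years must be > 0 (or None for lifetime)")
        if not (0.0 <= self.discount_rate_annual < 1.0):
            raise ValueError("discount_rate_annual must lie in [0, 1)")
        if self.max_treatment_cycles < 0:
            raise ValueError("max_treatment_cycles must be >= 0")
        if self.cycle_days <= 0:
            raise ValueError("cycle_days must be > 0")
        if self.background_mode not in ("floor", "add"):
            raise ValueError("background_mode must be 'floor' or 'add'")

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / DAYS_PER_MONTH

    def effective_horizon_months(self) -> float:
        if self.horizon_years is not None:
            return self.horizon_years * 12.0
        return (100.0 - self.start_age_years) * 12.0


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy with accrual weights.

    Row c holds the occupancy at the start of cycle c (time c*cycle);
    there are n_cycles+1 rows, the last being the end-of-horizon state.
    ``new_prog``/``new_dead`` are the flows during cycle c (0 in the last
    row); ``cycle_len_months`` is the accrual length of cycle c, with the
    final cycle truncated at the horizon.
    """

    time_months: np.ndarray
    pf: np.ndarray
    pp: np.ndarray
    dead: np.ndarray
    on_treatment: np.ndarray
    discount: np.ndarray
    new_prog: np.ndarray
    new_dead: np.ndarray
    cycle_len_months: np.ndarray
    config: ModelConfig

    @property
    def n_cycles(self) -> int:
        return int(self.time_months.size - 1)

    @property
    def alive(self) -> np.ndarray:
        return self.pf + self.pp

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.time_months.size),
                "time_months": self.time_months,
                "pf": self.pf,
                "pp": self.pp,
                "dead": self.dead,
                "on_treatment": self.on_treatment,
                "discount": self.discount,
            }
        )


def cycle_probability(S: ParametricSurvival, t_months: float, cycle_months: float) -> float:
    """Conditional probability of leaving the curve's state during
    [t, t+cycle): 1 - S(t+cycle)/S(t), clipped to [0, 1]."""
    s_t = S.survival(t_months)
    if s_t <= 0.0:
        return 1.0
    p = 1.0 - S.survival(t_months + cycle_months) / s_t
    return float(min(max(p, 0.0), 1.0))


def background_mortality(life_table: LifeTable, age_years: float, cycle_months: float) -> float:
    """Per-cycle background death probability at an attained age:
    annual q converted through 1 - (1-q)^(cycle/12)."""
    q = life_table.annual_q(age_years)
    if q >= 1.0:
        return 1.0
    return 1.0 - (1.0 - q) ** (cycle_months / 12.0)


def build_trace(
    os_curve: ParametricSurvival,
    pfs_curve: ParametricSurvival,
    life_table: LifeTable,
    config: ModelConfig,
) -> CohortTrace:
    """Run the cohort forward and return the full trace.

    PFS is clipped pointwise to min(PFS, OS) before conditional exit
    probabilities are formed.
    """
    dm = config.cycle_months
    horizon = config.effective_horizon_months()
    n_cycles = int(math.ceil(horizon / dm - 1e-12))
    lifetime = config.horizon_years is None

    bounds = np.arange(n_cycles + 1) * dm
    s_os = np.asarray(os_curve.survival(bounds), dtype=float)
    s_pfs = np.minimum(np.asarray(pfs_curve.survival(bounds), dtype=float), s_os)

    r = config.discount_rate_annual
    discount = (1.0 + r) ** (-(bounds / 12.0))

    pf = np.zeros(n_cycles + 1)
    pp = np.zeros(n_cycles + 1)
    dead = np.zeros(n_cycles + 1)
    new_prog = np.zeros(n_cycles + 1)
    new_dead = np.zeros(n_cycles + 1)
    pf[0] = 1.0

    last = n_cycles
    for c in range(n_cycles):
        t = bounds[c]
        p_os = 1.0 if s_os[c] <= 0 else min(max(1.0 - s_os[c + 1] / s_os[c], 0.0), 1.0)
        bg = background_mortality(life_table, config.start_age_years + t / 12.0, dm)
        if config.cure_scenario and t >= config.cure_time_months - 1e-9:
            p_death = bg
        elif config.background_mode == "floor":
            p_death = max(p_os, bg)
        else:
            p_death = 1.0 - (1.0 - p_os) * (1.0 - bg)
        p_exit_pf = 1.0 if s_pfs[c] <= 0 else min(max(1.0 - s_pfs[c + 1] / s_pfs[c], 0.0), 1.0)
        p_prog = min(max(p_exit_pf - p_death, 0.0), 1.0 - p_death)

        new_prog[c] = pf[c] * p_prog
        new_dead[c] = (pf[c] + pp[c]) * p_death
        pf[c + 1] = pf[c] * (1.0 - p_prog - p_death)
        pp[c + 1] = pp[c] * (1.0 - p_death) + pf[c] * p_prog
        dead[c + 1] = dead[c] + new_dead[c]
        if lifetime and pf[c + 1] + pp[c + 1] < 1e-6:
            last = c + 1
            break

    sl = slice(0, last + 1)
    cycle_len = np.full(last + 1, dm)
    cycle_len[-1] = 0.0
    if not lifetime:
        # truncate the final cycle so total accrual time equals the horizon
        cycle_len[last - 1] = horizon - bounds[last - 1]

    on_treatment = np.where(np.arange(last + 1) < config.max_treatment_cycles, pf[sl], 0.0)
    on_treatment[-1] = 0.0

    return CohortTrace(
        time_months=bounds[sl],
        pf=pf[sl],
        pp=pp[sl],
        dead=dead[sl],
        on_treatment=on_treatment,
        discount=discount[sl],
        new_prog=new_prog[sl],
        new_dead=new_dead[sl],
        cycle_len_months=cycle_len,
        config=config,
    )


def _accrual_weights(trace: CohortTrace, occupancy: np.ndarray) -> np.ndarray:
    """Per-cycle occupancy used for time-in-state accruals: trapezoidal
    (half-cycle corrected) or start-of-cycle, per the trace's config."""
    if trace.config.half_cycle_correction:
        return 0.5 * (occupancy[:-1] + occupancy[1:])
    return occupancy[:-1]


def life_years(trace: CohortTrace, discounted: bool = True) -> float:
    """Total (optionally discounted) life-years accrued over the trace."""
    occ = _accrual_weights(trace, trace.alive)
    years = trace.cycle_len_months[:-1] / 12.0
    df = trace.discount[:-1] if discounted else 1.0
    return float(np.sum(occ * years * df))
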