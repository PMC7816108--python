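"""Cost and QALY accrual over a cohort trace, and incremental
cost-effectiveness comparison of two strategies.

Cost components per arm:

* drug + administration: per cycle, paid at the start of each cycle for
  the progression-free fraction still on treatment (capped at the
  maximum number of treatment cycles); dispensed doses are whole, so
  these are start-of-cycle payments and not half-cycle corrected;
* postprogression therapy: each newly progressing patient triggers, with
  the arm's treated fraction, a fixed-duration per-cycle cost stream
  discounted from the progression cycle;
* one-time adverse-event costs and QALY decrements applied up front;
* an end-of-life cost per death (default 0 and equal across arms).

QALYs weight half-cycle-corrected time in state by the state utilities.
All accruals are discounted with the trace's per-cycle factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .markov_engine import CohortTrace, ModelConfig, _accrual_weights
from .parametric_survival import ParametricSurvival

__all__ = ["AdverseEvent", "ArmParameters", "ArmOutcome", "CEAResult", "accrue", "compare", "net_monetary_benefit"]


@dataclass(frozen=True)
class AdverseEvent:
    """One grade-3/4 toxicity: per-patient probability, one-time cost (USD)
    and one-time utility decrement (QALYs)."""

    probability: float
    cost: float = 0.0
    qaly_decrement: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("AE probability must lie in [0, 1]")
        if self.cost < 0 or self.qaly_decrement < 0:
            raise ValueError("AE cost and decrement must be >= 0")


@dataclass(frozen=True)
class ArmParameters:
    """Economic and clinical inputs for one strategy."""

    name: str
    os_curve: ParametricSurvival
    pfs_curve: ParametricSurvival
    drug_cost_per_cycle: float = 0.0
    admin_cost_per_cycle: float = 150.0
    utility_pf: float = 0.76
    utility_pp: float = 0.68
    postprog_treated_fraction: float = 0.0
    postprog_cost_per_cycle: float = 0.0
    postprog_duration_cycles: int = 6
    eol_cost: float = 0.0
    ae_profile: Tuple[AdverseEvent, ...] = ()

    def __post_init__(self) -> None:
        for nm in ("drug_cost_per_cycle", "admin_cost_per_cycle", "postprog_cost_per_cycle", "eol_cost"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        for nm in ("utility_pf", "utility_pp"):
            u = getattr(self, nm)
            if not (0.0 <= u <= 1.0):
                raise ValueError(f"{nm}={u} must lie in [0, 1]")
        if not (0.0 <= self.postprog_treated_fraction <= 1.0):
            raise ValueError("postprog_treated_fraction must lie in [0, 1]")
        if self.postprog_duration_cycles < 0:
            raise ValueError("postprog_duration_cycles must be >= 0")
        object.__setattr__(self, "ae_profile", tuple(self.ae_profile))


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted totals for one arm."""

    name: str
    total_cost: float
    life_years: float
    qalys: float


@dataclass(frozen=True)
class CEAResult:
    """Paired-arm summary: per-arm totals, incrementals and ICERs.

    ICER fields are present only when the incremental QALY (or LY) and
    incremental cost are both positive; otherwise ``dominance`` explains
    the configuration ('intervention dominant', 'intervention dominated',
    'equivalent', or 'cost saving, less effective').
    """

    reference: ArmOutcome
    intervention: ArmOutcome
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_ly: Optional[float]
    icer_per_qaly: Optional[float]
    dominance: Optional[str]

    def summary(self) -> str:
        rows = [
            ("", self.reference.name, self.intervention.name),
            ("Total cost, $", f"{self.reference.total_cost:,.0f}", f"{self.intervention.total_cost:,.0f}"),
            ("Life-years", f"{self.reference.life_years:.3f}", f"{self.intervention.life_years:.3f}"),
            ("QALYs", f"{self.reference.qalys:.3f}", f"{self.intervention.qalys:.3f}"),
            ("Incremental cost, $", "", f"{self.delta_cost:,.0f}"),
            ("Incremental LY", "", f"{self.delta_ly:.3f}"),
            ("Incremental QALY", "", f"{self.delta_qaly:.3f}"),
            ("ICER, $/LY", "NA", f"{self.icer_per_ly:,.0f}" if self.icer_per_ly is not None else str(self.dominance)),
            ("ICER, $/QALY", "NA", f"{self.icer_per_qaly:,.0f}" if self.icer_per_qaly is not None else str(self.dominance)),
        ]
        w = max(len(r[0]) for r in rows) + 2
        return "\n".join(f"{r[0]:<{w}}{r[1]:>14}{r[2]:>16}" for r in rows)


def accrue(trace: CohortTrace, arm: ArmParameters, config: ModelConfig) -> ArmOutcome:
    """Accrue discounted cost, life-years and QALYs for one arm."""
    if trace.config != config:
        raise ValueError("trace was built with a different model configuration")
    df = trace.discount[:-1]
    years = trace.cycle_len_months[:-1] / 12.0

    # drug + administration at cycle starts while on treatment
    cost = float(np.sum(trace.on_treatment[:-1] * (arm.drug_cost_per_cycle + arm.admin_cost_per_cycle) * df))

    # postprogression therapy: fixed-duration stream per newly progressed patient
    if arm.postprog_treated_fraction > 0 and arm.postprog_cost_per_cycle > 0:
        dur = arm.postprog_duration_cycles
        df_cum = np.concatenate([[0.0], np.cumsum(trace.discount)])  # df_cum[k] = sum of discount[0:k]
        n = trace.discount.size
        stream = np.array([df_cum[min(c + dur, n)] - df_cum[c] for c in range(n - 1)])
        cost += float(
            arm.postprog_treated_fraction
            * arm.postprog_cost_per_cycle
            * np.sum(trace.new_prog[:-1] * stream)
        )

    if arm.eol_cost > 0:
        cost += float(arm.eol_cost * np.sum(trace.new_dead[:-1] * df))

    ae_cost = sum(ae.probability * ae.cost for ae in arm.ae_profile)
    ae_decrement = sum(ae.probability * ae.qaly_decrement for ae in arm.ae_profile)
    cost += ae_cost

    ly = float(np.sum(_accrual_weights(trace, trace.alive) * years * df))
    qaly = float(
        np.sum(
            (_accrual_weights(trace, trace.pf) * arm.utility_pf
             + _accrual_weights(trace, trace.pp) * arm.utility_pp)
            * years
            * df
        )
    ) - ae_decrement

    return ArmOutcome(name=arm.name, total_cost=cost, life_years=ly, qalys=qaly)


_EPS = 1e-12


def compare(reference: ArmOutcome, intervention: ArmOutcome) -> CEAResult:
    """Incremental comparison (intervention minus reference)."""
    d_cost = intervention.total_cost - reference.total_cost
    d_ly = intervention.life_years - reference.life_years
    d_qaly = intervention.qalys - reference.qalys

    icer_ly = icer_qaly = None
    dominance = None
    if abs(d_cost) < 1e-6 and abs(d_qaly) < _EPS:
        dominance = "equivalent"
    elif d_qaly > _EPS and d_cost > 0:
        icer_qaly = d_cost / d_qaly
        icer_ly = d_cost / d_ly if d_ly > _EPS else None
    elif d_qaly > _EPS and d_cost <= 0:
        dominance = "intervention dominant"
    elif d_qaly <= _EPS and d_cost > 0:
        dominance = "intervention dominated"
    else:
        dominance = "cost saving, less effective"

    return CEAResult(
        reference=reference,
        intervention=intervention,
        delta_cost=d_cost,
        delta_ly=d_ly,
        delta_qaly=d_qaly,
        icer_per_ly=icer_ly,
        icer_per_qaly=icer_qaly,
        dominance=dominance,
    )


def net_monetary_benefit(result: CEAResult, wtp: float) -> float:
    """NMB = WTP * incremental QALY - incremental cost; positive iff the
    intervention is cost-effective at that willingness-to-pay."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * result.delta_qaly - result.delta_cost
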