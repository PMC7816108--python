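"""Sensitivity, threshold, scenario and subgroup analyses over the base
cost-effectiveness model.

The unit of work is a :class:`CEAModel` — the model configuration, the
two arms (reference first) and a life table — whose :meth:`CEAModel.run`
builds both cohort traces and returns the incremental comparison.
Parameters are addressed by dotted paths (``"pembrolizumab.drug_cost_per_cycle"``,
``"model.discount_rate_annual"``, ``"shared.utility_pp"``); the special
path ``"hr_os"`` re-derives the intervention's OS curve from the
reference curve by proportional hazards with a shared Weibull shape, and
``"<arm>.median_os"`` / ``"<arm>.median_pfs"`` recalibrate a curve to a
new median at its current shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .economics import ArmParameters, CEAResult, accrue, compare
from .markov_engine import ModelConfig, build_trace
from .parametric_survival import ParametricSurvival, calibrate_weibull
from .synthetic_data import LifeTable

__all__ = [
    "CEAModel",
    "ParameterSpec",
    "TornadoRow",
    "CEACPoint",
    "one_way",
    "two_way",
    "psa",
    "PSAResult",
    "threshold_price",
    "run_scenario",
    "subgroup",
    "ICER_CAP",
]

# Display/sorting cap for ICERs when the incremental QALY approaches 0
ICER_CAP = 2_000_000.0

DEFAULT_WTP = 150_000.0


@dataclass(frozen=True)
class CEAModel:
    """Base model context: configuration, reference and intervention arms,
    and the background-mortality life table."""

    config: ModelConfig
    reference: ArmParameters
    intervention: ArmParameters
    life_table: LifeTable
    hr_os: float = 0.78  # intervention-vs-reference OS hazard ratio (for PSA/subgroups)

    def run(self) -> CEAResult:
        ref_trace = build_trace(self.reference.os_curve, self.reference.pfs_curve, self.life_table, self.config)
        int_trace = build_trace(self.intervention.os_curve, self.intervention.pfs_curve, self.life_table, self.config)
        return compare(
            accrue(ref_trace, self.reference, self.config),
            accrue(int_trace, self.intervention, self.config),
        )

    def icer(self, cap: float = ICER_CAP) -> float:
        """ICER per QALY, capped when the incremental QALY is ~0 or the
        intervention is dominated; negative increments map to the cap
        (never cost-effective) or 0 (dominant)."""
        res = self.run()
        if res.icer_per_qaly is not None:
            return min(res.icer_per_qaly, cap)
        if res.dominance == "intervention dominant":
            return 0.0
        return cap

    # -- parameter plumbing ---------------------------------------------

    def set_param(self, path: str, value: float) -> "CEAModel":
        """Return a copy with one dotted-path parameter replaced."""
        if path == "hr_os":
            new_os = calibrate_weibull(None, hazard_ratio=value, reference=self.reference.os_curve)
            return replace(
                self,
                hr_os=float(value),
                intervention=replace(self.intervention, os_curve=new_os),
            )
        section, _, name = path.partition(".")
        if not name:
            raise KeyError(f"parameter path {path!r} must be 'section.name' or 'hr_os'")
        if section == "model":
            if not hasattr(self.config, name):
                raise KeyError(f"unknown model parameter {name!r}")
            return replace(self, config=replace(self.config, **{name: value}))
        if section == "shared":
            return self._set_arm("reference", name, value)._set_arm("intervention", name, value)
        for role, arm in (("reference", self.reference), ("intervention", self.intervention)):
            if arm.name == section:
                return self._set_arm(role, name, value)
        raise KeyError(f"unknown parameter section {section!r}")

    def _set_arm(self, role: str, name: str, value: float) -> "CEAModel":
        arm: ArmParameters = getattr(self, role)
        if name in ("median_os", "median_pfs"):
            attr = "os_curve" if name == "median_os" else "pfs_curve"
            curve: ParametricSurvival = getattr(arm, attr)
            new_curve = calibrate_weibull(float(value), shape=float(curve.params.get("shape", 1.0)))
            return replace(self, **{role: replace(arm, **{attr: new_curve})})
        if not hasattr(arm, name):
            raise KeyError(f"unknown arm parameter {name!r}")
        return replace(self, **{role: replace(arm, **{name: value})})

    def get_param(self, path: str) -> float:
        if path == "hr_os":
            return self.hr_os
        section, _, name = path.partition(".")
        if section == "model":
            return getattr(self.config, name)
        for arm in (self.reference, self.intervention):
            if arm.name == section or section == "shared":
                if name == "median_os":
                    return arm.os_curve.median()
                if name == "median_pfs":
                    return arm.pfs_curve.median()
                return getattr(arm, name)
        raise KeyError(path)


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain parameter: dotted path, base value, low/high range
    (printed CI where available, otherwise +/-20% of base) and an optional
    PSA distribution ('beta', 'gamma', 'lognormal' or 'uniform')."""

    path: str
    base: float
    low: float
    high: float
    distribution: Optional[str] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"{self.path}: need low <= base <= high, got {self.low}, {self.base}, {self.high}")
        if self.distribution is not None and self.distribution not in ("beta", "gamma", "lognormal", "uniform"):
            raise ValueError(f"unknown PSA distribution {self.distribution!r}")
        if self.label is None:
            object.__setattr__(self, "label", self.path)

    # -- PSA sampling ---------------------------------------------------

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Seeded draws; (low, high) is treated as a 95% interval for the
        method-of-moments beta/gamma/lognormal parameterizations."""
        if self.distribution is None:
            raise ValueError(f"{self.path} has no PSA distribution")
        if self.high == self.low:
            return np.full(size, self.base)
        sd = (self.high - self.low) / (2.0 * 1.959964)
        mean = self.base
        if self.distribution == "uniform":
            return rng.uniform(self.low, self.high, size)
        if self.distribution == "beta":
            v = sd**2
            v = min(v, mean * (1.0 - mean) * 0.999) if 0 < mean < 1 else v
            nu = mean * (1.0 - mean) / v - 1.0
            return rng.beta(mean * nu, (1.0 - mean) * nu, size)
        if self.distribution == "gamma":
            shape = (mean / sd) ** 2
            return rng.gamma(shape, sd**2 / mean, size)
        # lognormal: mean on the log scale from the geometric midpoint of the CI
        mu = 0.5 * (math.log(self.low) + math.log(self.high))
        sigma = (math.log(self.high) - math.log(self.low)) / (2.0 * 1.959964)
        return rng.lognormal(mu, sigma, size)

    def domain(self) -> Tuple[float, float]:
        if self.distribution == "beta":
            return (0.0, 1.0)
        if self.distribution in ("gamma", "lognormal"):
            return (0.0, math.inf)
        return (-math.inf, math.inf)


# ---------------------------------------------------------------------------
# one-way / two-way
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoRow:
    parameter: str
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def one_way(specs: Sequence[ParameterSpec], model: CEAModel) -> list[TornadoRow]:
    """Recompute the ICER at each parameter's low and high bound with all
    other parameters at base; rows sorted by spread, widest first."""
    rows = []
    for spec in specs:
        rows.append(
            TornadoRow(
                parameter=spec.label,
                icer_at_low=model.set_param(spec.path, spec.low).icer(),
                icer_at_high=model.set_param(spec.path, spec.high).icer(),
            )
        )
    return sorted(rows, key=lambda r: -r.spread)


def two_way(
    spec_a: ParameterSpec,
    spec_b: ParameterSpec,
    model: CEAModel,
    grid_n: int = 5,
    wtp: float = DEFAULT_WTP,
):
    """ICER over a grid of two parameters.

    Returns (a_values, b_values, icer_grid, cost_effective_grid) with
    ``icer_grid[i, j]`` evaluated at a_values[i], b_values[j].
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    a_vals = np.linspace(spec_a.low, spec_a.high, grid_n)
    b_vals = np.linspace(spec_b.low, spec_b.high, grid_n)
    grid = np.empty((grid_n, grid_n))
    for i, a in enumerate(a_vals):
        m_a = model.set_param(spec_a.path, float(a))
        for j, b in enumerate(b_vals):
            grid[i, j] = m_a.set_param(spec_b.path, float(b)).icer()
    return a_vals, b_vals, grid, grid <= wtp


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    prob_cost_effective: float


@dataclass(frozen=True)
class PSAResult:
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    ceac: Tuple[CEACPoint, ...]
    n_resampled: int

    def prob_cost_effective(self, wtp: float) -> float:
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost > 0.0))


def psa(
    specs: Sequence[ParameterSpec],
    model: CEAModel,
    n_draws: int = 10_000,
    seed: int = 1,
    wtp_grid: Optional[Sequence[float]] = None,
) -> PSAResult:
    """Monte Carlo PSA: joint independent draws of all parameters, one
    model run per draw, and the acceptability curve over a WTP grid.

    Draws falling outside a parameter's domain (e.g. a utility above 1)
    are rejected and redrawn; the count of resampled values is reported.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    for spec in specs:
        if spec.distribution is None:
            raise ValueError(f"PSA requires a distribution for every parameter ({spec.path} has none)")
    rng = np.random.default_rng(seed)
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 500_001.0, 10_000.0)

    draws: Dict[str, np.ndarray] = {}
    n_resampled = 0
    for spec in specs:
        x = spec.sample(rng, n_draws)
        lo, hi = spec.domain()
        bad = (x < lo) | (x > hi) | ~np.isfinite(x)
        while bad.any():
            n_resampled += int(bad.sum())
            x[bad] = spec.sample(rng, int(bad.sum()))
            bad = (x < lo) | (x > hi) | ~np.isfinite(x)
        draws[spec.path] = x

    d_cost = np.empty(n_draws)
    d_qaly = np.empty(n_draws)
    for k in range(n_draws):
        m = model
        for path, x in draws.items():
            m = m.set_param(path, float(x[k]))
        res = m.run()
        d_cost[k] = res.delta_cost
        d_qaly[k] = res.delta_qaly

    ceac = tuple(
        CEACPoint(float(w), float(np.mean(w * d_qaly - d_cost > 0.0))) for w in wtp_grid
    )
    return PSAResult(delta_cost=d_cost, delta_qaly=d_qaly, ceac=ceac, n_resampled=n_resampled)


# ---------------------------------------------------------------------------
# threshold, scenarios, subgroups
# ---------------------------------------------------------------------------


def threshold_price(
    model: CEAModel,
    target_wtp: float = DEFAULT_WTP,
    price_path: str = None,
    bracket: Tuple[float, float] = None,
    tol: float = 1.0,
) -> Tuple[float, float]:
    """Bisection on a per-cycle price until the ICER hits the target WTP.

    Returns (price, percent reduction from the current price).  The ICER
    is increasing in price, so a valid bracket has ICER(low) < target <
    ICER(high).
    """
    if price_path is None:
        price_path = f"{model.intervention.name}.drug_cost_per_cycle"
    base_price = float(model.get_param(price_path))
    if bracket is None:
        bracket = (0.0, max(base_price, 1.0))
    lo, hi = bracket

    def icer_at(p: float) -> float:
        return model.set_param(price_path, p).icer(cap=math.inf)

    f_lo, f_hi = icer_at(lo) - target_wtp, icer_at(hi) - target_wtp
    if f_lo >= 0 or f_hi <= 0:
        raise ValueError(
            f"no sign change in bracket: ICER({lo})={f_lo + target_wtp:,.0f}, "
            f"ICER({hi})={f_hi + target_wtp:,.0f}, target {target_wtp:,.0f}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = icer_at(mid) - target_wtp
        if abs(f_mid) < tol:
            lo = hi = mid
            break
        if f_mid > 0:
            hi = mid
        else:
            lo = mid
    price = 0.5 * (lo + hi)
    return price, 100.0 * (base_price - price) / base_price


SCENARIOS = ("cure_30mo", "dose_400q6w", "horizon")


def run_scenario(name: str, model: CEAModel, horizon_years: Optional[float] = 3.0, **overrides) -> CEAResult:
    """Named scenario analyses.

    * ``cure_30mo`` — survivors past 30 months face background mortality
      only, in both arms;
    * ``dose_400q6w`` — 400 mg every 6 weeks: the same drug cost per unit
      time (2x the per-3-week price per administration) with half as many
      administration visits, i.e. administration cost halved per 3-week
      cycle; clinical curves unchanged;
    * ``horizon`` — override the time horizon (``horizon_years=None``
      means lifetime: run until the alive fraction is < 1e-6 or age 100).
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    m = model
    if name == "cure_30mo":
        m = replace(m, config=replace(m.config, cure_scenario=True, cure_time_months=overrides.get("cure_time_months", 30.0)))
    elif name == "dose_400q6w":
        m = replace(
            m,
            intervention=replace(
                m.intervention,
                admin_cost_per_cycle=m.intervention.admin_cost_per_cycle / 2.0,
            ),
        )
    else:
        m = replace(m, config=replace(m.config, horizon_years=horizon_years))
    return m.run()


def subgroup(hr_os: float, model: CEAModel) -> CEAResult:
    """Re-run the CEA for a subgroup OS hazard ratio: the reference OS is
    fixed and the intervention OS is rescaled from it under proportional
    hazards with the shared Weibull shape."""
    if hr_os <= 0:
        raise ValueError("hr_os must be > 0")
    return model.set_param("hr_os", hr_os).run()
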