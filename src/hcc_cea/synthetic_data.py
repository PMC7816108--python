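"""Synthetic trial-data generator.

Emulates every upstream input the pipeline needs — patient-level
event/censoring times, digitized KM curve coordinates, number-at-risk
tables and a background-mortality life table — from known ground-truth
survival laws, so the reconstruction and fitting stages can be tested
against the truth that generated them.

The default simulation emulates a KEYNOTE-240-like two-arm trial:
pembrolizumab vs placebo in a 2:1 ratio, Weibull overall survival with
medians 13.9 / 10.6 months (pembrolizumab 30-month survival 25%, implying
a shape near 0.90 and an OS hazard ratio near 0.78), short progression-free
survival (medians ~3 months), uniform accrual over 18 months and
administrative censoring at a fixed data cutoff.

Per patient, progression-free and death times are drawn comonotonically
(one shared uniform through each law's inverse survival), so both
marginals are exactly the generating laws and progression never follows
death.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .km_ipd import DigitizedCurve, PseudoIPD, RiskTable, km_estimate
from .parametric_survival import ParametricSurvival, calibrate_weibull

__all__ = [
    "SimulationSpec",
    "LifeTable",
    "simulate_ipd",
    "digitize_curve",
    "make_risk_table",
    "default_life_table",
    "keynote240_like_spec",
]


@dataclass(frozen=True)
class LifeTable:
    """Annual probability of death by integer age, for background mortality."""

    age: np.ndarray
    annual_death_prob: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.age, dtype=int)
        q = np.asarray(self.annual_death_prob, dtype=float)
        if a.size == 0 or a.size != q.size:
            raise ValueError("life table needs equal-length, nonempty arrays")
        if np.any(np.diff(a) != 1):
            raise ValueError("ages must be strictly increasing and contiguous")
        if np.any((q < 0) | (q > 1)):
            raise ValueError("annual death probabilities must lie in [0, 1]")
        object.__setattr__(self, "age", a)
        object.__setattr__(self, "annual_death_prob", q)

    def annual_q(self, age_years: float) -> float:
        """Annual death probability at an attained (possibly fractional) age,
        clamped to the table's range."""
        idx = int(np.clip(np.floor(age_years), self.age[0], self.age[-1]) - self.age[0])
        return float(self.annual_death_prob[idx])

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.age, "annual_death_prob": self.annual_death_prob}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(df["age"].to_numpy(), df["annual_death_prob"].to_numpy())


def default_life_table(age_lo: int = 60, age_hi: int = 100, q_lo: float = 0.011, q_hi: float = 0.30) -> LifeTable:
    """Approximate US all-cause life table: annual death probability rising
    geometrically from ``q_lo`` at ``age_lo`` to ``q_hi`` at ``age_hi``
    (Gompertz-like)."""
    ages = np.arange(age_lo, age_hi + 1)
    frac = (ages - age_lo) / (age_hi - age_lo)
    q = q_lo * (q_hi / q_lo) ** frac
    return LifeTable(ages, q)


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth for a two-arm survival simulation.

    ``os_params``/``pfs_params`` map arm name -> family parameter dict;
    ``n_per_arm`` is one count for all arms or a per-arm mapping.
    """

    os_family: Mapping[str, str]
    os_params: Mapping[str, Mapping[str, float]]
    pfs_family: Mapping[str, str]
    pfs_params: Mapping[str, Mapping[str, float]]
    n_per_arm: Union[int, Mapping[str, int]]
    accrual_months: float = 18.0
    cutoff_months: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        ns = (
            [self.n_per_arm]
            if isinstance(self.n_per_arm, int)
            else list(self.n_per_arm.values())
        )
        if any(n < 1 for n in ns):
            raise ValueError("n_per_arm must be >= 1")
        if self.cutoff_months <= 0:
            raise ValueError("cutoff_months must be > 0")
        if self.accrual_months < 0:
            raise ValueError("accrual_months must be >= 0")

    def n_for(self, arm: str) -> int:
        return self.n_per_arm if isinstance(self.n_per_arm, int) else int(self.n_per_arm[arm])

    def curve(self, endpoint: str, arm: str) -> ParametricSurvival:
        endpoint = endpoint.upper()
        if endpoint == "OS":
            fam, par = self.os_family, self.os_params
        elif endpoint == "PFS":
            fam, par = self.pfs_family, self.pfs_params
        else:
            raise ValueError(f"endpoint must be OS or PFS, got {endpoint!r}")
        if arm not in fam:
            raise ValueError(f"unknown arm {arm!r}")
        return ParametricSurvival(fam[arm], par[arm])


def keynote240_like_spec(seed: int = 0, n_pembro: int = 278, n_placebo: int = 135) -> SimulationSpec:
    """Default two-arm spec mirroring the published trial summaries."""
    os_pem = calibrate_weibull(13.9, landmark=(30.0, 0.25))
    os_pla = calibrate_weibull(10.6, shape=os_pem.params["shape"])
    pfs_pem = calibrate_weibull(3.0, shape=1.2)
    pfs_pla = calibrate_weibull(2.8, shape=1.2)
    return SimulationSpec(
        os_family={"pembrolizumab": "weibull", "placebo": "weibull"},
        os_params={"pembrolizumab": os_pem.params, "placebo": os_pla.params},
        pfs_family={"pembrolizumab": "weibull", "placebo": "weibull"},
        pfs_params={"pembrolizumab": pfs_pem.params, "placebo": pfs_pla.params},
        n_per_arm={"pembrolizumab": n_pembro, "placebo": n_placebo},
        accrual_months=18.0,
        cutoff_months=30.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _rng_for(seed: int, *labels: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, label...) combination."""
    spawn = [zlib.crc32(lbl.encode()) for lbl in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *spawn]))


def _inverse_survival(curve: ParametricSurvival, u: np.ndarray) -> np.ndarray:
    """Draw event times by inversion: t = S^{-1}(u), u ~ U(0,1)."""
    from scipy import stats

    p = curve.params
    if curve.family == "exponential":
        return -p["scale"] * np.log(u)
    if curve.family == "weibull":
        return p["scale"] * (-np.log(u)) ** (1.0 / p["shape"])
    if curve.family == "loglogistic":
        return p["scale"] * ((1.0 - u) / u) ** (1.0 / p["shape"])
    return np.exp(p["mu"] + p["sigma"] * stats.norm.isf(u))


def simulate_ipd(spec: SimulationSpec, endpoint: str, arm: str) -> PseudoIPD:
    """Simulate observed (time, event) records for one arm and endpoint.

    OS and PFS times for the same (seed, arm) are drawn comonotonically —
    one shared uniform per patient through each law's inverse survival —
    so both marginals are exact and, because the PFS law lies below the
    OS law, progression never follows death; a max() guard covers any
    residual crossing.  Entry is uniform over the accrual window;
    follow-up is administratively censored at the cutoff.
    """
    endpoint = endpoint.upper()
    if endpoint not in ("OS", "PFS"):
        raise ValueError(f"endpoint must be OS or PFS, got {endpoint!r}")
    n = spec.n_for(arm)
    rng_event = _rng_for(spec.seed, "event", arm)
    rng_entry = _rng_for(spec.seed, "entry", arm)

    u = rng_event.uniform(size=n)
    t_pfs = _inverse_survival(spec.curve("PFS", arm), u)
    t_os = np.maximum(_inverse_survival(spec.curve("OS", arm), u), t_pfs)
    t_true = t_os if endpoint == "OS" else t_pfs

    entry = rng_entry.uniform(0.0, spec.accrual_months, size=n)
    censor = np.maximum(spec.cutoff_months - entry, 1e-6)
    event = (t_true <= censor).astype(int)
    time = np.where(event == 1, t_true, censor)
    time = np.maximum(time, 1e-9)
    return PseudoIPD(time, event, arm=arm, endpoint=endpoint)


def digitize_curve(
    ipd: PseudoIPD,
    grid_step_months: float,
    jitter_sd: float = 0.0,
    seed: int = 0,
    horizon_months: float | None = None,
) -> DigitizedCurve:
    """Emulate graph digitization: sample the KM estimate on a regular time
    grid and optionally perturb it with clipped, re-monotonized Gaussian
    jitter.  ``jitter_sd=0`` reproduces the exact KM step values."""
    if grid_step_months <= 0:
        raise ValueError("grid_step_months must be > 0")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    km = km_estimate(ipd)
    horizon = float(ipd.time_months.max()) if horizon_months is None else float(horizon_months)
    grid = np.arange(0.0, horizon + grid_step_months / 2.0, grid_step_months)
    s = km.at(grid).astype(float)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        s = s + rng.normal(0.0, jitter_sd, size=s.size)
        s[0] = min(s[0], 1.0)
        s = np.clip(s, 0.0, 1.0)
        from sklearn.isotonic import IsotonicRegression

        s = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0).fit_transform(
            np.arange(s.size), s
        )
    # strictly increasing times guaranteed by the grid
    return DigitizedCurve(grid, s)


def make_risk_table(ipd: PseudoIPD, interval_months: float) -> RiskTable:
    """Number of patients still at risk at each interval start."""
    if interval_months <= 0:
        raise ValueError("interval_months must be > 0")
    horizon = float(ipd.time_months.max())
    times = np.arange(0.0, horizon + interval_months / 2.0, interval_months)
    n_risk = np.array([(ipd.time_months >= t).sum() for t in times], dtype=int)
    return RiskTable(times, n_risk)
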