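"""Parametric survival laws: maximum-likelihood fitting, AIC selection,
and direct calibration of Weibull curves from published summary statistics.

Four families are supported, all parameterized through their survival
function S(t) for t in months:

* ``exponential``  S(t) = exp(-t / scale)
* ``weibull``      S(t) = exp(-(t / scale) ** shape)
* ``loglogistic``  S(t) = 1 / (1 + (t / scale) ** shape)
* ``lognormal``    S(t) = 1 - Phi((log t - mu) / sigma)

Fitting under right censoring is delegated to :mod:`lifelines`; the
log-likelihood stored on the result is recomputed from the fitted
parameters with the closed-form density/survival expressions so that AIC
comparisons are internally consistent across families.

A Weibull can also be *calibrated* rather than fitted, from any of:
a median plus a landmark survival probability (two equations, two
unknowns, closed form), a median plus a fixed shape, or a reference
curve plus a proportional-hazards ratio.  This is how published medians,
landmark survival and hazard ratios are turned into model inputs when
patient-level data are unavailable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "FAMILIES",
    "ParametricSurvival",
    "fit",
    "aic_select",
    "calibrate_weibull",
    "survival_at",
]

# Declared family order; also the tie-break order for AIC selection.
FAMILIES: Tuple[str, ...] = ("exponential", "weibull", "loglogistic", "lognormal")

_N_PARAMS = {"exponential": 1, "weibull": 2, "loglogistic": 2, "lognormal": 2}


class FitError(RuntimeError):
    """Raised when an MLE fit fails to converge."""


@dataclass(frozen=True)
class ParametricSurvival:
    """A survival law: family name plus family-specific parameters.

    ``loglik`` is present only for fitted curves (calibrated curves carry
    ``None``); ``n`` is the number of records the fit used.
    """

    family: str
    params: Mapping[str, float]
    loglik: Optional[float] = None
    n: Optional[int] = None
    n_params: int = field(default=0)

    def __post_init__(self) -> None:
        if self.family not in _N_PARAMS:
            raise ValueError(f"unknown survival family {self.family!r}")
        object.__setattr__(self, "params", dict(self.params))
        object.__setattr__(self, "n_params", _N_PARAMS[self.family])
        for name, value in self.params.items():
            if name not in ("mu",) and value <= 0:
                raise ValueError(f"{self.family} parameter {name}={value} must be > 0")

    # -- evaluation -----------------------------------------------------

    def survival(self, t) -> np.ndarray | float:
        """S(t) for scalar or array t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival is defined for t >= 0 only")
        p = self.params
        with np.errstate(divide="ignore"):
            if self.family == "exponential":
                s = np.exp(-t / p["scale"])
            elif self.family == "weibull":
                s = np.exp(-((t / p["scale"]) ** p["shape"]))
            elif self.family == "loglogistic":
                s = 1.0 / (1.0 + (t / p["scale"]) ** p["shape"])
            else:  # lognormal
                s = np.where(
                    t > 0,
                    stats.norm.sf((np.log(np.where(t > 0, t, 1.0)) - p["mu"]) / p["sigma"]),
                    1.0,
                )
        return float(s) if s.ndim == 0 else s

    def median(self) -> float:
        p = self.params
        if self.family == "exponential":
            return p["scale"] * math.log(2.0)
        if self.family == "weibull":
            return p["scale"] * math.log(2.0) ** (1.0 / p["shape"])
        if self.family == "loglogistic":
            return p["scale"]
        return math.exp(p["mu"])

    @property
    def aic(self) -> float:
        if self.loglik is None:
            raise ValueError("AIC undefined: curve was calibrated, not fitted")
        return 2.0 * self.n_params - 2.0 * self.loglik

    # -- (de)serialization ----------------------------------------------

    def to_json(self) -> str:
        out = {"family": self.family, "params": dict(self.params), "n": self.n}
        if self.loglik is not None:
            out["loglik"] = self.loglik
            out["aic"] = self.aic
        return json.dumps(out, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ParametricSurvival":
        d = json.loads(text)
        return cls(family=d["family"], params=d["params"], loglik=d.get("loglik"), n=d.get("n"))


def survival_at(curve: ParametricSurvival, t_months) -> float | np.ndarray:
    """Evaluate S(t) of a survival law at one or more times (months)."""
    return curve.survival(t_months)


# ---------------------------------------------------------------------------
# log-likelihood under right censoring
# ---------------------------------------------------------------------------


def _log_likelihood(family: str, params: Mapping[str, float], time, event) -> float:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    if family == "exponential":
        rate = 1.0 / params["scale"]
        return float(np.sum(e * np.log(rate) - rate * t))
    if family == "weibull":
        k, s = params["shape"], params["scale"]
        z = t / s
        log_h = np.log(k / s) + (k - 1.0) * np.log(z)
        return float(np.sum(e * log_h - z**k))
    if family == "loglogistic":
        b, a = params["shape"], params["scale"]
        z = (t / a) ** b
        log_pdf = np.log(b / a) + (b - 1.0) * np.log(t / a) - 2.0 * np.log1p(z)
        log_sf = -np.log1p(z)
        return float(np.sum(e * log_pdf + (1.0 - e) * log_sf))
    # lognormal
    mu, sg = params["mu"], params["sigma"]
    log_pdf = stats.norm.logpdf(np.log(t), mu, sg) - np.log(t)
    log_sf = stats.norm.logsf((np.log(t) - mu) / sg)
    return float(np.sum(e * log_pdf + (1.0 - e) * log_sf))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit(ipd, family: str) -> ParametricSurvival:
    """Fit one survival family to (pseudo-)IPD by maximum likelihood.

    ``ipd`` is any object with ``time_months`` and ``event`` array
    attributes (see :class:`hcc_cea.km_ipd.PseudoIPD`).  Requires at
    least two events.
    """
    import lifelines

    if family not in _N_PARAMS:
        raise ValueError(f"unknown survival family {family!r}; choose from {FAMILIES}")
    t = np.asarray(ipd.time_months, dtype=float)
    e = np.asarray(ipd.event, dtype=int)
    if int(e.sum()) < 2:
        raise FitError(f"need >= 2 events to fit a {family} model, got {int(e.sum())}")

    fitters = {
        "exponential": lifelines.ExponentialFitter,
        "weibull": lifelines.WeibullFitter,
        "loglogistic": lifelines.LogLogisticFitter,
        "lognormal": lifelines.LogNormalFitter,
    }
    try:
        f = fitters[family]().fit(t, e)
    except Exception as exc:  # lifelines raises several convergence error types
        raise FitError(
            f"{family} fit failed on n={t.size} records "
            f"({int(e.sum())} events, median time {np.median(t):.3g}): {exc}"
        ) from exc

    if family == "exponential":
        params = {"scale": float(f.lambda_)}
    elif family == "weibull":
        params = {"shape": float(f.rho_), "scale": float(f.lambda_)}
    elif family == "loglogistic":
        params = {"shape": float(f.beta_), "scale": float(f.alpha_)}
    else:
        params = {"mu": float(f.mu_), "sigma": float(f.sigma_)}

    ll = _log_likelihood(family, params, t, e)
    if not np.isfinite(ll):
        raise FitError(f"{family} fit produced a non-finite log-likelihood")
    return ParametricSurvival(family=family, params=params, loglik=ll, n=int(t.size))


def aic_select(fits: Sequence[ParametricSurvival]) -> ParametricSurvival:
    """Pick the fit with the smallest AIC = 2k - 2 log L.

    Ties are broken by fewer parameters, then by the declared family
    order (exponential, weibull, loglogistic, lognormal).
    """
    scored = [f for f in fits if f.loglik is not None]
    if not scored:
        raise ValueError("aic_select needs at least one fitted curve with a log-likelihood")
    return min(scored, key=lambda f: (f.aic, f.n_params, FAMILIES.index(f.family)))


# ---------------------------------------------------------------------------
# calibration from printed summaries
# ---------------------------------------------------------------------------

_LN2 = math.log(2.0)


def calibrate_weibull(
    median_months: float,
    landmark: Optional[Tuple[float, float]] = None,
    hazard_ratio: Optional[float] = None,
    reference: Optional[ParametricSurvival] = None,
    shape: Optional[float] = None,
) -> ParametricSurvival:
    """Build a Weibull (or exponential) survival law from summary statistics.

    Exactly one of the following modes applies:

    * ``landmark=(t_L, s_L)`` — solve S(median)=1/2 and S(t_L)=s_L for
      (shape, scale) in closed form.
    * ``hazard_ratio`` + ``reference`` — proportional hazards on the
      reference Weibull: same shape, scale = scale_ref * HR**(-1/shape).
      ``median_months`` may be None in this mode.
    * ``shape`` — fix the shape, solve the scale from the median.
    * none of the above — exponential with scale = median / ln 2.
    """
    modes = [landmark is not None, hazard_ratio is not None or reference is not None, shape is not None]
    if sum(modes) > 1:
        raise ValueError("supply at most one of landmark, hazard_ratio+reference, shape")

    if hazard_ratio is not None or reference is not None:
        if hazard_ratio is None or reference is None:
            raise ValueError("hazard-ratio calibration needs both hazard_ratio and reference")
        if hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if reference.family not in ("weibull", "exponential"):
            raise ValueError("hazard-ratio calibration requires a Weibull/exponential reference")
        k = float(reference.params.get("shape", 1.0))
        scale = float(reference.params["scale"]) * hazard_ratio ** (-1.0 / k)
        return ParametricSurvival("weibull", {"shape": k, "scale": scale})

    if median_months is None or median_months <= 0:
        raise ValueError("median_months must be > 0")

    if landmark is not None:
        t_l, s_l = landmark
        if not (0.0 < s_l < 1.0) or t_l <= 0:
            raise ValueError("landmark must have 0 < survival < 1 at time > 0")
        if (t_l > median_months) == (s_l >= 0.5) or math.isclose(t_l, median_months):
            raise ValueError(
                f"landmark S({t_l})={s_l} is inconsistent with a median of {median_months}"
            )
        # (t/sigma)^k = -ln S  at both the median and the landmark
        k = math.log(math.log(s_l) / math.log(0.5)) / math.log(t_l / median_months)
        scale = median_months / _LN2 ** (1.0 / k)
        return ParametricSurvival("weibull", {"shape": k, "scale": scale})

    if shape is not None:
        if shape <= 0:
            raise ValueError("shape must be > 0")
        scale = median_months / _LN2 ** (1.0 / shape)
        return ParametricSurvival("weibull", {"shape": shape, "scale": scale})

    return ParametricSurvival("exponential", {"scale": median_months / _LN2})
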