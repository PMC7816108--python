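"""Kaplan-Meier estimation and reconstruction of pseudo individual
patient data (pseudo-IPD) from digitized survival-curve coordinates and
published number-at-risk tables.

Published trials print a KM figure and a number-at-risk row, not the
underlying event times.  The reconstruction here inverts the product-limit
estimator interval by interval: within each inter-risk-table interval the
numbers of events and censorings are solved so that the KM curve of the
output tracks the digitized coordinates while the at-risk counts match the
risk table at the interval boundaries.  Censorings are placed evenly
within the interval, so the procedure is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["DigitizedCurve", "RiskTable", "PseudoIPD", "km_estimate", "reconstruct_ipd"]


class ReconstructionError(ValueError):
    """Inconsistent digitized curve / risk-table inputs."""


@dataclass(frozen=True)
class DigitizedCurve:
    """Ordered (time, survival) coordinates of a digitized KM curve."""

    time_months: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_months, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        if t.size != s.size or t.size == 0:
            raise ValueError("curve needs equal-length, nonempty time and survival arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("curve times must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("curve times must be nonnegative")
        if s[0] > 1.0 + 1e-12:
            raise ValueError("survival cannot exceed 1")
        if np.any(np.diff(s) > 1e-12) or np.any(s < -1e-12):
            raise ValueError("survival must be non-increasing and nonnegative")
        object.__setattr__(self, "time_months", t)
        object.__setattr__(self, "survival", np.clip(s, 0.0, 1.0))

    def at(self, t) -> np.ndarray:
        """Step-function evaluation (right-continuous), S=1 before the first point."""
        idx = np.searchsorted(self.time_months, np.asarray(t, dtype=float), side="right") - 1
        s = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return s

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_months": self.time_months, "survival": self.survival}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "DigitizedCurve":
        df = pd.read_csv(path)
        return cls(df["time_months"].to_numpy(), df["survival"].to_numpy())


@dataclass(frozen=True)
class RiskTable:
    """Number of patients at risk at each printed time point."""

    time_months: np.ndarray
    n_risk: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_months, dtype=float)
        n = np.asarray(self.n_risk, dtype=int)
        if t.size != n.size or t.size == 0:
            raise ValueError("risk table needs equal-length, nonempty arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(np.diff(n) > 0):
            bad = int(np.argmax(np.diff(n) > 0))
            raise ReconstructionError(
                f"at-risk counts increase between t={t[bad]} and t={t[bad + 1]}"
            )
        if np.any(n < 0):
            raise ValueError("at-risk counts must be nonnegative")
        object.__setattr__(self, "time_months", t)
        object.__setattr__(self, "n_risk", n)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_months": self.time_months, "n_risk": self.n_risk}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "RiskTable":
        df = pd.read_csv(path)
        return cls(df["time_months"].to_numpy(), df["n_risk"].to_numpy())


@dataclass(frozen=True)
class PseudoIPD:
    """Patient-level (time, event) records; event 1 = event, 0 = censored."""

    time_months: np.ndarray
    event: np.ndarray
    arm: str = ""
    endpoint: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_months, dtype=float)
        e = np.asarray(self.event, dtype=int)
        if t.size == 0 or t.size != e.size:
            raise ValueError("IPD needs equal-length, nonempty time and event arrays")
        if np.any(t <= 0):
            raise ValueError("all event/censoring times must be > 0")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "time_months", t)
        object.__setattr__(self, "event", e)

    def __len__(self) -> int:
        return int(self.time_months.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_months": self.time_months, "event": self.event}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, arm: str = "", endpoint: str = "") -> "PseudoIPD":
        df = pd.read_csv(path)
        return cls(df["time_months"].to_numpy(), df["event"].to_numpy(), arm, endpoint)


# ---------------------------------------------------------------------------
# Kaplan-Meier estimation
# ---------------------------------------------------------------------------


def km_estimate(ipd: PseudoIPD) -> DigitizedCurve:
    """Product-limit estimate of the survival curve of an IPD set.

    Returns the step curve evaluated at time 0 (S=1) and at every
    distinct event time.
    """
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter().fit(ipd.time_months, ipd.event)
    event_times = np.unique(ipd.time_months[ipd.event == 1])
    times = np.concatenate(([0.0], event_times))
    surv = kmf.survival_function_at_times(times).to_numpy()
    return DigitizedCurve(times, surv)


# ---------------------------------------------------------------------------
# reconstruction (Guyot-style inversion)
# ---------------------------------------------------------------------------


def _monotonize(survival: np.ndarray) -> np.ndarray:
    """Non-increasing isotonic repair of a noisy digitization (PAVA)."""
    from sklearn.isotonic import IsotonicRegression

    iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
    return iso.fit_transform(np.arange(survival.size), survival)


def _solve_interval(
    n_start: int,
    s_enter: float,
    times: np.ndarray,
    surv: np.ndarray,
    n_censor: int,
    t_lo: float,
    t_hi: float,
):
    """Walk the curve points of one interval assigning integer event counts.

    ``n_censor`` censorings are placed evenly over (t_lo, t_hi) and
    interleaved with the curve points in time order.  Returns the event
    counts per point, censor times, end-of-interval at-risk count and KM
    level.
    """
    if n_censor > 0:
        cens_times = t_lo + (np.arange(1, n_censor + 1) - 0.5) / n_censor * (t_hi - t_lo)
    else:
        cens_times = np.empty(0)
    events = np.zeros(times.size, dtype=int)
    r = n_start
    s_hat = s_enter
    ci = 0
    for j, (t_j, s_j) in enumerate(zip(times, surv)):
        while ci < n_censor and cens_times[ci] < t_j:
            r -= 1
            ci += 1
        if r <= 0 or s_hat <= 0:
            break
        d = int(round(r * (1.0 - s_j / s_hat)))
        d = max(0, min(d, r))
        if d > 0:
            s_hat *= 1.0 - d / r
            r -= d
        events[j] = d
    r -= n_censor - ci
    return events, cens_times, max(r, 0), s_hat


def reconstruct_ipd(
    curve: DigitizedCurve,
    risk: RiskTable,
    total_events: Optional[int] = None,
    arm: str = "",
    endpoint: str = "",
) -> PseudoIPD:
    """Reconstruct pseudo-IPD from a digitized KM curve and a risk table.

    Within each inter-risk-table interval, the number of censorings is
    first taken as the at-risk drop not explained by the KM steps, then
    the interval is re-solved once with those censorings spread evenly
    through it.  Event times sit at the digitized step times; the output
    has exactly as many records as the first at-risk count.  If
    ``total_events`` is given, interval event counts are rescaled to it
    by largest-remainder rounding before times are assigned.
    """
    if risk.n_risk[0] <= 0:
        raise ReconstructionError("first at-risk entry must be positive")
    surv = _monotonize(curve.survival.copy())
    times = curve.time_months
    # trailing risk entries beyond the digitized axis carry no usable curve
    # information; drop them rather than failing
    keep = risk.time_months <= times[-1] + 1e-9
    if not keep[0]:
        raise ReconstructionError(
            f"curve ends at t={times[-1]} before the first risk-table time "
            f"{risk.time_months[0]}"
        )

    bounds = list(risk.time_months[keep]) + [times[-1] + 1e-9]
    n_at = [int(v) for v in risk.n_risk[keep]]

    ev_times: list[float] = []
    cs_times: list[float] = []
    interval_events: list[np.ndarray] = []
    interval_points: list[np.ndarray] = []
    interval_cens: list[np.ndarray] = []

    r = int(n_at[0])
    s_enter = curve.at(bounds[0]) if times[0] <= bounds[0] else 1.0
    s_enter = float(s_enter)
    for i in range(len(n_at)):
        # a drop recorded at grid time t reflects events in (t-step, t], so a
        # drop at a risk-table boundary belongs to the interval ending there
        t_lo, t_hi = bounds[i], bounds[i + 1]
        mask = (times > t_lo + 1e-12) & (times <= t_hi + 1e-12)
        pts, svals = times[mask], surv[mask]
        # ... and those events happened (a.s.) before the boundary, so they
        # are placed just before it to keep at-risk counts consistent
        pts_emit = np.where(np.isclose(pts, t_hi, atol=1e-9), t_hi - 1e-6, pts)
        has_target = i + 1 < len(n_at)
        target = int(n_at[i + 1]) if has_target else 0

        # iterate the interval censoring count until the end-of-interval
        # at-risk count matches the table (final interval: events from the
        # curve only; the remainder is administratively censored later)
        n_cens = 0
        ev, ct, r_end, s_end = _solve_interval(r, s_enter, pts, svals, 0, t_lo, t_hi)
        if has_target:
            for _ in range(50):
                if r_end == target:
                    break
                new_c = max(0, n_cens + (r_end - target))
                if new_c == n_cens:
                    break
                n_cens = new_c
                ev, ct, r_end, s_end = _solve_interval(r, s_enter, pts, svals, n_cens, t_lo, t_hi)
            if r_end > target:
                # residual absorbed by extra censorings at the interval end
                ct = np.concatenate([ct, np.full(r_end - target, t_hi - 1e-9 * max(t_hi, 1.0))])
            elif r_end < target:
                # curve implies more events than the at-risk drop allows
                # (integer rounding); trim the latest events to honor the table
                deficit = target - r_end
                for j in range(ev.size - 1, -1, -1):
                    take = min(deficit, int(ev[j]))
                    ev[j] -= take
                    deficit -= take
                    if deficit == 0:
                        break
            r_end = target
        interval_events.append(ev)
        interval_points.append(pts_emit)
        interval_cens.append(ct)
        r = r_end
        s_enter = s_end if s_end > 0 else s_enter

    if total_events is not None:
        interval_events = _rescale_events(interval_events, int(total_events))

    for pts, ev, ct in zip(interval_points, interval_events, interval_cens):
        for t_j, d in zip(pts, ev):
            ev_times.extend([t_j] * int(d))
        cs_times.extend(ct.tolist())

    # whatever remains at risk after the last interval is censored at follow-up end
    n0 = int(risk.n_risk[0])
    n_used = len(ev_times) + len(cs_times)
    if n_used > n0:
        raise ReconstructionError("reconstruction assigned more records than patients at risk")
    if n_used < n0:
        cs_times.extend([float(times[-1])] * (n0 - n_used))

    t_all = np.concatenate([np.asarray(ev_times, float), np.asarray(cs_times, float)])
    e_all = np.concatenate([np.ones(len(ev_times), int), np.zeros(len(cs_times), int)])
    t_all = np.maximum(t_all, 1e-9)
    order = np.argsort(t_all, kind="stable")
    return PseudoIPD(t_all[order], e_all[order], arm=arm, endpoint=endpoint)


def _rescale_events(interval_events: list[np.ndarray], total: int) -> list[np.ndarray]:
    """Proportionally rescale per-interval event counts to a printed total,
    rounding by largest remainder."""
    flat = np.concatenate([ev.astype(float) for ev in interval_events]) if interval_events else np.empty(0)
    cur = flat.sum()
    if cur == 0 or total < 0:
        return interval_events
    scaled = flat * (total / cur)
    base = np.floor(scaled).astype(int)
    rem = scaled - base
    short = total - int(base.sum())
    if short > 0:
        base[np.argsort(-rem, kind="stable")[:short]] += 1
    out, k = [], 0
    for ev in interval_events:
        out.append(base[k : k + ev.size])
        k += ev.size
    return out
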