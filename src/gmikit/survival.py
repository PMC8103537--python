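"""Right-censored survival estimation, written from first principles.

Implements the Kaplan–Meier product-limit estimator with Greenwood
variances, median (and pointwise-band) confidence intervals by inverting a
complementary-log-log band (the Brookmeyer–Crowley construction used by the
standard survival packages), and a single-binary-covariate proportional
hazards model with the Efron correction for tied event times, maximised by
Newton–Raphson.

These estimators are deliberately self-contained: the same machinery is
reused on the time axis (TTD, PFS) and on the ratio axis, where the
"survival time" is a censored per-patient ratio of event times and the
curve describes the probability of exceeding a given ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .endpoints import TimeToEvent

__all__ = [
    "KMCurve",
    "MedianEstimate",
    "HazardRatioEstimate",
    "km_fit",
    "km_median",
    "km_survival_at",
    "ph_binary",
]


@dataclass
class KMCurve:
    """A fitted product-limit curve.

    ``times`` are the distinct observed times in ascending order (events and
    censorings); ``survival`` holds the right-continuous step values S(t).
    ``greenwood_var`` is the Greenwood estimate of Var[S(t)] at each step.
    """

    times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    n_censor: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    n_total: int
    n_censored: int
    # cumulative sum of d/(n(n-d)); needed for the clog-log band
    _gw_sum: np.ndarray = field(default=None, repr=False)

    def survival_at(
        self, t: float, side: Literal["right_value", "left_limit"] = "right_value"
    ) -> float:
        return km_survival_at(self, t, side)

    def confidence_band(self, level: float = 0.95) -> Tuple[np.ndarray, np.ndarray]:
        """Pointwise complementary-log-log band (lower, upper)."""
        z = norm.ppf(0.5 + level / 2.0)
        s = self.survival
        lo = np.empty_like(s)
        hi = np.empty_like(s)
        for i, si in enumerate(s):
            if si <= 0.0:
                lo[i] = hi[i] = 0.0
            elif si >= 1.0:
                lo[i] = hi[i] = 1.0
            else:
                se_cll = math.sqrt(self._gw_sum[i]) / abs(math.log(si))
                lo[i] = si ** math.exp(z * se_cll)
                hi[i] = si ** math.exp(-z * se_cll)
        return lo, hi

    def to_frame(self, level: float = 0.95) -> pd.DataFrame:
        """Curve export: time, n_risk, n_event, survival, std_err, CI."""
        lo, hi = self.confidence_band(level)
        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "n_censor": self.n_censor,
                "survival": self.survival,
                "std_err": np.sqrt(self.greenwood_var),
                "ci_low": lo,
                "ci_high": hi,
            }
        )


@dataclass
class MedianEstimate:
    """KM median with confidence bounds; None marks 'not estimable'."""

    median: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    level: float = 0.95


@dataclass
class HazardRatioEstimate:
    hr: float
    ci_low: float
    ci_high: float
    log_hr_se: float
    log_hr: float
    converged: bool = True

    def __post_init__(self) -> None:
        assert abs(self.hr - math.exp(self.log_hr)) <= 1e-9 * max(1.0, self.hr)


def km_fit(obs: Sequence[TimeToEvent]) -> KMCurve:
    """Product-limit estimator; events precede censorings at tied times."""
    if len(obs) == 0:
        raise ValueError("km_fit requires at least one observation")
    times = np.array([o.time for o in obs], dtype=float)
    events = np.array([o.event for o in obs], dtype=bool)
    if not np.all(np.isfinite(times)) or np.any(times < 0):
        raise ValueError("all times must be finite and nonnegative")

    distinct = np.unique(times)
    n = len(obs)
    n_risk = np.empty(len(distinct), dtype=int)
    n_event = np.empty(len(distinct), dtype=int)
    n_censor = np.empty(len(distinct), dtype=int)
    surv = np.empty(len(distinct))
    gvar = np.empty(len(distinct))
    gw = np.empty(len(distinct))

    at_risk = n
    s = 1.0
    gw_acc = 0.0
    for i, t in enumerate(distinct):
        here = times == t
        d = int(np.count_nonzero(here & events))
        c = int(np.count_nonzero(here & ~events))
        n_risk[i] = at_risk
        n_event[i] = d
        n_censor[i] = c
        if d > 0:
            s *= 1.0 - d / at_risk
            if at_risk > d:
                gw_acc += d / (at_risk * (at_risk - d))
        surv[i] = s
        gw[i] = gw_acc
        gvar[i] = s * s * gw_acc if s > 0 else 0.0
        at_risk -= d + c
    return KMCurve(
        times=distinct,
        n_risk=n_risk,
        n_event=n_event,
        n_censor=n_censor,
        survival=surv,
        greenwood_var=gvar,
        n_total=n,
        n_censored=int(np.count_nonzero(~events)),
        _gw_sum=gw,
    )


def km_survival_at(
    c: KMCurve, t: float, side: Literal["right_value", "left_limit"] = "right_value"
) -> float:
    """Read the step function: S(t) or its left limit S(t-).

    The left limit is the exceedance probability P(X >= t), which makes a
    value exactly at a threshold count as achieving it.
    """
    if t < 0:
        raise ValueError(f"t must be nonnegative, got {t}")
    if side == "right_value":
        idx = np.searchsorted(c.times, t, side="right") - 1
    elif side == "left_limit":
        idx = np.searchsorted(c.times, t, side="left") - 1
    else:
        raise ValueError(f"unknown side {side!r}")
    return 1.0 if idx < 0 else float(c.survival[idx])


def _first_time_at_or_below(
    times: np.ndarray, values: np.ndarray, level: float
) -> Optional[float]:
    hit = np.nonzero(values <= level + 1e-12)[0]
    return float(times[hit[0]]) if hit.size else None


def km_median(c: KMCurve, level: float = 0.95) -> MedianEstimate:
    """Median survival with a Brookmeyer–Crowley style interval.

    The median is the smallest observed event time with S(t) <= 0.5; the
    confidence bounds are the first times at which the pointwise
    complementary-log-log band crosses 0.5.  A bound (or the median) that
    never crosses is reported as not estimable (None).
    """
    event_mask = c.n_event > 0
    lo_band, hi_band = c.confidence_band(level)
    med = _first_time_at_or_below(
        c.times[event_mask], c.survival[event_mask], 0.5
    )
    ci_low = _first_time_at_or_below(c.times[event_mask], lo_band[event_mask], 0.5)
    ci_high = _first_time_at_or_below(c.times[event_mask], hi_band[event_mask], 0.5)
    return MedianEstimate(median=med, ci_low=ci_low, ci_high=ci_high, level=level)


def _efron_derivatives(
    beta: float,
    times: np.ndarray,
    events: np.ndarray,
    x: np.ndarray,
) -> Tuple[float, float, float]:
    """(log partial likelihood, score, information) with Efron ties."""
    order = np.argsort(times)
    times, events, x = times[order], events[order], x[order]
    ex = np.exp(beta * x)
    loglik = 0.0
    score = 0.0
    info = 0.0
    event_times = np.unique(times[events])
    for t in event_times:
        risk = times >= t
        dead = (times == t) & events
        d = int(np.count_nonzero(dead))
        s_r = float(np.sum(ex[risk]))
        s_rx = float(np.sum(x[risk] * ex[risk]))
        s_rx2 = float(np.sum(x[risk] ** 2 * ex[risk]))
        s_d = float(np.sum(ex[dead]))
        s_dx = float(np.sum(x[dead] * ex[dead]))
        s_dx2 = float(np.sum(x[dead] ** 2 * ex[dead]))
        loglik += beta * float(np.sum(x[dead]))
        for k in range(d):
            f = k / d
            denom = s_r - f * s_d
            num1 = s_rx - f * s_dx
            num2 = s_rx2 - f * s_dx2
            loglik -= math.log(denom)
            score -= num1 / denom
            info += num2 / denom - (num1 / denom) ** 2
        score += float(np.sum(x[dead]))
    return loglik, score, info


def _fit_ph(
    times: np.ndarray, events: np.ndarray, x: np.ndarray, tol: float = 1e-8
) -> Tuple[float, float, bool]:
    """Newton–Raphson for the scalar log hazard ratio; returns (beta, info, ok)."""
    beta = 0.0
    converged = False
    for _ in range(60):
        _, score, info = _efron_derivatives(beta, times, events, x)
        if info <= 0:
            break
        step = score / info
        # damp runaway steps under near-monotone likelihoods
        step = max(min(step, 2.0), -2.0)
        beta += step
        if abs(step) < tol:
            converged = True
            break
        if abs(beta) > 25.0:  # monotone likelihood: estimate diverges
            break
    _, _, info = _efron_derivatives(beta, times, events, x)
    return beta, info, converged


def ph_binary(
    obs: Sequence[Tuple[TimeToEvent, Hashable]],
    level: float = 0.95,
    cluster: Optional[Sequence[Hashable]] = None,
) -> HazardRatioEstimate:
    """Proportional-hazards ratio for group B vs group A.

    ``obs`` is a sequence of (TimeToEvent, group) pairs with exactly two
    group labels; the hazard ratio reported is for the lexicographically
    larger label relative to the smaller one.  Ties are handled with the
    Efron approximation and the maximum located by Newton–Raphson.  The
    default interval is the naive Wald CI from the observed information;
    when ``cluster`` labels are supplied (e.g. a patient id shared by both
    of a patient's outcomes), a leave-one-cluster-out jackknife standard
    error replaces it, acknowledging intrapatient pairing.
    """
    if not obs:
        raise ValueError("ph_binary requires observations")
    groups = sorted({g for _, g in obs}, key=str)
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    times = np.array([o.time for o, _ in obs], dtype=float)
    events = np.array([o.event for o, _ in obs], dtype=bool)
    x = np.array([1.0 if g == groups[1] else 0.0 for _, g in obs])
    if not events.any():
        raise ValueError("no events observed; hazard ratio undefined")

    beta, info, converged = _fit_ph(times, events, x)
    z = norm.ppf(0.5 + level / 2.0)
    if cluster is not None:
        labels = np.asarray(list(cluster))
        uniq = np.unique(labels)
        betas = []
        for g in uniq:
            keep = labels != g
            if events[keep].any() and len(set(x[keep])) == 2:
                b_g, _, _ = _fit_ph(times[keep], events[keep], x[keep])
                betas.append(b_g)
        betas = np.array(betas)
        g_eff = len(betas)
        se = math.sqrt((g_eff - 1) / g_eff * float(np.sum((betas - betas.mean()) ** 2)))
    else:
        se = 1.0 / math.sqrt(info) if info > 0 else math.inf
    if not converged:
        se = math.inf
    return HazardRatioEstimate(
        hr=math.exp(beta),
        ci_low=math.exp(beta - z * se) if math.isfinite(se) else 0.0,
        ci_high=math.exp(beta + z * se) if math.isfinite(se) else math.inf,
        log_hr_se=se,
        log_hr=beta,
        converged=converged,
    )
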