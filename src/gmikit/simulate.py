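"""Synthetic cohorts with the dependence structure the GMI analysis assumes.

No patient-level data from the motivating trial are public, so every stage
of the pipeline is exercised on simulated cohorts that reproduce its
structural features: three cohorts split like the trial's disposition
(38/13/20 of 71 by default), positively correlated (prior TTD, index PFS)
pairs, administrative censoring of patients still on therapy at cutoff,
partial-date missingness on prior-therapy dates, and best-response
categories that improve stochastically with time on therapy.

Dependence between a patient's successive event times is induced by a
shared gamma frailty: given a patient-level multiplier Z ~ Gamma(mean 1,
variance theta) both times are Weibull with hazard scaled by Z.  This is
exactly the Clayton-copula model, whose Kendall's tau has the closed form
theta / (theta + 2) — handy as an independent oracle.  theta = 0 recovers
independent marginals.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dates import PartialDate, impute_partial_date
from .endpoints import DAYS_PER_MONTH
from .gmi import DEFAULT_THRESHOLDS
from .records import (
    CohortLabel,
    DiscontinuationReason,
    PatientRecord,
    ResponseCategory,
    TherapyCategory,
    TherapyLine,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "default_config",
    "scale_for_marginal_median",
    "marginal_survival",
    "simulate_paired_times",
    "simulate_cohort",
    "oracle_gmi_distribution",
]

_TUMOUR_TYPES = [
    ("sarcoma", 0.225),
    ("NSCLC", 0.169),
    ("MASC", 0.169),
    ("thyroid", 0.099),
    ("breast", 0.085),
    ("colorectal", 0.085),
    ("pancreatic", 0.042),
    ("neuroendocrine", 0.056),
    ("other", 0.07),
]

_PRIOR_CATEGORIES = [
    (TherapyCategory.CHEMOTHERAPY, 0.67),
    (TherapyCategory.TARGETED, 0.23),
    (TherapyCategory.IMMUNOTHERAPY, 0.04),
    (TherapyCategory.MONOCLONAL_ANTIBODY, 0.04),
    (TherapyCategory.HORMONE, 0.02),
]


def scale_for_marginal_median(
    median: float, shape: float, theta: float
) -> float:
    """Weibull scale giving the requested *marginal* median under frailty.

    With gamma frailty of variance theta the marginal survival is
    S(t) = (1 + theta (t/scale)^shape)^(-1/theta); solving S = 1/2 gives
    the cumulative hazard (2^theta - 1)/theta at the median (log 2 in the
    theta -> 0 limit).
    """
    h = math.log(2.0) if theta == 0 else (2.0**theta - 1.0) / theta
    return median / h ** (1.0 / shape)


def marginal_survival(
    t: np.ndarray, shape: float, scale: float, theta: float
) -> np.ndarray:
    """Marginal survival of a frailty-mixed Weibull."""
    h = (np.asarray(t, dtype=float) / scale) ** shape
    if theta == 0:
        return np.exp(-h)
    return (1.0 + theta * h) ** (-1.0 / theta)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the motivating trial's topline shape: 71 patients
    split 38/13/20 across the three cohorts, marginal median index PFS
    near 11.2 months, marginal median prior TTD near 2.9 months, moderate
    intrapatient dependence (theta = 0.5, Kendall's tau 0.2), a 30-month
    accrual window inside a 36-month administrative window, and partial
    dates on roughly 10% (month) / 30% (day) of prior-therapy date fields.
    """

    n_patients: int = 71
    cohort_mix: Tuple[float, float, float] = (38 / 71, 13 / 71, 20 / 71)
    prior_ttd_weibull: Tuple[float, float] = (
        1.1,
        scale_for_marginal_median(2.9, 1.1, 0.5),
    )
    index_pfs_weibull: Tuple[float, float] = (
        1.1,
        scale_for_marginal_median(11.2, 1.1, 0.5),
    )
    frailty_theta: float = 0.5
    study_start: dt.date = dt.date(2015, 11, 1)
    accrual_months: float = 30.0
    admin_censor_months: float = 36.0
    ongoing_fraction_target: Optional[float] = None
    missing_month_prob: float = 0.10
    missing_day_prob: float = 0.30
    response_link: Dict[str, float] = field(
        default_factory=lambda: {
            "sigma": 0.22,
            "cut_pd": 0.18,
            "cut_sd": 0.40,
            "cut_cr": 0.97,
            "ne_prob": 0.05,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        mix = np.asarray(self.cohort_mix, dtype=float)
        if mix.shape != (3,) or np.any(mix < 0) or abs(mix.sum() - 1) > 1e-9:
            raise ValueError(
                "cohort_mix must be three nonnegative proportions summing to 1"
            )
        for name in ("prior_ttd_weibull", "index_pfs_weibull"):
            shape, scale = getattr(self, name)
            if shape <= 0 or scale <= 0:
                raise ValueError(f"{name}: shape and scale must be positive")
        if self.frailty_theta < 0:
            raise ValueError("frailty_theta must be nonnegative")
        for name in ("missing_month_prob", "missing_day_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ongoing_fraction_target is not None and not (
            0 <= self.ongoing_fraction_target < 1
        ):
            raise ValueError("ongoing_fraction_target must be in [0, 1)")
        if self.admin_censor_months <= 0 or self.accrual_months <= 0:
            raise ValueError("time windows must be positive")

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["cohort_mix"] = list(self.cohort_mix)
        d["prior_ttd_weibull"] = list(self.prior_ttd_weibull)
        d["index_pfs_weibull"] = list(self.index_pfs_weibull)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "SimulationConfig":
        d = dict(d)
        if "study_start" in d and isinstance(d["study_start"], str):
            d["study_start"] = dt.date.fromisoformat(d["study_start"])
        for key in ("cohort_mix", "prior_ttd_weibull", "index_pfs_weibull"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    cfg = dataclasses.replace(SimulationConfig(seed=seed), **overrides)
    cfg.validate()
    return cfg


@dataclass
class SyntheticCohort:
    """Emitted records plus the latent truth they were generated from."""

    patients: List[PatientRecord]
    truth: pd.DataFrame
    cutoff: dt.date
    config: SimulationConfig


def _draw_frailty(
    rng: np.random.Generator, theta: float, n: int
) -> np.ndarray:
    if theta == 0:
        return np.ones(n)
    return rng.gamma(shape=1.0 / theta, scale=theta, size=n)


def simulate_paired_times(
    cfg: SimulationConfig,
    n: int,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """(prior TTD, index PFS) pairs in months, shape (n, 2).

    Conditional on the shared frailty Z both times are Weibull with hazard
    multiplied by Z; marginally each is a frailty-mixed Weibull and jointly
    they follow a Clayton copula with parameter theta.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    z = _draw_frailty(rng, cfg.frailty_theta, n)
    out = np.empty((n, 2))
    for col, (shape, scale) in enumerate(
        (cfg.prior_ttd_weibull, cfg.index_pfs_weibull)
    ):
        e = rng.exponential(size=n)
        out[:, col] = scale * (e / z) ** (1.0 / shape)
    return out


def _months_to_days(m: float) -> int:
    return int(round(m * DAYS_PER_MONTH))


def _categorical(rng, items):
    labels = [x for x, _ in items]
    probs = np.array([p for _, p in items], dtype=float)
    probs = probs / probs.sum()
    return labels[rng.choice(len(labels), p=probs)]


def _largest_remainder(mix: Sequence[float], n: int) -> List[int]:
    raw = np.asarray(mix, dtype=float) * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in range(short):
        base[order[i]] += 1
    return base.tolist()


def _mask_date(
    d: dt.date, rng: np.random.Generator, p_month: float, p_day: float
) -> PartialDate:
    u = rng.random()
    if u < p_month:
        return PartialDate(d.year)
    if u < p_month + p_day:
        return PartialDate(d.year, d.month)
    return PartialDate.from_date(d)


def _index_response(
    rng: np.random.Generator, pfs_quantile: float, link: Dict[str, float]
) -> ResponseCategory:
    if rng.random() < link["ne_prob"]:
        return ResponseCategory.NOT_EVALUABLE
    u = pfs_quantile + rng.normal(0.0, link["sigma"])
    if u < link["cut_pd"]:
        return ResponseCategory.PD
    if u < link["cut_sd"]:
        return ResponseCategory.SD
    if u < link["cut_cr"]:
        return ResponseCategory.PR
    return ResponseCategory.CR


def _prior_response_documented(
    rng: np.random.Generator, ttd_quantile: float, link: Dict[str, float]
) -> ResponseCategory:
    u0 = rng.random()
    if u0 < 0.18:
        return ResponseCategory.UNKNOWN
    if u0 < 0.21:
        return ResponseCategory.NOT_EVALUABLE
    u = ttd_quantile + rng.normal(0.0, link["sigma"])
    if u < 0.45:
        return ResponseCategory.PD
    if u < 0.75:
        return ResponseCategory.SD
    if u < 0.96:
        return ResponseCategory.PR
    return ResponseCategory.CR


_NODOC_RESPONSES = [
    (ResponseCategory.SD, 0.45),
    (ResponseCategory.NON_CR_NON_PD, 0.08),
    (ResponseCategory.PR, 0.07),
    (ResponseCategory.NOT_EVALUABLE, 0.15),
    (ResponseCategory.UNKNOWN, 0.25),
]

_EARLIER_RESPONSES = [
    (ResponseCategory.PD, 0.40),
    (ResponseCategory.SD, 0.25),
    (ResponseCategory.PR, 0.05),
    (ResponseCategory.UNKNOWN, 0.30),
]

# Figure-1-style split of documented-progression reasons (13:14:11)
_DOC_REASONS = [
    (DiscontinuationReason.PRIMARY_RESISTANCE, 13 / 38),
    (DiscontinuationReason.PROGRESSIVE_DISEASE, 14 / 38),
    (DiscontinuationReason.OTHER, 11 / 38),  # paired with a progression date
]

_NODOC_REASONS = [
    (DiscontinuationReason.TOXICITY, 0.5),
    (DiscontinuationReason.COURSE_COMPLETED, 0.2),
    (DiscontinuationReason.OTHER, 0.3),
]

_EARLIER_REASONS = [
    (DiscontinuationReason.PROGRESSIVE_DISEASE, 0.70),
    (DiscontinuationReason.TOXICITY, 0.15),
    (DiscontinuationReason.OTHER, 0.15),
]

_N_LINES = [(1, 0.41), (2, 0.39), (3, 0.15), (4, 0.05)]


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic under a fixed seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    counts = _largest_remainder(cfg.cohort_mix, n)
    labels = (
        [CohortLabel.DOCUMENTED_PROGRESSION] * counts[0]
        + [CohortLabel.NO_DOCUMENTED_PROGRESSION] * counts[1]
        + [CohortLabel.NO_PRIOR_THERAPY] * counts[2]
    )

    # latent draws, all up front so the cutoff can be chosen from them
    z = _draw_frailty(rng, cfg.frailty_theta, n)
    k_t, s_t = cfg.prior_ttd_weibull
    k_p, s_p = cfg.index_pfs_weibull
    prior_ttd_m = s_t * (rng.exponential(size=n) / z) ** (1.0 / k_t)
    pfs_m = s_p * (rng.exponential(size=n) / z) ** (1.0 / k_p)
    # index TTD tracks PFS: usually discontinuation shortly after
    # progression, occasionally earlier (toxicity/choice)
    lag = rng.exponential(0.5, size=n)
    early = rng.random(n) < 0.15
    ttd_m = np.where(early, pfs_m * rng.uniform(0.5, 1.0, size=n), pfs_m + lag)

    accrual_days = rng.uniform(
        0, cfg.accrual_months * DAYS_PER_MONTH, size=n
    ).astype(int)
    index_starts = np.array(
        [cfg.study_start + dt.timedelta(days=int(d)) for d in accrual_days]
    )
    latent_end = np.array(
        [
            index_starts[i] + dt.timedelta(days=_months_to_days(ttd_m[i]))
            for i in range(n)
        ]
    )
    if cfg.ongoing_fraction_target is not None:
        q = float(np.quantile(
            [d.toordinal() for d in latent_end],
            1.0 - cfg.ongoing_fraction_target,
        ))
        cutoff = dt.date.fromordinal(int(q))
        # every patient must be enrolled before cutoff
        cutoff = max(cutoff, max(index_starts) + dt.timedelta(days=1))
    else:
        cutoff = cfg.study_start + dt.timedelta(
            days=_months_to_days(cfg.admin_censor_months)
        )
        if cutoff <= max(index_starts):
            raise ValueError(
                "admin_censor_months places the cutoff inside the accrual "
                "window; every patient must enrol before cutoff"
            )

    patients: List[PatientRecord] = []
    truth_rows = []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        label = labels[i]
        start = index_starts[i]
        end = latent_end[i]
        ongoing = end > cutoff
        pfs_date = start + dt.timedelta(days=_months_to_days(pfs_m[i]))
        pfs_censored = pfs_date > cutoff

        rec = PatientRecord(
            patient_id=pid,
            tumour_type=_categorical(rng, _TUMOUR_TYPES),
            index_start=start,
            index_end=None if ongoing else end,
            index_ongoing=bool(ongoing),
            index_pfs_event_date=None if pfs_censored else pfs_date,
            index_pfs_censor_date=cutoff if pfs_censored else None,
            cns_metastases=bool(rng.random() < 0.25),
        )
        pfs_q = 1.0 - float(
            marginal_survival(pfs_m[i], k_p, s_p, cfg.frailty_theta)
        )
        rec.index_best_response = _index_response(rng, pfs_q, cfg.response_link)

        true_mr_start = true_mr_end = None
        if label is not CohortLabel.NO_PRIOR_THERAPY:
            n_lines = _categorical(rng, _N_LINES)
            # most recent line uses the paired latent TTD
            gap = int(rng.integers(7, 61))
            mr_end = start - dt.timedelta(days=gap)
            mr_days = max(1, _months_to_days(prior_ttd_m[i]))
            mr_start = mr_end - dt.timedelta(days=mr_days)
            true_mr_start, true_mr_end = mr_start, mr_end
            ttd_q = 1.0 - float(
                marginal_survival(prior_ttd_m[i], k_t, s_t, cfg.frailty_theta)
            )
            if label is CohortLabel.DOCUMENTED_PROGRESSION:
                reason = _categorical(rng, _DOC_REASONS)
                prog = (
                    PartialDate.from_date(mr_end)
                    if reason is DiscontinuationReason.OTHER
                    else None
                )
                resp = _prior_response_documented(rng, ttd_q, cfg.response_link)
            else:
                reason = _categorical(rng, _NODOC_REASONS)
                prog = None
                resp = _categorical(rng, _NODOC_RESPONSES)
            lines = [
                TherapyLine(
                    line_number=n_lines,
                    category=_categorical(rng, _PRIOR_CATEGORIES),
                    start=_mask_date(
                        mr_start, rng, cfg.missing_month_prob, cfg.missing_day_prob
                    ),
                    end=_mask_date(
                        mr_end, rng, cfg.missing_month_prob, cfg.missing_day_prob
                    ),
                    best_response=resp,
                    discontinuation_reason=reason,
                    progression_date=prog,
                )
            ]
            # earlier lines stacked backwards in calendar time; their
            # masked end must not impute past the most recent line's end,
            # or imputation would reorder the history
            mr_imputed_end = lines[0].imputed_end(cap=start)
            prev_start = mr_start
            for ln in range(n_lines - 1, 0, -1):
                e_days = max(
                    1,
                    _months_to_days(
                        s_t * (rng.exponential() / z[i]) ** (1.0 / k_t)
                    ),
                )
                gap = int(rng.integers(14, 91))
                ln_end = prev_start - dt.timedelta(days=gap)
                ln_start = ln_end - dt.timedelta(days=e_days)
                end_masked = _mask_date(
                    ln_end, rng, cfg.missing_month_prob, cfg.missing_day_prob
                )
                if impute_partial_date(end_masked, "end", cap=start) > mr_imputed_end:
                    end_masked = PartialDate.from_date(ln_end)
                lines.append(
                    TherapyLine(
                        line_number=ln,
                        category=_categorical(rng, _PRIOR_CATEGORIES),
                        start=_mask_date(
                            ln_start, rng, cfg.missing_month_prob,
                            cfg.missing_day_prob,
                        ),
                        end=end_masked,
                        best_response=_categorical(rng, _EARLIER_RESPONSES),
                        discontinuation_reason=_categorical(
                            rng, _EARLIER_REASONS
                        ),
                        progression_date=None,
                    )
                )
                prev_start = ln_start
            rec.prior_lines = sorted(lines, key=lambda l: l.line_number)
        rec.validate()
        patients.append(rec)
        truth_rows.append(
            {
                "patient_id": pid,
                "cohort": label.value,
                "frailty": float(z[i]),
                "latent_prior_ttd_months": float(prior_ttd_m[i]),
                "latent_index_pfs_months": float(pfs_m[i]),
                "latent_index_ttd_months": float(ttd_m[i]),
                "true_prior_start": true_mr_start,
                "true_prior_end": true_mr_end,
                "true_pfs_date": pfs_date,
                "pfs_censored": bool(pfs_censored),
                "ongoing": bool(ongoing),
            }
        )
    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(
        patients=patients, truth=truth, cutoff=cutoff, config=cfg
    )


def oracle_gmi_distribution(
    cfg: SimulationConfig,
    n_mc: int,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    rng: Optional[np.random.Generator] = None,
) -> Dict[float, float]:
    """Monte-Carlo P(true PFS / true TTD >= x) from uncensored latent times.

    Brute-force oracle for parameter-recovery tests: no censoring, no date
    granularity, no imputation — just the latent ratio distribution.
    """
    pairs = simulate_paired_times(cfg, n_mc, rng=rng)
    ratio = pairs[:, 1] / pairs[:, 0]
    return {
        float(x): float(np.count_nonzero(ratio >= x) / n_mc)
        for x in thresholds
    }
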