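"""End-to-end analysis pipeline and report assembly.

Stage order mirrors the study analysis: classify patients into cohorts,
derive endpoints (TTD, PFS, ORR, response cross-tabulation), fit
Kaplan–Meier curves and the PFS-vs-TTD hazard ratio, then run the GMI
analysis on the documented-progression cohort.  The report is deterministic
given input and configuration; statistical failures (no events, empty
cohorts, undefined ratios) surface as structured warnings, not crashes.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from . import endpoints as ep
from .gmi import (
    DEFAULT_THRESHOLDS,
    GMIObservation,
    GMISummary,
    ZeroTTDError,
    compute_gmi,
    gmi_summarise,
)
from .records import (
    CohortLabel,
    PatientRecord,
    classify_cohort,
    most_recent_prior_line,
)
from .survival import HazardRatioEstimate, KMCurve, km_fit, km_median

__all__ = ["AnalysisReport", "run_pipeline", "render_tables", "report_to_json"]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


@dataclass
class AnalysisReport:
    n_input: int
    cohort_sizes: Dict[str, int]
    orr_tables: Dict[str, Dict[str, Optional[ep.ResponseSummary]]]
    response_crosstab: Optional[pd.DataFrame]
    km_results: Dict[str, Dict]
    hazard_ratio: Dict[str, Optional[HazardRatioEstimate]]
    gmi: Optional[GMISummary]
    gmi_observations: List[GMIObservation]
    curves: Dict[str, KMCurve]
    endpoints: pd.DataFrame
    exclusions: List[Dict[str, str]]
    warnings: List[str]
    provenance: Dict[str, str]


def _config_hash(payload: Dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    patients: Sequence[PatientRecord],
    cutoff: Optional[dt.date] = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    level: float = 0.95,
) -> AnalysisReport:
    """Run the full intrapatient comparative-efficacy analysis.

    ``cutoff`` is the administrative data-cutoff date used to censor
    ongoing index therapy; it defaults to the latest complete date in the
    input.  The GMI analysis is restricted to the documented-progression
    cohort, whose prior TTD reflects lack of efficacy rather than an
    elective switch.
    """
    if not patients:
        raise ValueError("run_pipeline requires at least one patient")
    if cutoff is None:
        cutoff = ep.observed_cutoff(patients)
    warnings: List[str] = []
    exclusions: List[Dict[str, str]] = []

    by_cohort: Dict[CohortLabel, List[PatientRecord]] = {
        c: [] for c in CohortLabel
    }
    for p in patients:
        by_cohort[classify_cohort(p)].append(p)
    cohort_sizes = {c.value: len(v) for c, v in by_cohort.items()}

    orr_tables: Dict[str, Dict[str, Optional[ep.ResponseSummary]]] = {}
    for label, group in by_cohort.items():
        if not group:
            orr_tables[label.value] = {"index": None, "most_recent_prior": None}
            continue
        entry: Dict[str, Optional[ep.ResponseSummary]] = {
            "index": ep.orr(group, "index")
        }
        entry["most_recent_prior"] = (
            ep.orr(group, "most_recent_prior")
            if label is not CohortLabel.NO_PRIOR_THERAPY
            else None
        )
        orr_tables[label.value] = entry

    with_priors = [p for p in patients if p.prior_lines]
    crosstab = ep.response_crosstab(with_priors) if with_priors else None

    table = ep.endpoints_table(patients, cutoff=cutoff)

    # KM analyses on the documented-progression cohort, as in the headline
    # comparisons
    doc = by_cohort[CohortLabel.DOCUMENTED_PROGRESSION]
    curves: Dict[str, KMCurve] = {}
    km_results: Dict[str, Dict] = {}
    hazard_ratio: Dict[str, Optional[HazardRatioEstimate]] = {
        "index_pfs_vs_index_ttd": None,
        "index_ttd_vs_index_pfs": None,
    }
    if doc:
        pfs_obs = [ep.index_pfs(p) for p in doc]
        ttd_obs = [ep.index_ttd(p, cutoff) for p in doc]
        prior_obs = [
            ep.prior_ttd(most_recent_prior_line(p), p.index_start) for p in doc
        ]
        for name, obs in (
            ("index_pfs", pfs_obs),
            ("index_ttd", ttd_obs),
            ("prior_ttd", prior_obs),
        ):
            curve = km_fit(obs)
            med = km_median(curve, level=level)
            curves[name] = curve
            km_results[name] = {
                "n": curve.n_total,
                "n_events": int(curve.n_event.sum()),
                "median": med.median,
                "ci_low": med.ci_low,
                "ci_high": med.ci_high,
                "level": level,
            }
        paired = [(o, "pfs") for o in pfs_obs] + [(o, "ttd") for o in ttd_obs]
        cluster = [p.patient_id for p in doc] * 2
        try:
            # group labels sort pfs < ttd, so the fitted coefficient is
            # ttd-vs-pfs; report both directions explicitly
            est = _ph(paired)
            hazard_ratio["index_ttd_vs_index_pfs"] = est
            hazard_ratio["index_pfs_vs_index_ttd"] = _invert_hr(est)
        except ValueError as exc:
            warnings.append(f"hazard ratio not estimable: {exc}")
    else:
        warnings.append(
            "no documented-progression patients: KM and GMI sections "
            "not applicable"
        )

    gmi_obs: List[GMIObservation] = []
    gmi_summary: Optional[GMISummary] = None
    if doc:
        for p in doc:
            line = most_recent_prior_line(p)
            try:
                gmi_obs.append(
                    compute_gmi(
                        ep.index_pfs(p),
                        ep.prior_ttd(line, p.index_start),
                        patient_id=p.patient_id,
                    )
                )
            except ZeroTTDError as exc:
                logger.warning("%s", exc)
                exclusions.append(
                    {"patient_id": p.patient_id, "reason": "zero prior TTD"}
                )
                warnings.append(str(exc))
        if gmi_obs:
            gmi_summary = gmi_summarise(gmi_obs, thresholds, level=level)
            curves["gmi"], _, _ = _gmi_curve(gmi_obs, thresholds, level)
        else:
            warnings.append("GMI not applicable: no evaluable ratios")

    provenance = {
        "schema_version": SCHEMA_VERSION,
        "cutoff": cutoff.isoformat(),
        "config_hash": _config_hash(
            {"thresholds": list(thresholds), "level": level,
             "cutoff": cutoff.isoformat()}
        ),
    }
    return AnalysisReport(
        n_input=len(patients),
        cohort_sizes=cohort_sizes,
        orr_tables=orr_tables,
        response_crosstab=crosstab,
        km_results=km_results,
        hazard_ratio=hazard_ratio,
        gmi=gmi_summary,
        gmi_observations=gmi_obs,
        curves=curves,
        endpoints=table,
        exclusions=exclusions,
        warnings=warnings,
        provenance=provenance,
    )


def _ph(paired):
    from .survival import ph_binary

    return ph_binary(paired)


def _invert_hr(est: HazardRatioEstimate) -> HazardRatioEstimate:
    import math

    return HazardRatioEstimate(
        hr=math.exp(-est.log_hr),
        ci_low=1.0 / est.ci_high if est.ci_high > 0 else math.inf,
        ci_high=1.0 / est.ci_low if est.ci_low > 0 else math.inf,
        log_hr_se=est.log_hr_se,
        log_hr=-est.log_hr,
        converged=est.converged,
    )


def _gmi_curve(obs, thresholds, level):
    from .gmi import gmi_km

    return gmi_km(obs, thresholds, level=level)


def _round_floats(obj, sig: int = 6):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def _summary_dict(s: Optional[ep.ResponseSummary]):
    if s is None:
        return None
    return {
        "n": s.n,
        "responders": s.responders,
        "orr": s.orr,
        "by_category": {k.value: v for k, v in s.by_category.items()},
    }


def report_to_json(report: AnalysisReport) -> str:
    """Serialise the report; floats at 6 significant digits, stable order."""
    gmi = report.gmi
    payload = {
        "schema_version": report.provenance["schema_version"],
        "n_input": report.n_input,
        "cohort_sizes": report.cohort_sizes,
        "orr": {
            c: {arm: _summary_dict(s) for arm, s in arms.items()}
            for c, arms in report.orr_tables.items()
        },
        "response_crosstab": (
            None
            if report.response_crosstab is None
            else {
                str(r): {str(c): int(v) for c, v in row.items()}
                for r, row in report.response_crosstab.iterrows()
            }
        ),
        "km": report.km_results,
        "hazard_ratio": {
            k: (
                None
                if v is None
                else {
                    "hr": v.hr,
                    "ci_low": v.ci_low,
                    "ci_high": v.ci_high,
                    "log_hr_se": v.log_hr_se,
                    "converged": v.converged,
                }
            )
            for k, v in report.hazard_ratio.items()
        },
        "gmi": (
            None
            if gmi is None
            else {
                "n": gmi.n,
                "n_censored": gmi.n_censored,
                "median_naive": gmi.median_naive,
                "range": list(gmi.range),
                "threshold_counts": {
                    str(x): {"count": c, "proportion": p}
                    for x, (c, p) in gmi.threshold_counts.items()
                },
                "km_median": {
                    "median": gmi.km_median.median,
                    "ci_low": gmi.km_median.ci_low,
                    "ci_high": gmi.km_median.ci_high,
                    "level": gmi.km_median.level,
                },
                "km_exceedance": {
                    str(x): p for x, p in gmi.km_exceedance.items()
                },
            }
        ),
        "exclusions": report.exclusions,
        "warnings": report.warnings,
        "provenance": report.provenance,
    }
    return json.dumps(_round_floats(payload), indent=2, sort_keys=True)


def render_tables(report: AnalysisReport) -> Dict[str, pd.DataFrame]:
    """Tidy-table renditions of the figure-style outputs.

    ``km_curves`` stacks every fitted curve in long format; ``gmi_waterfall``
    sorts patients by descending ratio with their censor flags; ``swimmer``
    pairs each prior-treated patient's prior TTD with their index PFS.
    """
    frames: Dict[str, pd.DataFrame] = {}
    if report.curves:
        parts = []
        for name, curve in report.curves.items():
            df = curve.to_frame()
            df.insert(0, "endpoint", name)
            parts.append(df)
        frames["km_curves"] = pd.concat(parts, ignore_index=True)
    if report.gmi_observations:
        wf = pd.DataFrame(
            [
                {
                    "patient_id": o.patient_id,
                    "gmi": o.ratio,
                    "pfs_censored": o.censored,
                    "prior_ttd": o.prior_ttd,
                    "index_pfs": o.index_pfs,
                }
                for o in report.gmi_observations
            ]
        ).sort_values("gmi", ascending=False, kind="mergesort")
        frames["gmi_waterfall"] = wf.reset_index(drop=True)
    swimmer = report.endpoints[report.endpoints["prior_ttd_months"].notna()]
    if len(swimmer):
        frames["swimmer"] = swimmer[
            [
                "patient_id",
                "cohort_label",
                "prior_ttd_months",
                "index_pfs_months",
                "index_pfs_event",
                "index_ttd_months",
                "index_ttd_event",
            ]
        ].reset_index(drop=True)
    return frames


def write_report(
    report: AnalysisReport, out_dir: Union[str, Path]
) -> Path:
    """Write report JSON plus per-stage CSVs into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_to_json(report) + "\n")
    report.endpoints.to_csv(out / "endpoints.csv", index=False)
    for name, df in render_tables(report).items():
        df.to_csv(out / f"{name}.csv", index=False)
    return out / "report.json"
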