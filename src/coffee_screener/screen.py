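"""Authenticity and compliance screening, and the batch pipeline.

Screening rules (all thresholds strict inequalities; boundary equality is
compliant, and every threshold is configurable):

* declared 100% arabica with OMC above 50 mg/kg — suspicious of robusta
  admixture (OMC occurs only in Coffea canephora);
* declared decaffeinated with caffeine at or above 1000 mg/kg — out of
  spec against the German coffee regulation limit;
* declared 100% robusta with kahweol at or above 300 mg/kg — suspicious
  of arabica character (off by default; see ``ScreeningRules``);
* green (raw) coffee — quantitative results are indicative only, because
  the method is validated for roasted coffee.

Suspicious findings require confirmatory analysis (e.g. the HPLC reference
procedure) before any enforcement conclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analytes import DEFAULT_ANALYTES, AnalyteDefinition
from .errors import CoffeeScreenerError, InvalidParameterError
from .quantify import EreticCalibration, integrate_window, quantify_sample
from .spectra import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "DECLARED_TYPES", "SampleDeclaration", "ScreeningRules", "ScreeningReport",
    "classify_sample", "qc_control_check", "run_pipeline",
]

DECLARED_TYPES = ("arabica_100", "robusta_100", "blend", "decaffeinated", "green")


@dataclass(frozen=True)
class SampleDeclaration:
    sample_id: str
    declared_type: str
    label_notes: str = ""

    def __post_init__(self) -> None:
        if self.declared_type not in DECLARED_TYPES:
            raise InvalidParameterError(
                f"declared_type must be one of {DECLARED_TYPES}")


@dataclass(frozen=True)
class ScreeningRules:
    """Guidance values in mg/kg. ``None`` disables a rule."""

    omc_arabica_max: float | None = 50.0
    caffeine_decaf_max: float | None = 1000.0
    kahweol_robusta_max: float | None = None  # opt-in; default 300.0 when enabled


@dataclass
class ScreeningReport:
    sample_id: str
    contents_mg_kg: dict[str, float]
    verdict: str  # consistent | suspicious | out_of_spec | indicative_only | error
    triggered_rules: list[str] = field(default_factory=list)
    notes: str = ""

    def __str__(self) -> str:
        rules = "; ".join(self.triggered_rules) or "-"
        return f"{self.sample_id}: {self.verdict} ({rules})"


def classify_sample(contents_mg_kg: dict[str, float],
                    declaration: SampleDeclaration,
                    rules: ScreeningRules = ScreeningRules()) -> ScreeningReport:
    """Apply the authenticity/compliance rules to quantified contents.

    Missing or non-finite analyte contents skip the affected rule with a
    warning, never silently pass it. For green-coffee declarations the
    verdict is capped at ``indicative_only`` regardless of rule outcomes.
    """
    triggered: list[str] = []
    notes: list[str] = []
    verdict = "consistent"

    def get(analyte: str, rule: str) -> float | None:
        v = contents_mg_kg.get(analyte)
        if v is None or not np.isfinite(v):
            msg = f"rule {rule!r} skipped: no {analyte} content"
            logger.warning("%s: %s", declaration.sample_id, msg)
            notes.append(msg)
            return None
        return v

    if declaration.declared_type == "arabica_100" and rules.omc_arabica_max is not None:
        omc = get("OMC", "omc_arabica")
        if omc is not None and omc > rules.omc_arabica_max:
            triggered.append(
                f"OMC {omc:.1f} mg/kg > {rules.omc_arabica_max:g} mg/kg in "
                "declared 100% arabica (robusta admixture)")
            verdict = "suspicious"
    if declaration.declared_type == "decaffeinated" \
            and rules.caffeine_decaf_max is not None:
        caf = get("caffeine", "caffeine_decaf")
        if caf is not None and caf >= rules.caffeine_decaf_max:
            triggered.append(
                f"caffeine {caf:.0f} mg/kg >= {rules.caffeine_decaf_max:g} mg/kg "
                "limit for decaffeinated coffee")
            verdict = "out_of_spec"
    if declaration.declared_type == "robusta_100" \
            and rules.kahweol_robusta_max is not None:
        kah = get("kahweol", "kahweol_robusta")
        if kah is not None and kah >= rules.kahweol_robusta_max:
            triggered.append(
                f"kahweol {kah:.0f} mg/kg >= {rules.kahweol_robusta_max:g} mg/kg "
                "in declared 100% robusta (arabica character)")
            verdict = "suspicious"

    if declaration.declared_type == "green":
        verdict = "indicative_only"
        notes.append("green coffee: results indicative only "
                     "(method validated for roasted coffee)")
    if triggered:
        notes.append("requires confirmatory analysis")
        for rule in triggered:
            logger.info("%s: triggered %s", declaration.sample_id, rule)
    return ScreeningReport(declaration.sample_id, dict(contents_mg_kg),
                           verdict, triggered, "; ".join(notes))


def qc_control_check(control_spectrum: Spectrum,
                     window_ppm: tuple[float, float],
                     expected_band: tuple[float, float],
                     method: str = "sum") -> bool:
    """Single-peak quality-control check on a control-solution spectrum.

    Passes iff the window integral lies inside the inclusive tolerance
    band. Run after a measurement series to confirm the instrument's
    quantitative response has not drifted.
    """
    res = integrate_window(control_spectrum, window_ppm, method=method)
    lo, hi = sorted(expected_band)
    ok = lo <= res.raw_area <= hi
    if not ok:
        logger.warning("QC control failed: area %.4g outside [%.4g, %.4g]",
                       res.raw_area, lo, hi)
    return ok


def run_pipeline(samples: list[tuple[Spectrum, SampleDeclaration]],
                 analytes: dict[str, AnalyteDefinition] | None = None,
                 cal: EreticCalibration | None = None,
                 rules: ScreeningRules = ScreeningRules(),
                 limits: dict[str, float] | None = None,
                 ) -> tuple[list[ScreeningReport], pd.DataFrame, int]:
    """Quantify and screen a batch of spectra.

    Returns the per-sample reports, a tidy batch table, and an exit status
    (0 if every sample is consistent or indicative-only, 1 if any sample
    is suspicious or out of spec — for operational triage). A failure in
    one sample is recorded as an ``error`` verdict and does not abort the
    batch.
    """
    analytes = analytes or DEFAULT_ANALYTES
    reports: list[ScreeningReport] = []
    rows: list[dict] = []
    for spectrum, decl in samples:
        try:
            quant = quantify_sample(spectrum, analytes, cal, limits=limits)
            contents = {q.analyte: q.content_mg_kg for q in quant}
            report = classify_sample(contents, decl, rules)
        except CoffeeScreenerError as exc:
            logger.error("sample %s failed: %s", decl.sample_id, exc)
            report = ScreeningReport(decl.sample_id, {}, "error", [],
                                     notes=str(exc))
        reports.append(report)
        row = {"sample_id": report.sample_id,
               "declared_type": decl.declared_type,
               "verdict": report.verdict,
               "triggered_rules": "; ".join(report.triggered_rules)}
        for name in analytes:
            row[f"{name}_mg_kg"] = report.contents_mg_kg.get(name, float("nan"))
        rows.append(row)
    status = int(any(r.verdict in ("suspicious", "out_of_spec") for r in reports))
    return reports, pd.DataFrame(rows), status
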