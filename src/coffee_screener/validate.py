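"""Method-validation statistics: limits, linearity, recovery, precision, ANOVA.

Detection and determination limits follow the calibration-line method of
DIN 32645: the critical value is derived from the residual standard
deviation of a calibration in the lower working range, the calibration
slope, and the design leverage; the determination limit solves its
defining equation by fixed-point iteration with the relative-uncertainty
factor k. Recovery (90-110% specification) and the coefficient of
variation (<15% specification) are computed per analyte and matrix, and
the three-factor ruggedness design (device x coffee type x shaking time)
is evaluated by a main-effects ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (DegenerateDesignError, InvalidParameterError,
                     UndefinedStatisticError, UnusableCalibrationError)

__all__ = [
    "CalibrationSeries", "AnalyticalLimits", "LinearityResult",
    "ValidationReport", "fit_calibration", "din32645_limits", "recovery",
    "precision_cv", "factorial_anova", "build_validation_report",
    "RECOVERY_SPEC_PCT", "CV_SPEC_PCT",
]

#: Recovery specification band, percent.
RECOVERY_SPEC_PCT = (90.0, 110.0)
#: Precision specification: CV strictly below this, percent.
CV_SPEC_PCT = 15.0


@dataclass
class CalibrationSeries:
    """Spiked-versus-measured content pairs of one calibration series."""

    analyte: str
    spiked_mg_kg: np.ndarray
    measured_mg_kg: np.ndarray
    matrix: str = ""
    device: str = ""
    shaking_min: int | None = None
    blank_mg_kg: float = 0.0

    def __post_init__(self) -> None:
        self.spiked_mg_kg = np.asarray(self.spiked_mg_kg, dtype=float)
        self.measured_mg_kg = np.asarray(self.measured_mg_kg, dtype=float)
        if self.spiked_mg_kg.shape != self.measured_mg_kg.shape:
            raise InvalidParameterError("spiked and measured must have equal length")
        if np.any(np.diff(self.spiked_mg_kg) <= 0):
            raise InvalidParameterError("spiked levels must be strictly increasing")

    @property
    def n_levels(self) -> int:
        return int(self.spiked_mg_kg.size)


@dataclass(frozen=True)
class AnalyticalLimits:
    """Detection (LOD) and determination (LOQ) limits per DIN 32645."""

    analyte: str
    lod_mg_kg: float
    loq_mg_kg: float
    concentration_range_used: tuple[float, float]
    alpha: float
    k_loq: float


@dataclass(frozen=True)
class LinearityResult:
    analyte: str
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    range_mg_kg: tuple[float, float]
    flags: tuple[str, ...] = ()


def fit_calibration(series: CalibrationSeries) -> LinearityResult:
    """Ordinary least squares of measured on spiked content."""
    x, y = series.spiked_mg_kg, series.measured_mg_kg
    if x.size < 3:
        if x.size < 2:
            raise InvalidParameterError("need at least 2 levels")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all spiked levels identical")
    res = stats.linregress(x, y)
    n = x.size
    resid = y - (res.intercept + res.slope * x)
    flags: tuple[str, ...] = ()
    if n == 2:
        residual_sd = float("nan")
        flags = ("under_determined",)
    else:
        residual_sd = float(np.sqrt(np.sum(resid ** 2) / (n - 2)))
    return LinearityResult(series.analyte, float(res.slope), float(res.intercept),
                           float(res.rvalue ** 2), residual_sd,
                           (float(x.min()), float(x.max())), flags)


def din32645_limits(series: CalibrationSeries, alpha: float = 0.01,
                    k_loq: float = 3.0, max_iter: int = 100,
                    tol: float = 1e-10) -> AnalyticalLimits:
    """Detection and determination limits, calibration-line method.

    With residual sd ``s_y``, slope ``b``, ``n`` calibration points, mean
    spike ``x_bar`` and spread ``Q_x = sum (x_i - x_bar)^2``:

        LOD = (s_y / b) * t(1-alpha; n-2) * sqrt(1 + 1/n + x_bar^2 / Q_x)

    (one future measurement), and the determination limit solves

        LOQ = k * (s_y / b) * t * sqrt(1 + 1/n + (LOQ - x_bar)^2 / Q_x)

    by fixed-point iteration; k is the reciprocal relative uncertainty
    accepted at the determination limit (k = 3 <-> 33%).
    """
    if series.n_levels < 5:
        raise InvalidParameterError("need >= 5 levels for limit estimation")
    line = fit_calibration(series)
    if not line.slope > 0:
        raise UnusableCalibrationError("calibration slope must be positive")
    x = series.spiked_mg_kg
    n = x.size
    x_bar = float(x.mean())
    q_x = float(np.sum((x - x_bar) ** 2))
    t_val = float(stats.t.ppf(1.0 - alpha, n - 2))
    s_x0 = line.residual_sd / line.slope  # process standard deviation
    lod = s_x0 * t_val * np.sqrt(1.0 + 1.0 / n + x_bar ** 2 / q_x)
    loq = k_loq * lod
    for _ in range(max_iter):
        new = k_loq * s_x0 * t_val * np.sqrt(1.0 + 1.0 / n + (loq - x_bar) ** 2 / q_x)
        if abs(new - loq) < tol * max(1.0, abs(loq)):
            loq = new
            break
        loq = new
    return AnalyticalLimits(series.analyte, float(lod), float(loq),
                            (float(x.min()), float(x.max())), alpha, k_loq)


def recovery(spiked_mg_kg: np.ndarray, measured_mg_kg: np.ndarray,
             blank_mg_kg: float = 0.0, aggregate: str = "mean") -> float:
    """Mean per-level recovery in percent: 100 (measured - blank) / spiked."""
    spiked = np.asarray(spiked_mg_kg, dtype=float)
    measured = np.asarray(measured_mg_kg, dtype=float)
    if spiked.shape != measured.shape or spiked.size == 0:
        raise InvalidParameterError("spiked and measured must be equal-length, non-empty")
    if np.any(spiked <= 0):
        raise InvalidParameterError("spiked amounts must be positive")
    per_level = 100.0 * (measured - blank_mg_kg) / spiked
    if aggregate == "mean":
        return float(per_level.mean())
    if aggregate == "median":
        return float(np.median(per_level))
    raise InvalidParameterError(f"unknown aggregate {aggregate!r}")


def precision_cv(replicates: np.ndarray) -> float:
    """Coefficient of variation in percent, sample standard deviation."""
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise InvalidParameterError("need >= 2 replicates for a CV")
    mean = x.mean()
    if mean == 0:
        raise UndefinedStatisticError("CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / abs(mean))


def factorial_anova(table: pd.DataFrame, response: str = "recovery_pct",
                    factors: tuple[str, ...] = ("device", "coffee_type", "shaking_min"),
                    alpha: float = 0.05,
                    include_interactions: bool = False) -> pd.DataFrame:
    """Main-effects ANOVA of the ruggedness design.

    Fits ``response ~ C(f1) + C(f2) + ...`` and returns a frame indexed by
    factor with F statistics, p values and significance calls at ``alpha``.
    Type-II sums of squares are used throughout (they coincide with type I
    on the balanced full design and remain meaningful if cells are lost).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in factors + (response,):
        if col not in table.columns:
            raise InvalidParameterError(f"missing column {col!r}")
    counts = table.groupby(list(factors)).size()
    if counts.min() < 1:
        raise InvalidParameterError("empty design cell")
    n_cells = np.prod([table[f].nunique() for f in factors])
    if len(counts) < n_cells:
        import warnings
        warnings.warn("unbalanced design: missing cells, using type-II SS",
                      stacklevel=2)
    terms = [f"C({f})" for f in factors]
    if include_interactions:
        terms += [f"C({a}):C({b})" for i, a in enumerate(factors)
                  for b in factors[i + 1:]]
    model = smf.ols(f"{response} ~ " + " + ".join(terms), data=table).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov = aov.rename(index={f"C({f})": f for f in factors})
    aov["significant"] = aov["PR(>F)"] < alpha
    return aov


@dataclass
class ValidationReport:
    """Assembled validation output: limits, linearity, recovery/CV, ANOVA."""

    limits: dict[str, AnalyticalLimits] = field(default_factory=dict)
    linearity: dict[str, LinearityResult] = field(default_factory=dict)
    recovery_pct: dict[tuple[str, str], float] = field(default_factory=dict)
    cv_pct: dict[tuple[str, str], float] = field(default_factory=dict)
    anova: dict[str, pd.DataFrame] = field(default_factory=dict)

    def recovery_in_spec(self, analyte: str, matrix: str) -> bool:
        r = self.recovery_pct[(analyte, matrix)]
        return RECOVERY_SPEC_PCT[0] <= r <= RECOVERY_SPEC_PCT[1]

    def cv_in_spec(self, analyte: str, matrix: str) -> bool:
        return self.cv_pct[(analyte, matrix)] < CV_SPEC_PCT

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(analyte, matrix) table with specification stars."""
        rows = []
        keys = sorted(set(self.recovery_pct) | set(self.cv_pct))
        for analyte, matrix in keys:
            rec = self.recovery_pct.get((analyte, matrix), np.nan)
            cv = self.cv_pct.get((analyte, matrix), np.nan)
            rows.append({
                "analyte": analyte, "matrix": matrix,
                "recovery_pct": rec,
                "recovery_in_spec": bool(RECOVERY_SPEC_PCT[0] <= rec <= RECOVERY_SPEC_PCT[1])
                if np.isfinite(rec) else False,
                "cv_pct": cv,
                "cv_in_spec": bool(cv < CV_SPEC_PCT) if np.isfinite(cv) else False,
            })
        return pd.DataFrame(rows)

    def render_text(self) -> str:
        lines = ["Validation report", "================="]
        if self.limits:
            lines.append("\nAnalytical limits (mg/kg):")
            for name, lim in self.limits.items():
                lines.append(f"  {name:<18} LOD {lim.lod_mg_kg:8.2f}   "
                             f"LOQ {lim.loq_mg_kg:8.2f}   "
                             f"range {lim.concentration_range_used[0]:g}-"
                             f"{lim.concentration_range_used[1]:g}")
        if self.linearity:
            lines.append("\nLinearity:")
            for name, lin in self.linearity.items():
                lines.append(f"  {name:<18} slope {lin.slope:7.4f}   "
                             f"R^2 {lin.r_squared:7.4f}   "
                             f"range {lin.range_mg_kg[0]:g}-{lin.range_mg_kg[1]:g} mg/kg")
        frame = self.to_frame()
        if not frame.empty:
            lines.append("\nRecovery / precision per matrix "
                         "(spec 90-110% and CV < 15%; * = out of spec):")
            for _, row in frame.iterrows():
                star_r = "" if row.recovery_in_spec else " *"
                star_c = "" if row.cv_in_spec else " *"
                lines.append(f"  {row.analyte:<18} {row.matrix:<14} "
                             f"recovery {row.recovery_pct:6.1f}%{star_r:<3} "
                             f"CV {row.cv_pct:6.1f}%{star_c}")
        for analyte, aov in self.anova.items():
            lines.append(f"\nANOVA ({analyte}):")
            for factor in aov.index:
                if factor == "Residual":
                    continue
                p = aov.loc[factor, "PR(>F)"]
                sig = "significant" if aov.loc[factor, "significant"] else "n.s."
                lines.append(f"  {factor:<14} F = {aov.loc[factor, 'F']:8.2f}   "
                             f"p = {p:8.4f}   {sig}")
        return "\n".join(lines)


def build_validation_report(measurements: pd.DataFrame,
                            limit_levels_mg_kg: tuple[float, float] | None = (7.5, 375.0),
                            linearity_matrix: str = "arabica_decaf",
                            alpha_limits: float = 0.01, k_loq: float = 3.0,
                            anova_alpha: float = 0.05) -> ValidationReport:
    """Assemble the full validation report from a tidy measurement table.

    ``measurements`` needs columns: analyte, matrix (coffee_type), device,
    shaking_min, spiked_mg_kg, measured_mg_kg, is_blank. Limits are fitted
    on the lower working range of the linearity matrix (optionally
    restricted to ``limit_levels_mg_kg``); recoveries and CVs are computed
    per analyte and matrix over all non-blank measurements; the ANOVA
    response is the per-cell mean recovery.
    """
    report = ValidationReport()
    if measurements.empty:
        return report
    df = measurements.copy()
    non_blank = df[~df["is_blank"]]

    for analyte, sub in non_blank.groupby("analyte"):
        # linearity and limits in the reference matrix
        ref = sub[sub["matrix"] == linearity_matrix]
        if not ref.empty:
            agg = ref.groupby("spiked_mg_kg")["measured_mg_kg"].mean().reset_index()
            series = CalibrationSeries(analyte, agg["spiked_mg_kg"].to_numpy(),
                                       agg["measured_mg_kg"].to_numpy(),
                                       matrix=linearity_matrix)
            report.linearity[analyte] = fit_calibration(series)
            low = ref.copy()
            if limit_levels_mg_kg is not None:
                lo, hi = limit_levels_mg_kg
                low = ref[(ref["spiked_mg_kg"] >= lo) & (ref["spiked_mg_kg"] <= hi)]
            agg_low = low.groupby("spiked_mg_kg")["measured_mg_kg"].mean().reset_index()
            if len(agg_low) >= 5:
                lo_series = CalibrationSeries(analyte, agg_low["spiked_mg_kg"].to_numpy(),
                                              agg_low["measured_mg_kg"].to_numpy(),
                                              matrix=linearity_matrix)
                try:
                    report.limits[analyte] = din32645_limits(
                        lo_series, alpha=alpha_limits, k_loq=k_loq)
                except UnusableCalibrationError:
                    pass

        cell_rows = []
        per_meas_rec: dict[str, list[np.ndarray]] = {}
        for (matrix, device, shaking), cell in sub.groupby(
                ["matrix", "device", "shaking_min"]):
            blanks = df[(df["analyte"] == analyte) & df["is_blank"]
                        & (df["matrix"] == matrix) & (df["device"] == device)
                        & (df["shaking_min"] == shaking)]
            blank = float(blanks["measured_mg_kg"].mean()) if not blanks.empty else 0.0
            rec_i = 100.0 * (cell["measured_mg_kg"].to_numpy() - blank) \
                / cell["spiked_mg_kg"].to_numpy()
            per_meas_rec.setdefault(matrix, []).append(rec_i)
            cell_rows.append({"matrix": matrix, "coffee_type": matrix,
                              "device": device, "shaking_min": shaking,
                              "recovery_pct": float(rec_i.mean())})
        cells = pd.DataFrame(cell_rows)
        for matrix, grp in cells.groupby("matrix"):
            report.recovery_pct[(analyte, matrix)] = float(grp["recovery_pct"].mean())
        # CV pooled over the matrix's blank-corrected per-level recoveries
        for matrix, recs in per_meas_rec.items():
            pooled = np.concatenate(recs)
            try:
                report.cv_pct[(analyte, matrix)] = precision_cv(pooled)
            except UndefinedStatisticError:
                report.cv_pct[(analyte, matrix)] = float("nan")
        if cells["device"].nunique() > 1 and cells["shaking_min"].nunique() > 1:
            report.anova[analyte] = factorial_anova(cells, alpha=anova_alpha)
    return report
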