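"""Performance indices, AAMI compliance, BHS grading, Bland-Altman.

Errors are oriented ``actual - estimated`` throughout (the mean of these
is the mean difference ME); the error standard deviation STD uses the
n-1 denominator.  The AAMI criterion passes a device whose |ME| <= 5 mmHg
and STD <= 8 mmHg over at least 85 subjects; BHS grades A/B/C require
stated cumulative percentages of absolute errors within 5/10/15 mmHg.
Bland-Altman agreement uses differences ``estimated - reference`` with
limits md +/- 1.96 sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegressionMetrics",
    "StandardsSpec",
    "AAMIVerdict",
    "BHSResult",
    "BlandAltman",
    "EvalReport",
    "regression_metrics",
    "aami_check",
    "bhs_grade",
    "bland_altman",
    "evaluate",
]


@dataclass(frozen=True)
class StandardsSpec:
    """AAMI limits and the BHS grade table (cumulative % at 5/10/15 mmHg)."""

    aami_max_me: float = 5.0
    aami_max_std: float = 8.0
    aami_min_subjects: int = 85
    bhs_grades: dict = field(
        default_factory=lambda: {
            "A": (60.0, 85.0, 95.0),
            "B": (50.0, 75.0, 90.0),
            "C": (40.0, 65.0, 85.0),
        }
    )

    def __post_init__(self) -> None:
        a, b, c = (self.bhs_grades[g] for g in ("A", "B", "C"))
        if not all(x > y > z for x, y, z in zip(a, b, c)):
            raise ValueError("BHS grade thresholds must be strictly ordered A > B > C")


DEFAULT_STANDARDS = StandardsSpec()


@dataclass(frozen=True)
class RegressionMetrics:
    """The six agreement indices for one (actual, estimated) pairing."""

    n: int
    r2: float
    mae: float
    mse: float
    rmse: float
    me: float
    std: float
    mean_actual: float


@dataclass(frozen=True)
class AAMIVerdict:
    passed: bool
    reasons: tuple[str, ...]
    me: float
    std: float
    n_subjects: int


@dataclass(frozen=True)
class BHSResult:
    cumulative: tuple[float, float, float]  # % of |errors| <= 5, 10, 15 mmHg
    grade: str


@dataclass(frozen=True)
class BlandAltman:
    md: float
    sd: float
    lower: float
    upper: float
    fraction_inside: float


@dataclass
class EvalReport:
    """Everything the standards assessment needs for one model/target."""

    target: str
    metrics: RegressionMetrics
    aami: AAMIVerdict
    bhs: BHSResult
    bland_altman: BlandAltman

    def as_dict(self) -> dict:
        m = self.metrics
        return {
            "target": self.target,
            "n": m.n,
            "r2": m.r2,
            "mae": m.mae,
            "mse": m.mse,
            "rmse": m.rmse,
            "me": m.me,
            "std": m.std,
            "aami_pass": self.aami.passed,
            "aami_reasons": list(self.aami.reasons),
            "bhs_pct_le5": self.bhs.cumulative[0],
            "bhs_pct_le10": self.bhs.cumulative[1],
            "bhs_pct_le15": self.bhs.cumulative[2],
            "bhs_grade": self.bhs.grade,
            "ba_md": self.bland_altman.md,
            "ba_sd": self.bland_altman.sd,
            "ba_lower": self.bland_altman.lower,
            "ba_upper": self.bland_altman.upper,
        }


def _pair(actual, estimated) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if a.shape != e.shape or a.ndim != 1:
        raise ValueError("actual and estimated must be equal-length 1-D arrays")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(e))):
        raise ValueError("non-finite values in actual/estimated")
    return a, e


def regression_metrics(actual, estimated) -> RegressionMetrics:
    """R^2, MAE, MSE, RMSE, ME and STD with errors ``actual - estimated``.

    R^2 is ``1 - SS_res/SS_tot`` about the mean of the *actual* values;
    for a constant actual vector it is undefined and reported as NaN.
    STD is the n-1-denominator standard deviation of the errors about ME.
    """
    a, e = _pair(actual, estimated)
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    err = a - e
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    me = float(np.mean(err))
    std = float(np.sqrt(np.sum((err - me) ** 2) / (a.size - 1)))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else float("nan")
    return RegressionMetrics(
        n=a.size, r2=r2, mae=mae, mse=mse, rmse=rmse, me=me, std=std,
        mean_actual=float(a.mean()),
    )


def aami_check(
    me: float,
    std: float,
    n_subjects: int,
    spec: StandardsSpec = DEFAULT_STANDARDS,
) -> AAMIVerdict:
    """AAMI verdict: pass iff |ME| <= 5, STD <= 8 and subjects >= 85.

    Boundary comparisons are inclusive.  Failing criteria are enumerated
    in ``reasons``.
    """
    reasons = []
    if abs(me) > spec.aami_max_me:
        reasons.append(f"|ME| {abs(me):.3f} > {spec.aami_max_me} mmHg")
    if std > spec.aami_max_std:
        reasons.append(f"STD {std:.3f} > {spec.aami_max_std} mmHg")
    if n_subjects < spec.aami_min_subjects:
        reasons.append(f"subjects {n_subjects} < {spec.aami_min_subjects}")
    return AAMIVerdict(
        passed=not reasons, reasons=tuple(reasons), me=me, std=std,
        n_subjects=n_subjects,
    )


def bhs_grade(
    actual,
    estimated,
    spec: StandardsSpec = DEFAULT_STANDARDS,
) -> BHSResult:
    """Cumulative error percentages at 5/10/15 mmHg and the BHS grade.

    The grade is the best one whose three thresholds are all met
    (inclusive); below grade C the result is "D".
    """
    a, e = _pair(actual, estimated)
    if a.size < 1:
        raise ValueError("need at least 1 pair")
    abs_err = np.abs(a - e)
    cumulative = tuple(float(100.0 * np.mean(abs_err <= t)) for t in (5.0, 10.0, 15.0))
    grade = "D"
    for g in ("C", "B", "A"):
        if all(c >= t for c, t in zip(cumulative, spec.bhs_grades[g])):
            grade = g
    return BHSResult(cumulative=cumulative, grade=grade)


def bland_altman(actual, estimated) -> BlandAltman:
    """Limits of agreement for differences ``estimated - actual``.

    md is the mean difference, sd its n-1 standard deviation, limits
    md +/- 1.96 sd; the fraction of points inside the limits is reported.
    """
    a, e = _pair(actual, estimated)
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = e - a
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lower, upper = md - 1.96 * sd, md + 1.96 * sd
    inside = float(np.mean((diff >= lower) & (diff <= upper)))
    return BlandAltman(md=md, sd=sd, lower=lower, upper=upper, fraction_inside=inside)


def evaluate(
    actual,
    estimated,
    n_subjects: int,
    target: str = "",
    spec: StandardsSpec = DEFAULT_STANDARDS,
) -> EvalReport:
    """Full report: six indices, AAMI verdict, BHS grade, Bland-Altman."""
    metrics = regression_metrics(actual, estimated)
    return EvalReport(
        target=target,
        metrics=metrics,
        aami=aami_check(metrics.me, metrics.std, n_subjects, spec),
        bhs=bhs_grade(actual, estimated, spec),
        bland_altman=bland_altman(actual, estimated),
    )
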