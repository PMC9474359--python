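"""Two-sample comparison statistics for cohort measurement tables.

Implements the tests the morphometry study design calls for: two-tailed
unpaired t-tests (Student's pooled-variance by default, Welch always
co-reported), Fisher's exact test for 2×2 demographics, the normal-
approximation sample-size formula for a two-group mean comparison, and a
cohort-comparison report combining them. No multiple-testing correction is
applied (a note is attached to reports running more than three tests).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "SummaryStats",
    "TestResult",
    "ComparisonReport",
    "t_test_from_summary",
    "t_test_from_samples",
    "fisher_exact_2x2",
    "min_sample_size",
    "compare_cohorts",
]


@dataclass(frozen=True)
class SummaryStats:
    """Group summary: count, mean, sample SD (ddof=1)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("SummaryStats requires n >= 2")
        if self.sd < 0:
            raise ValidationError("sd must be non-negative")

    @classmethod
    def from_samples(cls, xs) -> "SummaryStats":
        xs = np.asarray(xs, dtype=float)
        if xs.ndim != 1 or xs.size < 2:
            raise ValidationError("need at least 2 observations per group")
        return cls(int(xs.size), float(xs.mean()), float(xs.std(ddof=1)))


@dataclass(frozen=True)
class TestResult:
    """A two-sided test outcome. ``df`` is None for exact tests."""

    statistic: float
    df: float | None
    p_value: float
    method: str  # "student" | "welch" | "fisher"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p-value outside [0, 1]")

    def display_p(self) -> str:
        """Table-style display: 2 significant figures, floored at 0.0001."""
        if self.p_value < 1e-4:
            return "0.0001"
        return f"{self.p_value:.2g}"


def t_test_from_summary(a: SummaryStats, b: SummaryStats,
                        method: str = "student") -> TestResult:
    """Two-tailed unpaired t-test from group summaries.

    ``student``: pooled variance, df = n1 + n2 − 2. ``welch``: unpooled
    variance with Welch–Satterthwaite df. Degenerate case of two zero-SD
    groups: equal means give p = 1 by convention, unequal means p = 0 with a
    warning (the groups are two distinct constants).
    """
    if method not in ("student", "welch"):
        raise ValidationError(f"unknown t-test method {method!r}")
    diff = a.mean - b.mean
    if a.sd == 0.0 and b.sd == 0.0:
        if diff == 0.0:
            return TestResult(0.0, float(a.n + b.n - 2), 1.0, method)
        warnings.warn("both groups have zero variance with unequal means; "
                      "p = 0 by convention", stacklevel=2)
        return TestResult(math.copysign(math.inf, diff),
                          float(a.n + b.n - 2), 0.0, method)
    va, vb = a.sd ** 2, b.sd ** 2
    if method == "student":
        df = float(a.n + b.n - 2)
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        se = math.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    else:
        sa, sb = va / a.n, vb / b.n
        se = math.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa ** 2 / (a.n - 1) + sb ** 2 / (b.n - 1))
    t = diff / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(float(t), float(df), min(p, 1.0), method)


def t_test_from_samples(xs, ys, method: str = "student") -> TestResult:
    """Two-tailed unpaired t-test from raw samples (reduces to summaries)."""
    return t_test_from_summary(SummaryStats.from_samples(xs),
                               SummaryStats.from_samples(ys), method)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Fisher's exact test for the 2×2 table [[a, b], [c, d]].

    Two-sided p: the sum of hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's (with 1e-12 relative slack, matching the usual convention).
    The reported statistic is the sample odds ratio (a·d)/(b·c), inf or nan
    where undefined.
    """
    counts = (a, b, c, d)
    if any((not float(x).is_integer()) or x < 0 for x in counts):
        raise ValidationError(f"counts must be non-negative integers, got {counts}")
    a, b, c, d = (int(x) for x in counts)
    total = a + b + c + d
    if total <= 0:
        raise ValidationError("grand total must be positive")
    row1, col1 = a + b, a + c
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    if row1 == 0 or col1 == 0 or row1 == total or col1 == total:
        return TestResult(odds, None, 1.0, "fisher")
    rv = sps.hypergeom(total, row1, col1)
    k_lo = max(0, col1 - (total - row1))
    k_hi = min(row1, col1)
    ks = np.arange(k_lo, k_hi + 1)
    pmf = rv.pmf(ks)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return TestResult(odds, None, min(p, 1.0), "fisher")


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of the normal-approximation sample-size calculation, with the
    formula inputs echoed."""

    n_per_group: int
    n_unrounded: float
    sd: float
    delta: float
    alpha: float
    power: float
    formula: str = "n = 2 (z_{1-a/2} + z_{1-b})^2 (sd/delta)^2, normal approximation"


def min_sample_size(sd: float, delta: float, alpha: float = 0.05,
                    power: float = 0.8) -> SampleSizeResult:
    """Smallest per-group n (ears) detecting a mean difference ``delta`` with
    the given SD, two-sided level alpha and the given power, by the
    normal-approximation formula 2·(z₁₋α/2 + z₁₋β)²·(sd/δ)²."""
    if sd <= 0:
        raise ValidationError("sd must be positive")
    if delta <= 0:
        raise ValidationError("delta must be positive")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValidationError("alpha and power must lie in (0, 1)")
    z = float(sps.norm.ppf(1.0 - alpha / 2.0) + sps.norm.ppf(power))
    n_raw = 2.0 * z * z * (sd / delta) ** 2
    return SampleSizeResult(int(math.ceil(n_raw)), n_raw, sd, delta, alpha, power)


@dataclass(frozen=True)
class MeasureComparison:
    a: SummaryStats
    b: SummaryStats
    student: TestResult
    welch: TestResult


@dataclass(frozen=True)
class ComparisonReport:
    """Cohort-comparison report: per-measure summaries + t-tests, optional
    demographics (age t-test, sex Fisher), and provenance."""

    plane: str
    group_labels: tuple[str, str]
    measures: dict  # measure name -> MeasureComparison
    sex_table: tuple | None = None  # ((F_a, M_a), (F_b, M_b))
    sex_fisher: TestResult | None = None
    age: MeasureComparison | None = None
    notes: tuple[str, ...] = ()
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(x):
            if isinstance(x, (MeasureComparison, TestResult, SummaryStats)):
                return {k: conv(v) for k, v in asdict(x).items()}
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            return x

        return {
            "plane": self.plane,
            "group_labels": list(self.group_labels),
            "measures": conv(self.measures),
            "sex_table": conv(self.sex_table),
            "sex_fisher": conv(self.sex_fisher),
            "age": conv(self.age),
            "notes": list(self.notes),
            "provenance": conv(self.provenance),
        }

    def to_table(self) -> pd.DataFrame:
        """Human-readable summary table (1-decimal means/SDs, display p)."""
        rows = []
        items = list(self.measures.items())
        if self.age is not None:
            items.append(("age_yr", self.age))
        for name, mc in items:
            rows.append({
                "measure": name,
                f"{self.group_labels[0]} n": mc.a.n,
                f"{self.group_labels[0]} mean (SD)": f"{mc.a.mean:.1f} ({mc.a.sd:.1f})",
                f"{self.group_labels[1]} n": mc.b.n,
                f"{self.group_labels[1]} mean (SD)": f"{mc.b.mean:.1f} ({mc.b.sd:.1f})",
                "p value": mc.student.display_p(),
            })
        if self.sex_fisher is not None:
            (fa, ma), (fb, mb) = self.sex_table
            rows.append({
                "measure": "n female",
                f"{self.group_labels[0]} n": fa + ma,
                f"{self.group_labels[0]} mean (SD)": f"{fa} ({100 * fa / (fa + ma):.1f}%)",
                f"{self.group_labels[1]} n": fb + mb,
                f"{self.group_labels[1]} mean (SD)": f"{fb} ({100 * fb / (fb + mb):.1f}%)",
                "p value": self.sex_fisher.display_p(),
            })
        return pd.DataFrame(rows)


def _measure_comparison(xs, ys) -> MeasureComparison:
    a, b = SummaryStats.from_samples(xs), SummaryStats.from_samples(ys)
    return MeasureComparison(a, b, t_test_from_summary(a, b, "student"),
                             t_test_from_summary(a, b, "welch"))


def compare_cohorts(measurements_a: pd.DataFrame, measurements_b: pd.DataFrame,
                    demographics_a: pd.DataFrame | None = None,
                    demographics_b: pd.DataFrame | None = None,
                    group_labels: tuple[str, str] = ("A", "B"),
                    provenance: dict | None = None) -> ComparisonReport:
    """Compare two cohorts of ear measurements (ears are the analysis unit).

    Angle and length get per-group summaries plus Student (primary) and
    Welch t-tests; with demographics, age gets a t-test and sex a Fisher
    exact test on the female/male 2×2 table. Both measurement tables must
    use the same reference plane.
    """
    planes = set(measurements_a["plane"]) | set(measurements_b["plane"])
    if len(planes) != 1:
        raise ValidationError(f"mixed reference planes across inputs: {sorted(planes)}")
    measures = {
        "angle_deg": _measure_comparison(measurements_a["angle_deg"],
                                         measurements_b["angle_deg"]),
        "length_mm": _measure_comparison(measurements_a["length_mm"],
                                         measurements_b["length_mm"]),
    }
    sex_table = sex_fisher = age = None
    n_tests = 2
    if demographics_a is not None and demographics_b is not None:
        age = _measure_comparison(demographics_a["age_yr"], demographics_b["age_yr"])
        fa = int((demographics_a["sex"] == "F").sum())
        ma = int((demographics_a["sex"] == "M").sum())
        fb = int((demographics_b["sex"] == "F").sum())
        mb = int((demographics_b["sex"] == "M").sum())
        sex_table = ((fa, ma), (fb, mb))
        sex_fisher = fisher_exact_2x2(fa, ma, fb, mb)
        n_tests = 4
    notes = []
    if n_tests > 3:
        notes.append(f"{n_tests} tests reported without multiple-testing correction")
    return ComparisonReport(
        plane=planes.pop(),
        group_labels=tuple(group_labels),
        measures=measures,
        sex_table=sex_table,
        sex_fisher=sex_fisher,
        age=age,
        notes=tuple(notes),
        provenance=provenance or {},
    )
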