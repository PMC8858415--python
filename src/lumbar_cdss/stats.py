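"""Nonparametric comparison machinery for cohort tables.

Reproduces the analysis style of the source study: Me [Q1; Q3] summaries,
Mann-Whitney U for independent groups, Wilcoxon signed-rank for paired
timepoints, Pearson chi-square for binary traits, per-variable significance
at alpha = 0.05 with no multiplicity correction by default (a Holm option
exists but is off, mirroring the original analysis).

The tests themselves are delegated to scipy.stats; this module fixes the
policy — when the exact null distribution is used versus the tie- and
continuity-corrected normal approximation — and the report layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import Arm, PatientRecord, RuleConfig, Timepoint
from .engine import classify

__all__ = [
    "TestResult",
    "ComparisonReport",
    "quartile_summary",
    "format_quartiles",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "chi_square_2x2",
    "compare_cohorts",
    "paired_timepoints",
    "concordance",
    "ConcordanceResult",
]

ALPHA = 0.05

#: Largest min(n1, n2) for which the Mann-Whitney exact null is enumerated.
MW_EXACT_MAX_N = 8
#: Largest number of informative pairs for which the Wilcoxon exact null is used.
WILCOXON_EXACT_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def quartile_summary(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) under the linear-interpolation quantile definition."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("quartile_summary requires at least one value")
    q1, me, q3 = np.percentile(x, [25, 50, 75], method="linear")
    return float(me), float(q1), float(q3)


def format_quartiles(values) -> str:
    """Render values as "Me [Q1; Q3]", with integer rendering for integers."""
    me, q1, q3 = quartile_summary(values)

    def fmt(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else f"{v:.1f}"

    return f"{fmt(me)} [{fmt(q1)}; {fmt(q3)}]"


def _has_ties(*samples) -> bool:
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration when min(n1, n2) <= 8 and the pooled sample is
    tie-free; otherwise the normal approximation with midrank tie correction
    and continuity correction.  The reported statistic is U of the first
    sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    exact = min(x.size, y.size) <= MW_EXACT_MAX_N and not _has_ties(x, y)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        method=f"mann-whitney ({method}" + ("" if exact else ", tie/continuity corrected") + ")",
        n1=int(x.size),
        n2=int(y.size),
    )


def wilcoxon_signed_rank(before, after) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zero differences are dropped; the exact null is used for <= 12
    informative pairs with tie-free absolute differences, else the
    continuity-corrected normal approximation.  All-zero differences yield
    p = 1 with a warning (no evidence of change, no information either).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size != after.size:
        raise ValueError("paired samples must have equal length")
    d = before - after
    informative = d[d != 0]
    if informative.size == 0:
        warnings.warn("all paired differences are zero; returning p = 1", stacklevel=2)
        return TestResult(statistic=0.0, p_value=1.0, method="wilcoxon (degenerate)",
                          n1=int(before.size), n2=int(after.size))
    exact = informative.size <= WILCOXON_EXACT_MAX_N and not _has_ties(np.abs(informative))
    method = "exact" if exact else "approx"
    res = sps.wilcoxon(before, after, zero_method="wilcox", correction=not exact,
                       alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        method=f"wilcoxon ({method}" + ("" if exact else ", tie/continuity corrected") + ")",
        n1=int(before.size),
        n2=int(after.size),
    )


def chi_square_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]], df = 1.

    No continuity correction by default; pass ``yates=True`` for Yates'
    correction.  Margins must all be positive.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all table margins must be positive")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=yates)
    return TestResult(
        statistic=float(chi2),
        p_value=float(p),
        method="pearson chi-square" + (" (yates)" if yates else ""),
        n1=int(table[0].sum()),
        n2=int(table[1].sum()),
    )


# --- table-style reports -----------------------------------------------------

@dataclass(frozen=True)
class ComparisonRow:
    variable: str
    summary_a: str
    summary_b: str
    result: TestResult

    @property
    def significant(self) -> bool:
        return self.result.p_value < ALPHA


@dataclass(frozen=True)
class ComparisonReport:
    """Per-variable two-group comparison in the style of a cohort table."""

    rows: tuple[ComparisonRow, ...]
    label_a: str = "A"
    label_b: str = "B"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": [r.variable for r in self.rows],
                self.label_a: [r.summary_a for r in self.rows],
                self.label_b: [r.summary_b for r in self.rows],
                "statistic": [r.result.statistic for r in self.rows],
                "p": [r.result.p_value for r in self.rows],
                "method": [r.result.method for r in self.rows],
                "significant": [r.significant for r in self.rows],
            }
        )

    def to_text(self) -> str:
        frame = self.to_frame().copy()
        frame["p"] = frame["p"].map(lambda p: f"{p:.3f}")
        frame = frame.drop(columns=["statistic", "method"])
        return frame.to_string(index=False)

    def holm_adjusted(self) -> pd.DataFrame:
        """Holm step-down adjusted p-values (off by default in reports)."""
        frame = self.to_frame()
        p = frame["p"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        frame["p_holm"] = adj
        frame["significant_holm"] = frame["p_holm"] < ALPHA
        return frame


def _is_binary(series: pd.Series) -> bool:
    values = series.dropna().unique()
    if len(values) > 2:
        return False
    return series.dtype == bool or all(
        isinstance(v, (bool, np.bool_, str)) or v in (0, 1) for v in values
    )


def _binary_summary(series: pd.Series, positive) -> str:
    n = int((series == positive).sum())
    return f"{n} ({100 * n / len(series):.1f})" if len(series) else "0 (0.0)"


def compare_cohorts(
    frame_a: pd.DataFrame,
    frame_b: pd.DataFrame,
    variables: Sequence[str],
    label_a: str = "A",
    label_b: str = "B",
) -> ComparisonReport:
    """Compare two cohort tables variable by variable.

    Continuous and ordinal columns get Me [Q1; Q3] summaries and a
    Mann-Whitney test; binary columns (two-level, e.g. sex or tropism) get
    count (%) summaries and a Pearson chi-square on the 2x2 table.  Rows
    appear in input order; unknown variables raise KeyError.
    """
    rows: list[ComparisonRow] = []
    for name in variables:
        for frame, label in ((frame_a, label_a), (frame_b, label_b)):
            if name not in frame.columns:
                raise KeyError(f"variable {name!r} missing from cohort {label}")
        a, b = frame_a[name].dropna(), frame_b[name].dropna()
        if _is_binary(pd.concat([a, b])):
            levels = sorted(pd.concat([a, b]).unique(), key=str)
            positive = levels[-1]
            table = (
                int((a == positive).sum()), int((a != positive).sum()),
                int((b == positive).sum()), int((b != positive).sum()),
            )
            result = chi_square_2x2(*table)
            rows.append(ComparisonRow(
                variable=f"{name}={positive}",
                summary_a=_binary_summary(a, positive),
                summary_b=_binary_summary(b, positive),
                result=result,
            ))
        else:
            rows.append(ComparisonRow(
                variable=name,
                summary_a=format_quartiles(a),
                summary_b=format_quartiles(b),
                result=mann_whitney_u(a.to_numpy(float), b.to_numpy(float)),
            ))
    return ComparisonReport(rows=tuple(rows), label_a=label_a, label_b=label_b)


def paired_timepoints(
    cohort: Sequence[PatientRecord], score: str, tp_a: Timepoint, tp_b: Timepoint
) -> TestResult:
    """Wilcoxon signed-rank on one score between two timepoints of a cohort."""
    before, after = [], []
    for record in cohort:
        rec_a, rec_b = record.outcome_at(tp_a), record.outcome_at(tp_b)
        if rec_a is not None and rec_b is not None:
            before.append(getattr(rec_a, score))
            after.append(getattr(rec_b, score))
    if not before:
        raise ValueError(f"no patient carries both {tp_a.value} and {tp_b.value} scores")
    return wilcoxon_signed_rank(before, after)


@dataclass(frozen=True)
class ConcordanceResult:
    family_fraction: float
    arm_fraction: float
    table: pd.DataFrame  # per-patient recommended vs received


_ARM_FAMILY = {Arm.TDR: "dynamic", Arm.MI_TLIF: "rigid", Arm.O_TLIF: "rigid"}


def concordance(
    cohort: Sequence[PatientRecord], config: Optional[RuleConfig] = None
) -> ConcordanceResult:
    """Agreement between engine recommendations and the arms patients received.

    Family-level concordance counts a match when the recommended family
    equals the received arm's family; arm-level requires the exact arm.
    INDETERMINATE recommendations count as discordant at both levels.
    """
    records = [r for r in cohort]
    if not records:
        raise ValueError("concordance is undefined on an empty cohort")
    cfg = config or RuleConfig()
    rows = []
    for record in records:
        if record.received_arm is None:
            raise ValueError(f"record {record.id} lacks a received arm")
        rec = classify(record.profile, cfg)
        received_family = _ARM_FAMILY[record.received_arm]
        family_match = rec.arm != Arm.INDETERMINATE and rec.family.value == received_family
        rows.append(
            {
                "id": record.id,
                "received_arm": record.received_arm.value,
                "received_family": received_family,
                "recommended_arm": rec.arm.value,
                "recommended_family": rec.family.value,
                "family_match": bool(family_match),
                "arm_match": rec.arm == record.received_arm,
                "outcome_label": record.outcome_label.value if record.outcome_label else None,
            }
        )
    table = pd.DataFrame(rows)
    return ConcordanceResult(
        family_fraction=float(table["family_match"].mean()),
        arm_fraction=float(table["arm_match"].mean()),
        table=table,
    )
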