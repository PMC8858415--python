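"""Quantile-matched synthetic cohorts.

The published evidence base for this triage problem is a set of per-arm,
per-outcome-stratum summary tables — median and quartiles, Me [Q1; Q3] — with
no deposited patient-level data.  This module regenerates patient-level
cohorts whose marginal distributions match those summaries exactly at the
three printed quantiles, so the decision engine and the comparison machinery
can be exercised end to end at any sample size.

The sampler is a two-piece (split) normal pinned at (Q1, Me, Q3): each half
of the unit interval maps through a normal quantile function with its own
scale, ``sigma_low = (Me - Q1) / z0.75`` below the median and
``sigma_high = (Q3 - Me) / z0.75`` above it.  This is the minimal model that
reproduces all three printed quantiles, accommodates the strong skew of
entries like 6 [6; 8] (where sigma_low = 0 collapses the lower half to a
point mass at the median), and degenerates gracefully to a point mass for
m [m; m].  Variables are sampled independently within a stratum: the tables
print no correlations, so stratum membership carries all the dependence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import norm

from .types import (
    Arm,
    Level,
    OutcomeLabel,
    OutcomeRecord,
    PatientRecord,
    SegmentProfile,
    Sex,
    Timepoint,
    Tropism,
)

__all__ = [
    "QuartileSpec",
    "TwoPieceParams",
    "CohortSpec",
    "fit_two_piece",
    "sample_continuous",
    "sample_ordinal",
    "sample_tropism",
    "load_calibration",
    "cohort_spec",
    "generate_cohort",
    "generate_trajectories",
    "Z_UPPER_QUARTILE",
    "TROPISM_PRESENT_PROB",
]

#: Standard normal upper quartile, z such that Phi(z) = 0.75.
Z_UPPER_QUARTILE = float(norm.ppf(0.75))

#: Probability that tropism is present, by summary-table symbol.  The tables
#: print only "+", "-" or "+/-"; the 0.9/0.1/0.5 mapping is a documented
#: convention ("+" = predominantly present, "-" = predominantly absent,
#: "+/-" = mixed).
TROPISM_PRESENT_PROB = {"+": 0.9, "-": 0.1, "+/-": 0.5}

#: Follow-up schedule in months after surgery (preop at 0).
TIMEPOINT_MONTHS = {
    Timepoint.PREOP: 0.0,
    Timepoint.DISCHARGE: 0.5,
    Timepoint.M3: 3.0,
    Timepoint.M6: 6.0,
    Timepoint.M24: 24.0,
}


@dataclass(frozen=True)
class QuartileSpec:
    """A Me [Q1; Q3] calibration entry, with optional clamps and rounding."""

    me: float
    q1: float
    q3: float
    lower: Optional[float] = None
    upper: Optional[float] = None
    integer_valued: bool = False

    def __post_init__(self) -> None:
        if not (self.q1 <= self.me <= self.q3):
            raise ValueError(f"unordered quartiles: Q1={self.q1}, Me={self.me}, Q3={self.q3}")
        if self.lower is not None and self.lower > self.q1:
            raise ValueError("lower bound must not exceed Q1")
        if self.upper is not None and self.upper < self.q3:
            raise ValueError("upper bound must not fall below Q3")


@dataclass(frozen=True)
class TwoPieceParams:
    """Fitted two-piece normal: location and the two half-scales."""

    me: float
    sigma_low: float
    sigma_high: float
    lower: Optional[float] = None
    upper: Optional[float] = None
    integer_valued: bool = False

    def quantile(self, u) -> np.ndarray:
        """Closed-form quantile function (before clamping/rounding).

        Maps u < 0.5 through the lower half-scale and u >= 0.5 through the
        upper one; by construction quantile(0.25) = Q1, quantile(0.5) = Me,
        quantile(0.75) = Q3 to machine precision.
        """
        u = np.asarray(u, dtype=float)
        z = norm.ppf(u)
        sigma = np.where(u < 0.5, self.sigma_low, self.sigma_high)
        return self.me + sigma * z


def fit_two_piece(spec: QuartileSpec) -> TwoPieceParams:
    """Fit the two-piece normal sampler to a Me [Q1; Q3] entry.

    sigma_low = (Me - Q1) / z0.75 and sigma_high = (Q3 - Me) / z0.75, so the
    implied quantile function reproduces the three printed quantiles exactly;
    a zero half-width yields a point mass on that side.
    """
    return TwoPieceParams(
        me=float(spec.me),
        sigma_low=(spec.me - spec.q1) / Z_UPPER_QUARTILE,
        sigma_high=(spec.q3 - spec.me) / Z_UPPER_QUARTILE,
        lower=spec.lower,
        upper=spec.upper,
        integer_valued=spec.integer_valued,
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_continuous(params: TwoPieceParams, n: int, seed) -> np.ndarray:
    """Draw n values by inverse transform; clamp, then round if integer-valued.

    ``seed`` may be an integer or an existing :class:`numpy.random.Generator`
    (the latter lets a caller thread one stream through many draws).
    """
    if n < 1:
        return np.empty(0)
    rng = _as_rng(seed)
    u = rng.uniform(0.0, 1.0, size=n)
    x = params.quantile(u)
    if params.lower is not None or params.upper is not None:
        x = np.clip(x, params.lower, params.upper)
    if params.integer_valued:
        x = np.rint(x)
    return x


def sample_ordinal(spec: QuartileSpec, n: int, seed, scale: tuple[int, int]) -> np.ndarray:
    """Sample an ordinal grade via the two-piece model on the numeric grade axis.

    Values are rounded to the nearest integer and clamped to the scale; a
    degenerate spec m [m; m] yields all m.
    """
    lo, hi = scale
    if not (lo <= spec.q1 and spec.q3 <= hi):
        raise ValueError(f"grade spec {spec} outside the scale [{lo}, {hi}]")
    params = fit_two_piece(spec)
    x = np.rint(params.quantile(_as_rng(seed).uniform(0.0, 1.0, size=n)))
    return np.clip(x, lo, hi).astype(int)


def sample_tropism(symbol: str, n: int, seed) -> np.ndarray:
    """Draw n tropism-present booleans from a summary-table symbol."""
    key = symbol.replace("–", "-").replace("−", "-")  # dash variants
    if key not in TROPISM_PRESENT_PROB:
        raise ValueError(f"unknown tropism symbol {symbol!r}")
    return _as_rng(seed).uniform(size=n) < TROPISM_PRESENT_PROB[key]


# --- cohort assembly ---------------------------------------------------------

def load_calibration() -> dict:
    """Load the packaged per-arm calibration tables."""
    with resources.files(__package__).joinpath("calibration.json").open("r", encoding="utf-8") as fh:
        return json.load(fh)


def _qs(entry: Mapping, **kw) -> QuartileSpec:
    return QuartileSpec(me=entry["me"], q1=entry["q1"], q3=entry["q3"], **kw)


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one arm's synthetic cohort."""

    arm: Arm
    n_good: int
    n_poor: int
    calibration: Mapping[str, Mapping[str, QuartileSpec]]  # stratum -> variable -> spec
    grade_specs: Mapping[str, Mapping[str, QuartileSpec]]  # stratum -> {pfirrmann, fujiwara}
    tropism_symbol: Mapping[str, str]  # stratum -> "+", "-", "+/-"
    age: QuartileSpec = field(default=None)  # type: ignore[assignment]
    bmi: QuartileSpec = field(default=None)  # type: ignore[assignment]
    male_fraction: float = 0.5
    level_weights: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_good < 0 or self.n_poor < 0:
            raise ValueError("stratum counts must be non-negative")
        if not (0 <= self.male_fraction <= 1):
            raise ValueError("male_fraction must lie in [0, 1]")


_PROFILE_BOUNDS = {
    "linear_translation": dict(lower=0.0),
    "sagittal_angulation": dict(lower=0.0),
    "facet_angle": dict(lower=5.0, upper=175.0),
    "general_lordosis": dict(),
    "ivd_height": dict(lower=1.0),
    "adc": dict(lower=50.0),
}

_HEIGHT_LOSS_BOUNDS = dict(lower=1.0 / 3.0, upper=2.0 / 3.0)


def cohort_spec(
    arm: Arm | str,
    n_good: int | None = None,
    n_poor: int | None = None,
    seed: int = 0,
    population: str = "retrospective",
) -> CohortSpec:
    """Build a :class:`CohortSpec` from the packaged calibration tables.

    Stratum sizes default to the retrospective counts (35/7, 64/15, 62/13).
    ``population`` selects whose demographics to draw (retrospective or
    prospective); profile and outcome calibration always comes from the
    retrospective strata — the only patient-parameter summaries published.
    """
    arm = Arm(arm)
    cal = load_calibration()
    strata = cal["strata"][arm.value]
    demo = cal["demographics"][arm.value][population]
    assume = cal["assumptions"]

    calibration: dict[str, dict[str, QuartileSpec]] = {}
    grade_specs: dict[str, dict[str, QuartileSpec]] = {}
    tropism_symbol: dict[str, str] = {}
    for stratum in ("good", "poor"):
        entry = strata[stratum]
        variables = {
            name: _qs(entry["profile"][name], **_PROFILE_BOUNDS[name])
            for name in _PROFILE_BOUNDS
        }
        variables["height_loss_fraction"] = _qs(
            assume["height_loss_fraction"], **_HEIGHT_LOSS_BOUNDS
        )
        for score in ("odi", "vas_back", "vas_leg"):
            variables[f"{score}_m24"] = _qs(
                entry["outcomes_m24"][score], lower=0.0, upper=100.0, integer_valued=True
            )
        calibration[stratum] = variables
        grade_specs[stratum] = {
            "pfirrmann": _qs(entry["pfirrmann"]),
            "fujiwara": _qs(entry["fujiwara"]),
        }
        tropism_symbol[stratum] = entry["tropism"]

    total = demo["male"] + demo["female"]
    return CohortSpec(
        arm=arm,
        n_good=strata["good"]["n"] if n_good is None else n_good,
        n_poor=strata["poor"]["n"] if n_poor is None else n_poor,
        calibration=calibration,
        grade_specs=grade_specs,
        tropism_symbol=tropism_symbol,
        age=_qs(demo["age"], lower=18.0, upper=90.0, integer_valued=True),
        bmi=_qs(demo["bmi"], lower=15.0, upper=50.0),
        male_fraction=demo["male"] / total,
        level_weights=dict(demo["levels"]),
        seed=seed,
    )


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Generate ``n_good + n_poor`` patient records, fully seeded.

    Each record's stratum selects the quartile specs that calibrate its
    preoperative profile and 24-month scores; demographics are shared across
    strata (the tables stratify them by arm only).  Two calls with equal
    (spec, seed) return equal records.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[PatientRecord] = []
    levels = sorted(spec.level_weights)
    level_p = np.array([spec.level_weights[k] for k in levels], dtype=float)
    if levels:
        level_p = level_p / level_p.sum()

    for stratum, n in (("good", spec.n_good), ("poor", spec.n_poor)):
        if n == 0:
            continue
        cal = spec.calibration[stratum]
        draws = {
            name: sample_continuous(fit_two_piece(cal[name]), n, rng)
            for name in cal
        }
        pfirrmann = sample_ordinal(spec.grade_specs[stratum]["pfirrmann"], n, rng, (1, 5))
        fujiwara = sample_ordinal(spec.grade_specs[stratum]["fujiwara"], n, rng, (1, 4))
        tropism_present = sample_tropism(spec.tropism_symbol[stratum], n, rng)
        ages = sample_continuous(fit_two_piece(spec.age), n, rng)
        bmis = sample_continuous(fit_two_piece(spec.bmi), n, rng)
        is_male = rng.uniform(size=n) < spec.male_fraction
        if levels:
            level_draw = rng.choice(levels, size=n, p=level_p)
        else:
            level_draw = np.full(n, Level.L4_L5.value)

        for i in range(n):
            profile = SegmentProfile(
                level=Level(level_draw[i]),
                linear_translation=float(draws["linear_translation"][i]),
                sagittal_angulation=float(draws["sagittal_angulation"][i]),
                facet_angle=float(draws["facet_angle"][i]),
                tropism=Tropism.PRESENT if tropism_present[i] else Tropism.ABSENT,
                pfirrmann=int(pfirrmann[i]),
                fujiwara=int(fujiwara[i]),
                adc=float(draws["adc"][i]),
                ivd_height=float(draws["ivd_height"][i]),
                height_loss_fraction=float(draws["height_loss_fraction"][i]),
                general_lordosis=float(draws["general_lordosis"][i]),
            )
            records.append(
                PatientRecord(
                    id=f"{spec.arm.value}-{stratum}-{i + 1:03d}",
                    age=float(ages[i]),
                    sex=Sex.MALE if is_male[i] else Sex.FEMALE,
                    bmi=round(float(bmis[i]), 1),
                    profile=profile,
                    received_arm=spec.arm,
                    outcome_label=OutcomeLabel(stratum),
                    outcomes=(
                        OutcomeRecord(
                            timepoint=Timepoint.M24,
                            odi=float(draws["odi_m24"][i]),
                            vas_back=float(draws["vas_back_m24"][i]),
                            vas_leg=float(draws["vas_leg_m24"][i]),
                        ),
                    ),
                )
            )
    return records


def generate_trajectories(
    records: Sequence[PatientRecord],
    seed: int,
    noise_sd: float = 1.5,
    decay_months: float = 3.0,
) -> list[PatientRecord]:
    """Fill in the follow-up schedule (preop, discharge, 3 and 6 months).

    Each score relaxes from a preoperative level toward the patient's
    calibrated 24-month endpoint along an exponential decay
    ``s(t) = end + (pre - end) * exp(-t / decay_months)`` with additive
    Gaussian noise (sd ``noise_sd`` points/mm) at post-operative interior
    timepoints.  Preop levels are drawn from the packaged severe-symptoms
    assumption and floored at the endpoint, so with ``noise_sd = 0`` every
    trajectory is exactly monotone non-increasing.  The calibrated 24-month
    record is preserved untouched.
    """
    rng = np.random.default_rng(seed)
    assume = load_calibration()["assumptions"]["preop_scores"]
    pre_params = {
        score: fit_two_piece(_qs(assume[score], lower=0.0, upper=100.0))
        for score in ("odi", "vas_back", "vas_leg")
    }
    out: list[PatientRecord] = []
    interior = (Timepoint.PREOP, Timepoint.DISCHARGE, Timepoint.M3, Timepoint.M6)
    for record in records:
        m24 = record.outcome_at(Timepoint.M24)
        if m24 is None:
            raise ValueError(f"record {record.id} lacks a 24-month outcome to anchor the trajectory")
        ends = {"odi": m24.odi, "vas_back": m24.vas_back, "vas_leg": m24.vas_leg}
        pres = {
            score: max(float(sample_continuous(pre_params[score], 1, rng)[0]), ends[score])
            for score in ends
        }
        new_outcomes = []
        for tp in interior:
            t = TIMEPOINT_MONTHS[tp]
            scores = {}
            for name in ends:
                value = ends[name] + (pres[name] - ends[name]) * np.exp(-t / decay_months)
                if noise_sd > 0 and tp != Timepoint.PREOP:
                    value += rng.normal(0.0, noise_sd)
                scores[name] = float(np.clip(np.rint(value), 0.0, 100.0))
            new_outcomes.append(OutcomeRecord(timepoint=tp, odi=scores["odi"],
                                             vas_back=scores["vas_back"], vas_leg=scores["vas_leg"]))
        new_outcomes.append(m24)
        out.append(
            PatientRecord(
                id=record.id, age=record.age, sex=record.sex, bmi=record.bmi,
                profile=record.profile, received_arm=record.received_arm,
                outcome_label=record.outcome_label, outcomes=tuple(new_outcomes),
            )
        )
    return out
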