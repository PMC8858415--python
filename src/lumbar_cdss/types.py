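"""Domain data model for lumbar-segment triage.

Every measured quantity that enters the surgical-approach decision is housed
here: the biometric/radiological profile of a single lumbar segment, patient
demographics, patient-reported outcome scores, the full set of decision
thresholds, and the recommendation record the engine emits.

Validation is deliberately *total*: out-of-range values are representable and
are reported as violation messages by :func:`validate_profile`, never as
exceptions at construction time.  This keeps ingestion of messy checklist
files lossless — a row with Pfirrmann "VI" is a data error to be reported
with its line number, not a crash.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence


class Level(str, Enum):
    """Operated lumbar segment (lumbosacral transitional anatomy included)."""

    L2_L3 = "L2-L3"
    L3_L4 = "L3-L4"
    L4_L5 = "L4-L5"
    L5_S1 = "L5-S1"
    L5_L6 = "L5-L6"
    L6_S1 = "L6-S1"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Arm(str, Enum):
    """Surgical arm: motion-preserving arthroplasty or one of two fusions."""

    TDR = "TDR"
    MI_TLIF = "MI_TLIF"
    O_TLIF = "O_TLIF"
    INDETERMINATE = "INDETERMINATE"


class Family(str, Enum):
    """Biomechanical treatment family: dynamic fixation vs rigid stabilization."""

    DYNAMIC = "dynamic"
    RIGID = "rigid"


class Tropism(str, Enum):
    """Facet-joint tropism (left-right asymmetry of facet orientation)."""

    PRESENT = "present"
    ABSENT = "absent"
    UNKNOWN = "unknown"


class TropismPolarity(str, Enum):
    """Which fusion arm a present tropism points to.

    The algorithm's prose assigns ``absent -> MI, present -> O``; the
    retrospective summary table prints the opposite pattern for its
    good-outcome strata.  The contradiction is configured, not resolved:
    ``PROSE`` (default) follows the prose clauses, ``TABLE`` inverts them.
    """

    PROSE = "prose"
    TABLE = "table"


class Timepoint(str, Enum):
    PREOP = "preop"
    DISCHARGE = "discharge"
    M3 = "m3"
    M6 = "m6"
    M24 = "m24"


class OutcomeLabel(str, Enum):
    GOOD = "good"
    POOR = "poor"


class Band(str, Enum):
    """Which arm a single criterion's value is compatible with.

    ``TIE_MI_O`` marks values claimed by both fusion arms (e.g. Pfirrmann IV)
    and rigid-type instability findings, which are compatible with either
    fusion.  ``NEUTRAL`` marks values claimed by no clause (e.g. ADC in the
    1150-1240 gap): the engine must not invent a preference there.
    """

    TDR_COMPATIBLE = "TDR_compatible"
    MI = "MI"
    O = "O"
    TIE_MI_O = "tie_MI_O"
    NEUTRAL = "neutral"


PFIRRMANN_MIN, PFIRRMANN_MAX = 1, 5
FUJIWARA_MIN, FUJIWARA_MAX = 1, 4

_ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V"}
_ROMAN_INV = {v: k for k, v in _ROMAN.items()}


def grade_to_roman(grade: int) -> str:
    """Render an ordinal grade as the Roman numeral used in checklists."""
    try:
        return _ROMAN[int(grade)]
    except (KeyError, ValueError):
        raise ValueError(f"grade {grade!r} outside the I-V range")


def roman_to_grade(text: str) -> int:
    """Parse a Roman-numeral grade ("I".."V") to its integer value."""
    try:
        return _ROMAN_INV[str(text).strip().upper()]
    except KeyError:
        raise ValueError(f"unrecognized grade numeral {text!r}")


class ProfileValidationError(ValueError):
    """Raised when an operation requires a valid profile but got violations."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("; ".join(violations))


@dataclass(frozen=True)
class SegmentProfile:
    """Preoperative biometric/radiological parameters of one lumbar segment.

    Units follow the source measurements: translation and disc height in mm,
    angles in degrees, ADC (apparent diffusion coefficient, a DWI-MRI disc
    hydration measure) in s/mm².  ``sagittal_angulation`` is the segment's
    flexion-extension mobility ("sagittal range of motion"); one field serves
    both names since they carry the same 6° threshold.
    ``height_loss_fraction`` is the interbody height decrease relative to the
    superjacent disc, stored directly as a fraction so the 1/3-2/3 eligibility
    window is testable without recomputation.
    """

    level: Level
    linear_translation: float  # mm, anterior-posterior slip on functional films
    sagittal_angulation: float  # degrees, flexion-extension mobility
    facet_angle: float  # degrees, facet joint orientation
    tropism: Tropism
    pfirrmann: int  # disc degeneration grade, I..V (stored 1..5)
    fujiwara: int  # facet degeneration grade, I..IV (stored 1..4)
    adc: float  # s/mm², lower = more degenerated disc
    ivd_height: float  # mm
    height_loss_fraction: float  # in [0, 1], vs superjacent disc
    general_lordosis: float  # degrees

    def with_(self, **changes) -> "SegmentProfile":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def height_loss_fraction(disc_height_mm: float, superjacent_height_mm: float) -> float:
    """Height loss of a disc relative to its superjacent neighbour.

    Returns ``(h_sup - h) / h_sup`` clipped to [0, 1]; a disc taller than its
    neighbour counts as zero loss.
    """
    if superjacent_height_mm <= 0:
        raise ValueError("superjacent disc height must be positive")
    return min(1.0, max(0.0, (superjacent_height_mm - disc_height_mm) / superjacent_height_mm))


def validate_profile(profile: SegmentProfile) -> list[str]:
    """Check every profile invariant; return violation messages (empty = valid).

    Total over finite numeric inputs: never raises, each message names the
    offending field and the bound it violates.
    """
    v: list[str] = []

    def finite(name: str, x: float) -> bool:
        if not isinstance(x, (int, float)) or not math.isfinite(x):
            v.append(f"{name}: must be a finite number, got {x!r}")
            return False
        return True

    if finite("linear_translation", profile.linear_translation) and profile.linear_translation < 0:
        v.append(f"linear_translation: must be >= 0 mm, got {profile.linear_translation}")
    if finite("sagittal_angulation", profile.sagittal_angulation) and profile.sagittal_angulation < 0:
        v.append(f"sagittal_angulation: must be >= 0 degrees, got {profile.sagittal_angulation}")
    if finite("facet_angle", profile.facet_angle) and not (0 < profile.facet_angle < 180):
        v.append(f"facet_angle: must lie in (0, 180) degrees, got {profile.facet_angle}")
    if not isinstance(profile.tropism, Tropism):
        v.append(f"tropism: must be present/absent/unknown, got {profile.tropism!r}")
    if not (isinstance(profile.pfirrmann, int) and PFIRRMANN_MIN <= profile.pfirrmann <= PFIRRMANN_MAX):
        v.append(f"pfirrmann: grade must be in I..V, got {profile.pfirrmann!r}")
    if not (isinstance(profile.fujiwara, int) and FUJIWARA_MIN <= profile.fujiwara <= FUJIWARA_MAX):
        v.append(f"fujiwara: grade must be in I..IV, got {profile.fujiwara!r}")
    if finite("adc", profile.adc) and profile.adc <= 0:
        v.append(f"adc: must be > 0 s/mm², got {profile.adc}")
    if finite("ivd_height", profile.ivd_height) and profile.ivd_height <= 0:
        v.append(f"ivd_height: must be > 0 mm, got {profile.ivd_height}")
    if finite("height_loss_fraction", profile.height_loss_fraction) and not (
        0 <= profile.height_loss_fraction <= 1
    ):
        v.append(f"height_loss_fraction: must lie in [0, 1], got {profile.height_loss_fraction}")
    finite("general_lordosis", profile.general_lordosis)
    return v


def require_valid(profile: SegmentProfile) -> None:
    """Raise :class:`ProfileValidationError` if the profile has violations."""
    violations = validate_profile(profile)
    if violations:
        raise ProfileValidationError(violations)


@dataclass(frozen=True)
class RuleConfig:
    """All decision thresholds and policy switches of the triage algorithm.

    Defaults encode the published clauses verbatim, with inclusivity exactly
    as worded: translation "to a maximum of 4 mm" keeps 4 TDR-compatible;
    sagittal "not less than 6°" and facet "over 60°" make 6 and 60 vote
    rigid; ADC "not less than 1240" is TDR-inclusive while the 1150 and 950
    fusion bounds are strict upper bounds.
    """

    translation_max_tdr: float = 4.0  # mm, inclusive for TDR
    sagittal_min_rigid: float = 6.0  # degrees, inclusive for rigid
    facet_min_rigid: float = 60.0  # degrees, inclusive for rigid
    adc_min_tdr: float = 1240.0  # s/mm², inclusive for TDR
    adc_max_mi: float = 1150.0  # s/mm², exclusive upper bound of MI band
    adc_max_o: float = 950.0  # s/mm², exclusive upper bound of O band
    pfirrmann_tdr_max: int = 2  # I-II compatible with TDR
    pfirrmann_mi_band: tuple[int, int] = (3, 4)
    pfirrmann_o_band: tuple[int, int] = (4, 5)
    fujiwara_tdr_max: int = 2  # I-II compatible with TDR
    fujiwara_mi_band: tuple[int, int] = (2, 3)
    fujiwara_o_grade: int = 4
    tropism_polarity: TropismPolarity = TropismPolarity.PROSE
    height_loss_window: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)  # closed
    fuzzy_width_fraction: float = 0.10  # transition half-width, fraction of threshold

    def __post_init__(self) -> None:
        if not (self.adc_max_o < self.adc_max_mi < self.adc_min_tdr):
            raise ValueError("ADC thresholds must satisfy adc_max_o < adc_max_mi < adc_min_tdr")
        lo, hi = self.height_loss_window
        if not (0 <= lo <= hi <= 1):
            raise ValueError("height_loss_window must be ordered within [0, 1]")
        if self.fuzzy_width_fraction < 0:
            raise ValueError("fuzzy_width_fraction must be >= 0")

    _FLOAT_FIELDS = (
        "translation_max_tdr",
        "sagittal_min_rigid",
        "facet_min_rigid",
        "adc_min_tdr",
        "adc_max_mi",
        "adc_max_o",
        "fuzzy_width_fraction",
    )

    def to_mapping(self) -> dict:
        """Flat key-value form, as read from / written to a config file."""
        return {
            **{name: getattr(self, name) for name in self._FLOAT_FIELDS},
            "pfirrmann_tdr_max": self.pfirrmann_tdr_max,
            "fujiwara_tdr_max": self.fujiwara_tdr_max,
            "tropism_polarity": self.tropism_polarity.value,
            "height_loss_low": self.height_loss_window[0],
            "height_loss_high": self.height_loss_window[1],
        }

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "RuleConfig":
        """Build a config from a flat mapping; unknown keys are rejected."""
        kwargs: dict = {}
        window = list(cls().height_loss_window)
        for key, value in mapping.items():
            if key == "tropism_polarity":
                kwargs[key] = TropismPolarity(value)
            elif key == "height_loss_low":
                window[0] = float(value)
            elif key == "height_loss_high":
                window[1] = float(value)
            elif key in cls._FLOAT_FIELDS:
                kwargs[key] = float(value)
            elif key in ("pfirrmann_tdr_max", "fujiwara_tdr_max"):
                kwargs[key] = int(value)
            else:
                raise KeyError(f"unknown rule-config key {key!r}")
        kwargs["height_loss_window"] = (window[0], window[1])
        return cls(**kwargs)


def eligibility_gate(profile: SegmentProfile, config: RuleConfig | None = None) -> tuple[bool, list[str]]:
    """Inclusion gate on interbody height loss.

    Candidates for any arm must have lost more than 1/3 but no more than 2/3
    of interbody height relative to the superjacent disc (both ends closed
    under the default window).  Returns (eligible, reasons); reasons name the
    violated bound when ineligible.
    """
    require_valid(profile)
    config = config or RuleConfig()
    lo, hi = config.height_loss_window
    f = profile.height_loss_fraction
    reasons: list[str] = []
    if f < lo:
        reasons.append(f"height_loss_fraction {f:.3g} below the lower bound {lo:.3g} (insufficient collapse)")
    if f > hi:
        reasons.append(f"height_loss_fraction {f:.3g} above the upper bound {hi:.3g} (collapse too advanced)")
    return (not reasons, reasons)


@dataclass(frozen=True)
class CriterionVote:
    """One criterion's contribution to the recommendation, with its rationale."""

    criterion: str
    value: object
    band: Band
    rationale: str


@dataclass(frozen=True)
class Recommendation:
    """Engine output: arm, family, per-criterion votes, confidence, audit trail."""

    family: Family
    arm: Arm
    criterion_votes: Mapping[str, CriterionVote]
    confidence: float
    audit: tuple[str, ...]
    memberships: Optional[Mapping[str, float]] = None  # fuzzy mode only

    def to_json_dict(self) -> dict:
        d = {
            "arm": self.arm.value,
            "family": self.family.value,
            "confidence": round(self.confidence, 6),
            "votes": [
                {
                    "criterion": v.criterion,
                    "value": v.value.value if isinstance(v.value, Enum) else v.value,
                    "band": v.band.value,
                    "rationale": v.rationale,
                }
                for v in self.criterion_votes.values()
            ],
            "audit": list(self.audit),
        }
        if self.memberships is not None:
            d["memberships"] = {k: round(float(m), 6) for k, m in self.memberships.items()}
        return d


@dataclass(frozen=True)
class OutcomeRecord:
    """Patient-reported scores at one follow-up timepoint.

    ODI in points and VAS in mm, each on a 0-100 scale (VAS values observed
    in this population are small but the instrument's scale is 0-100 mm).
    """

    timepoint: Timepoint
    odi: float
    vas_back: float
    vas_leg: float

    def validate(self) -> list[str]:
        v = []
        for name in ("odi", "vas_back", "vas_leg"):
            x = getattr(self, name)
            if not (isinstance(x, (int, float)) and math.isfinite(x) and 0 <= x <= 100):
                v.append(f"{name}: must lie in [0, 100], got {x!r}")
        return v


@dataclass(frozen=True)
class PatientRecord:
    """One patient: demographics, segment profile, optional arm/outcome labels."""

    id: str
    age: float  # years
    sex: Sex
    bmi: float  # kg/m²
    profile: SegmentProfile
    received_arm: Optional[Arm] = None
    outcome_label: Optional[OutcomeLabel] = None
    outcomes: tuple[OutcomeRecord, ...] = field(default_factory=tuple)

    def validate(self) -> list[str]:
        v = []
        if not (isinstance(self.age, (int, float)) and math.isfinite(self.age) and self.age > 0):
            v.append(f"age: must be > 0 years, got {self.age!r}")
        if not (isinstance(self.bmi, (int, float)) and math.isfinite(self.bmi) and self.bmi > 0):
            v.append(f"bmi: must be > 0 kg/m², got {self.bmi!r}")
        v.extend(validate_profile(self.profile))
        for rec in self.outcomes:
            v.extend(rec.validate())
        return v

    def outcome_at(self, timepoint: Timepoint) -> Optional[OutcomeRecord]:
        for rec in self.outcomes:
            if rec.timepoint == timepoint:
                return rec
        return None
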