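"""Surgical-approach selection: crisp two-stage classifier and fuzzy variant.

Stage 1 assigns the biomechanical *family* from the instability triad
(linear translation, sagittal mobility, facet angle) by majority vote over
the three criteria.  Stage 2 picks the arm within the family: a dynamic
segment is a TDR candidate iff all degeneration criteria (Pfirrmann, ADC,
Fujiwara) are arthroplasty-compatible; a rigid segment is triaged between
minimally invasive and open fusion by tallying the four degeneration/tropism
votes.  Overlapping grade bands (Pfirrmann IV, Fujiwara II) are explicit tie
states, and the uncovered ADC gap [1150, 1240) is neutral — the engine never
invents a preference where the clauses state none.

The fuzzy variant replaces each crisp threshold t with a linear transition of
half-width ``fuzzy_width_fraction * t``; with width 0 it reduces exactly to
the crisp classifier.
"""

from __future__ import annotations

from typing import Callable, Sequence

from .types import (
    Arm,
    Band,
    CriterionVote,
    Family,
    ProfileValidationError,
    Recommendation,
    RuleConfig,
    SegmentProfile,
    Tropism,
    TropismPolarity,
    grade_to_roman,
    require_valid,
)

__all__ = [
    "instability_family",
    "adc_band",
    "pfirrmann_vote",
    "fujiwara_vote",
    "tropism_vote",
    "tdr_eligibility",
    "classify",
    "fuzzy_classify",
    "probe_boundary",
    "BoundaryNotFound",
    "CriterionVote",
    "Band",
]

#: The seven criteria every audit trail must cover, in reporting order.
CRITERIA = ("translation", "sagittal", "facet", "adc", "pfirrmann", "fujiwara", "tropism")


def instability_family(
    profile: SegmentProfile, config: RuleConfig | None = None
) -> tuple[Family, dict[str, bool]]:
    """Stage 1: dynamic vs rigid from the instability triad.

    Each of {translation > 4 mm, sagittal >= 6 deg, facet >= 60 deg} casts a
    rigid vote; the family is rigid iff at least two of the three vote rigid
    (a strict majority over an odd triad — no ties possible).

    Returns the family and the three boolean rigid votes.
    """
    require_valid(profile)
    cfg = config or RuleConfig()
    rigid_votes = {
        "translation": profile.linear_translation > cfg.translation_max_tdr,
        "sagittal": profile.sagittal_angulation >= cfg.sagittal_min_rigid,
        "facet": profile.facet_angle >= cfg.facet_min_rigid,
    }
    family = Family.RIGID if sum(rigid_votes.values()) >= 2 else Family.DYNAMIC
    return family, rigid_votes


def adc_band(adc: float, config: RuleConfig | None = None) -> Band:
    """Band the apparent diffusion coefficient (disc hydration, s/mm²).

    >= 1240 is arthroplasty-compatible; < 950 points to open fusion;
    [950, 1150) to minimally invasive fusion; the [1150, 1240) gap is claimed
    by no clause and stays neutral.
    """
    if not adc > 0:
        raise ProfileValidationError([f"adc: must be > 0 s/mm², got {adc}"])
    cfg = config or RuleConfig()
    if adc >= cfg.adc_min_tdr:
        return Band.TDR_COMPATIBLE
    if adc < cfg.adc_max_o:
        return Band.O
    if adc < cfg.adc_max_mi:
        return Band.MI
    return Band.NEUTRAL


def pfirrmann_vote(grade: int, config: RuleConfig | None = None) -> Band:
    """Band a Pfirrmann disc-degeneration grade (I..V as 1..5).

    I-II -> TDR-compatible; III -> MI; IV -> tie between the fusion arms
    (claimed by both the III-IV and IV-V bands); V -> open fusion.
    """
    cfg = config or RuleConfig()
    if not (isinstance(grade, int) and 1 <= grade <= 5):
        raise ProfileValidationError([f"pfirrmann: grade must be in I..V, got {grade!r}"])
    if grade <= cfg.pfirrmann_tdr_max:
        return Band.TDR_COMPATIBLE
    in_mi = cfg.pfirrmann_mi_band[0] <= grade <= cfg.pfirrmann_mi_band[1]
    in_o = cfg.pfirrmann_o_band[0] <= grade <= cfg.pfirrmann_o_band[1]
    if in_mi and in_o:
        return Band.TIE_MI_O
    if in_mi:
        return Band.MI
    if in_o:
        return Band.O
    return Band.NEUTRAL


def fujiwara_vote(
    grade: int, config: RuleConfig | None = None, family: Family = Family.DYNAMIC
) -> Band:
    """Band a Fujiwara facet-degeneration grade (I..IV as 1..4).

    Grade II sits in both the TDR (I-II) and MI (II-III) bands; the tie is
    resolved by the already-decided family: MI under a rigid family,
    TDR-compatible under a dynamic one.  I -> TDR-compatible, III -> MI,
    IV -> open fusion.
    """
    cfg = config or RuleConfig()
    if not (isinstance(grade, int) and 1 <= grade <= 4):
        raise ProfileValidationError([f"fujiwara: grade must be in I..IV, got {grade!r}"])
    if grade == cfg.fujiwara_o_grade:
        return Band.O
    in_tdr = grade <= cfg.fujiwara_tdr_max
    in_mi = cfg.fujiwara_mi_band[0] <= grade <= cfg.fujiwara_mi_band[1]
    if in_tdr and in_mi:
        return Band.MI if family == Family.RIGID else Band.TDR_COMPATIBLE
    if in_tdr:
        return Band.TDR_COMPATIBLE
    if in_mi:
        return Band.MI
    return Band.NEUTRAL


def tropism_vote(tropism: Tropism, config: RuleConfig | None = None) -> Band:
    """Band facet tropism under the configured polarity.

    Prose polarity (default): no tropism favours minimally invasive fusion,
    present tropism favours open fusion; table polarity inverts the mapping.
    Unknown tropism contributes no vote, and tropism never affects TDR
    eligibility ("regardless tropism").
    """
    cfg = config or RuleConfig()
    if tropism == Tropism.UNKNOWN:
        return Band.NEUTRAL
    present = tropism == Tropism.PRESENT
    if cfg.tropism_polarity == TropismPolarity.PROSE:
        return Band.O if present else Band.MI
    return Band.MI if present else Band.O


def tdr_eligibility(
    profile: SegmentProfile, config: RuleConfig | None = None
) -> tuple[bool, dict[str, bool]]:
    """Conjunctive arthroplasty check on the degeneration criteria.

    A dynamic segment is a TDR candidate iff Pfirrmann <= II, ADC >= 1240
    s/mm² and Fujiwara in {I, II}; tropism is ignored.  Returns the verdict
    and the per-criterion results (including the family requirement).
    """
    require_valid(profile)
    cfg = config or RuleConfig()
    family, _ = instability_family(profile, cfg)
    checks = {
        "family_dynamic": family == Family.DYNAMIC,
        "pfirrmann": profile.pfirrmann <= cfg.pfirrmann_tdr_max,
        "adc": adc_band(profile.adc, cfg) == Band.TDR_COMPATIBLE,
        "fujiwara": profile.fujiwara <= cfg.fujiwara_tdr_max,
    }
    return all(checks.values()), checks


_VOTE_WEIGHTS = {Band.MI: (1.0, 0.0), Band.O: (0.0, 1.0), Band.TIE_MI_O: (0.5, 0.5)}


def _stage2_tally(votes: Sequence[Band]) -> tuple[float, float, int]:
    """Tally MI/O weights over the four degeneration criteria.

    Returns (mi, o, neutral_count); a TDR-compatible band on a rigid segment
    carries no fusion preference and counts as neutral here, so
    mi + o + neutral == number of criteria always holds.
    """
    mi = o = 0.0
    neutral = 0
    for band in votes:
        if band in _VOTE_WEIGHTS:
            w_mi, w_o = _VOTE_WEIGHTS[band]
            mi += w_mi
            o += w_o
        else:
            neutral += 1
    return mi, o, neutral


def _collect_votes(profile: SegmentProfile, cfg: RuleConfig, family: Family,
                   rigid_votes: dict[str, bool]) -> dict[str, CriterionVote]:
    """Build the full seven-criterion vote table with rationales."""
    t = cfg.translation_max_tdr
    s = cfg.sagittal_min_rigid
    f = cfg.facet_min_rigid
    triad_rationale = {
        "translation": (
            f"linear translation {profile.linear_translation:g} mm "
            + (f"exceeds the {t:g} mm arthroplasty maximum" if rigid_votes["translation"]
               else f"within the {t:g} mm arthroplasty maximum")
        ),
        "sagittal": (
            f"sagittal mobility {profile.sagittal_angulation:g}° "
            + (f"not less than {s:g}° (rigid-type)" if rigid_votes["sagittal"]
               else f"less than {s:g}° (dynamic-type)")
        ),
        "facet": (
            f"facet angle {profile.facet_angle:g}° "
            + (f"at or over {f:g}° (rigid-type)" if rigid_votes["facet"]
               else f"less than {f:g}° (dynamic-compatible)")
        ),
    }
    votes: dict[str, CriterionVote] = {}
    for name in ("translation", "sagittal", "facet"):
        value = {
            "translation": profile.linear_translation,
            "sagittal": profile.sagittal_angulation,
            "facet": profile.facet_angle,
        }[name]
        votes[name] = CriterionVote(
            criterion=name,
            value=value,
            band=Band.TIE_MI_O if rigid_votes[name] else Band.TDR_COMPATIBLE,
            rationale=triad_rationale[name],
        )
    ab = adc_band(profile.adc, cfg)
    votes["adc"] = CriterionVote(
        criterion="adc",
        value=profile.adc,
        band=ab,
        rationale={
            Band.TDR_COMPATIBLE: f"ADC {profile.adc:g} not less than {cfg.adc_min_tdr:g} s/mm²",
            Band.MI: f"ADC {profile.adc:g} less than {cfg.adc_max_mi:g} s/mm²",
            Band.O: f"ADC {profile.adc:g} less than {cfg.adc_max_o:g} s/mm²",
            Band.NEUTRAL: (
                f"ADC {profile.adc:g} in the uncovered gap "
                f"[{cfg.adc_max_mi:g}, {cfg.adc_min_tdr:g}) — no clause applies"
            ),
        }[ab],
    )
    pb = pfirrmann_vote(profile.pfirrmann, cfg)
    votes["pfirrmann"] = CriterionVote(
        criterion="pfirrmann",
        value=grade_to_roman(profile.pfirrmann),
        band=pb,
        rationale=f"Pfirrmann grade {grade_to_roman(profile.pfirrmann)}"
        + (" claimed by both fusion bands" if pb == Band.TIE_MI_O else ""),
    )
    fb = fujiwara_vote(profile.fujiwara, cfg, family)
    votes["fujiwara"] = CriterionVote(
        criterion="fujiwara",
        value=grade_to_roman(profile.fujiwara),
        band=fb,
        rationale=f"Fujiwara grade {grade_to_roman(profile.fujiwara)}"
        + (
            " (grade II tie resolved by family)"
            if profile.fujiwara == 2
            else ""
        ),
    )
    tb = tropism_vote(profile.tropism, cfg)
    votes["tropism"] = CriterionVote(
        criterion="tropism",
        value=profile.tropism,
        band=tb,
        rationale=f"tropism {profile.tropism.value} under {cfg.tropism_polarity.value} polarity"
        + ("; TDR unaffected regardless of tropism" if family == Family.DYNAMIC else ""),
    )
    return votes


def classify(profile: SegmentProfile, config: RuleConfig | None = None) -> Recommendation:
    """Crisp two-stage triage of a segment to TDR / MI-TLIF / O-TLIF.

    A dynamic segment whose degeneration criteria fail the arthroplasty
    conjunction is INDETERMINATE (dynamic biomechanics with rigid-type
    degeneration — the algorithm assigns no arm).  On a rigid segment the
    MI/O tally runs over ADC, Pfirrmann, Fujiwara and tropism; ties resolve
    toward the less invasive MI-TLIF.  Confidence is the winning share of
    cast fusion votes (1.0 for TDR, 0.0 for INDETERMINATE).
    """
    cfg = config or RuleConfig()
    family, rigid_votes = instability_family(profile, cfg)
    votes = _collect_votes(profile, cfg, family, rigid_votes)
    n_rigid = sum(rigid_votes.values())
    audit = [f"family={family.value} ({n_rigid}/3 rigid instability votes)"]
    audit += [f"{name}: {votes[name].band.value} — {votes[name].rationale}" for name in CRITERIA]

    if family == Family.DYNAMIC:
        eligible, checks = tdr_eligibility(profile, cfg)
        if eligible:
            arm, confidence = Arm.TDR, 1.0
            audit.append("dynamic family and all arthroplasty criteria met -> TDR")
        else:
            arm, confidence = Arm.INDETERMINATE, 0.0
            failed = [k for k, ok in checks.items() if not ok and k != "family_dynamic"]
            audit.append(
                "dynamic biomechanics but rigid-type degeneration "
                f"(failed: {', '.join(failed)}) -> INDETERMINATE"
            )
    else:
        stage2 = [votes[name].band for name in ("adc", "pfirrmann", "fujiwara", "tropism")]
        mi, o, neutral = _stage2_tally(stage2)
        cast = mi + o
        if mi > o:
            arm = Arm.MI_TLIF
        elif o > mi:
            arm = Arm.O_TLIF
        else:
            arm = Arm.MI_TLIF  # tie (incl. 0-0) -> less invasive option
        winning = mi if arm == Arm.MI_TLIF else o
        confidence = winning / cast if cast > 0 else 0.0
        audit.append(
            f"rigid family: MI {mi:g} vs O {o:g} votes ({neutral} neutral) -> {arm.value}"
            + (" (tie resolved toward the less invasive arm)" if mi == o else "")
        )

    return Recommendation(
        family=family,
        arm=arm,
        criterion_votes=votes,
        confidence=confidence,
        audit=tuple(audit),
    )


# --- fuzzy variant -----------------------------------------------------------

def _ramp_up(x: float, threshold: float, width: float, *, strict: bool) -> float:
    """Membership of "x above threshold" with a linear transition.

    With width 0 this is the crisp indicator (strict ``x > t`` or inclusive
    ``x >= t``); otherwise 0 below t-w, 1 above t+w, 0.5 at t.
    """
    if width == 0:
        return float(x > threshold if strict else x >= threshold)
    lo, hi = threshold - width, threshold + width
    if x <= lo:
        return 0.0
    if x >= hi:
        return 1.0
    return (x - lo) / (hi - lo)


def fuzzy_classify(profile: SegmentProfile, config: RuleConfig | None = None) -> Recommendation:
    """Fuzzy-inference variant of :func:`classify`.

    Each continuous threshold t becomes a linear transition of half-width
    ``fuzzy_width_fraction * t``.  The rigid-family membership is the fuzzy
    2-of-3 majority (median) of the triad memberships; TDR activation is the
    conjunctive minimum of the dynamic-family and degeneration memberships;
    the fusion arms activate as the rigid membership capped by their
    normalized vote share.  Ordinal grades and tropism keep crisp
    memberships (a transition width has no natural meaning on a 4- or
    5-point scale).  The arm is the argmax activation, ties resolving in the
    order TDR, MI-TLIF, O-TLIF, INDETERMINATE; confidence is the activation
    margin between the top two arms.  With width 0 the output arm equals the
    crisp classifier's for every profile.
    """
    cfg = config or RuleConfig()
    require_valid(profile)
    frac = cfg.fuzzy_width_fraction
    if frac < 0:
        raise ValueError("fuzzy_width_fraction must be >= 0")

    def w(t: float) -> float:
        return frac * t

    # instability triad: membership of the rigid reading of each criterion
    r_trans = _ramp_up(profile.linear_translation, cfg.translation_max_tdr,
                       w(cfg.translation_max_tdr), strict=True)
    r_sag = _ramp_up(profile.sagittal_angulation, cfg.sagittal_min_rigid,
                     w(cfg.sagittal_min_rigid), strict=False)
    r_facet = _ramp_up(profile.facet_angle, cfg.facet_min_rigid,
                       w(cfg.facet_min_rigid), strict=False)
    rigid = sorted((r_trans, r_sag, r_facet))[1]  # fuzzy 2-of-3 majority
    dynamic = 1.0 - rigid

    # degeneration memberships
    m_adc_tdr = _ramp_up(profile.adc, cfg.adc_min_tdr, w(cfg.adc_min_tdr), strict=False)
    below_mi = 1.0 - _ramp_up(profile.adc, cfg.adc_max_mi, w(cfg.adc_max_mi), strict=False)
    below_o = 1.0 - _ramp_up(profile.adc, cfg.adc_max_o, w(cfg.adc_max_o), strict=False)
    m_adc_o = below_o
    m_adc_mi = min(1.0, max(0.0, below_mi - below_o))

    m_pf_tdr = float(profile.pfirrmann <= cfg.pfirrmann_tdr_max)
    pf_band = pfirrmann_vote(profile.pfirrmann, cfg)
    m_pf_mi = {Band.MI: 1.0, Band.TIE_MI_O: 0.5}.get(pf_band, 0.0)
    m_pf_o = {Band.O: 1.0, Band.TIE_MI_O: 0.5}.get(pf_band, 0.0)

    m_fj_tdr = float(profile.fujiwara <= cfg.fujiwara_tdr_max)
    fj_rigid_band = fujiwara_vote(profile.fujiwara, cfg, Family.RIGID)
    m_fj_mi = float(fj_rigid_band == Band.MI)
    m_fj_o = float(fj_rigid_band == Band.O)

    trop_band = tropism_vote(profile.tropism, cfg)
    m_tr_mi = float(trop_band == Band.MI)
    m_tr_o = float(trop_band == Band.O)

    tdr_conj = min(m_adc_tdr, m_pf_tdr, m_fj_tdr)
    a_tdr = min(dynamic, tdr_conj)
    a_ind = min(dynamic, 1.0 - tdr_conj)

    v_mi = m_adc_mi + m_pf_mi + m_fj_mi + m_tr_mi
    v_o = m_adc_o + m_pf_o + m_fj_o + m_tr_o
    cast = v_mi + v_o
    if cast > 0:
        s_mi, s_o = v_mi / cast, v_o / cast
    else:
        s_mi, s_o = 1.0, 0.0  # no fusion evidence either way -> less invasive
    a_mi = min(rigid, s_mi)
    a_o = min(rigid, s_o)

    activations = {Arm.TDR: a_tdr, Arm.MI_TLIF: a_mi, Arm.O_TLIF: a_o,
                   Arm.INDETERMINATE: a_ind}
    order = (Arm.TDR, Arm.MI_TLIF, Arm.O_TLIF, Arm.INDETERMINATE)
    arm = max(order, key=lambda a: (activations[a], -order.index(a)))
    ranked = sorted(activations.values(), reverse=True)
    confidence = ranked[0] - ranked[1]

    family = Family.RIGID if rigid > 0.5 or (rigid == 0.5 and arm in (Arm.MI_TLIF, Arm.O_TLIF)) \
        else Family.DYNAMIC
    _, rigid_votes = instability_family(profile, cfg)
    votes = _collect_votes(profile, cfg, family, rigid_votes)
    memberships = {
        "rigid": rigid,
        "dynamic": dynamic,
        "translation_rigid": r_trans,
        "sagittal_rigid": r_sag,
        "facet_rigid": r_facet,
        "adc_tdr": m_adc_tdr,
        "adc_mi": m_adc_mi,
        "adc_o": m_adc_o,
        "activation_TDR": a_tdr,
        "activation_MI_TLIF": a_mi,
        "activation_O_TLIF": a_o,
        "activation_INDETERMINATE": a_ind,
    }
    audit = [
        f"fuzzy inference, transition half-width fraction {frac:g}",
        f"rigid membership {rigid:.3f} (triad {r_trans:.3f}/{r_sag:.3f}/{r_facet:.3f}, 2-of-3 median)",
        f"activations: TDR {a_tdr:.3f}, MI {a_mi:.3f}, O {a_o:.3f}, indeterminate {a_ind:.3f}",
        f"argmax -> {arm.value} (margin {confidence:.3f})",
    ]
    return Recommendation(
        family=family,
        arm=arm,
        criterion_votes=votes,
        confidence=confidence,
        audit=tuple(audit),
        memberships=memberships,
    )


class BoundaryNotFound(ValueError):
    """The predicate never changed value over the scanned range."""


def probe_boundary(
    base_profile: SegmentProfile,
    parameter: str,
    start: float,
    stop: float,
    step: float,
    predicate: Callable[[Recommendation], bool],
    config: RuleConfig | None = None,
    classifier: Callable[[SegmentProfile, RuleConfig | None], Recommendation] = classify,
) -> float:
    """Scan one profile parameter and return the first value where the
    predicate flips relative to its value at the scan start.

    The crisp rules make every single-parameter predicate monotone, so the
    first flip is the decision boundary; a predicate that never flips (e.g. a
    single triad criterion that cannot reach the 2-of-3 majority alone)
    raises :class:`BoundaryNotFound`.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    cfg = config or RuleConfig()

    def evaluate(value: float) -> bool:
        return predicate(classifier(base_profile.with_(**{parameter: value}), cfg))

    initial: bool | None = None
    value = start
    # inclusive endpoint, guarded against float drift
    while value <= stop + step * 1e-9:
        result = evaluate(value)
        if initial is None:
            initial = result
        elif result != initial:
            return value
        value += step
    raise BoundaryNotFound(
        f"predicate on {parameter!r} never flipped over [{start:g}, {stop:g}] step {step:g}"
    )
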