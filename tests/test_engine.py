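"""Decision engine: banding, two-stage classification, fuzzy variant, probes."""

import numpy as np
import pytest

from lumbar_cdss import (
    Arm,
    Band,
    BoundaryNotFound,
    Family,
    ProfileValidationError,
    RuleConfig,
    Tropism,
    TropismPolarity,
    adc_band,
    classify,
    fujiwara_vote,
    fuzzy_classify,
    instability_family,
    pfirrmann_vote,
    probe_boundary,
    tdr_eligibility,
    tropism_vote,
)
from lumbar_cdss.engine import CRITERIA, _stage2_tally

from conftest import MEDIAN_PROFILES, make_profile, random_profile


class TestInstabilityFamily:
    @pytest.mark.parametrize(
        ("translation", "sagittal", "facet", "family", "n_rigid"),
        [
            (2, 4, 50, Family.DYNAMIC, 0),   # arthroplasty-nominal medians
            (7, 8, 70, Family.RIGID, 3),     # fusion-nominal medians
            (6, 3, 52, Family.DYNAMIC, 1),   # one rigid vote loses the majority
            (5, 6, 52, Family.RIGID, 2),     # two of three suffice
            (4, 5.9, 59.9, Family.DYNAMIC, 0),  # all strictly below thresholds
            (4.1, 6, 50, Family.RIGID, 2),   # 6 deg is rigid-inclusive
            (2, 6, 60, Family.RIGID, 2),     # 60 deg is rigid-inclusive
        ],
    )
    def test_majority_over_the_triad(self, translation, sagittal, facet, family, n_rigid):
        got, votes = instability_family(
            make_profile(
                linear_translation=translation,
                sagittal_angulation=sagittal,
                facet_angle=facet,
            )
        )
        assert got is family
        assert sum(votes.values()) == n_rigid

    def test_translation_boundary_is_tdr_inclusive(self):
        # "to a maximum of 4 mm": exactly 4 does not vote rigid
        _, votes = instability_family(make_profile(linear_translation=4.0))
        assert votes["translation"] is False
        _, votes = instability_family(make_profile(linear_translation=4.0001))
        assert votes["translation"] is True


class TestAdcBand:
    @pytest.mark.parametrize(
        ("adc", "band"),
        [
            (1540, Band.TDR_COMPATIBLE),
            (1240, Band.TDR_COMPATIBLE),  # "not less than 1240" is inclusive
            (1239, Band.NEUTRAL),
            (1200, Band.NEUTRAL),         # the uncovered 1150-1240 gap
            (1150, Band.NEUTRAL),
            (1149, Band.MI),
            (1000, Band.MI),
            (950, Band.MI),               # "less than 950" is strict
            (949, Band.O),
            (670, Band.O),
        ],
    )
    def test_bands(self, adc, band):
        assert adc_band(adc) is band

    def test_nonpositive_adc_rejected(self):
        with pytest.raises(ProfileValidationError):
            adc_band(0)


class TestGradeVotes:
    @pytest.mark.parametrize(
        ("grade", "band"),
        [(1, Band.TDR_COMPATIBLE), (2, Band.TDR_COMPATIBLE),
         (3, Band.MI), (4, Band.TIE_MI_O), (5, Band.O)],
    )
    def test_pfirrmann(self, grade, band):
        assert pfirrmann_vote(grade) is band

    def test_pfirrmann_out_of_scale(self):
        with pytest.raises(ProfileValidationError):
            pfirrmann_vote(6)

    @pytest.mark.parametrize(
        ("grade", "family", "band"),
        [
            (1, Family.DYNAMIC, Band.TDR_COMPATIBLE),
            (2, Family.DYNAMIC, Band.TDR_COMPATIBLE),  # tie resolved to TDR side
            (2, Family.RIGID, Band.MI),                # tie resolved to MI side
            (3, Family.DYNAMIC, Band.MI),
            (3, Family.RIGID, Band.MI),
            (4, Family.RIGID, Band.O),
        ],
    )
    def test_fujiwara(self, grade, family, band):
        assert fujiwara_vote(grade, family=family) is band

    def test_fujiwara_out_of_scale(self):
        with pytest.raises(ProfileValidationError):
            fujiwara_vote(5)


class TestTropismVote:
    @pytest.mark.parametrize(
        ("tropism", "polarity", "band"),
        [
            (Tropism.ABSENT, TropismPolarity.PROSE, Band.MI),
            (Tropism.PRESENT, TropismPolarity.PROSE, Band.O),
            (Tropism.ABSENT, TropismPolarity.TABLE, Band.O),
            (Tropism.PRESENT, TropismPolarity.TABLE, Band.MI),
            (Tropism.UNKNOWN, TropismPolarity.PROSE, Band.NEUTRAL),
            (Tropism.UNKNOWN, TropismPolarity.TABLE, Band.NEUTRAL),
        ],
    )
    def test_polarity_switch(self, tropism, polarity, band):
        cfg = RuleConfig(tropism_polarity=polarity)
        assert tropism_vote(tropism, cfg) is band


class TestTdrEligibility:
    def test_median_tdr_profile_is_eligible(self, tdr_profile):
        ok, checks = tdr_eligibility(tdr_profile)
        assert ok and all(checks.values())

    @pytest.mark.parametrize(
        ("overrides", "failed"),
        [
            (dict(adc=1100), "adc"),
            (dict(pfirrmann=4), "pfirrmann"),
            (dict(fujiwara=3), "fujiwara"),
            (dict(linear_translation=7, sagittal_angulation=8), "family_dynamic"),
        ],
    )
    def test_each_criterion_can_veto(self, overrides, failed):
        ok, checks = tdr_eligibility(make_profile(**overrides))
        assert not ok
        assert checks[failed] is False

    def test_tropism_is_ignored(self):
        ok_present, _ = tdr_eligibility(make_profile(tropism=Tropism.PRESENT))
        ok_absent, _ = tdr_eligibility(make_profile(tropism=Tropism.ABSENT))
        assert ok_present and ok_absent


class TestClassify:
    def test_tdr_median_profile(self, tdr_profile):
        rec = classify(tdr_profile)
        assert rec.arm is Arm.TDR
        assert rec.family is Family.DYNAMIC
        assert rec.confidence == 1.0

    def test_rigid_mi_tally(self):
        # Pfirrmann III -> MI, ADC 1180 neutral, Fujiwara III -> MI, tropism unknown
        rec = classify(
            make_profile(
                linear_translation=7, sagittal_angulation=8, facet_angle=70,
                pfirrmann=3, adc=1180, fujiwara=3,
            )
        )
        assert rec.arm is Arm.MI_TLIF
        assert rec.confidence == 1.0  # MI 2 of 2 cast

    def test_rigid_o_tally(self):
        rec = classify(
            make_profile(
                linear_translation=7, sagittal_angulation=8, facet_angle=70,
                pfirrmann=5, adc=670, fujiwara=4, tropism=Tropism.PRESENT,
            )
        )
        assert rec.arm is Arm.O_TLIF
        assert rec.confidence == 1.0  # O 4 of 4 cast

    def test_dynamic_with_rigid_degeneration_is_indeterminate(self):
        rec = classify(make_profile(pfirrmann=4, adc=800))
        assert rec.family is Family.DYNAMIC
        assert rec.arm is Arm.INDETERMINATE
        assert rec.confidence == 0.0

    def test_pfirrmann_iv_splits_the_fusion_vote(self):
        # only Pfirrmann casts: IV contributes 0.5 to each arm -> tie -> MI
        rec = classify(
            make_profile(
                linear_translation=7, sagittal_angulation=8, facet_angle=70,
                pfirrmann=4, adc=1300, fujiwara=1,
            )
        )
        assert rec.arm is Arm.MI_TLIF
        assert rec.confidence == pytest.approx(0.5)

    def test_audit_covers_all_seven_criteria(self, tdr_profile):
        rec = classify(tdr_profile)
        assert set(rec.criterion_votes) == set(CRITERIA)
        for name in CRITERIA:
            assert any(name in line for line in rec.audit)

    def test_determinism(self, tdr_profile):
        assert classify(tdr_profile) == classify(tdr_profile)

    def test_family_concordance_on_median_profiles(self):
        arm_family = {"TDR": Family.DYNAMIC, "MI_TLIF": Family.RIGID, "O_TLIF": Family.RIGID}
        for (arm, stratum), profile in MEDIAN_PROFILES.items():
            family = classify(profile).family
            if stratum == "good":
                assert family is arm_family[arm], (arm, stratum)
            else:
                assert family is not arm_family[arm], (arm, stratum)

    def test_vote_conservation_over_random_profiles(self):
        rng = np.random.default_rng(20260922)
        stage2 = ("adc", "pfirrmann", "fujiwara", "tropism")
        for _ in range(300):
            rec = classify(random_profile(rng))
            mi, o, neutral = _stage2_tally([rec.criterion_votes[c].band for c in stage2])
            assert mi + o + neutral == pytest.approx(4.0)


class TestFuzzyClassify:
    def test_width_zero_degenerates_to_crisp(self):
        cfg = RuleConfig(fuzzy_width_fraction=0.0)
        rng = np.random.default_rng(7)
        for _ in range(400):
            profile = random_profile(rng)
            assert fuzzy_classify(profile, cfg).arm is classify(profile, cfg).arm

    def test_adc_membership_midpoint_and_ramp_end(self):
        cfg = RuleConfig(fuzzy_width_fraction=0.10)
        mid = fuzzy_classify(make_profile(adc=1240.0), cfg)
        assert mid.memberships["adc_tdr"] == pytest.approx(0.5)
        end = fuzzy_classify(make_profile(adc=1240.0 * 1.10), cfg)
        assert end.memberships["adc_tdr"] == pytest.approx(1.0)
        below = fuzzy_classify(make_profile(adc=1240.0 * 0.90), cfg)
        assert below.memberships["adc_tdr"] == pytest.approx(0.0)

    def test_memberships_lie_in_unit_interval(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            rec = fuzzy_classify(random_profile(rng))
            assert all(0 <= m <= 1 for m in rec.memberships.values())

    def test_confidence_is_activation_margin(self, tdr_profile):
        rec = fuzzy_classify(tdr_profile)
        acts = sorted(
            (rec.memberships[f"activation_{arm.value}"] for arm in Arm), reverse=True
        )
        assert rec.confidence == pytest.approx(acts[0] - acts[1])


class TestProbeBoundary:
    def test_recovers_the_adc_threshold(self, tdr_profile, default_config):
        value = probe_boundary(
            tdr_profile, "adc", 1, 2000, 1, lambda r: r.arm is Arm.TDR
        )
        assert value == default_config.adc_min_tdr

    def test_single_triad_criterion_cannot_flip_the_family(self, tdr_profile):
        # translation alone cannot reach the 2-of-3 majority
        with pytest.raises(BoundaryNotFound):
            probe_boundary(
                tdr_profile, "linear_translation", 0, 20, 1,
                lambda r: r.family is Family.RIGID,
            )

    def test_predicate_true_throughout_never_flips(self):
        profile = make_profile(linear_translation=7, sagittal_angulation=8)
        with pytest.raises(BoundaryNotFound):
            probe_boundary(
                profile, "facet_angle", 1, 120, 1,
                lambda r: r.family is Family.RIGID,  # already rigid at facet 1
            )

    def test_nondefault_config_boundary_moves_with_the_config(self, tdr_profile):
        cfg = RuleConfig(adc_min_tdr=1300.0)
        value = probe_boundary(
            tdr_profile, "adc", 1, 2000, 1, lambda r: r.arm is Arm.TDR, config=cfg
        )
        assert value == 1300
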