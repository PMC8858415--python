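"""Shared fixtures: the six retrospective median-profile cases, random
profile generation, and brute-force enumeration oracles for the rank tests."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from lumbar_cdss import (
    Arm,
    Level,
    OutcomeLabel,
    PatientRecord,
    RuleConfig,
    SegmentProfile,
    Sex,
    Tropism,
)


@pytest.fixture
def default_config() -> RuleConfig:
    return RuleConfig()


def make_profile(**overrides) -> SegmentProfile:
    """An arthroplasty-nominal profile; override fields per test."""
    base = dict(
        level=Level.L4_L5,
        linear_translation=2.0,
        sagittal_angulation=4.0,
        facet_angle=50.0,
        tropism=Tropism.UNKNOWN,
        pfirrmann=2,
        fujiwara=1,
        adc=1540.0,
        ivd_height=10.0,
        height_loss_fraction=0.5,
        general_lordosis=30.0,
    )
    base.update(overrides)
    return SegmentProfile(**base)


@pytest.fixture
def tdr_profile() -> SegmentProfile:
    return make_profile()


#: Preoperative median profiles of the six retrospective strata, as printed.
#: Tropism "+/-" enters as unknown, "+" as present, "-" as absent.
MEDIAN_PROFILES: dict[tuple[str, str], SegmentProfile] = {
    ("TDR", "good"): make_profile(),
    ("TDR", "poor"): make_profile(
        linear_translation=6, sagittal_angulation=7, facet_angle=69,
        pfirrmann=3, fujiwara=2, adc=1050, ivd_height=6,
    ),
    ("MI_TLIF", "good"): make_profile(
        linear_translation=7, sagittal_angulation=8, facet_angle=70,
        tropism=Tropism.PRESENT, pfirrmann=3, fujiwara=3, adc=1180,
        ivd_height=6, general_lordosis=32,
    ),
    ("MI_TLIF", "poor"): make_profile(
        linear_translation=3, sagittal_angulation=3, facet_angle=52,
        pfirrmann=3, fujiwara=3, adc=1320, ivd_height=10, general_lordosis=32,
    ),
    ("O_TLIF", "good"): make_profile(
        linear_translation=7, sagittal_angulation=8, facet_angle=69,
        tropism=Tropism.ABSENT, pfirrmann=3, fujiwara=3, adc=670,
        ivd_height=4, general_lordosis=34,
    ),
    ("O_TLIF", "poor"): make_profile(
        linear_translation=3, sagittal_angulation=3, facet_angle=52,
        tropism=Tropism.PRESENT, pfirrmann=3, fujiwara=3, adc=1170, ivd_height=10,
    ),
}


@pytest.fixture
def median_profiles() -> dict[tuple[str, str], SegmentProfile]:
    return dict(MEDIAN_PROFILES)


@pytest.fixture
def median_records() -> list[PatientRecord]:
    """The six median profiles as labelled patient records."""
    return [
        PatientRecord(
            id=f"{arm}-{stratum}",
            age=40.0,
            sex=Sex.MALE,
            bmi=26.0,
            profile=profile,
            received_arm=Arm(arm),
            outcome_label=OutcomeLabel(stratum),
        )
        for (arm, stratum), profile in MEDIAN_PROFILES.items()
    ]


def random_profile(rng: np.random.Generator) -> SegmentProfile:
    """A random valid profile spanning the full clinical parameter space."""
    levels, tropisms = list(Level), list(Tropism)
    return make_profile(
        level=levels[rng.integers(len(levels))],
        linear_translation=float(rng.uniform(0, 12)),
        sagittal_angulation=float(rng.uniform(0, 15)),
        facet_angle=float(rng.uniform(20, 120)),
        tropism=tropisms[rng.integers(len(tropisms))],
        pfirrmann=int(rng.integers(1, 6)),
        fujiwara=int(rng.integers(1, 5)),
        adc=float(rng.uniform(300, 2000)),
        ivd_height=float(rng.uniform(2, 15)),
        height_loss_fraction=float(rng.uniform(0, 1)),
        general_lordosis=float(rng.uniform(10, 70)),
    )


# --- enumeration oracles (independent of the implementation under test) ------

def mann_whitney_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all rank assignments.

    Returns (U of x, p) with p = 2 * min(lower tail, upper tail), capped at 1.
    Requires a tie-free pooled sample.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array([
        ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        for comb in itertools.combinations(range(n1 + n2), n1)
    ])
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return float(u_obs), float(min(1.0, p))


def wilcoxon_enumeration(diffs) -> tuple[float, float]:
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors.

    Zero differences are dropped first; requires tie-free |d|.
    Returns (W+ observed, p) with the 2 * min-tail convention.
    """
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([
        (ranks * np.array(signs)).sum()
        for signs in itertools.product([0.0, 1.0], repeat=len(d))
    ])
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return float(w_obs), float(min(1.0, p))
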