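"""Triage a single lumbar segment and inspect the audit trail.

Builds one preoperative profile, runs the crisp two-stage classifier and the
fuzzy variant, and prints the recommendation with every criterion's vote.
"""

from lumbar_cdss import (
    Level,
    SegmentProfile,
    Tropism,
    classify,
    eligibility_gate,
    fuzzy_classify,
)

# A motion-preserved, mildly degenerated segment: low slip and mobility,
# sagittally oriented facets, hydrated disc (high ADC), early grades.
profile = SegmentProfile(
    level=Level.L4_L5,
    linear_translation=2.0,     # mm
    sagittal_angulation=4.0,    # degrees
    facet_angle=50.0,           # degrees
    tropism=Tropism.UNKNOWN,
    pfirrmann=2,                # disc degeneration grade II
    fujiwara=1,                 # facet degeneration grade I
    adc=1540.0,                 # s/mm^2
    ivd_height=10.0,            # mm
    height_loss_fraction=0.5,   # half the superjacent disc height lost
    general_lordosis=30.0,      # degrees
)

eligible, reasons = eligibility_gate(profile)
print(f"eligibility gate (height loss in [1/3, 2/3]): {'pass' if eligible else reasons}")

rec = classify(profile)
print(f"\ncrisp recommendation: {rec.arm.value} "
      f"(family {rec.family.value}, confidence {rec.confidence:.2f})")
for line in rec.audit:
    print(f"  {line}")

fuzzy = fuzzy_classify(profile)
print(f"\nfuzzy recommendation: {fuzzy.arm.value} (activation margin {fuzzy.confidence:.2f})")
print("  arm activations:",
      {k.split("_", 1)[1]: round(v, 3)
       for k, v in fuzzy.memberships.items() if k.startswith("activation")})

# The confidence is the share of fusion votes won (crisp) or the activation
# margin over the runner-up arm (fuzzy); 1.0 means no criterion dissented.
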