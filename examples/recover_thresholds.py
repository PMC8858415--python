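"""Recover every decision threshold by probing the engine from outside.

Scans one parameter at a time on otherwise-fixed profiles and reports where
the recommendation flips — the boundaries should equal the configured rule
thresholds exactly (4 mm, 6 deg, 60 deg, 1240/1150/950 s/mm^2 by default).
"""

from lumbar_cdss import Arm, Band, Family, adc_band, probe_boundary
from lumbar_cdss.cli import _nominal_profile as nominal

adc_tdr = probe_boundary(nominal(), "adc", 1, 2000, 1, lambda r: r.arm is Arm.TDR)
print(f"smallest ADC recommending arthroplasty:        {adc_tdr:g} s/mm^2")

# a single instability criterion cannot flip the 2-of-3 family majority, so
# each triad scan presets one other criterion to a rigid-voting value
flip = probe_boundary(nominal(sagittal_angulation=8), "linear_translation",
                      0, 20, 1, lambda r: r.arm is Arm.TDR)
print(f"largest translation compatible with TDR:       {flip - 1:g} mm")

sag = probe_boundary(nominal(facet_angle=70), "sagittal_angulation",
                     0, 20, 1, lambda r: r.family is Family.RIGID)
print(f"first rigid-voting sagittal angulation:        {sag:g} deg")

facet = probe_boundary(nominal(sagittal_angulation=8), "facet_angle",
                       1, 120, 1, lambda r: r.family is Family.RIGID)
print(f"first rigid-voting facet angle:                {facet:g} deg")

bands = [adc_band(v) for v in range(1, 2001)]
print(f"first ADC past the open-fusion band:           "
      f"{next(v for v, b in enumerate(bands, 1) if b is not Band.O):g} s/mm^2")
print(f"first ADC past the minimally-invasive band:    "
      f"{next(v for v, b in enumerate(bands, 1) if b not in (Band.O, Band.MI)):g} s/mm^2")
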