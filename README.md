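# lumbar-cdss

Rule-based surgical-approach triage for single-level degenerative lumbar
spine disease, with a quantile-matched synthetic cohort generator and the
nonparametric comparison machinery needed to evaluate it.

## The problem

When a single lumbar segment degenerates, the surgeon chooses between a
motion-preserving implant — total disc replacement (TDR) — and rigid
stabilization, performed either minimally invasively (MI-TLIF) or open
(O-TLIF). The choice hinges on measurable properties of the segment:

- the **instability triad** — linear vertebral translation (mm), sagittal
  range of motion (degrees), and facet joint angle (degrees) — separates
  *dynamic*-fixation candidates from *rigid*-stabilization candidates;
- **degeneration criteria** — Pfirrmann disc grade (I–V), apparent diffusion
  coefficient ADC (s/mm², a DWI-MRI disc-hydration measure; lower = more
  degenerated), Fujiwara facet grade (I–IV), and facet tropism — select the
  arm within a family.

This package implements that triage rule as an auditable engine:

- **Stage 1 (family).** Each of `translation > 4 mm`, `sagittal ≥ 6°`,
  `facet ≥ 60°` casts a *rigid* vote; the family is rigid iff ≥ 2 of 3 vote
  rigid.
- **Stage 2 (arm).** A dynamic segment is a TDR candidate iff
  `Pfirrmann ≤ II ∧ ADC ≥ 1240 ∧ Fujiwara ≤ II` (tropism is ignored);
  otherwise it is INDETERMINATE. A rigid segment tallies MI vs O votes over
  ADC band (`< 950` → O, `[950, 1150)` → MI), Pfirrmann (III → MI, IV → tie,
  V → O), Fujiwara (II–III → MI, IV → O) and tropism; ties resolve toward
  the less invasive MI-TLIF.

A fuzzy variant replaces each crisp threshold *t* by a linear transition of
half-width *w·t* (default *w* = 0.10); with *w* = 0 it reduces exactly to
the crisp engine.

Because no patient-level data accompany the published summaries, a
**synthetic cohort generator** reproduces them from their printed
Me [Q1; Q3] entries using a two-piece (split) normal pinned at the three
quartiles (σ_low = (Me−Q1)/z₀.₇₅, σ_high = (Q3−Me)/z₀.₇₅), and an
**outcomes-comparison module** provides the matching statistics: Me [Q1; Q3]
summaries, Mann–Whitney U, Wilcoxon signed-rank, Pearson χ², α = 0.05.

## Worked example

```python
from lumbar_cdss import SegmentProfile, Level, Tropism, classify

profile = SegmentProfile(
    level=Level.L4_L5, linear_translation=2.0, sagittal_angulation=4.0,
    facet_angle=50.0, tropism=Tropism.UNKNOWN, pfirrmann=2, fujiwara=1,
    adc=1540.0, ivd_height=10.0, height_loss_fraction=0.5, general_lordosis=30.0,
)
rec = classify(profile)
print(rec.arm.value, rec.family.value, rec.confidence)
```

prints `TDR dynamic 1.0`: all three instability criteria vote dynamic and
every degeneration criterion is arthroplasty-compatible, so the engine
recommends disc replacement with full confidence. The full audit trail (one
line per criterion) is in `rec.audit`; `examples/classify_patient.py` prints
it verbatim, e.g.

```
adc: TDR_compatible — ADC 1540 not less than 1240 s/mm²
pfirrmann: TDR_compatible — Pfirrmann grade II
```

`examples/simulate_cohort.py` generates the TDR arm at its published
stratum sizes (35 good / 7 poor outcomes) and prints the generated
marginals next to their calibration targets:

```
linear_translation   2.1 [1.2; 4.0]          (2 [1; 4])
adc                  1533.8 [1322.8; 1764.7] (1540 [1280; 1760])
24-month ODI good: 6 [6; 7]   poor: 17 [16; 19]
```

`examples/compare_groups.py` builds a cohort-table comparison (Mann–Whitney
on continuous rows, χ² on binary rows) and reports engine/received-arm
concordance; `examples/recover_thresholds.py` rediscovers every decision
threshold (4 mm, 6°, 60°, 1240/1150/950 s/mm²) by scanning the engine from
outside.

The same capabilities are available from a shell:

```bash
lumbar-cdss simulate TDR --seed 1 -o cohort.csv
lumbar-cdss classify cohort.csv -o recommendations.jsonl
lumbar-cdss evaluate good.csv poor.csv --variables odi_m24,adc -o report.csv
lumbar-cdss boundaries
lumbar-cdss show-config
```

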