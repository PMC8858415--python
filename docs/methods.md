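# Methods

This note documents the models and procedures the package implements, the
assumptions they rest on, and the choices made where the design was open.

## 1. The triage rule

### Inputs and validation

A `SegmentProfile` carries one segment's preoperative measurements: linear
translation (mm, ≥ 0), sagittal angulation (degrees, ≥ 0 — the segment's
flexion–extension range of motion; one field serves both names since both
carry the same 6° threshold), facet joint angle (degrees, in (0, 180)),
facet tropism (present / absent / unknown), Pfirrmann disc grade (I–V),
Fujiwara facet grade (I–IV), ADC (s/mm², > 0), disc height (mm, > 0),
height-loss fraction relative to the superjacent disc (in [0, 1]), and
general lordosis (degrees). Validation is total: out-of-range values are
reported as messages, never exceptions, so messy checklist rows surface as
line-numbered errors rather than crashes. Tropism is tri-state because the
source summaries print "+/–" for some strata; unknown casts no vote.

An eligibility gate requires the height-loss fraction to lie in the
[1/3, 2/3] window (a collapse of more than one third qualifies the patient;
more than two thirds disqualifies the segment for any studied arm). The
sources state the two bounds in different places without specifying
openness; both ends are closed here, a choice only measurable on exact
boundary values.

### Stage 1 — biomechanical family

The instability triad votes rigid on `translation > 4 mm`,
`sagittal ≥ 6°`, `facet ≥ 60°`; the family is rigid iff at least two of
three vote rigid. The source prose states the triad for both families but
not how to combine disagreeing criteria; majority over the odd triad is the
minimal deterministic resolution, and it reproduces all six retrospective
median-profile family assignments (good strata map to the family of the arm
received, poor strata to the opposite — the premise that poor outcomes
followed counter-indicated profiles).

Boundary inclusivity follows the wording exactly: "to a maximum of 4 mm"
keeps 4 TDR-compatible; "not less than 6°" and "over 60°" make 6 and 60
rigid-inclusive (60 is treated as rigid: the dynamic clause "less than 60°"
and the rigid clause "over 60°" leave the single point 60 unassigned, and
assigning it to the rigid side keeps the two clauses complementary);
"not less than 1240" is TDR-inclusive; 1150 and 950 are strict upper bounds.

### Stage 2 — arm within the family

*Dynamic:* TDR iff `Pfirrmann ≤ II ∧ ADC ≥ 1240 ∧ Fujiwara ∈ {I, II}`,
tropism ignored. A dynamic segment failing the conjunction is
INDETERMINATE — dynamic biomechanics with rigid-type degeneration is a
combination the rule never assigns, and the engine does not invent an arm
for it.

*Rigid:* ADC band, Pfirrmann, Fujiwara and tropism each cast an MI or O
vote. Overlaps become explicit tie states rather than silent precedence:
Pfirrmann IV sits in both fusion bands and contributes 0.5 to each;
Fujiwara II sits in both the TDR and MI bands and resolves by the
already-decided family (MI when rigid). The ADC gap [1150, 1240) satisfies
no clause and is neutral. The arm is the vote majority, ties resolving
toward the less invasive MI-TLIF; confidence is the winning share of cast
votes. Vote conservation holds by construction: MI + O + neutral = 4.

*Tropism polarity* is a configuration switch because the prose
(absent → MI, present → O) and the retrospective summary table (good-outcome
MI printed "+", good-outcome O printed "–") contradict each other; the
default follows the prose. Two further summary-table discrepancies are
surfaced rather than patched: the good-outcome MI median ADC (1180) lies in
the neutral gap above the MI clause's 1150 bound, and the good-outcome O
medians (Pfirrmann III, Fujiwara III) fall in the MI bands. The engine
follows the prose clauses; consequently arm-level (as opposed to
family-level) concordance on generated open-fusion cohorts is deliberately
low.

### Fuzzy variant

The knowledge base behind the original system is described only as built on
fuzzy-logic principles; the construction here is this package's own. Each
continuous threshold *t* becomes a linear membership ramp of half-width
`fuzzy_width_fraction · t` (default 0.10), centred at *t* with membership
0.5 at the threshold. Rigid-family membership is the fuzzy 2-of-3 majority
(the median of the three triad memberships). TDR activates as the
conjunctive minimum of the dynamic-family and degeneration memberships; the
fusion arms activate as the rigid membership capped by their normalized
fuzzy vote share; INDETERMINATE as min(dynamic, 1 − TDR conjunction). The
arm is the argmax activation (ties in the order TDR, MI, O, INDETERMINATE)
and the confidence is the margin over the runner-up. Ordinal grades and
tropism keep crisp memberships — a transition width has no natural meaning
on a four- or five-point scale. With width 0 every membership is the crisp
indicator and the output arm equals the crisp classifier's on every profile
(property-tested over 1,000 random profiles).

### Boundary probing

`probe_boundary` scans one profile parameter over a range and returns the
first value at which a predicate on the recommendation flips relative to the
scan start; the crisp rules make such predicates monotone. A single triad
criterion can never flip the family (one vote cannot reach the 2-of-3
majority), so family probes preset one other criterion to a rigid-voting
value; the integer scans then recover exactly the configured thresholds
(4 mm, 6°, 60°, 1240/1150/950 s/mm² under defaults).

## 2. The synthetic cohort generator

### What it emulates

The generator reproduces the published per-arm, per-outcome-stratum
summaries: preoperative profile medians and quartiles, 24-month ODI/VAS
endpoints, tropism symbols, ordinal grade summaries, demographics (age, sex,
BMI) and operated-level frequencies, at the printed stratum sizes
(35/7 TDR, 64/15 MI, 62/13 O good/poor). The calibration tables ship in
`calibration.json`, transcribed from the published summaries.

### The two-piece sampler

Each Me [Q1; Q3] entry is modelled as a split normal: a draw u ~ U(0, 1)
maps through `Me + σ_low·Φ⁻¹(u)` for u < 0.5 and `Me + σ_high·Φ⁻¹(u)`
otherwise, with `σ_low = (Me − Q1)/z₀.₇₅`, `σ_high = (Q3 − Me)/z₀.₇₅` and
z₀.₇₅ = Φ⁻¹(0.75) ≈ 0.6745 fixed as a named constant. The implied quantile
function reproduces (Q1, Me, Q3) to machine precision for every calibration
entry; entries like 6 [6; 8] degenerate to a half-point-mass at the median
and m [m; m] to a point mass. Clamping to physical bounds happens after
sampling, integer rounding (ODI, VAS, age, grades) last. Ordinal grades are
sampled on the numeric grade axis and rounded/clamped to their scale;
tropism symbols map to present-probabilities 0.9 ("+"), 0.1 ("–"),
0.5 ("+/–") — a documented convention, the sources print symbols only.

### What it does not emulate

Variables are independent within a stratum: the summaries print no
correlations, so generated profiles reproduce marginals, not joint
structure; stratum membership carries all the dependence. Passing tests
therefore demonstrate calibration of marginals and the engine's behaviour on
realistic marginal ranges, not performance under realistic within-patient
correlation. Height-loss fraction has no published summary; all strata use
an assumed 0.50 [0.40; 0.60] spec clamped to the eligibility window, so
every generated patient passes the gate. Comorbidity, bone density and
sagittal-balance variables are excluded (they enter the original study only
as exclusion criteria).

### Trajectories

Follow-up was recorded at discharge and 3 and 6 months, but only 24-month
endpoints are printed per stratum. Trajectories are therefore generated, not
calibrated: each score relaxes from a preoperative level toward the
patient's calibrated 24-month endpoint along
`s(t) = end + (pre − end)·e^(−t/τ)` with τ = 3 months and timepoints at
0.5/3/6/24 months, plus additive Gaussian noise (default sd 1.5 points) at
post-operative interior points. Preoperative levels are drawn from an
assumed severe-symptoms distribution (ODI 56 [48; 64], VAS back 70 [62; 78],
VAS leg 62 [54; 70] — typical surgical-candidate intensities) and floored at
the endpoint, so noise-free trajectories are exactly monotone
non-increasing. These trajectory assumptions are the package's own.

## 3. Statistics

Summaries use the linear-interpolation quantile definition (the original
software's convention is unstated; this one is fixed and documented).
Mann–Whitney U uses the exact enumerated null when min(n₁, n₂) ≤ 8 and the
pooled sample is tie-free, otherwise the normal approximation with midrank
tie correction and continuity correction; Wilcoxon signed-rank drops zero
differences, uses the exact null for ≤ 12 informative tie-free pairs, and
warns with p = 1 when every difference is zero. Both exact branches agree
with brute-force enumeration (all rank patterns; all 2ⁿ sign vectors) in the
test suite, and the asymptotic branch's type-I error at α = 0.05 under the
null (n = 20 vs 20) is verified to lie in [0.03, 0.07] over 2,000
replicates. The exact-branch cutoffs are a runtime choice. The 2×2 χ² is
Pearson without continuity correction by default — the variant that
reproduces the published TDR sex comparison p = 0.81 from its printed
counts — with Yates' correction behind a flag. Per-variable α = 0.05 with no
multiplicity correction mirrors the original analysis; a Holm adjustment is
available but off by default.

Concordance compares the engine's recommendation with the arm each patient
received: family-level counts a match when the recommended family equals
the received arm's family, arm-level requires the exact arm, and
INDETERMINATE is discordant at both levels.

## 4. Problem sizes and numerical notes

The acceptance script scans integer grids (ADC 1–2000, translation 0–20,
angles up to 120) and draws n = 20,000 per sampler median — large enough
that integer-scale medians are exact and the continuous ADC median is
stable well within ±2%. Monte-Carlo tests in the suite use n = 10⁴–10⁵
draws and 200 replicates for power/null-rate checks. All randomness flows
through seeded numpy generators; cohort generation is reproducible to
equality and CSV output byte-identical under a fixed seed. Probe scans
guard the inclusive endpoint against float drift; fuzzy memberships are
clipped compositions of linear ramps, so no iterative numerics are involved
anywhere in the package.

## 5. Known limitations

- The rule set encodes one centre's published clauses; it learns nothing
  from data and offers no thresholds fitting.
- Single-segment only: multi-level disease is an exclusion criterion of the
  original algorithm and is out of scope.
- The fuzzy variant is a faithful *construction over* the crisp rules, not
  a reconstruction of the proprietary knowledge base it stands in for.
- Synthetic cohorts validate internal consistency, calibration and power at
  the printed sample sizes; they cannot validate clinical performance.
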