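# Methods

This note documents the quantitative choices behind the pipeline: the rules
as implemented, the parameters that matter, what the synthetic generator does
and does not emulate, and the places where the design was genuinely open.

## Growth standardization (LMS)

Measurements are standardized with the LMS method: z = ((X/M)^L − 1)/(L·S)
for |L| above 1e−7 and z = ln(X/M)/S below it. The 1e−7 switch keeps the
transform numerically continuous across the L = 0 singularity: the analytic
gap between the two branches is (L/2)·S·z² SDS, i.e. below 1e−8 at the switch
point for any physiologic z and S. L, M and S are linearly interpolated
between grid ages, separately per component — the convention of common
growth-chart implementations, and one whose behaviour is analytically
checkable (interpolating a piecewise-linear reference on a refined grid is
exact). Queries outside the grid raise; there is no extrapolation, because a
−3 SDS threshold applied to extrapolated parameters is not meaningful.

Age is exact days since birth divided by 30.4375 (the mean Gregorian month).
Chart data carry calendar dates only, so all dates are day-resolution
ISO-8601. Real growth references (e.g. the WHO charts used in Canadian
practice) are supplied by the user as a tab-separated `measure sex age_months
L M S` file; the bundled tables are synthetic and exist so that tests control
every threshold exactly.

## IGF-1 classification

A result is *low* when strictly below the 2.5th-percentile bound of the assay
in effect on the collection date. Assay calendars assign a boundary date to
the newer assay; the defaults encode an IDS-iSYS era through 2017-09-30, a
Liaison era from 2017-10-01, and a GH-analyzer switch from Dxl (peak cutoff
5.4 ng/mL) to Roche (7.4 ng/mL) on 2019-11-27. Stratifier precedence is
Tanner stage > bone age > chronological age: puberty shifts IGF-1 norms more
than calendar age does. A staging read may be up to 365 days from the draw to
be used — a package default, since no clinical standard fixes this window.
Results with no applicable reference entry are logged and treated as
not-low: missing reference coverage must not exclude a patient. The first
low result (ties broken by result id) indexes all downstream temporal logic.

## Funnel rules and their boundaries

- Short stature is inclusive: z ≤ −3.0. Unrounded z-scores are compared
  directly; no rounding convention is imposed before thresholding.
- The one-year linkage window is symmetric and inclusive (|gap| ≤ 365 days);
  the linked height is the qualifying observation closest in time, earlier
  date winning ties.
- Secondary-cause diagnoses count from any date and either source (visit
  diagnosis or problem list), because problem lists are cumulative. Matching
  is prefix-based after dot-stripping ("E03" matches "E03.9"). The shipped
  prefix sets (malnutrition E40–E46/R63.4/R63.6, hypothyroidism E00–E03, GH
  deficiency E23.0, hypopituitarism E23.0/E23.6/E89.3, liver K70–K77) are
  editable defaults, not a validated standard; institutional code lists vary.
- The malnutrition proxy evaluates BMI at the encounter nearest the index
  date (heights and weights pair on the same encounter date by default) and
  excludes below the 5th percentile (z < −1.6449).

Abnormal-growth categories are multi-label: small-for-gestational-age from
birth z ≤ −2 (length or weight), medication adverse effect from a
glucocorticoid interval overlapping the index date, endocrine and genetic
labels from configurable code-prefix sets, transient pubertal slowing when
growth normalizes off GH with a pubertal (Tanner ≥ 2) read on file, and
idiopathic short stature as the residual label at height ≤ −2 SDS. The
diagnosis model carries ICD-10 codes only, so keyword matching over free-text
diagnoses is out of scope.

## Trajectory review

GH deficiency uses the maximum stimulated peak across all tests, judged
against the cutoff of the analyzer that produced that maximum; patients with
no test are indeterminate and stay under review (roughly half of reviewed
patients in practice are never tested). A good clinical GH response is a
height gain > 0.5 SDS between two on-treatment measurements ≤ 366 days apart
(366 absorbs leap years in "a 12-month period"). IGF-1 normalization is the
first not-low result after the index, labelled on-treatment when it falls in
a GH exposure interval (start ≤ d ≤ end, open-ended end allowed).

Growth normalization has no published numeric definition; the package rule —
latest height z above −2.0 after having been ≤ −3.0, or an off-treatment
gain > 0.5 SDS within 12 months — is a declared, configurable decision.
Verdict precedence: GH deficiency > GH-treatment-related (clinical response
or on-treatment IGF-1 normalization) > spontaneous both > spontaneous IGF-1 >
spontaneous growth > SPIGFD candidate. A growth-only spontaneous verdict
exists because normalization of *either* trajectory is exclusionary. The
same verdict function classifies chart-abstracted case summaries (GH
treatment flag, response descriptor, spontaneous normalization flags), which
is how the packaged 11-record review table is reclassified; a "good
laboratory response" on GH therapy counts as GH-related even when the
clinical response is poor, since on-treatment IGF-1 normalization is an
independent exclusion.

## Synthetic cohorts

The generator emulates a tertiary-care clinic over the 2013–2021 window.
Default archetype mix (chosen once as a plausible clinic mix that exercises
every funnel stage; nothing downstream is tuned to it): 40% normal stature,
25% short stature only, 15% secondary cause (five subtypes), 8%
constitutional-delay normalizers, 7% GH responders, 5% true SPIGFD.
Archetype counts use largest-remainder apportionment so planted counts are
exact. Visits are 6-monthly (±15 days) for 10 visits; entry ages 2–12 years.

Height trajectories are archetype-specific z-paths converted to centimetres
through the toy LMS tables, with 0.3 cm measurement noise (≈ 0.05–0.1 SDS);
weights are derived from a target BMI z (0 for most archetypes, −2.6 for the
malnutrition-BMI subtype) so the step-4 BMI rule is controlled directly.
IGF-1 values are far below (0.5× the smallest bound) or far above (1.5× the
largest bound) every reference stratum, so classification is robust to the
1 µg/L lab noise under any stratifier; spontaneous normalization times are
log-normal with median 10.8 months, log-SD 0.35, truncated to 6.1–24.1
months — a default echoing observed clinical timing, not a claim about its
distribution. Because labs are drawn on the visit grid, observed
normalization times are quantized to ~6-month steps.

What the generator does **not** emulate: realistic ICD-10 co-occurrence,
missing-data patterns, assay drift within an era, transfer in/out of care,
or demographic structure beyond age and sex. Passing tests therefore
demonstrate algorithmic correctness under the declared generative rules, not
field performance on real EMR extracts.

## Problem sizes and tolerances

The test suite runs the recovery harness at 200 patients × 20 seeds and the
oracle-equivalence checks at 50 patients — sizes at which the brute-force
oracles remain exhaustive. LMS round-trips are checked to 1e−9 SDS, branch
continuity to 1e−6 SDS over physiologic ranges (|z| ≤ 3.5, S ≤ 0.15),
percentile symmetry to 1e−9. Funnel percentages are rendered half-up with
one decimal against the short-stature denominator and as whole percents for
within-subset shares, matching epidemiological reporting conventions.

## Known limitations

- Reference-table fidelity is the user's responsibility; the bundled tables
  are synthetic.
- The ICD-10 exclusion sets are starting points and must be reviewed against
  institutional coding practice.
- Step 5 of the original workflow is a manual chart review; the package
  automates its GH-deficiency component and leaves residual secondary-cause
  judgement to the configured code sets.
- Unit handling assumes µg/L ≡ ng/mL for IGF-1 and ng/mL for GH peaks; no
  cross-assay calibration is attempted.
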