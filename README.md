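# spigfd

An EMR-agnostic case-finding pipeline for **severe primary IGF-1 deficiency
(SPIGFD)** in children with short stature, together with a seeded
synthetic-EMR generator so that every stage is testable without patient data.

SPIGFD — short stature with persistently low insulin-like growth factor 1
despite sufficient growth hormone (GH) and no secondary cause — is an
ultra-rare, likely underdiagnosed condition, and the children affected are
exactly the ones who could benefit from recombinant human IGF-1 therapy.
Finding them in a hospital's electronic medical record requires combining
growth-chart mathematics, assay-aware laboratory reference bounds, diagnosis
code sets and longitudinal trajectory logic. This package implements that
combination as a reusable pipeline for clinical informaticians and pediatric
endocrinology researchers working from flat EMR extracts.

## The algorithm

A patient is a *potential* SPIGFD case when all of the following hold
(steps 1–4, the automated funnel):

1. **Short stature** — some height-for-age z-score z ≤ −3.0 SDS, where z is
   computed by the LMS method: z = ((X/M)^L − 1)/(L·S), with the Box-Cox
   power L(t), median M(t) and coefficient of variation S(t) read from a
   sex-specific growth reference (log branch z = ln(X/M)/S when |L| < 1e−7).
2. **Low IGF-1** — at least one serum IGF-1 strictly below the 2.5th
   percentile of the assay in use on the collection date, stratified by sex
   and by Tanner stage, bone age, or chronological age (in that precedence);
   the first low result becomes the patient's *index*.
3. **Temporal linkage** — a qualifying short-stature height within ±365 days
   of the index low IGF-1.
4. **No secondary cause** — no ICD-10 code in the configured exclusion sets
   (malnutrition, hypothyroidism, GH deficiency/hypopituitarism, liver
   disease) and no BMI below the 5th percentile near the index date.

Survivors then pass a trajectory review (steps 5–6): exclusion for GH
deficiency (peak stimulated GH < 5.4 ng/mL on Dxl-era tests, < 7.4 ng/mL on
Roche-era tests), for a good response to GH therapy (height gain > 0.5 SDS
within 12 months on treatment, or IGF-1 normalization on treatment), or for
spontaneous normalization of IGF-1 and/or growth. True SPIGFD cannot
normalize spontaneously, so whatever survives every rule is the final
candidate set.

## Worked example

```python
from spigfd import CohortSpec, generate_cohort, run_pipeline, render_flowchart

gen = generate_cohort(CohortSpec(n_patients=200, seed=42))
result = run_pipeline(gen.cohort, gen.references)
print(render_flowchart(result.report["funnel"]["counts"]))
```

prints

```
[step1_short_stature] height-for-age at or below -3.0 SDS
    retained: 120 (100.0%)
[step2_low_igf1] at least one IGF-1 below the assay 2.5th percentile
    retained: 70 (58.3%)
[step3_temporal_link] short stature within one year of the low IGF-1
    retained: 70 (58.3%)
[step4_potential_spigfd] no coded secondary cause, BMI at or above the 5th percentile
    retained: 40 (33.3%)
[step6_reviewed] entering growth/IGF-1 trajectory review
    retained: 40 (33.3%)
```

120 of the 200 synthetic children are ever at or below −3 SDS for height; 70
of them also have a low IGF-1 linked in time, and 40 survive the
secondary-cause screen. The review then excludes the GH responders and the
spontaneous normalizers:

```python
print({k: v for k, v in result.report["review"]["verdict_counts"].items() if v})
# {'spigfd_candidate': 10, 'excluded_gh_response': 14, 'excluded_spont_both': 16}
print(result.report["review"]["spontaneous_igf1_normalization_months"])
# {'n': 16, 'median': 12.0, 'range': [6.4, 24.3]}
```

The ten surviving candidates are exactly the ten `true_spigfd` archetypes the
generator planted (`gen.ground_truth` carries the labels). The same pipeline
runs from the shell on any cohort bundle in the documented CSV schema:

```bash
spigfd simulate --seed 42 --out sim/          # synthetic bundle + references
spigfd run --config config.yaml --out out/    # report.json, funnel.csv, ...
spigfd fixtures --out fixtures/               # packaged study fixtures
spigfd report --funnel fixtures/funnel_counts.json
```

## Layout

- `spigfd.growth_reference` — LMS z-scores/percentiles, reference-table IO, BMI pairing
- `spigfd.igf1_reference` — assay calendars, stratified 2.5th-percentile classification
- `spigfd.ehr_model` — cohort bundle schema, validation, readers/writers
- `spigfd.case_finding` — funnel steps 1–4 and abnormal-growth categories
- `spigfd.longitudinal_review` — GH deficiency, GH response, normalization, verdicts
- `spigfd.synthetic_emr` — archetype-based cohort generator, toy references, fixtures
- `spigfd.reporting` / `spigfd.config` / `spigfd.cli` — orchestration, run configuration, CLI

See `docs/methods.md` for the modelling decisions and their rationale.
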