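# concord

Quantitative agreement between lesion annotations on **en face
choriocapillaris OCTA** and **ICGA** images, for central serous
chorioretinopathy (CSC) and similar choroidal disease.

Reading-centre comparisons of these two modalities face two problems:
the images live in different coordinate frames (different devices,
magnifications, orientations), and the diffuse borders of
choriocapillaris abnormalities are hard for graders to reproduce.
`concord` implements the standard quantitative workflow:

1. **Registration** — an orientation-preserving similarity transform
   (translation + rotation + isotropic rescaling) is estimated by
   closed-form least squares from user-specified landmark pairs,
   mapping the ICGA frame onto the OCTA frame, whose scan defines the
   6 × 6 mm analysis window.
2. **Circumcircle Jaccard index** — each annotated region is replaced
   by its *circumcircle* (smallest enclosing circle, computed with
   Welzl's algorithm), and agreement between two annotations is

   J(A, B) = |A ∩ B| / |A ∪ B| = |A ∩ B| / (|A| + |B| − |A ∩ B|)

   where A and B are the two circumcircle discs (closed-form
   circular-lens intersection, no rasterisation).  The circle, rather
   than the raw border, is the clinically meaningful unit: borders are
   unreliable between graders, and photodynamic therapy is delivered as
   a round spot covering the lesion.
3. **Area comparison** — matched OCTA and ICGA areas (mm²) are
   classified *equal* when their difference is within 10% of the ICGA
   reference area, otherwise *larger*/*smaller*.
4. **Cohort statistics** — lesion-type prevalences with half-up
   1-decimal percentages, acute/chronic cross-tabulations with a
   chi-squared test, and a paired t-test on matched areas.

A first-class synthetic-data generator produces paired pseudo-OCTA/ICGA
eyes with the three canonical choriocapillaris phenotypes (type A
hyper-reflective patch, type B dark halo gated on subretinal-fluid
thickness, type C hypo-reflective spots), known inter-modality
transforms, exact landmarks, simulated grader boundary noise, and the
analytic circle-JI of the ground truth — so every pipeline stage is
testable without clinical data.

## Worked example

```bash
concord simulate --out-dir demo --n-eyes 1 --seed 7
concord ji --octa-annot demo/eye-000/annotations.json \
           --landmarks demo/eye-000/landmarks.csv \
           --fov-mm 6.0 --out demo/agreements.csv
```

`demo/agreements.csv`:

```
eye_id,comparison,jaccard,area_first,area_second,relation
eye-000,interobserver_octa,0.9681993536839848,9.292090875083327,9.435752868830516,
eye-000,interobserver_icga,0.9133948634340404,7.898572019533092,8.152470313588386,
eye-000,octa_vs_icga,0.8237972885790282,9.292090875083327,8.220740015801793,larger
```

Reading the rows: the two simulated graders agree on the OCTA
hyper-reflective patch with circumcircle JI 0.97 and on the ICGA
hyperfluorescent region with JI 0.91 (each grader's outline carries
0.05 mm boundary noise); after registering ICGA onto OCTA, the
cross-modality JI is 0.82, and the 9.29 mm² OCTA patch is classified
**larger** than the 8.22 mm² ICGA region (difference exceeds 10% of the
ICGA area).  The generator's truth manifest stores the analytic
circle-JI for this eye (0.805) — the pipeline value differs only
through the simulated grader noise.

Cohort-level tabulation:

```bash
concord cohort --records demo/cohort.csv \
               --agreements demo/agreements.csv --out demo/summary.csv
```

All commands are thin wrappers; the same operations are available as
library functions (`concord.estimate_similarity`,
`concord.min_enclosing_circle`, `concord.circle_jaccard`,
`concord.merge_confluent`, `concord.cohort_summary`, …).

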