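# Methods

## The agreement model

Two annotations of the same lesion — by two graders on one modality, or
by one grader on two registered modalities — are compared through their
**circumcircles**: the smallest circle covering the annotated region.
Agreement is the Jaccard index of the two discs,

    J(A, B) = |A ∩ B| / (|A| + |B| − |A ∩ B|),

computed in closed form from the circular-lens intersection area.  The
choice of circle over raw border reflects how these lesions are treated
in practice: the border of a choriocapillaris flow abnormality is
diffuse and graders reproduce it poorly, while the circular spot of
photodynamic therapy makes "which circle covers the lesion" the
actionable question.  J = 1 means coincident circles, J = 0 disjoint
ones; for a concentric contained circle J = (r_inner / r_outer)².

The circumcircle of an annotation is defined as the minimum enclosing
circle of its polygon **vertices**.  Hand-drawn circumcircles could
plausibly be fit to the border curve instead; the vertex-based
construction is deterministic and reproducible, and no claim is made
that it matches any particular manual circle exactly.  A raster-mask
Jaccard (`mask_jaccard`) is kept for sensitivity analyses and for
cross-validating the analytic value, but is not the headline statistic.

### Amalgamation

Abnormal areas that appear confluent are merged before comparison:
annotations (same eye/modality/grader/label) whose polygons overlap or
lie within `gap_tolerance` of each other are unioned, transitively.
Because "appeared confluent" is a perceptual judgement, the tolerance is
an explicit knob; the default is 0 mm (only touching or overlapping
regions merge).  When an eye yields several disjoint merged regions, one
JI is computed per region and `area_weighted_mean_ji` gives the per-eye
figure, weighting by the union area of each comparison.

## Registration

ICGA is the moving image, OCTA the fixed one; the OCTA scan defines the
6 × 6 mm analysis window and all agreement computation happens in OCTA
physical coordinates.  The transform is an orientation-preserving
similarity (scale > 0, no reflection), estimated from landmark pairs by
the closed-form least-squares (Umeyama/Procrustes) solution as provided
by `skimage.transform.SimilarityTransform`.  Two non-coincident pairs
determine the transform; three non-collinear landmarks are the standard
protocol and the CLI warns below that number.  Pixel coordinates are
top-left-origin, x rightward, y downward; conversion to mm
(pixel size = field-of-view / image width) happens after registration.
Registration residuals (RMS of |t(source) − target|) are reported but no
threshold is enforced, since acceptable landmark disagreement is
study-specific.

## Geometry primitives

* **Polygon area** — absolute shoelace formula; polygons must be simple
  (checked via shapely), with ≥ 3 vertices.
* **Minimum enclosing circle** — iterative move-to-front Welzl.  Points
  are deduplicated and lexicographically sorted before an internally
  seeded shuffle, so the result is independent of caller input order;
  collinear/duplicate configurations fall back to the 1-/2-point base
  cases.  Containment and circle-identity use a relative tolerance of
  1e-9.
* **Circle intersection** — the closed-form lens area
  r₁²·acos(·) + r₂²·acos(·) − ½√(·), with the disjoint and contained
  branches handled exactly.  Identical circles give J = 1.0 *exactly*
  (the union reduces to the intersection in floating point), which the
  zero-noise pipeline tests rely on.

## Statistics

* Paired Student's t (two-sided) on matched OCTA vs ICGA areas, via
  `scipy.stats.ttest_rel`; the degenerate all-zero-difference case
  returns (t = 0, p = 1).
* Pearson chi-squared on 2 × 2 tables via `scipy.stats.chi2_contingency`
  with the continuity correction **off by default** (a `yates` flag
  enables it).  Published reports often omit which variant was used; the
  uncorrected Pearson statistic is the package default and both are
  available.
* Percentages are rounded half-up to one decimal, matching the printed
  style of clinical tables (e.g. 61/66 → 92.4%).
* p < 0.05 is used only for labelling, never for silent filtering.

`cohorts.cohort_from_counts` expands printed combination counts
(all-three / A+C-only / C-only, acute split, halo-by-duration split)
into explicit per-eye records so that every percentage a summary prints
is recomputed from records rather than copied.  The lesion-combination
model assumes the halo (type B) only occurs around a patch (type A) and
spots (type C) occur in every eye — the combinations actually observed
in CSC cohorts.

## Synthetic data

`generate_eye` builds one eye from geometric primitives:

| element | model | default |
|---|---|---|
| type A patch | ellipse + intensity lift + granular noise | center (3, 3) mm, semi-axes 2.2 × 1.8 mm (≈ 12.4 mm²), lift +80, σ 18 |
| type B halo | multiplicative darkening annulus around the patch | width 0.5 mm, factor 0.45 |
| SRF gate | halo present iff simulated SRF thickness > threshold | thickness 538 µm, threshold 300 µm |
| type C spots | dark disks inside the patch | 3 spots, radius 0.10–0.20 mm, factor 0.30 |
| ICGA hyper region | same ellipse, linearly scaled and offset | scale 0.968 (area ratio ≈ 0.94), offset 0.3 mm |
| modality transform | similarity, ICGA px → OCTA px | scale 1.05, rotation 3°, translation (8, −5) px |
| grader noise | radial Gaussian vertex perturbation | σ 0.05 mm |

The SRF gate encodes an observed *association* (thicker fluid pockets
cast the halo shadow) as the simplest faithful mechanism; the 300 µm
threshold is a free generator parameter sitting between the reported
group means for eyes with and without the halo (≈ 538 vs ≈ 243 µm), not
an empirical claim.  The ICGA hyper region is drawn slightly smaller
than and offset from the OCTA patch so that the cross-modality JI of the
defaults (≈ 0.83) and the OCTA-larger-than-ICGA area relation match the
regime reported for real cohorts.

Because the ellipse is sampled at 64 evenly spaced angles including the
major-axis endpoints, the minimum enclosing circle of the truth polygon
equals the circle on the major axis *exactly*; the stored `analytic_ji`
is therefore the closed-form circle JI of the two true circumcircles in
the OCTA mm frame, and the zero-noise pipeline must reproduce it to
floating-point accuracy (tested at 0.02 tolerance end-to-end, observed
≈ 1e-15).  Landmarks are emitted at three fixed non-collinear,
lesion-independent positions and are exactly consistent with the true
transform.

`generate_cohort` draws per-eye lesion presence from configured
prevalences (defaults: type A 61/66, type C 1.0), allocates
`round(n · acute_fraction)` acute eyes deterministically, and draws SRF
thickness from N(500, 200) µm for acute and N(310, 150) µm for chronic
eyes — chosen so the 300 µm gate yields halo rates near the published
acute/chronic split (≈ 0.84 vs ≈ 0.53).  Type A areas are drawn from
N(12.7, 3.8) mm² clipped to [4, 16]; the semi-major axis is capped so
that lesion plus halo fit the 6 mm window, preserving the drawn area by
flattening the aspect ratio.  ICGA/OCTA area ratios are N(0.937, 0.10).
All randomness flows from a single `numpy.random.default_rng(seed)`;
identical configs and seeds give byte-identical rasters.

What the generator does **not** emulate: OCTA speckle/decorrelation
physics, vascular texture, projection and shadow artifacts from PED or
fibrin, irregular lesion shapes, or inter-eye correlation in bilateral
disease.  Passing tests therefore demonstrate that the *measurement
pipeline* (registration, circumcircle construction, JI, area rules,
statistics) is correct on known geometry — not that the reference
threshold segmenter, or any automatic grading, works on clinical
images.  Lesion grading remains manual in practice;
`reference_segmenter` is plumbing that lets the CLI run end-to-end on
synthetic rasters.

## Numerical choices and degenerate inputs

* Geometry tolerance 1e-9 (relative) for containment and
  circle-identity; JI values clipped to [0, 1] against rounding.
* Welzl shuffle seed is fixed internally; results are input-order
  independent.
* `simulate_grader` clips radial perturbations at 90% of the
  centroid distance (keeping outlines star-shaped) and redraws up to 20
  times if a perturbation self-intersects, then raises.
* Zero-radius/zero-area degenerate ratios (JI of two empty regions,
  area relation against a zero ICGA area, zero-margin tables) raise
  typed errors rather than returning NaN.
* Problem sizes in the validation suite — 200 enclosing-circle
  instances (n ≤ 60), 50 Monte-Carlo circle pairs at 10⁷ samples, 100
  noiseless landmark systems, 50 synthetic eyes, 10⁴ null replicates
  per statistical test, 200 replicates per grader-noise level — were
  chosen to give the oracles comfortable statistical margins while the
  whole suite runs in a couple of minutes on one core.

## Known limitations

* The circumcircle is vertex-based; annotations intended as smooth
  curves should be sampled densely enough that the polygon hull matches
  the intended outline.
* Cross-modality comparison assumes one pixel size per modality image
  and a global similarity transform; deformable or projective
  distortion between modalities is out of scope.
* The ImageJ ROI importer reads polygon/freehand/traced outlines only
  and carries no eye/grader/label metadata (ImageJ stores none).
* JPEG input is deliberately unsupported (PNG/TIFF only): lossy
  block artifacts interact badly with threshold-based plumbing.
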