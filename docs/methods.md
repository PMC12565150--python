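# Methods

## Problem and measurement model

Left-ventricular (LV) wall thickness is a diagnostic and prognostic marker
(hypertrophy, dilated cardiomyopathy, ischemic thinning, and the apical
compact-layer thinning typical of excessive trabeculation).  Clinical
practice measures it with a manual caliper once per segment of the AHA
16-segment model, with the segment margins and the measurement point chosen
subjectively — a procedure with poor interobserver reliability.

`lvthick` implements the contour-based alternative: automated, high-density
distance sampling between the endocardial and epicardial contours of the
three long-axis (LAX) cine planes (2-, 3-, 4-chamber), followed by
anatomically anchored segmentation.

### Wall-distance sampling

Each plane contributes an open endo/epi contour pair (mm, image coordinates,
y down) running base → apex → base.  The endocardial contour is resampled to
N = 100 arc-length-uniform stations; the thickness at station *i* is the
minimal Euclidean distance from the station to the epicardial polyline
(point-to-segment over all segments, via shapely).  This metric is exact on
concentric annuli, robust to vertex density, and requires no normal
estimation.  Distances are anchored on the endocardium because the apex
landmark (below) is created by moving the endocardial contour.

### Apex landmark and segmentation

Studies are *apex-marked*: the reader collapses the endocardial contour onto
the epicardial contour over a ~10 mm window at the apex, so the distance
sequence dips to ~0 there (typically 4–8 near-zero samples at N = 100).
`detect_apex` finds all maximal runs of samples below ε (default 0.5 mm) and
selects the longest, breaking ties toward the run whose centre is closest to
the sequence midpoint, then toward the earlier run.  The apex index is the
lower-middle sample of the run.  A run touching either sequence end, or
longer than 30 % of the sequence, is an error; a run outside 2–15 samples
only warns.

The samples before and after the run — the two base→apex wall paths — are
each divided into three equal-count groups (basal, mid, apical) with
half-open floor boundaries ⌊k·m/3⌋, applied in base→apex orientation on
*both* sides so remainder samples fall toward the apex symmetrically.  The
apex-run samples are segment 17 (the apical cap) and contribute to nothing.

The 18 plane-side thirds map onto the AHA model: 2-chamber → anterior
(S1/S7/S13) and inferior (S4/S10/S15); 3-chamber → anteroseptal (S2/S8) and
inferolateral (S5/S11); 4-chamber → inferoseptal (S3/S9) and anterolateral
(S6/S12).  The apical septal (S14) and apical lateral (S16) segments are
seen by both the 3- and 4-chamber planes and take the unweighted mean of the
two apical-third means.  Aggregates are unweighted segment means:
S_AVG_BAS = mean(S1–S6), S_AVG_MID = mean(S7–S12), S_AVG_API = mean(S13–S16).
(Published aggregate rows for the automated method are not always the
unweighted mean of the printed segment means — they may be sample-weighted or
computed pre-rounding; this package uses the documented unweighted mean
everywhere.)

### Parameters

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 100 | distance stations per plane |
| `epsilon_mm` | 0.5 mm | apex-run threshold ("close to zero") |
| apex-run warning band | 2–15 samples | expected marking footprint |
| `flag_threshold_mm` | 5.0 mm | bull's-eye red flag (strictly below) |
| ICC model | ICC(2,1) | two-way random, absolute agreement, single rating |
| α | 0.05 | all gates and significance flags |

Boundary ICC values fall in the lower band: 0.5 and 0.75 are "moderate",
0.9 is "good"; only > 0.9 is "excellent".

## Statistics

ICC(2,1) is computed from the two-way ANOVA mean squares with the F-based
95 % confidence interval (Satterthwaite degrees of freedom); ICC(3,1) is
available for sensitivity analysis.  The interval is assumed two-sided 95 %.
Comparisons are normality-gated by Shapiro–Wilk on the relevant quantity
(paired differences, or each group): parametric → paired/independent t,
otherwise Wilcoxon signed-rank / Mann–Whitney U.  A `paper_compat` flag
replaces the nonparametric paired branch with a Kruskal–Wallis H-test to
replicate a published procedure that names that (independent-groups) test
for related parameters; the default follows statistical convention.  No
multiple-testing correction is applied.

## Synthetic phantoms

The phantom emulates a marked LAX study so the full chain is testable
without patient data.

* **Geometry** — epicardium: half-ellipse, semi-axes (30, 75) mm, vertices
  uniform in arc length (default 512).  Endocardium: inward normal offset by
  a region-wise thickness profile (six plane-side thirds per plane,
  collapsible to/from a 16-segment truth vector).  Offsets are validated
  against the curvature-safe limit a²/b (the minimal radius of curvature, at
  the apex).
* **Apex marking** — endocardial vertices within a 10 mm arc window centred
  on the apex are snapped onto the (noisy) epicardial contour, mirroring how
  readers align contours on screen; this keeps the marked window near 0 mm
  even under jitter.
* **Noise** — arc-length-correlated Gaussian jitter applied independently to
  both contours, correlation length 2 mm (the in-plane pixel scale at which
  tracing deviations decorrelate), marginal sd exact by kernel
  normalisation, stationary along the curve (periodic smoothing).  White
  per-vertex jitter is deliberately avoided: minimum-distance sampling
  against a jagged polyline is biased low, and tracing error is not white.
  Sensitivity: the 50-seed recovery MAE under 0.3 mm jitter moves from
  ≈0.29 mm (1 mm correlation) to ≈0.43 mm (8 mm), and contour-averaged ICCs
  from ≈0.87 to ≈0.65, because within-segment averaging only suppresses
  noise that decorrelates inside a segment.

**Marking-transition samples.** A marked endocardial contour must travel
~τ mm of arc to reach the epicardium at the window edge, and the sampled
distance can change by at most 1 mm per mm of arc, so ≥ (τ − ε) mm of arc per
side carries intermediate distances.  At ~1.6 mm station spacing this puts
~3 samples per side on the transition; they fall into the apical groups and
bias apical segment means low by ~0.4–0.6 mm (never high).  This is a
property of the marking convention itself, not of the implementation — real
marked exports contain the same shoulder samples — and it cancels between
readers, so reliability is unaffected.  The sequence-level generator
(`generate_sequence_study`), which emulates the distance-CSV export the
segmentation algorithm actually consumes, has no transition shoulders and is
the reference for exact-recovery checks (zero-noise recovery < 1e−9 mm,
asserted at 0.05 mm).

* **Cohorts** — group templates (basal/mid/apical, mm): HEALTHY-like
  6.5/5.9/5.4; LVET-like 6.4/5.7/4.75 (apical thinning).  Per-subject truth =
  template + subject-level offset (sd 0.4 mm) + per-segment noise (sd
  0.3 mm), i.e. between-subject sd ≈ 0.5 mm per segment; values floored at
  2 mm; sexes alternate.  Templates are scene-setting, not acceptance values.
* **Observers** — `single_caliper`: one measurement per segment, uniformly
  placed within the segment (there is no standard measurement point), read
  off a piecewise-linear within-wall thickness profile, plus 0.4 mm caliper
  noise; segments seen by two planes (S14/S16) average two draws.
  `contour_averaged`: each reader re-traces the contours (independent 0.3 mm
  jitter) and reports the full pipeline output.

### What the phantoms do and do not show

Passing tests demonstrate algorithmic correctness (apex detection, exact
partitioning, mapping, aggregation), geometric exactness on annuli, and the
qualitative reliability mechanism (averaging ~15 automated samples beats one
subjective caliper placement).  They do not demonstrate performance on real
anatomy: half-ellipse planes have no trabeculae, papillary muscles, valve
plane ambiguity, or through-plane motion, and the observer models are far
simpler than human readers.

Two simulation outcomes are worth stating plainly.  Under the default
contrast setting the contour-averaged observer dominates the single-caliper
observer in 20/20 seeds (median segment ICC ≈ 0.86 vs ≈ 0.58), but only
~20 % of contour-averaged segment ICCs exceed 0.9: with a between-subject
truth spread of 0.5 mm and 0.3 mm contour jitter, the attainable ICC tops
out near 0.25/(0.25+0.05) ≈ 0.85.  Real cohorts are far more heterogeneous
(segment SDs ~0.9–1.7 mm), which is what pushes observed automated ICCs
above 0.9; reproducing that band would require a wider truth spread than the
0.5 mm used here.

## Numerical choices and degenerate inputs

* Resampling is linear interpolation on cumulative arc length; first/last
  points are preserved exactly.
* Ties in apex detection and the lower-middle apex index are deterministic
  and documented above.
* Constant rating matrices raise an undefined-ICC error; identical rater
  columns give ICC = 1 with a degenerate interval; zero paired differences
  give p = 1 on the t branch; the Shapiro–Wilk gate treats constant samples
  as normal.
* Distance CSVs auto-detect layout (wide/long), delimiter (`,`/`;`/tab),
  decimal mark (`.`/`,`) and header; malformed rows are reported by number.
* All randomness flows through `numpy.random.SeedSequence` children, so any
  study, cohort or simulation is reproducible from its seed.

## Problem sizes used in checks

Oracle suites use 500 random sequences (apex detection), 200 random 10×2
matrices (ICC vs an independent ANOVA implementation and vs pingouin), 200
random partitions, 50 noise seeds for recovery, and 20 seeds × 50 subjects ×
2 readers for the reliability contrast; these sizes give Monte-Carlo error
comfortably below the asserted tolerances.

## Known limitations

* Long-axis planes only; no short-axis geometry, no 3-D reconstruction, no
  image-domain processing or DICOM ingestion.
* Mean segmental thickness only (no per-segment maxima/minima), and no
  segment-17 thickness by construction.
* The vendor CSV schema is unknown; the tolerant reader plus an explicit
  dialect is a mitigation, not an emulation of any specific export.
* Apical segment estimates from marked contours carry the transition bias
  described above; consumers comparing groups or readers are unaffected,
  but absolute apical values from contour input are conservative.
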