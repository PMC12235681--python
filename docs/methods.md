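# Methods notes

## The grading model

A grading record describes exactly one lesion in one B-scan. Its
fields mirror a printed questionnaire form whose boxes carry literal codes,
and the package treats those codes as the serialization contract:
`GEN-01`–`GEN-04` (scan gradable, dry late-AMD, wet late-AMD,
follow-up), `LAY-01A`–`LAY-05E` (five outer-retinal bands × five
states: bent down, unchanged, bent up, disrupted, not gradable),
`INSEP` (IZ–RPE separability), `BRI-01`–`BRI-05` (brightness),
`SP-01`–`SP-03` (confluent, drusen ooze, hyper-reflective only) and
`PRO-01`–`PRO-06` (progression at follow-up).

Validation enforces the rules that are derivable from the field
definitions: one state per band, one brightness, progression only on
follow-up scans, and no lesion-level grading on a non-gradable scan.
It returns violation lists rather than raising, so a batch of records
can be checked and reported in a single pass. `INSEP` is tri-state
(yes / no / unassessed): the separability must be *indicated*, but a
cohort in which it was not assessed must remain representable; the
same reasoning makes "progression not assessed" an explicit value
rather than a missing field. The special-property flags are
independent booleans (a lesion can be confluent *and* show drusen
ooze).

## Masks and morphometry

A mask pixel is any pixel whose RGB channels are not all equal —
colour against a greyscale B-scan. Grouping is by *exact* colour with
zero per-channel tolerance by default: confluent lesions are
delineated by touching masks of different colours, and any
nearest-colour clustering would merge them. The corollary, enforced by
the synthetic renderer and expected of annotation tools, is hard-edged
(non-anti-aliased) drawing. Each colour must form one 8-connected
region of at least two pixels; violations name the colour so the
grader can fix the drawing.

Morphometrics follow directly from the pixel set and the per-scan
calibration `(w, d)` = (lateral pixel width, axial pixel depth) in μm:

* cutting area `= |mask| · w · d` (μm²),
* projected diameter `= (max col − min col + 1) · w` (μm),
* centroid = arithmetic mean of `(row, col)`, real-valued.

The projected diameter is deliberately the *lateral* extent only:
lateral and axial pixel scales differ by a factor of ~3, and diameter
conventions in AMD grading refer to the transverse (fundus-plane)
extent. The `+1` makes a two-pixel horizontal mask span two columns; a
vertical two-pixel mask consequently has diameter 1 px, which is the
intended reading of "columns spanned". Calibration values are always
taken as supplied by the device export (or the user); the package
never derives them from scan geometry, because nominal scan depths and
row counts are rounded values that do not reproduce the device's own
pixel depth exactly.

## Greyscale conversion

Raw OCT intensities are compressed with a fourth root and binned to
256 levels: `g = round_half_up(255 · (v / m)^(1/4))`, where the
reference maximum `m` defaults to the per-scan maximum but may be
fixed to a device range. Round-half-up is chosen over banker's
rounding so the midpoint anchor `v = m/16 → 127.5 → 128` is stable
across platforms. The map is monotone; an all-zero scan maps to an
all-zero image.

## Lesion types, leading scan, tracking

The operational type rule reads the graded RPE state: bent down or
unchanged → SDD (the deposit sits on top of the RPE), bent up or
disrupted → drusen (the deposit lies under the RPE), not gradable →
unclassifiable. `SP-03` (hyper-reflective material only) takes
precedence over the RPE state — such a lesion deforms layers without
being a sub-/supra-RPE deposit and is counted as its own category even
when its RPE is bent.

The leading drusen is the lesion with the maximal cutting area in any
B-scan of a volume; ties break to the lowest scan index, then the
lowest lesion id, so selection is deterministic. Tracking matches
lesions across visits by annotation identity (same colour / lesion id)
— scanner eye-tracking keeps follow-up scans at the baseline position,
and automated spatial matching is out of scope. Growth/stationary/
remission gradings without a baseline partner are rejected as
inconsistent; everything else is advisory: "noticeable growth" has no
numeric definition in the instrument, so the consistency check uses a
configurable relative-change threshold (default 0.10) and only flags
mismatches for grader review. Area deltas are computed from the
unrounded μm² values; when cutting areas are rounded to integers
before differencing, deltas can differ by ±1 μm² from the values
obtained here.

## Cohort statistics

Log-normal fits use the moments of the natural logs (`meanlog`,
`sdlog` with ddof = 1), which are the maximum-likelihood estimates;
quantile-based fitting would be equally defensible but has no
advantage here. Shapiro–Wilk is run on the log values (the statistic
is invariant to the log base) and is limited to 3 ≤ n ≤ 5000, the
range where its p-value is accurate; `fit_lognormal` reports NaN for
the test beyond that. Size summaries exclude hyper-reflective-only
lesions by default, since they are not deposits in the drusen/SDD
sense; the exclusion list is user-overridable. Pixel-vs-μm unit
correlations use Pearson's product-moment coefficient with a
two-sided p.

## The synthetic generator

The generator exists so that every operation can be exercised, end to
end, without clinical data. One "patient" contributes one leading scan
of 496 rows × 512 columns. The five outer-retinal bands are flat
stripes in the lower third of the image (top rows ELM 360, EZ 368,
IZ 376, RPE 382, BM 389; thicknesses 2/4/2/5/2 rows; reflectivities
0.45/0.90/0.50/0.95/0.40 against a 0.05 background). Lesions are
injected as:

* **drusen** — a parabolic dome of deposit between BM and the RPE;
  the RPE and the bands above it drape upward over the dome, BM stays
  put (truth grading: LAY-01C…04C, LAY-05B);
* **SDD** — the same dome shape resting *on* an undisturbed RPE, with
  the bands above draped (LAY-03C wave, LAY-04B, LAY-05B);
* **hyper-reflective focus** — a bright ellipse above the bands with
  `SP-03` ticked;
* one "ungradable" variant rendered drusen-like but graded LAY-04E,
  so the unclassifiable branch of the type rule is exercised.

Dome height defaults to 0.4 × diameter (in μm, converted to rows), a
visually plausible aspect for small drusen. Speckle is multiplicative
log-normal noise (σ = 0.25) on the reflectivity field before
fourth-root conversion — a pragmatic stand-in, not a physical OCT
speckle model. Because masks are drawn hard-edged after greyscale
conversion, the mask round-trip is exact by construction regardless of
noise.

Cohort defaults are the study-scale conditions the instrument was
demonstrated under: lesion counts of `1 + Poisson(0.98)` per scan
(mean 1.98, so a 100-patient cohort carries ≈ 198 lesions and every
leading scan shows at least one); type proportions
142 : 54 : 1 : 1 (drusen : SDD : focus : ungradable); lesion diameters
log-normal with median 154.8 μm and `sdlog` 0.6, truncated at a
rendered width of 60 px so placements always fit the 512-column field
(the truncation affects < 0.5 % of draws); per-scan lateral pixel
width Normal(11.27, 0.3) μm at a fixed axial depth of 3.87 μm;
adjacent lesion pairs flagged confluent with probability 0.22, which
reproduces a ≈ 22 % confluent-lesion fraction. The `sdlog` of 0.6 is
chosen so that the implied diameter distribution matches the reported
spread of Early-AMD lesion diameters (mean/median ratio ≈ e^{σ²/2} ≈
1.2). All randomness flows from one integer seed through
`numpy.random.SeedSequence`; equal seeds give bit-identical datasets.

What the generator does **not** emulate: real speckle statistics and
shadowing, curved retinal geometry, inter-B-scan 3-D continuity,
late-AMD features, grader disagreement, and anti-aliased annotation
strokes. Passing tests therefore demonstrate the correctness of the
bookkeeping, geometry and statistics on idealized annotations — not
segmentation performance or grader reliability on clinical scans.

## Problem sizes and numerical choices

The test suite and the acceptance script run cohorts of 100–110
patients (≈ 200–220 lesions), 500 replicates of n = 197 for the
calibration of the log-normality test, and 10⁵ draws for parameter
recovery; together they complete in well under a minute on one CPU.
Mask connectivity uses `scipy.ndimage.label` with a 3×3 structuring
element on the mask's bounding box. Mask ordering in all outputs is
(min column, min row, colour bytes). Centroids are reported to two
decimals in CSV exports but kept at full precision in memory.

## Known limitations

* The enforced validation rules are the subset derivable from the
  field definitions; a grading protocol may impose further
  dependencies (e.g. between `INSEP` and the IZ/RPE states) that the
  schema accepts silently.
* Mask extraction with a non-zero channel tolerance can, in
  principle, split an anti-aliased stroke into several exact colours;
  the package's answer is to require hard-edged drawing rather than to
  cluster colours.
* The generator shares one size distribution across lesion types;
  per-type distributions are configurable but default to the shared
  one, as no per-type estimates are established.
* Cutting areas are raw single-scan values; no stereological
  correction for the sampling of a 3-D lesion by discrete B-scans is
  applied.
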