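# Methods

## The measurement model

A histology cross-section is reduced to two ordered polylines in micrometer
coordinates: the articular surface and the tidemark (the boundary between
uncalcified and calcified cartilage). The x axis runs along the section, y
increases toward the joint space; all measurements are taken over a 7 mm
region of interest (ROI) flanked on both sides by normal cartilage.

**Idealized surface.** Degenerated cartilage has no trustworthy local
geometry, so the reference for both roughness and measurement direction is
an *idealized smooth surface*: a least-squares polynomial (degree 2 by
default) fitted **only to the flank surface points** outside the ROI. A
quadratic captures condylar curvature without chasing lesions; the flanks
must each contribute at least 10 digitized points. Perpendicular directions
are normals of this idealized surface, not of the raw fibrillated surface,
whose normals are noise-dominated.

**Thickness** is the mean of 20 ray casts: at equally spaced ROI abscissae,
a ray starts on the *real* surface and follows the idealized surface's
inward normal to its nearest tidemark intersection. If a ray exits the
digitized tidemark (possible at extreme edge geometry) that point falls
back to the vertical surface–tidemark distance and the fallback is logged
at DEBUG level. The 20 points deliberately include lesion craters: the
window is defined through the region of greatest damage, and excluding
craters would bias a degenerated joint toward its intact thickness.

**Area** is the trapezoidal integral of the vertical surface–tidemark
separation over an evaluation window, i.e. the polygon bounded by the two
contours and the window-edge verticals. A negative separation anywhere in
the window (boundary crossing) is a hard geometry error.

**RMS roughness** is `sqrt((1/N) Σ (Y_ideal − Y_real)²)` over all N
digitized ROI surface points. **Normalized roughness** is RMS divided by
mean thickness. The raw ratio is ~0.02–0.05 for degenerated cartilage; the
package reports it ×1000 (`ratio_scale` switches the convention), which
puts typical values in the 20–45 range and corresponds to RMS values of
5–7 um — the physically plausible scale for fibrillation.

**Raster path.** For image input, the um/px scale is calibrated from a
rendered 1 mm ruler bar (the longest horizontal run of near-black pixels);
the tissue band must segment into exactly one connected component above the
tissue intensity threshold, and its per-column top/bottom contours become
surface and tidemark. Segmentation handles only this synthetic raster
dialect — general histology segmentation is out of scope.

## The synthetic study generator

The generator emulates the *statistical structure of the endpoint data* of
a three-arm ACLT study — treatment arms `channa` (51.4 mg/kg, converted
from a 1000 mg/70 kg human dose by the rabbit body-surface-area factor
3.6), `glucosamine` (77.5 mg/kg, recorded as administered) and `control` —
with 11 animals per arm assigned by block randomization in blocks of six,
and four compartments per joint. It does not model surgery, healing
dynamics or biomechanics.

**Geometry.** The condylar base curve is a parabola whose apex curvature
matches a 15 mm condylar radius, with the 7 mm ROI centred on the apex and
1 mm smooth flanks. The parabola gives genuinely non-vertical surface
normals (slope up to ~0.3 at the flank ends) so perpendicular-measurement
code is exercised, while remaining exactly representable by the degree-2
idealized-surface model; a true circular arc would deviate from any
quadratic by ~15 um over the fitted span, injecting reference-model error
an order of magnitude above the roughness signal — a misspecification the
real procedure (fitting smooth normal cartilage near the window) does not
face. The tidemark is the parallel (normal-offset) curve of the base at the
animal's thickness, so true perpendicular separation equals the drawn
thickness by construction. Point spacing is 5 um (≤ 5 um required).

**Fibrillation.** The roughness field is a sum of 3–8 random-phase
sinusoids (wavelengths 250–2000 um, log-uniform), cosine-tapered over
150 um at the ROI edges, zero in the flanks, and rescaled so its realized
RMS over the digitized ROI points equals the target exactly — making
roughness recovery analytically checkable rather than approximate.

**Per-animal truth.** Thickness and the normalized-roughness ratio are
drawn per animal from lognormal distributions parameterised by the preset
mean and between-animal SD (SD = group SEM × √11). Lognormal rather than
normal keeps both quantities strictly positive with an exact mean; a
truncated normal would bias the thinnest arm's mean upward by several um.
The per-animal RMS follows as ratio × thickness / 1000. Default group
truths: thickness 242.82 / 211.73 / 155.73 um and normalized roughness
22.18 / 33.82 / 45.10 (×1000) for channa / glucosamine / control.

**Area windows.** Group area truths (97,722 / 79,369 / 57,896 um²) are an
order of magnitude below the full-window geometric area (7 mm × 150–240 um
≈ 1.4 × 10⁶ um²). `cartilage_area` always computes geometrically correct
areas; each preset therefore carries a narrower evaluation window of
length `area_truth / thickness_mean` (371–402 um, centred in the ROI) over
which the expected measured area equals the group truth. The pipeline's
area endpoint uses the full ROI; the recovery protocol uses the preset
window.

**Ordinal endpoints.** Each compartment's OARSI truth is a target mean
total, split across components proportionally to scale width (structure
11/18, density 4/18, clusters 3/18) and realised as Binomial(scale_max,
mean/scale_max) draws — exact expected value, unimodal ordinal spread.
The drawn structure category is inverted through the 12-row rubric into a
lesion descriptor (extent drawn inside the row's <50% or ≥50% band); with
probability 0.4 a strictly less severe secondary lesion is added, so the
most-severe-lesion rule is exercised without moving the expected score.
Compartment targets: control MF 7.27 / MT 5.82 / LT 7.45 with LF 7.73 as
the residual of the 28.27 joint total; channa MF 4.36 / MT 2.55 / LT 3.82 /
LF 5.00 (total 15.73); glucosamine MF 3.64 with the remaining 13.91 of the
17.55 total split evenly. India-ink grade distributions per compartment are
calibrated so compartment medians are 1/1/1/1 (channa), 3/2/2/2
(glucosamine), 3/3/2/2 (control) and the induced modal cohort median of
the four-compartment sum is 4, 9 and 10 respectively.

**Lesion carving and profiles.** `build_profile` can carve erosion lesions
as cosine-tapered depressions whose peak depth is the category's fraction
of local thickness (⅓, ⅔, full), clamped at the tidemark. In the default
study configuration descriptors drive scoring but are *not* carved into the
measured geometry (`carve_lesions_in_profiles=False`): the arms' surface
degeneration signal is carried by the calibrated fibrillation RMS, because
group normalized-roughness truths of 22–45 (×1000) imply 5–7 um RMS,
whereas a single full-depth crater in the window would contribute tens of
um and make the roughness scale incompatible with those truths. Carving is
unit-tested through the explicit `lesions=` argument.

**Serum.** COMP / COX-2 / PGE2 are lognormal per animal, clipped to the
assay detection range 1.56–100 ng/ml (clipping logged). Group means are
not pinned by any recovery target; they are chosen once so that control
COMP exceeds both treatment arms (~1.4 between-animal SD), while COX-2 and
PGE2 do not separate the arms.

**Determinism.** A master seed feeds a `SeedSequence`; spawn 0 drives block
randomization and spawns 1..33 give each animal an independent substream
consumed in a fixed documented order. Identical (config, seed) reproduces
byte-identical datasets and pipeline outputs.

## Statistics

Plan selection per endpoint: ordinal scale → Kruskal–Wallis; continuous
scale → Shapiro–Wilk per group at α = 0.05 (constant groups count as
non-normal), all normal → one-way ANOVA with mean-centred Levene gating
the post hoc (Tukey's HSD if p > α, Dunnett's C otherwise), any non-normal
→ Kruskal–Wallis. Graphical normality checks (box plots) are emitted as
report artifacts, never used as gates.

Dunnett's C is implemented as the procedure defines it — decision-only:
pair (i, j) is significant when |mean difference| exceeds
`q̄ · sqrt((s²ᵢ/nᵢ + s²ⱼ/nⱼ)/2)`, with `q̄` the studentized-range quantile
at (k groups, n−1 df), averaged over the two groups' df when sizes differ.
No p-value is fabricated; reports carry the critical difference and flag.

Pairwise Mann–Whitney tests after Kruskal–Wallis use the exact null
distribution where possible (normal approximation with tie correction
otherwise) and Bonferroni ×3 adjustment by default (Holm available); the
adjustment method for "repeated tests with adjusted p" is a deliberate
design choice, Bonferroni being the simplest conservative option for three
pairs. Familywise type-I error of the entire gated pipeline under a null
simulation (3 normal groups, n = 11) is checked in the acceptance suite at
≤ 0.07 over 2000 replicates.

A planning helper implements the standard normal-approximation two-mean
sample-size formula; it is a convenience, not a validated surface.

## Problem sizes and what passing tests show

Recovery protocols use 50 simulated cohorts (11 animals per arm each; 550
animals per arm in total) for thickness, area, roughness and OARSI totals,
and 200 cohorts for the macroscopic medians — sizes at which the empirical
SEM of the cross-cohort mean is a few parts per thousand of the truth, so
the 3×SEM acceptance band is a genuinely tight bias check. Passing shows
the measurement and scoring stages are unbiased *for data with this
generator's structure*: smooth parabolic base geometry, sinusoidal
fibrillation, rubric-consistent descriptors, independent animals. It does
not certify performance on real stained sections — staining artifacts,
segmentation ambiguity, inter-rater variation in reading lesions, and
non-parabolic joint geometry are all outside the generator's scope.

## Numerical choices and degenerate inputs

* Polynomial fits use `numpy.polynomial.Polynomial.fit` with its internal
  domain mapping (well-conditioned for |x| up to 10⁴ um).
* Ray–polyline intersection solves each segment's 2×2 system vectorized;
  the nearest positive-distance hit wins; misses fall back vertically.
* Probability vectors must sum to 1 within 1e-9; the ROI must span
  7000 ± 1 um; surface below tidemark anywhere (beyond 1e-6 um) is a
  validation error.
* Extent ties at exactly 50% grade as ≥ 50% (the rubric's closed bound).
* Studentized-range quantiles are memoised (they cost ~0.1 s each and the
  (α, k, df) space in any one study is tiny).
* All-tied ordinal data and all-constant continuous groups raise
  degenerate-data errors rather than returning NaN statistics.

## Known limitations

* The generator targets endpoint-level statistical structure only; no
  longitudinal disease course, no within-joint spatial correlation between
  compartments beyond the shared per-animal thickness/roughness draw.
* Dunnett's C gives no p-values, so ranking near-threshold pairs is not
  possible on that branch.
* The raster round trip quantizes boundaries to the pixel grid; thickness
  error is bounded by ~2 px worth of um, which is why the default pixel
  size is 2 um/px.
* The glucosamine arm's per-compartment OARSI split (beyond MF) and all
  serum group means are design choices, not recovery targets.
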