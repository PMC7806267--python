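# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind the package, in the order of the processing pipeline.

## Track geometry

A pair trajectory holds timestamped 2-D centroids of the two sibling hair
cells, optional mature-cell reference centroids, the neuromast axis (A-P or
D-V), and optional per-cell reporter status.  Frame 0 is defined as the end
of the precursor division; callers trim earlier frames.  Angles are computed
in the imaging plane even when a z coordinate is available, matching the
projected-image workflow such measurements come from.

**Drift correction.**  The per-frame mean of the reference centroids,
relative to frame 0, estimates rigid sample drift and is subtracted from all
points.  This is a translation-only registration (the classical
"poor-man's" approach); rotational stage drift is not modeled and should be
negligible at neuromast field sizes.

**Angle series.**  With u the unit vector from cell *a* to cell *b* at frame
0, θ(t) is the signed (counterclockwise-positive, image y down) angle from u
to the current inter-cell vector, wrapped to (−180°, 180°]; the unwrapped
series accumulates the minimal-magnitude frame-to-frame change.  Swapping
the two cell labels flips both vectors and leaves θ unchanged.  Unwrapping
is valid while per-frame rotation stays below 90°; at 3–6 min sampling and
biological roll speeds this holds with a wide margin, and the constructor
rejects series with ≥180° jumps.  Missing centroids are linearly
interpolated across gaps of at most 2 frames; longer gaps raise an error
rather than silently inventing motion.

## Phase segmentation and classification

The segmentation operationalizes the verbal Rock/Roll criteria:

* **Rock band**: |θ| ≤ 30° (`rock_band_deg`).
* **Roll onset**: the first frame with |θ| above the band where the
  excursion *keeps increasing* — non-decreasing within 5°
  (`monotone_tolerance_deg`) over a 2-frame look-ahead
  (`roll_monotone_window`).  The window and tolerance are design choices
  (the verbal rule names no window); both are exposed in
  `ClassifierConfig`.
* **Roll end**: the frame at which the unwrapped angle reaches a multiple of
  180°, i.e. the inter-cell axis crosses the reference line with the pair in
  the exchanged (or re-returned) configuration.  For pairs that keep
  rotating (roll-back, repeated rolls) the *last* such crossing ends the
  Roll phase, so a roll-back pair's Roll phase includes its return leg.  An
  end rule based on a fixed sub-180° threshold would systematically clip
  recovered Roll durations on sampled ramps; the crossing event is exact.
* **Outcome**: `no_roll` if no onset (a sub-exchange excursion that returns
  into the band counts as rocking); `roll` if the final configuration is
  exchanged — final wrapped angle within 15° of 180°, i.e.
  `exchange_threshold_deg = 165°`, tolerating sampling/noise scatter around
  a half-turn; `roll_back` if at least one exchange completed but the final
  unwrapped angle is within 30° (`return_threshold_deg`) of 0 (mod 360°);
  `incomplete` otherwise (recording ended mid-roll).  Incomplete pairs are
  excluded from frequency tables and reported separately; recordings in the
  emulated studies continued until the process finished, so censoring rules
  are not described there and this is the package's own convention.
* `n_roll_events` counts completed half-turn crossings: 1 for a plain roll,
  2 for a roll-back, 3+ for repeated rolls.

Durations are quantized to the sampling interval and reported in minutes:
Rock = time from frame 0 to onset, Roll = onset to end.  Cohort summaries
compute duration means/SEM only over pairs whose Roll onset occurred, and
percentages are rounded half-up to integers, matching the display convention
of the summaries they mirror.

## Synthetic trajectory generator

The generator *defines* the study conditions the classifier is tested
against.  Two cells start diametrically opposed (8 px apart) about the
division midpoint.  The scheduled angle is:

* **Rock**: a sinusoid with amplitude < 30° (default 20°) and 12 min period.
  The waveform is a modeling choice — only the amplitude bound matters for
  ground truth.
* **Roll**: a linear ramp that leaves the rock band exactly at the scheduled
  onset frame and reaches 180° × (number of half-turns) exactly at the
  scheduled end frame.  Roll outcomes use an odd number of half-turns,
  roll-backs an even number (default 2: exchange, then return through
  360°); `n_extra_rolls` adds half-turns for vangl2-style repeated rolls.
  An alternative `partial_rollback` mode (excursion past the exchange point
  and back without a full 360° turn) is available behind a flag.
* **Noise**: i.i.d. Gaussian angle noise per frame (frame 0 noise-free since
  it defines the reference axis).  Optional random-walk translational drift
  can be added together with stationary reference cells to exercise drift
  correction.

Durations are drawn log-normally with the preset means and σ_log = 0.25
(only means ± SEM are reported in the literature; a log-normal keeps draws
positive with realistic right skew).  Cohort presets: WT — Roll/No-Roll/
Roll-back probabilities (0.57, 0.40, 0.03), Rock 90 min, Roll 75 min; LOF —
(0.59, 0.24, 0.17), Rock 67 min; GOF — (0.32, 0.68, 0), prolonged Roll
(105 min: reported only as "significantly longer", the value is this
package's choice); vangl2 — Roll frequency 0.33, prolonged Roll (120 min)
with two extra half-turns, built from the published positional summary
counts and the multi-roll example.  Class labels are multinomial; the
reporter-positive cell is placed so that it normally ends anterior/dorsal,
with an optional mislocation probability.

What the generator does *not* emulate: cell-shape changes, contact-mediated
mechanics, variable frame intervals within a recording, track fragmentation,
and mitotic pre-division frames.  Passing recovery tests therefore shows the
segmentation rules are implemented correctly and are robust to angular
noise — not that they are robust to every real imaging artifact.

## Protrusion quantification

Per frame: MIP over a chosen inclusive z-range → rolling-ball background
subtraction → Gaussian blur → 8-bit conversion → wand-style ROI → measure.

* **Rolling ball**: by default a grayscale opening with a disk structuring
  element (radius 50 px by default; tests and the synthetic geometry use
  15 px); the exact paraboloid variant (`skimage.restoration.rolling_ball`)
  is selectable via `ball_method="paraboloid"`.
* **8-bit anchor**: the min/max of *frame 0* scales the whole series.
  Anchoring per-frame would normalize away exactly the temporal intensity
  increase the analysis is meant to show.  A consequence: later frames can
  saturate at 255; mean-intensity comparisons remain valid as long as frame
  0 contains the brightest structure class of interest.
* **ROI**: the 8-connected component of pixels ≥ threshold containing the
  brightest pixel of a seed rectangle (the wand-tool analogue).  Empty mask
  if that pixel is below threshold.
* **Length**: image y increases downward and the apical surface is at
  smaller y.  The baseline is `min(nucleus_y − nucleus_radius)` over the two
  nuclei; the tip is the mask pixel with smallest y (ties toward smaller x);
  length = max(0, baseline − tip).  Nuclei centroids/radii are inputs, not
  auto-detected.

The synthetic stack renders the two nascent cells as 3-D Gaussian blobs, the
mature-cell apical signal as a thin bright band at the apical surface, and
the protrusion as a bright cylinder growing from the apex of the first cell
toward the apical band, plus Gaussian or Poisson noise.  The protrusion
grows along −y so that its length is measurable in the z-MIP; target lengths
beyond the apex-to-surface distance are rejected.  Ground truth records the
noise-free length and mean cylinder intensity per frame.

## Statistics

* **Pearson X²**: Σ(O−E)²/E with margin expectations, df = (r−1)(c−1), upper
  chi-squared tail.  *No Yates continuity correction anywhere*: the
  published 2×2 statistic 6.1774 on counts (30, 23; 20, 40) is reproduced
  exactly by the uncorrected statistic, confirming that convention.  Tables
  with a zero margin are rejected with advice to collapse categories.
* **Post-hoc pairwise X²** over group pairs along one axis, dropping
  within-pair all-zero categories; "FDR correction" is implemented as
  Benjamini–Hochberg (the procedure is not named in the source convention;
  BH is the standard reading).
* **Count reconstruction**: the integer composition of n minimizing the
  maximum deviation of 100·count/n from the printed percentages, constrained
  to round back to every printed value at its printed precision; ties break
  by largest remainder with a warning listing alternatives.  The
  reconstruction round-trips exactly on all 3-part compositions of n ≤ 100.
* **t-tests**: Student (pooled) and Welch via scipy; the degenerate
  zero-variance case returns statistic 0/p 1 for equal means and an
  infinite-statistic, p→0 contract otherwise, flagged in the result.
* **ANOVA/Wilks**: per-response one-way F with (k−1, N−k) df; Wilks'
  Λ = det(W)/det(W+B) with Rao's F approximation.  For a single response the
  exact identity F = ((1−Λ)/Λ)·(N−k)/(k−1) holds and is tested.  Dunnett's
  many-to-one test is provided only as a Bonferroni-adjusted pooled t
  approximation, explicitly labeled as such; exact Dunnett critical values
  are out of scope.

## QC filter

A cell passes iff n_unique_genes ∈ [400, 2500], n_UMI ≤ 10,000 and
mitochondrial fraction ≤ 5%.  All four rules are strict on the excluded side
("less than 400", "more than 2500", "more than 10,000", "more than 5%"), so
the boundary values 400, 2500, 10,000 and 5.0% pass.  Thresholds are
overridable; genes detected in fewer than 3 cells are flagged for removal.
Normalization, clustering and pseudotime are intentionally out of scope —
they are routine and depend on real data this package does not ship.

## Problem sizes and numerical notes

Acceptance-style checks run at 1,000 pairs per preset for classifier
recovery, 1,000 random series/tables for oracle equivalence, 10,000
replicates for type-I calibration, and 10–12-frame 12×96×64 stacks for
protrusion recovery — sizes chosen so the whole suite completes in well
under a minute while keeping Monte-Carlo error far below the asserted
tolerances.  Half-turn crossings are detected with a 10⁻⁹-degree slack so
exact-180° frames count; percentage display uses round-half-up; all
generators are deterministic given their seed, and cohort generation spawns
per-pair child seeds below 2³¹.

## Known limitations

* The classifier assumes a single connected recording beginning at the end
  of division; it does not detect the division itself.
* Exchange detection is angular only; it does not use cell-contact geometry
  beyond the centroid axis.
* The drift model is translational; rotating samples would need a rigid or
  affine registration upstream.
* The Dunnett approximation is conservative; use it for screening, not for
  reporting exact adjusted p-values.
* Synthetic cohorts quantize durations to the frame interval, so recovered
  duration means inherit up to half a frame of quantization bias relative to
  the continuous preset means.
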