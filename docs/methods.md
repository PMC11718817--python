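# Methods

This note records the models, conventions and numerical choices behind
`spherotrack`, in the spirit of a methods appendix: what each component
assumes, which knobs matter, and what the synthetic data can and cannot
tell you about real experiments.

## Data model and formats

Tracks are gap-free, uniformly sampled sequences of 3D positions in
physical µm, with time in decimal minutes and `frame_index` as the
authoritative ordering key.  Tracks with gaps are rejected at
validation rather than interpolated: arrest statistics are run-length
quantities, and silent interpolation would manufacture or destroy
below-threshold runs.  The native table is plain CSV written with
shortest round-trip float precision and read back with `round_trip`
parsing, so write → read is lossless and output bundles are byte-stable
for diffing.  The `imaris_position_export` dialect maps the
conventional position-export columns (`Position X/Y/Z`, `Unit`, `Time`
as a 1-based frame number, `TrackID`) onto the native schema; `mm` is
converted to µm (×1000).  Since that layout carries neither timestamps
nor condition labels, the reader takes a frame interval and label
arguments — a documented assumption, as vendors vary.

Spheroid surfaces are either analytic spheres (center, radius) or
closed triangle meshes in an OFF-style block format.  Watertightness
(every edge shared by exactly two faces) is enforced on read, and the
error reports the number of offending edges.

## Synthetic coculture generator

The generator emulates a 30-min video of a three-cell-type spheroid
coculture.  Defaults: 61 frames at Δt = 0.5 min, a 150 µm spheroid, and
300 tumor : 40 macrophage : 600 CTL agents — the experimental seeding
ratio 60,000 : 8,000 : 120,000 scaled down 200× for desk-scale runtime
(all counts configurable).  The acquisition frame rate of such
experiments is instrument-specific; 0.5 min resolves the 2 µm/min
arrest threshold comfortably (an arrested cell must move < 1 µm per
frame to sit below it).

**Motility.**  Each motile cell takes steps of length *s·Δt* with *s*
drawn per step from a log-normal with configured mean and CV, in a
direction obtained by a von Mises–Fisher perturbation of its previous
direction with concentration κ (isotropic at κ = 0, ballistic as
κ → ∞).  This is the minimal persistent-random-walk family whose
straightness can be tuned continuously between 0 and 1.

**Arrest.**  Independently of stepping, each cell carries a two-state
motile/arrested Markov chain with per-frame switching probabilities
1 − exp(−rate·Δt).  While arrested the cell holds the anchor position it
arrested at, plus isotropic Gaussian jitter (SD 0.15 µm per axis); the
config validator rejects jitter large enough that arrested frames would
exceed the 2 µm/min threshold with probability > 1%, so simulated
arrests are detectable by construction.  A two-state chain is the
simplest generative model producing the alternating high/low
instantaneous-velocity pattern seen in real CTL tracks, and it has a
closed-form stationary occupancy for parameter-recovery tests.  Note a
discretization subtlety: the per-frame chain's exact stationary
arrested fraction is p_on/(p_on + p_off) with p = 1 − exp(−k·Δt), which
converges to the continuous-time ratio k_on/(k_on + k_off) as Δt → 0
but sits measurably above it at Δt = 0.5 (0.320 vs 0.300 for
k_on = 0.3, k_off = 0.7 min⁻¹).  `MotilityParams.
discrete_stationary_arrest_fraction` exposes the exact value; initial
states are drawn from it so occupancy is unbiased from frame 0, and
recovery tests target the exact form.

**Interactions.**  Within `contact_radius` (12 µm, roughly one cell
diameter) of a live tumor cell, a cell's arrest-on rate is multiplied
by `contact_arrest_multiplier` — antigen contact promotes arrest.  A
CTL arrested in tumor contact kills its nearest target with probability
`kill_prob_per_arrest_min`·Δt per frame; killed tumor cells freeze and
carry a raised apoptosis flag for the remaining frames (mirroring the
accumulation of a caspase-3/7 dye), and each kill shrinks spheroid
volume by a fixed fraction.  This couples apoptosis to CTL proximity by
construction, which is what the apoptosis-proximity statistic must
detect.

**Initialization.**  Tumor cells are uniform in a slightly shrunken
ball (0.92 R) and jitter weakly; CTLs start inside with probability
`ctl_inside_fraction` (uniform in the ball) and otherwise in a shell
just outside the surface (1.05–1.35 R), with an inward drift
(`infiltration_bias`) applied to peripheral cells during the video.
The frame-0 inside fraction is an explicit parameter rather than the
outcome of a hidden burn-in walk: it makes the infiltration readout of
a condition a directly stated, auditable quantity.

**Reproducibility.**  One root seed; every cell draws from a substream
keyed by (seed, cell-type, index), so enlarging one population never
changes the random draws of existing cells; kill decisions use a
separate interaction stream.  Identical config ⇒ bit-identical output.

**Shipped conditions.**  `default_scenario(timepoint, genotype,
treatment)` encodes the study's condition grid.  The wild-type /
untreated-macrophage / early anchor was calibrated once: CTL κ = 7 and
mean speed 4.5 µm/min put cohort straightness at ≈ 0.47 (the observed
band is 0.4–0.5), and inside fractions 0.253 (early) and 0.3022 (late)
reproduce the reported infiltration percentages.  Condition effects are
encoded as qualitative orderings: IL-18R-deficient CTLs are 15% faster
with 45% higher arrest-on rate than WT; LPS/nigericin-activated
macrophages raise CTL speed 20% and cut the arrest-on rate by ~28%;
late scenarios have 50% higher arrest-on rates and a higher kill
probability.  These magnitudes are plausible placements within the
reported orderings, not fitted mechanistic parameters.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no imaging noise, segmentation or linking
errors, no track gaps or varying track lengths, no cell division,
crowding or volume exclusion, spheroids are perfect spheres, and no
chemokine fields or signaling mechanisms (condition labels select
parameter sets; they do not model NLRP3 biology).  Tests passing on
synthetic data validate the estimators, not the biology.

## Analysis conventions

- **Boundary**: signed distance ≤ 0 is infiltrating; a cell exactly on
  the surface counts as inside.  Track-level compartment is the
  majority of frame labels, ties → infiltrating — stable against
  single-frame noise.  Counts and percentages default to the first
  frame of a video (one value per video), overridable.
- **Mesh geometry**: unsigned distance is the exact point-to-triangle
  minimum over candidate faces pruned by a KD-tree on face centroids
  (64 candidates); containment is by generalized winding number
  (Van Oosterom–Strackee solid angles, threshold 2π), robust for
  watertight meshes.  Volume is the divergence-theorem tetrahedron sum.
  Surface-frame lookup matches track times within half a frame
  interval (spots and surfaces share the acquisition clock).
- **Drift correction**: per-frame rigid translation estimated as the
  componentwise median of tumor-cell frame-to-frame displacements
  (surface-centroid displacement as fallback), accumulated and
  subtracted from all spots and surfaces; frame 0 unchanged.  The
  median is shift-equivariant, so the correction exactly inverts any
  added rigid drift; it is off by default for simulated input (which
  has none) and selectable for external data.
- **Velocities** use forward differences, matching per-step tracking
  exports and keeping the arrest mask aligned with frame pairs;
  average speed = track length / track duration, which equals the mean
  instantaneous velocity under uniform sampling.  Straightness of a
  zero-length track is undefined (NaN) and excluded from cohort means
  with an exclusion count.
- **Arrest** uses strict inequality (v < threshold): a sample exactly
  at 2 µm/min is motile.  Minimum arrest run is one velocity sample —
  no minimum-duration filter.  Arrest durations are maximal-run
  lengths, so they sum exactly to coefficient × observed duration.
- **Density curves**: Gaussian KDE with Silverman bandwidth, reflected
  at 0 and 1 including second-order images (shifts ±2), evaluated on a
  512-point grid of [0, 1]; the estimate integrates to 1 on the unit
  interval because arrest coefficients cannot leave it.  All-identical
  samples degenerate Silverman's rule and raise an error suggesting an
  explicit bandwidth.
- **Fragments**: connected components of the tumor-cell position graph
  under single linkage; default linking radius is 2× the mean
  nearest-neighbor distance of the initial frame (reused for the final
  frame so both counts share one scale), components under 5 cells are
  debris.  Operating on positions rather than voxel masks keeps the
  whole layer image-free.
- **Proximity** is centroid-to-centroid distance to the nearest CTL; a
  hook exists to subtract a fixed cell radius where surface-to-spot
  distance is wanted.
- **Statistics**: Grubbs is single-pass (at most one removal),
  two-sided, with the t-quantile critical value at α/(2n); zero
  variance yields a flagged no-outlier result.  The two-group test
  always reports Welch (Welch–Satterthwaite df) — the conservative
  resolution of "use Welch if variances differ"; constant samples are
  handled as exact null/certain results.  Multi-group comparisons use
  ordinary one-way ANOVA with Tukey HSD adjusted p-values from the
  studentized-range distribution.  Bar-graph statistics run on
  per-video replicate means; density and duration displays pool all
  tracks within a condition.
- **Report bundles** are deterministic in row and column order, carry a
  manifest with version, seed, parameters and a config hash, and are
  byte-identical for identical config + seed.

## Problem sizes

Validation suites run at sizes chosen to give tight statistical power
on a desktop: occupancy and arrest-coefficient recovery use 500 tracks
× 120 steps (SE of the mean occupancy ≈ 0.003); infiltration
calibration averages 20 replicate videos per timepoint at full default
counts; the ANOVA null calibration uses 10,000 simulated triples of
n = 10.  The acceptance script uses a 200-track cohort for straightness
and the same 20-replicate design for infiltration.

## Known limitations

Mesh-distance pruning assumes reasonably uniform triangle sizes (true
of tracking-software surface exports); extremely anisotropic meshes
could in principle select a suboptimal candidate face.  The generator's
condition effects are ordinal placements, not inferred dynamics, so
cross-condition effect sizes in synthetic reports should not be read
quantitatively.  Fragment counting on sparse point clouds is sensitive
to the linking radius near the percolation point; the default
2× nearest-neighbor scale is a heuristic and should be fixed explicitly
when comparing across experiments.
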