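# Methods

`orgcompete` quantifies cell competition between two labelled cell
populations — wild-type liver (cholangiocyte-derived) cells and
intestinal cancer cells — in 3D confocal images of mixed organoids and
microtissues.  This note documents the models and procedures the
package implements, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Pipeline model

The analysis treats each organoid as a field of 3D nuclei carrying
per-channel marker content.  Processing follows three stages:

1. **Kernel-size estimation.**  The kernel radius is the minimal radius
   of the objects of interest (nuclei), estimated from the data itself:
   each confocal slice is roughly thresholded at its mean plus standard
   deviation, median-filtered with a kernel equal to the pixel
   resolution, and the 2D Euclidean distance transform (EDT) is
   computed.  Slices are ranked by optical density — implemented as the
   sum of raw intensities, the simplest monotone proxy for biological
   content — and the kernel radius is the mean of the EDT maxima of the
   top 5% of slices.  For time-lapse data the per-frame radii are
   averaged ("harmonized") into a single value.

2. **Per-channel processing** (all slice-wise, disk/square structuring
   elements in XY; 3D assembly happens at segmentation):
   - *Adapted top-hat*: the background is a copy of the slice after a
     Gaussian blur (sigma = kernel radius) followed by minimum and
     maximum filters of size `2r + 1` px (default) or `r` px for the
     H2B variant; it is subtracted and negatives are clipped.  Any
     constant image maps to zero.
   - *Foreground threshold*: the cutoff is the mean intensity of the
     pixels lying below the slice mean (a background-level estimate);
     foreground is strictly above it.  Masks are additionally gated to
     the rough mean + sd foreground of the raw slice — the same
     statistic the kernel step uses — which keeps noise fluctuations in
     object-free planes out of the masks while leaving noiseless
     outputs unchanged.
   - *Two-round watershed*: touching nuclei are split by a
     distance-transform watershed, the binarised result is
     median-filtered (kernel = pixel resolution), and a second
     watershed round partitions the cleaned foreground.  Watershed
     seeds are regional EDT maxima; near-coincident plateau maxima are
     merged by transitive clustering within the kernel radius.
   - Channel pipelines compose these: DAPI (top-hat, half-radius
     median, threshold, debris removal below `(r/2)²` px, two-round
     watershed, multiply by raw to preserve intensities); mTmG/Dendra2
     (blur + max/min filters, Dendra2 subtracted from mTmG to suppress
     bleed-through, threshold each); H2B (minimum filter, undoubled
     top-hat, half-radius median, bright-outlier removal, threshold);
     EdU (top-hat, pooled Li threshold, binary opening); pH3
     (grayscale opening, subtraction of the mean of above-mean
     intensities, pooled Li threshold); SOX9 (top-hat, median,
     outlier removal; intensities kept for the relative-level
     classifier).

3. **3D detection and phenotyping.**  Nuclei are 3D connected objects
   obtained by a seeded watershed on the Gaussian-smoothed physical EDT
   of the DAPI foreground.  Seed spacing is expressed in micrometres so
   that anisotropic sampling (2.5–5 µm optical sections vs sub-µm XY
   pixels) is handled uniformly; objects smaller than one third of the
   nominal kernel-sphere volume are discarded as debris; border-touching
   objects are kept but flagged.  Shape comes from the second-moment
   eigen-decomposition of the voxel cloud scaled as a uniform solid
   ellipsoid (`a = sqrt(5·lambda)`), giving semi-axes `a >= b >= c` and
   elongation `a/c`.

## Classification

- **Alpha.**  For each marker, `alpha = marker volume / nuclear volume`
  computed as an exact voxel-count ratio.  Positivity thresholds are
  0.1 for the membrane and pulse markers (mTmG, EdU, pH3) and 0.25 for
  the H2B nuclear label.  The comparison is inclusive (`>=`): boundary
  behaviour is unstated in the source description and inclusivity makes
  the printed thresholds themselves attainable.
- **SOX9.**  Mean nuclear intensities are normalised per experiment by
  that experiment's maximum (making classes invariant to
  per-experiment multiplicative scaling), pooled across experiments,
  and cut at the 25th/75th percentiles (linear interpolation, strict
  inequalities): low < P25, high > P75, mid otherwise.  An all-equal
  pool degenerates to all-mid with a warning.
- **FUCCI2.**  hCDT1-mCherry and hGeminin-mVenus mean intensities map
  through a 2×2 truth table: mCherry+/mVenus− is G1, mCherry−/mVenus+
  is S-G2-M, and the double negative is the G0-like arrested state.
  The double positive (G1/S transition) is reported as its own class
  rather than folded into S-G2-M, so the three reported fractions stay
  faithful to their definitions.  Default cutoffs are data-derived:
  Otsu on each channel's pooled per-nucleus means, refined by the
  Ridler–Calvard intermeans iteration so the cutoff settles mid-way
  between the intensity groups instead of at a histogram-bin edge;
  explicit cutoffs in the configuration override this.
- **EdU/pH3.**  EdU+ only is S phase, EdU+/pH3+ progressed from S into
  mitosis within the labelling window, pH3+ only is mitosis, and the
  double negative is the arrest candidate.

## Competition metrics

Per organoid and frame: class counts and fractions (fractions × total
reproduce counts exactly before display rounding); expansion ratio =
count at time t over count at the first analysed frame; doubling time
from an ordinary least-squares fit of log2(count) against time (the
two-point case reduces to `dt / log2(ratio)`); inter-nuclear distance
as the mean Euclidean distance (µm) to the five nearest same-population
neighbours, averaged over nuclei (k reduces to n−1 with a warning for
tiny populations); simple linear regression (OLS via
`scipy.stats.linregress`) with R² and the slope's two-sided p-value;
expected seeding fraction `100·a/(a+b)`; per-population microtissue
volumes as voxel counts × voxel volume; and Cleaved-Caspase3 counts in
three 250 × 250 × 50 µm (X/Y/Z) crops placed at seeded random positions
— a reproducible surrogate for blinded manual placement — counting
positive, wild-type, non-border-flagged nuclei (border exclusion is the
reproducible surrogate for "excluding debris and extruded cells").

## Synthetic data generator

The generator produces ground-truthed multi-channel stacks emulating
the statistical structure the analysis assumes.

**Geometry.**  Nuclei are ellipsoids (semi-axes drawn per nucleus,
default 4 ± 0.5 µm) placed by rejection sampling at pairwise physical
distances ≥ `min_separation_um` (default 9 µm) on an ellipsoidal shell
(organoids are hollow epithelial monolayers), in a solid mass, or — for
microtissues — as contiguous cancer patches surrounded by wild-type
tissue (nearest-seed assignment around randomly chosen patch centres).
Packing gives up after a bounded retry budget with an error naming the
attempted density.  Coordinates live in micrometres; voxel anisotropy
enters only at rasterisation.

**Growth.**  Between frames `dt` apart, each cycling nucleus divides
with probability `2^(dt/Td) − 1`, so the expected fold expansion at
time t is exactly `2^(t/Td)` regardless of the frame interval (a
first-order hazard discretisation would bias 60 h growth ~9% low at
2 h intervals).  Default doubling times: 24 h for pure wild-type
cells, 17.8 h for cancer cells; the mixed-competition preset slows
wild-type growth to 33 h and speeds cancer to 15 h.  A deterministic
mode divides every cell exactly once per doubling time for closed-form
tests.  Apoptosis removes nuclei at a per-hour rate; daughters inherit
the mother's shape and are offset by ~0.7 nuclear radii.

**Arrest and competition coupling.**  Daughter (and initial) wild-type
nuclei arrest into G0 with probability `arrest_prob_wt`.  In the mixed
preset, competition coupling scales that probability by the organoid's
current cancer fraction (base 0.6, so ~0.27 per division at 45%
cancer, consistent with roughly a third of competing wild-type cells
ending up double-negative for the proliferation markers).  This
coupling is what makes wild-type expansion depend on initial
composition — organoids seeded with more cancer arrest more wild-type
cells — reproducing the direction of the observed
expansion-vs-initial-percentage correlation.  Uncoupled arrest remains
the default so that `arrest_prob_wt = 1` freezes counts exactly.

**Phases.**  Cycle position advances linearly with age; fixed phase
fractions G1 0.5, S 0.3, G2 0.15, M 0.05 of the cycle (only the labels
matter downstream).  FUCCI rendering keeps mCherry on for a short
window into S (3% of the cycle) so the double-positive branch of the
classifier is exercisable.  SOX9 levels are high (0.6–1.0 relative)
for cycling cells and low (0.05–0.3) for arrested/differentiated ones.

**Rendering.**  Nuclear channels rasterise filled ellipsoids at the
nucleus's true mean level; membrane channels (mTmG, Dendra2) rasterise
shells spanning 0.85–1.25 of the nuclear ellipsoid, straddling the
nuclear boundary as blurred cortical signal does in real images (and
covering ~39% of the nuclear volume, which is what makes the 0.1
membrane alpha threshold meaningful).  Background is constant plus an
optional linear ramp; noise is additive Gaussian with optional Poisson
resampling; intensities are clipped to the declared bit depth (12-bit
default in 16-bit containers).  Compaction is imposed geometrically:
wild-type coordinates are scaled about their centroid, so every
pairwise distance — and hence any k-NN statistic — scales by exactly
the factor.  One top-level seed; per-frame and per-channel generators
are derived deterministically from it, so equal seeds give bit-identical
outputs regardless of call order.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: optical point-spread, refractive
aberration and depth attenuation (renders are hard-edged; the
morphological erosion of the channel pipelines is therefore *worst
case* here), photobleaching, drift, mechanical force-driven compaction
(imposed geometrically instead), nucleus tracking identity across
frames, and cell shapes beyond axis-aligned ellipsoids.  Real mixing by
clump volume at seeding is exposed only as a fraction by nucleus count.

## Numerical choices

- Filter footprints are odd-sized and centred; the DAPI post-top-hat
  median is sized at half the kernel radius (a radius-sized median
  erodes small nuclear cross-sections and contradicts its
  shape-preserving purpose).
- Li threshold: unshifted fixed-point iteration
  `t ← (mu_f − mu_b)/(ln mu_f − ln mu_b)` on pooled intensities,
  initialised at the global mean, tolerance 0.5 intensity units.  The
  cross-entropy objective is flat between well-separated modes, so
  different conventions settle at different points in the gap while
  producing identical masks.
- Strict `>` for every foreground threshold; inclusive `>=` only for
  the alpha positivity calls.
- Degenerate inputs: empty stacks detect zero nuclei (not an error);
  all-equal slices yield empty masks; voxel clouds under 4 voxels are
  flagged degenerate with NaN shape; zero initial counts flag the
  expansion ratio NaN; non-growing series give an infinite doubling
  time with a warning.
- Problem sizes: property suites run 50-seed branching checks at 200
  initial nuclei, end-to-end recovery on 250-nucleus noiseless stacks,
  and the directional competition experiment on 48 organoids of 100
  nuclei at 5 h intervals — large enough that the stochastic assertions
  hold with wide margins, small enough to keep the suite fast on one
  CPU.

## Known limitations

Equivalence with the original learning-based nucleus detector is
asserted only at the measurement interface (counts, centroids,
dimensions, marker volumes) on synthetic ground truth, not at the
algorithm level.  The per-slice threshold sentence in the source
description is ambiguous; the reading implemented here is documented
above and all derived behaviour is pinned by tests.  Segmentation
accuracy under strong noise relies on the rough-foreground gate;
extremely low-contrast markers (foreground within ~1 sd of background)
will under-segment.  Fractions of small populations are granular; the
k-NN distance is a proxy that saturates for populations of six or
fewer nuclei.
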