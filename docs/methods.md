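# Methods

This note records the models, conventions, parameter choices and known
limitations behind the package, in the order the pipeline runs.

## Conventions

All image coordinates are (row, col), 0-based, in pixels. Physical
distances are converted through a per-modality pixel size in µm
(`PipelineParams.pixel_size_um`). Label images use 0 for background and
positive integers for objects.

## Barcode library

The library maps guide ids to gene symbols and 20-nt spacers. Because the
amplified barcode is read in the reverse orientation, the dictionary used
for matching is built from **reverse complements** of the spacers (the
"detect sequences"). Entries with non-ACGT spacers are dropped with a
warning; duplicate spacers are kept but flagged — any read hitting a
flagged group is scored ambiguous, implementing the no-ambiguities rule
without silently discarding library content.

The scrambled-dictionary control permutes each detect sequence's own
characters with a seeded RNG, preserving per-sequence base composition
(the stricter of the two possible readings of an equal-base-composition
scramble; a library-wide permutation is available as an option). Mapping
rates against the scrambled dictionary estimate the chance-mapping floor.

## Registration

Cycles are aligned translation-only: same microscope, fixed sample, so
rotation/scale changes between cycles are not modeled, and non-rigid
tissue deformation is acknowledged but out of scope (the low-pass calling
variant exists for that regime). Shifts are integer pixels: spot
intensities are aggregated over a 5×5 window downstream, which absorbs
sub-pixel residuals; an upsampled refinement would add cost without
changing calls. The shift is found as the argmax of the FFT-computed
normalized cross-correlation of mean-subtracted nuclear images within
|shift| ≤ `max_shift` (default ±50 px; the true drift range is
instrument-dependent and configurable). A peak on the search boundary, or
below a correlation floor (default 0.3), raises an error rather than
returning an untrustworthy shift. Out-of-frame pixels after correction
are zero-filled; spots whose aggregation window touches the fill are
edge-flagged.

Convention: `register_translation(ref, mov)` returns the drift (dy, dx)
of `mov` relative to `ref` (i.e. `mov ≈ roll(ref, (dy, dx))`); the
applied correction is a translation by (−dy, −dx). This makes the
function antisymmetric under argument exchange.

## Spot detection and profiles

The detection image is the sum of all three sequencing channels over the
first `n_detection_cycles` (3) cycles — with a dark G the probability
that a real spot is bright in none of the first three cycles is 4⁻³ ≈
1.6%, which bounds the detection miss rate on clean data. The high-pass
filter is an unsharp mask (image minus Gaussian blur, σ = 4 px by
default) with negatives clipped. The detection threshold is
max(absolute floor, median + k·MAD) of the *signed* high-pass difference
(the clipped image has a zero-inflated background that collapses the
MAD); k defaults to 8, and the absolute floor (default 50 counts) guards
noiseless synthetic data where the MAD vanishes. Local maxima are strict
8-neighborhood maxima; equal-valued plateaus that dominate their border
keep the first pixel in scan order, making detection deterministic.

Per spot, each cycle/channel image is high-pass filtered, negatives
zeroed, and summed over the 5×5 window centered on the spot.

## Crosstalk estimation and base calling

The crosstalk matrix (rows = channels, columns = the three bright bases
in channel order) is self-calibrated: observations are provisionally
classified dark by the 20% rule on raw profiles, bright observations are
assigned to their argmax channel, the per-base mean channel vectors are
column-normalized (max = 1), and the classify→average step is iterated
once with unmixed calls. Each provisional base class must have ≥ 30
observations; fewer is an error, since a library without base diversity
cannot calibrate the matrix. A fixed matrix can be supplied instead. The
default channel→base mapping is A = channel 1 (477 nm), C = channel 2
(546 nm), T = channel 3 (638 nm), G dark; it is configurable because the
mapping is chemistry-dependent.

Unmixing multiplies each cycle's channel vector by the matrix inverse
(condition number checked, default bound 10³), preserving negatives;
calling then applies: G where all three unmixed values fall below 20% of
the spot's maximum unmixed intensity across all cycles, otherwise the
argmax channel; an exact top-two tie gives N; a spot with no positive
signal is all-N. N counts as a mismatch downstream. Phasing (one-cycle
signal lag) is simulated as a stress factor but not corrected in the
caller.

## Dictionary matching

Reads (length = number of sequencing cycles used) are matched against
detect-sequence prefixes with at most one mismatch and no ambiguities. An
exact hit takes priority over distance-1 hits; two or more hits within
the same distance tier are ambiguous. Lookup enumerates the 3·L
single-substitution variants against a hash of prefixes (O(L) per query);
tests verify exact agreement with an exhaustive Hamming scan. Prefix
collisions at the chosen read length form intrinsically ambiguous groups.

## Nucleus assignment

Each library-matched spot contributes its intensity to its guide inside
the nucleus containing its center pixel (a spot on a label boundary
belongs to the label under its center). The intensity functional is the
sum of positive unmixed entries across cycles and channels — it reuses
the already-computed profile and is scale-consistent with the dominance
ratio; alternatives (max entry, detection-image sum) are configurable in
principle but not defaults. Ambiguous-status spots count toward the
denominator but never toward a guide: they are evidence against dominance
purity. A nucleus is assigned when the top guide exceeds the dominance
fraction (2/3) of total library-spot intensity *and* the maximum
single-channel, single-cycle spot intensity passes the numeric gate
(7×10⁵ counts; 2×10⁵ preset for low-signal cell types). Multi-integration
nuclei fail dominance and are rejected, not deconvolved.

## Modality linking

Candidate phenotype/sequencing FOV pairs come from stage positions
(within one field width). The phenotype image is resampled onto the
sequencing pixel grid by the magnification ratio, correlated at
8×8-downsampled resolution to rank candidates, and the best pair is
refined at 2×2; a pair is accepted above a normalized correlation of 0.2
(the selection cutoff is not instrument-specified; it is logged).
Nucleus matching transforms phenotype centroids into the sequencing
frame; each takes its nearest sequencing centroid, accepted at ≤ 11.1 µm
movement and a two-fold area margin after scale² correction. Ambiguity is
quantified as: duplicate claims on one sequencing nucleus exclude all
claimants, and a second candidate inside the distance gate at less than
1.2× the nearest distance excludes the phenotype nucleus. Both knobs are
configurable; the published rule states only that ambiguous mappings were
excluded. Nuclear-stain-derived labels (adherent cells) and
membrane-derived cell labels shrunk by 5 px (suspension-derived cells,
z-aggregated) feed the same operation.

## Phenotyping

z-stacks are collapsed by averaging. Translocation is the Pearson
correlation between nuclear stain and reporter over each cell's pixels,
computed on raw channels (matching the processing order of the source
protocol); cells need ≥ 10 pixels and non-zero variance. Specking first
subtracts a local background: the image is 8×8 block-mean downsampled,
and each full-resolution pixel subtracts the minimum over the 9×9
downsampled neighborhood of its block, clamping at zero; the score is
the ratio of per-cell mean high-pass-filtered (σ = 2 px, negatives
zeroed) to overall reporter signal. Cells below the 5th percentile of
mean reporter intensity per run are flagged as low-expression — the
exclusion is published but its cutoff is not, so a percentile stand-in is
used and recorded.

## Screen statistics

Cells are pooled per targeted gene (not per guide) and compared to the
pooled non-targeting cells: two-sided Wilcoxon–Mann–Whitney (exact
enumeration for tie-free pooled n ≤ 12, otherwise normal approximation
with tie and continuity corrections — delegated to scipy and checked
against brute-force enumeration in tests), Benjamini–Hochberg step-up
across all tested genes (statsmodels, checked against the hand-computed
step-up), and a log2 fold change of means. Genes need ≥ 10 cells to be
tested. Metrics that can be negative (a Pearson correlation) are shifted
by +1 before the fold change — the transform is recorded and the
rank-based test is unaffected. Coverage saturation is measured by
subsampling k cells per gene without replacement and recording the
fraction of known hits at FDR < 0.05 with |log2 fc| > 1, averaged over
replicates.

## Synthetic scenes

The simulator renders what the calling model assumes: Gaussian-blob
nuclei (non-overlapping by rejection sampling), one amplification spot
per barcoded nucleus (two for multi-integration nuclei) whose cycle-c
channel vector is crosstalk × base indicator × amplitude with dark G,
optional one-cycle phasing, per-cycle stage drift, constant background
and white Gaussian noise. Defaults (512² px at 0.65 µm/px, ~120 nuclei of
4.5 µm radius, spot amplitude 2×10⁵ counts so that clean spots clear the
7×10⁵ aggregated-intensity gate, 6 cycles) describe one clean field of an
adherent-cell screen. Phenotype scenes plant gene-dependent nuclear
fractions (translocation) or Bernoulli puncta (specking) on the same
nuclei with configurable jitter. The metric-level generator
(`simulate_screen_metrics`) draws per-cell speck-ratio-like values from a
Gamma(4, 0.05) with multiplicative per-gene mean shifts, for statistics
studies where rendering images would add nothing.

What the simulator does **not** model: chromatin texture, non-Gaussian
PSFs, illumination fields, camera-specific noise, cell crowding/overlap,
segmentation errors of learned models, or tissue deformation. Passing
tests on these scenes therefore demonstrate correctness of the
*computational* chain under its stated model, not robustness to every
real-data artifact.

## Benchmark operating points

The benchmark suite (`nisseq.benchmarks`, driven by
`scripts/acceptance.py` and the end-to-end tests) uses problem sizes
chosen to give tight statistics at interactive runtimes on one CPU:
~1,000 spots across rendered fields for base calling, 600 profile-level
spots for crosstalk recovery, 10⁴ queries vs a 10³-member library for the
matching oracle, ten planted drifts up to ±20 px for registration, six
fields of 200 nuclei (30% unbarcoded) for end-to-end genotyping and the
scrambled-dictionary control, 200 nuclei at ≤ 5 µm jitter for nucleus
matching, and 200-gene screens at 100 cells/gene for calibration and
power. One property of the toy library scale is worth knowing: a guide
whose detect sequence starts with three dark-G bases is invisible to the
three-cycle detection image, so genotyping recall fluctuates with how
many of the ~50 simulated guides draw such prefixes (expected 1/64 per
guide). At genome scale this lottery averages out to the fixed ≈1.6%
detection floor; at toy scale it is the dominant seed-to-seed variance
in end-to-end recall. The saturation benchmark plants hits at |log2 fc| ≈ 1.3 — past the
|log2 fc| > 1 reporting threshold — because a hit planted exactly at the
threshold turns the reported detection fraction into a coin toss on
estimator sign rather than a measure of statistical power; the
fixed-coverage power benchmark keeps the exact 2× shift with FDR-only
detection.

## Known limitations

- Integer-pixel registration; no non-rigid correction (a low-pass
  calling variant mitigates mild misalignment).
- No phasing correction in the caller; phasing is a simulated stress
  only.
- No probabilistic deconvolution of multi-integration nuclei.
- The classical segmentation backend is exact on blob-like synthetic
  nuclei but is not a replacement for a learned segmenter on real,
  textured images; the backend interface exists precisely so a learned
  model can be plugged in.
- No cell tracking across live-imaging time series, and no 3D phenotype
  metrics (z is averaged).
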