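# Methods

## Study design and time axis

The temporal design is five subjects sampled every 15 minutes across five
contiguous phases: I (probe implantation / baseline, 60 min), II (occlusion
surgery, 60 min), III (ischemia, 120 min, split evenly into early IIIA and
late IIIB), and IV (reperfusion, 60 min).  Collections sit at
t = 0, 15, …, 300 min inclusive, giving 21 collections per subject and 105
samples in total; a collection belongs to the phase whose half-open window
[start, end) contains it, with the closing collection assigned to the last
phase.  Under these defaults exactly four baseline collections precede the
occlusion surgery.  The split of the ischemia block at its midpoint is a
convention; "early/late" carries no sharper boundary, and every function
accepts the fine tokens (IIIA, IIIB), the coarse token III, or unions such
as IIIA+IIIB.

## Synthetic data generator

`strokemap.synth` emulates the statistical structure the analysis assumes,
not the biochemistry.  Sixteen kinetic archetypes (A–P) are realized as
positive piecewise linear/Gaussian-bump templates over the collection grid:
ramp declines confined to phase I, a sharp baseline peak, double peaks
spanning adjacent phases, boundary peaks at the II→III and III→IV
transitions (narrow, broad, and incompletely recovering variants), a
reperfusion ramp, a late decline, global monotone rises and falls, and a
fluctuating profile.  These shapes were chosen as the simplest realizations
of the qualitative dynamics; their free parameters (bump widths,
amplitudes) were set so that the standardized templates are mutually well
separated (minimum pairwise Euclidean distance ≈ 2.5 on the 21-point grid),
which is what makes planted-partition recovery a meaningful benchmark.

A simulated measurement is

  intensity = base × template(t) × subject scale × noise × TIC × drift

with per-feature base abundances log-normal (median 5 × 10³, log-SD 1.0),
per-(feature, subject) scale factors log-normal with CV `subject_cv`
(default 0.25; the pooled design gives no variance model, so this is a
plausible biological heterogeneity level), mean-one log-normal measurement
noise with CV `noise_cv` (default 0.2, a typical untargeted LC-MS
replicate CV), a mean-one per-sample total-signal factor with CV
`tic_spread` (default 0.1), and a linear drift of relative amplitude
`drift_amplitude` (default 0.1) along a randomly permuted injection order.
Missing values (default rate 0.05) are injected uniformly among each
feature's below-median cells, mimicking limit-of-detection dropout.
Planted events override a feature's template with a flat baseline raised to
the requested fold change over the key phase, so the pooled key-phase /
baseline ratio equals the request exactly at zero noise.  The generator
default of 10,529 features (60 % archetypal, 40 % null) matches the
temporal feature count of the design it emulates.

What the generator does **not** model: chromatographic artifacts, adducts
and isotopes, between-run retention drift, correlated (pathway-structured)
noise, autocorrelated within-subject noise, or probe-membrane exchange
kinetics.  Passing tests therefore show the pipeline recovers structure of
the kind it assumes; they do not certify performance on real dialysate
data, where nuisance structure is richer.

The pixel-grid generator plants `n_peaks` consensus m/z centers (0.5 Da
spacing, > 2× the binning tolerance) shared by all pixels, with per-pixel
m/z jitter (SD 0.02 Da) and multiplicative intensity noise; a rectangular
lesion mask and its mirrored contralateral region receive the requested
log2 fold-change offsets on a chosen number of peaks.

## Preprocessing

The chain is: strict >500-count maximum-intensity filter → total-ion-current
normalization → LOESS injection-order correction → half-minimum gap fill →
per-feature z-scoring.  Choices that were genuinely open:

* **TIC target** — each sample is scaled to the *median* raw total, which
  keeps the data on a familiar scale and is robust to outlier samples.
* **LOESS correction** — fitted per feature against injection order over
  all samples pooled (no QC-injection scheme is assumed), default span
  0.75, and applied divisively (MS intensities are multiplicative).  The
  trend is renormalized to mean one so the correction never changes a
  feature's average level.
* **Gap fill** — half the feature's minimum observed value, the
  conservative limit-of-detection convention.  Features with no observed
  values cannot be filled and are dropped with a warning.
* **Standardization** — clustering must compare trajectory *shapes*;
  Euclidean distances on raw intensities would cluster by abundance.
  Constant features have no shape and are excluded (and listed).
* **Shape space** — clustering operates on subject-pooled per-collection
  means (21-point vectors), z-scored per feature.  Pooling first removes
  between-subject scale heterogeneity, which otherwise leaks into the
  shape metric and inflates within-cluster scatter.

Every step appends itself to a transform log, serialized with the outputs.

## Fuzzy c-means, validity, and parameter selection

The membership and centroid updates are the classical Bezdek alternating
scheme with Euclidean distances; the objective
J_m = Σ_ik u_ik^m ‖x_i − v_k‖² is non-increasing across iterations and is
asserted on every fit.  Numerical choices:

* **Initialization** — k-means++ seeding, best of `n_init` = 10 restarts by
  final J_m; deterministic given the seed.
* **Convergence** — max |Δu_ik| < 10⁻⁶ or 200 iterations.
* **Coincident points** — a point lying exactly on one or more centroids
  (the membership formula's singular case) has its membership split equally
  among the coincident centroids, the symmetric resolution.
* **Degenerate fits** — duplicate centroids make the Xie–Beni denominator
  zero; `xie_beni` raises, while the grid search records +∞ so
  over-clustered cells eliminate themselves.
* **Fuzzifier grid** — default {1.05, 1.10, …, 2.0}.  Fuzzifiers much
  above 2 pull centroids toward the grand mean and make the u^m-weighted
  validity index an unreliable basis for comparing cluster counts (at
  m = 3 the joint argmin flips between correct and merged partitions
  run-to-run on planted data, while every slice with m ≤ 2.5 selects the
  planted count decisively).  The 1–2.5 range is also the span generally
  recommended for fuzzy clustering practice.  Ties in the (c, m) grid break
  toward smaller c, then smaller m.

## Kinetic labels

Cluster centroids are annotated automatically (where a five-hour experiment
with 16 clusters could be annotated by eye, automation makes the labels
reproducible).  The classifier works on the standardized centroid: interior
maxima are detected with a prominence margin of 0.5 standardized units; a
single peak within one collection of a phase transition is a boundary peak;
two prominent peaks in different coarse phases make a biphasic shape; three
or more, a fluctuating one.  Shapes with edge maxima are tested for a
phase-restricted trend (the coarse phase holding the largest variation,
provided the remainder varies < 35 % as much and the within-phase Spearman
|ρ| ≥ 0.8) and then for a global monotone trend (|ρ| ≥ 0.8 over all
collections).  All margins are exposed as function parameters.  Letter
codes are assigned by a narrative ordering — phase-localized events first,
in order of occurrence, then global trends and fluctuating shapes — so the
letters are reproducible; they are display names, not identities.

The dominant set defaults to the four clusters holding the largest total
membership mass (an explicit override accepts a code list).  The
drowning-effect correction and the >0.5 selection threshold use **raw**
memberships; renormalizing over non-dominant clusters before thresholding
is a defensible alternative that would select more features, and is not
the default.  Hierarchical grouping of features uses Ward linkage on
Euclidean distances in membership space.

## Trajectory statistics

SD Energy is defined here as the standard deviation of the (TIC-normalized,
pooled) trajectory across all collections — a global fluctuation magnitude
on the intensity scale, so it scales linearly with abundance while the
key-time fold change is scale-free.  Fold changes divide the key-phase mean
by the phase-I baseline mean; the four pre-occlusion collections make that
baseline.  Statistics are computed on pooled per-collection subject means;
per-subject statistics can be derived from the same functions for
dispersion reporting.  Fold changes are computed on the gap-filled,
TIC-normalized intensities *before* standardization (z-scores have no
meaningful ratios).

## Spatial chain

Spectrum smoothing is a 3-point centered moving average along the m/z axis
with shrunken edge windows (a constant spectrum is preserved exactly).
Peak binning groups all pixel peaks greedily in order of decreasing
intensity into ±0.180 Da windows around consensus centers; within a window
each pixel contributes its maximum-intensity peak, and bins detected in
fewer than 3.84 % of pixels are discarded.  Pixel segmentation applies the
Ward Lance–Williams update to cosine dissimilarities — reproducing the
behaviour of the commercial imaging software this mirrors, not a claim that
cosine geometry is Euclidean.  The ROI differential uses
log2((mean_A + ε)/(mean_B + ε)) with ε defaulting to 1 % of the global
median bin intensity, so empty contralateral bins cannot produce
infinities; the pass rule |log2FC| > 1 is strict.

## Enrichment

One-sided Fisher's exact tests per pathway against a caller-supplied
annotation map, background = all annotated features.  The pass flag uses
the raw p-value at a strict p < 0.01; a Benjamini–Hochberg column is
emitted for transparency but deliberately does not drive the flag, since
the curation rule being reproduced is a raw-p rule.

## Benchmarks and problem sizes

The validation suite (`strokemap.benchmarks`, exercised by
`tests/test_acceptance.py` and `scripts/acceptance.py`) isolates one noise
source per benchmark: the clustering benchmark plants 50 features per
archetype (800 total) with 5 % measurement noise and no TIC/drift/dropout
nuisances, then selects c from {8, 12, 16, 20} (fuzzifier grid
{1.1, 1.5, 2.0}, 3 restarts per cell) by Xie–Beni and fits at the
selection; the binning benchmark uses a 40×40 grid with 285 well-separated
peaks; the differential benchmark plants 21 up- and 29 down-regulated bins
at |log2FC| = 2 under 2 % noise; the fold-change benchmarks plant a
ten-fold phase-IV surge and a six-fold IIIA–IIIB plateau (8 collections,
i.e. two hours) among null features at 10 % noise and pool per-collection
subject means.  The full nuisance stack is exercised separately by the
pipeline tests and the `analysis/` scripts at a 1,600-feature
demonstration scale, chosen so the whole story runs in seconds; every
stage is O(n) in features and runs identically at the full 10,529.

## Known limitations

* LOESS over injection order can partially absorb genuine phase-locked
  signal when one phase's samples happen to cluster in injection order;
  with a randomized order and span 0.75 the effect is usually small, but
  fold changes of sharp events are mildly attenuated after correction.
* Half-minimum imputation biases low-abundance phases upward and is the
  dominant contributor to within-cluster scatter at realistic dropout
  rates.
* The letter codes depend on the narrative ordering rule; comparing labels
  across runs requires comparing annotations, not letters.
* The Xie–Beni criterion compares poorly across very soft fuzzifiers
  (see above); the default grid caps at 2.0.
* SD Energy has no dimensionless form here; comparisons across features of
  very different abundance should use the fold change instead.
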