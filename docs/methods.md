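# Methods

`readrsa` implements a multivariate fMRI analysis of single-word reading:
representational similarity analysis (RSA) comparing local neural pattern
geometry against five hypothesis models of word similarity, separately for
words read aloud and words read silently, with Bayes-factor group inference.
This note documents the models, the numerical choices, and what the
synthetic-data validation does and does not establish.

## Hypothesis models

Each model is a representational dissimilarity matrix (RDM) over a word
list: symmetric, zero on the diagonal, one row/column per word. In the
default design each participant's 30 words are split 15/15 between the
aloud and silent conditions, so the analysis RDMs are 15 × 15 (105 unique
pairs); model-independence screening uses 30-item "exemplar" RDMs over the
full word list (435 pairs).

- **Visual** — words are rasterised as binary silhouette images (lowercase,
  centered on a fixed canvas, intensity binarised at 0.5) and compared by
  correlation distance, 1 − Pearson r, between the flattened images. The
  default font is DejaVu Sans resolved from matplotlib's bundled font set,
  a deterministic sans-serif stand-in for a presentation font;
  `RenderConfig` exposes font, size, canvas and threshold.
- **Orthographic** — unconstrained open bigrams: every ordered letter pair
  of a word with any positional gap, counted with multiplicity (a word of
  length L yields L(L−1)/2 bigram tokens). Words are compared by
  correlation distance between their bigram count vectors over the shared
  vocabulary. Counts (not binary presence) preserve repeated-letter
  structure.
- **Phonological (acoustic)** — each spoken-word token is an MFCC frame
  sequence. A sequence is split into k = 10 contiguous, equal-count
  segments; each segment is reduced to its mean frame; the distance between
  two words is the mean Euclidean distance between corresponding segment
  means. Fixing the segment count makes the measure invariant to word
  duration. Distances are computed within speaker only, then averaged
  across speakers. The package consumes precomputed MFCC sequences; audio
  processing is out of scope.
- **Semantic** — cosine distance (1 − cosine similarity) between word
  embedding vectors, supplied by the user or synthesised.
- **Articulatory** — feature-weighted phonological edit distance: dynamic
  programming over phoneme sequences where substituting phoneme a for b
  costs the fraction of mismatched binary articulatory features and
  insertion/deletion costs 1.0 (the maximum substitution cost); the total
  is divided by the longer transcription's length, bounding the result in
  [0, 1]. A 23-phoneme, 10-feature toy inventory ships with the package;
  any feature table with full coverage of the transcriptions can be
  substituted.

**Independence screening.** Pairwise Pearson correlations between
vectorised exemplar models, each accompanied by a Bayes factor for a
nonzero correlation (uniform prior on ρ, n = number of RDM cells — 435 for
30 words). Models flagged at BF₁₀ ≥ 3 share variance by construction;
downstream multiple regression partials shared variance out, but only
imperfectly when the planted/true geometry is realised with error, so
validation claims about "independent" models are restricted to pairs the
screen itself passes.

## Pattern estimation (least-squares-all)

Each run's 30 trials get one regressor each: a boxcar over the 2.5 s word
presentation, convolved with a gamma-density HRF with mean (lag) 6 s and
standard deviation 3 s — shape (6/3)² = 4, scale 1.5 s, mode at 4.5 s —
sampled at dt = 0.1 s, normalised to unit area, and read off at volume
onsets t = i·TR. All trial regressors, optional nuisance columns, and an
always-present intercept are fitted jointly by OLS at every in-mask voxel;
nuisance and intercept coefficients are discarded. Item patterns are the
mean of each word's four trial coefficients across runs; the per-voxel mean
across the 15 items of a condition ("cocktail blank") is then subtracted,
making per-voxel item means exactly zero. An optional per-voxel linear
detrend (off by default) stands in for high-pass filtering on real data.

Unit-area HRF normalisation is a convention choice (peak-normalisation
rescales all trial regressors by a common factor, which the searchlight's
z-scoring absorbs). The intercept-always policy keeps noiseless recovery
exact while guarding against non-zero-mean baselines.

## Searchlight RSA

At each in-mask voxel, the sphere of radius 3 voxels (123 lattice offsets)
is intersected with the mask; spheres truncated below 10 voxels are skipped
(NaN). The 15 item patterns restricted to the sphere give a neural RDM of
pairwise correlation distances; its vectorised lower triangle (n(n−1)/2
entries, row-major) is z-scored (sample sd) and regressed on the five
z-scored model vectors plus an intercept. The five coefficients (β) are
written at the centre voxel. Edge handling (truncation rather than
rejection) and the sphere-size floor are configurable; the GLM's intercept
is harmless under z-scoring and guards against numerical drift. β maps are
invariant to any common rescaling of the patterns.

## Group inference

For each model and condition, a right-tailed one-sample JZS Bayes t-test at
every voxel asks whether β > 0 across subjects (10 within-condition maps);
a two-sided paired test on aloud − silent differences gives 5
between-condition maps. Voxels missing in any subject are excluded
(complete case). All maps are thresholded at BF₁₀ ≥ 3.0 (inclusive —
"moderate evidence"). Between-condition maps are split by the sign of the
group-mean difference and masked by the thresholded within-condition map of
the minuend condition, so a difference only counts as "aloud > silent"
where information is actually decodable in aloud; exact ties (d = 0) enter
neither direction, keeping the two outputs disjoint. Clusters are
26-connected components of at least 20 voxels, reported with extent,
mean/max BF₁₀ and a BF-weighted centre of gravity in mm.

**JZS Bayes factor.** The prior on the standardised effect δ is
Cauchy(0, √2⁄2); one-sided tests truncate it to the positive (negative)
half-line, which implies (BF_right + BF_left)/2 = BF_two exactly. The
marginal likelihood is evaluated by a vectorised two-level Gauss–Legendre
scheme using the scale-mixture identity p(t | ν, ncp) = E_W[W φ(tW − ncp)]
with W = √(χ²_ν/ν): the δ axis uses composite panels resolving both the
Cauchy core and the likelihood bump, the w axis a window centred on the
analytic mode of the w-integrand. Agreement with adaptive quadrature of
scipy's noncentral-t density is ~1e-8 relative over the relevant range, and
the one-sided mixture identity holds to machine precision. Evaluating ~2700
voxels takes about a second per map on one CPU.

**Correlation Bayes factor.** For the independence screen: uniform
(stretched beta, κ = 1) prior on ρ, numerator integrated from the exact
sampling density of r (hypergeometric form) by adaptive quadrature. The
implementation agrees with an independent closed-form route (pingouin's
exact formula) to ~1e-8.

## Synthetic studies and planted geometry

The generator reproduces the target design: 30 pronounceable CV-syllable
words of 6–10 letters with synthetic transcriptions (letters mapped onto
the toy phoneme inventory), iid standard-normal 50-d embeddings, and
per-speaker MFCC trajectories (smooth integrated-noise prototypes with
speaker offsets and jitter, 2 speakers); a uniformly random 15/15
aloud/silent split per subject; 4 runs × 30 trials at a fixed 6 s SOA, word
duration 2.5 s, TR 1.8 s — exactly 100 volumes per run (30·6/1.8). Volumes
default to 24 × 24 × 16 voxels with an ellipsoidal mask (~4200 voxels), a
desk-scale stand-in for a brain. One master seed fans out through
`SeedSequence.spawn` (lexicon first, then per subject: allocation,
planting, events, BOLD noise), recorded in the dataset manifest.

**Planting.** To endow a region with a model's geometry, classical MDS of
√RDM gives prototype item coordinates (so squared prototype distances track
the RDM, and correlation distance between row-standardised patterns is
proportional to squared Euclidean distance); a random linear map embeds
them into the region's voxels; the embedded signal is mixed with iid noise
patterns. The mixing weight is calibrated by bisection until the mean (over
20 random replicates) Pearson correlation between the patterns' neural RDM
and the vectorised model reaches the target ρ; the replicate whose own
measured correlation is closest to the target is returned with its achieved
value, so the stored ground truth is exact by construction rather than
approximately calibrated. ρ = 0 returns pure noise.

**BOLD synthesis.** Each run is design × ground-truth item patterns plus
Gaussian noise — white by default, optionally stationary AR(1) (φ = 0.3 is
the suggested setting). The default noise standard deviation is 0.5
relative to unit-variance item patterns; this was fixed once, by a pilot at
the scaled-down study size, so that planted geometry at ρ = 0.5 produces
the medium-to-large group effects (d ≈ 1–1.5) that the validation is meant
to emulate.

**What the validation shows — and does not.** Passing tests demonstrate
that the estimation chain is self-consistent: geometry planted at a known
strength is recovered where and only where it was planted, directional
contrasts behave as specified, and a null study produces no clusters. The
generator omits most structure of real fMRI noise (drift, physiological
cycles, motion, spatial autocorrelation, inter-run misalignment) and all of
real preprocessing; performance on synthetic studies therefore bounds
implementation correctness, not real-data sensitivity or specificity.

## Scaled-down validation sizes

The planted-geometry and null-study checks run at 12 subjects on the
24 × 24 × 16 volume with a 179-voxel spherical target region — sizes chosen
so the full pipeline (including ten null replicates) completes on a single
CPU in minutes while leaving the group tests enough power at the planted
effect size. The study-design constants themselves (30 words, 4 runs, 100
volumes, TR 1.8 s) are never scaled.

**False positives under the null.** Because neighbouring searchlight
spheres share almost all of their voxels, β maps are spatially smooth; the
voxels that exceed BF₁₀ ≥ 3 under a pure-noise study (at the nominal
voxel-level rate, roughly 0.5–1% for n = 12) therefore arrive as contiguous
blobs rather than isolated speckles, and a 20-voxel minimum extent does not
remove them. Null studies at the default validation size produce a handful
of such clusters per study across the 25 reported maps — in every map
family, including the doubly-masked directional contrasts. The evidence
threshold and extent floor shape what is reported; they are not a
false-positive guarantee, and consumers of cluster tables should read them
accordingly. The acceptance script measures this null cluster rate
explicitly.

## Known limitations

- The searchlight loops over centre voxels in Python; whole-brain
  real-data volumes (~50k voxels) take minutes per subject rather than
  seconds. The per-sphere mathematics, not throughput, was the priority.
- One-sided Bayes factors are defined by prior truncation; software that
  instead rescales by posterior odds can differ slightly for small |t|.
- The orthographic model's bigram vocabulary is defined by the word set
  entering the RDM, so a 15-word condition RDM is not exactly a submatrix
  of the 30-word exemplar RDM (all other measures are pairwise and
  restriction-exact).
- Cluster extents are reported in voxels; conversion to mm³ is left to the
  caller because it depends on the affine.
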