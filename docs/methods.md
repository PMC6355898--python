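# Methods

This note documents the models and procedures implemented in `cohera`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical decisions a maintainer should know about.

## Semantic space

The space is a classical LSA model: a term–document count matrix from a
plain-text corpus, log(1 + count) local weighting times a per-term entropy
global weight, truncated SVD, word vectors = U·S rows. Log-entropy is the
standard LSA weighting; it is configurable (`weighting="log"` or `"raw"`)
because corpora with pathological structure (e.g. identical documents)
reduce every term's entropy weight to zero, in which case the default
weighting correctly refuses to build a space. Terms whose weight falls to
zero are dropped from the vocabulary rather than kept as zero vectors.

Numerical choices: the Lanczos SVD is run with a fixed start vector so the
decomposition is bit-reproducible; the sign of each component is fixed by
forcing its largest-magnitude loading positive (cosines are unaffected).
Token normalization is lowercase + punctuation stripping, no stemming, and
no stoplist by default; a stoplist, if supplied, excludes words from
passage vectors only, not from the space. Passage vectors are unweighted
means of in-vocabulary word vectors; a passage with no in-vocabulary token
is flagged undefined, never silently zero. Out-of-vocabulary lookups return
a sentinel, never zeros. `k` defaults to 300 for real corpora; the tests
and analysis scripts use k in [2, 20], which is ample for the synthetic
topic structure.

## Coherence

Global coherence of word *i* is 100 × max(0, cos) between the passage
vector of the 20-word window ending at *i* and the leave-one-out prototype
(mean passage vector of the other speakers' responses to the prompt,
averaged per response, not per pooled word). Negative cosines are possible
after SVD even though the reported scale is 0–100; they are clamped to 0
for reporting and the raw cosine is kept alongside. Cosine of two
bit-identical vectors is returned as exactly 1 to avoid round-off at the
scale's upper endpoint.

Words with index < 20 have no defined per-word value; the block level is
the normative remedy: block 1 of every response takes block 2's value, and
any other block with no defined word values takes the nearest later defined
block's value (logged). Words map to 5-s blocks by onset time over
half-open intervals [start, end), with a uniform-rate fallback
(n_words / period_length) when onsets are missing.

Local coherence — the relatedness of adjoining stretches of speech — is
computed as 100 × max(0, cos) between the window ending at word *i* and the
immediately preceding non-overlapping 20-word window. The windowing of the
local measure is this package's reconstruction of common practice; other
window pairings exist in the literature, so treat cross-study comparisons
of absolute local-coherence values with care.

A single-prompt dataset and a prototype built from one other response are
allowed (the latter warns), so small pilot datasets can be scored.

## Speech measures and factors

Per 5-s block: word count, type:token ratio, closed-class proportion, and
mean frequency, concreteness, age of acquisition, semantic diversity and
phoneme length of nouns. Nouns and closed-class words are identified by
lookup lists supplied with the norms table — no POS tagger dependency —
and blocks without listed nouns have their noun means flagged undefined
and handled pairwise-complete in correlations, preserving sample size for
the defined measures.

Factor extraction is a principal components analysis of the z-scored
measure table: components with eigenvalues > 1 retained, promax rotation
(kappa = 4, the conventional default) for interpretability, explained
variance reported on the unrotated components. The promax implementation
(varimax with Kaiser normalization, then the least-squares oblique map
onto the kappa-powered target) reproduces R's `stats::promax` to 6
decimals on a frozen reference case in the tests. Scores use the
regression method, Z·R⁻¹·S with S the structure matrix; standardization
constants and the fit-sample correlation matrix are stored in the model so
new blocks can be scored. In recovery tests, factor order and sign are
arbitrary, so estimated factors are matched to planted ones by maximum
absolute Tucker congruence under a Hungarian assignment.

## Design construction

Four conditions are modelled — extended speech planning (8-s blocks),
extended production (50-s periods as ten concatenated 5-s blocks),
automatic (rote) speech planning and production (15 s) — as boxcars
convolved with the canonical double-gamma HRF (gamma shapes 6 and 16,
undershoot ratio 1/6, 32-s support, peak-normalized). Convolution runs on
a microtime grid of 16 bins per TR (TR 2.2 s) and samples the middle bin
of each volume, the conventional sampling most analysts assume; the HRF
agrees with nilearn's SPM canonical shape at r > 0.998 in the tests.

Parametric modulators (block coherence, time-in-period 1..10, factor
scores) are prepared per run: values outside mean ± 2 SD of the raw run
(SD with n−1 denominator) are clipped to the bound, then the post-clipping
mean is subtracted, so the series is exactly zero-mean and bounded.
Winsorize-then-centre guarantees both properties simultaneously; the
reverse order would not. Because clipping shrinks the SD, re-deriving
bounds from a prepared series would clip again — preparation is therefore
idempotent *by contract*: the bounds are defined on raw run statistics and
a series flagged as prepared is returned unchanged.

Time-shifted ("early"/"late") models move modulator values one 5-s block
backward or forward strictly within trials; the block left vacant at a
trial edge takes its nearest within-trial neighbour's value (mirroring the
first-block substitution), with no leakage across trials.

Drift is modelled inside the GLM as a per-run discrete-cosine basis with a
180-s cutoff — floor(2·T/180) columns per run, constants as separate
per-run intercepts — which is mathematically equivalent to high-pass
filtering the data within the GLM and easier to test. Nuisance columns
(six motion parameters and six externally supplied noise components) enter
unconvolved.

## GLM and group analyses

First level is ordinary least squares per voxel; rank-deficient designs
are fitted with the pseudo-inverse after a warning naming dependent
columns, and degrees of freedom use the design's rank. Contrasts are
w'β with t = effect/SE. AR(1) noise correlation is not pre-whitened; at
the simulation's noise levels this costs efficiency, not bias, and the
recovery tests bound the resulting error directly.

Second level is a one-sample GLM per voxel with centred covariates
(intercept test plus one slope test per covariate). A participant's
propensity to move is summarized as the mean over the six motion
parameters of the mean absolute scan-to-scan change, and is the standard
nuisance covariate. Voxels with zero residual variance return ±inf t
values (flagged, not NaN). The 2×2 hemisphere-by-region ANCOVA on ROI
effects tests each within-participant contrast (two main effects,
interaction) by regressing per-participant contrast scores on an intercept
plus the centred covariate, giving F(1, n−2); with two-level factors no
sphericity correction is needed. Whether the displacement covariate is
included at ROI level is exposed as an argument, since both variants are
defensible.

ROIs come from probabilistic atlas images: strictly greater than the 0.30
threshold (a probability of exactly 0.30 is excluded), with an optional
medial cut removing voxels with |x| < 30 mm in world coordinates — used
for pars orbitalis, which otherwise extends into medial prefrontal
territory. ROI effects are unweighted voxel means. Quintile analyses rank
blocks by a parameter (stable sort, ties by block order), split them into
five near-equal bins, fit one regressor per bin, and report bin effects
relative to the count-weighted mean, so the weighted relative effects sum
to zero.

The cluster-extent threshold is Monte Carlo: Gaussian white noise on the
mask grid, smoothed to the stated FWHM, standardized over the mask,
thresholded one-tailed at voxel p = .005 (SPM-style t contrasts are
directional; two-tailed is a switch), largest 26-connected cluster
recorded per simulation. The minimum cluster size is the smallest k such
that the proportion of null fields with a cluster ≥ k voxels is ≤ 0.05 —
the 95th percentile of the max-cluster distribution plus one, evaluated on
the discrete distribution. Smoothness is a config input (the applied
smoothing kernel is known in this design); residual-based smoothness
estimation is out of scope. Defaults are 5000 simulations; the analysis
scripts use 1000 on a 24³ grid, which the validation script shows already
calibrates the family-wise error within Monte-Carlo error of 5%.

## Synthetic data

The generators are pure functions of (spec, seed) and define the
conditions under which the pipeline is validated.

* **Corpus**: 8 topics by default (a desk-scale stand-in for a study with
  ~20 distinct prompts), 40 words per topic, Dirichlet unigram emissions,
  optional shared vocabulary. Few-topic corpora are a degenerate regime:
  with only 2–3 topics the leave-one-out prototype is itself a strong
  on/off-topic mixture and drift recovery is not interpretable.
* **Responses**: 10 blocks of 5 s at 10 words per block (the observed
  speaking rate), on-topic probability declining linearly from 1.0 by 0.08
  per block. Off-topic words arrive in excursions (runs of 5 words) whose
  start hazard is deflated so the realized off-topic share matches the
  nominal drift; excursions make speech locally coherent while globally
  drifting. Limitation: with 5-word excursions inside 20-word windows,
  local and global coherence remain substantially correlated in the
  synthetic data; real speech dissociates them more strongly.
* **Norms**: reproducible random lexical properties, a third of words
  designated nouns and a disjoint fifth closed-class. The factor analyses
  use a separate planted-structure generator (four modestly correlated
  factors — complexity, specificity, coherence, verbosity — loadings 0.75,
  unique noise SD 0.85), calibrated so four components exceed the
  eigenvalue-1 rule and explain ≈ 66% of variance.
* **BOLD**: signal = design × planted betas on a small grid (default 20³),
  each effect carried by a seeded random half of the voxels, plus AR(1)
  Gaussian noise. No spatial autocorrelation, physiological noise, motion
  artefact or spatial preprocessing is simulated — passing recovery tests
  demonstrates the estimator chain is correct, not that real-data effect
  sizes would be attained.

What the synthetic path does **not** show: performance of the coherence
measure on natural language (vocabulary growth, polysemy, syntax),
behaviour of the GLM under realistic physiological noise, or anatomical
claims of any kind. Problem sizes in the tests and scripts (64-document
corpora, k = 10, 5–8 speakers, 6³–20³ grids, 1000-simulation thresholds)
were chosen as the smallest sizes at which the validated properties are
stable.

## Scope

Audio processing, spatial preprocessing (realignment, normalization,
smoothing), the PCA-based denoising toolbox that produces the six noise
components (accepted here as a supplied covariate table), and anatomical
labelling of clusters are outside this package.
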