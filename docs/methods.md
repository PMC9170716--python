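# Methods

`orgaprofiler` implements an image-based profiling analysis for 3D organoid
drug screens: patient-derived tumour organoids grown in 384-well plates,
stained for DNA, actin and cell permeability, imaged as 16-slice confocal
z-stacks, perturbed with compound libraries, and read out at single-organoid
resolution.  This note describes the models and procedures, their
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## Synthetic study conditions

The raw imaging data of such screens is restricted-access, so the package
ships a first-class generator (`synthetic_data`) whose defaults define the
study conditions every test and the acceptance script run under:

* **Plate design.** 384-well plates, 16 DMSO negative-control wells per
  plate (the count is exposed as `controls_per_plate` because screen designs
  vary), 8 positive-control wells (bortezomib and SN-38 at two
  concentrations, both treated as fully lethal), and library wells — a
  clinical-style library of 63 drugs at 5 five-fold dilutions (339 assigned
  wells) or a kinase/stemness-style library of 464 single-concentration
  compounds split across plates.  Well positions are randomised under the
  seed.
* **Organoid sizes.** Each line draws log-area from a two-component
  log-normal mixture (defaults: small component at log-mean 4.0, line-specific
  large component at log-mean 5.8–7.0, weights ~0.3–0.5), matching the
  bimodal size distributions organoid lines exhibit.
* **Death.** Dead organoids come from one cluster shared across lines —
  small (log-mean 3.2), high permeability signal, low actin texture energy —
  and each well's dead fraction interpolates between a 3% baseline and the
  drug's configured lethality with dose.
* **Drug effects.** Each drug shifts the generic morphology block along a
  unit direction; drugs within one mechanism-of-action (MoA) group share a
  direction up to an angular jitter of 0.15 (expected within-group cosine
  ~0.98), and group directions are orthogonal by default so between-group
  similarity is ~0.  Dose scaling is linear in dose rank.
* **Multi-view data.** 22 samples (11 lines x 2 replicates) x five views
  with the real screen's dimensions (size 1, mutations 12, expression 3222,
  morphology 25, drug activity 252), generated as `Y_v = Z W_v^T + eps` from
  k = 3 factors; replicates share line-level scores up to Gaussian jitter of
  0.1 x signal sd; the mutation view is thresholded to 30% prevalence and
  loses 2 samples, mirroring the missing mutation profiles.

What the generator does **not** emulate: optical artefacts beyond Gaussian
PSF blur and additive noise, uneven seeding densities, plate-position
biology, batch drift beyond additive feature offsets, correlated noise
across views, or any nonlinear genotype-phenotype coupling.  Passing tests
therefore demonstrate that each algorithm recovers the structure it assumes
when that structure is present — not that real screens satisfy those
assumptions.

## Image processing

**Maximum-contrast projection.** For each channel and pixel, the retained
z-slice maximises the local intensity variance in a 3x3 window (reflective
borders, window configurable); ties break toward the lowest slice, so a
constant stack projects to slice 0.  The z-choice is made independently per
channel, preserving per-stain sharpness.  Local variance is the simplest
neighbourhood contrast statistic; the implementation is exactly equal to a
brute-force per-pixel argmax (tested on random stacks).

**Illumination correction.** Slices are divided by a per-channel gain image
and rescaled to preserve the channel mean.  In `estimate` mode the gain is a
second-order polynomial surface fitted to the mean slice — a parametric
stand-in for prospective flatfield methods that removes linear and smooth
quadratic shading exactly.

**Segmentation.** Foreground is an automatic threshold (Otsu by default) on
the Gaussian-smoothed sum of the DNA and actin channels; holes are filled;
touching organoids are split by a watershed on the distance transform seeded
at local maxima at least `min_seed_distance` (10 px) apart.  The distance
map is smoothed before seed detection so ragged thresholded boundaries do
not spawn spurious basins.  Fields whose foreground/background separation is
under 3 background standard deviations are treated as empty, which makes
pure-noise fields yield empty masks instead of speckle.  Objects of 300
pixels or fewer are removed as debris (area 301 survives).

## Features, filtering, PCA

Per organoid: 12 shape features, 14 moment features (7 Hu + 7 normalised
central moments), 10 intensity statistics per channel, and 6 gray-level
co-occurrence (Haralick-style) texture properties per offset (1, 2, 4, 8 px)
per channel — 128 named features.  The catalogue is the package's own; what
is reproduced from the field's practice are the *filtering rules*:

1. texture offsets larger than the smallest organoids (5th percentile of
   equivalent diameter, guarding against outliers) are dropped;
2. a feature is well-defined only if its median absolute deviation over the
   whole dataset is strictly positive — if more than half of all organoids
   share one value the feature is discarded;
3. any column still containing missing values is dropped, so the result
   needs no imputation;
4. batch effects are removed by subtracting per-batch means (batch =
   staining/imaging group).

The filter is idempotent.  PCA (25 components by default) is fitted either
full-batch or incrementally over row chunks; on well-conditioned spectra the
chunked fit matches the full fit to |r| >= 0.999 per component.  Features
enter PCA centred but not rescaled, as is usual when the feature set has
already been filtered for degeneracy.

## Landscape, clustering, trajectories

UMAP (min_dist 0.1, 15 neighbours, fixed seed) embeds the PC scores; Leiden
community detection runs on a symmetrised kNN graph.  At the tiny resolution
used for screen-scale landscapes (1e-7) only graph components survive, so
well-separated morphologies remain distinct while diffuse data collapses —
the intended behaviour for describing a landscape rather than subdividing
it.

Dose trajectories are principal curves fitted by projection-expectation
iterations: points (a seeded uniform downsample of 5%, floor 200, cap
10,000, outside any excluded clusters) are projected onto the current
polyline, each coordinate is smoothed against arc length with a cubic
smoothing spline whose smoothing level comes from a first-difference noise
estimate, and the curve is resampled at 100 points.  Iterations stop when
the mean squared projection distance improves by less than 1e-4 of the
squared embedding diameter, and the objective trace is non-increasing by
construction.  Pseudotime is arc length, oriented so the control-dense end
is 0 (flip when the baseline's median arc length exceeds the overall
median).  Principal curves flare at their extreme ends where data runs out;
trajectory guarantees therefore concern the curve interior.  On small
screens with few discrete doses, UMAP tends to tear the dose continuum into
islands; trajectories are then better fitted in the PC plane (the embedding
argument accepts any 2D coordinates).

## Live/dead classification and dose-response

A random forest with 10 trees per organoid line is trained on raw
(pre-filter) organoid features to separate DMSO controls (live) from
bortezomib/SN-38 at their two highest screened concentrations (dead), with a
60/40 stratified train/validation split.  Channel ablations drop every
feature derived from a withheld channel.  Per-organoid dead probabilities
are binarised at 0.5 and averaged within wells into a lethality score in
[0, 1]; wells without organoids carry no score.  Cross-line evaluation
applies one line's classifier to another line's controls; generalisation
rests on the death signature (size, permeability, texture) being shared
across lines.

CTG luminescence plates are edge-corrected by a loess-style local weighted
linear regression over (row, column) with tricube weights, span 0.75 of the
wells, and two Cleveland robustness iterations so outlying wells (strong
treatment effects, dead wells) do not deform the trend they are corrected
against; all wells are then divided by the DMSO median, which is exactly 1
afterwards.

Dose-response curves use the three-parameter Hill model
`v(c) = E_inf + (1 - E_inf) / (1 + (c/EC50)^slope)` with `E_0` fixed at 1,
fitted by bounded least squares (log-EC50, log-slope, E_inf in [0, 1]) from
several starts including the no-effect and complete-kill corners.  Among
(near-)equal-cost solutions the exact no-effect curve is preferred, so flat
data gives AUC = 0 exactly.  AUC is the mean of `1 - min(v, 1)` over the
tested log10-dose interval: 0 = no effect anywhere, 1 = complete kill
everywhere, monotone under pointwise-lower curves.  **Identifiability
caveat:** on a 5-point five-fold dilution design whose EC50 sits near the
top of the tested range, EC50 and E_inf trade off; at response noise sd 0.05
the least-squares EC50 has a ~2x spread and a downward median bias (~0.8x)
even though noiseless recovery is exact and AUC is recovered to ±0.05.  AUC,
not EC50, is the robust summary on this design.  Fit failures fall back to a
flagged trapezoid AUC over the observed points.

## Drug-effect profiles and MoA enrichment

Per (line, treatment): organoids are split 50/50 (stratified); the L2
strength of a logistic regression (grid 1e-3..1e3, 7 values) is chosen by
5-fold cross-validation on the first half; the final model is refit on the
second half and its AUROC estimated by 10-fold cross-validation there.
Features are standardised inside the model pipeline (fitted on training
folds only) for optimisation conditioning, and coefficients are mapped back
to the PC scale.  The AUROC is oriented (relabelling treated/control maps
a -> 1-a with a coefficient sign flip) and clipped to [0.5, 1].  The
coefficient vector — the normal of the separating hyperplane — is the drug
effect profile.

A treatment is *active* when its line-mean AUROC strictly exceeds 0.85
(exactly 0.85 is not active).  For clustering, each treatment unit (each
(drug, concentration) by default) concatenates its per-line unit directions
scaled by `(AUROC - 0.5) * 2`, zero-filling missing lines; cosine distance
then weights lines by activity without changing direction.  Alternatives:
Euclidean distance on per-unit mean phenotype shifts, or correlation
distance.  Linkage is average by default.  Every dendrogram node with at
least 3 leaves is tested bottom-up for each drug-target annotation among its
leaves with a one-sided Fisher's exact test (equal to the hypergeometric
tail; unannotated drugs count as non-target), Benjamini-Hochberg adjusted
over all node x target tests.

## Multi-view factor analysis

The five views are assembled as: size = location of the large component of a
two-component log-normal mixture fitted (EM, with a single-component
fallback) to each sample's DMSO organoid areas; morphology = per-sample mean
DMSO 25-PC profile; expression filtered to the top 10% of genes by
coefficient of variation (ties broken by gene id); binary mutations as
given (missing samples allowed); drug activity = AUROC matrix of drugs
active in at least one observation.  Each view is standardised feature-wise
and scaled to unit total variance; the scaling state is stored.

The factor model `Y_v ~ Z W_v^T` (k = 3) is fitted by alternating least
squares across views with a small ridge (1e-6) for conditioning; samples
missing from a view are excluded from that view's objective; the objective
is non-increasing.  This estimator stands in for heavier variational
treatments of the same linear model: the contract is subspace and
variance-decomposition recovery, not parameter-for-parameter equality with
any particular implementation.  After convergence the scores are
orthogonalised by SVD and loadings refit, which makes the per-factor
variance-explained entries lie in [0, 100] and sum per view to at most the
total variance explained; factors are ordered by total variance explained
and signed so their correlation with the size view (when substantial) or
their largest loading is positive.  Because an unpenalised linear factor
model is identified only up to an invertible mixing, recovery is assessed at
the subspace level: each reference factor is correlated with its
least-squares reconstruction from the estimated factors, and per-view
variance explained is compared via the rotation-invariant all-factor
quantity.  Note that with 22 samples, an ordinary-least-squares refit
explains ~k/(n-1) ~ 14% of even an independent view by chance; per-factor
shrinkage priors, which would push that toward zero, are out of scope.

**Projection.** Drug-perturbed mean morphology profiles are scaled with the
training view's stored standardisation and multiplied by the pseudoinverse
of the transposed morphology loading matrix — the least-squares solution of
`Y ~ Z_proj W^T`.  Projecting the training view itself reproduces the
training scores up to the least-squares residual (exactly, on noiseless
full-rank data); per-factor fidelity degrades for factors that carry little
morphology signal in a given draw.

**GSEA.** Preranked enrichment uses the weighted running-sum statistic
(weight 1): increments of `|score|` (normalised) at set members, uniform
decrements elsewhere; the enrichment score is the extremum of the running
sum, computed analytically at its change points and equal to a brute-force
oracle to machine precision.  The null permutes gene labels (default
100,000 permutations, configurable; evaluated in chunks); the p-value is
one-sided among same-sign null scores with the +1 correction, and
NES = ES / mean |same-sign null ES|.  BH adjustment applies across sets.

**Target association.** For every drug target annotated on at least 3 of
the drugs under test, `value ~ 1[target]` is fitted — equivalent to an
equal-variance two-sample t test — on factor loadings or projected factor
scores (pooled across lines, with per-line stratification available);
zero-variance inputs are flagged rather than tested; BH across targets.

## Numerical choices and degenerate inputs

* All randomness flows through `numpy.random.default_rng(seed)`; generators
  are bitwise-reproducible.
* Blank image fields give empty masks (not errors); saturated constant
  fields give a single-component mask with a warning.
* Constant objects have zero GLCM contrast by convention; GLCM offsets with
  no valid in-mask pixel pairs yield missing values, which the
  well-definedness filter then removes.
* Class-starved cross-validation folds are reduced with a warning.
* A drug-effect vector of exactly zero is excluded from clustering with a
  warning; a rank-deficient morphology loading matrix still projects via the
  pseudoinverse, with its condition number logged.
* The strict activity threshold uses a 1e-9 float guard so a mean AUROC of
  exactly 0.85 is never called active by summation error.

## Problem sizes

Tests and the acceptance script run the full pipeline at reduced scale
chosen to keep every stochastic check well-powered: 200x200 px fields with
~10 organoids, screens of 2-6 drugs x 5 doses x 30-200 organoids/well,
50 null drugs for activity calibration, 15 drugs in 3 MoA groups for
clustering, the real screen's full 22 x 5-view dimensions for the factor
model, 101 replicate curves for dose-response calibration, and 200 x 1,000
permutations for GSEA null calibration.

## Known limitations

* Intensity thresholding plus watershed stands in for learned segmentation
  refinement; heavily overlapping organoids beyond ~20% radius overlap are
  not reliably split.
* The texture catalogue (6 GLCM properties per offset/channel) is smaller
  than catalogues computed by some imaging toolkits; counts differ, rules
  do not.
* EC50 from 5-point designs is reported but weakly identified (see above).
* The factor model provides no automatic factor-count selection and no
  sparsity; k is a user choice.
* Cross-line viability generalisation assumes a shared death signature; a
  line whose death phenotype differs qualitatively would need its own
  classifier (which is why classifiers are trained per line).
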