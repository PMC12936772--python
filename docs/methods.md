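# Methods

`lungsig` re-implements, as an open and tested pipeline, a multimodal
diagnostic-signature analysis for suspected lung cancer: texture and
autoencoder features from a lesion CT, immune-subset percentages from
flow cytometry, exosome dot-blot intensities, a Bayesian logistic model
with built-in covariate selection, repeated-split stability selection,
three data-fusion levels, and ROC/Youden evaluation. Because no patient
data are distributed, a synthetic cohort generator reproduces the
statistical structure the analysis assumes and doubles as the test bed.

## Synthetic cohort generator

`synthetic.GenerativeSpec` defaults encode the study conditions: 170
patients, cancer prevalence 46.5% (79/91 with `exact_counts`), stages
allocated to cancers with weights (23, 9, 18, 29)/79, and two planted
immune effects — KIR3DL1+ CD8 T cells up in cancer (+1.0) and cDC2 down
(−1.0) on the latent logit scale. Dot-blot columns carry no signal by
default (an optional weak `PD1` effect is available).

Feature marginals are chosen for boundedness and realism rather than
fitted to anything: immune subsets are logit-normal percent-of-parent
values in [0, 100]; dot-blot intensities are log-normal, positive and
unbounded. Effects are planted as latent-Gaussian location shifts of
`effect × sd²`, so for equal-variance classes the implied discriminating
logistic coefficient on the latent scale equals the declared effect.
Informative columns sit at a fixed baseline of logit 0 (50% of parent):
the logit transform is locally symmetric there, so a +1 and a −1 effect
produce the same feature-scale separation; tying the baseline to a
random draw would make the effect-size parameter mean different things
in different seeds. Noise columns draw their baselines from
N(−1.5, 0.8) (typical small subsets).

Lesions are spiculated ellipsoids in a 64×64×32 voxel, 1 mm isotropic
volume: a volume-preserving random axis anisotropy (±15%), a sinusoidal
angular modulation of the boundary radius (the spiculation amplitude),
lesion attenuation around +20 HU (benign) or +60 HU (cancer) on a
−800 HU noisy background. Radius draws are truncated below at 3 mm,
mirroring the clinical exclusion of lesions under 6 mm diameter, and
above at the field of view; cancers draw larger radius (8.0 vs 6.0 mm
mean), attenuation and spiculation. Every draw derives from
`(seed, stream tag, CRC32(patient_id))`, so single lesions regenerate
bit-identically.

What the generator does *not* emulate: scanner physics and
reconstruction kernels, partial-volume effects, anatomical context
(vessels, pleura), correlated immune panels, batch effects, or any
dependence of feature effects on stage (stage is independent of the
features by default, and staging is deliberately excluded from
modelling). Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes — not clinical performance
on real data.

## CTTA: filtration-histogram texture features

The image is band-pass filtered with a negated Laplacian-of-Gaussian
kernel at spatial scale filters (SSF, mm); SSF = 0 is the unfiltered
image. The SSF-to-width map is σ = SSF/2, which peaks the LoG response
for objects of diameter ≈ SSF mm; both the map and the scale set are
configurable. The default scale set is {0, 1, 2, 3, 4, 5, 6} mm — the
seven-element set consistent with 42 features = 7 scales × 6 statistics
and with the named features `mean_0` and `mpp_3`.

Kernels are sampled in millimetres on the voxel grid (anisotropic
spacing honoured), weighted by the voxel volume so the discrete
convolution approximates the continuous integral (response independent
of sampling density), and shifted to exact zero sum — so constant
offsets affect only SSF = 0 features. Boundaries are mirror-padded;
truncation is 4σ per axis.

Per scale, six ROI-histogram statistics are computed: mean, population
sd, Shannon entropy (base 2, 64 bins spanning the ROI min–max of the
filtered values), mean of strictly positive pixels (MPP; 0 and flagged
if no positive values), skewness and excess kurtosis (standardised
central moments; 0 by convention and flagged for zero variance).
Binning and the 2-D default (the axial slice with the largest ROI area,
conventional single-slice practice; a 3-D mode is available) are
documented choices — the upstream commercial tool's exact settings are
not public.

## DLA: autoencoder latent features

Patches (default 48 mm field resampled to 64×64, bilinear) are taken
from the largest-ROI axial slice, centred on the mask centroid, clipped
to the HU window [−1000, 400] *before* resampling (so out-of-window
values cannot bleed through interpolation), then min-max scaled to
[0, 1] (constant patches map to 0).

The autoencoder is a fully-connected network written directly on numpy:
4096 → 256 → 32 (linear bottleneck) → 256 → 4096, ReLU hidden units and
a sigmoid output, trained on mean-squared reconstruction error with
Adam (lr 1e-3, batch 32). Initialisation and minibatch order are
functions of the seed, so training is bit-deterministic. The 32
bottleneck activations (`dla_00`..`dla_31`) are the imaging features;
`latent_traversal` sweeps one latent coordinate and decodes, which on
synthetic corpora isolates axes for lesion size and morphology. The
architecture is deliberately minimal — unsupervised features with a
32-dim bottleneck are the contract, not a specific network family — and
all hyperparameters are exposed.

## BMR: Bayesian logistic regression with covariate selection

Covariates are z-scored internally. The model is logistic regression
with independent N(0, prior_sd²) priors on standardised coefficients
(default prior_sd 2.0 — diffuse on the log-odds scale yet proper, so
perfect separation keeps finite estimates) and N(0, 10²) on the
intercept. The marginal likelihood of a covariate subset is
approximated by Laplace's method at the posterior mode (damped Newton),
plus the standard fourth-order moment correction — the Gaussian
expectation of the cubic/quartic Taylor remainder — which brings the
approximation within ~0.01 nats of numerically integrated evidence on
small fits (the regime where plain Laplace errs by ~0.1–0.2 nats). The
correction is O(1/n) and is skipped above 512 rows, where it is far
below 0.01 nats and its pairwise cost would dominate.

Selection is greedy forward search: at each step the covariate whose
addition most increases the selection objective is added; the search
stops when no addition improves it or at `max_covariates` (default 12,
the size of the headline signature). The objective is the log evidence
plus a subset-size prior with independent inclusion probability
κ = 1/p — the standard Bayesian multiplicity correction. Without it the
prior odds of inclusion do not scale with the number of candidates and,
with 40+ noise covariates at n ≈ 130, some noise covariate clears a
plain evidence comparison in roughly half of null datasets; with it the
null false-selection rate stays below ~5%. Ties in evidence gain break
lexicographically (reproducible).

Per selected covariate the fit reports Beta (posterior mode,
standardised scale), a posterior sd from the inverse-Hessian diagonal,
a two-sided normal-tail p-value for Beta, and the raw-scale signature
weight Beta/sd(x). These p-values are *not* selection-adjusted; under a
global null the pre-selection screen is approximately uniform, and no
conditional validity is claimed. A risk score is the raw-scale linear
predictor: intercept + Σ weight·x.

The elastic-net comparator (scikit-learn, saga solver, penalty chosen
by cross-validated deviance) is fitted on the same standardised scale
and reported alongside; on wide noisy data it shows the larger
train-to-test AUC drop that motivates the evidence-based selector.

## Stability selection and fusion

`make_splits` holds out one quarter of patients as an internal test
set, 8 times. The default `balanced_train` mode draws an equal-class
training set of round(0.75·n)//2 per class — 64/64 training and
27/15 test at the study composition — with a `proportional`
(class-stratified, largest-remainder) mode also available. Plans are
keyed on sorted patient ids, so they are invariant to row order.

Covariates selected in ≥ 50% of repeats (≥ 4 of 8; "at least half", and
configurable) form the final covariate set, refit on the full cohort.
The resulting full-cohort ROC is labelled *apparent (optimistic)* in
all outputs; when nothing passes the threshold the report states that
no final model was generated. Fusion levels: *early* concatenates raw
modality matrices (name collisions get a modality prefix);
*intermediate* concatenates only each single-modality signature's
selected covariates; *late* builds one risk-score column per modality.
Fused matrices are refit with the same selector (rather than averaging
scores), so fusion models also report per-covariate associations.

## Evaluation

AUC is the trapezoidal area under the empirical ROC (= Mann–Whitney
with ties counted ½); the 95% CI uses the DeLong structural-components
variance with a normal interval truncated to [0, 1]. Higher score means
higher cancer risk throughout, and a case is called positive at
score ≥ threshold. The Youden threshold maximises
sensitivity + specificity − 1 over midpoints between consecutive
distinct scores; ties break toward the lower threshold (higher
sensitivity), and perfect separation reports the midpoint of the
separating gap. Stratified tables report per-stage detected/total
(sensitivity), the non-cancer correct/total (specificity), and an
external-cancer mode for scoring a signature on a cancers-only cohort;
rendered percentages round to the nearest integer. The default is a
single full-cohort Youden threshold (per-split thresholds were also
plausible; the single threshold is the simpler, reproducible choice).

## Problem sizes and numerical conventions

Test and acceptance runs use the study-scale cohort (n = 170) for
pipeline properties, n = 1000 × 100 replicates for posterior-interval
coverage, n = 128, p = 40 × 100 replicates for null calibration,
500 simulations for DeLong coverage, 200 lesion patches for autoencoder
training checks, and 5 generator seeds for stability recovery; these
sizes give binomial error comfortably inside the asserted margins.
Newton iterations stop at gradient sup-norm 1e-9; evidence comparisons
use a 1e-12 strict-improvement margin; constant columns are excluded
from fits with a warning.

## Known limitations

- The evidence-based selector approximates an unpublished commercial
  algorithm; only its documented behaviour (evidence-driven selection,
  Beta/p/weight reporting) is reproduced, not its numerics.
- Synthetic lesions are far simpler than thoracic CT; autoencoder
  latents on real data would encode context the generator lacks.
- The full-cohort final ROC is optimistic by construction; the
  repeated-split test AUCs are the honest performance summary.
- p-values are marginal, not selection-conditional.
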