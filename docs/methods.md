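# Methods

This note documents the statistical procedure, the synthetic-data model,
the numerical choices, and the design decisions taken where the design
was genuinely open.

## The prediction pipeline

**Features.** The connectivity weight of an ROI pair is the Pearson
correlation of their mean BOLD time courses. For a network of *n* ROIs
the feature vector is the strict upper triangle of the *n* × *n*
correlation matrix in row-major order, *m* = *n*(*n* − 1)/2 edges; edge
labels always travel with the features. Between-network analyses pool
the two ROI lists (first network's ROIs, then the second's) and treat
the union as a single network, so the features include both within- and
cross-network edges. ROI order within a network is atlas-id ascending
with the id-less amygdala pair appended last (left before right); the
ordering is arbitrary but must be fixed, because it defines feature
identity downstream.

**Sex residualization.** Each edge feature is replaced by its residual
from a simple linear regression on the binary sex indicator (with
intercept), fitted once on the full cohort. For a binary covariate this
equals subtracting the subject's own sex-group mean. Residualizing
before — rather than inside — the cross-validation loop is the original
form of this analysis design; it leaks a small amount of information
across the CV boundary and is retained deliberately as the default
(`lambda_mode: full-cohort`).

**LASSO and the penalty scale.** The fit minimizes
(1/2*n*)·Σ(*y* − *b*₀ − *Xb*)² + λ·Σ|*b*|. Features are z-scored with
*training-set* statistics inside every fit (LASSO is scale-sensitive and
the procedure is otherwise ill-defined across edges of different
variance); test-set features reuse the training means/SDs, and constant
training columns are centered only. λ therefore always refers to
standardized features, with the response in raw score units.

**λ selection.** Candidate penalties are the LARS path knots of the
standardized full-cohort problem, augmented with the geometric midpoint
of every consecutive knot pair and floored at 10⁻³·λ_max. Two numerical
facts motivate the augmentation: between knots the active set is
constant but predictions still change with λ, so knots alone can be
uninformative (a one-predictor problem has a single positive knot —
λ_max itself — whose leave-one-out predictions are near-constant); and
coordinate descent at penalties near machine precision returns a dense
interpolator rather than the sparse path limit when *m* > *n* (10⁻³ is
the α_min/α_max ratio sklearn's own grids use). For each candidate, each
subject is predicted by a model fitted on the other *N* − 1 subjects
(one LARS pass per fold, evaluated at all candidates by the path's
piecewise linearity in λ); the candidate maximizing corr(*Ŷ*_loo, *Y*)
wins, ties broken toward the largest (sparsest) λ. Selection runs once
on the full cohort before the prediction CV — the published, leaky
procedure. `nested=True` (CLI `--nested-lambda`) instead re-selects λ
inside every training fold.

**Leave-ten-out CV.** Per repeat, subjects are randomly partitioned into
⌊*N*/10⌋ folds of 10 plus one remainder fold (58 → 10,10,10,10,10,8; an
exact all-tens partition is impossible at N = 58). Each fold is
predicted from the intercept and betas of a LASSO fitted on its
complement at the selected λ. The per-repeat statistic is the Pearson
correlation between the *pooled* held-out predictions and the observed
scores — pooled rather than averaged fold-wise, matching the "array of
predicted values" reading — and the reported R is the mean over 10
repeats. A repeat whose pooled predictions are constant (possible at
very large λ) scores R = 0 with a warning rather than NaN.

**Inference.** R is converted to *t* = R·√(*N* − 2)/√(1 − R²) and tested
against the upper tail of Student's t with *N* − 2 df. Testing is
one-tailed because a negative cross-validated R is not interpretable as
predictive power; a two-tailed mode exists behind a flag. Within a
hypothesis family the one-tailed p values receive the Benjamini–Hochberg
step-up adjustment, and a cell is flagged only when adjusted p < 0.05
*and* R > 0. Family membership is configuration-driven (default: one
family for the between-network grid, one for the within-network grid)
rather than hard-coded.

**Sham controls.** A sham network of size *s* is drawn without
replacement from the ROI pool, ignoring functional labels, and submitted
to the identical pipeline. Sham size is an explicit parameter: the
published control sizes (35 for a 25-ROI network's finding, 56 for the
pooled pair) are not internally consistent, so no size is assumed.

## The synthetic cohort generator

The generator emulates the study's shape — 58 subjects (30 female), 198
ROIs, 144 timepoints at TR 2.5 s — with the following model. Per
subject, a target correlation matrix has `rho_within` (default 0.3)
inside every canonical-network block and `rho_between` (default 0.05)
elsewhere; a fixed set of *k* informative edges inside one designated
network receives subject-specific deviations δₑ ~ N(0, τ²)
(`edge_sd`, default τ = 0.3). If a perturbed matrix loses positive
definiteness (detected by Cholesky failure) it is replaced by its
nearest correlation matrix via Higham's alternating projections
(tolerance 10⁻⁸). Time series are multivariate-normal draws band-limited
to 0.01–0.1 Hz by frequency-domain masking — the simplest spectral
control matching the resting-state fluctuation band; haemodynamics,
physiological noise and head motion are deliberately not modeled.

The coupled trait (default EC) is built from the same deviations: with
unit random-sign weights *w*, the latent z = *w*·δ/(τ√*k*) is exactly
standard normal, and the trait latent is √e·z + √(1 − e)·ε plus
`sex_effect`·(sex − mean), affinely mapped (subscale-typical mean/SD)
and rounded into integer 0–30 scores. With `noise_sd = 1` the population
R² between the edge deviations and the pre-rounding trait equals
`effect_size` exactly, so corr(trait, *w*·δ) ≈ √e (≈ 0.71 at e = 0.5);
rounding costs about 1%. The three uncoupled subscales are independent
latents. Item-level responses (six 0–5 items per subscale) are generated
by splitting each score into six base items and adding integer-rounded
noise; zero noise reproduces the totals exactly, and growing noise
drives Cronbach's α toward zero.

**Why the defaults are what they are.** T = 144 samples band-limited to
0.01–0.1 Hz retain ≈ 45% of the spectrum, so an edge-correlation
estimate carries noise of roughly (1 − r²)/√(0.45·T) ≈ 0.09; with
τ = 0.3 the estimated edges track the true deviations at reliability
τ²/(τ² + 0.09²) ≈ 0.92. An informative edge's correlation with the trait
is √(e·rel/k); against it stands the maximum spurious edge–trait
correlation among the *m* null edges, ≈ 0.33–0.44 at N = 58 for
*m* = 55–300. A coupling spread over many edges of a 300-edge network is
therefore *not identifiable* at this sample size — an oracle given the
true edges still predicts well, but no selection procedure can find them
— so the default designated network is the compact dorsal-attention set
(11 ROIs, 55 edges ≈ N) with *k* = 2 equally weighted edges, placing the
planted coupling (per-edge correlation ≈ 0.47) reliably above the
selection noise floor. The hard *m* ≫ *N* regime remains one
configuration switch away (`informative_network="somatomotor"`,
larger `n_informative_edges`) and is the honest reading of why, in real
data of this size, only some network–subscale cells can reach
significance.

What passing synthetic tests do **not** show: robustness to
haemodynamic variability, motion artifacts, non-Gaussian BOLD,
distributed (non-sparse) trait couplings, or site effects. The generator
establishes that the *pipeline* recovers what its own model plants, not
that real cohorts behave like the model.

## Numerical choices and degenerate inputs

- Sphere extraction uses a closed ball: voxels whose mm-center is
  exactly at the radius are included; overlapping spheres each keep all
  their voxels. Empty spheres abort with the offending ROI named.
- Zero-variance time courses abort connectivity computation (silent
  NaNs would corrupt the LASSO stage); connectivity weights are clipped
  to [−1, 1] and the diagonal forced to 1 before vectorization.
- LASSO fits run coordinate descent to tolerance 10⁻¹²; solutions
  satisfy the KKT stationarity conditions to well under 10⁻⁶. λ = 0
  falls back to least squares.
- Cronbach's α uses population variances throughout; any consistent
  convention gives the same value.
- All randomness descends from one master seed through NumPy
  `SeedSequence.spawn`: simulation, per-repeat CV partitions, sham draws
  and item noise each get dedicated children, making every table
  byte-reproducible and every cell replayable in isolation.

## Known limitations

- The full-cohort defaults (pre-CV λ selection and
  residualization) inflate R under the null relative to fully nested CV;
  the measured null inflation at the defaults is small (mean null R ≈ 0
  over 20 cohorts) but the nested mode is the statistically clean one.
- The 24-item, positively-keyed questionnaire variant is implemented as
  specified; the widely used 28-item form with reverse-scored items is
  not modeled.
- Problem sizes in the test suite and acceptance script (20 replicates
  per condition; compact networks for the recovery study) were chosen to
  make the Monte-Carlo checks sharp yet quick on a single CPU.
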