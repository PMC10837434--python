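# Methods

This note documents the models, parameter choices and numerical
conventions of `hipposcn`, and what the synthetic validation does and
does not establish.

## Synthetic generative model

Each subject `i` has two independent standard-normal latent factors:
`f_i` drives the anterior-hippocampus seed and a designated "network"
region; `g_i` drives the posterior seed. Voxel densities are

```
anterior seed:   x_v = b + λ_s f_i + ε
network:         x_v = b + λ_n f_i + ε
posterior seed:  x_v = b + λ_s g_i + ε
background:      x_v = ε,            ε ~ N(0, σ²) i.i.d., then clipped at 0
```

Defaults: baseline `b = 4.0` (arbitrary modulated-density units),
loadings `λ_s = λ_n = 0.6`, noise `σ = 0.8`, 93 subjects on a
20×24×20 lattice at 2 mm. The baseline sits 4 noise SDs above zero in
signal regions, so the non-negativity clip is a mild truncation that
effectively only bites in background (where it halves the noise mass
at exactly 0; background voxels remain exchangeable across subjects,
which is what the permutation machinery needs). The closed-form
seed–network correlation of this one-factor model, used as the
recovery oracle, is

```
ρ = λ_s λ_n / sqrt((λ_s² + σ²/m)(λ_n² + σ²))
```

with `m` the number of anterior-seed voxels (the seed mean averages
noise over `m` voxels). At the defaults (m = 280) this gives
ρ ≈ 0.598.

Geometry mirrors the MNI convention: the second lattice axis is the
anterior–posterior y axis with posterior negative, the head blobs
placed at y ∈ [−20, −8] mm, the body at [−30, −24] and the tail at
[−40, −34], so the −32/−21 mm cuts excise exactly the body. The
lattice must span roughly −44…−8 mm along y; grids smaller than 8
voxels per dimension are rejected outright, and otherwise an
informative error points at the voxel size. Hemispheres are mirrored
x bands; the network is a pair of large superior blobs so that the
latent pattern is dominated by `f`, giving the anterior-specific sign
structure the analysis is supposed to detect.

**Subject masks.** Per-subject subfield label maps equal the truth map
except at region boundaries (6-neighbour sense), where with
probability `mask_jitter_prob` a voxel's membership is re-randomized
by a fair coin (equivalently: flipped with probability jitter/2). The
re-randomization convention is chosen so that at jitter = 1 the
boundary is maximally uncertain and probabilistic-template values
converge to 0.5 there, while a plain deterministic flip would merely
invert the boundary. Interior voxels never change.

**EMA counts.** The schedule is 14 days × 5 slots, slots 2–4 probing
TR-IMs (42 TR-IM surveys, 70 total). Each slot is completed
independently with `completion_prob` (default 0.84, matching a
realistic ~35/42 completed TR-IM surveys). A completed TR-IM slot
draws a Poisson count with daily log rate `β₀ + β·z(f_i)` and the
day's exposure split equally over its three TR-IM slots. Defaults
`β₀ = log 1.5` (≈21 expected TR-IMs over 14 days) and `β = −0.105`
(IRR 0.9 per SD) put the planted cohort at the scale of a clinical
EMA sample. Follow-up duration is the span from first to last
completed survey, inclusive; it is exactly 14 when completion is
full. All randomness flows from a single `rng_seed` through spawned
seed sequences, so identical configurations reproduce cohorts
bit for bit.

## Template construction

Template values are exact rationals k/n (k = number of subjects whose
mask contains the voxel). Thresholding at probability `p` keeps
voxels with value ≥ p, implemented on the integer counts
(`k ≥ ceil(p·n)` with a 1e−9 guard) so that exact fractions like
70/93 at p = 0.75 behave as printed arithmetic dictates (70/93 kept,
69/93 dropped). Thresholding is idempotent, and with zero jitter the
thresholded template reproduces the truth region at any threshold.

Longitudinal-axis cuts use the voxel-centre y coordinate and are
inclusive on both criteria (posterior keeps y ≤ −32 mm, anterior
y ≥ −21 mm), so the printed criterion coordinates themselves are
retained. Membership by voxel centre is the simplest defensible
convention; partial-volume alternatives would change nothing on the
axis-aligned grids used here. The cut is applied after probabilistic
merging and thresholding; because it is a per-voxel restriction along
a fixed axis, it commutes with both, so the order (which the
analysis-rule description leaves open) is immaterial. Hemispheres are
split by the sign of the voxel-centre x coordinate.

## Morphometry

Subregion volume is the sum of in-mask densities (mean density ×
voxel count per hemisphere, left + right — the two forms are
algebraically identical and tested as such). Volumes are reported in
density-weighted voxel units; multiplying by the voxel volume gives
density-weighted mm³ when physical units are wanted.

The analysis mask keeps voxels whose across-subject mean density
exceeds a cutoff, default 0.1 — the conventional gray-matter
probability cutoff; no principled value exists for the synthetic
density scale, so the default is a documented, configurable surface.
On the default synthetic cohort the background's clipped-noise mean
(≈0.32) exceeds 0.1, so the mask is the full grid; this is harmless
(background voxels carry ~0 salience) and keeps the seed regions in
the matrix.

Smoothing is isotropic Gaussian, σ = FWHM/(2√(2 ln 2)) per axis in mm
converted through the affine's voxel sizes, default FWHM 8 mm (the
standard VBM choice), boundary mode half-sample-symmetric mirroring
(conserves total mass to float precision), kernel truncated at 6σ so
truncation error stays below 1e−6.

## Seed-based non-rotated PLS

The association between seed means and voxels is Pearson correlation
by default. The cited methodology says "covariance", but the standard
toolbox practice is cross-correlation; a `covariance` option exists
and the default is pinned throughout the tests. The matrix and all
resampling inference use unsmoothed images (as stated for the seed
means); brain scores use smoothed images (as stated for score
computation). This asymmetry is deliberate and documented here.

The a priori contrast is normalized to unit length; saliences are its
projection of the association matrix and the singular value their
Euclidean norm. Zero-variance voxels get association 0 and a flag;
a zero-variance seed is an error.

*Permutation test*: the seed table's subject rows are permuted
(without replacement) relative to the voxel matrix; p is the plain
proportion of permuted singular values ≥ observed (the toolbox
convention; p = 0 is possible), with an optional
`(count+1)/(n_perm+1)` variant. *Bootstrap*: subjects resampled with
replacement, saliences recomputed per replicate under the fixed
contrast — no per-replicate re-standardization or sign correction is
needed precisely because the contrast is fixed a priori. The
bootstrap SE is the across-replicate SD (ddof = 1); BSR = salience /
SE, NaN (and flagged, never reportable) where the SE is 0. Reliability
threshold |BSR| ≥ 3.3 (≈ two-tailed p = 0.001) and the ≥100-voxel
cluster reporting rule are the analysis defaults; clusters are
connected components per sign (default 26-connectivity), peak = voxel
of maximal |BSR|, reported in mm.

**Calibration caveat.** The seeds' own voxels stay inside the
voxelwise matrix (the reported hippocampal peaks imply inclusion).
Because the seed means are computed from those same voxels, the
"no-association" null is false for the seed columns even when no
structure is planted — the seed mean tautologically covaries with its
constituents — so a global-null rejection rate over the full matrix
exceeds α (measured ≈0.15 at α = 0.05 on small null cohorts). This is
the permutation test correctly detecting a real (if trivial)
association, not a defect; calibration of the machinery is therefore
assessed on the non-seed columns, where the null genuinely holds and
the p-value is uniform (KS and binomial checks in the acceptance
suite). Users comparing a global-null reference should be aware the
observed statistic always carries this seed-self-covariance
component.

## Poisson count models

Fitting is iteratively reweighted least squares via statsmodels GLM
(Poisson family, log link), relative tolerance 1e−8, at most 100
iterations, offset log follow-up days; non-convergence is flagged on
the result, never silent. Continuous predictors are standardized to
mean 0, SD 1 (sample SD) so coefficients are per-SD log-IRRs; binary
predictors (e.g. sex) are centered but not scaled — "one unit = one
SD" reads naturally for continuous variables only, and the convention
is configurable. IRR CIs are exp(β ± 1.96 SE). Nagelkerke R² is
R²_CS/(1 − exp(2 ll₀/n)) with R²_CS = 1 − exp((2/n)(ll₀ − ll)); a
model log-likelihood below the null's is rejected as a numerical
pathology. Overdispersion is not modeled (plain Poisson, matching the
analysis being implemented), but the Pearson dispersion statistic is
reported for transparency. The model ladder mirrors the analysis
design: aHPC-volume and pHPC-volume models, the brain-score model,
and the brain-score model with the CAPS-5 composite (non-intrusion
symptom severity) as a sensitivity covariate.

## Pipeline determinism and problem sizes

`run_all` is a pure function of its configuration: stage seeds are
spawned deterministically from the global `rng_seed`, reports carry a
config hash and a report hash, and identical configurations reproduce
identical hashes. Stages raise stage-named errors and (in CLI use)
retain partial outputs.

Validation problem sizes were chosen so the full suite runs in a few
minutes on one CPU while keeping each check well-powered: null
calibration uses 200 replicate cohorts of 50 subjects on a coarse
12×16×12 / 3 mm lattice with n_perm = 200; CI coverage uses 400
replicate count cohorts at n = 200; IRR recovery uses one cohort at
n = 1000 (Wald SE ≈ 0.007 on the log scale, bracket [0.87, 0.93]);
the PLS oracle comparison uses 50 subjects × 5000 voxels at 1e−10.

## What the synthetic validation does not show

The generator is a one-factor linear-Gaussian model on box-shaped
regions: it contains no registration error, scanner artifact,
cortical anatomy, spatial noise correlation, age/sex effects on
morphology, or overdispersed counts. Passing tests therefore
establish that the estimators recover what they claim under their own
assumptions — correct linear algebra, calibrated resampling
inference, correct offset handling — not that those assumptions hold
in real imaging cohorts. Real-data effect sizes (e.g. a brain-score /
anterior-volume correlation of ~0.6 rather than the ~0.99 of the
planted cohort, or pseudo-R² values) depend on anatomy and cohort
composition and are only reproduced here in sign and ordering, by
design.
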