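# Methods

This note documents the statistical model, the synthetic cohort the tests
run on, and the numerical and design choices that were genuinely open.

## Signal model

The infusion response is modelled as a ramped unit step `u(t)`: 0 for
t ≤ 300 s, `(t − 300)/480` for 300 < t < 780 s, and 1 afterwards. The
timing encodes the administration protocol: the infusion scan starts with
the pretreatment (saline or antagonist) infusion, the drug itself starts at
5 min and is delivered in divided boluses until 13 min, after which its
effect is assumed to plateau. The EV is not convolved with a hemodynamic
response function: the response evolves over minutes, so the ~6 s HRF is
negligible relative to the ramp. Each voxel is fit by OLS with Gaussian
errors:

    y = a·u + SVD onset regressors + drift + WM + CSF + intercept + ε

`a` (the "amplitude") is the statistic of interest. No autocorrelation
model (prewhitening) is applied; with a 598-frame series and interest in a
single slow regressor, OLS amplitude estimates are unbiased and the group
level inference rests on between-subject variance anyway. Temporal
high-pass filtering is deliberately absent everywhere — it would remove the
signal itself.

### Onset-uncertainty (SVD) regressors

The true ramp onset varies with local pharmacodynamics. We build the family
of ramps shifted by −60…+60 s in 15 s steps, residualize each against
span{nominal EV, intercept}, and take the top k = 3 left singular vectors.
These columns are orthonormal and exactly orthogonal to the nominal EV and
intercept, so they cannot change the amplitude fitted to on-time responses,
but they absorb the component of an onset-shifted response that the nominal
EV misses; in simulation (+60 s true shift, unit noise) they cut the
amplitude bias by half or more. The ±60 s / 15 s / k = 3 family is this
package's concrete construction for an approach whose published recipe is
not fully specified; all three knobs are configurable.

### t→z conversion

t statistics are mapped to z scores by matching tail quantiles through the
survival function, which keeps precision far into the tail; the map is odd
and monotone, and |z| is clipped at 8 (beyond any plausible inference
boundary; also caps the noiseless phantom's infinite t values).

## Group model

Each subject contributes one amplitude map per condition; inference is the
classical paired t test on within-subject differences with n − 1 degrees of
freedom, z-transformed as above. This replaces a Bayesian mixed-effects
variance model with its classical equivalent for a paired design — the
design matrix is identical, and with 13 subjects the practical difference
is the variance shrinkage, not the estimand. Group inference runs inside
gray matter: that is where the BOLD effects of interest (and the phantom's
planted responses) live.

## Mixture/MRF inference and PPMs

The group z map is modelled as a K = 3 Gaussian mixture — deactivated,
null, activated — because infusion contrasts genuinely show responses of
both signs; a 2-class model cannot represent that. Class labels carry a
soft-max MRF prior

    p_k(v) ∝ π_k · exp(β · m_k(v)),

with `m_k(v)` the number of 6-connected in-mask neighbors labelled k and
β ∈ [0, 5] the coupling. Estimation is hard-label ICM:

1. **Init**: null class at the median and 1.4826·MAD of the in-mask z
   values (robust against heavy activation tails — a trimmed sd breaks once
   the activated fraction exceeds the trim), alternative classes at
   ±(2 + s₀) with sd 1 and mixing 0.05, labels by nearest mean, β = 0.
2. **M-step first**: class moments/weights are re-estimated from the
   initial labels *before* the first sweep. Sweeping with the crude init
   parameters would destroy the init labels whenever the init null sd is
   inflated (a broad null outcompetes a tight activated class far in the
   tail).
3. **Label sweep**: raster-order greedy update, each voxel taking
   argmax_k prior×likelihood. Raster order is fixed; ICM is order-dependent,
   so the order is part of the contract. At fixed parameters each sweep
   cannot decrease the joint pseudo-posterior (Σ log π + β·#same-label
   edges + Σ log N); this is asserted at run time and recorded per sweep.
4. **Parameter updates**: weighted ML from the hard labels, σ floored at
   0.05; a class that loses all members is removed. β is re-estimated by
   maximizing the Besag pseudo-likelihood of the label field with a bounded
   1-D search.
5. **Stop** when a sweep changes no label (and β has stabilized) or after
   `max_sweeps` (default 50).

After convergence an **identifiability guard** runs: an alternative class
whose fitted mean lies within `sqrt(2 ln V)` fitted null standard
deviations of the null mean (the universal threshold for the extremes of V
null draws) is absorbed back into the null class. Without it, a
hard-assignment mixture on a signal-free field parks a small class on the
null tail (class mean ≈ 3σ for a few thousand voxels) and produces ~1%
false detections; planted effects in this package's simulations sit at
z ≈ 6–8 and are unaffected. The cost is deliberate conservatism: a real but
weak effect whose class mean stays inside the universal threshold is
declared null.

PPMs condition on the converged hard labels: `ppm_k(v)` is the normalized
`prior_k(v)·N(z_v; μ_k, σ_k²)` with the prior taken at the final label
field. Detection uses the strict rule PPM > 0.5 (a voxel at exactly 0.5 is
excluded). With β = 0 the whole machine reduces exactly — to machine
precision, verified against an independently coded oracle — to a
non-spatial hard-EM Gaussian mixture.

## Functional connectivity

Only the last 5 minutes of the scan are analyzed (drug steady state;
`⌊300/TR⌋ = 120` frames). The seed timecourse is the mean over the seed
ROI. Each gray-matter voxel's partial correlation with the seed given
intercept, within-window linear drift, and within-window WM/CSF mean
timecourses is computed by residualizing both series against the nuisance
matrix and correlating the residuals; this is algebraically identical to
the inverse-covariance partial correlation, and the test suite checks both
routes agree to 1e-10. r is clipped at 1 − 1e-7 before the Fisher
transform `z = atanh(r)`. Under the null, `var(atanh r) ≈ 1/(n − q − 3)`
with q = 3 conditioned regressors — the intercept is absorbed into the
conventional −3 (mean removal); the suite verifies this within 10%. Group
inference reuses the paired contrast and mixture/MRF engine on the
Fisher-z maps.

## Cluster reporting

Detection masks are decomposed into connected components at 26-connectivity
(the usual reporting convention — distinct from the MRF's 6-neighborhood,
which is a model choice). Each cluster reports its |z| peak (ties broken by
lowest linear index), the peak's world coordinates via the affine,
laterality (x > +2 mm → R, x < −2 mm → L, else B — a ±2 mm midline band),
voxel count, and volume = n·voxelvolume/1000 cm³ exactly. Tables list
increased responses before decreased ones, ordered by peak y descending
within sign. The reporting voxel size follows the map's affine; published
tables in this literature are typically at 2 mm isotropic after standard
space resampling, which is why the test values use 2 mm voxels.

## The synthetic cohort

The phantom emulates the study conditions: a randomized two-condition
crossover with 13 subjects, TR 2.5 s, 600 volumes (25 min), 3.5 mm
isotropic voxels, desk-scale 20×20×10 grid (64×64×41 via config). The
"brain" is a concentric ellipsoid — WM core, GM shell, CSF rim — at
baseline 1000 arbitrary units; planted amplitudes are absolute additive
units on that scale so GLM estimates compare directly to truth. Per
session, voxel series are baseline + planted ramp(s) + per-session linear
drift (slope ~ N(0, 2) units/scan) + AR(1) compartment nuisances (sd 2,
lag-1 0.95; full amplitude in WM/CSF, 0.3× bleed into GM so the covariates
have real work to do) + white Gaussian noise (sd 1). The default planted
activation is a 78-voxel gray-matter patch at amplitude 1.5 in condition A
only — a strong, clearly detectable effect; the true BOLD magnitude of any
particular drug is not calibrated here.

Two phantom design rules came out of failure analysis and are deliberate:

- **Planted signals live in gray matter.** A planted response overlapping
  the WM/CSF compartments leaks into the nuisance regressors and induces a
  global negative bias in everything regressed against them — the classic
  signal-in-nuisance artifact (cf. global signal regression).
- **The seed's intrinsic fluctuation exists in both conditions; only the
  target's coupling to it is condition-specific.** Injecting the latent
  signal into the seed in one condition only changes the seed's variance
  between conditions and biases its correlation with the entire brain.

The seed network: a caudate-like 26-voxel GM seed and a 132-voxel GM
target, sharing a latent N(0,1) timecourse (coupling 1.5) during the final
5-minute window, in condition A only. Detection is evaluated by Dice
overlap with the planted masks; the 5 mm smoothing kernel spreads true
signal about one voxel beyond each planted boundary, which bounds the
achievable Dice and is why planted regions are sized a few smoothing
widths across.

What the phantom does **not** emulate: head motion, spin-history and
scanner artifacts, physiological noise spectra, subject-specific anatomy
and registration error, and any real pharmacokinetics beyond onset jitter.
Passing tests therefore demonstrate the correctness and calibration of the
estimators on data satisfying their assumptions, not robustness to the
full mess of real acquisitions (motion correction, brain extraction and
registration are out of scope and assumed done upstream).

## Determinism and problem sizes

One root seed sequence per cohort is split per subject by counter, then per
condition, making outputs bit-identical across runs and independent of
generation order. NIfTI gzip members are written with mtime 0 so pipeline
reruns are byte-identical. Simulation-based checks use 200 replicates for
amplitude recovery, 1000 for null-z calibration, 2000 voxels × 13 pairs
for paired-contrast calibration, and 5000 replicates for Fisher-z variance
— sizes at which the Monte-Carlo error is a small fraction of each
tolerance. The full desk-scale pipeline runs in about a minute on one CPU.

## Known limitations

- No prewhitening: single-subject z maps are mildly miscalibrated under
  strong temporal autocorrelation; group inference is unaffected.
- Hard-label ICM finds a local optimum; the raster order is fixed for
  reproducibility rather than optimality.
- The universal-threshold class guard trades sensitivity to weak diffuse
  effects for null calibration.
- Laterality is a peak-voxel property; a truly bilateral cluster with an
  off-midline peak is labelled by its peak.
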