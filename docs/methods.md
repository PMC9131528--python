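# Methods

This note records the models, estimators, defaults and numerical choices
behind `anxnet`, and what the synthetic-data tests do and do not establish
about behaviour on real data.

## Morphometry

**Model.** Atrophy is the annualized two-timepoint thickness change,
`(CT_fu − CT_bl)/Δt` in mm/yr (negative = thinning); subcortical volumes can
be treated identically. The symptom association per region is the partial
Pearson correlation of the atrophy rate with the score given age and sex:
both sides are residualized on `[1, age_centered, sex]` (age centering is
numerical hygiene only and does not change r), then
`t = r·√((n−k−2)/(1−r²))` with k = 2 covariates and a two-sided p from the
t(n−k−2) reference distribution. Listwise deletion handles missing rows.

**Sign convention.** The atrophy rate is kept signed, so "more thinning with
higher anxiety" appears as a *negative* r on the rate; detection is
two-sided and no sign is hard-coded. To emulate the clinical direction,
pass a negative `r_pop` to the generator; the magnitude is what the power
analyses use.

**FWE correction.** Symptom scores are permuted across subjects (covariates
stay attached to their subjects, valid because under the null the score is
exchangeable); each permutation recomputes all adjusted correlations.
Suprathreshold regions (two-sided p < 0.05 by default, configurable) are
grouped into sign-homogeneous connected clusters under a user-supplied
region adjacency; cluster mass is Σ|t| and each observed cluster is referred
to the permutation null of the *maximum* mass:
`p = (1 + #{null ≥ obs}) / (1 + n_perm)`. With no adjacency every region is
its own cluster, which reduces to max-|t| correction. Ties in |t| cannot
affect membership (clusters are defined by the threshold), and region order
is fixed by region id for reproducibility.

**What the calibration shows.** Under fully null synthetic cohorts
(n = 92, 68 regions, 500 permutations) the measured family-wise error is
0.05 to within binomial sampling error. Power at the study scale is
modest: a single planted region at population r = 0.3, n = 92 reaches the
uncorrected p < 0.05 level in ~80% of replicates but survives 68-region
max-mass correction in well under half of them — a direct consequence of
the max-statistic null (95th percentile near |t| ≈ 4) against a noncentral
t with mean ≈ 2.9. Region-count and effect-size combinations where a single
planted region is reliably (≥ 90%) recovered require |r| around 0.5 at this
n; the acceptance suite reports the measured rate at r = 0.3 unchanged.

## Atrophy network mapping

**Preprocessing** (optional; synthetic BOLD is already stationary): spatial
Gaussian smoothing with σ = FWHM/(2√(2 ln 2)) converted to voxel units
(default FWHM 6 mm at 3 mm voxels), OLS residualization on confounds plus
intercept (collinear columns dropped with a warning), then a zero-phase
4th-order Butterworth bandpass, default 0.01–0.08 Hz (the filter family is
our choice; only the passband is prescribed by the emulated design).
Passbands are validated against the Nyquist rate 1/(2·TR).

**Connectivity and group map.** The seed time course is the unweighted mean
over seed voxels; per-voxel Pearson correlations are Fisher-transformed with
|r| clamped at 1 − 1e−7 before `atanh` (self-correlated voxels thus get a
large finite z). The group map is a one-sample t of z against 0 with
voxel-wise listwise deletion; a zero-variance voxel with non-zero mean is
assigned ±∞ and survives. FWE is Bonferroni across in-brain voxels — the
conservative exact choice; random-field corrections are out of scope. The
binary map is two-sided by default (`|t| > cutoff`), one-sided optionally.
An atlas summary ranks regions by suprathreshold fraction and peak |t|.

**Emulation.** The normative sample is emulated as modular voxel grids:
voxels of a module load on a shared latent with weight √ρ, giving pairwise
within-module correlation ρ and zero correlation elsewhere; optional AR(1)
smoothness is re-standardized to keep ρ. Real BOLD has spatial
autocorrelation, global signals, motion and physiological structure that
this generator deliberately omits — the recovery tests (Dice ≥ 0.8 at
ρ = 0.4, 50 subjects, 15³ grid) validate the inferential chain, not
robustness to realistic confounds.

## Effective connectivity

**MVAR estimation** is multivariate least squares on the stacked lag
regression (channels demeaned; residual covariance with denominator
n_eff − c·p). This approximates the stepwise least-squares of classical
autoregressive-fit toolboxes; for the long, well-conditioned signals used
here the difference is negligible. Order selection minimizes Schwarz's
Bayesian criterion `ln|Σ̂_p| + c²p·ln(N)/N` over a common effective sample.

**PDC / TPDC.** The original column-normalized PDC is used:
`π_{i←j}(f) = |Ā_{ij}(f)|/√(Σ_m |Ā_{mj}(f)|²)`, which satisfies
`Σ_i π_{i←j}(f)² = 1` exactly (machine precision; verified to 1e−10 over
random stable models). TPDC is sliding-window PDC (default window 2 s, step
0.5 s) averaged across windows, then across band grid points (1-Hz default
grid; theta 4–7 Hz, gamma 30–70 Hz). Windowed averages carry a small Jensen
bias relative to the full-signal PDC (the tests bound it at ~0.1).

**Bootstrap threshold.** The record is cut into non-overlapping shuffle
windows (default 1 s); each replicate permutes the window order — one
permutation applied to all channels — refits the windowed MVAR chain and
recomputes band-averaged TPDC. The default decision threshold is the mean
of all off-diagonal null values per band, one global threshold for all
connections. Because the common permutation preserves within-window
cross-channel structure, this null is *not* coupling-destroying: the
threshold acts as a grand-mean cutoff that strong connections exceed and
absent ones fall below. The stricter per-connection 95th-percentile
thresholds are returned alongside and are used in the white-noise
calibration test. Both conventions are deterministic given the seed.

**Time reversal.** A connection passes only if it exceeds the bootstrap
threshold *and* its net direction `π_{i←j} − π_{j←i}` (band-averaged) flips
sign when the samples are reversed. For the moderately damped planted
models used in the tests this flip is essentially certain; a known
limitation is the near-unit-resonance regime (oscillator pole radius
≳ 0.9), where the source column's diagonal term `|Ā_jj|` collapses at the
resonance frequency, PDC saturates toward 1 in both time directions and the
flip heuristic loses power. The generator's default pole radius is 0.8
(chosen by pilot simulation of the model class) to represent physiological,
moderately damped band-limited rhythms.

**DICS.** With sensor cross-spectral density C (Welch average over the
band, Hann window, 50% overlap) and lead-field column l, the unit-gain
filter is `w = C_r⁻¹l / (lᴴC_r⁻¹l)` with `C_r = C + λ·mean(diag C)·I`
(default λ = 0.05); source power is `Re(wᴴCw)` and the filters extract
source time courses. λ → ∞ flattens power toward lead-field norms; λ = 0 on
a singular C raises an error advising regularization. Lead fields are
inputs (forward modelling is out of scope); the synthetic stand-in is a
random full-rank unit-column-norm gain matrix.

**Group comparison** is a fixed-effects two-factor ANOVA (group,
connection) with type-II sums of squares via statsmodels, plus per-
connection two-sided pooled-variance t tests.

## SEM

Observed-variable path analysis only (the emulated models relate measured
volumes to a measured score). With path matrix B and exogenous/residual
covariance Ψ, `Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ`; acyclicity is validated by
topological sort. Exogenous covariances are free by default (lavaan-style
saturated exogenous block) and can be fixed to zero in the model text
(`x ~~ 0*y`), which is how the df = 3 calibration model is built.

Fitting minimizes F_ML by L-BFGS-B with variances bounded at 1e−8, started
from recursive-OLS values computed directly from S (near-exact for
recursive models, making the optimization a polish step), with up to five
seeded multiplicative-jitter restarts; non-PD Σ(θ) excursions are handled
by a smooth penalty. Convergence is reported via the gradient norm.
`χ² = (n−1)F_min` with covariance denominator n−1. RMSEA is defined as 0
for a saturated model (with a warning); AIC uses the χ² + 2·#free
convention, appropriate for comparing models of one dataset (an
alternative −2lnL-based value would differ by a data-dependent constant).
Standardized coefficients use implied SDs, so a unit change in one
variable's scale divides its raw coefficient and leaves s invariant
(tested). Calibration: at n = 5000, path estimates recover the generating
standardized weights within ±0.05 per replicate, the saturated model yields
χ² ≈ 0, and the correctly specified df = 3 model has RMSEA < 0.05 in ≳ 99%
of replicates; χ² follows its nominal χ²(df) rejection rate at n = 2000.

## Task EEG

Epochs are cut on half-open sample windows `[cue + round(tmin·fs),
cue + round(tmax·fs))` — 1750 samples at 250 Hz for −2..+5 s; boundary
trials are dropped with a logged count, and the kept + dropped bookkeeping
is preserved across the chain. TMS excision removes samples
`[tms − round(pre·fs), tms + round(post·fs)]` inclusive: 7 samples (28 ms)
at 250 Hz for the 5/20 ms defaults — the integer-sample quantization of
the nominal 25 ms window; `mode="interpolate"` replaces the span by linear
interpolation instead (exact on locally linear signals). Shock-flagged
trials are removed before statistics. Average re-referencing subtracts the
across-channel mean per sample (idempotent; residual channel means at
machine precision). Band power is the squared analytic-signal envelope of
the zero-phase 4th-order Butterworth bandpassed data (multitaper would be a
drop-in alternative; the envelope of an in-band sinusoid of amplitude a is
a² up to edge effects), averaged across trials per condition.

The cluster test uses pointwise pooled-variance two-sample t values,
two-sided cluster-forming threshold p < 0.05, clustering by channel
adjacency × temporal contiguity split by sign, mass Σ|t|, and a max-mass
permutation null over group-label reassignments (exact enumeration replaces
sampling when feasible, logged). Observed t maps and cluster masses agree
with mne-python's implementation on shared inputs (tested). Calibration:
empirical FWE 0.046 over 500 null datasets (32 channels × 100 points,
15 vs 15 subjects, 500 permutations); a planted +1 SD mean shift on a
6-channel × 30-point block (pilot-calibrated SNR) is detected in 100% of
datasets.

**Emulation.** The task generator produces broadband noise plus band-limited
theta/gamma components, cue events with threat/safe labels, 33% shock flags
on threat trials, condition-dependent amplitude multipliers in chosen
windows/channels, and a decaying-exponential TMS-like burst 1 s after each
cue (its exact shape is irrelevant because the pipeline excises the
window). It does not emulate electrode geometry, ocular/muscle artifacts,
or TMS decay tails beyond the excision window — ICA-based cleanup is out of
scope by design.

## Problem sizes used by the acceptance script

PDC identity: 100 random stable models (2–5 channels, order 1–3). Worked
PDC example: exact. TPDC recovery and time reversal: 20 seeds × 30 000
samples at 125 Hz, 200 bootstrap replicates (scaled down from the 1000
used as the analysis default). Morphometry FWE: 200 null cohorts
(92 × 68) × 500 permutations; planted-region detection: 50 cohorts at
r = 0.3 × 1000 permutations. Network mapping: 50 subjects, 15³ grid,
ρ = 0.4, 124 frames. SEM: 50 replicates at n = 5000. EEG cluster test: 500
null datasets × 500 permutations, 20 planted-effect datasets. DICS: 20
seeds, 64 channels, 3 candidate sources. All randomness derives from the
single `--seed` via `numpy.random.SeedSequence` fan-out.

## Known limitations

- Surface-based vertex analysis, FreeSurfer/SPM preprocessing, ICA artifact
  removal, FEM head modelling and realistic physiological noise are out of
  scope; inputs are assumed already aligned on a common grid.
- The global mean bootstrap threshold is a crude separator by construction
  (see above); use the per-connection percentile mode when absolute
  false-positive control per connection matters.
- PDC saturation near sharp resonances weakens the time-reversal check.
- Power of the region-level max-mass correction at n ≈ 92 over 68 regions
  is limited for |r| ≲ 0.4 (see Morphometry); vertex-level designs with
  large contiguous clusters behave differently.
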