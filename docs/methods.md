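# Methods

This note documents the models implemented in `dcgradient`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Signal model and preprocessing

Recordings are multichannel fNIRS time series over the prefrontal
cortex: per channel, oxygenated (HbO) and deoxygenated (HbR) hemoglobin
concentration changes sampled at 10 Hz for 12 minutes (7200 samples).

**Modified Beer–Lambert law.** Raw dual-wavelength intensities are
converted channel-wise via ΔOD(λ, t) = −log10 I(t)/I₀ with I₀ the
temporal mean intensity of the recording, then the 2×2 system
ΔOD = d · DPF(λ) · ε(λ, ·) · [ΔHbO, ΔHbR]ᵀ is solved per sample.
Defaults: wavelengths 695/830 nm, source–detector distance d = 3 cm,
DPF = 6.0 at both wavelengths, instrument-typical extinction
coefficients in 1/(mM·cm); all overridable in `OpticsConfig`. Because
I₀ is the temporal mean, the conversion fixes a per-channel baseline
gauge; the simulator's inverse (`generate_raw_intensities`) is exact up
to that gauge, which is immaterial for Δ-quantities and removed by
standardization.

**Channel repair.** Signal-free channels are replaced sample-wise by
2-D spatial interpolation over the good channels at the grid
coordinates: linear barycentric interpolation (exact for fields linear
in the coordinates) with nearest-neighbor fallback outside the convex
hull. At study scale this machinery touches about 0.6% of channel
slots (15 of 2432).

**Motion-artifact correction (CBSI).** Motion moves HbO and HbR in the
same direction, whereas hemodynamics moves them oppositely. With
x = ΔHbO, y = ΔHbR and α = sd(x)/sd(y), the corrected signals are
x′ = (x − αy)/2 and y′ = −x′/α. The output is perfectly anticorrelated
by construction (asserted to 1e−12), the transform is idempotent, and a
shared artifact orthogonal to the true signal with equal SDs cancels
exactly. Correction is channel-wise.

**Standardization.** Each channel is brought to mean 0 and SD 1
(ddof = 1). The fixed pipeline order is interpolate → CBSI →
standardize; no filtering, detrending, or resampling is applied
anywhere before model fitting, since such smoothing is known to create
spurious Granger-causal structure. The relative order of
standardization and channel repair is a convention; interpolate-first
is the one this package fixes.

## Directed coherence

Each measurement is modelled as a VAR(p) process, default p = 20
(a 2 s lag window at 10 Hz), fitted by per-equation ordinary least
squares on the standardized HbO traces (after CBSI, HbR is proportional
and spectrally identical). One joint VAR over all 32 analyzed channels
is the default (7200 samples against 640 regressors per equation);
per-hemisphere fitting is available by configuration. The residual
covariance Σ is the innovation covariance estimate. Instability of a
*fitted* model (companion spectral radius ≥ 1) is a recorded warning,
not an error, because short empirical fits can be borderline; a cheap
power-iteration screen avoids paying for an exact eigendecomposition on
every fit.

The transfer function H(f) = [I − Σₖ Aₖ e^(−i2πfk/fs)]⁻¹ is evaluated
on the grid obtained by zero-padding the coefficient sequence to the
length of the fitted series (grid spacing fs/7200 ≈ 0.0014 Hz; the
native resolution of the estimate remains fs/p = 0.5 Hz). Directed
coherence from source j to sink i is the noise-weighted, sink-normalized
transfer magnitude

  γᵢⱼ(f) = σⱼ Hᵢⱼ(f) / sqrt(Σₘ σₘ² |Hᵢₘ(f)|²),   σₘ = √Σₘₘ,

so Σⱼ |γᵢⱼ(f)|² = 1 per sink and frequency (checked to 1e−10). The
reported value per ordered pair is max |γ| over 0.06–0.12 Hz, edges
inclusive — the low-frequency band where hemodynamic coupling is
expressed while respiratory and cardiac bands are avoided. The
magnitude |γ| (not |γ|²) is reported; both lie in [0, 1] and order
identically, and the unweighted (DTF-style) variant is available via
`noise_weighted=False`.

## Network extraction

The analyzed montage is, per hemisphere, 4 rostro-caudal streams of 4
channels (levels; 1 = most rostral) on a diamond lattice with 3 cm
optode spacing, hence 2.1 cm diagonal channel distance. Only directly
neighboring level pairs within a stream enter the statistics: 12
connections per hemisphere, each in two directions (rostro-caudal =
influence from lower onto higher level), 48 rows per measurement.
Hemispheres are relabelled ipsi-/contralateral with respect to the
hemisphere of disease onset; the onset *hemisphere* is taken as
contralateral to the first symptomatic body side, and the mapping is
explicit in `label_hemispheres`. Participants without a recorded onset
side cannot be labelled and must be excluded, mirroring the cohort
handling. Tercile splits of covariates are provided for summaries only
and never enter the models.

## Mixed-effects models

Connection-level DC values are modelled with linear mixed models fitted
by maximum likelihood, with random intercepts for participant × stream
(streams hemisphere-specific, 8 per participant) and participant ×
level-pair, never reduced. Model 1 crosses direction × hemisphere ×
stimulation state with each of five covariates (age at onset, disease
duration before implantation, time since implantation, LEDD, VAT);
Model 2 is direction × state × duration-before-implantation on the
three-state data (ON/OFF/ON2). Sum-to-zero contrasts are used, as
required for meaningful Type III marginal tests; covariates enter
untransformed by default (a centering switch exists because interaction
interpretation depends on it).

**Estimation.** The variance structure is a plain variance-components
model, so the likelihood is profiled analytically over the fixed
effects and the residual variance, leaving only the variance *ratios*
γₖ = τₖ/σ². All quantities are computed from crossproduct matrices via
the Woodbury identity, making one likelihood evaluation O(q³) in the
number of random-effect levels and independent of the row count, and a
full fit a 2-parameter bounded quasi-Newton problem. This is what makes
the Monte-Carlo calibration suites (hundreds of fits) tractable. The
implementation is cross-checked in the test suite against statsmodels
`MixedLM` (log-likelihood, estimates) and against frozen values from R
`lmerTest`/`emmeans` on a deterministic fixture.

**Type III tests and degrees of freedom.** With sum coding and all
marginality-respecting lower-order terms present, the Type III
hypothesis for a term is that its own design columns vanish; the Wald F
statistic uses the GLS covariance of the fixed effects. Denominator
degrees of freedom follow Satterthwaite's approximation: the covariance
of the variance parameters is the inverse observed information of the
profiled log-likelihood in log-variance coordinates (central finite
differences, relative step 1e−4), and for a contrast ℓ,
ν = 2(ℓᵀVℓ)²/(gᵀAg) with g the gradient of ℓᵀV(θ)ℓ. Multi-df terms use
the eigendecomposition construction (independent 1-df contrasts, pooled
by ν = 2E/(E−q) with E = Σ νᵢ/(νᵢ−2)). Variance components estimated at
the zero boundary are excluded from θ and flagged; if the information
matrix is not positive definite the residual df are used as a labelled
fallback.

**Reduction.** Top-down: at each step the currently maximal (non-nested)
interaction terms are tested; among those with p > α (default 0.05) the
largest-p term is removed — one term per refit — until every maximal
term is significant. Main effects are never removed, so marginality
holds in every intermediate model; the full history is recorded.

**Post hoc.** Least-squares means average model predictions over
non-focal factor levels with covariates at their data means; simple
slopes are exact derivatives of the linear predictor within factor
cells. Pairwise comparisons use Tukey's studentized-range adjustment at
the family size of the cell grid, with Satterthwaite df per contrast;
confidence bands are pointwise 95% (non-simultaneous). Multicollinearity
is screened with VIFs computed from the fixed-effects design (flag
threshold 5, configurable). Control refits substitute (I) overall
disease duration for the pre-/post-implantation pair and (II)
chronological age for all three time covariates, rerunning the same
reduction.

## Synthetic-data generator

No real recordings ship with this package, so the generator defines the
acceptance surface. It emulates:
24 participants; sessions ON (n = 24), steady-state OFF (n = 22) and
ON2 (n = 18) with nested, seed-deterministic dropout; 12-min, 10 Hz
recordings on the 32-channel analyzed grid (38-channel montage
optional); covariates from zero-truncated normal distributions with the
pre-implantation duration engineered to correlate 0.79 with the overall
disease duration (the generating bivariate correlation is solved
numerically from the target); and motion artifacts that move HbO and
HbR with a common sign.

**Signal architecture.** Signals come from a generative VAR so that the
analysis model class contains the generator. Every channel carries an
AR(2) resonance centered at 0.09 Hz (pole radius 0.90) — band-limited
Gaussian activity inside the 0.06–0.12 Hz analysis band rather than a
pure sinusoid, whose spectrum would be degenerate. Neighboring levels
within a stream are coupled at a 3-sample lag. Coupling strengths are
parametrized in units of the resonance peak gain (κ = raw coefficient ×
peak |H|): on this scale adjacent-pair DC responds like κ/√(1+κ²), so
κ ≈ 1 sits on the sensitive part of the detection curve, and reciprocal
coupling is stable when κ_rc·κ_cr stays well below 1 (chain resonances
tighten the pairwise bound by ≈ 1.6×, and a saturation ceiling of
κ = 2.2 per connection keeps extreme covariate combinations inside the
stable region; stability is asserted at generation and refused with the
spectral radius otherwise). HbR = −HbO exactly until artifacts are
injected.

**Injected effects (defaults, κ units).** Caudo-rostral base 0.10;
direction effect +0.75; stimulation × direction +0.20 (ON states);
stimulation × direction × duration −0.35 per SD of pre-implantation
duration (z-scores clipped at ±2); VAT × direction and LEDD × direction
+0.15 each; participant × stream and participant × level-pair gain
jitters of SD 0.05 create genuine variance at the grouping structure
the mixed models assume. Magnitudes were fixed once by a design
analysis of the κ→DC response so that the direction effect is
unambiguous and the three-way interaction is comfortably detectable at
n = 24 — the strengths are free parameters of the generator, since the
study reports no numeric DC values to anchor them to.

A linearized fast path (`simulate_connection_table`) draws connection
tables directly at the DC level (response ≈ 0.10 + 0.08·κ plus random
intercepts and white noise, scales matched to the signal-level
pipeline); it powers the 500-replicate calibration suites where the
signal-level pipeline would be wasteful.

**What the generator does not emulate.** Systemic physiology (Mayer
waves, respiration, cardiac pulsation), superficial-layer contamination,
optode-coupling drift, anatomical variability of channel placement, and
any nonlinearity of the hemodynamic response. Passing tests therefore
demonstrate correctness and calibration of the estimators under the
model class, and detection power under idealized coupling — not
robustness to physiological confounds in real recordings.

## Problem sizes and runtime choices

The calibration suites use sizes chosen to keep a full run at desk
scale: the end-to-end interaction-recovery check runs 20 cohorts of 64
measurements each in the test suite (10 in the acceptance script); the
null-retention and type-I-error suites run 500 table-level replicates
in the test suite (200 in the script) at reduced cohort sizes (8–10
participants), where the table-level generator makes each replicate a
fraction of a second. The detection check runs 100 twelve-minute
two-channel simulations. Seeds are explicit everywhere; identical seeds
give bitwise-identical cohorts, signals and fits.

## Known limitations

* Directed coherence attributes influence to innovation sources, so
  with strong cascades part of an adjacent pair's apparent influence is
  inherited from upstream drive; the generator's κ-parametrization makes
  the mean response monotone, but individual level pairs can respond
  non-monotonically at extreme gains.
* Satterthwaite df rely on a numeric observed-information matrix; at
  variance boundaries the affected tests fall back to residual df and
  are flagged rather than silently trusted.
* Like the reference R implementation it was validated against (the
  agreement on matched fixtures is ~1e-7 in p), the multi-df
  Satterthwaite F test is mildly liberal at very small cohort sizes:
  at 8–10 participants the empirical size of a nominal 5% test of a
  2-df interaction runs around 6–9%. This is a property of the
  approximation, not of this implementation, and it shrinks as the
  number of participants grows.
* The MBLL inverse is exact only up to the mean-intensity baseline
  gauge (a per-channel additive constant), which is irrelevant after
  standardization.
* The channel layout is a faithful schematic of the montage geometry,
  not a coordinate-exact reconstruction of the instrument's optode
  positions; layouts are user-configurable.
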