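# Methods

This note documents the models and numerical choices behind specfluor, what
the synthetic generator does and does not emulate, and the limitations a
user should know before applying the pipeline to measured data.

## Fluorescence model

Raw PAM readings per leaf are (F₀, Fm, Fs, F′m, T). Derived quantities:

| quantity | formula | notes |
|---|---|---|
| PSII_max | (Fm − F₀)/Fm | maximum PSII photochemical efficiency (Fv/Fm) |
| NPQ | (Fm − F′m)/F′m | non-photochemical quenching |
| F′₀ | F₀ / (PSII_max + F₀/F′m) | Oxborough–Baker estimate |
| qL | (F′m − Fs)/(F′m − F′₀) · F′₀/Fs | open-centre fraction, lake model |
| K_D | max(0.03·T + 0.0773, 0.87) | constitutive dissipation; T in °C |
| K_N | NPQ · (K_F + K_D) | regulated heat dissipation |
| K_P | (F′m − Fs)/Fs · (K_F + K_D + K_N) | photochemistry |
| Φ_X | K_X / (K_P + K_N + K_F + K_D) | X ∈ {P, N, F, D}; sums to 1 exactly |

K_F = 0.05 is exposed as an overridable constant. Two algebraic identities
anchor the implementation and are asserted to 1e-12 in tests: the four
yields sum to one for every valid record, and F′₀ = F₀ whenever F′m = Fm.
The F′₀ relation circulates in several typeset variants; the form above is
the one that satisfies that identity. qL values outside [0, 1] (possible
with noisy readings, Fs < F′₀) are clipped with a warning, never silently.
Validation enforces 0 < F₀ < Fm and 0 < Fs < F′m ≤ Fm per record, naming
violators.

Skewness and kurtosis in the descriptive tables use the biased moment
definitions (excess kurtosis); CV is 100·sd/mean with the sample (n−1) sd.
Constant columns report CV 0 and NA shape statistics.

## Fractional-order derivatives

The Grünwald–Letnikov derivative of order α on the unit (1-nm) grid is the
causal convolution with c₀ = 1, c_k = c_{k−1}(k − 1 − α)/k, equivalently
(−1)^k·binom(α, k). The recurrence avoids evaluating Γ at non-positive
integers, terminates exactly for integer α (first/second difference
stencils), and composes: the coefficient sequences convolve as the formal
power series (1 − z)^α, so fod(α)∘fod(β) = fod(α+β) — verified numerically
to 1e-9.

Window policy: the default is the full expanding history back to the first
band (no padding or reflection), because no truncation length is part of
the method definition; a fixed memory of m terms is available. The operator
is applied as an exact lower-triangular Toeplitz matrix product rather than
an FFT convolution, trading a little speed (2001² matrix, still
milliseconds at 189 samples) for bit-level reproducibility and exact
integer-order stencils. Values within the first few bands use however many
series terms exist; a `burn_in_nm` flag can mark them, and is off by
default because short-wavelength bands are legitimate search candidates.

## Scatter transforms

* Log: absorbance convention log₁₀(1/R); natural log available by flag.
  Requires strictly positive input, so it applies to reflectance, not to
  derivative spectra.
* SNV: per-spectrum centring and scaling across bands with the n−1 sd
  (documented so round trips reproduce).
* MSC: per-spectrum OLS x = a + b·ref, output (x − a)/b. The reference
  defaults to the dataset mean and can be frozen and reused on new data.
* EMSC: adds a degree-1 or degree-2 polynomial in the wavelength rescaled
  to [−1, 1]; degree 0 is rejected (that is MSC). No known-constituent
  spectra terms.

Transforms are applied after trimming to 400–2400 nm.

## Index engine and band search

Nine developable families (R, SR, D, ND, ID, DDn, mSR1, mSR2, mND) are
computed on any transformed matrix. On derivative or scatter-corrected
spectra a ratio denominator may vanish; |den| < 1e-12 yields a missing
value for that sample rather than an infinity, and the search excludes
candidates missing for more than 5 % of samples, preventing tiny-n
artifacts from winning on AIC.

The search enumerates every combination on a coarse grid (default 10 nm):
201 single bands, 201·200 ordered SR pairs, C(201,2) = 20 100 unordered
pairs for D/ND/ID (swapping bands only flips the sign, leaving the linear
fit's AIC unchanged — the reporting convention is λ₁ < λ₂), and all
(λ₁, Δλ) with λ₁ ± Δλ in range for the offset families. Each candidate is
scored by OLS of the parameter on the index, AIC = n·ln(RSS/n) + 2k with
k = 3 (intercept, slope, error variance); k is constant within a family so
the AIC winner is also the R² winner there, and fixed across families for
comparability. Ties break deterministically to the smaller λ₁, then the
smaller λ₂/Δλ. Both within-family winners and the cross-family overall
winner per (group, parameter) are reported. The vectorised scorer is
validated against an explicit per-candidate brute-force oracle on reduced
grids for all nine families.

Published empirical indices live in an editable YAML registry. PRI, ARI2,
CRI1, CRI2, EVI, PSRI and RGI follow the standard literature forms; RSI,
OCAR and YCAR circulate in several variants, and the shipped simple-ratio
forms are placeholders that should be checked against the source
publication before quantitative use.

## Regression, bootstrap and relative importance

The headline model regresses a parameter on the winning index plus species
dummies (reference level = first species alphabetically). Training uses
case-resampling bootstrap (default B = 1000): replicates that lose all but
one species level or go singular are redrawn (counted, capped at 10·B).
Reported coefficients are bootstrap means with 2.5/97.5 percentile
intervals; the headline R²/r/RMSE/MAE apply the bootstrap-mean coefficient
vector to the full dataset, which matches the predicted-vs-observed
reporting convention of in-sample scatter plots. Because in-sample metrics
are optimistic, out-of-bag metrics (each sample predicted only by
replicates that excluded it) are reported alongside, clearly labelled.

Relative importance uses the LMG decomposition at the level of two
predictor groups — the index, and the species dummies as a block — i.e.
each group's incremental R² averaged over the two orders of entry. Shares
are nonnegative and sum to the full-model R² exactly; the group treatment
makes the dummy coding immaterial. Under an orthogonalised design each
share equals its marginal R², which the tests use as an independent check.

## Synthetic generator

The generator emulates the study design the analysis assumes, not any
particular measured dataset:

* **Spectra.** Reflectance = 0.02 + 0.50·exp(−A(λ)) with A a smooth
  baseline plus Gaussian absorption features at pigment (430/460/670 nm),
  carotenoid (490 nm), water (1200/1450/1940 nm) and dry-matter
  (1720/2100/2300 nm) centres, scaled by per-sample latent traits drawn
  from group-specific truncated normals and nudged by small multiplicative
  species offsets. Additive sensor noise defaults to SD 0.002 reflectance
  units — a free choice at the scale typical of field spectroradiometers,
  since no instrument noise figure is part of the method definition.
* **Fluorescence.** Latent PSII_max, NPQ and qL are drawn per leaf group
  from truncated normals calibrated to published shaded/sunlit field
  envelopes (e.g. PSII_max 0.77 ± 0.009 on [0.75, 0.80] shaded, 0.79 on
  [0.76, 0.82] sunlit; NPQ 0.96 vs 0.55; qL 0.30 vs 0.48), shifted by
  additive per-species offsets, then inverted exactly to raw readings:
  F₀ = Fm(1 − PSII_max), F′m = Fm/(1 + NPQ), F′₀ from Oxborough–Baker, and
  Fs = F′m·F′₀/(qL·(F′m − F′₀) + F′₀). The inversion guarantees the
  ordering constraints and makes re-derivation exact to machine precision.
  Leaf temperature defaults to 25 °C (not part of the emulated protocol's
  reporting), where the K_D floor binds.
* **Planted links.** A link injects narrow multiplicative Gaussian bumps
  (default relative SD 0.15, width 4 nm — locally confined: |change|
  < 1e-6 beyond ±30 nm) at its index's bands, then defines the target
  latent as slope·index + intercept + noise. `calibrate_link` measures the
  realised index distribution under the same seed and picks
  slope/intercept for a requested parameter mean/SD and noise for a
  requested R²; if the index is heavy-tailed (ratio families on derivative
  spectra), the slope is shrunk affinely until every latent stays inside
  physiological bounds, which leaves the planted R² unchanged. Violations
  raise; nothing is silently clipped.
* **Determinism.** One root seed spawns independent substreams (traits,
  noise, fluorescence, Fm scale, bumps), so identical configurations are
  bit-identical.

What passing tests on synthetic data do *not* show: real leaf spectra have
structure the generator omits (directional/specular effects, detector
splice artifacts, correlated noise, covariance between optical traits and
photosynthetic parameters beyond what is planted). In particular, base
parameter latents are drawn independently of the spectra, so un-planted
index–parameter R² is near zero by construction — useful as a null, but it
means recovery results quantify pipeline correctness, not field
predictability.

## Problem sizes and runtime choices

The default pipeline (21 derivative orders + 4 scatter transforms × 9
families × 6 parameters × 2 groups at a 10-nm step) is sized for a
workstation run of a few minutes; the test suite exercises the identical
code paths on scaled configurations (fewer transforms/families, 50–100 nm
steps, 24–189 samples, B = 20–1000) chosen so the whole suite runs in well
under a minute apart from the 20-seed recovery study. Recovery acceptance
uses n = 189 and B = 1000 — the emulated study's sizes.

Other numerical choices: OLS via closed-form moment sums in the vectorised
search (with a cancellation guard for constant targets) and `lstsq`
elsewhere; RSS floored at 1e-300 inside the AIC log so numerically perfect
fits remain comparable; CSVs written with %.17g and read with
round-trip float parsing so write/read cycles are bitwise.

## Known limitations

* Empirical-index definitions for RSI/OCAR/YCAR are unverified placeholders
  (editable registry).
* The bootstrap "training" convention (coefficient averaging, in-sample
  headline metrics) is one defensible reading of common practice; OOB
  metrics are provided because the in-sample numbers are optimistic.
* AIC comparisons across candidates with different effective n (after
  missing-value exclusion) are approximate; the ≤5 % missing cap bounds
  the distortion.
* No radiative-transfer leaf model backs the generator; PROSPECT-class
  simulation would be a natural future backend.
* Stage outputs are recomputed on every run rather than cached; at these
  problem sizes a content-addressed cache adds failure modes without
  observable benefit.
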