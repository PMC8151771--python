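# Methods

## Scope and model

The package implements the standard multivariate-calibration workflow for
quantifying olive-drupe quality parameters from diffuse-reflectance NIR
spectra, together with the statistics needed to compare several
acquisition systems that predict the same reference chemistry. The
statistical model throughout is linear: absorbance is treated as a
Beer–Lambert mixture, a PLS1 regression relates spectra to one response at
a time, and system comparison operates on the prediction-error vectors of
models sharing a common prediction set.

## Synthetic campaign generator

Real olive campaigns rarely deposit raw spectra, so the generator emulates
one at full scale: 267 sample units, two laboratory replicates per
chemical response, two replicate scans per instrument, three instruments
(FT-NIR integrating sphere and fiber-optic probe on 12,500–3,600 cm⁻¹, a
handheld Vis/NIR device on 500–1,000 nm).

**Chemistry.** True concentrations are drawn from a Gaussian copula with
uniform (default) or range-truncated-normal marginals on the observed
constituent ranges: moisture 39.3–87.2 %, oil 1.9–26.0 %, TPC 2.5–60.6
g_GA/kg, DPPH 2.4–165.0 % inhibition/mg. The soluble-solids span (5–30
°Bx) is an invented but agronomically plausible default, flagged as such
in the configuration docs. Moisture and oil are negatively correlated
(latent correlation −0.5, the dominant compositional trade-off in ripening
drupes); DPPH is a noisy monotone function of TPC, implemented as a copula
dependence whose latent correlation 2·sin(π·0.6/6) yields a Spearman rank
correlation of 0.6 — antioxidant activity tracks phenolics, but its
extremes need not coincide with TPC extremes. Laboratory replicates
multiply the truth by (1 + N(0, cv)) with cv = 0.03, chosen so the
resulting standard error of laboratory for moisture (≈2 % at a 63 % mean)
sits in the range typical of gravimetric reference methods.

**Spectra.** Each constituent carries a small library of Gaussian bands.
FT-NIR centers follow the usual overtone/combination assignments (water
6900 and 5200 cm⁻¹ broad bands; oil C–H overtones at 8300, 5800/5650 and
4335/4262 cm⁻¹; phenol-correlated structure in the 8700–8300 and
5800–5650 cm⁻¹ regions); Vis/NIR uses the anthocyanin (~540 nm) and
chlorophyll (~680 nm) pigment peaks plus third-overtone water/C–H bands at
750–970 nm. Sugar band placements are invented (plausible C–H/O–H
regions). Amplitudes are set so full-range concentrations give peak
absorbances of order 0.1–1 AU. A replicate scan is
`m·S + b₀ + b₁·x + ε` with multiplicative scatter `m ~ 1 + N(0, 0.08)`,
baseline offset and tilt `b₀, b₁ ~ N(0, 0.02)` AU, and detector noise
`ε ~ N(0, 0.002)` AU — exactly the artifact classes SNV and the first
derivative are designed to remove, at magnitudes that leave visible but
correctable structure. The probe grid carries a 1.3× gain, mimicking its
systematically higher absorbances.

**Grids.** The FT-NIR default is 2,309 points on 3,600–12,500 cm⁻¹,
chosen so the standard trim to 4,000–10,500 cm⁻¹ keeps exactly 1,686
variables with no point sitting on an interval boundary; the Vis/NIR
default is 1,647 points on 500–1,000 nm (~0.3 nm step). These counts
mirror the matrix widths such campaigns report; they are a construction
choice, not derivable from the instruments' nominal resolutions.

**Randomness.** One root seed feeds named `numpy` Philox/PCG64 substreams:
`[seed, 0]` for chemistry, `[seed, k]` for the k-th configured instrument.
Identical configurations are bit-identical.

**What the generator does not emulate.** No Kubelka–Munk/radiative-transfer
physics, no wavelength-dependent noise, no cultivar or ripening structure
(units are exchangeable draws), no instrument drift between sessions, no
nonlinear detector response. Passing tests therefore demonstrate that the
*pipeline mechanics* are correct under the stated linear-mixture model;
they say nothing about attainable accuracy on real drupes, where
heterogeneity and path-length effects dominate.

## Preprocessing

* Replicate spectra are arithmetically averaged to one spectrum per unit.
* FT-NIR blocks are trimmed to 4,000–10,500 cm⁻¹ (closed intervals;
  membership uses a 10⁻⁹ relative tolerance so float-reconstructed grid
  endpoints are kept); the Vis/NIR block is used whole.
* SNV centers and scales each spectrum with the n−1 standard deviation
  (n−1 is used for every dispersion estimate in the package, for
  consistency with the SEP definition).
* The Savitzky–Golay first derivative uses an order-2 polynomial over 11
  points and is expressed per axis unit (divided by the grid step) so
  derivatives are comparable across instruments. Edge points are computed
  by refitting the polynomial on the truncated one-sided window rather
  than dropped, keeping matrix widths stable across pretreatments.
  Interior points use `scipy.signal.savgol_filter`.
* In the combined recipe the steps run in label order, `snv` then `d1`;
  the order is configurable.
* TPC is modelled as its reciprocal (kg/g_GA) and DPPH on log₁₀ — the
  conventional symmetrizing transforms for these right-skewed
  constituents. Back-transforms are provided for reporting; figures of
  merit stay on the transformed scale, as calibration tables for these
  responses conventionally do.

## Partitioning

The five unit-mean chemical variables and every SNV-treated averaged block
are column-concatenated (5 + 1,686 + 1,686 + 1,647 = 5,024 variables at
default sizes), autoscaled, and decomposed by SVD-based PCA (deterministic
sign: each component's largest-magnitude loading is positive). Kennard–
Stone runs on the scores of the components reaching 95 % cumulative
explained variance (configurable, "all" allowed), capped at the numeric
rank of the matrix. The classic max–min algorithm seeds with the two
mutually farthest points and stops at round-half-up(0.70·n) — 187 of 267 —
leaving 80 prediction units. Rows are processed in sorted-unit-id order so
the split is invariant to row permutations; ties break toward the lower
id. Apparent outliers are never removed. Venetian-blind cross-validation
assigns the unit at position i to segment i mod 10; the default ordering
is the Kennard–Stone selection order (acquisition order being undefined
for synthetic data), with "as-loaded" order selectable.

## PLS1 calibration

NIPALS with X and y deflation: per component w = X'y/‖X'y‖, t = Xw,
p = X't/(t't), q = y't/(t't). X is mean-centered (unit-variance scaling
optional, off by default — spectra after SNV/d1 are already on comparable
scales). Regression vectors for every LV count up to `max_lvs` (default
20) are assembled as b = W(P'W)⁻¹q. Extraction stops early, with a
warning, when ‖X'y‖ falls below 10⁻¹² of its initial value — the relevant
case being noise-free synthetic data of exact rank 5. Cross-validation
refits centering inside every fold (no leakage); the LV count minimizes
RMSECV, ties toward fewer components, with a warning when the minimum sits
at the largest count tried. R² is the squared Pearson correlation of
predicted vs measured (the chemometric convention); the 1 − SSE/SST
variant is exposed alongside. Prediction metrics obey
RMSEP² = bias² + SEP²·(n−1)/n with SEP on n−1. Models serialize to JSON
(shortest-round-trip floats), so save → load → predict is bitwise stable.

## System comparison

* **SEL** from m duplicate pairs defaults to √(Σd²/2m), the standard
  duplicate-precision estimator of a single measurement's SD (it converges
  to the replicate noise SD); √(Σd²/m) — the SD of the *difference* — is
  selectable, and results record which form was used.
* **SEP < 2·SEL_ref** (strict) is reported as the good/not-good rule of
  thumb.
* **Bias comparison**: paired-t 95 % CI on the difference of two error
  series; a zero-variance difference with nonzero mean is reported as a
  degenerate rejection.
* **Fearn K/L interval**: SDs are the bias-corrected SEPs; r is the
  Pearson correlation of the raw error vectors;
  K = 1 + 2(1 − r²)t²₍ₙ₋₂,₀.₀₂₅₎/(n − 2), L = √(K + √(K² − 1)); the ratio
  interval (ratio/L, ratio·L) excluding 1 flags a significant difference.
  K ≥ 1 always, decreasing in |r| and n; the verdict is scale-invariant
  and symmetric under swapping the models. Identical error series are
  short-circuited to r = 1, K = L = 1. No separate F-test is implemented:
  the bias question is settled by the paired-t interval and the dispersion
  question by the K/L interval. α = 0.05 two-sided throughout, with no
  multiplicity correction across the 5 responses × 3 system pairs.

## Pipeline and problem sizes

`run_pipeline` executes generate → transform → average/trim → merge →
split → per-(response, system) pretreatment search → external validation →
SEL/SEP/comparison tables, and persists every artifact (config copy, data,
split sidecar, models, metrics) needed to reproduce any number. The
pretreatment per cell is chosen by minimum RMSECV over
{none, SNV, d1, SNV+d1} — the natural criterion given that the LV count is
chosen the same way. `SEL_NIR` predicts each replicate spectrum of the
prediction units separately through the trained model and applies the
duplicate formula to the predictions.

`response_scale` selects the working scale of the responses. The default
"transformed" models 1/TPC and log₁₀ DPPH. The "native" setting models
all five responses in their own units and exists because linear
parameter-recovery checks are only meaningful there: absorbance is linear
in concentration, so no linear regression can reproduce a *reciprocal* of
a spectral linear combination exactly — on noise-free rank-5 spectra the
best linear approximation to 1/TPC tops out near R² ≈ 0.5 by
construction, regardless of implementation quality. Recovery benchmarks
therefore use native units, where the noise-free pipeline reproduces every
response to machine precision.

Test and benchmark problem sizes are chosen to exercise every code path
at desk scale: structural checks run the full 267-unit campaign; the
recovery benchmark uses 60 units (rank, not n, limits a noise-free fit);
statistical-calibration simulations use n = 80 error pairs with 10,000
replicates (Monte-Carlo SE of a 95 % proportion ≈ 0.2 %), and the power
scenario 200 replicates at an SD ratio of 1.6.

## Known limitations

* PLS1 only; no PLS2, variable selection, or prediction intervals.
* The generator's exchangeable units cannot reproduce cultivar/seasonal
  clustering, so Kennard–Stone's behaviour on structured real data is
  untested here.
* The comparison statistics assume approximately bivariate-normal error
  pairs; heavy-tailed prediction errors will distort the K/L interval's
  coverage.
* Replicate-chemistry noise is multiplicative and homogeneous across the
  range; real assay CVs are typically concentration-dependent.
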