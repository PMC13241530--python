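# Methods

This note records the models, default parameters and numerical choices
behind `chemocal`, and what the synthetic study conditions do and do not
establish about real instrument data.

## Synthetic spectra

Mixture absorbance follows Beer–Lambert additivity at unit path length:
`A(i, λ) = Σ_k c_ik · ε_k(λ) + baseline(λ) + e(i, λ)` with
`e ~ N(0, σ²)` i.i.d. per cell. Pure absorptivity profiles `ε_k` are sums
of Gaussian bands on the 210–350 nm / 1 nm grid (141 variables).

Default band library (center nm, σ nm, peak AU·mL·µg⁻¹):

* TAZO: (211, 8, 0.12), (280, 10, 0.02) — the dominant high-intensity band
  near 211 nm plus a weak subsidiary band near 280 nm.
* CFPM: (257, 12, 0.05), (275, 9, 0.07), (214, 10, 0.04) — the principal
  270–280 nm region plus strong short-wavelength absorption below 250 nm.

The third CFPM band sits at 214 nm rather than mid-window: with a
mid-window placement the two profiles correlate only weakly over
210–250 nm, whereas the system this generator emulates is defined by
severe short-wavelength overlap. With the defaults, the cosine similarity
of the restricted profiles is 0.75 and both analytes absorb (strictly
positively) at every grid wavelength, so no univariate calibration is
possible. Band heights keep absorbance over the working ranges (CFPM
1–17, TAZO 1–9 µg/mL) within ≈0.1–1.7 AU, the linear photometric regime.
Absorbance magnitudes are otherwise a free scale; the library is fully
configurable.

Noise defaults to σ = 0.002 AU (typical double-beam photometric noise),
baseline drift off. The plasma model scales each analyte's contribution by
`1 − suppression` (defaults 1.7% for CFPM, 2.0% for TAZO, i.e. matrix
factors 0.983/0.980, percent-level suppression as seen after protein
precipitation) and adds a small smooth exponentially decaying background
(≤0.01 AU) standing in for residual matrix absorbance.

What the generator deliberately omits: stray light and detector
nonlinearity, day-to-day instrument drift, pH/solvatochromic band shifts,
wavelength-dependent (heteroscedastic) noise, and any structured artifact
correlated across wavelengths. Passing tests therefore demonstrate the
correctness of the algorithms under ideal bilinear conditions, not the
error levels a real instrument would deliver.

## Experimental design

The calibration set is the full five-level factorial over both analytes:
coded levels (−2…+2) map affinely onto each working range, giving 25
mixtures with level 0 at the range centre (9 µg/mL CFPM, 5 µg/mL TAZO).
Runs are ordered in cyclic-shift blocks; the ordering is conventional and
affects nothing downstream.

Validation mixtures are selected by classic Fedorov exchange from the
1 µg/mL candidate lattice (153 points, minus the 25 calibration
coordinates → 128 candidates). The information model defaults to a
quadratic response surface in [−1, 1]-scaled factors (6 terms): a purely
linear model would concentrate all information at the domain corners,
whereas a curvature-aware criterion spreads the 13 points over peripheral,
intermediate and central regions, which is what a validation set should
probe. A linear model remains available. Selection runs 20 random restarts
(singular starts re-drawn, up to 50 attempts), accepts the best
variance-function swap per iteration until the relative determinant gain
falls below 1e−9, and breaks ties toward the lowest candidate index so a
seed fully determines the output. Scaling to [−1, 1] makes the selected
points invariant to affine rescaling of the concentration domain.

## Calibration models

All three models consume a `SpectraMatrix` and reference
`ConcentrationTable` and return predictions in µg/mL.

**PCR.** Spectra are mean-centered; responses are regressed on the leading
SVD scores. The component count minimizes leave-one-out RMSECV (pooled
over analytes), with an absolute 1e−12 floor so numerically exact fits
tie-break toward fewer components, plus an optional relative parsimony
tolerance. Autoscaling (unit variance per wavelength) is available but off
by default: on data containing information-free spectral channels it
promotes pure noise to the same influence as analytical bands and inflates
prediction error by two orders of magnitude; it is only sensible when
every channel carries comparable signal.

**FA-PLS.** Per-analyte NIPALS PLS1 on a firefly-selected wavelength mask.
Fireflies carry continuous positions in [0,1]^p thresholded at 0.5;
brightness is 5-fold cross-validated RMSECV of a 2-component PLS on the
masked variables (5-fold rather than leave-one-out inside the swarm purely
for cost; the final model still uses LOO to pick its latent rank). Motion
toward every brighter firefly uses attractiveness `β₀e^(−γr²)` with
Euclidean `r` between position vectors plus uniform perturbation `α(u−½)`;
the global best is preserved unmodified each generation, and masks falling
under `min_wavelengths` (default 4) are repaired by activating the
highest-position variables. Default swarm: population 25, 100 generations,
`β₀ = 1`, per-analyte `α` (0.25 CFPM / 0.20 TAZO) and `γ` (0.9 / 0.8).
Swarms are run per analyte (the control parameters differ per analyte);
joint fitting over both responses is available by flag.

**MCR-ALS.** Rank from EFA (singular values of growing forward/backward
row windows; the estimate counts full-matrix singular values above
`σ·√(n·p)` when the noise SD is supplied, else above a noise floor
estimated from the trailing half of the singular spectrum). Alternating
non-negative least squares (per-row/per-column NNLS) under non-negativity
on both factors. Closure rescales each calibration row of C to its known
concentration total, which simultaneously anchors C in µg/mL; because
closure and unit-norm spectral normalization impose conflicting scales,
they are mutually exclusive — normalization (with the compensating scale
moved into C, leaving `CSᵀ` unchanged to 1e−10) only applies when closure
is off, and closure is automatically disabled when the resolved rank
differs from the analyte count. Optional selectivity windows force chosen
spectral regions of a component to zero. Iteration stops when the relative
change in lack of fit drops below 0.1% (default) or after 50 cycles.
Components map to analytes by maximal correlation of resolved calibration
profiles with the references (Hungarian assignment), and per-analyte
affine quantification lines absorb any residual scale. New spectra are
resolved against the frozen S by NNLS; closure never applies to unknowns,
whose totals are unknown.

With strictly bilinear noiseless data and the correct rank, initialization
at the reference concentrations makes the constrained fixed point exact:
lack of fit reaches machine zero and the resolved spectra match the
generating profiles up to scale.

## Validation statistics

For a prediction set (y reference, ŷ predicted, n samples):
`RMSE = √(Σ(yᵢ−ŷᵢ)²/n)`, `bias = Σ(yᵢ−ŷᵢ)/n`,
`SEC = √(Σ(yᵢ−ŷᵢ−bias)²/(n−1))` (the same bias-removed expression computed
on a prediction set is reported as BCRMSEP), and the exact identity
`RMSE² = bias² + (n−1)/n·SEC²` is asserted in tests. The relative RMSEP is
reported in two conventions: the standard `RMSE/ȳ·100` (primary, used for
all acceptance thresholds) and a variant dividing by `n` instead of `√n`,
which is exactly `√n` times smaller; both are exposed so the conventions
cannot be silently confused. NAS figures of merit project analyte k's
unit-concentration spectrum onto the orthogonal complement of the other
components; `SEN = ‖NAS‖`, `LOD = 3.3·δr/SEN`, `LOQ = 10·δr/SEN` (ratio
10/3.3 identically), with `δr` defaulting to the RMS spectral
reconstruction residual of the fitted model on calibration data. The EJCR
regresses predicted on reference (`ŷ = a + b·y`) and draws
`{(a*,b*): (β̂−β*)ᵀXᵀX(β̂−β*) ≤ 2s²F(2, n−2, 1−α)}`; a perfect fit
(s² = 0) is reported as a zero-area region at the estimate rather than an
error. ANOVA groups are the per-model recovery vectors on the shared
validation set; all quantiles come from scipy's t and F distributions.

## Pipeline and reproducibility

`RunConfig` (JSON round-trippable, SHA-256 hash echoed into every results
file) fixes every seed; per-stage seeds derive from the pipeline seed by
fixed offsets (+1 design, +2/+3 calibration/validation noise, +4 plasma,
+10+i per-analyte swarms). Default pipeline seed 20260605. Model archives
are JSON metadata plus full-precision (`%.17g`) CSV matrices and round-trip
predictions to 1e−12.

## Model ordering under ideal noise

Across seeded replicates of the default conditions, MCR-ALS attains the
lowest median validation RMSEP — it exploits the true bilinear structure,
non-negativity and closure. FA-PLS, however, does **not** beat
full-spectrum PCR here: with strictly additive signal and i.i.d.
homoscedastic noise, every discarded wavelength is discarded signal
averaging, so wavelength selection can only pay off when parts of the
spectrum are corrupted, nonlinear or noise-dominated in a structured way.
The hierarchy "wavelength-selected PLS beats full-spectrum PCR" seen on
real spectra reflects exactly such structured artifacts, which this
generator deliberately omits; the property suite therefore asserts only
MCR-ALS's lead.

## Problem sizes and runtimes

The test suite and the reproduction script use the study's native sizes —
25 calibration + 13 validation mixtures on 141 wavelengths; the full
25-firefly × 100-generation swarm runs in a few seconds per analyte, and
the complete default pipeline in under ten seconds. Statistical property
checks use 100 EFA replicates, 1000 EJCR coverage replicates and 10–20
pipeline replicates, enough for the asserted tolerances.

## Known limitations

* The generator's idealizations (above) mean error magnitudes on real
  spectra will be larger and model ordering may differ.
* EFA's default noise-floor heuristic assumes i.i.d. noise; strongly
  correlated residuals can inflate the estimated rank.
* MCR-ALS rotational ambiguity is tamed here by closure and correlation
  assignment; systems with more components or without reference totals may
  need selectivity windows to resolve uniquely.
* The firefly fitness uses a fixed 2-component inner PLS; systems with
  higher chemical rank should raise `inner_components`.
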