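# Methods

## Scope and model

`nrespec` couples two models. The first is chemometric: organ nitrogen
concentration N_mass (g N kg⁻¹ DM) is predicted from VIS–NIR reflectance of
dried, ground organ samples by univariate partial least squares regression.
The second is agronomic bookkeeping: post-anthesis nitrogen remobilization is
quantified from N_mass and dry mass (DM, kg ha⁻¹) at anthesis and maturity,

    NAA  = N_mass × DM / 1000        [kg N ha⁻¹]
    NRA  = NAA_anthesis − NAA_maturity
    NRE  = NRA / NAA_anthesis        [fraction; % at the I/O boundary]
    ΔN_mass = (N_anth − N_mat) / N_anth

The /1000 in NAA is the unit bridge (g/kg × kg/ha = g/ha → kg/ha); it is
explicit in the code and covered by tests. The whole plant is the organ sum:
stage-wise NAA totals, then the same ratios. That makes whole-plant NRE the
NAA_anthesis-weighted mean of organ NREs, an identity the tests check to
1e-12. Chaff is included in the aggregate by default; `include_organs`
restricts the set (both conventions are defensible, so both are exposed).
Negative NRE (net N gain after anthesis) is flagged, never clamped.

## Reflectance calibration

Two-point calibration against a grey panel of known reflectance:
`R = (raw − dark)/(white − dark) × R_panel`, with white and dark spatially
averaged to per-band vectors before the ratio (suppresses reference noise).
The dark frame is optional and defaults to zero — the calibration degrades
gracefully to a one-point ratio. Output is clipped to [0, 1.5]: specular
glint can legitimately exceed the panel reflectance, and clipping at 1.0
would silently bias such pixels. Any band where the averaged white does not
exceed the dark raises a degenerate-reference error naming the band. The
wavelength grid is always carried as data (header/config), never derived
from a nominal range, because instrument band counts and nominal ranges
frequently disagree.

## PLSR, component choice and diagnostics

NIPALS was chosen over SIMPLS as the canonical univariate-response
algorithm: it is deterministic, needs no initialization, and its
weights/scores/loadings are exactly what the VIP formula consumes. Columns
are mean-centered only by default; unit-variance scaling is behind a flag
(`scale=True`), since reflectance spectra share a common scale and scaling
would inflate noise-only bands. When the residual weight norm falls below
1e-12 of the Frobenius norm of the centered matrix (rank exhaustion, e.g. a
constant response), the fit truncates at the last valid component and sets
a `truncated` flag instead of failing; predictions at `a = 0` return the
training mean.

The model-building protocol is: random 75/25 calibration/validation split
(banker's rounding on `fraction·n`, unstratified — an optional stratified
mode was considered and left out as the default protocol draws plainly at
random); 10-times-repeated 5-fold cross-validation on the calibration set;
PRESS summed over all repeats and folds, with `PRESS(0)` from the
fold-training mean; the component count is the PRESS argmin with ties broken
toward fewer components (parsimony). The requested component ceiling is
capped at `min(smallest training fold − 1, p)` with a logged warning.
Metrics: R² is the squared Pearson correlation of observed vs predicted
(the scatter-plot convention; a 1 − SSE/SST variant is available via
`method="ss"`); RMSE in g/kg; RPD = sd(observed, ddof=1)/RMSE, so
RPD·RMSE reproduces sd(observed) identically and a perfect fit reports RPD
as an `inf` sentinel; bias = mean(obs) − mean(pred); regression bias is the
intercept of the observed-on-predicted least-squares line (the regression
direction is a convention and is recorded here because the opposite
orientation gives a different number).

VIP is computed at the selected component count, not the fitted ceiling.
Wavelength subsetting keeps VIP strictly greater than the threshold
(default 0.8) and re-runs the identical protocol on the reduced matrix under
the same seed, returning both reports for comparison.

Every protocol run is a pure function of (data, config, seed): rows are
canonicalized by sample_id before any random draw, and per-organ runs derive
their seeds from (seed, organ name), so reports are invariant to row order
and to which other organs are present.

## Synthetic data

The generator emulates organ powder spectra, not any particular instrument:
an organ-specific smooth baseline (quadratic in normalized wavelength;
leaves darker in the VIS than non-leaf organs, which is what makes the PCA
of the pooled set separate leaf from non-leaf groups) minus Gaussian
absorption features at 550, 680 and 910 nm whose depth is linear in N_mass,
plus Gaussian noise, clipped to [0.01, 1.2]. The linear (Beer–Lambert-like)
depth keeps a closed-form recoverable slope for oracle tests; a
`nonlinearity` knob bends the response for robustness checks. Depths are
normalized so the strongest band spans 0.2 reflectance over the organ's N
range, and the noise sd is `noise_frac` (default 0.05) times that span —
"5 % noise" therefore means 5 % of the N-induced signal range. The default
grid is 375–1050 nm at 5 nm (136 points).

Per-organ N ranges follow the observed vertical pattern: the flag leaf
spans 8.72–48.5 g/kg and the union of the nine default ranges spans
2.68–48.5 g/kg; intermediate organs were fixed once at plausible,
monotonically narrowing ranges (top leaves > basal leaves > internodes,
remaining internodes lowest). Trajectories use a 2-cultivar × 3-irrigation
× 3-replicate layout (18 plots): per plot and organ, anthesis NAA is drawn
log-normally around an organ-level scale, a target NRE (leaves ≈ 0.70–0.75,
internodes ≈ 0.45–0.65, chaff 0.55, modulated by small treatment/cultivar
multipliers) with optional multiplicative noise gives maturity NAA, and
N_mass is backed out of a shrinking DM trajectory. Ground truth (target and
realized NRE per plot × organ, plus the realized whole-plant aggregate) is
recorded alongside, so at zero noise the trait engine inverts the generator
exactly. The generators emit the same CSV schemas the readers consume;
round-trip identity is tested.

What the synthetic data does *not* emulate: scattering nonlinearity,
baseline drift correlated with N, instrument-specific band correlation, or
spatial within-sample heterogeneity. Passing tests therefore demonstrate
the correctness and statistical behavior of the pipeline, not field-level
prediction accuracy on real powders.

## Numerical choices and degenerate inputs

- Equal DM at both stages makes NRE ≡ ΔN_mass algebraically; the trait
  engine detects that case and computes NRE via the DM-free form so the
  identity holds to the last bit.
- Whole-plant sums are accumulated in sorted organ order, making aggregates
  bit-identical regardless of input order.
- Zero total NRA makes contribution shares undefined (error); negative
  shares (organ net gain) are legal and flagged.
- A constant regressor in trait regressions and zero-variance observed
  vectors in the metric suite raise domain errors rather than returning
  NaNs.
- `fit_plsr` accepts n ≥ 2 (one component), which the tiny-fold
  cross-validation cases require.

## Problem sizes

The simulation-backed checks run at sizes chosen to exercise the full
protocol while keeping the suite quick: signal-recovery and null-control
runs use 200 single-organ samples × 136 bands over 20 seeds; planted-band
VIP recovery uses 60 samples over 20 seeds; pipeline-closure runs the
18-plot × 9-organ × 2-stage paired dataset (324 spectra, nine organ models)
over 20 seeds at each of three noise levels. Medians over seeds are
reported to be robust to individual draws.

## Known limitations

- Single-response PLSR only; no kernel/sparse variants, no derivative or
  SNV preprocessing (out of scope by design).
- The PRESS selector has no one-standard-error alternative; ties and flat
  PRESS curves default to the smaller model.
- ENVI I/O covers the BSQ float32/float64 layout this pipeline writes; it
  is not a general ENVI reader.
- The trait regressions are plain OLS on per-plot values; no mixed-effects
  structure for the replicate/treatment design.
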