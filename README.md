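# nrespec

Organ-level spectroscopic estimation of nitrogen concentration and
post-anthesis nitrogen remobilization in cereals.

## The problem

In wheat, most of the grain's nitrogen is remobilized after flowering from
the vegetative organs — leaves, internodes and chaff. Quantifying that
process requires the nitrogen concentration (N_mass, g N kg⁻¹ dry mass) and
dry mass (DM, kg ha⁻¹) of each organ at two stages, anthesis and maturity.
Wet-chemistry N determination (Kjeldahl/Dumas) is the bottleneck; VIS–NIR
reflectance of dried, ground organ samples is a fast, non-destructive
substitute once a calibration model links spectra to N_mass.

`nrespec` implements that full chain as a tested Python library:

1. **Reflectance calibration & ROI extraction** (`nrespec.cube`) — two-point
   calibration of hyperspectral image cubes against a grey reference panel,
   `R = (raw − dark)/(white − dark) · R_panel`, and reduction of sample
   regions of interest to mean spectra.
2. **PLSR core** (`nrespec.plsr`) — univariate partial least squares
   regression via NIPALS, prediction at any component count, and variable
   importance in projection (VIP) scores, with
   `VIP_j = sqrt( p · Σ_k SS_k (w_jk/‖w_k‖)² / Σ_k SS_k )`,
   `SS_k = q_k² t_kᵀt_k`, so that `Σ_j VIP_j² = p`.
3. **Model-building protocol** (`nrespec.pipeline`) — random 75/25
   calibration/validation split, 10-times-repeated 5-fold cross-validation,
   component choice by minimum PRESS, the metric suite
   (R², RMSE, RPD = sd(obs)/RMSE, bias, regression bias), VIP > 0.8
   wavelength subsetting with recalibration, a PCA diversity summary, and
   per-organ plus pooled model runs.
4. **Remobilization traits** (`nrespec.traits`) —
   `NAA = N_mass · DM / 1000` (kg N ha⁻¹),
   `NRA = NAA_anthesis − NAA_maturity`, `NRE = NRA / NAA_anthesis`,
   `ΔN_mass = (N_anth − N_mat)/N_anth`, organ-to-whole-plant aggregation
   (whole-plant NAA is the organ sum), NRA contribution shares, and the
   trait regressions (whole-plant NRE ~ organ NRE / ΔN_mass).
5. **Synthetic data** (`nrespec.synthetic`) — spectra with Beer–Lambert-like
   absorption features whose depth is linear in N_mass, and plot-structured
   organ N/DM trajectories with recorded ground-truth NRE, so every stage
   is testable end to end without external data.

## Worked example

```bash
python examples/01_predict_nitrogen_from_spectra.py
```

```
samples: 90 calibration / 30 validation
latent components (min PRESS): 1
calibration  R2 = 0.997   RMSE = 0.68 g/kg
validation   R2 = 0.996   RMSE = 0.68 g/kg
RPD = 15.26   bias = 0.145 g/kg   regression bias = -0.330 g/kg

31 wavelengths with VIP > 0.8, e.g. [535. 540. 545. 550. 555. 560. 565. 660.] nm
```

Validation R² near 1 with RPD well above 3 means the spectra predict flag-leaf
N_mass accurately enough to replace the laboratory assay; the VIP-selected
wavelengths cluster around the planted absorption features. The other
examples show the trait engine (`02_remobilization_traits.py` — per-organ
NRA/NRE, whole-plant NRE ≈ 63%, and the best single-organ proxy regression)
and cube calibration (`03_cube_to_spectrum.py`).

A thin CLI wraps the same calls:

```bash
nrespec generate --out demo --seed 3
nrespec fit --spectra demo/spectra.csv --nmass demo/nmass.csv --out demo
nrespec traits --stages demo/stages.csv --out demo/traits.csv
nrespec regress --traits demo/traits.csv --out demo/regressions.csv
# or all stages with a manifest:
nrespec run --config config.yaml --out demo
```

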