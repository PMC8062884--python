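"""Predict organ nitrogen concentration from powder reflectance spectra.

Generates synthetic flag-leaf spectra with a known N signal, runs the full
model-building protocol (75/25 split, 10x repeated 5-fold CV, PRESS-based
component choice), and prints the validation report plus the wavelengths
the VIP diagnostic flags as informative.
"""

import numpy as np

from nrespec import ProtocolConfig, SpectraGenConfig, build_model, generate_spectra, vip_scores

# 120 flag-leaf (TL1) samples, N drawn uniformly over 8.72-48.5 g/kg,
# noise sd = 5% of the strongest absorption band's signal span
cfg = SpectraGenConfig(
    profiles={"TL1": SpectraGenConfig().profiles["TL1"]}, n_per_organ=120, noise_frac=0.05
)
table, n_mass = generate_spectra(cfg, seed=7)

run = build_model(table, n_mass, ProtocolConfig(a_max=8), seed=7, dataset="TL1")
r = run.report
print(f"samples: {r.n_cal} calibration / {r.n_val} validation")
print(f"latent components (min PRESS): {r.components}")
print(f"calibration  R2 = {r.r2_cal:.3f}   RMSE = {r.rmse_cal:.2f} g/kg")
print(f"validation   R2 = {r.r2_val:.3f}   RMSE = {r.rmse_val:.2f} g/kg")
print(f"RPD = {r.rpd:.2f}   bias = {r.bias:.3f} g/kg   regression bias = {r.regression_bias:.3f} g/kg")

vip = vip_scores(run.model, a=max(run.a_star, 1))
informative = table.wavelengths[vip > 0.8]
print(f"\n{len(informative)} wavelengths with VIP > 0.8, e.g. "
      f"{np.array2string(informative[:8], precision=0)} nm")
print("An R2 near 1 and RPD well above 3 mean the spectra carry enough signal")
print("to replace wet-chemistry N measurements for this organ.")
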