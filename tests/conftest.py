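import numpy as np
import pandas as pd
import pytest

from nrespec import SpectraGenConfig, SpectrumTable, generate_spectra


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_table(rng):
    """A 40-sample, 12-wavelength single-organ table with a linear N signal."""
    n, p = 40, 12
    wl = np.linspace(400, 950, p)
    y = rng.uniform(10, 40, n)
    X = 0.5 - 0.004 * y[:, None] * np.exp(-((wl - 680) ** 2) / (2 * 30**2))
    X = X + rng.normal(0, 1e-3, (n, p))
    meta = pd.DataFrame({"sample_id": [f"s{i:03d}" for i in range(n)], "organ": "TL1"})
    table = SpectrumTable(X, wl, meta)
    return table, pd.Series(y, index=meta["sample_id"], name="N_mass")


@pytest.fixture()
def flagleaf_table():
    """Synthetic flag-leaf spectra at the default 5% noise, n=120."""
    cfg = SpectraGenConfig(
        profiles={"TL1": SpectraGenConfig().profiles["TL1"]}, n_per_organ=120
    )
    return generate_spectra(cfg, seed=7)
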