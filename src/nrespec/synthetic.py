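"""Synthetic spectra and organ N/DM trajectories with known ground truth.

The study's raw data (powder-sample reflectance cubes plus Kjeldahl N and
dry-mass records) are not publicly deposited, so every pipeline stage is
exercised on simulated data that carries its own ground truth.

Spectra follow a Beer-Lambert-like construction on a VIS-NIR grid
(375-1050 nm at 5 nm by default): an organ-specific smooth baseline (a
low-order polynomial in normalized wavelength, separating leaf from
non-leaf organs the way real powder spectra separate in a PCA) minus
Gaussian absorption features whose depth grows linearly with N
concentration, plus Gaussian noise, clipped to [0.01, 1.2]::

    R(lambda) = baseline_organ(lambda)
                - sum_b depth_b * N_mass * exp(-(lambda - c_b)^2 / (2 s_b^2))
                + eps

Default features sit at 550, 680 and 910 nm (green peak, red chlorophyll
absorption, NIR water/structure region); they are illustrative, not fitted
to any instrument.  Depths are normalized per organ so that the strongest
band spans ~0.2 reflectance over the organ's N range, and the noise sd is
``noise_frac`` times that span (default 5%).  The linear depth keeps a
closed-form recoverable slope for oracle tests; ``nonlinearity`` bends it
for robustness checks.

Per-organ N ranges follow the vertical pattern seen in wheat at anthesis:
the flag leaf spans 8.72-48.5 g/kg, basal organs are lower and narrower,
and the union of the default ranges spans 2.68-48.5 g/kg.

The remobilization generator draws per-plot organ NAA at anthesis, applies
a target remobilization efficiency (with optional multiplicative noise and
treatment/cultivar multipliers), and backs N_mass out of a shrinking
dry-mass trajectory — so the tidy stage table it emits, run through the
trait engine, reproduces the recorded ground truth exactly at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .spectra import ORGANS, SpectrumTable

__all__ = [
    "OrganSpectraProfile",
    "SpectraGenConfig",
    "RemobOrganProfile",
    "RemobGenConfig",
    "generate_spectra",
    "generate_remobilization",
    "generate_paired_dataset",
    "PairedDataset",
    "N_MASS_ENVELOPE",
]

CULTIVARS = ("JM22", "ND399")
TREATMENTS = ("W0", "W1", "W2")

# strongest-band reflectance span over each organ's N range (depth normalizer)
_SIGNAL_SPAN = 0.2
_BASE_DEPTH_WEIGHTS = {550.0: 0.4, 680.0: 1.0, 910.0: 0.6}
_BAND_WIDTHS = {550.0: 15.0, 680.0: 12.0, 910.0: 25.0}

# Per-organ N_mass ranges (g/kg): flag leaf widest/highest, basal organs
# lower and narrower; union spans 2.68-48.5 g/kg.
_N_RANGES = {
    "TL1": (8.72, 48.5),
    "TL2": (7.5, 45.0),
    "TL3": (6.5, 40.0),
    "RLs": (4.0, 30.0),
    "TIN1": (4.0, 25.0),
    "TIN2": (3.2, 18.0),
    "TIN3": (2.9, 14.0),
    "RINs": (2.68, 10.0),
    "Chaff": (4.0, 22.0),
}

# Baseline polynomial coefficients (constant, linear, quadratic in the
# 0-1-normalized wavelength): leaves darker in the VIS than non-leaf organs,
# everything bright enough that absorption dips never reach the clip floor.
_BASELINES = {
    "TL1": (0.34, 0.30, -0.05),
    "TL2": (0.36, 0.28, -0.04),
    "TL3": (0.38, 0.26, -0.04),
    "RLs": (0.40, 0.22, -0.02),
    "TIN1": (0.52, 0.18, -0.03),
    "TIN2": (0.55, 0.20, -0.04),
    "TIN3": (0.53, 0.16, -0.02),
    "RINs": (0.50, 0.12, 0.00),
    "Chaff": (0.58, 0.14, -0.03),
}


@dataclass(frozen=True)
class OrganSpectraProfile:
    """Generative parameters for one organ's powder spectra."""

    organ: str
    baseline: tuple[float, float, float]  # polynomial in normalized wavelength
    bands: tuple[tuple[float, float, float], ...]  # (center nm, width nm, depth per g/kg)
    n_range: tuple[float, float]  # g/kg


def _default_profile(organ: str) -> OrganSpectraProfile:
    lo, hi = _N_RANGES[organ]
    span = hi - lo
    bands = tuple(
        (c, _BAND_WIDTHS[c], _SIGNAL_SPAN * w / span) for c, w in _BASE_DEPTH_WEIGHTS.items()
    )
    return OrganSpectraProfile(organ, _BASELINES[organ], bands, (lo, hi))


def default_profiles() -> dict[str, OrganSpectraProfile]:
    return {o: _default_profile(o) for o in ORGANS}


# global envelope of the default organ N ranges (g/kg)
N_MASS_ENVELOPE = (
    min(r[0] for r in _N_RANGES.values()),
    max(r[1] for r in _N_RANGES.values()),
)


@dataclass
class SpectraGenConfig:
    """Configuration of the spectra generator (defaults = study conditions)."""

    wl_start: float = 375.0
    wl_stop: float = 1050.0
    wl_step: float = 5.0
    profiles: dict[str, OrganSpectraProfile] = field(default_factory=default_profiles)
    n_per_organ: int = 20
    noise_frac: float = 0.05  # noise sd as a fraction of the strongest band's signal span
    nonlinearity: float = 0.0  # curvature of the depth-vs-N response (0 = linear)
    clip: tuple[float, float] = (0.01, 1.2)

    def wavelengths(self) -> np.ndarray:
        return np.arange(self.wl_start, self.wl_stop + self.wl_step / 2, self.wl_step)

    def validate(self) -> None:
        wl = self.wavelengths()
        for prof in self.profiles.values():
            lo, hi = prof.n_range
            if not 0 < lo < hi:
                raise ConfigError(f"{prof.organ}: invalid N range {prof.n_range}")
            for center, width, depth in prof.bands:
                if not wl[0] <= center <= wl[-1]:
                    raise ConfigError(
                        f"{prof.organ}: band at {center} nm outside grid "
                        f"[{wl[0]}, {wl[-1]}]"
                    )
                if width <= 0 or depth < 0:
                    raise ConfigError(f"{prof.organ}: band width/depth must be positive")


def _organ_spectrum(
    profile: OrganSpectraProfile,
    n_mass: np.ndarray,
    wl: np.ndarray,
    nonlinearity: float,
) -> np.ndarray:
    u = (wl - wl[0]) / (wl[-1] - wl[0]) if wl[-1] > wl[0] else np.zeros_like(wl)
    b0, b1, b2 = profile.baseline
    base = b0 + b1 * u + b2 * u**2
    n_col = np.asarray(n_mass, dtype=float)[:, None]
    response = n_col * (1.0 + nonlinearity * n_col / max(profile.n_range[1], 1e-9))
    spectra = np.broadcast_to(base, (len(n_col), len(wl))).copy()
    for center, width, depth in profile.bands:
        g = np.exp(-((wl - center) ** 2) / (2.0 * width**2))
        spectra -= depth * response * g
    return spectra


def noise_sd(profile: OrganSpectraProfile, noise_frac: float) -> float:
    """Noise sd convention: fraction of the strongest band's reflectance span
    over the organ's N range."""
    lo, hi = profile.n_range
    return noise_frac * max(d for _, _, d in profile.bands) * (hi - lo)


def generate_spectra(
    cfg: SpectraGenConfig, seed: int = 0
) -> tuple[SpectrumTable, pd.Series]:
    """Draw per-organ spectra with uniform N_mass over each organ's range.

    Returns the SpectrumTable and the true N_mass per sample (Series indexed
    by sample_id).  Bit-reproducible from the seed.
    """
    cfg.validate()
    wl = cfg.wavelengths()
    rng = np.random.default_rng(seed)
    blocks, metas, ys, ids = [], [], [], []
    design = [(c, t) for c in CULTIVARS for t in TREATMENTS]
    for organ in sorted(cfg.profiles):
        prof = cfg.profiles[organ]
        lo, hi = prof.n_range
        n_mass = rng.uniform(lo, hi, size=cfg.n_per_organ)
        clean = _organ_spectrum(prof, n_mass, wl, cfg.nonlinearity)
        eps = rng.normal(0.0, noise_sd(prof, cfg.noise_frac), size=clean.shape) if cfg.noise_frac > 0 else 0.0
        blocks.append(np.clip(clean + eps, *cfg.clip))
        for i in range(cfg.n_per_organ):
            cult, treat = design[i % len(design)]
            sid = f"{organ}_{i:03d}"
            ids.append(sid)
            metas.append(
                {"sample_id": sid, "organ": organ, "cultivar": cult, "treatment": treat, "stage": "pooled"}
            )
        ys.append(n_mass)
    table = SpectrumTable(np.vstack(blocks), wl, pd.DataFrame(metas))
    y = pd.Series(np.concatenate(ys), index=pd.Index(ids, name="sample_id"), name="N_mass")
    return table, y


# ---------------------------------------------------------------------------
# remobilization trajectories


@dataclass(frozen=True)
class RemobOrganProfile:
    """Per-organ generative parameters for the stage table."""

    organ: str
    naa_anthesis: float  # mean anthesis N accumulation, kg N / ha
    nre_target: float  # fraction in (-0.2, 1)
    dm_anthesis: float  # mean anthesis dry mass, kg / ha
    dm_loss: float  # fractional DM loss anthesis -> maturity


# Plausible magnitudes for irrigated winter wheat: leaves remobilize most
# (NRE ~0.7-0.75), internodes less, chaff intermediate; NAA concentrated in
# the flag leaf, peduncle and chaff.
_REMOB_DEFAULTS = {
    "TL1": RemobOrganProfile("TL1", 30.0, 0.75, 900.0, 0.35),
    "TL2": RemobOrganProfile("TL2", 22.0, 0.72, 750.0, 0.35),
    "TL3": RemobOrganProfile("TL3", 14.0, 0.70, 600.0, 0.35),
    "RLs": RemobOrganProfile("RLs", 10.0, 0.55, 800.0, 0.30),
    "TIN1": RemobOrganProfile("TIN1", 25.0, 0.65, 1800.0, 0.25),
    "TIN2": RemobOrganProfile("TIN2", 18.0, 0.60, 1700.0, 0.25),
    "TIN3": RemobOrganProfile("TIN3", 10.0, 0.58, 1300.0, 0.20),
    "RINs": RemobOrganProfile("RINs", 8.0, 0.45, 2500.0, 0.20),
    "Chaff": RemobOrganProfile("Chaff", 20.0, 0.55, 1600.0, 0.15),
}


@dataclass
class RemobGenConfig:
    """Field-design structure and noise levels of the trajectory generator.

    The default layout is 2 cultivars x 3 irrigation levels x 3 replicates
    (18 plots); treatment and cultivar multipliers perturb the target NRE so
    plots differ systematically as well as randomly.
    """

    organs: dict[str, RemobOrganProfile] = field(default_factory=lambda: dict(_REMOB_DEFAULTS))
    cultivars: tuple[str, ...] = CULTIVARS
    treatments: tuple[str, ...] = TREATMENTS
    replicates: int = 3
    naa_cv: float = 0.15  # between-plot lognormal sd on anthesis NAA
    dm_cv: float = 0.10  # between-plot lognormal sd on anthesis DM
    nre_noise: float = 0.05  # multiplicative noise on realized NRE
    treatment_nre: dict[str, float] = field(
        default_factory=lambda: {"W0": 0.92, "W1": 1.05, "W2": 1.0}
    )
    cultivar_nre: dict[str, float] = field(
        default_factory=lambda: {"JM22": 1.02, "ND399": 0.98}
    )

    def validate(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be positive")
        for prof in self.organs.values():
            if not -0.2 < prof.nre_target < 1:
                raise ConfigError(f"{prof.organ}: NRE target {prof.nre_target} outside (-0.2, 1)")
            if prof.naa_anthesis <= 0 or prof.dm_anthesis <= 0:
                raise ConfigError(f"{prof.organ}: NAA/DM scales must be positive")
            if not 0 <= prof.dm_loss < 1:
                raise ConfigError(f"{prof.organ}: DM loss must be in [0, 1)")


def generate_remobilization(
    cfg: RemobGenConfig, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the tidy per-plot stage table and its ground truth.

    Returns ``(stage_table, truth)``: the stage table has one row per
    plot x organ x stage with N_mass (g/kg) and DM (kg/ha); the truth frame
    records, per plot x organ, the target NRE (before noise) and the realized
    NRE actually baked into the trajectory, plus per-plot ``whole_plant``
    rows with the realized aggregate NRE.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for cult in cfg.cultivars:
        for treat in cfg.treatments:
            for rep in range(1, cfg.replicates + 1):
                plot_id = f"{cult}_{treat}_r{rep}"
                mult = cfg.treatment_nre.get(treat, 1.0) * cfg.cultivar_nre.get(cult, 1.0)
                tot_naa_a = tot_naa_m = 0.0
                for organ in sorted(cfg.organs):
                    prof = cfg.organs[organ]
                    naa_a = prof.naa_anthesis * np.exp(rng.normal(0.0, cfg.naa_cv)) if cfg.naa_cv > 0 else prof.naa_anthesis
                    target = prof.nre_target * mult
                    realized = target * (1.0 + cfg.nre_noise * rng.normal()) if cfg.nre_noise > 0 else target
                    if realized >= 1.0:
                        raise ConfigError(
                            f"{organ}: realized NRE {realized:.3f} >= 1 leaves no N at maturity"
                        )
                    naa_m = naa_a * (1.0 - realized)
                    dm_a = prof.dm_anthesis * np.exp(rng.normal(0.0, cfg.dm_cv)) if cfg.dm_cv > 0 else prof.dm_anthesis
                    dm_m = dm_a * (1.0 - prof.dm_loss)
                    base = {"plot_id": plot_id, "cultivar": cult, "treatment": treat, "replicate": rep, "organ": organ}
                    rows.append({**base, "stage": "anthesis", "N_mass": naa_a / dm_a * 1000.0, "DM": dm_a})
                    rows.append({**base, "stage": "maturity", "N_mass": naa_m / dm_m * 1000.0, "DM": dm_m})
                    truth_rows.append({**base, "NRE_target": target, "NRE_realized": realized, "NAA_anthesis": naa_a})
                    tot_naa_a += naa_a
                    tot_naa_m += naa_m
                truth_rows.append(
                    {
                        "plot_id": plot_id,
                        "cultivar": cult,
                        "treatment": treat,
                        "replicate": rep,
                        "organ": "whole_plant",
                        "NRE_target": np.nan,
                        "NRE_realized": (tot_naa_a - tot_naa_m) / tot_naa_a,
                        "NAA_anthesis": tot_naa_a,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


@dataclass
class PairedDataset:
    """Stage table + matching spectra, with ground truth for closure tests."""

    spectra: SpectrumTable
    n_mass: pd.Series  # true N_mass per spectrum (indexed by sample_id)
    stage_table: pd.DataFrame
    truth: pd.DataFrame


def generate_paired_dataset(
    remob_cfg: RemobGenConfig | None = None,
    spectra_cfg: SpectraGenConfig | None = None,
    seed: int = 0,
) -> PairedDataset:
    """One spectrum per plot x organ x stage sample, generated at that
    sample's true N_mass — the full-pipeline benchmark (spectra -> model ->
    predicted N_mass -> traits, scored against recorded ground truth)."""
    remob_cfg = remob_cfg or RemobGenConfig()
    spectra_cfg = spectra_cfg or SpectraGenConfig()
    spectra_cfg.validate()
    stage_table, truth = generate_remobilization(remob_cfg, seed)
    wl = spectra_cfg.wavelengths()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7_654_321]))
    X_rows, metas, ids, yvals = [], [], [], []
    for _, row in stage_table.iterrows():
        prof = spectra_cfg.profiles[row["organ"]]
        clean = _organ_spectrum(prof, np.array([row["N_mass"]]), wl, spectra_cfg.nonlinearity)[0]
        if spectra_cfg.noise_frac > 0:
            clean = clean + rng.normal(0.0, noise_sd(prof, spectra_cfg.noise_frac), size=clean.shape)
        X_rows.append(np.clip(clean, *spectra_cfg.clip))
        sid = f"{row['plot_id']}_{row['organ']}_{row['stage']}"
        ids.append(sid)
        yvals.append(row["N_mass"])
        metas.append(
            {
                "sample_id": sid,
                "organ": row["organ"],
                "cultivar": row["cultivar"],
                "treatment": row["treatment"],
                "stage": row["stage"],
                "plot_id": row["plot_id"],
            }
        )
    spectra = SpectrumTable(np.vstack(X_rows), wl, pd.DataFrame(metas))
    y = pd.Series(yvals, index=pd.Index(ids, name="sample_id"), name="N_mass", dtype=float)
    return PairedDataset(spectra=spectra, n_mass=y, stage_table=stage_table, truth=truth)
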