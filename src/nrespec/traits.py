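"""Post-anthesis nitrogen-remobilization traits, organ to whole plant.

Traits are built from per-organ nitrogen concentration (N_mass, g N per kg
dry mass) and dry mass per ground area (DM, kg/ha) at the two stages that
bound grain filling, anthesis and maturity:

* N accumulation   NAA = N_mass x DM / 1000            [kg N / ha]
  (the /1000 bridges g/kg x kg/ha = g/ha down to kg/ha);
* remobilized N    NRA = NAA_anthesis - NAA_maturity   [kg N / ha];
* remobilization efficiency  NRE = NRA / NAA_anthesis  [fraction];
* concentration change  dN_mass = (N_anth - N_mat) / N_anth  [fraction].

NRE equals dN_mass exactly whenever DM is unchanged between stages.  The
whole plant is the organ sum: stage-wise NAA totals, then the same two
ratios — algebraically the NAA_anthesis-weighted mean of the organ NREs.
Negative NRE / dN_mass (net N gain after anthesis) is legal output and is
flagged, never clamped.  NRE is kept as a fraction internally and formatted
as a percentage only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, LabelError, NrespecError, UndefinedMetricError
from .spectra import ORGANS

__all__ = [
    "OrganTimepoint",
    "OrganRemobilization",
    "n_accumulation",
    "remobilization",
    "whole_plant",
    "nra_contributions",
    "trait_regression",
    "compute_plot_traits",
    "trait_regression_matrix",
]

STAGES = ("anthesis", "maturity")


@dataclass(frozen=True)
class OrganTimepoint:
    """One organ at one stage: N concentration and dry mass."""

    organ: str
    stage: str
    n_mass: float  # g N / kg DM
    dm: float  # kg / ha

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise LabelError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if not (self.n_mass > 0 and np.isfinite(self.n_mass)):
            raise DomainError(f"N_mass must be positive, got {self.n_mass}")
        if not (self.dm > 0 and np.isfinite(self.dm)):
            raise DomainError(f"DM must be positive, got {self.dm}")


def n_accumulation(tp: OrganTimepoint) -> float:
    """N accumulation NAA = N_mass x DM / 1000, in kg N per hectare."""
    return tp.n_mass * tp.dm / 1000.0


@dataclass(frozen=True)
class OrganRemobilization:
    """Anthesis-to-maturity remobilization entry for one organ (or the
    whole-plant aggregate)."""

    organ: str
    naa_anthesis: float  # kg N / ha
    naa_maturity: float  # kg N / ha
    nra: float  # kg N / ha
    nre: float  # fraction
    delta_n_mass: float | None  # fraction; None for aggregates of unequal DM organs
    net_gain: bool  # True when maturity NAA exceeds anthesis NAA

    @property
    def nre_percent(self) -> float:
        return 100.0 * self.nre


def remobilization(anthesis: OrganTimepoint, maturity: OrganTimepoint) -> OrganRemobilization:
    """Per-organ remobilization amount, efficiency and concentration change.

    Both timepoints must carry the same organ label.  A maturity NAA above
    the anthesis NAA yields a negative NRE with the ``net_gain`` flag set.
    """
    if anthesis.organ != maturity.organ:
        raise LabelError(f"organ mismatch: {anthesis.organ!r} vs {maturity.organ!r}")
    if anthesis.stage != "anthesis" or maturity.stage != "maturity":
        raise LabelError("timepoints must be (anthesis, maturity) in that order")
    naa_a = n_accumulation(anthesis)
    naa_m = n_accumulation(maturity)
    nra = naa_a - naa_m
    delta = (anthesis.n_mass - maturity.n_mass) / anthesis.n_mass
    # Equal DM at both stages: NRE and dN_mass coincide algebraically; use
    # the DM-free form so the identity holds to the last bit.
    nre = delta if anthesis.dm == maturity.dm else nra / naa_a
    return OrganRemobilization(
        organ=anthesis.organ,
        naa_anthesis=naa_a,
        naa_maturity=naa_m,
        nra=nra,
        nre=nre,
        delta_n_mass=delta,
        net_gain=nra < 0,
    )


def whole_plant(
    results: Iterable[OrganRemobilization],
    include_organs: Sequence[str] | None = None,
) -> OrganRemobilization:
    """Whole-plant entry from organ entries: stage-wise NAA sums, then the
    same NRA/NRE ratios on the sums.

    Addition order is canonicalized by organ label so the aggregate is
    bit-identical regardless of input order.  Equals the NAA_anthesis-
    weighted mean of organ NREs (an algebraic identity).
    """
    listed = list(results)
    if len(listed) == 0:
        raise LabelError("need at least one organ entry")
    organs = [r.organ for r in listed]
    if len(set(organs)) != len(organs):
        raise LabelError("duplicate organ labels in whole-plant aggregation")
    entries = {r.organ: r for r in listed}
    if include_organs is not None:
        missing = set(include_organs) - set(entries)
        if missing:
            raise LabelError(f"organs not present: {sorted(missing)}")
        entries = {o: entries[o] for o in include_organs}
    order = sorted(entries)
    naa_a = 0.0
    naa_m = 0.0
    for organ in order:
        naa_a += entries[organ].naa_anthesis
        naa_m += entries[organ].naa_maturity
    nra = naa_a - naa_m
    return OrganRemobilization(
        organ="whole_plant",
        naa_anthesis=naa_a,
        naa_maturity=naa_m,
        nra=nra,
        nre=nra / naa_a,
        delta_n_mass=None,
        net_gain=nra < 0,
    )


def nra_contributions(results: Iterable[OrganRemobilization]) -> dict[str, float]:
    """Each organ's share of the total remobilized N.

    Fractions sum to 1; an organ with net N gain contributes a negative
    share (legal, not an error).  A zero total is undefined.
    """
    entries = list(results)
    organs = [r.organ for r in entries]
    if len(set(organs)) != len(organs):
        raise LabelError("duplicate organ labels in contribution set")
    total = sum(r.nra for r in sorted(entries, key=lambda r: r.organ))
    if total == 0:
        raise UndefinedMetricError("total NRA is zero; contributions undefined")
    return {r.organ: r.nra / total for r in entries}


@dataclass(frozen=True)
class TraitRegression:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def trait_regression(x: np.ndarray, y: np.ndarray) -> TraitRegression:
    """Ordinary least squares of trait y on trait x (per-plot values):
    R^2 of the fit and the two-sided p-value for the slope."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise UndefinedMetricError("trait regression needs n >= 3 paired values")
    if np.std(x) == 0:
        raise DomainError("regressor trait is constant")
    fit = stats.linregress(x, y)
    return TraitRegression(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
        p_value=float(fit.pvalue),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# tidy-table interface


def _require_columns(df: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise NrespecError(f"trait table missing columns {missing}")


def compute_plot_traits(
    df: pd.DataFrame,
    include_organs: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-plot organ and whole-plant traits from a tidy stage table.

    Input columns: plot_id, organ, stage (anthesis/maturity), N_mass, DM
    (plus any passthrough metadata such as cultivar/treatment).  Output has
    one row per plot x organ plus a ``whole_plant`` row per plot, with
    NAA at both stages, NRA, NRE (fraction and %), and dN_mass.
    """
    _require_columns(df, ["plot_id", "organ", "stage", "N_mass", "DM"])
    rows = []
    passthrough = [c for c in ("cultivar", "treatment", "replicate") if c in df.columns]
    for plot_id, g in df.groupby("plot_id", sort=True):
        entries = []
        meta = {c: g[c].iloc[0] for c in passthrough}
        for organ, og in g.groupby("organ", sort=True):
            stages = og.set_index("stage")
            if not {"anthesis", "maturity"}.issubset(stages.index):
                raise LabelError(f"plot {plot_id} organ {organ}: need both stages")
            if stages.index.duplicated().any():
                raise LabelError(f"plot {plot_id} organ {organ}: duplicate stage rows")
            anth = OrganTimepoint(
                organ, "anthesis", float(stages.loc["anthesis", "N_mass"]), float(stages.loc["anthesis", "DM"])
            )
            mat = OrganTimepoint(
                organ, "maturity", float(stages.loc["maturity", "N_mass"]), float(stages.loc["maturity", "DM"])
            )
            entries.append(remobilization(anth, mat))
        wp = whole_plant(entries, include_organs=include_organs)
        for entry in entries + [wp]:
            rows.append(
                {
                    "plot_id": plot_id,
                    **meta,
                    "organ": entry.organ,
                    "NAA_anthesis": entry.naa_anthesis,
                    "NAA_maturity": entry.naa_maturity,
                    "NRA": entry.nra,
                    "NRE": entry.nre,
                    "NRE_percent": entry.nre_percent,
                    "delta_N_mass": entry.delta_n_mass,
                    "net_gain": entry.net_gain,
                }
            )
    return pd.DataFrame(rows)


def trait_regression_matrix(traits: pd.DataFrame) -> pd.DataFrame:
    """Per-organ R^2/p grid of the three standard trait relationships:
    whole-plant NRE ~ organ NRE, organ NRE ~ organ dN_mass, and whole-plant
    NRE ~ organ dN_mass, across plots."""
    _require_columns(traits, ["plot_id", "organ", "NRE", "delta_N_mass"])
    wp = traits[traits["organ"] == "whole_plant"].set_index("plot_id")["NRE"]
    rows = []
    for organ in [o for o in ORGANS if (traits["organ"] == o).any()]:
        og = traits[traits["organ"] == organ].set_index("plot_id")
        common = og.index.intersection(wp.index)
        nre_o = og.loc[common, "NRE"].to_numpy(dtype=float)
        dnm_o = og.loc[common, "delta_N_mass"].to_numpy(dtype=float)
        nre_w = wp.loc[common].to_numpy(dtype=float)
        row: dict[str, object] = {"organ": organ}
        for label, (xx, yy) in {
            "NREwhole_vs_NREorgan": (nre_o, nre_w),
            "NREorgan_vs_dNmass": (dnm_o, nre_o),
            "NREwhole_vs_dNmass": (dnm_o, nre_w),
        }.items():
            fit = trait_regression(xx, yy)
            row[f"R2_{label}"] = fit.r2
            row[f"p_{label}"] = fit.p_value
        rows.append(row)
    return pd.DataFrame(rows)
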