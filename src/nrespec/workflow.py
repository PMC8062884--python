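"""End-to-end workflow: spectra -> organ models -> predicted traits.

Ties the stages together the way the study uses them: organ-specific PLSR
models predict N_mass from each sample's spectrum, the predictions replace
the laboratory N_mass in the tidy stage table, and the trait engine then
yields organ and whole-plant remobilization traits from spectra alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import NrespecError
from .pipeline import ModelRun, ProtocolConfig, run_organ_models
from .plsr import predict
from .spectra import SpectrumTable
from .synthetic import PairedDataset
from .traits import compute_plot_traits

__all__ = ["predict_stage_nmass", "end_to_end_traits", "ClosureResult", "end_to_end_closure"]


def predict_stage_nmass(
    runs: dict[str, ModelRun],
    spectra: SpectrumTable,
    stage_table: pd.DataFrame,
) -> pd.DataFrame:
    """Replace the stage table's N_mass with organ-model predictions.

    Every spectrum's sample_id must be ``{plot_id}_{organ}_{stage}``, the
    convention of the paired generator and the extraction stage.
    """
    preds: dict[str, float] = {}
    for organ, run in runs.items():
        if organ == "across_organs":
            continue
        sub = spectra.for_organ(organ)
        if len(sub) == 0:
            continue
        yhat = predict(run.model, sub, a=run.a_star)
        preds.update(zip(sub.meta["sample_id"], yhat))
    out = stage_table.copy()
    ids = out["plot_id"] + "_" + out["organ"] + "_" + out["stage"]
    missing = [s for s in ids if s not in preds]
    if missing:
        raise NrespecError(f"no prediction for samples {missing[:5]} (no organ model?)")
    out["N_mass"] = [preds[s] for s in ids]
    return out


def end_to_end_traits(
    paired: PairedDataset,
    config: ProtocolConfig = ProtocolConfig(),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, ModelRun]]:
    """Fit organ models on the paired spectra and compute traits from the
    predicted N_mass.  Returns (per-plot trait table, model runs)."""
    runs = run_organ_models(paired.spectra, paired.n_mass, config, seed)
    predicted = predict_stage_nmass(runs, paired.spectra, paired.stage_table)
    return compute_plot_traits(predicted), runs


@dataclass
class ClosureResult:
    """Pipeline-closure score: predicted vs true whole-plant NRE."""

    nre_pred_mean: float
    nre_true_mean: float
    abs_error: float
    per_plot_abs_error: pd.Series

    @property
    def median_abs_error(self) -> float:
        return float(self.per_plot_abs_error.median())


def end_to_end_closure(
    paired: PairedDataset,
    config: ProtocolConfig = ProtocolConfig(),
    seed: int = 0,
) -> ClosureResult:
    """Score the spectra->model->traits pipeline against the generator's
    recorded ground truth (realized whole-plant NRE per plot)."""
    traits_pred, _ = end_to_end_traits(paired, config, seed)
    pred = (
        traits_pred[traits_pred["organ"] == "whole_plant"]
        .set_index("plot_id")["NRE"]
        .sort_index()
    )
    truth = (
        paired.truth[paired.truth["organ"] == "whole_plant"]
        .set_index("plot_id")["NRE_realized"]
        .sort_index()
    )
    per_plot = (pred - truth).abs()
    return ClosureResult(
        nre_pred_mean=float(pred.mean()),
        nre_true_mean=float(truth.mean()),
        abs_error=float(np.abs(pred.mean() - truth.mean())),
        per_plot_abs_error=per_plot,
    )
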