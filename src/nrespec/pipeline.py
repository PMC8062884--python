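"""Model-building protocol for N-concentration spectra models.

The protocol mirrors standard chemometric practice for organ nitrogen
calibration: a random 75/25 calibration/validation split, 10-times-repeated
five-fold cross-validation on the calibration set, latent-component choice
by minimum PRESS (predicted residual error sum of squares, summed over all
repeats and folds, ties broken toward fewer components), refit at the chosen
count, and a validation report carrying R^2, RMSE, RPD, bias and regression
bias.  Wavelength selection keeps bands whose VIP exceeds a threshold
(strictly) and re-runs the identical protocol on the reduced matrix.

Conventions, fixed once for the whole package:

* R^2 is the squared Pearson correlation between observed and predicted
  (an explained-sum-of-squares variant is available via ``method="ss"``);
* RPD = sd(observed, ddof=1) / RMSE, so RPD * RMSE reproduces the observed
  standard deviation identically;
* bias = mean(observed) - mean(predicted);
* regression bias = intercept of the least-squares regression of observed
  on predicted;
* every run is a pure function of (data, config, seed): rows are put in
  canonical sample_id order before any random draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    SampleSizeError,
    ThresholdError,
    UndefinedMetricError,
)
from .plsr import PLSRModel, fit_plsr, predict, vip_scores
from .spectra import ORGANS, SpectrumTable

__all__ = [
    "CvPlan",
    "PressCurve",
    "FitReport",
    "ProtocolConfig",
    "split_calibration_validation",
    "make_cv_plan",
    "cross_validate",
    "select_components",
    "evaluate",
    "build_model",
    "vip_subset_recalibrate",
    "pca_diversity",
    "run_organ_models",
    "reports_to_frame",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Knobs of the model-building protocol (defaults = the study protocol)."""

    fraction: float = 0.75  # calibration share of the random split
    k: int = 5  # folds
    repeats: int = 10
    a_max: int = 15  # requested ceiling on latent components (capped by fold size)
    vip_threshold: float = 0.8
    scale: bool = False
    min_organ_n: int = 12
    r2_method: str = "pearson"


@dataclass
class CvPlan:
    """Fold assignments for repeated k-fold cross-validation.

    ``assignments[r, i]`` is the fold id of sample ``i`` in repeat ``r``;
    each repeat is an independent random partition into k near-equal folds.
    """

    k: int
    repeats: int
    seed: int
    assignments: np.ndarray  # (repeats, n) int fold ids

    @property
    def n(self) -> int:
        return self.assignments.shape[1]

    def min_training_size(self) -> int:
        sizes = [
            self.n - np.sum(self.assignments[r] == f)
            for r in range(self.repeats)
            for f in range(self.k)
        ]
        return int(min(sizes))


def make_cv_plan(n: int, k: int = 5, repeats: int = 10, seed: int = 0) -> CvPlan:
    if n < k:
        raise SampleSizeError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    assignments = np.empty((repeats, n), dtype=int)
    base = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
    for r in range(repeats):
        assignments[r] = base[rng.permutation(n)]
    return CvPlan(k=k, repeats=repeats, seed=seed, assignments=assignments)


@dataclass
class PressCurve:
    """PRESS per component count, summed over all repeats and folds.

    ``press[a]`` covers a = 0..A_max; a = 0 is the fold-training-mean null
    model.  ``per_fold`` keeps the (repeat, fold, a) breakdown for logging.
    """

    press: np.ndarray
    per_fold: np.ndarray  # (repeats, k, A_max+1)
    a_max: int
    capped: bool = False


def split_calibration_validation(
    table: SpectrumTable, fraction: float = 0.75, seed: int = 0
) -> tuple[SpectrumTable, SpectrumTable]:
    """Random disjoint calibration/validation split of the table rows.

    The calibration size is ``round(fraction * n)`` (banker's rounding);
    the split is reproducible from the seed, with rows first canonicalized
    by sample_id so the result is invariant to input row order.
    """
    n = len(table)
    if n < 8:
        raise SampleSizeError(f"need at least 8 samples to split, got {n}")
    if not 0.0 < fraction < 1.0:
        raise SampleSizeError("calibration fraction must lie strictly between 0 and 1")
    n_cal = int(np.round(fraction * n))
    n_cal = min(max(n_cal, 3), n - 2)  # keep both sides usable
    canon = table.sorted_by_sample_id()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return canon.subset_rows(np.sort(perm[:n_cal])), canon.subset_rows(np.sort(perm[n_cal:]))


def cross_validate(
    table: SpectrumTable | np.ndarray,
    y: np.ndarray,
    plan: CvPlan,
    a_max: int,
) -> PressCurve:
    """Accumulate held-out squared errors for every component count.

    For each repeat and fold, a PLSR model with the (possibly capped)
    maximum component count is fitted on the k-1 training folds and the
    held-out fold is predicted at every a from 0 (training-fold mean) to
    A_max.  ``a_max`` is capped at min(smallest training fold - 1, p) with
    a warning when the cap binds.
    """
    X = table.X if isinstance(table, SpectrumTable) else np.asarray(table, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if plan.n != n:
        raise SampleSizeError("CV plan size does not match data")
    cap = min(plan.min_training_size() - 1, p)
    capped = a_max > cap
    if capped:
        warnings.warn(
            f"a_max={a_max} exceeds min(training fold size - 1, p)={cap}; capped",
            stacklevel=2,
        )
        a_max = cap
    per_fold = np.zeros((plan.repeats, plan.k, a_max + 1))
    for r in range(plan.repeats):
        folds = plan.assignments[r]
        for f in range(plan.k):
            test = folds == f
            train = ~test
            model = fit_plsr(X[train], y[train], A=a_max)
            y_test = y[test]
            per_fold[r, f, 0] = np.sum((y_test - y[train].mean()) ** 2)
            for a in range(1, a_max + 1):
                # truncated fits repeat their last valid component's error
                a_eff = min(a, model.A_max)
                pred = predict(model, X[test], a=a_eff)
                per_fold[r, f, a] = np.sum((y_test - pred) ** 2)
    return PressCurve(
        press=per_fold.sum(axis=(0, 1)), per_fold=per_fold, a_max=a_max, capped=capped
    )


def select_components(curve: PressCurve) -> int:
    """Component count minimizing PRESS; ties go to the smaller count."""
    return int(np.argmin(curve.press))


@dataclass
class FitReport:
    """Metric bundle for one calibrated model (one table row of a report)."""

    dataset: str
    components: int
    n_cal: int
    r2_cal: float
    rmse_cal: float
    n_val: int
    r2_val: float
    rmse_val: float
    rpd: float
    bias: float
    regression_bias: float


@dataclass
class MetricSet:
    r2: float
    rmse: float
    rpd: float
    bias: float
    regression_bias: float
    n: int


def evaluate(y_obs: np.ndarray, y_pred: np.ndarray, method: str = "pearson") -> MetricSet:
    """Observed-vs-predicted metric suite.

    R^2 is the squared Pearson correlation by default (``method="ss"``
    switches to 1 - SSE/SST); RMSE in response units; RPD = sd(obs)/RMSE
    (+inf sentinel for a perfect fit); bias = mean(obs) - mean(pred);
    regression bias = intercept of the obs-on-pred least-squares line.
    """
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_obs) != len(y_pred) or len(y_obs) < 2:
        raise UndefinedMetricError("need two equal-length vectors of length >= 2")
    sd_obs = float(np.std(y_obs, ddof=1))
    if sd_obs == 0:
        raise UndefinedMetricError("observed values have zero variance; R^2 undefined")
    resid = y_obs - y_pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y_obs - y_obs.mean()) ** 2))
    sd_pred = float(np.std(y_pred, ddof=1))
    if method == "ss":
        r2 = 1.0 - sse / sst
    else:
        if sd_pred == 0:
            r2 = 0.0  # constant prediction carries no correlation
        else:
            r2 = float(np.corrcoef(y_obs, y_pred)[0, 1]) ** 2
    rpd = float("inf") if rmse == 0 else sd_obs / rmse
    bias = float(y_obs.mean() - y_pred.mean())
    if sd_pred == 0:
        regression_bias = float(y_obs.mean())
    else:
        slope = float(np.cov(y_pred, y_obs, ddof=1)[0, 1]) / sd_pred**2
        regression_bias = float(y_obs.mean() - slope * y_pred.mean())
    return MetricSet(r2=r2, rmse=rmse, rpd=rpd, bias=bias, regression_bias=regression_bias, n=len(y_obs))


@dataclass
class ModelRun:
    """Everything one protocol execution produced."""

    report: FitReport
    model: PLSRModel
    press: PressCurve
    a_star: int
    cal_ids: list[str] = field(default_factory=list)
    val_ids: list[str] = field(default_factory=list)


def build_model(
    table: SpectrumTable,
    y: pd.Series,
    config: ProtocolConfig = ProtocolConfig(),
    seed: int = 0,
    dataset: str = "all",
) -> ModelRun:
    """Run the full protocol on one table: split, repeated CV, PRESS
    selection, refit, and calibration/validation evaluation."""
    from .spectra import match_response

    cal, val = split_calibration_validation(table, config.fraction, seed)
    y_cal = match_response(cal, y)
    y_val = match_response(val, y)
    plan = make_cv_plan(len(cal), config.k, config.repeats, seed)
    curve = cross_validate(cal, y_cal, plan, config.a_max)
    a_star = select_components(curve)
    a_fit = max(a_star, 1)
    model = fit_plsr(cal, y_cal, A=a_fit, scale=config.scale)
    a_use = min(a_star, model.A_max)
    pred_cal = predict(model, cal, a=a_use)
    pred_val = predict(model, val, a=a_use)
    m_cal = evaluate(y_cal, pred_cal, method=config.r2_method)
    m_val = evaluate(y_val, pred_val, method=config.r2_method)
    report = FitReport(
        dataset=dataset,
        components=a_use,
        n_cal=len(cal),
        r2_cal=m_cal.r2,
        rmse_cal=m_cal.rmse,
        n_val=len(val),
        r2_val=m_val.r2,
        rmse_val=m_val.rmse,
        rpd=m_val.rpd,
        bias=m_val.bias,
        regression_bias=m_val.regression_bias,
    )
    return ModelRun(
        report=report,
        model=model,
        press=curve,
        a_star=a_use,
        cal_ids=cal.meta["sample_id"].tolist(),
        val_ids=val.meta["sample_id"].tolist(),
    )


@dataclass
class VipRecalibration:
    selected: np.ndarray  # wavelengths (nm) kept
    vip: np.ndarray  # VIP per original wavelength
    run_all: ModelRun
    run_subset: ModelRun


def vip_subset_recalibrate(
    table: SpectrumTable,
    y: pd.Series,
    config: ProtocolConfig = ProtocolConfig(),
    seed: int = 0,
    threshold: float | None = None,
) -> VipRecalibration:
    """Fit the all-wavelength model, keep wavelengths with VIP strictly above
    the threshold, and re-run the identical protocol on the reduced matrix."""
    threshold = config.vip_threshold if threshold is None else threshold
    run_all = build_model(table, y, config, seed, dataset="all_wavelengths")
    vip = vip_scores(run_all.model, a=max(run_all.a_star, 1))
    keep = np.flatnonzero(vip > threshold)
    if keep.size == 0:
        raise ThresholdError(
            f"VIP threshold {threshold} leaves no wavelengths (max VIP "
            f"{vip.max():.3f}); lower the cut"
        )
    reduced = table.subset_wavelengths(keep)
    run_subset = build_model(reduced, y, config, seed, dataset="vip_subset")
    return VipRecalibration(
        selected=table.wavelengths[keep], vip=vip, run_all=run_all, run_subset=run_subset
    )


@dataclass
class PcaSummary:
    explained: np.ndarray  # variance fractions, non-increasing
    scores: np.ndarray  # n x min(3, rank) scores


def pca_diversity(table: SpectrumTable | np.ndarray, n_scores: int = 3) -> PcaSummary:
    """Centered PCA of the spectra via SVD: explained-variance fractions and
    scores of the leading components (diversity summary of a spectral set)."""
    X = table.X if isinstance(table, SpectrumTable) else np.asarray(table, dtype=float)
    if X.shape[0] < 4:
        raise SampleSizeError("PCA diversity summary needs at least 4 samples")
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        explained = np.zeros(len(s))
    else:
        explained = s**2 / total
    k = min(n_scores, len(s))
    return PcaSummary(explained=explained, scores=U[:, :k] * s[:k])


def _organ_seed(seed: int, name: str) -> int:
    # stage/organ-keyed substream: stable across organ-set changes
    digest = np.random.SeedSequence(
        [seed, int.from_bytes(name.encode()[:8].ljust(8, b"\0"), "big") % (2**31)]
    )
    return int(digest.generate_state(1)[0] % (2**31))


def run_organ_models(
    table: SpectrumTable,
    y: pd.Series,
    config: ProtocolConfig = ProtocolConfig(),
    seed: int = 0,
) -> dict[str, ModelRun]:
    """One model per organ stratum plus a pooled across-organ model.

    Organs below ``config.min_organ_n`` samples are skipped with a warning.
    Each stratum gets a seed derived from (seed, organ name), so the report
    map is invariant to row order and to which other organs are present.
    """
    runs: dict[str, ModelRun] = {}
    present = [o for o in ORGANS if (table.meta["organ"] == o).any()]
    for organ in present:
        sub = table.for_organ(organ)
        if len(sub) < config.min_organ_n:
            warnings.warn(f"organ {organ}: n={len(sub)} below minimum {config.min_organ_n}; skipped")
            continue
        runs[organ] = build_model(sub, y, config, _organ_seed(seed, organ), dataset=organ)
    if len(table) >= config.min_organ_n:
        runs["across_organs"] = build_model(
            table, y, config, _organ_seed(seed, "across_organs"), dataset="across_organs"
        )
    return runs


def reports_to_frame(runs: Mapping[str, ModelRun]) -> pd.DataFrame:
    """Flatten a run map into a report table (one row per dataset), mirroring
    the conventional organ-model summary layout."""
    rows = []
    for name, run in runs.items():
        r = run.report
        rows.append(
            {
                "dataset": name,
                "components": r.components,
                "n_cal": r.n_cal,
                "R2_cal": r.r2_cal,
                "RMSE_cal": r.rmse_cal,
                "n_val": r.n_val,
                "R2_val": r.r2_val,
                "RMSE_val": r.rmse_val,
                "RPD": r.rpd,
                "bias": r.bias,
                "regression_bias": r.regression_bias,
            }
        )
    return pd.DataFrame(rows)
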