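"""Partial least squares regression for a single response, via NIPALS.

The model projects the mean-centered spectra onto successive latent
components that maximize covariance with the (centered) response.  For a
univariate response NIPALS is deterministic: at step ``a`` the weight vector
is ``w_a = X_a' y_a / ||X_a' y_a||``, scores ``t_a = X_a w_a``, loadings
``p_a = X_a' t_a / t_a't_a`` and ``q_a = y_a't_a / t_a't_a``, after which
``X`` and ``y`` are deflated by ``t_a p_a'`` and ``q_a t_a``.  Regression
coefficients at ``a`` components are ``B_a = W_a (P_a' W_a)^-1 q_a`` on the
centered scale.

Mean-centering only by default; optional unit-variance scaling of the
columns sits behind ``scale=True``.  When the residual weight norm collapses
(rank exhaustion) the fit truncates at the last valid component and sets a
warning flag rather than failing.

Variable importance in projection (VIP) summarizes each wavelength's
contribution across the first ``a`` components:

    VIP_j = sqrt( p * sum_k SS_k (w_jk / ||w_k||)^2 / sum_k SS_k ),
    SS_k = q_k^2 t_k't_k

whose squares always average to 1 over the p wavelengths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import (
    ComponentRangeError,
    DegenerateModelError,
    GridMismatchError,
    NrespecError,
)
from .spectra import SpectrumTable

__all__ = ["PLSRModel", "fit_plsr", "predict", "vip_scores", "save_model", "load_model"]

# relative tolerance on ||w|| below which a component is considered rank-collapsed
WEIGHT_COLLAPSE_RTOL = 1e-12


@dataclass
class PLSRModel:
    """Fitted NIPALS decomposition up to ``A_max`` components."""

    wavelengths: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    x_scale: np.ndarray  # ones when scaling is off
    W: np.ndarray  # p x A weights (unit columns)
    P: np.ndarray  # p x A x-loadings
    q: np.ndarray  # length-A y-loadings
    T: np.ndarray  # n x A training scores
    A_max: int
    truncated: bool = False
    scaled: bool = False

    def coefficients(self, a: int | None = None) -> np.ndarray:
        """Regression coefficients on the original (unscaled) X, using the
        first ``a`` components.  ``a = 0`` gives the zero vector."""
        a = self.A_max if a is None else a
        self._check_a(a)
        if a == 0:
            return np.zeros(len(self.x_mean))
        Wa, Pa, qa = self.W[:, :a], self.P[:, :a], self.q[:a]
        beta = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
        return beta / self.x_scale

    def _check_a(self, a: int) -> None:
        if not 0 <= a <= self.A_max:
            raise ComponentRangeError(f"a={a} outside [0, {self.A_max}]")


def fit_plsr(
    table: SpectrumTable | np.ndarray,
    y: np.ndarray,
    A: int,
    scale: bool = False,
) -> PLSRModel:
    """Fit a univariate PLSR model with ``A`` latent components.

    Parameters
    ----------
    table
        SpectrumTable or bare n x p matrix (rows already aligned with ``y``).
    y
        Response values (N_mass, g/kg), one per row.
    A
        Requested component count, ``1 <= A <= min(n-1, p)``.
    scale
        Divide centered columns by their sample standard deviation.

    Raises
    ------
    ComponentRangeError
        If ``A`` is out of range or fewer than 3 samples are given.
    """
    if isinstance(table, SpectrumTable):
        X, wavelengths = table.X, table.wavelengths
    else:
        X = np.asarray(table, dtype=float)
        wavelengths = np.arange(X.shape[1], dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise NrespecError("response length does not match sample count")
    if n < 2:
        raise ComponentRangeError(f"need at least 2 samples, got {n}")
    if not 1 <= A <= min(n - 1, p):
        raise ComponentRangeError(f"A={A} outside [1, min(n-1, p)={min(n - 1, p)}]")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xa = X - x_mean
    if scale:
        sd = Xa.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x_scale = sd
    else:
        x_scale = np.ones(p)
    Xa = Xa / x_scale
    ya = y - y_mean

    w_tol = WEIGHT_COLLAPSE_RTOL * max(np.linalg.norm(Xa), 1e-300)
    W, P, Q, T = [], [], [], []
    truncated = False
    for _ in range(A):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if not np.isfinite(nw) or nw <= w_tol:
            truncated = True
            break
        w = w / nw
        t = Xa @ w
        tt = float(t @ t)
        if tt <= (w_tol * w_tol):
            truncated = True
            break
        p_load = Xa.T @ t / tt
        q_a = float(ya @ t) / tt
        Xa = Xa - np.outer(t, p_load)
        ya = ya - q_a * t
        W.append(w)
        P.append(p_load)
        Q.append(q_a)
        T.append(t)

    A_fit = len(W)
    shape = (p, A_fit)
    return PLSRModel(
        wavelengths=np.asarray(wavelengths, dtype=float),
        x_mean=x_mean,
        y_mean=y_mean,
        x_scale=x_scale,
        W=np.array(W).T.reshape(shape),
        P=np.array(P).T.reshape(shape),
        q=np.array(Q, dtype=float),
        T=np.array(T).T.reshape((n, A_fit)),
        A_max=A_fit,
        truncated=truncated,
        scaled=scale,
    )


def predict(
    model: PLSRModel,
    table: SpectrumTable | np.ndarray,
    a: int | None = None,
) -> np.ndarray:
    """Predict the response for new rows using the first ``a`` components.

    ``a = 0`` is the null model and returns the training mean for every row.
    The wavelength grid must be identical to the training grid.
    """
    a = model.A_max if a is None else a
    model._check_a(a)
    if isinstance(table, SpectrumTable):
        if not np.array_equal(table.wavelengths, model.wavelengths):
            raise GridMismatchError("prediction wavelength grid differs from training grid")
        X = table.X
    else:
        X = np.atleast_2d(np.asarray(table, dtype=float))
        if X.shape[1] != len(model.x_mean):
            raise GridMismatchError("prediction matrix width differs from training grid")
    return model.y_mean + (X - model.x_mean) @ model.coefficients(a)


def vip_scores(model: PLSRModel, a: int | None = None) -> np.ndarray:
    """VIP score per wavelength from the first ``a`` components.

    Scores are non-negative and satisfy ``mean(VIP^2) = 1`` exactly.
    """
    a = model.A_max if a is None else a
    if not 1 <= a <= model.A_max:
        raise ComponentRangeError(f"a={a} outside [1, {model.A_max}]")
    p = model.W.shape[0]
    ss = model.q[:a] ** 2 * np.einsum("ij,ij->j", model.T[:, :a], model.T[:, :a])
    total = ss.sum()
    if total <= 0:
        raise DegenerateModelError("all components carry zero explained variance")
    # W columns are unit-norm by construction
    return np.sqrt(p * (model.W[:, :a] ** 2 @ ss) / total)


# ---------------------------------------------------------------------------
# serialization: arrays in .npz, scalars/config in a JSON sidecar


def save_model(path_stem: str | Path, model: PLSRModel) -> tuple[Path, Path]:
    stem = Path(path_stem)
    npz_path = stem.with_suffix(".npz")
    json_path = stem.with_suffix(".json")
    np.savez(
        npz_path,
        wavelengths=model.wavelengths,
        x_mean=model.x_mean,
        x_scale=model.x_scale,
        W=model.W,
        P=model.P,
        q=model.q,
        T=model.T,
    )
    json_path.write_text(
        json.dumps(
            {
                "y_mean": model.y_mean,
                "A_max": model.A_max,
                "truncated": model.truncated,
                "scaled": model.scaled,
                "n_wavelengths": int(len(model.wavelengths)),
            },
            indent=2,
        )
    )
    return npz_path, json_path


def load_model(path_stem: str | Path) -> PLSRModel:
    stem = Path(path_stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    with np.load(stem.with_suffix(".npz")) as z:
        return PLSRModel(
            wavelengths=z["wavelengths"],
            x_mean=z["x_mean"],
            y_mean=float(meta["y_mean"]),
            x_scale=z["x_scale"],
            W=z["W"],
            P=z["P"],
            q=z["q"],
            T=z["T"],
            A_max=int(meta["A_max"]),
            truncated=bool(meta["truncated"]),
            scaled=bool(meta["scaled"]),
        )
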