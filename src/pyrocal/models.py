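"""Calibration models mapping DTG curves to component contents.

The central estimator is :class:`NipalsPLS`, a single-response partial
least squares regression fitted by the NIPALS sequence. It is written out
explicitly (rather than delegating to a library) because the
variable-importance screening needs direct access to the per-component
weight vectors ``w_a`` and explained response sums of squares ``SS_a``,
and because latent-variable selection combines a cumulative-contribution
rule with cross-validated RMSE.

Around it sit the comparison models of the study: kernel SVR with
penalty/width tuned by cross-validated grid search, a Gaussian-process
ensemble over three kernels (squared-exponential, exponential, rational
quadratic) whose reported metrics are the mean over kernels, and three
baselines — minimum-norm multiple linear regression, random forest, and a
single-hidden-layer neural network. Everything but the PLS core delegates
to scikit-learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    Matern,
    RationalQuadratic,
    WhiteKernel,
)
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "rmse",
    "r_squared",
    "SplitSpec",
    "split_dataset",
    "NipalsPLS",
    "fit_pls",
    "select_n_latent",
    "fit_svr",
    "GPREnsemble",
    "fit_gpr_ensemble",
    "fit_baseline",
    "ModelEvalResult",
    "evaluate_all",
    "MODEL_NAMES",
]

MODEL_NAMES = ("PLS", "SVR", "GPR", "MLR", "RF", "SNN")


# ---------------------------------------------------------------------------
# metrics


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean squared error, ``sqrt(mean((y - ŷ)²))``."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("rmse needs two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination ``1 − SS_res / SS_tot``.

    Out-of-sample values may be negative when predictions are worse than
    the test-set mean.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("r_squared needs two equal-length non-empty vectors")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y_true is constant; R² undefined")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


# ---------------------------------------------------------------------------
# train/test split


@dataclass
class SplitSpec:
    """A seeded shuffle split into train and test index lists."""

    test_fraction: float = 0.25
    seed: int = 0
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie strictly in (0, 1)")


def split_dataset(n: int, spec: SplitSpec) -> SplitSpec:
    """Populate a :class:`SplitSpec` with a seeded shuffle split of ``n``.

    The test size is ``round(n · test_fraction)`` (at least 1, at most
    n − 1); e.g. 157 samples at 0.25 give 118 train / 39 test.
    """
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    n_test = int(round(n * spec.test_fraction))
    n_test = min(max(n_test, 1), n - 1)
    perm = np.random.default_rng(spec.seed).permutation(n)
    return SplitSpec(
        test_fraction=spec.test_fraction,
        seed=spec.seed,
        train_idx=np.sort(perm[n_test:]),
        test_idx=np.sort(perm[:n_test]),
    )


# ---------------------------------------------------------------------------
# NIPALS PLS


class NipalsPLS(BaseEstimator, RegressorMixin):
    """Single-response PLS regression fitted by the NIPALS sequence.

    Predictors and response are mean-centered (no variance scaling, so
    relative DTG peak magnitudes are preserved); each component extracts
    the direction of maximal covariance with the current response
    residual, then deflates both blocks.

    Parameters
    ----------
    n_components : int
        Number of latent variables A.

    Attributes
    ----------
    x_mean_, y_mean_ : centering applied before projection.
    x_weights_ : (p, A) unit-norm weight vectors ``w_a``.
    x_loadings_ : (p, A) loadings ``p_a``.
    y_loadings_ : (A,) response loadings ``q_a``.
    x_scores_ : (n, A) training score vectors ``t_a`` (orthogonal).
    ss_y_ : (A,) response sum of squares explained per component,
        ``SS_a = q_a² · t_aᵀt_a``; feeds VIP scores and the
        cumulative-contribution rule.
    coef_ : (p,) regression vector b with
        ``ŷ = (x − x_mean_)·b + y_mean_``.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NipalsPLS":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if len(y) != n:
            raise ValueError("X and y have different numbers of samples")
        A = self.n_components
        if not 1 <= A <= min(n - 1, p):
            raise ValueError(
                f"n_components={A} must lie in [1, min(n-1, p)] = "
                f"[1, {min(n - 1, p)}]"
            )
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xd = X - self.x_mean_
        yd = y - self.y_mean_

        W = np.zeros((p, A))
        P = np.zeros((p, A))
        T = np.zeros((n, A))
        q = np.zeros(A)
        ss = np.zeros(A)
        for a in range(A):
            w = Xd.T @ yd
            nw = np.linalg.norm(w)
            if nw <= np.finfo(float).eps * max(n, p):
                # residual response orthogonal to X: stop early, keep a comps
                A = a
                break
            w /= nw
            t = Xd @ w
            tt = float(t @ t)
            pa = (Xd.T @ t) / tt
            qa = float(yd @ t) / tt
            Xd = Xd - np.outer(t, pa)
            yd = yd - qa * t
            W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
            ss[a] = qa * qa * tt
        if A == 0:
            raise ValueError("response has no covariance with X")
        self.n_components_ = A
        self.total_ss_y_ = float(np.sum((y - self.y_mean_) ** 2))
        self.x_weights_ = W[:, :A]
        self.x_loadings_ = P[:, :A]
        self.x_scores_ = T[:, :A]
        self.y_loadings_ = q[:A]
        self.ss_y_ = ss[:A]
        # b = W (PᵀW)⁻¹ q maps centered x directly to centered ŷ
        self.coef_ = self.x_weights_ @ np.linalg.solve(
            self.x_loadings_.T @ self.x_weights_, self.y_loadings_
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_

    def predict_components(self, X: np.ndarray) -> np.ndarray:
        """Predictions of every nested sub-model, shape (n, A).

        Column a−1 is the prediction using the first ``a`` latent
        variables; the last column equals :meth:`predict`. Used to get all
        RMSECV values from one fit per fold.
        """
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        Xd = X - self.x_mean_
        A = self.n_components_
        preds = np.zeros((X.shape[0], A))
        acc = np.zeros(X.shape[0])
        for a in range(A):
            t = Xd @ self.x_weights_[:, a]
            acc = acc + self.y_loadings_[a] * t
            Xd = Xd - np.outer(t, self.x_loadings_[:, a])
            preds[:, a] = acc + self.y_mean_
        return preds

    def explained_y_variance_ratio(self) -> np.ndarray:
        """Per-component fraction of centered response SS explained."""
        check_is_fitted(self, "coef_")
        if self.total_ss_y_ == 0:
            raise ValueError("training response was constant")
        return self.ss_y_ / self.total_ss_y_


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> NipalsPLS:
    """Functional wrapper: fit a :class:`NipalsPLS` with A components."""
    return NipalsPLS(n_components=n_components).fit(X, y)


def select_n_latent(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int,
    cv_folds: int = 10,
    cum_threshold: float = 0.90,
    seed: int = 0,
) -> int:
    """Choose the PLS latent-variable count A.

    Combines two rules: the cumulative contribution of the latent
    variables to the response variance should reach about
    ``cum_threshold`` (90% by default), and the cross-validated RMSE
    should be relatively small — operationalized as the one-standard-error
    band around the RMSECV minimum. The smallest A satisfying both is
    returned; if none does, the RMSECV-minimizing A.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if max_components < 1 or cv_folds < 2:
        raise ValueError("max_components ≥ 1 and cv_folds ≥ 2 required")
    max_components = min(max_components, p)
    if max_components == 1:
        return 1

    # cumulative explained response variance from a full-data fit
    full = NipalsPLS(min(max_components, n - 1)).fit(X, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    cum = np.cumsum(full.ss_y_) / ss_tot
    A_hi = full.n_components_

    # RMSECV over 1..A_hi, one nested fit per fold
    kf = KFold(n_splits=min(cv_folds, n), shuffle=True, random_state=seed)
    fold_rmse = []
    for tr, te in kf.split(X):
        A_fold = min(A_hi, len(tr) - 1)
        m = NipalsPLS(A_fold).fit(X[tr], y[tr])
        preds = m.predict_components(X[te])  # (n_te, A_fold_eff)
        err = preds - y[te][:, None]
        per_a = np.sqrt(np.mean(err**2, axis=0))
        if len(per_a) < A_hi:  # early stop or small fold: pad with last value
            per_a = np.concatenate([per_a, np.full(A_hi - len(per_a), per_a[-1])])
        fold_rmse.append(per_a)
    fold_rmse = np.vstack(fold_rmse)
    rmsecv = fold_rmse.mean(axis=0)
    a_min = int(np.argmin(rmsecv))
    se_min = float(fold_rmse[:, a_min].std(ddof=1) / np.sqrt(fold_rmse.shape[0]))

    ok = (cum[:A_hi] >= cum_threshold) & (rmsecv <= rmsecv[a_min] + se_min)
    if np.any(ok):
        return int(np.argmax(ok)) + 1
    return a_min + 1


# ---------------------------------------------------------------------------
# comparison models (scikit-learn backed)


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    cv_folds: int = 5,
    seed: int = 0,
    param_grid: dict | None = None,
):
    """RBF-kernel SVR tuned by cross-validated grid search.

    The penalty C, tube width epsilon and kernel width gamma are searched
    on logarithmic grids minimizing CV squared-error loss. The response is
    standardized internally (SVR's epsilon is scale-dependent). Returns
    ``(model, hyperparameters)`` where ``model.predict`` works on the
    original scale.
    """
    if cv_folds < 2:
        raise ValueError("cv_folds must be at least 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    grid = param_grid or {
        "C": [0.1, 1.0, 10.0, 100.0, 1000.0],
        "epsilon": [0.01, 0.05, 0.1, 0.3],
        "gamma": ["scale"],
    }
    y_mean, y_sd = float(y.mean()), float(y.std())
    y_sd = y_sd if y_sd > 0 else 1.0
    search = GridSearchCV(
        SVR(kernel="rbf"),
        grid,
        scoring="neg_mean_squared_error",
        cv=KFold(n_splits=min(cv_folds, len(y)), shuffle=True, random_state=seed),
    )
    search.fit(X, (y - y_mean) / y_sd)

    class _Rescaled:
        def __init__(self, inner):
            self._inner = inner

        def predict(self, Xq):
            return self._inner.predict(np.asarray(Xq, dtype=float)) * y_sd + y_mean

    params = dict(search.best_params_)
    params["y_mean"], params["y_sd"] = y_mean, y_sd
    return _Rescaled(search.best_estimator_), params


class GPREnsemble(BaseEstimator, RegressorMixin):
    """Gaussian-process regression averaged over three kernels.

    Fits one GP per kernel family — squared exponential (RBF), exponential
    (Matern ν=1/2) and rational quadratic — each with a learned constant
    prefactor and white-noise term. Reported R²/RMSE are the arithmetic
    mean of the three models' metrics, so no single kernel family
    dominates the comparison;
    :meth:`predict` returns the mean prediction for convenience. A kernel
    whose hyperparameter optimization fails is dropped with a warning and
    the ensemble continues with the remaining kernels.
    """

    KERNELS = ("SE", "Exp", "RQ")

    def __init__(self, random_state: int = 0, normalize_y: bool = True):
        self.random_state = random_state
        self.normalize_y = normalize_y

    def _make_kernels(self):
        base = {
            "SE": RBF(length_scale=1.0),
            "Exp": Matern(length_scale=1.0, nu=0.5),
            "RQ": RationalQuadratic(length_scale=1.0, alpha=1.0),
        }
        return {
            name: ConstantKernel(1.0) * k + WhiteKernel(1e-5)
            for name, k in base.items()
        }

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GPREnsemble":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) < 5:
            raise ValueError("GPR ensemble needs at least 5 samples")
        self.models_ = {}
        for name, kernel in self._make_kernels().items():
            gp = GaussianProcessRegressor(
                kernel=kernel,
                normalize_y=self.normalize_y,
                random_state=self.random_state,
                n_restarts_optimizer=0,
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    gp.fit(X, y)
                self.models_[name] = gp
            except Exception as exc:  # noqa: BLE001 - per-kernel isolation
                warnings.warn(f"GPR kernel {name} failed to fit: {exc}")
        if not self.models_:
            raise RuntimeError("all GPR kernels failed to fit")
        return self

    def predict_all(self, X: np.ndarray) -> dict[str, np.ndarray]:
        check_is_fitted(self, "models_")
        X = np.asarray(X, dtype=float)
        return {name: gp.predict(X) for name, gp in self.models_.items()}

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = self.predict_all(X)
        return np.mean(list(preds.values()), axis=0)

    def mean_metrics(self, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """Arithmetic mean of per-kernel (R², RMSE) on the given data."""
        y = np.asarray(y, dtype=float).ravel()
        r2s, rmses = [], []
        for pred in self.predict_all(X).values():
            r2s.append(r_squared(y, pred))
            rmses.append(rmse(y, pred))
        return float(np.mean(r2s)), float(np.mean(rmses))


def fit_gpr_ensemble(X: np.ndarray, y: np.ndarray, seed: int = 0) -> GPREnsemble:
    """Functional wrapper: fit the three-kernel GP ensemble."""
    return GPREnsemble(random_state=seed).fit(X, y)


def fit_baseline(X: np.ndarray, y: np.ndarray, kind: str, seed: int = 0):
    """Fit one of the reference baselines: 'MLR', 'RF' or 'SNN'.

    MLR is ordinary least squares (the minimum-norm solution when p > n),
    RF a seeded random forest, SNN a single-hidden-layer (width 32)
    network with early stopping. Returns ``(model, hyperparameters)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if kind == "MLR":
        model = LinearRegression().fit(X, y)
        return model, {"kind": "OLS/minimum-norm"}
    if kind == "RF":
        params = {"n_estimators": 200, "random_state": seed}
        return RandomForestRegressor(**params).fit(X, y), params
    if kind == "SNN":
        params = {
            "hidden_layer_sizes": (32,),
            "max_iter": 2000,
            "early_stopping": True,
            "random_state": seed,
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = MLPRegressor(**params).fit(X, y)
        return model, params
    raise ValueError(f"unknown baseline kind '{kind}'")


# ---------------------------------------------------------------------------
# full evaluation


@dataclass
class ModelEvalResult:
    """Train/test metrics of one (component, model) pair."""

    component: str
    model: str
    r2_train: float
    rmse_train: float
    r2_test: float
    rmse_test: float
    n_latent: int | None = None
    hyperparameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "component": self.component,
            "model": self.model,
            "r2_train": self.r2_train,
            "rmse_train": self.rmse_train,
            "r2_test": self.r2_test,
            "rmse_test": self.rmse_test,
            "n_latent": self.n_latent,
            "hyperparameters": json.dumps(self.hyperparameters, default=str),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelEvalResult":
        n_latent = d.get("n_latent")
        if n_latent is not None and not (isinstance(n_latent, float) and np.isnan(n_latent)):
            n_latent = int(n_latent)
        else:
            n_latent = None
        return cls(
            component=d["component"],
            model=d["model"],
            r2_train=float(d["r2_train"]),
            rmse_train=float(d["rmse_train"]),
            r2_test=float(d["r2_test"]),
            rmse_test=float(d["rmse_test"]),
            n_latent=n_latent,
            hyperparameters=json.loads(d["hyperparameters"])
            if isinstance(d.get("hyperparameters"), str)
            else d.get("hyperparameters", {}),
        )


def _fit_one(model_name: str, Xtr, ytr, seed: int, max_components: int, cv_folds: int):
    """Fit one model family; returns (predict_fn, n_latent, hyperparams)."""
    if model_name == "PLS":
        A = select_n_latent(Xtr, ytr, max_components, cv_folds=cv_folds, seed=seed)
        m = NipalsPLS(A).fit(Xtr, ytr)
        return m.predict, m.n_components_, {"n_latent": m.n_components_}
    if model_name == "SVR":
        m, params = fit_svr(Xtr, ytr, cv_folds=min(cv_folds, 5), seed=seed)
        return m.predict, None, params
    if model_name == "GPR":
        m = GPREnsemble(random_state=seed).fit(Xtr, ytr)
        return m, None, {"kernels": list(m.models_.keys())}
    m, params = fit_baseline(Xtr, ytr, model_name, seed=seed)
    return m.predict, None, params


def evaluate_all(
    X: np.ndarray,
    table,
    split: SplitSpec,
    components: Sequence[str] | None = None,
    models: Sequence[str] = MODEL_NAMES,
    max_components: int = 30,
    cv_folds: int = 10,
    seed: int = 0,
) -> list[ModelEvalResult]:
    """Fit every requested model to every requested component.

    ``X`` is the (n_samples, n_grid) DTG matrix aligned with ``table``
    rows; ``split`` must already be populated. Components missing from the
    table are skipped with a warning. GPR rows report the mean of the
    three kernels' metrics.
    """
    if split.train_idx is None or split.test_idx is None:
        raise ValueError("split must be populated via split_dataset")
    names = components if components is not None else table.component_names
    results: list[ModelEvalResult] = []
    for comp in names:
        if comp not in table.component_names:
            warnings.warn(f"component '{comp}' missing from table; skipped")
            continue
        y = table.values_for(comp)
        Xtr, Xte = X[split.train_idx], X[split.test_idx]
        ytr, yte = y[split.train_idx], y[split.test_idx]
        for model_name in models:
            if model_name not in MODEL_NAMES:
                raise ValueError(f"unknown model '{model_name}'")
            max_A = min(max_components, len(ytr) - 1, X.shape[1])
            fitted, n_latent, params = _fit_one(
                model_name, Xtr, ytr, seed, max_A, cv_folds
            )
            if model_name == "GPR":
                r2_tr, rmse_tr = fitted.mean_metrics(Xtr, ytr)
                r2_te, rmse_te = fitted.mean_metrics(Xte, yte)
            else:
                pred_tr, pred_te = fitted(Xtr), fitted(Xte)
                r2_tr, rmse_tr = r_squared(ytr, pred_tr), rmse(ytr, pred_tr)
                r2_te, rmse_te = r_squared(yte, pred_te), rmse(yte, pred_te)
            results.append(
                ModelEvalResult(
                    component=comp,
                    model=model_name,
                    r2_train=r2_tr,
                    rmse_train=rmse_tr,
                    r2_test=r2_te,
                    rmse_test=rmse_te,
                    n_latent=n_latent,
                    hyperparameters=params,
                )
            )
    return results


def results_to_frame(results: list[ModelEvalResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def results_from_frame(df: pd.DataFrame) -> list[ModelEvalResult]:
    return [ModelEvalResult.from_dict(row) for row in df.to_dict(orient="records")]
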