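"""Feature- and pixel-based predictors of complexity ratings.

Models follow the evaluation discipline of the complexity-prediction
literature: inputs standardised to zero mean and unit variance on the
training folds only (targets never rescaled), validation on held-out data
(10-fold, leave-one-out, or image-grouped splits), and Pearson's r as the
headline metric since the ratings live on an interval scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import transform as sktransform
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.model_selection import (
    GridSearchCV,
    GroupShuffleSplit,
    KFold,
    LeaveOneOut,
)
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import UndefinedCorrelationError, ValidationError

__all__ = [
    "ModelConfig",
    "FitResult",
    "correlation_metrics",
    "ComplexityRegressor",
    "fit_feature_models",
    "pixel_regression",
    "descriptor_vectors",
]

MODEL_KINDS = ("linear", "lasso", "ridge", "svr", "mlp", "pixel_linear")
CV_SCHEMES = ("kfold10", "loo", "grouped")


def default_alpha_grid() -> np.ndarray:
    """10 log-spaced regularisation strengths spanning 1e-15 .. 20."""
    return np.logspace(np.log10(1e-15), np.log10(20.0), 10)


@dataclass(frozen=True)
class ModelConfig:
    model_kind: str = "linear"
    alpha_grid: Sequence[float] = field(default_factory=lambda: tuple(default_alpha_grid()))
    mlp_layers: tuple[int, ...] = (128, 64, 32)
    svr_kernel: str = "rbf"
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    cv_scheme: str = "loo"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValidationError(f"unknown model_kind {self.model_kind!r}")
        if self.cv_scheme not in CV_SCHEMES:
            raise ValidationError(f"unknown cv_scheme {self.cv_scheme!r}")


@dataclass
class FitResult:
    """Pooled validation predictions and the correlation metrics."""

    predictions: pd.Series  # index = item id, validation predictions pooled over folds
    fold_of: pd.Series  # index = item id, fold number
    pearson_r: float
    spearman_rho: float
    coefficients: pd.Series | None = None
    alpha: float | None = None
    model_kind: str = "linear"
    cv_scheme: str = "loo"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model_kind": self.model_kind,
            "cv_scheme": self.cv_scheme,
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "alpha": self.alpha,
            "predictions": {str(k): float(v) for k, v in self.predictions.items()},
            "fold_of": {str(k): int(v) for k, v in self.fold_of.items()},
            "coefficients": (
                None
                if self.coefficients is None
                else {str(k): float(v) for k, v in self.coefficients.items()}
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def correlation_metrics(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """(Pearson r, Spearman rho); raises on zero-variance input."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValidationError("correlation needs two equal-length 1-D vectors, n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("correlation inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    r = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    return r, rho


class ComplexityRegressor(RegressorMixin, BaseEstimator):
    """Standardise-then-regress estimator over a configurable model family.

    model_kind: 'linear' (OLS), 'lasso'/'ridge' (alpha chosen on a log grid
    by inner 5-fold CV), 'svr' (RBF kernel, C=1, epsilon=0.1 by default),
    'mlp' (ReLU layers (128, 64, 32, 1), 200 epochs, early stopping on a
    10% inner split), or 'pixel_linear' (ridge-stabilised least squares for
    p >> n pixel vectors).  Feature standardisation is fit inside the
    estimator, so cross-validation around it never leaks validation data.
    """

    def __init__(
        self,
        model_kind: str = "linear",
        alpha_grid: Sequence[float] | None = None,
        mlp_layers: tuple[int, ...] = (128, 64, 32),
        svr_kernel: str = "rbf",
        svr_c: float = 1.0,
        svr_epsilon: float = 0.1,
        pixel_alpha: float = 1e-3,
        inner_cv: int = 5,
        max_iter: int = 200,
        random_state: int | None = 0,
    ):
        self.model_kind = model_kind
        self.alpha_grid = alpha_grid
        self.mlp_layers = mlp_layers
        self.svr_kernel = svr_kernel
        self.svr_c = svr_c
        self.svr_epsilon = svr_epsilon
        self.pixel_alpha = pixel_alpha
        self.inner_cv = inner_cv
        self.max_iter = max_iter
        self.random_state = random_state

    def _base_model(self):
        kind = self.model_kind
        if kind == "linear":
            return LinearRegression()
        if kind == "lasso":
            return Lasso(max_iter=50_000)
        if kind == "ridge":
            return Ridge()
        if kind == "svr":
            return SVR(kernel=self.svr_kernel, C=self.svr_c, epsilon=self.svr_epsilon)
        if kind == "mlp":
            return MLPRegressor(
                hidden_layer_sizes=tuple(self.mlp_layers),
                activation="relu",
                max_iter=self.max_iter,
                early_stopping=True,
                validation_fraction=0.1,
                random_state=self.random_state,
            )
        if kind == "pixel_linear":
            return Ridge(alpha=self.pixel_alpha)
        raise ValidationError(f"unknown model_kind {self.model_kind!r}")

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        model = self._base_model()
        if self.model_kind in ("lasso", "ridge"):
            grid = (
                np.asarray(list(self.alpha_grid), dtype=np.float64)
                if self.alpha_grid is not None
                else default_alpha_grid()
            )
            model = GridSearchCV(
                model,
                {"alpha": grid},
                cv=min(self.inner_cv, max(2, len(y) // 2)),
                scoring="neg_mean_squared_error",
            )
        pipeline = Pipeline([("scale", StandardScaler()), ("model", model)])
        import warnings

        from scipy.linalg import LinAlgWarning

        with warnings.catch_warnings():
            # the alpha grid deliberately probes the unregularised end
            # (1e-15), which is ill-conditioned when p is close to n
            warnings.simplefilter("ignore", LinAlgWarning)
            pipeline.fit(X, y)
        self.pipeline_ = pipeline
        self.n_features_in_ = X.shape[1]
        fitted = pipeline.named_steps["model"]
        if isinstance(fitted, GridSearchCV):
            self.alpha_ = float(fitted.best_params_["alpha"])
            inner = fitted.best_estimator_
        else:
            self.alpha_ = None
            inner = fitted
        self.coef_ = getattr(inner, "coef_", None)
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        X = check_array(X, dtype=np.float64)
        return self.pipeline_.predict(X)


def _make_cv(cv_scheme: str, n: int, seed: int, groups: np.ndarray | None):
    if cv_scheme == "loo":
        if n < 3:
            raise ValidationError("leave-one-out needs n >= 3")
        return LeaveOneOut(), None
    if cv_scheme == "kfold10":
        if n < 10:
            raise ValidationError(f"10-fold CV needs n >= 10, got {n}")
        return KFold(n_splits=10, shuffle=True, random_state=seed), None
    if cv_scheme == "grouped":
        if groups is None:
            raise ValidationError("grouped CV needs group labels")
        return GroupShuffleSplit(n_splits=10, test_size=0.1, random_state=seed), groups
    raise ValidationError(f"unknown cv_scheme {cv_scheme!r}")


def fit_feature_models(
    features: pd.DataFrame,
    ratings: Mapping[str, float] | pd.Series,
    cfg: ModelConfig | None = None,
    groups: Mapping[str, str] | None = None,
) -> FitResult:
    """Cross-validate a feature model and return pooled validation metrics.

    ``features`` rows and ``ratings`` are aligned by image id; rows without
    a rating are dropped.  Standardisation happens inside each training
    fold (see :class:`ComplexityRegressor`), so validation items never
    influence the scaling.  For grouped CV each validation fold is a
    held-out 10% of the groups; predictions from all folds are pooled
    before the correlation is computed (for grouped CV an item can be
    predicted several times; the last fold's prediction is kept, while the
    metric averages per-fold correlations).
    """
    cfg = cfg or ModelConfig()
    ratings = pd.Series(dict(ratings) if not isinstance(ratings, pd.Series) else ratings)
    common = features.index.intersection(ratings.index)
    if len(common) < 3:
        raise ValidationError("need at least 3 rated feature rows")
    X = features.loc[common].to_numpy(dtype=np.float64)
    y = ratings.loc[common].to_numpy(dtype=np.float64)
    group_array = (
        np.asarray([groups[i] for i in common]) if groups is not None else None
    )

    cv, group_array = _make_cv(cfg.cv_scheme, len(common), cfg.seed, group_array)
    estimator = ComplexityRegressor(
        model_kind=cfg.model_kind,
        alpha_grid=cfg.alpha_grid,
        mlp_layers=cfg.mlp_layers,
        svr_kernel=cfg.svr_kernel,
        svr_c=cfg.svr_c,
        svr_epsilon=cfg.svr_epsilon,
        random_state=cfg.seed,
    )

    predictions = np.full(len(common), np.nan)
    fold_of = np.full(len(common), -1, dtype=int)
    alphas: list[float] = []
    coefs: list[np.ndarray] = []
    fold_rs: list[float] = []
    for fold, (train_idx, val_idx) in enumerate(cv.split(X, y, group_array)):
        est = clone(estimator)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[val_idx])
        predictions[val_idx] = pred
        fold_of[val_idx] = fold
        if est.alpha_ is not None:
            alphas.append(est.alpha_)
        if est.coef_ is not None:
            coefs.append(np.ravel(est.coef_))
        if len(val_idx) >= 3 and np.std(pred) > 0 and np.std(y[val_idx]) > 0:
            fold_rs.append(correlation_metrics(pred, y[val_idx])[0])

    mask = np.isfinite(predictions)
    if cfg.cv_scheme == "grouped" and fold_rs:
        # folds overlap across splits; report the mean per-fold validation r
        pearson_r = float(np.mean(fold_rs))
        _, spearman_rho = correlation_metrics(predictions[mask], y[mask])
    else:
        pearson_r, spearman_rho = correlation_metrics(predictions[mask], y[mask])

    coefficients = None
    if coefs:
        coefficients = pd.Series(np.mean(coefs, axis=0), index=list(features.columns))
    return FitResult(
        predictions=pd.Series(predictions[mask], index=common[mask]),
        fold_of=pd.Series(fold_of[mask], index=common[mask]),
        pearson_r=pearson_r,
        spearman_rho=spearman_rho,
        coefficients=coefficients,
        alpha=(max(set(alphas), key=alphas.count) if alphas else None),  # modal pick
        model_kind=cfg.model_kind,
        cv_scheme=cfg.cv_scheme,
    )


def pixel_regression(
    images: Mapping[str, np.ndarray],
    ratings: Mapping[str, float] | pd.Series,
    cfg: ModelConfig | None = None,
    raster: tuple[int, int] = (64, 64),
) -> FitResult:
    """Linear regression on raw pixel vectors under 10-fold CV.

    Every image is resized to a common raster and flattened to a
    height*width*3 vector; since p typically exceeds n the least squares is
    ridge-stabilised.  Baseline for pixel-level learning.
    """
    cfg = cfg or ModelConfig(model_kind="pixel_linear", cv_scheme="kfold10")
    if not images:
        raise ValidationError("pixel_regression needs at least one image")
    rows = {}
    for image_id, array in images.items():
        array = np.asarray(array, dtype=np.float64)
        if array.ndim == 2:
            array = np.stack([array] * 3, axis=-1)
        resized = sktransform.resize(array[..., :3], raster, anti_aliasing=True)
        rows[image_id] = resized.ravel()
    frame = pd.DataFrame.from_dict(rows, orient="index")
    pixel_cfg = ModelConfig(
        model_kind="pixel_linear",
        cv_scheme=cfg.cv_scheme if cfg.cv_scheme != "loo" else "kfold10",
        seed=cfg.seed,
    )
    return fit_feature_models(frame, ratings, pixel_cfg)


def descriptor_vectors(
    descriptors: Mapping[str, np.ndarray], n_sample: int = 500, seed: int = 0
) -> pd.DataFrame:
    """Fixed-length per-image vectors by resampling keypoint descriptors.

    ``n_sample`` keypoints are drawn with replacement from each image's
    descriptor set (shape (k, d), k >= 1) and concatenated into a vector of
    length n_sample*d, controlling for keypoint count while preserving
    descriptor character.
    """
    rng = np.random.default_rng(seed)
    dim = None
    rows = {}
    for image_id, desc in descriptors.items():
        desc = np.asarray(desc, dtype=np.float64)
        if desc.ndim != 2 or desc.shape[0] < 1:
            raise ValidationError(f"image {image_id!r} has no keypoint descriptors")
        if dim is None:
            dim = desc.shape[1]
        elif desc.shape[1] != dim:
            raise ValidationError(
                f"descriptor dimension mismatch for {image_id!r}: {desc.shape[1]} != {dim}"
            )
        picks = rng.integers(0, desc.shape[0], size=n_sample)
        rows[image_id] = desc[picks].ravel()
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "image_id"
    return frame
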