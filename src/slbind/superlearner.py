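"""Stacked-generalization (super learner) regression with NNLS meta-weights.

The super learner combines m base regression algorithms into one model in
three steps:

1. each base learner is trained and evaluated under a shared K-fold
   scheme, producing an n x m matrix Z of *out-of-fold* predictions
   (Z[i, j] is learner j's prediction for sample i made by a model that
   never saw sample i's fold — the construction that prevents information
   leakage into the combination step);
2. the meta-model m(z; beta) is a weighted combination of base-learner
   outputs whose weights solve the non-negative least-squares problem
   min ||Z beta - y||, beta >= 0 (Lawson-Hanson active set, implemented in
   :mod:`slbind.nnls`);
3. every base learner is refitted on the full training set; a prediction
   is the beta-weighted sum of the refitted learners' outputs.

The ten default base learners and their fixed hyperparameters: adaptive
boosting, bootstrap aggregation / random forest / extremely randomized
trees (1000 estimators each), decision tree, elastic net (max 1,000,000
iterations), k-nearest neighbors, ordinary linear regression, support
vector regression, and extreme gradient boosting (squared-error
objective); remaining settings are the defaults of the underlying
scikit-learn / xgboost implementations. Learners that are sensitive to
feature scale (elastic net, k-NN, SVR) standardize features inside their
own pipeline, fitted on training folds only.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import sklearn
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import (
    AdaBoostRegressor,
    BaggingRegressor,
    ExtraTreesRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBRegressor

from .errors import SlbindError
from .evaluation import rmse
from .nnls import kkt_residuals, nnls

__all__ = [
    "LEARNER_NAMES",
    "BaseLearnerSpec",
    "default_learner_specs",
    "FoldAssignment",
    "assign_folds",
    "compute_oof",
    "MetaModel",
    "fit_meta",
    "cross_validated_meta_predictions",
    "SuperLearnerRegressor",
    "fit_superlearner",
    "predict",
    "predict_individual",
    "load_superlearner",
]

#: Registry order; fixed, and also the column order of the OOF matrix.
LEARNER_NAMES = (
    "adaptive_boosting",
    "bootstrap_aggregation",
    "decision_tree",
    "elastic_net",
    "extremely_randomized_trees",
    "k_nearest_neighbors",
    "linear_regression",
    "random_forest",
    "support_vector_regression",
    "extreme_gradient_boosting",
)

# fixed per-learner seed offsets derived from the master seed
_LEARNER_SEED_OFFSET = 1001
_FOLD_SEED_OFFSET = 0


def _build_estimator(name: str, hyperparameters: dict, seed: int):
    hp = dict(hyperparameters)
    if name == "adaptive_boosting":
        return AdaBoostRegressor(random_state=seed, **hp)
    if name == "bootstrap_aggregation":
        hp.setdefault("n_estimators", 1000)
        return BaggingRegressor(random_state=seed, **hp)
    if name == "decision_tree":
        return DecisionTreeRegressor(random_state=seed, **hp)
    if name == "elastic_net":
        hp.setdefault("max_iter", 1_000_000)
        return make_pipeline(StandardScaler(), ElasticNet(random_state=seed, **hp))
    if name == "extremely_randomized_trees":
        hp.setdefault("n_estimators", 1000)
        return ExtraTreesRegressor(random_state=seed, **hp)
    if name == "k_nearest_neighbors":
        return make_pipeline(StandardScaler(), KNeighborsRegressor(**hp))
    if name == "linear_regression":
        return LinearRegression(**hp)
    if name == "random_forest":
        hp.setdefault("n_estimators", 1000)
        return RandomForestRegressor(random_state=seed, **hp)
    if name == "support_vector_regression":
        return make_pipeline(StandardScaler(), SVR(**hp))
    if name == "extreme_gradient_boosting":
        hp.setdefault("objective", "reg:squarederror")
        hp.setdefault("n_jobs", 1)
        return XGBRegressor(random_state=seed, **hp)
    raise SlbindError(f"unknown learner {name!r}; registry: {list(LEARNER_NAMES)}")


@dataclass(frozen=True)
class BaseLearnerSpec:
    """Name + hyperparameter overrides + seed for one base learner."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in LEARNER_NAMES:
            raise SlbindError(
                f"unknown learner {self.name!r}; registry: {list(LEARNER_NAMES)}"
            )

    def build(self):
        return _build_estimator(self.name, self.hyperparameters, self.seed)


def default_learner_specs(
    seed: int = 0, tree_estimators: int | None = None
) -> list[BaseLearnerSpec]:
    """The ten-learner registry with the fixed production hyperparameters.

    ``tree_estimators`` overrides the ensemble size of bagging, random
    forest and extra trees (used by simulation studies where the full
    1000-tree setting is computationally gratuitous; the default None
    keeps the production value).
    """
    specs = []
    for j, name in enumerate(LEARNER_NAMES):
        hp: dict = {}
        if tree_estimators is not None and name in (
            "bootstrap_aggregation",
            "extremely_randomized_trees",
            "random_forest",
        ):
            hp["n_estimators"] = tree_estimators
        specs.append(
            BaseLearnerSpec(name=name, hyperparameters=hp, seed=seed + _LEARNER_SEED_OFFSET + j)
        )
    return specs


# ---------------------------------------------------------------------------
# Folds and the out-of-fold matrix


@dataclass(frozen=True)
class FoldAssignment:
    n: int
    k: int
    fold_of: np.ndarray  # sample index -> fold index
    seed: int = 0

    def rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)


def assign_folds(n: int, k: int, seed: int = 0) -> FoldAssignment:
    """Seeded shuffle then contiguous blocks; fold sizes differ by <= 1."""
    if not 2 <= k <= n:
        raise SlbindError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f, block in enumerate(np.array_split(order, k)):
        fold_of[block] = f
    return FoldAssignment(n=n, k=k, fold_of=fold_of, seed=seed)


def compute_oof(
    X: np.ndarray,
    y: np.ndarray,
    learners: list[BaseLearnerSpec],
    folds: FoldAssignment,
) -> np.ndarray:
    """The n x m out-of-fold prediction matrix Z.

    For every fold f and learner j, learner j is trained on all rows
    outside f and predicts the rows of f, so each row is predicted exactly
    once per learner by a model that never saw it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0] or X.shape[0] != folds.n:
        raise SlbindError("X, y and folds disagree on sample count")
    Z = np.full((folds.n, len(learners)), np.nan)
    for f in range(folds.k):
        test = folds.rows(f)
        train = np.flatnonzero(folds.fold_of != f)
        for j, spec in enumerate(learners):
            est = spec.build()
            try:
                est.fit(X[train], y[train])
                Z[test, j] = est.predict(X[test])
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise SlbindError(
                    f"base learner {spec.name!r} failed on fold {f}: {exc}"
                ) from exc
    if not np.isfinite(Z).all():
        raise SlbindError("out-of-fold matrix contains non-finite predictions")
    return Z


# ---------------------------------------------------------------------------
# Meta-model


@dataclass(frozen=True)
class MetaModel:
    """Non-negative combination weights over the base learners."""

    beta: np.ndarray
    intercept: float = 0.0
    fitted_on: tuple = ()

    def combine(self, base_predictions: np.ndarray) -> np.ndarray:
        return np.asarray(base_predictions, dtype=float) @ self.beta + self.intercept


def fit_meta(Z: np.ndarray, y: np.ndarray, renormalize: bool = False) -> MetaModel:
    """NNLS fit of the meta-weights on the out-of-fold matrix.

    No intercept; weights are not rescaled unless ``renormalize`` asks for
    a sum-to-one comparison variant. An all-zero solution (no learner
    helps) is allowed but warned about.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = nnls(Z, y)
    stationarity, dual = kkt_residuals(Z, y, beta)
    scale = max(1.0, float(np.abs(Z.T @ y).max()))
    if max(stationarity, dual) > 1e-6 * scale:  # pragma: no cover - solver guard
        raise SlbindError("meta NNLS failed KKT check")
    if beta.sum() == 0:
        warnings.warn("meta-model degenerate: all NNLS weights are zero", stacklevel=2)
    elif renormalize:
        beta = beta / beta.sum()
    return MetaModel(beta=beta, intercept=0.0, fitted_on=(len(y), Z.shape[1]))


def cross_validated_meta_predictions(
    Z: np.ndarray, y: np.ndarray, folds: FoldAssignment
) -> np.ndarray:
    """Honest super-learner predictions: refit beta without each fold.

    For every fold, NNLS weights are fitted on the out-of-fold rows of Z
    belonging to the *other* folds and applied to the held-out rows, so
    the returned vector is cross-validated at the base level (Z itself)
    and at the meta level (beta). Used for reporting the super learner's
    own cross-validated RMSE / R^2.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    yhat = np.empty_like(y)
    for f in range(folds.k):
        test = folds.rows(f)
        train = np.flatnonzero(folds.fold_of != f)
        beta = nnls(Z[train], y[train])
        yhat[test] = Z[test] @ beta
    return yhat


# ---------------------------------------------------------------------------
# The estimator


class SuperLearnerRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn style super-learner regressor.

    Parameters
    ----------
    learner_specs : list of BaseLearnerSpec, optional
        Base-learner registry; defaults to the ten-learner production
        registry seeded from ``random_state``.
    k : int
        Number of folds of the out-of-fold scheme (default 10).
    random_state : int
        Master seed; fold and per-learner seeds derive from it by fixed
        offsets.
    renormalize_weights : bool
        Rescale the NNLS weights to sum to one (comparison variant; the
        default False keeps the plain NNLS solution).

    Attributes (after fit)
    ----------------------
    learner_names_ : tuple of base-learner names (column order of Z)
    base_models_ : list of refitted estimators (trained on all rows)
    beta_ : non-negative meta-weights
    meta_ : MetaModel
    oof_ : the out-of-fold matrix Z
    folds_ : FoldAssignment
    cv_rmse_, cv_r2_ : per-learner out-of-fold RMSE and R^2
    sl_cv_rmse_, sl_cv_r2_ : cross-validated metrics of the combination
    """

    def __init__(
        self,
        learner_specs: list[BaseLearnerSpec] | None = None,
        k: int = 10,
        random_state: int = 0,
        renormalize_weights: bool = False,
    ) -> None:
        self.learner_specs = learner_specs
        self.k = k
        self.random_state = random_state
        self.renormalize_weights = renormalize_weights

    def _specs(self) -> list[BaseLearnerSpec]:
        if self.learner_specs is None:
            return default_learner_specs(seed=self.random_state)
        return [
            dataclasses.replace(s, seed=s.seed if s.seed else self.random_state + _LEARNER_SEED_OFFSET + j)
            for j, s in enumerate(self.learner_specs)
        ]

    def fit(self, X, y):
        X, y = self._validate_data(X, y)
        n = X.shape[0]
        if n < 2 * self.k:
            raise SlbindError(
                f"n={n} is too small for k={self.k} folds; use a smaller k (need n >= 2k)"
            )
        specs = self._specs()
        self.learner_names_ = tuple(s.name for s in specs)
        self.folds_ = assign_folds(n, self.k, seed=self.random_state + _FOLD_SEED_OFFSET)
        self.oof_ = compute_oof(X, y, specs, self.folds_)
        self.meta_ = fit_meta(self.oof_, y, renormalize=self.renormalize_weights)
        self.beta_ = self.meta_.beta

        ybar = y.mean()
        ss_tot = float(((y - ybar) ** 2).sum())

        def _r2(yhat: np.ndarray) -> float:
            # R^2 is undefined for a zero-variance target; report 0.0
            if ss_tot == 0.0:
                return 0.0
            return 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot

        self.cv_rmse_ = {
            name: rmse(y, self.oof_[:, j]) for j, name in enumerate(self.learner_names_)
        }
        self.cv_r2_ = {
            name: _r2(self.oof_[:, j]) for j, name in enumerate(self.learner_names_)
        }
        yhat_cv = cross_validated_meta_predictions(self.oof_, y, self.folds_)
        self.sl_cv_rmse_ = rmse(y, yhat_cv)
        self.sl_cv_r2_ = _r2(yhat_cv)

        self.base_models_ = []
        for spec in specs:
            est = spec.build()
            try:
                est.fit(X, y)
            except Exception as exc:  # noqa: BLE001
                raise SlbindError(f"full-set refit of {spec.name!r} failed: {exc}") from exc
            self.base_models_.append(est)
        self._fit_specs_ = specs
        return self

    def _validate_data(self, X, y=None, reset=True):
        X = np.asarray(getattr(X, "values", X), dtype=float)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {X.shape}")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        if reset:
            self.n_features_in_ = X.shape[1]
        elif X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fitted with {self.n_features_in_}"
            )
        if y is None:
            return X
        y = np.asarray(getattr(y, "values", y), dtype=float).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if not np.isfinite(y).all():
            raise ValueError("y contains non-finite values")
        return X, y

    def base_predictions(self, X) -> np.ndarray:
        """n x m matrix of full-set-refit base-learner predictions."""
        check_is_fitted(self, "base_models_")
        X = self._validate_data(X, reset=False)
        return np.column_stack([m.predict(X) for m in self.base_models_])

    def predict(self, X) -> np.ndarray:
        """Weighted combination sum_j beta_j f_j(x), in kcal/mol."""
        check_is_fitted(self, "beta_")
        if self.beta_.sum() == 0:
            warnings.warn(
                "meta-model degenerate (all weights zero); predictions are 0", stacklevel=2
            )
        return self.meta_.combine(self.base_predictions(X))

    def predict_individual(self, X, learner_name: str) -> np.ndarray:
        """Prediction of one named base learner (full-set refit)."""
        check_is_fitted(self, "base_models_")
        if learner_name not in self.learner_names_:
            raise SlbindError(
                f"unknown learner {learner_name!r}; registry: {list(self.learner_names_)}"
            )
        j = self.learner_names_.index(learner_name)
        X = self._validate_data(X, reset=False)
        return self.base_models_[j].predict(X)

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize as a bundle directory: manifest.json + model blobs."""
        check_is_fitted(self, "base_models_")
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format": "slbind-superlearner-bundle/1",
            "python": platform.python_version(),
            "sklearn": sklearn.__version__,
            "numpy": np.__version__,
            "params": {
                "k": self.k,
                "random_state": self.random_state,
                "renormalize_weights": self.renormalize_weights,
            },
            "learner_names": list(self.learner_names_),
            "learner_specs": [
                {"name": s.name, "hyperparameters": s.hyperparameters, "seed": s.seed}
                for s in self._fit_specs_
            ],
            "beta": self.beta_.tolist(),
            "n_features_in": int(self.n_features_in_),
            "folds": {"n": self.folds_.n, "k": self.folds_.k, "seed": self.folds_.seed},
            "cv_rmse": self.cv_rmse_,
            "cv_r2": self.cv_r2_,
            "sl_cv_rmse": self.sl_cv_rmse_,
            "sl_cv_r2": self.sl_cv_r2_,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
        joblib.dump(self.base_models_, path / "base_models.joblib")

    @classmethod
    def load(cls, path: str | Path) -> "SuperLearnerRegressor":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text(encoding="utf-8"))
        if manifest.get("format") != "slbind-superlearner-bundle/1":
            raise SlbindError(f"{path} is not a super-learner bundle")
        specs = [
            BaseLearnerSpec(name=s["name"], hyperparameters=s["hyperparameters"], seed=s["seed"])
            for s in manifest["learner_specs"]
        ]
        obj = cls(
            learner_specs=specs,
            k=manifest["params"]["k"],
            random_state=manifest["params"]["random_state"],
            renormalize_weights=manifest["params"]["renormalize_weights"],
        )
        obj.learner_names_ = tuple(manifest["learner_names"])
        obj.beta_ = np.asarray(manifest["beta"], dtype=float)
        obj.meta_ = MetaModel(beta=obj.beta_, intercept=0.0)
        obj.n_features_in_ = manifest["n_features_in"]
        obj.cv_rmse_ = manifest["cv_rmse"]
        obj.cv_r2_ = manifest["cv_r2"]
        obj.sl_cv_rmse_ = manifest["sl_cv_rmse"]
        obj.sl_cv_r2_ = manifest["sl_cv_r2"]
        obj.base_models_ = joblib.load(path / "base_models.joblib")
        obj._fit_specs_ = specs
        return obj


# ---------------------------------------------------------------------------
# Thin functional wrappers


def fit_superlearner(
    X,
    y,
    learners: list[BaseLearnerSpec] | None = None,
    k: int = 10,
    seed: int = 0,
    renormalize_weights: bool = False,
) -> SuperLearnerRegressor:
    return SuperLearnerRegressor(
        learner_specs=learners, k=k, random_state=seed, renormalize_weights=renormalize_weights
    ).fit(X, y)


def predict(sl: SuperLearnerRegressor, X) -> np.ndarray:
    return sl.predict(X)


def predict_individual(sl: SuperLearnerRegressor, X, learner_name: str) -> np.ndarray:
    return sl.predict_individual(X, learner_name)


def load_superlearner(path: str | Path) -> SuperLearnerRegressor:
    return SuperLearnerRegressor.load(path)
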