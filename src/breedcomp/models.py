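"""Model backends sharing one predict-GBC contract, plus (de)serialisation.

Four backends — the numpy MLP (:mod:`.mlp`), random forest, support vector
regression and the supervised ancestry-likelihood estimator
(:mod:`.likelihood`) — all consume the one-hot genotype feature matrix and
return one ancestry vector per sample. RF and SVR have no structural
simplex guarantee, so their raw multi-output regressions are clipped to
``[0, 1]`` and renormalised to sum to 1 (an all-zero row raises instead of
silently renormalising).

Each backend also exists in a classification-framework variant (the "-CLA"
ablation): targets become one-hot class labels over the purebreds plus an
explicit hybrid class, the loss becomes cross-entropy (or the native
classifier criterion), and ``predict`` returns class probabilities rather
than ancestry proportions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.svm import SVC, SVR

from .likelihood import SupervisedAdmixture
from .mlp import MLPGBCRegressor

__all__ = [
    "MLPGBCRegressor",
    "SupervisedAdmixture",
    "RandomForestGBC",
    "SVRGBC",
    "make_backend",
    "train_mlp",
    "train_rf",
    "train_svr",
    "fit_supervised_likelihood",
    "predict_gbc",
    "save_model",
    "load_model",
    "simplex_project",
]


class NotOnSimplexError(ValueError):
    """Raw predictions clipped to an all-zero row; cannot renormalise."""


def simplex_project(raw: np.ndarray) -> np.ndarray:
    """Clip component-wise to [0, 1] then renormalise rows to sum to 1."""
    clipped = np.clip(raw, 0.0, 1.0)
    sums = clipped.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        bad = int(np.argmax(sums[:, 0] == 0))
        raise NotOnSimplexError(
            f"prediction row {bad} clipped to all zeros; cannot renormalise"
        )
    return clipped / sums


def _check_targets(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    if y.ndim != 2:
        raise ValueError("targets must be a 2-D matrix")
    if int((y.max(axis=0) > 0).sum()) < 2:
        raise ValueError("degenerate targets: fewer than 2 breeds/classes represented")
    return y


def _resolve_names(breeds, k: int) -> tuple[str, ...]:
    names = tuple(breeds) if breeds is not None else tuple(f"class{i}" for i in range(k))
    if len(names) != k:
        raise ValueError(f"{len(names)} names given but targets have {k} columns")
    return names


def _check_width(est, X) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != est.n_features_in_:
        got = X.shape[1] if X.ndim == 2 else X.shape
        raise ValueError(f"expected {est.n_features_in_} features, got {got}")
    return X


class RandomForestGBC(BaseEstimator):
    """Random-forest GBC backend (natively multi-output regression trees)."""

    def __init__(
        self,
        n_estimators: int = 100,
        max_depth: int | None = None,
        max_features: str | float = "sqrt",
        framework: str = "regression",
        breeds: tuple[str, ...] | None = None,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_features = max_features
        self.framework = framework
        self.breeds = breeds
        self.random_state = random_state

    def fit(self, X, y):
        y = _check_targets(y)
        kwargs = dict(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            max_features=self.max_features,
            random_state=self.random_state,
        )
        if self.framework == "regression":
            self.model_ = RandomForestRegressor(**kwargs).fit(X, y)
        elif self.framework == "classification":
            self.model_ = RandomForestClassifier(**kwargs).fit(X, y.argmax(axis=1))
        else:
            raise ValueError(f"unknown framework {self.framework!r}")
        self.n_features_in_ = np.asarray(X).shape[1]
        self.n_outputs_ = y.shape[1]
        self.breeds_ = _resolve_names(self.breeds, y.shape[1])
        return self

    def predict(self, X) -> np.ndarray:
        X = _check_width(self, X)
        if self.framework == "regression":
            return simplex_project(np.atleast_2d(self.model_.predict(X)))
        probs = np.zeros((X.shape[0], self.n_outputs_))
        probs[:, self.model_.classes_] = self.model_.predict_proba(X)
        return probs

    predict_gbc = predict


class SVRGBC(BaseEstimator):
    """Support-vector GBC backend: one epsilon-SVR per breed component."""

    def __init__(
        self,
        kernel: str = "rbf",
        C: float = 10.0,
        gamma: str | float = "scale",
        degree: int = 3,
        epsilon: float = 0.01,
        framework: str = "regression",
        breeds: tuple[str, ...] | None = None,
        random_state: int = 0,
    ):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.degree = degree
        self.epsilon = epsilon
        self.framework = framework
        self.breeds = breeds
        self.random_state = random_state

    def fit(self, X, y):
        y = _check_targets(y)
        kwargs = dict(kernel=self.kernel, C=self.C, gamma=self.gamma, degree=self.degree)
        if self.framework == "regression":
            self.models_ = [
                SVR(epsilon=self.epsilon, **kwargs).fit(X, y[:, k])
                for k in range(y.shape[1])
            ]
        elif self.framework == "classification":
            self.model_ = SVC(
                probability=True, random_state=self.random_state, **kwargs
            ).fit(X, y.argmax(axis=1))
        else:
            raise ValueError(f"unknown framework {self.framework!r}")
        self.n_features_in_ = np.asarray(X).shape[1]
        self.n_outputs_ = y.shape[1]
        self.breeds_ = _resolve_names(self.breeds, y.shape[1])
        return self

    def predict(self, X) -> np.ndarray:
        X = _check_width(self, X)
        if self.framework == "regression":
            raw = np.column_stack([m.predict(X) for m in self.models_])
            return simplex_project(raw)
        probs = np.zeros((X.shape[0], self.n_outputs_))
        probs[:, self.model_.classes_] = self.model_.predict_proba(X)
        return probs

    predict_gbc = predict


_BACKENDS = {
    "mlp": MLPGBCRegressor,
    "rf": RandomForestGBC,
    "svr": SVRGBC,
    "likelihood": SupervisedAdmixture,
}


def make_backend(name: str, **params) -> BaseEstimator:
    """Instantiate a backend by short name: mlp, rf, svr or likelihood."""
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise ValueError(
            f"unknown backend {name!r}; choose from {sorted(_BACKENDS)}"
        ) from None
    if name == "likelihood" and "framework" in params:
        if params.pop("framework") != "regression":
            raise ValueError("the likelihood backend only supports the regression framework")
    return cls(**params)


# -- spec-level convenience wrappers --------------------------------------

def train_mlp(x, y, **params) -> MLPGBCRegressor:
    return MLPGBCRegressor(**params).fit(_values(x), y)


def train_rf(x, y, **params) -> RandomForestGBC:
    return RandomForestGBC(**params).fit(_values(x), y)


def train_svr(x, y, **params) -> SVRGBC:
    return SVRGBC(**params).fit(_values(x), y)


def fit_supervised_likelihood(x, y, **params) -> SupervisedAdmixture:
    return SupervisedAdmixture(**params).fit(_values(x), y)


def predict_gbc(model, x) -> np.ndarray:
    """Predict ancestry vectors (or class probabilities for -CLA models)."""
    return model.predict(_values(x))


def _values(x) -> np.ndarray:
    return x.values if hasattr(x, "values") else np.asarray(x)


# -- serialisation ---------------------------------------------------------

@dataclass
class _Codec:
    save: callable
    load: callable


def _save_mlp(m: MLPGBCRegressor, d: Path) -> None:
    arrays = {f"w{i}": w for i, w in enumerate(m.weights_)}
    arrays.update({f"b{i}": b for i, b in enumerate(m.biases_)})
    np.savez(d / "params.npz", **arrays)


def _load_mlp(m: MLPGBCRegressor, d: Path) -> None:
    data = np.load(d / "params.npz")
    n = len([k for k in data.files if k.startswith("w")])
    m.weights_ = [data[f"w{i}"] for i in range(n)]
    m.biases_ = [data[f"b{i}"] for i in range(n)]


def _save_likelihood(m: SupervisedAdmixture, d: Path) -> None:
    np.savez(d / "params.npz", freqs=m.freqs_)


def _load_likelihood(m: SupervisedAdmixture, d: Path) -> None:
    m.freqs_ = np.load(d / "params.npz")["freqs"]


def _save_sklearn(m, d: Path) -> None:
    inner = m.models_ if hasattr(m, "models_") else m.model_
    joblib.dump(inner, d / "params.joblib")


def _load_sklearn(m, d: Path) -> None:
    inner = joblib.load(d / "params.joblib")
    if isinstance(inner, list):
        m.models_ = inner
    else:
        m.model_ = inner


_CODECS = {
    "mlp": _Codec(_save_mlp, _load_mlp),
    "likelihood": _Codec(_save_likelihood, _load_likelihood),
    "rf": _Codec(_save_sklearn, _load_sklearn),
    "svr": _Codec(_save_sklearn, _load_sklearn),
}
_CLASS_TO_BACKEND = {cls.__name__: name for name, cls in _BACKENDS.items()}


def save_model(model: BaseEstimator, model_dir) -> None:
    """Serialise a fitted backend to a directory (config JSON + parameter blobs)."""
    d = Path(model_dir)
    d.mkdir(parents=True, exist_ok=True)
    backend = _CLASS_TO_BACKEND[type(model).__name__]
    fitted = {
        k: getattr(model, k)
        for k in ("n_features_in_", "n_outputs_", "n_epochs_", "best_val_loss_")
        if hasattr(model, k)
    }
    config = {
        "backend": backend,
        "framework": getattr(model, "framework", "regression"),
        "breeds": list(model.breeds_),
        "params": _jsonable(model.get_params()),
        "fitted": _jsonable(fitted),
    }
    (d / "config.json").write_text(json.dumps(config, indent=2))
    _CODECS[backend].save(model, d)


def load_model(model_dir) -> BaseEstimator:
    d = Path(model_dir)
    config = json.loads((d / "config.json").read_text())
    backend = config["backend"]
    params = dict(config["params"])
    for key in ("breeds", "hidden_sizes"):
        if params.get(key) is not None:
            params[key] = tuple(params[key])
    model = _BACKENDS[backend](**params)
    model.breeds_ = tuple(config["breeds"])
    for k, v in config["fitted"].items():
        setattr(model, k, v)
    _CODECS[backend].load(model, d)
    return model


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
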