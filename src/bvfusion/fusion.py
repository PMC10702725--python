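"""Fusing per-feature belief-values into one label.

Three fusers operate on the length-N belief vector F: majority voting
over the component signs, a linear SVM on F, and a small multilayer
perceptron (two tanh hidden layers of five units, linear output,
squared-error loss) that can capture non-linear complementarity between
the per-feature classifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVC

from .errors import ConfigurationError, InputError, NumericError, StateError

__all__ = ["FusionModel", "majority_vote", "fit_fusion", "predict_fusion", "FUSION_METHODS"]

FUSION_METHODS = ("majority", "linear_svm", "mlp")

#: MLP architecture: two hidden layers of five units each
_MLP_HIDDEN = (5, 5)
_MLP_MAX_ITER = 2000


@dataclass
class FusionModel:
    """A fitted fuser; ``estimator`` is None for majority voting."""

    method: str
    estimator: Any = field(default=None, repr=False)
    train_seed: int = 0

    def to_dict(self) -> dict:
        out: dict[str, Any] = {"method": self.method, "train_seed": self.train_seed}
        if self.method == "linear_svm" and self.estimator is not None:
            out["w"] = self.estimator.coef_.ravel().tolist()
            out["b"] = float(self.estimator.intercept_[0])
        elif self.method == "mlp" and self.estimator is not None:
            out["coefs"] = [c.tolist() for c in self.estimator.coefs_]
            out["intercepts"] = [c.tolist() for c in self.estimator.intercepts_]
        return out


def majority_vote(F: np.ndarray) -> int:
    """Label by the sign of the summed component signs.

    An exactly zero vote sum is broken toward the sign of the component
    with the largest magnitude (the confidence the belief-value itself
    defines); a fully zero vector defaults to +1.
    """
    F = np.asarray(F, dtype=float).ravel()
    if not np.all(np.isfinite(F)):
        raise InputError("belief vector must be finite")
    total = np.sign(F).sum()
    if total > 0:
        return 1
    if total < 0:
        return -1
    top = F[int(np.argmax(np.abs(F)))]
    if top > 0:
        return 1
    if top < 0:
        return -1
    return 1


def fit_fusion(
    F_train: np.ndarray, y: np.ndarray, method: str = "mlp", seed: int = 0
) -> FusionModel:
    """Train a fuser on training-subject belief vectors.

    Deterministic given (F_train, y, method, seed).  ``majority``
    returns a parameterless model.
    """
    if method not in FUSION_METHODS:
        raise ConfigurationError(f"method must be one of {FUSION_METHODS}, got {method!r}")
    if method == "majority":
        return FusionModel(method=method, train_seed=seed)
    F_train = np.asarray(F_train, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if F_train.ndim != 2 or len(F_train) != len(y):
        raise InputError(f"F_train shape {F_train.shape} incompatible with y length {len(y)}")
    if np.unique(y).size < 2:
        raise InputError("both classes must be present to fit a fusion model")
    if method == "linear_svm":
        est = SVC(kernel="linear", C=1.0)
        est.fit(F_train, y)
        return FusionModel(method=method, estimator=est, train_seed=seed)
    est = MLPRegressor(
        hidden_layer_sizes=_MLP_HIDDEN,
        activation="tanh",
        solver="lbfgs",
        max_iter=_MLP_MAX_ITER,
        tol=1e-6,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # hitting the iteration cap is an accepted stopping rule here
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(F_train, y)
    if not np.isfinite(est.loss_):
        raise NumericError(f"MLP training diverged (loss {est.loss_})")
    return FusionModel(method="mlp", estimator=est, train_seed=seed)


def predict_fusion(model: FusionModel, F: np.ndarray) -> np.ndarray | int:
    """Predict labels for one belief vector (1-D) or a stack of them (2-D).

    The MLP thresholds its scalar output at 0 (0 maps to +1); the
    linear fuser uses the sign of its decision function.
    """
    F = np.asarray(F, dtype=float)
    single = F.ndim == 1
    F2 = F[None, :] if single else F
    if model.method == "majority":
        labels = np.array([majority_vote(row) for row in F2])
    else:
        if model.estimator is None:
            raise StateError("fusion model is not fitted")
        n_expected = (
            model.estimator.coef_.shape[1]
            if model.method == "linear_svm"
            else model.estimator.coefs_[0].shape[0]
        )
        if F2.shape[1] != n_expected:
            raise InputError(f"F has {F2.shape[1]} components, model expects {n_expected}")
        if model.method == "linear_svm":
            score = model.estimator.decision_function(F2)
        else:
            score = model.estimator.predict(F2)
        labels = np.where(score >= 0, 1, -1)
    return int(labels[0]) if single else labels
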