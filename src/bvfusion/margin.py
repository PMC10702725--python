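"""Linear maximum-margin classifier with geometric-margin probabilities.

One linear SVM is trained per feature type.  The raw decision value is
converted to a geometric (Euclidean) distance from the hyperplane, and
that distance to a signed probability

    s = sign(r) / (1 + exp(-|r|)),

an odd, sigmoid-shaped map whose magnitude grows from 1/2 at the
boundary towards 1 far from it.  Training points store their labelled
geometric margins r_i = y_i (w.x_i + b) / ||w||, which are positive
exactly when the point is on its own class's side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .errors import InputError, NumericError, StateError

__all__ = ["MarginModel", "fit_margin_classifier", "signed_distance", "margin_probability"]


@dataclass
class MarginModel:
    """Trained hyperplane plus the training-point margin bookkeeping.

    ``train_margins`` are the labelled geometric margins r_i,
    ``train_probs`` the corresponding probabilities signed by the true
    label, and ``train_sides`` the predicted side of each training
    point (sign of its unlabelled distance).
    """

    w: np.ndarray
    b: float
    C: float
    X_train: np.ndarray = field(repr=False)
    y_train: np.ndarray = field(repr=False)
    train_margins: np.ndarray = field(repr=False)
    train_probs: np.ndarray = field(repr=False)
    train_sides: np.ndarray = field(repr=False)
    _cov_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_features(self) -> int:
        return self.w.shape[0]

    def to_dict(self) -> dict:
        """JSON-serialisable summary (weights, offset, C, training hash)."""
        return {
            "w": self.w.tolist(),
            "b": self.b,
            "C": self.C,
            "n_train": int(len(self.y_train)),
            "train_hash": hash(self.X_train.tobytes() + self.y_train.tobytes()) & 0x7FFFFFFF,
        }


def fit_margin_classifier(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> MarginModel:
    """Fit a linear SVM and store per-training-point margins.

    Deterministic given (X, y, C).  Raises on single-class input or a
    degenerate (zero-norm) hyperplane.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InputError(f"X shape {X.shape} incompatible with y length {y.shape[0]}")
    classes = np.unique(y)
    if not np.array_equal(classes, [-1.0, 1.0]):
        if classes.size < 2:
            raise InputError("both classes must be present to fit a margin classifier")
        raise InputError(f"labels must be -1/+1, got {classes}")
    svc = SVC(kernel="linear", C=C)
    svc.fit(X, y)
    w = svc.coef_.ravel().astype(float)
    b = float(svc.intercept_[0])
    norm = float(np.linalg.norm(w))
    if norm == 0.0:
        raise NumericError("degenerate fit: hyperplane normal has zero norm")
    raw = (X @ w + b) / norm
    margins = y * raw
    probs = y / (1.0 + np.exp(-np.abs(margins)))
    return MarginModel(
        w=w,
        b=b,
        C=C,
        X_train=X,
        y_train=y.astype(int),
        train_margins=margins,
        train_probs=probs,
        train_sides=np.sign(raw).astype(int),
    )


def signed_distance(model: MarginModel, x: np.ndarray) -> float | np.ndarray:
    """Unlabelled geometric distance (w.x + b) / ||w||; sign = predicted side."""
    if model is None or model.w is None:
        raise StateError("model is not fitted")
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.n_features:
        raise InputError(f"x has dimension {x.shape[-1]}, model expects {model.n_features}")
    if not np.all(np.isfinite(x)):
        raise InputError("x contains non-finite values")
    r = (x @ model.w + model.b) / np.linalg.norm(model.w)
    return float(r) if np.ndim(r) == 0 else r


def margin_probability(r: float | np.ndarray) -> float | np.ndarray:
    """Signed sigmoid probability of a geometric margin.

    ``sign(r) / (1 + exp(-|r|))``; a point exactly on the boundary
    (r = 0) maps to 0 and contributes no class evidence.
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise InputError("margin must be finite")
    s = np.sign(r) / (1.0 + np.exp(-np.abs(r)))
    return float(s) if s.ndim == 0 else s
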