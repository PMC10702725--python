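"""Belief-values: distribution-based spatial transform of SVM outputs.

A test sample's belief-value combines two sources of evidence from the
training points lying on its predicted side of the hyperplane (its
"nearest neighbours" in this construction):

1. distance information — each neighbour's signed margin probability
   s_j (how confidently the SVM places the neighbour);
2. local density information — a Gaussian weight w_j = phi(d'_j) of the
   neighbour's z-scored distance d'_j from the test sample.

Each neighbour contributes an effect f_j = w_j * s_j (ablations: f = s
alone, or f = w signed by the neighbour's class), and the belief-value
is the mean effect.  Its sign is the predicted label; its magnitude a
local, per-sample confidence.  Distances may be Euclidean, Manhattan or
Mahalanobis (with shrinkage-regularised training covariance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError, NumericError, StateError
from .features import FEATURE_NAMES
from .margin import MarginModel, margin_probability, signed_distance

__all__ = [
    "DstConfig",
    "NeighborSet",
    "BeliefVector",
    "pairwise_distance",
    "regularized_covariance",
    "normalize_distances",
    "gaussian_weight",
    "neighbor_effect",
    "compute_neighbor_set",
    "belief_value",
    "classify_bv",
    "belief_vector",
]

logger = logging.getLogger(__name__)

_METRICS = ("euclidean", "manhattan", "mahalanobis")
_EFFECT_MODES = ("w", "s", "w_times_s")
_SIGN_SOURCES = ("true_label", "predicted")

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class DstConfig:
    """Switches of the distribution-based spatial transform.

    ``distance_metric`` selects the sample-space metric; ``effect_mode``
    the neighbour effect (product of weight and probability, probability
    alone, or weight alone signed by the neighbour's class);
    ``neighbor_sign`` whether a neighbour's probability carries its true
    label or its predicted side; ``cov_shrinkage`` the ridge fraction
    added to the Mahalanobis covariance (times mean eigenvalue).
    """

    distance_metric: str = "mahalanobis"
    effect_mode: str = "w_times_s"
    neighbor_sign: str = "true_label"
    cov_shrinkage: float = 1e-2

    def __post_init__(self) -> None:
        if self.distance_metric not in _METRICS:
            raise ConfigurationError(
                f"distance_metric must be one of {_METRICS}, got {self.distance_metric!r}"
            )
        if self.effect_mode not in _EFFECT_MODES:
            raise ConfigurationError(
                f"effect_mode must be one of {_EFFECT_MODES}, got {self.effect_mode!r}"
            )
        if self.neighbor_sign not in _SIGN_SOURCES:
            raise ConfigurationError(
                f"neighbor_sign must be one of {_SIGN_SOURCES}, got {self.neighbor_sign!r}"
            )
        if not self.cov_shrinkage > 0:
            raise ConfigurationError(f"cov_shrinkage must be > 0, got {self.cov_shrinkage}")


@dataclass(frozen=True)
class NeighborSet:
    """Intermediate quantities of one belief-value computation."""

    members: np.ndarray
    distances: np.ndarray
    normalized: np.ndarray
    weights: np.ndarray
    probabilities: np.ndarray
    effects: np.ndarray

    @property
    def p(self) -> int:
        return int(self.members.size)


@dataclass(frozen=True)
class BeliefVector:
    """Per-feature belief-values F = [B-V_1 ... B-V_N] for one subject."""

    subject_id: str
    F: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if len(self.F) != len(self.feature_names):
            raise InputError(
                f"F has length {len(self.F)}, expected {len(self.feature_names)}"
            )
        if not np.all(np.isfinite(self.F)):
            raise InputError(f"belief vector of {self.subject_id} is not finite")


def regularized_covariance(X: np.ndarray, shrinkage: float) -> np.ndarray:
    """Sample covariance plus a ridge of ``shrinkage * (trace/dim) * I``."""
    X = np.asarray(X, dtype=float)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    dim = cov.shape[0]
    scale = np.trace(cov) / dim
    if scale <= 0:
        scale = 1.0  # zero-variance training block: fall back to identity ridge
    return cov + shrinkage * scale * np.eye(dim)


def _inverse_covariance(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(cov)
    except np.linalg.LinAlgError as err:
        raise NumericError(f"regularized covariance is singular: {err}") from err


def pairwise_distance(
    x: np.ndarray, x_j: np.ndarray, metric: str, cov: np.ndarray | None = None
) -> float:
    """Distance between two points under the configured metric.

    For ``mahalanobis``, ``cov`` is the (already regularised)
    covariance; with the identity it reduces to the Euclidean distance.
    """
    x = np.asarray(x, dtype=float).ravel()
    x_j = np.asarray(x_j, dtype=float).ravel()
    if x.shape != x_j.shape:
        raise InputError(f"dimension mismatch: {x.shape} vs {x_j.shape}")
    diff = x - x_j
    if metric == "euclidean":
        return float(np.linalg.norm(diff))
    if metric == "manhattan":
        return float(np.abs(diff).sum())
    if metric == "mahalanobis":
        if cov is None:
            raise ConfigurationError("mahalanobis distance requires a covariance matrix")
        vi = _inverse_covariance(np.asarray(cov, dtype=float))
        return float(np.sqrt(diff @ vi @ diff))
    raise ConfigurationError(f"unknown metric {metric!r}")


def _distances_to(x: np.ndarray, neighbors: np.ndarray, metric: str, vi) -> np.ndarray:
    diffs = neighbors - x[None, :]
    if metric == "euclidean":
        return np.sqrt((diffs**2).sum(axis=1))
    if metric == "manhattan":
        return np.abs(diffs).sum(axis=1)
    # mahalanobis; quadratic form clipped at 0 against round-off
    q = np.einsum("ij,jk,ik->i", diffs, vi, diffs)
    return np.sqrt(np.clip(q, 0.0, None))


def normalize_distances(D: np.ndarray) -> np.ndarray:
    """Z-score distances: (d - mean) / population SD; all-equal -> zeros."""
    D = np.asarray(D, dtype=float).ravel()
    if D.size == 0:
        raise InputError("distance set is empty")
    mu = D.mean()
    sigma = D.std(ddof=0)
    if sigma == 0.0:
        return np.zeros_like(D)
    return (D - mu) / sigma


def gaussian_weight(d_prime: float | np.ndarray) -> float | np.ndarray:
    """Standard-normal density of the normalised distance."""
    d = np.asarray(d_prime, dtype=float)
    if not np.all(np.isfinite(d)):
        raise InputError("normalized distance must be finite")
    w = np.exp(-0.5 * d**2) / _SQRT_2PI
    return float(w) if w.ndim == 0 else w


def neighbor_effect(
    w_j: float | np.ndarray, s_j: float | np.ndarray, mode: str = "w_times_s"
) -> float | np.ndarray:
    """Effect of one neighbour on the test sample.

    ``w_times_s``: product of weight and signed probability; ``s``: the
    probability alone; ``w``: the weight alone, signed by the class sign
    of s (a pure-density effect still needs a class sign to average
    meaningfully).
    """
    w_j = np.asarray(w_j, dtype=float)
    s_j = np.asarray(s_j, dtype=float)
    if mode == "w_times_s":
        f = w_j * s_j
    elif mode == "s":
        f = s_j + 0.0 * w_j  # broadcast-compatible copy
    elif mode == "w":
        f = w_j * np.sign(s_j)
    else:
        raise ConfigurationError(f"unknown effect mode {mode!r}")
    return float(f) if f.ndim == 0 else f


def _mahalanobis_vi(model: MarginModel, config: DstConfig) -> np.ndarray:
    """Inverse regularised covariance of the model's training points, memoised."""
    key = ("vi", config.cov_shrinkage)
    vi = model._cov_cache.get(key)
    if vi is None:
        cov = regularized_covariance(model.X_train, config.cov_shrinkage)
        vi = _inverse_covariance(cov)
        model._cov_cache[key] = vi
    return vi


def compute_neighbor_set(
    model: MarginModel,
    x: np.ndarray,
    config: DstConfig | None = None,
    exclude_index: int | None = None,
) -> NeighborSet | None:
    """Assemble the neighbour quantities for one test sample.

    Neighbours are every training point predicted on the same side of
    the hyperplane as ``x`` (excluding ``exclude_index``, used when the
    test sample itself is part of the training set).  Returns ``None``
    when that side is empty.
    """
    config = config or DstConfig()
    r_x = signed_distance(model, x)
    side = 1 if r_x >= 0 else -1
    mask = model.train_sides == side
    if exclude_index is not None:
        mask = mask.copy()
        mask[exclude_index] = False
    members = np.flatnonzero(mask)
    if members.size == 0:
        return None
    vi = _mahalanobis_vi(model, config) if config.distance_metric == "mahalanobis" else None
    D = _distances_to(np.asarray(x, dtype=float), model.X_train[members], config.distance_metric, vi)
    d_prime = normalize_distances(D)
    weights = gaussian_weight(d_prime)
    mags = 1.0 / (1.0 + np.exp(-np.abs(model.train_margins[members])))
    if config.neighbor_sign == "true_label":
        probs = model.y_train[members] * mags
    else:
        probs = model.train_sides[members] * mags
    effects = neighbor_effect(weights, probs, config.effect_mode)
    return NeighborSet(
        members=members,
        distances=D,
        normalized=d_prime,
        weights=np.asarray(weights),
        probabilities=np.asarray(probs),
        effects=np.asarray(effects),
    )


def belief_value(
    model: MarginModel,
    x: np.ndarray,
    config: DstConfig | None = None,
    exclude_index: int | None = None,
) -> float:
    """Belief-value of a test sample: mean neighbour effect.

    Falls back to the sample's own margin probability when its predicted
    side holds no training points (pathological small folds); the
    fallback is logged.
    """
    if model is None or getattr(model, "w", None) is None:
        raise StateError("margin model is not fitted")
    nn = compute_neighbor_set(model, x, config, exclude_index)
    if nn is None:
        bv = float(margin_probability(signed_distance(model, x)))
        logger.warning("empty neighbour side; belief-value fell back to own margin probability")
        return bv
    return float(nn.effects.mean())


def classify_bv(bv: float, svm_side: int = 1) -> int:
    """Label from a belief-value: its sign; exact zero -> the SVM side."""
    if not np.isfinite(bv):
        raise InputError(f"belief-value must be finite, got {bv}")
    if bv > 0:
        return 1
    if bv < 0:
        return -1
    return 1 if svm_side >= 0 else -1


def belief_vector(
    models: dict[str, MarginModel],
    feature_vectors: dict[str, np.ndarray],
    subject_id: str,
    config: DstConfig | None = None,
) -> BeliefVector:
    """Belief-values of one subject across all feature-type classifiers.

    ``models`` and ``feature_vectors`` are keyed by feature name; every
    model must have been fitted on the same training subjects (checked
    via training-set size).
    """
    names = tuple(models)
    sizes = {len(m.y_train) for m in models.values()}
    if len(sizes) > 1:
        raise StateError(f"models were fitted on different training-set sizes: {sorted(sizes)}")
    missing = set(names) - set(feature_vectors)
    if missing:
        raise InputError(f"feature vectors missing for: {sorted(missing)}")
    F = np.array([belief_value(models[n], feature_vectors[n], config) for n in names])
    return BeliefVector(subject_id=subject_id, F=F, feature_names=names)
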