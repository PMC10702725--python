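"""Repeated nested cross-validation of the fusion pipeline.

The protocol: stratified 10-fold outer cross-validation repeated 10
times.  Inside each outer training set, an inner stratified CV jointly
tunes, per feature type, the ROI-screening p-threshold and the SVM
regularisation C by maximising held-out belief-value-classifier
accuracy.  Final per-feature models are refit on the full outer
training set; the fuser is trained on training-subject belief vectors
(out-of-fold by default) and outer test subjects are scored exactly
once per repeat.  Every selection decision — ROI screening, (p, C)
tuning, covariance estimation, fusion training — sees training
subjects only.

Metrics treat the control group (+1) as the positive class.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .belief import DstConfig, belief_value, classify_bv
from .cohort import SubjectRecord
from .errors import ConfigurationError, InputError
from .features import (
    FEATURE_NAMES,
    FeatureConfig,
    FeatureSet,
    build_feature_sets,
    feature_matrix,
    select_rois,
)
from .fusion import FUSION_METHODS, fit_fusion, predict_fusion
from .margin import fit_margin_classifier, signed_distance

__all__ = [
    "CVConfig",
    "MetricReport",
    "FoldResult",
    "CVReport",
    "confusion_metrics",
    "run_nested_cv",
    "roi_frequency",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    """Protocol parameters for the repeated nested cross-validation."""

    outer_folds: int = 10
    repeats: int = 10
    inner_folds: int = 10
    p_grid: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.05)
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    fusion_method: str = "mlp"
    dst: DstConfig = field(default_factory=DstConfig)
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    master_seed: int = 0
    fusion_train_bv: str = "out_of_fold"

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ConfigurationError("outer_folds and inner_folds must both be >= 2")
        if self.repeats < 1:
            raise ConfigurationError("repeats must be >= 1")
        if not self.p_grid or not self.c_grid:
            raise ConfigurationError("p_grid and c_grid must be non-empty")
        if self.fusion_method not in FUSION_METHODS:
            raise ConfigurationError(f"fusion_method must be one of {FUSION_METHODS}")
        if self.fusion_train_bv not in ("out_of_fold", "resubstitution"):
            raise ConfigurationError(
                "fusion_train_bv must be 'out_of_fold' or 'resubstitution'"
            )


@dataclass(frozen=True)
class MetricReport:
    """Confusion counts and the rates derived from them (percentages).

    Rates with a zero denominator are ``None`` (reported missing, never
    silently zero).
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def _rate(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    @property
    def acc(self) -> float | None:
        return self._rate(self.tp + self.tn, self.n)

    @property
    def sen(self) -> float | None:
        return self._rate(self.tp, self.tp + self.fn)

    @property
    def spe(self) -> float | None:
        return self._rate(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._rate(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._rate(self.tn, self.tn + self.fn)

    @property
    def f1(self) -> float | None:
        return self._rate(2 * self.tp, 2 * self.tp + self.fp + self.fn)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "acc": self.acc,
            "sen": self.sen,
            "spe": self.spe,
            "ppv": self.ppv,
            "npv": self.npv,
            "f1": self.f1,
        }

    def __add__(self, other: "MetricReport") -> "MetricReport":
        return MetricReport(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricReport:
    """Confusion counts with the control group (+1) as positive class."""
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise InputError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    bad = set(np.unique(np.concatenate([y_true, y_pred]))) - {-1, 1}
    if bad:
        raise InputError(f"labels must be -1/+1, got extra values {sorted(bad)}")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))
    tn = int(np.sum((y_true == -1) & (y_pred == -1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    return MetricReport(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class FoldResult:
    """Everything recorded for one outer fold of one repeat."""

    repeat: int
    fold: int
    test_indices: np.ndarray
    y_true: np.ndarray
    chosen_p: dict[str, float]
    chosen_c: dict[str, float]
    selected_rois: dict[str, np.ndarray]
    model_params: dict[str, tuple[np.ndarray, float]]
    feature_preds: dict[str, np.ndarray]
    test_bvs: np.ndarray  # (n_test, N) belief vectors
    fused_preds: dict[str, np.ndarray]  # per fusion method
    fusion_params: dict[str, dict]


@dataclass(frozen=True)
class CVReport:
    """Full record of a repeated nested cross-validation run."""

    config: CVConfig
    folds: list[FoldResult]
    n_subjects: int
    n_rois: int

    def _fold_confusions(self, method: str | None = None, feature: str | None = None):
        for fr in self.folds:
            preds = fr.feature_preds[feature] if feature else fr.fused_preds[method]
            yield fr.repeat, confusion_metrics(fr.y_true, preds)

    def aggregate(self, method: str | None = None, feature: str | None = None) -> MetricReport:
        """Pooled confusion over all folds (fused by default)."""
        method = method or self.config.fusion_method
        total = MetricReport(0, 0, 0, 0)
        for _, cm in self._fold_confusions(method=None if feature else method, feature=feature):
            total = total + cm
        return total

    def per_repeat(self, method: str | None = None, feature: str | None = None) -> list[MetricReport]:
        """One pooled confusion per repeat."""
        method = method or self.config.fusion_method
        by_rep: dict[int, MetricReport] = {}
        for rep, cm in self._fold_confusions(method=None if feature else method, feature=feature):
            by_rep[rep] = by_rep.get(rep, MetricReport(0, 0, 0, 0)) + cm
        return [by_rep[k] for k in sorted(by_rep)]

    def summarize(self, method: str | None = None, feature: str | None = None) -> dict:
        """Mean +/- SD over repeats for each rate, plus pooled counts."""
        reps = self.per_repeat(method=method, feature=feature)
        out: dict = {"n_repeats": len(reps)}
        for name in ("acc", "sen", "spe", "ppv", "npv", "f1"):
            vals = [getattr(r, name) for r in reps]
            vals = [v for v in vals if v is not None]
            if vals:
                out[name] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=0))}
            else:
                out[name] = None
        out["pooled"] = self.aggregate(method=method, feature=feature).as_dict()
        return out

    @property
    def roi_selection_counts(self) -> dict[str, np.ndarray]:
        """Per feature, how many outer folds selected each ROI."""
        counts = {name: np.zeros(self.n_rois, dtype=int) for name in FEATURE_NAMES}
        for fr in self.folds:
            for name, idx in fr.selected_rois.items():
                counts[name][idx] += 1
        return counts

    def to_json(self, path) -> None:
        payload = {
            "n_subjects": self.n_subjects,
            "n_rois": self.n_rois,
            "fusion_method": self.config.fusion_method,
            "summary": {m: self.summarize(method=m) for m in FUSION_METHODS},
            "per_feature_summary": {f: self.summarize(feature=f) for f in FEATURE_NAMES},
            "roi_selection_counts": {
                k: v.tolist() for k, v in self.roi_selection_counts.items()
            },
            "folds": [
                {
                    "repeat": fr.repeat,
                    "fold": fr.fold,
                    "test_indices": fr.test_indices.tolist(),
                    "chosen_p": fr.chosen_p,
                    "chosen_c": fr.chosen_c,
                    "fused_preds": {k: v.tolist() for k, v in fr.fused_preds.items()},
                }
                for fr in self.folds
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _seed_from(master: int, *key: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=key).generate_state(1)[0] % (2**31))


def _bv_predictions(model, X_test, dst, exclude=None):
    """Belief-values and belief-value labels for a block of test rows."""
    bvs = np.empty(len(X_test))
    preds = np.empty(len(X_test), dtype=int)
    for i, x in enumerate(X_test):
        ex = exclude[i] if exclude is not None else None
        bv = belief_value(model, x, dst, exclude_index=ex)
        side = 1 if signed_distance(model, x) >= 0 else -1
        bvs[i] = bv
        preds[i] = classify_bv(bv, side)
    return bvs, preds


def _tune_feature(Xf, y, config: CVConfig, seed: int):
    """Inner CV over (p-threshold, C); returns the best pair and the
    out-of-fold belief-values of every training subject at that pair."""
    inner = StratifiedKFold(n_splits=config.inner_folds, shuffle=True, random_state=seed)
    splits = list(inner.split(Xf, y))
    pvals = [select_rois(Xf[tr], y[tr], max(config.p_grid)).p_values for tr, _ in splits]

    def _mask(p_fold, thr):
        sel = p_fold < thr
        if not sel.any():
            sel = np.zeros_like(sel)
            sel[int(np.argmin(p_fold))] = True
        return np.flatnonzero(sel)

    best = None  # (acc, -p_rank, -c_rank, p, C)
    for ip, p_thr in enumerate(config.p_grid):
        masks = [_mask(pv, p_thr) for pv in pvals]
        for ic, c_val in enumerate(config.c_grid):
            correct = total = 0
            for (tr, va), cols in zip(splits, masks):
                model = fit_margin_classifier(Xf[tr][:, cols], y[tr], c_val)
                _, preds = _bv_predictions(model, Xf[va][:, cols], config.dst)
                correct += int(np.sum(preds == y[va]))
                total += len(va)
            acc = correct / total
            cand = (acc, -ip, -ic, p_thr, c_val)
            if best is None or cand > best:
                best = cand
    _, _, _, best_p, best_c = best

    oof_bv = np.empty(len(y))
    masks = [_mask(pv, best_p) for pv in pvals]
    for (tr, va), cols in zip(splits, masks):
        model = fit_margin_classifier(Xf[tr][:, cols], y[tr], best_c)
        bvs, _ = _bv_predictions(model, Xf[va][:, cols], config.dst)
        oof_bv[va] = bvs
    return best_p, best_c, oof_bv


def run_nested_cv(
    cohort: list[SubjectRecord],
    config: CVConfig | None = None,
    feature_sets: list[FeatureSet] | None = None,
) -> CVReport:
    """Run the full repeated nested cross-validation on a cohort.

    ``feature_sets`` may be supplied to reuse precomputed features; they
    must align with ``cohort``.  The report is a pure function of
    (cohort, config): the same master seed reproduces it exactly.
    """
    config = config or CVConfig()
    if len(cohort) < 20:
        raise InputError(f"cohort must have >= 20 subjects, got {len(cohort)}")
    y = np.array([rec.label for rec in cohort])
    if np.unique(y).size < 2:
        raise InputError("cohort must contain both classes")
    if feature_sets is None:
        feature_sets = build_feature_sets(cohort, config.feature_config)
    mats = {name: feature_matrix(feature_sets, name) for name in FEATURE_NAMES}
    n_rois = mats["mean"].shape[1]

    folds: list[FoldResult] = []
    for rep in range(config.repeats):
        outer = StratifiedKFold(
            n_splits=config.outer_folds,
            shuffle=True,
            random_state=_seed_from(config.master_seed, rep),
        )
        for k, (tr, te) in enumerate(outer.split(np.zeros(len(y)), y)):
            if np.unique(y[tr]).size < 2:
                raise InputError(f"outer fold {k} of repeat {rep} has a single-class training set")
            chosen_p: dict[str, float] = {}
            chosen_c: dict[str, float] = {}
            sel_rois: dict[str, np.ndarray] = {}
            model_params: dict[str, tuple[np.ndarray, float]] = {}
            feat_preds: dict[str, np.ndarray] = {}
            F_train = np.empty((len(tr), len(FEATURE_NAMES)))
            F_test = np.empty((len(te), len(FEATURE_NAMES)))
            for fi, name in enumerate(FEATURE_NAMES):
                Xf = mats[name]
                inner_seed = _seed_from(config.master_seed, rep, k, fi)
                best_p, best_c, oof_bv = _tune_feature(Xf[tr], y[tr], config, inner_seed)
                mask = select_rois(Xf[tr], y[tr], best_p)
                cols = mask.indices
                model = fit_margin_classifier(Xf[tr][:, cols], y[tr], best_c)
                chosen_p[name] = best_p
                chosen_c[name] = best_c
                sel_rois[name] = cols
                model_params[name] = (model.w.copy(), model.b)
                bvs_te, preds_te = _bv_predictions(model, Xf[te][:, cols], config.dst)
                feat_preds[name] = preds_te
                F_test[:, fi] = bvs_te
                if config.fusion_train_bv == "out_of_fold":
                    F_train[:, fi] = oof_bv
                else:
                    bvs_tr, _ = _bv_predictions(
                        model, Xf[tr][:, cols], config.dst, exclude=np.arange(len(tr))
                    )
                    F_train[:, fi] = bvs_tr
            fused_preds: dict[str, np.ndarray] = {}
            fusion_params: dict[str, dict] = {}
            fusion_seed = _seed_from(config.master_seed, rep, k, 99)
            for method in FUSION_METHODS:
                fmodel = fit_fusion(F_train, y[tr], method=method, seed=fusion_seed)
                fused_preds[method] = np.asarray(predict_fusion(fmodel, F_test))
                fusion_params[method] = fmodel.to_dict()
            folds.append(
                FoldResult(
                    repeat=rep,
                    fold=k,
                    test_indices=te,
                    y_true=y[te],
                    chosen_p=chosen_p,
                    chosen_c=chosen_c,
                    selected_rois=sel_rois,
                    model_params=model_params,
                    feature_preds=feat_preds,
                    test_bvs=F_test,
                    fused_preds=fused_preds,
                    fusion_params=fusion_params,
                )
            )
    return CVReport(config=config, folds=folds, n_subjects=len(y), n_rois=n_rois)


def roi_frequency(report: CVReport, top_k: int = 10) -> dict[str, list[tuple[int, float]]]:
    """Rank ROIs per feature by how often outer folds selected them.

    Frequency is count / total outer folds; ties break toward the lower
    ROI index; ``top_k`` larger than the ROI count returns all ROIs.
    """
    total = len(report.folds)
    out: dict[str, list[tuple[int, float]]] = {}
    for name, counts in report.roi_selection_counts.items():
        order = np.lexsort((np.arange(len(counts)), -counts))
        k = min(top_k, len(counts))
        out[name] = [(int(j), counts[j] / total) for j in order[:k]]
    return out
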