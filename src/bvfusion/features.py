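"""Per-ROI scalar features and t-test ROI screening.

Seven features summarise each ROI's time series: four time-domain
moments (mean, unbiased variance, skewness, excess kurtosis), two
frequency-domain features (energy of the slowest variational mode, and
the amplitude of low-frequency fluctuations) and one complexity feature
(sample entropy).  ROI screening keeps, per feature, the ROIs whose
two-sample Welch t-test between groups falls below a p-value threshold;
it operates on training subjects only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .cohort import SubjectRecord
from .errors import ConfigurationError, InputError
from .vmd import vmd

__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "FeatureSet",
    "RoiMask",
    "extract_time_domain",
    "extract_alff",
    "extract_vmd_feature",
    "extract_sample_entropy",
    "build_feature_sets",
    "feature_matrix",
    "select_rois",
]

logger = logging.getLogger(__name__)

#: canonical ordering of the N = 7 feature types
FEATURE_NAMES = ("mean", "variance", "kurtosis", "skewness", "vmd", "alff", "sampen")


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction parameters shared across a cohort.

    ``alff_band`` is the low-frequency band in Hz over which spectral
    amplitude is averaged; ``tr`` is the sampling interval in seconds.
    VMD uses ``vmd_modes`` modes with bandwidth penalty ``vmd_penalty``;
    sample entropy uses embedding length ``sampen_m`` and tolerance
    ``sampen_r`` x SD of the series.
    """

    tr: float = 2.0
    alff_band: tuple[float, float] = (0.01, 0.08)
    vmd_modes: int = 4
    vmd_penalty: float = 2000.0
    vmd_tol: float = 1e-7
    sampen_m: int = 2
    sampen_r: float = 0.2


@dataclass(frozen=True)
class FeatureSet:
    """The seven per-ROI feature vectors for one subject."""

    subject_id: str
    features: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        unknown = set(self.features) - set(FEATURE_NAMES)
        if unknown:
            raise InputError(f"unknown feature names: {sorted(unknown)}")
        lengths = {v.shape for v in self.features.values()}
        if len(lengths) > 1:
            raise InputError(f"feature vectors of {self.subject_id} differ in length: {lengths}")


@dataclass(frozen=True)
class RoiMask:
    """Result of t-test ROI screening for one feature.

    ``selected[j]`` is true when ``p_values[j] < threshold``; when no
    ROI passes, the single minimum-p ROI is kept and ``fallback`` set.
    """

    selected: np.ndarray
    p_values: np.ndarray
    threshold: float
    fallback: bool = False

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)


def _check_series(x: np.ndarray, min_len: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_len:
        raise InputError(f"series length {x.size} < required {min_len}")
    if not np.all(np.isfinite(x)):
        raise InputError("series contains non-finite values")
    return x


def extract_time_domain(ts_column: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, unbiased variance, population skewness and excess kurtosis.

    Kurtosis follows the Fisher convention (normal -> 0); skewness and
    kurtosis use population-moment estimators, variance the unbiased
    (n-1) estimator.
    """
    x = _check_series(ts_column, 4)
    mean = float(np.mean(x))
    variance = float(np.var(x, ddof=1))
    skew = float(stats.skew(x, bias=True))
    kurt = float(stats.kurtosis(x, fisher=True, bias=True))
    return mean, variance, kurt, skew


def extract_alff(
    ts_column: np.ndarray, tr: float, band: tuple[float, float] = (0.01, 0.08)
) -> float:
    """Amplitude of low-frequency fluctuations.

    The mean of the amplitude spectrum (square root of periodogram
    power) over the frequency bins inside ``band``; the DC bin is
    excluded and the series is demeaned first.
    """
    x = _check_series(ts_column, 4)
    f_lo, f_hi = band
    freqs, power = signal.periodogram(x - x.mean(), fs=1.0 / tr)
    in_band = (freqs >= f_lo) & (freqs <= f_hi) & (freqs > 0)
    if not in_band.any():
        raise ConfigurationError(
            f"ALFF band {band} Hz contains no frequency bins "
            f"(resolution {freqs[1]:.4g} Hz, Nyquist {freqs[-1]:.4g} Hz)"
        )
    return float(np.mean(np.sqrt(power[in_band])))


def extract_vmd_feature(
    ts_column: np.ndarray,
    k_modes: int = 4,
    penalty: float = 2000.0,
    tol: float = 1e-7,
) -> float:
    """Energy (variance) of the VMD mode with the lowest centre frequency."""
    x = _check_series(ts_column, 2 * k_modes)
    if np.ptp(x) == 0.0:
        return 0.0  # constant: no oscillatory content to decompose
    modes, _ = vmd(x, k_modes=k_modes, penalty=penalty, tol=tol)
    return float(np.var(modes[0]))


def _embed(x: np.ndarray, m: int, count: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, m)[:count]


def extract_sample_entropy(ts_column: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy -ln(A/B) with Chebyshev template matching.

    B counts pairs of length-``m`` templates within tolerance
    ``r * SD(series)``, A the same for length ``m + 1``; both counts run
    over the first ``T - m`` templates and exclude self-matches.  If
    either count is zero the series admits no entropy estimate and
    ``inf`` is returned as a sentinel (callers replace it by the cohort
    maximum).
    """
    x = _check_series(ts_column, m + 2)
    sd = float(np.std(x, ddof=0))
    if sd == 0.0:
        return 0.0  # constant series: every template matches at both lengths
    tol = r * sd
    n_templates = x.size - m
    counts = []
    for length in (m, m + 1):
        templ = _embed(x, length, n_templates)
        dist = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=2)
        matches = (dist <= tol).sum() - n_templates  # drop self-matches
        counts.append(matches // 2)
    b_count, a_count = counts
    if a_count == 0 or b_count == 0:
        return math.inf
    return float(-math.log(a_count / b_count))


def build_feature_sets(
    cohort: list[SubjectRecord], config: FeatureConfig | None = None
) -> list[FeatureSet]:
    """Apply all seven extractors column-wise to every subject.

    Sample-entropy sentinels (no template matches) are replaced by the
    largest finite sample entropy observed anywhere in the cohort.
    """
    config = config or FeatureConfig()
    n_rois_set = {rec.ts.shape[1] for rec in cohort}
    if len(n_rois_set) > 1:
        raise InputError(f"subjects disagree on ROI count: {sorted(n_rois_set)}")
    sets: list[FeatureSet] = []
    for rec in cohort:
        vals = {name: np.empty(rec.ts.shape[1]) for name in FEATURE_NAMES}
        for j in range(rec.ts.shape[1]):
            col = rec.ts[:, j]
            try:
                mean, var, kurt, skew = extract_time_domain(col)
                vals["mean"][j] = mean
                vals["variance"][j] = var
                vals["kurtosis"][j] = kurt
                vals["skewness"][j] = skew
                vals["alff"][j] = extract_alff(col, config.tr, config.alff_band)
                vals["vmd"][j] = extract_vmd_feature(
                    col, config.vmd_modes, config.vmd_penalty, config.vmd_tol
                )
                vals["sampen"][j] = extract_sample_entropy(
                    col, config.sampen_m, config.sampen_r
                )
            except (InputError, ConfigurationError) as err:
                raise InputError(
                    f"feature extraction failed for subject {rec.subject_id}, "
                    f"ROI column {j}: {err}"
                ) from err
        sets.append(FeatureSet(rec.subject_id, vals))

    sampen_all = np.concatenate([fs.features["sampen"] for fs in sets])
    finite = sampen_all[np.isfinite(sampen_all)]
    ceiling = float(finite.max()) if finite.size else 0.0
    n_sentinel = int(np.sum(~np.isfinite(sampen_all)))
    if n_sentinel:
        logger.warning(
            "sample entropy undefined for %d ROI series; set to cohort maximum %.4g",
            n_sentinel,
            ceiling,
        )
        for fs in sets:
            v = fs.features["sampen"]
            v[~np.isfinite(v)] = ceiling
    return sets


def feature_matrix(feature_sets: list[FeatureSet], name: str) -> np.ndarray:
    """Stack one feature across subjects into a (subjects x ROIs) matrix."""
    if name not in FEATURE_NAMES:
        raise ConfigurationError(f"unknown feature {name!r}; expected one of {FEATURE_NAMES}")
    return np.vstack([fs.features[name] for fs in feature_sets])


def select_rois(
    train_features: np.ndarray, labels: np.ndarray, threshold: float
) -> RoiMask:
    """Screen ROIs by two-sided Welch t-test between the two groups.

    Must be called with training subjects only; the mask is a pure
    function of its arguments, so test subjects cannot leak in.  When
    no ROI clears ``threshold`` the single minimum-p ROI is kept and
    the mask flagged as a fallback.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(labels)
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError(f"threshold must be in (0, 1), got {threshold}")
    pos, neg = X[y == 1], X[y == -1]
    if len(pos) == 0 or len(neg) == 0:
        raise InputError("both classes must be present for ROI selection")
    p_values = stats.ttest_ind(pos, neg, axis=0, equal_var=False).pvalue
    p_values = np.where(np.isfinite(p_values), p_values, 1.0)
    selected = p_values < threshold
    fallback = False
    if not selected.any():
        selected = np.zeros_like(selected)
        selected[int(np.argmin(p_values))] = True
        fallback = True
    return RoiMask(selected=selected, p_values=p_values, threshold=threshold, fallback=fallback)
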