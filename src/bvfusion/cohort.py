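"""Synthetic two-group cohorts of parcellated ROI time-series matrices.

Each subject is a matrix (time points x ROIs) mimicking a resting-state
fMRI data matrix after atlas parcellation.  The control-like group (+1)
is stationary AR(1) Gaussian noise per ROI; the patient-like group (-1)
carries planted effects on a known ROI subset: a mean shift, an
innovation-variance rescaling and an added low-frequency sinusoid.  The
three effect knobs map onto the downstream feature families (moments,
variance/entropy, spectral amplitude) so every pipeline stage has a
ground-truth fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InputError

__all__ = ["CohortSpec", "SubjectRecord", "generate_cohort", "write_cohort", "read_cohort"]

#: burn-in samples discarded so the AR(1) process is effectively stationary
_AR_BURN_IN = 100


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated two-group cohort.

    Parameters
    ----------
    n_per_group
        Subjects per group (>= 2); the cohort has ``2 * n_per_group`` subjects.
    n_timepoints, n_rois
        Matrix dimensions; defaults mirror a 170-volume scan parcellated
        into 116 atlas regions.
    affected_rois
        ROI column indices that carry the planted group difference.
    mean_shift
        Additive shift of the patient group's signal on affected ROIs,
        in units of the (unit) innovation SD.
    var_ratio
        Multiplier (> 0) on the innovation variance of affected ROIs in
        the patient group.
    osc_amplitude_delta
        Amplitude of the in-band sinusoid added to affected ROIs of the
        patient group (the groups' oscillation amplitudes differ by this).
    osc_freq
        Sinusoid frequency in Hz; must lie below Nyquist = 1 / (2 * tr).
    tr
        Repetition time (sampling interval) in seconds.
    ar_coeff
        AR(1) coefficient in (-1, 1) giving temporal autocorrelation.
    seed
        Master seed; per-subject substreams are derived from it so that
        growing the cohort never reshuffles earlier subjects.
    """

    n_per_group: int
    n_timepoints: int = 170
    n_rois: int = 116
    affected_rois: tuple[int, ...] = ()
    mean_shift: float = 0.0
    var_ratio: float = 1.0
    osc_amplitude_delta: float = 0.0
    osc_freq: float = 0.05
    tr: float = 2.0
    ar_coeff: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise InputError(f"n_per_group must be >= 2, got {self.n_per_group}")
        if self.n_timepoints < 4:
            raise InputError(f"n_timepoints must be >= 4, got {self.n_timepoints}")
        if self.n_rois < 1:
            raise InputError(f"n_rois must be >= 1, got {self.n_rois}")
        rois = tuple(int(j) for j in self.affected_rois)
        object.__setattr__(self, "affected_rois", rois)
        if any(j < 0 or j >= self.n_rois for j in rois):
            raise InputError(f"affected_rois must lie in [0, {self.n_rois}), got {rois}")
        if not self.var_ratio > 0:
            raise InputError(f"var_ratio must be > 0, got {self.var_ratio}")
        if not -1.0 < self.ar_coeff < 1.0:
            raise InputError(f"ar_coeff must be in (-1, 1), got {self.ar_coeff}")
        if self.tr <= 0:
            raise InputError(f"tr must be positive, got {self.tr}")
        nyquist = 1.0 / (2.0 * self.tr)
        if not 0.0 < self.osc_freq < nyquist:
            raise InputError(
                f"osc_freq must be in (0, Nyquist={nyquist:g}) Hz, got {self.osc_freq}"
            )


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: an identifier, a group label and a time-series matrix.

    ``label`` is -1 for the patient-like group and +1 for the
    control-like group (controls are the positive class downstream).
    """

    subject_id: str
    label: int
    ts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.label not in (-1, 1):
            raise InputError(f"label must be -1 or +1, got {self.label}")
        if not np.all(np.isfinite(self.ts)):
            raise InputError(f"time series of {self.subject_id} contains non-finite values")


def _simulate_subject(spec: CohortSpec, label: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate one (n_timepoints x n_rois) matrix for the given group."""
    t_total = spec.n_timepoints + _AR_BURN_IN
    innov = rng.standard_normal((t_total, spec.n_rois))
    affected = list(spec.affected_rois)
    if label == -1 and affected and spec.var_ratio != 1.0:
        innov[:, affected] *= np.sqrt(spec.var_ratio)
    # x_t = ar * x_{t-1} + e_t, filtered along time then burn-in dropped
    ts = signal.lfilter([1.0], [1.0, -spec.ar_coeff], innov, axis=0)[_AR_BURN_IN:]
    if label == -1 and affected:
        ts[:, affected] += spec.mean_shift
        if spec.osc_amplitude_delta != 0.0:
            t = np.arange(spec.n_timepoints) * spec.tr
            phases = rng.uniform(0.0, 2.0 * np.pi, size=len(affected))
            ts[:, affected] += spec.osc_amplitude_delta * np.sin(
                2.0 * np.pi * spec.osc_freq * t[:, None] + phases[None, :]
            )
    return ts


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate a balanced two-group cohort.

    Returns ``2 * n_per_group`` records: first the control-like group
    (label +1), then the patient-like group (label -1).  Output is a
    pure function of ``spec`` (including its seed); each subject draws
    from its own substream keyed by (group, index), so changing
    ``n_per_group`` leaves earlier subjects bit-identical.
    """
    records: list[SubjectRecord] = []
    for group_key, label, prefix in ((0, 1, "NC"), (1, -1, "ASD")):
        for i in range(spec.n_per_group):
            ss = np.random.SeedSequence(spec.seed, spawn_key=(group_key, i))
            rng = np.random.default_rng(ss)
            ts = _simulate_subject(spec, label, rng)
            records.append(SubjectRecord(f"{prefix}_{i:04d}", label, ts))
    return records


def write_cohort(records: list[SubjectRecord], out_dir: str | Path) -> Path:
    """Write one TSV per subject plus a cohort index CSV.

    Subject files have ROI-named columns (``ROI_001`` ...) and one row
    per time point.  Returns the path of the index CSV
    (columns: subject_id, label, path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        n_rois = rec.ts.shape[1]
        cols = [f"ROI_{j + 1:03d}" for j in range(n_rois)]
        path = out_dir / f"{rec.subject_id}.tsv"
        pd.DataFrame(rec.ts, columns=cols).to_csv(path, sep="\t", index=False)
        rows.append({"subject_id": rec.subject_id, "label": rec.label, "path": path.name})
    index_path = out_dir / "cohort.csv"
    pd.DataFrame(rows).to_csv(index_path, index=False)
    return index_path


def read_cohort(index_csv: str | Path) -> list[SubjectRecord]:
    """Load a cohort written by :func:`write_cohort` (or user data in the same layout)."""
    index_csv = Path(index_csv)
    base = index_csv.parent
    table = pd.read_csv(index_csv)
    records = []
    for row in table.itertuples(index=False):
        ts = pd.read_csv(base / str(row.path), sep="\t").to_numpy(dtype=float)
        records.append(SubjectRecord(str(row.subject_id), int(row.label), ts))
    return records
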