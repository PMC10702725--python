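"""Canonical synthetic study conditions.

One place defines the cohort and protocol used for end-to-end
validation: a balanced 92-subject cohort (46 per group) of 170 x 116
time-series matrices with all three effects planted on a 10-ROI
subset (mean shift 2x the unit noise SD, doubled innovation variance,
and a 1.5-amplitude 0.05 Hz oscillation), evaluated by a 3-repeat
10-fold outer / 5-fold inner nested cross-validation over the full
p-threshold and C grids.
"""

from __future__ import annotations

from .cohort import CohortSpec
from .evaluation import CVConfig

__all__ = ["study_cohort_spec", "study_cv_config", "STUDY_AFFECTED_ROIS"]

STUDY_AFFECTED_ROIS = tuple(range(10))


def study_cohort_spec(seed: int) -> CohortSpec:
    """The reference synthetic cohort for end-to-end evaluation."""
    return CohortSpec(
        n_per_group=46,
        n_timepoints=170,
        n_rois=116,
        affected_rois=STUDY_AFFECTED_ROIS,
        mean_shift=2.0,
        var_ratio=2.0,
        osc_amplitude_delta=1.5,
        osc_freq=0.05,
        tr=2.0,
        ar_coeff=0.3,
        seed=seed,
    )


def study_cv_config(master_seed: int, repeats: int = 3) -> CVConfig:
    """The reduced repeated nested-CV protocol used for the synthetic study."""
    return CVConfig(
        outer_folds=10,
        repeats=repeats,
        inner_folds=5,
        master_seed=master_seed,
    )
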