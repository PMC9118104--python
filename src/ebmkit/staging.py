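"""Maximum-likelihood patient staging under a fitted event ordering.

A subject's stage is the number of events that have occurred: the value of
k maximizing P(k) prod_{i<=k} P(x|E) prod_{i>k} P(x|not E) along the fitted
ordering, with a uniform stage prior.  Ties go to the lowest stage (the
most conservative reading: fewest events).  Controls are staged with the
same model but never used in sequence fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ebm import EventLikelihoodMatrix, _check_sequence, _log_prior

__all__ = [
    "StagingResult",
    "ClassificationRates",
    "stage_log_likelihoods",
    "stage_subject",
    "stage_cohort",
    "classify_by_stage",
]


@dataclass
class StagingResult:
    """Per subject-visit stage assignments plus the per-stage score vectors."""

    stages: pd.DataFrame  # columns: subject_id, stage, log_likelihood (+metadata)
    stage_log_likelihoods: np.ndarray  # (N, Z+1)
    sequence: np.ndarray

    def __len__(self) -> int:
        return len(self.stages)

    def to_csv(self, path) -> None:
        self.stages.to_csv(path, index=False)


@dataclass
class ClassificationRates:
    accuracy: float
    sensitivity: float | None
    specificity: float | None


def stage_log_likelihoods(p_event_row, p_not_event_row, s, prior=None) -> np.ndarray:
    """Log-likelihood of each stage k in 0..Z for one subject.

    The log-sum-exp of this vector equals the subject's contribution to the
    full sequence likelihood (the stage-marginalized model), which the test
    suite uses as a consistency oracle.
    """
    p_e = np.asarray(p_event_row, dtype=float).ravel()
    p_ne = np.asarray(p_not_event_row, dtype=float).ravel()
    z = len(p_e)
    s = _check_sequence(s, z)
    if not (np.all(np.isfinite(p_e)) and np.all(np.isfinite(p_ne))):
        raise ValueError("non-finite likelihood entries")
    if np.any(p_e <= 0) or np.any(p_ne <= 0):
        raise ValueError("likelihood entries must be strictly positive")
    lam = np.log(p_e[s]) - np.log(p_ne[s])
    cum = np.concatenate([[0.0], np.cumsum(lam)])
    lp = _log_prior(prior, z)
    return cum + lp + np.sum(np.log(p_ne))


def stage_subject(p_event_row, p_not_event_row, s, prior=None) -> tuple[int, np.ndarray]:
    """Maximum-likelihood stage for one subject; ties break to the lowest stage."""
    ll = stage_log_likelihoods(p_event_row, p_not_event_row, s, prior=prior)
    return int(np.argmax(ll)), ll


def stage_cohort(
    L: EventLikelihoodMatrix, s, metadata: pd.DataFrame | None = None, prior=None
) -> StagingResult:
    """Stage every row of a likelihood matrix against one fitted ordering.

    ``metadata`` (optional) supplies per-row columns such as ``group`` and
    ``visit``, aligned positionally with the matrix rows.
    """
    s = _check_sequence(s, L.n_events)
    n = L.n_subjects
    lp = _log_prior(prior, L.n_events)
    lam = np.log(L.p_event[:, s]) - np.log(L.p_not_event[:, s])
    cum = np.concatenate([np.zeros((n, 1)), np.cumsum(lam, axis=1)], axis=1)
    mat = cum + lp[None, :] + np.sum(np.log(L.p_not_event), axis=1, keepdims=True)
    # np.argmax returns the first (lowest) index on ties
    stages = np.argmax(mat, axis=1)
    frame = pd.DataFrame({"subject_id": L.subject_ids})
    if metadata is not None:
        if len(metadata) != n:
            raise ValueError("metadata must have one row per subject")
        for col in metadata.columns:
            if col not in frame.columns:
                frame[col] = np.asarray(metadata[col])
    frame["stage"] = stages
    frame["log_likelihood"] = mat[np.arange(n), stages]
    return StagingResult(stages=frame, stage_log_likelihoods=mat, sequence=s)


def classify_by_stage(staging: StagingResult, threshold_stage: int) -> ClassificationRates:
    """Case/control classification by thresholding the assigned stage.

    Predict "case" iff stage >= ``threshold_stage``; requires a ``group``
    column in the staging frame.  With a single-class input the undefined
    rate is returned as ``None``.
    """
    if "group" not in staging.stages.columns:
        raise ValueError("staging result carries no group labels")
    stage = staging.stages["stage"].to_numpy()
    is_case = (staging.stages["group"] == "case").to_numpy()
    pred_case = stage >= threshold_stage
    accuracy = float(np.mean(pred_case == is_case))
    sensitivity = float(np.mean(pred_case[is_case])) if is_case.any() else None
    specificity = float(np.mean(~pred_case[~is_case])) if (~is_case).any() else None
    return ClassificationRates(accuracy, sensitivity, specificity)
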