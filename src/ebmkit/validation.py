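"""Resampling validation of the fitted ordering and longitudinal checks.

Two complementary views of sequence uncertainty: MCMC sampling (within one
model fit) tends to understate it, while re-estimating the whole model on
bootstrap resamples gives a more liberal estimate.  Repeated stratified
k-fold cross-validation additionally scores held-out staging-threshold
classification.  Longitudinal utilities check that stages do not decrease
from baseline to follow-up and regress external outcomes on stage.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import RepeatedStratifiedKFold

from . import simulate as sim
from .ebm import (
    EventLikelihoodMatrix,
    fit_ebm,
    greedy_ascent,
    likelihood_matrix_from_fits,
    positional_variance,
)
from .mixture import KDEMixture
from .preprocess import CovariateAdjuster, select_biomarkers
from .simulate import SimulationConfig, event_columns, generate_cohort, generate_followup
from .staging import StagingResult, classify_by_stage, stage_cohort

__all__ = [
    "CrossValidationReport",
    "LongitudinalReport",
    "AssociationReport",
    "PipelineConfig",
    "PipelineReports",
    "fit_mixtures",
    "bootstrap_sequences",
    "repeated_stratified_kfold",
    "longitudinal_consistency",
    "stage_association",
    "run_pipeline",
]


# --------------------------------------------------------------------------- reports
@dataclass
class CrossValidationReport:
    """Per-resample ML sequences with their aggregated positional variance."""

    method: str  # "bootstrap" | "repeated_stratified_kfold"
    sequences: np.ndarray  # (n_resamples, Z)
    positional_variance: np.ndarray
    n_resamples: int
    event_names: list[str]
    held_out_accuracy: list[float] = field(default_factory=list)
    skipped: int = 0

    @property
    def modal_sequence(self) -> np.ndarray:
        """Most frequent resample ML sequence (first-seen on ties)."""
        seqs, counts = np.unique(self.sequences, axis=0, return_counts=True)
        return seqs[int(np.argmax(counts))]

    def to_json(self, path) -> None:
        payload = {
            "method": self.method,
            "n_resamples": self.n_resamples,
            "skipped": self.skipped,
            "event_names": self.event_names,
            "sequences": self.sequences.tolist(),
            "positional_variance": self.positional_variance.tolist(),
            "held_out_accuracy": self.held_out_accuracy,
            "modal_sequence": self.modal_sequence.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CrossValidationReport":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            method=p["method"],
            sequences=np.asarray(p["sequences"], dtype=int),
            positional_variance=np.asarray(p["positional_variance"]),
            n_resamples=p["n_resamples"],
            event_names=p["event_names"],
            held_out_accuracy=p["held_out_accuracy"],
            skipped=p["skipped"],
        )


@dataclass
class LongitudinalReport:
    """Baseline-to-follow-up stage consistency for matched subjects."""

    n_pairs: int
    fraction_non_decreasing: float
    mean_stage_change: float
    pairs: pd.DataFrame  # subject_id, baseline_stage, followup_stage

    def to_json(self, path) -> None:
        payload = {
            "n_pairs": self.n_pairs,
            "fraction_non_decreasing": self.fraction_non_decreasing,
            "mean_stage_change": self.mean_stage_change,
            "pairs": self.pairs.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class AssociationReport:
    """OLS association of an outcome with model stage."""

    beta: float
    conf_int: tuple[float, float]
    intercept: float
    r_squared: float
    n: int
    p_value: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "beta": self.beta,
                    "conf_int": list(self.conf_int),
                    "intercept": self.intercept,
                    "r_squared": self.r_squared,
                    "n": self.n,
                    "p_value": self.p_value,
                },
                fh,
            )


# --------------------------------------------------------------------- model fitting
def fit_mixtures(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    event_names=None,
    mixture_params: Mapping | None = None,
) -> dict[str, KDEMixture]:
    """Fit one KDE mixture per event column from adjusted tables."""
    names = list(event_names) if event_names is not None else event_columns(cases)
    params = dict(mixture_params or {})
    fits = {}
    for name in names:
        x = np.concatenate([controls[name].to_numpy(float), cases[name].to_numpy(float)])
        y = np.concatenate([np.zeros(len(controls), int), np.ones(len(cases), int)])
        fits[name] = KDEMixture(**params).fit(x, y)
    return fits


def _case_likelihoods(fits, cases, names) -> EventLikelihoodMatrix:
    return likelihood_matrix_from_fits(fits, cases, names)


def bootstrap_sequences(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    n_boot: int = 100,
    seed: int | None = None,
    event_names=None,
    n_init: int = 4,
    mixture_params: Mapping | None = None,
    resample_hook: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> CrossValidationReport:
    """Re-estimate the ordering on bootstrap resamples of the cases.

    Cases are drawn with replacement; the full control set is kept fixed for
    mixture fitting (it anchors the normal component).  Each resample refits
    every mixture and the EBM (greedy ascent) and records the ML sequence;
    the aggregated matrix holds the proportion of resamples placing each
    event at each position.  Resamples with a degenerate event are skipped
    with a warning.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(event_names) if event_names is not None else event_columns(cases)
    sequences, skipped = [], 0
    for _ in range(n_boot):
        idx = (
            resample_hook(rng, len(cases))
            if resample_hook is not None
            else rng.integers(0, len(cases), len(cases))
        )
        resampled = cases.iloc[idx].reset_index(drop=True)
        try:
            fits = fit_mixtures(resampled, controls, names, mixture_params)
        except ValueError as err:
            warnings.warn(f"bootstrap resample skipped: {err}")
            skipped += 1
            continue
        L = _case_likelihoods(fits, resampled, names)
        seq, _, _ = greedy_ascent(L, n_init=n_init, seed=rng)
        sequences.append(seq)
    if not sequences:
        raise ValueError("all bootstrap resamples were degenerate")
    sequences = np.array(sequences)
    return CrossValidationReport(
        method="bootstrap",
        sequences=sequences,
        positional_variance=positional_variance(sequences),
        n_resamples=len(sequences),
        event_names=names,
        skipped=skipped,
    )


def repeated_stratified_kfold(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    k: int = 5,
    repeats: int = 10,
    seed: int | None = None,
    event_names=None,
    n_init: int = 4,
    threshold_stage: int = 2,
    mixture_params: Mapping | None = None,
) -> CrossValidationReport:
    """Repeated stratified k-fold re-estimation with held-out staging accuracy.

    Folds are stratified on group label.  Within each fold the mixtures and
    the ordering are refitted on the training split (cases only for the
    ordering) and the held-out subjects are staged and classified at
    ``threshold_stage``; ``k * repeats`` fold models are produced and their
    ML sequences aggregated position-wise.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    names = list(event_names) if event_names is not None else event_columns(cases)
    params = dict(mixture_params or {})
    min_group = KDEMixture(**params).min_group_size
    combined = pd.concat([cases, controls], ignore_index=True)
    labels = (combined["group"] == "case").to_numpy(int)
    if min(labels.sum(), len(labels) - labels.sum()) < k:
        raise ValueError("fold too small: fewer subjects than folds in one group")
    splitter = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    rng = np.random.default_rng(seed)
    sequences, accuracies = [], []
    for train_idx, test_idx in splitter.split(combined, labels):
        train, test = combined.iloc[train_idx], combined.iloc[test_idx]
        tr_cases = train[train["group"] == "case"]
        tr_controls = train[train["group"] == "control"]
        if len(tr_cases) < min_group or len(tr_controls) < min_group:
            raise ValueError("fold too small for mixture estimation")
        fits = fit_mixtures(tr_cases, tr_controls, names, params)
        L_train = _case_likelihoods(fits, tr_cases, names)
        seq, _, _ = greedy_ascent(L_train, n_init=n_init, seed=rng)
        sequences.append(seq)
        L_test = likelihood_matrix_from_fits(fits, test, names)
        staged = stage_cohort(L_test, seq, metadata=test[["group"]].reset_index(drop=True))
        accuracies.append(classify_by_stage(staged, threshold_stage).accuracy)
    sequences = np.array(sequences)
    return CrossValidationReport(
        method="repeated_stratified_kfold",
        sequences=sequences,
        positional_variance=positional_variance(sequences),
        n_resamples=len(sequences),
        event_names=names,
        held_out_accuracy=accuracies,
    )


# ------------------------------------------------------------------- longitudinal
def longitudinal_consistency(
    baseline: StagingResult, followup: StagingResult
) -> LongitudinalReport:
    """Fraction of matched subjects whose stage does not decrease over follow-up."""
    b = baseline.stages[["subject_id", "stage"]].rename(columns={"stage": "baseline_stage"})
    f = followup.stages[["subject_id", "stage"]].rename(columns={"stage": "followup_stage"})
    pairs = b.merge(f, on="subject_id")
    if pairs.empty:
        raise ValueError("no matched subject pairs between baseline and follow-up")
    change = pairs["followup_stage"] - pairs["baseline_stage"]
    return LongitudinalReport(
        n_pairs=len(pairs),
        fraction_non_decreasing=float((change >= 0).mean()),
        mean_stage_change=float(change.mean()),
        pairs=pairs,
    )


def stage_association(staging: StagingResult, outcome) -> AssociationReport:
    """OLS of an outcome (e.g. a clinical severity score) on model stage.

    One observation per subject-visit; rows with a missing outcome are
    dropped.  Normal-theory 95% confidence interval on the slope.
    """
    stage = staging.stages["stage"].to_numpy(float)
    y = np.asarray(outcome, dtype=float).ravel()
    if len(y) != len(stage):
        raise ValueError("outcome must align with staging rows")
    mask = np.isfinite(y)
    stage, y = stage[mask], y[mask]
    if len(y) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(stage) == 0:
        raise ValueError("zero variance in stage: association undefined")
    X = sm.add_constant(stage)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)[1]
    return AssociationReport(
        beta=float(fit.params[1]),
        conf_int=(float(ci[0]), float(ci[1])),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        n=int(len(y)),
        p_value=float(fit.pvalues[1]),
    )


# ---------------------------------------------------------------------- pipeline
@dataclass
class PipelineConfig:
    """End-to-end run configuration (simulation through validation)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    family_alpha: float = 0.05
    threshold_stage: int = 2
    n_init: int = 10
    mcmc_iterations: int = 50_000
    burn_in: int = 10_000
    n_boot: int = 100
    kfold_k: int = 5
    kfold_repeats: int = 10
    severity_slope: float = 1.5
    severity_noise_sd: float = 5.0
    mixture_params: dict = field(default_factory=dict)
    run_bootstrap: bool = True
    run_kfold: bool = True
    seed: int = 0


@dataclass
class PipelineReports:
    config: PipelineConfig
    adjuster: CovariateAdjuster
    selection: object
    mixtures: dict
    ebm_result: object
    baseline_staging: StagingResult
    followup_staging: StagingResult
    classification: object
    longitudinal: LongitudinalReport
    association: AssociationReport
    bootstrap: CrossValidationReport | None
    kfold: CrossValidationReport | None
    truth: sim.GroundTruth
    manifest: dict


def _config_hash(config: PipelineConfig) -> str:
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineReports:
    """Simulate, preprocess, fit, stage and validate in one deterministic run.

    A synthetic severity score (``severity_slope * true_stage + noise``,
    emulating a clinical rating scale) is generated for the stage
    association check.  With ``out_dir`` set, every report plus a
    reproducibility manifest is written to disk.
    """
    scfg = config.simulation
    table, truth = generate_cohort(scfg)
    followup, fu_truth = generate_followup(table, truth, scfg)

    controls = table[table["group"] == "control"].reset_index(drop=True)
    cases = table[table["group"] == "case"].reset_index(drop=True)
    adjuster = CovariateAdjuster().fit(controls)
    adj_cases = adjuster.transform(cases)
    adj_controls = adjuster.transform(controls)
    adj_followup = adjuster.transform(followup)

    selection = select_biomarkers(adj_cases, adj_controls, config.family_alpha)
    names = selection.selected
    if not names:
        raise RuntimeError("pipeline aborted at selection: no biomarker passed")

    mixtures = fit_mixtures(adj_cases, adj_controls, names, config.mixture_params)
    L_cases = likelihood_matrix_from_fits(mixtures, adj_cases, names)
    ebm_result = fit_ebm(
        L_cases,
        n_init=config.n_init,
        mcmc_iterations=config.mcmc_iterations,
        burn_in=config.burn_in,
        seed=config.seed,
    )
    seq = ebm_result.ml_sequence

    adj_all = pd.concat([adj_cases, adj_controls], ignore_index=True)
    L_all = likelihood_matrix_from_fits(mixtures, adj_all, names)
    baseline_staging = stage_cohort(
        L_all, seq, metadata=adj_all[["group", "visit"]].reset_index(drop=True)
    )
    fu_cases = adj_followup[adj_followup["group"] == "case"].reset_index(drop=True)
    L_fu = likelihood_matrix_from_fits(mixtures, fu_cases, names)
    followup_staging = stage_cohort(
        L_fu, seq, metadata=fu_cases[["group", "visit"]].reset_index(drop=True)
    )

    classification = classify_by_stage(baseline_staging, config.threshold_stage)
    case_mask = baseline_staging.stages["group"] == "case"
    baseline_case_staging = StagingResult(
        stages=baseline_staging.stages[case_mask].reset_index(drop=True),
        stage_log_likelihoods=baseline_staging.stage_log_likelihoods[case_mask.to_numpy()],
        sequence=seq,
    )
    longitudinal = longitudinal_consistency(baseline_case_staging, followup_staging)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    true_stages = truth.stages.set_index("subject_id").loc[
        baseline_case_staging.stages["subject_id"], "true_stage"
    ].to_numpy()
    severity = (
        config.severity_slope * true_stages
        + rng.normal(0.0, config.severity_noise_sd, len(true_stages))
    )
    association = stage_association(baseline_case_staging, severity)

    bootstrap = (
        bootstrap_sequences(
            adj_cases, adj_controls, config.n_boot, seed=config.seed,
            event_names=names, mixture_params=config.mixture_params,
        )
        if config.run_bootstrap
        else None
    )
    kfold = (
        repeated_stratified_kfold(
            adj_cases, adj_controls, k=config.kfold_k, repeats=config.kfold_repeats,
            seed=config.seed, event_names=names,
            threshold_stage=config.threshold_stage,
            mixture_params=config.mixture_params,
        )
        if config.run_kfold
        else None
    )

    import sklearn
    import scipy

    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_selected_events": len(names),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }

    reports = PipelineReports(
        config=config,
        adjuster=adjuster,
        selection=selection,
        mixtures=mixtures,
        ebm_result=ebm_result,
        baseline_staging=baseline_staging,
        followup_staging=followup_staging,
        classification=classification,
        longitudinal=longitudinal,
        association=association,
        bootstrap=bootstrap,
        kfold=kfold,
        truth=truth,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_reports(reports, Path(out_dir))
    return reports


def _write_reports(reports: PipelineReports, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    reports.adjuster.to_json(out / "covariate_model.json")
    reports.selection.to_csv(out / "selection.csv")
    reports.ebm_result.to_json(out / "ebm_result.json")
    reports.ebm_result.positional_variance_tsv(out / "positional_variance.tsv")
    reports.baseline_staging.to_csv(out / "stages_baseline.csv")
    reports.followup_staging.to_csv(out / "stages_followup.csv")
    reports.longitudinal.to_json(out / "longitudinal.json")
    reports.association.to_json(out / "association.json")
    if reports.bootstrap is not None:
        reports.bootstrap.to_json(out / "bootstrap.json")
    if reports.kfold is not None:
        reports.kfold.to_json(out / "kfold.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(reports.manifest, fh, indent=2)
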