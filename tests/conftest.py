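"""Shared fixtures: synthetic cohorts and the sequence/stage recovery experiment.

The recovery experiment (50 seeds at the study-scale conditions: 10 events,
300 cases / 200 controls, two-scale-unit normal/abnormal separation) is
computed once per session and shared by the sequence-recovery, staging and
longitudinal tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau

from ebmkit import (
    CovariateAdjuster,
    SimulationConfig,
    fit_ebm,
    generate_cohort,
    generate_followup,
    stage_cohort,
)
from ebmkit.ebm import likelihood_matrix_from_fits
from ebmkit.validation import fit_mixtures


def make_config(
    seed: int,
    n_cases: int = 300,
    n_controls: int = 200,
    n_events: int = 10,
    separation: float = 2.0,
    scale: float = 5.0,
    **kwargs,
) -> SimulationConfig:
    """Volume-like cohort config with a given normal/abnormal separation in SD."""
    return SimulationConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        n_events=n_events,
        normal_loc=100.0,
        normal_scale=scale,
        abnormal_loc=100.0 - separation * scale,
        abnormal_scale=scale,
        seed=seed,
        **kwargs,
    )


@dataclass
class RecoveryRun:
    seed: int
    tau: float
    case_exact_fraction: float
    control_stage0_fraction: float


def run_recovery_seed(seed: int, separation: float = 2.0) -> RecoveryRun:
    """Full pipeline (adjust -> mixtures -> EBM -> staging) against ground truth.

    Selection is bypassed so recovery is scored against the complete
    ground-truth ordering.
    """
    cfg = make_config(seed, separation=separation)
    table, truth = generate_cohort(cfg)
    controls = table[table["group"] == "control"].reset_index(drop=True)
    cases = table[table["group"] == "case"].reset_index(drop=True)
    adjuster = CovariateAdjuster().fit(controls)
    adj_cases = adjuster.transform(cases)
    adj_controls = adjuster.transform(controls)
    adj_all = adjuster.transform(table)
    names = [c for c in table.columns if c.startswith("roi")]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mixtures = fit_mixtures(adj_cases, adj_controls, names)
    L_cases = likelihood_matrix_from_fits(mixtures, adj_cases, names)
    result = fit_ebm(L_cases, n_init=10, mcmc_iterations=0, seed=seed)
    tau = kendalltau(
        np.argsort(result.ml_sequence), np.argsort(truth.true_sequence)
    ).correlation
    L_all = likelihood_matrix_from_fits(mixtures, adj_all, names)
    staged = stage_cohort(L_all, result.ml_sequence, metadata=table[["group"]])
    merged = staged.stages.merge(truth.stages, on="subject_id")
    case_rows = merged[merged["group"] == "case"]
    control_rows = merged[merged["group"] == "control"]
    return RecoveryRun(
        seed=seed,
        tau=float(tau),
        case_exact_fraction=float((case_rows["stage"] == case_rows["true_stage"]).mean()),
        control_stage0_fraction=float((control_rows["stage"] == 0).mean()),
    )


@pytest.fixture(scope="session")
def recovery_experiment() -> list[RecoveryRun]:
    """50-seed recovery experiment at two-scale-unit separation."""
    return [run_recovery_seed(seed) for seed in range(50)]


@dataclass
class LongitudinalRun:
    fraction_non_decreasing: float
    mean_stage_change: float


@pytest.fixture(scope="session")
def longitudinal_experiment() -> list[LongitudinalRun]:
    """Strong-separation cohorts with a +1-stage follow-up, staged with the
    baseline-fitted model.

    Baseline stages are drawn uniformly over 0..Z-1 so the +1 increment is
    never truncated at the ceiling and the true mean change is exactly 1.
    """
    from ebmkit import longitudinal_consistency
    from ebmkit.staging import StagingResult

    runs = []
    for seed in (0, 1, 2):
        z = 10
        stage_p = np.zeros(z + 1)
        stage_p[:z] = 1.0 / z
        cfg = make_config(
            seed, separation=4.0, stage_distribution=stage_p, followup_stage_increment=1
        )
        table, truth = generate_cohort(cfg)
        followup, fu_truth = generate_followup(table, truth, cfg)
        controls = table[table["group"] == "control"].reset_index(drop=True)
        cases = table[table["group"] == "case"].reset_index(drop=True)
        fu_cases = followup[followup["group"] == "case"].reset_index(drop=True)
        adjuster = CovariateAdjuster().fit(controls)
        adj_cases = adjuster.transform(cases)
        adj_controls = adjuster.transform(controls)
        adj_fu = adjuster.transform(fu_cases)
        names = [c for c in table.columns if c.startswith("roi")]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mixtures = fit_mixtures(adj_cases, adj_controls, names)
        L_cases = likelihood_matrix_from_fits(mixtures, adj_cases, names)
        result = fit_ebm(L_cases, n_init=10, mcmc_iterations=0, seed=seed)
        base_staging = stage_cohort(L_cases, result.ml_sequence)
        fu_staging = stage_cohort(
            likelihood_matrix_from_fits(mixtures, adj_fu, names), result.ml_sequence
        )
        report = __import__("ebmkit").longitudinal_consistency(base_staging, fu_staging)
        runs.append(
            LongitudinalRun(
                fraction_non_decreasing=report.fraction_non_decreasing,
                mean_stage_change=report.mean_stage_change,
            )
        )
    return runs


def brute_force_sequence_likelihood(p_event, p_not_event, sequence, prior=None):
    """Literal stage-product enumeration of the sequence likelihood.

    Independent oracle: materializes, for every subject and stage k, the
    product of the first k events' P(x|E) and the remaining events'
    P(x|not E), sums over stages weighted by the prior, and multiplies over
    subjects (in log space only at the subject level).
    """
    p_event = np.asarray(p_event, float)
    p_not_event = np.asarray(p_not_event, float)
    n, z = p_event.shape
    prior = np.full(z + 1, 1.0 / (z + 1)) if prior is None else np.asarray(prior, float)
    total = 0.0
    for j in range(n):
        subject_sum = 0.0
        for k in range(z + 1):
            product = prior[k]
            for pos, ev in enumerate(sequence):
                product *= p_event[j, ev] if pos < k else p_not_event[j, ev]
            subject_sum += product
        total += np.log(subject_sum)
    return total


def random_likelihood_instance(rng, n_subjects, n_events):
    """Random strictly-positive likelihood matrices for oracle comparisons."""
    return (
        rng.uniform(0.05, 1.0, (n_subjects, n_events)),
        rng.uniform(0.05, 1.0, (n_subjects, n_events)),
    )
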