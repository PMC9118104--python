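"""Synthetic cohorts with the generative structure the event-based model assumes.

The generator draws a control cohort entirely from per-region "normal"
volume distributions and a patient cohort at heterogeneous latent disease
stages: a subject at stage ``k`` has the first ``k`` events of a ground-truth
ordering drawn from the "abnormal" (lower-volume, atrophic) distribution and
the rest from the normal one.  Covariate effects (age, sex, total
intracranial volume, scanner) are added additively so that the linear
adjustment step is exactly invertible.  A follow-up visit advances each
case's stage by a configurable non-negative increment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_ROI_NAMES",
    "ID_COLUMNS",
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_followup",
    "event_columns",
    "write_cohort",
]

#: Metadata columns of a biomarker table; every other column is one
#: event/region-of-interest volume.
ID_COLUMNS = ("subject_id", "visit", "group", "age", "sex", "tiv", "scanner")

#: Default 19-region layout: 4 brainstem, 3 cerebellar, 7 subcortical and
#: 5 cortical regions, the granularity at which atrophy ordering is studied
#: in progressive supranuclear palsy.
DEFAULT_ROI_NAMES = (
    "medulla", "pons", "scp", "midbrain",
    "cerebellar_cortex", "cerebellar_deep_nuclei", "vermis",
    "thalamus", "globus_pallidus", "striatum", "ventral_dc",
    "hippocampus", "amygdala", "nucleus_accumbens",
    "insula", "frontal", "temporal", "parietal", "occipital",
)


def event_columns(table: pd.DataFrame) -> list[str]:
    """Event (region) columns of a biomarker table, in stored order."""
    return [c for c in table.columns if c not in ID_COLUMNS]


def _as_event_array(value, n_events: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n_events,)).copy()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass
class SimulationConfig:
    """Study-condition parameters for cohort generation.

    Volumes are in arbitrary (mm^3-like) units.  The default separation of
    two scale units between the normal and abnormal component means mirrors
    the degree of case/control separation exercised throughout the test
    suite.  ``skew`` is the shape parameter of a skew-normal transform
    applied to the abnormal component (0 = Gaussian), used to stress the
    non-parametric mixture fits.
    """

    n_cases: int = 341
    n_controls: int = 260
    n_events: int = 19
    true_sequence: Sequence[int] | str = "random"
    stage_distribution: Sequence[float] | None = None  # uniform over 0..Z
    normal_loc: float | Sequence[float] = 100.0
    normal_scale: float | Sequence[float] = 5.0
    abnormal_loc: float | Sequence[float] = 90.0
    abnormal_scale: float | Sequence[float] = 5.0
    skew: float | Sequence[float] = 0.0
    covariate_effects: Mapping[str, object] = field(
        default_factory=lambda: {
            "age": -0.3,            # volume units per year
            "sex": 2.0,             # male (sex=1) offset
            "tiv": 0.02,            # per unit TIV
            "scanner": (0.0, 1.5, -1.0),  # additive offset per scanner level
        }
    )
    followup_stage_increment: int | Mapping[int, float] | str = 1
    event_names: Sequence[str] | None = None
    seed: int = 0

    # -- derived/validated views -------------------------------------------------
    def resolved_event_names(self) -> list[str]:
        if self.event_names is not None:
            names = list(self.event_names)
        elif self.n_events == len(DEFAULT_ROI_NAMES):
            names = list(DEFAULT_ROI_NAMES)
        else:
            names = [f"roi_{i:02d}" for i in range(self.n_events)]
        if len(names) != self.n_events:
            raise ValueError("event_names length must equal n_events")
        return names

    def resolved_sequence(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.true_sequence, str):
            if self.true_sequence != "random":
                raise ValueError(f"unknown true_sequence value {self.true_sequence!r}")
            return rng.permutation(self.n_events)
        seq = np.asarray(self.true_sequence, dtype=int)
        if sorted(seq.tolist()) != list(range(self.n_events)):
            raise ValueError("true_sequence must be a permutation of 0..n_events-1")
        return seq

    def resolved_stage_distribution(self) -> np.ndarray:
        z = self.n_events
        if self.stage_distribution is None:
            return np.full(z + 1, 1.0 / (z + 1))
        p = np.asarray(self.stage_distribution, dtype=float)
        if p.shape != (z + 1,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("stage_distribution must be a length Z+1 probability vector")
        return p / p.sum()

    def validate(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0 or self.n_events < 1:
            raise ValueError("counts must be non-negative and n_events >= 1")
        z = self.n_events
        n_loc = _as_event_array(self.normal_loc, z, "normal_loc")
        a_loc = _as_event_array(self.abnormal_loc, z, "abnormal_loc")
        _as_event_array(self.normal_scale, z, "normal_scale")
        _as_event_array(self.abnormal_scale, z, "abnormal_scale")
        if np.any(a_loc >= n_loc):
            raise ValueError(
                "abnormal location must lie below the normal location for every "
                "event (abnormal = atrophic = smaller volume)"
            )
        self.resolved_stage_distribution()
        self.resolved_event_names()


@dataclass
class GroundTruth:
    """Latent state of a generated cohort: the event ordering and per-row stage."""

    true_sequence: np.ndarray
    stages: pd.DataFrame  # columns: subject_id, visit, true_stage
    #: direction of abnormality per event (-1: abnormal is lower); recorded
    #: so downstream checks never have to re-infer it.
    abnormal_direction: int = -1

    def stage_of(self, subject_id: str, visit: str = "baseline") -> int:
        sel = self.stages[
            (self.stages["subject_id"] == subject_id) & (self.stages["visit"] == visit)
        ]
        if sel.empty:
            raise KeyError(f"no ground-truth stage for {subject_id!r}/{visit!r}")
        return int(sel["true_stage"].iloc[0])


def _component_draw(rng, loc, scale, skew):
    """Draw one value per (row, event) from skew-normal components.

    ``skewnorm`` with shape a=0 reduces exactly to a Gaussian; the draws are
    re-centred so that ``loc`` is the component mean regardless of skew.
    """
    loc = np.asarray(loc, float)
    scale = np.asarray(scale, float)
    a = np.asarray(skew, float)
    raw = stats.skewnorm.rvs(
        np.broadcast_to(a, loc.shape), loc=0.0, scale=1.0,
        size=loc.shape, random_state=rng,
    )
    # subtract the skew-normal mean so loc stays the component mean
    delta = a / np.sqrt(1 + a**2)
    raw = raw - delta * np.sqrt(2 / np.pi)
    return loc + scale * raw


def _covariates(rng: np.random.Generator, n: int, config: SimulationConfig):
    eff = config.covariate_effects
    scanner_offsets = np.asarray(eff.get("scanner", (0.0,)), dtype=float)
    n_scanners = max(len(scanner_offsets), 1)
    age = rng.normal(66.0, 8.0, n)
    sex = rng.integers(0, 2, n)
    tiv = rng.normal(1450.0, 130.0, n)
    scanner = rng.integers(0, n_scanners, n)
    shift = (
        float(eff.get("age", 0.0)) * age
        + float(eff.get("sex", 0.0)) * sex
        + float(eff.get("tiv", 0.0)) * tiv
        + scanner_offsets[scanner]
    )
    return age, sex, tiv, scanner, shift


def _draw_values(rng, stages, sequence, config):
    """Values for rows at given stages: first-k events in sequence abnormal."""
    z = config.n_events
    n = len(stages)
    n_loc = _as_event_array(config.normal_loc, z, "normal_loc")
    n_scale = _as_event_array(config.normal_scale, z, "normal_scale")
    a_loc = _as_event_array(config.abnormal_loc, z, "abnormal_loc")
    a_scale = _as_event_array(config.abnormal_scale, z, "abnormal_scale")
    skew = _as_event_array(config.skew, z, "skew")

    # position of each event within the ordering
    position = np.empty(z, dtype=int)
    position[sequence] = np.arange(z)
    abnormal = position[None, :] < np.asarray(stages)[:, None]  # (n, z)

    loc = np.where(abnormal, a_loc[None, :], n_loc[None, :])
    scale = np.where(abnormal, a_scale[None, :], n_scale[None, :])
    skew_m = np.where(abnormal, skew[None, :], 0.0)
    if n == 0:
        return np.empty((0, z))
    return _component_draw(rng, loc, scale, skew_m)


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a baseline cohort table and its ground truth.

    Controls are drawn entirely from the normal components (stage 0); each
    case receives a latent stage from ``stage_distribution`` and has exactly
    the first ``stage`` events of the true ordering drawn from the abnormal
    components.  All randomness flows from ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
    z = config.n_events
    names = config.resolved_event_names()
    sequence = config.resolved_sequence(rng)
    stage_p = config.resolved_stage_distribution()

    case_stages = rng.choice(z + 1, size=config.n_cases, p=stage_p)
    control_stages = np.zeros(config.n_controls, dtype=int)
    stages = np.concatenate([case_stages, control_stages])
    group = ["case"] * config.n_cases + ["control"] * config.n_controls
    subject_id = [f"case_{i:04d}" for i in range(config.n_cases)] + [
        f"ctrl_{i:04d}" for i in range(config.n_controls)
    ]
    n = len(stages)

    age, sex, tiv, scanner, shift = _covariates(rng, n, config)
    values = _draw_values(rng, stages, sequence, config) + shift[:, None]

    table = pd.DataFrame(
        {
            "subject_id": subject_id,
            "visit": "baseline",
            "group": group,
            "age": age,
            "sex": sex,
            "tiv": tiv,
            "scanner": [f"scanner_{s}" for s in scanner],
        }
    )
    for j, name in enumerate(names):
        table[name] = values[:, j]

    truth = GroundTruth(
        true_sequence=sequence,
        stages=pd.DataFrame(
            {"subject_id": subject_id, "visit": "baseline", "true_stage": stages}
        ),
    )
    return table, truth


def _increment_draw(rng, dist, n: int) -> np.ndarray:
    if isinstance(dist, str):
        if dist == "poisson":
            return rng.poisson(1.0, n)
        raise ValueError(f"unknown followup_stage_increment {dist!r}")
    if isinstance(dist, Mapping):
        ks = np.array(sorted(dist), dtype=int)
        ps = np.array([dist[int(k)] for k in ks], dtype=float)
        if np.any(ks < 0) or np.any(ps < 0) or not np.isclose(ps.sum(), 1.0):
            raise ValueError("increment distribution must be over non-negative "
                             "integers and sum to 1")
        return ks[rng.choice(len(ks), size=n, p=ps / ps.sum())]
    k = int(dist)
    if k < 0:
        raise ValueError("stage increment must be non-negative")
    return np.full(n, k, dtype=int)


def generate_followup(
    table: pd.DataFrame, truth: GroundTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """A 12-month follow-up visit: case stages advance, volumes are re-drawn.

    Each case's follow-up stage is ``min(Z, baseline + increment)`` with the
    increment drawn from ``config.followup_stage_increment``; controls stay
    at stage 0.  Covariates are carried over (age advanced by one year).
    """
    if truth is None or truth.stages.empty:
        raise ValueError("baseline ground truth is required to generate follow-up")
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.Generator(np.random.PCG64(ss.spawn(2)[1]))
    z = config.n_events

    base = table[table["visit"] == "baseline"].reset_index(drop=True)
    base_truth = truth.stages[truth.stages["visit"] == "baseline"]
    stage_map = dict(zip(base_truth["subject_id"], base_truth["true_stage"]))
    baseline_stages = np.array([stage_map[s] for s in base["subject_id"]], dtype=int)

    is_case = (base["group"] == "case").to_numpy()
    inc = _increment_draw(rng, config.followup_stage_increment, int(is_case.sum()))
    new_stages = baseline_stages.copy()
    new_stages[is_case] = np.minimum(z, baseline_stages[is_case] + inc)

    eff = config.covariate_effects
    followup = base.copy()
    followup["visit"] = "m12"
    followup["age"] = base["age"] + 1.0
    scanner_offsets = np.asarray(eff.get("scanner", (0.0,)), dtype=float)
    scanner_idx = base["scanner"].str.removeprefix("scanner_").astype(int).to_numpy()
    shift = (
        float(eff.get("age", 0.0)) * followup["age"].to_numpy()
        + float(eff.get("sex", 0.0)) * base["sex"].to_numpy()
        + float(eff.get("tiv", 0.0)) * base["tiv"].to_numpy()
        + scanner_offsets[np.minimum(scanner_idx, len(scanner_offsets) - 1)]
    )
    values = _draw_values(rng, new_stages, truth.true_sequence, config) + shift[:, None]
    names = config.resolved_event_names()
    followup[names] = values

    fu_truth = GroundTruth(
        true_sequence=truth.true_sequence,
        stages=pd.DataFrame(
            {
                "subject_id": base["subject_id"],
                "visit": "m12",
                "true_stage": new_stages,
            }
        ),
    )
    return followup, fu_truth


def write_cohort(
    out_dir: str | Path,
    table: pd.DataFrame,
    truth: GroundTruth | None = None,
    prefix: str = "cohort",
) -> None:
    """Write a cohort table (CSV) and its ground truth (CSV + JSON sidecars)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / f"{prefix}.csv", index=False)
    if truth is not None:
        truth.stages.to_csv(out / f"{prefix}_true_stages.csv", index=False)
        with open(out / f"{prefix}_true_sequence.json", "w") as fh:
            json.dump({"true_sequence": truth.true_sequence.tolist()}, fh)
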