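"""Covariate adjustment, region combination and biomarker selection.

Regional volumes are confounded by age, sex, head size (TIV) and scanner.
Following standard practice for event-based modelling, a linear model per
region is fitted on the *control* cohort only and its prediction subtracted
from every subject's value; the residuals ("adjusted volumes") are the
biomarkers.  Selection keeps regions whose adjusted volumes differ between
cases and controls under a two-tailed Welch t-test at a Bonferroni-corrected
threshold (family-wise alpha / number of regions).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import event_columns

__all__ = [
    "CovariateAdjuster",
    "SelectionReport",
    "combine_lateral_regions",
    "fit_covariate_model",
    "adjust",
    "select_biomarkers",
    "chi_square_2x2",
    "welch_t_from_summary",
]

DEFAULT_COVARIATES = ("age", "sex", "tiv", "scanner")


def _combined_name(left: str, right: str) -> str:
    for token in ("left_", "right_"):
        if left.lower().startswith(token):
            return left[len(token):]
    for token in ("_left", "_right"):
        if left.lower().endswith(token):
            return left[: -len(token)]
    return f"{left}+{right}"


def combine_lateral_regions(
    table: pd.DataFrame, pairs: Sequence[tuple[str, ...]]
) -> pd.DataFrame:
    """Replace each (left, right) column pair by their sum.

    ``pairs`` entries are ``(left, right)`` or ``(left, right, name)``; the
    default combined name strips a leading/trailing left/right token from
    the left column's name.  Other columns are untouched; an empty pair list
    returns the table unchanged.
    """
    out = table.copy()
    for pair in pairs:
        if len(pair) == 3:
            left, right, name = pair
        else:
            left, right = pair
            name = _combined_name(left, right)
        for col in (left, right):
            if col not in out.columns:
                raise KeyError(f"lateral column {col!r} not present in table")
        combined = out[left] + out[right]
        insert_at = out.columns.get_loc(left)
        out = out.drop(columns=[left, right])
        out.insert(min(insert_at, len(out.columns)), name, combined)
    return out


class CovariateAdjuster(TransformerMixin, BaseEstimator):
    """Per-region linear covariate model fitted on controls.

    Ordinary least squares of each event column on an intercept, age, sex,
    TIV and reference-level scanner indicators.  ``transform`` returns the
    table with each value replaced by its residual (observed minus
    predicted), applied to cases and controls alike, so that the control
    distribution of every adjusted biomarker is centred at zero.

    Parameters
    ----------
    covariates : tuple of str
        Covariate columns to adjust for; ``scanner`` is treated as
        categorical with the first observed level as reference.
    """

    def __init__(self, covariates: Sequence[str] = DEFAULT_COVARIATES):
        self.covariates = covariates

    # -- design matrix -----------------------------------------------------------
    def _design(self, table: pd.DataFrame, fit: bool) -> np.ndarray:
        cols = [np.ones(len(table))]
        names = ["intercept"]
        for cov in self.covariates:
            if cov == "scanner":
                if fit:
                    self.scanner_levels_ = sorted(table["scanner"].unique())
                ref = self.scanner_levels_[0]
                seen = set(self.scanner_levels_)
                values = table["scanner"]
                unseen = set(values.unique()) - seen
                if unseen:
                    warnings.warn(
                        f"unseen scanner levels {sorted(unseen)} mapped to "
                        f"reference level {ref!r}"
                    )
                    values = values.where(values.isin(seen), ref)
                for level in self.scanner_levels_[1:]:
                    cols.append((values == level).to_numpy(float))
                    names.append(f"scanner[{level}]")
            else:
                cols.append(table[cov].to_numpy(float))
                names.append(cov)
        X = np.column_stack(cols)
        if fit:
            keep = [0]
            for j in range(1, X.shape[1]):
                if np.std(X[:, j]) <= 0:
                    warnings.warn(
                        f"covariate {names[j]!r} is constant in the control set; dropped"
                    )
                else:
                    keep.append(j)
            self._keep_ = keep
            self.design_columns_ = [names[j] for j in keep]
        else:
            name_to_col = dict(zip(names, range(X.shape[1])))
            keep = [name_to_col[n] for n in self.design_columns_]
        return X[:, keep]

    def fit(self, X: pd.DataFrame, y=None) -> "CovariateAdjuster":
        controls = X
        if "group" in controls.columns and (controls["group"] != "control").any():
            raise ValueError("covariate model must be fitted on controls only")
        self.event_names_ = event_columns(controls)
        D = self._design(controls, fit=True)
        if len(controls) < D.shape[1] + 2:
            raise ValueError("not enough control rows to fit the covariate model")
        Y = controls[self.event_names_].to_numpy(float)
        coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
        self.coef_ = pd.DataFrame(
            coef, index=self.design_columns_, columns=self.event_names_
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "coef_"):
            raise ValueError("CovariateAdjuster is not fitted")
        missing = [c for c in self.event_names_ if c not in X.columns]
        if missing:
            raise KeyError(f"event columns missing from table: {missing}")
        D = self._design(X, fit=False)
        predicted = D @ self.coef_.to_numpy()
        out = X.copy()
        out[self.event_names_] = X[self.event_names_].to_numpy(float) - predicted
        return out

    # -- serialization -----------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "covariates": list(self.covariates),
            "scanner_levels": getattr(self, "scanner_levels_", []),
            "design_columns": self.design_columns_,
            "coef": self.coef_.to_dict(orient="split"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CovariateAdjuster":
        with open(path) as fh:
            payload = json.load(fh)
        model = cls(covariates=tuple(payload["covariates"]))
        model.scanner_levels_ = payload["scanner_levels"]
        model.design_columns_ = payload["design_columns"]
        d = payload["coef"]
        model.coef_ = pd.DataFrame(d["data"], index=d["index"], columns=d["columns"])
        model.event_names_ = list(model.coef_.columns)
        return model


def fit_covariate_model(
    controls: pd.DataFrame, covariates: Sequence[str] = DEFAULT_COVARIATES
) -> CovariateAdjuster:
    """OLS covariate model per event column, fitted on the control cohort."""
    return CovariateAdjuster(covariates=covariates).fit(controls)


def adjust(table: pd.DataFrame, model: CovariateAdjuster) -> pd.DataFrame:
    """Residualize every event column against the control-fitted model."""
    return model.transform(table)


@dataclass
class SelectionReport:
    """Per-event group-difference tests with the Bonferroni threshold applied."""

    table: pd.DataFrame  # columns: event, t, p, selected
    threshold: float
    family_alpha: float

    @property
    def selected(self) -> list[str]:
        return self.table.loc[self.table["selected"], "event"].tolist()

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.attrs = {}
        out.to_csv(path, index=False)


def select_biomarkers(
    cases: pd.DataFrame, controls: pd.DataFrame, family_alpha: float = 0.05
) -> SelectionReport:
    """Two-tailed Welch t-test per event; pass iff p < family_alpha / Z.

    Expects covariate-adjusted tables.  Events with zero variance in both
    groups have an undefined test and are flagged as not selected.
    """
    events = event_columns(cases)
    if event_columns(controls) != events:
        raise ValueError("case and control tables must share event columns")
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need at least two rows per group")
    z = len(events)
    threshold = family_alpha / z
    rows = []
    for ev in events:
        a = cases[ev].to_numpy(float)
        b = controls[ev].to_numpy(float)
        if np.var(a) == 0 and np.var(b) == 0:
            warnings.warn(f"event {ev!r} has zero variance in both groups; not selected")
            rows.append((ev, np.nan, np.nan, False))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append((ev, float(t), float(p), bool(p < threshold)))
    table = pd.DataFrame(rows, columns=["event", "t", "p", "selected"])
    return SelectionReport(table=table, threshold=threshold, family_alpha=family_alpha)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for a 2x2 table.

    Rows are groups, columns are categories: ``[[a, b], [c, d]]``.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0) or table.sum() <= 0:
        raise ValueError("counts must be non-negative with a positive total")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: zero marginal total")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Welch two-sample t-test from summary statistics.

    The sign convention is ``mean1 - mean2``: a negative statistic means
    group 1 has the smaller mean.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    return float(res.statistic), float(res.pvalue)
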