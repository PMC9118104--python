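"""Two-component kernel-density mixture models for event likelihoods.

For each biomarker the event-based model needs P(x|E) and P(x|not E): the
density of a value under the abnormal and the normal distribution.  Rather
than assuming Gaussian components, both densities are responsibility-
weighted kernel density estimates refitted inside an EM-style loop, which
keeps the fits faithful when the abnormal distribution is skewed.

Controls anchor the normal component (their responsibilities are fixed);
case responsibilities and the abnormal mixing fraction theta are updated
each iteration.  The fitted posterior P(E|x) is forced to be non-increasing
in the biomarker value (volumes shrink with atrophy) by pooled-adjacent-
violators over a dense grid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

__all__ = ["KDEMixture", "GaussianMixtureBaseline", "fit_kde_mixture", "event_likelihoods"]


def _weighted_kde(
    values: np.ndarray, weights: np.ndarray, bw_floor: float = 0.0
) -> stats.gaussian_kde:
    """Responsibility-weighted Gaussian KDE with Silverman bandwidth.

    ``bw_floor`` keeps a component estimated from a handful of points from
    degenerating into spikes narrower than the data resolution.
    """
    mask = weights > 1e-12
    v, w = values[mask], weights[mask]
    if len(v) < 2 or np.allclose(v, v[0]):
        raise ValueError("degenerate bandwidth: component has (near-)zero variance")
    kde = stats.gaussian_kde(v, bw_method="silverman", weights=w)
    bw = np.sqrt(kde.covariance[0, 0])
    if bw < bw_floor:
        kde.set_bandwidth(bw_method=kde.factor * bw_floor / bw)
    return kde


class KDEMixture(BaseEstimator):
    """Constrained two-component KDE mixture for one biomarker.

    Parameters
    ----------
    init_percentile : float
        Control percentile below which case values are initialized as
        abnormal (volumes: abnormal is the lower tail).
    max_iter, tol : int, float
        EM-style loop stops when the largest absolute responsibility change
        falls below ``tol`` or after ``max_iter`` iterations.
    theta_clip : (float, float)
        The abnormal mixing fraction is clamped to this interval so a
        component can never vanish entirely.
    grid_size : int
        Evaluation grid for the monotone posterior cleanup.
    floor : float
        Density floor applied when evaluating likelihoods, keeping
        log-likelihoods finite for outliers.
    min_bandwidth_fraction : float
        Component bandwidths may not undercut this fraction of the pooled
        Silverman bandwidth (keeps tiny components from spiking).
    contamination : float
        Weight of a uniform outlier component mixed into both densities
        when forming the posterior, so one extreme value is never read as
        definitive evidence.

    Attributes
    ----------
    theta_ : float
        Fitted abnormal mixing fraction among cases.
    converged_ : bool, n_iter_ : int
        Loop diagnostics.
    """

    def __init__(
        self,
        init_percentile: float = 10.0,
        max_iter: int = 200,
        tol: float = 1e-4,
        theta_clip: tuple[float, float] = (0.01, 0.99),
        grid_size: int = 512,
        floor: float = 1e-10,
        monotone: bool = True,
        min_group_size: int = 10,
        min_bandwidth_fraction: float = 0.25,
        contamination: float = 0.01,
    ):
        self.init_percentile = init_percentile
        self.max_iter = max_iter
        self.tol = tol
        self.theta_clip = theta_clip
        self.grid_size = grid_size
        self.floor = floor
        self.monotone = monotone
        self.min_group_size = min_group_size
        self.min_bandwidth_fraction = min_bandwidth_fraction
        self.contamination = contamination

    # ------------------------------------------------------------------ fitting
    def fit(self, X, y) -> "KDEMixture":
        """Fit from pooled values ``X`` with labels ``y`` (0 control, 1 case)."""
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=int).ravel()
        if x.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite biomarker value")
        controls = x[y == 0]
        cases = x[y == 1]
        if len(controls) < self.min_group_size or len(cases) < self.min_group_size:
            raise ValueError(
                f"need at least {self.min_group_size} values per group"
            )
        if np.std(x) == 0:
            raise ValueError("degenerate bandwidth: zero variance data")

        # initial case responsibilities: below a control percentile -> abnormal
        cut = np.percentile(controls, self.init_percentile)
        order = np.argsort(cases)
        r = self._enforce_component_sizes((cases < cut).astype(float), order)

        # With both components free KDEs, soft EM is degenerate (the
        # abnormal KDE can absorb the whole case distribution), so each
        # responsibility update is projected to a hard monotone split:
        # abnormal iff the monotone-cleaned posterior exceeds 1/2.  Controls
        # stay anchored in the normal component throughout.
        lo, hi = self.theta_clip
        pooled = np.concatenate([controls, cases])
        # component bandwidths may not undercut a fraction of the pooled
        # Silverman bandwidth (guards tiny components against spiking)
        pooled_bw = np.sqrt(stats.gaussian_kde(pooled, bw_method="silverman").covariance[0, 0])
        bw_floor = self.min_bandwidth_fraction * pooled_bw
        pad = 3 * np.std(pooled)
        grid = np.linspace(pooled.min() - pad, pooled.max() + pad, self.grid_size)
        # the monotone cleanup runs over the observed data range only: in
        # the padded tails the posterior reverts to uninformative values
        # that would otherwise be averaged into the genuine signal
        support = np.linspace(pooled.min(), pooled.max(), self.grid_size)
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=False)
        self.converged_ = False
        for it in range(1, self.max_iter + 1):
            w_normal = np.concatenate([np.ones(len(controls)), 1.0 - r])
            kde_n = _weighted_kde(pooled, w_normal, bw_floor)
            kde_a = _weighted_kde(cases, r, bw_floor)
            theta = float(np.clip(r.mean(), lo, hi))

            f_a = np.maximum(kde_a(support), self.floor)
            f_n = np.maximum(kde_n(support), self.floor)
            post_grid = iso.fit_transform(
                support, theta * f_a / (theta * f_a + (1 - theta) * f_n)
            )
            r_new = (np.interp(cases, support, post_grid) > 0.5).astype(float)
            r_new = self._enforce_component_sizes(r_new, order)

            delta = float(np.max(np.abs(r_new - r)))
            r = r_new
            if delta < self.tol:
                self.converged_ = True
                break
        if not self.converged_:
            warnings.warn("KDE mixture did not converge; returning best fit")

        self.n_iter_ = it
        self.theta_ = float(np.clip(r.mean(), lo, hi))
        self.responsibilities_ = r
        w_normal = np.concatenate([np.ones(len(controls)), 1.0 - r])
        self.kde_normal_ = _weighted_kde(pooled, w_normal, bw_floor)
        self.kde_abnormal_ = _weighted_kde(cases, r, bw_floor)
        self._training_values_ = pooled

        self.grid_ = grid
        cleaned = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=False).fit_transform(
            support, self._raw_posterior(support)
        )
        # constant extension beyond the data range keeps monotonicity
        self.posterior_grid_ = np.interp(grid, support, cleaned)
        return self

    @staticmethod
    def _enforce_component_sizes(r: np.ndarray, order: np.ndarray) -> np.ndarray:
        """Keep >=2 case values in each component so both KDEs stay estimable.

        ``order`` sorts the case values ascending; the monotone split means
        responsibilities are contiguous in that order.
        """
        r = r.copy()
        if r.sum() < 2:
            r[order[:2]] = 1.0
        if (1 - r).sum() < 2:
            r[order[-2:]] = 0.0
        return r

    # ------------------------------------------------------------------ queries
    def _check_fitted(self):
        if not hasattr(self, "theta_"):
            raise ValueError("KDEMixture is not fitted")

    def pdf_normal(self, x) -> np.ndarray:
        self._check_fitted()
        return self.kde_normal_(np.asarray(x, float).ravel())

    def pdf_abnormal(self, x) -> np.ndarray:
        self._check_fitted()
        return self.kde_abnormal_(np.asarray(x, float).ravel())

    def _raw_posterior(self, x) -> np.ndarray:
        """Mixture posterior P(E|x); grid points where both densities sit at
        the floor carry no evidence and are filled from the nearest
        informative point so they cannot distort the monotone cleanup."""
        x = np.asarray(x, dtype=float).ravel()
        # unfloored densities: flooring before the ratio would distort the
        # posterior near the support edge (a floored component inflates the
        # weaker density by orders of magnitude).  A small uniform
        # contamination term in both components keeps a lone outlier from
        # reading as definitive evidence either way.
        u = self.contamination / max(self.grid_[-1] - self.grid_[0], 1e-300)
        f_a = (1 - self.contamination) * self.pdf_abnormal(x) + u
        f_n = (1 - self.contamination) * self.pdf_normal(x) + u
        mix = self.theta_ * f_a + (1 - self.theta_) * f_n
        with np.errstate(invalid="ignore", divide="ignore"):
            post = np.where(mix > 0, self.theta_ * f_a / np.maximum(mix, 1e-300), 0.5)
        informative = mix > self.floor
        if informative.any() and not informative.all():
            order = np.argsort(x, kind="stable")
            xs, ps, inf_s = x[order], post[order], informative[order]
            filled = np.interp(xs, xs[inf_s], ps[inf_s])
            post = np.empty_like(filled)
            post[order] = filled
        return post

    def posterior(self, x) -> np.ndarray:
        """P(E|x), monotone non-increasing in x when ``monotone`` is set."""
        self._check_fitted()
        x = np.asarray(x, dtype=float).ravel()
        if self.monotone:
            return np.interp(x, self.grid_, self.posterior_grid_)
        return self._raw_posterior(x)

    def likelihoods(self, x) -> tuple[np.ndarray, np.ndarray]:
        """(P(x|E), P(x|not E)), floored at ``floor``.

        With the monotone cleanup active the component densities are
        reconstructed from the cleaned posterior ``q`` and the mixture
        density ``m``: P(x|E) = q m / theta, P(x|not E) = (1-q) m / (1-theta),
        which preserves the mixture while guaranteeing a monotone
        likelihood ratio.
        """
        self._check_fitted()
        x = np.asarray(x, dtype=float).ravel()
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite biomarker value")
        f_a = np.maximum(self.pdf_abnormal(x), self.floor)
        f_n = np.maximum(self.pdf_normal(x), self.floor)
        # far outside the support both densities hit the floor and the
        # value carries no evidence either way: likelihood ratio 1
        far = (f_a <= self.floor) & (f_n <= self.floor)
        if not self.monotone:
            return np.where(far, self.floor, f_a), np.where(far, self.floor, f_n)
        m = self.theta_ * f_a + (1 - self.theta_) * f_n
        q = self.posterior(x)
        p_event = np.maximum(q * m / self.theta_, self.floor)
        p_not_event = np.maximum((1 - q) * m / (1 - self.theta_), self.floor)
        return np.where(far, self.floor, p_event), np.where(far, self.floor, p_not_event)

    def score_samples(self, x) -> np.ndarray:
        """Log mixture density (theta-weighted) at ``x``."""
        self._check_fitted()
        x = np.asarray(x, dtype=float).ravel()
        f_a = np.maximum(self.pdf_abnormal(x), self.floor)
        f_n = np.maximum(self.pdf_normal(x), self.floor)
        return np.log(self.theta_ * f_a + (1 - self.theta_) * f_n)

    # ------------------------------------------------------------ serialization
    def to_dict(self) -> dict:
        self._check_fitted()

        def kde_payload(kde):
            return {
                "locations": kde.dataset.ravel().tolist(),
                "weights": kde.weights.tolist(),
                "bandwidth": float(np.sqrt(kde.covariance[0, 0])),
            }

        return {
            "theta": self.theta_,
            "converged": self.converged_,
            "n_iter": self.n_iter_,
            "normal": kde_payload(self.kde_normal_),
            "abnormal": kde_payload(self.kde_abnormal_),
            "params": self.get_params(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    return float(v[np.searchsorted(cw, 0.5 * cw[-1])])


class GaussianMixtureBaseline(BaseEstimator):
    """Two-Gaussian analogue of :class:`KDEMixture`, used as a comparison.

    Same constrained EM structure (controls anchored to the normal
    component) with Gaussian components in place of weighted KDEs.
    """

    def __init__(self, init_percentile=10.0, max_iter=200, tol=1e-4,
                 theta_clip=(0.01, 0.99), floor=1e-10):
        self.init_percentile = init_percentile
        self.max_iter = max_iter
        self.tol = tol
        self.theta_clip = theta_clip
        self.floor = floor

    def fit(self, X, y) -> "GaussianMixtureBaseline":
        x = np.asarray(X, float).ravel()
        y = np.asarray(y, int).ravel()
        controls, cases = x[y == 0], x[y == 1]
        cut = np.percentile(controls, self.init_percentile)
        r = (cases < cut).astype(float)
        if r.sum() < 2:
            r[np.argsort(cases)[:2]] = 1.0
        lo, hi = self.theta_clip
        pooled = np.concatenate([controls, cases])
        self.converged_ = False
        for it in range(1, self.max_iter + 1):
            w_n = np.concatenate([np.ones(len(controls)), 1 - r])
            mu_n = np.average(pooled, weights=w_n)
            sd_n = max(np.sqrt(np.average((pooled - mu_n) ** 2, weights=w_n)), 1e-8)
            w_sum = max(r.sum(), 1e-8)
            mu_a = np.average(cases, weights=np.maximum(r, 1e-12))
            sd_a = max(np.sqrt(np.average((cases - mu_a) ** 2,
                                          weights=np.maximum(r, 1e-12))), 1e-8)
            theta = float(np.clip(r.mean(), lo, hi))
            f_a = np.maximum(stats.norm.pdf(cases, mu_a, sd_a), self.floor)
            f_n = np.maximum(stats.norm.pdf(cases, mu_n, sd_n), self.floor)
            r_new = theta * f_a / (theta * f_a + (1 - theta) * f_n)
            if mu_a >= mu_n:
                r_new = (cases < cut).astype(float)
            delta = float(np.max(np.abs(r_new - r)))
            r = r_new
            if delta < self.tol:
                self.converged_ = True
                break
        self.n_iter_ = it
        self.theta_ = float(np.clip(r.mean(), lo, hi))
        self.mu_normal_, self.sd_normal_ = float(mu_n), float(sd_n)
        self.mu_abnormal_, self.sd_abnormal_ = float(mu_a), float(sd_a)
        return self

    def score_samples(self, x) -> np.ndarray:
        x = np.asarray(x, float).ravel()
        f_a = np.maximum(stats.norm.pdf(x, self.mu_abnormal_, self.sd_abnormal_), self.floor)
        f_n = np.maximum(stats.norm.pdf(x, self.mu_normal_, self.sd_normal_), self.floor)
        return np.log(self.theta_ * f_a + (1 - self.theta_) * f_n)


def fit_kde_mixture(control_values, case_values, **params) -> KDEMixture:
    """Fit a :class:`KDEMixture` from separate control and case value arrays."""
    control_values = np.asarray(control_values, float).ravel()
    case_values = np.asarray(case_values, float).ravel()
    x = np.concatenate([control_values, case_values])
    y = np.concatenate([np.zeros(len(control_values), int), np.ones(len(case_values), int)])
    return KDEMixture(**params).fit(x, y)


def event_likelihoods(fit: KDEMixture, values) -> tuple[np.ndarray, np.ndarray]:
    """(P(x|E), P(x|not E)) for each value under a fitted mixture."""
    return fit.likelihoods(values)
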