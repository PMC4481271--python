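"""Multivariate-Gaussian cohort prior over combined parameters.

The prior is built by fitting whole PSA courses of a reference cohort and
taking the sample mean and covariance of the fitted 13-vectors (initial
conditions included: they are patient-specific, but the cohort spread of
presenting tumor burdens is itself informative and is priored deliberately).
A small ridge is added to the covariance diagonal because 13 parameters
estimated from a few dozen patients can give a near-singular matrix.

Mardia's multivariate skewness and kurtosis are provided to check whether a
cohort of fitted vectors is plausibly Gaussian at all.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import linalg, stats

from .model import CombinedParameters, N_PARAMS


@dataclass(frozen=True)
class PriorModel:
    """Mean and (ridge-regularized) covariance of cohort parameter vectors."""

    mean: np.ndarray            # (13,)
    covariance: np.ndarray      # (13, 13), symmetric positive definite
    ridge: float                # diagonal inflation that was added
    n_cohort: int               # number of vectors the prior was built from

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        if mean.shape != (N_PARAMS,) or cov.shape != (N_PARAMS, N_PARAMS):
            raise ValueError("prior must be 13-dimensional")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    @property
    def precision(self) -> np.ndarray:
        """Inverse covariance, via a Cholesky solve."""
        try:
            cho = linalg.cho_factor(self.covariance)
        except linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "prior covariance is not positive definite; "
                "use a positive ridge") from err
        return linalg.cho_solve(cho, np.eye(N_PARAMS))

    def to_json(self, path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "covariance": self.covariance.tolist(),
            "ridge": self.ridge,
            "n_cohort": self.n_cohort,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PriorModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(mean=np.array(payload["mean"], dtype=float),
                   covariance=np.array(payload["covariance"], dtype=float),
                   ridge=float(payload["ridge"]),
                   n_cohort=int(payload["n_cohort"]))


class MardiaResult(NamedTuple):
    skewness_stat: float   # N * b1p / 6, chi-square under normality
    skewness_p: float
    kurtosis_stat: float   # standardized b2p, standard normal under normality
    kurtosis_p: float      # two-sided


def _stack(fitted: Sequence) -> np.ndarray:
    rows = [f.to_array() if isinstance(f, CombinedParameters)
            else np.asarray(f, dtype=float) for f in fitted]
    X = np.vstack(rows)
    if X.ndim != 2 or X.shape[1] != N_PARAMS:
        raise ValueError("each cohort member must be a 13-vector")
    if not np.all(np.isfinite(X)):
        raise ValueError("cohort parameter vectors contain non-finite values")
    return X


def build_prior(fitted: Sequence, ridge: float | None = None) -> PriorModel:
    """Sample mean and covariance (denominator N-1) of cohort fits.

    ridge defaults to 1e-8 * trace(S)/13, enough to make the covariance
    positive definite even for degenerate cohorts while perturbing a
    well-conditioned one negligibly.
    """
    X = _stack(fitted)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 fitted vectors to build a prior")
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    if ridge is None:
        tr = float(np.trace(cov))
        ridge = 1e-8 * (tr / N_PARAMS if tr > 0 else 1.0)
    cov = cov + float(ridge) * np.eye(N_PARAMS)
    return PriorModel(mean=mean, covariance=cov, ridge=float(ridge),
                      n_cohort=n)


def prior_quadform(params, prior: PriorModel) -> float:
    """Half squared Mahalanobis distance (p - pbar)' S^-1 (p - pbar) / 2."""
    p = (params.to_array() if isinstance(params, CombinedParameters)
         else np.asarray(params, dtype=float))
    d = p - prior.mean
    try:
        cho = linalg.cho_factor(prior.covariance)
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "prior covariance is singular; build the prior with a positive "
            "ridge") from err
    return 0.5 * float(d @ linalg.cho_solve(cho, d))


def mardia_tests(fitted: Sequence) -> MardiaResult:
    """Mardia's multivariate skewness and kurtosis tests of normality.

    Skewness: b1p = mean over pairs of the cubed Mahalanobis cross products;
    N*b1p/6 is referred to chi-square with p(p+1)(p+2)/6 degrees of freedom.
    Kurtosis: b2p = mean squared Mahalanobis distance, standardized with
    Mardia's finite-sample mean p(p+2)(N-1)/(N+1) and variance 8p(p+2)/N,
    referred (two-sided) to the standard normal.  Both use the maximum
    -likelihood covariance (denominator N).
    """
    X = _stack(fitted)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than dimensions "
                         f"({p}) for Mardia's tests")
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / n
    try:
        cho = linalg.cho_factor(S)
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "sample covariance is singular; Mardia's tests are undefined"
        ) from err
    D = Xc @ linalg.cho_solve(cho, Xc.T)
    b1 = float((D ** 3).sum()) / n ** 2
    b2 = float((np.diag(D) ** 2).sum()) / n

    skew_stat = n * b1 / 6.0
    skew_df = p * (p + 1) * (p + 2) / 6.0
    skew_p = float(stats.chi2.sf(skew_stat, skew_df))

    kurt_mean = p * (p + 2) * (n - 1) / (n + 1)
    kurt_sd = np.sqrt(8.0 * p * (p + 2) / n)
    z = (b2 - kurt_mean) / kurt_sd
    kurt_p = float(2.0 * stats.norm.sf(abs(z)))
    return MardiaResult(float(skew_stat), skew_p, float(z), kurt_p)
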