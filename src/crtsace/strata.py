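"""Multinomial-logistic principal-strata membership model.

Participants in a two-arm trial with mortality fall into latent principal
strata defined by their pair of potential survival statuses: never-survivors
(``00``), protected individuals (``10``, survive only if treated) and
always-survivors (``11``).  Membership is modeled by multinomial logistic
regression on baseline covariates with always-survivors — typically the
largest stratum — as the reference category:

    P(G=00) = exp(x'beta)  / (1 + exp(x'beta) + exp(x'gamma))
    P(G=10) = exp(x'gamma) / (1 + exp(x'beta) + exp(x'gamma))
    P(G=11) = 1            / (1 + exp(x'beta) + exp(x'gamma))

Each component of ``beta`` (never- vs always-survivor) and ``gamma``
(protected vs always-survivor) is a log odds ratio.  When membership is
correlated within randomized clusters, an optional shared cluster random
intercept ``chi_i ~ N(0, phi2)`` is added to both non-reference linear
predictors.

All probability computations run on the log scale with max-subtraction so
linear predictors up to |700| neither overflow nor destroy the simplex
constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "G_NEVER",
    "G_PROTECTED",
    "G_ALWAYS",
    "STRATUM_LABELS",
    "StrataParams",
    "stratum_log_probs",
    "stratum_probabilities",
    "membership_log_likelihood",
    "latent_icc_to_phi2",
]

# Integer codes for the three strata; the string labels follow the
# potential-survival notation (S(1), S(0)).
G_NEVER, G_PROTECTED, G_ALWAYS = 0, 1, 2
STRATUM_LABELS = ("00", "10", "11")

# Variance of the standard-logistic latent residual.
_LOGISTIC_VAR = np.pi**2 / 3.0

# Probabilities are floored here before logging so membership
# log-likelihoods stay finite unless a stratum truly underflows.
_LOG_FLOOR = np.log(1e-300)


@dataclass
class StrataParams:
    """Coefficients of the principal-strata membership model.

    Parameters
    ----------
    beta, gamma
        Length-``p`` log-odds-ratio vectors for never-survivors and protected
        individuals, each against the always-survivor reference.
    chi
        Optional length-``I`` cluster random intercepts, shared by both
        non-reference linear predictors.
    phi2
        Variance of ``chi``; required (and positive) when ``chi`` is present.
    """

    beta: np.ndarray
    gamma: np.ndarray
    chi: np.ndarray | None = None
    phi2: float | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.beta.ndim != 1 or self.gamma.ndim != 1:
            raise ValueError("beta and gamma must be one-dimensional")
        if self.beta.shape != self.gamma.shape:
            raise ValueError(
                f"beta (p={self.beta.size}) and gamma (p={self.gamma.size}) "
                "must have identical length"
            )
        if not (np.all(np.isfinite(self.beta)) and np.all(np.isfinite(self.gamma))):
            raise ValueError("non-finite strata coefficients")
        if self.chi is not None:
            self.chi = np.asarray(self.chi, dtype=float)
            if self.phi2 is None or self.phi2 <= 0:
                raise ValueError("phi2 must be positive when chi is present")

    @property
    def p(self) -> int:
        return self.beta.size


def _linear_predictors(
    X: np.ndarray, params: StrataParams, cluster_index: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.p:
        raise ValueError(
            f"covariate row length {X.shape[1]} does not match p={params.p}"
        )
    a = X @ params.beta
    b = X @ params.gamma
    if params.chi is not None:
        if cluster_index is None:
            raise ValueError("cluster_index required when chi is present")
        idx = np.asarray(cluster_index)
        if np.any(idx < 0) or np.any(idx >= params.chi.size):
            raise ValueError("cluster_index out of range")
        a = a + params.chi[idx]
        b = b + params.chi[idx]
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite linear predictor")
    return a, b


def three_term_lse(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log(exp(a) + exp(b) + 1), computed with max-subtraction."""
    m = np.maximum(np.maximum(a, b), 0.0)
    return m + np.log(np.exp(a - m) + np.exp(b - m) + np.exp(-m))


def stratum_log_probs(
    X: np.ndarray,
    params: StrataParams,
    cluster_index: np.ndarray | None = None,
) -> np.ndarray:
    """Log membership probabilities, shape ``(n, 3)`` ordered (00, 10, 11).

    Vectorized over rows of ``X``; the softmax runs through a
    max-subtracted log-sum-exp so no overflow occurs for linear predictors
    with magnitude up to ~700.
    """
    a, b = _linear_predictors(X, params, cluster_index)
    lse = three_term_lse(a, b)
    return np.stack([a - lse, b - lse, -lse], axis=-1)


def stratum_probabilities(
    x: np.ndarray,
    params: StrataParams,
    cluster_index: int | np.ndarray | None = None,
) -> np.ndarray:
    """Membership probability triple(s) ``(p00, p10, p11)`` for row(s) ``x``.

    A single covariate row returns a length-3 vector; a matrix of rows
    returns an ``(n, 3)`` array.  Rows sum to one to floating precision.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single and cluster_index is not None:
        cluster_index = np.atleast_1d(cluster_index)
    out = np.exp(stratum_log_probs(x, params, cluster_index))
    return out[0] if single else out


def membership_log_likelihood(
    memberships: np.ndarray,
    X: np.ndarray,
    params: StrataParams,
    cluster_index: np.ndarray | None = None,
) -> float:
    """Joint log-likelihood of the latent membership labels.

    Sum over participants of the log probability the membership model puts
    on each current label (coded 0=never, 1=protected, 2=always).  This is
    the Metropolis target for the strata coefficients.  Probabilities are
    floored at 1e-300 before logging, so the result is finite unless an
    assigned stratum genuinely underflows, in which case it is ``-inf``.
    """
    G = np.asarray(memberships)
    if np.any((G < 0) | (G > 2)):
        raise ValueError("membership labels must be coded in {0, 1, 2}")
    logp = stratum_log_probs(X, params, cluster_index)
    picked = np.take_along_axis(logp, G.reshape(-1, 1), axis=1)[:, 0]
    picked = np.where(picked < _LOG_FLOOR, -np.inf, picked)
    return float(np.sum(picked))


def membership_log_likelihood_by_cluster(
    memberships: np.ndarray,
    X: np.ndarray,
    params: StrataParams,
    cluster_index: np.ndarray,
    n_clusters: int,
) -> np.ndarray:
    """Per-cluster decomposition of :func:`membership_log_likelihood`.

    Used by the Metropolis update of the cluster intercepts ``chi_i``, whose
    targets factorize over clusters.
    """
    G = np.asarray(memberships)
    logp = stratum_log_probs(X, params, cluster_index)
    picked = np.take_along_axis(logp, G.reshape(-1, 1), axis=1)[:, 0]
    picked = np.where(picked < _LOG_FLOOR, -np.inf, picked)
    return np.bincount(cluster_index, weights=picked, minlength=n_clusters)


def latent_icc_to_phi2(icc: float) -> float:
    """Random-intercept variance inducing a given latent-scale ICC.

    On the latent-response scale of a logistic model the residual variance
    is pi^2/3, so an intracluster correlation ``icc`` corresponds to
    ``phi2 = icc/(1-icc) * pi^2/3``, i.e. phi2/(phi2 + pi^2/3) = icc.
    """
    if not 0 <= icc < 1:
        raise ValueError(f"latent-scale ICC must lie in [0, 1); got {icc}")
    return icc / (1.0 - icc) * _LOGISTIC_VAR
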