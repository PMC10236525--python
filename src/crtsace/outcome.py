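"""Per-(stratum, arm) linear mixed models for the potential outcomes.

Only three cells of the stratum-by-arm table carry an observable outcome:
always-survivors under treatment (coefficients ``alpha_11_1``),
always-survivors under control (``alpha_11_0``), and protected individuals
under treatment (``alpha_10_1``).  Never-survivors have no outcome, and
protected individuals die under control.  The three cells share one
cluster random effect ``eta_i ~ N(0, tau2)`` and one residual variance
``sigma2``:

    Y_ij(d) | G, cluster i  ~  N(x_ij' alpha_{G,d} + eta_i, sigma2)

With conjugate normal priors on every regression coefficient and
inverse-gamma priors on the variances, all conditional posteriors are
available in closed form; the Gibbs updates below draw from them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import CRTDataset
from .strata import G_ALWAYS, G_PROTECTED

__all__ = [
    "OutcomeParams",
    "Priors",
    "outcome_log_density",
    "gibbs_update_coefficients",
    "gibbs_update_cluster_effects",
    "gibbs_update_variances",
    "outcome_icc",
]

# Modeled (stratum, arm) cells in a fixed order.
CELLS = ((G_ALWAYS, 1), (G_ALWAYS, 0), (G_PROTECTED, 1))
CELL_ATTRS = ("alpha_11_1", "alpha_11_0", "alpha_10_1")


@dataclass
class OutcomeParams:
    """State of the outcome model.

    ``alpha_11_1``, ``alpha_11_0``, ``alpha_10_1`` are the length-``p``
    coefficient vectors of the three modeled cells; ``eta`` holds one
    random effect per cluster; ``sigma2``/``tau2`` are the residual and
    cluster-effect variances.
    """

    alpha_11_1: np.ndarray
    alpha_11_0: np.ndarray
    alpha_10_1: np.ndarray
    eta: np.ndarray
    sigma2: float
    tau2: float

    def __post_init__(self) -> None:
        for name in CELL_ATTRS + ("eta",):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.sigma2 <= 0 or self.tau2 <= 0:
            raise ValueError("sigma2 and tau2 must be positive")

    def cell_alpha(self, stratum: int, arm: int) -> np.ndarray:
        try:
            return getattr(self, CELL_ATTRS[CELLS.index((stratum, arm))])
        except ValueError:
            raise ValueError(
                f"no outcome model for stratum={stratum}, arm={arm}: only "
                "always-survivors (both arms) and protected-treated are modeled"
            ) from None


@dataclass
class Priors:
    """Hyperparameters of the conjugate priors.

    Every regression coefficient (outcome and strata models alike) gets an
    independent ``N(0, coef_prior_var)`` prior; ``sigma2``, ``tau2`` and the
    optional strata-intercept variance ``phi2`` share an
    ``InvGamma(ig_shape, ig_rate)`` prior.  The defaults are diffuse.
    """

    coef_prior_var: float = 1e4
    ig_shape: float = 0.01
    ig_rate: float = 0.01

    def __post_init__(self) -> None:
        if min(self.coef_prior_var, self.ig_shape, self.ig_rate) <= 0:
            raise ValueError("prior hyperparameters must be strictly positive")


def outcome_log_density(
    y: float,
    x: np.ndarray,
    arm: int,
    stratum: int,
    params: OutcomeParams,
    cluster_index: int,
) -> float:
    """Normal log-density of an outcome in one of the three modeled cells."""
    alpha = params.cell_alpha(stratum, arm)
    mean = float(np.asarray(x, dtype=float) @ alpha) + params.eta[cluster_index]
    resid = y - mean
    return -0.5 * np.log(2 * np.pi * params.sigma2) - 0.5 * resid**2 / params.sigma2


def _cell_masks(dataset: CRTDataset, memberships: np.ndarray) -> list[np.ndarray]:
    """Boolean row masks for the three modeled cells, observed outcomes only."""
    obs = dataset.S == 1
    return [
        obs & (dataset.D == arm) & (memberships == stratum)
        for stratum, arm in CELLS
    ]


def gibbs_update_coefficients(
    dataset: CRTDataset,
    memberships: np.ndarray,
    params: OutcomeParams,
    priors: Priors,
    rng: np.random.Generator,
) -> OutcomeParams:
    """Draw the three alpha vectors from their exact conditional posteriors.

    For each cell with design ``X_c`` and outcomes ``y_c`` (net of cluster
    effects) the conditional is multivariate normal with precision
    ``X_c'X_c / sigma2 + I / coef_prior_var`` and mean
    ``precision^{-1} X_c'(y_c - eta) / sigma2``.  An empty cell draws from
    the prior, keeping the chain irreducible.
    """
    p = dataset.p
    prior_prec = np.eye(p) / priors.coef_prior_var
    for mask, attr in zip(_cell_masks(dataset, memberships), CELL_ATTRS):
        if not mask.any():
            draw = rng.normal(0.0, np.sqrt(priors.coef_prior_var), size=p)
        else:
            Xc = dataset.X[mask]
            r = dataset.Y[mask] - params.eta[dataset.cluster[mask]]
            prec = Xc.T @ Xc / params.sigma2 + prior_prec
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, Xc.T @ r / params.sigma2)
            z = rng.standard_normal(p)
            draw = mean + np.linalg.solve(chol.T, z)
        if not np.all(np.isfinite(draw)):
            raise FloatingPointError(f"non-finite coefficient draw for {attr}")
        setattr(params, attr, draw)
    return params


def _row_residuals(dataset: CRTDataset, memberships: np.ndarray, params: OutcomeParams) -> tuple[np.ndarray, np.ndarray]:
    """Residuals y - x'alpha_cell for observed-outcome rows (before eta)."""
    masks = _cell_masks(dataset, memberships)
    rows = np.zeros(dataset.n, dtype=bool)
    resid = np.zeros(dataset.n)
    for mask, attr in zip(masks, CELL_ATTRS):
        if mask.any():
            resid[mask] = dataset.Y[mask] - dataset.X[mask] @ getattr(params, attr)
            rows |= mask
    return resid, rows


def gibbs_update_cluster_effects(
    dataset: CRTDataset,
    memberships: np.ndarray,
    params: OutcomeParams,
    rng: np.random.Generator,
) -> OutcomeParams:
    """Draw each cluster effect from its conditional normal posterior.

    With ``k_i`` observed-outcome rows in cluster ``i`` and residual sum
    ``R_i`` (net of fixed effects), the conditional is
    ``N(R_i/sigma2 / (k_i/sigma2 + 1/tau2), 1/(k_i/sigma2 + 1/tau2))``;
    clusters with no contributing rows draw from ``N(0, tau2)``.
    """
    I = dataset.n_clusters
    resid, rows = _row_residuals(dataset, memberships, params)
    k = np.bincount(dataset.cluster[rows], minlength=I)
    rsum = np.bincount(dataset.cluster[rows], weights=resid[rows], minlength=I)
    prec = k / params.sigma2 + 1.0 / params.tau2
    mean = (rsum / params.sigma2) / prec
    params.eta = mean + rng.standard_normal(I) / np.sqrt(prec)
    return params


def gibbs_update_variances(
    dataset: CRTDataset,
    memberships: np.ndarray,
    params: OutcomeParams,
    priors: Priors,
    rng: np.random.Generator,
) -> OutcomeParams:
    """Draw sigma2 and tau2 from their inverse-gamma conditionals.

    sigma2 ~ InvGamma(ig_shape + N_obs/2, ig_rate + SSR/2) with SSR the sum
    of squared residuals net of fixed and cluster effects; tau2 ~
    InvGamma(ig_shape + I/2, ig_rate + sum(eta_i^2)/2).
    """
    resid, rows = _row_residuals(dataset, memberships, params)
    full_resid = resid[rows] - params.eta[dataset.cluster[rows]]
    shape_s = priors.ig_shape + 0.5 * rows.sum()
    rate_s = priors.ig_rate + 0.5 * float(full_resid @ full_resid)
    params.sigma2 = rate_s / rng.gamma(shape_s)
    shape_t = priors.ig_shape + 0.5 * dataset.n_clusters
    rate_t = priors.ig_rate + 0.5 * float(params.eta @ params.eta)
    params.tau2 = rate_t / rng.gamma(shape_t)
    return params


def outcome_icc(tau2: float, sigma2: float) -> float:
    """Intracluster correlation of the outcome, rho = tau2/(tau2 + sigma2)."""
    if tau2 <= 0 or sigma2 <= 0:
        raise ValueError("variances must be positive")
    return tau2 / (tau2 + sigma2)
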