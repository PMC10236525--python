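"""Joint MCMC for the principal-strata and outcome models.

Each iteration augments the latent stratum labels under monotonicity, runs
conjugate Gibbs updates for the outcome linear mixed models, and updates
the multinomial-logit strata coefficients by blocked random-walk Metropolis
with multivariate-t proposals whose scale matrices are tuned during burn-in
from the empirical covariance of the chain (Haario-style adaptation, frozen
after burn-in so the retained chain is Markov).

Monotonicity makes two of the four observed cells deterministic: treated
deaths are never-survivors and control survivors are always-survivors.
Treated survivors split between always-survivor and protected using both
the membership probabilities and the outcome likelihood under the two
candidate regressions; control deaths split between protected and
never-survivor using membership probabilities alone (their outcome is
truncated, so no likelihood term exists).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import CRTDataset
from .estimands import sace_draw, strata_proportion_draw
from .outcome import (
    OutcomeParams,
    Priors,
    gibbs_update_cluster_effects,
    gibbs_update_coefficients,
    gibbs_update_variances,
    outcome_icc,
)
from .strata import (
    _LOG_FLOOR,
    G_ALWAYS,
    G_NEVER,
    G_PROTECTED,
    StrataParams,
    _linear_predictors,
    membership_log_likelihood_by_cluster,
    three_term_lse,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MhTuning",
    "RunConfig",
    "PosteriorDraws",
    "MultiChainResult",
    "initial_state",
    "sample_memberships",
    "mh_update_strata_coefficients",
    "mh_update_cluster_intercepts",
    "adapt_proposal",
    "run_chain",
    "run_chains",
]


@dataclass
class MhTuning:
    """Random-walk Metropolis tuning state for the strata coefficients.

    Proposals are multivariate t with ``t_df`` degrees of freedom and
    scale ``s * T`` per block.  ``s`` starts at the Gelman-Roberts-Gilks
    optimum 2.38^2/p and is rescaled by ``exp(accept_rate - target_rate)``
    at each adaptation event; ``T`` is replaced by the empirical covariance
    of the burn-in history (plus a 1e-6 ridge).  Adaptation runs from
    ``adapt_start``, every ``adapt_interval`` iterations, and stops at the
    end of burn-in.
    """

    t_df: float = 4.0
    adapt_start: int = 200
    adapt_interval: int = 100
    target_rate: float = 0.234
    s_beta: float | None = None
    s_gamma: float | None = None
    T_beta: np.ndarray | None = None
    T_gamma: np.ndarray | None = None
    s_chi: float = 0.5

    def resolve(self, dataset: CRTDataset) -> "MhTuning":
        """Fill unset scales with data-driven defaults for this dataset."""
        p = dataset.p
        s0 = 2.38**2 / p
        # Logistic-information heuristic: coefficient covariance is of the
        # order 6 * (X'X)^{-1}, which puts the initial proposal near the
        # posterior scale instead of hundreds of sigma away.
        T0 = 6.0 * np.linalg.inv(dataset.X.T @ dataset.X + 1e-8 * np.eye(p))
        out = replace(self)
        out.s_beta = s0 if self.s_beta is None else self.s_beta
        out.s_gamma = s0 if self.s_gamma is None else self.s_gamma
        out.T_beta = T0.copy() if self.T_beta is None else np.asarray(self.T_beta, float)
        out.T_gamma = T0.copy() if self.T_gamma is None else np.asarray(self.T_gamma, float)
        for name in ("T_beta", "T_gamma"):
            T = getattr(out, name)
            if T.shape != (p, p) or not np.allclose(T, T.T):
                raise ValueError(f"{name} must be a symmetric {p}x{p} matrix")
            np.linalg.cholesky(T)  # SPD check
        return out


@dataclass
class RunConfig:
    """MCMC run settings.

    Defaults mirror a single simulation-study fit: 10,000 iterations with
    a 2,500-iteration burn-in.
    """

    iterations: int = 10_000
    burn_in: int = 2_500
    chains: int = 2
    thin: int = 1
    seed: int = 0
    priors: Priors = field(default_factory=Priors)
    tuning: MhTuning = field(default_factory=MhTuning)
    strata_clustering: bool = False

    def validate(self, dataset: CRTDataset) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.chains < 1 or self.thin < 1:
            raise ValueError("chains and thin must be >= 1")
        for T in (self.tuning.T_beta, self.tuning.T_gamma):
            if T is not None and np.asarray(T).shape != (dataset.p, dataset.p):
                raise ValueError("tuning scale matrix does not match p")
        if self.strata_clustering and np.any(dataset.cluster_sizes <= 1):
            logger.warning(
                "strata-level clustering requested but %d cluster(s) have size 1; "
                "the random-intercept strata model tends not to converge with "
                "extremely small clusters — consider the unclustered strata model",
                int(np.sum(dataset.cluster_sizes <= 1)),
            )


@dataclass
class PosteriorDraws:
    """Retained draws of one chain, one row per post-burn-in iteration."""

    beta: np.ndarray
    gamma: np.ndarray
    alpha_11_1: np.ndarray
    alpha_11_0: np.ndarray
    alpha_10_1: np.ndarray
    sigma2: np.ndarray
    tau2: np.ndarray
    phi2: np.ndarray | None
    delta: np.ndarray
    ybar1: np.ndarray
    ybar0: np.ndarray
    prop00: np.ndarray
    prop10: np.ndarray
    prop11: np.ndarray
    rho: np.ndarray
    strata_counts: np.ndarray
    as_profile: np.ndarray        # per-draw covariate means among always-survivors
    accept_beta: float
    accept_gamma: float
    accept_chi: float | None
    n_empty_always: int           # draws with no always-survivor (excluded)
    covariate_names: list[str]

    @property
    def n_retained(self) -> int:
        return self.delta.size

    def scalar_series(self) -> dict[str, np.ndarray]:
        out = {
            "delta": self.delta,
            "ybar1": self.ybar1,
            "ybar0": self.ybar0,
            "prop00": self.prop00,
            "prop10": self.prop10,
            "prop11": self.prop11,
            "rho": self.rho,
            "sigma2": self.sigma2,
            "tau2": self.tau2,
        }
        names = ["intercept"] + self.covariate_names
        for vec_name in ("beta", "gamma", "alpha_11_1", "alpha_11_0", "alpha_10_1"):
            arr = getattr(self, vec_name)
            for k, cname in enumerate(names):
                out[f"{vec_name}[{cname}]"] = arr[:, k]
        if self.phi2 is not None:
            out["phi2"] = self.phi2
        return out

    def to_tidy(self, chain: int = 0) -> pd.DataFrame:
        """One row per retained iteration x parameter, for external diagnostics."""
        frames = []
        for name, series in self.scalar_series().items():
            frames.append(
                pd.DataFrame(
                    {
                        "chain": chain,
                        "iteration": np.arange(series.size),
                        "parameter": name,
                        "value": series,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass
class MultiChainResult:
    """Pooled multi-chain output with split-R-hat diagnostics."""

    chains: list[PosteriorDraws]

    def pooled(self, name: str) -> np.ndarray:
        return np.concatenate([c.scalar_series()[name] for c in self.chains])

    def rhat(self) -> pd.DataFrame:
        """Split-R-hat per scalar parameter (rank-normalized, via arviz)."""
        import arviz as az

        rows = []
        for name in self.chains[0].scalar_series():
            stacked = np.stack([c.scalar_series()[name] for c in self.chains])
            with np.errstate(invalid="ignore"):
                val = float(az.rhat(az.convert_to_dataset(stacked)).x)
            rows.append({"parameter": name, "rhat": val})
        return pd.DataFrame(rows)

    def acceptance(self) -> pd.DataFrame:
        rows = []
        for k, c in enumerate(self.chains):
            rows.append(
                {
                    "chain": k,
                    "accept_beta": c.accept_beta,
                    "accept_gamma": c.accept_gamma,
                    "accept_chi": c.accept_chi,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cached strata linear predictors
# ---------------------------------------------------------------------------

@dataclass
class _Linpreds:
    """Per-row strata linear predictors and their log-normalizer.

    Depends only on (beta, gamma, chi), so one evaluation per parameter
    change serves the swap move, the membership update, and the current
    Metropolis target within an iteration.
    """

    a: np.ndarray      # x'beta (+ chi)
    b: np.ndarray      # x'gamma (+ chi)
    lse: np.ndarray    # log(e^a + e^b + 1)


def _make_linpreds(dataset: CRTDataset, params: StrataParams) -> _Linpreds:
    a, b = _linear_predictors(dataset.X, params, dataset.cluster)
    return _Linpreds(a=a, b=b, lse=three_term_lse(a, b))


def _loglik_from(G: np.ndarray, lp: _Linpreds) -> float:
    """Membership log-likelihood of labels ``G`` given cached predictors."""
    sel = np.where(G == G_NEVER, lp.a, np.where(G == G_PROTECTED, lp.b, 0.0)) - lp.lse
    sel = np.where(sel < _LOG_FLOOR, -np.inf, sel)
    return float(sel.sum())


# ---------------------------------------------------------------------------
# latent-membership data augmentation
# ---------------------------------------------------------------------------

def sample_memberships(
    dataset: CRTDataset,
    strata_params: StrataParams,
    outcome_params: OutcomeParams,
    rng: np.random.Generator,
    linpreds: _Linpreds | None = None,
) -> np.ndarray:
    """Draw stratum labels from their full conditional under monotonicity.

    Treated deaths are set to never-survivor and control survivors to
    always-survivor deterministically.  A treated survivor is
    always-survivor with probability

        p11 N(y | x'a_11_1 + eta, s2) /
            [p11 N(y | x'a_11_1 + eta, s2) + p10 N(y | x'a_10_1 + eta, s2)]

    and protected otherwise; a control death is protected with probability
    p10/(p10 + p00), never-survivor otherwise (no outcome term — the
    outcome is truncated).  If both components of a treated survivor's
    posterior underflow, the membership probabilities alone decide and a
    warning is logged.

    The softmax normalizer cancels in both two-way splits, so only the
    linear predictors are needed; ``linpreds`` can supply them precomputed.
    """
    lp = linpreds if linpreds is not None else _make_linpreds(dataset, strata_params)
    G = np.empty(dataset.n, dtype=np.int8)
    d, s = dataset.D, dataset.S
    G[(d == 1) & (s == 0)] = G_NEVER
    G[(d == 0) & (s == 1)] = G_ALWAYS

    m = (d == 1) & (s == 1)
    if m.any():
        y = dataset.Y[m]
        eta = outcome_params.eta[dataset.cluster[m]]
        inv2s2 = 0.5 / outcome_params.sigma2
        ll_a = -inv2s2 * (y - dataset.X[m] @ outcome_params.alpha_11_1 - eta) ** 2
        ll_b = -inv2s2 * (y - dataset.X[m] @ outcome_params.alpha_10_1 - eta) ** 2
        with np.errstate(invalid="ignore"):
            p11 = expit(-lp.b[m] + ll_a - ll_b)
        bad = ~np.isfinite(p11)
        if bad.any():
            logger.warning(
                "%d treated survivors had underflowing outcome likelihoods; "
                "assigned by strata probabilities alone",
                int(bad.sum()),
            )
            p11[bad] = expit(-lp.b[m][bad])
        G[m] = np.where(rng.random(p11.size) < p11, G_ALWAYS, G_PROTECTED)

    m = (d == 0) & (s == 0)
    if m.any():
        p10 = expit(lp.b[m] - lp.a[m])
        G[m] = np.where(rng.random(p10.size) < p10, G_PROTECTED, G_NEVER)
    return G


def swap_treated_components(
    dataset: CRTDataset,
    strata_params: StrataParams,
    outcome_params: OutcomeParams,
    rng: np.random.Generator,
    linpreds: _Linpreds | None = None,
) -> tuple[OutcomeParams, bool]:
    """Collapsed Metropolis move against the treated-arm pairing mode.

    The mixture over treated survivors admits a spurious local mode in
    which the always-survivor-treated and protected-treated regressions
    exchange roles (each fitting the other stratum's subpopulation).  This
    move proposes swapping ``alpha_11_1`` with ``alpha_10_1`` with the
    treated survivors' latent labels integrated out analytically: each
    such row contributes a two-component mixture likelihood

        p11(x) N(y | x'a + eta, s2) + p10(x) N(y | x'b + eta, s2)

    and the proposal exchanges the roles of ``a`` and ``b``.  The
    (symmetric) coefficient priors cancel, the swap is an involution, and
    the labels are redrawn from their full conditional immediately
    afterwards (the regular membership update), making this a valid
    partially collapsed step.  From the dominant pairing the move is
    essentially never accepted; from the crossed pairing it is accepted
    quickly, so short chains cannot commit to the wrong mode.
    """
    m = (dataset.D == 1) & (dataset.S == 1)
    if not m.any():
        return outcome_params, False
    if linpreds is None:
        linpreds = _make_linpreds(dataset, strata_params)
    b = linpreds.b[m]  # the softmax normalizer cancels in the ratio
    y = dataset.Y[m]
    eta = outcome_params.eta[dataset.cluster[m]]
    inv2s2 = 0.5 / outcome_params.sigma2
    ll_a = -inv2s2 * (y - dataset.X[m] @ outcome_params.alpha_11_1 - eta) ** 2
    ll_b = -inv2s2 * (y - dataset.X[m] @ outcome_params.alpha_10_1 - eta) ** 2
    cur = np.logaddexp(ll_a, b + ll_b)
    prop = np.logaddexp(ll_b, b + ll_a)
    if np.log(rng.random()) < float(prop.sum() - cur.sum()):
        outcome_params.alpha_11_1, outcome_params.alpha_10_1 = (
            outcome_params.alpha_10_1,
            outcome_params.alpha_11_1,
        )
        return outcome_params, True
    return outcome_params, False


# ---------------------------------------------------------------------------
# Metropolis updates for the strata model
# ---------------------------------------------------------------------------

def _mvt_step(
    scale_chol: np.ndarray, t_df: float, rng: np.random.Generator
) -> np.ndarray:
    z = scale_chol @ rng.standard_normal(scale_chol.shape[0])
    u = rng.chisquare(t_df) / t_df
    return z / np.sqrt(u)


def _log_prior(v: np.ndarray, var: float) -> float:
    return -0.5 * float(v @ v) / var


def mh_update_strata_coefficients(
    dataset: CRTDataset,
    memberships: np.ndarray,
    strata_params: StrataParams,
    tuning: MhTuning,
    priors: Priors,
    rng: np.random.Generator,
    linpreds: _Linpreds | None = None,
) -> tuple[StrataParams, bool, bool]:
    """One random-walk Metropolis sweep over the beta then gamma blocks.

    Proposals are centered at the current value with multivariate-t steps of
    scale ``s_beta * T_beta`` / ``s_gamma * T_gamma``; the proposal is
    symmetric so the acceptance probability is the posterior ratio
    ``min(1, exp(delta log-likelihood + delta log-prior))``.  A non-finite
    target at the proposal rejects.  When ``linpreds`` is supplied it is
    updated in place on acceptance, keeping the cache current.
    """
    lp = linpreds if linpreds is not None else _make_linpreds(dataset, strata_params)
    chi_row = (
        strata_params.chi[dataset.cluster] if strata_params.chi is not None else 0.0
    )
    cur_ll = _loglik_from(memberships, lp)
    accepted = []
    for block in ("beta", "gamma"):
        s = tuning.s_beta if block == "beta" else tuning.s_gamma
        T = tuning.T_beta if block == "beta" else tuning.T_gamma
        chol = np.linalg.cholesky(s * T)
        current = getattr(strata_params, block)
        proposal = current + _mvt_step(chol, tuning.t_df, rng)
        if not np.all(np.isfinite(proposal)):
            accepted.append(False)
            continue
        pred = dataset.X @ proposal + chi_row
        if block == "beta":
            prop_lp = _Linpreds(a=pred, b=lp.b, lse=three_term_lse(pred, lp.b))
        else:
            prop_lp = _Linpreds(a=lp.a, b=pred, lse=three_term_lse(lp.a, pred))
        prop_ll = _loglik_from(memberships, prop_lp)
        log_ratio = (
            prop_ll + _log_prior(proposal, priors.coef_prior_var)
            - cur_ll - _log_prior(current, priors.coef_prior_var)
        )
        if np.isfinite(prop_ll) and np.log(rng.random()) < log_ratio:
            setattr(strata_params, block, proposal)
            lp.a, lp.b, lp.lse = prop_lp.a, prop_lp.b, prop_lp.lse
            cur_ll = prop_ll
            accepted.append(True)
        else:
            accepted.append(False)
    return strata_params, accepted[0], accepted[1]


def adapt_proposal(
    history: np.ndarray,
    T: np.ndarray,
    s: float,
    accept_rate: float,
    target_rate: float,
) -> tuple[np.ndarray, float]:
    """Haario-style adaptation of one proposal block.

    ``T`` becomes the empirical covariance of the draw history plus a
    1e-6 identity ridge; ``s`` is multiplied by
    ``exp(accept_rate - target_rate)``.  A degenerate history (zero
    variance, e.g. a chain that has never moved) leaves ``T`` unchanged and
    halves ``s`` instead.
    """
    hist = np.atleast_2d(np.asarray(history, dtype=float))
    p = hist.shape[1]
    if hist.shape[0] < 2 * p:
        raise ValueError(f"need at least {2 * p} draws to adapt (got {hist.shape[0]})")
    cov = np.cov(hist, rowvar=False)
    if np.trace(np.atleast_2d(cov)) <= 0:
        return T, s / 2.0
    return np.atleast_2d(cov) + 1e-6 * np.eye(p), s * float(np.exp(accept_rate - target_rate))


def mh_update_cluster_intercepts(
    dataset: CRTDataset,
    memberships: np.ndarray,
    strata_params: StrataParams,
    priors: Priors,
    tuning: MhTuning,
    rng: np.random.Generator,
) -> tuple[StrataParams, float]:
    """Scalar random-walk Metropolis on each cluster intercept, then phi2.

    The strata-model target factorizes over clusters given (beta, gamma),
    so every ``chi_i`` is proposed and accepted independently with target
    equal to its cluster's membership log-likelihood plus the N(0, phi2)
    prior.  ``phi2`` then draws from its inverse-gamma conditional.
    Returns the updated params and the fraction of clusters accepted.
    """
    I = dataset.n_clusters
    chi = strata_params.chi
    cur_ll = membership_log_likelihood_by_cluster(
        memberships, dataset.X, strata_params, dataset.cluster, I
    )
    step = tuning.s_chi * rng.standard_t(tuning.t_df, size=I)
    prop_params = replace(strata_params, chi=chi + step)
    prop_ll = membership_log_likelihood_by_cluster(
        memberships, dataset.X, prop_params, dataset.cluster, I
    )
    phi2 = strata_params.phi2
    log_ratio = (
        prop_ll - cur_ll
        - 0.5 * ((chi + step) ** 2 - chi**2) / phi2
    )
    accept = np.log(rng.random(I)) < log_ratio
    chi = np.where(accept, chi + step, chi)
    shape = priors.ig_shape + 0.5 * I
    rate = priors.ig_rate + 0.5 * float(chi @ chi)
    strata_params.chi = chi
    strata_params.phi2 = rate / rng.gamma(shape)
    return strata_params, float(accept.mean())


# ---------------------------------------------------------------------------
# initialization and the main loop
# ---------------------------------------------------------------------------

def initial_state(
    dataset: CRTDataset,
    config: RunConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, StrataParams, OutcomeParams]:
    """Random but data-informed starting point.

    Arm-level survival rates moment-match the initial stratum shares
    (control-arm survival estimates the always-survivor share; the
    treated-minus-control survival difference estimates the protected
    share), and ambiguous memberships are drawn at those odds.  This
    starts the augmentation near the identified mode: a uniform split of
    treated survivors instead starts the protected-treated regression on a
    half-wrong mixture, from which short chains occasionally fail to
    escape.  Outcome coefficients start at per-cell least squares (small
    jitter), variances at residual moments, and the strata coefficients at
    the share-matched intercepts plus N(0, 0.1^2) jitter.
    """
    n, p, I = dataset.n, dataset.p, dataset.n_clusters
    d, s = dataset.D, dataset.S
    surv_c = float(np.mean(s[d == 0])) if np.any(d == 0) else 0.5
    surv_t = float(np.mean(s[d == 1])) if np.any(d == 1) else 0.5
    pi11 = np.clip(surv_c, 0.02, 0.96)
    pi10 = np.clip(surv_t - surv_c, 0.02, 0.96)
    pi00 = np.clip(1.0 - surv_t, 0.02, 0.96)
    G = np.empty(n, dtype=np.int8)
    G[(d == 1) & (s == 0)] = G_NEVER
    G[(d == 0) & (s == 1)] = G_ALWAYS
    m = (d == 1) & (s == 1)
    G[m] = np.where(
        rng.random(int(m.sum())) < pi11 / (pi11 + pi10), G_ALWAYS, G_PROTECTED
    )
    m = (d == 0) & (s == 0)
    G[m] = np.where(
        rng.random(int(m.sum())) < pi10 / (pi10 + pi00), G_PROTECTED, G_NEVER
    )

    from .outcome import CELLS, CELL_ATTRS

    alphas = {}
    resid_var = []
    for (stratum, arm), attr in zip(CELLS, CELL_ATTRS):
        mask = (s == 1) & (d == arm) & (G == stratum)
        if mask.sum() >= p:
            coef, *_ = np.linalg.lstsq(dataset.X[mask], dataset.Y[mask], rcond=None)
            resid = dataset.Y[mask] - dataset.X[mask] @ coef
            resid_var.append(float(np.var(resid)))
        else:
            coef = np.zeros(p)
        alphas[attr] = coef + rng.normal(0.0, 0.01, size=p)
    sigma2 = max(float(np.mean(resid_var)) if resid_var else 1.0, 0.1)
    obs = s == 1
    cluster_means = np.bincount(
        dataset.cluster[obs], weights=dataset.Y[obs], minlength=I
    )
    counts = np.bincount(dataset.cluster[obs], minlength=I)
    with np.errstate(invalid="ignore"):
        cluster_means = np.where(counts > 0, cluster_means / np.maximum(counts, 1), 0.0)
    tau2 = max(float(np.var(cluster_means[counts > 0])) / 2.0, 0.01)

    outcome_params = OutcomeParams(
        eta=np.zeros(I), sigma2=sigma2, tau2=tau2, **alphas
    )
    beta0 = np.zeros(p)
    gamma0 = np.zeros(p)
    beta0[0] = np.log(pi00 / pi11)
    gamma0[0] = np.log(pi10 / pi11)
    strata_params = StrataParams(
        beta=beta0 + rng.normal(0.0, 0.1, size=p),
        gamma=gamma0 + rng.normal(0.0, 0.1, size=p),
        chi=np.zeros(I) if config.strata_clustering else None,
        phi2=0.1 if config.strata_clustering else None,
    )
    return G, strata_params, outcome_params


def _assert_admissible(dataset: CRTDataset, G: np.ndarray) -> None:
    d, s = dataset.D, dataset.S
    ok = (
        np.all(G[(d == 1) & (s == 0)] == G_NEVER)
        and np.all(G[(d == 0) & (s == 1)] == G_ALWAYS)
        and np.all(G[(d == 1) & (s == 1)] != G_NEVER)
        and np.all(G[(d == 0) & (s == 0)] != G_ALWAYS)
    )
    if not ok:
        raise AssertionError("membership state violates monotonicity constraints")


def run_chain(
    dataset: CRTDataset,
    config: RunConfig,
    seed: int | None = None,
) -> PosteriorDraws:
    """Run one MCMC chain and return the retained draws.

    Update order per iteration: collapsed pairing-swap move, membership
    augmentation, outcome coefficients, cluster effects, variances, strata
    coefficients (and optional strata cluster intercepts), then estimand
    recording.  Proposal adaptation runs only during burn-in.
    Deterministic given ``seed``.
    """
    config.validate(dataset)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tuning = config.tuning.resolve(dataset)
    priors = config.priors
    G, strata_params, outcome_params = initial_state(dataset, config, rng)
    p = dataset.p

    total, burn = config.iterations, config.burn_in
    n_keep = (total - burn + config.thin - 1) // config.thin
    keep = {
        name: np.empty((n_keep, p))
        for name in ("beta", "gamma", "alpha_11_1", "alpha_11_0", "alpha_10_1")
    }
    scalars = {
        name: np.empty(n_keep)
        for name in (
            "sigma2", "tau2", "delta", "ybar1", "ybar0",
            "prop00", "prop10", "prop11", "rho",
        )
    }
    phi2_draws = np.empty(n_keep) if config.strata_clustering else None
    strata_counts = np.empty((n_keep, 3), dtype=np.int64)
    as_profile = np.full((n_keep, p), np.nan)

    beta_hist = np.empty((burn, p))
    gamma_hist = np.empty((burn, p))
    acc = {"beta": 0, "gamma": 0, "chi": 0.0}
    acc_post = {"beta": 0, "gamma": 0}
    win = {"beta": 0, "gamma": 0}
    win_n = 0
    n_empty_always = 0
    kept = 0

    linpreds = _make_linpreds(dataset, strata_params)
    for it in range(total):
        # the collapsed pairing-swap precedes the membership redraw, which
        # completes the partially collapsed update with an exact G | rest draw
        outcome_params, _ = swap_treated_components(
            dataset, strata_params, outcome_params, rng, linpreds=linpreds
        )
        G = sample_memberships(
            dataset, strata_params, outcome_params, rng, linpreds=linpreds
        )
        _assert_admissible(dataset, G)
        outcome_params = gibbs_update_coefficients(dataset, G, outcome_params, priors, rng)
        outcome_params = gibbs_update_cluster_effects(dataset, G, outcome_params, rng)
        outcome_params = gibbs_update_variances(dataset, G, outcome_params, priors, rng)
        strata_params, acc_b, acc_g = mh_update_strata_coefficients(
            dataset, G, strata_params, tuning, priors, rng, linpreds=linpreds
        )
        if config.strata_clustering:
            strata_params, chi_rate = mh_update_cluster_intercepts(
                dataset, G, strata_params, priors, tuning, rng
            )
            acc["chi"] += chi_rate
            linpreds = _make_linpreds(dataset, strata_params)
        acc["beta"] += acc_b
        acc["gamma"] += acc_g
        win["beta"] += acc_b
        win["gamma"] += acc_g
        win_n += 1

        if it < burn:
            beta_hist[it] = strata_params.beta
            gamma_hist[it] = strata_params.gamma
            due = it + 1 >= max(tuning.adapt_start, 2 * p) and (
                (it + 1 - tuning.adapt_start) % tuning.adapt_interval == 0
            )
            if due:
                rate_b = win["beta"] / win_n
                rate_g = win["gamma"] / win_n
                # second half of the history: discards the initialization
                # transient that would otherwise inflate the covariance
                lo = max((it + 1) // 2, 0)
                if it + 1 - lo < 2 * p:
                    lo = 0
                tuning.T_beta, tuning.s_beta = adapt_proposal(
                    beta_hist[lo : it + 1], tuning.T_beta, tuning.s_beta,
                    rate_b, tuning.target_rate,
                )
                tuning.T_gamma, tuning.s_gamma = adapt_proposal(
                    gamma_hist[lo : it + 1], tuning.T_gamma, tuning.s_gamma,
                    rate_g, tuning.target_rate,
                )
                if config.strata_clustering:
                    tuning.s_chi *= float(
                        np.exp(acc["chi"] / (it + 1) - tuning.target_rate)
                    )
                win = {"beta": 0, "gamma": 0}
                win_n = 0
        else:
            acc_post["beta"] += acc_b
            acc_post["gamma"] += acc_g
            if (it - burn) % config.thin == 0:
                delta, ybar1, ybar0 = sace_draw(dataset, G, outcome_params)
                if np.isnan(delta):
                    n_empty_always += 1
                else:
                    mask11 = G == G_ALWAYS
                    as_profile[kept] = dataset.X[mask11].mean(axis=0)
                p00, p10, p11 = strata_proportion_draw(G)
                for name, val in (
                    ("sigma2", outcome_params.sigma2),
                    ("tau2", outcome_params.tau2),
                    ("delta", delta),
                    ("ybar1", ybar1),
                    ("ybar0", ybar0),
                    ("prop00", p00),
                    ("prop10", p10),
                    ("prop11", p11),
                    ("rho", outcome_icc(outcome_params.tau2, outcome_params.sigma2)),
                ):
                    scalars[name][kept] = val
                keep["beta"][kept] = strata_params.beta
                keep["gamma"][kept] = strata_params.gamma
                keep["alpha_11_1"][kept] = outcome_params.alpha_11_1
                keep["alpha_11_0"][kept] = outcome_params.alpha_11_0
                keep["alpha_10_1"][kept] = outcome_params.alpha_10_1
                strata_counts[kept] = np.bincount(G, minlength=3)
                if phi2_draws is not None:
                    phi2_draws[kept] = strata_params.phi2
                kept += 1

    if n_empty_always:
        logger.warning(
            "%d retained draws had an empty always-survivor set and were "
            "excluded from SACE summaries", n_empty_always,
        )
    n_post = total - burn
    return PosteriorDraws(
        beta=keep["beta"][:kept],
        gamma=keep["gamma"][:kept],
        alpha_11_1=keep["alpha_11_1"][:kept],
        alpha_11_0=keep["alpha_11_0"][:kept],
        alpha_10_1=keep["alpha_10_1"][:kept],
        sigma2=scalars["sigma2"][:kept],
        tau2=scalars["tau2"][:kept],
        phi2=None if phi2_draws is None else phi2_draws[:kept],
        delta=scalars["delta"][:kept],
        ybar1=scalars["ybar1"][:kept],
        ybar0=scalars["ybar0"][:kept],
        prop00=scalars["prop00"][:kept],
        prop10=scalars["prop10"][:kept],
        prop11=scalars["prop11"][:kept],
        rho=scalars["rho"][:kept],
        strata_counts=strata_counts[:kept],
        as_profile=as_profile[:kept],
        accept_beta=acc_post["beta"] / n_post,
        accept_gamma=acc_post["gamma"] / n_post,
        accept_chi=(acc["chi"] / total) if config.strata_clustering else None,
        n_empty_always=n_empty_always,
        covariate_names=dataset.covariate_names,
    )


def run_chains(dataset: CRTDataset, config: RunConfig) -> MultiChainResult:
    """Run ``config.chains`` independent chains with per-chain seeds."""
    seeds = np.random.SeedSequence(config.seed).generate_state(config.chains)
    chains = [
        run_chain(dataset, config, seed=int(s) % (2**31)) for s in seeds
    ]
    return MultiChainResult(chains=chains)
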