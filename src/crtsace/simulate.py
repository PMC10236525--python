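"""Synthetic two-arm CRT generator with latent strata and known truth.

The generator emulates the kind of trial the estimator targets: clusters
randomized 1:1 to treatment, baseline covariates X1 ~ Normal(0, variance 4)
and X2 ~ Uniform(-5, 5), stratum membership drawn from the multinomial
logistic model, potential outcomes from the per-(stratum, arm) linear mixed
models, and the observed data produced by masking — each participant's
observed survival and outcome are the potential versions selected by their
cluster's treatment, and the outcome is removed (truncated) whenever the
selected survival status is death.

The default parameter values define the reference study conditions used
throughout the test-bench: cluster size 15 x 100 clusters (1,500
participants), beta = (-1, 0.3, 0.5), gamma = (-0.8, 0.6, 0.4),
alpha_11_1 = (1.5, 0.5, 0.8), alpha_11_0 = (0.2, 0.3, 0.6),
alpha_10_1 = (-1.5, 0.9, 0.5), sigma2 = 5, tau2 = 1 (outcome ICC 1/6),
giving marginal stratum shares of about 21.1% / 26.5% / 52.4%
(never / protected / always).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CRTDataset
from .strata import (
    G_ALWAYS,
    G_NEVER,
    G_PROTECTED,
    StrataParams,
    latent_icc_to_phi2,
    stratum_probabilities,
)

__all__ = ["SimConfig", "SyntheticTruth", "TrueSace", "generate_crt", "true_sace_oracle"]


@dataclass
class SimConfig:
    """Data-generating settings for one synthetic CRT.

    ``m`` is the cluster size (the mean size when ``cv`` > 0), ``n`` the
    number of clusters, and ``cv`` the coefficient of variation
    sd(size)/mean(size) of cluster sizes (0 gives equal sizes).
    ``strata_icc`` switches on a cluster random intercept in the membership
    model with variance chosen to induce that latent-scale ICC.
    """

    m: int = 15
    n: int = 100
    cv: float = 0.0
    beta: tuple[float, ...] = (-1.0, 0.3, 0.5)
    gamma: tuple[float, ...] = (-0.8, 0.6, 0.4)
    alpha_11_1: tuple[float, ...] = (1.5, 0.5, 0.8)
    alpha_11_0: tuple[float, ...] = (0.2, 0.3, 0.6)
    alpha_10_1: tuple[float, ...] = (-1.5, 0.9, 0.5)
    sigma2: float = 5.0
    tau2: float = 1.0
    strata_icc: float | None = None
    allocation: float = 0.5
    x1_var: float = 4.0
    x2_halfwidth: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.m < 2 or self.n < 2:
            raise ValueError("need m >= 2 and n >= 2")
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if min(self.sigma2, self.tau2, self.x1_var) <= 0:
            raise ValueError("variances must be positive")
        if not 0 < self.allocation < 1:
            raise ValueError("allocation must lie in (0, 1)")
        lens = {len(self.beta), len(self.gamma), len(self.alpha_11_1),
                len(self.alpha_11_0), len(self.alpha_10_1)}
        if len(lens) != 1:
            raise ValueError("all coefficient vectors must share one length")

    @property
    def p(self) -> int:
        return len(self.beta)

    @property
    def contrast(self) -> np.ndarray:
        """alpha_11_1 - alpha_11_0, the coefficient contrast behind the SACE."""
        return np.asarray(self.alpha_11_1) - np.asarray(self.alpha_11_0)


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated dataset.

    ``G`` holds the true stratum codes; ``Y1``/``Y0`` the potential
    outcomes (nan where the participant would die under that arm);
    ``strata_props`` the realized label shares (never, protected, always).
    The observed dataset is a deterministic masking of these arrays by the
    cluster-level treatment.
    """

    G: np.ndarray
    Y1: np.ndarray
    Y0: np.ndarray
    strata_props: tuple[float, float, float]

    def to_dataframe(self) -> pd.DataFrame:
        from .strata import STRATUM_LABELS

        return pd.DataFrame(
            {
                "G": [STRATUM_LABELS[g] for g in self.G],
                "Y1": self.Y1,
                "Y0": self.Y0,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _cluster_sizes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.cv == 0:
        return np.full(config.n, config.m, dtype=np.int64)
    # Gamma with mean m and sd cv*m, rounded, floored at 2 so no degenerate
    # single-participant clusters are produced.
    shape = 1.0 / config.cv**2
    scale = config.m * config.cv**2
    sizes = np.round(rng.gamma(shape, scale, size=config.n)).astype(np.int64)
    return np.maximum(sizes, 2)


def _draw_covariates(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    x1 = rng.normal(0.0, np.sqrt(config.x1_var), size=n)
    x2 = rng.uniform(-config.x2_halfwidth, config.x2_halfwidth, size=n)
    return np.column_stack([np.ones(n), x1, x2])


def generate_crt(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[CRTDataset, SyntheticTruth]:
    """Simulate one CRT and its ground truth.

    Steps: draw cluster sizes, randomize ``round(allocation * n)`` clusters
    to treatment, draw covariates, draw true stratum labels from the
    membership model (with a cluster intercept when ``strata_icc`` is set),
    draw cluster effects and potential outcomes for the three modeled
    cells, then mask by treatment: S = S(D), Y = Y(D), Y missing iff S=0.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sizes = _cluster_sizes(config, rng)
    n_rows = int(sizes.sum())
    cluster = np.repeat(np.arange(config.n), sizes)

    n_treated = int(round(config.allocation * config.n))
    D_cluster = np.zeros(config.n, dtype=np.int8)
    D_cluster[rng.choice(config.n, size=n_treated, replace=False)] = 1

    X = _draw_covariates(n_rows, config, rng)
    if config.strata_icc:
        phi2 = latent_icc_to_phi2(config.strata_icc)
        chi = rng.normal(0.0, np.sqrt(phi2), size=config.n)
        strata_params = StrataParams(config.beta, config.gamma, chi=chi, phi2=phi2)
    else:
        strata_params = StrataParams(config.beta, config.gamma)
    probs = stratum_probabilities(X, strata_params, cluster)
    u = rng.random(n_rows)
    cum = np.cumsum(probs, axis=1)
    G = (u[:, None] >= cum).sum(axis=1).astype(np.int8)  # 0=never,1=prot,2=always

    eta = rng.normal(0.0, np.sqrt(config.tau2), size=config.n)
    sd = np.sqrt(config.sigma2)
    Y1 = np.full(n_rows, np.nan)
    Y0 = np.full(n_rows, np.nan)
    m = G == G_ALWAYS
    Y1[m] = X[m] @ np.asarray(config.alpha_11_1) + eta[cluster[m]] + rng.normal(0, sd, m.sum())
    Y0[m] = X[m] @ np.asarray(config.alpha_11_0) + eta[cluster[m]] + rng.normal(0, sd, m.sum())
    m = G == G_PROTECTED
    Y1[m] = X[m] @ np.asarray(config.alpha_10_1) + eta[cluster[m]] + rng.normal(0, sd, m.sum())

    D = D_cluster[cluster]
    S1 = (G != G_NEVER).astype(np.int8)           # survive if treated
    S0 = (G == G_ALWAYS).astype(np.int8)          # survive if control
    S = np.where(D == 1, S1, S0).astype(np.int8)
    Y = np.where(D == 1, Y1, Y0)
    Y = np.where(S == 1, Y, np.nan)

    dataset = CRTDataset(
        cluster=cluster, D=D, S=S, Y=Y, X=X, covariate_names=["X1", "X2"]
    )
    props = tuple(np.bincount(G, minlength=3) / n_rows)
    truth = SyntheticTruth(G=G, Y1=Y1, Y0=Y0, strata_props=props)
    return dataset, truth


@dataclass
class TrueSace:
    """Monte-Carlo truth for the SACE of a data-generating configuration."""

    value: float
    se: float


def true_sace_oracle(
    config: SimConfig,
    n_draws: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> TrueSace:
    """Brute-force truth: E[x'(alpha_11_1 - alpha_11_0) | G = 11].

    Simulates ``n_draws`` covariate rows and stratum labels directly from
    the membership model and averages the coefficient contrast over the
    realized always-survivors.  Because the SACE is a difference of linear
    predictors sharing the cluster effect, neither eta nor the residual
    noise enters the truth.  Returns the estimate with its standard error.
    """
    if n_draws < 1e5:
        raise ValueError("use at least 1e5 draws for a stable oracle")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    contrast = config.contrast
    phi2 = latent_icc_to_phi2(config.strata_icc) if config.strata_icc else None
    total = 0.0
    total_sq = 0.0
    count = 0
    chunk = 200_000
    remaining = int(n_draws)
    while remaining > 0:
        k = min(chunk, remaining)
        X = _draw_covariates(k, config, rng)
        if phi2 is not None:
            # one intercept draw per row integrates over the cluster effect
            chi = rng.normal(0.0, np.sqrt(phi2), size=k)
            params = StrataParams(config.beta, config.gamma, chi=chi, phi2=phi2)
            p11 = stratum_probabilities(X, params, np.arange(k))[:, G_ALWAYS]
        else:
            p11 = stratum_probabilities(X, StrataParams(config.beta, config.gamma))[:, G_ALWAYS]
        keep = rng.random(k) < p11
        vals = X[keep] @ contrast
        total += float(vals.sum())
        total_sq += float(vals @ vals)
        count += int(keep.sum())
        remaining -= k
    if count == 0:
        raise ValueError("no always-survivors realized; configuration degenerate")
    mean = total / count
    var = max(total_sq / count - mean**2, 0.0)
    return TrueSace(value=mean, se=float(np.sqrt(var / count)))
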