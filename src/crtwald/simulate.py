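"""Beta-binomial simulation of two-arm cluster-randomized trials.

Within-cluster correlation is induced the classical beta-binomial way: each
cluster draws its event probability p_i from Beta(a, b), and subjects in the
cluster are independent Bernoulli(p_i) given p_i.  The Beta shapes are set
from the arm's marginal event proportion mu = a/(a+b) and the intraclass
correlation rho = 1/(1+a+b).  Cluster sizes are drawn from a normal
distribution with mean nbar and standard deviation nbar*cv, rounded, and
clamped below at 1.

The intervention arm's marginal proportion is the control proportion's odds
multiplied by the odds ratio and mapped back to a probability; with a control
proportion of 0.25 and an odds ratio of 1.5 this gives 1/3.  (The generator
controls marginal moments only; the conditional cluster-specific odds ratio
of the analysis model is attenuated relative to this marginal one — see the
methods documentation.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "TrialScenario",
    "BetaShapes",
    "CRTDataset",
    "beta_shapes",
    "draw_cluster_sizes",
    "apply_odds_ratio",
    "simulate_trial",
    "empirical_random_effect_variance",
    "latent_logit_variance",
]


@dataclass(frozen=True)
class TrialScenario:
    """Full generative specification of one simulated CRT configuration."""

    K: int                  # total clusters, split equally across two arms
    nbar: float             # mean cluster size
    cv: float               # coefficient of variation of cluster sizes
    icc: float              # beta-binomial intraclass correlation rho
    mu_control: float = 0.25
    odds_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.K < 4 or self.K % 2:
            raise ValueError("K must be an even integer >= 4")
        if self.nbar < 1:
            raise ValueError("mean cluster size must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if not 0 < self.icc < 1:
            raise ValueError("icc must lie in (0, 1)")
        if not 0 < self.mu_control < 1:
            raise ValueError("mu_control must lie in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")


@dataclass(frozen=True)
class BetaShapes:
    a: float
    b: float


@dataclass
class CRTDataset:
    """Subject-level records of one two-arm CRT."""

    cluster_ids: np.ndarray   # integer label per subject
    arm: np.ndarray           # 0/1 per subject, constant within cluster
    y: np.ndarray             # 0/1 outcome per subject

    def __post_init__(self):
        self.cluster_ids = np.asarray(self.cluster_ids)
        self.arm = np.asarray(self.arm, dtype=int)
        self.y = np.asarray(self.y, dtype=int)
        if not (len(self.cluster_ids) == len(self.arm) == len(self.y)):
            raise ValueError("cluster_ids, arm and y must have equal length")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("outcomes must be binary 0/1")
        if not np.isin(self.arm, (0, 1)).all():
            raise ValueError("arm indicators must be 0/1")
        order = np.argsort(self.cluster_ids, kind="stable")
        cid, arm = self.cluster_ids[order], self.arm[order]
        mixed = (cid[1:] == cid[:-1]) & (arm[1:] != arm[:-1])
        if mixed.any():
            bad = cid[1:][mixed][0]
            raise ValueError(f"cluster {bad!r} contains both treatment arms")

    @property
    def cluster_sizes(self) -> np.ndarray:
        _, counts = np.unique(self.cluster_ids, return_counts=True)
        return counts

    @property
    def N(self) -> int:
        return len(self.y)

    @property
    def K(self) -> int:
        return len(np.unique(self.cluster_ids))


def beta_shapes(mu: float, rho: float) -> BetaShapes:
    """Beta shape parameters with marginal mean mu and ICC rho.

    Inverts mu = a/(a+b), rho = 1/(1+a+b):
    a = mu(1-rho)/rho, b = (1-mu)(1-rho)/rho.
    """
    if not 0 < mu < 1:
        raise ValueError("mu must lie in (0, 1)")
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1)")
    scale = (1 - rho) / rho
    return BetaShapes(a=mu * scale, b=(1 - mu) * scale)


def draw_cluster_sizes(K: int, nbar: float, cv: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Cluster sizes ~ round(Normal(nbar, (nbar*cv)^2)), clamped at 1."""
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    draws = rng.normal(loc=nbar, scale=nbar * cv, size=K)
    return np.maximum(1, np.rint(draws)).astype(int)


def apply_odds_ratio(mu: float, odds_ratio: float) -> float:
    """Multiply a proportion's odds by ``odds_ratio`` and map back."""
    odds = mu / (1 - mu) * odds_ratio
    return odds / (1 + odds)


def simulate_trial(scenario: TrialScenario,
                   rng: np.random.Generator | None = None) -> CRTDataset:
    """Generate one two-arm CRT under the beta-binomial model.

    The first K/2 clusters are control (arm 0), the rest intervention;
    randomizing the labels would not change any distributional property.
    """
    s = scenario
    if rng is None:
        rng = np.random.default_rng(s.seed)
    sizes = draw_cluster_sizes(s.K, s.nbar, s.cv, rng)
    half = s.K // 2
    arm_c = np.repeat([0, 1], half)
    mu1 = apply_odds_ratio(s.mu_control, s.odds_ratio)
    shapes = {0: beta_shapes(s.mu_control, s.icc), 1: beta_shapes(mu1, s.icc)}
    p = np.empty(s.K)
    for a in (0, 1):
        mask = arm_c == a
        p[mask] = rng.beta(shapes[a].a, shapes[a].b, size=mask.sum())
    y = rng.binomial(1, np.repeat(p, sizes))
    return CRTDataset(
        cluster_ids=np.repeat(np.arange(s.K), sizes),
        arm=np.repeat(arm_c, sizes),
        y=y,
    )


def simulate_conditional(K: int, n: int, tau2: float, beta: float,
                         mu_control: float = 0.25,
                         rng: np.random.Generator | None = None) -> CRTDataset:
    """Generate a CRT directly from the conditional logistic GLMM.

    Unlike the beta-binomial generator, which fixes marginal moments, this
    draws normal random intercepts b_i ~ N(0, tau2) and sets
    logit(p_i) = logit(mu_control) + beta * arm + b_i with equal cluster
    sizes n.  Used for parameter-recovery experiments where the estimand is
    the conditional (cluster-specific) effect itself.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if K < 2 or K % 2:
        raise ValueError("K must be an even integer >= 2")
    b = rng.normal(0.0, np.sqrt(tau2), K)
    arm_c = np.repeat([0, 1], K // 2)
    eta = np.log(mu_control / (1 - mu_control)) + beta * arm_c + b
    y = rng.binomial(1, np.repeat(special.expit(eta), n))
    return CRTDataset(cluster_ids=np.repeat(np.arange(K), n),
                      arm=np.repeat(arm_c, n), y=y)


def latent_logit_variance(mu: float, rho: float) -> float:
    """Var(logit p) for p ~ Beta(a, b) with the given marginal mean and ICC.

    Since logit p = log p - log(1-p) and (log p, log(1-p)) have the trigamma
    covariance structure of the Beta law, Var(logit p) = psi1(a) + psi1(b).
    This is the latent heterogeneity the beta-binomial generator implies on
    the scale of the GLMM's random intercept.
    """
    sh = beta_shapes(mu, rho)
    return float(special.polygamma(1, sh.a) + special.polygamma(1, sh.b))


def empirical_random_effect_variance(mu: float, rho: float, n_clusters: int,
                                     cluster_size: int,
                                     rng: np.random.Generator | None = None):
    """Diagnostic: tau2-hat from one large one-arm beta-binomial dataset.

    Simulates ``n_clusters`` clusters of common size with marginal mean
    ``mu`` and ICC ``rho``, fits the intercept-only random-intercept logistic
    GLMM, and returns ``(tau2_hat, converged)``.  This measures the latent
    variance the generator implies; it is a diagnostic, not a calibrated
    quantity.
    """
    from . import glmm

    if rng is None:
        rng = np.random.default_rng(0)
    sh = beta_shapes(mu, rho)
    p = rng.beta(sh.a, sh.b, size=n_clusters)
    y = rng.binomial(1, np.repeat(p, cluster_size))
    data = CRTDataset(
        cluster_ids=np.repeat(np.arange(n_clusters), cluster_size),
        arm=np.zeros(n_clusters * cluster_size, dtype=int),
        y=y,
    )
    fit = glmm.fit_glmm(data, intercept_only=True)
    return fit.varcomp.tau2, fit.converged
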