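"""Wald F tests for the intervention effect with five DDF approximations.

The Wald chi-square for the single-row contrast L (default [0, 1], the
treatment-arm effect) is T^2 = (L beta)^2 / (L Cov(beta) L'), and the Wald F
statistic is F = T^2 / r with r = 1 numerator degree of freedom.  The five
denominator-degrees-of-freedom rules compared here are

    Residual        N - rank(X)
    Containment     N - K          (random intercepts contain the arm effect)
    Between-Within  K - rank(X)    (arm is constant within clusters)
    Satterthwaite   d = 2 (L C L')^2 / Var[L C L']   (delta method over the
                    variance-component uncertainty, C = (X'V^-1 X)^-1)
    Kenward-Roger   same d at r = 1, but with the fixed-effects covariance
                    inflated for variance-component uncertainty.

Only rank-one contrasts are supported: the arm effect in a two-arm CRT is a
single-degree-of-freedom hypothesis, and the multi-row spectral machinery is
deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .glmm import FitResult

__all__ = [
    "Contrast",
    "TestResult",
    "DDF_METHODS",
    "ddf_residual",
    "ddf_containment",
    "ddf_between_within",
    "ddf_satterthwaite",
    "kr_adjusted",
    "wald_chi2",
    "wald_f_test",
    "run_all_tests",
    "test_arm_effect",
]

DDF_METHODS = ("residual", "containment", "between_within",
               "satterthwaite", "kenward_roger")


@dataclass(frozen=True)
class Contrast:
    """Single-row contrast of the fixed effects (rank r = 1 only)."""

    L: np.ndarray

    def __post_init__(self):
        L = np.atleast_2d(np.asarray(self.L, dtype=float))
        if L.shape[0] != 1:
            raise NotImplementedError(
                "only rank-1 contrasts are supported; the intervention-effect "
                "test has a single numerator degree of freedom")
        object.__setattr__(self, "L", L)

    @property
    def r(self) -> int:
        return 1


def arm_contrast(p: int = 2) -> Contrast:
    L = np.zeros(p)
    L[-1] = 1.0
    return Contrast(L)


@dataclass
class TestResult:
    """One Wald F test of the intervention effect."""

    method: str
    estimate: float
    se: float
    F: float
    num_df: int
    ddf: float
    scale_phi: float
    p_value: float
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return "failed" not in self.flags


# ---------------------------------------------------------------------------
# closed-form DDF rules
# ---------------------------------------------------------------------------

def ddf_residual(N: int, rank_X: int) -> int:
    """Residual rule: total subjects minus the fixed-effects rank."""
    if N <= rank_X:
        raise ValueError("residual DDF requires N > rank(X)")
    return N - rank_X


def ddf_containment(N: int, K: int) -> int:
    """Containment rule: N - K when random intercepts contain the arm effect."""
    if N <= K:
        raise ValueError("containment DDF requires N > K")
    return N - K


def ddf_between_within(K: int, rank_X: int) -> int:
    """Between-Within rule: between-cluster degrees of freedom K - rank(X)."""
    if K <= rank_X:
        raise ValueError("between-within DDF requires K > rank(X)")
    return K - rank_X


# ---------------------------------------------------------------------------
# Satterthwaite / Kenward-Roger
# ---------------------------------------------------------------------------

def _theta_names(fit: FitResult) -> list[str]:
    return ["tau2"] if fit.varcomp_cov.shape == (1, 1) else ["tau2", "phi"]


def _contrast_var_gradient(fit: FitResult, L: Contrast) -> np.ndarray:
    """Gradient of L C L' in theta, C = (X'V^-1 X)^-1.

    By the inverse-derivative identity dC/dtheta_k = C H_k C with
    H_k = X'V^-1 (dV/dtheta_k) V^-1 X (dV/dtau2 = ZZ', dV/dphi = W^-1),
    assembled cluster-blockwise during the fit.
    """
    C = fit.cov_beta
    Lm = L.L
    return np.array([(Lm @ C @ fit.H[n] @ C @ Lm.T).item()
                     for n in _theta_names(fit)])


def ddf_satterthwaite(fit: FitResult, L: Contrast | None = None):
    """Delta-method Satterthwaite DDF for a rank-one contrast.

    d = 2 (L C L')^2 / Var[L C L'] with Var[L C L'] = g' A g, g the gradient
    of the contrast variance in the variance components and A their REML
    covariance.  Returns ``(d, flags)``; d is not capped, but values beyond
    N are flagged, as is a non-positive delta-method variance (boundary or
    singular information).
    """
    if L is None:
        L = arm_contrast(fit.rank_X)
    flags: list[str] = []
    c = (L.L @ fit.cov_beta @ L.L.T).item()
    g = _contrast_var_gradient(fit, L)
    var_c = (g @ fit.varcomp_cov @ g).item()
    if var_c <= 0:
        if np.isclose(var_c, 0.0):
            return np.inf, ["ddf_unbounded"]
        return np.nan, ["failed", "nonpositive_delta_variance"]
    d = 2.0 * c * c / var_c
    if not np.isfinite(d):
        flags.append("ddf_unbounded")
    elif d > fit.N:
        flags.append("ddf_exceeds_N")
    return d, flags


def kr_adjusted(fit: FitResult, L: Contrast | None = None):
    """Kenward-Roger small-sample adjustment for a rank-one contrast.

    Inflates the model-based covariance with the classical two-term
    second-order correction for a covariance structure linear in theta:

        C_adj = C + 2 C [ sum_jk A_jk (N_jk - H_j C H_k) ] C,

    where H_j = X'V^-1 (dV_j) V^-1 X and N_jk = X'V^-1 dV_j V^-1 dV_k V^-1 X
    (the second-derivative term vanishes because V is linear in theta).  The
    contrast's adjusted variance is floored at the unadjusted one so the
    adjustment never reports a deflated standard error.  The DDF is the
    Satterthwaite value computed from the unadjusted covariance — at r = 1
    the two methods share d — and the statistic's scale is 1.

    Returns ``(cov_adj, phi_scale, d, flags)``.
    """
    if L is None:
        L = arm_contrast(fit.rank_X)
    names = _theta_names(fit)
    A = fit.varcomp_cov
    C = fit.cov_beta
    p = C.shape[0]
    Lam = np.zeros((p, p))
    for a, na in enumerate(names):
        for b, nb in enumerate(names):
            key = (na, nb) if (na, nb) in fit.Nm else (nb, na)
            Lam += A[a, b] * (fit.Nm[key] - fit.H[na] @ C @ fit.H[nb])
    cov_adj = C + 2.0 * C @ Lam @ C
    flags: list[str] = []
    Lm = L.L
    v_adj = (Lm @ cov_adj @ Lm.T).item()
    v_raw = (Lm @ C @ Lm.T).item()
    if v_adj < v_raw:
        flags.append("kr_deflation_floored")
        # restore the contrast direction via a rank-one bump
        cov_adj = cov_adj + (v_raw - v_adj) * (C @ Lm.T @ Lm @ C) / v_raw**2
    d, sflags = ddf_satterthwaite(fit, L)
    flags.extend(sflags)
    return cov_adj, 1.0, d, flags


# ---------------------------------------------------------------------------
# Wald statistics
# ---------------------------------------------------------------------------

def wald_chi2(beta_hat: np.ndarray, cov: np.ndarray,
              L: Contrast | None = None) -> float:
    """Wald chi-square T^2 = (L beta)' (L cov L')^-1 (L beta)."""
    if L is None:
        L = arm_contrast(len(beta_hat))
    num = (L.L @ beta_hat).item()
    den = (L.L @ cov @ L.L.T).item()
    if den <= 0:
        raise np.linalg.LinAlgError("contrast variance is not positive")
    return num * num / den


def wald_f_test(T2: float, r: int, d: float, phi_scale: float = 1.0):
    """F = T^2/(phi*r) referred to F(r, d); returns (F, p)."""
    if r != 1:
        raise NotImplementedError("only r = 1 is supported")
    if not d > 0:
        raise ValueError("denominator degrees of freedom must be positive")
    if phi_scale <= 0:
        raise ValueError("scale must be positive")
    F = T2 / (phi_scale * r)
    if np.isinf(d):
        p = float(stats.chi2.sf(F * r, r))
    else:
        p = float(stats.f.sf(F, r, d))
    return F, p


def test_arm_effect(fit: FitResult, method: str,
                    L: Contrast | None = None) -> TestResult:
    """One Wald F test of the intervention effect with the named DDF rule."""
    if method not in DDF_METHODS:
        raise ValueError(f"unknown DDF method {method!r}")
    if L is None:
        L = arm_contrast(fit.rank_X)
    flags: list[str] = []
    cov = fit.cov_beta
    phi_scale = 1.0
    if method == "residual":
        d = float(ddf_residual(fit.N, fit.rank_X))
    elif method == "containment":
        d = float(ddf_containment(fit.N, fit.K))
    elif method == "between_within":
        d = float(ddf_between_within(fit.K, fit.rank_X))
    elif method == "satterthwaite":
        d, flags = ddf_satterthwaite(fit, L)
    else:  # kenward_roger
        cov, phi_scale, d, flags = kr_adjusted(fit, L)
    estimate = (L.L @ fit.beta_hat).item()
    se = np.sqrt(L.L @ cov @ L.L.T).item()
    if "failed" in flags or not d > 0:
        return TestResult(method=method, estimate=estimate, se=se,
                          F=np.nan, num_df=1, ddf=np.nan, scale_phi=phi_scale,
                          p_value=np.nan, flags=flags + ["failed"]
                          if "failed" not in flags else flags)
    T2 = wald_chi2(fit.beta_hat, cov, L)
    F, p = wald_f_test(T2, L.r, d, phi_scale)
    return TestResult(method=method, estimate=estimate, se=se, F=F,
                      num_df=1, ddf=d, scale_phi=phi_scale, p_value=p,
                      flags=flags)


def run_all_tests(fit: FitResult, methods=DDF_METHODS) -> list[TestResult]:
    return [test_arm_effect(fit, m) for m in methods]
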