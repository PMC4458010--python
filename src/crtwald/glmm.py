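"""Pseudo-likelihood fitting of the random-intercept logistic GLMM.

The model for a two-arm cluster-randomized trial (CRT) with binary outcomes is

    y_ij | b_i ~ Bernoulli(mu_ij),   logit(mu_ij) = x_i' beta + b_i,
    b_i ~ N(0, tau2),   i = 1..K clusters,  j = 1..n_i subjects,

with cluster-constant covariates x_i (here an intercept and the treatment-arm
indicator).  Estimation follows the classical pseudo-likelihood (PQL-type)
scheme: the GLMM is linearized around the current estimates into a working
linear mixed model

    z = X beta + Z b + e,   Var(b) = tau2 * I_K,   Var(e) = phi * W^{-1},

where z is the working response, W the diagonal matrix of working weights
mu(1-mu), and phi a residual scale that absorbs over/under-dispersion.  The
working model is fitted by REML, the random effects are updated by BLUP, and
the linearization is re-expanded until the parameters stabilize.

Every cluster's working covariance V_i = tau2 * J + phi * W_i^{-1} is a
rank-one update of a diagonal matrix; all determinants, inverses, traces and
quadratic forms below use the Sherman-Morrison identity in O(n_i) time.  With
cluster-constant fixed effects every p x p cross-product reduces to a
per-cluster scalar times x_i x_i', which is what makes large Monte-Carlo
studies affordable.

The REML information matrix of (tau2, phi) — expected (Fisher) by default,
observed on request — supplies the variance-component covariance needed by
the Satterthwaite and Kenward-Roger degrees-of-freedom methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "ModelMatrices",
    "VarianceComponents",
    "FitOptions",
    "FitResult",
    "WorkingState",
    "fit_glmm",
    "reml_criterion",
    "reml_information",
    "varcomp_covariance",
    "anova_icc",
    "logistic_irls",
]

# Working weights mu(1-mu) are floored here to avoid division blow-ups near
# fitted probabilities of 0 or 1; fits that hit the floor are flagged.
WEIGHT_FLOOR = 1e-10
# Fitted probabilities within this distance of 0/1 indicate quasi-separation.
SEPARATION_TOL = 1e-10
# tau2 estimates at or below this value are treated as the zero boundary.
BOUNDARY_TOL = 1e-8


@dataclass
class ModelMatrices:
    """Design of the working model, at cluster resolution.

    ``Xc`` holds one row of fixed covariates per cluster (covariates are
    cluster-constant in a CRT); the subject-level X is ``Xc`` with rows
    repeated ``sizes`` times, and Z is the cluster-membership incidence.
    """

    Xc: np.ndarray          # (K, p) cluster-level design
    y: np.ndarray           # (N,) binary outcomes, sorted by cluster block
    sizes: np.ndarray       # (K,) cluster sizes n_i
    starts: np.ndarray      # (K,) block start offsets into subject arrays

    @property
    def K(self) -> int:
        return len(self.sizes)

    @property
    def N(self) -> int:
        return int(self.sizes.sum())

    @property
    def p(self) -> int:
        return self.Xc.shape[1]


@dataclass
class VarianceComponents:
    tau2: float
    phi: float


@dataclass
class FitOptions:
    """Tunable knobs of the PQL/REML fit."""

    fix_phi: bool = False          # hold the residual scale at 1
    reml: bool = True              # False: ML on the working model
    tol: float = 1e-8              # max relative change in (beta, tau2, phi)
    max_iter: int = 200            # outer linearization sweeps
    tau2_init: float = 0.1
    phi_init: float = 1.0
    expected_information: bool = True  # Fisher info for the varcomp covariance
    # Compound-symmetry parameterization: the between-cluster component may
    # go negative, down to the positive-definiteness limit of the working
    # covariance.  This is what keeps the Between-Within test calibrated at
    # small ICC; set False to constrain tau2 >= 0 (clamped and flagged).
    allow_negative_tau2: bool = True


@dataclass
class FitResult:
    """Converged (or flagged) state of one GLMM fit."""

    beta_hat: np.ndarray           # (p,)
    cov_beta: np.ndarray           # (p, p) model-based (X'V^-1 X)^-1
    varcomp: VarianceComponents
    varcomp_cov: np.ndarray        # covariance A of (tau2[, phi]) estimates
    b_hat: np.ndarray              # (K,) BLUPs of the random intercepts
    converged: bool
    n_iter: int
    N: int
    K: int
    rank_X: int
    flags: list[str] = field(default_factory=list)
    # Small-matrix summaries consumed by the DDF module.  H_* are the p x p
    # matrices X'V^-1 (dV/dtheta) V^-1 X; Nm_* the X'V^-1 dV V^-1 dV V^-1 X
    # second-order analogues; theta order is (tau2, phi) or (tau2,) if phi
    # is fixed.
    H: dict = field(default_factory=dict)
    Nm: dict = field(default_factory=dict)
    working_state: "WorkingState | None" = None

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.varcomp.tau2, self.varcomp.phi])


@dataclass
class WorkingState:
    """Final working responses/weights of the linearized model."""

    z: np.ndarray           # (N,) working response
    w: np.ndarray           # (N,) working weights mu(1-mu)
    mm: ModelMatrices
    reml: bool = True
    fix_phi: bool = False

    def _blocks(self):
        mm = self.mm
        sw = np.add.reduceat(self.w, mm.starts)
        swz = np.add.reduceat(self.w * self.z, mm.starts)
        swz2 = np.add.reduceat(self.w * self.z * self.z, mm.starts)
        return sw, swz, swz2


# ---------------------------------------------------------------------------
# dataset -> model matrices
# ---------------------------------------------------------------------------

def build_matrices(dataset, intercept_only: bool = False) -> ModelMatrices:
    """Assemble cluster-blocked design matrices from a CRTDataset.

    Subjects are sorted into contiguous cluster blocks (stable order of
    first appearance of each cluster label).  ``intercept_only`` drops the
    arm column — used for one-arm diagnostic fits.
    """
    cluster = np.asarray(dataset.cluster_ids)
    labels, first, inv = np.unique(cluster, return_index=True,
                                   return_inverse=True)
    # renumber clusters in order of first appearance so round-trips are stable
    rank = np.empty(len(labels), dtype=int)
    rank[np.argsort(first)] = np.arange(len(labels))
    codes = rank[inv]
    order = np.argsort(codes, kind="stable")
    codes = codes[order]
    y = np.asarray(dataset.y, dtype=float)[order]
    arm = np.asarray(dataset.arm, dtype=float)[order]
    sizes = np.bincount(codes)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    arm_c = arm[starts]
    if not intercept_only and not np.all(np.repeat(arm_c, sizes) == arm):
        raise ValueError("treatment arm is not constant within clusters")
    if intercept_only:
        Xc = np.ones((len(sizes), 1))
    else:
        Xc = np.column_stack([np.ones(len(sizes)), arm_c])
        if len(np.unique(arm_c)) < 2:
            raise ValueError("both treatment arms must be present to fit the arm effect")
    return ModelMatrices(Xc=Xc, y=y, sizes=sizes, starts=starts)


# ---------------------------------------------------------------------------
# REML criterion of the working model (compound-symmetry fast path)
# ---------------------------------------------------------------------------

def _gls_pieces(state: WorkingState, tau2: float, phi: float):
    """Per-cluster scalars of the GLS solve under V_i = tau2*J + phi*W_i^-1."""
    mm = state.mm
    sw, swz, swz2 = state._blocks()
    t = 1.0 + tau2 * sw / phi           # Sherman-Morrison denominators
    g = sw / (phi * t)                  # 1' V_i^-1 1
    u = swz / (phi * t)                 # 1' V_i^-1 z_i
    XtViX = (mm.Xc * g[:, None]).T @ mm.Xc
    XtViz = mm.Xc.T @ u
    C = np.linalg.inv(XtViX)
    beta = C @ XtViz
    zViz = (swz2 - tau2 * swz**2 / (phi * t)).sum() / phi
    quad = zViz - XtViz @ C @ XtViz     # z' P z
    return sw, t, g, u, XtViX, XtViz, C, beta, quad


def _neg2_reml(state: WorkingState, tau2: float, phi: float,
               with_grad: bool = False):
    mm = state.mm
    N, p = mm.N, mm.p
    sw, t, g, u, XtViX, XtViz, C, beta, quad = _gls_pieces(state, tau2, phi)
    logdetV = N * np.log(phi) - np.log(state.w).sum() + np.log(t).sum()
    val = logdetV + quad
    if state.reml:
        with np.errstate(invalid="ignore"):
            sign, ld = np.linalg.slogdet(XtViX)
        if sign <= 0 or not np.isfinite(ld):
            # numerically singular near the PD edge: steer the optimizer away
            val = 1e30
        else:
            val += ld + (N - p) * np.log(2 * np.pi)
    else:
        val += N * np.log(2 * np.pi)
    if not np.isfinite(val):
        val = 1e30
    if not with_grad:
        return val
    # residual r = z - X beta and e = V^-1 r, cluster-blockwise
    fitted = np.repeat(mm.Xc @ beta, mm.sizes)
    r = state.z - fitted
    wr = state.w * r
    swr = np.add.reduceat(wr, mm.starts)
    e = (wr - (tau2 / phi) * state.w * np.repeat(swr / t, mm.sizes)) / phi
    one_e = swr / (phi * t)             # 1' V_i^-1 r_i
    # trace terms: tr(P dV) with P = V^-1 - V^-1 X C X' V^-1 (REML) or V^-1 (ML)
    G2 = (mm.Xc * (g**2)[:, None]).T @ mm.Xc
    hphi = sw / (phi * t) ** 2          # 1' V^-1 W^-1 V^-1 1
    Hphi = (mm.Xc * hphi[:, None]).T @ mm.Xc
    tr_tau = g.sum()
    tr_phi = (mm.sizes / phi - tau2 * sw / (phi**2 * t)).sum()
    if state.reml:
        tr_tau -= np.trace(C @ G2)
        tr_phi -= np.trace(C @ Hphi)
    grad_tau = tr_tau - (one_e**2).sum()
    grad_phi = tr_phi - (e**2 / state.w).sum()
    if state.fix_phi:
        grad = np.array([grad_tau])
    else:
        grad = np.array([grad_tau, grad_phi])
    return val, grad


def reml_criterion(state: WorkingState, tau2: float, phi: float) -> float:
    """Restricted log-likelihood of the working linear mixed model.

    Computed cluster-by-cluster with the rank-one update identity for
    V_i = tau2*J + phi*W_i^{-1}; raises on a non-positive-definite V_i.
    """
    sw = np.add.reduceat(state.w, state.mm.starts)
    if phi <= 0 or np.any(1.0 + tau2 * sw / phi <= 0):
        raise np.linalg.LinAlgError("working covariance is not positive definite")
    return -0.5 * _neg2_reml(state, tau2, phi)


def _optimize_theta(state: WorkingState, theta0: np.ndarray,
                    allow_negative: bool = True) -> np.ndarray:
    """Maximize the (RE)ML criterion by bounded quasi-Newton.

    In the compound-symmetry parameterization (``allow_negative``) the
    between-cluster component is optimized as gamma = tau2/phi, bounded
    below by the positive-definiteness limit -1/max_i(sum_j w_ij) of the
    working covariance; otherwise tau2 is bounded at 0.
    """
    sw = np.add.reduceat(state.w, state.mm.starts)
    gmin = -(1.0 - 1e-6) / sw.max() if allow_negative else 0.0
    opts = {"ftol": 1e-13, "gtol": 1e-9, "maxiter": 200}
    if state.fix_phi:
        fun = lambda th: _neg2_reml(state, th[0], 1.0, with_grad=True)
        x0 = np.clip(theta0[:1], gmin, None)
        res = optimize.minimize(fun, x0, jac=True, method="L-BFGS-B",
                                bounds=[(gmin, None)], options=opts)
        return np.array([res.x[0], 1.0])

    def fun(x):
        gam, phi = x
        val, grad = _neg2_reml(state, gam * phi, phi, with_grad=True)
        # chain rule from (tau2, phi) to (gamma, phi)
        return val, np.array([phi * grad[0], grad[1] + gam * grad[0]])

    x0 = np.array([theta0[0] / theta0[1], theta0[1]])
    x0[0] = np.clip(x0[0], gmin * (1 - 1e-9) if gmin < 0 else gmin, None)
    x0[1] = max(x0[1], 1e-8)
    res = optimize.minimize(fun, x0, jac=True, method="L-BFGS-B",
                            bounds=[(gmin, None), (1e-8, None)], options=opts)
    gam, phi = res.x
    return np.array([gam * phi, max(phi, 1e-8)])


# ---------------------------------------------------------------------------
# REML information in theta = (tau2[, phi])
# ---------------------------------------------------------------------------

def _per_cluster_summaries(state: WorkingState, tau2: float, phi: float):
    mm = state.mm
    sw, _, _ = state._blocks()
    sw2 = np.add.reduceat(state.w**2, mm.starts)
    t = 1.0 + tau2 * sw / phi
    g = sw / (phi * t)
    hphi = sw / (phi * t) ** 2
    return sw, sw2, t, g, hphi


def _info_matrices(state: WorkingState, tau2: float, phi: float):
    """Expected REML information and the H/N small matrices for the DDF step."""
    mm = state.mm
    sw, sw2, t, g, hphi = _per_cluster_summaries(state, tau2, phi)
    Xc = mm.Xc

    def xmat(s):
        return (Xc * s[:, None]).T @ Xc

    H = {"tau2": xmat(g**2), "phi": xmat(hphi)}
    Nm = {
        ("tau2", "tau2"): xmat(g**3),
        ("tau2", "phi"): xmat(g * hphi),
        ("phi", "phi"): xmat(g / (phi * t) ** 2),
    }
    XtViX = xmat(g)
    C = np.linalg.inv(XtViX)
    beta_cs = tau2 / (phi**2 * t)
    T = {
        ("tau2", "tau2"): (g**2).sum(),
        ("tau2", "phi"): hphi.sum(),
        ("phi", "phi"): (mm.sizes / phi**2 - 2 * beta_cs * sw / phi
                         + beta_cs**2 * sw**2).sum(),
    }
    names = ["tau2"] if state.fix_phi else ["tau2", "phi"]
    q = len(names)
    info = np.empty((q, q))
    for a, na in enumerate(names):
        for b, nb in enumerate(names):
            key = (na, nb) if (na, nb) in Nm else (nb, na)
            val = T[key]
            if state.reml:
                val += -2.0 * np.trace(C @ Nm[key]) \
                    + np.trace(C @ H[na] @ C @ H[nb])
            info[a, b] = 0.5 * val
    return info, H, Nm, C, XtViX


def _apply_Vinv(state: WorkingState, tau2: float, phi: float, v: np.ndarray):
    mm = state.mm
    sw, _, t, _, _ = _per_cluster_summaries(state, tau2, phi)
    wv = state.w * v
    swv = np.add.reduceat(wv, mm.starts)
    return (wv - (tau2 / phi) * state.w * np.repeat(swv / t, mm.sizes)) / phi


def _apply_P(state: WorkingState, tau2: float, phi: float, C: np.ndarray,
             v: np.ndarray):
    mm = state.mm
    Viv = _apply_Vinv(state, tau2, phi, v)
    if not state.reml:
        return Viv
    XtViv = mm.Xc.T @ np.add.reduceat(Viv, mm.starts)
    proj = np.repeat(mm.Xc @ (C @ XtViv), mm.sizes)
    return Viv - _apply_Vinv(state, tau2, phi, proj)


def reml_information(state: WorkingState, tau2: float, phi: float,
                     expected: bool = True) -> np.ndarray:
    """Information matrix of the (RE)ML criterion in theta = (tau2[, phi]).

    ``expected=True`` gives the Fisher information 0.5*tr(P dV_a P dV_b);
    ``expected=False`` the observed information (negative Hessian of the
    restricted log-likelihood), which for the linear covariance structure is
    z'P dV_a P dV_b P z - 0.5*tr(P dV_a P dV_b).
    """
    info, _, _, C, _ = _info_matrices(state, tau2, phi)
    if expected:
        return info
    mm = state.mm
    e = _apply_P(state, tau2, phi, C, state.z)   # P z
    one_e = np.add.reduceat(e, mm.starts)
    v = {"tau2": np.repeat(one_e, mm.sizes), "phi": e / state.w}
    names = ["tau2"] if state.fix_phi else ["tau2", "phi"]
    obs = np.empty_like(info)
    Pv = {n: _apply_P(state, tau2, phi, C, v[n]) for n in names}
    for a, na in enumerate(names):
        for b, nb in enumerate(names):
            obs[a, b] = v[na] @ Pv[nb] - info[a, b]
    return obs


def varcomp_covariance(fit: FitResult, expected: bool | None = None) -> np.ndarray:
    """Covariance A of the variance-component estimates.

    Inverse of the REML information at theta-hat (expected/Fisher by
    default).  A singular information — typically tau2 pinned at the zero
    boundary with a flat profile — falls back to the pseudo-inverse and
    flags the fit.
    """
    state = fit.working_state
    if expected is None:
        expected = True
    info = reml_information(state, fit.varcomp.tau2, fit.varcomp.phi,
                            expected=expected)
    try:
        cond = np.linalg.cond(info)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        if "singular_information" not in fit.flags:
            fit.flags.append("singular_information")
        return np.linalg.pinv(info)
    return np.linalg.inv(info)


# ---------------------------------------------------------------------------
# plain logistic regression (initializer and i.i.d. reference)
# ---------------------------------------------------------------------------

def logistic_irls(X: np.ndarray, y: np.ndarray, tol: float = 1e-10,
                  max_iter: int = 100) -> np.ndarray:
    """Newton/IRLS fit of a plain logistic GLM (no random effects)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = special.expit(eta)
        w = np.clip(mu * (1 - mu), WEIGHT_FLOOR, None)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(Xw.T @ X, Xw.T @ z)
        if np.max(np.abs(beta_new - beta)) < tol * (1 + np.max(np.abs(beta))):
            return beta_new
        beta = beta_new
    return beta


# ---------------------------------------------------------------------------
# outer PQL loop
# ---------------------------------------------------------------------------

def fit_glmm(data, options: FitOptions | None = None,
             intercept_only: bool = False) -> FitResult:
    """Fit the random-intercept logistic GLMM by pseudo-likelihood.

    Alternates (i) REML estimation of (tau2, phi) in the working linear
    mixed model, (ii) GLS update of beta and BLUP update of the random
    intercepts, and (iii) re-linearization of the logistic mean, until the
    maximum relative change in (beta, tau2, phi) drops below ``options.tol``.

    Failures are flagged, not raised: non-convergence, quasi-separation
    (fitted probabilities within 1e-10 of 0/1), working weights at the
    floor, and tau2 at the zero boundary.
    """
    opts = options or FitOptions()
    mm = build_matrices(data, intercept_only=intercept_only)
    y = mm.y
    if y.min() == y.max():
        raise ValueError("outcomes are all identical; the model is not identifiable")
    if mm.N < mm.p + 1:
        raise ValueError("fewer subjects than parameters")

    Xs = np.repeat(mm.Xc, mm.sizes, axis=0)
    beta = logistic_irls(Xs, y)
    b = np.zeros(mm.K)
    theta = np.array([opts.tau2_init, 1.0 if opts.fix_phi else opts.phi_init])
    flags: list[str] = []
    converged = False
    state = None
    n_iter = 0

    for n_iter in range(1, opts.max_iter + 1):
        eta = np.repeat(mm.Xc @ beta, mm.sizes) + np.repeat(b, mm.sizes)
        mu = special.expit(eta)
        if np.any(mu < SEPARATION_TOL) or np.any(mu > 1 - SEPARATION_TOL):
            flags.append("quasi_separation")
            break
        w = mu * (1 - mu)
        if np.any(w < WEIGHT_FLOOR):
            w = np.clip(w, WEIGHT_FLOOR, None)
            if "weight_floor" not in flags:
                flags.append("weight_floor")
        z = eta + (y - mu) / w
        state = WorkingState(z=z, w=w, mm=mm, reml=opts.reml, fix_phi=opts.fix_phi)
        theta_new = _optimize_theta(state, theta,
                                    allow_negative=opts.allow_negative_tau2)
        tau2, phi = theta_new
        sw, t, g, u, XtViX, XtViz, C, beta_new, _ = _gls_pieces(state, tau2, phi)
        fitted = np.repeat(mm.Xc @ beta_new, mm.sizes)
        swr = np.add.reduceat(w * (z - fitted), mm.starts)
        b_new = tau2 * swr / (phi * t)
        old = np.concatenate([beta, theta])
        new = np.concatenate([beta_new, theta_new])
        delta = np.max(np.abs(new - old) / (1.0 + np.abs(old)))
        beta, b, theta = beta_new, b_new, theta_new
        if delta < opts.tol:
            converged = True
            break

    tau2, phi = theta
    if state is None:  # separation on the very first linearization
        state = WorkingState(z=y, w=np.full(mm.N, 0.25), mm=mm,
                             reml=opts.reml, fix_phi=opts.fix_phi)
    if not converged and "quasi_separation" not in flags:
        flags.append("not_converged")
    if opts.allow_negative_tau2:
        if state is not None:
            sw_max = np.add.reduceat(state.w, mm.starts).max()
            if tau2 / phi <= -(1.0 - 1e-5) / sw_max:
                # pinned at the singular edge of the parameter space: the
                # working covariance is effectively non-positive-definite
                # and the fit is not a trustworthy interior optimum
                flags.append("cs_boundary")
                converged = False
        if tau2 < 0:
            flags.append("tau2_negative")
    elif tau2 <= BOUNDARY_TOL:
        flags.append("tau2_boundary")
        tau2 = max(tau2, 0.0)

    _, _, _, _, XtViX, _, C, _, _ = _gls_pieces(state, tau2, phi)
    info, H, Nm, _, _ = _info_matrices(state, tau2, phi)
    fit = FitResult(
        beta_hat=beta,
        cov_beta=C,
        varcomp=VarianceComponents(tau2=float(tau2), phi=float(phi)),
        varcomp_cov=np.empty((0, 0)),
        b_hat=b,
        converged=converged,
        n_iter=n_iter,
        N=mm.N,
        K=mm.K,
        rank_X=mm.p,
        flags=flags,
        H=H,
        Nm=Nm,
        working_state=state,
    )
    fit.varcomp_cov = varcomp_covariance(fit, expected=opts.expected_information)
    return fit


# ---------------------------------------------------------------------------
# ANOVA moment estimator of the ICC (reporting and simulator diagnostics)
# ---------------------------------------------------------------------------

def anova_icc(cluster_ids, y, arm=None) -> float:
    """One-way ANOVA moment estimator of the intraclass correlation.

    When ``arm`` is given, outcomes are centered on their arm means first so
    the treatment effect does not masquerade as between-cluster variance.
    Uses the classical (MSB - MSW) / (MSB + (n0 - 1) MSW) estimator with
    n0 = (N - sum n_i^2 / N) / (K - 1).
    """
    cluster_ids = np.asarray(cluster_ids)
    y = np.asarray(y, dtype=float)
    if arm is not None:
        arm = np.asarray(arm)
        for a in np.unique(arm):
            y = np.where(arm == a, y - y[arm == a].mean() + y.mean(), y)
    labels, codes = np.unique(cluster_ids, return_inverse=True)
    K = len(labels)
    N = len(y)
    n = np.bincount(codes).astype(float)
    means = np.bincount(codes, weights=y) / n
    grand = y.mean()
    ssb = (n * (means - grand) ** 2).sum()
    ssw = ((y - means[codes]) ** 2).sum()
    msb = ssb / (K - 1)
    msw = ssw / (N - K)
    n0 = (N - (n**2).sum() / N) / (K - 1)
    return float((msb - msw) / (msb + (n0 - 1) * msw))
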