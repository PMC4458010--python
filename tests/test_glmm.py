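"""PQL/REML engine: oracles, information matrices, invariances."""

import numpy as np
import pytest
import statsmodels.api as sm

import crtwald as cw
from crtwald import glmm
from crtwald.glmm import (
    FitOptions,
    _apply_Vinv,
    _gls_pieces,
    _neg2_reml,
    build_matrices,
)


def _tiny_dataset(seed=11, K=4, n=6):
    rng = np.random.default_rng(seed)
    arm = np.repeat([0] * (K // 2) + [1] * (K - K // 2), n)
    p = rng.beta(4.75, 14.25, K)
    y = rng.binomial(1, np.repeat(p, n))
    if y.min() == y.max():  # pragma: no cover - seed chosen to avoid this
        raise RuntimeError("degenerate tiny dataset")
    return cw.CRTDataset(cluster_ids=np.repeat(np.arange(K), n), arm=arm, y=y)


class TestAgainstPlainLogistic:
    def test_singleton_clusters_match_glm(self):
        # with one subject per cluster there is no within-cluster replication
        # and the PQL fit must coincide with ordinary logistic regression
        rng = np.random.default_rng(5)
        n = 400
        arm = np.repeat([0, 1], n // 2)
        y = rng.binomial(1, np.where(arm == 0, 0.25, 1 / 3))
        ds = cw.CRTDataset(cluster_ids=np.arange(n), arm=arm, y=y)
        fit = cw.fit_glmm(ds)
        X = np.column_stack([np.ones(n), arm])
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.max(np.abs(fit.beta_hat - ref.params)
                      / np.abs(ref.params)) < 1e-6


class TestRemlCriterion:
    def test_rank_one_inverse_matches_dense(self):
        rng = np.random.default_rng(3)
        ds = _tiny_dataset()
        mm = build_matrices(ds)
        w = rng.uniform(0.05, 0.25, mm.N)
        z = rng.normal(size=mm.N)
        state = glmm.WorkingState(z=z, w=w, mm=mm)
        for tau2, phi in [(0.3, 1.1), (0.0, 0.8), (2.0, 1.0), (-0.05, 1.0)]:
            v = rng.normal(size=mm.N)
            got = _apply_Vinv(state, tau2, phi, v)
            expect = np.empty_like(v)
            for s, n_i in zip(mm.starts, mm.sizes):
                sl = slice(s, s + n_i)
                V = tau2 * np.ones((n_i, n_i)) + phi * np.diag(1 / w[sl])
                expect[sl] = np.linalg.solve(V, v[sl])
            assert np.max(np.abs(got - expect)) < 1e-10

    def test_collapse_to_independent_errors(self):
        # tau2 = 0, phi = 1: the criterion must equal the weighted
        # least-squares restricted likelihood computed densely
        ds = _tiny_dataset()
        mm = build_matrices(ds)
        rng = np.random.default_rng(4)
        w = rng.uniform(0.1, 0.25, mm.N)
        z = rng.normal(size=mm.N)
        state = glmm.WorkingState(z=z, w=w, mm=mm)
        X = np.repeat(mm.Xc, mm.sizes, axis=0)
        V = np.diag(1 / w)
        Vi = np.diag(w)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ z)
        r = z - X @ beta
        dense = -0.5 * (np.linalg.slogdet(V)[1]
                        + np.linalg.slogdet(XtViX)[1]
                        + r @ Vi @ r
                        + (mm.N - mm.p) * np.log(2 * np.pi))
        assert cw.reml_criterion(state, 0.0, 1.0) == pytest.approx(
            dense, rel=1e-10)

    def test_invariant_to_cluster_relabeling(self, small_trial):
        mm = build_matrices(small_trial)
        rng = np.random.default_rng(6)
        w = rng.uniform(0.1, 0.25, mm.N)
        z = rng.normal(size=mm.N)
        state = glmm.WorkingState(z=z, w=w, mm=mm)
        # relabel clusters by permuting whole blocks of subjects
        perm = rng.permutation(mm.K)
        idx = np.concatenate([np.arange(s, s + n) for s, n in
                              zip(mm.starts[perm], mm.sizes[perm])])
        ds2 = cw.CRTDataset(
            cluster_ids=np.repeat(np.arange(mm.K), mm.sizes[perm]),
            arm=np.repeat(mm.Xc[perm, 1].astype(int), mm.sizes[perm]),
            y=mm.y[idx].astype(int))
        mm2 = build_matrices(ds2)
        state2 = glmm.WorkingState(z=z[idx], w=w[idx], mm=mm2)
        assert cw.reml_criterion(state2, 0.2, 1.1) == pytest.approx(
            cw.reml_criterion(state, 0.2, 1.1), rel=1e-12)

    def test_nonpositive_definite_raises(self):
        ds = _tiny_dataset()
        mm = build_matrices(ds)
        state = glmm.WorkingState(z=mm.y, w=np.full(mm.N, 0.2), mm=mm)
        with pytest.raises(np.linalg.LinAlgError):
            cw.reml_criterion(state, -5.0, 1.0)


class TestOptimizer:
    def test_matches_brute_force_grid(self):
        # 1-D brute force over the profiled criterion with phi fixed at 1
        ds = _tiny_dataset()
        fit = cw.fit_glmm(ds, FitOptions(fix_phi=True,
                                         allow_negative_tau2=False))
        state = fit.working_state
        grid = np.arange(0.0, 5.0, 1e-4)
        vals = np.array([_neg2_reml(state, t, 1.0) for t in grid])
        t_grid = grid[np.argmin(vals)]
        assert abs(fit.varcomp.tau2 - t_grid) <= 1e-4 + 1e-12

    def test_interior_gradient_vanishes(self, small_fit):
        state = small_fit.working_state
        tau2, phi = small_fit.varcomp.tau2, small_fit.varcomp.phi
        _, grad = _neg2_reml(state, tau2, phi, with_grad=True)
        # gradient of the restricted log-likelihood itself
        assert np.linalg.norm(0.5 * grad) < 1e-5


class TestInformation:
    def test_observed_info_matches_finite_differences(self, small_fit):
        state = small_fit.working_state
        th = np.array([max(small_fit.varcomp.tau2, 0.05),
                       small_fit.varcomp.phi])
        obs = cw.reml_information(state, th[0], th[1], expected=False)
        h = 1e-5
        fd = np.empty((2, 2))
        for a in range(2):
            for b in range(2):
                e1 = np.zeros(2); e1[a] = h
                e2 = np.zeros(2); e2[b] = h
                fd[a, b] = -(cw.reml_criterion(state, *(th + e1 + e2))
                             - cw.reml_criterion(state, *(th + e1 - e2))
                             - cw.reml_criterion(state, *(th - e1 + e2))
                             + cw.reml_criterion(state, *(th - e1 - e2))
                             ) / (4 * h * h)
        assert np.max(np.abs(obs - fd)) < 1e-4 * np.linalg.norm(fd)

    def test_fixed_phi_gives_1x1_covariance(self):
        ds = _tiny_dataset(seed=13, K=8, n=10)
        fit = cw.fit_glmm(ds, FitOptions(fix_phi=True))
        assert fit.varcomp_cov.shape == (1, 1)
        assert fit.varcomp.phi == 1.0

    def test_varcomp_covariance_shrinks_like_one_over_K(self):
        # the tau2 variance should scale roughly as 1/K
        a00 = []
        Ks = [20, 80, 320]
        for K in Ks:
            vals = []
            for seed in range(5):
                sc = cw.TrialScenario(K=K, nbar=20, cv=0.0, icc=0.05,
                                      seed=seed)
                ds = cw.simulate_trial(sc, np.random.default_rng(
                    10_000 + 17 * K + seed))
                fit = cw.fit_glmm(ds)
                if fit.converged:
                    vals.append(fit.varcomp_cov[0, 0])
            a00.append(np.mean(vals))
        slope = np.polyfit(np.log(Ks), np.log(a00), 1)[0]
        assert -1.3 < slope < -0.7


class TestFitInvariances:
    def test_cov_beta_matches_dense_gls(self, small_fit):
        state = small_fit.working_state
        mm = state.mm
        tau2, phi = small_fit.varcomp.tau2, small_fit.varcomp.phi
        X = np.repeat(mm.Xc, mm.sizes, axis=0)
        V = np.zeros((mm.N, mm.N))
        for s, n_i in zip(mm.starts, mm.sizes):
            sl = slice(s, s + n_i)
            V[sl, sl] = tau2
        V[np.diag_indices(mm.N)] += phi / state.w
        dense = np.linalg.inv(X.T @ np.linalg.solve(V, X))
        assert np.max(np.abs(small_fit.cov_beta - dense)) < 1e-10

    def test_refit_invariant_to_relabeling(self, small_trial):
        fit1 = cw.fit_glmm(small_trial)
        rng = np.random.default_rng(8)
        # permute subjects wholesale; cluster labels shuffled
        relabel = rng.permutation(small_trial.K)
        order = rng.permutation(small_trial.N)
        ds2 = cw.CRTDataset(
            cluster_ids=relabel[small_trial.cluster_ids][order],
            arm=small_trial.arm[order],
            y=small_trial.y[order])
        fit2 = cw.fit_glmm(ds2)
        assert abs(fit1.varcomp.tau2 - fit2.varcomp.tau2) < 1e-10
        assert np.max(np.abs(fit1.beta_hat - fit2.beta_hat)) < 1e-10

    def test_mean_tau2_nondecreasing_in_rho(self):
        means = []
        for rho in (0.01, 0.05, 0.1):
            vals = []
            for seed in range(15):
                sc = cw.TrialScenario(K=60, nbar=30, cv=0.0, icc=rho,
                                      seed=seed)
                ds = cw.simulate_trial(sc, np.random.default_rng(seed))
                fit = cw.fit_glmm(ds)
                if fit.converged:
                    vals.append(fit.varcomp.tau2)
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]

    def test_all_identical_outcomes_rejected(self):
        ds = cw.CRTDataset(cluster_ids=np.repeat(np.arange(4), 5),
                           arm=np.repeat([0, 0, 1, 1], 5),
                           y=np.zeros(20, dtype=int))
        with pytest.raises(ValueError):
            cw.fit_glmm(ds)

    def test_single_arm_requires_intercept_only(self):
        ds = cw.CRTDataset(cluster_ids=np.repeat(np.arange(4), 5),
                           arm=np.zeros(20, dtype=int),
                           y=np.tile([0, 1, 0, 0, 1], 4))
        with pytest.raises(ValueError):
            cw.fit_glmm(ds)
        fit = cw.fit_glmm(ds, intercept_only=True)
        assert fit.rank_X == 1


class TestAnovaIcc:
    def test_iid_data_gives_near_zero(self):
        rng = np.random.default_rng(2)
        y = rng.binomial(1, 0.25, 5000)
        cid = np.repeat(np.arange(100), 50)
        icc = cw.anova_icc(cid, y)
        assert abs(icc) < 0.01
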