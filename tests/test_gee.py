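import numpy as np
import pytest

from mtmat.gee import (
    DesignData,
    GeeError,
    WorkingCorrelation,
    fit_null,
    score_test,
    wald_test,
)

from _oracle import score_oracle, wald_oracle


def random_instance(rng, balanced=False):
    """Small random GEE problem: N in [6,20] subjects, 1-4 visits, 1-3
    covariate columns (incl. intercept), binary subject-level phenotype."""
    N = int(rng.integers(6, 21))
    p = int(rng.integers(1, 4))
    if balanced:
        sizes = [int(rng.integers(2, 5))] * N
    else:
        sizes = [int(rng.integers(1, 5)) for _ in range(N)]
    subjects = np.repeat(np.arange(N), sizes)
    visits = np.concatenate([np.arange(1, s + 1) for s in sizes])
    n = subjects.size
    Z = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p - 1)])
    # at least two case and two control subjects: with a single case
    # subject the y-block leverage approaches 1 and the small-sample
    # factor (I - P)^{-1} is ill-conditioned
    status = (rng.random(N) < 0.4).astype(float)
    while status.sum() < 2 or (1 - status).sum() < 2:
        status = (rng.random(N) < 0.4).astype(float)
    y = np.repeat(status, sizes)
    b = rng.normal(size=(N,))
    x = Z @ rng.normal(size=p) + np.repeat(0.5 * b, sizes) + rng.normal(size=n)
    return x, Z, y, subjects, visits


STRUCTURES = ["identity", "CS", "AR1"]


class TestOracleEquivalence:
    @pytest.mark.parametrize("structure", STRUCTURES + ["UN"])
    def test_score_statistic_matches_dense_transcription(self, structure):
        rng = np.random.default_rng(99)
        for rep in range(25):
            x, Z, y, s, v = random_instance(rng, balanced=(structure == "UN"))
            data = DesignData(x, Z, y, s, v)
            wc = WorkingCorrelation(structure)
            for small in (False, True):
                fit = score_test(data, wc, small_sample=small)
                ref = score_oracle(x, Z, y, s, v, structure, small)
                np.testing.assert_allclose(fit.alpha_hat, ref["alpha"],
                                           rtol=1e-8)
                np.testing.assert_allclose(fit.H, ref["H"], rtol=1e-8)
                np.testing.assert_allclose(fit.B, ref["B"], rtol=1e-8)
                assert fit.T == pytest.approx(ref["T"], rel=1e-8)

    @pytest.mark.parametrize("structure", STRUCTURES + ["UN"])
    def test_wald_statistic_matches_dense_transcription(self, structure):
        rng = np.random.default_rng(7)
        for rep in range(25):
            x, Z, y, s, v = random_instance(rng, balanced=(structure == "UN"))
            data = DesignData(x, Z, y, s, v)
            wc = WorkingCorrelation(structure)
            for small in (False, True):
                fit = wald_test(data, wc, small_sample=small)
                ref = wald_oracle(x, Z, y, s, v, structure, small)
                assert fit.beta_hat == pytest.approx(ref["beta"], rel=1e-8)
                assert fit.V_hat == pytest.approx(ref["V"], rel=1e-8)
                assert fit.T == pytest.approx(ref["T"], rel=1e-8)


class TestReductions:
    def test_identity_null_fit_is_ols(self, rng):
        x, Z, y, s, v = random_instance(rng)
        alpha, cov = fit_null(DesignData(x, Z, y, s, v),
                              WorkingCorrelation("identity"))
        ols = np.linalg.lstsq(Z, x, rcond=None)[0]
        np.testing.assert_allclose(alpha, ols, rtol=1e-10)
        assert cov.sigma_kk > 0

    @pytest.mark.parametrize("structure", ["CS", "AR1", "UN"])
    def test_single_visit_collapses_to_identity(self, structure, rng):
        N = 15
        subjects = np.arange(N)
        visits = np.ones(N, dtype=int)
        Z = np.ones((N, 1))
        y = (rng.random(N) < 0.5).astype(float)
        if y.std() == 0:
            y[0] = 1 - y[0]
        x = rng.normal(size=N) + 0.2 * y
        d = DesignData(x, Z, y, subjects, visits)
        f_struct = score_test(d, WorkingCorrelation(structure))
        f_ident = score_test(d, WorkingCorrelation("identity"))
        assert f_struct.T == pytest.approx(f_ident.T, rel=1e-10)

    def test_constant_phenotype_rejected(self, rng):
        x, Z, _, s, v = random_instance(rng)
        y = np.ones_like(x)
        with pytest.raises(GeeError, match="no variance"):
            wald_test(DesignData(x, Z, y, s, v), WorkingCorrelation("identity"))


class TestInvariances:
    def test_score_statistic_affine_invariant_in_response(self, rng):
        x, Z, y, s, v = random_instance(rng)
        wc = WorkingCorrelation("CS")
        t0 = score_test(DesignData(x, Z, y, s, v), wc).T
        t1 = score_test(DesignData(3.7 * x - 11.0, Z, y, s, v), wc).T
        assert t1 == pytest.approx(t0, rel=1e-8)

    def test_subject_relabeling_invariant(self, rng):
        x, Z, y, s, v = random_instance(rng)
        wc = WorkingCorrelation("AR1")
        t0 = score_test(DesignData(x, Z, y, s, v), wc).T
        relabel = {u: f"subj_{u}" for u in set(s)}
        s2 = np.array([relabel[u] for u in s])
        t1 = score_test(DesignData(x, Z, y, s2, v), wc).T
        assert t1 == pytest.approx(t0, rel=1e-10)

    def test_general_contrast_reduces_to_default(self, rng):
        x, Z, y, s, v = random_instance(rng)
        p = Z.shape[1]
        L = np.zeros((1, p + 1))
        L[0, -1] = 1.0
        d = DesignData(x, Z, y, s, v)
        wc = WorkingCorrelation("identity")
        assert (score_test(d, wc, L=L).T
                == pytest.approx(score_test(d, wc).T, rel=1e-12))


class TestCrossChecks:
    def test_joint_fit_matches_statsmodels_independence_gee(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        x, Z, y, s, v = random_instance(rng)
        fit = wald_test(DesignData(x, Z, y, s, v),
                        WorkingCorrelation("identity"), small_sample=False)
        M = np.column_stack([Z, y])
        model = sm.GEE(x, M, groups=s,
                       cov_struct=sm.cov_struct.Independence())
        res = model.fit()
        np.testing.assert_allclose(
            np.append(fit.alpha_hat, fit.beta_hat), res.params, rtol=1e-6)

    def test_exchangeable_fit_close_to_statsmodels(self, rng):
        # the moment estimators of rho differ in finite-sample corrections,
        # so compare at a subject count where both have converged
        sm = pytest.importorskip("statsmodels.api")
        N, n = 300, 3
        subjects = np.repeat(np.arange(N), n)
        b = rng.normal(size=N)
        status = (rng.random(N) < 0.4).astype(float)
        y = np.repeat(status, n)
        x = 0.3 * y + np.repeat(0.7 * b, n) + rng.normal(size=N * n)
        Z = np.ones((N * n, 1))
        fit = wald_test(DesignData(x, Z, y, subjects),
                        WorkingCorrelation("CS"), small_sample=False)
        M = np.column_stack([Z, y])
        res = sm.GEE(x, M, groups=subjects,
                     cov_struct=sm.cov_struct.Exchangeable()).fit()
        np.testing.assert_allclose(
            np.append(fit.alpha_hat, fit.beta_hat), res.params, atol=0.02)
        assert fit.cov.wc.params == pytest.approx(
            res.cov_struct.dep_params, abs=0.05)


class TestNullCalibration:
    def test_permutation_null_rejection_rate(self, rng):
        # score test on exchangeable Gaussian data: empirical P(p < 0.05)
        # within 3 MC standard errors of 0.05
        N, n = 40, 3
        subjects = np.repeat(np.arange(N), n)
        reps = 600
        hits = 0
        for _ in range(reps):
            b = rng.normal(size=N)
            x = np.repeat(b * 0.6, n) + rng.normal(size=N * n)
            status = np.zeros(N)
            status[rng.choice(N, 20, replace=False)] = 1
            y = np.repeat(status, n)
            fit = score_test(DesignData(x, np.ones((N * n, 1)), y, subjects),
                             WorkingCorrelation("CS"))
            hits += fit.p < 0.05
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se
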