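import numpy as np
import pytest

from rbc_rispec import (
    ExtinctionSpectrum,
    SyntheticScenario,
    alpha_covariance,
    average_dilutions,
    combine_samples,
    covariance_psi,
    extinction_from_transmittance,
    generate_series,
    total_uncertainty,
)


@pytest.fixture(scope="module")
def fitted_problem(small_basis, constants, fast_quadrature):
    sc = SyntheticScenario(noise_rel_std=0.0, seed=8)
    ds = generate_series(sc, small_basis, constants, fast_quadrature)
    spec = average_dilutions(extinction_from_transmittance(ds.series))
    return ds, spec


class TestCovariancePsi:
    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_doubling_uncertainties_doubles_stds(self, fitted_problem,
                                                 small_basis, constants,
                                                 fast_quadrature):
        """With the CBC term switched off, u(y) -> 2u(y) doubles every std."""
        ds, spec = fitted_problem
        from dataclasses import replace

        loose_cbc = replace(ds.cbc, mcv_u=1e9, rdw_u=1e9)  # w_CBC ~ 0
        r1 = covariance_psi(ds.params_true, spec, loose_cbc, small_basis,
                            constants, fast_quadrature)
        spec2 = ExtinctionSpectrum(
            spec.lam_nm, spec.cext_um2, 2 * spec.u_cext_um2
        )
        r2 = covariance_psi(ds.params_true, spec2, loose_cbc, small_basis,
                            constants, fast_quadrature)
        s1 = np.sqrt(np.diag(r1.Sigma_psi))
        s2 = np.sqrt(np.diag(r2.Sigma_psi))
        assert s2 == pytest.approx(2 * s1, rel=1e-4)

    def test_symmetric_and_psd(self, fitted_problem, small_basis, constants,
                               fast_quadrature):
        ds, spec = fitted_problem
        rep = covariance_psi(ds.params_true, spec, ds.cbc, small_basis,
                             constants, fast_quadrature)
        S = rep.Sigma_psi
        assert np.abs(S - S.T).max() == 0.0
        evals = np.linalg.eigvalsh(S)
        assert evals.min() >= -1e-10 * evals.max()
        assert rep.u_alpha.shape == small_basis.lam_grid.shape


class TestAlphaCovariance:
    def test_identity_gives_GGT(self, small_basis):
        S = alpha_covariance(np.eye(small_basis.n_coefs), small_basis)
        assert S == pytest.approx(small_basis.G @ small_basis.G.T)

    def test_rank_bounded_by_M(self, small_basis):
        S = alpha_covariance(np.eye(small_basis.n_coefs), small_basis)
        assert np.linalg.matrix_rank(S) <= small_basis.n_coefs

    def test_matches_direct_monte_carlo(self, small_basis):
        """G Sigma G^T vs sampling a ~ N(a0, Sigma) and propagating."""
        rng = np.random.default_rng(12)
        m = small_basis.n_coefs
        A = rng.standard_normal((m, m)) * 0.01
        Sigma_a = A @ A.T
        S = alpha_covariance(Sigma_a, small_basis)
        draws = rng.multivariate_normal(np.zeros(m), Sigma_a, size=200_000)
        emp = np.var(draws @ small_basis.G.T, axis=0, ddof=1)
        assert emp == pytest.approx(np.diag(S), rel=0.01)

    def test_shape_mismatch(self, small_basis):
        with pytest.raises(ValueError):
            alpha_covariance(np.eye(3), small_basis)


class TestCombineSamples:
    def test_identical_curves_zero_variance(self):
        a = np.full(5, 0.22)
        mean, var = combine_samples([a, a, a])
        assert mean == pytest.approx(a)
        assert np.all(var == 0.0)

    def test_two_sample_hand_arithmetic(self):
        # values 0.21 and 0.23: mean 0.22, Sigma_ii = 2e-4/2 = 1e-4, std 0.01
        mean, var = combine_samples([np.array([0.21]), np.array([0.23])])
        assert mean[0] == pytest.approx(0.22)
        assert var[0] == pytest.approx(1e-4)
        assert np.sqrt(var[0]) == pytest.approx(0.01)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        curves = list(0.22 + 0.01 * rng.standard_normal((5, 9)))
        m1, v1 = combine_samples(curves)
        m2, v2 = combine_samples(curves[::-1])
        assert m1 == pytest.approx(m2)
        assert v1 == pytest.approx(v2)

    def test_single_sample_flagged(self):
        with pytest.raises(ValueError):
            combine_samples([np.ones(3)])

    def test_variance_shrinks_with_sample_count(self):
        rng = np.random.default_rng(31)
        pool = 0.22 + 0.01 * rng.standard_normal((40, 7))
        _, v_small = combine_samples(list(pool[:10]))
        _, v_large = combine_samples(list(pool))
        # SEM^2 scales ~1/P for same population spread
        assert v_large.mean() < v_small.mean()


class TestSystematicsExceedLinearizedBand:
    def test_spectral_tilt_bias_inflates_between_sample_spread(
        self, small_basis, constants, fast_quadrature
    ):
        """The Gauss-Newton band covers spectral noise and CBC uncertainty
        only; when per-sample systematic errors (here +-2% spectral tilts)
        dominate the noise, the empirical between-sample spread of the
        retrieved alpha exceeds the linearized band."""
        from rbc_rispec import FitConfig, SyntheticScenario, fit, generate_series

        ds = generate_series(
            SyntheticScenario(seed=9), small_basis, constants, fast_quadrature
        )
        clean = ds.reference.cext_um2
        lam = small_basis.lam_grid
        u = 0.0005 * clean  # high-quality repeated-measurement noise level
        tilt = (lam - lam.mean()) / (lam[-1] - lam[0])
        config = FitConfig(
            n_starts=1, n_survivors=1, stage1_iters=5, stage2_iters=40,
            seed=0, quadrature=fast_quadrature,
        )
        rng = np.random.default_rng(13)
        alphas = []
        for bias in (-0.02, -0.01, 0.01, 0.02):
            y = clean * (1 + bias * tilt) + u * rng.standard_normal(lam.size)
            res = fit(
                ExtinctionSpectrum(lam, y, u), ds.cbc, config, small_basis,
                constants, initial_psi=ds.params_true,
            )
            alphas.append(res.alpha_hat)
        spread = np.vstack(alphas).std(axis=0, ddof=1)
        rep = covariance_psi(
            ds.params_true, ExtinctionSpectrum(lam, clean, u), ds.cbc,
            small_basis, constants, fast_quadrature,
        )
        assert np.median(spread) > np.median(rep.u_alpha)


class TestTotalUncertainty:
    def test_zero_systematic_term(self):
        var = np.array([1e-6, 4e-6])
        assert total_uncertainty(var, 0.0) == pytest.approx(np.sqrt(var))

    def test_pure_medium_term(self):
        # dalpha/dn = 3 mL/g with u[n_m] = 3e-4 -> 9e-4 mL/g
        u = total_uncertainty(np.zeros(3), 9e-4)
        assert u == pytest.approx(np.full(3, 9e-4))

    def test_dominates_each_component(self):
        var = np.array([1e-6])
        u = total_uncertainty(var, 9e-4)
        assert u[0] >= np.sqrt(var[0]) and u[0] >= 9e-4

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            total_uncertainty(np.array([-1.0]), 0.0)
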