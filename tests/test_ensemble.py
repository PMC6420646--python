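import numpy as np
import pytest

from rbc_rispec import (
    ForwardParams,
    PopulationParams,
    QuadratureConfig,
    SphereSpec,
    cbc_from_theta,
    ensemble_extinction,
    mie_extinction_cross_section,
    theta_from_cbc,
)
from rbc_rispec.splines import alpha_on_grid


def _params(basis, alpha_level=0.22, mchc=329.0, **kw):
    theta = theta_from_cbc(86.0, 12.7, mchc)
    a = basis.project(np.full(basis.lam_grid.size, alpha_level))
    defaults = dict(
        a=a, sigma_cHb=theta.sigma_cHb, mu_R=theta.mu_R,
        sigma_R=theta.sigma_R, eta=0.0, mchc_fixed=mchc,
    )
    defaults.update(kw)
    return ForwardParams(**defaults)


class TestEnsembleExtinction:
    def test_delta_limits_reduce_to_single_sphere(self, basis5, constants):
        p = _params(basis5, sigma_cHb=0.0, sigma_R=0.0)
        cbar = ensemble_extinction(basis5.lam_grid, p, constants, basis5)
        r = np.exp(p.mu_R)
        for i in (5, 60, 130):
            lam = basis5.lam_grid[i]
            n_p = complex(
                constants.n_water(lam) + p.mchc_fixed * 0.22e-3,
                p.mchc_fixed * constants.gamma(lam) * 1e-3,
            )
            single = mie_extinction_cross_section(
                SphereSpec(r, n_p, float(constants.n_medium(lam)), lam)
            )
            assert cbar[i] == pytest.approx(single, rel=1e-6)

    def test_eta_is_exact_prefactor(self, basis5, constants, fast_quadrature):
        p0 = _params(basis5)
        p5 = _params(basis5, eta=0.05)
        c0 = ensemble_extinction(
            basis5.lam_grid, p0, constants, basis5, fast_quadrature
        )
        c5 = ensemble_extinction(
            basis5.lam_grid, p5, constants, basis5, fast_quadrature
        )
        assert c5 == pytest.approx(1.05 * c0, rel=1e-14)

    def test_quadrature_matches_dense_trapezoid(self, basis5, constants):
        """16x16 Gauss quadrature vs a 2001x2001 trapezoid oracle."""
        from rbc_rispec.mie import mie_qext_batch

        p = _params(basis5)
        idx = np.linspace(3, basis5.lam_grid.size - 4, 10).astype(int)
        lam_sel = basis5.lam_grid[idx]
        cbar = ensemble_extinction(basis5.lam_grid, p, constants, basis5)[idx]

        n_grid = 2001
        c = np.linspace(
            p.mchc_fixed - 5 * p.sigma_cHb, p.mchc_fixed + 5 * p.sigma_cHb, n_grid
        )
        qc = np.exp(-0.5 * ((c - p.mchc_fixed) / p.sigma_cHb) ** 2)
        qc /= np.trapezoid(qc, c)
        u = np.linspace(p.mu_R - 5 * p.sigma_R, p.mu_R + 5 * p.sigma_R, n_grid)
        ru = np.exp(-0.5 * ((u - p.mu_R) / p.sigma_R) ** 2)
        ru /= np.trapezoid(ru, u)
        R = np.exp(u)

        for lam, expect in zip(lam_sel, cbar):
            n_med = float(constants.n_medium(lam))
            gam = float(constants.gamma(lam))
            n_w = float(constants.n_water(lam))
            x = 2 * np.pi * R * n_med / (lam * 1e-3)
            m = (n_w + c * 0.22e-3 + 1j * c * gam * 1e-3) / n_med
            # C(R, c) factorizes through the kernel on the outer product grid
            X = np.repeat(x, n_grid)
            M = np.tile(m, n_grid)
            q = mie_qext_batch(X, M).reshape(n_grid, n_grid)
            cext = q * np.pi * R[:, None] ** 2
            inner = np.trapezoid(cext * qc[None, :], c, axis=1)
            dense = np.trapezoid(inner * ru, u)
            assert expect == pytest.approx(dense, rel=1e-4)

    def test_positive_and_smoother_than_single_cell(self, basis5, constants):
        p = _params(basis5)
        cbar = ensemble_extinction(basis5.lam_grid, p, constants, basis5)
        assert np.all(cbar > 0)
        single = ensemble_extinction(
            basis5.lam_grid,
            _params(basis5, sigma_cHb=0.0, sigma_R=0.0),
            constants,
            basis5,
        )
        tv = lambda y: np.abs(np.diff(y)).sum()
        assert tv(cbar) < tv(single)

    def test_soret_gamma_dominates_sensitivity(self, basis5, constants, fast_quadrature):
        p = _params(basis5)
        c0 = ensemble_extinction(
            basis5.lam_grid, p, constants, basis5, fast_quadrature
        )
        boosted = constants.replace(
            gamma_oxy_table=1.10 * constants.gamma_oxy_table
        )
        c1 = ensemble_extinction(
            basis5.lam_grid, p, boosted, basis5, fast_quadrature
        )
        lam_max = basis5.lam_grid[np.argmax(np.abs(c1 - c0))]
        assert 400 <= lam_max <= 440

    def test_mchc_alpha_degeneracy(self, basis5, constants, fast_quadrature):
        """Scaling MCHC up and alpha down by 1.02 barely changes the spectrum."""
        p = _params(basis5)
        scaled = _params(
            basis5, mchc=329.0 * 1.02,
            a=p.a / 1.02,
            sigma_cHb=p.sigma_cHb,
        )
        c0 = ensemble_extinction(
            basis5.lam_grid, p, constants, basis5, fast_quadrature
        )
        c1 = ensemble_extinction(
            basis5.lam_grid, scaled, constants, basis5, fast_quadrature
        )
        rms = np.sqrt(np.mean(((c1 - c0) / c0) ** 2))
        assert rms < 0.005


class TestCBCMaps:
    def test_degenerate_lognormal_closed_form(self):
        theta = PopulationParams(329.0, 23.0, np.log(2.737), 0.0)
        mcv, rdw = cbc_from_theta(theta)
        assert mcv == pytest.approx(85.9, abs=0.1)
        assert rdw == 0.0

    def test_mcv_invariant_on_compensated_curve(self):
        # 3 mu + 4.5 sigma^2 = const leaves MCV unchanged
        const = 3 * np.log(2.737)
        for s in (0.0, 0.05, 0.1):
            mu = (const - 4.5 * s**2) / 3.0
            mcv, _ = cbc_from_theta(PopulationParams(329.0, 23.0, mu, s))
            assert mcv == pytest.approx(85.884, abs=1e-2)

    @pytest.mark.parametrize(
        "mcv,rdw", [(86.0, 12.7), (62.3, 15.7), (99.5, 12.5)]
    )
    def test_roundtrip_through_cbc(self, mcv, rdw):
        theta = theta_from_cbc(mcv, rdw, 330.0)
        got = cbc_from_theta(theta)
        assert got[0] == pytest.approx(mcv, abs=1e-8)
        assert got[1] == pytest.approx(rdw, abs=1e-8)

    def test_theta_roundtrip_exact(self):
        theta = PopulationParams(330.0, 20.0, np.log(2.7), 0.042)
        mcv, rdw = cbc_from_theta(theta)
        back = theta_from_cbc(mcv, rdw, 330.0, hdw_pct=20.0 / 330.0 * 100)
        assert back.mu_R == pytest.approx(theta.mu_R, abs=1e-10)
        assert back.sigma_R == pytest.approx(theta.sigma_R, abs=1e-10)

    def test_hdw_hand_arithmetic(self):
        theta = theta_from_cbc(86.0, 12.7, 330.0, hdw_pct=7.0)
        assert theta.sigma_cHb == pytest.approx(23.1)

    def test_rdw_limits(self):
        assert theta_from_cbc(86.0, 1e-9, 330.0).sigma_R == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(ValueError):
            theta_from_cbc(86.0, 120.0, 330.0)


class TestValidation:
    def test_quadrature_minimum_nodes(self):
        with pytest.raises(ValueError):
            QuadratureConfig(n_chb=4)

    def test_population_invariants(self):
        with pytest.raises(ValueError):
            PopulationParams(-1.0, 20.0, 1.0, 0.04)

    def test_eta_floor(self, basis5):
        with pytest.raises(ValueError):
            _params(basis5, eta=-1.5)
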