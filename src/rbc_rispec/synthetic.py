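"""Synthetic ground-truth spectra and transmittance dilution series.

Emulates the measurement chain end to end: a known real RI increment
alpha(lambda) (constant level ~0.22 mL/g plus an optional dispersion feature
near the Soret band), CBC-consistent size/concentration distributions, the
ensemble Mie forward model, Beer-Lambert transmittance T = exp(-Cbar d c) for
a dilution series spanning roughly T in [0.30, 0.95], multiplicative
log-normal detector noise, and an optional true concentration error eta that
rescales every reduced spectrum by (1 + eta).

Every generated dataset carries a truth record so inversion accuracy can be
measured exactly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import (
    CBCRecord,
    ForwardParams,
    QuadratureConfig,
    ensemble_extinction,
    theta_from_cbc,
)
from .materials import OpticalConstants
from .spectra import ExtinctionSpectrum, TransmittanceSeries
from .splines import RIIncrementExpansion, alpha_on_grid

__all__ = ["SyntheticScenario", "SyntheticDataset", "generate_alpha_truth",
           "generate_series"]

#: reference wavelength for dilution planning (mid-visible, off the Soret band)
REFERENCE_LAMBDA_NM = 500.0


@dataclass(frozen=True)
class SyntheticScenario:
    """Specification of one synthetic experiment.

    The alpha truth is ``alpha_level`` plus a dispersion-shaped feature
    (derivative-of-Gaussian) at ``feature_center_nm`` with the given
    peak-to-peak amplitude; both are projected into the spline basis so the
    truth is exactly representable.  CBC values default to a healthy adult
    sample; ``noise_rel_std`` is the per-wavelength relative standard
    deviation of the multiplicative transmittance noise.
    """

    alpha_level: float = 0.22            # mL/g
    feature_center_nm: float = 420.0
    feature_width_nm: float = 18.0
    feature_pp: float = 0.06             # peak-to-peak amplitude, mL/g
    mchc_g_per_L: float = 329.0
    mcv_fL: float = 86.0
    rdw_pct: float = 12.7
    hdw_pct: float = 7.0
    c_rbc_per_pL: float = 4.6
    dilution_phi: float = 1670.0
    path_mm: float = 10.0
    n_dilutions: int = 6
    t_span: tuple = (0.30, 0.95)
    noise_rel_std: float = 0.0
    eta_true: float = 0.0
    seed: int = 0

    def cbc(self) -> CBCRecord:
        return CBCRecord(
            c_rbc_per_pL=self.c_rbc_per_pL,
            mchc_g_per_L=self.mchc_g_per_L,
            mcv_fL=self.mcv_fL,
            rdw_pct=self.rdw_pct,
            hdw_pct=self.hdw_pct,
            dilution_phi=self.dilution_phi,
        )

    def theta(self):
        return theta_from_cbc(
            self.mcv_fL, self.rdw_pct, self.mchc_g_per_L, self.hdw_pct
        )


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated series plus the exact generating truth."""

    series: TransmittanceSeries
    reference: ExtinctionSpectrum     # noiseless (1+eta)-free ensemble spectrum
    alpha_true: np.ndarray            # on the working grid, mL/g
    a_true: np.ndarray                # orthonormal-basis coefficients
    params_true: ForwardParams
    cbc: CBCRecord


def generate_alpha_truth(scenario: SyntheticScenario, basis: RIIncrementExpansion):
    """Truth alpha(lambda) on the basis grid, exactly basis-representable.

    Returns ``(alpha_values, a_coefficients)``.  The dispersion feature is the
    first derivative of a Gaussian, scaled to the requested peak-to-peak
    amplitude — the characteristic S-shape of anomalous dispersion across an
    absorption band.
    """
    lam = basis.lam_grid
    curve = np.full(lam.size, scenario.alpha_level)
    if scenario.feature_pp > 0:
        t = (lam - scenario.feature_center_nm) / scenario.feature_width_nm
        shape = -t * np.exp(-0.5 * t**2)          # S-curve, extrema at t=+-1
        shape /= shape.max() - shape.min()        # unit peak-to-peak
        curve = curve + scenario.feature_pp * shape
    a = basis.project(curve)
    return alpha_on_grid(basis, a), a


def generate_series(
    scenario: SyntheticScenario,
    basis: RIIncrementExpansion,
    constants: OpticalConstants,
    quadrature: QuadratureConfig = QuadratureConfig(),
) -> SyntheticDataset:
    """Generate a transmittance dilution series with known ground truth.

    Dilution concentrations are chosen so the noiseless transmittance of the
    most dilute and most concentrated samples hit ``t_span`` at the reference
    wavelength (500 nm), with intermediate dilutions log-spaced in -ln T.
    """
    lam = basis.lam_grid
    alpha_true, a_true = generate_alpha_truth(scenario, basis)
    theta = scenario.theta()
    params = ForwardParams(
        a=a_true,
        sigma_cHb=theta.sigma_cHb,
        mu_R=theta.mu_R,
        sigma_R=theta.sigma_R,
        eta=scenario.eta_true,
        mchc_fixed=scenario.mchc_g_per_L,
    )
    cbar = ensemble_extinction(
        lam, params, constants, basis, quadrature, alpha_values=alpha_true
    ) / (1.0 + scenario.eta_true)  # bare ensemble spectrum, no prefactor

    c_ref = np.interp(REFERENCE_LAMBDA_NM, lam, cbar)
    d_um = scenario.path_mm * 1e3
    t_lo, t_hi = min(scenario.t_span), max(scenario.t_span)
    if not (0 < t_lo < t_hi <= 1):
        raise ValueError("infeasible transmittance span")
    # optical depths at the reference wavelength, log-spaced dilutions
    tau = np.geomspace(-np.log(t_hi), -np.log(t_lo), scenario.n_dilutions)
    c_nominal = tau / (c_ref * d_um)              # nominal concentrations um^-3
    c_actual = c_nominal * (1.0 + scenario.eta_true)

    rng = np.random.default_rng(scenario.seed)
    T = np.exp(-cbar[None, :] * d_um * c_actual[:, None])
    if scenario.noise_rel_std > 0:
        s = scenario.noise_rel_std
        sigma_log = np.sqrt(np.log1p(s**2))
        noise = rng.lognormal(
            mean=-0.5 * sigma_log**2, sigma=sigma_log, size=T.shape
        )
        T = np.minimum(T * noise, 1.0)

    series = TransmittanceSeries(
        lam_nm=lam,
        transmittance=T,
        cell_conc_um3=c_nominal,
        path_mm=scenario.path_mm,
    )
    reference = ExtinctionSpectrum(
        lam_nm=lam,
        cext_um2=cbar,
        u_cext_um2=np.maximum(scenario.noise_rel_std, 0.005) * cbar,
    )
    return SyntheticDataset(
        series=series,
        reference=reference,
        alpha_true=alpha_true,
        a_true=a_true,
        params_true=params,
        cbc=scenario.cbc(),
    )
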