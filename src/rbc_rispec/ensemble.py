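"""Ensemble-averaged extinction of a polydisperse RBC suspension.

The measured quantity is the average of the single-sphere extinction cross
section over the joint distribution of cell radius R and intracellular Hb
concentration c_Hb, assumed independent:

    Cbar_ext(lambda) = int int C(lambda; c_Hb, R) q(c_Hb) r(R) dc_Hb dR,

with q normal (mean MCHC, width sigma_cHb) and r log-normal in R with
parameters (mu_R, sigma_R) of ln R.  The forward model adds a free scale
factor absorbing cell-number-concentration errors:

    M(lambda; psi) = (1 + eta) * Cbar_ext(lambda; a, theta).

The c_Hb integral uses Gauss-Hermite quadrature (16 nodes), the R integral
Gauss-Legendre on ln R over mu_R +/- 5 sigma_R (16 nodes); weights are
renormalized to unit mass so degenerate (sigma -> 0) limits are exact.

CBC summary statistics follow from log-normal moments:
MCV = (4 pi / 3) E[R^3] = (4 pi / 3) exp(3 mu_R + 4.5 sigma_R^2) and
RDW = std(V)/mean(V) = sqrt(exp(9 sigma_R^2) - 1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import OpticalConstants
from .mie import mie_qext_batch
from .splines import RIIncrementExpansion, alpha_on_grid

__all__ = [
    "PopulationParams",
    "ForwardParams",
    "CBCRecord",
    "QuadratureConfig",
    "ensemble_extinction",
    "cbc_from_theta",
    "theta_from_cbc",
]


@dataclass(frozen=True)
class PopulationParams:
    """Parameters theta of the size/concentration distributions.

    mu_cHb (= MCHC, g/L) and sigma_cHb (g/L) describe the normal q(c_Hb);
    mu_R (log-um) and sigma_R the log-normal r(R) of the radius.
    """

    mu_cHb: float
    sigma_cHb: float
    mu_R: float
    sigma_R: float

    def __post_init__(self):
        if self.mu_cHb <= 0:
            raise ValueError("mu_cHb must be positive")
        if self.sigma_cHb < 0 or self.sigma_R < 0:
            raise ValueError("distribution widths must be non-negative")


@dataclass(frozen=True)
class ForwardParams:
    """Free parameter vector psi = (a, theta_2..theta_4, eta) + fixed MCHC."""

    a: np.ndarray           # spline coefficients (orthonormal basis)
    sigma_cHb: float        # theta_2, g/L
    mu_R: float             # theta_3, log-um
    sigma_R: float          # theta_4
    eta: float              # concentration-error prefactor parameter
    mchc_fixed: float       # theta_1, g/L, held at the CBC value

    def __post_init__(self):
        if 1.0 + self.eta <= 0:
            raise ValueError("1 + eta must be positive")

    @property
    def theta(self) -> PopulationParams:
        return PopulationParams(
            self.mchc_fixed, self.sigma_cHb, self.mu_R, self.sigma_R
        )


@dataclass(frozen=True)
class CBCRecord:
    """Complete-blood-count side information for one sample."""

    c_rbc_per_pL: float
    mchc_g_per_L: float
    mcv_fL: float
    rdw_pct: float
    mchc_u: float = 6.0
    mcv_u: float = 1.0
    rdw_u: float = 1.0
    hdw_pct: float | None = None
    dilution_phi: float = 1.0

    def __post_init__(self):
        for name in ("c_rbc_per_pL", "mchc_g_per_L", "mcv_fL", "rdw_pct",
                     "mchc_u", "mcv_u", "rdw_u", "dilution_phi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def cell_concentration_um3(self) -> float:
        """Diluted cell number concentration, um^-3 (1 pL = 1e9 um^3)."""
        return self.c_rbc_per_pL / self.dilution_phi * 1e-9


@dataclass(frozen=True)
class QuadratureConfig:
    """Node counts for the (c_Hb, R) double quadrature."""

    n_chb: int = 16
    n_radius: int = 16
    n_sigma_range: float = 5.0

    def __post_init__(self):
        if self.n_chb < 8 or self.n_radius < 8:
            raise ValueError("quadrature node counts must be >= 8")


def _chb_nodes(mu, sigma, n):
    """Gauss-Hermite nodes/weights for the normal c_Hb density (unit mass)."""
    if sigma == 0.0:
        return np.array([mu]), np.array([1.0])
    t, w = np.polynomial.hermite.hermgauss(n)
    c = mu + np.sqrt(2.0) * sigma * t
    w = w / np.sqrt(np.pi)
    keep = c > 0  # the density is supported on (0, inf); truncated mass ~0
    c, w = c[keep], w[keep]
    return c, w / w.sum()


def _radius_nodes(mu_R, sigma_R, n, n_sigma):
    """Gauss-Legendre nodes/weights in u = ln R against the normal density."""
    if sigma_R == 0.0:
        return np.array([np.exp(mu_R)]), np.array([1.0])
    t, w = np.polynomial.legendre.leggauss(n)
    half = n_sigma * sigma_R
    u = mu_R + half * t
    dens = np.exp(-0.5 * ((u - mu_R) / sigma_R) ** 2) / (
        sigma_R * np.sqrt(2.0 * np.pi)
    )
    wu = w * half * dens
    return np.exp(u), wu / wu.sum()


def ensemble_extinction(
    lam_grid,
    params: ForwardParams,
    constants: OpticalConstants,
    basis: RIIncrementExpansion | None = None,
    quadrature: QuadratureConfig = QuadratureConfig(),
    alpha_values=None,
):
    """Forward model M(lambda; psi) = (1+eta) Cbar_ext(lambda), um^2.

    ``alpha_values`` may be passed directly (mL/g on ``lam_grid``); otherwise
    it is reconstructed from ``params.a`` through ``basis``.
    """
    lam = np.asarray(lam_grid, dtype=float)
    if alpha_values is None:
        if basis is None:
            raise ValueError("either a basis or explicit alpha_values is required")
        alpha_values = alpha_on_grid(basis, params.a)
    alpha_values = np.asarray(alpha_values, dtype=float)
    if alpha_values.shape != lam.shape:
        raise ValueError("alpha_values must match the wavelength grid")

    c_nodes, c_w = _chb_nodes(params.mchc_fixed, params.sigma_cHb, quadrature.n_chb)
    r_nodes, r_w = _radius_nodes(
        params.mu_R, params.sigma_R, quadrature.n_radius, quadrature.n_sigma_range
    )

    n_wat = constants.n_water(lam)
    n_med = constants.n_medium(lam)
    gam = constants.gamma(lam)
    lam_um = lam * 1e-3

    nl, nr, nc = lam.size, r_nodes.size, c_nodes.size
    # particle relative index: (lambda, c); size parameter: (lambda, R)
    n_part = (
        n_wat[:, None]
        + c_nodes[None, :] * alpha_values[:, None] * 1e-3
        + 1j * c_nodes[None, :] * gam[:, None] * 1e-3
    )
    m_rel = n_part / n_med[:, None]                      # (nl, nc)
    x = 2.0 * np.pi * r_nodes[None, :] * n_med[:, None] / lam_um[:, None]  # (nl, nr)

    x_flat = np.broadcast_to(x[:, :, None], (nl, nr, nc)).ravel()
    m_flat = np.broadcast_to(m_rel[:, None, :], (nl, nr, nc)).ravel()
    qext = mie_qext_batch(
        np.ascontiguousarray(x_flat), np.ascontiguousarray(m_flat)
    ).reshape(nl, nr, nc)
    cext = qext * (np.pi * r_nodes[None, :, None] ** 2)
    cbar = np.einsum("lrc,r,c->l", cext, r_w, c_w)
    return (1.0 + params.eta) * cbar


def cbc_from_theta(theta: PopulationParams):
    """Map theta to (MCV in fL, RDW in %) via log-normal moments."""
    mcv = (4.0 * np.pi / 3.0) * np.exp(3.0 * theta.mu_R + 4.5 * theta.sigma_R**2)
    rdw = np.sqrt(np.expm1(9.0 * theta.sigma_R**2)) * 100.0
    return float(mcv), float(rdw)


def theta_from_cbc(mcv_fL, rdw_pct, mchc_g_per_L, hdw_pct=7.0) -> PopulationParams:
    """Invert the CBC summary statistics to distribution parameters.

    HDW (relative width of the c_Hb distribution, %) is not part of the
    standard CBC; the default 7% matches the typical cell-to-cell spread.
    """
    if not 0 <= rdw_pct < 100:
        raise ValueError("RDW must lie in [0, 100) percent")
    rdw = rdw_pct / 100.0
    sigma_R = np.sqrt(np.log1p(rdw**2)) / 3.0
    mu_R = (np.log(3.0 * mcv_fL / (4.0 * np.pi)) - 4.5 * sigma_R**2) / 3.0
    sigma_chb = hdw_pct / 100.0 * mchc_g_per_L
    return PopulationParams(mchc_g_per_L, float(sigma_chb), float(mu_R), float(sigma_R))
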