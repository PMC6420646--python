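"""Mie extinction of a homogeneous sphere.

Standard Lorenz-Mie series for a homogeneous (possibly absorbing) sphere in a
non-absorbing host.  The series is truncated at the Wiscombe criterion
n_max = ceil(x + 4 x^(1/3) + 2); the logarithmic derivative of the
Riccati-Bessel function of the internal argument m*x is obtained by downward
recurrence started 15 orders above n_max, and psi/chi of the real size
parameter by upward recurrence (BHMIE convention).  Cross sections depend on
(R, lambda, n) only through the size parameter x = 2 pi R n_medium / lambda
and the relative refractive index m = n_particle / n_medium.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "SphereSpec",
    "mie_extinction_cross_section",
    "mie_efficiencies",
    "mie_qext_batch",
]

#: hard cap on series terms; x beyond ~6000 is outside this package's regime
_MAX_TERMS = 10_000


@njit(cache=True, fastmath=True)
def _mie_q_single(x, m):  # pragma: no cover - exercised via wrappers
    """Return (Qext, Qsca) for size parameter x and relative index m."""
    nmax = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    z = m * x
    # downward recurrence for D_n(z) = psi_n'(z)/psi_n(z)
    nstart = nmax + 15
    D = np.empty(nmax + 1, dtype=np.complex128)
    d = 0.0 + 0.0j
    for n in range(nstart, 0, -1):
        d = n / z - 1.0 / (d + n / z)
        if n - 1 <= nmax:
            D[n - 1] = d
    # upward recurrence for Riccati-Bessel psi, chi of real x
    psi_nm1 = np.cos(x)   # psi_{-1}
    psi_n = np.sin(x)     # psi_0
    chi_nm1 = -np.sin(x)  # chi_{-1}
    chi_n = np.cos(x)     # chi_0
    qext = 0.0
    qsca = 0.0
    for n in range(1, nmax + 1):
        psi = (2.0 * n - 1.0) / x * psi_n - psi_nm1
        chi = (2.0 * n - 1.0) / x * chi_n - chi_nm1
        xi = psi - 1j * chi
        xi_nm1 = psi_n - 1j * chi_n
        da = D[n] / m + n / x
        db = D[n] * m + n / x
        an = (da * psi - psi_n) / (da * xi - xi_nm1)
        bn = (db * psi - psi_n) / (db * xi - xi_nm1)
        fac = 2.0 * n + 1.0
        qext += fac * (an.real + bn.real)
        qsca += fac * (an.real ** 2 + an.imag ** 2 + bn.real ** 2 + bn.imag ** 2)
        psi_nm1, psi_n = psi_n, psi
        chi_nm1, chi_n = chi_n, chi
    qext *= 2.0 / (x * x)
    qsca *= 2.0 / (x * x)
    return qext, qsca


@njit(cache=True, fastmath=True)
def mie_qext_batch(x, m):  # pragma: no cover - thin loop over the kernel
    """Vectorized extinction efficiency: x (float array), m (complex array)."""
    out = np.empty(x.shape[0])
    for i in range(x.shape[0]):
        out[i] = _mie_q_single(x[i], m[i])[0]
    return out


@dataclass(frozen=True)
class SphereSpec:
    """One homogeneous sphere: radius (um), complex particle RI, real host RI
    and vacuum wavelength (nm)."""

    radius_um: float
    n_particle: complex
    n_medium: float
    lam_nm: float

    def __post_init__(self):
        if not (
            np.isfinite(self.radius_um)
            and np.isfinite(self.n_medium)
            and np.isfinite(self.n_particle)
        ):
            raise ValueError("non-finite sphere specification")
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")
        if self.n_medium <= 0:
            raise ValueError("medium RI must be positive")
        if self.n_particle.imag < 0:
            raise ValueError("Im(n_particle) must be >= 0")

    @property
    def size_parameter(self) -> float:
        return 2.0 * np.pi * self.radius_um * self.n_medium / (self.lam_nm * 1e-3)

    @property
    def relative_index(self) -> complex:
        return self.n_particle / self.n_medium


def mie_efficiencies(spec: SphereSpec):
    """Return (Qext, Qsca) for a sphere."""
    x = spec.size_parameter
    if x <= 0:
        raise ValueError("size parameter must be positive")
    if x + 4 * x ** (1 / 3) + 2 > _MAX_TERMS:
        raise ValueError("size parameter too large for the configured term cap")
    qext, qsca = _mie_q_single(float(x), complex(spec.relative_index))
    return float(qext), float(qsca)


def mie_extinction_cross_section(spec: SphereSpec) -> float:
    """Extinction cross section C_ext in um^2."""
    qext, _ = mie_efficiencies(spec)
    return float(qext * np.pi * spec.radius_um**2)
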