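"""Cubic B-spline representation of the real RI increment alpha(lambda).

alpha(lambda) is expanded over M orthonormalized cubic (third-order, C^2)
cardinal B-splines on a uniform knot grid (default spacing 10 nm) covering the
working wavelength range:

    alpha(lambda_i) = sum_j a_j g_j(lambda_i)   i.e.   alpha = G a,

where G is the N x M matrix of basis functions on the working grid,
orthonormal under the unweighted discrete inner product (G^T G = I).
Orthonormalization is a QR factorization of the raw B-spline design matrix B:
B = G R with R upper triangular, so raw coefficients b and orthonormal
coefficients a describe the same curve via a = R b.  The raw basis has local
support (each column of B spans four knot intervals), which the fitter
exploits for sparse finite-difference Jacobians; the orthonormal basis is the
reporting/covariance basis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["RIIncrementExpansion", "build_basis", "alpha_on_grid", "default_grid"]

_ORDER = 4  # cubic


def default_grid(lam_min=290.0, lam_max=1100.0, step=2.0):
    """Uniform working wavelength grid in nm (default 2 nm on [290, 1100])."""
    return np.arange(lam_min, lam_max + 1e-9, step)


@dataclass(frozen=True)
class RIIncrementExpansion:
    """Spline basis for alpha(lambda) on a fixed wavelength grid.

    Attributes
    ----------
    lam_grid : (N,) nm working grid.
    knots : full (padded) knot vector, nm.
    B : (N, M) raw cubic B-spline design matrix (local support).
    G : (N, M) orthonormalized basis, G^T G = I.
    R : (M, M) upper-triangular map with B = G R; a = R b.
    """

    lam_grid: np.ndarray
    knots: np.ndarray
    B: np.ndarray
    G: np.ndarray
    R: np.ndarray
    knot_spacing: float

    @property
    def n_coefs(self) -> int:
        return self.B.shape[1]

    def raw_to_ortho(self, b):
        """Map raw B-spline coefficients to orthonormal-basis coefficients."""
        return self.R @ np.asarray(b, dtype=float)

    def ortho_to_raw(self, a):
        """Inverse map (solve the triangular system R b = a)."""
        from scipy.linalg import solve_triangular

        return solve_triangular(self.R, np.asarray(a, dtype=float), lower=False)

    def project(self, alpha_values):
        """Least-squares coefficients a of a curve sampled on ``lam_grid``."""
        return self.G.T @ np.asarray(alpha_values, dtype=float)

    def export_csv(self, path):
        """Write the orthonormal basis matrix G (rows = wavelengths) to CSV."""
        import pandas as pd

        df = pd.DataFrame(
            self.G, columns=[f"g{j}" for j in range(self.n_coefs)]
        )
        df.insert(0, "wavelength_nm", self.lam_grid)
        df.to_csv(path, index=False)


def build_basis(lam_grid, knot_spacing=10.0) -> RIIncrementExpansion:
    """Build the orthonormalized cubic B-spline basis on ``lam_grid``.

    Knots are uniform with ``knot_spacing`` covering [min, max] of the grid and
    extended three intervals beyond each edge so the basis is complete there.
    For [290, 1100] nm at 10 nm spacing this yields M = 81 + 3 = 84 functions.
    """
    lam = np.asarray(lam_grid, dtype=float)
    if lam.ndim != 1 or lam.size < 2 or np.any(np.diff(lam) <= 0):
        raise ValueError("lam_grid must be strictly increasing")
    lo, hi = lam[0], lam[-1]
    n_int = int(np.ceil((hi - lo) / knot_spacing - 1e-9))
    if n_int < 1:
        raise ValueError("grid narrower than one knot interval")
    knots = lo + knot_spacing * np.arange(-(_ORDER - 1), n_int + _ORDER)
    n_basis = len(knots) - _ORDER
    if lam.size < n_basis:
        raise ValueError(
            f"grid has {lam.size} points but the basis needs >= {n_basis}"
        )
    B = BSpline.design_matrix(lam, knots, _ORDER - 1, extrapolate=False).toarray()
    G, R = np.linalg.qr(B)
    # fix QR sign ambiguity so diag(R) > 0 (deterministic basis)
    sign = np.sign(np.diag(R))
    sign[sign == 0] = 1.0
    G = G * sign
    R = R * sign[:, None]
    return RIIncrementExpansion(
        lam_grid=lam, knots=knots, B=B, G=G, R=R, knot_spacing=float(knot_spacing)
    )


def alpha_on_grid(expansion: RIIncrementExpansion, a):
    """Evaluate alpha = G a on the expansion's wavelength grid (mL/g)."""
    a = np.asarray(a, dtype=float)
    if a.shape != (expansion.n_coefs,):
        raise ValueError(
            f"coefficient vector must have length {expansion.n_coefs}, got {a.shape}"
        )
    return expansion.G @ a
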