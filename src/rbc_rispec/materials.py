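"""Optical constants of the cell interior and suspending medium.

The complex refractive index of a red blood cell is modelled as that of an
aqueous hemoglobin solution,

    n(lambda, c_Hb) = n_H2O(lambda) + c_Hb * [alpha(lambda) + i gamma(lambda)],

where ``alpha`` and ``gamma`` are the real and imaginary refractive-index
increments with Hb mass concentration (mL/g) and ``c_Hb`` is in g/L (the
product carries a factor 1e-3 since g/L x mL/g = 1e-3).  The suspending
medium (sphering reagent) is water plus a small constant real offset.

Wavelengths are vacuum wavelengths in nm throughout.  Tabulated constants are
interpolated with a monotone-safe piecewise cubic (PCHIP); evaluation outside
the table range raises.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "OpticalConstants",
    "cell_complex_ri",
    "medium_ri",
    "gamma_from_attenuation",
    "hb_mass_to_molar",
    "HB_MOLAR_MASS_TETRAMER_G_PER_MOL",
]

#: Molar mass of the hemoglobin tetramer, g/mol; the subunit is one quarter.
HB_MOLAR_MASS_TETRAMER_G_PER_MOL = 64500.0


def gamma_from_attenuation(eps_mass, lam_nm):
    """Convert specific attenuation to the imaginary RI increment gamma.

    Parameters
    ----------
    eps_mass : array_like
        Decadic specific attenuation coefficient, L g^-1 cm^-1 (>= 0).
    lam_nm : array_like
        Vacuum wavelength in nm.

    Returns
    -------
    gamma : ndarray or float
        Imaginary RI increment in mL/g, via k = lambda * mu_a / (4 pi) with
        mu_a = ln(10) * eps_mass * c_Hb, i.e.
        gamma = ln(10) * eps_mass * lambda / (4 pi)  (lambda in cm, result
        converted from L/g to mL/g).
    """
    eps_mass = np.asarray(eps_mass, dtype=float)
    if np.any(eps_mass < 0):
        raise ValueError("specific attenuation must be non-negative")
    lam_cm = np.asarray(lam_nm, dtype=float) * 1e-7
    gamma_L_per_g = np.log(10.0) * eps_mass * lam_cm / (4.0 * np.pi)
    out = gamma_L_per_g * 1e3  # L/g -> mL/g
    return out if out.ndim else float(out)


def hb_mass_to_molar(c_hb, basis="monomer"):
    """Convert a hemoglobin mass concentration (g/L) to mM.

    ``basis`` selects the molar mass: ``"tetramer"`` uses 64.5 kg/mol,
    ``"monomer"`` (single Hb subunit, the laboratory-medicine convention)
    one quarter of that.
    """
    if c_hb < 0:
        raise ValueError("c_Hb must be non-negative")
    if basis == "tetramer":
        m = HB_MOLAR_MASS_TETRAMER_G_PER_MOL
    elif basis == "monomer":
        m = HB_MOLAR_MASS_TETRAMER_G_PER_MOL / 4.0
    else:
        raise ValueError(f"unknown basis {basis!r}; use 'monomer' or 'tetramer'")
    return c_hb / m * 1e3  # mol/L -> mM


def _interpolator(lam, val):
    return PchipInterpolator(lam, val, extrapolate=False)


@dataclass
class OpticalConstants:
    """Wavelength-tabulated optical constants.

    Attributes
    ----------
    wavelengths : ndarray
        Strictly increasing nm grid of the bundled tables.
    n_water_table, gamma_oxy_table, gamma_deoxy_table : ndarray
        Values on ``wavelengths``; gamma tables in mL/g.
    delta_n_medium : float
        Real RI offset of the suspending medium over water (default 0.002,
        the measured sphering-reagent offset).
    deoxy_fraction : float
        Fraction f in [0, 1] of deoxyHb in the gamma mixture
        gamma_mix = (1-f) gamma_oxy + f gamma_deoxy.
    """

    wavelengths: np.ndarray
    n_water_table: np.ndarray
    gamma_oxy_table: np.ndarray
    gamma_deoxy_table: np.ndarray | None = None
    delta_n_medium: float = 0.002
    deoxy_fraction: float = 0.0
    _n_water_ip: PchipInterpolator = field(init=False, repr=False)
    _gamma_oxy_ip: PchipInterpolator = field(init=False, repr=False)
    _gamma_deoxy_ip: PchipInterpolator | None = field(init=False, repr=False)

    def __post_init__(self):
        lam = np.asarray(self.wavelengths, dtype=float)
        if lam.ndim != 1 or lam.size < 4 or np.any(np.diff(lam) <= 0):
            raise ValueError("wavelengths must be a strictly increasing 1-d grid")
        if np.any(np.asarray(self.n_water_table) <= 1.0):
            raise ValueError("n_water must exceed 1 on the tabulated range")
        if np.any(np.asarray(self.gamma_oxy_table) < 0):
            raise ValueError("gamma_oxy must be non-negative")
        if not 0.0 <= self.deoxy_fraction <= 1.0:
            raise ValueError("deoxy_fraction must lie in [0, 1]")
        if self.deoxy_fraction > 0 and self.gamma_deoxy_table is None:
            raise ValueError("deoxy_fraction > 0 requires a deoxy gamma table")
        self.wavelengths = lam
        self._n_water_ip = _interpolator(lam, self.n_water_table)
        self._gamma_oxy_ip = _interpolator(lam, self.gamma_oxy_table)
        self._gamma_deoxy_ip = (
            _interpolator(lam, self.gamma_deoxy_table)
            if self.gamma_deoxy_table is not None
            else None
        )

    # -- table access -----------------------------------------------------
    def _eval(self, ip, lam_nm):
        out = ip(lam_nm)
        if np.any(np.isnan(out)):
            lo, hi = self.wavelengths[0], self.wavelengths[-1]
            raise ValueError(
                f"wavelength outside tabulated range [{lo:g}, {hi:g}] nm"
            )
        return out

    def n_water(self, lam_nm):
        """Real RI of water at ``lam_nm``."""
        return self._eval(self._n_water_ip, lam_nm)

    def gamma(self, lam_nm):
        """Mixture imaginary RI increment gamma_mix(lambda), mL/g."""
        g = self._eval(self._gamma_oxy_ip, lam_nm)
        f = self.deoxy_fraction
        if f > 0:
            g = (1.0 - f) * g + f * self._eval(self._gamma_deoxy_ip, lam_nm)
        return g

    def n_medium(self, lam_nm):
        """Real RI of the suspending medium: n_water + delta_n_medium."""
        return self.n_water(lam_nm) + self.delta_n_medium

    def replace(self, **kwargs) -> "OpticalConstants":
        """Return a copy with some fields replaced (e.g. delta_n_medium=0)."""
        fields = dict(
            wavelengths=self.wavelengths,
            n_water_table=self.n_water_table,
            gamma_oxy_table=self.gamma_oxy_table,
            gamma_deoxy_table=self.gamma_deoxy_table,
            delta_n_medium=self.delta_n_medium,
            deoxy_fraction=self.deoxy_fraction,
        )
        fields.update(kwargs)
        return OpticalConstants(**fields)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_tables(
        cls,
        water_ri_table,
        gamma_oxy_table,
        gamma_deoxy_table=None,
        delta_n_medium=0.002,
        deoxy_fraction=0.0,
    ) -> "OpticalConstants":
        """Build from CSV paths.

        The water table has columns (wavelength_nm, n_water); the gamma tables
        carry specific attenuation (wavelength_nm, eps_mass_L_per_g_cm) and are
        converted via :func:`gamma_from_attenuation`.  All tables must share
        one wavelength grid.
        """
        wat = pd.read_csv(water_ri_table)
        lam = wat.iloc[:, 0].to_numpy(float)
        oxy = pd.read_csv(gamma_oxy_table)
        if not np.array_equal(oxy.iloc[:, 0].to_numpy(float), lam):
            raise ValueError("gamma table grid differs from water table grid")
        g_oxy = gamma_from_attenuation(oxy.iloc[:, 1].to_numpy(float), lam)
        g_deoxy = None
        if gamma_deoxy_table is not None:
            deo = pd.read_csv(gamma_deoxy_table)
            if not np.array_equal(deo.iloc[:, 0].to_numpy(float), lam):
                raise ValueError("gamma table grid differs from water table grid")
            g_deoxy = gamma_from_attenuation(deo.iloc[:, 1].to_numpy(float), lam)
        return cls(
            wavelengths=lam,
            n_water_table=wat.iloc[:, 1].to_numpy(float),
            gamma_oxy_table=g_oxy,
            gamma_deoxy_table=g_deoxy,
            delta_n_medium=delta_n_medium,
            deoxy_fraction=deoxy_fraction,
        )

    @classmethod
    def default(cls, delta_n_medium=0.002, deoxy_fraction=0.0) -> "OpticalConstants":
        """Bundled tables: Sellmeier water RI plus synthetic Hb band models."""
        data = resources.files("rbc_rispec") / "data"
        return cls.from_tables(
            Path(str(data / "water_ri.csv")),
            Path(str(data / "hb_attenuation_oxy_synthetic.csv")),
            Path(str(data / "hb_attenuation_deoxy_synthetic.csv")),
            delta_n_medium=delta_n_medium,
            deoxy_fraction=deoxy_fraction,
        )


def cell_complex_ri(lam_nm, c_hb, alpha_at_lam, constants: OpticalConstants):
    """Complex RI of the cell interior at ``lam_nm``.

    Parameters
    ----------
    lam_nm : array_like
        Vacuum wavelength, nm (within the tabulated range).
    c_hb : float or array_like
        Intracellular Hb mass concentration, g/L (>= 0).
    alpha_at_lam : float or array_like
        Real RI increment alpha(lambda), mL/g, already evaluated at lam_nm.
    """
    c_hb = np.asarray(c_hb, dtype=float)
    if np.any(c_hb < 0):
        raise ValueError("c_Hb must be non-negative")
    n_re = constants.n_water(lam_nm) + c_hb * np.asarray(alpha_at_lam) * 1e-3
    n_im = c_hb * constants.gamma(lam_nm) * 1e-3
    return n_re + 1j * n_im


def medium_ri(lam_nm, constants: OpticalConstants):
    """Real RI of the suspending medium (water + constant offset)."""
    return constants.n_medium(lam_nm)
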