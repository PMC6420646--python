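"""Reduction of transmittance dilution series to extinction cross sections.

For a dilute suspension measured in a cuvette of path length d with cell
number concentration c_j (dilution j), single scattering gives

    Cbar_ext,j(lambda) = -ln T_j(lambda) / (d c_j),

with d in mm (converted to um internally), c in um^-3 and Cbar in um^2.
Agreement of the per-dilution curves is the experimental check that multiple
scattering is negligible; the per-sample spectrum analysed downstream is their
pointwise mean with a standard-error uncertainty.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TransmittanceSeries",
    "ExtinctionSpectrum",
    "extinction_from_transmittance",
    "check_single_scattering",
    "average_dilutions",
    "read_spectra_csv",
    "write_extinction_csv",
]

#: transmittance below this is treated as unusable (signal-starved)
T_FLOOR_DEFAULT = 0.01


@dataclass(frozen=True)
class TransmittanceSeries:
    """Collimated-transmittance dilution series on a common wavelength grid."""

    lam_nm: np.ndarray          # (N,)
    transmittance: np.ndarray   # (J, N), values in (0, 1]
    cell_conc_um3: np.ndarray   # (J,) number concentrations
    path_mm: float

    def __post_init__(self):
        lam = np.asarray(self.lam_nm, float)
        T = np.atleast_2d(np.asarray(self.transmittance, float))
        c = np.atleast_1d(np.asarray(self.cell_conc_um3, float))
        if T.shape != (c.size, lam.size):
            raise ValueError("transmittance must be (n_dilutions, n_wavelengths)")
        if np.any(T <= 0) or np.any(T > 1.0 + 1e-12):
            raise ValueError("transmittance must lie in (0, 1]")
        if np.any(c <= 0) or self.path_mm <= 0:
            raise ValueError("concentrations and path length must be positive")
        object.__setattr__(self, "lam_nm", lam)
        object.__setattr__(self, "transmittance", T)
        object.__setattr__(self, "cell_conc_um3", c)


@dataclass(frozen=True)
class ExtinctionSpectrum:
    """Ensemble extinction spectrum y_i with standard uncertainties u(y_i)."""

    lam_nm: np.ndarray
    cext_um2: np.ndarray
    u_cext_um2: np.ndarray
    usable: np.ndarray = None  # bool mask; False = excluded from fitting

    def __post_init__(self):
        lam = np.asarray(self.lam_nm, float)
        y = np.asarray(self.cext_um2, float)
        u = np.asarray(self.u_cext_um2, float)
        if y.shape != lam.shape or u.shape != lam.shape:
            raise ValueError("spectrum columns must share one grid")
        mask = (
            np.ones(lam.shape, bool)
            if self.usable is None
            else np.asarray(self.usable, bool)
        )
        object.__setattr__(self, "lam_nm", lam)
        object.__setattr__(self, "cext_um2", y)
        object.__setattr__(self, "u_cext_um2", u)
        object.__setattr__(self, "usable", mask)

    @property
    def weights(self):
        """Least-squares weights w_i = 1/u(y_i)^2."""
        return 1.0 / self.u_cext_um2**2


def extinction_from_transmittance(
    series: TransmittanceSeries, t_floor=T_FLOOR_DEFAULT
):
    """Reduce each dilution to an :class:`ExtinctionSpectrum`.

    Wavelengths with T below ``t_floor`` are kept but flagged unusable.
    Uncertainties are set later by :func:`average_dilutions`; here a
    placeholder of 1 um^2 is carried.
    """
    d_um = series.path_mm * 1e3
    out = []
    for T, c in zip(series.transmittance, series.cell_conc_um3):
        y = -np.log(T) / (d_um * c)
        out.append(
            ExtinctionSpectrum(
                lam_nm=series.lam_nm,
                cext_um2=y,
                u_cext_um2=np.ones_like(y),
                usable=T >= t_floor,
            )
        )
    return out


def check_single_scattering(spectra, tol=0.05):
    """Relative spread between per-dilution curves; pass iff <= tol.

    Returns ``(passed, max_relative_spread)``.  The spread at each wavelength
    is (max - min) / mean over dilutions, maximized over usable wavelengths.
    A single dilution yields ``(None, nan)`` (not applicable).
    """
    if len(spectra) < 2:
        return None, float("nan")
    _assert_common_grid(spectra)
    Y = np.vstack([s.cext_um2 for s in spectra])
    usable = np.all(np.vstack([s.usable for s in spectra]), axis=0)
    Yu = Y[:, usable]
    spread = (Yu.max(axis=0) - Yu.min(axis=0)) / Yu.mean(axis=0)
    worst = float(spread.max())
    return worst <= tol, worst


def average_dilutions(spectra, rel_floor=0.005):
    """Pointwise mean spectrum with standard-error uncertainties.

    u(y_i) is the standard error of the mean over dilutions, floored at
    ``rel_floor`` times the mean value.
    """
    _assert_common_grid(spectra)
    Y = np.vstack([s.cext_um2 for s in spectra])
    usable = np.all(np.vstack([s.usable for s in spectra]), axis=0)
    mean = Y.mean(axis=0)
    if Y.shape[0] > 1:
        se = Y.std(axis=0, ddof=1) / np.sqrt(Y.shape[0])
    else:
        se = np.zeros_like(mean)
    u = np.maximum(se, rel_floor * np.abs(mean))
    return ExtinctionSpectrum(
        lam_nm=spectra[0].lam_nm, cext_um2=mean, u_cext_um2=u, usable=usable
    )


def _assert_common_grid(spectra):
    lam0 = spectra[0].lam_nm
    for s in spectra[1:]:
        if not np.array_equal(s.lam_nm, lam0):
            raise ValueError("dilution spectra are on different wavelength grids")


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_spectra_csv(path, path_mm=None, cell_conc_um3=None):
    """Read either a transmittance series or a pre-reduced spectrum.

    Auto-detects by header: long-form (sample_id, dilution_id, wavelength_nm,
    transmittance) yields a :class:`TransmittanceSeries` (requires ``path_mm``
    and ``cell_conc_um3`` keyed by dilution order); columns (wavelength_nm,
    cext_um2, u_cext_um2) yield an :class:`ExtinctionSpectrum`.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"wavelength_nm", "cext_um2", "u_cext_um2"} <= cols:
        return ExtinctionSpectrum(
            df["wavelength_nm"].to_numpy(float),
            df["cext_um2"].to_numpy(float),
            df["u_cext_um2"].to_numpy(float),
        )
    if {"dilution_id", "wavelength_nm", "transmittance"} <= cols:
        if path_mm is None or cell_conc_um3 is None:
            raise ValueError(
                "transmittance input needs path_mm and per-dilution cell_conc_um3"
            )
        piv = df.pivot_table(
            index="dilution_id", columns="wavelength_nm", values="transmittance",
            sort=True,
        )
        return TransmittanceSeries(
            lam_nm=piv.columns.to_numpy(float),
            transmittance=piv.to_numpy(float),
            cell_conc_um3=np.asarray(cell_conc_um3, float),
            path_mm=float(path_mm),
        )
    raise ValueError(f"unrecognized spectra header: {sorted(cols)}")


def write_extinction_csv(path, spectrum: ExtinctionSpectrum):
    pd.DataFrame(
        {
            "wavelength_nm": spectrum.lam_nm,
            "cext_um2": spectrum.cext_um2,
            "u_cext_um2": spectrum.u_cext_um2,
            "usable": spectrum.usable.astype(int),
        }
    ).to_csv(path, index=False)


def resample_to_grid(spectrum: ExtinctionSpectrum, lam_grid):
    """Local linear interpolation of a spectrum onto a working grid."""
    lam_grid = np.asarray(lam_grid, float)
    if lam_grid[0] < spectrum.lam_nm[0] or lam_grid[-1] > spectrum.lam_nm[-1]:
        raise ValueError("working grid extends beyond the measured range")
    y = np.interp(lam_grid, spectrum.lam_nm, spectrum.cext_um2)
    u = np.interp(lam_grid, spectrum.lam_nm, spectrum.u_cext_um2)
    usable = np.interp(lam_grid, spectrum.lam_nm, spectrum.usable.astype(float)) >= 1.0
    return ExtinctionSpectrum(lam_grid, y, u, usable)
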