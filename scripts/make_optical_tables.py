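"""Regenerate the bundled optical-constant tables under src/rbc_rispec/data/.

* water_ri.csv — real refractive index of water from the Daimon & Masumura
  (2007) four-term Sellmeier dispersion at 21.5 degC, valid 182-1129 nm,
  sampled every 2 nm on 280-1110 nm.
* hb_attenuation_oxy_synthetic.csv / hb_attenuation_deoxy_synthetic.csv —
  SYNTHETIC specific-attenuation spectra eps_mass(lambda) in L g^-1 cm^-1 for
  oxygenated / deoxygenated hemoglobin: smooth analytic band models (Soret band
  near 420 nm, Q bands near 540/580 nm, weak NIR tail) with peak magnitudes
  taken from standard tabulations.  They are fixtures for testing the pipeline,
  not metrologically traceable reference data.
"""
from pathlib import Path

import numpy as np
import pandas as pd

DATA = Path(__file__).resolve().parents[1] / "src" / "rbc_rispec" / "data"


def water_ri(lam_nm):
    """Daimon & Masumura Sellmeier for water at 21.5 degC (lambda in nm)."""
    lam_um2 = (np.asarray(lam_nm, dtype=float) / 1e3) ** 2
    terms = [
        (5.684027565e-1, 5.101829712e-3),
        (1.726177391e-1, 1.821153936e-2),
        (2.086189578e-2, 2.620722293e-2),
        (1.130748688e-1, 1.069792721e1),
    ]
    n2 = 1.0 + sum(a * lam_um2 / (lam_um2 - b) for a, b in terms)
    return np.sqrt(n2)


def _gauss(lam, center, width, peak):
    return peak * np.exp(-0.5 * ((lam - center) / width) ** 2)


def eps_oxy(lam):
    """Synthetic oxyHb mass attenuation, L g^-1 cm^-1."""
    return (
        _gauss(lam, 415.0, 17.0, 8.1)      # Soret
        + _gauss(lam, 345.0, 30.0, 0.45)   # N band shoulder
        + _gauss(lam, 542.0, 11.0, 0.80)   # Q alpha
        + _gauss(lam, 577.0, 10.0, 0.78)   # Q beta
        + _gauss(lam, 280.0, 25.0, 1.0)    # protein UV edge
        + 0.015                            # broad residual background
    )


def eps_deoxy(lam):
    """Synthetic deoxyHb mass attenuation, L g^-1 cm^-1."""
    return (
        _gauss(lam, 430.0, 16.0, 8.2)
        + _gauss(lam, 345.0, 30.0, 0.50)
        + _gauss(lam, 555.0, 17.0, 0.82)   # single Q band
        + _gauss(lam, 760.0, 20.0, 0.025)  # NIR deoxy band
        + _gauss(lam, 280.0, 25.0, 1.0)
        + 0.015
    )


def main():
    DATA.mkdir(parents=True, exist_ok=True)
    lam = np.arange(280.0, 1110.0 + 1e-9, 2.0)
    pd.DataFrame({"wavelength_nm": lam, "n_water": water_ri(lam)}).to_csv(
        DATA / "water_ri.csv", index=False, float_format="%.8f"
    )
    pd.DataFrame(
        {"wavelength_nm": lam, "eps_mass_L_per_g_cm": eps_oxy(lam)}
    ).to_csv(DATA / "hb_attenuation_oxy_synthetic.csv", index=False,
             float_format="%.6e")
    pd.DataFrame(
        {"wavelength_nm": lam, "eps_mass_L_per_g_cm": eps_deoxy(lam)}
    ).to_csv(DATA / "hb_attenuation_deoxy_synthetic.csv", index=False,
             float_format="%.6e")
    print("wrote tables to", DATA)


if __name__ == "__main__":
    main()
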