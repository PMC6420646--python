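"""End-to-end retrieval on a synthetic dataset (reduced size, ~1 minute).

Simulates a transmittance dilution series from a known alpha(lambda) with a
Soret-band dispersion feature, reduces it to an extinction spectrum, checks
dilution consistency, fits the CBC-constrained model with the multistart
protocol, and compares the retrieved RI increment with the truth, including
the linearized uncertainty band.
"""
import numpy as np

from rbc_rispec import (
    FitConfig,
    OpticalConstants,
    QuadratureConfig,
    SyntheticScenario,
    average_dilutions,
    build_basis,
    check_single_scattering,
    covariance_psi,
    default_grid,
    extinction_from_transmittance,
    fit,
    generate_series,
)

constants = OpticalConstants.default()
basis = build_basis(default_grid(420.0, 680.0, 10.0), knot_spacing=40.0)
quad = QuadratureConfig(n_chb=8, n_radius=8)

scenario = SyntheticScenario(noise_rel_std=0.0005, eta_true=0.02, seed=7)
ds = generate_series(scenario, basis, constants, quad)
spectra = extinction_from_transmittance(ds.series)
ok, spread = check_single_scattering(spectra)
print(f"dilution consistency: spread {spread:.2%} -> {'pass' if ok else 'FAIL'}")

spec = average_dilutions(spectra)
config = FitConfig(n_starts=6, n_survivors=2, stage1_iters=10,
                   stage2_iters=60, seed=1, quadrature=quad)
res = fit(spec, ds.cbc, config, basis, constants)
rep = covariance_psi(res.psi_hat, spec, ds.cbc, basis, constants, quad)

lam = basis.lam_grid
interior = (lam >= 450) & (lam <= 650)  # away from the range edges
err = np.abs(res.alpha_hat - ds.alpha_true)
print(f"chi^2 at optimum        : {res.chi2:.2f}")
print(f"true eta / fitted eta   : {scenario.eta_true:+.3f} / {res.psi_hat.eta:+.3f}")
print(f"fitted MCV, RDW         : {res.mcv_fit:.1f} fL, {res.rdw_fit:.1f} %")
print(f"max |alpha err| interior: {err[interior].max():.4f} mL/g")
print(f"median alpha band u     : {np.median(rep.u_alpha):.4f} mL/g")
print()
print("The fitted eta absorbs the injected concentration error; alpha is")
print("recovered within the shaded +-1u band away from the range edges.")
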