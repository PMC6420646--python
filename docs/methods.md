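# Methods

## Model

A sphered RBC is a homogeneous absorbing sphere whose interior refractive
index is that of an aqueous Hb solution, `n(λ, c_Hb) = n_H2O(λ) +
c_Hb[α(λ) + iγ(λ)]`, suspended in a medium `n_m(λ) = n_H2O(λ) + Δn` with
`Δn = 0.002` by default (the measured offset of the sphering reagent; the
offset is assumed wavelength-independent). The membrane is neglected: it is
thin compared with the wavelength and has a low volume fraction. Units are
fixed project-wide: λ in vacuum nm, `c_Hb` in g/L, α and γ in mL/g (so the
RI product carries 10⁻³), radii in μm, cross sections in μm², number
concentrations in μm⁻³, cuvette path in mm.

`γ(λ)` is derived from a tabulated decadic specific attenuation ε(λ)
(L g⁻¹ cm⁻¹) via `γ = ln(10)·ε·λ/(4π)`. An oxy/deoxy mixture uses
`γ_mix = (1−f)γ_oxy + f·γ_deoxy` with `f ∈ [0, 1]` (default 0: fully
oxygenated, the case the model is intended for; `f = 0.1` exists to probe
how partial deoxygenation degrades the fit).

The population model assumes radius R ~ log-normal(μ_R, σ_R) and
c_Hb ~ normal(MCHC, σ_cHb), statistically independent. Log-normal moments
give closed forms used throughout: `MCV = (4π/3)exp(3μ_R + 4.5σ_R²)`,
`RDW = sqrt(exp(9σ_R²) − 1)`. The normal c_Hb density is truncated at zero
by the integration domain; at the physiological width (~7% of MCHC) the
truncated mass is negligible and the quadrature weights are renormalized to
unit mass, which also makes the degenerate σ → 0 limits exact.

## Numerics

**Mie series.** Truncation at the Wiscombe criterion
`n_max = ⌈x + 4x^{1/3} + 2⌉`; the logarithmic derivative of the internal
Riccati–Bessel function by downward recurrence from `n_max + 15`; ψ/χ of
the real size parameter by upward recurrence. The kernel is numba-compiled
and verified in the tests against an independent high-precision series
(half-integer Bessel functions at 30 digits) to 10⁻⁸ relative. Size
parameters in this problem reach x ≈ 100 (290 nm, largest cells).

**Ensemble quadrature.** Gauss–Hermite (16 nodes) in c_Hb and
Gauss–Legendre (16 nodes) in ln R over μ_R ± 5σ_R. The tests compare
against a 2001×2001 trapezoidal oracle; agreement is better than 10⁻⁴
relative.

**Spline basis.** "Third-order cardinal splines" are cubic C² B-splines on
a uniform 10 nm knot grid, extended three intervals beyond each range edge
so the basis is complete there; on [290, 1100] nm this gives M = 84
functions. Orthonormalization is QR of the design matrix under the
unweighted discrete inner product on the working grid (the paper-style
G matrix is then directly reusable in the covariance algebra). Because the
triangular change of basis preserves the spanned space exactly, the
optimizer works in the raw local-support coefficients — giving a sparse
finite-difference Jacobian — and reports in the orthonormal basis.

**Working grid.** The measurement grid is spectrometer-defined; spectra are
resampled by local linear interpolation. The library default working grid
is 2 nm on [290, 1100] nm. The test suite and the acceptance script use a
5 nm grid (N = 163 > M + 4 = 88, so the problem stays overdetermined) and
reduced multistart counts; these sizes are the package's reference
configuration for synthetic studies. Wavelengths where T falls below 1%
are flagged unusable and excluded from fitting.

**Optimization.** Trust-region-reflective least squares on the concatenated
weighted residual vector (spectral + CBC). Bounds keep σ's positive and
`η > −0.9`. Stage iteration caps are realized as `max_nfev` limits (the
solver evaluates the cost approximately once per accepted or rejected
step). Defaults follow the two-stage protocol: 25 starts × 15 iterations,
then the 6 best up to 150 iterations or until relative cost/step change
< 10⁻¹⁰. Initialization: α set to a constant ~N(0.235, 0.04) mL/g plus
independent per-coefficient noise scaled (through the mean squared row norm
of the B-spline design matrix) to produce ~0.004 mL/g pointwise dispersion
features; mean(R) jittered by 120 nm and std(R) by 30 nm; σ_cHb ~
N(7% MCHC, 10 g/L); η ~ N(0, 3%); invalid draws are redrawn. All
randomness flows from one seed; fits are bitwise reproducible.

**Covariance.** Jacobians at the optimum by forward finite differences
(relative step 10⁻⁶ with an absolute floor per parameter scale), the same
settings as the fitting Jacobian. The Gauss–Newton information matrix is
Jacobi-preconditioned before inversion; a preconditioned condition number
above 10¹² triggers a flagged pseudo-inverse fallback. The inverse is
symmetrized and eigenvalues clipped at −10⁻¹⁰ relative. Cross-sample
combination is the unweighted mean with standard-error-of-the-mean
variance; the medium-RI systematic `u_nm[α] = (Δα/Δn)·u[n_m]`
(u[n_m] = 3×10⁻⁴ by default) is added in quadrature. Δα/Δn is measured
empirically by the generate-with-offset / fit-without-offset experiment;
the compensation is essentially `Δα ≈ Δn/MCHC ≈ 6×10⁻³ mL/g per 0.002`,
i.e. the fit preserves the absolute interior RI.

## Synthetic data

The generator emulates the measurement chain: truth α (constant level
0.22 mL/g plus a derivative-of-Gaussian dispersion feature at 420 nm,
0.06 mL/g peak-to-peak, projected into the spline basis so it is exactly
representable), a CBC-consistent population, Beer–Lambert transmittance
for 6 dilutions log-spaced in optical depth so T spans [0.30, 0.95] at
500 nm, multiplicative log-normal noise independent across wavelengths
(clipped at T = 1), and a true concentration error η that rescales the
reduced spectra by 1 + η. Default CBC values describe a healthy adult
(MCHC 329 g/L, MCV 86 fL, RDW 12.7%, HDW 7%).

What the generator does **not** model: stray light, finite acceptance
angle, slit functions, dark-current residuals, spectrally correlated noise,
correlated (R, c_Hb) distributions, and non-spherical residual shapes.
Passing recovery tests therefore demonstrates correctness of the numerics
and identifiability under the stated noise model, not instrument-level
accuracy on real spectra.

The bundled Hb attenuation tables are synthetic analytic band models
(Soret at 415/430 nm, Q bands at 542/577 or 555 nm, weak NIR tail) with
peak magnitudes consistent with standard tabulations; they exercise every
code path that real literature tables would, but carry no metrological
claim. The water RI uses the Daimon–Masumura Sellmeier fit at 21.5 °C;
published water-dispersion parameterizations differ in the fourth decimal,
which is absorbed by the Δn offset convention. Tables are interpolated
with monotone-safe PCHIP and never extrapolated.

## Design choices and limitations

- MCHC is never a free parameter: the α level and MCHC trade against each
  other almost exactly (a ±2% MCHC rescaling compensated by α changes the
  spectrum by < 0.5% RMS), so the CBC value is trusted instead.
- The dilution-series consistency check uses the range/mean spread of the
  per-dilution curves with a 5% default tolerance, matching the ~4–6%
  concentration-uncertainty chain; the per-sample spectrum is the pointwise
  mean with a standard-error uncertainty floored at 0.5% relative.
- Edge spline coefficients are weakly constrained; recovery and uncertainty
  statements are made for the interior band (320–1050 nm by default).
- The linearized covariance accounts for spectral noise and CBC
  uncertainty only; systematic model errors (e.g. a multiplicative
  spectral bias) produce between-sample spread larger than the linearized
  band, which is why multi-sample combination uses the empirical variance.
- Coated spheres, spheroids and angle-resolved quantities are out of
  scope; the host medium is assumed non-absorbing above 290 nm.
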