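# rbc-rispec

Retrieval of the wavelength-dependent real refractive-index increment of
hemoglobin from optical extinction spectra of sphered red blood cells.

## The problem

The complex refractive index of a red blood cell (RBC) is, to an excellent
approximation, that of the aqueous hemoglobin solution filling it:

```
n(λ, c_Hb) = n_H2O(λ) + c_Hb · [α(λ) + i γ(λ)]
```

where `c_Hb` is the intracellular hemoglobin mass concentration (g/L),
`γ(λ)` (mL/g) follows from the well-known Hb absorption spectrum, and the
real increment `α(λ)` (mL/g) is the quantity every light-scattering,
flow-cytometric and holographic analysis of blood needs — and for which
published values disagree by more than 30%.

This package implements a route to `α(λ)` that uses intact cells instead of
artificial Hb solutions. RBCs are isovolumetrically sphered, so the
extinction cross section of a single cell is given exactly by the Mie
solution for a homogeneous sphere. A collimated-transmittance measurement of
a dilute suspension in a cuvette of path length `d` yields the
ensemble-averaged cross section

```
C̄_ext(λ) = −ln T(λ) / (d c),        c = c_RBC / φ,
```

which averages the single-cell Mie cross section `C(λ; c_Hb, R)` over the
cell radius distribution `r(R)` (log-normal) and the concentration
distribution `q(c_Hb)` (normal). The forward model

```
M(λ; ψ) = (1 + η) ∬ C(λ; c_Hb, R) q(c_Hb) r(R) dc_Hb dR
```

carries the free parameters `ψ = (a, σ_cHb, μ_R, σ_R, η)`: spline
coefficients `a` of `α(λ) = Σ_j a_j g_j(λ)` over orthonormalized cubic
B-splines (10 nm knots, 290–1100 nm, M = 84), the distribution widths and a
prefactor `1 + η` absorbing cell-counting/dilution errors. The inverse
problem minimizes

```
χ²(ψ) = Σ_i w_i [M(λ_i; ψ) − y_i]² + Σ_j w_j^CBC [M_j^CBC(θ) − z_j]²
```

with the mean corpuscular Hb concentration (MCHC) fixed at its
blood-count value and the cell volume statistics (MCV, RDW) from the
complete blood count (CBC) entering as a penalty — without this side
information the retrieval is ambiguous, because MCHC, MCV and the `α` level
can mutually compensate. Minimization uses a two-stage randomized
multistart trust-region least-squares protocol, and parameter uncertainties
follow from the Gauss–Newton covariance
`Σ(ψ̂) = [Jᵀ W J + J_CBCᵀ W_CBC J_CBC]⁻¹`, propagated to the α curve by
`Σ(α̂) = G Σ(â) Gᵀ`.

## Worked example

`examples/retrieve_alpha_synthetic.py` simulates a dilution series from a
known `α(λ)` with a Soret-band dispersion feature, a 2% concentration error
and multiplicative detector noise, reduces it and runs the full retrieval
(reduced 420–680 nm range, ~1 minute):

```
dilution consistency: spread 2.60% -> pass
chi^2 at optimum        : 1.31
true eta / fitted eta   : +0.020 / +0.016
fitted MCV, RDW         : 86.0 fL, 12.7 %
max |alpha err| interior: 0.0024 mL/g
median alpha band u     : 0.0026 mL/g
```

The dilution curves agree to within the single-scattering tolerance; the
fitted `η` absorbs the injected concentration error; `α(λ)` is recovered
within the linearized ±1u uncertainty band away from the range edges; and
the fitted MCV/RDW reproduce the CBC values, as the penalty demands.

Other examples: `single_sphere_extinction.py` (Mie cross section of an
average RBC vs the geometric limit 2πR² ≈ 47 μm²), `forward_spectrum.py`
(CBC → ensemble spectrum), `medium_ri_sensitivity.py` (below). A thin CLI
mirrors the workflow: `rbc-rispec simulate | reduce | fit | sensitivity |
mie-single` (see `--help`).

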