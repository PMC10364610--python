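# Methods

## Physical model

The myocardium is treated as a bidomain continuum. When the transmembrane
potential V_m is prescribed, the extracellular potential Φ obeys a Poisson
equation −∇·((G_i+G_e)∇Φ) = ∇·(G_i ∇V_m). We take V_m to be an ideal
travelling step: a planar front parallel to the YZ plane moving in +X at
constant speed v, switching V_m from φ_rest to φ_max. The right-hand side
then reduces to a dipole sheet of surface strength (φ_max−φ_rest)·g_i,xx
spanning the wall −L ≤ z ≤ 0 at x = vt, where g_i,xx is the intracellular
conductivity in the propagation direction after rotating the transversely
isotropic tensor by the fiber angle ψ. Everything is independent of Y, so
the problem is two-dimensional and solutions are stacks of dipole lines.

Three solution levels are implemented, in increasing fidelity:

1. **Homogenized**: one effective conductivity g̃ everywhere. The potential
   is a difference of two arctangents — the planar angle Θ₁ under which the
   wall section of the front is seen from the electrode. The 3D solid angle
   is exactly 2Θ₁ for this slab geometry (certified numerically by
   `numeric_oracle.solid_angle_numeric`).
2. **Isotropic three-layer**: blood g_B / tissue g_M / torso g_T. Mirror
   images of the source across the two interfaces produce a geometric
   series of angle terms with reflection factors h_* = (g_M−g_*)/(g_M+g_*)
   and transmission factors v_* = 2g_*/(g_M+g_*).
3. **Anisotropic three-layer**: the transmural coordinate inside the wall
   is stretched by η = √(g_M/g_zz), which restores isotropy at the price of
   an apparent wall thickness ℓ = ηL and modified factors
   H_* = (g_M−ηg_*)/(g_M+ηg_*), V_* = 2g_*/(g_M+ηg_*). This is the full
   model; it reduces to level 2 when η = 1 and to level 1 when additionally
   g_B = g_T = g_M.

A note on the series prefactor: the source strength carries g_i,xx (not the
total g_M), and only with g_i,xx in the prefactor do the three levels nest
exactly — the isotropic series at matched media reproduces the homogenized
solution bit-for-bit, and comparing leading terms identifies
g̃ = g_B/V_B = (g_M + η g_B)/2, the anisotropy-weighted arithmetic mean of
tissue and blood conductivities. The package therefore uses g_i,xx in all
series prefactors.

Bipolar signals are pointwise differences Φ(r_dist) − Φ(r_prox), with the
proximal electrode at r_dist + d(cosα cosβ, cosα sinβ, sinα). The
distal-minus-proximal convention is the default; a `bipolar_sign` switch
flips it, since both conventions appear in the literature.

## Parameters, units, defaults

Units are mm, ms, mV, S/m throughout; speeds in m/s and mm/ms are
numerically identical so no conversion ever occurs.

| parameter | meaning | default | rationale |
|---|---|---|---|
| g_i,l / g_i,t | intracellular conductivity along/across fibers | 0.1527 / 0.0312 S/m | standard bidomain simulation values |
| g_e,l / g_e,t | extracellular counterparts | 0.5485 / 0.3361 S/m | idem |
| g_B, g_T | blood / torso conductivity | 0.7 S/m | saline-blood bath value |
| φ_rest, φ_max | transmembrane step | −86, +10 mV | epicardial ventricular action-potential upstroke; configurable (φ_max = 30 mV is also common in plots) |
| L | wall thickness | 5 mm | mid-range ventricular wall |
| ψ | fiber angle vs propagation | 0° | wave along fibers |
| h, d | electrode height, spacing | 1 mm, 2 mm | clinical bipolar catheter scale; h < 1 mm is where point-electrode assumptions degrade |
| v_∥ | longitudinal conduction velocity | 0.42 m/s | measured anchor for the v(ψ) scaling |

The conduction-velocity model uses the monodomain diffusion constant
D(ψ) = g_i,xx g_e,xx/(g_i,xx+g_e,xx); the membrane factor 1/(β_M C_M)
cancels in v(ψ)/v(0) = √(D(ψ)/D(0)), so β_M and C_M are never required
(they are accepted in `MonodomainConstants` for completeness). With the
default conductivities this predicts a transverse velocity of 0.205 m/s.

## Numerical choices

- **arctan branch**: the angle term is evaluated as
  arctan((z+ℓ)/u) − arctan(z/u) with the principal branch. This form is
  continuous across the front for z > 0 and automatically carries the
  physical branch-cut jump (±π per sheet crossing) for z inside the wall;
  at u = 0 the midpoint of the one-sided limits is returned. There is no
  singularity anywhere — only a finite discontinuity at the front inside
  the tissue.
- **Series truncation**: terms are added until π·|coefficient| < tol
  (default 1e−12, cap 200 terms). Since |H_B|, |H_T| < 1 for any positive
  conductivities the neglected tail is geometrically bounded; the bound is
  exposed as `tail_bound` on the evaluator and asserted in tests.
- **Peak-to-peak extraction** for analytic traces: a 2001-point coarse scan
  over the lateral offset followed by bounded scalar minimization refined
  to 1e−9 mm. The traces are smooth with one extremum per lobe, so this is
  robust. Sampled-trace features in the sweep use a sinh-stretched time
  grid (dense near the front passage, tails out to 40(ℓ+h+d)) so that the
  missed |Φ| mass stays well below 0.5% while thick-wall peaks remain
  resolved.
- **W90 inversion**: the completion fraction S(t) is a trapezoidal
  cumulative integral of |Φ|; its 5%/95% quantiles are found by linear
  interpolation, which is exact for piecewise-linear |Φ|. No pre-filtering
  is applied (analytic traces are smooth and densely sampled).
- **Finite-volume oracle**: node-centred 5-point scheme on a uniform XZ
  grid whose nodes align with both interfaces; x-conductivities on
  interface rows average the two adjacent layers (half control volumes),
  the dipole sheet is two charged columns ±(φ_max−φ_rest)g_i,xx/dx with
  half-weight end nodes, boundaries are zero-flux, the gauge is fixed by
  pinning one corner and removing the mean (the discrete solution is odd
  in x about the front on the symmetric grid). The linear system is solved
  by direct sparse factorization. Convergence is second order; probe
  points keep |x−front| ≥ 2dx and z ≥ h/2 to avoid source-discretization
  artefacts, and comparisons Richardson-extrapolate two grids.
- **Decay fits**: unweighted least squares of log|V| on log R over a
  geometric grid, exponent = −slope. Grids starting below 4(L+d) trigger a
  non-asymptotic warning, as does detectable curvature of the log–log fit.

## What the fixture generator emulates — and what it does not

`sweep_workbench.generate_fixture` produces "simulation-like" traces: the
analytic depolarization complex plus an inverted, widened, delayed and
scaled copy of itself as a repolarization (T-wave) surrogate, plus seeded
Gaussian noise. It reproduces the gross morphology (QRS-like deflection,
opposite-polarity late wave, sampling noise) that feature-extraction code
must tolerate, and it is byte-reproducible for a fixed spec. It does *not*
emulate bath loading (front curvature near the blood interface), far-field
boundary artefacts of finite simulation boxes, true repolarization
dispersion, or electrode-size and contact effects. Tests that pass on
fixtures therefore certify the feature definitions and their invariances,
not the fidelity of any particular electro-anatomical recording.

## Known limitations and honest discrepancies

- The series is derived for the blood pool (z ≥ 0); wall-interior fields
  are available only in the homogenized approximation, and torso-side
  potentials are not implemented.
- Planar fronts only: no bath-loading V-shape, no curved walls, no finite
  electrode area, no repolarization in the analytic model.
- With the default parameter set the model gives unipolar peak-to-peak
  amplitudes of 4.837 mV (ψ=0°) and 1.340 mV (ψ=90°) at h = 1 mm, L = 5 mm,
  ratio 3.609. Published bidomain-simulation figures for this configuration
  are a few percent lower in absolute amplitude (bath loading and finite
  meshes are absent here); the ratio is robust.
- The perpendicular-bipolar fixed-phase decay exponent fitted over
  R ∈ [50, 400] mm is ≈ 2.92, not the asymptotic 3: the exact signal is
  u·L·d·(2R+d+L)/[R(R+L)(R+d)(R+d+L)], whose local log-slope only reaches
  −2.974 at R = 400 mm. The fit converges to 3 for R ≳ 5 m, which a test
  verifies separately. The other three exponents (unipolar fixed-phase 2,
  unipolar amplitude 1, parallel-bipolar amplitude 2) are recovered within
  ±0.05 on the 50–400 mm grid.
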