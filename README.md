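# egmslab

Analytic forward modelling of intracardiac electrograms (iEGMs) above a
myocardial slab, for computational electrophysiologists and for anyone who
needs quantitative intuition about what an electro-anatomical mapping
catheter actually measures.

## The problem and the model

A mapping catheter records the extracellular potential a millimetre or two
above the endocardium. Clinically, amplitude thresholds on these signals
(e.g. unipolar > 1.5 mV for healthy tissue) are applied as constants, even
though the amplitude also depends on wall thickness, fiber direction and
catheter pose. `egmslab` computes those dependencies in closed form.

The geometry is a three-layer volume conductor: blood pool (conductivity
`g_B`, z > 0), myocardial wall (−L ≤ z ≤ 0) with parallel myofibers at angle
ψ to the propagation direction, and torso (`g_T`, z < −L). A planar
depolarization front travelling at speed v carries the transmembrane step
φ_max − φ_rest and acts electrostatically as a uniform dipole sheet spanning
the wall. Writing g_M = g_i,xx + g_e,xx and g_zz = g_i,zz + g_e,zz for the
total tissue conductivities along and across the wall, and
η = √(g_M / g_zz) for the anisotropy ratio, the blood-pool unipolar
potential is a mirror-image series of subtended angles:

    Φ_B(x, z, t) = V_B g_i,xx (φ_max − φ_rest) / (2π g_B)
                   · Σ_j  H_B^⌊j/2⌋ H_T^⌈j/2⌉
                     [ arctan((x−vt)/(z + jηL)) − arctan((x−vt)/(z + (j+1)ηL)) ]

with reflection/transmission factors
H_* = (g_M − η g_*)/(g_M + η g_*), V_* = 2 g_*/(g_M + η g_*). The j = 0 term
is the classical solid-angle picture, Φ ≈ A·Θ̃₁ with
A = (φ_max − φ_rest) g_i,xx / (π (g_M + η g_B)); higher terms are reflections
of the source at the endo- and epicardial conductivity jumps. Truncating to
one term and ignoring the angle rescaling recovers a homogenized-medium
solution with effective conductivity g̃ = (g_M + η g_B)/2. Bipolar signals
are differences of two unipolar samples at the electrode positions set by
the catheter pose (height h, spacing d, elevation α, azimuth β).

The package provides:

- `tissue_model` — conductivity-tensor rotation, lumped conductivities,
  η, g̃, mirror coefficients, and the monodomain velocity scaling
  v(ψ) = v_∥ √(D(ψ)/D(0)) with D = g_i,xx g_e,xx/(g_i,xx + g_e,xx);
- `forward_model` — homogenized, isotropic-series and anisotropic-series
  unipolar solvers, bipolar traces for arbitrary catheter poses, and
  log–log power-law fits of the far-field decay;
- `signal_features` — extrema, peak-to-peak amplitude, the W90 width
  (5%–95% quantiles of the cumulative |Φ| mass) and windowed RMSE;
- `numeric_oracle` — an independent 2D finite-volume Poisson solver and a
  numerical solid-angle integrator used to validate the series;
- `sweep_workbench` — parameter sweeps with feature tables, reproducible
  simulation-like fixture traces, and the headline-number report.

## Worked example

```python
import numpy as np
from egmslab import (SlabModel, CatheterPose, bipolar, peak_to_peak,
                     unipolar_series_anisotropic, conduction_velocity,
                     DEFAULT_CONDUCTIVITIES, DEFAULT_MEMBRANE)

slab = SlabModel(L=5.0, psi=0.0)          # 5 mm wall, wave along the fibers
print(round(slab.g_tilde, 4))             # 0.8342  homogenized conductivity (S/m)
print(round(slab.eta, 4))                 # 1.3817  anisotropy ratio

v = conduction_velocity(DEFAULT_CONDUCTIVITIES, 90.0, 0.42)
print(round(v, 3))                        # 0.205   transverse velocity (m/s)

phi = unipolar_series_anisotropic(slab, v=1.0)
pp = peak_to_peak(lambda u: phi(u, 1.0, 0.0), 160.0)
print(round(pp, 3))                       # 4.837   unipolar pp at h=1 mm (mV)

vb = bipolar(CatheterPose(h=1.0, d=2.0, alpha=90.0), slab, v=1.0)
t = np.linspace(-60, 60, 1201)
print(round(float(np.ptp(vb(t))), 3))     # 2.677   perpendicular bipolar pp (mV)
```

The unipolar peak-to-peak drops from 4.837 mV with the wave running along
the fibers to 1.340 mV across them — a 3.6-fold reduction caused almost
entirely by the prefactor A(ψ), which is why amplitude thresholds that
ignore fiber direction misclassify tissue.

The same computations are available from the shell:

```bash
egm trace --solver aniso --h 1 --d 2 --alpha 90 --out trace.csv
egm features trace.csv
egm decay --quantity unipolar_fixed_phase --out decay.json
egm validate-series            # series vs finite-difference oracle
egm sweep --out-dir results/   # feature table over L, psi, poses
```

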