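# kvmfit

Viscoelastic analysis of AFM force–indentation curves with an explicit
Kelvin–Voigt–Maxwell (KVM) contact model.

## The problem

Indenting a cell or soft hydrogel with an AFM cantilever and fitting the
approach curve with the Hertz model yields a single apparent Young's
modulus — but the hysteresis between approach and retraction shows that
these materials are viscoelastic, not elastic. Step-hold and oscillatory
protocols measure viscoelasticity properly but require special acquisition.
`kvmfit` instead extracts viscoelastic parameters from the *same
constant-velocity approach curves* that every Hertzian analysis already
uses.

The material is modelled as a Kelvin–Voigt element (spring `E0`, dashpot
`η`) in parallel with a Maxwell element (spring `E1`, relaxation time `λ`).
For a rigid sphere of radius `R` approaching at constant speed `v`, the
force at indentation depth `δ` follows the explicit relation

```
F(δ) = F_el(E0, δ) + F_el(E1, δ)·exp(−α1 δ/(v λ)) + α2 √(R δ) η v

F_el(E, δ) = (4/3) · E/(1−ν²) · √R · δ^{3/2} · (1 − 0.15 δ/R)
```

where `F_el` is the Hertz sphere force with a large-deformation
(hyperelastic) correction, and `α1 = 0.365`, `α2 = 7.25` are dimensionless
constants calibrated against finite-element simulations of KVM indentation
(the viscous exponents are both 1/2). Because `E0` and `E1` become
degenerate when `λ` is far from the indentation time `t_ind = δ_max/v`, the
fit also reports the robust derived moduli

```
Eu   = E0 + E1                      (unrelaxed elasticity)
Eapp = E0 + E1·exp(−α1 δ_max/(v λ)) (apparent elasticity at t_ind)
```

The package covers the whole pipeline: reading plain-text curve files,
tip–sample separation correction, line+polynomial contact-point estimation,
bounded Nelder–Mead fitting of the KVM relation (contact point re-fitted
jointly), sphere-on-sphere effective-radius and confinement corrections for
rounded cells, a finite-thickness ("bottom effect") over-estimation
diagnostic, per-cell aggregation with Kruskal–Wallis group comparison, a
ground-truth synthetic-curve generator, and an independent
hereditary-integral (Lee–Radok-type) forward oracle used to validate the
explicit relation.

Audience: force-spectroscopy practitioners and developers of AFM analysis
pipelines who want viscoelastic parameters from routine force curves.

## Worked example

```python
import kvmfit as kf

# simulate one noisy approach curve with known ground truth:
# E0 = 800 Pa, E1 = 280 Pa, lambda = 0.088 s, eta = 2.71 Pa s
spec = kf.SyntheticCurveSpec(
    params=kf.ViscoelasticParams(E0=800.0, E1=280.0, lam=0.088, eta=2.71),
    sampling_rate=25000.0, noise_sigma=2e-11, seed=42,
)
curve = kf.generate_kvm_curve(spec)

res = kf.KVMModel(curve).fit()   # statsmodels-style: Model -> Results
print(res.summary())
```

prints

```
KVM force-indentation fit
============================================
E0 (Kelvin-Voigt modulus)            0.8448 kPa
E1 (Maxwell modulus)                 0.2710 kPa
lambda (relaxation time)             0.0617 s
eta (apparent viscosity)             2.3401 Pa s
Eu = E0 + E1 (unrelaxed)             1.1158 kPa
Eapp (apparent, at t_ind)            0.9402 kPa
--------------------------------------------
contact point                        0.7986 um
max indentation                      0.8816 um
indentation time t_ind               0.1763 s
rms force residual                   0.0206 nN
function evaluations                     18
flags                                  none
```

The fit recovers the generator's moduli to a few percent from a single
curve carrying 1% force noise; `η` and `λ` scatter more per curve (they are
the least identifiable parameters — compare medians across curves, which is
what the `compare` tooling does). `flags` reports contact failures,
relaxation times pinned at the `[t_ind/5, 10·t_ind]` identifiability box,
and `E1 ≈ 0` degeneracy.

The same pipeline from the shell:

```
kvmfit simulate --output curves/ --groups "interphase:800:0:0:2.71;mitotic:2200:760:0.1:1.71" --seed 1
kvmfit fit      --input curves/ --output results.csv
kvmfit compare  --input results.csv --output comparison
```

`fit` writes one CSV row per curve (`E0_Pa, E1_Pa, lambda_s, eta_Pa_s,
Eu_Pa, Eapp_Pa, cp_m, ...`) plus a JSON provenance record; `compare`
aggregates triplicate curves to per-cell medians and reports
Kruskal–Wallis + Welch-t post-hoc statistics per parameter.

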