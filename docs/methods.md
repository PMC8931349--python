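# Methods

## The contact model

A viscoelastic half-space is represented by a Kelvin–Voigt element (spring
`E0` [Pa], dashpot `η` [Pa·s]) in parallel with a Maxwell element (spring
`E1` [Pa], dashpot `λ·E1`, so `λ` [s] is the relaxation time). The
Kelvin–Voigt part carries creep and full shape recovery; the Maxwell part
carries stress relaxation. Indented by a rigid sphere (radius `R`) at
constant velocity `v`, the approach force is the sum of the three parallel
arms:

    F(δ) = F_el(E0, δ) + F_el(E1, δ)·exp(−α1·δ/(v·λ)) + α2·δ^½·R^½·η·v

with the hyperelastic-corrected sphere force

    F_el(E, δ) = (4/3)·E/(1−ν²)·√R·δ^{3/2}·(1 − 0.15·δ/R).

The correction factor extends the Hertz law to indentations comparable to
`R` for a neo-Hookean solid; it is exactly `(1 − 0.15·δ/R)`, with no square
root. The exponential argument uses the elapsed contact time inferred from
the constant-velocity protocol, `t = δ/v`. The calibration constants
`α1 = 0.365`, `α2 = 7.25`, `α3 = α4 = ½` were fixed once against
finite-element indentation simulations and are never refitted; `α3 = α4 = ½`
is also forced by dimensional analysis (the viscous term is then
`α2·√(Rδ)·η·v`, the same `√(Rδ)·η·v` form as the Lee–Radok Kelvin–Voigt
drag, with a calibrated prefactor — the numerical relation between `α2` and
the analytic Lee–Radok prefactor, 8/3 for ν = ½, is an observation, not a
derivation). Poisson's ratio is held at ν = 0.5 (incompressible soft
matter) throughout.

Assumptions: constant approach velocity, approach segment only (retraction
carries adhesion artefacts and needs a Ting-type treatment, out of scope),
no adhesion, spherical probe, semi-infinite sample (the finite-thickness
error is *diagnosed*, not corrected — see below).

### Derived moduli

When `λ` is far from the indentation time `t_ind = δ_max/v` the individual
parameters degenerate: for `λ ≫ t_ind` the Maxwell arm never relaxes and
only `E0+E1` is constrained; for `λ ≪ t_ind` the arm relaxes before it is
observed and `E1` is arbitrary. The fit therefore also reports

    Eu   = E0 + E1
    Eapp = E0 + E1·exp(−α1·δ_max/(v·λ)),

which stay well-determined in both limits, and confines `λ` to
`[t_ind/5, 10·t_ind]`. The box edges correspond to ≈ 0.6% and ≈ 90% of the
Maxwell modulus still unrelaxed after `t_ind` (bare `exp(−t_ind/λ)`:
`exp(−5) ≈ 0.006`, `exp(−1/10) ≈ 0.9`; note the bound rationale uses the
elapsed-time exponential without `α1`, whereas `Eapp` carries `α1`).

## Pipeline

1. **Separation correction.** The tip–sample separation is the piezo
   height corrected for cantilever deflection, `s = −z − F/k`, oriented so
   `s` increases into the sample. Indentation is `δ = s − cp`.
2. **Segment split** at the piezo-height extremum (or explicit labels);
   only the approach is analysed.
3. **Initial contact point.** Exhaustive scan over candidate samples in
   the central 80% of the approach (capped at ~600 evenly spaced
   candidates; finer grids are far below the estimator's uncertainty). At
   each candidate the curve is fitted piecewise: a linear baseline
   `F = m·δ + d` for `δ < 0` (least squares on pre-contact data only) and
   the rational branch `F = δ³/(aδ² + bδ + c) + m·δ + d` for `δ > 0`
   (non-negative linearised solve plus a log-space Levenberg–Marquardt
   polish at the winner; non-negative coefficients keep the denominator
   pole-free). The candidate with minimal total squared residual wins; ties
   break toward smaller separation. Because the cubic-onset branch rises
   more slowly than `δ^{3/2}`, this minimum sits systematically a few
   percent of `δ_max` *before* the true contact — the estimate is an
   initial guess by design, and the KVM fit re-optimises `cp`. The baseline
   `(m, d)` is never refitted jointly with the branch: joint polishing lets
   branch-model mismatch leak into a spurious baseline slope that would
   bias the subsequent material fit.
4. **KVM fit.** After baseline subtraction and removal of samples above
   the force setpoint (instrument overshoot violates constant `v`), the sum
   of squared force residuals over the whole approach (zero force before
   `cp`, the explicit relation after) is minimised over
   `(E0, E1, λ, η, cp)`:
   - *Initialisation:* the model is linear in `(E0, E1, η)` once `(λ, cp)`
     are fixed, so a coarse `(λ, cp)` grid profiled by non-negative least
     squares locates the global basin. The best candidate — plus the best
     candidate at a distinctly different `cp`, since the `cp` profile can
     be double-welled (contact onset vs. the viscous `√δ` rise) — seeds the
     optimiser.
   - *Search:* Nelder–Mead (lmfit; box bounds via its internal smooth
     transform: `E0, E1, η ≥ 0`, `λ` in its box, `cp` within ±12% of the
     depth around the initial estimate) followed by a trust-region polish.
     Parameters are scaled to kPa/s/Pa·s/µm internally so the simplex works
     on O(1) coordinates. Residuals are unweighted.
   - The `λ` box depends on `t_ind`, which depends on the fitted `cp`; if
     the refit moves `cp` enough to change `t_ind` by >1% the fit runs a
     second pass with the updated box.
   - *Flags:* `λ` is reported "at a bound" when the estimate sits within 1%
     of the box **or** when pinning it at the edge (re-fitting the linear
     parameters) worsens the fit by less than a χ²-scale increment —
     simplex and trust-region methods stop anywhere along the flat `λ`
     valley of a degenerate curve, so edge proximity alone misses genuine
     saturation. `E1 ≤ 0.1%·E0` raises `E1_at_zero`; curves whose force
     never exceeds the baseline noise raise a no-contact error.
5. **Rounded-cell geometry.** For spherical (mitotic-like) cells of radius
   `Rcell`, the force law uses the effective radius
   `1/Reff = 1/Rcell + 1/R`, and the measured indentation is scaled by the
   confinement factor `K = Rcell^⅓/(Rcell^⅓ + Reff^⅓)` (the rounded cell,
   squeezed between probe and dish, deforms more than the contact alone
   indicates). For 7.5 µm cells and 2.5 µm beads: `Reff = 1.875` µm,
   `K = 0.6135`.
6. **Bottom-effect diagnostic.** For a layer of thickness `h` on a rigid
   support, with the simplified relaxation function `φ = Eapp + η·δ(t)`,
   the first two terms of the layer series are
   `F0 = (16/9)√(R·I)[(9/2)ηv + Eapp·I]` and
   `F1 = 1.133·(16/9)(R·I/h)[6ηv + Eapp·I]`; the half-space analysis
   over-estimates the force by `F1/F0` (terms of order `I^{3/2}/h²`
   truncated). This is reported as a diagnostic only; the fitted model
   neglects the substrate. The Stokes drag `6πμRv` on the bead is likewise
   reported: ≈ 2.4×10⁻⁴ nN in water at 5 µm/s, four orders below the
   material response.

## Synthetic data and the independent oracle

The generator forward-evaluates the explicit relation on a constant-
velocity approach: tip position advances at `v` on the separation axis,
contact at `cp_offset`, linear baseline `m·δ + d`, i.i.d. Gaussian force
noise with a fixed seed, and the piezo trace reconstructed from the
noiseless force so the separation correction round-trips exactly. Defaults
emulate routine spherical-probe acquisition: `R = 2.5` µm, `v = 5` µm/s,
`δ_max = 0.88` µm, 0.05 N/m cantilever, 10 kHz sampling, contact after
0.8 µm of baseline travel. An optional mirrored retract ramp (baseline
force only) exists solely for segment-split tests.

What the generator does **not** emulate: pre-contact force onset and
negative detachment forces (diffuse-interface effects), adhesion, baseline
drift nonlinearity, finite-thickness effects, piezo nonlinearity. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the model's own assumptions, not robustness to every real-
world artefact.

The hereditary-integral oracle computes the same physics by an independent
route: trapezoidal quadrature of
`F(t) = 4/(3(1−ν²))·√R·∫₀ᵗ (E0 + E1·e^{−(t−τ)/λ})·d/dτ[δ^{3/2}] dτ` plus
the closed-form Dirac (dashpot) term `η·(3/2)·√δ·δ̇`. It shares no code
with the explicit relation; agreement between the two (elastic reductions
exact to quadrature tolerance ~10⁻⁴; elastic content converging to `Eu` and
`E0` in the slow/fast relaxation limits within 5%) is therefore a
meaningful cross-check. Step-halving changes the oracle output by < 0.1%
at the standard 2000-sample resolution.

## Recovery-suite conditions (and why)

The acceptance-level recovery suite fits 100 seeded curves with noise of 1%
of the peak force. A Cramér–Rao analysis of the five-parameter fit
(`E0, E1, λ, η, cp`) shows `E0` becomes nearly collinear with `E1` as `λ`
approaches `2·t_ind` (expected median error tens to hundreds of percent
regardless of realistic sampling), so the suite probes the identifiable end
of the admissible range, `λ = t_ind/2`, where the Maxwell arm decays
visibly within the curve; the `λ`-outside-the-box regimes are covered by
the separate bound-saturation tests, which assert only the robust moduli.
Material values are cell-like: `E0 = 800` Pa, `E1 = 280` Pa,
`η = 2.71` Pa·s. Sampling is 25 kHz (raw deflection rate of modern
instruments); at 10 kHz the `η` estimator is dominated by a flat `cp`–`η`
likelihood valley. Under these conditions the observed median errors are
≈ 5% for `E0` and `η`, ≈ 1% for `Eu`, ≈ 0.3% for `Eapp`, against asserted
bounds of 10%/10%/5%/5%. Single-curve `λ` and `E1` are *not* asserted —
their per-curve scatter is the model's stated motivation for reporting
`Eu`/`Eapp`.

Problem sizes used elsewhere: unit-test curves are sampled at 2 kHz (~670
approach points), the saturation tests at 5 kHz, the recovery suite at
25 kHz (~8400 points).

## Statistics

Per-cell values are medians over that cell's (typically triplicate)
curves. Groups are compared with Kruskal–Wallis; pairwise Welch t-tests
serve as post-hoc analysis, uncorrected by default (a Holm switch is
provided). Labels: `***` for p < 0.001, `n.s.` for p > 0.05. All-tied
input degenerates to H = 0, p = 1. Summaries report median,
10/25/75/90th percentiles and mean ± SEM.

## Numerical choices and degenerate inputs

- Strict SI units internally; kPa/µm/nN only at presentation level.
- Negative indentation: model evaluators raise by default and return zero
  under the piecewise-contact flag used by the fitter (the residual spans
  the pre-contact baseline).
- `E1 > 0` with `λ = 0` is rejected (Maxwell arm undefined); all moduli,
  `λ`, `η` are constrained non-negative; `ν ∈ [0, 0.5]`.
- Velocity comes from metadata, else the median `|ds/dt|` of the approach;
  the exponential always uses this constant velocity, not per-sample
  velocity.
- Contact-scan candidates whose rational denominator is non-positive are
  excluded; `c > 0` is enforced; ties break to the smallest `cp`.
- Curve files must carry unit-suffixed columns (`time_s`, `height_m`,
  `force_N`); unit-less files are rejected rather than guessed at.
- All randomness (generator noise, dataset trees) flows through explicit
  integer seeds; identical spec + seed reproduces bit-identical curves.

## Known limitations

- Approach-only: no Ting/retraction analysis, no adhesion models.
- Spherical probes only (no cones/pyramids); no power-law rheology.
- The bottom effect is diagnosed, not corrected inside the fit; only the
  two-term layer series is evaluated.
- The initial contact-point estimator carries a systematic early bias of a
  few percent of `δ_max` on sphere-contact data (intrinsic to the
  line+polynomial objective); downstream results rely on the model refit
  of `cp`.
- Single-curve `λ` and `E1` estimates are noisy near the identifiability
  limits; compare groups on `Eu`, `Eapp`, `E0`, `η` medians.
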