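# Methods

This note documents the model the package implements, the assumptions and
numerical choices behind it, what the synthetic-data generator does and
does not emulate, and the known limitations.

## The quantitation model

SIFT-MS is absolute quantitation from reaction kinetics.  Mass-selected
reagent ions R⁺ (or R⁻) are injected into a carrier-gas flow tube, sampled
air is added, and analytes M are chemically ionized:

    R⁺ + M → P⁺ + N        (rate coefficient k, branching ratios R_b)

In the pseudo-first-order, thin-reaction limit (analyte in vast excess
over ions, conversion of reagent ions small), the product/reagent signal
ratio is P⁺/R⁺ = k·[M]·t_r, with t_r the ion residence (reaction) time.
Inverting, and correcting measured count rates for m/z-dependent detection
efficiency with the instrument calibration function (ICF):

    [M] = P⁺·ICF(P⁺) / ( R⁺·ICF(R⁺) · k · t_r )        (single channel)

The per-product-ion form used for reporting divides the ICF-corrected sum
of one primary product and its configured secondary products (water/CO₂
adducts and similar) by that channel's branching ratio, and divides by the
k_j-weighted, ICF- and attenuation-corrected reagent ladder (the injected
reagent ion plus its hydrates, j = 0..3), times t_r.  Several such [M]_i
(one per selected primary ion) are converted to sample ppbv and combined
by the tolerance rule below.

**Approximations inherited from the method** (all deliberate):

* hydrated reagent ions are counted at their downstream signal although
  hydration develops gradually along the tube;
* R_b is a single library value irrespective of reagent hydration;
* hydrate rate coefficients k_j default to the bare-ion k (per-hydrate
  values may be supplied in the library);
* no detector dead-time correction — reagent attenuation keeps the
  counting system linear.

### Flow-tube number density

Concentrations convert between flow-tube number density and sampled-air
ppbv through the total gas density n_g(P_g, T_g) and the dilution factor
φ_s/(φ_c + φ_s).  n_g uses the instrument-convention constant
c = 3.894×10¹⁵ cm⁻³ at 1 Torr, scaled by P_g and by (300 K / T_g); the
300 K reference is this package's choice of anchor for the 1/T scaling.
An ideal-gas evaluation from R = 62.48 Torr L K⁻¹ mol⁻¹ and
N_A = 6.022×10²³ is computed alongside and the ratio between the two is
reported as a performance-check diagnostic (≈ 8.3 under the default
conditions).  The convention value is used throughout and never silently
"corrected"; because the simulator and the analysis share one density
function, every round trip is self-consistent regardless.  Flow rates are
carried in Torr L s⁻¹; sccm inputs are converted with a factor of
1.3715×10⁻² (the mean of the 22 sccm ↔ 0.3 and 145 sccm ↔ 2 Torr L s⁻¹
operating-point pairings).

### The performance check

* **Reaction time.**  The O₂⁺• + C₂H₄ → C₂H₄⁺• + O₂ reaction of the
  certified standard has a single product at m/z 28; transmission is
  assumed equal across m/z 28–32 (the definitional ICF plateau), so
  t_r = (P₂₈/R₃₂) / (k·[C₂H₄]).  A product/reagent ratio above 0.25
  triggers a thin-limit warning.
* **ICF anchors.**  For each standard component (known concentration
  ≈ 2 ppmv, known k, O₂⁺•/NO⁺ reagent whose own ICF is 1),
  ICF(P_i⁺) = k_i·C_i'·t_r·R_j⁺/P_i⁺ with C_i' the component's flow-tube
  density.  Anchors within m/z 28–32 are 1 by definition.
* **Low-mass reagent anchors.**  ICF(+19) (H₃O⁺) is solved from benzene
  and toluene, which react with both H₃O⁺ and O₂⁺• and whose H₃O⁺
  products (79, 93) sit 1 Da above the O₂⁺• products (78, 92): the
  product-ion ICF is interpolated from the already-anchored curve and the
  anchor equation is solved for the reagent ICF.  Both solutions are
  averaged (the scheme allows either; averaging is this package's
  choice).  ICF(−17) (OH⁻) is the mean of three solutions via the
  fluoroaromatic standard components (products at −149, −183, −235,
  interpolated on the mirrored curve), and ICF(−16) (O⁻•) is solved from
  the O⁻• + hexafluorobenzene reaction at −183.
* **Curve assembly.**  Anchors are interpolated linearly in (m/z, ICF)
  space — no log transform; the value at ±400 is extrapolated from the
  186 and 236 anchors; the negative side at −28..−400 mirrors the
  positive; below the lowest anchor the curve extends flat down to
  |m/z| 10.  Shape diagnostics flag extreme low-mass anchors (outside
  0.05–20× the plateau), anchors deviating > 50 % from the line through
  their neighbours, trend reversals at high m/z and mirror
  inconsistencies; diagnostics warn, never abort.
* **Standard composition.**  Six components are fixed (ethene, benzene,
  toluene, tetrafluorobenzene 150, hexafluorobenzene 186,
  octafluorotoluene 236); the seventh, mid-mass component is configurable
  and defaults to 1,4-difluorobenzene (m/z 114).  Rate coefficients for
  the standard's reactions and the fluoroaromatics' negative-ion channels
  are literature-typical fixture values (1–2×10⁻⁹ cm³ s⁻¹); nothing in
  the analysis depends on their particular magnitude because the same
  values drive simulation and inversion.

### Tolerance reporting

With several per-ion concentrations, the ions reading ≤ (1 + tolerance) ×
the minimum (inclusive; default tolerance 0.2) are averaged — unweighted,
as the instrument convention states — and the rest rejected as interfered.
The reported value therefore never exceeds 1.2× the lowest per-ion
reading.  Rejections raise an "inspect individual ions" flag: overreading
usually means interference, underreading usually means missing secondary
chemistry.

### Interference corrections

Applied after per-ion quantitation and before tolerance selection:

* **Isotopologue subtraction**: C_corr = C_app − C_int·f, where C_int is
  the interferent measured at its predominant-isotope ion *with the
  target's kinetic data* (so sensitivities cancel) and f is the
  isotopologue contribution.  The default (linear) f = n_iso·a; the exact
  option uses the binomial satellite-to-monoisotopic ratio
  n_iso·a/(1−a), which is the factually correct multiplier for a
  monoisotopic-peak measurement.  The two agree within 5 % for
  n_iso·a < 0.1.  Negative results floor at 0 with a flag (a SIFT-MS
  report is an upper limit to the true concentration).
* **Primary-ion subtraction**: C_A = C_AB − r·C_B, with the response
  factor r = C_pseudo/C_B measured on a pure interferent sample
  (C_pseudo computed with the target's kinetics at the shared m/z).
* **Linear-combination deconvolution**: for co-reacting components with
  similar k but contrasting branching (ethylbenzene 70:30 vs xylenes
  20:80 at m/z 91/106 under O₂⁺•), the branching matrix is solved
  against the ICF-corrected signals, fractions are clipped to [0, 1] and
  renormalized (with a flag) when noise pushes them outside, and applied
  to the summed concentration from a non-discriminating reagent (NO⁺ or
  H₃O⁺).  Because the matrix carries branching ratios only, a k contrast
  among components tilts the split by the same ratio; the method premise
  (k within ~10 %) bounds that bias.  Identical branching rows raise a
  non-resolvable error pointing to sum reporting, which labels the value
  (e.g. "sum of o-xylene + m-xylene + p-xylene") and annotates sums over
  members whose k spread exceeds 10 %.
* **Secondary-product-ion interference** is not correctable here; the
  error message names the two viable calibration routes (constant-
  humidity calibration, or a concentration-dependent calibration of the
  interferent's secondary chemistry).

## The synthetic-data generator

The simulator is the package's test harness: it inverts the analysis
equations exactly.  Product expectations are

    E[P] = Σ_j k_j R_j · [M] · t_r · R_b,

partitioned over configured secondary splits (default 80 % primary /
20 % secondary — adduct formation has no general rate law, so splits are
simulation inputs) and, optionally, over each product ion's isotopologue
pattern.  Recorded signals are physical signals divided by the injected
transmission truth g(m/z) (with g ≡ 1 on m/z 28–32, so that a perfect
calibration recovers g as the ICF), and reagent-side signals are further
divided by the attenuation factor.  Counting noise is Poisson over the
dwell time; the seed is mandatory and reproducibility is exact.

Design choices and what they mean for test evidence:

* **Signal-level simulation.**  Products are linear in the *recorded*
  reagent signal rather than integrated along the tube; this matches how
  the instrument folds transport into the ICF, and it is what makes
  "quantify(simulate(truth)) = truth" exact rather than approximate.  The
  exponential reagent decay with diffusion loss and the thin-limit
  product expression (with the differential diffusion enhancement D_e)
  are exposed as standalone physics operations and are verified against
  a generic ODE integrator; a depletion option scales recorded reagent
  ladders by the conversion factor for overload scenarios.
* **Dry performance check.**  Check frames carry no hydrate ladder,
  mirroring the requirement that the check run under dry conditions;
  hydrates in wet sample frames are fixed user-set fractions of the
  reagent signal.
* **What passing tests show.**  Round-trip exactness demonstrates that
  the analysis is the correct inverse of the stated signal model, and
  the noisy tests that uncertainty propagation is right under Poisson
  statistics.  They do not validate the signal model against a real
  instrument: real data add drift, humidity-dependent secondary
  chemistry, non-Poisson detector effects and m/z-calibration error,
  none of which are emulated.

## Default study conditions

Flow tube 0.46 Torr at 393.15 K; carrier 2.0 Torr L s⁻¹; sample flow
0.3 Torr L s⁻¹; reagent base signals 1–6 Mcps behind a 100× attenuation;
t_r 6 ms; standard components at 2000 ppbv; dwell times 0.06 s (reagents)
and 0.1 s (products); transmission truth rising from 1 at the plateau to
4.4 at m/z 236.  Statistical tests use 200-seed ensembles (400–500 for
distribution-law checks), sizes at which the ensemble mean resolves the
propagated standard error comfortably while the full suite runs in
seconds.

## Numerical choices

* Rate coefficients: Langevin k_L = 2πe√(α/μ) (prefactor from CODATA
  constants; 2.342×10⁻⁹ for α in Å³, μ in Da); the dipole capture ratio
  uses the trajectory parametrization in x = μ_D/√(2αk_BT), clamped to
  ≥ 1 (its x < 2 branch dips to 0.999997 at x = 0); temperature
  rescaling of tabulated polar-analyte rates uses the ratio of capture
  rates at the two temperatures; association channels refuse
  recomputation (no theory applies in N₂ at elevated temperature).
* Isotopologue patterns are exact multinomial convolutions over integer
  mass offsets; fractions below 10⁻¹² are folded into the monoisotopic
  peak to preserve normalization.  Default per-atom abundances: ¹³C
  1.1 %, ¹⁸O 0.2 %, ³⁴S 4 %, ³⁷Cl 24.5 %, ⁸¹Br 49.3 %; H and N are
  treated as monoisotopic.
* SIM counts are stored as non-negative floats so noise-free expectation
  frames are exact; real acquisitions are integers.
* Deconvolution uses least squares with a rank check (tolerance 10⁻¹⁰
  relative) and treats sub-10⁻⁹ clipping as numerically clean.
* Zero-count product ions report an SE of one count over the dwell time
  rather than zero.

## Limitations

* The interferent in an isotopologue correction must itself be measured
  with good signal-to-noise; the correction propagates its error.
* The branching-only deconvolution model is exact only for equal rate
  coefficients; the builtin ethylbenzene/xylene pair (2.0 vs
  1.9×10⁻⁹ cm³ s⁻¹) carries a ≈ 2.5 % split bias by construction.
* Humidity dependence (of branching ratios, hydrate ladders and
  secondary chemistry) is not modelled; hydrate fractions and secondary
  splits are static inputs.
* The ICF below the lowest anchor (|m/z| < 16–19) is a flat
  extrapolation; no instrument data constrain it.
* Conventional calibration-curve workflows, full-scan peak picking and
  multivariate fingerprinting are out of scope.
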