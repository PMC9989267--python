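# Methods

This note records the models, conventions and design decisions behind
`breastdwi`, in the order a reader meets them: signal models, the
abbreviated estimators and their algebra, the reference fits, noise,
phantoms, DTI, maps and the S-index. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Units

b-values are s/mm², diffusivities mm²/s, so every exponent `b·D` is
dimensionless. Signal amplitudes are arbitrary units fixed by `s0`.
A property test verifies the invariance `b → b·s, D → D/s` of all
forward models. This fixed unit system matters because one published
intermediate (the H term, below) is dimensionally inconsistent and can
only be evaluated "verbatim" once units are pinned.

## Signal models

`TissueState` carries `(s0, f_ivim, d_star, d_blood, adc0, kurtosis)`.
The IVIM bi-exponential and the IVIM-kurtosis model are as in the README.
Defaults `d_blood = 1.7e-3` mm²/s and `d_star = 10e-3` mm²/s are
synthesis configuration, not measured constants: the literature names
both symbols without fixing values, and the 4-b estimators never use
them.

Two synthesis modes:

- **physical** evaluates the model verbatim. The quadratic kurtosis
  exponent turns over at `b_max = 3/(ADC₀·K)`; beyond that the model
  predicts rising signal, which is non-physical, so physical-mode
  synthesis refuses such b rather than silently corrupting estimator
  benchmarks downstream.
- **assumption_matched** realizes exactly the premise of the abbreviated
  derivation: perfusion contributes fully at the smallest b of the
  scheme and exactly zero at every larger b. It exists so estimator
  *algebra* can be validated in isolation from model-mismatch bias, and
  it is the default for phantom synthesis for the same reason. The
  boundary reading ("fully present at b0, absent at b1 and above") is
  pinned by what the closed-form derivation needs; with the default
  quadruple b0 = 0 this makes `S(b0) = s0` exactly.

## The abbreviated 4-b estimators

With `L(b) = -ln[S(b)/S(b0)]`, b0 = 0, and the assumption-matched model,

```
L(b) = c + b·ADC₀ - b²·Q,   c = -ln(1-f),   Q = ADC₀²·K/6,
```

so the slopes `D_i = L(b_i)/b_i = ADC₀ - b_i·Q + c/b_i` are rational in
the unknowns. Direct elimination (re-derived symbolically with sympy in
the test suite) gives the identities

```
sADC = ADC₀ - (b1+b3)·Q
A    = [(D2-D3)/(b3-b2) - (D1-D2)·b1/((b2-b1)·b3)] · b3/(b3-b1)  = Q
f    = 1 - exp[-(D1-D2)·b1·b2/(b2-b1) + A·b1·b2]
ADC₀ = sADC + (b1+b3)·A,   K = 6·A/ADC₀²
```

which is the `exact_closed_form` method: exact to machine precision for
noise-free assumption-matched input, for all f ∈ [0, 1), K ≥ 0 inside
the signal-positivity domain. D\* never appears — it is not estimable
from four points.

The published approximate pipeline (`as_printed`) is retained verbatim
in its stated dependency order: F → H → f → A, with

```
F = 1 - exp[-(D1-D2)·b1·b2/(b2-b1)]
H = (D2-D3)/(b3-b2) + ln(1-F)/(b3·b2)
f ≈ 1 - exp[-(D1-D2-H)·b1·b2/(b2-b1)]
A = (D2-D3)/(b3-b2) + ln(1-f)/(b3·b2)
```

Three fidelity facts, all regression-tested:

1. For K = 0 the as-printed fraction is exact (F = f identically).
2. For K > 0 it carries a finite bias, monotone increasing in K: the H
   term that is meant to cancel the kurtosis contribution to the D1–D2
   angle has A's units (mm⁴/s²) while D1-D2 has slope units (mm²/s), so
   in this unit system it under-corrects by orders of magnitude and
   f̂ ≈ F. We evaluate it verbatim anyway; `exact_closed_form` is the
   corrected alternative.
3. The published ADC₀ correction multiplies A by the *product* b1·b3.
   The algebra above requires the *sum* b1+b3 (only that form passes the
   exactness round trips; the product form is off by >100% whenever
   K > 0 and >4000% at ADC₀ = 1.2e-3, K = 0.8). Whether the product is a
   typo or an unstated unit convention cannot be resolved from the text,
   so both ship behind `correction_mode` (`derived_sum` default,
   `paper_product` verbatim) and `discrepancy_report()` tabulates the
   gap.

Other conventions: "S(0)" in the D1–D3 definitions is read as the signal
at b0 with divisors `b_i - b0`, so quadruples with b0 > 0 are accepted
(the closed-form exactness statements hold for b0 = 0, where the
derivation lives). F and estimated fractions are clamped into
[0, 1 - 1e-12] before logs, with qc flags on every clamp. Negative K
estimates are *kept* and qc-flagged rather than clamped: clamping at 0
would bias noise studies. Non-monotone input signals are flagged, not
rejected — at high noise they are common and the estimates remain
well-defined.

## Reference fits (the oracle)

`fit_ivim_kurtosis` fits the model by bounded nonlinear least squares on
a dense scheme (16 b-values from 0 to 1500 s/mm²), with residuals on the
linear signal scale (closer to the Rician noise structure at high b than
log residuals). Bounds: f ∈ [0, 0.5], ADC₀ ∈ [1e-5, 4e-3] mm²/s,
K ∈ [0, 3], lumped pseudo-diffusion D\*+D_blood ∈ [3e-3, 5e-2] mm²/s —
the two fast rates are not separable, and the pseudo-diffusion rate is
notoriously ill-determined even by full fitting. Initialization comes
from a log-quadratic high-b prefit plus two deterministically scaled
restarts; given the initialization the fit is deterministic.

The fit takes a `mode` mirroring the synthesis modes: assumption-matched
data are fit with the assumption-matched model (a physical-model fit
cannot reach 1e-6 agreement on such data because the bounded
pseudo-diffusion tail never vanishes exactly at b1). This keeps the
oracle an independent *route* — dense-scheme least squares versus
four-point closed algebra — to the same parameters.

`fit_segmented` is the classical two-stage alternative: a quadratic
regression of the log-signal on b ≥ 200 s/mm² gives (amplitude, ADC₀,
K) — exact on noise-free data since the log-signal is exactly quadratic
there — and the perfusion fraction is the lowest-b excess over the
extrapolated tissue line, `f = 1 - T(b_lo)/S(b_lo)`. On physically
synthesized data the perfusion tail above the split biases f slightly
downward; the comparison harness tabulates this.

`compare_estimators` reports bias and RMSE per estimator, tissue and
noise level. Closed-form estimators are vectorized over all replicates;
the iterative fitters are looped and therefore run fewer replicates by
default (the replicate counts appear in the table and metadata). Voxels
whose flagged degeneracies produce non-finite estimates (non-positive
ADC₀ → NaN K) are excluded from the moments and counted in
`n_finite_*` columns. With a fixed seed the CSV regenerates
byte-identically.

## Rician noise

`add_rician` draws `sqrt((S+n1)² + n2²)` with independent Gaussians of
standard deviation σ — single-coil magnitude statistics; multi-coil
non-central-χ is out of scope. Background sigma estimation inverts the
Rayleigh mean (`mean/sqrt(π/2)`; RMS/sqrt(2) available as an
alternative). `noise_floor_correct` is power subtraction
`sqrt(max(M² - 2σ², 0))`, a stated convention benchmarked rather than
assumed: it is exact in expectation for the *second moment*
(E[M²] = S² + 2σ²).

The ADC-bias benchmark therefore works at the ensemble level: an
ROI-style ADC from the RMS magnitude over 10⁴ voxels at SNR ≈ 5 at
b = 1500 is biased low by ≈ 2% (the floor inflates the high-b signal
level), and power subtraction applied to the RMS removes nearly all of
it. Two subtleties found while validating, worth recording: the
*per-voxel log* ADC is essentially unbiased at SNR 5 (the Rician floor
term and the log-concavity term cancel to O(σ⁴)), and per-voxel power
subtraction *followed by* averaging over-corrects (concavity of the
square root) — so neither is used as the benchmark estimator.

## Phantom

`make_phantom` fills an ellipsoidal tissue region on a default 36×36×12
grid with uniform per-voxel parameter draws and embeds spherical lesions
(outer rim shell, inner core). The label contrasts emulate,
qualitatively, the appearance of breast lesions on quantitative
diffusion maps: a densely cellular rim (ADC₀ 0.8–1.2e-3 mm²/s, K
0.9–1.4, f 0.08–0.15), a necrosis-like core (high ADC₀ 2.2–2.8e-3, low K
0.1–0.3, high f) and fibroglandular background (ADC₀ 1.6–2.2e-3, K
0.4–0.7, f 0.02–0.06). These ranges are fixture conventions chosen to be
physiologically plausible — not measured values — and are fully
configurable. Default s0 = 100 and σ = 2 give SNR 50 at b = 0. Voxels
outside the mask are air: zero signal, pure Rayleigh noise after
synthesis.

What passing phantom tests show — and what they do not: the phantom has
no anatomy, no partial volume, no fat signal, no motion or EPI
distortion, and its voxels are independent. Exact map recovery on the
noise-free phantom validates the *estimator pipeline*, not robustness to
real acquisition artifacts; the noisy-phantom separation results
validate contrast propagation under Rician noise only.

## DTI

The tensor is fit log-linearly: `ln S = ln S0 - b·gᵀDg` solved by least
squares over ≥ 6 non-degenerate directions plus a low-b row; rank < 7
raises a conditioning error. Because a DTI acquisition repeats b across
directions, the DTI module takes plain `(signals, b_values, directions)`
arrays instead of an `AcquisitionScheme` (whose b-values are unique by
contract). MD is the eigenvalue mean; FA uses the standard
normalized-variance definition `sqrt(3/2)·||λ-MD||/||λ||` (the source
texts name FA without printing a formula). Noise-driven negative
eigenvalues are clipped at 0 with a qc flag. The λ estimates and FA are
strongly non-linear in the data and noise-sensitive; low FA in low-MD
lesions need not mean reduced anisotropy — a scientific caution, not an
implementable rule.

`md_three_orthogonal` demonstrates the 3-direction MD shortcut. Two
conventions exist and they differ in an instructive way: averaging the
three axis-wise ADCs equals trace/3 = MD *exactly* in any orientation
(the trace is rotation invariant), while the common vendor practice of
averaging the three DWIs before taking one ADC underestimates MD by
Jensen's inequality whenever the axis diffusivities differ. The latter
(`combine="signal_mean"`) is the default, since it is the variant whose
failure under anisotropy needs demonstrating; `adc_mean` is available
and documented as the trace identity.

## Maps and the S-index

`compute_maps` extracts the configured quadruple from the scheme,
optionally applies noise-floor correction, runs the (vectorized) 4-b
estimator per voxel and writes NaN — never 0, since K = 0 is a valid
value — for masked-out or degenerate voxels, with a bitmask qc map.
Maps inherit the input affine unchanged; indexing is 0-based. Every
`MapSet` carries a provenance record (scheme, quadruple, method,
correction mode, sigma, seed, version) sufficient to regenerate it.

The S-index scores a voxel's normalized attenuation against a library of
forward-synthesized reference signatures: with d_b, d_m the Euclidean
distances to the benign-like and malignant-like anchors,
`S = 100·d_b/(d_b+d_m)` (0 at the benign anchor, 100 at the malignant
anchor, 50 when equidistant, including the degenerate coincident case).
This is a documented reconstruction of the signature-distance idea — the
originally published scoring is defined in work not reproduced here —
and it is isolated behind one function so it can be swapped. Default
anchors are the phantom's background and lesion-rim central parameters,
making desk-scale tests self-consistent without external calibration;
published patient S-index values are not comparison targets for this
reconstruction.

## Problem sizes

The test suite and acceptance script use: 1,000 tissues for the Gaussian
identity; a 20×20 (ADC₀, K) grid for no-IVIM exactness; a 5×4×3
(f, K, ADC₀) grid for full exactness and oracle agreement; 10⁶ draws for
Rayleigh moments; 10⁴ voxels for the noise-floor benchmark; 5,000
replicates per cell for closed-form noise studies and 100 for the
iterative fitters; and the 36×36×12 default phantom (~6,100 tissue
voxels) end-to-end. All randomness flows from explicit seeds.

## Known limitations

- Diffusion-time and TE dependence of the signal are not modelled; IVIM
  is isotropic.
- The closed-form exactness statements are tied to b0 = 0 and the
  assumption-matched premise; on physically synthesized data all 4-b
  estimators inherit a small residual-perfusion bias at b1, which the
  comparison harness quantifies rather than hides.
- Single-coil Rician noise only; no k-space, coil-combination or
  artifact simulation.
- D\* is reported nowhere: four b-values cannot constrain it, and even
  dense fitting determines it poorly.
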