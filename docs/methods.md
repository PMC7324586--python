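# Methods

## Dose–response models

All four NTCP models are implemented as closed forms in the common
(D50, γ50) parameterization (`lungntcp.models`):

* **Lyman (probit)** — P(D) = ½(1 − erf[γ50√π(1 − D/D50)]), the CDF of
  a Gaussian in dose. The equivalent integral form is
  ∫₀ᴰ (γ50/D50)·exp(−π[γ50(x−D50)/D50]²) dx: with the −π[…]² exponent
  the integrand integrates to 1 over the real line and reproduces the
  probit form exactly up to the mass truncated below D = 0,
  ½(1 − erf(γ50√π)) (≈ 3.6e-4 at γ50 = 1.35). The package treats the
  closed form as canonical; an adaptive-quadrature oracle of the
  integral form exists purely as an independent numerical cross-check
  and is tested to agree within 1e-6 plus the truncation term.
* **Logit (log-logistic)** — P(D) = 1/(1 + (D50/D)^k). The steepness
  exponent k is never a free parameter: it is stored as γ50 = k/4, so a
  single (D50, γ50) pair describes every model. P(0) is defined as 0 by
  continuity (the raw expression is 0/0-adjacent); evaluation goes
  through expit(4γ50·ln(D/D50)) for numerical stability.
* **Poisson** — P(D) = 2^(−exp[e·γ50(1 − D/D50)]), a cell-kill
  derivation. Its γ parameter is identified with γ50, but the true
  normalized gradient at D50 is (e·ln2/2)·γ50 ≈ 0.9421·γ50; the
  package keeps the printed-form convention and documents (and tests)
  the exact slope factor rather than pretending the identity is exact.
* **Weibull** — P(D) = 1 − exp[−ln2·(D/D50)^((2/ln2)γ50)].

Shared identities, enforced by tests: P(D50) = ½ to 1e-12; strict
monotonicity in dose (up to float saturation at 0/1); analytic
dP/dD and ∂P/∂(D50, γ50) agreeing with central differences.

## Synthetic phantom

`lungntcp.phantom` generates the study conditions end to end with one
seed: a planning chest CT (air −1000 HU, body +40 HU, two lung
ellipsoids −800 HU, Gaussian HU noise SD 20 — a typical parenchymal
noise level), an SBRT-like dose block, and a follow-up CT equal to the
planning scan plus ΔHUmax·P_true(D(x)) inside the lung compartment
(ΔHUmax = 200 HU, a realistic maximal fibrotic densification), with
independent noise, resampled under a configurable rigid mis-alignment
(default a (+4, −2, +3) mm translation).

The dose block is a generalized-Gaussian radial profile
D(r) = Dmax·exp(−ln2(r/r50)^q) (defaults Dmax = 60 Gy, r50 = 18 mm,
q = 2) on a 1-mm isotropic grid — a surrogate for a conformal SBRT dose
distribution, not a beam/transport simulation; the analysis only
requires a steep, monotone gradient spanning 0–60 Gy. The truth model
defaults to a Lyman sigmoid at (D50, γ50) = (35.29, 1.35), magnitudes
typical of pooled clinical fits of this kind of data.

Grid choices: the default volume is 97³ voxels at 1 mm, which runs the
full pipeline in seconds and — deliberately odd-sized — places the
lung-centred isocenter exactly on a voxel center. With an even-sized
grid the isocenter falls on half-integer coordinates and *every*
nearest-neighbour dose lookup becomes a 0.5-voxel tie resolved by
round-half-even, a systematic, mirror-asymmetric bias. The dose block
likewise uses an odd voxel count so a grid point carries exactly Dmax.
The default block is ~50 mm (scaled with the compact phantom anatomy;
the ~100 mm clinical export size is exercised in tests on a larger
volume). Clinical-style anisotropic spacing (0.94 × 0.94 × 3 mm) is
available via the config.

What the phantom does **not** emulate: real parenchymal texture,
airways/vessels, respiratory motion and deformation, scanner artifacts,
tumor regression, and spatially correlated noise. Passing recovery
tests therefore demonstrates correctness of the algorithmic chain under
the stated model, not clinical performance on patient data — rigid
registration in particular is far easier on a rigid phantom than on a
breathing thorax.

## Image pipeline

Conventions: world frame is patient LPS in mm; volumes are axis-aligned
grids with voxel-center sampling, world = origin + index·spacing.
NIfTI (nibabel) and DICOM CT series / RTDOSE (pydicom, with rescale
slope/intercept, DoseGridScaling and GridFrameOffsetVector applied) are
normalized into this frame; oblique orientations are rejected rather
than silently mishandled.

**Segmentation** — threshold below −400 HU (the standard lung /
soft-tissue separation point; the value is configurable), discard
components touching the in-plane volume boundary (external air), keep
components ≥ 50 cm³ (configurable down for compact phantoms), then a
3-mm ball closing and slice-wise hole filling so dense structures
inside the lung border (vessels, nodules) are retained. Note the
closing radius sets a floor on anatomical gaps: structures closer than
twice the radius will be bridged.

**Registration** — 6-DOF rigid (3 translations + 3 rotations in
degrees, Rz·Ry·Rx about the fixed-volume center), maximizing NCC over
the overlap, with a translation-only mode. Search is coarse-to-fine
over subsampling levels (4, 2, 1): an exhaustive ±20 mm translation
grid at the coarsest level (reduced to integer-shift array slicing when
the grids are congruent), then Nelder–Mead refinement at every level
with level-scaled tolerances (xatol 0.05·level mm) and initial simplex
steps, so the finest level only polishes. The returned transform maps
fixed-frame (follow-up) world coordinates into moving-frame (planning)
coordinates, and is guaranteed never worse than the identity transform
by a final comparison. On noisy phantoms the recovery error is
~0.01–0.05 mm, far inside the half-voxel acceptance.

**Dose mapping** — each follow-up voxel center is carried into planning
coordinates and assigned the *nearest* dose-grid sample (trilinear
available as an option); voxels outside the dose block receive NaN and
are excluded downstream, so nearest-neighbour mapping never invents
dose values.

## Dose–response extraction

ΔHU(x) = HU_followup(x) − HU_planning(T(x)) with trilinear sampling of
the planning CT (mode `pixelwise`, the default — it matches the
pixel-wise framing of the analysis); a `block_mean` mode subtracts a
single scalar baseline (mean registered planning-lung HU over the valid
dose region) instead. Pixels in lung with valid dose are binned into
half-open 6-Gy bins over 0–60 Gy; doses ≥ 60 Gy clamp into the top bin
by default (the top bin is defined as holding the maximal response;
exclusion is available). The representative bin dose is the midpoint
(3, 9, …, 57 Gy) for reproducibility from curve files alone; the
member-mean dose is recorded alongside for diagnostics. Per-patient
curves are normalized to their maximum bin (negative noisy bins are
retained and may scale below 0); pooling averages normalized curves
bin-wise over contributing patients and renormalizes the pooled curve
to its own maximum (a no-op in the nominal case; logged when not).

## Fitting and model comparison

`NTCPModel(dose, response, model).fit()` minimizes
Σᵢ (P(binDoseᵢ) − responseᵢ)² over (D50, γ50) with bounds
D50 ∈ [1, 200] Gy, γ50 ∈ [0.05, 20], by bounded trust-region least
squares (analytic Jacobians) from a 5×4 multi-start grid
(D50 ∈ {15, 25, 35, 45, 55}, γ50 ∈ {0.5, 1, 2, 4}); the spreadsheet
generalized-reduced-gradient solver of the original workflow is
replaced by this deterministic, reproducible equivalent of the same
objective. Results carry the estimates, Gauss–Newton asymptotic
standard errors and Wald intervals, SSR, adjusted R², AIC/BIC, the
number of starts agreeing with the best optimum (≥ 80% on clean
curves), and an `at_bounds` flag marking non-informative fits (e.g. a
flat curve pinning γ50 at a bound).

Information criteria use the Gaussian least-squares forms
AIC = n·ln(SSR/n) + 2k and BIC = n·ln(SSR/n) + k·ln(n) with k = 2 and
n = bins used, so BIC − AIC = 2·ln(n) − 4 identically (≈ 0.605 at
n = 10). SSR is floored at 1e-12 (with a warning) to keep the logs
finite on perfect fits. Rankings are invariant to any additive
constant shared across models. Curve normalization couples the top bin
toward 1, which biases absolute parameter recovery slightly; recovery
tests therefore compare pipeline fits against the same model *refit on
the normalized truth curve*, separating estimator error from
normalization bias.

**Significance of fit** is an extra-sum-of-squares F test of the fitted
sigmoid against the constant-mean null:
F = (SSR_null − SSR_fit) / (SSR_fit/(n−2)), p from F(1, n−2). Against
this *monotone, bounded* family the test is conservative under the
null: flat-noise curves with a negative empirical trend cannot be
chased (the fit pins at the γ50 bound, F ≤ 0, p ≈ 1), so the achieved
null rejection rate is about α/2 (measured ≈ 0.02–0.03 at α = 0.05 over
1000 seeded replicates) rather than α. It is never anti-conservative,
which is the property that matters for declaring a fit significant.
**Cross-model comparison** uses standard one-way ANOVA of the fitted
D50 (and γ50) across the four model groups, with the degenerate
all-equal case defined as F = 0, p = 1; ties in per-criterion rankings
break lexicographically by model name.

## Registration-error robustness

The experiment adds ±s mm (default 3) to the baseline transform's
translation along one anatomical axis at a time — six trials, pure
translations, no rotational perturbation — re-runs dose mapping → ΔHU →
binning → normalization → Lyman fit for each, and reports the maximal
percent change of D50 and γ50 against the unperturbed reference (plus
an optional zero-shift control that must reproduce the reference
bit-exactly). Shifts are applied to the *optimal* alignment (on
phantoms, the known truth), matching the reading that perturbations
probe an already-registered study. The expected physics reproduces on
phantoms: D50, an average-dose-like quantity along the 50%-response
contour, moves by a few percent, while γ50, which reflects response
heterogeneity across that contour, moves an order of magnitude more —
the steeper the dose gradient (smaller r50), the starker the contrast.

## Problem sizes and determinism

Default experiment sizes: 97³-voxel phantoms, 10-bin curves, 100
replicates for noisy-recovery statistics, 1000 replicates for the
F-test calibration, 10 seeds for the robustness sweep. All randomness
flows through explicit integer seeds (numpy `default_rng`); repeated
runs are bit-identical, which the zero-shift control and determinism
tests assert. `scripts/acceptance.py` derives every seed from its
`--seed` argument.

## Known limitations

* Rigid registration only; no deformable model, so breathing-induced
  deformation in real thoracic data is out of scope.
* The phantom's simplified anatomy makes segmentation and registration
  easier than clinical data; parameter-recovery results are upper
  bounds on real-data performance.
* The Poisson model's γ is a steepness parameter, not exactly the
  normalized gradient; comparisons of γ50 across models inherit the
  0.942 factor ambiguity of the printed forms.
* Absolute AIC/BIC values depend on the likelihood constant convention;
  only differences and rankings are meaningful.
* Curves with responses far outside the normalized 0–1 scale are
  rejected by the fitter rather than silently rescaled.
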