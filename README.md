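# lungntcp

NTCP dose–response modelling of radiation-induced lung density change
on serial chest CT.

After stereotactic body radiotherapy (SBRT) of lung or hilar targets,
irradiated lung parenchyma densifies — radiation pneumonitis early
(2–5 months) and fibrosis later (6–9 months) — and the densification is
visible as an increase in CT Hounsfield units (HU) long before (or
without) clinical symptoms. Because an SBRT plan delivers a steep dose
gradient across the lung, a *single* patient's scan pair samples the
whole 0–60 Gy dose range, so a full dose–response curve can be read off
one follow-up scan. `lungntcp` implements that analysis for researchers
in radiation oncology physics and quantitative imaging:

1. segment the lungs on the follow-up CT (threshold + morphology);
2. rigidly register the follow-up CT to the planning CT by maximizing
   normalized cross-correlation (NCC), coarse-to-fine;
3. pull the planned 3D dose grid onto the follow-up image (nearest
   grid point) through the registration;
4. compute the pixel-wise HU change ΔHU inside lung, bin it by local
   dose into 6-Gy bins over 0–60 Gy, average per bin, and normalize the
   curve to its maximum bin (per patient; patient curves can be pooled);
5. fit four NTCP sigmoids to the normalized curve and compare them.

## The models

Each model is parameterized by D50 (the dose in Gy producing half the
maximal response) and γ50 (the dimensionless normalized slope at D50,
γ50 = D50·P′(D50)):

| model   | P(D) |
|---------|------|
| lyman   | ½(1 − erf[γ50·√π·(1 − D/D50)]) |
| logit   | 1 / (1 + (D50/D)^(4γ50)) |
| poisson | 2^(−exp[e·γ50·(1 − D/D50)]) |
| weibull | 1 − exp[−ln2·(D/D50)^((2/ln2)·γ50)] |

All satisfy P(D50) = ½ exactly; lyman/logit/weibull satisfy the slope
identity exactly, while the Poisson form's normalized gradient at D50 is
(e·ln2/2)·γ50 ≈ 0.942·γ50. Fits are ranked by SSR, adjusted R², AIC
and BIC (Gaussian least-squares forms, k = 2), with an
extra-sum-of-squares F test for significance of each fit and one-way
ANOVA across models for D50 and γ50.

Since no patient imaging ships with the package, a synthetic phantom
module generates thoracic CT pairs (air/body/lung compartments with HU
noise), an SBRT-like dose block with a sharp radial falloff, a known
rigid mis-alignment, and a follow-up HU increase that follows a chosen
sigmoid of local dose — every stage of the pipeline is testable against
known ground truth.

## Worked example

Fit a Lyman sigmoid to a synthetic 10-bin dose–response curve:

```python
import numpy as np
from lungntcp import NTCPModel, NTCPParams, generate_binned_curve

edges = tuple(float(x) for x in range(0, 66, 6))        # 6-Gy bins, 0-60 Gy
curve = generate_binned_curve("lyman", NTCPParams(35.29, 1.35),
                              edges, noise_sd=0.03, seed=11)
res = NTCPModel(curve.bin_dose, curve.response, model="lyman").fit()
print(res.summary())
```

```
NTCP dose-response fit: lyman
==============================================
n bins used                   10
converged                   True
starts agreeing            20/20
----------------------------------------------
            estimate   std err          95% CI
D50 (Gy)      35.332     0.452   [ 34.29,  36.37]
gamma50        1.362     0.086   [  1.16,   1.56]
----------------------------------------------
SSR             0.007428    adj-R2      0.9930
AIC               -68.05    BIC         -67.45
F (vs const)    1470.148    p         2.35e-10
```

The curve was generated from (D50, γ50) = (35.29, 1.35) with 0.03
response noise; the fit recovers D50 = 35.3 ± 0.5 Gy and γ50 = 1.36 ±
0.09, and the F test confirms the sigmoid fits far better than a
constant (p ≈ 2e-10). `compare_models(curve)` fits all four models and
ranks them per criterion (`report.summary()` prints the Table-style
comparison; `res.plot()` draws data and fit).

The same analysis runs end-to-end from volumes on disk:

```sh
lungntcp simulate --out phantom --seed 1
lungntcp analyze --planning phantom/planning.nii.gz \
                 --followup phantom/followup.nii.gz \
                 --dose phantom/dose.nii.gz \
                 --translation-only --out results
lungntcp robustness --planning phantom/planning.nii.gz \
                    --followup phantom/followup.nii.gz \
                    --dose phantom/dose.nii.gz \
                    --transform results/transform.json --out robust
lungntcp fit-curve --curve results/curve_normalized.csv --out fits
```

`analyze` writes the binned curve (CSV), the recovered rigid transform
(JSON), and a four-row model-comparison table; `robustness` re-runs the
downstream pipeline under ±3 mm registration shifts along each
anatomical axis and tabulates the maximal percent change of D50 and γ50
(D50 is robust at the few-percent level; γ50 is an order of magnitude
more sensitive).

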